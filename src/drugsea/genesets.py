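"""Gene-set (pathway) database container shared across pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass
class GeneSetDB:
    """A named collection of pathways, each a non-empty set of gene IDs."""

    db_name: str
    pathways: dict[str, tuple[str, frozenset[str]]]  # id -> (description, genes)

    def __post_init__(self):
        for pid, (_, genes) in self.pathways.items():
            if not genes:
                raise ValueError(f"{self.db_name}: pathway {pid!r} is empty")

    def __len__(self) -> int:
        return len(self.pathways)

    def genes_of(self, pathway_id: str) -> frozenset[str]:
        return self.pathways[pathway_id][1]

    def pathway_ids(self) -> list[str]:
        return list(self.pathways)

    def pathways_containing(self, gene_id: str) -> set[str]:
        return {pid for pid, (_, genes) in self.pathways.items() if gene_id in genes}

    def gene_universe(self) -> set[str]:
        out: set[str] = set()
        for _, genes in self.pathways.values():
            out |= genes
        return out
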