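"""Pathway expression profiles: convert ranked gene lists to ranked pathways.

For every (drug, pathway) cell, the pathway's genes are scored against the
drug's ranked gene list with the KS enrichment kernel, yielding an ES and a
permutation p-value; per drug, pathways are then ordered by ES descending
(ties by raw p ascending, then pathway ID) to form the drug's pathway
expression profile. One profile table is built per pathway database.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .enrichment import PermutationNull, es_from_hits
from .genesets import GeneSetDB
from .ranking import RankedGeneMatrix

log = logging.getLogger("drugsea.profiles")

__all__ = ["PathwayDrugMatrix", "build_pep", "rank_pathways"]

PEP_COLUMNS = ["drug", "pathway", "es", "p"]


@dataclass
class PathwayDrugMatrix:
    """Per-drug ranked pathways of one database, with ES and raw p.

    ``table`` columns: drug, pathway, es, p, rank (1 = most up-modulated);
    per drug the rank column is a permutation of 1..n_pathways.
    """

    db_name: str
    table: pd.DataFrame

    @property
    def drugs(self) -> list[str]:
        return sorted(self.table["drug"].unique())

    @property
    def pathway_ids(self) -> list[str]:
        return sorted(self.table["pathway"].unique())

    def ordering(self, drug: str) -> list[str]:
        sub = self.table[self.table["drug"] == drug].sort_values("rank")
        return list(sub["pathway"])


def build_pep(
    ranked_genes: RankedGeneMatrix,
    gene_set_db: GeneSetDB,
    n_permutations: int = 10_000,
    seed: int = 0,
    min_overlap: int = 1,
    null: PermutationNull | None = None,
) -> pd.DataFrame:
    """ES and permutation p for every (drug, pathway) of one database.

    Pathways whose overlap with the compendium's gene universe is below
    ``min_overlap`` (or total, making the score undefined) are excluded with
    a warning. A shared :class:`PermutationNull` may be passed so several
    databases reuse null draws for equal (N, set size).
    """
    genes = ranked_genes.genes
    gene_idx = {g: i for i, g in enumerate(genes)}
    n = len(genes)
    ranks = ranked_genes.ranks.to_numpy()  # drugs x genes, values 1..N
    drugs = ranked_genes.drugs
    if null is None:
        null = PermutationNull(seed, n_permutations)

    records: list[pd.DataFrame] = []
    dropped = []
    for pid in gene_set_db.pathway_ids():
        members = gene_set_db.genes_of(pid)
        cols = [gene_idx[g] for g in members if g in gene_idx]
        k = len(cols)
        if k < min_overlap or k == 0 or k >= n:
            dropped.append(pid)
            continue
        hits = ranks[:, cols]  # each row: the pathway's positions in that drug
        es = es_from_hits(hits, n)
        p = null.pvalues(es, n, k)
        records.append(pd.DataFrame({"drug": drugs, "pathway": pid, "es": es, "p": p}))
    if dropped:
        log.warning(
            "%s: excluded %d unscoreable pathway(s): %s",
            gene_set_db.db_name,
            len(dropped),
            ", ".join(dropped[:5]) + ("..." if len(dropped) > 5 else ""),
        )
    if not records:
        raise ValueError(f"no scoreable pathway in database {gene_set_db.db_name!r}")
    pep = pd.concat(records, ignore_index=True)[PEP_COLUMNS]
    return pep.sort_values(["drug", "pathway"], kind="mergesort").reset_index(drop=True)


def rank_pathways(pep: pd.DataFrame, db_name: str) -> PathwayDrugMatrix:
    """Order each drug's pathways by ES desc, ties by p asc then pathway ID."""
    df = pep.sort_values(
        ["drug", "es", "p", "pathway"],
        ascending=[True, False, True, True],
        kind="mergesort",
    ).reset_index(drop=True)
    df["rank"] = df.groupby("drug").cumcount() + 1
    return PathwayDrugMatrix(db_name=db_name, table=df)
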