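"""Synthetic inputs with planted, recoverable signal.

Generators for every input the pipeline consumes: per-locus variant tables
with Bayes factors (one dominant causal variant), LD r² matrices with
exponential positional decay, eQTL association tables with planted
variant-gene links, random pathway databases, and a drug-perturbation
expression compendium in which a planted family of drugs shifts the
expression of every gene belonging to a pathway that contains the target
gene. All generators are pure functions of (arguments, seed).

Default scale emulates a desk-size perturbation compendium (200 drugs x
1,000 genes, 3 replicate arms) with three pathway collections of 150
pathways each; the planted signal is a 12-drug active family sharing one
target gene, mirroring a screen in which a handful of compounds out of the
compendium genuinely engage the risk gene's pathway biology.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .enrichment import rng_for
from .finemap import LDMatrix
from .genesets import GeneSetDB
from .ranking import ExpressionCompendium

log = logging.getLogger("drugsea.simulate")

__all__ = [
    "ConfigError",
    "PlantingError",
    "SimulationConfig",
    "PlantedTruth",
    "gene_id",
    "drug_id",
    "simulate_locus",
    "simulate_pathway_db",
    "simulate_compendium",
    "simulate_eqtl_table",
    "simulate_databases",
]


class ConfigError(ValueError):
    pass


class PlantingError(ValueError):
    pass


def gene_id(i: int) -> str:
    return f"G{i:04d}"


def drug_id(i: int) -> str:
    return f"D{i:04d}"


def _default_planted_pairs() -> list[tuple[int, int]]:
    # a family of 12 active drugs sharing one target gene; see docs/methods.md
    return [(d, 0) for d in range(12)]


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic experiment."""

    n_variants_per_locus: int = 50
    n_loci: int = 3
    n_genes: int = 1000
    n_drugs: int = 200
    n_pathways_per_db: int = 150
    n_databases: int = 3
    pathway_size_range: tuple[int, int] = (5, 50)
    n_control_samples: int = 3
    n_treatment_samples: int = 3
    n_instances: int = 1
    effect_size: float = 2.0  # mean shift in units of noise_sd
    noise_sd: float = 1.0
    planted_pairs: list[tuple[int, int]] = field(
        default_factory=_default_planted_pairs
    )
    min_planted_annotations: int = 3
    bf_dominance: float = 25.0
    ld_decay: float = 0.04  # r² e-folding rate per kb of distance
    n_eqtl_sets: int = 4
    n_eqtl_background: int = 60
    seed: int = 0

    def validate(self) -> None:
        counts = {
            "n_variants_per_locus": self.n_variants_per_locus,
            "n_loci": self.n_loci,
            "n_genes": self.n_genes,
            "n_drugs": self.n_drugs,
            "n_pathways_per_db": self.n_pathways_per_db,
            "n_databases": self.n_databases,
            "n_control_samples": self.n_control_samples,
            "n_treatment_samples": self.n_treatment_samples,
            "n_instances": self.n_instances,
        }
        for name, v in counts.items():
            if int(v) < 1:
                raise ConfigError(f"{name} must be >= 1, got {v}")
        lo, hi = self.pathway_size_range
        if lo < 2 or hi > self.n_genes or lo > hi:
            raise ConfigError(
                f"pathway_size_range {self.pathway_size_range} must satisfy "
                f"2 <= min <= max <= n_genes"
            )
        if self.effect_size < 0:
            raise ConfigError("effect_size must be >= 0")
        if self.noise_sd <= 0:
            raise ConfigError("noise_sd must be > 0")
        if not 1 <= self.min_planted_annotations <= self.n_pathways_per_db:
            raise ConfigError(
                "min_planted_annotations must lie in [1, n_pathways_per_db]"
            )
        if self.bf_dominance <= 1:
            raise ConfigError("bf_dominance must be > 1")
        if self.ld_decay <= 0:
            raise ConfigError("ld_decay must be > 0")
        for d, g in self.planted_pairs:
            if not (0 <= d < self.n_drugs and 0 <= g < self.n_genes):
                raise ConfigError(f"planted pair ({d}, {g}) out of range")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["pathway_size_range"] = list(self.pathway_size_range)
        d["planted_pairs"] = [list(p) for p in self.planted_pairs]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "pathway_size_range" in d:
            d["pathway_size_range"] = tuple(d["pathway_size_range"])
        if "planted_pairs" in d:
            d["planted_pairs"] = [tuple(p) for p in d["planted_pairs"]]
        cfg = cls(**d)
        cfg.validate()
        return cfg

    def planted_genes(self) -> list[str]:
        seen: dict[str, None] = {}
        for _, g in self.planted_pairs:
            seen.setdefault(gene_id(g))
        return list(seen)

    def planted_drugs(self) -> list[str]:
        seen: dict[str, None] = {}
        for d, _ in self.planted_pairs:
            seen.setdefault(drug_id(d))
        return list(seen)


@dataclass
class PlantedTruth:
    """Ground truth recorded by the generators for recovery tests."""

    planted_pairs: list[tuple[str, str]]  # (drug_id, target gene_id)
    affected_genes: dict[str, list[str]]  # "drug|gene" -> shifted genes
    causal_variants: dict[str, str] = field(default_factory=dict)  # locus -> variant

    @staticmethod
    def pair_key(drug: str, gene: str) -> str:
        return f"{drug}|{gene}"

    def to_dict(self) -> dict:
        return {
            "planted_pairs": [list(p) for p in self.planted_pairs],
            "affected_genes": self.affected_genes,
            "causal_variants": self.causal_variants,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PlantedTruth":
        return cls(
            planted_pairs=[tuple(p) for p in d["planted_pairs"]],
            affected_genes={k: list(v) for k, v in d["affected_genes"].items()},
            causal_variants=dict(d.get("causal_variants", {})),
        )


def simulate_locus(
    n_variants: int,
    causal_index: int,
    bf_dominance: float = 25.0,
    decay_rate: float = 0.04,
    seed: int = 0,
    locus_id: str = "locus00",
) -> tuple[pd.DataFrame, LDMatrix]:
    """One risk locus: variant table with Bayes factors plus its LD matrix.

    Null Bayes factors are log-normal; the causal variant's BF is set to
    ``bf_dominance`` times the largest null BF, so it is the strict maximum
    by construction. r² decays exponentially with positional distance
    (``decay_rate`` per kb) with mild multiplicative jitter, clipped to
    [0, 1], symmetric, unit diagonal.
    """
    if n_variants < 1:
        raise ValueError("n_variants must be >= 1")
    if not 0 <= causal_index < n_variants:
        raise ValueError("causal_index out of range")
    if bf_dominance <= 1:
        raise ValueError("bf_dominance must be > 1")
    if decay_rate <= 0:
        raise ValueError("decay_rate must be > 0")
    rng = rng_for(seed, "locus", locus_id)
    gaps = rng.integers(500, 2000, size=n_variants)
    positions = np.cumsum(gaps) - gaps[0] + 1  # 1-based, ascending
    bf = rng.lognormal(mean=0.0, sigma=1.0, size=n_variants)
    if n_variants > 1:
        others = np.delete(bf, causal_index)
        bf[causal_index] = bf_dominance * others.max()
    variant_ids = [f"{locus_id}_v{i:03d}" for i in range(n_variants)]
    variants = pd.DataFrame(
        {
            "variant_id": variant_ids,
            "locus_id": locus_id,
            "position": positions,
            "bayes_factor": bf,
        }
    )
    dist_kb = np.abs(positions[:, None] - positions[None, :]) / 1000.0
    base = np.exp(-decay_rate * dist_kb)
    jitter = np.exp(rng.normal(0.0, 0.05, size=base.shape))
    jitter = np.sqrt(jitter * jitter.T)  # symmetric multiplicative noise
    r2 = np.clip(base * jitter, 0.0, 1.0)
    np.fill_diagonal(r2, 1.0)
    ld = LDMatrix(locus_id=locus_id, variants=variant_ids, positions=positions, r2=r2)
    return variants, ld


def simulate_pathway_db(
    n_pathways: int,
    gene_universe,
    size_range: tuple[int, int] = (5, 50),
    seed: int = 0,
    db_name: str = "db1",
    include_genes=(),
    min_annotations: int = 1,
) -> GeneSetDB:
    """Random pathway collection over a gene universe.

    Pathway sizes are uniform on ``size_range`` (inclusive); members are
    sampled without replacement. Genes listed in ``include_genes`` are
    guaranteed to appear in at least ``min_annotations`` pathways: while a
    listed gene falls short, a random member of a random pathway not yet
    containing it is swapped out for it (sizes are preserved). Prioritised
    disease genes are well-annotated in curated collections; a gene with a
    single annotation cannot carry pathway-level signal.
    """
    universe = list(gene_universe)
    if not universe:
        raise ValueError("gene universe is empty")
    lo, hi = size_range
    if lo < 2 or hi > len(universe) or lo > hi:
        raise ValueError(f"size_range {size_range} invalid for universe of "
                         f"{len(universe)} genes")
    if n_pathways < 1:
        raise ValueError("n_pathways must be >= 1")
    rng = rng_for(seed, "pathways", db_name)
    universe_arr = np.asarray(universe)
    pathways: dict[str, tuple[str, frozenset[str]]] = {}
    members_list = []
    for i in range(n_pathways):
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(universe_arr, size=size, replace=False)
        members_list.append(set(members.tolist()))
    if min_annotations > n_pathways:
        raise ValueError("min_annotations cannot exceed n_pathways")
    universe_set = set(universe)
    for g in include_genes:
        if g not in universe_set:
            raise ValueError(f"include gene {g!r} not in the universe")
        have = sum(g in m for m in members_list)
        while have < min_annotations:
            tgt = int(rng.integers(0, n_pathways))
            if g in members_list[tgt]:
                continue
            candidates = sorted(members_list[tgt] - {g})
            victim = candidates[int(rng.integers(0, len(candidates)))]
            members_list[tgt].discard(victim)
            members_list[tgt].add(g)
            have += 1
    for i, members in enumerate(members_list):
        pid = f"{db_name}_P{i:03d}"
        pathways[pid] = (f"synthetic pathway {i} of {db_name}", frozenset(members))
    return GeneSetDB(db_name=db_name, pathways=pathways)


def simulate_databases(config: SimulationConfig) -> list[GeneSetDB]:
    """The config's pathway databases, planted genes guaranteed annotatable."""
    config.validate()
    universe = [gene_id(i) for i in range(config.n_genes)]
    return [
        simulate_pathway_db(
            config.n_pathways_per_db,
            universe,
            config.pathway_size_range,
            seed=config.seed,
            db_name=f"db{j + 1}",
            include_genes=config.planted_genes(),
            min_annotations=config.min_planted_annotations,
        )
        for j in range(config.n_databases)
    ]


def simulate_compendium(
    config: SimulationConfig, databases
) -> tuple[ExpressionCompendium, PlantedTruth]:
    """Expression compendium with planted drug-target signal.

    Per-gene baselines are drawn once (uniform 50-150 intensity units);
    every replicate adds i.i.d. Gaussian noise of SD ``noise_sd``. For each
    planted (drug, target gene) pair, the treatment replicates of that drug
    are shifted upward by ``effect_size * noise_sd`` for every gene in the
    union, over all databases, of pathways containing the target gene;
    control replicates are untouched.
    """
    config.validate()
    databases = list(databases)
    if not databases:
        raise ValueError("need at least one pathway database")
    genes = [gene_id(i) for i in range(config.n_genes)]
    drugs = [drug_id(i) for i in range(config.n_drugs)]
    rng = rng_for(config.seed, "compendium")

    sample_ids, meta_rows = [], []
    for d in drugs:
        for inst in range(config.n_instances):
            for r in range(config.n_control_samples):
                sample_ids.append(f"{d}_i{inst}_c{r}")
                meta_rows.append((d, "control", f"i{inst}"))
            for r in range(config.n_treatment_samples):
                sample_ids.append(f"{d}_i{inst}_t{r}")
                meta_rows.append((d, "treatment", f"i{inst}"))
    samples = pd.DataFrame(
        meta_rows, index=pd.Index(sample_ids, name="sample_id"),
        columns=["drug", "arm", "instance"],
    )

    baseline = rng.uniform(50.0, 150.0, size=config.n_genes)
    values = baseline[:, None] + rng.normal(
        0.0, config.noise_sd, size=(config.n_genes, len(sample_ids))
    )
    expr = pd.DataFrame(values, index=pd.Index(genes, name="gene_id"),
                        columns=sample_ids)

    gene_pos = {g: i for i, g in enumerate(genes)}
    affected: dict[str, list[str]] = {}
    pairs: list[tuple[str, str]] = []
    shift = config.effect_size * config.noise_sd
    treat_cols = {
        d: [s for s in sample_ids
            if samples.loc[s, "drug"] == d and samples.loc[s, "arm"] == "treatment"]
        for d in {drug_id(di) for di, _ in config.planted_pairs}
    }
    for di, gi in config.planted_pairs:
        d, g = drug_id(di), gene_id(gi)
        union: set[str] = set()
        for db in databases:
            for pid in db.pathways_containing(g):
                union |= db.genes_of(pid)
        if not union:
            raise PlantingError(
                f"target gene {g!r} belongs to no pathway in any database; "
                "signal cannot be planted"
            )
        rows = [gene_pos[x] for x in sorted(union)]
        cols = [expr.columns.get_loc(s) for s in treat_cols[d]]
        expr.iloc[rows, cols] += shift
        pairs.append((d, g))
        affected[PlantedTruth.pair_key(d, g)] = sorted(union)

    truth = PlantedTruth(planted_pairs=pairs, affected_genes=affected)
    return ExpressionCompendium(expression=expr, samples=samples), truth


def simulate_eqtl_table(
    variants: pd.DataFrame,
    gene_universe,
    planted_links,
    seed: int = 0,
    n_sets: int = 4,
    n_background: int = 60,
) -> pd.DataFrame:
    """eQTL association table with planted minimum-p links.

    Background records pair random variants with random genes at p uniform
    on (1e-3, 1]; each planted link (eqtl_set_id, variant_id, gene_id) gets
    p uniform on (1e-8, 1e-4), strictly below every background p in its
    set by construction.
    """
    genes = list(gene_universe)
    if not genes:
        raise ValueError("gene universe is empty")
    rng = rng_for(seed, "eqtl")
    set_ids = [f"eqtl{s:02d}" for s in range(n_sets)]
    vids = list(variants["variant_id"])
    rows = []
    for _ in range(n_background):
        rows.append(
            (
                set_ids[int(rng.integers(0, n_sets))],
                vids[int(rng.integers(0, len(vids)))],
                genes[int(rng.integers(0, len(genes)))],
                float(rng.uniform(1e-3, 1.0)),
            )
        )
    known = set(vids)
    for set_id, vid, g in planted_links:
        if vid not in known:
            raise ValueError(f"planted link references unknown variant {vid!r}")
        if g not in genes:
            raise ValueError(f"planted link references unknown gene {g!r}")
        if set_id not in set_ids:
            raise ValueError(f"planted link references unknown eQTL set {set_id!r}")
        rows.append((set_id, vid, g, float(rng.uniform(1e-8, 1e-4))))
    out = pd.DataFrame(rows, columns=["eqtl_set_id", "variant_id", "gene_id", "p_value"])
    return out.sort_values(
        ["eqtl_set_id", "p_value", "variant_id"], kind="mergesort"
    ).reset_index(drop=True)
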