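"""Fine-mapping of GWAS risk loci and eQTL-based candidate-gene mapping.

Per-variant Bayes factors from an association meta-analysis are normalised
within each risk locus to causal posterior probabilities under a uniform
single-causal-variant prior (PP_i = BF_i / sum_j BF_j). A locus window is
the span from the leftmost to the rightmost variant whose r² with the lead
variant is at least the window threshold (default 0.6); every variant
positioned inside the span is a member even if its own r² falls below the
threshold. The causal variant of a locus is the posterior argmax, ties
broken by smallest genomic position.

Candidate genes come from eQTL overlap: within each eQTL set, each gene's
most significant variant association is taken, and the gene is a candidate
iff that variant has r² strictly greater than the candidate threshold
(default 0.8) with at least one lead variant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger("drugsea.finemap")

__all__ = [
    "LDMatrix",
    "Locus",
    "posterior_probabilities",
    "add_posteriors",
    "define_ld_window",
    "select_causal_variant",
    "map_candidate_genes",
]

#: column layout of a variant summary table
VARIANT_COLUMNS = ["variant_id", "locus_id", "position", "bayes_factor"]
#: column layout of an eQTL association table
EQTL_COLUMNS = ["eqtl_set_id", "variant_id", "gene_id", "p_value"]


@dataclass
class LDMatrix:
    """Pairwise r² for the variants of one locus, in position order."""

    locus_id: str
    variants: list[str]
    positions: np.ndarray
    r2: np.ndarray
    _index: dict = field(init=False, repr=False)

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.r2 = np.asarray(self.r2, dtype=float)
        self._index = {v: i for i, v in enumerate(self.variants)}
        self.validate()

    def validate(self) -> None:
        n = len(self.variants)
        if len(self._index) != n:
            raise ValueError(f"{self.locus_id}: duplicate variant IDs")
        if self.positions.shape != (n,) or self.r2.shape != (n, n):
            raise ValueError(f"{self.locus_id}: shape mismatch")
        if not np.allclose(np.diag(self.r2), 1.0):
            raise ValueError(f"{self.locus_id}: r² diagonal must be 1")
        if not np.allclose(self.r2, self.r2.T):
            raise ValueError(f"{self.locus_id}: r² must be symmetric")
        if self.r2.min() < 0 or self.r2.max() > 1 + 1e-12:
            raise ValueError(f"{self.locus_id}: r² must lie in [0, 1]")

    def index_of(self, variant_id: str) -> int:
        try:
            return self._index[variant_id]
        except KeyError:
            raise KeyError(f"variant {variant_id!r} not in locus {self.locus_id}")

    def __contains__(self, variant_id: str) -> bool:
        return variant_id in self._index

    def r2_with(self, a: str, b: str) -> float:
        return float(self.r2[self.index_of(a), self.index_of(b)])


@dataclass
class Locus:
    locus_id: str
    lead_variant: str
    window: tuple[str, str]  # (leftmost variant, rightmost variant), inclusive
    members: list[str]


def posterior_probabilities(bayes_factors) -> np.ndarray:
    """Causal posteriors within one locus: PP_i = BF_i / sum(BF)."""
    bf = np.asarray(bayes_factors, dtype=float)
    if bf.size == 0:
        raise ValueError("locus has no variants")
    if np.any(~np.isfinite(bf)) or np.any(bf <= 0):
        raise ValueError("Bayes factors must be finite and > 0")
    return bf / bf.sum()


def add_posteriors(variants: pd.DataFrame) -> pd.DataFrame:
    """Return a copy of a variant table with a per-locus `posterior` column."""
    out = variants.copy()
    out["posterior"] = (
        out.groupby("locus_id")["bayes_factor"].transform(lambda b: b / b.sum())
    )
    return out


def define_ld_window(
    lead_variant: str, ld_matrix: LDMatrix, r2_threshold: float = 0.6
) -> Locus:
    """Locus window spanned by variants with r²(·, lead) >= threshold.

    Inclusive comparison; all variants positioned between the leftmost and
    rightmost qualifying variant are members regardless of their own r².
    """
    if not 0 < r2_threshold <= 1:
        raise ValueError("r2_threshold must lie in (0, 1]")
    li = ld_matrix.index_of(lead_variant)
    qualifying = np.flatnonzero(ld_matrix.r2[:, li] >= r2_threshold)
    pos = ld_matrix.positions
    left = qualifying[np.argmin(pos[qualifying])]
    right = qualifying[np.argmax(pos[qualifying])]
    lo, hi = pos[left], pos[right]
    inside = np.flatnonzero((pos >= lo) & (pos <= hi))
    members = [ld_matrix.variants[i] for i in inside[np.argsort(pos[inside])]]
    return Locus(
        locus_id=ld_matrix.locus_id,
        lead_variant=lead_variant,
        window=(ld_matrix.variants[left], ld_matrix.variants[right]),
        members=members,
    )


def select_causal_variant(locus_variants: pd.DataFrame) -> str:
    """Variant with the highest posterior; ties go to the smallest position."""
    if len(locus_variants) == 0:
        raise ValueError("empty locus")
    if "posterior" not in locus_variants:
        raise ValueError("posteriors not computed; call add_posteriors first")
    df = locus_variants.sort_values(
        ["posterior", "position", "variant_id"], ascending=[False, True, True]
    )
    return str(df.iloc[0]["variant_id"])


def _best_lead_r2(
    variant_id: str,
    lead_variants: Iterable[str],
    ld_matrices: Mapping[str, LDMatrix],
) -> float | None:
    """Max r² between a variant and any lead it shares an LD matrix with.

    None when the variant appears in no matrix (unresolvable).
    """
    best = None
    for ld in ld_matrices.values():
        if variant_id not in ld:
            continue
        best = 0.0 if best is None else best
        for lead in lead_variants:
            if lead in ld:
                best = max(best, ld.r2_with(variant_id, lead))
    return best


def map_candidate_genes(
    eqtl_table: pd.DataFrame,
    lead_variants: Sequence[str],
    ld_matrices: Mapping[str, LDMatrix],
    r2_threshold: float = 0.8,
    per_set_only: bool = False,
) -> pd.DataFrame:
    """eQTL-overlap candidate genes with provenance.

    For each eQTL set (and, by default, each gene within it) the
    minimum-p association is taken; its gene is a candidate iff the
    association's variant has r² strictly > ``r2_threshold`` with any lead
    variant. ``per_set_only=True`` keeps a single minimum-p association per
    set instead of one per (set, gene). Output has one row per candidate
    gene (smallest qualifying p wins), columns: gene_id, eqtl_set_id,
    variant_id, p_value, best_r2.
    """
    cols = ["gene_id", "eqtl_set_id", "variant_id", "p_value", "best_r2"]
    if len(eqtl_table) == 0:
        return pd.DataFrame(columns=cols)
    df = eqtl_table.sort_values(["p_value", "variant_id", "gene_id"], kind="mergesort")
    group = ["eqtl_set_id"] if per_set_only else ["eqtl_set_id", "gene_id"]
    best = df.drop_duplicates(subset=group, keep="first")

    rows = []
    skipped = 0
    for rec in best.itertuples(index=False):
        r2 = _best_lead_r2(rec.variant_id, lead_variants, ld_matrices)
        if r2 is None:
            skipped += 1
            continue
        if r2 > r2_threshold:  # strict: exactly at threshold is not a candidate
            rows.append(
                {
                    "gene_id": rec.gene_id,
                    "eqtl_set_id": rec.eqtl_set_id,
                    "variant_id": rec.variant_id,
                    "p_value": rec.p_value,
                    "best_r2": r2,
                }
            )
    if skipped:
        log.warning("skipped %d association(s) with unresolvable variants", skipped)
    if not rows:
        return pd.DataFrame(columns=cols)
    out = pd.DataFrame(rows, columns=cols)
    out = out.sort_values(["p_value", "gene_id"], kind="mergesort")
    out = out.drop_duplicates(subset="gene_id", keep="first").reset_index(drop=True)
    return out
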