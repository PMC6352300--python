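"""Drug-gene fold changes and the ranked drug-gene matrix.

From a perturbation compendium (genes x samples, each sample belonging to a
drug, an arm, and an instance such as a cell line), compute per-drug log2
control-vs-treatment fold changes and order the full gene universe per drug,
rank 1 = most up-regulated. Multiple instances of a drug are merged on the
rank scale (Borda: average rank, re-ranked), which is scale-free across
instances; fold changes themselves are computed per instance with a
pseudo-count guard for non-positive intensities.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

log = logging.getLogger("drugsea.ranking")

__all__ = [
    "MissingControlError",
    "ExpressionCompendium",
    "RankedGeneMatrix",
    "fold_changes",
    "rank_genes",
    "merge_instances",
    "rank_drug_genes",
]

#: drug label marking control samples usable by any drug in the same instance
SHARED_CONTROL = "shared"


class MissingControlError(ValueError):
    pass


@dataclass
class ExpressionCompendium:
    """Expression values (genes x samples) plus per-sample metadata.

    ``samples`` is indexed by sample_id with columns drug, arm
    ('control'/'treatment') and instance. Control samples match a treatment
    either by sharing its drug label or by carrying the shared-control label.
    """

    expression: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        if list(self.expression.columns) != list(self.samples.index):
            raise ValueError("expression columns and sample metadata disagree")
        if self.expression.isna().any().any():
            raise ValueError("expression matrix contains NaN values")
        bad = set(self.samples["arm"]) - {"control", "treatment"}
        if bad:
            raise ValueError(f"unknown arm label(s): {sorted(bad)}")
        meta = self.samples
        for (drug, instance), grp in meta[meta["arm"] == "treatment"].groupby(
            ["drug", "instance"]
        ):
            if len(self._control_samples(drug, instance)) == 0:
                raise MissingControlError(
                    f"drug {drug!r} (instance {instance!r}) has no control samples"
                )

    def _control_samples(self, drug: str, instance) -> pd.Index:
        meta = self.samples
        sel = (
            (meta["arm"] == "control")
            & (meta["instance"] == instance)
            & (meta["drug"].isin([drug, SHARED_CONTROL]))
        )
        return meta.index[sel]

    @property
    def genes(self) -> list[str]:
        return list(self.expression.index)

    def drugs(self) -> list[str]:
        meta = self.samples
        return sorted(set(meta.loc[meta["arm"] == "treatment", "drug"]))

    def instances_of(self, drug: str) -> list:
        meta = self.samples
        sel = (meta["arm"] == "treatment") & (meta["drug"] == drug)
        return sorted(set(meta.loc[sel, "instance"]))


@dataclass
class RankedGeneMatrix:
    """Per-drug complete orderings of the gene universe.

    ``ranks`` is a drugs x genes integer frame; rank 1 = most up-regulated.
    Every row is a permutation of 1..N. ``log_fc`` optionally stores the
    underlying (instance-averaged) log2 fold changes.
    """

    ranks: pd.DataFrame
    log_fc: pd.DataFrame | None = None

    def __post_init__(self):
        n = self.ranks.shape[1]
        vals = self.ranks.to_numpy()
        expected = np.arange(1, n + 1)
        if not np.all(np.sort(vals, axis=1) == expected):
            raise ValueError("each drug's ranks must be a permutation of 1..N")

    @property
    def drugs(self) -> list[str]:
        return list(self.ranks.index)

    @property
    def genes(self) -> list[str]:
        return list(self.ranks.columns)

    def ordering(self, drug: str) -> list[str]:
        """Gene IDs of one drug from most up- to most down-regulated."""
        row = self.ranks.loc[drug].to_numpy()
        return [self.genes[i] for i in np.argsort(row, kind="stable")]


def fold_changes(
    compendium: ExpressionCompendium,
    pseudocount: float = 1.0,
    per_instance: bool = False,
) -> pd.DataFrame:
    """log2 control-vs-treatment fold change for every drug-gene pair.

    FC = log2((mean treatment + eps) / (mean control + eps)), computed per
    instance. By default instances of the same drug are averaged into a
    drugs x genes frame; ``per_instance=True`` returns a (drug, instance)
    MultiIndexed frame instead.
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    expr = compendium.expression
    rows = []
    index = []
    for drug in compendium.drugs():
        for instance in compendium.instances_of(drug):
            meta = compendium.samples
            tsel = (
                (meta["arm"] == "treatment")
                & (meta["drug"] == drug)
                & (meta["instance"] == instance)
            )
            t_mean = expr[meta.index[tsel]].mean(axis=1)
            c_cols = compendium._control_samples(drug, instance)
            if len(c_cols) == 0:
                raise MissingControlError(f"drug {drug!r} has no control samples")
            c_mean = expr[c_cols].mean(axis=1)
            num = t_mean + pseudocount
            den = c_mean + pseudocount
            if (num <= 0).any() or (den <= 0).any():
                raise ValueError(
                    f"non-positive mean intensity for drug {drug!r}; "
                    "increase the pseudocount"
                )
            rows.append(np.log2(num / den).to_numpy())
            index.append((drug, instance))
    fc = pd.DataFrame(
        rows,
        index=pd.MultiIndex.from_tuples(index, names=["drug", "instance"]),
        columns=expr.index,
    )
    if per_instance:
        return fc
    return fc.groupby(level="drug").mean()


def _order_to_ranks(order: np.ndarray, n: int) -> np.ndarray:
    ranks = np.empty(n, dtype=np.int64)
    ranks[order] = np.arange(1, n + 1)
    return ranks


def rank_genes(fc: pd.DataFrame) -> RankedGeneMatrix:
    """Rank genes per drug by fold change, descending; ties by gene ID."""
    if fc.isna().any().any():
        raise ValueError("fold-change matrix contains NaN")
    genes = np.asarray(fc.columns)
    lex = np.argsort(genes, kind="stable")  # gene-ID ascending base order
    vals = fc.to_numpy()
    rank_rows = []
    for row in vals:
        order = lex[np.argsort(-row[lex], kind="stable")]
        rank_rows.append(_order_to_ranks(order, len(genes)))
    ranks = pd.DataFrame(rank_rows, index=fc.index, columns=fc.columns, dtype=np.int64)
    return RankedGeneMatrix(ranks=ranks, log_fc=fc.copy())


def merge_instances(instance_ranks: pd.DataFrame) -> pd.Series:
    """Borda-merge per-instance rankings of one drug into a single ranking.

    ``instance_ranks`` is instances x genes of ranks over one shared gene
    universe. Genes are re-ranked by average rank (ascending); ties broken
    by gene ID.
    """
    if instance_ranks.shape[0] < 1:
        raise ValueError("need at least one instance ranking")
    n = instance_ranks.shape[1]
    vals = instance_ranks.to_numpy()
    if not np.all(np.sort(vals, axis=1) == np.arange(1, n + 1)):
        raise ValueError("instance rankings are not permutations of one universe")
    avg = vals.mean(axis=0)
    genes = np.asarray(instance_ranks.columns)
    lex = np.argsort(genes, kind="stable")
    order = lex[np.argsort(avg[lex], kind="stable")]
    return pd.Series(_order_to_ranks(order, n), index=instance_ranks.columns)


def rank_drug_genes(
    compendium: ExpressionCompendium, pseudocount: float = 1.0
) -> RankedGeneMatrix:
    """Compendium -> per-drug gene ranking (the ranked drug-gene matrix).

    Each instance is ranked separately from its fold changes and instances
    of a drug are Borda-merged, so cross-instance scale differences never
    leak into the merged ordering. The stored log_fc is the
    instance-averaged fold change, kept for reporting.
    """
    fc_inst = fold_changes(compendium, pseudocount, per_instance=True)
    merged = {}
    for drug, grp in fc_inst.groupby(level="drug"):
        per_inst = rank_genes(grp.droplevel("drug"))
        merged[drug] = merge_instances(per_inst.ranks)
    ranks = pd.DataFrame(merged).T
    ranks.index.name = "drug"
    ranks = ranks.sort_index()
    return RankedGeneMatrix(
        ranks=ranks.astype(np.int64), log_fc=fc_inst.groupby(level="drug").mean()
    )
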