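"""Cross-database consensus: FDR filter per database, intersect survivors.

A drug is a consensus candidate iff its BH-adjusted p-value is at or below
the FDR threshold in *every* pathway database tested (inclusive comparison:
the selection removes drugs with adjusted p strictly above the cutoff). The
consensus table reports each candidate's per-database rank (its position in
that database's full drug ranking) and adjusted p, ordered by mean rank.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import pandas as pd

__all__ = ["ConsensusTable", "filter_significant", "intersect_candidates"]


@dataclass
class ConsensusTable:
    """Candidate drugs x databases, with rank and adjusted p per cell."""

    table: pd.DataFrame  # index: drug; columns: rank_<db>, adj_p_<db>, mean_rank
    databases: list[str]
    fdr_threshold: float

    @property
    def candidates(self) -> list[str]:
        return list(self.table.index)


def filter_significant(
    drug_ranking: pd.DataFrame, fdr_threshold: float = 0.01
) -> pd.DataFrame:
    """Drugs with adjusted p <= threshold, original ranks retained."""
    if "adj_p" not in drug_ranking.columns:
        raise ValueError("drug ranking lacks an adj_p column")
    if drug_ranking["adj_p"].isna().any():
        raise ValueError("drug ranking has missing adjusted p-values")
    return drug_ranking[drug_ranking["adj_p"] <= fdr_threshold].reset_index(drop=True)


def intersect_candidates(
    surviving: Mapping[str, pd.DataFrame], fdr_threshold: float = 0.01
) -> ConsensusTable:
    """Consensus table from per-database surviving drug lists.

    ``surviving`` maps database name -> filtered DrugRanking frame (columns
    drug, es, p, adj_p, rank). Candidates are the set intersection across
    all databases; an empty intersection yields an empty table.
    """
    if not surviving:
        raise ValueError("need at least one database list")
    databases = list(surviving)
    common: set[str] | None = None
    for db in databases:
        drugs = set(surviving[db]["drug"])
        common = drugs if common is None else (common & drugs)
    cols: dict[str, pd.Series] = {}
    for db in databases:
        sub = surviving[db].set_index("drug").loc[sorted(common)]
        cols[f"rank_{db}"] = sub["rank"]
        cols[f"adj_p_{db}"] = sub["adj_p"]
    table = pd.DataFrame(cols)
    rank_cols = [f"rank_{db}" for db in databases]
    if len(table):
        table["mean_rank"] = table[rank_cols].mean(axis=1)
        # mean rank ascending, ties by drug ID (stable second sort)
        table = table.sort_index(kind="mergesort").sort_values(
            "mean_rank", kind="mergesort"
        )
    else:
        table["mean_rank"] = pd.Series(dtype=float)
    table.index.name = "drug"
    return ConsensusTable(table=table, databases=databases, fdr_threshold=fdr_threshold)
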