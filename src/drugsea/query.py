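"""Query stage: risk gene(s) -> pathway set -> PSEA ranking of all drugs.

Given query gene(s) and one pathway database, the pathway set is the union
of pathways annotated to at least one query gene. Every drug's ranked
pathway list is then scored against that set with the KS kernel (pathway
set enrichment analysis): a strongly positive ES means the drug
up-modulates the query genes' pathways (predicted activation), strongly
negative means down-modulation (predicted inhibition). p-values are BH
adjusted across all drugs within the database.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .enrichment import PermutationNull, bh_adjust, es_from_hits
from .genesets import GeneSetDB
from .profiles import PathwayDrugMatrix

log = logging.getLogger("drugsea.query")

__all__ = ["NoAnnotationError", "PathwaySet", "pathways_for_genes", "psea_rank_drugs"]

RANKING_COLUMNS = ["drug", "es", "p", "adj_p", "rank"]


class NoAnnotationError(ValueError):
    pass


@dataclass
class PathwaySet:
    db_name: str
    query_genes: list[str]
    pathways: set[str]


def pathways_for_genes(query_genes, gene_set_db: GeneSetDB) -> PathwaySet:
    """Union of pathways annotated to >=1 query gene in one database."""
    genes = list(query_genes)
    if not genes:
        raise ValueError("need at least one query gene")
    pathways: set[str] = set()
    unmatched = []
    for g in genes:
        hit = gene_set_db.pathways_containing(g)
        if hit:
            pathways |= hit
        else:
            unmatched.append(g)
    if unmatched:
        log.warning(
            "%s: %d query gene(s) match no pathway: %s",
            gene_set_db.db_name,
            len(unmatched),
            ", ".join(unmatched[:5]) + ("..." if len(unmatched) > 5 else ""),
        )
    if not pathways:
        raise NoAnnotationError(
            f"no pathway in database {gene_set_db.db_name!r} contains any query gene"
        )
    return PathwaySet(db_name=gene_set_db.db_name, query_genes=genes, pathways=pathways)


def psea_rank_drugs(
    pathway_set: PathwaySet,
    pathway_drug_matrix: PathwayDrugMatrix,
    n_permutations: int = 10_000,
    seed: int = 0,
    null: PermutationNull | None = None,
) -> pd.DataFrame:
    """Score every drug's ranked pathway list against the query pathway set.

    Returns one row per drug (drug, es, p, adj_p, rank) sorted by ES
    descending (ties by p ascending, then drug ID); rank 1 = strongest
    predicted activation. BH adjustment spans all drugs of the database.
    """
    pdm = pathway_drug_matrix
    universe = pdm.pathway_ids
    present = pathway_set.pathways & set(universe)
    missing = len(pathway_set.pathways) - len(present)
    if missing:
        log.warning(
            "%s: %d query pathway(s) absent from the profile matrix",
            pdm.db_name,
            missing,
        )
    n = len(universe)
    if not present or len(present) >= n:
        raise NoAnnotationError(
            f"query pathway set is empty or saturating for database {pdm.db_name!r}"
        )
    if null is None:
        null = PermutationNull(seed, n_permutations)

    # rank column of the member pathways, pivoted to drugs x hits
    table = pdm.table
    sub = table[table["pathway"].isin(present)]
    hits = sub.pivot(index="drug", columns="pathway", values="rank")
    k = hits.shape[1]
    es = es_from_hits(hits.to_numpy(), n)
    p = null.pvalues(es, n, k)
    out = pd.DataFrame({"drug": hits.index, "es": es, "p": p})
    out["adj_p"] = bh_adjust(out["p"].to_numpy())
    out = out.sort_values(
        ["es", "p", "drug"], ascending=[False, True, True], kind="mergesort"
    ).reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    return out[RANKING_COLUMNS]
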