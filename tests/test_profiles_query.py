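"""Pathway expression profiles and the drug-query (PSEA) stage."""

import numpy as np
import pandas as pd
import pytest

from drugsea.enrichment import PermutationNull, bh_adjust, derive_seed, \
    enrichment_score
from drugsea.genesets import GeneSetDB
from drugsea.profiles import build_pep, rank_pathways
from drugsea.query import NoAnnotationError, pathways_for_genes, psea_rank_drugs
from drugsea.ranking import RankedGeneMatrix


def random_rgm(rng, n_drugs, n_genes):
    genes = [f"g{i:03d}" for i in range(n_genes)]
    ranks = pd.DataFrame(
        [rng.permutation(np.arange(1, n_genes + 1)) for _ in range(n_drugs)],
        index=[f"d{i:02d}" for i in range(n_drugs)],
        columns=genes,
    )
    return RankedGeneMatrix(ranks=ranks)


def random_db(rng, n_pathways, genes, lo, hi, db_name="dbX"):
    pathways = {}
    for i in range(n_pathways):
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(genes, size=size, replace=False)
        pathways[f"P{i:02d}"] = (f"pathway {i}", frozenset(members.tolist()))
    return GeneSetDB(db_name=db_name, pathways=pathways)


class TestBuildPep:
    def test_top_block_pathway_scores_plus_one(self):
        rng = np.random.default_rng(0)
        rgm = random_rgm(rng, 3, 20)
        top5 = rgm.ordering("d01")[:5]
        db = GeneSetDB("one", {"Ptop": ("top genes", frozenset(top5))})
        pep = build_pep(rgm, db, n_permutations=50, seed=0)
        cell = pep[(pep["drug"] == "d01") & (pep["pathway"] == "Ptop")]
        assert cell["es"].iloc[0] == pytest.approx(1.0)

    def test_output_has_one_row_per_drug_pathway(self):
        rng = np.random.default_rng(1)
        rgm = random_rgm(rng, 2, 10)
        db = random_db(rng, 1, rgm.genes, 3, 5)
        pep = build_pep(rgm, db, n_permutations=20, seed=0)
        assert len(pep) == 2

    def test_recomposition_matches_direct_kernel_calls(self):
        rng = np.random.default_rng(2)
        rgm = random_rgm(rng, 5, 20)
        db = random_db(rng, 8, rgm.genes, 3, 8)
        seed = 13
        null = PermutationNull(derive_seed(seed, "kernel"), 400)
        pep = build_pep(rgm, db, 400, seed=seed, null=null)
        for row in pep.itertuples():
            ordering = rgm.ordering(row.drug)
            members = db.genes_of(row.pathway)
            es = enrichment_score(ordering, members)
            assert row.es == pytest.approx(es, abs=1e-14)
            k = len(members & set(rgm.genes))
            p = float(null.pvalues(es, len(ordering), k))
            assert row.p == pytest.approx(p, abs=0)

    def test_unscoreable_pathways_excluded_with_warning(self, caplog):
        rng = np.random.default_rng(3)
        rgm = random_rgm(rng, 2, 10)
        db = GeneSetDB(
            "mixed",
            {
                "Pok": ("fine", frozenset(rgm.genes[:3])),
                "Pghost": ("alien genes", frozenset({"zz1", "zz2"})),
            },
        )
        with caplog.at_level("WARNING", logger="drugsea.profiles"):
            pep = build_pep(rgm, db, 20, seed=0)
        assert set(pep["pathway"]) == {"Pok"}
        assert "Pghost" in caplog.text

    def test_all_unscoreable_raises_with_db_name(self):
        rng = np.random.default_rng(4)
        rgm = random_rgm(rng, 2, 6)
        db = GeneSetDB("hollow", {"P0": ("none", frozenset({"zz"}))})
        with pytest.raises(ValueError, match="hollow"):
            build_pep(rgm, db, 20, seed=0)

    def test_deterministic_across_calls(self):
        rng = np.random.default_rng(5)
        rgm = random_rgm(rng, 4, 15)
        db = random_db(rng, 5, rgm.genes, 3, 6)
        a = build_pep(rgm, db, 100, seed=3)
        b = build_pep(rgm, db, 100, seed=3)
        pd.testing.assert_frame_equal(a, b)


class TestRankPathways:
    def test_forced_ordering_by_es(self):
        pep = pd.DataFrame(
            {
                "drug": ["d"] * 3,
                "pathway": ["P1", "P2", "P3"],
                "es": [0.9, -0.9, 0.0],
                "p": [0.01, 0.01, 0.5],
            }
        )
        pdm = rank_pathways(pep, "db")
        assert pdm.ordering("d") == ["P1", "P3", "P2"]

    def test_full_tie_falls_back_to_lexicographic(self):
        pep = pd.DataFrame(
            {
                "drug": ["d"] * 3,
                "pathway": ["Pb", "Pa", "Pc"],
                "es": [0.1] * 3,
                "p": [0.2] * 3,
            }
        )
        assert rank_pathways(pep, "db").ordering("d") == ["Pa", "Pb", "Pc"]

    def test_matches_sort_oracle_and_is_permutation(self):
        rng = np.random.default_rng(6)
        rows = []
        for d in range(4):
            for p in range(12):
                rows.append((f"d{d}", f"P{p:02d}", float(rng.uniform(-1, 1)),
                             float(rng.uniform(0.001, 1))))
        pep = pd.DataFrame(rows, columns=["drug", "pathway", "es", "p"])
        pdm = rank_pathways(pep, "db")
        for d, grp in pep.groupby("drug"):
            expect = [
                r.pathway
                for r in sorted(grp.itertuples(),
                                key=lambda r: (-r.es, r.p, r.pathway))
            ]
            assert pdm.ordering(d) == expect
            ranks = pdm.table[pdm.table["drug"] == d]["rank"]
            assert sorted(ranks) == list(range(1, 13))


class TestPathwaysForGenes:
    def test_direct_lookup(self, toy_db):
        ps = pathways_for_genes(["g0"], toy_db)
        assert ps.pathways == {"P1", "P3"}

    def test_union_of_disjoint_annotations(self, toy_db):
        ps = pathways_for_genes(["g1", "g2"], toy_db)
        assert ps.pathways == {"P1", "P2"}

    def test_matches_membership_scan_oracle(self):
        rng = np.random.default_rng(7)
        genes = [f"g{i:03d}" for i in range(60)]
        db = random_db(rng, 25, genes, 3, 10)
        query = list(rng.choice(genes, size=20, replace=False))
        ps = pathways_for_genes(query, db)
        expected = {
            pid
            for pid, (_, members) in db.pathways.items()
            if any(g in members for g in query)
        }
        assert ps.pathways == expected

    def test_no_annotation_raises_with_db_name(self, toy_db):
        with pytest.raises(NoAnnotationError, match="toy"):
            pathways_for_genes(["not_a_gene"], toy_db)


class TestPseaRankDrugs:
    def _pdm(self, rng, n_drugs=6, n_pathways=20):
        rows = []
        for d in range(n_drugs):
            order = rng.permutation([f"P{i:02d}" for i in range(n_pathways)])
            for r, pid in enumerate(order, start=1):
                rows.append((f"d{d}", pid, 0.0, 0.5, r))
        from drugsea.profiles import PathwayDrugMatrix
        return PathwayDrugMatrix(
            "db", pd.DataFrame(rows, columns=["drug", "pathway", "es", "p",
                                              "rank"])
        )

    def test_top_block_query_scores_plus_one_and_rank_one(self):
        rng = np.random.default_rng(8)
        pdm = self._pdm(rng)
        from drugsea.query import PathwaySet
        top = set(pdm.ordering("d3")[:4])
        ranking = psea_rank_drugs(
            PathwaySet("db", ["gq"], top), pdm, n_permutations=200, seed=0
        )
        row = ranking[ranking["drug"] == "d3"].iloc[0]
        assert row["es"] == pytest.approx(1.0)
        assert row["rank"] == 1

    def test_mirror_rankings_get_opposite_es(self):
        from drugsea.profiles import PathwayDrugMatrix
        from drugsea.query import PathwaySet
        pathways = [f"P{i:02d}" for i in range(10)]
        rows = []
        for r, pid in enumerate(pathways, start=1):
            rows.append(("fwd", pid, 0.0, 0.5, r))
            rows.append(("rev", pid, 0.0, 0.5, 11 - r))
        pdm = PathwayDrugMatrix(
            "db", pd.DataFrame(rows, columns=["drug", "pathway", "es", "p",
                                              "rank"])
        )
        query = PathwaySet("db", ["gq"], {"P01", "P03", "P04"})
        ranking = psea_rank_drugs(query, pdm, n_permutations=100, seed=0)
        es = ranking.set_index("drug")["es"]
        assert es["fwd"] == pytest.approx(-es["rev"])

    def test_recomposition_matches_kernel_and_bh(self):
        rng = np.random.default_rng(9)
        pdm = self._pdm(rng, n_drugs=10, n_pathways=30)
        from drugsea.query import PathwaySet
        query = PathwaySet("db", ["gq"],
                           set(rng.choice([f"P{i:02d}" for i in range(30)], 6,
                                          replace=False)))
        seed = 21
        null = PermutationNull(derive_seed(seed, "kernel"), 300)
        ranking = psea_rank_drugs(query, pdm, 300, seed=seed, null=null)
        es_direct, p_direct = {}, {}
        for d in pdm.drugs:
            es = enrichment_score(pdm.ordering(d), query.pathways)
            es_direct[d] = es
            p_direct[d] = float(null.pvalues(es, 30, 6))
        for row in ranking.itertuples():
            assert row.es == pytest.approx(es_direct[row.drug], abs=1e-14)
            assert row.p == pytest.approx(p_direct[row.drug], abs=0)
        adj = bh_adjust(ranking["p"].to_numpy())
        np.testing.assert_allclose(ranking["adj_p"], adj, atol=1e-15)

    def test_every_drug_appears_exactly_once(self):
        rng = np.random.default_rng(10)
        pdm = self._pdm(rng, n_drugs=7)
        from drugsea.query import PathwaySet
        query = PathwaySet("db", ["gq"], {"P00", "P05"})
        ranking = psea_rank_drugs(query, pdm, 50, seed=0)
        assert sorted(ranking["drug"]) == sorted(pdm.drugs)
        assert sorted(ranking["rank"]) == list(range(1, 8))

    def test_disjoint_query_raises(self):
        rng = np.random.default_rng(11)
        pdm = self._pdm(rng)
        from drugsea.query import PathwaySet
        with pytest.raises(NoAnnotationError):
            psea_rank_drugs(PathwaySet("db", ["gq"], {"ZZ"}), pdm, 50, seed=0)
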