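"""End-to-end orchestration: simulate -> fine-map -> rank -> profiles ->
drug query -> consensus, with a manifest recording every tunable.

`run_pipeline` is the file-writing entry point used by the `run-all` CLI
command; `run_synthetic_experiment` is the in-memory equivalent used by the
test suite and the acceptance script when only the end results matter.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import __version__
from .config import RunConfig
from .consensus import ConsensusTable, filter_significant, intersect_candidates
from .enrichment import PermutationNull, derive_seed
from .finemap import add_posteriors, define_ld_window, map_candidate_genes, \
    select_causal_variant
from .genesets import GeneSetDB
from .io import write_compendium, write_gmt, write_ld_matrix, write_matrix_tsv, \
    write_ranked_gene_matrix, write_truth
from .profiles import build_pep, rank_pathways
from .query import pathways_for_genes, psea_rank_drugs
from .ranking import rank_drug_genes
from .simulate import PlantedTruth, SimulationConfig, simulate_compendium, \
    simulate_databases, simulate_eqtl_table, simulate_locus

log = logging.getLogger("drugsea.pipeline")

__all__ = ["SyntheticResult", "run_synthetic_experiment", "run_pipeline"]


@dataclass
class SyntheticResult:
    """In-memory products of one synthetic end-to-end run."""

    config: RunConfig
    truth: PlantedTruth
    databases: list[GeneSetDB]
    rankings: dict[str, pd.DataFrame]  # db -> DrugRanking frame
    consensus: ConsensusTable
    candidate_genes: pd.DataFrame  # fine-mapping output
    query_genes: list[str]


def _simulate_genetics(sim: SimulationConfig, truth: PlantedTruth):
    """Loci, LD matrices and an eQTL table wired to the planted genes.

    One locus per distinct planted target gene (extra loci carry no planted
    link); each locus's causal variant is planted mid-locus and linked to
    its gene in the first eQTL set.
    """
    planted_genes = [g for g in dict.fromkeys(g for _, g in truth.planted_pairs)]
    variants_frames, ld_matrices, links = [], {}, []
    for li in range(sim.n_loci):
        locus_id = f"locus{li:02d}"
        causal = sim.n_variants_per_locus // 2
        vt, ld = simulate_locus(
            sim.n_variants_per_locus,
            causal,
            bf_dominance=sim.bf_dominance,
            decay_rate=sim.ld_decay,
            seed=derive_seed(sim.seed, "genetics", li),
            locus_id=locus_id,
        )
        variants_frames.append(vt)
        ld_matrices[locus_id] = ld
        truth.causal_variants[locus_id] = vt.iloc[causal]["variant_id"]
        if li < len(planted_genes):
            links.append(("eqtl00", vt.iloc[causal]["variant_id"], planted_genes[li]))
    variants = pd.concat(variants_frames, ignore_index=True)
    from .simulate import gene_id  # local import to avoid cycle noise

    genes = [gene_id(i) for i in range(sim.n_genes)]
    eqtl = simulate_eqtl_table(
        variants, genes, links, seed=sim.seed,
        n_sets=sim.n_eqtl_sets, n_background=sim.n_eqtl_background,
    )
    return variants, ld_matrices, eqtl


def _finemap_stage(variants, ld_matrices, eqtl, config: RunConfig):
    """Posteriors, per-locus causal/lead variants, eQTL candidate genes."""
    variants = add_posteriors(variants)
    leads = {}
    for locus_id, grp in variants.groupby("locus_id"):
        leads[locus_id] = select_causal_variant(grp)
        define_ld_window(leads[locus_id], ld_matrices[locus_id], config.window_r2)
    candidates = map_candidate_genes(
        eqtl, list(leads.values()), ld_matrices, r2_threshold=config.eqtl_r2
    )
    return variants, leads, candidates


def _query_genes(config: RunConfig, truth: PlantedTruth, candidates: pd.DataFrame):
    if config.query_from == "planted":
        return [g for g in dict.fromkeys(g for _, g in truth.planted_pairs)]
    if config.query_from == "finemap":
        return list(candidates["gene_id"])
    return [
        line.strip()
        for line in Path(config.query_genes_path).read_text().splitlines()
        if line.strip()
    ]


def run_synthetic_experiment(config: RunConfig) -> SyntheticResult:
    """Full in-memory synthetic run returning rankings and the consensus."""
    config.validate()
    sim = config.simulation
    databases = simulate_databases(sim)
    compendium, truth = simulate_compendium(sim, databases)
    variants, ld_matrices, eqtl = _simulate_genetics(sim, truth)
    variants, leads, candidates = _finemap_stage(variants, ld_matrices, eqtl, config)

    ranked = rank_drug_genes(compendium, pseudocount=config.pseudocount)
    null = PermutationNull(derive_seed(config.seed, "kernel"), config.n_permutations)
    query = _query_genes(config, truth, candidates)

    rankings: dict[str, pd.DataFrame] = {}
    for db in databases:
        pep = build_pep(ranked, db, config.n_permutations,
                        seed=config.seed, null=null)
        pdm = rank_pathways(pep, db.db_name)
        ps = pathways_for_genes(query, db)
        rankings[db.db_name] = psea_rank_drugs(
            ps, pdm, config.n_permutations, seed=config.seed, null=null
        )
    surviving = {db: filter_significant(r, config.fdr) for db, r in rankings.items()}
    cons = intersect_candidates(surviving, config.fdr)
    return SyntheticResult(
        config=config,
        truth=truth,
        databases=databases,
        rankings=rankings,
        consensus=cons,
        candidate_genes=candidates,
        query_genes=query,
    )


def planted_recovery_trial(
    seed: int,
    effect_size: float = 2.0,
    n_permutations: int = 2000,
    fdr: float = 0.01,
) -> dict:
    """One end-to-end run at generator defaults; reports whether the first
    planted drug clears the FDR cut in every database and reaches the
    consensus table."""
    cfg = RunConfig(n_permutations=n_permutations, fdr=fdr, seed=seed)
    cfg.simulation.seed = seed
    cfg.simulation.effect_size = effect_size
    res = run_synthetic_experiment(cfg)
    drug = res.truth.planted_pairs[0][0]
    adj = {
        db: float(r.set_index("drug").loc[drug, "adj_p"])
        for db, r in res.rankings.items()
    }
    return {
        "planted_drug": drug,
        "adj_p": adj,
        "significant_everywhere": all(v <= fdr for v in adj.values()),
        "in_consensus": drug in res.consensus.candidates,
        "n_candidates": len(res.consensus.candidates),
    }


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig, outdir) -> ConsensusTable:
    """File-writing end-to-end run; every stage's artefact lands in outdir.

    The manifest records the package version, the full configuration
    (every tunable), and SHA-256 digests of the generated inputs, so a run
    is reproducible from the manifest alone. No timestamps are recorded:
    fixed-seed runs are byte-identical.
    """
    outdir = Path(outdir)
    config.validate()
    if config.query_from == "file" and not Path(config.query_genes_path).exists():
        raise FileNotFoundError(
            f"query gene list {config.query_genes_path!r} does not exist; "
            "fix query_genes_path before running"
        )
    outdir.mkdir(parents=True, exist_ok=True)
    sim = config.simulation

    log.info("stage=simulate generating synthetic inputs")
    databases = simulate_databases(sim)
    compendium, truth = simulate_compendium(sim, databases)
    variants, ld_matrices, eqtl = _simulate_genetics(sim, truth)

    for db in databases:
        write_gmt(db, outdir / f"{db.db_name}.gmt")
    write_compendium(compendium, outdir / "expression.tsv", outdir / "samples.tsv")
    variants.to_csv(outdir / "variants.tsv", sep="\t", index=False)
    for locus_id, ld in ld_matrices.items():
        write_ld_matrix(ld, outdir / f"ld_{locus_id}.tsv")
    eqtl.to_csv(outdir / "eqtl.tsv", sep="\t", index=False)
    write_truth(truth, outdir / "truth.json")

    log.info("stage=finemap mapping candidate genes")
    variants, leads, candidates = _finemap_stage(variants, ld_matrices, eqtl, config)
    candidates.to_csv(outdir / "candidate_genes.tsv", sep="\t", index=False)

    log.info("stage=rank building the ranked drug-gene matrix")
    ranked = rank_drug_genes(compendium, pseudocount=config.pseudocount)
    write_ranked_gene_matrix(ranked, outdir / "ranked_genes.tsv")

    null = PermutationNull(derive_seed(config.seed, "kernel"), config.n_permutations)
    query = _query_genes(config, truth, candidates)
    (outdir / "query_genes.txt").write_text("".join(g + "\n" for g in query))

    rankings = {}
    for db in databases:
        log.info("stage=build-peps database=%s", db.db_name)
        pep = build_pep(ranked, db, config.n_permutations, seed=config.seed, null=null)
        pep.to_csv(outdir / f"pep_{db.db_name}.tsv", sep="\t", index=False,
                   float_format="%.17g")
        pdm = rank_pathways(pep, db.db_name)
        log.info("stage=gene2drug database=%s", db.db_name)
        ps = pathways_for_genes(query, db)
        ranking = psea_rank_drugs(ps, pdm, config.n_permutations,
                                  seed=config.seed, null=null)
        ranking.to_csv(outdir / f"ranking_{db.db_name}.tsv", sep="\t", index=False,
                       float_format="%.17g")
        rankings[db.db_name] = ranking

    log.info("stage=consensus intersecting significant lists")
    surviving = {db: filter_significant(r, config.fdr) for db, r in rankings.items()}
    cons = intersect_candidates(surviving, config.fdr)
    cons.table.to_csv(outdir / "consensus.tsv", sep="\t", float_format="%.17g")

    manifest = {
        "drugsea_version": __version__,
        "config": config.to_dict(),
        "databases": [db.db_name for db in databases],
        "query_genes": query,
        "n_candidates": len(cons.candidates),
        "input_digests": {
            name: _sha256(outdir / name)
            for name in sorted(
                p.name for p in outdir.glob("*")
                if p.suffix in {".gmt", ".tsv"} and not p.name.startswith(
                    ("ranking_", "pep_", "consensus", "candidate_", "ranked_")
                )
            )
        },
    }
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True)
    )
    config.write(outdir / "config.json")
    return cons
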