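# Methods

`drugsea` implements a genetics-driven drug-repurposing analysis for a
complex disease such as inflammatory bowel disease (IBD): candidate risk
genes are prioritised from GWAS risk loci, and drugs are then ranked by how
strongly they modulate the biological pathways those genes belong to, using
a drug-perturbation expression compendium and several pathway databases.
This note describes the models, the defaults, and the design decisions
taken where the procedure admitted more than one reasonable reading.

## Fine-mapping and candidate-gene mapping

Each risk locus carries per-variant Bayes factors (BF) from an association
meta-analysis; computing BFs from genotypes is out of scope — they are
inputs. Under a uniform single-causal-variant prior the causal posterior is

    PP_i = BF_i / Σ_j BF_j,

which normalises to 1 within each locus (enforced to 1e-12). The prior is
the standard fine-mapping convention; nothing in the procedure requires a
different one. The causal variant of a locus is the posterior argmax, with
ties broken by smallest genomic position so output is deterministic.
Credible sets (cumulative-PP) are deliberately not implemented: only the
argmax rule is part of the procedure.

A locus window spans the leftmost to the rightmost variant whose r² with
the lead variant is **at least** 0.6 (inclusive, following the rule's
wording); every variant positioned inside the span is a member even if its
own r² dips below the threshold — LD is not monotone in position, and the
window is defined by its endpoints. Lowering the threshold can only widen
the window.

Candidate genes come from eQTL overlap. Within each eQTL set, each gene's
most significant variant association is taken (min-p per (set, gene); an
alternative one-association-per-set reading is available via
`per_set_only=True`), and the gene is a candidate iff that variant's r²
with some lead variant is **strictly greater** than 0.8 (the rule says
"r² > 0.8", so equality does not qualify). Variants that cannot be placed
in any locus LD matrix are skipped with a warning. We do not additionally
require the eQTL variant to lie inside the LD window; the candidate rule as
stated is purely an r² condition.

Coordinates are 1-based, windows inclusive on both ends, one chromosome per
locus.

## Drug-gene ranking

For every drug-gene pair the compendium yields a log2 fold change

    FC(d, g) = log2((mean treatment + ε) / (mean control + ε)),

computed per instance (e.g. per cell line), with pseudo-count ε (default
1.0 on the raw-intensity scale) guarding against non-positive intensities.
log2 symmetrises up- and down-regulation, which the two-sided enrichment
score requires. Controls are matched within instance, either drug-matched
or via the shared-control label.

Each instance is ranked separately (FC descending, ties by gene ID
ascending) and instances of a drug are merged by average rank
(Borda merge, re-ranked, ties by gene ID). Rank merging is scale-free
across instances, so platform- or cell-line-specific intensity scales never
leak into the merged ordering; averaging FCs would not have this property.
The merge is idempotent, and every per-drug ranking is a complete
permutation of the gene universe.

## The enrichment kernel

One statistic is used twice: the unweighted Kolmogorov–Smirnov-type
enrichment score of a set S against a ranked list of N items. Walking down
the list, a running sum gains 1/|S| at members and loses 1/(N−|S|) at
non-members; the ES is the signed extremum of largest magnitude, in
[−1, 1], with +1 iff S occupies exactly the top |S| positions and −1 iff
exactly the bottom. The unweighted (classic) form is used because the
pathway level has no natural per-item weight; a score-weighted variant is
available (`enrichment_score_weighted`) but off by default and not used by
the pipeline.

Numerical choices:

- The running sum scaled by |S|·(N−|S|) is integer-valued, so extrema are
  selected in exact integer arithmetic; the documented tie rule (an exact
  tie between the largest positive and negative deviation resolves to the
  positive value) can never be flipped by floating-point rounding.
- p-values are two-sided permutation estimates with the add-one
  convention: B random same-size sets, p = (1 + #{|ES_b| ≥ |ES_obs|}) /
  (B + 1). Two-sided because a drug may act by activation (top of the
  list) or inhibition (bottom); add-one avoids p = 0. An exhaustive mode
  enumerates all C(N, |S|) sets when that count is small.
- Because the unweighted ES depends on the list only through the hit
  positions, its permutation null is a function of (N, |S|) alone. Null
  draws are therefore cached per (N, |S|) with seeds derived from
  (master seed, N, |S|) via a stable blake2 hash, and shared across every
  (drug, pathway) cell and every database with the same geometry. This is
  statistically identical to drawing per cell and is what makes scoring
  90,000 cells with B = 2,000 tractable on one CPU; it also makes results
  independent of evaluation order (serial or parallel).
- Benjamini–Hochberg adjustment is the standard step-up
  q_(i) = min_{j≥i} p_(j)·m/j, capped at 1, applied across all drugs
  within one database.
- Set members absent from the ranked list are dropped with a warning
  (pathway databases always annotate genes outside a given compendium);
  a fully absent or fully saturating set is an error, not a 0.

## Pathway profiles and the drug query

For each pathway database, every (drug, pathway) cell gets an ES and p
from the kernel applied to the drug's ranked gene list; per drug, pathways
are ordered by ES descending (ties by raw p ascending, then pathway ID) —
the profile ranks pathways by how much the drug modulates them, a
magnitude criterion, with p only as a tiebreaker. Pathways with no
scoreable gene are excluded and logged; the minimum-overlap floor is 1
gene by default (configurable).

A query maps gene(s) to the union of pathways containing them in a given
database (one pooled set per database, one PSEA per database — matching a
single reported drug list per database; a per-gene mode is available), and
every drug's ranked pathway list is scored against that set. Drugs are
ordered by ES descending; rank 1 is the strongest predicted activation,
the bottom the strongest predicted inhibition. Significance, not sign,
gates candidacy.

## Consensus selection

Per database, drugs with BH-adjusted p ≤ the FDR threshold survive
(inclusive: the rule removes drugs with adjusted p strictly above the
cutoff, default 0.01); the consensus candidates are the intersection of
all databases' surviving lists. The consensus table reports each
candidate's per-database rank and adjusted p; ranks are positions in the
full drug ranking (not within the significant subset), and candidates are
ordered by mean rank. Adding a database can only shrink the candidate set;
lowering the threshold can only shrink each surviving list.

### The permutation floor and why FDR screens need multiple active drugs

With the add-one estimator the smallest attainable p is 1/(B+1); after BH
across m drugs, a drug ranked j-th among the jointly smallest p-values has
adjusted p ≥ (m/j)·1/(B+1). At the default B = 2,000 and m = 200 this
floor is ≈ 0.1 for a solitary active drug — no single drug, however
strong, can clear FDR 0.01. The screen is informative precisely when a
family of truly active drugs shares the floor (j ≥ 10 at these settings),
which is also the regime the consensus rule is designed for: a screen that
reports several candidate compounds surviving the cutoff in every
database. Users running single-candidate analyses should either raise B or
relax the FDR threshold accordingly.

## The synthetic-data generator

The generator emulates, at desk scale, the inputs of the real analysis:

- **Loci**: positions with random 0.5–2 kb gaps; log-normal null Bayes
  factors with the causal variant's BF set to `bf_dominance` (default 25)
  times the largest null BF, so it is the strict maximum; r² decaying as
  exp(−`ld_decay`·distance_kb) (default 0.04/kb, giving windows of roughly
  ±10 variants at r² ≥ 0.6) with mild symmetric jitter.
- **eQTL tables**: background records at p uniform on (1e-3, 1]; planted
  (set, variant, gene) links at p uniform on (1e-8, 1e-4], strictly below
  every background p in their set by construction.
- **Pathway databases**: uniform sizes on (5, 50) over a 1,000-gene
  universe, 150 pathways per database, 3 databases by default (six as in a
  full-scale analysis are one config key away). Planted target genes are
  guaranteed membership in at least `min_planted_annotations` pathways per
  database (default 3, enforced by swapping the gene into random pathways
  without changing sizes): prioritised disease genes are multiply
  annotated in curated collections, and a gene with a single annotation
  cannot carry pathway-level signal.
- **Compendium**: per-gene baselines drawn once (uniform 50–150 intensity
  units), i.i.d. Gaussian noise (SD = `noise_sd`, default 1.0) per
  replicate, 3 control + 3 treatment replicates per drug, 200 drugs. For
  each planted (drug, target gene) pair, the drug's treatment replicates
  are shifted upward by `effect_size`·`noise_sd` (default effect 2.0) for
  every gene in the union, across databases, of pathways containing the
  target gene; controls are untouched. The recorded ground truth includes
  exactly these affected sets.
- **Planted family**: by default 12 drugs share the one target gene. This
  mirrors the intended use case — a screen recovering a family of
  compounds engaging the same target biology — and respects the
  permutation-floor arithmetic above: at B = 2,000 and 200 drugs a
  consensus at FDR 0.01 is reachable only with ≥ 10 drugs at the floor.

What the generator does **not** emulate: microarray normalisation
artefacts, batch effects, correlated gene-gene noise, cell-line-specific
biology, LD computed from genotypes, or real file formats of any public
compendium. Passing tests therefore demonstrate that the statistical
machinery recovers planted signal under clean assumptions — not that the
pipeline is robust to the technical structure of real expression data.

## Orchestration and reproducibility

A single YAML/JSON config drives `run-all`; every tunable lands in the run
manifest together with SHA-256 digests of the generated inputs, and no
timestamps are recorded, so fixed-seed runs are byte-identical. All
randomness flows from one master seed through labelled blake2-derived
sub-seeds. By default the drug query uses the planted target genes
(`query_from: planted`) so the calibration of the drug-ranking stage can
be read independently of fine-mapping errors; `query_from: finemap` chains
the fine-mapped candidate genes into the query instead, and
`query_from: file` accepts an explicit list.

## Problem sizes used in the checks

The acceptance suite runs the full pipeline at the default study
conditions (200 drugs × 1,000 genes, 150 pathways × 3 databases,
B = 2,000) over 20 seeds for the planted-signal arm and 20 for the null
arm; kernel calibration uses 2,000 random draws at B = 999; fine-mapping
recovery uses 100 seeded loci of 50 variants. These sizes were chosen so
the whole suite completes in a few minutes on a single core while leaving
the binomial bands on every rate narrow enough to be meaningful.

## Known limitations

- Only single-causal-variant fine-mapping; no credible sets, no
  colocalisation.
- The permutation p resolution is 1/(B+1); very small adjusted p-values
  as reported by analytic tools are out of reach by design (analytic KS
  p-values are deliberately not implemented).
- The weighted ES variant is provided but untested against any external
  reference implementation.
- Consensus ranks are reported within the full drug list; the
  alternative (positions within the significant subset) is noted but not
  implemented.
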