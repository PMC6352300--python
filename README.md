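# drugsea

Genetics-driven drug repurposing for complex disease. Given GWAS risk loci,
`drugsea` prioritises candidate risk genes (Bayes-factor causal posteriors,
LD-window locus definition, eQTL overlap), then ranks every drug in a
perturbation expression compendium by how strongly it modulates the
pathways those genes belong to, and finally selects consensus candidates —
drugs significant at a false-discovery-rate cutoff in **every** pathway
database tested. The intended users are computational biologists screening
for repurposing candidates from genetic association results, as was done
for inflammatory bowel disease.

## The method

**Fine-mapping.** Within each risk locus, per-variant Bayes factors BF_i
give causal posteriors PP_i = BF_i / Σ_j BF_j under a uniform
single-causal-variant prior; the locus's causal variant is the posterior
argmax. The locus window spans the leftmost to rightmost variant with
r² ≥ 0.6 against the lead variant. A gene is an eQTL candidate when its
most significant association within an eQTL set involves a variant with
r² > 0.8 to a lead SNP.

**Drug ranking.** For each drug d and gene g the compendium yields
FC(d,g) = log2((mean treatment + ε)/(mean control + ε)); genes are ranked
per drug (cell-line instances merged on the rank scale). Given a pathway
database, each drug's ranked gene list is converted to a *pathway
expression profile*: every pathway is scored with the unweighted
Kolmogorov–Smirnov enrichment score

ES = signed extremum of the running sum (+1/|S| at members, −1/(N−|S|)
elsewhere), ES ∈ [−1, 1],

and pathways are ranked per drug by ES. A query gene's pathway set (all
pathways containing it) is then scored against every drug's ranked pathway
list — pathway-set enrichment analysis (PSEA) — giving each drug an ES,
a two-sided permutation p-value (add-one estimator over B random same-size
sets), and a Benjamini–Hochberg adjusted p across all drugs. Drugs at the
top of the resulting ranking are predicted activators of the query gene's
pathway biology, drugs at the bottom predicted inhibitors.

**Consensus.** Per database, drugs with adjusted p ≤ 0.01 survive; the
candidates are the intersection of all surviving lists, reported with
per-database rank and adjusted p.

A synthetic-data module generates all inputs (loci, LD, eQTL tables,
pathway databases, expression compendium) with planted, recoverable
signal, so the whole pipeline is testable without any external download.
See `docs/methods.md` for models, defaults and design decisions.

## Worked example

```python
from drugsea import RunConfig, SimulationConfig, run_synthetic_experiment

cfg = RunConfig(
    simulation=SimulationConfig(
        n_genes=300, n_drugs=40, n_pathways_per_db=40, n_databases=3,
        pathway_size_range=(5, 15),
        planted_pairs=[(0, 0), (1, 0), (2, 0), (3, 0)],  # 4 drugs hit gene 0
        min_planted_annotations=2, seed=42,
    ),
    n_permutations=2000, fdr=0.05, seed=42,
)
res = run_synthetic_experiment(cfg)
print("query genes:", res.query_genes)
print(res.rankings["db1"].head(6).to_string(index=False))
print(res.consensus.table.round(4).to_string())
```

prints

```
query genes: ['G0000']
 drug       es        p    adj_p  rank
D0000 1.000000 0.004498 0.044978     1
D0001 1.000000 0.004498 0.044978     2
D0002 1.000000 0.004498 0.044978     3
D0003 1.000000 0.004498 0.044978     4
D0017 0.894737 0.042479 0.319840     5
D0019 0.868421 0.063968 0.319840     6

       rank_db1  adj_p_db1  rank_db2  adj_p_db2  rank_db3  adj_p_db3  mean_rank
drug
D0000         1      0.045         1      0.045         1      0.045        1.0
D0001         2      0.045         2      0.045         2      0.045        2.0
D0002         3      0.045         3      0.045         3      0.045        3.0
D0003         4      0.045         4      0.045         4      0.045        4.0
```

The four planted drugs reach ES = 1 (the query gene's pathways occupy the
very top of their pathway profiles) with p at the permutation floor
1/(B+1) ≈ 5·10⁻⁴; BH across 40 drugs puts their adjusted p at
0.045, and all four appear in the consensus across the three databases.
Note the floor arithmetic: with B permutations and m drugs, a drug ranked
j-th among the smallest p-values cannot beat adjusted p = m/(j·(B+1)), so
small toy screens need either a larger B or a looser FDR than a full-scale
run (this example uses 0.05; the defaults — 200 drugs, a 12-drug planted
family, FDR 0.01 — clear the cutoff comfortably).

The same pipeline is available from the shell:

```sh
drugsea run-all --config config.yaml --outdir run1 --seed 7
drugsea simulate / finemap / rank / build-peps / gene2drug / consensus / score
```

Each `run-all` output directory contains every intermediate artefact
(GMT databases, expression TSVs, variant/LD/eQTL tables, pathway profiles,
per-database drug rankings, the consensus table) plus a manifest with all
parameters and input digests; fixed-seed runs are byte-identical.

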