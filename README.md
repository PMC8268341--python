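# kea — kinase-activity enrichment analysis for phosphoproteomics

`kea` infers which protein kinases are over- or under-active between two
biological conditions from label-free phosphoproteomics data. It takes
MaxQuant `Phospho (STY)Sites` tables, builds a phosphosite × sample
intensity matrix, preprocesses it (contaminant/reverse filtering,
localization-probability filtering at ≥ 0.75, log2 transform, quantile
normalization, missingness-aware imputation), tests every site with Welch's
t-test, and runs an overlap-aware ranked-list enrichment of kinase
substrate sets drawn from a kinase–substrate meta-database, optionally
extended with motif-based NetworKIN predictions. The output is a ranked
table of kinases per direction with exact enrichment p-values,
Bonferroni-corrected p-values, Monte-Carlo FDR estimates and dependence
scores, plus waterfall and network-import tables.

It is aimed at proteomics bioinformaticians analysing perturbation
experiments (e.g. kinase-inhibitor treatment of cell lines) who want
kinase-level hypotheses from site-level differential data.

## The statistic at the core

Sites are ordered by signed evidence s(i) = sign(Δᵢ)·(−log10 pᵢ), where Δᵢ
is the log2 fold change and pᵢ the Welch p-value of site i — once
descending (over-activity ranking) and once ascending (under-activity
ranking); no significance cutoff is applied. For a kinase whose measured
substrate set has K members in the ranked universe of N sites, the minimum
hypergeometric (mHG) statistic is

    s = min over t = 1..N of  P[ X ≥ k(t) ],   X ~ Hypergeom(N, K, t),

with k(t) the number of substrates in the top t. Because the minimum scans
all cutoffs, s is not itself a p-value; the exact null probability
P(S ≤ s) is computed by a dynamic program over the C(N, K) equally likely
substrate placements (no approximation). Kinase sets that are significant
only through sites shared with another significant set are discarded via a
set-dependence graph: an edge A→B is added when B's p-value, recomputed
after deleting A's members from both the set and the universe, exceeds the
0.01 threshold, and a node is dropped when the union of its explainers
accounts for all of its signal. Retained kinases are reported at primary
p ≤ 0.01 and permutation-FDR ≤ 0.05.

## Worked example

```python
from kea import run_pipeline

summary = run_pipeline({
    "input": {"simulate": {"n_sites": 2000, "n_kinases": 43,
                           "substrates_per_kinase": 20, "n_active": 3}},
    "comparison": {"test": "treat", "reference": "control"},
    "seed": 11,
    "output": "scratch/example_run",
})
```

prints (abridged):

```json
{
 "comparison": "treat_vs_control",
 "coverage_fraction": 0.428656,
 "db_n_associations": 860,
 "n_records": 1998,
 "n_sets_tested": 43,
 "n_significant_over": 3,
 "n_significant_under": 0,
 "n_sites_processed": 1696,
 "n_sites_raw": 1998,
 "reported_kinases": ["KIN001", "KIN002", "KIN003"],
 "seed": 11
}
```

The simulated experiment plants three over-active kinases (+1.5 log2 on
their substrates in `treat`); the pipeline recovers exactly those three as
significant over-active kinases and none of the 40 decoys.
`coverage_fraction` is the share of measured phosphosites carrying at least
one kinase annotation; `n_sites_processed` counts sites surviving the
quality filters. The run directory holds every stage output (matrices,
differential table, enrichment tables, waterfall, network node table and
edge-request manifest, `summary.json`).

Real data run the same way: point `input.phospho` at one or more MaxQuant
`Phospho (STY)Sites.txt` files (fraction files are summed per sample),
`input.design` at a `sample,condition,replicate` CSV, and `database.sources`
or `database.load` at kinase–substrate snapshots/bundle. The same pipeline
is available as a shell command (`kea run config.yaml`, plus `kea
build-db`, `kea simulate`, `kea report`), and `examples/` walks through
each capability step by step.

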