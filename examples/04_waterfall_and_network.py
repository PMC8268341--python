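"""Reporting: waterfall table/plot, cancer-role annotation, network export."""

import tempfile
from pathlib import Path

import pandas as pd

from kea import (SimulationConfig, annotate_ts, assemble_matrix,
                 enrich_kinases, export_network_table, preprocess_matrix,
                 simulate_dataset, waterfall_data, welch_test)
from kea.report import plot_waterfall

cfg = SimulationConfig(n_sites=1500, n_kinases=30, substrates_per_kinase=15,
                       n_active=4, active_direction="mixed", seed=8)
_, design, db, truth = simulate_dataset(cfg)
m = preprocess_matrix(assemble_matrix(truth.records, design), seed=8)
results = enrich_kinases(welch_test(m, "treat", "control"), db, seed=8)

wf = waterfall_data(results)
print("waterfall rows (signed height = signed -log10 primary p):")
print(wf.to_string(index=False))

workdir = Path(tempfile.mkdtemp())
roles = workdir / "roles.tsv"
pd.DataFrame({"gene": ["KIN001", "KIN003"],
              "role": ["oncogene", "tumor_suppressor"]}).to_csv(
    roles, sep="\t", index=False)
wf = annotate_ts(wf, roles)  # left-join of literature-mined cancer roles
plot_waterfall(wf, workdir / "waterfall.png")

nodes, manifest = export_network_table(results, outdir=workdir)
print("\nnetwork node table for STRING/Cytoscape import:")
print(nodes.to_string(index=False))
print(f"\noutputs written under {workdir}")
# positive bars (red) are over-active kinases, negative (blue) under-active;
# the manifest records the minimum edge confidence (0.8) to request on import
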