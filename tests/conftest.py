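import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


def make_matrix(values, conditions, sites=None, stage="imputed", scale="log2",
                meta=None):
    """Small ExpressionMatrix literal for unit tests."""
    from kea.matrix import ExpressionMatrix

    values = np.asarray(values, dtype=float)
    n, p = values.shape
    samples = [f"s{j}" for j in range(p)]
    if sites is None:
        sites = [f"G{i}_S{i + 1}_m1" for i in range(n)]
    design = pd.DataFrame(
        {"condition": conditions}, index=pd.Index(samples, name="sample")
    )
    data = pd.DataFrame(values, index=pd.Index(sites, name="site"), columns=samples)
    if meta is None:
        meta = pd.DataFrame(
            {
                "localization_prob": 1.0,
                "is_reverse": False,
                "is_contaminant": False,
            },
            index=data.index,
        )
    return ExpressionMatrix(data=data, design=design, row_meta=meta,
                            stage=stage, scale=scale)


@pytest.fixture(scope="session")
def planted_run():
    """One standard planted simulation run through the whole pipeline."""
    from kea import (SimulationConfig, assemble_matrix, enrich_kinases,
                     preprocess_matrix, simulate_dataset, welch_test)

    cfg = SimulationConfig(n_sites=2000, n_kinases=43, substrates_per_kinase=20,
                           n_active=3, effect_size=1.5, noise_sd=0.5, seed=11)
    table, design, db, truth = simulate_dataset(cfg)
    m = preprocess_matrix(assemble_matrix(truth.records, design), seed=11)
    diff = welch_test(m, "treat", "control")
    results = enrich_kinases(diff, db, b_null=100, seed=11)
    return {"cfg": cfg, "table": table, "design": design, "db": db,
            "truth": truth, "matrix": m, "diff": diff, "results": results}
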