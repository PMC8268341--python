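"""Per-site Welch tests and direction-specific ranked site lists.

Differential phosphorylation between two conditions is assessed per site
with Welch's unequal-variance t-test (degrees of freedom by
Welch-Satterthwaite).  No significance cutoff is applied downstream:
instead the full site universe is ordered twice, once with the strongest
over-expressed sites first and once with the strongest under-expressed
sites first, and both rankings feed the kinase enrichment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .matrix import ExpressionMatrix

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class RankedList:
    """Ordered site keys; rank 1 carries the strongest evidence for the direction."""

    direction: str  # "over" or "under"
    sites: tuple[str, ...]

    def __len__(self) -> int:
        return len(self.sites)

    def index(self) -> dict[str, int]:
        return {s: i for i, s in enumerate(self.sites)}


def welch_test(
    m: ExpressionMatrix,
    test_cond: str,
    ref_cond: str,
    min_per_group: int = 2,
) -> pd.DataFrame:
    """Two-sided Welch t-test of ``test_cond`` against ``ref_cond`` per site.

    Returns a DataFrame indexed by site key with columns mean_test,
    mean_ref, log2fc (= mean_test - mean_ref), t_stat, df, p_value and
    imputed_fraction.  Sites with fewer than ``min_per_group`` usable values
    in either group are dropped (count logged).
    """
    for cond in (test_cond, ref_cond):
        if cond not in m.conditions:
            raise ValueError(f"unknown condition {cond!r}")
    a = m.data[m.samples_of(test_cond)]
    b = m.data[m.samples_of(ref_cond)]
    return _welch_frame(m, a, b)


def one_vs_rest(
    m: ExpressionMatrix,
    target_cond: str,
    reference: str = "pooled",
) -> pd.DataFrame:
    """Welch test of one condition against the aggregate of all others.

    ``reference='pooled'`` pools every non-target replicate into one group,
    preserving the within-group variance Welch needs.
    ``reference='mean_of_means'`` first averages the replicates of each
    other condition and uses those per-condition means as the reference
    observations.
    """
    others = [c for c in m.conditions if c != target_cond]
    if target_cond not in m.conditions:
        raise ValueError(f"unknown condition {target_cond!r}")
    if not others:
        raise ValueError("one_vs_rest needs at least two conditions")
    a = m.data[m.samples_of(target_cond)]
    if reference == "pooled":
        ref_samples = [s for c in others for s in m.samples_of(c)]
        b = m.data[ref_samples]
    elif reference == "mean_of_means":
        b = pd.DataFrame(
            {c: m.data[m.samples_of(c)].mean(axis=1) for c in others}
        )
    else:
        raise ValueError(f"unknown reference mode {reference!r}")
    return _welch_frame(m, a, b)


def _welch_frame(
    m: ExpressionMatrix, a: pd.DataFrame, b: pd.DataFrame, min_per_group: int = 2
) -> pd.DataFrame:
    usable = (a.notna().sum(axis=1) >= min_per_group) & (
        b.notna().sum(axis=1) >= min_per_group
    )
    n_dropped = int((~usable).sum())
    if n_dropped:
        log.info("welch: dropped %d sites with <%d values per group",
                 n_dropped, min_per_group)
    a = a.loc[usable]
    b = b.loc[usable]

    with np.errstate(invalid="ignore", divide="ignore"):
        res = stats.ttest_ind(
            a.to_numpy(), b.to_numpy(), axis=1, equal_var=False, nan_policy="omit"
        )
    t = np.asarray(res.statistic, dtype=float)
    p = np.asarray(res.pvalue, dtype=float)
    df = np.asarray(res.df, dtype=float)
    mean_a = a.mean(axis=1).to_numpy()
    mean_b = b.mean(axis=1).to_numpy()
    fc = mean_a - mean_b
    # zero-variance groups with identical means: no evidence either way
    degenerate = ~np.isfinite(t) & (np.abs(fc) < 1e-12)
    t[degenerate] = 0.0
    p[degenerate] = 1.0

    imput = m.imputed_fraction().loc[usable.index[usable]]
    out = pd.DataFrame(
        {
            "mean_test": mean_a,
            "mean_ref": mean_b,
            "log2fc": fc,
            "t_stat": t,
            "df": df,
            "p_value": p,
            "imputed_fraction": imput.to_numpy(),
        },
        index=a.index,
    )
    return out


def rank_sites(diff: pd.DataFrame, direction: str) -> RankedList:
    """Order the site universe by signed evidence for one direction.

    The score is sign(log2fc) * (-log10 p): the ``over`` ranking sorts it
    descending, the ``under`` ranking ascending, so each direction places
    its strongest sites first while keeping the full universe (no cutoff).
    Ties break by |log2fc| descending, then site key, making the order
    deterministic and independent of input row order.
    """
    if direction not in ("over", "under"):
        raise ValueError(f"direction must be 'over' or 'under', got {direction!r}")
    if diff.empty:
        raise ValueError("empty differential table")
    p = diff["p_value"].to_numpy(dtype=float)
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    score = np.sign(diff["log2fc"].to_numpy()) * (-np.log10(p))
    frame = pd.DataFrame(
        {
            "site": diff.index.to_numpy(),
            "score": score,
            "absfc": diff["log2fc"].abs().to_numpy(),
        }
    )
    ascending = direction == "under"
    frame = frame.sort_values(
        by=["score", "absfc", "site"],
        ascending=[ascending, False, True],
        kind="mergesort",
    )
    return RankedList(direction=direction, sites=tuple(frame["site"]))
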