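"""Filtering, normalization, missingness classification and imputation.

The preprocessing chain for a phosphosite intensity matrix is:

    filter -> log2 -> quantile normalize -> drop under-quantified
           -> classify missingness -> impute

Missing values in label-free phosphoproteomics arise from two mechanisms.
Sporadic dropout of a single replicate within a condition is treated as
missing at random (MAR) and filled with the conditional expectation under a
multivariate normal model fitted by expectation-maximization.  Systematic
absence of two or more replicates is treated as missing not at random
(MNAR), i.e. left-censoring of low-abundance sites, and filled by the
MinProb rule: draws from a narrow Gaussian centred on a low quantile of the
sample's observed intensity distribution.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix, StageError

log = logging.getLogger(__name__)


def filter_sites(m: ExpressionMatrix, loc_prob_min: float = 0.75) -> ExpressionMatrix:
    """Remove contaminant/reverse rows and poorly localized sites.

    Sites with localization probability >= ``loc_prob_min`` are kept (the
    boundary value survives).
    """
    if m.stage != "raw":
        raise StageError(f"filter_sites expects stage raw, got {m.stage}")
    meta = m.row_meta
    keep = (
        ~meta["is_reverse"].astype(bool)
        & ~meta["is_contaminant"].astype(bool)
        & (meta["localization_prob"] >= loc_prob_min)
    )
    if not keep.any():
        raise ValueError("empty matrix after filtering")
    n_removed = int((~keep).sum())
    if n_removed:
        log.info("filter_sites: removed %d of %d sites", n_removed, len(keep))
    out = m.with_data(m.data.loc[keep])
    out.row_meta = meta.loc[keep]
    return out.advance("filtered")


def log2_transform(m: ExpressionMatrix) -> ExpressionMatrix:
    """log2-transform linear intensities; missing cells stay missing."""
    if m.scale != "linear":
        raise ValueError("matrix is already on the log2 scale")
    values = m.data.to_numpy()
    bad = np.nansum(values <= 0)
    if bad:
        raise ValueError(
            f"{int(bad)} non-missing intensities are <= 0; zeros must be read as missing"
        )
    return m.with_data(pd.DataFrame(np.log2(values), index=m.data.index,
                                    columns=m.data.columns), scale="log2")


def quantile_normalize(m: ExpressionMatrix) -> ExpressionMatrix:
    """Classic sort/row-mean/restore quantile normalization across samples.

    Missing cells are excluded from rank computation and remain missing.
    The reference distribution is the per-quantile mean of the sorted
    columns, linearly interpolated to a common grid so columns with unequal
    numbers of observed values share one reference; for complete data this
    reduces exactly to the textbook procedure.  Tied values receive the mean
    of their tied reference values.
    """
    if m.scale != "log2":
        raise ValueError("quantile normalization expects log2-scale values")
    X = m.data.to_numpy(dtype=float)
    n_rows, n_cols = X.shape
    if n_cols < 2:
        warnings.warn("single-sample matrix: quantile normalization skipped")
        return m.advance("normalized")

    grid = np.linspace(0.0, 1.0, n_rows)
    # reference quantile function: mean over columns of each column's
    # empirical quantile function evaluated on the common grid
    ref = np.zeros(n_rows)
    for j in range(n_cols):
        col = np.sort(X[~np.isnan(X[:, j]), j])
        if col.size < 1:
            raise ValueError(f"sample {m.data.columns[j]!r} has no observed values")
        pos = np.linspace(0.0, 1.0, col.size)
        ref += np.interp(grid, pos, col)
    ref /= n_cols

    out = np.full_like(X, np.nan)
    for j in range(n_cols):
        obs = ~np.isnan(X[:, j])
        col = X[obs, j]
        # average ranks over ties => tied cells get the mean of their
        # tied reference values, deterministically
        ranks = pd.Series(col).rank(method="average").to_numpy() - 1.0
        pos = ranks / max(col.size - 1, 1)
        out[obs, j] = np.interp(pos, grid, ref)

    data = pd.DataFrame(out, index=m.data.index, columns=m.data.columns)
    return m.with_data(data).advance("normalized")


def classify_missingness(m: ExpressionMatrix) -> pd.DataFrame:
    """Label every (site, condition) as complete, MAR or MNAR.

    With r of n replicates observed: ``complete`` if none missing, ``MAR``
    if exactly one replicate is missing, ``MNAR`` if two or more are
    missing (for triplicates: 2 or 3 missing).
    """
    labels = {}
    for cond in m.conditions:
        cols = m.samples_of(cond)
        if len(cols) < 2:
            raise ValueError(f"condition {cond!r} has fewer than 2 replicates")
        n_missing = m.data[cols].isna().sum(axis=1)
        lab = pd.Series("complete", index=m.data.index)
        lab[n_missing == 1] = "MAR"
        lab[n_missing >= 2] = "MNAR"
        labels[cond] = lab
    return pd.DataFrame(labels)


def drop_underquantified(m: ExpressionMatrix) -> ExpressionMatrix:
    """Drop sites with at most one observed value across all samples."""
    keep = m.data.notna().sum(axis=1) >= 2
    n_removed = int((~keep).sum())
    if n_removed:
        log.info("drop_underquantified: removed %d sites", n_removed)
    out = m.with_data(m.data.loc[keep])
    out.row_meta = m.row_meta.loc[keep]
    return out


def impute(
    m: ExpressionMatrix,
    labels: pd.DataFrame | None = None,
    mode: str = "impute",
    seed: int | None = None,
    minprob_q: float = 0.01,
    minprob_sigma_scale: float = 0.3,
) -> ExpressionMatrix:
    """Fill missing cells according to their missingness mechanism.

    mode ``impute``
        MAR cells get their conditional expectation under a multivariate
        normal over the condition's replicates, fitted by EM; MNAR cells are
        drawn from Normal(q, sigma) with q the ``minprob_q``-quantile of the
        sample's observed values and sigma = ``minprob_sigma_scale`` times
        the sample's observed standard deviation (MinProb).
    mode ``zero``
        MNAR cells are set to 0, giving extra weight to sites present in
        only one condition; MAR cells are still filled by EM.

    Observed cells are never altered.  Fully reproducible for a fixed seed.
    """
    if m.stage != "normalized":
        raise StageError(f"impute expects stage normalized, got {m.stage}")
    if mode not in ("impute", "zero"):
        raise ValueError(f"unknown imputation mode {mode!r}")
    if labels is None:
        labels = classify_missingness(m)
    if mode == "impute" and seed is None:
        raise ValueError("a seed is required for MinProb draws")
    rng = np.random.default_rng(seed)

    X = m.data.to_numpy(dtype=float).copy()
    cols = list(m.data.columns)
    col_idx = {s: i for i, s in enumerate(cols)}

    # per-sample MinProb parameters from observed values
    q_low = np.empty(len(cols))
    sigma = np.empty(len(cols))
    for j in range(len(cols)):
        obs = X[~np.isnan(X[:, j]), j]
        if obs.size < 2:
            raise ValueError(f"sample {cols[j]!r} has fewer than 2 observed values")
        q_low[j] = np.quantile(obs, minprob_q)
        sigma[j] = minprob_sigma_scale * obs.std(ddof=1)

    for cond in labels.columns:
        cond_samples = m.samples_of(cond)
        jdx = np.array([col_idx[s] for s in cond_samples])
        sub = X[:, jdx]
        lab = labels[cond].to_numpy()

        # MNAR: left-censored draws (or zero), independently per cell
        mnar_rows = np.flatnonzero(lab == "MNAR")
        for i in mnar_rows:
            for j_local, j in enumerate(jdx):
                if np.isnan(sub[i, j_local]):
                    if mode == "zero":
                        X[i, j] = 0.0
                    else:
                        X[i, j] = rng.normal(q_low[j], sigma[j])

        # MAR: EM conditional expectation over the condition's replicates
        mar_rows = np.flatnonzero(lab == "MAR")
        if mar_rows.size:
            complete_rows = np.flatnonzero(lab == "complete")
            fit_rows = np.concatenate([complete_rows, mar_rows])
            mu, cov = _em_mvnorm(sub[fit_rows])
            for i in mar_rows:
                row = sub[i]
                miss = np.isnan(row)
                obs = ~miss
                cov_oo = cov[np.ix_(obs, obs)]
                cov_mo = cov[np.ix_(miss, obs)]
                sol = np.linalg.solve(
                    cov_oo + 1e-10 * np.eye(obs.sum()), row[obs] - mu[obs]
                )
                fill = mu[miss] + cov_mo @ sol
                X[i, jdx[miss]] = fill

    data = pd.DataFrame(X, index=m.data.index, columns=m.data.columns)
    return m.with_data(data).advance("imputed")


def _em_mvnorm(
    X: np.ndarray, max_iter: int = 100, tol: float = 1e-6
) -> tuple[np.ndarray, np.ndarray]:
    """ML fit of a multivariate normal to rows with missing entries, by EM.

    Convergence is declared when the observed-data log-likelihood improves
    by less than ``tol``.  Returns (mean, covariance).
    """
    n, d = X.shape
    miss = np.isnan(X)
    # moment initialisation from observed margins
    mu = np.nanmean(X, axis=0)
    centered = np.where(miss, 0.0, X - mu)
    counts = (~miss).astype(float).T @ (~miss).astype(float)
    cov = (centered.T @ centered) / np.maximum(counts, 1.0)
    cov += 1e-8 * np.eye(d)

    prev_ll = -np.inf
    for _ in range(max_iter):
        Xhat = X.copy()
        corr = np.zeros((d, d))
        ll = 0.0
        for i in range(n):
            mi = miss[i]
            if not mi.any():
                obs = ~mi
            else:
                obs = ~mi
                cov_oo = cov[np.ix_(obs, obs)]
                cov_mo = cov[np.ix_(mi, obs)]
                sol = np.linalg.solve(cov_oo + 1e-10 * np.eye(obs.sum()),
                                      (X[i, obs] - mu[obs]))
                Xhat[i, mi] = mu[mi] + cov_mo @ sol
                corr[np.ix_(mi, mi)] += (
                    cov[np.ix_(mi, mi)]
                    - cov_mo @ np.linalg.solve(
                        cov_oo + 1e-10 * np.eye(obs.sum()), cov_mo.T
                    )
                )
            # observed-data log-likelihood contribution
            o = np.flatnonzero(obs)
            cov_oo = cov[np.ix_(o, o)] + 1e-10 * np.eye(o.size)
            diff = X[i, o] - mu[o]
            sign, logdet = np.linalg.slogdet(cov_oo)
            ll -= 0.5 * (
                o.size * np.log(2 * np.pi) + logdet
                + diff @ np.linalg.solve(cov_oo, diff)
            )
        mu = Xhat.mean(axis=0)
        diffs = Xhat - mu
        cov = (diffs.T @ diffs + corr) / n + 1e-8 * np.eye(d)
        if abs(ll - prev_ll) < tol:
            break
        prev_ll = ll
    return mu, cov


def preprocess_matrix(
    m: ExpressionMatrix,
    loc_prob_min: float = 0.75,
    impute_mode: str = "impute",
    seed: int | None = None,
    minprob_q: float = 0.01,
    minprob_sigma_scale: float = 0.3,
) -> ExpressionMatrix:
    """Run the full chain: filter, log2, quantile-normalize, drop, impute."""
    m = filter_sites(m, loc_prob_min=loc_prob_min)
    m = log2_transform(m)
    m = quantile_normalize(m)
    m = drop_underquantified(m)
    labels = classify_missingness(m)
    return impute(
        m, labels, mode=impute_mode, seed=seed,
        minprob_q=minprob_q, minprob_sigma_scale=minprob_sigma_scale,
    )
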