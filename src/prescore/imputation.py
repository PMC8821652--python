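"""Multiple imputation by chained equations with predictive mean matching.

Each incomplete variable is regressed (OLS) on all other variables using
the current completions; a missing entry is filled with the observed
value of a donor chosen at random among the ``k`` observed cases whose
regression-predicted means are closest to the missing case's predicted
mean.  Sweeps repeat ``n_iter`` times in order of ascending missingness,
and the whole procedure runs ``m`` times on independent RNG streams to
yield ``m`` completed datasets.

UACR is imputed on the log scale, consistent with how it enters the Cox
model, and back-transformed afterwards.
"""

from __future__ import annotations

import zlib

import numpy as np
import pandas as pd

from .config import ImputationConfig

LOG_COLUMNS_PREFIX = "uacr"


def _pmm_fill(
    y: np.ndarray,
    X: np.ndarray,
    obs: np.ndarray,
    mis: np.ndarray,
    k: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """One PMM step: regress y[obs] on X[obs], match predicted means."""
    A = np.column_stack([np.ones(obs.sum()), X[obs]])
    coef, *_ = np.linalg.lstsq(A, y[obs], rcond=None)
    pred_obs = A @ coef
    pred_mis = np.column_stack([np.ones(mis.sum()), X[mis]]) @ coef
    y_obs = y[obs]
    filled = np.empty(mis.sum())
    order = np.argsort(pred_obs, kind="stable")
    sorted_pred = pred_obs[order]
    for i, pm in enumerate(pred_mis):
        pos = np.searchsorted(sorted_pred, pm)
        lo = max(0, pos - k)
        hi = min(len(sorted_pred), pos + k)
        window = order[lo:hi]
        dist = np.abs(pred_obs[window] - pm)
        donors = window[np.argsort(dist, kind="stable")[:k]]
        filled[i] = y_obs[rng.choice(donors)]
    return filled


def impute_pmm(
    table: pd.DataFrame,
    config: ImputationConfig,
    columns: list[str] | None = None,
) -> list[pd.DataFrame]:
    """Return ``m`` completed copies of ``table``.

    Parameters
    ----------
    table :
        Cohort table; blanks (NaN) only in numeric marker columns.
    config :
        ``m`` datasets, ``k`` donors, ``n_iter`` chained sweeps, seed.
    columns :
        Numeric columns participating in the imputation model.  Defaults
        to every numeric column with at least one blank plus every fully
        observed numeric marker column (``*_base``/``*_m6``/``egfr_base``
        /``age``).
    """
    if columns is None:
        numeric = [
            c for c in table.columns
            if c == "age" or c.endswith(("_base", "_m6"))
        ]
    else:
        numeric = list(columns)

    work = table[numeric].copy()
    # model skewed albuminuria on the log scale
    log_cols = [c for c in numeric if c.startswith(LOG_COLUMNS_PREFIX)]
    for c in log_cols:
        work[c] = np.log(work[c])

    incomplete = [c for c in numeric if work[c].isna().any()]
    if not incomplete:
        return [table.copy() for _ in range(config.m)]
    fully_observed = [c for c in numeric if not work[c].isna().any()]
    if not fully_observed:
        raise ValueError("need at least one fully observed numeric variable")
    for c in incomplete:
        n_obs = int(work[c].notna().sum())
        if n_obs == 0:
            raise ValueError(f"column {c!r} has no observed values")
        if n_obs < config.k:
            raise ValueError(
                f"column {c!r} has {n_obs} observed values, fewer than k={config.k}"
            )
    # visit order: ascending missingness
    incomplete.sort(key=lambda c: (work[c].isna().sum(), c))

    masks = {c: work[c].isna().to_numpy() for c in incomplete}
    results = []
    for rep in range(config.m):
        rng = np.random.default_rng(
            [config.seed & 0x7FFFFFFF, zlib.crc32(b"pmm"), rep]
        )
        cur = work.copy()
        # initialize blanks with random draws from the observed marginals
        for c in incomplete:
            obs_vals = cur[c].dropna().to_numpy()
            cur.loc[masks[c], c] = rng.choice(obs_vals, size=masks[c].sum(), replace=True)
        for _ in range(config.n_iter):
            for c in incomplete:
                others = [o for o in numeric if o != c]
                y = cur[c].to_numpy(dtype=float)
                X = cur[others].to_numpy(dtype=float)
                mis = masks[c]
                obs = ~mis
                y[mis] = _pmm_fill(y, X, obs, mis, config.k, rng)
                cur[c] = y
        out = table.copy()
        for c in numeric:
            vals = cur[c].to_numpy(dtype=float)
            out[c] = np.exp(vals) if c in log_cols else vals
        results.append(out)
    return results


def pool_estimates(
    estimates: np.ndarray | list[float],
    variances: np.ndarray | list[float],
) -> tuple[float, float]:
    """Combine per-dataset estimates with Rubin's rules.

    Returns ``(pooled estimate, total variance)`` where total variance =
    mean within-imputation variance + (1 + 1/m) * between-imputation
    variance.
    """
    est = np.asarray(estimates, dtype=float)
    var = np.asarray(variances, dtype=float)
    if est.shape != var.shape:
        raise ValueError("estimates and variances must have equal length")
    m = est.shape[0]
    if m < 2:
        raise ValueError("pooling requires m >= 2 imputed datasets")
    qbar = est.mean()
    within = var.mean()
    between = est.var(ddof=1)
    total = within + (1.0 + 1.0 / m) * between
    return float(qbar), float(total)
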