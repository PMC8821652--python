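"""Responder-enrichment simulations.

A *responder* is a treated patient whose six-month marker change is an
improvement at least as large as the treated-arm median change (ties at
the median count as responders).  Shifting the responder proportion and
re-scoring maps how the predicted RRR depends on the response
distribution of a single marker, and the inverse query finds the mean
placebo-corrected effect needed to reach a target RRR.

UACR changes are handled on the log scale; its required effect is
reported as a percent change on the natural scale.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import ScoreConfig
from .score import compute_pre_rrr
from .survival import RiskModel


def _changes(trial: pd.DataFrame, marker: str, log_scale: bool) -> pd.Series:
    base = trial[f"{marker}_base"]
    m6 = trial[f"{marker}_m6"]
    if log_scale:
        return np.log(m6) - np.log(base)
    return m6 - base


def responder_threshold(
    trial: pd.DataFrame, marker: str, harm_direction: int = 1, log_scale: bool = False
) -> float:
    """Median treated-arm change; the cut that defines a responder.

    A responder has ``harm_direction * change <= harm_direction * threshold``
    — i.e. an improvement of at least the median magnitude, with ties at
    the median included.
    """
    treated = trial[trial["arm"] == "treated"]
    if treated.empty:
        raise ValueError("treated arm is empty")
    return float(_changes(treated, marker, log_scale).median())


def _responder_mask(
    changes: np.ndarray, threshold: float, harm_direction: int
) -> np.ndarray:
    return harm_direction * changes <= harm_direction * threshold + 1e-12


def shift_responders(
    trial: pd.DataFrame,
    marker: str,
    proportion: float,
    seed: int = 0,
    harm_direction: int = 1,
    log_scale: bool = False,
    mode: str = "bootstrap",
) -> pd.DataFrame:
    """Re-draw treated-arm changes to a target responder proportion.

    ``mode='bootstrap'`` (default) resamples each treated patient's
    change from the empirical responder stratum with probability
    ``proportion`` and from the non-responder stratum otherwise; the
    placebo arm is untouched.  ``mode='location_shift'`` instead shifts
    the whole treated change distribution until the responder fraction
    matches (a parametric alternative).
    """
    if not 0 <= proportion <= 1:
        raise ValueError("proportion must be in [0, 1]")
    treated_mask = (trial["arm"] == "treated").to_numpy()
    if not treated_mask.any():
        raise ValueError("treated arm is empty")
    changes = _changes(trial[treated_mask], marker, log_scale).to_numpy()
    thr = responder_threshold(trial, marker, harm_direction, log_scale)
    resp = _responder_mask(changes, thr, harm_direction)
    rng = np.random.default_rng(
        [seed & 0x7FFFFFFF, zlib.crc32(f"shift-{marker}".encode())]
    )
    n_t = treated_mask.sum()

    if mode == "bootstrap":
        resp_pool = changes[resp]
        nonresp_pool = changes[~resp]
        if proportion > 0 and resp_pool.size == 0:
            raise ValueError("responder stratum is empty")
        if nonresp_pool.size == 0:
            # degenerate: the inclusive median rule made everyone a
            # responder (e.g. constant changes); any resample is a
            # responder draw
            nonresp_pool = resp_pool
        if proportion < 1 and nonresp_pool.size == 0:
            raise ValueError("non-responder stratum is empty")
        pick_resp = rng.random(n_t) < proportion
        new_changes = np.where(
            pick_resp,
            rng.choice(resp_pool, size=n_t, replace=True) if resp_pool.size else 0.0,
            rng.choice(nonresp_pool, size=n_t, replace=True),
        )
    elif mode == "location_shift":
        # find the additive shift that achieves the target responder fraction
        signed = harm_direction * (changes - thr)
        order = np.sort(signed)
        q = np.quantile(order, proportion) if 0 < proportion < 1 else (
            order[-1] + 1e-9 if proportion == 1 else order[0] - 1e-9
        )
        new_changes = changes - harm_direction * q
    else:
        raise ValueError(f"unknown mode {mode!r}")

    out = trial.copy()
    base = out.loc[treated_mask, f"{marker}_base"].to_numpy(dtype=float)
    if log_scale:
        out.loc[treated_mask, f"{marker}_m6"] = np.exp(np.log(base) + new_changes)
    else:
        out.loc[treated_mask, f"{marker}_m6"] = base + new_changes
    return out


@dataclass
class EnrichmentCurve:
    """Predicted RRR as a function of the responder proportion."""

    marker: str
    threshold: float
    proportions: np.ndarray
    rrr: np.ndarray
    seed: int
    baseline_fraction: float = float("nan")
    extra: dict = field(default_factory=dict)

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "marker": self.marker,
            "proportion": self.proportions,
            "rrr": self.rrr,
        })


def _marker_props(model: RiskModel, marker: str) -> tuple[int, bool]:
    harm = model.harm_directions.get(marker, 1)
    log_scale = marker in model.log_markers
    return harm, log_scale


def enrichment_curve(
    model: RiskModel,
    trial: pd.DataFrame,
    markers: list[str],
    grid: np.ndarray | list[float],
    config: ScoreConfig | None = None,
    mode: str = "bootstrap",
) -> dict[str, EnrichmentCurve]:
    """One RRR-vs-responder-proportion curve per marker."""
    config = config or ScoreConfig()
    grid = np.asarray(sorted(grid), dtype=float)
    if grid.size == 0:
        raise ValueError("empty proportion grid")
    unknown = [m for m in markers if m not in model.markers]
    if unknown:
        raise KeyError(f"marker(s) not in model: {', '.join(unknown)}")
    curves = {}
    for marker in markers:
        harm, log_scale = _marker_props(model, marker)
        thr = responder_threshold(trial, marker, harm, log_scale)
        treated = trial[trial["arm"] == "treated"]
        observed = _responder_mask(
            _changes(treated, marker, log_scale).to_numpy(), thr, harm
        ).mean()
        rrrs = np.empty(grid.size)
        for i, p in enumerate(grid):
            shifted = shift_responders(
                trial, marker, float(p), seed=config.seed + i,
                harm_direction=harm, log_scale=log_scale, mode=mode,
            )
            rrrs[i] = compute_pre_rrr(model, shifted, config).rrr
        curves[marker] = EnrichmentCurve(
            marker=marker,
            threshold=thr,
            proportions=grid,
            rrr=rrrs,
            seed=config.seed,
            baseline_fraction=float(observed),
        )
    return curves


def _apply_uniform_shift(
    trial: pd.DataFrame, marker: str, delta: float, log_scale: bool
) -> pd.DataFrame:
    """Add a uniform change to the treated arm's month-6 marker."""
    out = trial.copy()
    treated = (out["arm"] == "treated").to_numpy()
    m6 = out.loc[treated, f"{marker}_m6"].to_numpy(dtype=float)
    if log_scale:
        out.loc[treated, f"{marker}_m6"] = np.exp(np.log(m6) + delta)
    else:
        out.loc[treated, f"{marker}_m6"] = m6 + delta
    return out


def required_effect(
    model: RiskModel,
    trial: pd.DataFrame,
    marker: str,
    target_rrr: float,
    config: ScoreConfig | None = None,
    tol: float = 0.1,
    max_abs_shift: float = 4.0,
) -> float:
    """Mean treated-arm shift needed (on top of observed changes,
    relative to the current mean effect) for the predicted RRR to reach
    ``target_rrr``.

    The returned value is the total mean placebo-corrected effect:
    additive in the marker's unit, or for UACR a percent change on the
    natural scale (negative = reduction).  Solved by bisection over
    uniform treated-arm shifts to within ``tol`` percentage points of
    RRR.
    """
    if marker not in model.markers:
        raise KeyError(f"marker {marker!r} not in model")
    config = config or ScoreConfig()
    harm, log_scale = _marker_props(model, marker)

    # current mean placebo-corrected effect on the working scale
    eff_t = _changes(trial[trial["arm"] == "treated"], marker, log_scale).mean()
    eff_p = _changes(trial[trial["arm"] == "placebo"], marker, log_scale).mean()
    current = float(eff_t - eff_p)

    def rrr_at(extra: float) -> float:
        shifted = _apply_uniform_shift(trial, marker, extra, log_scale)
        return compute_pre_rrr(model, shifted, config).rrr

    # benefit direction: improving shift is -harm on the working scale
    span = max_abs_shift
    lo, hi = -harm * span, harm * span  # hi = harmful direction
    r_best, r_worst = rrr_at(lo), rrr_at(hi)
    r_min, r_max = min(r_best, r_worst), max(r_best, r_worst)
    if not r_min - tol <= target_rrr <= r_max + tol:
        raise ValueError(
            f"target RRR {target_rrr:.1f}% unreachable; achievable range "
            f"[{r_min:.1f}, {r_max:.1f}]% within +-{span} shift"
        )
    a, b = lo, hi  # rrr_at(a) >= rrr_at(b) if benefit at a
    if r_best < r_worst:
        a, b = b, a
    for _ in range(60):
        mid = 0.5 * (a + b)
        r = rrr_at(mid)
        if abs(r - target_rrr) <= tol:
            break
        if r > target_rrr:
            a = mid
        else:
            b = mid
    else:
        mid = 0.5 * (a + b)

    total = current + mid
    if log_scale:
        return 100.0 * (np.exp(total) - 1.0)  # percent change, natural scale
    return total
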