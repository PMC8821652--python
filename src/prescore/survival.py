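"""Cox proportional hazards fitting and absolute-risk prediction.

The risk model is ``h(t) = h0(t) * exp(beta . x)`` fitted by maximizing
the Cox partial likelihood (Efron tie correction by default, Breslow
selectable) with Newton iterations and step-halving.  Covariates are
mean-centered before fitting and the centering means are stored, so
predictions are invariant to that choice.  Absolute risk at a horizon T
is ``1 - S0(T)^exp(lp)`` with ``lp = beta . (x - means)`` and ``S0`` the
Breslow-type baseline survival at the centering means.

UACR enters the model on the natural-log scale; all other markers enter
untransformed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: markers entered on the log scale
LOG_MARKERS = ("uacr",)


def transform_markers(
    raw: pd.DataFrame, log_markers: tuple[str, ...] = LOG_MARKERS
) -> pd.DataFrame:
    """Map raw marker values to the modelling scale.

    Columns named in ``log_markers`` (UACR by default) are replaced by
    their natural log; everything else passes through unchanged.
    Non-positive values in a log column raise, identifying the offending
    record(s).
    """
    out = raw.copy()
    for col in log_markers:
        if col not in out.columns:
            continue
        v = out[col].to_numpy(dtype=float)
        bad = np.where(v <= 0)[0]
        if bad.size:
            raise ValueError(
                f"non-positive {col} at row(s) {bad[:10].tolist()}; "
                "log transform requires strictly positive values"
            )
        out[col] = np.log(v)
    return out


@dataclass
class SurvivalDataset:
    """Covariates on the modelling scale plus one endpoint's follow-up."""

    X: pd.DataFrame
    time: np.ndarray
    event: np.ndarray

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event, dtype=int)
        if len(self.X) != len(self.time) or len(self.time) != len(self.event):
            raise ValueError("X, time and event must have equal length")
        if np.any(self.time <= 0):
            raise ValueError("follow-up times must be > 0")
        if not np.isin(self.event, (0, 1)).all():
            raise ValueError("event indicators must be 0/1")
        if self.X.isna().any().any():
            raise ValueError("covariates must be complete at fit time")

    @property
    def covariates(self) -> list[str]:
        return list(self.X.columns)

    @classmethod
    def from_table(
        cls,
        table: pd.DataFrame,
        endpoint: str,
        markers: list[str],
        suffix: str = "_base",
        log_markers: tuple[str, ...] = LOG_MARKERS,
    ) -> "SurvivalDataset":
        """Build a dataset from a cohort table (``<marker><suffix>``,
        ``time_<endpoint>``, ``event_<endpoint>`` columns)."""
        raw = table[[f"{m}{suffix}" for m in markers]].copy()
        raw.columns = markers
        X = transform_markers(raw, log_markers)
        return cls(
            X=X,
            time=table[f"time_{endpoint}"].to_numpy(),
            event=table[f"event_{endpoint}"].to_numpy(),
        )


# ---------------------------------------------------------------------------
# Partial likelihood
# ---------------------------------------------------------------------------

def _partial_likelihood_parts(
    beta: np.ndarray, X: np.ndarray, time: np.ndarray, event: np.ndarray, ties: str
) -> tuple[float, np.ndarray, np.ndarray]:
    """Log partial likelihood, gradient and (negative) Hessian.

    Risk-set sums S0 = sum w, S1 = sum w*x, S2 = sum w*x x' are built as
    suffix sums over distinct-time blocks; only blocks containing events
    contribute terms, with Breslow or Efron handling of ties.
    """
    n, p = X.shape
    order = np.argsort(time, kind="stable")
    Xs, ts, es = X[order], time[order], event[order]
    eta = Xs @ beta
    w = np.exp(eta)

    starts = np.flatnonzero(np.r_[True, ts[1:] != ts[:-1]])
    wX = Xs * w[:, None]
    wXX = wX[:, :, None] * Xs[:, None, :]
    # suffix (risk-set) sums per distinct time
    S0 = np.cumsum(np.add.reduceat(w, starts)[::-1])[::-1]
    S1 = np.cumsum(np.add.reduceat(wX, starts, axis=0)[::-1], axis=0)[::-1]
    S2 = np.cumsum(np.add.reduceat(wXX, starts, axis=0)[::-1], axis=0)[::-1]
    # event-only sums per distinct time
    ev = es == 1
    d_blk = np.add.reduceat(ev.astype(int), starts)
    S0d = np.add.reduceat(np.where(ev, w, 0.0), starts)
    S1d = np.add.reduceat(np.where(ev[:, None], wX, 0.0), starts, axis=0)
    S2d = np.add.reduceat(np.where(ev[:, None, None], wXX, 0.0), starts, axis=0)
    eta_d = np.add.reduceat(np.where(ev, eta, 0.0), starts)
    Xd_sum = np.add.reduceat(np.where(ev[:, None], Xs, 0.0), starts, axis=0)

    ll = 0.0
    grad = np.zeros(p)
    info = np.zeros((p, p))
    for b in np.flatnonzero(d_blk):
        d = int(d_blk[b])
        ll += eta_d[b]
        grad += Xd_sum[b]
        if ties == "breslow" or d == 1:
            xbar = S1[b] / S0[b]
            ll -= d * np.log(S0[b])
            grad -= d * xbar
            info += d * (S2[b] / S0[b] - np.outer(xbar, xbar))
        else:  # efron
            for l in range(d):
                f = l / d
                den = S0[b] - f * S0d[b]
                num1 = S1[b] - f * S1d[b]
                num2 = S2[b] - f * S2d[b]
                xbar = num1 / den
                ll -= np.log(den)
                grad -= xbar
                info += num2 / den - np.outer(xbar, xbar)
    return ll, grad, info


@dataclass
class CoxFit:
    """Fitted Cox model: coefficients, uncertainty and fit metadata."""

    beta: pd.Series
    se: pd.Series
    covariance: pd.DataFrame
    log_likelihood: float
    ties: str
    centering_means: pd.Series
    n: int
    n_events: int

    def __post_init__(self) -> None:
        if (self.se <= 0).any():
            raise ValueError("standard errors must be positive")

    @property
    def covariates(self) -> list[str]:
        return list(self.beta.index)


def fit_cox(data: SurvivalDataset, ties: str = "efron") -> CoxFit:
    """Maximize the Cox partial likelihood by Newton iteration.

    Covariates are mean-centered first.  Step-halving guards each Newton
    step; convergence requires a coefficient change below 1e-9 within
    100 iterations and a gradient norm below 1e-8 at the optimum.
    Standard errors come from the inverse observed information.
    """
    if ties not in ("efron", "breslow"):
        raise ValueError(f"unknown ties method {ties!r}")
    n_events = int(data.event.sum())
    if n_events == 0:
        raise ValueError("no events in dataset; cannot fit Cox model")
    if n_events < 2:
        raise ValueError("at least 2 events are required")

    means = data.X.mean()
    Xc = (data.X - means).to_numpy(dtype=float)
    sd = Xc.std(axis=0)
    if np.any(sd < 1e-12):
        dead = [c for c, s in zip(data.covariates, sd) if s < 1e-12]
        raise ValueError(f"constant covariate(s): {', '.join(dead)}")
    # fit on the standardized scale for conditioning; back-transform after
    Xz = Xc / sd
    p = Xz.shape[1]
    beta = np.zeros(p)
    ll, grad, info = _partial_likelihood_parts(beta, Xz, data.time, data.event, ties)
    for _ in range(100):
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError as exc:
            raise ValueError("singular information matrix (collinear covariates?)") from exc
        # step-halving: insist on non-decreasing partial likelihood
        scale = 1.0
        for _ in range(40):
            cand = beta + scale * step
            ll_new, grad_new, info_new = _partial_likelihood_parts(
                cand, Xz, data.time, data.event, ties
            )
            if np.isfinite(ll_new) and ll_new >= ll - 1e-12:
                break
            scale *= 0.5
        else:
            raise ValueError("step-halving failed; likelihood may be monotone")
        delta = np.max(np.abs(cand - beta))
        beta, ll, grad, info = cand, ll_new, grad_new, info_new
        if np.max(np.abs(beta)) > 80:
            raise ValueError(
                "diverging coefficients: monotone partial likelihood "
                "(perfect separation of events by a covariate?)"
            )
        if delta < 1e-9:
            break
    else:
        raise ValueError("Newton iteration did not converge in 100 steps")
    if np.linalg.norm(grad) > 1e-8 * max(1.0, abs(ll)):
        raise ValueError(f"gradient norm {np.linalg.norm(grad):.3g} too large at optimum")

    cov_z = np.linalg.inv(info)
    # undo standardization
    beta_nat = beta / sd
    cov_nat = cov_z / np.outer(sd, sd)
    se_nat = np.sqrt(np.diag(cov_nat))
    cols = data.covariates
    return CoxFit(
        beta=pd.Series(beta_nat, index=cols),
        se=pd.Series(se_nat, index=cols),
        covariance=pd.DataFrame(cov_nat, index=cols, columns=cols),
        log_likelihood=float(ll),
        ties=ties,
        centering_means=means,
        n=len(data.X),
        n_events=n_events,
    )


# ---------------------------------------------------------------------------
# Baseline survival and risk prediction
# ---------------------------------------------------------------------------

@dataclass
class StepSurvival:
    """Right-continuous baseline survival step function S0(t).

    ``knots`` are event times in ascending order, ``values`` the survival
    just after each knot; S0(0) = 1.  Evaluation beyond ``t_max`` (the
    largest observed time, censored or not) raises — no extrapolation.
    """

    knots: np.ndarray
    values: np.ndarray
    t_max: float

    def __post_init__(self) -> None:
        self.knots = np.asarray(self.knots, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if np.any(np.diff(self.knots) <= 0):
            raise ValueError("knots must be strictly increasing")
        if np.any(np.diff(self.values) > 1e-12):
            raise ValueError("survival values must be non-increasing")
        if np.any((self.values <= 0) | (self.values > 1)):
            raise ValueError("survival values must lie in (0, 1]")

    def __call__(self, t) -> np.ndarray | float:
        t_arr = np.atleast_1d(np.asarray(t, dtype=float))
        if np.any(t_arr < 0):
            raise ValueError("negative time")
        if np.any(t_arr > self.t_max + 1e-12):
            raise ValueError(
                f"time beyond last observed follow-up ({self.t_max:.4g}); no extrapolation"
            )
        idx = np.searchsorted(self.knots, t_arr, side="right")
        vals = np.concatenate([[1.0], self.values])[idx]
        return vals if np.ndim(t) else float(vals[0])


def baseline_survival(fit: CoxFit, data: SurvivalDataset) -> StepSurvival:
    """Breslow baseline cumulative hazard at the centering means.

    ``H0(t) = sum_{t_k <= t} d_k / sum_{i in R(t_k)} exp(lp_i)`` with
    centered linear predictors, and ``S0(t) = exp(-H0(t))``.
    """
    Xc = (data.X[fit.covariates] - fit.centering_means).to_numpy(dtype=float)
    w = np.exp(Xc @ fit.beta.to_numpy())
    time, event = data.time, data.event
    order = np.argsort(time, kind="stable")
    ts, es, ws = time[order], event[order], w[order]
    # suffix sums: risk set of t = all with time >= t
    rev_cum = np.cumsum(ws[::-1])[::-1]
    event_times = []
    h_increments = []
    i = 0
    n = len(ts)
    while i < n:
        j = i
        while j < n and ts[j] == ts[i]:
            j += 1
        d = int(es[i:j].sum())
        if d > 0:
            event_times.append(ts[i])
            h_increments.append(d / rev_cum[i])
        i = j
    H0 = np.cumsum(h_increments)
    return StepSurvival(
        knots=np.asarray(event_times),
        values=np.exp(-H0),
        t_max=float(ts.max()),
    )


@dataclass
class RiskModel:
    """Everything needed to predict absolute risk at a horizon."""

    fit: CoxFit
    s0: StepSurvival
    horizon: float
    log_markers: tuple[str, ...] = LOG_MARKERS
    endpoint: str = ""
    harm_directions: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0 < self.horizon <= self.s0.t_max + 1e-12:
            raise ValueError(
                f"horizon {self.horizon} outside observed follow-up (0, {self.s0.t_max:.4g}]"
            )

    @property
    def markers(self) -> list[str]:
        return self.fit.covariates

    def linear_predictor(self, raw_markers: pd.DataFrame) -> np.ndarray:
        missing = [m for m in self.markers if m not in raw_markers.columns]
        if missing:
            raise KeyError(f"marker vector missing model covariate(s): {', '.join(missing)}")
        X = transform_markers(raw_markers[self.markers], self.log_markers)
        Xc = (X - self.fit.centering_means).to_numpy(dtype=float)
        return Xc @ self.fit.beta.to_numpy()

    def predict_risk(
        self,
        raw_markers: pd.DataFrame,
        horizon: float | None = None,
        beta_override: np.ndarray | None = None,
    ) -> np.ndarray:
        """Absolute event risk by the horizon: ``1 - S0(T)^exp(lp)``."""
        T = self.horizon if horizon is None else horizon
        s0_T = self.s0(T)
        if beta_override is None:
            lp = self.linear_predictor(raw_markers)
        else:
            X = transform_markers(raw_markers[self.markers], self.log_markers)
            Xc = (X - self.fit.centering_means).to_numpy(dtype=float)
            lp = Xc @ np.asarray(beta_override, dtype=float)
        return 1.0 - np.power(s0_T, np.exp(lp))


def fit_risk_model(
    table: pd.DataFrame,
    endpoint: str,
    markers: list[str],
    ties: str = "efron",
    horizon: float | None = None,
    harm_directions: dict[str, int] | None = None,
) -> RiskModel:
    """Fit a Cox model on a background cohort table and package it.

    The risk horizon defaults to the cohort's median follow-up.
    """
    data = SurvivalDataset.from_table(table, endpoint, markers)
    fit = fit_cox(data, ties=ties)
    s0 = baseline_survival(fit, data)
    if horizon is None:
        horizon = float(np.median(data.time))
    return RiskModel(
        fit=fit,
        s0=s0,
        horizon=horizon,
        endpoint=endpoint,
        harm_directions=harm_directions or {},
    )


# ---------------------------------------------------------------------------
# Serialization (bit-exact round trip through JSON)
# ---------------------------------------------------------------------------

def save_model(model: RiskModel, path) -> None:
    doc = {
        "endpoint": model.endpoint,
        "markers": model.markers,
        "beta": model.fit.beta.tolist(),
        "se": model.fit.se.tolist(),
        "covariance": model.fit.covariance.to_numpy().tolist(),
        "log_likelihood": model.fit.log_likelihood,
        "ties": model.fit.ties,
        "centering_means": model.fit.centering_means.tolist(),
        "n": model.fit.n,
        "n_events": model.fit.n_events,
        "s0_knots": model.s0.knots.tolist(),
        "s0_values": model.s0.values.tolist(),
        "s0_t_max": model.s0.t_max,
        "horizon": model.horizon,
        "log_markers": list(model.log_markers),
        "harm_directions": model.harm_directions,
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def load_model(path) -> RiskModel:
    with open(path) as fh:
        doc = json.load(fh)
    cols = doc["markers"]
    fit = CoxFit(
        beta=pd.Series(doc["beta"], index=cols),
        se=pd.Series(doc["se"], index=cols),
        covariance=pd.DataFrame(doc["covariance"], index=cols, columns=cols),
        log_likelihood=doc["log_likelihood"],
        ties=doc["ties"],
        centering_means=pd.Series(doc["centering_means"], index=cols),
        n=doc["n"],
        n_events=doc["n_events"],
    )
    s0 = StepSurvival(
        knots=np.asarray(doc["s0_knots"]),
        values=np.asarray(doc["s0_values"]),
        t_max=doc["s0_t_max"],
    )
    return RiskModel(
        fit=fit,
        s0=s0,
        horizon=doc["horizon"],
        log_markers=tuple(doc["log_markers"]),
        endpoint=doc["endpoint"],
        harm_directions={k: int(v) for k, v in doc.get("harm_directions", {}).items()},
    )
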