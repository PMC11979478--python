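"""Kaplan-Meier cumulative incidence with exponential-Greenwood intervals.

The estimator is the standard product-limit form S(t) = prod_{t_j <= t}
(1 - d_j/n_j) over distinct event times, with administrative censoring at the
analysis horizon and the events-first convention for ties between events and
censorings at the same time.  Curves are reported on the cumulative-incidence
scale 1 - S(t).

Confidence bands use Greenwood's exponential (log(-log)) formula: with the
Greenwood variance accumulator V(t) = sum d_j / (n_j (n_j - d_j)) and
se(t) = sqrt(V(t)) / |ln S(t)|, the survival bounds are
S(t)^{exp(+/- z_{alpha/2} se(t))}, which are guaranteed to stay inside (0, 1);
incidence bands are one minus those bounds with the order swapped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm


@dataclass
class SurvivalCurve:
    """One group's product-limit curve on an event-time grid (days)."""

    times: np.ndarray          # distinct event times t_j (days since index)
    at_risk: np.ndarray        # n_j
    events: np.ndarray         # d_j
    survival: np.ndarray       # S(t_j)
    ci_lower: np.ndarray | None = None  # incidence-scale bands
    ci_upper: np.ndarray | None = None
    alpha: float | None = None
    n_subjects: int = 0
    horizon: float = 365.0

    @property
    def cumulative_incidence(self) -> np.ndarray:
        return 1.0 - self.survival

    def survival_at(self, t: float) -> float:
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])

    def incidence_at(self, t: float) -> float:
        return 1.0 - self.survival_at(t)

    def ci_at(self, t: float) -> tuple[float, float]:
        if self.ci_lower is None:
            raise ValueError("confidence bands not computed")
        idx = np.searchsorted(self.times, t, side="right") - 1
        if idx < 0:
            return (0.0, 0.0)
        return float(self.ci_lower[idx]), float(self.ci_upper[idx])

    def to_frame(self) -> pd.DataFrame:
        d = {
            "time": self.times,
            "at_risk": self.at_risk,
            "events": self.events,
            "incidence": self.cumulative_incidence,
        }
        if self.ci_lower is not None:
            d["ci_lower"] = self.ci_lower
            d["ci_upper"] = self.ci_upper
        return pd.DataFrame(d)


def km_cumulative_incidence(
    time_to_event,
    event_flag,
    horizon: float = 365.0,
    alpha: float | None = 0.05,
) -> SurvivalCurve:
    """Fit the Kaplan-Meier curve with administrative censoring at ``horizon``.

    ``time_to_event`` are follow-up days from the index date; ``event_flag``
    marks observed events (censored otherwise).  Events beyond the horizon are
    treated as censored at the horizon.  With ``alpha`` set, exponential-
    Greenwood bands at level 1 - alpha are attached.
    """
    t = np.asarray(time_to_event, dtype=np.float64)
    e = np.asarray(event_flag, dtype=bool)
    if t.size == 0:
        raise ValueError("no subjects")
    if np.any(t < 0):
        raise ValueError("negative follow-up times")
    e = e & (t <= horizon)
    t = np.minimum(t, horizon)

    event_times = np.unique(t[e])
    n_j = np.array([(t >= tj).sum() for tj in event_times], dtype=np.int64)
    d_j = np.array([((t == tj) & e).sum() for tj in event_times], dtype=np.int64)
    surv = np.cumprod(1.0 - d_j / n_j) if len(event_times) else np.array([])
    curve = SurvivalCurve(
        times=event_times,
        at_risk=n_j,
        events=d_j,
        survival=surv,
        n_subjects=int(t.size),
        horizon=horizon,
    )
    if alpha is not None:
        curve = greenwood_exponential_ci(curve, alpha=alpha)
    return curve


def greenwood_exponential_ci(
    curve: SurvivalCurve, alpha: float = 0.05, method: str = "exponential"
) -> SurvivalCurve:
    """Attach 1 - alpha confidence bands to a fitted curve.

    ``method='exponential'`` (default) is the log(-log) transformation, which
    keeps the bands inside [0, 1]; ``method='linear'`` is the plain Greenwood
    band S +/- z * S * sqrt(V), clipped to [0, 1].  Where S = 0 the band is
    undefined and reported as NaN; where no events have occurred (V = 0) the
    band collapses to the point estimate.
    """
    n_j, d_j, surv = curve.at_risk, curve.events, curve.survival
    if len(surv) == 0:
        return SurvivalCurve(
            **{**curve.__dict__, "ci_lower": np.array([]),
               "ci_upper": np.array([]), "alpha": alpha}
        )
    z = norm.ppf(1.0 - alpha / 2.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        v = np.cumsum(
            np.where(n_j > d_j, d_j / (n_j * (n_j - d_j)), np.nan)
        )
        lo_s = np.full_like(surv, np.nan)
        hi_s = np.full_like(surv, np.nan)
        ok = (surv > 0) & (surv < 1) & np.isfinite(v)
        if method == "exponential":
            se = np.sqrt(v[ok]) / np.abs(np.log(surv[ok]))
            lo_s[ok] = surv[ok] ** np.exp(z * se)   # lower survival bound
            hi_s[ok] = surv[ok] ** np.exp(-z * se)  # upper survival bound
        elif method == "linear":
            half = z * surv[ok] * np.sqrt(v[ok])
            lo_s[ok] = np.clip(surv[ok] - half, 0.0, 1.0)
            hi_s[ok] = np.clip(surv[ok] + half, 0.0, 1.0)
        else:
            raise ValueError(f"unknown CI method {method!r}")
    collapsed = (v == 0) | (surv == 1)
    lo_s[collapsed] = surv[collapsed]
    hi_s[collapsed] = surv[collapsed]
    # incidence-scale bands: 1 - survival bounds, order swapped
    return SurvivalCurve(
        times=curve.times,
        at_risk=n_j,
        events=d_j,
        survival=surv,
        ci_lower=1.0 - hi_s,
        ci_upper=1.0 - lo_s,
        alpha=alpha,
        n_subjects=curve.n_subjects,
        horizon=curve.horizon,
    )


def empirical_incidence(time_to_event, event_flag, t: float) -> float:
    """Plain empirical fraction with an event by time t (no censoring)."""
    tt = np.asarray(time_to_event, dtype=np.float64)
    ee = np.asarray(event_flag, dtype=bool)
    return float((ee & (tt <= t)).mean())
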