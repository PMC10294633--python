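"""Four-parameter Weibull decay model for OD600 kill curves.

Kill curves record the loss of prey optical density as the predator lyses
the culture, sampled on a plate reader (20-min intervals over 42 h). The
decline is modelled with the type-1 four-parameter Weibull dose-response
function in its standard (W1.4) convention:

    f(t) = c + (d − c) · exp(−exp(b · (ln t − ln e)))

with upper asymptote ``d`` (initial OD), lower asymptote ``c`` (fully
lysed), scale/inflection time ``e`` (min) and slope ``b`` (> 0 for a
decay). At t = 0 the model is defined as ``f(0) = d`` by continuity.

The effective kill time for a killed fraction q (EKT, with EKT50 at
q = 0.5) has the closed form ``e · exp(ln(−ln(1 − q)) / b)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.optimize import least_squares

__all__ = ["KillCurve", "WeibullFit", "weibull4", "fit_weibull4", "ekt"]


@dataclass
class KillCurve:
    """One optical-density time series (strictly increasing times, min)."""

    times: np.ndarray
    od: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.od = np.asarray(self.od, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.od.shape:
            raise ValueError("times and od must be 1-D arrays of equal length")
        if len(self.times) and (np.diff(self.times) <= 0).any():
            raise ValueError("times must be strictly increasing")
        if (self.times < 0).any():
            raise ValueError("times must be >= 0")
        if not np.isfinite(self.od).all():
            raise ValueError("od values must be finite")

    def __len__(self) -> int:
        return len(self.times)


@dataclass
class WeibullFit:
    """Fitted Weibull parameters with least-squares diagnostics."""

    b: float
    c: float
    d: float
    e: float
    rss: float
    n_points: int
    converged: bool
    message: str = ""

    def __post_init__(self) -> None:
        if self.converged:
            if self.d <= self.c:
                raise ValueError("converged fit requires d > c")
            if self.e <= 0:
                raise ValueError("converged fit requires e > 0")
        if self.rss < 0:
            raise ValueError("rss must be >= 0")

    def predict(self, t) -> np.ndarray:
        return weibull4(t, self.b, self.c, self.d, self.e)


def weibull4(t, b: float, c: float, d: float, e: float):
    """Evaluate the four-parameter Weibull decay at times ``t`` (min).

    ``f(0)`` is ``d`` by continuity (for b > 0 the inner exponent
    diverges to −∞ as t → 0⁺).
    """
    if e <= 0:
        raise ValueError(f"scale parameter e must be > 0, got {e}")
    scalar = np.ndim(t) == 0
    t = np.atleast_1d(np.asarray(t, dtype=float))
    if (t < 0).any():
        raise ValueError("t must be >= 0")
    out = np.empty_like(t)
    pos = t > 0
    with np.errstate(over="ignore"):
        out[pos] = c + (d - c) * np.exp(-np.exp(b * (np.log(t[pos]) - np.log(e))))
    out[~pos] = d
    return float(out[0]) if scalar else out


def _initial_guess(t: np.ndarray, od: np.ndarray) -> np.ndarray:
    """Deterministic starting point: asymptotes from the data range, scale
    at the sample nearest the half-response, unit slope."""
    d0 = float(od.max())
    c0 = float(od.min())
    mid = (c0 + d0) / 2.0
    nonzero = t > 0
    e0 = float(t[nonzero][np.argmin(np.abs(od[nonzero] - mid))]) if nonzero.any() else 1.0
    if e0 <= 0:
        e0 = 1.0
    return np.array([1.0, c0, d0, e0])


def fit_weibull4(curve: KillCurve) -> WeibullFit:
    """Least-squares fit of the four-parameter Weibull decay to a kill curve.

    Deterministic given the data: a fixed initialization heuristic and a
    bounded trust-region solver (b > 0, e > 0; c, d free). Degenerate
    inputs (constant OD) return ``converged=False`` with a diagnostic
    instead of raising.
    """
    if len(curve) < 6:
        raise ValueError(f"need >= 6 points to fit, got {len(curve)}")
    t, od = curve.times, curve.od
    if np.ptp(od) == 0:
        return WeibullFit(
            b=1.0, c=float(od[0]), d=float(od[0]), e=1.0,
            rss=0.0, n_points=len(curve), converged=False,
            message="degenerate data: od is constant",
        )

    def resid(theta):
        b, c, d, e = theta
        return weibull4(t, b, c, d, e) - od

    x0 = _initial_guess(t, od)
    lo = np.array([1e-9, -np.inf, -np.inf, 1e-9])
    hi = np.array([np.inf, np.inf, np.inf, np.inf])
    res = least_squares(resid, x0, bounds=(lo, hi), method="trf", xtol=1e-14,
                        ftol=1e-14, gtol=1e-14)
    b, c, d, e = res.x
    rss = float(np.sum(res.fun**2))
    converged = bool(res.success and d > c and e > 0)
    if not converged:
        warnings.warn(f"Weibull fit did not converge: {res.message}")
    return WeibullFit(
        b=float(b), c=float(c), d=float(d), e=float(e),
        rss=rss, n_points=len(curve), converged=converged,
        message=str(res.message),
    )


def ekt(fit: WeibullFit, fraction: float = 0.5) -> float:
    """Effective kill time: minutes until a fraction ``q`` of the prey
    signal is lost, from the fitted curve.

    Solves (f(t) − c)/(d − c) = 1 − q in closed form:
    ``EKT_q = e · exp(ln(−ln(1 − q)) / b)``; at q = 0.5 this is
    ``e · exp(ln(ln 2)/b)``.
    """
    if not fit.converged:
        raise ValueError("cannot compute EKT from an unconverged fit")
    if fit.b <= 0:
        raise ValueError("EKT requires a decaying fit (b > 0)")
    if not 0 < fraction < 1:
        raise ValueError("fraction must lie in (0, 1)")
    return fit.e * float(np.exp(np.log(-np.log(1 - fraction)) / fit.b))
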