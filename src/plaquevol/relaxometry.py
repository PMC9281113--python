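"""Decay-rate estimation and relaxivity fitting.

Two small least-squares problems underpin the pipeline:

* ``fit_decay`` — per-site R2* (= 1/T2*, ms^-1) from a multi-echo intensity
  series via log-linear least squares on the mono-exponential model
  S(TE) = S0 * exp(-R2* * TE).  Its goodness of fit is the decay-consistency
  score used by the long-TE false-positive filter.
* ``fit_relaxivity`` — the transverse relaxivity r2 (s^-1 mM^-1) as the
  ordinary-least-squares slope of relaxation rate against contrast-agent
  iron concentration over a dilution series, the standard characterization
  of an SPIO contrast agent.

Rates are ms^-1 on the imaging side and s^-1 on the dilution-table side;
``rate_from_t2`` / ``rate_from_intensity`` convert at the interface.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "DecayFit",
    "RelaxivityFit",
    "fit_decay",
    "fit_relaxivity",
    "rate_from_t2",
    "rate_from_intensity",
]


@dataclass(frozen=True)
class DecayFit:
    """Mono-exponential fit of one intensity-vs-TE series."""

    s0_hat: float  # signal units
    r2star_hat: float  # ms^-1
    r_squared: float  # of ln(S) vs TE, in [0, 1]
    clipped: bool = False  # non-positive intensities were floored before log

    def __post_init__(self) -> None:
        if self.s0_hat < 0:
            raise ValueError("s0_hat must be >= 0")
        if not 0.0 <= self.r_squared <= 1.0:
            raise ValueError("r_squared must lie in [0, 1]")


@dataclass(frozen=True)
class RelaxivityFit:
    """OLS line R2(C) = intercept + r2_slope * C over a dilution series."""

    r2_slope: float  # s^-1 mM^-1
    intercept: float  # s^-1
    r_squared: float
    n_points: int

    def __post_init__(self) -> None:
        if self.n_points < 2:
            raise ValueError("relaxivity fit needs >= 2 points")
        if not 0.0 <= self.r_squared <= 1.0:
            raise ValueError("r_squared must lie in [0, 1]")


def _r_squared(y: np.ndarray, yhat: np.ndarray) -> float:
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot <= 1e-30:  # constant data: any flat line is a perfect fit
        return 1.0
    ss_res = float(np.sum((y - yhat) ** 2))
    return float(np.clip(1.0 - ss_res / ss_tot, 0.0, 1.0))


def fit_decay(intensities, te_list, floor_fraction: float = 1e-6) -> DecayFit:
    """Least-squares mono-exponential decay fit in log space.

    Parameters
    ----------
    intensities : array-like
        Signal magnitude per echo, same length as ``te_list``.
    te_list : array-like
        Echo times in ms, at least two.
    floor_fraction : float
        Non-positive intensities (possible after noise) are clipped to
        ``floor_fraction * max(intensities)`` before taking logs; the result
        is then flagged ``clipped``.

    On noiseless exponential data the generating S0 and R2* are recovered
    exactly; with n = 2 echoes the fit reduces to the two-point closed form
    R2* = ln(S1/S2) / (TE2 - TE1).
    """
    s = np.asarray(intensities, dtype=float)
    te = np.asarray(te_list, dtype=float)
    if s.shape != te.shape or s.ndim != 1:
        raise ValueError("intensities and te_list must be 1-D and the same length")
    if s.size < 2:
        raise ValueError("fit_decay needs at least two echoes")
    clipped = bool(np.any(s <= 0))
    if clipped:
        if np.all(s <= 0):
            raise ValueError("all intensities non-positive; nothing to fit")
        s = np.maximum(s, floor_fraction * float(s.max()))
    ln_s = np.log(s)
    slope, intercept = np.polyfit(te, ln_s, 1)
    fit = DecayFit(
        s0_hat=float(np.exp(intercept)),
        r2star_hat=float(-slope),
        r_squared=_r_squared(ln_s, slope * te + intercept),
        clipped=clipped,
    )
    return fit


def fit_relaxivity(concentrations, relaxation_rates) -> RelaxivityFit:
    """OLS relaxivity line over a dilution series (concentration in mM, rate in s^-1)."""
    c = np.asarray(concentrations, dtype=float)
    r = np.asarray(relaxation_rates, dtype=float)
    if c.shape != r.shape or c.ndim != 1 or c.size < 2:
        raise ValueError("need matching 1-D arrays with >= 2 points")
    if np.ptp(c) == 0:
        raise ValueError("all concentrations identical: slope is unidentifiable")
    res = stats.linregress(c, r)
    r2 = _r_squared(r, res.intercept + res.slope * c)
    return RelaxivityFit(
        r2_slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=r2,
        n_points=int(c.size),
    )


def rate_from_t2(t2_ms) -> np.ndarray | float:
    """R2 in s^-1 from T2 in ms: 1000 / T2."""
    t2 = np.asarray(t2_ms, dtype=float)
    if np.any(t2 <= 0):
        raise ValueError("T2 must be > 0")
    out = 1000.0 / t2
    return float(out) if out.ndim == 0 else out


def rate_from_intensity(intensity, s0, te_ms) -> np.ndarray | float:
    """R2 in s^-1 from a single-TE ROI intensity: -ln(S / S0) / TE * 1000."""
    s = np.asarray(intensity, dtype=float)
    if np.any(s <= 0) or s0 <= 0 or te_ms <= 0:
        raise ValueError("intensity, s0 and te_ms must be > 0")
    out = -np.log(s / s0) / te_ms * 1000.0
    return float(out) if out.ndim == 0 else out
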