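"""Thioflavin-T aggregation kinetics: Boltzmann-sigmoid fitting.

Amyloid formation monitored by ThT fluorescence follows a sigmoidal time
course (lag, growth, plateau) modelled here by the Boltzmann function

    y(x) = (A1 - A2) / (1 + exp((x - x0) / dx)) + A2

with A1 the initial and A2 the maximum fluorescence, x0 the time at
half-maximal fluorescence (h) and dx the rate constant (h).  Fitting is
nonlinear least squares (scipy ``curve_fit``) with a data-driven initial
guess and a small number of deterministic jittered restarts to guard
against local minima.  Endpoint comparisons across conditions average the
terminal window of each curve and delegate the group test to
:func:`synucleo.ephys_analysis.compare_groups`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import curve_fit
from scipy.special import expit

__all__ = [
    "ThTCurve",
    "BoltzmannParams",
    "BoltzmannFit",
    "boltzmann",
    "normalize_to_max",
    "fit_boltzmann",
    "compare_endpoints",
]


@dataclass
class ThTCurve:
    """One fluorescence time course (time in hours, AU fluorescence)."""

    time: np.ndarray
    fluorescence: np.ndarray
    condition_label: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.time, dtype=float)
        y = np.asarray(self.fluorescence, dtype=float)
        if t.shape != y.shape or t.ndim != 1:
            raise ValueError("time and fluorescence must be equal-length 1-D arrays")
        if len(t) > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("time must be strictly increasing")
        self.time, self.fluorescence = t, y


@dataclass(frozen=True)
class BoltzmannParams:
    A1: float
    A2: float
    x0: float
    dx: float

    def __post_init__(self) -> None:
        if self.dx == 0:
            raise ValueError("dx must be non-zero")

    def as_array(self) -> np.ndarray:
        return np.array([self.A1, self.A2, self.x0, self.dx])


@dataclass
class BoltzmannFit:
    params: BoltzmannParams | None
    success: bool
    r_squared: float = np.nan
    residual_variance: float = np.nan
    covariance: np.ndarray | None = None
    message: str = ""

    def predict(self, x: np.ndarray) -> np.ndarray:
        if self.params is None:
            raise RuntimeError("fit failed; no parameters available")
        return boltzmann(np.asarray(x, float), *self.params.as_array())


def boltzmann(x: np.ndarray, a1: float, a2: float, x0: float, dx: float) -> np.ndarray:
    """y = (A1 - A2)/(1 + e^((x - x0)/dx)) + A2, overflow-safe via expit."""
    return a2 + (a1 - a2) * expit(-(np.asarray(x, float) - x0) / dx)


def normalize_to_max(curve: ThTCurve) -> ThTCurve:
    """Rescale fluorescence to percent of its maximum (max becomes 100)."""
    ymax = float(np.max(curve.fluorescence))
    if ymax <= 0:
        raise ValueError("cannot normalise: maximum fluorescence is not positive")
    return ThTCurve(
        curve.time.copy(),
        100.0 * curve.fluorescence / ymax,
        curve.condition_label,
    )


def _default_init(t: np.ndarray, y: np.ndarray) -> np.ndarray:
    a1, a2 = float(np.min(y)), float(np.max(y))
    mid = 0.5 * (a1 + a2)
    x0 = float(t[np.argmin(np.abs(y - mid))])
    dx = (float(t[-1]) - float(t[0])) / 10.0 or 1.0
    return np.array([a1, a2, x0, dx])


def fit_boltzmann(
    curve: ThTCurve,
    init: BoltzmannParams | None = None,
    max_restarts: int = 5,
) -> BoltzmannFit:
    """Least-squares Boltzmann fit of one ThT curve.

    Initial guess: A1 = min(y), A2 = max(y), x0 = time of the sample
    closest to mid-amplitude, dx = span/10; up to ``max_restarts``
    deterministic jittered restarts keep the best solution.  Returns a
    failed :class:`BoltzmannFit` (never raises) when no start converges.
    """
    t, y = curve.time, curve.fluorescence
    if len(t) < 5:
        raise ValueError("need at least 5 points to fit")
    p0 = init.as_array() if init is not None else _default_init(t, y)
    rng = np.random.default_rng(0)  # fixed: restarts are deterministic
    best: tuple[float, np.ndarray, np.ndarray] | None = None
    message = ""
    for k in range(max_restarts + 1):
        trial = p0 if k == 0 else p0 * rng.normal(1.0, 0.2, size=4)
        if trial[3] == 0:
            trial[3] = p0[3] or 1.0
        try:
            popt, pcov = curve_fit(
                boltzmann, t, y, p0=trial, maxfev=20000,
                xtol=1e-14, ftol=1e-14, gtol=1e-14,
            )
        except (RuntimeError, ValueError) as exc:
            message = str(exc)
            continue
        ss_res = float(np.sum((y - boltzmann(t, *popt)) ** 2))
        if best is None or ss_res < best[0]:
            best = (ss_res, popt, pcov)
        if ss_res <= 1e-20 * max(1.0, float(np.sum(y**2))):
            break
    if best is None:
        return BoltzmannFit(None, False, message=f"no restart converged: {message}")
    ss_res, popt, pcov = best
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    dof = max(len(t) - 4, 1)
    return BoltzmannFit(
        params=BoltzmannParams(*popt),
        success=True,
        r_squared=1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0,
        residual_variance=ss_res / dof,
        covariance=pcov,
    )


def compare_endpoints(
    curves: Sequence[ThTCurve],
    window_fraction: float = 0.1,
    window: tuple[float, float] | None = None,
):
    """Terminal-window means per condition, with a group test when possible.

    ``window`` is an explicit (t_lo, t_hi) range in hours; otherwise the
    final ``window_fraction`` of each curve's time axis is used (default
    the last 10%).  Returns ``(means, comparison)`` where ``means`` maps
    condition label -> list of per-replicate window means, and
    ``comparison`` is the :func:`compare_groups` report when every
    condition has >= 3 replicates and >= 2 conditions exist (else None).
    """
    if not curves:
        raise ValueError("no curves supplied")
    means: dict[str, list[float]] = {}
    for c in curves:
        if window is not None:
            lo, hi = window
        else:
            lo = c.time[-1] - window_fraction * (c.time[-1] - c.time[0])
            hi = c.time[-1]
        mask = (c.time >= lo) & (c.time <= hi)
        if not mask.any():
            raise ValueError(
                f"endpoint window [{lo}, {hi}] contains no samples of "
                f"curve {c.condition_label!r}"
            )
        means.setdefault(c.condition_label, []).append(
            float(c.fluorescence[mask].mean())
        )
    comparison = None
    if len(means) >= 2 and all(len(v) >= 3 for v in means.values()):
        from .ephys_analysis import compare_groups

        comparison = compare_groups({k: np.array(v) for k, v in means.items()})
    return means, comparison
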