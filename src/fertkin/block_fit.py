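"""Exponential block-model fits to event-count curves.

Two saturating-exponential models describe the post-fertilization blocks:

* penetration block:  f(t) = A * (1 - exp(-t / tau_PB)), fitted with both
  the plateau A (sperm/oocyte) and the time constant tau_PB (min) free.
  The implied penetration rate at the moment of fertilization is the
  derivative at t=0, A / tau_PB, reported per hour.
* fusion block:  f(t) = a * (1 - exp(-t / tau_FB)) with the amplitude a
  held fixed at the observed number of extra (polyspermic) fusions per
  fertilized oocyte; only tau_FB is fitted.

A constant-rate baseline (slope through the origin) describes penetration
into unfertilized oocytes.  All fits are unweighted least squares on the
mean curve — grid points are strongly autocorrelated, so per-point weights
are not meaningful — and 95% CIs come from refitting each bootstrap
resample curve.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.optimize import least_squares

from .window_stats import Align, CountCurve, Counted

_TAU_STARTS = (5.0, 15.0, 50.0, 150.0)  # minutes; multistart grid


class FitError(RuntimeError):
    """Model fit failed to converge."""


@dataclass
class PenetrationBlockFit:
    """Fitted A(1-exp(-t/tau_PB)) penetration-block model."""

    A: float                      # plateau, sperm/oocyte
    tau_pb: float                 # minutes (nan if unidentified)
    initial_rate: float           # A/tau_PB, sperm/oocyte/hour
    A_ci: Optional[tuple[float, float]] = None
    tau_ci: Optional[tuple[float, float]] = None
    rate_ci: Optional[tuple[float, float]] = None
    rss: float = 0.0
    tau_identified: bool = True


@dataclass
class FusionBlockFit:
    """Fitted fixed-amplitude fusion-block model."""

    amplitude: float              # extra fusions per fertilized oocyte, held fixed
    tau_fb: float                 # minutes
    tau_ci: Optional[tuple[float, float]] = None
    rss: float = 0.0
    at_boundary: bool = False


@dataclass
class ConstantRateFit:
    """Constant penetration rate (unfertilized-oocyte baseline)."""

    rate: float                   # sperm/oocyte/hour
    rate_ci: Optional[tuple[float, float]] = None
    rss: float = 0.0


def _saturating(t: np.ndarray, A: float, tau: float) -> np.ndarray:
    return A * (1.0 - np.exp(-t / tau))


def _fit_sat_exp(t: np.ndarray, y: np.ndarray, starts=None) -> tuple[float, float, float]:
    """Least-squares (A, tau) of A(1-exp(-t/tau)); returns (A, tau, rss)."""
    plateau = max(float(y[-max(1, len(y) // 10):].mean()), float(y.max()), 1e-12)
    best = None
    for tau0 in starts or _TAU_STARTS:
        try:
            res = least_squares(
                lambda p: _saturating(t, p[0], p[1]) - y,
                x0=[plateau, tau0],
                bounds=([0.0, 1e-6], [np.inf, 1e7]),
            )
        except Exception:
            continue
        if res.success and (best is None or res.cost < best.cost):
            best = res
    if best is None:
        raise FitError("penetration-block fit did not converge from any start")
    A, tau = best.x
    return float(A), float(tau), float(2 * best.cost)


def fit_penetration_block(curve: CountCurve) -> PenetrationBlockFit:
    """Fit the penetration-block model to a post-fertilization penetration
    count curve; 95% CIs by refitting each bootstrap resample curve."""
    if curve.align is not Align.FIRST_FUSION or curve.counted is not Counted.PENETRATION:
        raise ValueError("expected a curve aligned to first_fusion counting penetrations")
    t, y = curve.grid, curve.mean
    if float(np.max(np.abs(y))) < 1e-12:
        return PenetrationBlockFit(0.0, float("nan"), 0.0, rss=0.0, tau_identified=False)
    A, tau, rss = _fit_sat_exp(t, y)
    fit = PenetrationBlockFit(A, tau, A / tau * 60.0, rss=rss)
    if curve.boot_curves is not None:
        As, taus = [], []
        for yb in curve.boot_curves:
            if float(np.max(np.abs(yb))) < 1e-12:
                continue
            try:
                Ab, taub, _ = _fit_sat_exp(t, yb, starts=(tau,))
            except FitError:
                continue
            As.append(Ab)
            taus.append(taub)
        if As:
            As, taus = np.array(As), np.array(taus)
            rates = As / taus * 60.0
            pct = lambda a: (float(np.percentile(a, 2.5)), float(np.percentile(a, 97.5)))
            fit.A_ci, fit.tau_ci, fit.rate_ci = pct(As), pct(taus), pct(rates)
    return fit


def fit_fusion_block(curve: CountCurve, amplitude: float) -> FusionBlockFit:
    """One-parameter fit of tau_FB with the amplitude held fixed at the
    observed extra fusions per fertilized oocyte."""
    if amplitude <= 0:
        raise ValueError("amplitude must be positive")
    if curve.align is not Align.FIRST_FUSION or curve.counted is not Counted.FUSION:
        raise ValueError("expected a curve aligned to first_fusion counting extra fusions")
    t, y = curve.grid, curve.mean

    def fit_one(yv: np.ndarray) -> tuple[float, float]:
        best = None
        for tau0 in _TAU_STARTS:
            res = least_squares(
                lambda p: _saturating(t, amplitude, p[0]) - yv,
                x0=[tau0],
                bounds=([1e-6], [1e7]),
            )
            if res.success and (best is None or res.cost < best.cost):
                best = res
        if best is None:
            raise FitError("fusion-block fit did not converge")
        return float(best.x[0]), float(2 * best.cost)

    tau, rss = fit_one(y)
    # a time constant below the grid resolution is indistinguishable from an
    # instantaneous step: flag it as a boundary estimate
    step = float(t[1] - t[0]) if len(t) > 1 else 1.0
    fit = FusionBlockFit(amplitude, tau, rss=rss, at_boundary=tau <= step)
    if curve.boot_curves is not None:
        taus = []
        for yb in curve.boot_curves:
            try:
                taus.append(fit_one(yb)[0])
            except FitError:
                continue
        if taus:
            fit.tau_ci = (float(np.percentile(taus, 2.5)), float(np.percentile(taus, 97.5)))
    return fit


def fit_constant_rate(curve: CountCurve) -> ConstantRateFit:
    """Least-squares slope through the origin of a cumulative penetration
    curve, reported in sperm/oocyte/hour."""
    if curve.align is Align.FIRST_FUSION:
        raise ValueError("constant-rate baseline expects an unfertilized-cohort curve")
    t, y = curve.grid, curve.mean
    if len(t) < 2:
        raise ValueError("need at least 2 grid points")
    denom = float(np.dot(t, t))
    if denom == 0.0:
        raise ValueError("degenerate grid")
    slope = float(np.dot(t, y)) / denom  # per minute
    rss = float(np.sum((y - slope * t) ** 2))
    fit = ConstantRateFit(slope * 60.0, rss=rss)
    if curve.boot_curves is not None:
        rates = curve.boot_curves @ t / denom * 60.0
        fit.rate_ci = (float(np.percentile(rates, 2.5)), float(np.percentile(rates, 97.5)))
    return fit


def implied_initial_rate(fit: PenetrationBlockFit) -> float:
    """Penetration rate at the moment of fertilization, A/tau_PB per hour.

    This is the analytic derivative of A(1-exp(-t/tau)) at t=0.
    """
    if not (fit.tau_pb > 0):
        if fit.A == 0.0:
            return 0.0
        raise ValueError("tau_PB must be positive")
    return fit.A / fit.tau_pb * 60.0
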