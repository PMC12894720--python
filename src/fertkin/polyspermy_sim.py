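"""Mechanistic Monte Carlo simulator of sperm penetration and fusion.

Per oocyte, sperm enter the perivitelline space as a Poisson process with
baseline rate lambda0 (sperm/oocyte/hour, the intrinsic permeability of the
zona pellucida).  Each penetrant at time P draws a penetration-to-fusion
delay D and attempts to fuse at P + D.  The chronologically first attempt
always succeeds, fertilizing the oocyte at time T1, which triggers the two
blocks:

* penetration block — the zona becomes progressively impermeable; entries
  after T1 are thinned with probability exp(-(t - T1)/tau_PB), so the
  expected cumulative count of post-T1 penetrations is exactly
  lambda0*tau_PB*(1 - exp(-(t-T1)/tau_PB)).
* fusion block — a sperm attempting to fuse at time A > T1 succeeds with
  probability exp(-(A - T1)/tau_FB) and never re-attempts, so the rate of
  extra fusion events decays as exp(-dt/tau_FB).

Either time constant may be infinite (block disabled).  All events are
truncated at the observation horizon.  Scenario toggles reproduce the
what-if analysis: no fusion block, no penetration block, tripled zona
permeability, and halved fusion time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Optional

import numpy as np

#: fitted defaults: baseline permeability, block time constants, fusion delay
DEFAULT_LAMBDA0 = 1.21        # sperm/oocyte/hour
DEFAULT_TAU_PB = 48.3         # minutes
DEFAULT_TAU_FB = 6.2          # minutes
DEFAULT_DELAY_MEAN = 15.8     # minutes
DEFAULT_DELAY_SD = 5.7        # minutes


class DelayFamily(str, Enum):
    GAMMA = "gamma"
    LOGNORMAL = "lognormal"
    EXPONENTIAL = "exponential"
    FIXED = "fixed"


@dataclass(frozen=True)
class KineticParams:
    """Kinetic parameters of the penetration/fusion process."""

    lambda0: float = DEFAULT_LAMBDA0
    tau_pb: float = DEFAULT_TAU_PB       # minutes, or inf to disable
    tau_fb: float = DEFAULT_TAU_FB       # minutes, or inf to disable
    delay_mean: float = DEFAULT_DELAY_MEAN
    delay_sd: float = DEFAULT_DELAY_SD
    delay_family: DelayFamily = DelayFamily.GAMMA
    horizon: float = 240.0               # minutes
    n_oocytes: int = 10_000

    def __post_init__(self) -> None:
        if self.lambda0 < 0:
            raise ValueError("lambda0 must be >= 0")
        if not (self.tau_pb > 0) or not (self.tau_fb > 0):
            raise ValueError("time constants must be positive (or infinite)")
        if self.delay_mean <= 0 or self.delay_sd < 0:
            raise ValueError("delay_mean must be > 0 and delay_sd >= 0")
        if self.horizon <= 0 or self.n_oocytes < 1:
            raise ValueError("horizon must be > 0 and n_oocytes >= 1")
        object.__setattr__(self, "delay_family", DelayFamily(self.delay_family))


class Scenario(str, Enum):
    BASELINE = "baseline"
    NO_FUSION_BLOCK = "no_fusion_block"
    NO_PENETRATION_BLOCK = "no_penetration_block"
    PERMEABILITY_X3 = "permeability_x3"
    HALF_FUSION_TIME = "half_fusion_time"


@dataclass
class OocyteEvents:
    """Event log of one simulated oocyte (times in minutes)."""

    penetration_times: np.ndarray          # realized entries, <= horizon
    fusion_times: np.ndarray               # nan per sperm where fusion failed/after horizon
    first_fusion: Optional[float]          # T1, None if unfertilized within horizon

    @property
    def n_penetrations(self) -> int:
        return len(self.penetration_times)

    @property
    def n_fusions(self) -> int:
        return int(np.isfinite(self.fusion_times).sum())


@dataclass
class SimResult:
    """Cohort simulation output."""

    params: KineticParams
    oocytes: list[OocyteEvents]
    grid: np.ndarray                       # minutes after T1
    extra_fusion_mean: np.ndarray          # mean cumulative extra fusions/fertilized oocyte
    mean_post_t1_penetrations: float       # among fertilized oocytes
    polyspermy_fraction: float             # >=2 fusions among fertilized
    n_fertilized: int


def _sample_delays(p: KineticParams, n: int, rng: np.random.Generator) -> np.ndarray:
    """Penetration-to-fusion delays, moment-matched to (delay_mean, delay_sd)."""
    m, s = p.delay_mean, p.delay_sd
    fam = p.delay_family
    if n == 0:
        return np.empty(0)
    if fam is DelayFamily.FIXED or s == 0:
        return np.full(n, m)
    if fam is DelayFamily.GAMMA:
        shape = (m / s) ** 2
        return rng.gamma(shape, m / shape, size=n)
    if fam is DelayFamily.LOGNORMAL:
        sigma2 = math.log1p((s / m) ** 2)
        mu = math.log(m) - sigma2 / 2.0
        return rng.lognormal(mu, math.sqrt(sigma2), size=n)
    return rng.exponential(m, size=n)  # exponential ignores delay_sd


def _decay_prob(dt: np.ndarray, tau: float) -> np.ndarray:
    """exp(-dt/tau), with tau=inf meaning no decay."""
    if math.isinf(tau):
        return np.ones_like(dt)
    return np.exp(-np.asarray(dt, float) / tau)


def simulate_oocyte(p: KineticParams, rng: np.random.Generator) -> OocyteEvents:
    """Simulate one oocyte's penetration and fusion history.

    Candidate entries are a homogeneous Poisson process at lambda0; those
    after the realized first fusion T1 are thinned by the penetration block.
    Draw order (entries, delays, thinning, fusion attempts) is fixed so that
    scenarios sharing a seed are coupled.
    """
    rate_per_min = p.lambda0 / 60.0
    times: list[float] = []
    t = 0.0
    if rate_per_min > 0:
        while True:
            t += rng.exponential(1.0 / rate_per_min)
            if t > p.horizon:
                break
            times.append(t)
    pen = np.asarray(times)
    delays = _sample_delays(p, len(pen), rng)
    u_thin = rng.random(len(pen))
    u_fuse = rng.random(len(pen))
    if len(pen) == 0:
        return OocyteEvents(pen, np.empty(0), None)

    attempts = pen + delays
    t1 = float(attempts.min())
    if t1 > p.horizon:
        return OocyteEvents(pen, np.full(len(pen), np.nan), None)

    # penetration block: thin candidate entries after T1 (the fertilizing
    # sperm penetrated before T1 and is never thinned)
    keep = (pen <= t1) | (u_thin < _decay_prob(pen - t1, p.tau_pb))
    pen, attempts, u_fuse = pen[keep], attempts[keep], u_fuse[keep]

    # fusion block: the first attempt (at T1) succeeds; later attempts
    # succeed with probability exp(-(A-T1)/tau_FB)
    success = (attempts <= p.horizon) & (
        (attempts == t1) | (u_fuse < _decay_prob(attempts - t1, p.tau_fb))
    )
    fusion = np.where(success, attempts, np.nan)
    return OocyteEvents(pen, fusion, t1)


def simulate_cohort(p: KineticParams, seed: int, grid_step: float = 1.0) -> SimResult:
    """Simulate n_oocytes independent oocytes and aggregate the
    polyspermy-relevant summaries.

    Per-oocyte RNG substreams are spawned from the master seed, so results
    do not depend on iteration order.
    """
    streams = np.random.SeedSequence(seed).spawn(p.n_oocytes)
    oocytes = [simulate_oocyte(p, np.random.default_rng(s)) for s in streams]

    grid = np.arange(0.0, p.horizon + 0.5 * grid_step, grid_step)
    fert = [o for o in oocytes if o.first_fusion is not None]
    extra = np.zeros_like(grid)
    post_pens = 0
    poly = 0
    for o in fert:
        t1 = o.first_fusion
        dts = o.fusion_times[np.isfinite(o.fusion_times)] - t1
        dts = dts[dts > 0]  # extra fusions only
        if len(dts) > 0:
            poly += 1
            extra += np.searchsorted(np.sort(dts), grid, side="right")
        post_pens += int((o.penetration_times > t1).sum())
    n_fert = len(fert)
    return SimResult(
        params=p,
        oocytes=oocytes,
        grid=grid,
        extra_fusion_mean=extra / n_fert if n_fert else extra,
        mean_post_t1_penetrations=post_pens / n_fert if n_fert else float("nan"),
        polyspermy_fraction=poly / n_fert if n_fert else float("nan"),
        n_fertilized=n_fert,
    )


def run_scenario(base: KineticParams, scenario: Scenario | str, seed: int) -> SimResult:
    """Simulate a what-if variant of the base parameters.

    baseline: unchanged; no_fusion_block: tau_FB -> inf; no_penetration_block:
    tau_PB -> inf; permeability_x3: lambda0 x3; half_fusion_time: delay mean
    and sd halved.
    """
    scenario = Scenario(scenario)
    if scenario is Scenario.BASELINE:
        p = base
    elif scenario is Scenario.NO_FUSION_BLOCK:
        p = replace(base, tau_fb=math.inf)
    elif scenario is Scenario.NO_PENETRATION_BLOCK:
        p = replace(base, tau_pb=math.inf)
    elif scenario is Scenario.PERMEABILITY_X3:
        p = replace(base, lambda0=base.lambda0 * 3.0)
    else:  # HALF_FUSION_TIME
        p = replace(base, delay_mean=base.delay_mean * 0.5, delay_sd=base.delay_sd * 0.5)
    return simulate_cohort(p, seed)
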