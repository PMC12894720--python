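"""Uniform-within-window Monte Carlo estimation of event-count kinetics.

The chronogram fixes each penetration/fusion only to a time window.  With no
reason to prefer one instant over another, each event time is imputed
uniformly within its window; for a fused sperm whose fusion window overlaps
its penetration window, the pair is uniform on the region of the window
rectangle where fusion >= penetration.  Averaging cumulative event counts
over many such realizations — with the alignment event (first fusion or
first penetration) itself realized per draw, so its uncertainty propagates —
yields mean count curves per oocyte; 95% confidence bands come from a
percentile bootstrap over oocytes evaluated on realizations shared across
resamples, capturing both between-oocyte and within-window uncertainty.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

import numpy as np

from .chronogram import Chronogram, ChronogramError, Fate

DEFAULT_N_REALIZATIONS = 1000
DEFAULT_N_BOOTSTRAP = 1000
_REJECTION_BATCHES = 10_000  # overlap regions have positive measure; this is a safety net


class Align(str, Enum):
    FIRST_FUSION = "first_fusion"
    FIRST_PENETRATION = "first_penetration"
    NONE = "none"


class Counted(str, Enum):
    PENETRATION = "penetration"
    FUSION = "fusion"
    PVS_OCCUPANCY = "pvs_occupancy"


@dataclass
class Realization:
    """One joint draw of event times, as (penetration, fusion|None) per sperm."""

    times: dict[tuple[str, str], tuple[float, Optional[float]]]

    def __getitem__(self, key):
        return self.times[key]


@dataclass
class CountCurve:
    """Mean cumulative event count per oocyte vs time since the alignment event."""

    grid: np.ndarray            # minutes relative to the alignment event
    mean: np.ndarray            # events per oocyte
    ci_low: np.ndarray
    ci_high: np.ndarray
    n_oocytes: int
    n_realizations: int
    align: Align = Align.NONE
    counted: Counted = Counted.PENETRATION
    boot_curves: Optional[np.ndarray] = field(default=None, repr=False)  # (B, T)


@dataclass
class DelayCurve:
    """Probability that a fertilizing sperm has fused within dt of penetrating."""

    grid: np.ndarray
    prob: np.ndarray
    mean_delay: float
    ci_low: float
    ci_high: float
    n_sperm: int
    n_realizations: int


# ---------------------------------------------------------------------------
# Flattened chronogram arrays (internal)
# ---------------------------------------------------------------------------

@dataclass
class _Flat:
    oocyte_ids: list[str]
    sperm_keys: list[tuple[str, str]]
    oidx: np.ndarray       # oocyte index per sperm
    pen_lo: np.ndarray
    pen_hi: np.ndarray
    fused: np.ndarray      # bool per sperm
    fus_lo: np.ndarray     # nan where not fused
    fus_hi: np.ndarray
    horizon: np.ndarray    # per oocyte

    @property
    def n_oocytes(self) -> int:
        return len(self.oocyte_ids)

    @property
    def n_sperm(self) -> int:
        return len(self.sperm_keys)


def _flatten(c: Chronogram) -> _Flat:
    oocyte_ids, keys, oidx = [], [], []
    pen_lo, pen_hi, fused, fus_lo, fus_hi, horizon = [], [], [], [], [], []
    for i, o in enumerate(c.oocytes):
        oocyte_ids.append(o.oocyte_id)
        horizon.append(o.horizon)
        for s in o.sperm:
            keys.append((o.oocyte_id, s.sperm_id))
            oidx.append(i)
            pen_lo.append(s.penetration.lower)
            pen_hi.append(s.penetration.upper)
            fused.append(s.fused)
            fus_lo.append(s.fusion.lower if s.fused else np.nan)
            fus_hi.append(s.fusion.upper if s.fused else np.nan)
    return _Flat(
        oocyte_ids,
        keys,
        np.asarray(oidx, dtype=np.intp),
        np.asarray(pen_lo, float),
        np.asarray(pen_hi, float),
        np.asarray(fused, bool),
        np.asarray(fus_lo, float),
        np.asarray(fus_hi, float),
        np.asarray(horizon, float),
    )


def _sample_times(flat: _Flat, rng: np.random.Generator, n: int) -> tuple[np.ndarray, np.ndarray]:
    """Draw n independent realizations of all event times.

    Returns (pen, fus) of shape (n, n_sperm); fus is nan for non-fused sperm.
    Fused pairs respect fusion >= penetration, uniform on the constrained
    rectangle region (rejection from the product uniform).
    """
    s = flat.n_sperm
    pen = flat.pen_lo + (flat.pen_hi - flat.pen_lo) * rng.random((n, s))
    fus = np.full((n, s), np.nan)
    f = flat.fused
    if f.any():
        if np.any(flat.fus_hi[f] < flat.pen_lo[f]):
            raise ChronogramError("fused sperm with fusion window entirely before penetration")
        fus[:, f] = flat.fus_lo[f] + (flat.fus_hi[f] - flat.fus_lo[f]) * rng.random((n, f.sum()))
        bad = fus[:, f] < pen[:, f]
        for _ in range(_REJECTION_BATCHES):
            if not bad.any():
                break
            rows, cols = np.nonzero(bad)
            sp = np.flatnonzero(f)[cols]
            pen_new = flat.pen_lo[sp] + (flat.pen_hi[sp] - flat.pen_lo[sp]) * rng.random(len(sp))
            fus_new = flat.fus_lo[sp] + (flat.fus_hi[sp] - flat.fus_lo[sp]) * rng.random(len(sp))
            pen[rows, sp] = pen_new
            fview = fus[:, f]
            fview[rows, cols] = fus_new
            fus[:, f] = fview
            bad = fus[:, f] < pen[:, f]
        else:  # pragma: no cover
            raise ChronogramError("rejection sampling failed to satisfy fusion >= penetration")
    return pen, fus


def realize(c: Chronogram, seed: int, n_realizations: int = 1) -> list[Realization]:
    """Draw uniform-within-window realizations of all event times.

    Reproducible given the seed; degenerate windows yield their exact time.
    """
    flat = _flatten(c)
    rng = np.random.default_rng(seed)
    pen, fus = _sample_times(flat, rng, n_realizations)
    out = []
    for r in range(n_realizations):
        times = {
            key: (float(pen[r, j]), float(fus[r, j]) if flat.fused[j] else None)
            for j, key in enumerate(flat.sperm_keys)
        }
        out.append(Realization(times))
    return out


# ---------------------------------------------------------------------------
# Count curves
# ---------------------------------------------------------------------------

def _alignment_times(flat: _Flat, pen: np.ndarray, fus: np.ndarray, align: Align) -> np.ndarray:
    """Per-realization, per-oocyte alignment times, shape (n, n_oocytes)."""
    n = pen.shape[0]
    if align is Align.NONE:
        return np.zeros((n, flat.n_oocytes))
    t1 = np.full((n, flat.n_oocytes), np.inf)
    src = fus if align is Align.FIRST_FUSION else pen
    mask = flat.fused if align is Align.FIRST_FUSION else np.ones(flat.n_sperm, bool)
    cols = np.flatnonzero(mask)
    if cols.size:
        rr = np.repeat(np.arange(n), cols.size)
        cc = np.tile(flat.oidx[cols], n)
        np.minimum.at(t1, (rr, cc), src[:, cols].ravel())
    if np.isinf(t1).any():
        which = align.value.replace("_", " ")
        raise ChronogramError(f"alignment event ({which}) absent for some oocyte")
    return t1


def _accumulate(
    deltas: np.ndarray, oidx: np.ndarray, grid: np.ndarray, n_oocytes: int, sign: float,
    acc: np.ndarray, include_nonpositive: bool,
) -> None:
    """Add cumulative step functions of the given event deltas into acc (O, T)."""
    step = grid[1] - grid[0] if len(grid) > 1 else 1.0
    d = deltas.ravel()
    ocol = np.broadcast_to(oidx, deltas.shape).ravel()
    ok = np.isfinite(d)
    if include_nonpositive:
        ok &= d <= grid[-1]
        bins = np.clip(np.ceil(np.maximum(d[ok], 0.0) / step).astype(np.intp), 0, len(grid) - 1)
    else:
        ok &= (d > 0) & (d <= grid[-1])
        bins = np.ceil(d[ok] / step).astype(np.intp)
    hist = np.zeros((n_oocytes, len(grid)))
    np.add.at(hist, (ocol[ok], bins), sign)
    acc += np.cumsum(hist, axis=1)


def count_curve(
    c: Chronogram,
    align: Align | str = Align.NONE,
    counted: Counted | str = Counted.PENETRATION,
    n_realizations: int = DEFAULT_N_REALIZATIONS,
    seed: int = 0,
    n_bootstrap: int = DEFAULT_N_BOOTSTRAP,
    grid_step: float = 1.0,
    grid_max: Optional[float] = None,
) -> CountCurve:
    """Mean cumulative event count per oocyte on a grid of minutes since the
    alignment event, with a 95% bootstrap confidence band.

    With ``align=first_fusion`` and ``counted`` penetration/fusion, events at
    or before the alignment event are excluded (the curves describe what
    happens *after* the oocyte is fertilized; for fusions this drops the
    fertilizing fusion itself).  ``pvs_occupancy`` counts realized
    penetrants not yet fused at each grid time, including those already in
    the PVS at alignment.
    """
    align, counted = Align(align), Counted(counted)
    if c.n_oocytes == 0:
        raise ChronogramError("empty chronogram")
    if n_realizations < 1:
        raise ValueError("n_realizations must be >= 1")
    if align is Align.FIRST_FUSION and any(o.fate is not Fate.FERTILIZED for o in c.oocytes):
        raise ChronogramError("align=first_fusion requires every oocyte fertilized")

    flat = _flatten(c)
    rng = np.random.default_rng(seed)
    if grid_max is None:
        grid_max = float(flat.horizon.max())
    grid = np.arange(0.0, grid_max + 0.5 * grid_step, grid_step)

    # per-oocyte mean over realizations, accumulated realization-by-realization
    acc = np.zeros((flat.n_oocytes, len(grid)))
    chunk = max(1, min(n_realizations, 200))
    done = 0
    while done < n_realizations:
        n = min(chunk, n_realizations - done)
        pen, fus = _sample_times(flat, rng, n)
        t1 = _alignment_times(flat, pen, fus, align)
        t1s = t1[:, flat.oidx] if flat.n_sperm else np.zeros((n, 0))
        if counted is Counted.PENETRATION:
            _accumulate(pen - t1s, flat.oidx, grid, flat.n_oocytes, 1.0, acc,
                        include_nonpositive=align is not Align.FIRST_FUSION)
        elif counted is Counted.FUSION:
            _accumulate(fus - t1s, flat.oidx, grid, flat.n_oocytes, 1.0, acc,
                        include_nonpositive=align is not Align.FIRST_FUSION)
        else:  # PVS occupancy = cumulative penetrations - cumulative fusions
            _accumulate(pen - t1s, flat.oidx, grid, flat.n_oocytes, 1.0, acc,
                        include_nonpositive=True)
            _accumulate(fus - t1s, flat.oidx, grid, flat.n_oocytes, -1.0, acc,
                        include_nonpositive=True)
        done += n
    per_oocyte = acc / n_realizations  # (O, T)

    mean = per_oocyte.mean(axis=0)
    if n_bootstrap > 0:
        idx = rng.integers(0, flat.n_oocytes, size=(n_bootstrap, flat.n_oocytes))
        boot = per_oocyte[idx].mean(axis=1)  # (B, T)
        ci_low = np.percentile(boot, 2.5, axis=0)
        ci_high = np.percentile(boot, 97.5, axis=0)
    else:
        boot = None
        ci_low = ci_high = mean.copy()
    # the band is a percentile interval; make it contain the point estimate
    ci_low = np.minimum(ci_low, mean)
    ci_high = np.maximum(ci_high, mean)
    return CountCurve(
        grid, mean, ci_low, ci_high, flat.n_oocytes, n_realizations, align, counted, boot
    )


def fusion_delay_curve(
    c: Chronogram,
    n_realizations: int = DEFAULT_N_REALIZATIONS,
    seed: int = 0,
    n_bootstrap: int = DEFAULT_N_BOOTSTRAP,
    grid_step: float = 1.0,
) -> DelayCurve:
    """Probability that a fertilizing sperm has fused within dt of its
    penetration, plus the mean penetration-to-fusion delay with 95% CI.

    Delays are pooled over all fused sperm; the CI bootstraps oocytes.
    """
    flat = _flatten(c)
    if not flat.fused.any():
        raise ChronogramError("chronogram contains no fused sperm")
    rng = np.random.default_rng(seed)
    pen, fus = _sample_times(flat, rng, n_realizations)
    f = flat.fused
    delays = fus[:, f] - pen[:, f]  # (R, n_fused)
    grid = np.arange(0.0, float(delays.max()) + grid_step, grid_step)
    prob = (delays.ravel()[None, :] <= grid[:, None]).mean(axis=1)
    mean_delay = float(delays.mean())
    o_of_fused = flat.oidx[f]
    per_oocyte = np.array(
        [delays[:, o_of_fused == o].mean() for o in np.unique(o_of_fused)]
    )
    if n_bootstrap > 0 and len(per_oocyte) > 0:
        idx = rng.integers(0, len(per_oocyte), size=(n_bootstrap, len(per_oocyte)))
        boot = per_oocyte[idx].mean(axis=1)
        lo, hi = float(np.percentile(boot, 2.5)), float(np.percentile(boot, 97.5))
    else:
        lo = hi = mean_delay
    return DelayCurve(grid, prob, mean_delay, lo, hi, int(f.sum()), n_realizations)
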