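"""Synthetic chronograms with the observation structure of the experiment.

Ground-truth penetration/fusion histories come from the mechanistic
simulator; the observation process then censors them the way the live
imaging did: each oocyte is visited in discrete rounds (default 0.5-10 min
long) separated by gaps ranging from a few minutes to more than an hour
(default 3-70 min).  A penetration seen during a round is dated exactly; one
that happened between rounds is bracketed by the inter-round gap.  Fused
sperm additionally progress through the post-fusion landmarks (head
disappearance, PB2 protrusion, angle crossover, PB2 completion), and the
stage visible at each round feeds the interval rules of
:mod:`fertkin.window_refinement`, which intersect into the fusion window.

Landmark delays are drawn per sperm from normals truncated to mean +/- 1 SD
(configurable) and redrawn if their ordering inverts.  The +/- 1 SD support
keeps every generated observation consistent with the refinement arithmetic,
whose interval rules span exactly mean +/- SD — the synthetic counterpart of
the empirical fact that all per-oocyte windows overlapped.

The recovery experiment closes the loop: generate, censor, estimate curves,
fit the block models, and report bias/spread/CI coverage of the kinetic
parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .block_fit import (
    FitError,
    fit_fusion_block,
    fit_penetration_block,
    implied_initial_rate,
)
from .chronogram import Chronogram, ChronogramError, OocyteRecord, SpermRecord, TimeWindow
from .polyspermy_sim import KineticParams, simulate_oocyte
from .window_refinement import (
    InconsistencyError,
    LandmarkSet,
    ObservationRound,
    ObservedState,
    refine_fusion_window,
)
from .window_stats import Align, Counted, count_curve, fusion_delay_curve

OBS_LOG_COLUMNS = [
    "oocyte_id",
    "sperm_id",
    "round_start_min",
    "round_end_min",
    "state",
    "horizon_min",
]


@dataclass(frozen=True)
class ObservationSchedule:
    """Random observation-round process: round lengths and inter-round gaps
    drawn uniformly within the given ranges (minutes), independently per
    oocyte, until the horizon."""

    round_duration_range: tuple[float, float] = (0.5, 10.0)
    gap_range: tuple[float, float] = (3.0, 70.0)

    def __post_init__(self) -> None:
        for lo, hi in (self.round_duration_range, self.gap_range):
            if lo < 0 or hi < lo:
                raise ValueError("ranges must satisfy 0 <= lo <= hi")

    def draw(self, horizon: float, rng: np.random.Generator) -> list[tuple[float, float]]:
        """Non-overlapping, increasing rounds [(start, end), ...] within [0, horizon]."""
        rounds = []
        t = 0.0
        while True:
            gap = rng.uniform(*self.gap_range)
            start = t + gap
            if start >= horizon:
                break
            dur = rng.uniform(*self.round_duration_range)
            end = min(start + dur, horizon)
            rounds.append((start, end))
            t = end
            if end >= horizon:
                break
        return rounds


@dataclass
class SpermTruth:
    """Ground truth for one sperm: exact event and landmark times."""

    sperm_id: str
    pen_time: float
    fusion_time: Optional[float] = None
    head_disappearance: Optional[float] = None
    pb2_onset: Optional[float] = None
    pb2_angle_crossover: Optional[float] = None
    pb2_complete: Optional[float] = None


@dataclass
class OocyteTruth:
    oocyte_id: str
    horizon: float
    sperm: list[SpermTruth] = field(default_factory=list)

    @property
    def first_fusion(self) -> Optional[float]:
        times = [s.fusion_time for s in self.sperm if s.fusion_time is not None]
        return min(times) if times else None


def _draw_landmarks(
    lm: LandmarkSet, rng: np.random.Generator, truncate_sd: float
) -> tuple[float, float, float, float]:
    """Post-fusion landmark delays: independent truncated normals, redrawn
    until positive and ordered."""
    marks = (lm.head_disappearance, lm.pb2_onset, lm.pb2_angle_crossover, lm.pb2_complete)

    def draw_one(mark):
        while True:
            d = rng.normal(mark.mean, mark.sd)
            if d > 0 and abs(d - mark.mean) <= truncate_sd * mark.sd:
                return d

    for _ in range(1000):
        ds = tuple(draw_one(m) for m in marks)
        if all(b > a for a, b in zip(ds, ds[1:])):
            return ds
    raise RuntimeError("could not draw ordered landmark delays")  # pragma: no cover


def generate_truth(
    p: KineticParams,
    lm: LandmarkSet = LandmarkSet(),
    seed: int = 0,
    truncate_sd: float = 1.0,
) -> list[OocyteTruth]:
    """Simulate per-oocyte event histories plus landmark times per fused sperm."""
    streams = np.random.SeedSequence(seed).spawn(p.n_oocytes)
    out = []
    for i, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        ev = simulate_oocyte(p, rng)
        oid = f"oo{i:05d}"
        sperm = []
        for j, pen in enumerate(ev.penetration_times):
            fus = ev.fusion_times[j] if np.isfinite(ev.fusion_times[j]) else None
            st = SpermTruth(f"sp{j:03d}", float(pen), None if fus is None else float(fus))
            if fus is not None:
                d = _draw_landmarks(lm, rng, truncate_sd)
                st.head_disappearance = fus + d[0]
                st.pb2_onset = fus + d[1]
                st.pb2_angle_crossover = fus + d[2]
                st.pb2_complete = fus + d[3]
            sperm.append(st)
        out.append(OocyteTruth(oid, p.horizon, sperm))
    return out


# ---------------------------------------------------------------------------
# Observation censoring
# ---------------------------------------------------------------------------

def _state_at(s: SpermTruth, t: float) -> ObservedState:
    """Stage of a sperm visible at instant t (after its penetration)."""
    if s.fusion_time is None or t < s.fusion_time:
        return ObservedState.UNFUSED_MOTILE
    if t < s.head_disappearance:
        return ObservedState.HEAD_VISIBLE_FUSED
    if t < s.pb2_onset:
        return ObservedState.FLAGELLUM_ONLY
    if t < s.pb2_angle_crossover:
        return ObservedState.PB2_PROTRUSION_ANGLE_GT_90
    if t < s.pb2_complete:
        return ObservedState.PB2_EXTRACTING_ANGLE_LT_90
    return ObservedState.PB2_COMPLETE


def censor(
    truth: list[OocyteTruth],
    sched: ObservationSchedule = ObservationSchedule(),
    lm: LandmarkSet = LandmarkSet(),
    seed: int = 0,
    condition: str = "synthetic",
) -> tuple[Chronogram, pd.DataFrame]:
    """Apply the round/gap observation process to ground truth.

    Returns the interval-censored chronogram plus the observation log it was
    derived from (schedule rows with empty sperm_id, one state row per sperm
    per round after its entry; live sightings appear as degenerate rounds).
    Events after the last round are censored out.
    """
    streams = np.random.SeedSequence(seed).spawn(len(truth))
    log_rows = []
    for o, ss in zip(truth, streams):
        rng = np.random.default_rng(ss)
        for s in o.sperm:
            if s.fusion_time is not None and s.fusion_time < s.pen_time:
                raise ChronogramError(
                    f"truth for {o.oocyte_id}/{s.sperm_id}: fusion before penetration"
                )
        rounds = sched.draw(o.horizon, rng)
        for start, end in rounds:
            log_rows.append((o.oocyte_id, "", start, end, "", o.horizon))
        last_end = rounds[-1][1] if rounds else 0.0
        for s in o.sperm:
            if s.pen_time > last_end:
                continue  # never observed
            live_pen = any(a <= s.pen_time <= b for a, b in rounds)
            if live_pen:
                log_rows.append(
                    (o.oocyte_id, s.sperm_id, s.pen_time, s.pen_time,
                     ObservedState.UNFUSED_MOTILE.value, o.horizon)
                )
            fus = s.fusion_time
            fused_seen = fus is not None and fus <= last_end
            for a, b in rounds:
                if b <= s.pen_time:
                    continue
                if fused_seen and a <= fus <= b:
                    if s.pen_time < a < fus:
                        # sperm already present and visibly unfused from the
                        # round start until the arrest
                        log_rows.append(
                            (o.oocyte_id, s.sperm_id, a, fus,
                             ObservedState.UNFUSED_MOTILE.value, o.horizon)
                        )
                    # arrest witnessed live: log the exact instant
                    log_rows.append(
                        (o.oocyte_id, s.sperm_id, fus, fus,
                         ObservedState.ARREST_OBSERVED.value, o.horizon)
                    )
                    continue
                mid = 0.5 * (max(a, s.pen_time) + b)
                state = _state_at(s, mid) if fused_seen else ObservedState.UNFUSED_MOTILE
                log_rows.append(
                    (o.oocyte_id, s.sperm_id, max(a, s.pen_time), b, state.value, o.horizon)
                )
    obs_log = pd.DataFrame(log_rows, columns=OBS_LOG_COLUMNS)
    chron = chronogram_from_observation_log(obs_log, lm, condition=condition)
    return chron, obs_log


def chronogram_from_observation_log(
    obs_log: pd.DataFrame, lm: LandmarkSet = LandmarkSet(), condition: str = ""
) -> Chronogram:
    """Build an interval-censored chronogram from an observation log.

    Penetration windows come from the gap between the last sperm-free round
    and the first round where the sperm appears (degenerate when the first
    row is a live sighting inside a round); fusion windows from intersecting
    the landmark rules over the sperm's state rows.
    """
    missing = [c for c in OBS_LOG_COLUMNS if c not in obs_log.columns]
    if missing:
        raise ChronogramError(f"observation log missing columns: {missing}")
    oocytes = []
    for oid, g in obs_log.groupby("oocyte_id", sort=True):
        horizon = float(g["horizon_min"].iloc[0])
        sched_rows = g[g["sperm_id"].isna() | (g["sperm_id"] == "")]
        sched = sorted(zip(sched_rows["round_start_min"], sched_rows["round_end_min"]))
        sperm_records = []
        sperm_groups = g[~(g["sperm_id"].isna() | (g["sperm_id"] == ""))].groupby(
            "sperm_id", sort=True
        )
        for sid, sg in sperm_groups:
            sg = sg.sort_values(["round_start_min", "round_end_min"])
            first_start = float(sg["round_start_min"].iloc[0])
            first_end = float(sg["round_end_min"].iloc[0])
            first_state = str(sg["state"].iloc[0])
            # only a live penetration sighting is logged as a degenerate
            # round in the still-unfused state
            live = (
                first_start == first_end
                and first_state == ObservedState.UNFUSED_MOTILE.value
            )
            if live:
                pen = TimeWindow(first_start, first_start)
            else:
                prev_end = max((b for a, b in sched if b <= first_start), default=0.0)
                pen = TimeWindow(prev_end, min(first_start, horizon))
            rounds = [
                ObservationRound(float(r.round_start_min), float(r.round_end_min),
                                 ObservedState(r.state))
                for r in sg.itertuples()
            ]
            fused_states = [r for r in rounds if r.state is not ObservedState.UNFUSED_MOTILE]
            fusion = None
            if fused_states:
                fusion = refine_fusion_window(rounds, lm, pen, horizon)
            sperm_records.append(SpermRecord(str(sid), str(oid), pen, fusion))
        oocytes.append(OocyteRecord(str(oid), sperm_records, horizon))
    return Chronogram(oocytes, condition)


# ---------------------------------------------------------------------------
# Parameter-recovery experiment
# ---------------------------------------------------------------------------

def _estimate_replicate(
    chron: Chronogram,
    n_realizations: int,
    n_bootstrap: int,
    seed: int,
) -> dict:
    """Curve estimation + block fits on one censored chronogram."""
    fert = chron.fertilized()
    out: dict = {"n_fertilized": fert.n_oocytes}
    if fert.n_oocytes == 0:
        return out
    pen_curve = count_curve(
        fert, Align.FIRST_FUSION, Counted.PENETRATION,
        n_realizations=n_realizations, seed=seed, n_bootstrap=n_bootstrap,
    )
    try:
        pfit = fit_penetration_block(pen_curve)
    except FitError:
        pfit = None
    if pfit is not None and pfit.tau_identified:
        out.update(
            A_hat=pfit.A, tau_pb_hat=pfit.tau_pb,
            lambda0_hat=implied_initial_rate(pfit),
            tau_pb_ci_low=pfit.tau_ci[0] if pfit.tau_ci else np.nan,
            tau_pb_ci_high=pfit.tau_ci[1] if pfit.tau_ci else np.nan,
        )
    n_extra = sum(max(len(o.fused_sperm) - 1, 0) for o in fert.oocytes)
    out["n_extra_fusions"] = n_extra
    if n_extra > 0:
        fus_curve = count_curve(
            fert, Align.FIRST_FUSION, Counted.FUSION,
            n_realizations=n_realizations, seed=seed + 1, n_bootstrap=n_bootstrap,
        )
        ffit = fit_fusion_block(fus_curve, n_extra / fert.n_oocytes)
        out.update(
            tau_fb_hat=ffit.tau_fb,
            tau_fb_ci_low=ffit.tau_ci[0] if ffit.tau_ci else np.nan,
            tau_fb_ci_high=ffit.tau_ci[1] if ffit.tau_ci else np.nan,
        )
    delay = fusion_delay_curve(
        fert, n_realizations=n_realizations, seed=seed + 2, n_bootstrap=n_bootstrap
    )
    out.update(
        delay_mean_hat=delay.mean_delay,
        delay_ci_low=delay.ci_low,
        delay_ci_high=delay.ci_high,
    )
    return out


def recovery_experiment(
    p: KineticParams,
    sched: ObservationSchedule = ObservationSchedule(),
    lm: LandmarkSet = LandmarkSet(),
    n_replicates: int = 10,
    seed: int = 0,
    n_realizations: int = 300,
    n_bootstrap: int = 300,
) -> pd.DataFrame:
    """Generate-censor-estimate replicates; one row per replicate with point
    estimates, bootstrap CIs, and truth-coverage flags for lambda0, tau_PB,
    tau_FB and the fusion-delay mean."""
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    rows = []
    for rep in range(n_replicates):
        base = seed + 1000 * rep
        truth = generate_truth(p, lm, seed=base)
        chron, _ = censor(truth, sched, lm, seed=base + 1)
        row = {"replicate": rep, **_estimate_replicate(chron, n_realizations, n_bootstrap, base + 2)}
        if "tau_pb_ci_low" in row and np.isfinite(row.get("tau_pb_ci_low", np.nan)):
            row["tau_pb_covered"] = row["tau_pb_ci_low"] <= p.tau_pb <= row["tau_pb_ci_high"]
        if "tau_fb_ci_low" in row and np.isfinite(row.get("tau_fb_ci_low", np.nan)):
            row["tau_fb_covered"] = row["tau_fb_ci_low"] <= p.tau_fb <= row["tau_fb_ci_high"]
        if "delay_ci_low" in row:
            row["delay_covered"] = row["delay_ci_low"] <= p.delay_mean <= row["delay_ci_high"]
        rows.append(row)
    return pd.DataFrame(rows)


def recovery_summary(report: pd.DataFrame, p: KineticParams) -> dict:
    """Bias, spread and CI coverage across replicates."""
    out = {}
    for col, true in (
        ("lambda0_hat", p.lambda0),
        ("tau_pb_hat", p.tau_pb),
        ("tau_fb_hat", p.tau_fb),
        ("delay_mean_hat", p.delay_mean),
    ):
        if col in report:
            vals = report[col].dropna()
            if len(vals):
                out[col] = {
                    "true": true,
                    "mean": float(vals.mean()),
                    "bias": float(vals.mean() - true),
                    "sd": float(vals.std(ddof=1)) if len(vals) > 1 else 0.0,
                    "n": int(len(vals)),
                }
    for col in ("tau_pb_covered", "tau_fb_covered", "delay_covered"):
        if col in report:
            flags = report[col].dropna()
            if len(flags):
                out[col.replace("_covered", "_coverage")] = float(flags.mean())
    return out
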