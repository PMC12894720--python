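"""Fusion-window refinement from second-polar-body landmarks.

Fusion of a sperm with the oolemma triggers a stereotyped sequence of
morphological landmarks whose delays after fusion were calibrated with
mean +/- SD:

  (i)   sperm head disappearance completed     24 +/- 3 min after fusion
  (ii)  onset of PB2 protrusion                28 +/- 2 min after fusion
  (iii) PB2 contact angle crosses 90 degrees   49 +/- 6 min after fusion
  (iv)  PB2 extrusion completed                73 +/- 10 min after fusion

Observing which stage an oocyte is in at time t_obs therefore brackets the
fusion time t_F.  Using mean+SD for the latest and mean-SD for the earliest
plausible completion of each landmark yields six interval rules (offsets
27, 21, 26/55, 43/83 and 63 min); the refined fusion window is the
intersection of the rule windows across all observation rounds, further
bounded below by the penetration window.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

from .chronogram import TimeWindow


class InconsistencyError(ValueError):
    """Observed states are mutually inconsistent (no common fusion window)."""


@dataclass(frozen=True)
class Landmark:
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.mean <= 0 or self.sd <= 0:
            raise ValueError("landmark mean and sd must be positive")

    @property
    def early(self) -> float:
        """Earliest plausible completion delay (mean - sd)."""
        return self.mean - self.sd

    @property
    def late(self) -> float:
        """Latest plausible completion delay (mean + sd)."""
        return self.mean + self.sd


@dataclass(frozen=True)
class LandmarkSet:
    """Calibrated post-fusion landmark delays (minutes, mean +/- SD)."""

    head_disappearance: Landmark = Landmark(24.0, 3.0)
    pb2_onset: Landmark = Landmark(28.0, 2.0)
    pb2_angle_crossover: Landmark = Landmark(49.0, 6.0)
    pb2_complete: Landmark = Landmark(73.0, 10.0)

    def __post_init__(self) -> None:
        means = [
            self.head_disappearance.mean,
            self.pb2_onset.mean,
            self.pb2_angle_crossover.mean,
            self.pb2_complete.mean,
        ]
        if any(b <= a for a, b in zip(means, means[1:])):
            raise ValueError("landmark means must be strictly increasing")


class ObservedState(str, Enum):
    """Per-round sperm/oocyte state used to date the fusion."""

    UNFUSED_MOTILE = "unfused_motile"
    ARREST_OBSERVED = "arrest_observed"
    HEAD_VISIBLE_FUSED = "head_visible_fused"
    FLAGELLUM_ONLY = "flagellum_only"
    PB2_PROTRUSION_ANGLE_GT_90 = "pb2_protrusion_angle_gt_90"
    PB2_EXTRACTING_ANGLE_LT_90 = "pb2_extracting_angle_lt_90"
    PB2_COMPLETE = "pb2_complete"


@dataclass(frozen=True)
class ObservationRound:
    """One observation of a sperm/oocyte, spanning [t_start, t_end] minutes."""

    t_start: float
    t_end: float
    state: ObservedState

    def __post_init__(self) -> None:
        if self.t_start > self.t_end:
            raise ValueError(f"round start {self.t_start} after end {self.t_end}")

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.t_start + self.t_end)


def penetration_window_from_rounds(prev_round_end: float, next_round_start: float) -> TimeWindow:
    """Penetration window for an entry seen between two observation rounds.

    A penetration observed live yields the degenerate window at the observed
    time (pass the same value twice).
    """
    if prev_round_end > next_round_start:
        raise ValueError(
            f"previous round end {prev_round_end} after next round start {next_round_start}"
        )
    return TimeWindow(prev_round_end, next_round_start)


def rule_window(
    state: ObservedState, t_obs: float, lm: LandmarkSet, horizon: float
) -> TimeWindow:
    """Fusion-time window implied by one observed state at time t_obs.

    With the default landmark calibration the bounds are: still motile ->
    [t_obs, horizon]; arrest seen live -> t_obs +/- 1; head still visible ->
    [t_obs-27, t_obs]; flagellum only -> [0, t_obs-21]; PB2 protruding at
    angle >90 deg -> [t_obs-55, t_obs-26]; PB2 extracting at angle <90 deg ->
    [t_obs-83, t_obs-43]; PB2 complete -> [0, t_obs-63].  One-sided rules are
    closed by clipping to [0, horizon].
    """
    if not (0 <= t_obs <= horizon):
        raise ValueError(f"t_obs {t_obs} outside [0, {horizon}]")
    head, onset = lm.head_disappearance, lm.pb2_onset
    cross, comp = lm.pb2_angle_crossover, lm.pb2_complete
    if state is ObservedState.UNFUSED_MOTILE:
        lo, hi = t_obs, horizon
    elif state is ObservedState.ARREST_OBSERVED:
        lo, hi = t_obs - 1.0, t_obs + 1.0
    elif state is ObservedState.HEAD_VISIBLE_FUSED:
        lo, hi = t_obs - head.late, t_obs
    elif state is ObservedState.FLAGELLUM_ONLY:
        lo, hi = 0.0, t_obs - head.early
    elif state is ObservedState.PB2_PROTRUSION_ANGLE_GT_90:
        lo, hi = t_obs - cross.late, t_obs - onset.early
    elif state is ObservedState.PB2_EXTRACTING_ANGLE_LT_90:
        lo, hi = t_obs - comp.late, t_obs - cross.early
    elif state is ObservedState.PB2_COMPLETE:
        lo, hi = 0.0, t_obs - comp.early
    else:  # pragma: no cover
        raise ValueError(f"unknown state {state!r}")
    if hi < 0:
        raise InconsistencyError(
            f"state {state.value!r} at t_obs={t_obs} implies fusion before insemination"
        )
    return TimeWindow(max(lo, 0.0), min(hi, horizon))


def refine_fusion_window(
    rounds: list[ObservationRound],
    lm: LandmarkSet,
    pen: TimeWindow,
    horizon: float,
) -> TimeWindow:
    """Intersect the per-round rule windows into one fusion window.

    Each round contributes rule_window(state, round midpoint); the result is
    further intersected with [pen.lower, horizon] since fusion cannot precede
    penetration.  Raises InconsistencyError (reporting the conflicting
    rounds) if the intersection is empty — correctly identified states always
    overlap.
    """
    if not rounds:
        raise ValueError("refine_fusion_window requires at least one round")
    window = TimeWindow(min(pen.lower, horizon), horizon)
    applied: list[tuple[ObservationRound, TimeWindow]] = []
    for rnd in sorted(rounds, key=lambda r: (r.t_start, r.t_end, r.state.value)):
        w = rule_window(rnd.state, rnd.midpoint, lm, horizon)
        nxt = window.intersect(w)
        if nxt is None:
            conflict = ", ".join(
                f"{r.state.value}@[{r.t_start},{r.t_end}]->[{w2.lower},{w2.upper}]"
                for r, w2 in applied
            )
            raise InconsistencyError(
                f"round {rnd.state.value}@[{rnd.t_start},{rnd.t_end}] gives "
                f"[{w.lower},{w.upper}], disjoint from the running intersection "
                f"[{window.lower},{window.upper}] (prior rounds: {conflict or 'none'})"
            )
        window = nxt
        applied.append((rnd, w))
    return window
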