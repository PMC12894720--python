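"""Interval-censored penetration/fusion chronograms.

A *chronogram* records, for each oocyte in an in-vitro fertilization
experiment, the time window within which each spermatozoon entered the
perivitelline space (PVS, penetration) and — if it fertilized the oocyte —
the window within which it fused with the oolemma.  Windows arise because
oocytes are observed in discrete rounds: an event seen live gets a
degenerate (zero-width) window, an event inferred between rounds gets the
inter-round gap, and fusion windows are further narrowed by second-polar-body
landmarks (see :mod:`fertkin.window_refinement`).

Times are minutes post-insemination throughout; the default observation
horizon is 240 min (a 4 h recording).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

import pandas as pd

DEFAULT_HORIZON = 240.0

TABLE_COLUMNS = [
    "oocyte_id",
    "sperm_id",
    "pen_lower_min",
    "pen_upper_min",
    "fus_lower_min",
    "fus_upper_min",
    "horizon_min",
    "condition",
]


class ChronogramError(ValueError):
    """Invalid chronogram structure or table contents."""


@dataclass(frozen=True, order=True)
class TimeWindow:
    """Closed interval of minutes post-insemination bounding one event.

    A degenerate window (``lower == upper``) encodes a directly observed
    event time.
    """

    lower: float
    upper: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.lower) and math.isfinite(self.upper)):
            raise ChronogramError(f"non-finite window bounds ({self.lower}, {self.upper})")
        if self.lower < 0:
            raise ChronogramError(f"window lower bound {self.lower} < 0")
        if self.lower > self.upper:
            raise ChronogramError(
                f"window lower bound {self.lower} exceeds upper bound {self.upper}"
            )

    @property
    def width(self) -> float:
        return self.upper - self.lower

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.lower + self.upper)

    def contains(self, t: float) -> bool:
        return self.lower <= t <= self.upper

    def intersect(self, other: "TimeWindow") -> Optional["TimeWindow"]:
        """Intersection with another window, or None if disjoint."""
        lo = max(self.lower, other.lower)
        hi = min(self.upper, other.upper)
        if lo > hi:
            return None
        return TimeWindow(lo, hi)

    def clip(self, lo: float, hi: float) -> "TimeWindow":
        return TimeWindow(min(max(self.lower, lo), hi), min(max(self.upper, lo), hi))


@dataclass(frozen=True)
class SpermRecord:
    """One spermatozoon observed in the PVS of one oocyte."""

    sperm_id: str
    oocyte_id: str
    penetration: TimeWindow
    fusion: Optional[TimeWindow] = None

    def __post_init__(self) -> None:
        if self.fusion is not None and self.fusion.upper < self.penetration.lower:
            raise ChronogramError(
                f"sperm {self.sperm_id!r} of oocyte {self.oocyte_id!r}: fusion window "
                f"[{self.fusion.lower}, {self.fusion.upper}] certainly precedes penetration "
                f"window [{self.penetration.lower}, {self.penetration.upper}]"
            )

    @property
    def fused(self) -> bool:
        return self.fusion is not None


class Fate(str, Enum):
    """Outcome of an oocyte over the observation period."""

    FERTILIZED = "fertilized"
    PENETRATED_UNFERTILIZED = "penetrated_unfertilized"
    UNPENETRATED = "unpenetrated"


class SpermCategory(str, Enum):
    """Display category of a sperm within a fertilized oocyte.

    Mirrors the black/green/purple/yellow chronogram colouring: the fused
    (fertilizing) sperm, sperm that certainly entered the PVS before the
    first fertilization, sperm that certainly entered after it, and sperm
    whose ordering relative to fertilization is uncertain.
    """

    FERTILIZING = "fertilizing"
    PRE_FERTILIZATION = "pre_fertilization"
    POST_FERTILIZATION = "post_fertilization"
    AMBIGUOUS = "ambiguous"


@dataclass
class OocyteRecord:
    """One oocyte with its observed sperm and observation horizon."""

    oocyte_id: str
    sperm: list[SpermRecord] = field(default_factory=list)
    horizon: float = DEFAULT_HORIZON

    def __post_init__(self) -> None:
        ids = [s.sperm_id for s in self.sperm]
        if len(set(ids)) != len(ids):
            raise ChronogramError(f"duplicate sperm ids in oocyte {self.oocyte_id!r}")
        for s in self.sperm:
            if s.oocyte_id != self.oocyte_id:
                raise ChronogramError(
                    f"sperm {s.sperm_id!r} carries oocyte id {s.oocyte_id!r}, "
                    f"expected {self.oocyte_id!r}"
                )

    @property
    def fate(self) -> Fate:
        if not self.sperm:
            return Fate.UNPENETRATED
        if any(s.fused for s in self.sperm):
            return Fate.FERTILIZED
        return Fate.PENETRATED_UNFERTILIZED

    @property
    def fused_sperm(self) -> list[SpermRecord]:
        return [s for s in self.sperm if s.fused]

    def first_fertilizing(self) -> SpermRecord:
        """The fused sperm taken as the fertilization reference.

        Deterministic convention: smallest fusion-window lower bound, ties
        broken by sperm id.
        """
        fused = self.fused_sperm
        if not fused:
            raise ChronogramError(f"oocyte {self.oocyte_id!r} has no fused sperm")
        return min(fused, key=lambda s: (s.fusion.lower, s.sperm_id))


@dataclass
class Chronogram:
    """A cohort of oocytes sharing an experimental condition label."""

    oocytes: list[OocyteRecord] = field(default_factory=list)
    condition_label: str = ""

    def __post_init__(self) -> None:
        ids = [o.oocyte_id for o in self.oocytes]
        if len(set(ids)) != len(ids):
            raise ChronogramError("duplicate oocyte ids in chronogram")

    @property
    def n_oocytes(self) -> int:
        return len(self.oocytes)

    def fertilized(self) -> "Chronogram":
        """Sub-chronogram of fertilized oocytes only."""
        return Chronogram(
            [o for o in self.oocytes if o.fate is Fate.FERTILIZED], self.condition_label
        )


# ---------------------------------------------------------------------------
# Table I/O
# ---------------------------------------------------------------------------

def _parse_bound(value, column: str, row: int) -> float:
    try:
        out = float(value)
    except (TypeError, ValueError):
        raise ChronogramError(f"row {row}: non-numeric {column} value {value!r}") from None
    if math.isnan(out):
        raise ChronogramError(f"row {row}: missing {column}")
    return out


def sniff_delimiter(path) -> str:
    """Comma or tab, detected from the header line."""
    with open(path) as fh:
        header = fh.readline()
    return "\t" if "\t" in header else ","


def read_chronogram(path) -> Chronogram:
    """Read a chronogram table (comma- or tab-delimited, autodetected).

    One row per sperm; oocytes with no sperm appear as a row with empty
    ``sperm_id`` and ``pen_*`` fields; empty ``fus_*`` fields mean the sperm
    never fused.
    """
    df = pd.read_csv(
        path,
        sep=sniff_delimiter(path),
        dtype={"oocyte_id": str, "sperm_id": str},
        float_precision="round_trip",
    )
    missing = [c for c in TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ChronogramError(f"chronogram table missing columns: {missing}")

    oocytes: dict[str, dict] = {}
    condition = ""
    for i, row in df.iterrows():
        oid = row["oocyte_id"]
        if pd.isna(oid) or str(oid) == "":
            raise ChronogramError(f"row {i}: missing oocyte_id")
        oid = str(oid)
        horizon = _parse_bound(row["horizon_min"], "horizon_min", i)
        entry = oocytes.setdefault(oid, {"horizon": horizon, "sperm": []})
        if not pd.isna(row["condition"]):
            condition = str(row["condition"])
        sid = row["sperm_id"]
        if pd.isna(sid) or str(sid) == "":
            continue  # oocyte marker row: unpenetrated
        sid = str(sid)
        if pd.isna(row["pen_lower_min"]) or pd.isna(row["pen_upper_min"]):
            raise ChronogramError(f"row {i}: sperm {sid!r} lacks penetration bounds")
        fus_lo, fus_hi = row["fus_lower_min"], row["fus_upper_min"]
        if pd.isna(fus_lo) != pd.isna(fus_hi):
            raise ChronogramError(f"row {i}: fusion bounds must both be present or both empty")
        try:
            pen = TimeWindow(
                _parse_bound(row["pen_lower_min"], "pen_lower_min", i),
                _parse_bound(row["pen_upper_min"], "pen_upper_min", i),
            )
            fusion = None
            if not pd.isna(fus_lo):
                fusion = TimeWindow(
                    _parse_bound(fus_lo, "fus_lower_min", i),
                    _parse_bound(fus_hi, "fus_upper_min", i),
                )
            entry["sperm"].append(SpermRecord(sid, oid, pen, fusion))
        except ChronogramError as exc:
            raise ChronogramError(f"row {i}: {exc}") from None

    records = [
        OocyteRecord(oid, entry["sperm"], entry["horizon"]) for oid, entry in oocytes.items()
    ]
    return Chronogram(records, condition)


def write_chronogram(c: Chronogram, path) -> None:
    """Write a chronogram table (CSV), rows ordered by oocyte then sperm id.

    Deterministic: two writes of the same object are byte-identical.
    """
    rows = []
    for o in sorted(c.oocytes, key=lambda o: o.oocyte_id):
        if not o.sperm:
            rows.append(
                {
                    "oocyte_id": o.oocyte_id,
                    "sperm_id": "",
                    "pen_lower_min": "",
                    "pen_upper_min": "",
                    "fus_lower_min": "",
                    "fus_upper_min": "",
                    "horizon_min": o.horizon,
                    "condition": c.condition_label,
                }
            )
        for s in sorted(o.sperm, key=lambda s: s.sperm_id):
            rows.append(
                {
                    "oocyte_id": o.oocyte_id,
                    "sperm_id": s.sperm_id,
                    "pen_lower_min": s.penetration.lower,
                    "pen_upper_min": s.penetration.upper,
                    "fus_lower_min": s.fusion.lower if s.fused else "",
                    "fus_upper_min": s.fusion.upper if s.fused else "",
                    "horizon_min": o.horizon,
                    "condition": c.condition_label,
                }
            )
    df = pd.DataFrame(rows, columns=TABLE_COLUMNS)
    df.to_csv(path, index=False, float_format="%.10g")


# ---------------------------------------------------------------------------
# Classification and summaries
# ---------------------------------------------------------------------------

def classify_sperm(o: OocyteRecord) -> dict[str, SpermCategory]:
    """Assign each sperm of a fertilized oocyte its chronogram category.

    Non-fused sperm are classified by *certain* window ordering relative to
    the first fertilizing sperm: pre-fertilization if its penetration window
    certainly precedes that sperm's penetration window, post-fertilization if
    it certainly follows that sperm's fusion window, otherwise ambiguous.
    Boundary equality counts as certain (closed intervals, measure-zero
    overlap).
    """
    if o.fate is not Fate.FERTILIZED:
        raise ChronogramError(
            f"classify_sperm requires a fertilized oocyte; {o.oocyte_id!r} is {o.fate.value}"
        )
    ref = o.first_fertilizing()
    out: dict[str, SpermCategory] = {}
    for s in o.sperm:
        if s.fused:
            out[s.sperm_id] = SpermCategory.FERTILIZING
        elif s.penetration.upper <= ref.penetration.lower:
            out[s.sperm_id] = SpermCategory.PRE_FERTILIZATION
        elif s.penetration.lower >= ref.fusion.upper:
            out[s.sperm_id] = SpermCategory.POST_FERTILIZATION
        else:
            out[s.sperm_id] = SpermCategory.AMBIGUOUS
    return out


def _first_penetrant_outcome(o: OocyteRecord) -> str:
    """Outcome of the certainly-first penetrating sperm of a fertilized oocyte.

    Returns 'fertilized' / 'failed' if one sperm's penetration window
    certainly precedes all others' (upper <= their lowers), else 'ambiguous'.
    """
    for s in o.sperm:
        if all(
            s.penetration.upper <= u.penetration.lower
            for u in o.sperm
            if u.sperm_id != s.sperm_id
        ):
            return "fertilized" if s.fused else "failed"
    return "ambiguous"


def summarize(c: Chronogram) -> dict:
    """Descriptive summary: fates, penetration multiplicities, first-penetrant
    outcomes, fused fractions among certain pre-/post-fertilization
    penetrants, and the dispermy count."""
    fates = {f.value: 0 for f in Fate}
    pen_per_oocyte: dict[int, int] = {}
    first = {"fertilized": 0, "failed": 0, "ambiguous": 0}
    pre_total = pre_fused = post_total = post_fused = 0
    dispermic = 0
    for o in c.oocytes:
        fates[o.fate.value] += 1
        n = len(o.sperm)
        pen_per_oocyte[n] = pen_per_oocyte.get(n, 0) + 1
        if o.fate is not Fate.FERTILIZED:
            continue
        if len(o.fused_sperm) >= 2:
            dispermic += 1
        first[_first_penetrant_outcome(o)] += 1
        ref = o.first_fertilizing()
        for s in o.sperm:
            # certain ordering relative to the first fusion window
            if s.penetration.upper <= ref.fusion.lower:
                pre_total += 1
                pre_fused += s.fused
            elif s.penetration.lower >= ref.fusion.upper and s.sperm_id != ref.sperm_id:
                post_total += 1
                post_fused += s.fused
    n_fert = fates[Fate.FERTILIZED.value]

    def frac(a, b):
        return a / b if b else float("nan")

    return {
        "n_oocytes": c.n_oocytes,
        "fate_counts": fates,
        "penetrations_per_oocyte": dict(sorted(pen_per_oocyte.items())),
        "n_fertilized": n_fert,
        "first_penetrant_counts": first,
        "first_penetrant_fractions": {k: frac(v, n_fert) for k, v in first.items()},
        "pre_fertilization_penetrants": pre_total,
        "pre_fertilization_fused_fraction": frac(pre_fused, pre_total),
        "post_fertilization_penetrants": post_total,
        "post_fertilization_fused_fraction": frac(post_fused, post_total),
        "dispermic_oocytes": dispermic,
    }
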