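"""Water-borne exposure scenarios for EE2 and TB.

A scenario is a set of non-overlapping time segments per chemical, each with
a nominal water concentration.  Flow-through segments hold the concentration
constant; static segments may decay exponentially from the nominal value
(half-life in hours).  Outside all segments — including depuration phases —
the water concentration is zero.  Concentrations are stored in nmol/L;
ng/L and ug/L inputs are converted via molecular weight.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

from .parameters import MOLECULAR_WEIGHTS

__all__ = ["Segment", "ExposureScenario", "build_scenario", "to_nmol_per_l"]

EXPOSABLE = ("EE2", "TB")


def to_nmol_per_l(value: float, unit: str, chemical: str) -> float:
    """Convert a water concentration to nmol/L."""
    mw = MOLECULAR_WEIGHTS[chemical]
    unit = unit.replace("µ", "u").lower()
    if unit in ("nmol/l", "nm"):
        return float(value)
    if unit == "ng/l":
        return float(value) / mw
    if unit in ("ug/l", "mcg/l"):
        return float(value) * 1000.0 / mw
    raise ValueError(f"unsupported concentration unit: {unit!r}")


@dataclass(frozen=True)
class Segment:
    t_start: float            # hr
    t_end: float              # hr
    concentration: float      # nmol/L, nominal at t_start
    decay_halflife: float = math.inf   # hr; inf = flow-through

    def __post_init__(self):
        if self.t_end <= self.t_start:
            raise ValueError("segment must have t_end > t_start")
        if self.concentration < 0:
            raise ValueError("concentration must be non-negative")
        if self.decay_halflife <= 0:
            raise ValueError("decay half-life must be positive")

    @property
    def decay_rate(self) -> float:
        return 0.0 if math.isinf(self.decay_halflife) \
            else math.log(2.0) / self.decay_halflife


@dataclass
class ExposureScenario:
    """Piecewise exposure profiles, one list of segments per chemical."""

    segments: dict = field(default_factory=dict)   # chemical -> [Segment]

    def __post_init__(self):
        for chem, segs in self.segments.items():
            if chem not in EXPOSABLE:
                raise ValueError(f"unknown exposure chemical: {chem!r}")
            segs.sort(key=lambda s: s.t_start)
            for a, b in zip(segs, segs[1:]):
                if b.t_start < a.t_end:
                    raise ValueError(f"overlapping segments for {chem}")

    @classmethod
    def zero(cls) -> "ExposureScenario":
        return cls({})

    @classmethod
    def single(cls, chemical: str, conc: float, unit: str,
               t_start: float = 0.0, t_end: float = 504.0,
               decay_halflife: float = math.inf) -> "ExposureScenario":
        c = to_nmol_per_l(conc, unit, chemical)
        return cls({chemical: [Segment(t_start, t_end, c, decay_halflife)]})

    def combined(self, other: "ExposureScenario") -> "ExposureScenario":
        """Mixture: merge segment lists of two scenarios."""
        segs = {c: list(s) for c, s in self.segments.items()}
        for c, s in other.segments.items():
            segs.setdefault(c, []).extend(s)
        return ExposureScenario(segs)

    def water_concentration(self, chemical: str, t: float) -> float:
        """Water concentration of ``chemical`` at time t (nmol/L)."""
        if t < 0:
            raise ValueError("time must be non-negative")
        for seg in self.segments.get(chemical, ()):
            if seg.t_start <= t < seg.t_end:
                return seg.concentration * math.exp(
                    -seg.decay_rate * (t - seg.t_start))
        return 0.0

    @property
    def breakpoints(self) -> list:
        """Sorted segment boundaries (integration restart points)."""
        pts = set()
        for segs in self.segments.values():
            for s in segs:
                pts.add(s.t_start)
                pts.add(s.t_end)
        return sorted(pts)

    @property
    def end_time(self) -> float:
        pts = self.breakpoints
        return pts[-1] if pts else 0.0


def build_scenario(spec) -> ExposureScenario:
    """Build a scenario from a config mapping or a CSV schedule.

    Mapping form: ``{"segments": [{"chemical": "TB", "t_start_hr": 0,
    "t_end_hr": 504, "conc": 0.5, "unit": "ug/L",
    "decay_halflife_hr": null}, ...]}``.  A path-like / DataFrame argument
    is read as a CSV with the same columns.  An empty spec yields a
    zero-exposure scenario.
    """
    if spec is None:
        return ExposureScenario.zero()
    if isinstance(spec, ExposureScenario):
        return spec
    if isinstance(spec, dict):
        rows = spec.get("segments", [])
    else:
        df = spec if isinstance(spec, pd.DataFrame) else pd.read_csv(spec)
        rows = df.to_dict("records")
    segments: dict = {}
    for row in rows:
        chem = str(row["chemical"]).upper()
        if chem not in EXPOSABLE:
            raise ValueError(f"unknown exposure chemical: {chem!r}")
        conc = to_nmol_per_l(float(row["conc"]), str(row.get("unit", "nmol/L")), chem)
        hl = row.get("decay_halflife_hr")
        hl = math.inf if hl in (None, "", float("inf")) or pd.isna(hl) else float(hl)
        segments.setdefault(chem, []).append(
            Segment(float(row["t_start_hr"]), float(row["t_end_hr"]), conc, hl))
    return ExposureScenario(segments)
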