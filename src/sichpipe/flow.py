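"""Flow-cytometry gating for the DEspR+CD11b+ neutrophil subset.

The workflow mirrors standard two-color immunotyping: (1) identify the
neutrophil cloud on the forward/side-scatter plane with a polygon gate,
(2) set fluorescence positivity thresholds from a control tube (isotype
by default, FMO as an alternative) at a high quantile of the control
distribution, (3) partition gated events into quadrants by the two
thresholds; quadrant 2 (both channels above threshold) counts the
DEspR+CD11b+ double positives.  An absolute Q2 concentration requires an
external anchor neutrophil concentration (cells/μl).

Events travel as pandas DataFrames with columns ``fsc``, ``ssc``,
``fl_despr``, ``fl_cd11b`` and ``is_control`` in
{stain, isotype, fmo_despr, fmo_cd11b}.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from shapely import Point, contains_xy
from shapely.geometry import Polygon

from .errors import ConfigError, DomainError, GeometryError

EVENT_COLUMNS = ["fsc", "ssc", "fl_despr", "fl_cd11b", "is_control"]
CONTROL_CLASSES = ("stain", "isotype", "fmo_despr", "fmo_cd11b")

#: Default scatter gate for the synthetic neutrophil cloud (fsc, ssc) —
#: a generous box around the granulocyte region of the generator.
DEFAULT_NEUTROPHIL_GATE = [
    (400.0, 300.0), (1000.0, 300.0), (1000.0, 1000.0), (400.0, 1000.0)]


@dataclass
class QuadrantResult:
    """Quadrant counts/fractions for one gated sample."""

    t_despr: float
    t_cd11b: float
    counts: dict[str, int]       # q1..q4
    fractions: dict[str, float]
    q2_fraction: float
    q2_concentration: float | None = None

    def __post_init__(self):
        total = sum(self.counts.values())
        if total and abs(sum(self.fractions.values()) - 1.0) > 1e-9:
            raise DomainError("quadrant fractions must sum to 1")


def validate_events(events: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in EVENT_COLUMNS if c not in events.columns]
    if missing:
        raise ConfigError(f"event table missing column(s): {missing}")
    num = events[["fsc", "ssc", "fl_despr", "fl_cd11b"]].to_numpy(float)
    if not np.isfinite(num).all():
        raise DomainError("event channels must be finite")
    return events


def gate_neutrophils(events: pd.DataFrame,
                     gate: list[tuple[float, float]] | None = None
                     ) -> pd.DataFrame:
    """Keep events inside (boundary included) the scatter-gate polygon."""
    validate_events(events)
    poly = Polygon(gate if gate is not None else DEFAULT_NEUTROPHIL_GATE)
    if not poly.is_valid or poly.area == 0:
        raise GeometryError("gate polygon is self-intersecting or degenerate")
    x = events["fsc"].to_numpy(float)
    y = events["ssc"].to_numpy(float)
    inside = contains_xy(poly, x, y)
    # boundary counts as inside: covers = contains + touches
    if not inside.all():
        on_edge = ~inside
        edge_pts = [Point(px, py)
                    for px, py in zip(x[on_edge], y[on_edge])]
        inside[on_edge] = [poly.covers(p) for p in edge_pts]
    return events.loc[inside].reset_index(drop=True)


def quadrant_thresholds(controls: pd.DataFrame, quantile: float = 0.999,
                        control: str = "isotype") -> tuple[float, float]:
    """Positivity thresholds from a control tube.

    Each channel's threshold is the given quantile of the matching
    control's fluorescence.  For FMO the channel-specific tube is used
    (``fmo_despr`` sets the DEspR threshold and vice versa).
    """
    validate_events(controls)
    if not 0 < quantile <= 1:
        raise DomainError("quantile must be in (0, 1]")

    def _pick(cls: str, channel: str) -> float:
        sub = controls.loc[controls["is_control"] == cls, channel]
        if sub.empty:
            raise ConfigError(f"no events for control class {cls!r}")
        return float(np.quantile(sub.to_numpy(float), quantile))

    if control == "isotype":
        return _pick("isotype", "fl_despr"), _pick("isotype", "fl_cd11b")
    if control == "fmo":
        return _pick("fmo_despr", "fl_despr"), _pick("fmo_cd11b", "fl_cd11b")
    raise ConfigError(f"unknown control scheme {control!r}")


def quadrant_counts(gated: pd.DataFrame,
                    thresholds: tuple[float, float],
                    anchor_per_ul: float | None = None) -> QuadrantResult:
    """Partition gated events into quadrants.

    Positivity is *strictly above* threshold (the convention is stated
    because analysis packages differ).  Quadrants: Q1 DEspR+ only,
    Q2 double positive, Q3 double negative, Q4 CD11b+ only.
    """
    validate_events(gated)
    if len(gated) == 0:
        raise DomainError("cannot form fractions over zero gated events")
    t_despr, t_cd11b = thresholds
    despr = gated["fl_despr"].to_numpy(float) > t_despr
    cd11b = gated["fl_cd11b"].to_numpy(float) > t_cd11b
    counts = {
        "q1": int((despr & ~cd11b).sum()),
        "q2": int((despr & cd11b).sum()),
        "q3": int((~despr & ~cd11b).sum()),
        "q4": int((~despr & cd11b).sum()),
    }
    n = len(gated)
    fractions = {k: v / n for k, v in counts.items()}
    q2f = fractions["q2"]
    conc = q2f * anchor_per_ul if anchor_per_ul is not None else None
    return QuadrantResult(t_despr, t_cd11b, counts, fractions, q2f, conc)


def load_events_csv(path) -> pd.DataFrame:
    """Read an event table from CSV and validate its schema."""
    return validate_events(pd.read_csv(path))


def save_events_csv(events: pd.DataFrame, path) -> None:
    validate_events(events).to_csv(path, index=False)
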