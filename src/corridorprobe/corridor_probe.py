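"""Core corridor analysis: place the virtual bore probe between the entry and
exit landmarks, sample HU at 1 mm stations over the probe cross-section,
detect cortical perforation away from the entry/exit crossings, decide
accessibility, measure length and classify the perforation site.

Conventions (fixed here, configurable where noted):

* A station is *cortical* when the maximum interpolated HU over its disc
  samples strictly exceeds the cortical threshold (default 400 HU); a value
  of exactly 400 does not count.  The disc maximum — not the centreline
  value — is used so that wall grazing at the probe boundary is detected.
* The permitted entry/exit crossings are the maximal contiguous cortical
  runs containing the first and last station.  Any other cortical run is a
  perforation.  A single run spanning the whole corridor means the probe
  never traverses trabecular bone and the corridor is not accessible.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .volume_geometry import (
    HUVolume,
    LandmarkPair,
    OutOfBoundsError,
    disc_offsets,
    interpolate_hu,
    probe_stations,
)

__all__ = [
    "AnalysisConfig",
    "StationSample",
    "ProbeProfile",
    "CorticalRun",
    "PerforationEvent",
    "AccessibilityResult",
    "ArcIntervalRegions",
    "LabelVolumeRegions",
    "UnclassifiableError",
    "corridor_length",
    "sample_bore_probe",
    "find_cortical_runs",
    "assess_accessibility",
    "classify_perforation_site",
    "result_record",
    "write_results_json",
    "results_csv_rows",
]

logger = logging.getLogger(__name__)

REGION_RAMUS = "ramus"
REGION_ACETABULUM = "acetabulum"
REGION_OTHER = "other"
REGION_UNASSIGNED = "unassigned"


class UnclassifiableError(ValueError):
    """Perforation events exist but none carries a usable region label."""


@dataclass(frozen=True)
class AnalysisConfig:
    """Parameters of the virtual bore-probe analysis."""

    probe_diameter_mm: float = 7.5
    step_mm: float = 1.0
    cortical_threshold_hu: float = 400.0
    n_rings: int = 2
    n_angles: int = 16

    def __post_init__(self):
        if self.probe_diameter_mm <= 0:
            raise ValueError("probe_diameter_mm must be positive")
        if self.step_mm <= 0:
            raise ValueError("step_mm must be positive")
        if not np.isfinite(self.cortical_threshold_hu):
            raise ValueError("cortical_threshold_hu must be finite")

    @property
    def probe_radius_mm(self) -> float:
        return self.probe_diameter_mm / 2.0

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class StationSample:
    index: int
    arc_mm: float
    center_hu: float
    mean_hu: float
    max_hu: float
    is_cortical: bool


@dataclass
class ProbeProfile:
    """Per-station HU samples of one bore probe."""

    specimen_id: str
    side: str
    stations: list[StationSample]
    length_mm: float
    config: AnalysisConfig

    def __post_init__(self):
        if len(self.stations) < 2:
            raise ValueError("a profile needs at least 2 stations")
        if abs(self.stations[-1].arc_mm - self.length_mm) > 1e-6:
            raise ValueError("length_mm must equal the last station's arc_mm")

    @property
    def arc_mm(self) -> np.ndarray:
        return np.array([s.arc_mm for s in self.stations])

    @property
    def mean_hu(self) -> np.ndarray:
        return np.array([s.mean_hu for s in self.stations])

    @property
    def max_hu(self) -> np.ndarray:
        return np.array([s.max_hu for s in self.stations])

    @property
    def center_hu(self) -> np.ndarray:
        return np.array([s.center_hu for s in self.stations])

    @property
    def is_cortical(self) -> np.ndarray:
        return np.array([s.is_cortical for s in self.stations], dtype=bool)


@dataclass(frozen=True)
class CorticalRun:
    """Maximal contiguous run of cortical stations (inclusive bounds)."""

    start: int
    end: int
    is_entry: bool
    is_exit: bool

    @property
    def is_interior(self) -> bool:
        return not (self.is_entry or self.is_exit)


@dataclass
class PerforationEvent:
    station_start: int
    station_end: int
    arc_start_mm: float
    arc_end_mm: float
    region: str = REGION_UNASSIGNED


@dataclass
class AccessibilityResult:
    accessible: bool
    length_mm: Optional[float]
    events: list[PerforationEvent] = field(default_factory=list)
    group: Optional[int] = None

    def __post_init__(self):
        if self.accessible and self.events:
            raise ValueError("accessible result cannot carry perforation events")


# ---------------------------------------------------------------------------
# Region maps
# ---------------------------------------------------------------------------

class ArcIntervalRegions:
    """Region lookup by arc-length intervals [start_mm, end_mm) along the
    corridor.  Positions not covered by any interval are 'unassigned'."""

    def __init__(self, intervals: Sequence[tuple[float, float, str]]):
        self.intervals = [(float(a), float(b), str(lab)) for a, b, lab in intervals]
        for a, b, _ in self.intervals:
            if not b > a:
                raise ValueError(f"empty region interval ({a}, {b})")

    def lookup(self, arc_mm: float, point=None) -> str:
        for a, b, lab in self.intervals:
            if a <= arc_mm < b or (arc_mm == b and b == self.intervals[-1][1]):
                return lab
        return REGION_UNASSIGNED

    @classmethod
    def from_yaml(cls, path) -> "ArcIntervalRegions":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls([(d["start_mm"], d["end_mm"], d["region"]) for d in data["intervals"]])

    def to_yaml(self, path) -> None:
        import yaml

        data = {
            "intervals": [
                {"start_mm": a, "end_mm": b, "region": lab} for a, b, lab in self.intervals
            ]
        }
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


class LabelVolumeRegions:
    """Region lookup by nearest-neighbour query into an integer label volume."""

    def __init__(self, labels: HUVolume, label_map: dict[int, str]):
        self.labels = labels
        self.label_map = {int(k): str(v) for k, v in label_map.items()}

    def lookup(self, arc_mm: float, point=None) -> str:
        if point is None:
            raise ValueError("label-volume regions need the event's axis point")
        idx = np.rint(self.labels.world_to_index(np.asarray(point, dtype=float))).astype(int)
        shape = np.array(self.labels.shape)
        if np.any(idx < 0) or np.any(idx >= shape):
            return REGION_UNASSIGNED
        lab = int(self.labels.values[tuple(idx)])
        return self.label_map.get(lab, REGION_UNASSIGNED)


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def corridor_length(lm: LandmarkPair) -> float:
    """Euclidean entry-exit distance in mm (the screw-length measure)."""
    return lm.separation_mm


def sample_bore_probe(vol: HUVolume, lm: LandmarkPair,
                      cfg: AnalysisConfig = AnalysisConfig()) -> ProbeProfile:
    """Sample the cylindrical bore probe between the landmarks.

    One :class:`StationSample` per 1 mm (``cfg.step_mm``) station; each
    station is sampled over a disc of the probe radius orthogonal to the
    corridor axis.
    """
    stations = probe_stations(lm, cfg.step_mm)
    offsets = disc_offsets(lm.direction, cfg.probe_radius_mm, cfg.n_rings, cfg.n_angles)
    n_stations, n_pts = len(stations.arc_mm), len(offsets)
    pts = (stations.points[:, None, :] + offsets[None, :, :]).reshape(-1, 3)
    try:
        hu = interpolate_hu(vol, pts)
    except OutOfBoundsError as exc:
        bad_station = int(exc.indices[0]) // n_pts if exc.indices.size else -1
        raise OutOfBoundsError(
            f"probe leaves the volume at station {bad_station} "
            f"(arc {stations.arc_mm[bad_station]:.1f} mm) for specimen "
            f"{lm.specimen_id!r}/{lm.side}: {exc}",
            indices=exc.indices,
        ) from exc
    hu = hu.reshape(n_stations, n_pts)
    max_hu = hu.max(axis=1)
    # strict >: exactly-threshold values are not cortical; the epsilon absorbs
    # trilinear round-off (weights summing to 1 only to machine precision)
    thr = cfg.cortical_threshold_hu + 1e-6
    samples = [
        StationSample(
            index=i,
            arc_mm=float(stations.arc_mm[i]),
            center_hu=float(hu[i, 0]),
            mean_hu=float(hu[i].mean()),
            max_hu=float(max_hu[i]),
            is_cortical=bool(max_hu[i] > thr),
        )
        for i in range(n_stations)
    ]
    return ProbeProfile(
        specimen_id=lm.specimen_id,
        side=lm.side,
        stations=samples,
        length_mm=lm.separation_mm,
        config=cfg,
    )


def find_cortical_runs(profile: ProbeProfile) -> list[CorticalRun]:
    """Maximal contiguous runs of cortical stations, flagged entry/exit when
    they contain the first/last station."""
    cortical = profile.is_cortical
    runs: list[CorticalRun] = []
    n = len(cortical)
    i = 0
    while i < n:
        if cortical[i]:
            j = i
            while j + 1 < n and cortical[j + 1]:
                j += 1
            runs.append(CorticalRun(start=i, end=j, is_entry=(i == 0), is_exit=(j == n - 1)))
            i = j + 1
        else:
            i += 1
    return runs


def assess_accessibility(profile: ProbeProfile, regions=None,
                         landmarks: LandmarkPair | None = None) -> AccessibilityResult:
    """Decide accessibility of the corridor for this probe.

    Accessible iff there is no interior cortical run and no single cortical
    run spans the whole corridor.  Each interior run becomes a
    :class:`PerforationEvent`; regions are assigned from ``regions`` (an
    :class:`ArcIntervalRegions` or :class:`LabelVolumeRegions`) when given.
    Label-volume lookups need ``landmarks`` to locate the event's axis point.
    """
    runs = find_cortical_runs(profile)
    interior = [r for r in runs if r.is_interior]
    spanning = any(r.is_entry and r.is_exit for r in runs)
    accessible = not interior and not spanning

    if accessible:
        return AccessibilityResult(accessible=True, length_mm=profile.length_mm)

    arcs = profile.arc_mm
    events = []
    source = interior if interior else [r for r in runs if r.is_entry and r.is_exit]
    for run in source:
        mid_arc = 0.5 * (arcs[run.start] + arcs[run.end])
        region = REGION_UNASSIGNED
        if regions is not None:
            axis_pt = None
            if landmarks is not None:
                axis_pt = landmarks.entry.as_array() + mid_arc * landmarks.direction
            region = regions.lookup(mid_arc, axis_pt)
        events.append(
            PerforationEvent(
                station_start=run.start,
                station_end=run.end,
                arc_start_mm=float(arcs[run.start]),
                arc_end_mm=float(arcs[run.end]),
                region=region,
            )
        )
    group = None
    try:
        group = classify_perforation_site(events)
    except UnclassifiableError:
        logger.warning(
            "specimen %s/%s: not accessible but no event carries a ramus/acetabulum "
            "region; group left unassigned", profile.specimen_id, profile.side,
        )
    return AccessibilityResult(accessible=False, length_mm=None, events=events, group=group)


def classify_perforation_site(events: Sequence[PerforationEvent]) -> int:
    """Group 1: perforation only along the pubic ramus; group 2: only the
    acetabular joint surface; group 3: both.  Events labelled other/unassigned
    do not contribute."""
    if not events:
        raise ValueError("classify_perforation_site requires at least one event")
    regions = {e.region for e in events}
    ignored = regions - {REGION_RAMUS, REGION_ACETABULUM}
    if ignored:
        logger.debug("ignoring perforation regions %s for grouping", sorted(ignored))
    has_ramus = REGION_RAMUS in regions
    has_acet = REGION_ACETABULUM in regions
    if has_ramus and has_acet:
        return 3
    if has_ramus:
        return 1
    if has_acet:
        return 2
    raise UnclassifiableError("no event carries a ramus/acetabulum region")


# ---------------------------------------------------------------------------
# Result serialization
# ---------------------------------------------------------------------------

def result_record(profile: ProbeProfile, result: AccessibilityResult) -> dict:
    """One JSON-serializable record per specimen/side."""
    return {
        "specimen_id": profile.specimen_id,
        "side": profile.side,
        "accessible": result.accessible,
        "length_mm": result.length_mm,
        "n_events": len(result.events),
        "group": result.group,
        "stations": [
            {
                "arc_mm": s.arc_mm,
                "center_hu": s.center_hu,
                "mean_hu": s.mean_hu,
                "max_hu": s.max_hu,
                "is_cortical": s.is_cortical,
            }
            for s in profile.stations
        ],
    }


def write_results_json(records: Sequence[dict], path) -> None:
    Path(path).write_text(json.dumps(list(records), indent=1, sort_keys=True) + "\n")


def results_csv_rows(records: Sequence[dict]) -> "pandas.DataFrame":  # noqa: F821
    """Flat one-row-per-specimen/side summary for cohort work."""
    import pandas as pd

    rows = [
        {
            "specimen_id": r["specimen_id"],
            "side": r["side"],
            "accessible": r["accessible"],
            "length_mm": r["length_mm"],
            "n_events": r["n_events"],
            "group": r["group"],
        }
        for r in records
    ]
    return pd.DataFrame(rows)
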