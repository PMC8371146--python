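"""Cohort-level aggregation: length-normalized mean HU profiles, length
summary tables and perforation-group tallies.

Length statistics are computed over accessible specimens only — specimens
with a perforation are excluded from length analysis.  SDs use the sample
(n - 1) convention.  Rates are kept at full precision internally and rounded
only at presentation time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .corridor_probe import ProbeProfile

__all__ = [
    "NormalizedProfile",
    "MeanProfile",
    "StratumStats",
    "CohortSummary",
    "normalize_profile",
    "aggregate_profiles",
    "summarize_cohort",
    "rate_percent",
]


@dataclass
class NormalizedProfile:
    """A profile's mean-HU sequence resampled to a fixed station count."""

    values: np.ndarray
    n_ref: int
    specimen_id: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if len(self.values) != self.n_ref:
            raise ValueError("values length must equal n_ref")


@dataclass
class MeanProfile:
    mean: np.ndarray
    sd: np.ndarray
    n_ref: int
    n_profiles: int

    @property
    def arc_fraction(self) -> np.ndarray:
        return np.linspace(0.0, 1.0, self.n_ref)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"arc_fraction": self.arc_fraction, "mean_hu": self.mean, "sd_hu": self.sd}
        )


def normalize_profile(profile: ProbeProfile, n_ref: int,
                      specimen_id: Optional[str] = None) -> NormalizedProfile:
    """Linearly resample a profile's station mean-HU sequence onto ``n_ref``
    equally spaced arc positions over [0, length].  Endpoints are preserved
    exactly and interpolated values never leave the original range."""
    if n_ref < 2:
        raise ValueError("n_ref must be >= 2")
    arcs = profile.arc_mm
    if len(arcs) < 2 or profile.length_mm <= 0:
        raise ValueError("degenerate profile")
    grid = np.linspace(0.0, profile.length_mm, n_ref)
    values = np.interp(grid, arcs, profile.mean_hu)
    return NormalizedProfile(
        values=values,
        n_ref=n_ref,
        specimen_id=profile.specimen_id if specimen_id is None else specimen_id,
    )


def aggregate_profiles(profiles: Sequence[ProbeProfile],
                       n_ref: Optional[int] = None) -> MeanProfile:
    """Pointwise mean (and SD) of the accessible specimens' profiles after
    normalization to a common station count.

    When ``n_ref`` is not given it defaults to round(mean length in mm) + 1,
    i.e. a nominal 1 mm spacing on the cohort-average corridor.
    """
    profiles = list(profiles)
    if not profiles:
        raise ValueError("aggregate_profiles requires at least one profile")
    if n_ref is None:
        mean_len = float(np.mean([p.length_mm for p in profiles]))
        n_ref = int(round(mean_len)) + 1
    stack = np.vstack([normalize_profile(p, n_ref).values for p in profiles])
    sd = stack.std(axis=0, ddof=1) if len(profiles) > 1 else np.zeros(n_ref)
    return MeanProfile(mean=stack.mean(axis=0), sd=sd, n_ref=n_ref,
                       n_profiles=len(profiles))


# ---------------------------------------------------------------------------
# Cohort summary
# ---------------------------------------------------------------------------

@dataclass
class StratumStats:
    n: int
    n_accessible: int
    mean_length_mm: Optional[float] = None
    min_length_mm: Optional[float] = None
    max_length_mm: Optional[float] = None
    sd_length_mm: Optional[float] = None

    @property
    def accessibility_rate(self) -> Optional[float]:
        return self.n_accessible / self.n if self.n else None


@dataclass
class CohortSummary:
    total: StratumStats
    by_sex: dict[str, StratumStats] = field(default_factory=dict)
    by_ethnicity: dict[str, StratumStats] = field(default_factory=dict)
    group_tallies: dict[str, dict[int, int]] = field(default_factory=dict)

    def table1_frame(self) -> pd.DataFrame:
        rows = []

        def row(label, s: StratumStats):
            rows.append({
                "stratum": label,
                "n": s.n,
                "n_accessible": s.n_accessible,
                "accessibility_pct": rate_percent(s.accessibility_rate),
                "mean_mm": s.mean_length_mm,
                "min_mm": s.min_length_mm,
                "max_mm": s.max_length_mm,
                "sd_mm": s.sd_length_mm,
            })

        row("all", self.total)
        for sex in sorted(self.by_sex):
            row(f"sex={sex}", self.by_sex[sex])
        for eth in sorted(self.by_ethnicity):
            row(f"ethnicity={eth}", self.by_ethnicity[eth])
        return pd.DataFrame(rows)

    def table2_frame(self) -> pd.DataFrame:
        rows = []
        for sex in sorted(self.group_tallies):
            tally = self.group_tallies[sex]
            rows.append({
                "sex": sex,
                "n_excluded": sum(tally.values()),
                "group1_ramus": tally.get(1, 0),
                "group2_acetabulum": tally.get(2, 0),
                "group3_both": tally.get(3, 0),
                "unclassified": tally.get(0, 0),
            })
        return pd.DataFrame(
            rows,
            columns=["sex", "n_excluded", "group1_ramus", "group2_acetabulum",
                     "group3_both", "unclassified"],
        )


def rate_percent(rate: Optional[float]) -> Optional[float]:
    """Presentation rounding: a [0, 1] rate as a percentage to 1 d.p."""
    if rate is None:
        return None
    return round(rate * 100.0, 1)


_REQUIRED_COLUMNS = ("specimen_id", "side", "sex", "ethnicity", "accessible", "length_mm")


def _stratum(df: pd.DataFrame) -> StratumStats:
    n = len(df)
    acc = df[df["accessible"].astype(bool)]
    stats = StratumStats(n=n, n_accessible=len(acc))
    lengths = acc["length_mm"].dropna().to_numpy(dtype=float)
    if lengths.size:
        stats.mean_length_mm = float(lengths.mean())
        stats.min_length_mm = float(lengths.min())
        stats.max_length_mm = float(lengths.max())
        stats.sd_length_mm = float(lengths.std(ddof=1)) if lengths.size > 1 else 0.0
    return stats


def summarize_cohort(records) -> CohortSummary:
    """Aggregate per-specimen accessibility results with covariates.

    ``records`` is a DataFrame or list of dicts with columns
    specimen_id, side, sex, ethnicity, accessible, length_mm and optionally
    group (1|2|3, or None/0 for unclassified); length statistics use
    accessible specimens only, group tallies excluded specimens only.
    """
    df = records if isinstance(records, pd.DataFrame) else pd.DataFrame(list(records))
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"records missing required columns: {missing}")
    if df[["sex", "ethnicity"]].isna().any().any():
        raise ValueError("every record needs sex and ethnicity covariates")
    df = df.sort_values(["specimen_id", "side"], kind="stable").reset_index(drop=True)

    summary = CohortSummary(total=_stratum(df))
    for sex, sub in df.groupby("sex", sort=True):
        summary.by_sex[str(sex)] = _stratum(sub)
    for eth, sub in df.groupby("ethnicity", sort=True):
        summary.by_ethnicity[str(eth)] = _stratum(sub)

    excluded = df[~df["accessible"].astype(bool)]
    for sex, sub in excluded.groupby("sex", sort=True):
        tally: dict[int, int] = {}
        if "group" in sub.columns:
            groups = pd.to_numeric(sub["group"], errors="coerce").fillna(0).astype(int)
        else:
            groups = pd.Series(0, index=sub.index)
        for g in groups:
            g = g if g in (1, 2, 3) else 0
            tally[g] = tally.get(g, 0) + 1
        summary.group_tallies[str(sex)] = tally
    return summary
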