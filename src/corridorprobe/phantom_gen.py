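"""Parametric curved-corridor bone phantoms with analytic ground truth.

A phantom is a tube of trabecular bone wrapped in a cortical shell, built
around a circular-arc centreline of given chord length and sagitta, capped
with cortex at both ends so a probe between the chord endpoints crosses
cortical bone exactly at entry and exit.  The trabecular interior has a
low-HU segment (pubic-ramus analogue) and an intermediate-HU segment
(periacetabular analogue); the exit cap is densest (lateral-ilium analogue).
An optional spherical cortical cap offset laterally near the periacetabular
zone stands in for the acetabular joint surface.

Geometry is exact before voxelization: a straight probe of radius rho fits
inside a tube of inner radius r around an arc of sagitta h iff r - h >= rho,
so every phantom knows its own accessibility verdict in closed form.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .corridor_probe import (
    REGION_ACETABULUM,
    REGION_OTHER,
    REGION_RAMUS,
    ArcIntervalRegions,
)
from .volume_geometry import HUVolume, LandmarkPair, WorldPoint

__all__ = [
    "HULevel",
    "PhantomSpec",
    "GroundTruth",
    "CohortSpec",
    "Phantom",
    "DEFAULT_HU_LEVELS",
    "make_phantom",
    "phantom_landmarks",
    "sample_cohort",
]

REFERENCE_PROBE_RADIUS_MM = 3.75  # 7.5 mm probe


@dataclass(frozen=True)
class HULevel:
    mean: float
    sd: float

    def __post_init__(self):
        if self.sd < 0:
            raise ValueError("HU level SD must be non-negative")


DEFAULT_HU_LEVELS = {
    "background": HULevel(40.0, 15.0),
    "trabecular_ramus": HULevel(150.0, 30.0),
    "trabecular_periacetabular": HULevel(350.0, 15.0),
    "cortex": HULevel(800.0, 60.0),
    "exit_cortex": HULevel(1100.0, 100.0),
}


@dataclass(frozen=True)
class PhantomSpec:
    """Parametric description of one corridor phantom."""

    chord_length_mm: float = 70.0
    sagitta_mm: float = 1.0
    inner_radius_mm: float = 6.0
    waist_inner_radius_mm: Optional[float] = None  # mid-corridor minimum radius
    cortex_thickness_mm: float = 2.0
    hu_levels: dict = field(default_factory=lambda: dict(DEFAULT_HU_LEVELS))
    periacetabular_span: tuple[float, float] = (0.60, 0.85)  # arc fraction
    acetabular_wall_offset_mm: Optional[float] = None
    acetabular_wall_radius_mm: float = 8.0
    spacing_mm: tuple[float, float, float] = (0.7, 0.7, 0.6)
    margin_mm: float = 4.0
    noise_seed: int = 0

    def __post_init__(self):
        if self.chord_length_mm <= 0:
            raise ValueError("chord_length_mm must be positive")
        if self.sagitta_mm < 0:
            raise ValueError("sagitta_mm must be non-negative")
        if self.sagitta_mm >= self.chord_length_mm / 2:
            raise ValueError("sagitta_mm must be below half the chord length")
        if self.inner_radius_mm <= 0:
            raise ValueError("inner_radius_mm must be positive")
        if self.waist_inner_radius_mm is not None:
            if not 0 < self.waist_inner_radius_mm <= self.inner_radius_mm:
                raise ValueError("waist radius must be in (0, inner_radius_mm]")
        if self.cortex_thickness_mm <= 0:
            raise ValueError("cortex_thickness_mm must be positive")
        levels = {k: (v if isinstance(v, HULevel) else HULevel(**v))
                  for k, v in self.hu_levels.items()}
        missing = set(DEFAULT_HU_LEVELS) - set(levels)
        if missing:
            raise ValueError(f"hu_levels missing {sorted(missing)}")
        if levels["cortex"].mean <= 400 or levels["exit_cortex"].mean <= 400:
            raise ValueError("cortex HU means must exceed 400 to express 'cortical'")
        if levels["trabecular_ramus"].mean >= 400 or levels["trabecular_periacetabular"].mean >= 400:
            raise ValueError("trabecular HU means must be below 400")
        a, b = self.periacetabular_span
        if not 0 <= a < b <= 1:
            raise ValueError("periacetabular_span must be an ordered interval in [0, 1]")
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError("spacing_mm components must be positive")
        object.__setattr__(self, "hu_levels", levels)

    @property
    def min_inner_radius_mm(self) -> float:
        return (self.waist_inner_radius_mm
                if self.waist_inner_radius_mm is not None else self.inner_radius_mm)


@dataclass(frozen=True)
class GroundTruth:
    """Analytically known answers for a phantom, computed before voxelization."""

    accessible_expected: bool
    min_clearance_mm: float
    length_mm: float
    region_intervals: tuple  # ((start_mm, end_mm, label), ...)
    wall_intrudes: bool = False
    wall_margin_mm: float = math.inf  # signed probe-to-wall-shell clearance


@dataclass
class Phantom:
    volume: HUVolume
    landmarks: LandmarkPair
    regions: ArcIntervalRegions
    ground_truth: GroundTruth
    spec: PhantomSpec


# ---------------------------------------------------------------------------
# Arc geometry
# ---------------------------------------------------------------------------

def _arc_point(spec: PhantomSpec, s: float) -> np.ndarray:
    """Centreline point at arc fraction s, in phantom coordinates.

    The chord runs from (0,0,0) to (L,0,0); the arc bows towards +y.
    """
    L, h = spec.chord_length_mm, spec.sagitta_mm
    if h == 0:
        return np.array([s * L, 0.0, 0.0])
    R = (L * L / 4.0 + h * h) / (2.0 * h)
    center = np.array([L / 2.0, h - R])
    alpha = math.atan2(L / 2.0, R - h)  # angular half-width
    theta = (math.pi / 2.0 + alpha) - s * 2.0 * alpha  # entry -> exit
    p = center + R * np.array([math.cos(theta), math.sin(theta)])
    return np.array([p[0], p[1], 0.0])


def _inner_radius_at(spec: PhantomSpec, s) -> np.ndarray:
    """Inner (medullary) radius at arc fraction s; optional waist profile with
    a mid-corridor minimum."""
    s = np.asarray(s, dtype=float)
    if spec.waist_inner_radius_mm is None:
        return np.full_like(s, spec.inner_radius_mm)
    r_end, r_mid = spec.inner_radius_mm, spec.waist_inner_radius_mm
    return r_mid + (r_end - r_mid) * (2.0 * s - 1.0) ** 2


def phantom_landmarks(spec: PhantomSpec, specimen_id: str = "phantom",
                      side: str = "left") -> LandmarkPair:
    """Entry/exit landmarks at the chord endpoints (phantom coordinates)."""
    return LandmarkPair(
        entry=WorldPoint(0.0, 0.0, 0.0),
        exit=WorldPoint(spec.chord_length_mm, 0.0, 0.0),
        specimen_id=specimen_id,
        side=side,
    )


def _wall_center(spec: PhantomSpec) -> Optional[np.ndarray]:
    if spec.acetabular_wall_offset_mm is None:
        return None
    a, b = spec.periacetabular_span
    c = _arc_point(spec, 0.5 * (a + b))
    return c + np.array([0.0, 0.0, spec.acetabular_wall_offset_mm])


def _wall_margin(spec: PhantomSpec, probe_radius_mm: float) -> float:
    """Signed clearance between the probe surface and the outer wall shell.

    Negative means the spherical-cap cortical shell reaches into the straight
    probe; +inf when no wall is present.  The probe cylinder extends far
    beyond the sphere on both sides, so the shell reaches the probe iff the
    closest approach of the probe axis is under the outer shell radius plus
    the probe radius (a probe axis through the sphere interior still crosses
    the shell on the way out).
    """
    c = _wall_center(spec)
    if c is None:
        return math.inf
    # distance from sphere centre to the chord (x-axis segment [0, L])
    x = min(max(c[0], 0.0), spec.chord_length_mm)
    d = float(np.linalg.norm(c - np.array([x, 0.0, 0.0])))
    r_out = spec.acetabular_wall_radius_mm + spec.cortex_thickness_mm
    return d - probe_radius_mm - r_out


def ground_truth(spec: PhantomSpec,
                 probe_radius_mm: float = REFERENCE_PROBE_RADIUS_MM) -> GroundTruth:
    """Closed-form accessibility, clearance and regions for a spec."""
    clearance = spec.min_inner_radius_mm - spec.sagitta_mm
    wall_margin = _wall_margin(spec, probe_radius_mm)
    wall = wall_margin < 0
    accessible = (clearance >= probe_radius_mm) and not wall
    L = spec.chord_length_mm
    a, b = spec.periacetabular_span
    intervals = (
        (0.0, a * L, REGION_RAMUS),
        (a * L, b * L, REGION_ACETABULUM),
        (b * L, L, REGION_OTHER),
    )
    return GroundTruth(
        accessible_expected=accessible,
        min_clearance_mm=clearance,
        length_mm=L,
        region_intervals=intervals,
        wall_intrudes=wall,
        wall_margin_mm=wall_margin,
    )


# ---------------------------------------------------------------------------
# Voxelization
# ---------------------------------------------------------------------------

def _arc_coordinates(spec: PhantomSpec, xx, yy, zz):
    """Distance to the arc centreline and clamped arc fraction for a grid of
    phantom-coordinate points."""
    L, h = spec.chord_length_mm, spec.sagitta_mm
    if h == 0:
        t = np.clip(xx, 0.0, L)
        dist = np.sqrt((xx - t) ** 2 + yy ** 2 + zz ** 2)
        return dist, t / L
    R = (L * L / 4.0 + h * h) / (2.0 * h)
    cx, cy = L / 2.0, h - R
    alpha = math.atan2(L / 2.0, R - h)
    vx, vy = xx - cx, yy - cy
    theta = np.arctan2(vy, vx)
    theta_entry = math.pi / 2.0 + alpha
    theta_exit = math.pi / 2.0 - alpha
    s = np.clip((theta_entry - theta) / (2.0 * alpha), 0.0, 1.0)
    # distance to the full circle, valid where theta is inside the arc range
    vnorm = np.hypot(vx, vy)
    d_circle = np.sqrt((vnorm - R) ** 2 + zz ** 2)
    # distance to the clamped endpoints elsewhere
    entry = _arc_point(spec, 0.0)
    exitp = _arc_point(spec, 1.0)
    d_entry = np.sqrt((xx - entry[0]) ** 2 + (yy - entry[1]) ** 2 + zz ** 2)
    d_exit = np.sqrt((xx - exitp[0]) ** 2 + (yy - exitp[1]) ** 2 + zz ** 2)
    inside = (theta <= theta_entry) & (theta >= theta_exit)
    dist = np.where(inside, d_circle, np.where(s <= 0.5, d_entry, d_exit))
    return dist, s


def make_phantom(spec: PhantomSpec,
                 probe_radius_mm: float = REFERENCE_PROBE_RADIUS_MM) -> Phantom:
    """Voxelize a phantom spec into an HU volume with landmarks, a region
    map and its analytic ground truth."""
    gt = ground_truth(spec, probe_radius_mm)
    L, h = spec.chord_length_mm, spec.sagitta_mm
    t = spec.cortex_thickness_mm
    r_max = spec.inner_radius_mm + t
    m = spec.margin_mm
    lateral = max(r_max, probe_radius_mm) + m

    lo = np.array([-m - t, -lateral, -lateral])
    hi = np.array([L + m + t, h + lateral, lateral])
    wc = _wall_center(spec)
    if wc is not None:
        r_w = spec.acetabular_wall_radius_mm + t
        lo = np.minimum(lo, wc - r_w - m)
        hi = np.maximum(hi, wc + r_w + m)

    spacing = np.asarray(spec.spacing_mm, dtype=float)
    n = np.maximum(np.ceil((hi - lo) / spacing).astype(int) + 1, 2)
    affine = np.diag([*spacing, 1.0])
    affine[:3, 3] = lo

    ax = lo[0] + spacing[0] * np.arange(n[0])
    ay = lo[1] + spacing[1] * np.arange(n[1])
    az = lo[2] + spacing[2] * np.arange(n[2])
    xx, yy, zz = np.meshgrid(ax, ay, az, indexing="ij", sparse=False)

    dist, s = _arc_coordinates(spec, xx, yy, zz)
    arc_len = _arc_length(spec)
    ell = s * arc_len
    r_s = _inner_radius_at(spec, s)

    in_tube = dist <= r_s + t
    cap_entry = in_tube & (ell <= t)
    cap_exit = in_tube & (ell >= arc_len - t)
    caps = cap_entry | cap_exit
    trabecular = in_tube & ~caps & (dist <= r_s)
    shell = in_tube & ~caps & ~trabecular
    a, b = spec.periacetabular_span
    periace = trabecular & (s >= a) & (s < b)
    ramus = trabecular & ~periace

    # class index per voxel: 0 background, 1 ramus, 2 periacetabular, 3 cortex, 4 exit cortex
    cls = np.zeros(xx.shape, dtype=np.uint8)
    cls[ramus] = 1
    cls[periace] = 2
    cls[shell] = 3
    cls[cap_entry] = 3
    cls[cap_exit] = 4

    if wc is not None:
        d_wall = np.sqrt((xx - wc[0]) ** 2 + (yy - wc[1]) ** 2 + (zz - wc[2]) ** 2)
        wall_shell = ((d_wall >= spec.acetabular_wall_radius_mm)
                      & (d_wall <= spec.acetabular_wall_radius_mm + t)
                      & ~caps)
        cls[wall_shell] = 3

    level_names = ("background", "trabecular_ramus", "trabecular_periacetabular",
                   "cortex", "exit_cortex")
    means = np.array([spec.hu_levels[k].mean for k in level_names])
    sds = np.array([spec.hu_levels[k].sd for k in level_names])
    rng = np.random.default_rng(spec.noise_seed)
    values = means[cls]
    if np.any(sds > 0):
        values = values + sds[cls] * rng.standard_normal(cls.shape)

    vol = HUVolume(values=values, affine=affine)
    lm = phantom_landmarks(spec)
    regions = ArcIntervalRegions(gt.region_intervals)
    return Phantom(volume=vol, landmarks=lm, regions=regions, ground_truth=gt, spec=spec)


def _arc_length(spec: PhantomSpec) -> float:
    L, h = spec.chord_length_mm, spec.sagitta_mm
    if h == 0:
        return L
    R = (L * L / 4.0 + h * h) / (2.0 * h)
    alpha = math.atan2(L / 2.0, R - h)
    return 2.0 * R * alpha


# ---------------------------------------------------------------------------
# Cohort sampling
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TruncNormal:
    mean: float
    sd: float
    lo: float = -np.inf
    hi: float = np.inf

    def __post_init__(self):
        if not np.isfinite(self.mean) or not np.isfinite(self.sd) or self.sd < 0:
            raise ValueError("invalid distribution parameters")
        if not self.lo < self.hi:
            raise ValueError("truncation bounds must be ordered")

    def draw(self, rng: np.random.Generator) -> float:
        if self.sd == 0:
            return float(np.clip(self.mean, self.lo, self.hi))
        for _ in range(10_000):
            x = rng.normal(self.mean, self.sd)
            if self.lo <= x <= self.hi:
                return float(x)
        raise RuntimeError("truncated-normal rejection sampling failed")


@dataclass(frozen=True)
class SexParams:
    """Per-sex corridor-narrowness distributions (free parameters: the source
    cohort quantifies neither radii nor curvature, only that female corridors
    are narrower and more curved)."""

    inner_radius: TruncNormal
    sagitta: TruncNormal
    wall_probability: float = 0.0
    wall_offset: TruncNormal = TruncNormal(11.0, 2.5, 6.0, 18.0)


# Defaults calibrated so the *realized* accessibility after voxelization at
# the default 1.0 mm cohort spacing lands near 0.68 for males and 0.54 for
# females (voxelization + noise shift the effective clearance boundary by
# roughly half a voxel above the analytic 3.75 mm).  Females draw narrower,
# more curved corridors and closer acetabular walls.
DEFAULT_MALE = SexParams(
    inner_radius=TruncNormal(6.82, 0.8, 4.0, 9.0),
    sagitta=TruncNormal(1.75, 0.6, 0.0, 6.0),
    wall_probability=0.25,
    wall_offset=TruncNormal(15.5, 1.5, 12.5, 20.0),
)
DEFAULT_FEMALE = SexParams(
    inner_radius=TruncNormal(6.55, 0.8, 4.0, 9.0),
    sagitta=TruncNormal(1.87, 0.7, 0.0, 6.0),
    wall_probability=0.40,
    wall_offset=TruncNormal(15.0, 1.5, 12.0, 20.0),
)


@dataclass(frozen=True)
class CohortSpec:
    """Sampling plan for a synthetic cohort of corridor phantoms.

    Lengths are drawn from one distribution for both sexes (length does not
    differ by sex or ethnicity); narrowness parameters are drawn per sex so
    expected accessibility is higher for males.
    """

    n_specimens: int = 100
    male_fraction: float = 0.54  # 81 of 150 in the reference demographics
    length_dist: TruncNormal = TruncNormal(131.7, 10.71, 104.9, 161.4)
    male: SexParams = DEFAULT_MALE
    female: SexParams = DEFAULT_FEMALE
    ethnicities: tuple[str, ...] = ("european", "japanese")
    ethnicity_fractions: tuple[float, ...] = (2 / 3, 1 / 3)
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)  # coarse-ish default
    master_seed: int = 0

    def __post_init__(self):
        if self.n_specimens < 1:
            raise ValueError("n_specimens must be >= 1")
        if not 0 <= self.male_fraction <= 1:
            raise ValueError("male_fraction must be in [0, 1]")
        if len(self.ethnicities) != len(self.ethnicity_fractions):
            raise ValueError("ethnicity labels and fractions differ in length")
        if abs(sum(self.ethnicity_fractions) - 1.0) > 1e-9:
            raise ValueError("ethnicity_fractions must sum to 1")

    @classmethod
    def from_yaml(cls, path) -> "CohortSpec":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        for key in ("length_dist",):
            if key in data:
                data[key] = TruncNormal(**data[key])
        for key in ("male", "female"):
            if key in data:
                d = dict(data[key])
                for sub in ("inner_radius", "sagitta", "wall_offset"):
                    if sub in d:
                        d[sub] = TruncNormal(**d[sub])
                data[key] = SexParams(**d)
        for key in ("ethnicities", "ethnicity_fractions", "spacing_mm"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)


def sample_cohort(cohort: CohortSpec) -> list[tuple[PhantomSpec, dict]]:
    """Draw a reproducible list of (PhantomSpec, covariates) pairs.

    Per-specimen seeds are derived deterministically from ``master_seed``, so
    identical cohort specs yield identical spec lists.
    """
    ss = np.random.SeedSequence(cohort.master_seed)
    child_seeds = ss.spawn(cohort.n_specimens)
    eth_cum = np.cumsum(cohort.ethnicity_fractions)
    out = []
    for i, child in enumerate(child_seeds):
        rng = np.random.default_rng(child)
        sex = "m" if rng.random() < cohort.male_fraction else "f"
        eth = cohort.ethnicities[int(np.searchsorted(eth_cum, rng.random()))]
        params = cohort.male if sex == "m" else cohort.female
        length = cohort.length_dist.draw(rng)
        inner_radius = params.inner_radius.draw(rng)
        sagitta = params.sagitta.draw(rng)
        wall = None
        if rng.random() < params.wall_probability:
            wall = params.wall_offset.draw(rng)
        noise_seed = int(rng.integers(0, 2**31 - 1))
        spec = PhantomSpec(
            chord_length_mm=length,
            sagitta_mm=sagitta,
            inner_radius_mm=inner_radius,
            acetabular_wall_offset_mm=wall,
            spacing_mm=cohort.spacing_mm,
            noise_seed=noise_seed,
        )
        covariates = {
            "specimen_id": f"s{i:04d}",
            "side": "left" if i % 2 == 0 else "right",
            "sex": sex,
            "ethnicity": eth,
        }
        out.append((spec, covariates))
    return out
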