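"""Volume I/O, world/index coordinate handling and probe sample-point geometry.

All analysis happens in world millimetres.  A volume carries a 4x4
index-to-world affine; nothing here assumes axis-aligned anatomy.  HU
interpolation is trilinear and refuses to extrapolate: a probe leaving the
scanned volume is treated as a hard error, not as missing data.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np

__all__ = [
    "HUVolume",
    "WorldPoint",
    "LandmarkPair",
    "Stations",
    "OutOfBoundsError",
    "VolumeFormatError",
    "read_volume",
    "write_volume",
    "read_landmarks",
    "write_landmarks",
    "interpolate_hu",
    "probe_stations",
    "disc_samples",
]


class VolumeFormatError(ValueError):
    """Raised for unreadable, ambiguous or unsupported volume files."""


class OutOfBoundsError(ValueError):
    """A world point maps outside the volume's index grid.

    ``indices`` holds the positions (into the queried point array) of the
    offending points so callers can translate them into domain terms.
    """

    def __init__(self, message: str, indices: np.ndarray | None = None):
        super().__init__(message)
        self.indices = indices if indices is not None else np.array([], dtype=int)


def _as_xyz(p) -> np.ndarray:
    """Coerce a WorldPoint / sequence / array into a float (..., 3) array."""
    if isinstance(p, WorldPoint):
        return p.as_array()
    arr = np.asarray(p, dtype=float)
    if arr.shape[-1] != 3:
        raise ValueError(f"expected 3 coordinates, got shape {arr.shape}")
    return arr


@dataclass(frozen=True)
class WorldPoint:
    """A point in world coordinates (mm)."""

    x: float
    y: float
    z: float

    def __post_init__(self):
        if not np.all(np.isfinite([self.x, self.y, self.z])):
            raise ValueError("WorldPoint coordinates must be finite")

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z], dtype=float)

    @classmethod
    def from_array(cls, a) -> "WorldPoint":
        a = np.asarray(a, dtype=float)
        return cls(float(a[0]), float(a[1]), float(a[2]))


@dataclass(frozen=True)
class LandmarkPair:
    """Entry/exit landmarks of one corridor, in world mm."""

    entry: WorldPoint
    exit: WorldPoint
    specimen_id: str = ""
    side: str = "left"

    def __post_init__(self):
        if self.separation_mm <= 0:
            raise ValueError("entry and exit landmarks must be distinct")
        if self.side not in ("left", "right"):
            raise ValueError(f"side must be 'left' or 'right', got {self.side!r}")

    @property
    def separation_mm(self) -> float:
        return float(np.linalg.norm(self.exit.as_array() - self.entry.as_array()))

    @property
    def direction(self) -> np.ndarray:
        """Unit vector from entry to exit."""
        d = self.exit.as_array() - self.entry.as_array()
        return d / np.linalg.norm(d)


@dataclass
class HUVolume:
    """A 3D HU scalar grid with an index-to-world affine (world units mm)."""

    values: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self):
        self.values = np.asarray(self.values)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("values must be a 3D array")
        if any(n < 2 for n in self.values.shape):
            raise ValueError("grid needs at least 2 voxels per axis")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        det = np.linalg.det(self.affine)
        if not np.isfinite(det) or abs(det) < 1e-12:
            raise ValueError("affine is not invertible")
        self._inv_affine = np.linalg.inv(self.affine)

    @property
    def spacing(self) -> np.ndarray:
        """Per-axis voxel size (mm), derived from the affine column norms."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def shape(self) -> tuple:
        return self.values.shape

    def world_to_index(self, points) -> np.ndarray:
        pts = _as_xyz(points)
        flat = np.atleast_2d(pts)
        hom = np.c_[flat, np.ones(len(flat))]
        idx = (self._inv_affine @ hom.T).T[:, :3]
        return idx.reshape(pts.shape)

    def index_to_world(self, indices) -> np.ndarray:
        idx = np.asarray(indices, dtype=float)
        flat = np.atleast_2d(idx)
        hom = np.c_[flat, np.ones(len(flat))]
        w = (self.affine @ hom.T).T[:, :3]
        return w.reshape(idx.shape)


# ---------------------------------------------------------------------------
# File formats
# ---------------------------------------------------------------------------

_MET_TYPES = {
    "MET_CHAR": np.int8,
    "MET_UCHAR": np.uint8,
    "MET_SHORT": np.int16,
    "MET_USHORT": np.uint16,
    "MET_INT": np.int32,
    "MET_UINT": np.uint32,
    "MET_FLOAT": np.float32,
    "MET_DOUBLE": np.float64,
}


def read_volume(path) -> HUVolume:
    """Read a NIfTI-1 (.nii/.nii.gz) or MetaImage (.mha/.mhd) volume.

    HU values are returned exactly as stored, with only the format's own
    slope/intercept scaling applied (NIfTI ``scl_slope``/``scl_inter``).
    """
    path = Path(path)
    name = path.name.lower()
    if name.endswith((".nii", ".nii.gz")):
        return _read_nifti(path)
    if name.endswith((".mha", ".mhd")):
        return _read_metaimage(path)
    raise VolumeFormatError(f"unrecognized volume format: {path}")


def write_volume(vol: HUVolume, path, dtype=np.float32) -> None:
    """Write a volume as NIfTI-1 or MetaImage depending on the extension."""
    path = Path(path)
    name = path.name.lower()
    if name.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        img = nib.Nifti1Image(vol.values.astype(dtype), vol.affine)
        nib.save(img, str(path))
    elif name.endswith((".mha", ".mhd")):
        _write_metaimage(vol, path, dtype)
    else:
        raise VolumeFormatError(f"unrecognized volume format: {path}")


def _read_nifti(path: Path) -> HUVolume:
    import nibabel as nib

    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises a zoo of error types
        raise VolumeFormatError(f"cannot read NIfTI file {path}: {exc}") from exc
    data = np.asarray(img.get_fdata(dtype=np.float64))  # applies scl_slope/inter
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    return HUVolume(values=data, affine=np.asarray(img.affine, dtype=float))


def _read_metaimage(path: Path) -> HUVolume:
    header: dict[str, str] = {}
    raw: bytes
    with open(path, "rb") as fh:
        while True:
            line = fh.readline()
            if not line:
                raise VolumeFormatError(f"{path}: truncated MetaImage header")
            key, _, value = line.decode("ascii", "replace").partition("=")
            key, value = key.strip(), value.strip()
            header[key] = value
            if key == "ElementDataFile":
                break
        if header["ElementDataFile"].upper() == "LOCAL":
            raw = fh.read()
        else:
            data_path = path.parent / header["ElementDataFile"]
            raw = data_path.read_bytes()

    ndims = int(header.get("NDims", "3"))
    if ndims != 3:
        raise VolumeFormatError(f"{path}: only 3D MetaImages supported (NDims={ndims})")
    dims = [int(v) for v in header["DimSize"].split()]
    etype = header.get("ElementType", "MET_FLOAT")
    if etype not in _MET_TYPES:
        raise VolumeFormatError(f"{path}: unsupported ElementType {etype}")
    dtype = np.dtype(_MET_TYPES[etype])
    if header.get("BinaryDataByteOrderMSB", "False").lower() == "true":
        dtype = dtype.newbyteorder(">")
    if header.get("CompressedData", "False").lower() == "true":
        raw = zlib.decompress(raw)
    n = int(np.prod(dims))
    arr = np.frombuffer(raw[: n * dtype.itemsize], dtype=dtype)
    if arr.size != n:
        raise VolumeFormatError(f"{path}: expected {n} voxels, found {arr.size}")
    # MetaImage raw order is x-fastest
    values = arr.reshape(dims[::-1]).transpose(2, 1, 0).astype(np.float64)

    spacing = np.array([float(v) for v in header.get("ElementSpacing", "1 1 1").split()])
    offset = np.array([float(v) for v in header.get("Offset", "0 0 0").split()])
    tm = header.get("TransformMatrix", "1 0 0 0 1 0 0 0 1")
    direction = np.array([float(v) for v in tm.split()]).reshape(3, 3)
    affine = np.eye(4)
    affine[:3, :3] = direction * spacing  # scale columns by per-axis spacing
    affine[:3, 3] = offset
    return HUVolume(values=values, affine=affine)


def _write_metaimage(vol: HUVolume, path: Path, dtype) -> None:
    dtype = np.dtype(dtype)
    rev = {np.dtype(v): k for k, v in _MET_TYPES.items()}
    if dtype not in rev:
        raise VolumeFormatError(f"unsupported MetaImage dtype {dtype}")
    spacing = vol.spacing
    direction = vol.affine[:3, :3] / spacing
    offset = vol.affine[:3, 3]
    header = [
        "ObjectType = Image",
        "NDims = 3",
        "BinaryData = True",
        "BinaryDataByteOrderMSB = False",
        "CompressedData = False",
        "TransformMatrix = " + " ".join(f"{v:.17g}" for v in direction.ravel()),
        "Offset = " + " ".join(f"{v:.17g}" for v in offset),
        "ElementSpacing = " + " ".join(f"{v:.17g}" for v in spacing),
        "DimSize = " + " ".join(str(n) for n in vol.shape),
        f"ElementType = {rev[dtype]}",
    ]
    data = np.ascontiguousarray(vol.values.transpose(2, 1, 0).astype(dtype))
    if path.name.lower().endswith(".mhd"):
        raw_name = path.with_suffix(".raw").name
        header.append(f"ElementDataFile = {raw_name}")
        path.write_text("\n".join(header) + "\n")
        (path.parent / raw_name).write_bytes(data.tobytes())
    else:
        header.append("ElementDataFile = LOCAL")
        with open(path, "wb") as fh:
            fh.write(("\n".join(header) + "\n").encode("ascii"))
            fh.write(data.tobytes())


_LANDMARK_COLUMNS = [
    "specimen_id", "side",
    "entry_x", "entry_y", "entry_z",
    "exit_x", "exit_y", "exit_z",
]


def read_landmarks(path) -> list[LandmarkPair]:
    """Read landmark pairs from CSV (header columns of ``_LANDMARK_COLUMNS``)
    or an equivalent JSON list of objects."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        records = json.loads(path.read_text())
    else:
        import pandas as pd

        df = pd.read_csv(path)
        missing = [c for c in _LANDMARK_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"landmark CSV missing columns: {missing}")
        records = df.to_dict("records")
    out = []
    for r in records:
        out.append(
            LandmarkPair(
                entry=WorldPoint(float(r["entry_x"]), float(r["entry_y"]), float(r["entry_z"])),
                exit=WorldPoint(float(r["exit_x"]), float(r["exit_y"]), float(r["exit_z"])),
                specimen_id=str(r["specimen_id"]),
                side=str(r["side"]),
            )
        )
    return out


def write_landmarks(pairs: Sequence[LandmarkPair], path) -> None:
    import pandas as pd

    rows = []
    for lm in pairs:
        e, x = lm.entry, lm.exit
        rows.append([lm.specimen_id, lm.side, e.x, e.y, e.z, x.x, x.y, x.z])
    pd.DataFrame(rows, columns=_LANDMARK_COLUMNS).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Sampling geometry
# ---------------------------------------------------------------------------

def interpolate_hu(vol: HUVolume, points):
    """Trilinear HU interpolation at one or many world points.

    Exact voxel-centre queries return the stored value.  Points outside the
    index grid raise :class:`OutOfBoundsError` — never silent extrapolation.
    Returns a scalar for a single point, an array otherwise.
    """
    pts = _as_xyz(points)
    single = pts.ndim == 1
    flat = np.atleast_2d(pts)
    idx = vol.world_to_index(flat)

    shape = np.array(vol.shape)
    eps = 1e-9
    oob = np.any((idx < -eps) | (idx > shape - 1 + eps), axis=1)
    if np.any(oob):
        bad = np.flatnonzero(oob)
        raise OutOfBoundsError(
            f"{bad.size} sample point(s) outside the volume grid "
            f"(first at world {flat[bad[0]]}, index {idx[bad[0]]})",
            indices=bad,
        )
    idx = np.clip(idx, 0.0, shape - 1)

    i0 = np.minimum(np.floor(idx).astype(int), shape - 2)
    f = idx - i0
    v = vol.values
    x0, y0, z0 = i0[:, 0], i0[:, 1], i0[:, 2]
    fx, fy, fz = f[:, 0], f[:, 1], f[:, 2]

    out = np.zeros(len(flat))
    for dx in (0, 1):
        wx = fx if dx else 1.0 - fx
        for dy in (0, 1):
            wy = fy if dy else 1.0 - fy
            for dz in (0, 1):
                wz = fz if dz else 1.0 - fz
                out += wx * wy * wz * v[x0 + dx, y0 + dy, z0 + dz]
    return float(out[0]) if single else out


class Stations(NamedTuple):
    """Ordered probe stations along a straight corridor."""

    points: np.ndarray  # (n, 3) world mm
    arc_mm: np.ndarray  # (n,) distance from entry


def probe_stations(lm: LandmarkPair, step_mm: float = 1.0) -> Stations:
    """Stations at 0, step, 2*step, ... along the entry->exit segment.

    The exit point is always appended as the final station, even when the
    last interval is shorter than ``step_mm``, so the full corridor length
    is covered.
    """
    if step_mm <= 0:
        raise ValueError("step_mm must be positive")
    length = lm.separation_mm
    if length <= 0:
        raise ValueError("degenerate corridor: entry equals exit")
    arcs = np.arange(0.0, length, step_mm)
    if length - arcs[-1] > 1e-9:
        arcs = np.append(arcs, length)
    else:
        arcs[-1] = length
    entry = lm.entry.as_array()
    points = entry[None, :] + arcs[:, None] * lm.direction[None, :]
    return Stations(points=points, arc_mm=arcs)


def _orthonormal_frame(axis: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Two unit vectors spanning the plane orthogonal to ``axis``."""
    norm = np.linalg.norm(axis)
    if norm < 1e-12:
        raise ValueError("axis vector must be nonzero")
    a = axis / norm
    helper = np.zeros(3)
    helper[np.argmin(np.abs(a))] = 1.0
    u = np.cross(a, helper)
    u /= np.linalg.norm(u)
    v = np.cross(a, u)
    return u, v


def disc_samples(center, axis, radius_mm: float, n_rings: int = 2,
                 n_angles: int = 16) -> np.ndarray:
    """Sample points on a disc orthogonal to ``axis``: the centre plus
    ``n_rings`` concentric rings of ``n_angles`` points, outermost ring at
    exactly ``radius_mm``.  Returns an array of shape (1 + n_rings*n_angles, 3).
    """
    if radius_mm < 0:
        raise ValueError("radius_mm must be non-negative")
    c = _as_xyz(center)
    if radius_mm == 0:
        return c[None, :].copy()
    if n_angles < 4:
        raise ValueError("n_angles must be >= 4 for a positive radius")
    if n_rings < 1:
        raise ValueError("n_rings must be >= 1 for a positive radius")
    u, v = _orthonormal_frame(np.asarray(axis, dtype=float))
    theta = np.linspace(0.0, 2.0 * np.pi, n_angles, endpoint=False)
    radii = radius_mm * np.arange(1, n_rings + 1) / n_rings
    offsets = [np.zeros((1, 3))]
    for r in radii:
        ring = r * (np.cos(theta)[:, None] * u[None, :] + np.sin(theta)[:, None] * v[None, :])
        offsets.append(ring)
    return c[None, :] + np.vstack(offsets)


def disc_offsets(axis, radius_mm: float, n_rings: int = 2, n_angles: int = 16) -> np.ndarray:
    """Disc sample offsets around the origin (see :func:`disc_samples`)."""
    return disc_samples(np.zeros(3), axis, radius_mm, n_rings, n_angles)
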