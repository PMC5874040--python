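"""Domain types and I/O for embryo movie bundles.

Coordinates are micrometers everywhere, using a voxel-center convention:
0-based voxel index ``i`` along an axis maps to physical position
``(i + 0.5) * voxel_size_um``.  Volumes are stored as boolean arrays with
axis order (x, y, z); on disk they are multi-page TIFFs with one page per
z slice (page axis = z), uint8, nonzero = labeled, with a YAML sidecar
recording voxel size, channel and timepoint.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml
from scipy import ndimage

from .errors import ParseError, ValidationError

CHANNELS = ("pan_nuclear", "fiducial_gfp", "reporter_gfp")

NUCLEI_COLUMNS = ("t", "x_um", "y_um", "z_um", "intensity")


@dataclass(frozen=True)
class AcquisitionGrid:
    """Isotropic voxel grid plus the two-phase imaging schedule.

    The default schedule is 20 stacks at 10-min intervals (T1-T20, slow
    phase used for staging) followed by 125 stacks at 2-min intervals
    (T21-T145, fast phase through morphogenesis to twitching).
    """

    shape_voxels: tuple[int, int, int]
    voxel_size_um: float = 0.1625
    slow_interval_min: float = 10.0
    fast_interval_min: float = 2.0
    slow_count: int = 20
    fast_count: int = 125

    def __post_init__(self) -> None:
        if self.voxel_size_um <= 0:
            raise ValidationError("voxel_size_um must be positive")
        if len(self.shape_voxels) != 3 or any(int(s) < 1 for s in self.shape_voxels):
            raise ValidationError("shape_voxels must be three integers >= 1")
        object.__setattr__(self, "shape_voxels", tuple(int(s) for s in self.shape_voxels))
        if self.slow_interval_min <= 0 or self.fast_interval_min <= 0:
            raise ValidationError("frame intervals must be positive")

    @property
    def extent_um(self) -> np.ndarray:
        """Physical frame extent along (x, y, z)."""
        return np.asarray(self.shape_voxels, dtype=float) * self.voxel_size_um

    @property
    def n_timepoints(self) -> int:
        return self.slow_count + self.fast_count

    def time_of(self, index: int) -> float:
        """Acquisition time in minutes of 1-based timepoint ``index``."""
        if not 1 <= index <= self.n_timepoints:
            raise ValidationError(f"timepoint index {index} outside 1..{self.n_timepoints}")
        if index <= self.slow_count:
            return (index - 1) * self.slow_interval_min
        slow_end = (self.slow_count - 1) * self.slow_interval_min
        return slow_end + (index - self.slow_count) * self.fast_interval_min

    def times_min(self) -> np.ndarray:
        return np.array([self.time_of(i) for i in range(1, self.n_timepoints + 1)])

    def index_near(self, time_min: float) -> int:
        """1-based timepoint whose acquisition time is closest to ``time_min``."""
        times = self.times_min()
        return int(np.argmin(np.abs(times - time_min))) + 1

    def voxel_centers_um(self, indices: np.ndarray) -> np.ndarray:
        """Physical centers of voxels given an (n, 3) array of 0-based indices."""
        return (np.asarray(indices, dtype=float) + 0.5) * self.voxel_size_um


@dataclass
class CountSeries:
    """Nuclear counts over time, possibly interpolated.

    ``interpolation_factor`` is 1 for raw (integer) counts; interpolated
    series keep the factor so downstream code knows the lattice step.
    """

    times_min: np.ndarray
    counts: np.ndarray
    interpolation_factor: int = 1

    def __post_init__(self) -> None:
        self.times_min = np.asarray(self.times_min, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        if self.times_min.shape != self.counts.shape or self.times_min.ndim != 1:
            raise ValidationError("times and counts must be equal-length 1-D vectors")
        if np.any(np.diff(self.times_min) <= 0):
            raise ValidationError("times must be strictly increasing")
        if np.any(self.counts < 0):
            raise ValidationError("counts must be nonnegative")
        if self.interpolation_factor < 1:
            raise ValidationError("interpolation_factor must be >= 1")
        if self.interpolation_factor == 1 and not np.allclose(self.counts, np.round(self.counts)):
            raise ValidationError("raw (uninterpolated) counts must be integers")

    @property
    def step_min(self) -> float:
        return float(self.times_min[1] - self.times_min[0]) if len(self.times_min) > 1 else np.nan

    def __len__(self) -> int:
        return len(self.times_min)


@dataclass
class NucleiTimeSeries:
    """Per-timepoint nuclear centers from the pan-nuclear channel."""

    records: pd.DataFrame  # columns t, x_um, y_um, z_um, intensity
    grid: AcquisitionGrid

    def __post_init__(self) -> None:
        df = self.records
        missing = [c for c in NUCLEI_COLUMNS[:4] if c not in df.columns]
        if missing:
            raise ValidationError(f"nuclei records missing columns {missing}")
        if "intensity" not in df.columns:
            df = df.assign(intensity=np.nan)
        df = df.astype({"t": int}).sort_values(["t"], kind="stable").reset_index(drop=True)
        ts = np.unique(df["t"].to_numpy())
        if len(ts) == 0:
            raise ValidationError("empty nuclei table")
        if ts[0] != 1 or not np.array_equal(ts, np.arange(1, len(ts) + 1)):
            raise ValidationError("timepoint indices must be contiguous from 1")
        extent = self.grid.extent_um
        xyz = df[["x_um", "y_um", "z_um"]].to_numpy(float)
        bad = np.where((xyz < 0).any(axis=1) | (xyz > extent).any(axis=1))[0]
        if len(bad):
            r = df.iloc[bad[0]]
            raise ValidationError(
                f"nuclear center outside frame extent {extent.round(2).tolist()} um: "
                f"t={int(r['t'])}, ({r['x_um']}, {r['y_um']}, {r['z_um']})"
            )
        self.records = df

    @property
    def timepoints(self) -> np.ndarray:
        return np.unique(self.records["t"].to_numpy())

    def centers(self, t: int) -> np.ndarray:
        sel = self.records[self.records["t"] == t]
        if sel.empty:
            raise ValidationError(f"no nuclei stored for timepoint {t}")
        return sel[["x_um", "y_um", "z_um"]].to_numpy(float)

    def count_series(self) -> CountSeries:
        ts = self.timepoints
        counts = self.records.groupby("t").size().reindex(ts).to_numpy(float)
        times = np.array([self.grid.time_of(int(t)) for t in ts])
        return CountSeries(times_min=times, counts=counts, interpolation_factor=1)


@dataclass
class LabelVolume:
    """Binary mask for one channel at one timepoint on the acquisition grid."""

    grid: AcquisitionGrid
    channel: str
    timepoint_index: int
    mask: np.ndarray  # bool, shape grid.shape_voxels, axis order (x, y, z)

    def __post_init__(self) -> None:
        if self.channel not in CHANNELS:
            raise ValidationError(f"unknown channel {self.channel!r}; expected one of {CHANNELS}")
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != tuple(self.grid.shape_voxels):
            raise ValidationError(
                f"mask shape {self.mask.shape} != grid shape {self.grid.shape_voxels}"
            )

    def labeled_points_um(self) -> np.ndarray:
        """(n, 3) physical centers of labeled voxels."""
        idx = np.argwhere(self.mask)
        return self.grid.voxel_centers_um(idx)

    @property
    def n_labeled(self) -> int:
        return int(self.mask.sum())


# ---------------------------------------------------------------------------
# readers / writers


def read_nuclei_table(path: str | Path, grid: AcquisitionGrid) -> NucleiTimeSeries:
    """Read a headered CSV of nuclear centers (columns t,x_um,y_um,z_um[,intensity])."""
    path = Path(path)
    if not path.exists():
        raise ParseError(f"nuclei table not found: {path}")
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ParseError(f"could not parse {path}: {exc}") from exc
    missing = [c for c in NUCLEI_COLUMNS[:4] if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    for col in NUCLEI_COLUMNS[:4]:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = np.where(coerced.isna() & df[col].notna())[0]
        if len(bad):
            # +2: 1-based line numbers, plus the header line
            raise ParseError(f"{path}: malformed value in column {col!r} at line {bad[0] + 2}")
        if coerced.isna().any():
            raise ParseError(f"{path}: empty value in column {col!r}")
        df[col] = coerced
    return NucleiTimeSeries(records=df, grid=grid)


def write_nuclei_table(series: NucleiTimeSeries, path: str | Path) -> None:
    cols = list(NUCLEI_COLUMNS)
    series.records.loc[:, cols].to_csv(path, index=False)


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".yaml")


def write_label_volume(volume: LabelVolume, path: str | Path) -> None:
    """Write mask as multi-page TIFF (page = z slice) plus a YAML sidecar."""
    path = Path(path)
    pages = volume.mask.astype(np.uint8).transpose(2, 1, 0)  # (z, y, x)
    tifffile.imwrite(path, pages, compression="zlib", photometric="minisblack")
    meta = {
        "voxel_size_um": float(volume.grid.voxel_size_um),
        "channel": volume.channel,
        "timepoint_index": int(volume.timepoint_index),
        "shape_voxels": list(volume.grid.shape_voxels),
    }
    _sidecar_path(path).write_text(yaml.safe_dump(meta))


def read_label_volume(
    path: str | Path,
    channel: str,
    timepoint_index: int,
    grid: AcquisitionGrid,
) -> LabelVolume:
    """Read a multi-page TIFF mask; nonzero voxels are labeled."""
    path = Path(path)
    if not path.exists():
        raise ParseError(f"label volume not found: {path}")
    try:
        pages = tifffile.imread(path)
    except Exception as exc:
        raise ParseError(f"could not read TIFF {path}: {exc}") from exc
    if pages.size == 0:
        raise ParseError(f"empty TIFF stack: {path}")
    if pages.ndim == 2:
        pages = pages[None]
    mask = (pages != 0).transpose(2, 1, 0)  # back to (x, y, z)
    if mask.shape != tuple(grid.shape_voxels):
        raise ValidationError(
            f"{path}: stack shape {mask.shape} (x,y,z) does not match grid {grid.shape_voxels}"
        )
    return LabelVolume(grid=grid, channel=channel, timepoint_index=timepoint_index, mask=mask)


def resample_z_isotropic(stack: np.ndarray, z_spacing_um: float, voxel_xy_um: float) -> np.ndarray:
    """Linearly interpolate a (x, y, z) stack along z to isotropic voxels.

    Slices are treated as slabs of thickness ``z_spacing_um`` spanning a
    physical extent of ``n * z_spacing_um``; the output tiles that extent
    with slabs of thickness ``voxel_xy_um`` (last slab may overhang) and
    interpolates linearly between the nearest input slab centers.  A
    93-slice stack at 0.5 um spacing resampled to 0.1625 um voxels yields
    287 slices.
    """
    n = stack.shape[2]
    span = n * z_spacing_um
    n_out = int(np.ceil(span / voxel_xy_um - 1e-9))
    z_old = (np.arange(n) + 0.5) * z_spacing_um  # slab centers
    z_new = (np.arange(n_out) + 0.5) * voxel_xy_um
    idx = np.searchsorted(z_old, z_new, side="right") - 1
    idx = np.clip(idx, 0, n - 2)
    frac = np.clip((z_new - z_old[idx]) / z_spacing_um, 0.0, 1.0)
    out = stack[:, :, idx] * (1 - frac) + stack[:, :, idx + 1] * frac
    return out


# ---------------------------------------------------------------------------
# channel preprocessing


def subtract_bleedthrough(
    green: np.ndarray, red: np.ndarray, factor: float = 1.0 / 15.0
) -> np.ndarray:
    """Remove red-channel bleedthrough from the green channel.

    ``out = max(green - factor * red, 0)`` elementwise; negative results are
    clamped to zero since intensities are photon counts.
    """
    green = np.asarray(green, dtype=float)
    red = np.asarray(red, dtype=float)
    if green.shape != red.shape:
        raise ValidationError(f"shape mismatch: green {green.shape}, red {red.shape}")
    if factor < 0:
        raise ValidationError("bleedthrough factor must be >= 0")
    return np.maximum(green - factor * red, 0.0)


@dataclass(frozen=True)
class CoreCylinder:
    """Cylinder (in um) cored out of the fiducial mask around the nerve ring."""

    axis_point_um: tuple[float, float, float]
    direction: tuple[float, float, float]
    radius_um: float
    half_length_um: float

    def contains(self, points_um: np.ndarray) -> np.ndarray:
        d = np.asarray(self.direction, dtype=float)
        d = d / np.linalg.norm(d)
        rel = np.asarray(points_um, dtype=float) - np.asarray(self.axis_point_um, dtype=float)
        axial = rel @ d
        radial = np.linalg.norm(rel - np.outer(axial, d), axis=1)
        return (np.abs(axial) <= self.half_length_um) & (radial <= self.radius_um)


_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


def largest_components(mask: np.ndarray, max_objects: int) -> np.ndarray:
    """Keep the ``max_objects`` largest 26-connected components of a 3-D mask."""
    labels, n = ndimage.label(mask, structure=_STRUCT_26)
    if n <= max_objects:
        return mask.copy()
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    # stable ranking: ties broken by lower label id
    order = np.lexsort((np.arange(1, n + 1), -sizes))
    keep = order[:max_objects] + 1
    return np.isin(labels, keep)


def refine_fiducial_mask(
    volume: LabelVolume,
    core_cylinder: CoreCylinder | None = None,
    blur_sigma_um: float = 0.0,
    max_objects: int = 17,
    anterior_half_only: bool = False,
    p1: np.ndarray | None = None,
    centroid_um: np.ndarray | None = None,
) -> LabelVolume:
    """Clean up a fiducial-nucleus segmentation before registration.

    Optionally restricts to the anterior half (P1 coordinate above the embryo
    centroid), cores out a cylinder around the nerve ring, fills gaps with a
    Gaussian blur re-thresholded at 0.5, and keeps only the ``max_objects``
    largest 26-connected components.
    """
    mask = volume.mask.copy()
    grid = volume.grid
    if anterior_half_only:
        if p1 is None or centroid_um is None:
            raise ValidationError("anterior_half_only requires p1 and centroid_um")
        idx = np.argwhere(mask)
        if len(idx):
            pts = grid.voxel_centers_um(idx)
            coord = (pts - np.asarray(centroid_um, float)) @ np.asarray(p1, float)
            drop = idx[coord < 0]
            mask[tuple(drop.T)] = False
    if core_cylinder is not None:
        idx = np.argwhere(mask)
        if len(idx):
            pts = grid.voxel_centers_um(idx)
            drop = idx[core_cylinder.contains(pts)]
            mask[tuple(drop.T)] = False
    if blur_sigma_um > 0:
        sigma_vox = blur_sigma_um / grid.voxel_size_um
        blurred = ndimage.gaussian_filter(mask.astype(float), sigma=sigma_vox)
        mask = blurred >= 0.5
    mask = largest_components(mask, max_objects)
    return replace(volume, mask=mask)
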