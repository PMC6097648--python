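"""Stack and mask I/O with explicit voxel geometry.

Confocal channels are handled as 3D 8-bit grids with array axes ordered
``(slice, row, col)``.  By default the slice axis sweeps anterior to
posterior (frontal sections) and the column axis is mediolateral; both
conventions are metadata on :class:`VoxelGeometry`, never assumptions made
downstream.  Physical positions are voxel-center times pitch, with 0-based
indices.

Masks on disk are single-channel 8-bit TIFFs, 0 = false and 255 = true; any
other nonzero value reads as true with a logged warning.  16-bit intensity
inputs are linearly rescaled onto [0, 255] with a logged warning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import tifffile

logger = logging.getLogger(__name__)

__all__ = [
    "CongruenceError",
    "VoxelGeometry",
    "VoxelStack",
    "ChannelSet",
    "BinaryMask",
    "SpecimenRecord",
    "read_channel_set",
    "write_channel_set",
    "read_stack",
    "write_stack",
    "read_mask",
    "write_mask",
    "crop_roi",
    "subtract_mask_region",
    "read_manifest",
    "write_manifest",
    "load_specimen",
]

#: In-plane pixel pitch (μm) of the acquisitions this pipeline was built for.
DEFAULT_PIXEL_UM = 0.22


class CongruenceError(ValueError):
    """Two grids that must share shape and geometry do not."""


@dataclass(frozen=True)
class VoxelGeometry:
    """Voxel pitches (μm) plus anatomical axis semantics.

    ``dz`` is the pitch along the slice (anteroposterior) axis, ``dx`` the
    pitch along the mediolateral axis and ``dy`` the pitch along the
    remaining in-plane axis.  ``medial_direction`` is the sign (+1/-1) along
    the mediolateral array axis that points medially for this specimen's
    side.
    """

    dx: float = DEFAULT_PIXEL_UM
    dy: float = DEFAULT_PIXEL_UM
    dz: float = 1.0
    ap_axis: int = 0
    ml_axis: int = 2
    medial_direction: int = 1

    def __post_init__(self) -> None:
        if not (self.dx > 0 and self.dy > 0 and self.dz > 0):
            raise ValueError(
                f"voxel pitches must be positive, got dx={self.dx}, dy={self.dy}, dz={self.dz}"
            )
        if self.ap_axis not in (0, 1, 2):
            raise ValueError(f"ap_axis must be 0, 1 or 2, got {self.ap_axis}")
        if self.ml_axis not in (0, 1, 2):
            raise ValueError(f"ml_axis must be 0, 1 or 2, got {self.ml_axis}")
        if self.ap_axis == self.ml_axis:
            raise ValueError("ap_axis and ml_axis must differ")
        if self.medial_direction not in (1, -1):
            raise ValueError(f"medial_direction must be +1 or -1, got {self.medial_direction}")

    def axis_pitch(self, axis: int) -> float:
        """Physical pitch (μm) along the given array axis."""
        if axis == self.ap_axis:
            return self.dz
        if axis == self.ml_axis:
            return self.dx
        return self.dy

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in μm³."""
        return self.dx * self.dy * self.dz

    @property
    def slice_area_pitch(self) -> float:
        """In-plane area of one voxel footprint (μm²), i.e. the product of
        the two pitches orthogonal to the slice axis."""
        axes = [a for a in (0, 1, 2) if a != self.ap_axis]
        return self.axis_pitch(axes[0]) * self.axis_pitch(axes[1])

    def isclose(self, other: "VoxelGeometry", rtol: float = 1e-6) -> bool:
        return (
            np.isclose(self.dx, other.dx, rtol=rtol)
            and np.isclose(self.dy, other.dy, rtol=rtol)
            and np.isclose(self.dz, other.dz, rtol=rtol)
            and self.ap_axis == other.ap_axis
            and self.ml_axis == other.ml_axis
            and self.medial_direction == other.medial_direction
        )


def _as_uint8(arr: np.ndarray, what: str) -> np.ndarray:
    """Validate/coerce an intensity array to 3D uint8."""
    arr = np.asarray(arr)
    if arr.ndim != 3 or arr.size == 0:
        raise ValueError(f"{what}: expected a nonempty 3D array, got shape {arr.shape}")
    if arr.dtype == np.uint8:
        return arr
    if np.issubdtype(arr.dtype, np.integer):
        if arr.min() < 0 or arr.max() > 255:
            raise ValueError(f"{what}: integer intensities outside [0, 255]")
        return arr.astype(np.uint8)
    raise ValueError(f"{what}: expected 8-bit integer intensities, got dtype {arr.dtype}")


@dataclass
class VoxelStack:
    """One channel's 3D 8-bit intensity grid plus voxel geometry."""

    intensities: np.ndarray
    geometry: VoxelGeometry = field(default_factory=VoxelGeometry)
    channel_name: str = ""

    def __post_init__(self) -> None:
        self.intensities = _as_uint8(self.intensities, f"channel {self.channel_name!r}")

    @property
    def shape(self) -> tuple:
        return self.intensities.shape

    def with_intensities(self, arr: np.ndarray) -> "VoxelStack":
        return VoxelStack(arr, self.geometry, self.channel_name)


@dataclass
class BinaryMask:
    """3D boolean grid congruent with the stack it was derived from."""

    voxels: np.ndarray
    geometry: VoxelGeometry = field(default_factory=VoxelGeometry)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3 or self.voxels.size == 0:
            raise ValueError(f"mask: expected a nonempty 3D array, got shape {self.voxels.shape}")
        if self.voxels.dtype != bool:
            self.voxels = self.voxels.astype(bool)

    @property
    def shape(self) -> tuple:
        return self.voxels.shape

    def count(self) -> int:
        return int(self.voxels.sum())

    def volume(self) -> float:
        """Foreground volume in μm³."""
        return self.count() * self.geometry.voxel_volume


def require_congruent(a, b, what: str = "operands") -> None:
    """Hard error unless two stacks/masks share shape and geometry."""
    if a.shape != b.shape:
        raise CongruenceError(f"{what}: shape mismatch {a.shape} vs {b.shape}")
    if not a.geometry.isclose(b.geometry):
        raise CongruenceError(f"{what}: geometry mismatch {a.geometry} vs {b.geometry}")


class ChannelSet:
    """Named collection of congruent :class:`VoxelStack` channels."""

    def __init__(self, channels: Mapping[str, VoxelStack]):
        if not channels:
            raise ValueError("ChannelSet requires at least one channel")
        self.channels: dict[str, VoxelStack] = dict(channels)
        first = next(iter(self.channels.values()))
        for name, stack in self.channels.items():
            require_congruent(first, stack, f"channels {next(iter(self.channels))!r} vs {name!r}")
            stack.channel_name = name

    @property
    def shape(self) -> tuple:
        return next(iter(self.channels.values())).shape

    @property
    def geometry(self) -> VoxelGeometry:
        return next(iter(self.channels.values())).geometry

    def names(self) -> list[str]:
        return list(self.channels)

    def __contains__(self, name: str) -> bool:
        return name in self.channels

    def __getitem__(self, name: str) -> VoxelStack:
        try:
            return self.channels[name]
        except KeyError:
            raise KeyError(
                f"unknown channel {name!r}; available channels: {sorted(self.channels)}"
            ) from None

    def map(self, fn) -> "ChannelSet":
        return ChannelSet({n: fn(s) for n, s in self.channels.items()})


# ---------------------------------------------------------------------------
# ROI and manual-mask arithmetic
# ---------------------------------------------------------------------------

def crop_roi(channel_set: ChannelSet, roi_mask: BinaryMask) -> ChannelSet:
    """Zero every voxel outside the ROI in every channel.

    Mirrors restricting the analysis to the afferent axons and the primary
    dendrite by trimming the stack to a drawn region.
    """
    require_congruent(next(iter(channel_set.channels.values())), roi_mask, "ROI crop")
    keep = roi_mask.voxels

    def _crop(stack: VoxelStack) -> VoxelStack:
        out = np.where(keep, stack.intensities, 0).astype(np.uint8)
        return stack.with_intensities(out)

    return channel_set.map(_crop)


def subtract_mask_region(stack: VoxelStack, region: BinaryMask) -> VoxelStack:
    """Zero intensities *inside* the region.

    Complement of :func:`crop_roi` on a single channel: applying a JO-A mask
    with crop and subtracting the same mask from the original yields the
    JO-B complement image, and their voxelwise sum reconstructs the input.
    """
    require_congruent(stack, region, "mask subtraction")
    out = np.where(region.voxels, 0, stack.intensities).astype(np.uint8)
    return stack.with_intensities(out)


# ---------------------------------------------------------------------------
# TIFF I/O
# ---------------------------------------------------------------------------

def _coerce_read(arr: np.ndarray, path) -> np.ndarray:
    if arr.dtype == np.uint8:
        return arr
    if arr.dtype == np.uint16:
        logger.warning("%s: 16-bit input linearly rescaled to 8-bit", path)
        return np.round(arr.astype(np.float64) * (255.0 / 65535.0)).astype(np.uint8)
    raise ValueError(f"{path}: unsupported dtype {arr.dtype}; expected uint8 or uint16")


def read_stack(path, geometry: VoxelGeometry, channel_name: str = "") -> VoxelStack:
    arr = tifffile.imread(str(path))
    if arr.ndim == 2:
        arr = arr[None]
    return VoxelStack(_coerce_read(arr, path), geometry, channel_name)


def write_stack(stack: VoxelStack, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(
        str(path),
        stack.intensities,
        photometric="minisblack",
        metadata={"axes": "ZYX"},
    )
    return path


def read_mask(path, geometry: VoxelGeometry) -> BinaryMask:
    arr = tifffile.imread(str(path))
    if arr.ndim == 2:
        arr = arr[None]
    values = np.unique(arr)
    if not set(values.tolist()) <= {0, 255}:
        logger.warning("%s: mask has values other than 0/255; any nonzero reads as true", path)
    return BinaryMask(arr != 0, geometry)


def write_mask(mask: BinaryMask, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(
        str(path),
        (mask.voxels.astype(np.uint8) * 255),
        photometric="minisblack",
        metadata={"axes": "ZYX"},
    )
    return path


def read_channel_set(source, channel_map, geometry: VoxelGeometry) -> ChannelSet:
    """Read a multi-channel set.

    Parameters
    ----------
    source
        Either a mapping ``{channel name: TIFF path}`` (one single-channel
        z-stack per file) or a single multi-channel TIFF path whose array is
        4D with axes ``(C, Z, Y, X)``.
    channel_map
        For a path mapping: iterable of channel names to load (``None`` =
        all).  For a single 4D file: mapping ``{channel name: channel
        index}``.
    geometry
        Voxel geometry shared by all channels.
    """
    channels: dict[str, VoxelStack] = {}
    if isinstance(source, Mapping):
        wanted = list(source) if channel_map is None else list(channel_map)
        for name in wanted:
            if name not in source:
                raise KeyError(
                    f"unknown channel {name!r}; available channels: {sorted(source)}"
                )
            channels[name] = read_stack(source[name], geometry, name)
    else:
        arr = tifffile.imread(str(source))
        if arr.ndim == 3:
            arr = arr[None]
        if arr.ndim != 4:
            raise ValueError(f"{source}: expected a (C, Z, Y, X) stack, got shape {arr.shape}")
        if not isinstance(channel_map, Mapping):
            raise ValueError("for a single multi-channel file, channel_map must map name -> index")
        for name, idx in channel_map.items():
            if not 0 <= int(idx) < arr.shape[0]:
                raise KeyError(
                    f"unknown channel {name!r} (index {idx}); "
                    f"available channel indices: {list(range(arr.shape[0]))}"
                )
            channels[name] = VoxelStack(_coerce_read(arr[int(idx)], source), geometry, name)
    return ChannelSet(channels)


def write_channel_set(channel_set: ChannelSet, directory, prefix: str = "") -> dict[str, Path]:
    """Write one single-channel TIFF per channel; returns name -> path."""
    directory = Path(directory)
    out = {}
    for name, stack in channel_set.channels.items():
        out[name] = write_stack(stack, directory / f"{prefix}{name}.tif")
    return out


# ---------------------------------------------------------------------------
# Specimen manifest
# ---------------------------------------------------------------------------

_MANIFEST_BASE_COLS = ["specimen_id", "group", "dx", "dy", "dz", "ap_axis", "medial_direction"]


@dataclass
class SpecimenRecord:
    """One manifest row: identity, group label, geometry and file paths."""

    specimen_id: str
    group: str
    geometry: VoxelGeometry
    channel_paths: dict[str, Path] = field(default_factory=dict)
    mask_paths: dict[str, Path] = field(default_factory=dict)


def write_manifest(records: Iterable[SpecimenRecord], path) -> Path:
    """Write the specimen manifest CSV.

    Columns: specimen_id, group, dx, dy, dz, ap_axis, medial_direction plus
    one ``channel:<name>`` column per channel and ``mask:<name>`` per mask;
    paths are stored relative to the manifest's directory when possible.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in records:
        row = {
            "specimen_id": rec.specimen_id,
            "group": rec.group,
            "dx": rec.geometry.dx,
            "dy": rec.geometry.dy,
            "dz": rec.geometry.dz,
            "ap_axis": rec.geometry.ap_axis,
            "medial_direction": rec.geometry.medial_direction,
        }
        for name, p in rec.channel_paths.items():
            row[f"channel:{name}"] = _relativize(p, path.parent)
        for name, p in rec.mask_paths.items():
            row[f"mask:{name}"] = _relativize(p, path.parent)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


def _relativize(p, base: Path) -> str:
    p = Path(p)
    try:
        return str(p.relative_to(base))
    except ValueError:
        return str(p)


def read_manifest(path) -> list[SpecimenRecord]:
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in _MANIFEST_BASE_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: manifest missing required columns {missing}")
    records = []
    for _, row in df.iterrows():
        geom = VoxelGeometry(
            dx=float(row["dx"]),
            dy=float(row["dy"]),
            dz=float(row["dz"]),
            ap_axis=int(row["ap_axis"]),
            medial_direction=int(row["medial_direction"]),
        )
        chans, masks = {}, {}
        for col, value in row.items():
            if pd.isna(value):
                continue
            if str(col).startswith("channel:"):
                chans[str(col)[len("channel:"):]] = path.parent / str(value)
            elif str(col).startswith("mask:"):
                masks[str(col)[len("mask:"):]] = path.parent / str(value)
        records.append(
            SpecimenRecord(str(row["specimen_id"]), str(row["group"]), geom, chans, masks)
        )
    ids = [r.specimen_id for r in records]
    dupes = sorted({i for i in ids if ids.count(i) > 1})
    if dupes:
        raise ValueError(f"{path}: duplicate specimen_id values {dupes}")
    return records


def load_specimen(record: SpecimenRecord):
    """Load a manifest row into memory.

    Returns ``(ChannelSet, {mask name: BinaryMask})``.
    """
    channels = read_channel_set(record.channel_paths, None, record.geometry)
    masks = {name: read_mask(p, record.geometry) for name, p in record.mask_paths.items()}
    for m in masks.values():
        require_congruent(next(iter(channels.channels.values())), m, "specimen mask")
    return channels, masks
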