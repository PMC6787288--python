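"""Acquisition geometry and raw-image preprocessing for block-face serial
two-photon tomography (STPT) stacks.

STPT alternates two-photon imaging of a few optical planes just below the cut
surface of an agarose-embedded brain with vibratome removal of the imaged
slab.  Each coronal plane is acquired as a mosaic of overlapping tiles that
are flat-field corrected and stitched; the optical planes of one physical
section are collapsed by maximum-intensity projection (MIP), and the MIP
images are downsampled before pixel classification.

Conventions used throughout the package
---------------------------------------
* voxel indices are 0-based with axis order ``(section, row, col)`` =
  (anterior->posterior, dorsal->ventral, left->right);
* the physical position of a voxel center is ``index * spacing``;
* 2-D images are ``(row, col)`` or ``(row, col, channel)`` arrays;
* raw channels are 16-bit, probability maps 8-bit; out-of-range values are
  clipped, never wrapped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import tifffile

logger = logging.getLogger("stptquant")

__all__ = [
    "OpticalSchedule",
    "RawTileGrid",
    "SectionImage",
    "VolumeStack",
    "AcquisitionSummary",
    "flat_field_correct",
    "stitch_tiles",
    "make_mip",
    "downsample",
    "plan_acquisition",
    "round_half_away",
    "write_stack",
    "read_stack",
]


def round_half_away(x: np.ndarray | float) -> np.ndarray:
    """Round to the nearest integer, halves away from zero (0.5 -> 1, -0.5 -> -1).

    numpy's ``round`` rounds halves to even; image intensities here follow the
    commercial-scanner convention instead so that 127.5 maps to 128.
    """
    x = np.asarray(x, dtype=np.float64)
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


def _cast_like(values: np.ndarray, dtype: np.dtype) -> np.ndarray:
    """Cast float values back to ``dtype``, clipping integer ranges."""
    if np.issubdtype(dtype, np.integer):
        info = np.iinfo(dtype)
        return np.clip(round_half_away(values), info.min, info.max).astype(dtype)
    return values.astype(dtype)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class OpticalSchedule:
    """Imaging schedule of an STPT acquisition.

    Parameters
    ----------
    cut_thickness_um:
        Vibratome advance between physical sections, in micrometres.
    plane_depths_um:
        Depths of the optical planes below the freshly cut surface (strictly
        increasing, each in ``(0, cut_thickness_um]``).
    n_physical_sections:
        Number of physical sections cut over the whole brain.
    lateral_resolution_um:
        In-plane pixel size of the raw mosaics.
    channels:
        Ordered emission-channel names.
    """

    cut_thickness_um: float
    plane_depths_um: tuple[float, ...]
    n_physical_sections: int
    lateral_resolution_um: float
    channels: tuple[str, ...] = ("red", "green", "blue")

    def __post_init__(self) -> None:
        depths = tuple(float(d) for d in self.plane_depths_um)
        object.__setattr__(self, "plane_depths_um", depths)
        object.__setattr__(self, "channels", tuple(self.channels))
        if self.cut_thickness_um <= 0:
            raise ValueError("cut_thickness_um must be positive")
        if self.lateral_resolution_um <= 0:
            raise ValueError("lateral_resolution_um must be positive")
        if self.n_physical_sections < 1:
            raise ValueError("n_physical_sections must be a positive integer")
        if not depths:
            raise ValueError("at least one optical plane is required")
        if any(d <= 0 or d > self.cut_thickness_um for d in depths):
            raise ValueError("plane depths must lie in (0, cut_thickness]")
        if any(b <= a for a, b in zip(depths, depths[1:])):
            raise ValueError("plane depths must be strictly increasing")


@dataclass(frozen=True)
class AcquisitionSummary:
    total_images: int
    n_physical_sections: int
    sampled_depth_um: float


@dataclass
class SectionImage:
    """A single stitched coronal plane.

    ``pixels`` is ``(rows, cols)`` or ``(rows, cols, channels)``;
    ``pixel_size_um`` the in-plane sampling; ``section_index`` the 0-based
    position along the anterior-posterior axis.
    """

    pixels: np.ndarray
    pixel_size_um: float
    section_index: int = 0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim not in (2, 3):
            raise ValueError("pixels must be 2-D or 2-D multi-channel")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")

    @property
    def n_channels(self) -> int:
        return 1 if self.pixels.ndim == 2 else self.pixels.shape[2]


@dataclass
class RawTileGrid:
    """Rectangular mosaic of single-plane tiles, row-major acquisition order.

    ``tiles[r][c]`` is the tile at grid position (r, c); adjacent tiles share
    ``overlap_px`` pixels along each axis.  ``flat_field`` optionally holds a
    per-channel illumination profile applied before stitching.
    """

    tiles: Sequence[Sequence[np.ndarray]]
    overlap_px: int = 0
    flat_field: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.overlap_px < 0:
            raise ValueError("overlap_px must be nonnegative")
        rows = [list(r) for r in self.tiles]
        if not rows or not rows[0]:
            raise ValueError("tile grid must be fully populated")
        ncols = len(rows[0])
        shape = np.asarray(rows[0][0]).shape
        for r in rows:
            if len(r) != ncols:
                raise ValueError("tile grid must be fully populated")
            for t in r:
                if np.asarray(t).shape != shape:
                    raise ValueError("all tiles must have the same shape")
        self.tiles = [[np.asarray(t) for t in r] for r in rows]

    @property
    def grid_shape(self) -> tuple[int, int]:
        return len(self.tiles), len(self.tiles[0])

    @property
    def tile_shape(self) -> tuple[int, ...]:
        return self.tiles[0][0].shape


@dataclass
class VolumeStack:
    """Ordered stack of coronal sections with physical spacing metadata.

    ``provenance`` records which stage produced the stack: ``"raw"`` (optical
    planes), ``"mip"`` (one image per physical section) or ``"probability"``.
    """

    sections: list[SectionImage]
    axial_spacing_um: float
    provenance: str = "raw"
    channels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if not self.sections:
            raise ValueError("a VolumeStack needs at least one section")
        if self.axial_spacing_um <= 0:
            raise ValueError("axial_spacing_um must be positive")
        if self.provenance not in ("raw", "mip", "probability"):
            raise ValueError(f"unknown provenance {self.provenance!r}")
        shape = self.sections[0].pixels.shape
        px = self.sections[0].pixel_size_um
        for s in self.sections:
            if s.pixels.shape != shape:
                raise ValueError("all sections must share one shape")
            if s.pixel_size_um != px:
                raise ValueError("all sections must share one pixel size")

    @property
    def pixel_size_um(self) -> float:
        return self.sections[0].pixel_size_um

    @property
    def shape(self) -> tuple[int, ...]:
        return (len(self.sections),) + self.sections[0].pixels.shape

    @property
    def n_channels(self) -> int:
        return self.sections[0].n_channels

    def as_array(self) -> np.ndarray:
        """Return ``(sections, rows, cols[, channels])`` array."""
        return np.stack([s.pixels for s in self.sections])

    def channel(self, name_or_index: str | int) -> np.ndarray:
        """Single-channel ``(sections, rows, cols)`` view by name or index."""
        arr = self.as_array()
        if arr.ndim == 3:
            return arr
        if isinstance(name_or_index, str):
            if self.channels is None or name_or_index not in self.channels:
                raise KeyError(f"unknown channel {name_or_index!r}")
            idx = self.channels.index(name_or_index)
        else:
            idx = int(name_or_index)
        return arr[..., idx]

    @classmethod
    def from_array(
        cls,
        arr: np.ndarray,
        pixel_size_um: float,
        axial_spacing_um: float,
        provenance: str = "raw",
        channels: tuple[str, ...] | None = None,
    ) -> "VolumeStack":
        arr = np.asarray(arr)
        sections = [
            SectionImage(arr[i], pixel_size_um, section_index=i)
            for i in range(arr.shape[0])
        ]
        return cls(sections, axial_spacing_um, provenance, channels)


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def flat_field_correct(tile: np.ndarray, flat_field: np.ndarray) -> np.ndarray:
    """Divide out an illumination profile, preserving mean brightness.

    The tile is divided by ``flat_field / mean(flat_field)`` so that a uniform
    field is a no-op; the result is clipped to the input dtype's range.
    """
    tile = np.asarray(tile)
    flat_field = np.asarray(flat_field, dtype=np.float64)
    if tile.shape != flat_field.shape:
        raise ValueError(
            f"tile shape {tile.shape} != flat-field shape {flat_field.shape}"
        )
    if np.any(flat_field <= 0):
        raise ValueError("flat field must be strictly positive")
    corrected = tile.astype(np.float64) / (flat_field / flat_field.mean())
    return _cast_like(corrected, tile.dtype)


def stitch_tiles(grid: RawTileGrid) -> SectionImage:
    """Assemble a tile grid into one mosaic coronal section.

    Tile (r, c) is placed at offset ``(r*(h-overlap), c*(w-overlap))``.
    Overlap zones are resolved first-writer-wins in row-major order, which
    makes reassembly of a sliced reference image bit-exact.  If the grid
    carries a flat field it is applied to every tile first.
    """
    n_rows, n_cols = grid.grid_shape
    tiles = grid.tiles
    if grid.flat_field is not None:
        ff = np.asarray(grid.flat_field, dtype=np.float64)
        tiles = [[flat_field_correct(t, ff) for t in row] for row in tiles]
    t0 = tiles[0][0]
    h, w = t0.shape[:2]
    ov = grid.overlap_px
    if ov >= h or ov >= w:
        raise ValueError("overlap_px must be smaller than the tile size")
    out_shape = (n_rows * (h - ov) + ov, n_cols * (w - ov) + ov) + t0.shape[2:]
    mosaic = np.zeros(out_shape, dtype=t0.dtype)
    # writing in reverse row-major order leaves the first writer on top
    for r in reversed(range(n_rows)):
        for c in reversed(range(n_cols)):
            r0, c0 = r * (h - ov), c * (w - ov)
            mosaic[r0 : r0 + h, c0 : c0 + w] = tiles[r][c]
    return SectionImage(mosaic, pixel_size_um=1.0)


def make_mip(planes: Sequence[SectionImage]) -> SectionImage:
    """Per-pixel, per-channel maximum over co-registered optical planes."""
    if len(planes) == 0:
        raise ValueError("make_mip needs at least one plane")
    shape = planes[0].pixels.shape
    for p in planes:
        if p.pixels.shape != shape:
            raise ValueError("all planes must have the same shape")
    mip = np.maximum.reduce([p.pixels for p in planes])
    return SectionImage(mip, planes[0].pixel_size_um, planes[0].section_index)


def _area_weights(n_in: int, n_out: int, ratio: float) -> np.ndarray:
    """1-D area-resampling matrix: output j averages source [j*ratio, (j+1)*ratio)."""
    w = np.zeros((n_out, n_in))
    for j in range(n_out):
        a = min(j * ratio, float(n_in))
        b = min((j + 1) * ratio, float(n_in))
        for i in range(int(np.floor(a)), min(int(np.ceil(b)), n_in)):
            w[j, i] = min(b, i + 1) - max(a, i)
        s = w[j].sum()
        if s > 0:
            w[j] /= s
    return w


def downsample(image: SectionImage, target_pixel_size_um: float) -> SectionImage:
    """Area-average an image to a coarser pixel grid.

    Output dimensions are ``round(dim * in_px / target_px)``; each output pixel
    averages its source footprint (area interpolation), which preserves summed
    signal far better than nearest-neighbour decimation.  Integer inputs are
    cast back by round-half-away-from-zero.  Upsampling is refused.
    """
    if target_pixel_size_um < image.pixel_size_um:
        raise ValueError("target pixel size must be >= source pixel size")
    if target_pixel_size_um == image.pixel_size_um:
        return replace(image)
    ratio = target_pixel_size_um / image.pixel_size_um
    h, w = image.pixels.shape[:2]
    out_h = max(1, int(round(h * image.pixel_size_um / target_pixel_size_um)))
    out_w = max(1, int(round(w * image.pixel_size_um / target_pixel_size_um)))
    wr = _area_weights(h, out_h, ratio)
    wc = _area_weights(w, out_w, ratio)
    px = image.pixels.astype(np.float64)
    if px.ndim == 2:
        out = wr @ px @ wc.T
    else:
        out = np.einsum("ab,bcq,dc->adq", wr, px, wc)
    return SectionImage(
        _cast_like(out, image.pixels.dtype), target_pixel_size_um, image.section_index
    )


def downsample_stack(stack: VolumeStack, target_pixel_size_um: float) -> VolumeStack:
    """Downsample every section of a stack (axial spacing unchanged)."""
    return VolumeStack(
        [downsample(s, target_pixel_size_um) for s in stack.sections],
        stack.axial_spacing_um,
        stack.provenance,
        stack.channels,
    )


def mip_stack(raw: VolumeStack, schedule: OpticalSchedule) -> VolumeStack:
    """Collapse each physical section's optical planes into one MIP image.

    The raw stack must contain ``n_planes`` consecutive optical planes per
    physical section in acquisition order.  The stored axial spacing of the
    result is the cut thickness (one image per physical section); the finer
    pre-MIP axial sampling survives only as schedule metadata.
    """
    n_planes = len(schedule.plane_depths_um)
    if len(raw.sections) % n_planes:
        raise ValueError(
            f"stack length {len(raw.sections)} is not a multiple of "
            f"{n_planes} optical planes"
        )
    mips = []
    for k in range(len(raw.sections) // n_planes):
        planes = raw.sections[k * n_planes : (k + 1) * n_planes]
        m = make_mip(planes)
        m.section_index = k
        mips.append(m)
    return VolumeStack(mips, schedule.cut_thickness_um, "mip", raw.channels)


def plan_acquisition(schedule: OpticalSchedule) -> AcquisitionSummary:
    """Totals implied by an imaging schedule.

    ``total_images`` counts every stitched 2-D coronal image (physical
    sections x optical planes); ``sampled_depth_um`` is the tissue depth
    consumed by sectioning.
    """
    return AcquisitionSummary(
        total_images=schedule.n_physical_sections * len(schedule.plane_depths_um),
        n_physical_sections=schedule.n_physical_sections,
        sampled_depth_um=schedule.n_physical_sections * schedule.cut_thickness_um,
    )


# ---------------------------------------------------------------------------
# I/O: multi-page TIFF + plain-text sidecar metadata
# ---------------------------------------------------------------------------

_SIDECAR_SUFFIX = ".meta.txt"


def write_stack(stack: VolumeStack, path: str | Path) -> Path:
    """Write a stack as a multi-page TIFF (one page per section, planar
    channels) plus a ``.meta.txt`` sidecar with spacings and provenance."""
    path = Path(path)
    arr = stack.as_array()
    if arr.ndim == 4:  # (S, H, W, C) -> planar (S, C, H, W)
        arr = np.moveaxis(arr, -1, 1)
    tifffile.imwrite(path, arr)
    meta = {
        "pixel_size_um": repr(stack.pixel_size_um),
        "axial_spacing_um": repr(stack.axial_spacing_um),
        "provenance": stack.provenance,
        "channels": ",".join(stack.channels) if stack.channels else "",
        "n_sections": str(len(stack.sections)),
    }
    sidecar = path.with_name(path.name + _SIDECAR_SUFFIX)
    sidecar.write_text("".join(f"{k}: {v}\n" for k, v in meta.items()))
    return path


def read_stack(path: str | Path) -> VolumeStack:
    """Read a stack written by :func:`write_stack`."""
    path = Path(path)
    sidecar = path.with_name(path.name + _SIDECAR_SUFFIX)
    if not sidecar.exists():
        raise FileNotFoundError(f"missing sidecar metadata {sidecar}")
    meta: dict[str, str] = {}
    for line in sidecar.read_text().splitlines():
        if ":" in line:
            k, v = line.split(":", 1)
            meta[k.strip()] = v.strip()
    arr = tifffile.imread(path)
    n_sections = int(meta["n_sections"])
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim == 4:  # planar (S, C, H, W) -> (S, H, W, C)
        arr = np.moveaxis(arr, 1, -1)
    elif arr.ndim == 3 and arr.shape[0] != n_sections:
        # single multi-channel section stored planar
        arr = np.moveaxis(arr, 0, -1)[None]
    channels = tuple(meta["channels"].split(",")) if meta.get("channels") else None
    return VolumeStack.from_array(
        arr,
        float(meta["pixel_size_um"]),
        float(meta["axial_spacing_um"]),
        meta.get("provenance", "raw"),
        channels,
    )
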