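"""Synthetic brain phantoms with complete ground truth.

The phantom module emulates, at desk scale, everything the real pipeline
consumes: a toy hierarchical atlas (block-tiled leaf regions mirrored about
a sagittal midline under a root -> hemisphere -> leaf ontology), a two-channel
image stack containing bright round cell bodies, dimmer tubular processes,
diffuse tissue autofluorescence and an optional bright stroke-like patch,
plus the binary masks, per-region counts and sparse annotations needed to
train and validate the classifier.  An optional smooth deformation warps the
rendered stack away from atlas space so registration has something real to
recover.

Everything is driven by one seeded generator per call, so phantoms are
bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy import ndimage

from .classify import AnnotationSet
from .register import AtlasBundle, Region
from .volio import VolumeStack

__all__ = [
    "PhantomSpec",
    "GroundTruth",
    "generate_atlas",
    "generate_stack",
    "generate_annotations",
    "default_cells_per_region",
]

#: margin of outside-brain background around the tissue block, voxels
_MARGIN = 4


@dataclass
class PhantomSpec:
    """Parameters of one synthetic brain.

    The defaults describe a 64 x 96 x 96 voxel block at 10 um isotropic —
    large enough for 8 mirrored leaf regions and hundreds of cells, small
    enough for seconds-scale tests.  Intensities are 16-bit counts and must
    be ordered stroke >= cell > process > autofluorescence > 0; the default
    cell-to-autofluorescence contrast is far above the noise sigma, matching
    the bright viral/dye labeling the classifier is meant to pick out.
    """

    volume_shape: tuple[int, int, int] = (64, 96, 96)
    voxel_size_um: float = 10.0
    n_regions: int = 8
    cells_per_region: Mapping[int, int] | None = None
    cell_radius_um: float = 20.0
    process_fraction: float = 0.3
    cell_intensity: float = 20000.0
    process_intensity: float = 8000.0
    autofluorescence_level: float = 3000.0
    stroke_intensity: float = 30000.0
    noise_sigma: float = 1000.0
    stroke_region: int | None = None
    deformation_amplitude_vox: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_regions < 2 or self.n_regions % 2:
            raise ValueError("n_regions must be an even integer >= 2")
        if not (
            self.stroke_intensity >= self.cell_intensity
            and self.cell_intensity > self.process_intensity
            and self.process_intensity > self.autofluorescence_level
            and self.autofluorescence_level > 0
        ):
            raise ValueError(
                "intensities must satisfy stroke >= cell > process > autofluorescence > 0"
            )
        if self.cell_radius_um < self.voxel_size_um:
            raise ValueError("cell radius must be at least one voxel")
        if self.cells_per_region is not None and any(
            v < 0 for v in self.cells_per_region.values()
        ):
            raise ValueError("cell counts must be nonnegative")
        if self.noise_sigma < 0 or not (0 <= self.process_fraction <= 1):
            raise ValueError("invalid noise_sigma or process_fraction")

    @property
    def cell_radius_vox(self) -> float:
        return self.cell_radius_um / self.voxel_size_um


@dataclass
class GroundTruth:
    """Everything the phantom knows that a real experiment would not.

    Masks are in sample space (i.e. after any deformation), matching the
    rendered stack; ``region_cell_voxels`` counts cell-mask voxels per atlas
    region in atlas space, the quantity the pipeline tries to recover.
    """

    cell_mask: np.ndarray
    process_mask: np.ndarray
    stroke_mask: np.ndarray
    brain_mask: np.ndarray
    region_cell_counts: dict[int, int]
    region_cell_voxels: dict[int, int]
    deformation_field: np.ndarray | None
    seed: int

    @property
    def total_cells(self) -> int:
        return sum(self.region_cell_counts.values())


def default_cells_per_region(atlas: AtlasBundle, cells_per_leaf: int = 25):
    """Uniform per-leaf cell request; the study-condition default."""
    return {r.id: cells_per_leaf for r in atlas.leaves()}


# ---------------------------------------------------------------------------
# Toy atlas
# ---------------------------------------------------------------------------


def generate_atlas(spec: PhantomSpec) -> AtlasBundle:
    """Block-tiled toy atlas mirrored about the sagittal midline.

    The tissue block is the volume minus a background margin; each
    hemisphere is divided into ``n_regions / 2`` equal slabs along the
    anterior-posterior axis.  The ontology has two levels below the root
    (hemisphere groups, then leaves).  The template is a smoothed
    region-intensity pattern so that mutual-information registration has
    structure to lock onto.
    """
    ns, nr, nc = spec.volume_shape
    n_half = spec.n_regions // 2
    lo_s, hi_s = _MARGIN, ns - _MARGIN
    lo_r, hi_r = _MARGIN, nr - _MARGIN
    lo_c, hi_c = _MARGIN, nc - _MARGIN
    mid = nc // 2
    if hi_s - lo_s < n_half:
        raise ValueError(
            f"{n_half} slabs per hemisphere do not tile {hi_s - lo_s} sections"
        )
    if min(hi_r - lo_r, mid - lo_c) < 1:
        raise ValueError("volume too small for the background margin")

    labels = np.zeros(spec.volume_shape, dtype=np.int32)
    # unequal slab widths (~ k+2) so the anterior-posterior block pattern has
    # no shift self-similarity an intensity-agnostic metric could lock onto
    weights = np.arange(2, n_half + 2, dtype=np.float64)
    edges = lo_s + np.round(
        np.concatenate([[0.0], np.cumsum(weights)]) / weights.sum() * (hi_s - lo_s)
    ).astype(int)
    for k in range(n_half):
        sl = slice(edges[k], edges[k + 1])
        labels[sl, lo_r:hi_r, lo_c:mid] = 100 + k  # left leaf
        labels[sl, lo_r:hi_r, mid:hi_c] = 200 + k  # right leaf (mirror)

    ontology = [
        Region(1, "ROOT", "toy brain root", None),
        Region(2, "LH", "left hemisphere group", 1),
        Region(3, "RH", "right hemisphere group", 1),
    ]
    for k in range(n_half):
        ontology.append(Region(100 + k, f"L{k + 1}", f"left leaf {k + 1}", 2))
        ontology.append(Region(200 + k, f"R{k + 1}", f"right leaf {k + 1}", 3))

    # template: per-region intensity pattern, mirrored, with smooth in-plane
    # gradients so every axis carries alignment information, then smoothed
    template = np.zeros(spec.volume_shape, dtype=np.float64)
    template[labels > 0] = 60.0
    for k in range(n_half):
        bump = 40.0 * (k + 1)
        template[labels == 100 + k] += bump
        template[labels == 200 + k] += bump
    midline = (nc - 1) / 2.0
    gr, gc = np.mgrid[:nr, :nc].astype(np.float64)
    dv = np.cos(np.pi * (gr - (nr - 1) / 2) / max(1, nr))  # dorsal-ventral
    lr = np.abs(gc - midline) / max(1.0, midline)  # mirrored left-right ramp
    template += (30.0 * dv + 25.0 * lr)[None, :, :] * (labels > 0)
    template = ndimage.gaussian_filter(template, 1.5)
    return AtlasBundle(
        template.astype(np.float32),
        labels,
        ontology,
        midline,
        (spec.voxel_size_um,) * 3,
    )


# ---------------------------------------------------------------------------
# Stack rendering
# ---------------------------------------------------------------------------


def _ball_mask(radius: float) -> np.ndarray:
    r = int(np.ceil(radius))
    g = np.mgrid[-r : r + 1, -r : r + 1, -r : r + 1]
    return (g**2).sum(axis=0) <= radius**2


def _ball_offsets(radius: float) -> np.ndarray:
    r = int(np.ceil(radius))
    g = np.mgrid[-r : r + 1, -r : r + 1, -r : r + 1]
    keep = (g**2).sum(axis=0) <= radius**2
    return np.argwhere(keep) - r


def _paint(mask: np.ndarray, centers: np.ndarray, offsets: np.ndarray) -> None:
    shape = np.array(mask.shape)
    for ctr in centers:
        pts = ctr + offsets
        ok = np.all((pts >= 0) & (pts < shape), axis=1)
        pts = pts[ok]
        mask[pts[:, 0], pts[:, 1], pts[:, 2]] = True


def _stroke_ellipsoid(atlas: AtlasBundle, region_id: int) -> np.ndarray:
    """Bright stroke-like patch: an ellipsoid filling ~half of the region."""
    where = np.argwhere(atlas.labels == region_id)
    if where.size == 0:
        raise ValueError(f"stroke region {region_id} has no voxels")
    center = where.mean(axis=0)
    half = (where.max(axis=0) - where.min(axis=0) + 1) / 2.0
    semi = np.maximum(1.5, half * 0.55)
    grid = np.mgrid[: atlas.labels.shape[0], : atlas.labels.shape[1], : atlas.labels.shape[2]]
    d2 = sum(((g - c) / a) ** 2 for g, c, a in zip(grid, center, semi))
    return (d2 <= 1.0) & (atlas.labels > 0)


def _smooth_displacement(
    shape: tuple[int, int, int], amplitude: float, rng: np.random.Generator
) -> np.ndarray:
    """Smooth random displacement field (voxels), tapered to zero at the
    volume boundary so tissue never leaves the field of view."""
    coarse = rng.uniform(-1.0, 1.0, size=(3, 4, 5, 5))
    field = np.stack(
        [
            ndimage.zoom(coarse[a], np.array(shape) / np.array(coarse[a].shape), order=3)
            for a in range(3)
        ],
        axis=-1,
    )
    field = field[: shape[0], : shape[1], : shape[2]]
    peak = np.abs(field).max()
    if peak > 0:
        field /= peak  # cubic zoom can overshoot the coarse-grid range
    taper = np.ones(shape)
    for ax, n in enumerate(shape):
        w = np.minimum(np.arange(n), np.arange(n)[::-1]) / max(1, _MARGIN * 2)
        w = np.clip(w, 0, 1)
        taper *= w.reshape([-1 if a == ax else 1 for a in range(3)])
    return field * (amplitude * taper[..., None])


def _warp(arr: np.ndarray, disp: np.ndarray, order: int) -> np.ndarray:
    """sample(x) = original(x + d(x)): pull-back warp by the displacement."""
    grid = np.mgrid[: arr.shape[0], : arr.shape[1], : arr.shape[2]].astype(np.float64)
    coords = grid + np.moveaxis(disp, -1, 0)
    return ndimage.map_coordinates(
        arr.astype(np.float64), coords, order=order, mode="constant", cval=0.0
    )


def _to_sample_space(atlas_points: np.ndarray, disp: np.ndarray) -> np.ndarray:
    """Invert the pull-back map: find y with y + d(y) = p for each atlas
    point p, by fixed-point iteration (the field is smooth and small)."""
    y = atlas_points.astype(np.float64).copy()
    for _ in range(8):
        d = np.stack(
            [
                ndimage.map_coordinates(disp[..., a], y.T, order=1, mode="nearest")
                for a in range(3)
            ],
            axis=1,
        )
        y = atlas_points - d
    return y


def generate_stack(
    spec: PhantomSpec, atlas: AtlasBundle
) -> tuple[VolumeStack, GroundTruth]:
    """Render a two-channel phantom stack with complete ground truth.

    The red channel carries the smoothed tissue pattern used for
    registration (autofluorescence modulated by the template) plus the
    stroke patch; the green channel carries autofluorescence, cell bodies,
    processes and a dimmer stroke echo.  Gaussian noise is added to both
    and intensities are clipped to the 16-bit range.

    When a deformation is requested it acts on the geometry, the way real
    tissue deforms under a sharp microscope: cell positions and the label
    field are displaced and objects are rendered crisply at their displaced
    sample-space positions (only the smooth background fields are resampled),
    so the image keeps realistic sharp object boundaries instead of an
    interpolation halo.
    """
    rng = np.random.default_rng(spec.seed)
    shape = spec.volume_shape
    if atlas.labels.shape != shape:
        raise ValueError("atlas grid does not match the phantom spec")

    cells = (
        dict(spec.cells_per_region)
        if spec.cells_per_region is not None
        else default_cells_per_region(atlas)
    )
    valid_ids = {r.id for r in atlas.ontology}
    for rid in cells:
        if rid not in valid_ids:
            raise ValueError(f"cells requested in nonexistent region {rid}")

    # geometry: d maps a sample voxel x to its atlas position x + d(x)
    disp = None
    if spec.deformation_amplitude_vox > 0:
        disp = _smooth_displacement(shape, spec.deformation_amplitude_vox, rng)
    if disp is not None:
        sample_labels = _warp(atlas.labels, disp, order=0).astype(np.int32)
    else:
        sample_labels = atlas.labels
    brain = sample_labels > 0

    stroke_atlas = (
        _stroke_ellipsoid(atlas, spec.stroke_region)
        if spec.stroke_region is not None
        else np.zeros(shape, dtype=bool)
    )
    stroke_mask = (
        (_warp(stroke_atlas, disp, order=0) > 0.5) if disp is not None else stroke_atlas
    )

    radius = spec.cell_radius_vox
    offsets = _ball_offsets(radius)
    r_int = int(np.ceil(radius))
    # suppress placement inside (and immediately around) the lesion so no
    # cell body overlaps infarcted tissue
    stroke_keepout = (
        ndimage.binary_dilation(stroke_atlas, _ball_mask(r_int + 1))
        if stroke_atlas.any()
        else stroke_atlas
    )
    cell_mask = np.zeros(shape, dtype=bool)
    region_counts: dict[int, int] = {}
    all_centers: list[np.ndarray] = []
    for rid in sorted(cells):
        n = cells[rid]
        region_counts[rid] = n
        if n == 0:
            continue
        cand = np.argwhere((atlas.labels == rid) & ~stroke_keepout)
        # keep spheres inside the volume
        inside = np.all(
            (cand >= r_int + 2) & (cand < np.array(shape) - r_int - 2), axis=1
        )
        cand = cand[inside]
        if len(cand) < n:
            raise ValueError(f"region {rid} cannot host {n} cells")
        pick = cand[rng.choice(len(cand), size=n, replace=False)]
        if disp is not None:
            pick = np.round(_to_sample_space(pick, disp)).astype(int)
            pick = np.clip(pick, r_int, np.array(shape) - r_int - 1)
        _paint(cell_mask, pick, offsets)
        all_centers.append(pick)

    # processes: 1-voxel-radius random-walk tubes anchored to a cell subset
    process_mask = np.zeros(shape, dtype=bool)
    tube_offsets = _ball_offsets(1.0)
    if all_centers and spec.process_fraction > 0:
        centers = np.concatenate(all_centers)
        n_proc = int(round(spec.process_fraction * len(centers)))
        anchors = centers[rng.choice(len(centers), size=n_proc, replace=False)]
        for a in anchors:
            pos = a.astype(np.float64)
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            for _ in range(25):
                direction += 0.4 * rng.normal(size=3)
                direction /= np.linalg.norm(direction)
                pos = pos + direction
                vox = np.clip(np.round(pos).astype(int), 0, np.array(shape) - 1)
                if not brain[tuple(vox)]:
                    break
                _paint(process_mask, vox[None], tube_offsets)
    process_mask &= ~cell_mask

    # per-region cell-voxel counts, attributed through the deformed labels
    voxel_regions = np.bincount(
        sample_labels[cell_mask], minlength=int(atlas.labels.max()) + 1
    )
    region_cell_voxels = {
        rid: int(voxel_regions[rid]) for rid in sorted(cells) if rid < len(voxel_regions)
    }

    # the tissue (red) channel carries the anatomy the registration locks
    # onto; its structural contrast sits well above the noise floor, as in
    # real autofluorescence imaging where anatomy is plainly visible
    tnorm = atlas.template / max(1e-9, float(atlas.template.max()))
    if disp is not None:
        tnorm = _warp(tnorm, disp, order=1)
    red = spec.autofluorescence_level * (0.5 * brain + 4.0 * tnorm)
    red += spec.stroke_intensity * stroke_mask
    green = spec.autofluorescence_level * brain.astype(np.float64)
    green += spec.cell_intensity * cell_mask
    green += spec.process_intensity * process_mask
    green += 0.7 * spec.stroke_intensity * stroke_mask

    noisy = np.stack([red, green], axis=-1)
    noisy = noisy + rng.normal(0.0, spec.noise_sigma, size=noisy.shape)
    img = np.clip(np.round(noisy), 0, 65535).astype(np.uint16)

    stack = VolumeStack.from_array(
        img,
        pixel_size_um=spec.voxel_size_um,
        axial_spacing_um=spec.voxel_size_um,
        provenance="mip",
        channels=("red", "green"),
    )
    truth = GroundTruth(
        cell_mask=cell_mask,
        process_mask=process_mask,
        stroke_mask=stroke_mask,
        brain_mask=brain,
        region_cell_counts=region_counts,
        region_cell_voxels=region_cell_voxels,
        deformation_field=disp,
        seed=spec.seed,
    )
    return stack, truth


# ---------------------------------------------------------------------------
# Annotations
# ---------------------------------------------------------------------------


def _stratified_pick(
    mask: np.ndarray, n: int, rng: np.random.Generator, label: str
) -> list[tuple[int, int, int]]:
    """Sample n voxels from a mask, spread over >= 3 sections when possible."""
    total = int(mask.sum())
    if total < n:
        raise ValueError(
            f"label {label!r} has only {total} available voxels, {n} requested"
        )
    sections = np.unique(np.argwhere(mask)[:, 0])
    order = rng.permutation(sections)
    picks: list[tuple[int, int, int]] = []
    per_section = {int(s): np.argwhere(mask[s]) for s in order}
    used: dict[int, int] = {int(s): 0 for s in order}
    i = 0
    while len(picks) < n:
        s = int(order[i % len(order)])
        avail = per_section[s]
        if used[s] < len(avail):
            idx = rng.integers(0, len(avail))
            # swap-remove to avoid duplicates within a section
            avail[[used[s], (used[s] + idx) % len(avail)]] = avail[
                [(used[s] + idx) % len(avail), used[s]]
            ]
            r, c = avail[used[s]]
            picks.append((s, int(r), int(c)))
            used[s] += 1
        i += 1
    return picks


def generate_annotations(
    truth: GroundTruth,
    stack: VolumeStack,
    n_pixels_per_label: int = 2000,
    seed: int = 0,
) -> AnnotationSet:
    """Seeded sparse annotations drawn from the ground-truth masks.

    Emulates a human annotating a handful of representative sections:
    ``cell_bodies`` from the cell mask, ``processes`` and ``stroke`` from
    theirs when present, ``autofluorescence`` from in-brain tissue outside
    all object masks, and ``background`` from outside the brain; each label's
    picks are spread over at least three sections when the mask allows.
    """
    if n_pixels_per_label < 1:
        raise ValueError("n_pixels_per_label must be positive")
    rng = np.random.default_rng(seed)
    occupied = truth.cell_mask | truth.process_mask | truth.stroke_mask
    tissue = truth.brain_mask & ~occupied
    sources: dict[str, np.ndarray] = {
        "background": ~truth.brain_mask,
        "autofluorescence": tissue,
        "cell_bodies": truth.cell_mask,
    }
    if truth.process_mask.any():
        sources["processes"] = truth.process_mask
    if truth.stroke_mask.any():
        sources["stroke"] = truth.stroke_mask
    entries: list[tuple[int, int, int, str]] = []
    for label, mask in sources.items():
        if label == "autofluorescence" and occupied.any():
            # Emulate iterative retraining toward minimal visible
            # misclassification: an annotator brushes carefully around the
            # objects, so half the tissue picks are hard negatives from the
            # 2-voxel rim surrounding objects.
            rim = (
                ndimage.binary_dilation(occupied, _ball_mask(2)) & tissue
            )
            n_rim = min(int(rim.sum()), n_pixels_per_label // 2)
            far = tissue & ~rim
            for s, r, c in _stratified_pick(rim, n_rim, rng, label):
                entries.append((s, r, c, label))
            for s, r, c in _stratified_pick(
                far, n_pixels_per_label - n_rim, rng, label
            ):
                entries.append((s, r, c, label))
            continue
        for s, r, c in _stratified_pick(mask, n_pixels_per_label, rng, label):
            entries.append((s, r, c, label))
    return AnnotationSet(entries, tuple(sources))
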