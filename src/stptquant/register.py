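"""Volumetric registration of a sample stack into a labeled reference atlas.

The sample's red (tissue autofluorescence) channel is aligned to the atlas
template with a three-stage chain — rigid, then affine initialized from the
rigid result, then b-spline initialized from the affine result — each stage
maximizing Mattes mutual information over a multi-resolution pyramid with
random coordinate sampling.  The fixed image is the atlas template and the
moving image is the sample, so the one fitted chain both registers the
dataset into atlas space and pulls sample-space probability maps onto the
atlas grid (linear interpolation for probabilities, nearest for masks).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import SimpleITK as sitk

from .classify import ProbabilityMap, export_probability_map
from .volio import VolumeStack

logger = logging.getLogger("stptquant")

__all__ = [
    "Region",
    "AtlasBundle",
    "RegistrationSettings",
    "TransformChain",
    "register_to_atlas",
    "warp_volume",
    "displacement_field_voxels",
    "save_atlas",
    "load_atlas",
]


# ---------------------------------------------------------------------------
# Atlas bundle
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Region:
    """One node of the region ontology; ``parent_id`` is None at the root."""

    id: int
    acronym: str
    name: str
    parent_id: int | None


@dataclass
class AtlasBundle:
    """Reference template + integer label volume + region ontology.

    ``template`` and ``labels`` share one ``(section, row, col)`` grid with
    ``spacing_um`` micron spacing per axis.  Label ID 0 means outside-brain
    background and does not appear in the ontology, whose parent links must
    form a single rooted tree.  ``midline`` is the left-right voxel
    coordinate of the sagittal midplane.
    """

    template: np.ndarray
    labels: np.ndarray
    ontology: list[Region]
    midline: float
    spacing_um: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.template = np.asarray(self.template)
        self.labels = np.asarray(self.labels)
        self.spacing_um = tuple(float(s) for s in self.spacing_um)
        if self.template.shape != self.labels.shape:
            raise ValueError("template and labels must share one grid")
        if any(s <= 0 for s in self.spacing_um):
            raise ValueError("spacings must be positive")
        ids = {r.id for r in self.ontology}
        if 0 in ids:
            raise ValueError("label 0 is reserved for outside-brain background")
        present = set(np.unique(self.labels)) - {0}
        missing = present - ids
        if missing:
            raise ValueError(f"label IDs missing from ontology: {sorted(missing)}")
        roots = [r for r in self.ontology if r.parent_id is None]
        if len(roots) != 1:
            raise ValueError("ontology must have exactly one root")
        for r in self.ontology:
            if r.parent_id is not None and r.parent_id not in ids:
                raise ValueError(f"region {r.id} has unknown parent {r.parent_id}")

    @property
    def root(self) -> Region:
        return next(r for r in self.ontology if r.parent_id is None)

    @property
    def voxel_volume_mm3(self) -> float:
        s, r, c = self.spacing_um
        return s * r * c * 1e-9

    def children_map(self) -> dict[int | None, list[int]]:
        ch: dict[int | None, list[int]] = {}
        for r in self.ontology:
            ch.setdefault(r.parent_id, []).append(r.id)
        return ch

    def leaves(self) -> list[Region]:
        parents = {r.parent_id for r in self.ontology}
        return [r for r in self.ontology if r.id not in parents]

    def by_acronym(self, acronym: str) -> Region:
        for r in self.ontology:
            if r.acronym == acronym:
                return r
        raise KeyError(f"unknown region acronym {acronym!r}")


def save_atlas(atlas: AtlasBundle, directory: str | Path, stem: str = "atlas"):
    """Write template/labels as NIfTI and the ontology as a JSON array
    of ``{id, acronym, name, parent_id}`` (the structure-graph shape used by
    public mouse-brain atlases, so a real atlas can be dropped in)."""
    import nibabel as nib

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    # NIfTI axis order is (x, y, z) = (col, row, section)
    spacing_mm = [s / 1000.0 for s in atlas.spacing_um]
    affine = np.diag(spacing_mm[::-1] + [1.0])
    nib.save(
        nib.Nifti1Image(np.asarray(atlas.template, np.float32).T, affine),
        directory / f"{stem}_template.nii",
    )
    nib.save(
        nib.Nifti1Image(np.asarray(atlas.labels, np.int32).T, affine),
        directory / f"{stem}_labels.nii",
    )
    meta = {
        "midline": atlas.midline,
        "spacing_um": list(atlas.spacing_um),
        "ontology": [
            {"id": r.id, "acronym": r.acronym, "name": r.name, "parent_id": r.parent_id}
            for r in atlas.ontology
        ],
    }
    (directory / f"{stem}_ontology.json").write_text(json.dumps(meta, indent=1))
    return directory


def load_atlas(directory: str | Path, stem: str = "atlas") -> AtlasBundle:
    import nibabel as nib

    directory = Path(directory)
    meta = json.loads((directory / f"{stem}_ontology.json").read_text())
    template = np.asarray(
        nib.load(directory / f"{stem}_template.nii").get_fdata()
    ).T.astype(np.float32)
    labels = np.asarray(
        nib.load(directory / f"{stem}_labels.nii").get_fdata()
    ).T.astype(np.int32)
    ontology = [
        Region(d["id"], d["acronym"], d["name"], d["parent_id"])
        for d in meta["ontology"]
    ]
    return AtlasBundle(
        template, labels, ontology, float(meta["midline"]), tuple(meta["spacing_um"])
    )


# ---------------------------------------------------------------------------
# Registration settings and transform chain
# ---------------------------------------------------------------------------


@dataclass
class RegistrationSettings:
    """Tunables of the three-stage registration.

    Defaults target full-size brains: a 6-level pyramid, 32 mutual-information
    histogram bins, 2,048 random coordinates per iteration drawn from
    2 x 2 x 4 mm subregions, and a 0.5 mm b-spline control grid.  On small
    volumes the pyramid auto-shrinks so no level falls below 8 voxels and the
    b-spline grid spacing is capped at a quarter of the volume extent.
    """

    levels: int = 6
    histogram_bins: int = 32
    sampling_points: int = 2048
    sample_region_mm: tuple[float, float, float] = (2.0, 2.0, 4.0)
    bspline_grid_spacing_mm: float = 0.5
    iterations_rigid: int = 200
    iterations_affine: int = 200
    iterations_bspline: int = 80
    stages: tuple[str, ...] = ("rigid", "affine", "bspline")
    seed: int = 0
    exclusion_mask: np.ndarray | None = None  # optional lesion mask, default off


@dataclass
class TransformChain:
    """Ordered rigid -> affine -> b-spline stages mapping atlas (fixed) space
    to sample (moving) space, in the resampling convention, plus the metric
    trace recorded per stage."""

    stages: list[tuple[str, sitk.Transform]]
    traces: dict[str, list[float]] = field(default_factory=dict)
    fixed_size: tuple[int, int, int] | None = None  # ITK (x, y, z)
    fixed_spacing_mm: tuple[float, float, float] | None = None
    moving_size: tuple[int, int, int] | None = None
    moving_spacing_mm: tuple[float, float, float] | None = None

    def as_composite(self) -> sitk.Transform:
        """Total fixed->moving resampling transform.

        The affine stage is initialized from the rigid result and optimized
        as the full linear map, so it subsumes the rigid stage; the b-spline
        refinement composes with that last linear stage (CompositeTransform
        applies the last-added transform first, so the b-spline acts before
        the affine, matching how it was fitted with a moving-initial
        transform).
        """
        linear = [t for name, t in self.stages if name in ("rigid", "affine")]
        bspline = [t for name, t in self.stages if name == "bspline"]
        parts: list[sitk.Transform] = []
        if linear:
            parts.append(linear[-1])
        parts.extend(bspline)
        if not parts:
            return sitk.Transform(3, sitk.sitkIdentity)
        if len(parts) == 1:
            return parts[0]
        return sitk.CompositeTransform(parts)

    def save(self, path: str | Path) -> Path:
        """Plain-text parameter file readable without the package."""
        lines = ["stptquant-transform-chain v1"]
        for key in ("fixed_size", "fixed_spacing_mm", "moving_size", "moving_spacing_mm"):
            val = getattr(self, key)
            if val is not None:
                lines.append(f"{key}: " + " ".join(repr(v) for v in val))
        for name, t in self.stages:
            lines.append(f"stage: {name} {t.GetName()}")
            lines.append("fixed_params: " + " ".join(repr(v) for v in t.GetFixedParameters()))
            lines.append("params: " + " ".join(repr(v) for v in t.GetParameters()))
        path = Path(path)
        path.write_text("\n".join(lines) + "\n")
        return path

    @staticmethod
    def load(path: str | Path) -> "TransformChain":
        lines = Path(path).read_text().splitlines()
        if not lines or not lines[0].startswith("stptquant-transform-chain"):
            raise ValueError(f"{path} is not a transform-chain file")
        chain = TransformChain(stages=[])
        current: sitk.Transform | None = None
        for line in lines[1:]:
            if not line.strip():
                continue
            key, _, rest = line.partition(":")
            key, rest = key.strip(), rest.strip()
            if key in ("fixed_size", "moving_size"):
                setattr(chain, key, tuple(int(float(v)) for v in rest.split()))
            elif key in ("fixed_spacing_mm", "moving_spacing_mm"):
                setattr(chain, key, tuple(float(v) for v in rest.split()))
            elif key == "stage":
                name, cls_name = rest.split()
                factory = {
                    "Euler3DTransform": lambda: sitk.Euler3DTransform(),
                    "AffineTransform": lambda: sitk.AffineTransform(3),
                    "BSplineTransform": lambda: sitk.BSplineTransform(3),
                    "TranslationTransform": lambda: sitk.TranslationTransform(3),
                }[cls_name]
                current = factory()
                chain.stages.append((name, current))
            elif key == "fixed_params":
                assert current is not None
                current.SetFixedParameters([float(v) for v in rest.split()])
            elif key == "params":
                assert current is not None
                current.SetParameters([float(v) for v in rest.split()])
        return chain


# ---------------------------------------------------------------------------
# SimpleITK conversion helpers
# ---------------------------------------------------------------------------


def volume_to_sitk(
    arr: np.ndarray, spacing_um: Sequence[float], dtype=np.float32
) -> sitk.Image:
    """(section, row, col) array -> SimpleITK image with mm spacing.

    ITK size order is (x, y, z) = (col, row, section); physical units are mm.
    """
    img = sitk.GetImageFromArray(np.ascontiguousarray(arr.astype(dtype)))
    s, r, c = (float(v) / 1000.0 for v in spacing_um)
    img.SetSpacing((c, r, s))
    return img


def atlas_to_sitk(atlas: AtlasBundle) -> sitk.Image:
    return volume_to_sitk(atlas.template, atlas.spacing_um)


def stack_to_sitk(stack: VolumeStack, channel: str | int = "red") -> sitk.Image:
    arr = stack.channel(channel) if stack.n_channels > 1 else stack.as_array()
    if arr.ndim == 4:
        arr = arr[..., 0]
    return volume_to_sitk(
        arr, (stack.axial_spacing_um, stack.pixel_size_um, stack.pixel_size_um)
    )


def _effective_levels(requested: int, *images: sitk.Image) -> int:
    """Shrink the pyramid so the coarsest level keeps every dimension >= 8."""
    min_dim = min(min(img.GetSize()) for img in images)
    max_levels = 1
    while min_dim // (2**max_levels) >= 8:
        max_levels += 1
    return max(1, min(requested, max_levels))


def _sample_region_mask(
    fixed: sitk.Image, settings: RegistrationSettings, rng: np.random.Generator
) -> sitk.Image | None:
    """Random-coordinate sampling restricted to subregions of the stated
    physical size: realized as a union of randomly placed boxes used as the
    metric's fixed-image mask.  Volumes no larger than one region are
    unrestricted."""
    size = np.array(fixed.GetSize())  # (x, y, z)
    spacing = np.array(fixed.GetSpacing())
    extent = size * spacing
    region = np.array(settings.sample_region_mm)[::-1]  # (x, y, z) from (s, r, c)
    if np.all(region >= extent):
        return None
    box_vox = np.maximum(1, np.minimum(size, np.round(region / spacing))).astype(int)
    n_boxes = max(4, int(np.ceil(2 * np.prod(extent) / np.prod(region))))
    mask = np.zeros(tuple(size[::-1]), dtype=np.uint8)  # (z, y, x)
    for _ in range(n_boxes):
        lo = [rng.integers(0, s - b + 1) if s > b else 0 for s, b in zip(size, box_vox)]
        mask[
            lo[2] : lo[2] + box_vox[2],
            lo[1] : lo[1] + box_vox[1],
            lo[0] : lo[0] + box_vox[0],
        ] = 1
    m = sitk.GetImageFromArray(mask)
    m.CopyInformation(fixed)
    return m


def _make_method(
    fixed: sitk.Image,
    settings: RegistrationSettings,
    iterations: int,
    levels: int,
    seed: int,
    mask: sitk.Image | None,
    learning_rate: float = 0.05,
    sampling_points: int | None = None,
    sigma_boost: float = 0.0,
) -> tuple[sitk.ImageRegistrationMethod, list[float]]:
    reg = sitk.ImageRegistrationMethod()
    reg.SetMetricAsMattesMutualInformation(settings.histogram_bins)
    reg.SetMetricSamplingStrategy(reg.RANDOM)
    # the configured number of random coordinates at every pyramid level
    n_pts = sampling_points or settings.sampling_points
    n_vox = int(np.prod(fixed.GetSize()))
    shrink = [2**l for l in reversed(range(levels))]
    fracs = [
        float(min(1.0, n_pts / max(1, n_vox / f**3)))
        for f in shrink
    ]
    reg.SetMetricSamplingPercentagePerLevel(fracs, seed)
    if mask is not None:
        reg.SetMetricFixedMask(mask)
    if settings.exclusion_mask is not None:
        excl = sitk.GetImageFromArray(
            (settings.exclusion_mask == 0).astype(np.uint8)
        )
        excl.CopyInformation(fixed)
        reg.SetMetricFixedMask(excl)
    reg.SetInterpolator(sitk.sitkLinear)
    # with parameter scales normalized to physical shift, the learning rate
    # is an initial step in mm; the regular-step schedule halves it on
    # oscillation, which keeps the noisy sampled metric from diverging
    reg.SetOptimizerAsRegularStepGradientDescent(
        learningRate=learning_rate,
        minStep=1e-5,
        numberOfIterations=iterations,
        relaxationFactor=0.6,
    )
    reg.SetOptimizerScalesFromPhysicalShift()
    reg.SetShrinkFactorsPerLevel(shrink)
    reg.SetSmoothingSigmasPerLevel([f / 2.0 + sigma_boost for f in shrink])
    reg.SmoothingSigmasAreSpecifiedInPhysicalUnitsOff()
    trace: list[float] = []
    reg.AddCommand(sitk.sitkIterationEvent, lambda: trace.append(reg.GetMetricValue()))
    return reg, trace


def register_to_atlas(
    sample: VolumeStack | sitk.Image,
    atlas: AtlasBundle,
    settings: RegistrationSettings | None = None,
) -> TransformChain:
    """Fit the rigid -> affine -> b-spline chain mapping atlas space to
    sample space.

    The atlas template is the fixed image; the sample red channel (or the
    sole channel) is the moving image.  Stages are fitted sequentially, each
    initialized from the previous result and optimized over a multi-
    resolution pyramid (auto-shrunk for small volumes) by maximizing Mattes
    mutual information estimated from randomly sampled coordinates.
    """
    settings = settings or RegistrationSettings()
    fixed = atlas_to_sitk(atlas)
    if isinstance(sample, VolumeStack):
        if len(sample.sections) < 2:
            raise ValueError("registration needs a volume, not a single section")
        moving = stack_to_sitk(sample)
    else:
        moving = sitk.Cast(sample, sitk.sitkFloat32)
        if moving.GetSize()[2] < 2:
            raise ValueError("registration needs a volume, not a single section")
    rng = np.random.default_rng(settings.seed)
    levels = _effective_levels(settings.levels, fixed, moving)
    if levels < settings.levels:
        logger.info("pyramid reduced to %d levels for small volume", levels)
    mask = _sample_region_mask(fixed, settings, rng)

    chain = TransformChain(
        stages=[],
        fixed_size=tuple(fixed.GetSize()),
        fixed_spacing_mm=tuple(fixed.GetSpacing()),
        moving_size=tuple(moving.GetSize()),
        moving_spacing_mm=tuple(moving.GetSpacing()),
    )

    current: sitk.Transform | None = None
    for stage in settings.stages:
        seed_offset = {"rigid": 1, "affine": 2, "bspline": 3}[stage]
        stage_seed = (settings.seed * 7919 + seed_offset) % (2**31 - 1) or 1
        if stage == "rigid":
            init = sitk.CenteredTransformInitializer(
                fixed,
                moving,
                sitk.Euler3DTransform(),
                sitk.CenteredTransformInitializerFilter.GEOMETRY,
            )
            reg, trace = _make_method(
                fixed, settings, settings.iterations_rigid, levels, stage_seed, mask
            )
            reg.SetInitialTransform(sitk.Euler3DTransform(init), inPlace=True)
            current = reg.Execute(fixed, moving)
            current = sitk.Euler3DTransform(current)
        elif stage == "affine":
            aff = sitk.AffineTransform(3)
            if current is not None:
                e = sitk.Euler3DTransform(current)
                aff.SetMatrix(e.GetMatrix())
                aff.SetTranslation(e.GetTranslation())
                aff.SetCenter(e.GetCenter())
            reg, trace = _make_method(
                fixed, settings, settings.iterations_affine, levels, stage_seed, mask
            )
            reg.SetInitialTransform(aff, inPlace=True)
            current = reg.Execute(fixed, moving)
            current = sitk.AffineTransform(current)
        elif stage == "bspline":
            size = np.array(fixed.GetSize())
            spacing = np.array(fixed.GetSpacing())
            extent = size * spacing
            grid_mm = np.minimum(settings.bspline_grid_spacing_mm, extent / 4.0)
            mesh = [max(1, int(round(e / g))) for e, g in zip(extent, grid_mm)]
            bsp = sitk.BSplineTransformInitializer(fixed, mesh)
            # the nonrigid refinement starts from a near-aligned state, so it
            # runs on the two finest pyramid levels only, with small steps, a
            # denser coordinate sample and extra smoothing: sampled mutual
            # information on noisy intensities otherwise rewards half-voxel
            # offsets (linear interpolation averages noise), which a flexible
            # transform would chase
            reg, trace = _make_method(
                fixed,
                settings,
                settings.iterations_bspline,
                min(2, levels),
                stage_seed,
                mask,
                learning_rate=0.01,
                sampling_points=4 * settings.sampling_points,
                sigma_boost=0.5,
            )
            if current is not None:
                reg.SetMovingInitialTransform(current)
            reg.SetInitialTransform(bsp, inPlace=True)
            out = reg.Execute(fixed, moving)
            current = None  # stages now compose through the chain
            chain.traces[stage] = trace
            chain.stages.append((stage, sitk.BSplineTransform(out)))
            continue
        else:
            raise ValueError(f"unknown registration stage {stage!r}")
        chain.traces[stage] = trace
        chain.stages.append((stage, current))

    # warn on apparently failed overlap
    if chain.traces:
        last_stage = settings.stages[-1]
        tr = chain.traces.get(last_stage, [])
        if tr and tr[-1] > -1e-3:
            logger.warning(
                "final mutual information near zero; images may not overlap"
            )
    return chain


def _composition_transform(chain: TransformChain) -> sitk.Transform:
    return chain.as_composite()


def warp_volume(
    chain: TransformChain,
    volume: VolumeStack | ProbabilityMap | np.ndarray,
    atlas: AtlasBundle,
    interpolation: str | None = None,
):
    """Resample a sample-space volume onto the atlas grid through the chain.

    Interpolation defaults to linear for probability maps and intensity
    volumes and must be ``"nearest"`` for integer label masks; out-of-field
    voxels are 0.  Returns the same kind of object it was given.
    """
    fixed = atlas_to_sitk(atlas)
    if isinstance(volume, ProbabilityMap):
        arr = volume.probabilities
        spacing = (volume.axial_spacing_um, volume.pixel_size_um, volume.pixel_size_um)
        interp = interpolation or "linear"
    elif isinstance(volume, VolumeStack):
        arr = volume.as_array()
        if arr.ndim == 4:
            raise ValueError("warp one channel at a time")
        spacing = (volume.axial_spacing_um, volume.pixel_size_um, volume.pixel_size_um)
        interp = interpolation or "linear"
    else:
        arr = np.asarray(volume)
        spacing = atlas.spacing_um
        interp = interpolation or (
            "nearest" if np.issubdtype(arr.dtype, np.integer) else "linear"
        )
    if chain.moving_size is not None:
        expected = tuple(int(v) for v in chain.moving_size)
        if tuple(arr.shape[::-1]) != expected:
            raise ValueError(
                f"volume grid {arr.shape[::-1]} does not match the grid the "
                f"chain was fitted on {expected}"
            )
        got_sp = tuple(round(s / 1000.0, 9) for s in spacing[::-1])
        want_sp = tuple(round(s, 9) for s in chain.moving_spacing_mm)
        if got_sp != want_sp:
            raise ValueError("volume spacing does not match the fitted chain")
    dtype = np.float64 if interp == "linear" else arr.dtype
    moving = volume_to_sitk(
        arr, spacing, np.float32 if interp == "linear" else np.int32
    )
    interpolator = {"linear": sitk.sitkLinear, "nearest": sitk.sitkNearestNeighbor}[
        interp
    ]
    res = sitk.Resample(
        moving, fixed, _composition_transform(chain), interpolator, 0.0
    )
    out = sitk.GetArrayFromImage(res).astype(dtype)
    if isinstance(volume, ProbabilityMap):
        return export_probability_map(
            np.clip(out, 0.0, 1.0),
            volume.label_name,
            atlas.spacing_um[1],
            atlas.spacing_um[0],
        )
    if isinstance(volume, VolumeStack):
        return VolumeStack.from_array(
            out.astype(arr.dtype) if interp == "nearest" else out,
            atlas.spacing_um[1],
            atlas.spacing_um[0],
            volume.provenance,
        )
    return out.astype(arr.dtype) if interp == "nearest" else out


def displacement_field_voxels(
    chain: TransformChain, atlas: AtlasBundle
) -> np.ndarray:
    """Displacement of every atlas voxel center under the chain, in voxel
    units per (section, row, col) axis — the test-friendly summary of how far
    the recovered transform moves points."""
    fixed = atlas_to_sitk(atlas)
    f = sitk.TransformToDisplacementFieldFilter()
    f.SetReferenceImage(fixed)
    disp = sitk.GetArrayFromImage(f.Execute(_composition_transform(chain)))
    # disp is (z, y, x, 3) with components (dx, dy, dz) in mm
    spacing_mm = np.array(atlas.spacing_um)[::-1] / 1000.0  # (c, r, s)
    return disp[..., ::-1] / (spacing_mm[::-1])
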