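"""Supervised pixel classification of STPT sections.

A random forest is trained from sparse, human-style pixel annotations on a
bank of multi-scale image features (the standard interactive-segmentation
feature set: Gaussian smoothing, gradient magnitude, Laplacian of Gaussian,
Hessian eigenvalues and structure-tensor eigenvalues at several scales, plus
raw intensity).  The fitted model is applied unchanged to every stack of a
cohort and its per-label class probabilities are exported as 8-bit
probability maps: stored value 0 means probability 0, 255 means 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import joblib
import numpy as np
from scipy import ndimage
from skimage.feature import (
    hessian_matrix,
    hessian_matrix_eigvals,
    structure_tensor,
    structure_tensor_eigenvalues,
)
from sklearn.ensemble import RandomForestClassifier

from .volio import SectionImage, VolumeStack, round_half_away

__all__ = [
    "DEFAULT_SCALES",
    "AnnotationSet",
    "FeatureStack",
    "PixelClassifier",
    "ProbabilityMap",
    "compute_features",
    "compute_features_stack",
    "train_classifier",
    "predict_probabilities",
    "predict_stack",
    "export_probability_map",
    "write_probability_map",
    "read_probability_map",
]

#: default feature scales (sigma, px); configurable per call
DEFAULT_SCALES: tuple[float, ...] = (1.0, 2.5, 5.0)

#: truncation radius of Gaussian kernels, in sigmas
_TRUNCATE = 4.0


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class AnnotationSet:
    """Sparse pixel labels: rows of (section, row, col, label_name)."""

    entries: list[tuple[int, int, int, str]]
    label_names: tuple[str, ...]

    def __post_init__(self) -> None:
        self.entries = [(int(s), int(r), int(c), str(l)) for s, r, c, l in self.entries]
        self.label_names = tuple(self.label_names)
        known = set(self.label_names)
        for s, r, c, l in self.entries:
            if l not in known:
                raise ValueError(f"annotation label {l!r} not in label_names")

    def used_labels(self) -> tuple[str, ...]:
        present = {l for _, _, _, l in self.entries}
        return tuple(l for l in self.label_names if l in present)

    def extended(self, more: Sequence[tuple[int, int, int, str]]) -> "AnnotationSet":
        """New set with additional entries — supports iterative retraining."""
        return AnnotationSet(self.entries + [tuple(e) for e in more], self.label_names)

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        lines = ["section,row,col,label"]
        lines += [f"{s},{r},{c},{l}" for s, r, c, l in self.entries]
        path.write_text("\n".join(lines) + "\n")
        return path

    @classmethod
    def from_csv(cls, path: str | Path, label_names: Sequence[str] | None = None):
        rows = Path(path).read_text().strip().splitlines()
        entries = []
        for line in rows[1:]:
            s, r, c, l = line.split(",")
            entries.append((int(s), int(r), int(c), l))
        if label_names is None:
            seen: list[str] = []
            for *_, l in entries:
                if l not in seen:
                    seen.append(l)
            label_names = seen
        return cls(entries, tuple(label_names))


@dataclass
class FeatureStack:
    """Per-pixel feature vectors: ``features`` is (..., n_features)."""

    features: np.ndarray
    feature_names: tuple[str, ...]

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features)
        self.feature_names = tuple(self.feature_names)
        if len(self.feature_names) != len(set(self.feature_names)):
            raise ValueError("feature names must be unique")
        if self.features.shape[-1] != len(self.feature_names):
            raise ValueError("feature count does not match feature_names")
        if not np.all(np.isfinite(self.features)):
            raise ValueError("features must be finite")


@dataclass
class PixelClassifier:
    """A trained random-forest pixel model bound to its feature bank.

    ``cohort_id`` enforces one-model-per-cohort binding: a pipeline applies a
    classifier only to stacks of the cohort it was trained for.
    """

    model: RandomForestClassifier
    label_names: tuple[str, ...]
    feature_names: tuple[str, ...]
    n_trees: int
    seed: int
    training_accuracy: float
    cohort_id: str | None = None

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        joblib.dump(self, path)
        return path

    @staticmethod
    def load(path: str | Path) -> "PixelClassifier":
        clf = joblib.load(path)
        if not isinstance(clf, PixelClassifier):
            raise TypeError(f"{path} does not contain a PixelClassifier")
        return clf


@dataclass
class ProbabilityMap:
    """8-bit per-label probability volume: stored value v encodes p = v/255."""

    values: np.ndarray
    label_name: str
    pixel_size_um: float
    axial_spacing_um: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.dtype != np.uint8:
            raise ValueError("probability maps are stored as uint8")
        if self.pixel_size_um <= 0 or self.axial_spacing_um <= 0:
            raise ValueError("spacings must be positive")

    @property
    def probabilities(self) -> np.ndarray:
        return self.values.astype(np.float64) / 255.0

    @property
    def voxel_volume_mm3(self) -> float:
        return (self.pixel_size_um**2 * self.axial_spacing_um) * 1e-9


# ---------------------------------------------------------------------------
# Feature extraction
# ---------------------------------------------------------------------------


def _channel_features(img: np.ndarray, scales: Sequence[float], prefix: str):
    """Feature images for one 2-D channel: raw + 7 responses per scale."""
    img = img.astype(np.float64)
    feats = [img]
    names = [f"{prefix}raw"]
    for s in scales:
        smooth = ndimage.gaussian_filter(img, s, truncate=_TRUNCATE)
        grad = ndimage.gaussian_gradient_magnitude(img, s, truncate=_TRUNCATE)
        log = ndimage.gaussian_laplace(img, s, truncate=_TRUNCATE)
        helems = hessian_matrix(img, sigma=s, use_gaussian_derivatives=True)
        h1, h2 = hessian_matrix_eigvals(helems)
        telems = structure_tensor(img, sigma=s, order="rc")
        t1, t2 = structure_tensor_eigenvalues(telems)
        feats += [smooth, grad, log, h1, h2, t1, t2]
        names += [
            f"{prefix}{op}_s{s:g}"
            for op in ("gauss", "gradmag", "log", "hess_e1", "hess_e2", "st_e1", "st_e2")
        ]
    return feats, names


def compute_features(
    image: SectionImage | np.ndarray, scales: Sequence[float] = DEFAULT_SCALES
) -> FeatureStack:
    """Multi-scale feature bank for one section.

    For each scale sigma the bank holds Gaussian smoothing, Gaussian gradient
    magnitude, Laplacian of Gaussian, both Hessian eigenvalues and both
    structure-tensor eigenvalues, plus the raw intensity: with 3 scales that
    is 22 features per pixel per channel.
    """
    if len(scales) == 0:
        raise ValueError("at least one feature scale is required")
    if any(s <= 0 for s in scales):
        raise ValueError("feature scales must be positive")
    px = image.pixels if isinstance(image, SectionImage) else np.asarray(image)
    if px.ndim == 2:
        px = px[..., None]
    feats: list[np.ndarray] = []
    names: list[str] = []
    for ch in range(px.shape[2]):
        prefix = f"c{ch}_" if px.shape[2] > 1 else ""
        f, n = _channel_features(px[..., ch], scales, prefix)
        feats += f
        names += n
    return FeatureStack(np.stack(feats, axis=-1), tuple(names))


def compute_features_stack(
    stack: VolumeStack, scales: Sequence[float] = DEFAULT_SCALES
) -> FeatureStack:
    """Per-section features for a whole stack: (S, H, W, n_features).

    Features are 2-D, computed section by section, mirroring interactive
    per-slice training on coronal images.
    """
    per_section = [compute_features(s, scales) for s in stack.sections]
    return FeatureStack(
        np.stack([f.features for f in per_section]), per_section[0].feature_names
    )


# ---------------------------------------------------------------------------
# Training and prediction
# ---------------------------------------------------------------------------


def train_classifier(
    features: FeatureStack,
    annotations: AnnotationSet,
    n_trees: int = 100,
    seed: int = 0,
    cohort_id: str | None = None,
) -> PixelClassifier:
    """Fit a random forest on annotated pixels.

    The forest uses bootstrap resampling, sqrt(d) feature subsampling and
    unbounded depth; ``seed`` makes training fully deterministic.  Training
    accuracy on the annotated pixels is recorded on the returned model.
    """
    if features.features.ndim != 4:
        raise ValueError("train_classifier expects stack features (S, H, W, F)")
    shape = features.features.shape[:3]
    used = annotations.used_labels()
    if len(used) < 2:
        raise ValueError("training requires annotations for at least 2 labels")
    coords = np.array([(s, r, c) for s, r, c, _ in annotations.entries])
    if (coords < 0).any() or (coords >= np.array(shape)).any():
        raise ValueError("annotation coordinate outside the image bounds")
    X = features.features[coords[:, 0], coords[:, 1], coords[:, 2]]
    y = np.array([l for *_, l in annotations.entries])
    model = RandomForestClassifier(
        n_estimators=n_trees,
        max_features="sqrt",
        bootstrap=True,
        random_state=seed,
        n_jobs=1,
    )
    model.fit(X, y)
    acc = float((model.predict(X) == y).mean())
    return PixelClassifier(
        model=model,
        label_names=used,
        feature_names=features.feature_names,
        n_trees=n_trees,
        seed=seed,
        training_accuracy=acc,
        cohort_id=cohort_id,
    )


def predict_probabilities(
    classifier: PixelClassifier, features: FeatureStack
) -> dict[str, np.ndarray]:
    """Per-label probability volumes in [0, 1], summing to 1 at every pixel."""
    if features.feature_names != classifier.feature_names:
        raise ValueError("feature bank does not match the classifier's")
    arr = features.features
    flat = arr.reshape(-1, arr.shape[-1])
    proba = classifier.model.predict_proba(flat)
    classes = list(classifier.model.classes_)
    out: dict[str, np.ndarray] = {}
    for label in classifier.label_names:
        out[label] = proba[:, classes.index(label)].reshape(arr.shape[:-1])
    return out


def predict_stack(
    classifier: PixelClassifier,
    stack: VolumeStack,
    scales: Sequence[float] = DEFAULT_SCALES,
) -> dict[str, ProbabilityMap]:
    """Classify a whole stack and export one 8-bit map per trained label."""
    features = compute_features_stack(stack, scales)
    probs = predict_probabilities(classifier, features)
    return {
        label: export_probability_map(
            p, label, stack.pixel_size_um, stack.axial_spacing_um
        )
        for label, p in probs.items()
    }


def export_probability_map(
    prob: np.ndarray,
    label_name: str,
    pixel_size_um: float,
    axial_spacing_um: float,
) -> ProbabilityMap:
    """Quantize real probabilities to the 8-bit storage convention.

    Stored value = round(p * 255) with halves away from zero, so p = 0 maps to
    0, p = 1 to 255 and p = 0.5 to 128; quantization error is at most 0.5/255.
    """
    prob = np.asarray(prob, dtype=np.float64)
    if prob.size and (prob.min() < 0 or prob.max() > 1):
        raise ValueError("probabilities must lie in [0, 1]")
    values = round_half_away(prob * 255.0).astype(np.uint8)
    return ProbabilityMap(values, label_name, pixel_size_um, axial_spacing_um)


# ---------------------------------------------------------------------------
# Probability-map I/O (8-bit multi-page TIFF per label)
# ---------------------------------------------------------------------------


def write_probability_map(pmap: ProbabilityMap, directory: str | Path, sample: str):
    """Write ``<sample>_<label>_prob.tif`` plus a metadata sidecar."""
    import tifffile

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    path = directory / f"{sample}_{pmap.label_name}_prob.tif"
    tifffile.imwrite(path, pmap.values)
    path.with_name(path.name + ".meta.txt").write_text(
        f"label: {pmap.label_name}\n"
        f"pixel_size_um: {pmap.pixel_size_um!r}\n"
        f"axial_spacing_um: {pmap.axial_spacing_um!r}\n"
    )
    return path


def read_probability_map(path: str | Path) -> ProbabilityMap:
    import tifffile

    path = Path(path)
    meta: dict[str, str] = {}
    for line in path.with_name(path.name + ".meta.txt").read_text().splitlines():
        if ":" in line:
            k, v = line.split(":", 1)
            meta[k.strip()] = v.strip()
    values = tifffile.imread(path)
    if values.ndim == 2:
        values = values[None]
    return ProbabilityMap(
        values.astype(np.uint8),
        meta["label"],
        float(meta["pixel_size_um"]),
        float(meta["axial_spacing_um"]),
    )
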