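"""End-to-end orchestration: classify -> register -> warp -> quantify.

A single declarative YAML configuration names the samples (each bound to a
cohort), the model or training annotations per cohort, the atlas bundle and
the output directory.  Every run writes a manifest recording the package
version, a config hash, all seeds and the checksum of every artifact, so
runs are auditable and re-runs with unchanged inputs skip completed stages.

Two provenance rules are enforced and logged: each cohort's classifier is
applied unchanged to every stack of that cohort, and the registration chain
fitted on the red channel is the one applied to every label's probability
map.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from . import __version__
from .classify import (
    AnnotationSet,
    PixelClassifier,
    compute_features_stack,
    predict_stack,
    read_probability_map,
    train_classifier,
    write_probability_map,
)
from .quantify import (
    DEFAULT_THRESHOLD_FRACTION,
    aggregate_hierarchy,
    quantify_regions,
)
from .register import (
    RegistrationSettings,
    TransformChain,
    load_atlas,
    register_to_atlas,
    warp_volume,
)
from .volio import read_stack

logger = logging.getLogger("stptquant")

__all__ = ["SampleSpec", "PipelineConfig", "PipelineError", "run_pipeline"]

_STAGES = ("classify", "register", "warp", "quantify")


class PipelineError(RuntimeError):
    """Raised by the CLI when one or more samples failed."""


@dataclass
class SampleSpec:
    id: str
    stack: str
    cohort: str


@dataclass
class PipelineConfig:
    samples: list[SampleSpec]
    cohorts: dict[str, dict[str, Any]]
    atlas_dir: str
    out_dir: str
    atlas_stem: str = "atlas"
    threshold_fraction: float = DEFAULT_THRESHOLD_FRACTION
    seed: int = 0
    steps: dict[str, bool] = field(
        default_factory=lambda: {s: True for s in _STAGES}
    )
    registration: dict[str, Any] = field(default_factory=dict)
    scales: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        for s in self.samples:
            if s.cohort not in self.cohorts:
                raise ValueError(f"sample {s.id!r}: cohort {s.cohort!r} has no model binding")
        for name in self.steps:
            if name not in _STAGES:
                raise ValueError(f"unknown pipeline step {name!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        samples = [SampleSpec(**s) for s in raw.get("samples", [])]
        steps = {s: True for s in _STAGES}
        steps.update(raw.get("steps", {}))
        return cls(
            samples=samples,
            cohorts=raw.get("cohorts", {}),
            atlas_dir=raw["atlas"]["dir"],
            atlas_stem=raw["atlas"].get("stem", "atlas"),
            out_dir=raw["out_dir"],
            threshold_fraction=float(
                raw.get("threshold_fraction", DEFAULT_THRESHOLD_FRACTION)
            ),
            seed=int(raw.get("seed", 0)),
            steps=steps,
            registration=raw.get("registration", {}),
            scales=tuple(raw["scales"]) if "scales" in raw else None,
        )

    def config_hash(self) -> str:
        blob = json.dumps(
            dataclasses.asdict(self), sort_keys=True, default=str
        ).encode()
        return hashlib.sha256(blob).hexdigest()


def _label_from_name(name: str, prefix: str) -> str:
    """Recover the label from ``<prefix>_<label>_prob.tif`` (labels may
    themselves contain underscores)."""
    if not (name.startswith(prefix + "_") and name.endswith("_prob.tif")):
        raise ValueError(f"unexpected probability-map filename {name!r}")
    return name[len(prefix) + 1 : -len("_prob.tif")]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _stage_record(inputs_hash: str, outputs: dict[str, Path]) -> dict[str, Any]:
    return {
        "inputs_hash": inputs_hash,
        "outputs": {str(p): _sha256(p) for p in outputs.values()},
    }


def _can_skip(prev: dict | None, inputs_hash: str) -> bool:
    if not prev or prev.get("inputs_hash") != inputs_hash:
        return False
    for p, digest in prev.get("outputs", {}).items():
        if not Path(p).exists() or _sha256(Path(p)) != digest:
            return False
    return True


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Execute the enabled stages for every sample.

    Returns the run manifest (also written to ``<out_dir>/manifest.json``).
    A stage failure aborts that sample and is recorded under ``failures``;
    other samples continue.  Re-running with unchanged inputs skips stages
    whose recorded input hashes and output checksums still match.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log_path = out_dir / "run.log"
    handler = logging.FileHandler(log_path)
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)

    manifest_path = out_dir / "manifest.json"
    previous = (
        json.loads(manifest_path.read_text()) if manifest_path.exists() else {}
    )
    manifest: dict[str, Any] = {
        "tool": "stptquant",
        "version": __version__,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "samples": {},
        "failures": [],
    }
    if previous.get("config_hash") != manifest["config_hash"]:
        previous = {}

    atlas = None
    if any(config.steps.get(s) for s in ("register", "warp", "quantify")):
        atlas = load_atlas(config.atlas_dir, config.atlas_stem)

    classifiers: dict[str, PixelClassifier] = {}

    def cohort_model(cohort: str) -> PixelClassifier:
        if cohort in classifiers:
            return classifiers[cohort]
        cfg = config.cohorts[cohort]
        if "model" in cfg:
            clf = PixelClassifier.load(cfg["model"])
            if clf.cohort_id not in (None, cohort):
                raise ValueError(
                    f"model {cfg['model']} is bound to cohort {clf.cohort_id!r}, "
                    f"not {cohort!r}"
                )
        else:
            train_stack = read_stack(cfg["train_stack"])
            ann = AnnotationSet.from_csv(cfg["annotations"])
            feats = compute_features_stack(
                train_stack, config.scales or (1.0, 2.5, 5.0)
            )
            clf = train_classifier(
                feats,
                ann,
                n_trees=int(cfg.get("n_trees", 100)),
                seed=config.seed,
                cohort_id=cohort,
            )
            clf.save(out_dir / f"model_{cohort}.joblib")
        classifiers[cohort] = clf
        return clf

    for sample in config.samples:
        t0 = time.monotonic()
        srec: dict[str, Any] = {"cohort": sample.cohort, "stages": {}}
        manifest["samples"][sample.id] = srec
        prev_stages = (
            previous.get("samples", {}).get(sample.id, {}).get("stages", {})
        )
        sdir = out_dir / sample.id
        sdir.mkdir(exist_ok=True)
        try:
            stack = None

            def get_stack():
                nonlocal stack
                if stack is None:
                    stack = read_stack(sample.stack)
                return stack

            stack_hash = _sha256(Path(sample.stack))

            prob_paths: dict[str, Path] = {}
            if config.steps.get("classify"):
                ih = hashlib.sha256(
                    f"{stack_hash}|{config.seed}|{config.scales}|classify".encode()
                ).hexdigest()
                if _can_skip(prev_stages.get("classify"), ih):
                    logger.info("[classify] %s: unchanged, skipped", sample.id)
                    srec["stages"]["classify"] = prev_stages["classify"]
                    prob_paths = {
                        _label_from_name(Path(p).name, sample.id): Path(p)
                        for p in prev_stages["classify"]["outputs"]
                        if p.endswith(".tif")
                    }
                else:
                    clf = cohort_model(sample.cohort)
                    if clf.cohort_id not in (None, sample.cohort):
                        raise ValueError("cohort-model binding violated")
                    maps = predict_stack(
                        clf, get_stack(), config.scales or (1.0, 2.5, 5.0)
                    )
                    for label, pmap in maps.items():
                        prob_paths[label] = write_probability_map(
                            pmap, sdir, sample.id
                        )
                    srec["stages"]["classify"] = _stage_record(ih, prob_paths)
                    logger.info(
                        "[classify] %s: %d labels, %.1fs",
                        sample.id,
                        len(prob_paths),
                        time.monotonic() - t0,
                    )

            chain_path = sdir / "transform.txt"
            if config.steps.get("register"):
                reg_kwargs = dict(config.registration)
                reg_kwargs.setdefault("seed", config.seed)
                settings = RegistrationSettings(**reg_kwargs)
                ih = hashlib.sha256(
                    f"{stack_hash}|{settings}|register".encode()
                ).hexdigest()
                if _can_skip(prev_stages.get("register"), ih):
                    logger.info("[register] %s: unchanged, skipped", sample.id)
                    srec["stages"]["register"] = prev_stages["register"]
                else:
                    chain = register_to_atlas(get_stack(), atlas, settings)
                    chain.save(chain_path)
                    srec["stages"]["register"] = _stage_record(
                        ih, {"transform": chain_path}
                    )
                    logger.info(
                        "[register] %s: red-channel chain fitted (%s stages)",
                        sample.id,
                        len(chain.stages),
                    )

            warped_paths: dict[str, Path] = {}
            if config.steps.get("warp"):
                if not prob_paths:
                    prob_paths = {
                        _label_from_name(p.name, sample.id): p
                        for p in sorted(sdir.glob(f"{sample.id}_*_prob.tif"))
                    }
                ih = hashlib.sha256(
                    (
                        "|".join(
                            f"{p}:{_sha256(p)}" for p in sorted(prob_paths.values())
                        )
                        + f"|{_sha256(chain_path)}|warp"
                    ).encode()
                ).hexdigest()
                if _can_skip(prev_stages.get("warp"), ih):
                    logger.info("[warp] %s: unchanged, skipped", sample.id)
                    srec["stages"]["warp"] = prev_stages["warp"]
                    warped_paths = {
                        _label_from_name(Path(p).name, f"{sample.id}_ccf"): Path(p)
                        for p in prev_stages["warp"]["outputs"]
                        if p.endswith(".tif")
                    }
                else:
                    chain = TransformChain.load(chain_path)
                    wdir = sdir / "atlas_space"
                    for label, p in prob_paths.items():
                        pmap = read_probability_map(p)
                        # one red-channel chain warps every label's map
                        warped = warp_volume(chain, pmap, atlas, "linear")
                        warped_paths[label] = write_probability_map(
                            warped, wdir, f"{sample.id}_ccf"
                        )
                    srec["stages"]["warp"] = _stage_record(ih, warped_paths)
                    logger.info(
                        "[warp] %s: %d maps resampled with the red-channel "
                        "transform",
                        sample.id,
                        len(warped_paths),
                    )

            if config.steps.get("quantify"):
                if not warped_paths:
                    wdir = sdir / "atlas_space"
                    warped_paths = {
                        _label_from_name(p.name, f"{sample.id}_ccf"): p
                        for p in sorted(wdir.glob(f"{sample.id}_ccf_*_prob.tif"))
                    }
                ih = hashlib.sha256(
                    (
                        "|".join(
                            f"{p}:{_sha256(p)}" for p in sorted(warped_paths.values())
                        )
                        + f"|{config.threshold_fraction}|quantify"
                    ).encode()
                ).hexdigest()
                quant_path = sdir / f"{sample.id}_quant.csv"
                if _can_skip(prev_stages.get("quantify"), ih):
                    logger.info("[quantify] %s: unchanged, skipped", sample.id)
                    srec["stages"]["quantify"] = prev_stages["quantify"]
                else:
                    import pandas as pd

                    tables = []
                    for label, p in sorted(warped_paths.items()):
                        pmap = read_probability_map(p)
                        leaf = quantify_regions(
                            pmap, atlas, config.threshold_fraction, sample.id
                        )
                        tables.append(aggregate_hierarchy(leaf, atlas))
                    full = pd.concat(tables, ignore_index=True)
                    full.to_csv(quant_path, index=False, float_format="%.10g")
                    srec["stages"]["quantify"] = _stage_record(
                        ih, {"quant": quant_path}
                    )
                    logger.info("[quantify] %s: wrote %s", sample.id, quant_path)
        except Exception as exc:  # noqa: BLE001 - per-sample isolation
            logger.exception("[pipeline] sample %s failed", sample.id)
            manifest["failures"].append({"sample": sample.id, "error": str(exc)})

    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    logger.removeHandler(handler)
    handler.close()
    return manifest
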