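"""End-to-end orchestration: cohort → smoothing → CV curves → maps → report.

A single declarative :class:`PipelineConfig` drives the whole run.  The
cohort is either generated synthetically or loaded from a directory of NIfTI
volumes plus a two-column labels table.  Outputs are plain-text/NIfTI files
in the output directory:

* ``metrics_{n}fold.csv``   — one row per k: accuracy, specificity, sensitivity
* ``best.json``             — best (k, accuracy, specificity, sensitivity) per scheme
* ``weight_map.nii``, ``activation_map.nii``, ``activation_normalized.nii``,
  ``activation_thresholded.nii`` (+ JSON sidecars)
* ``manifest.json``         — config echo, seeds, package version, output list

The manifest carries no timestamps, and NIfTI is written uncompressed, so a
rerun with the same config is byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from . import crossval, maps, pca, preprocess, svm
from .errors import ConfigurationError
from .synthetic import CohortConfig, EffectRegion, generate_cohort, read_cohort

__all__ = ["PipelineConfig", "validate_config", "run_pipeline", "config_from_yaml"]

log = logging.getLogger("vbmdecode")


@dataclass
class PipelineConfig:
    cohort: CohortConfig | None = None  # synthetic source ...
    input_dir: str | None = None  # ... or a directory of NIfTI + labels.tsv
    output_dir: str = "vbmdecode_run"
    mask_strategy: str = "nonzero-any"
    smoothing_fwhm_mm: float = 8.0
    schemes: tuple[int, ...] = (20, 10)
    cv_seed: int = 0
    C: float = 1.0
    k_range: tuple[int, ...] | None = None
    convention: str = "standard"
    map_normalization: str = "abs-minmax"
    map_threshold: float = 0.5

    def __post_init__(self) -> None:
        self.schemes = tuple(int(s) for s in self.schemes)


def validate_config(config: PipelineConfig) -> list[str]:
    """Collect every violation at once; an empty list means the config is valid."""
    violations: list[str] = []
    if config.cohort is None and config.input_dir is None:
        violations.append("either a synthetic cohort config or input_dir must be given")
    if config.cohort is not None and config.input_dir is not None:
        violations.append("cohort and input_dir are mutually exclusive")
    if config.input_dir is not None:
        d = Path(config.input_dir)
        if not d.is_dir():
            violations.append(f"input_dir does not exist: {d}")
        elif not (d / "labels.tsv").exists():
            violations.append(f"missing labels table: {d / 'labels.tsv'}")
    if config.mask_strategy not in ("all", "nonzero-any"):
        violations.append(f"mask_strategy must be 'all' or 'nonzero-any', got {config.mask_strategy!r}")
    if config.smoothing_fwhm_mm < 0:
        violations.append(f"smoothing_fwhm_mm must be nonnegative, got {config.smoothing_fwhm_mm}")
    if not config.schemes or any(s < 2 for s in config.schemes):
        violations.append(f"schemes must be fold counts >= 2, got {config.schemes}")
    if config.C <= 0:
        violations.append(f"C must be positive, got {config.C}")
    if config.convention not in crossval.CONVENTIONS:
        violations.append(f"convention must be one of {crossval.CONVENTIONS}, got {config.convention!r}")
    if config.map_normalization not in ("abs-minmax", "signed-minmax"):
        violations.append(f"map_normalization must be 'abs-minmax' or 'signed-minmax', got {config.map_normalization!r}")
    if not 0.0 <= config.map_threshold <= 1.0:
        violations.append(f"map_threshold must lie in the [0, 1] bound, got {config.map_threshold}")
    if config.k_range is not None and (len(config.k_range) == 0 or min(config.k_range) < 1):
        violations.append(f"k_range must contain positive integers, got {config.k_range}")
    return violations


def _cohort_dict(cfg: CohortConfig) -> dict:
    d = dataclasses.asdict(cfg)
    d["effect_regions"] = [{"center": list(r.center), "radius": r.radius} for r in cfg.effect_regions]
    d["grid_shape"] = list(cfg.grid_shape)
    d["voxel_size_mm"] = list(cfg.voxel_size_mm)
    return d


def config_from_yaml(path: str | Path, **overrides) -> PipelineConfig:
    """Load a declarative YAML config; keyword overrides take precedence."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    raw.update({k: v for k, v in overrides.items() if v is not None})
    cohort = raw.pop("cohort", None)
    if isinstance(cohort, dict):
        regions = cohort.pop("effect_regions", None)
        if regions is not None:
            cohort["effect_regions"] = tuple(
                EffectRegion(tuple(r["center"]), float(r["radius"])) if isinstance(r, dict) else EffectRegion(tuple(r[0]), float(r[1]))
                for r in regions
            )
        for key in ("grid_shape", "voxel_size_mm"):
            if key in cohort:
                cohort[key] = tuple(cohort[key])
        cohort = CohortConfig(**cohort)
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ConfigurationError(f"unknown config fields: {sorted(unknown)}")
    if "schemes" in raw:
        raw["schemes"] = tuple(raw["schemes"])
    if raw.get("k_range") is not None:
        raw["k_range"] = tuple(raw["k_range"])
    return PipelineConfig(cohort=cohort, **raw)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and return the report (also written to the output dir)."""
    violations = validate_config(config)
    if violations:
        raise ConfigurationError("invalid pipeline config: " + "; ".join(violations))
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[str] = []

    log.info("stage: cohort")
    if config.cohort is not None:
        cohort = generate_cohort(config.cohort)
        volumes, labels = cohort.volumes, cohort.labels
    else:
        volumes, labels, _ = read_cohort(config.input_dir)

    log.info("stage: preprocessing (FWHM %.1f mm, mask %s)", config.smoothing_fwhm_mm, config.mask_strategy)
    smoothed = preprocess.smooth_cohort(volumes, config.smoothing_fwhm_mm)
    mask = preprocess.build_mask(smoothed, config.mask_strategy)
    features = preprocess.vectorize(smoothed, mask)

    results: dict[int, crossval.CVResult] = {}
    best: dict[str, dict] = {}
    for n_subsets in config.schemes:
        log.info("stage: %d-fold cross-validation", n_subsets)
        res = crossval.run_cv(
            features,
            labels,
            n_subsets=n_subsets,
            k_range=config.k_range,
            C=config.C,
            seed=config.cv_seed,
            convention=config.convention,
        )
        csv_path = out / f"metrics_{n_subsets}fold.csv"
        res.to_csv(csv_path)
        written.append(csv_path.name)
        results[n_subsets] = res
        best[f"{n_subsets}-fold"] = res.summary()
        log.info(
            "  best: k=%d accuracy=%.3f specificity=%.3f sensitivity=%.3f",
            res.best_k,
            *res.best_metrics,
        )
    best_path = out / "best.json"
    best_path.write_text(json.dumps(best, indent=1, sort_keys=True))
    written.append(best_path.name)

    # final maps from a model trained on the full cohort at the primary scheme's best k
    primary = results[config.schemes[0]]
    k = primary.best_k
    log.info("stage: discriminative maps (k=%d)", k)
    model = pca.fit_pca(features)
    coeffs = pca.project(model, features)
    ranking = pca.fdr_rank(coeffs, labels)
    top = ranking.order[: min(k, model.n_components)]
    clf = svm.train(coeffs.values[:, top], labels, C=config.C)

    wmap = maps.weight_map(clf, model, features, component_subset=top)
    inputs = maps.build_pattern_inputs(clf, model, coeffs.values[:, top], component_subset=top)
    amap = maps.haufe_activation_map(inputs, features)
    norm = maps.normalize_map(amap, config.map_normalization)
    thresh = maps.threshold_map(norm, config.map_threshold)

    voxel = features.voxel_size_mm
    for name, vmap in (
        ("weight_map.nii", wmap),
        ("activation_map.nii", amap),
        ("activation_normalized.nii", norm),
        ("activation_thresholded.nii", thresh),
    ):
        maps.write_map(vmap, out / name, voxel_size_mm=voxel)
        written.append(name)
        written.append(Path(name).with_suffix(".json").name)

    manifest = {
        "package_version": __version__,
        "config": {
            **{k_: v for k_, v in dataclasses.asdict(config).items() if k_ != "cohort"},
            "cohort": _cohort_dict(config.cohort) if config.cohort is not None else None,
        },
        "n_subjects": int(len(labels)),
        "n_features": int(features.n_features),
        "outputs": written,
        "best": best,
        "map_k": int(k),
    }
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
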