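"""End-to-end orchestration: simulate -> extract -> compare.

A run is configured by a flat key/value mapping (JSON or YAML file, or a
plain dict), executes the enabled stages in order inside one output
directory, and produces a machine-readable report embedding the tool
version, the seed and a hash of the configuration. Identical config and
seed give identical outputs, byte for byte.

Recognized configuration keys (all optional unless noted)::

    out_dir            output directory (required)
    seed               integer master seed (default 0)
    simulate           bool, run the phantom stage (default true)
    extract            bool, run feature extraction (default true)
    compare            bool, run the group comparison (default true)
    manifest           existing manifest CSV (required if simulate=false
                       and extract=true)
    features           existing feature CSV (required if extract=false
                       and compare=true)
    n_control, n_case  cohort sizes (defaults 20 / 19)
    grid_rows, grid_cols        phantom grid (default 256 x 256)
    pixel_spacing_mm            isotropic spacing (default 240/256)
    binning            "unit" | "count:<k>" | "width:<w>" (default unit)
    alpha              significance level (default 0.05)
    log_level          python logging level name (default INFO)
    control_<p>, case_<p>       group-model overrides, where <p> is one of
                       mean, sd, skewness, kurtosis, mean_between_sd,
                       sd_between_sd, area_mean, area_sd
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path
from typing import Any, Mapping

import yaml

from . import __version__
from .errors import ConfigError, HistofeatError
from .features import extract_features, parse_binning
from .io import (
    FeatureRecord,
    read_feature_table,
    read_image,
    read_manifest,
    read_mask,
    write_feature_table,
)
from .phantom import (
    CohortSpec,
    case_group_model,
    control_group_model,
    generate_cohort,
)
from .stats import compare_cohorts, write_comparison_table

__all__ = ["RunConfig", "load_config", "cohort_spec_from_config", "run_study"]

logger = logging.getLogger("histofeat")

_GROUP_OVERRIDE_KEYS = (
    "mean",
    "sd",
    "skewness",
    "kurtosis",
    "mean_between_sd",
    "sd_between_sd",
    "area_mean",
    "area_sd",
)

_KNOWN_KEYS = {
    "out_dir",
    "seed",
    "simulate",
    "extract",
    "compare",
    "manifest",
    "features",
    "n_control",
    "n_case",
    "grid_rows",
    "grid_cols",
    "pixel_spacing_mm",
    "binning",
    "alpha",
    "log_level",
} | {f"{g}_{k}" for g in ("control", "case") for k in _GROUP_OVERRIDE_KEYS}


@dataclasses.dataclass(frozen=True)
class RunConfig:
    """Validated run configuration; see the module docstring for keys."""

    out_dir: Path
    seed: int = 0
    simulate: bool = True
    extract: bool = True
    compare: bool = True
    manifest: Path | None = None
    features: Path | None = None
    n_control: int = 20
    n_case: int = 19
    grid_rows: int = 256
    grid_cols: int = 256
    pixel_spacing_mm: float = 240.0 / 256.0
    binning: str = "unit"
    alpha: float = 0.05
    log_level: str = "INFO"
    group_overrides: tuple[tuple[str, float], ...] = ()

    @classmethod
    def from_mapping(cls, cfg: Mapping[str, Any]) -> "RunConfig":
        unknown = set(cfg) - _KNOWN_KEYS
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        if "out_dir" not in cfg:
            raise ConfigError("config must set out_dir")
        overrides = tuple(
            sorted(
                (k, float(v))
                for k, v in cfg.items()
                if k.split("_", 1)[0] in ("control", "case")
                and k not in ("control", "case")
            )
        )
        rc = cls(
            out_dir=Path(cfg["out_dir"]),
            seed=int(cfg.get("seed", 0)),
            simulate=bool(cfg.get("simulate", True)),
            extract=bool(cfg.get("extract", True)),
            compare=bool(cfg.get("compare", True)),
            manifest=Path(cfg["manifest"]) if cfg.get("manifest") else None,
            features=Path(cfg["features"]) if cfg.get("features") else None,
            n_control=int(cfg.get("n_control", 20)),
            n_case=int(cfg.get("n_case", 19)),
            grid_rows=int(cfg.get("grid_rows", 256)),
            grid_cols=int(cfg.get("grid_cols", 256)),
            pixel_spacing_mm=float(cfg.get("pixel_spacing_mm", 240.0 / 256.0)),
            binning=str(cfg.get("binning", "unit")),
            alpha=float(cfg.get("alpha", 0.05)),
            log_level=str(cfg.get("log_level", "INFO")),
            group_overrides=overrides,
        )
        parse_binning(rc.binning)  # fail early on a bad directive
        if rc.extract and not rc.simulate and rc.manifest is None:
            raise ConfigError(
                "extract stage enabled without simulate: set 'manifest'"
            )
        if rc.compare and not rc.extract and rc.features is None:
            raise ConfigError(
                "compare stage enabled without extract: set 'features'"
            )
        return rc

    def canonical_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["out_dir"] = str(self.out_dir)
        d["manifest"] = None if self.manifest is None else str(self.manifest)
        d["features"] = None if self.features is None else str(self.features)
        d["group_overrides"] = [list(p) for p in self.group_overrides]
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.canonical_dict(), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def load_config(path: str | Path) -> dict[str, Any]:
    """Load a flat JSON or YAML config file into a dict."""
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: config must be a flat mapping")
    return data


def cohort_spec_from_config(config: RunConfig) -> CohortSpec:
    """Build the phantom cohort spec, applying any group-model overrides."""
    models = {"control": control_group_model(), "case": case_group_model()}
    for key, value in config.group_overrides:
        group, param = key.split("_", 1)
        model = models[group]
        if param in ("mean", "sd", "skewness", "kurtosis"):
            field = {
                "mean": "target_mean",
                "sd": "target_sd",
                "skewness": "target_skewness",
                "kurtosis": "target_kurtosis",
            }[param]
            dist = dataclasses.replace(model.distribution, **{field: value})
            models[group] = dataclasses.replace(model, distribution=dist)
        elif param in ("area_mean", "area_sd"):
            field = "area_mean_cm2" if param == "area_mean" else "area_sd_cm2"
            models[group] = dataclasses.replace(model, **{field: value})
        else:
            models[group] = dataclasses.replace(model, **{param: value})
    sp = config.pixel_spacing_mm
    return CohortSpec(
        n_control=config.n_control,
        n_case=config.n_case,
        control=models["control"],
        case=models["case"],
        grid_size=(config.grid_rows, config.grid_cols),
        pixel_spacing_mm=(sp, sp),
        seed=config.seed,
    )


def extract_manifest_features(
    manifest_path: str | Path,
    out_path: str | Path,
    binning: str = "unit",
) -> Path:
    """Extract the feature panel for every manifest row into a CSV."""
    manifest_path = Path(manifest_path)
    base = manifest_path.parent
    manifest = read_manifest(manifest_path)
    records = []
    for row in manifest.itertuples(index=False):
        img_path = base / row.image_path
        mask_path = base / row.mask_path
        image = read_image(img_path)
        mask = read_mask(mask_path)
        fv = extract_features(image, mask, binning=binning)
        records.append(
            FeatureRecord(
                subject_id=row.subject_id, group_label=row.group, features=fv
            )
        )
    return write_feature_table(records, out_path)


def run_study(config: RunConfig | Mapping[str, Any]) -> dict[str, Any]:
    """Run the enabled stages and return (and write) the run report.

    Any stage failure halts the run; the raised error names the stage.
    """
    if not isinstance(config, RunConfig):
        config = RunConfig.from_mapping(config)
    logging.basicConfig(
        level=getattr(logging, config.log_level.upper(), logging.INFO),
        format="%(asctime)s %(levelname)s %(name)s: %(message)s",
    )
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    report: dict[str, Any] = {
        "tool": "histofeat",
        "version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "config": config.canonical_dict(),
        "stages": {},
        "notes": [
            "p-values are two-tailed and uncorrected for multiple comparisons"
        ],
    }

    manifest_path = config.manifest
    features_path = config.features

    def _stage(name: str, fn):
        logger.info("stage %s: starting", name)
        try:
            result = fn()
        except HistofeatError as exc:
            report["stages"][name] = {"status": "failed", "error": str(exc)}
            raise type(exc)(f"stage {name}: {exc}") from exc
        report["stages"][name] = {"status": "ok", **result}
        logger.info("stage %s: done", name)
        return result

    if config.simulate:

        def do_simulate():
            spec = cohort_spec_from_config(config)
            generate_cohort(spec, out)
            return {"manifest": str(out / "manifest.csv")}

        manifest_path = Path(
            _stage("simulate", do_simulate)["manifest"]
        )
    if config.extract:

        def do_extract():
            path = extract_manifest_features(
                manifest_path, out / "features.csv", binning=config.binning
            )
            return {"features": str(path)}

        features_path = Path(_stage("extract", do_extract)["features"])
    if config.compare:

        def do_compare():
            table = read_feature_table(features_path)
            rows = compare_cohorts(table, alpha=config.alpha)
            write_comparison_table(rows, out / "comparison.csv")
            return {
                "comparison": str(out / "comparison.csv"),
                "rows": [
                    {
                        "feature": r.feature_name,
                        "test_used": r.test_used,
                        "p_two_tailed": r.p_two_tailed,
                        "significant": r.significant,
                    }
                    for r in rows
                ],
            }

        _stage("compare", do_compare)

    (out / "report.json").write_text(json.dumps(report, indent=2))
    return report
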