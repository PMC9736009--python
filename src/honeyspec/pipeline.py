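"""Configuration-driven end-to-end runner.

simulate -> preprocess -> features -> classify -> evaluate, per
honey x syrup combination, with every stage seeded deterministically
from one master seed and every intermediate persisted as plain text
(CSV/JSON) so any stage can be recomputed bit-identically from the
artifact of the stage above it.

By default one classifier is trained per honey x syrup combination over
the four adulterated purity classes (90/80/70/60 % honey by mass);
``joint=True`` pools every combination into a single problem with
combination-qualified labels.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .exceptions import ConfigurationError, StageError
from .grid import WavelengthGrid
from .synthetic import (
    EndmemberLibrary,
    Hypercube,
    IlluminationParams,
    NoiseModel,
    generate_endmembers,
    make_mixture_design,
    mixture_spectrum,
)
from .preprocess import (
    SpectralCurveSet,
    average_neighborhoods,
    compute_transmittance,
    select_roi,
    subsample_curves,
)
from .features import FeatureMatrix, build_feature_matrix
from .classify import FoldAssignment, ModelSpec, cross_validate, stratified_folds, PredictionSet
from .metrics import confusion_matrix, metrics_table

MODEL_ALIASES = {"lda": "lda", "svm": "svm_quadratic", "svm_quadratic": "svm_quadratic", "nn": "nn"}


@dataclass
class PipelineConfig:
    """Resolved run configuration; YAML keys mirror the field names."""

    grid_start_nm: float = 420.0
    grid_stop_nm: float = 730.0
    n_bands: int = 311
    honeys: list[str] = field(default_factory=lambda: ["Q", "GS"])
    syrups: list[str] = field(default_factory=lambda: ["F", "G", "M"])
    fractions: list[float] = field(default_factory=lambda: [90.0, 80.0, 70.0, 60.0])
    total_mass_g: float = 23.0
    mixing_mode: str = "linear"
    separation: float = 0.15
    cube_rows: int = 64
    cube_cols: int = 64
    sigma_read: float = 0.002
    illumination_falloff: float = 0.15
    roi_size: int | None = None  # None = full cube extent
    neighborhood: int = 4
    n_per_class: int = 100
    n_terms: int = 8
    restarts: int = 5
    models: list[str] = field(default_factory=lambda: ["lda", "svm", "nn"])
    k_folds: int = 10
    seed: int = 0
    outdir: str = "honeyspec_out"
    joint: bool = False

    def __post_init__(self):
        for m in self.models:
            if m not in MODEL_ALIASES:
                raise ConfigurationError(f"unknown model '{m}'")
        if self.mixing_mode not in ("linear", "beer_lambert"):
            raise ConfigurationError(f"unknown mixing_mode '{self.mixing_mode}'")
        for f in self.fractions:
            if not 0 <= float(f) <= 100:
                raise ConfigurationError(f"fraction {f} outside [0, 100]")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as f:
            raw = yaml.safe_load(f) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    # -- derived pieces ----------------------------------------------------

    @property
    def grid(self) -> WavelengthGrid:
        return WavelengthGrid(np.linspace(self.grid_start_nm, self.grid_stop_nm, self.n_bands))

    @property
    def combinations(self) -> list[tuple[str, str]]:
        return [(h, s) for h in self.honeys for s in self.syrups]

    def combo_name(self, honey: str, syrup: str) -> str:
        return f"{honey}+{syrup}"

    def combo_dir(self, honey: str, syrup: str) -> Path:
        return Path(self.outdir) / f"{honey}_{syrup}"

    def class_labels(self, honey: str) -> list[str]:
        return [f"{honey}{f:g}" for f in self.fractions]

    def derive_seed(self, *keys) -> int:
        """Stable per-stage seed below 2**31, derived from the master seed."""
        tokens = [zlib.crc32(str(k).encode()) for k in keys]
        ss = np.random.SeedSequence([int(self.seed)] + tokens)
        return int(ss.generate_state(1)[0] % (2**31))

    def model_specs(self) -> dict[str, ModelSpec]:
        return {
            m: ModelSpec(family=MODEL_ALIASES[m], seed=self.derive_seed("model", m))
            for m in self.models
        }


# ---------------------------------------------------------------------------
# Stage helpers
# ---------------------------------------------------------------------------

def _concat_curve_sets(sets: list[SpectralCurveSet]) -> SpectralCurveSet:
    first = sets[0]
    curves = np.vstack([s.curves for s in sets])
    labels = np.concatenate([s.labels for s in sets])
    provenance = pd.concat([s.provenance for s in sets], ignore_index=True)
    flagged = None
    if all(s.flagged is not None for s in sets):
        flagged = np.concatenate([s.flagged for s in sets])
    return SpectralCurveSet(
        curves=curves, grid=first.grid, labels=labels, provenance=provenance, flagged=flagged
    )


def _simulate_pair(cfg: PipelineConfig, library: EndmemberLibrary, honey: str, syrup: str,
                   fraction: float) -> tuple[Hypercube, Hypercube]:
    tau = mixture_spectrum(library, honey, syrup, fraction, mode=cfg.mixing_mode)
    return simulate_pair_from_curve(cfg, tau, honey, syrup, fraction)


def simulate_pair_from_curve(cfg, tau, honey, syrup, fraction):
    from .synthetic import simulate_cube_pair

    return simulate_cube_pair(
        tau,
        cfg.grid,
        dims=(cfg.cube_rows, cfg.cube_cols),
        illumination=IlluminationParams(falloff=cfg.illumination_falloff),
        noise=NoiseModel(sigma_read=cfg.sigma_read),
        seed=cfg.derive_seed("cube", honey, syrup, f"{fraction:g}"),
        metadata={"honey": honey, "syrup": syrup, "fraction": float(fraction)},
    )


def _pair_to_curves(cfg: PipelineConfig, sample: Hypercube, white: Hypercube,
                    label: str, cube_id: str) -> SpectralCurveSet:
    roi_kwargs = (
        {"roi": "center", "size": cfg.roi_size}
        if cfg.roi_size is not None
        else {"roi": "center", "size": min(cfg.cube_rows, cfg.cube_cols)}
    )
    k = cfg.neighborhood
    sample_avg = average_neighborhoods(
        select_roi(sample, neighborhood=k, **roi_kwargs), k=k, label=label, cube_id=cube_id
    )
    white_avg = average_neighborhoods(
        select_roi(white, neighborhood=k, **roi_kwargs), k=k, label=label,
        cube_id=cube_id + ":white",
    )
    return compute_transmittance(sample_avg, white_avg)


def build_library(cfg: PipelineConfig) -> EndmemberLibrary:
    return generate_endmembers(
        list(cfg.honeys) + list(cfg.syrups),
        grid=cfg.grid,
        seed=cfg.derive_seed("endmembers"),
        separation=cfg.separation,
    )


def _combo_filter(cfg: PipelineConfig, combination: str | None):
    combos = cfg.combinations
    if combination is None:
        return combos
    keep = [(h, s) for h, s in combos if cfg.combo_name(h, s) == combination]
    if not keep:
        raise ConfigurationError(f"unknown combination '{combination}'")
    return keep


# ---------------------------------------------------------------------------
# File-driven stages
# ---------------------------------------------------------------------------

def stage_simulate(cfg: PipelineConfig, combination: str | None = None) -> list[Path]:
    """Write raw cube pairs (HDF5) for every combination x fraction."""
    library = build_library(cfg)
    out = Path(cfg.outdir) / "cubes"
    out.mkdir(parents=True, exist_ok=True)
    written = []
    design = make_mixture_design(cfg.total_mass_g, cfg.fractions)
    for honey, syrup in _combo_filter(cfg, combination):
        for fraction in design.fractions:
            sample, white = _simulate_pair(cfg, library, honey, syrup, fraction)
            for cube in (sample, white):
                path = out / f"{honey}_{syrup}_{fraction:g}_{cube.kind}.h5"
                cube.to_hdf5(path)
                written.append(path)
    return written


def stage_preprocess(cfg: PipelineConfig, combination: str | None = None,
                     cubes: dict | None = None) -> dict[str, Path]:
    """Cube pairs -> labeled transmittance curves (curves.csv per combination).

    Reads cubes from ``outdir/cubes`` unless an in-memory mapping
    ``{(honey, syrup, fraction): (sample, white)}`` is supplied.
    """
    paths = {}
    for honey, syrup in _combo_filter(cfg, combination):
        per_class = []
        for fraction in cfg.fractions:
            key = (honey, syrup, float(fraction))
            if cubes is not None and key in cubes:
                sample, white = cubes[key]
            else:
                stem = Path(cfg.outdir) / "cubes" / f"{honey}_{syrup}_{fraction:g}"
                sample = Hypercube.from_hdf5(f"{stem}_sample.h5")
                white = Hypercube.from_hdf5(f"{stem}_white_reference.h5")
            label = f"{honey}{fraction:g}"
            per_class.append(
                _pair_to_curves(cfg, sample, white, label, cube_id=f"{honey}_{syrup}_{fraction:g}")
            )
        curves = _concat_curve_sets(per_class)
        curves = subsample_curves(
            curves, n_per_class=cfg.n_per_class,
            seed=cfg.derive_seed("subsample", honey, syrup),
        )
        combo_dir = cfg.combo_dir(honey, syrup)
        combo_dir.mkdir(parents=True, exist_ok=True)
        path = combo_dir / "curves.csv"
        curves.to_csv(path)
        paths[cfg.combo_name(honey, syrup)] = path
    return paths


def stage_features(cfg: PipelineConfig, combination: str | None = None) -> dict[str, Path]:
    """Curves -> 3*n_terms-column coefficient matrices (features.csv)."""
    paths = {}
    for honey, syrup in _combo_filter(cfg, combination):
        combo_dir = cfg.combo_dir(honey, syrup)
        curves = SpectralCurveSet.from_csv(combo_dir / "curves.csv")
        fm = build_feature_matrix(
            curves, n_terms=cfg.n_terms, restarts=cfg.restarts,
            seed=cfg.derive_seed("features", honey, syrup),
        )
        path = combo_dir / "features.csv"
        fm.to_csv(path, metadata_path=combo_dir / "features_meta.json")
        paths[cfg.combo_name(honey, syrup)] = path
    return paths


def _load_features(cfg: PipelineConfig, honey: str, syrup: str) -> FeatureMatrix:
    combo_dir = cfg.combo_dir(honey, syrup)
    return FeatureMatrix.from_csv(
        combo_dir / "features.csv", metadata_path=combo_dir / "features_meta.json"
    )


def _classification_problems(cfg: PipelineConfig, combination: str | None):
    """Yield (name, outdir, features) per classification problem."""
    combos = _combo_filter(cfg, combination)
    if not cfg.joint:
        for honey, syrup in combos:
            yield cfg.combo_name(honey, syrup), cfg.combo_dir(honey, syrup), \
                _load_features(cfg, honey, syrup)
        return
    mats = []
    for honey, syrup in combos:
        fm = _load_features(cfg, honey, syrup)
        labels = np.asarray(
            [f"{cfg.combo_name(honey, syrup)}:{lab}" for lab in fm.labels], dtype=object
        )
        mats.append((fm, labels))
    values = np.vstack([fm.values for fm, _ in mats])
    labels = np.concatenate([lab for _, lab in mats])
    rmse = np.concatenate([fm.rmse for fm, _ in mats])
    converged = np.concatenate([fm.converged for fm, _ in mats])
    joint = FeatureMatrix(
        values=values, labels=labels, rmse=rmse, converged=converged,
        n_terms=cfg.n_terms, metadata={"joint": True},
    )
    outdir = Path(cfg.outdir) / "joint"
    outdir.mkdir(parents=True, exist_ok=True)
    yield "joint", outdir, joint


def stage_classify(cfg: PipelineConfig, combination: str | None = None,
                   model: str | None = None) -> dict[tuple[str, str], Path]:
    """Features -> out-of-fold predictions per model family."""
    specs = cfg.model_specs()
    if model is not None and model != "all":
        if model not in specs:
            raise ConfigurationError(f"model '{model}' not in configured models {cfg.models}")
        specs = {model: specs[model]}
    paths = {}
    for name, outdir, fm in _classification_problems(cfg, combination):
        folds = stratified_folds(
            fm.labels, k=cfg.k_folds, seed=cfg.derive_seed("folds", name)
        )
        for mname, spec in specs.items():
            preds = cross_validate(spec, fm, folds)
            path = Path(outdir) / f"predictions_{mname}.csv"
            preds.to_csv(path)
            with open(Path(outdir) / f"model_{mname}.json", "w") as f:
                json.dump(spec.to_dict(), f, indent=2, sort_keys=True)
            paths[(name, mname)] = path
    return paths


def stage_evaluate(cfg: PipelineConfig, combination: str | None = None,
                   model: str | None = None) -> dict[tuple[str, str], dict]:
    """Predictions -> confusion matrices and metric tables."""
    models = cfg.models if model in (None, "all") else [model]
    results = {}
    for name, outdir, fm in _classification_problems(cfg, combination):
        class_order = sorted(set(fm.labels), key=list(fm.labels).index)
        for mname in models:
            pred_path = Path(outdir) / f"predictions_{mname}.csv"
            frame = pd.read_csv(pred_path)
            cm = confusion_matrix(
                (frame["true_label"].astype(str).to_numpy(),
                 frame["predicted_label"].astype(str).to_numpy()),
                class_order,
            )
            table = metrics_table(cm)
            cm.to_csv(Path(outdir) / f"confusion_{mname}.csv")
            table.to_csv(Path(outdir) / f"metrics_{mname}.csv")
            table.to_json(Path(outdir) / f"metrics_{mname}.json")
            results[(name, mname)] = table.to_json()
    return results


def _write_run_log(cfg: PipelineConfig) -> None:
    import sklearn
    import scipy

    log = {
        "config": asdict(cfg),
        "honeyspec_version": __version__,
        "library_versions": {
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
            "scikit-learn": sklearn.__version__,
        },
        "derived_seeds": {
            "endmembers": cfg.derive_seed("endmembers"),
            **{
                f"subsample:{h}+{s}": cfg.derive_seed("subsample", h, s)
                for h, s in cfg.combinations
            },
            **{
                f"features:{h}+{s}": cfg.derive_seed("features", h, s)
                for h, s in cfg.combinations
            },
            **{f"model:{m}": cfg.derive_seed("model", m) for m in cfg.models},
        },
    }
    Path(cfg.outdir).mkdir(parents=True, exist_ok=True)
    with open(Path(cfg.outdir) / "run_log.json", "w") as f:
        json.dump(log, f, indent=2, sort_keys=True)


def run_pipeline(cfg: PipelineConfig, combination: str | None = None,
                 keep_cubes: bool = False) -> dict:
    """Run every stage end to end and return the report bundle.

    Cubes are held in memory unless ``keep_cubes`` is set (the
    ``simulate`` subcommand persists them explicitly).  Two identical
    invocations produce byte-identical CSV outputs.
    """
    try:
        _write_run_log(cfg)
        library = build_library(cfg)
        cubes = {}
        for honey, syrup in _combo_filter(cfg, combination):
            for fraction in cfg.fractions:
                cubes[(honey, syrup, float(fraction))] = _simulate_pair(
                    cfg, library, honey, syrup, fraction
                )
        if keep_cubes:
            stage_simulate(cfg, combination)
        stage_preprocess(cfg, combination, cubes=cubes)
        del cubes
        stage_features(cfg, combination)
        stage_classify(cfg, combination)
        results = stage_evaluate(cfg, combination)
    except ConfigurationError:
        raise
    except Exception as exc:  # attach stage context for the CLI
        raise StageError("run_pipeline", str(exc)) from exc
    return {
        "outdir": cfg.outdir,
        "metrics": {f"{name}/{model}": res for (name, model), res in results.items()},
    }


def report_summary(cfg: PipelineConfig) -> pd.DataFrame:
    """Accuracy per (combination, model) read back from metrics JSONs."""
    rows = []
    names = (
        ["joint"] if cfg.joint else [cfg.combo_name(h, s) for h, s in cfg.combinations]
    )
    for name in names:
        outdir = (
            Path(cfg.outdir) / "joint" if name == "joint"
            else cfg.combo_dir(*name.split("+"))
        )
        for model in cfg.models:
            path = outdir / f"metrics_{model}.json"
            if not path.exists():
                continue
            with open(path) as f:
                payload = json.load(f)
            rows.append(
                {
                    "combination": name,
                    "model": model,
                    "accuracy": payload["accuracy"],
                    **{f"macro_{k}": v for k, v in payload["macro"].items()},
                }
            )
    return pd.DataFrame(rows)
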