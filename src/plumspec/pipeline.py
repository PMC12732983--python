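"""End-to-end experiment orchestration.

Wires the stages together behind one run configuration: generate or load
spectra, truncate the noisy blue end, run the repeated-split protocol over
a preprocessing-by-model grid, fix the best split, run the metaheuristic
wavelength selectors against that split, and re-model on the selected
wavelengths.  Every report row carries the seed and a hash of the effective
configuration.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import evaluation as _eval
from . import models as _models
from . import selection as _sel
from . import spectra_io as _io
from . import synthetic as _syn
from .preprocessing import PreprocessingSpec

__all__ = [
    "RunConfig",
    "load_config",
    "load_or_generate",
    "run_model_comparison",
    "run_wavelength_experiment",
    "run_full",
]

log = logging.getLogger("plumspec")

DEFAULT_MODEL_GRID = (
    {"family": "svr", "kernel": "rbf"},
    {"family": "dt", "max_splits": 10},
    {"family": "plsr", "n_components": "select"},
)


@dataclass
class RunConfig:
    """Validated configuration of one full experiment."""

    seed: int = 0
    output_dir: str = "out"
    # either CSV inputs ...
    input_spectra: str | None = None
    input_reference: str | None = None
    # ... or generator overrides (fields of synthetic.GeneratorConfig)
    generator: dict = field(default_factory=dict)
    truncation_nm: tuple[float, float] = _io.DEFAULT_TRUNCATION_NM
    preprocessing: list = field(default_factory=lambda: ["none", "normalization"])
    models: list = field(default_factory=lambda: [dict(m) for m in DEFAULT_MODEL_GRID])
    n_reps: int = 20
    proportions: tuple[float, float, float] = _eval.DEFAULT_PROPORTIONS
    base_seed: int | None = None
    selection_algorithms: list = field(
        default_factory=lambda: sorted(_sel.ALGORITHM_DEFAULTS)
    )
    selection: dict = field(
        default_factory=lambda: {"k_max": 15, "iterations": 30, "n_runs": 1}
    )
    fitness_model: dict = field(
        default_factory=lambda: {"family": "svr", "kernel": "linear"}
    )

    def __post_init__(self) -> None:
        self.truncation_nm = tuple(self.truncation_nm)
        self.proportions = tuple(self.proportions)
        if self.base_seed is None:
            self.base_seed = self.seed
        # fail fast: build every nested spec once before any computation
        self.preprocessing_specs()
        self.model_specs()
        self.selector_configs()
        if self.input_spectra and not self.input_reference:
            raise ValueError("input_spectra given without input_reference")

    # -- nested spec construction -------------------------------------------

    def preprocessing_specs(self) -> list[PreprocessingSpec]:
        out = []
        for item in self.preprocessing:
            if isinstance(item, str):
                out.append(PreprocessingSpec(method=item))
            else:
                out.append(PreprocessingSpec.from_dict(item))
        if not out:
            raise ValueError("preprocessing grid is empty")
        return out

    def model_specs(self) -> list[_models.ModelSpec]:
        out = [_models.ModelSpec.from_dict(d) for d in self.models]
        if not out:
            raise ValueError("model grid is empty")
        return out

    def selector_configs(self) -> list[_sel.OptimizerConfig]:
        return [
            _sel.OptimizerConfig(
                algorithm=a,
                k_max=int(self.selection.get("k_max", 15)),
                iterations=int(self.selection.get("iterations", 30)),
                n_runs=int(self.selection.get("n_runs", 1)),
                seed=self.seed,
                params=dict(self.selection.get("params", {}).get(a, {})),
            )
            for a in self.selection_algorithms
        ]

    def fitness_model_spec(self) -> _models.ModelSpec:
        return _models.ModelSpec.from_dict(self.fitness_model)

    def generator_config(self) -> _syn.GeneratorConfig:
        kw = dict(self.generator)
        kw.setdefault("seed", self.seed)
        if "cultivars" in kw:
            kw["cultivars"] = [_syn.CultivarPPO(**c) for c in kw["cultivars"]]
        if "scatter" in kw and isinstance(kw["scatter"], dict):
            kw["scatter"] = _syn.ScatterSpec(**kw["scatter"])
        if "bands" in kw:
            kw["bands"] = [_syn.Band(**b) for b in kw["bands"]]
        if "planted_wavelengths_nm" in kw:
            kw["planted_wavelengths_nm"] = tuple(kw["planted_wavelengths_nm"])
        return _syn.GeneratorConfig(**kw)

    # -- serialization -------------------------------------------------------

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        """Hash of the scientific configuration (the output path does not
        change what is computed, so it is excluded)."""
        doc = {k: v for k, v in self.to_dict().items() if k != "output_dir"}
        blob = json.dumps(doc, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]

    def persist(self, out_dir: Path) -> None:
        out_dir.mkdir(parents=True, exist_ok=True)
        with open(out_dir / "config.yaml", "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


def load_config(path, overrides: dict | None = None) -> RunConfig:
    """Read a YAML/JSON config document; CLI scalars override file values."""
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    if not isinstance(doc, dict):
        raise ValueError("config document must be a mapping")
    if overrides:
        doc.update({k: v for k, v in overrides.items() if v is not None})
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(doc) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**doc)


def load_or_generate(
    cfg: RunConfig,
) -> tuple[_io.SpectraSet, _io.ReferenceTable, _syn.PhantomTruth | None]:
    """Load CSV inputs or generate a synthetic campaign, then truncate the
    wavelength range to the configured analysis window."""
    if cfg.input_spectra:
        spectra = _io.read_spectra_table(cfg.input_spectra)
        reference = _io.read_reference_table(cfg.input_reference)
        truth = None
    else:
        gen_cfg = cfg.generator_config()
        spectra, reference, truth = _syn.generate_dataset(gen_cfg)
    spectra = _io.truncate_wavelengths(spectra, *cfg.truncation_nm)
    return spectra, reference, truth


def run_model_comparison(
    cfg: RunConfig,
    spectra: _io.SpectraSet,
    reference: _io.ReferenceTable,
    out_dir: Path | None = None,
) -> tuple[_eval.ProtocolResult, _eval.SplitAssignment, pd.DataFrame]:
    """Repeated-split protocol, best-split selection, and the fixed-split
    re-evaluation of the full preprocessing-by-model grid."""
    y = reference.aligned_to(spectra)
    X = spectra.absorbance
    w = spectra.wavelengths_nm
    prep_grid = cfg.preprocessing_specs()
    model_grid = cfg.model_specs()
    log.info(
        "protocol: %d reps x %d preprocessings x %d models on %dx%d",
        cfg.n_reps, len(prep_grid), len(model_grid), *X.shape,
    )
    result = _eval.run_protocol(
        X, y, w, prep_grid, model_grid,
        n_reps=cfg.n_reps, base_seed=cfg.base_seed, proportions=cfg.proportions,
    )
    best_rep = _eval.select_best_split(result)
    fixed_split = _eval.make_split(X.shape[0], cfg.proportions, seed=cfg.base_seed + best_rep)
    log.info("fixed split: repetition %d (seed %d)", best_rep, fixed_split.seed)

    fixed_rows = []
    for rec in result.records:
        if rec["rep"] == best_rep and rec.get("report") is not None:
            row = {
                "preprocessing": rec["preprocessing"],
                "model": rec["model"],
                "rep": best_rep,
                "seed": rec["seed"],
            }
            row.update(rec["report"].row())
            fixed_rows.append(row)
    fixed_df = pd.DataFrame(fixed_rows)

    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
        proto_df = result.to_frame()
        proto_df["config_hash"] = cfg.config_hash()
        proto_df.to_csv(out_dir / "protocol.csv", index=False, float_format="%.12g")
        fixed_df2 = fixed_df.copy()
        fixed_df2["config_hash"] = cfg.config_hash()
        fixed_df2.to_csv(out_dir / "fixed_split.csv", index=False, float_format="%.12g")
        fixed_split.to_frame().to_csv(out_dir / "fixed_split_assignment.csv", index=False)
    return result, fixed_split, fixed_df


def run_wavelength_experiment(
    cfg: RunConfig,
    spectra: _io.SpectraSet,
    reference: _io.ReferenceTable,
    fixed_split: _eval.SplitAssignment,
    out_dir: Path | None = None,
) -> tuple[list[_sel.SelectionResult], pd.DataFrame, pd.DataFrame]:
    """Run the configured selectors on the fixed split, then re-model DT,
    SVR and PLSR on each selector's wavelengths."""
    y = reference.aligned_to(spectra)
    X = spectra.absorbance
    w = spectra.wavelengths_nm
    fitness_spec = cfg.fitness_model_spec()
    results = []
    for opt_cfg in cfg.selector_configs():
        log.info("selector %s: %d iterations", opt_cfg.algorithm, opt_cfg.iterations)
        results.append(
            _sel.run_selector(opt_cfg, X, y, w, fixed_split, fitness_spec)
        )
    comparison = _sel.summarize_selectors(results)

    remodel_rows = []
    for res in results:
        mask = res.best_mask
        for model_spec in cfg.model_specs():
            row = {
                "selector": res.algorithm,
                "n_selected": res.n_selected,
                "model": model_spec.label(),
                "seed": cfg.seed,
                "config_hash": cfg.config_hash(),
            }
            try:
                report = _remodel_on_mask(X, y, w, mask, fixed_split, model_spec)
                row.update(report.row())
            except Exception as exc:
                row["error"] = f"{type(exc).__name__}: {exc}"
            remodel_rows.append(row)
    remodel_df = pd.DataFrame(remodel_rows)

    if out_dir is not None:
        sel_dir = out_dir / "selection"
        sel_dir.mkdir(parents=True, exist_ok=True)
        comparison.to_csv(sel_dir / "selector_comparison.csv", index=False, float_format="%.12g")
        remodel_df.to_csv(sel_dir / "remodeling.csv", index=False, float_format="%.12g")
        for res in results:
            with open(sel_dir / f"{res.algorithm}.json", "w") as fh:
                json.dump(res.to_jsonable(), fh, indent=1)
    return results, comparison, remodel_df


def _remodel_on_mask(
    X: np.ndarray,
    y: np.ndarray,
    wavelengths: np.ndarray,
    mask: np.ndarray,
    split: _eval.SplitAssignment,
    model_spec: _models.ModelSpec,
) -> _eval.MetricsReport:
    Xm = X[:, mask]
    wm = wavelengths[mask]
    if model_spec.family == "plsr" and model_spec.n_components == "select":
        _, fitted = _models.select_plsr_components(
            Xm[split.train], y[split.train], Xm[split.validation], y[split.validation]
        )
    else:
        fitted = _models.fit(model_spec, Xm[split.train], y[split.train], wm)
    parts = {}
    for part in ("train", "validation", "test"):
        idx = getattr(split, part)
        parts[part] = _eval.compute_metrics(y[idx], _models.predict(fitted, Xm[idx]))
    return _eval.MetricsReport(parts["train"], parts["validation"], parts["test"])


def run_full(cfg: RunConfig) -> dict:
    """generate/load -> protocol -> fixed split -> selection -> re-modeling."""
    out_dir = Path(cfg.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cfg.persist(out_dir)
    spectra, reference, truth = load_or_generate(cfg)
    _io.write_spectra_table(spectra, out_dir / "spectra.csv")
    _io.write_reference_table(reference, out_dir / "reference.csv")
    if truth is not None:
        with open(out_dir / "truth.json", "w") as fh:
            json.dump(truth.to_jsonable(), fh, indent=1, default=str)
    protocol, fixed_split, fixed_df = run_model_comparison(cfg, spectra, reference, out_dir)
    results, comparison, remodel_df = run_wavelength_experiment(
        cfg, spectra, reference, fixed_split, out_dir
    )
    return {
        "spectra": spectra,
        "reference": reference,
        "truth": truth,
        "protocol": protocol,
        "fixed_split": fixed_split,
        "fixed_split_report": fixed_df,
        "selection_results": results,
        "selector_comparison": comparison,
        "remodeling": remodel_df,
    }
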