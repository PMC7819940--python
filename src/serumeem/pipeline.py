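"""End-to-end orchestration: simulate/load -> preprocess -> PARAFAC -> PLS.

``run_pipeline`` executes the full calibration workflow and returns a
:class:`RunReport` that is serializable to JSON and exactly reproducible
from the configured seed.  Each stage failure is re-raised as a
:class:`PipelineStageError` naming the stage.

Stage seeds are derived deterministically from the master seed so that the
simulation, the calibration/validation split, the PARAFAC restarts, the CV
folds and the permutation test each get an independent stream.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from serumeem.eem_core import (
    EEMStack,
    average_replicates,
    build_stack,
    fold,
    read_manifest,
    unfold,
)
from serumeem.parafac import (
    ParafacConfig,
    component_peaks,
    fit_parafac,
    score_reference_correlation,
    select_n_components,
)
from serumeem.pls import (
    choose_components_cv,
    coefficient_map,
    compute_metrics,
    fit_pls,
    interpret_rpd,
    permutation_test,
    predict,
    vip_scores,
)
from serumeem.preprocess import ScatterBands, remove_scatter, uv_scale
from serumeem.simulate import (
    SerumSimConfig,
    simulate_dataset,
    split_calibration_validation,
)

log = logging.getLogger("serumeem.pipeline")


class PipelineStageError(RuntimeError):
    """A pipeline stage failed; ``stage`` names it."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Everything needed for one reproducible run.

    ``mode`` is "simulate" (use ``sim``) or "load" (use ``manifest`` /
    ``reference`` paths).  ``parafac_f`` fixes the component number; if
    None the number is selected over ``parafac_f_range`` by CORCONDIA.
    ``replicate_policy`` is "average" (default: one averaged scan per sample
    enters PLS) or "all" (every replicate scan is a PLS row).
    ``n_perm = 0`` skips the permutation test.
    """

    mode: str = "simulate"
    manifest: str | None = None
    reference: str | None = None
    sim: SerumSimConfig = field(default_factory=SerumSimConfig)
    scatter_bands: ScatterBands = field(default_factory=ScatterBands)
    parafac_f: int | None = None
    parafac_f_range: tuple[int, int] = (2, 7)
    corcondia_threshold: float = 60.0
    parafac_n_starts: int = 10
    parafac_max_iter: int = 2500
    parafac_rel_tol: float = 1e-8
    max_lv: int = 10
    k_folds: int = 7
    n_perm: int = 100
    n_cal: int = 145
    n_val: int = 63
    replicate_policy: str = "average"
    seed: int = 0
    outdir: str | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("simulate", "load"):
            raise ValueError("mode must be simulate|load")
        if self.mode == "load" and not self.manifest:
            raise ValueError("load mode needs a manifest path")
        if self.replicate_policy not in ("average", "all"):
            raise ValueError("replicate_policy must be average|all")

    # -- flat config file (YAML-compatible subset) --------------------------

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"{path}: config must be a flat key-value map")
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict[str, Any]) -> "PipelineConfig":
        raw = dict(raw)
        sim_keys = {f.name for f in dataclasses.fields(SerumSimConfig)}
        sim_kwargs = {}
        for k in list(raw):
            if k in sim_keys:
                sim_kwargs[k] = raw.pop(k)
        if "conc_range" in sim_kwargs:
            sim_kwargs["conc_range"] = tuple(sim_kwargs["conc_range"])
        for gk in ("ex_grid", "em_grid"):
            if gk in sim_kwargs:
                sim_kwargs[gk] = tuple(sim_kwargs[gk])
        band_map = {
            "rayleigh1_halfwidth_nm": "rayleigh1_halfwidth",
            "rayleigh2_halfwidth_nm": "rayleigh2_halfwidth",
            "raman_shift_cm1": "raman_shift",
            "raman_halfwidth_nm": "raman_halfwidth",
            "scatter_mode": "mode",
        }
        band_kwargs = {}
        for k, attr in band_map.items():
            if k in raw:
                band_kwargs[attr] = raw.pop(k)
        if "parafac_f_range" in raw:
            raw["parafac_f_range"] = tuple(raw["parafac_f_range"])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        if sim_kwargs:
            seed = sim_kwargs.pop("seed", cfg.seed)
            cfg.sim = dataclasses.replace(SerumSimConfig(seed=seed),
                                          **sim_kwargs)
        if band_kwargs:
            cfg.scatter_bands = dataclasses.replace(ScatterBands(),
                                                    **band_kwargs)
        return cfg

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["sim"] = dataclasses.asdict(self.sim)
        d["scatter_bands"] = dataclasses.asdict(self.scatter_bands)
        return d


@dataclass
class RunReport:
    """Machine-readable record of one pipeline run."""

    config: dict[str, Any]
    parafac: dict[str, Any]
    calibration: dict[str, Any]
    vip_peaks: list[tuple[float, float]]
    permutation: dict[str, Any] | None
    timings_s: dict[str, float]
    version: str = "0.1.0"

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    def to_json(self, path: str | Path | None = None, indent: int = 2) -> str:
        text = json.dumps(self.to_dict(), indent=indent, default=_jsonify)
        if path is not None:
            Path(path).write_text(text)
        return text


def _jsonify(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            t0 = time.perf_counter()
            log.info("stage %-12s started", name)
            try:
                out = fn(*args, **kwargs)
            except PipelineStageError:
                raise
            except Exception as exc:
                raise PipelineStageError(name, str(exc)) from exc
            log.info("stage %-12s done in %.1f s", name,
                     time.perf_counter() - t0)
            return out
        return wrapped
    return deco


@_stage("input")
def _load_input(config: PipelineConfig) -> EEMStack:
    if config.mode == "simulate":
        sim = dataclasses.replace(config.sim, seed=config.seed)
        return simulate_dataset(sim).stack
    manifest = Path(config.manifest)
    if not manifest.exists():
        raise FileNotFoundError(f"manifest not found: {manifest}")
    ref = config.reference
    if ref is None:
        candidate = manifest.parent / "reference.csv"
        ref = candidate if candidate.exists() else None
    return read_manifest(manifest, ref)


@_stage("preprocess")
def _preprocess(stack: EEMStack, bands: ScatterBands
                ) -> tuple[EEMStack, EEMStack]:
    """Return (excised stack for PARAFAC, interpolated stack for PLS)."""
    excise = dataclasses.replace(bands, mode="excise")
    interp = dataclasses.replace(bands, mode="interpolate")
    excised = EEMStack([remove_scatter(e, excise) for e in stack.eems],
                       reference=stack.reference)
    interped = EEMStack([remove_scatter(e, interp) for e in stack.eems],
                        reference=stack.reference)
    return excised, interped


@_stage("parafac")
def _run_parafac(stack: EEMStack, config: PipelineConfig) -> dict[str, Any]:
    pf_config = ParafacConfig(
        n_starts=config.parafac_n_starts,
        max_iter=config.parafac_max_iter,
        rel_tol=config.parafac_rel_tol,
        seed=config.seed + 2,
    )
    if config.parafac_f is not None:
        n_components = int(config.parafac_f)
        selection = None
    else:
        lo, hi = config.parafac_f_range
        selection = select_n_components(
            stack, range(lo, hi + 1), threshold=config.corcondia_threshold,
            config=pf_config, return_diagnostics=True,
        )
        n_components = selection.n_components
    model = fit_parafac(stack, n_components, pf_config)
    peaks = component_peaks(model, stack.ex_grid, stack.em_grid)
    correlations = []
    if stack.reference is not None:
        ref = stack.reference_vector()
        for f in range(model.n_components):
            r, p, n = score_reference_correlation(model, f, ref)
            correlations.append({"component": f, "r": r, "p": p, "n": n})
    out = {
        "n_components": model.n_components,
        "corcondia": model.corcondia,
        "explained_pct": model.explained_pct,
        "converged": model.converged,
        "n_iter": model.n_iter,
        "peaks_ex_em_nm": peaks,
        "score_reference_correlations": correlations,
        "_model": model,
    }
    if selection is not None:
        out["selection_corcondia_by_f"] = selection.corcondia_by_f
        out["selection_warned"] = selection.warned
    return out


@_stage("calibration")
def _run_pls(pls_stack: EEMStack, config: PipelineConfig) -> dict[str, Any]:
    if pls_stack.reference is None:
        raise ValueError("PLS calibration needs a reference table")
    cal_stack, val_stack = split_calibration_validation(
        pls_stack, config.n_cal, config.n_val, seed=config.seed + 1
    )
    if config.replicate_policy == "average":
        cal_stack = average_replicates(cal_stack)
        val_stack = average_replicates(val_stack)
    X_cal_raw, vmap = unfold(cal_stack, missing_policy="drop")
    X_val_raw, _ = unfold(val_stack, missing_policy="drop")
    y_cal = cal_stack.reference_vector()
    y_val = val_stack.reference_vector()
    X_cal, scaling = uv_scale(X_cal_raw)
    a_star, q2 = choose_components_cv(
        X_cal, y_cal, max_a=config.max_lv, k_folds=config.k_folds,
        seed=config.seed + 3,
    )
    model = fit_pls(X_cal, y_cal, a_star, scaling=scaling, variable_map=vmap)
    yhat_cal = model.fitted
    yhat_val = predict(model, X_val_raw)
    metrics = compute_metrics(y_cal, yhat_cal, y_val, yhat_val,
                              model.n_lv, q2_cv=float(q2[a_star - 1]))
    vip = vip_scores(model)
    return {
        "a_selected": a_star,
        "q2_by_a": q2.tolist(),
        "metrics": dataclasses.asdict(metrics),
        "rpd_band": interpret_rpd(metrics.rpd),
        "_model": model,
        "_vip": vip,
        "_pred": {
            "cal": (cal_stack.sample_ids, y_cal, yhat_cal),
            "val": (val_stack.sample_ids, y_val, yhat_val),
        },
        "_X_cal": X_cal,
        "_y_cal": y_cal,
    }


@_stage("permutation")
def _run_permutation(X_cal, y_cal, a_star, config: PipelineConfig
                     ) -> dict[str, Any] | None:
    if config.n_perm == 0:
        return None
    perm = permutation_test(X_cal, y_cal, a_star, n_perm=config.n_perm,
                            seed=config.seed + 4, k_folds=config.k_folds)
    return {
        "n_perm": perm.n_perm,
        "r2_intercept": perm.r2_intercept,
        "q2_intercept": perm.q2_intercept,
    }


@_stage("report")
def _write_artifacts(outdir: Path, parafac_out, pls_out, report: RunReport
                     ) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    model = parafac_out["_model"]
    for name, arr in (("ex_loadings", model.ex_loadings),
                      ("em_loadings", model.em_loadings),
                      ("sample_scores", model.sample_scores)):
        pd.DataFrame(arr, columns=[f"component_{f + 1}"
                                   for f in range(arr.shape[1])]
                     ).to_csv(outdir / f"parafac_{name}.csv", index=False)
    pls_model = pls_out["_model"]
    vip = pls_out["_vip"]
    vmap = pls_model.variable_map
    pd.DataFrame({
        "ex_nm": vmap.ex_nm, "em_nm": vmap.em_nm,
        "coefficient": pls_model.coefficients, "vip": vip.vip,
    }).to_csv(outdir / "pls_variables.csv", index=False)
    em_index = vmap.em_grid.values
    ex_cols = vmap.ex_grid.values
    pd.DataFrame(coefficient_map(pls_model), index=em_index, columns=ex_cols
                 ).to_csv(outdir / "coefficient_map.csv")
    pd.DataFrame(vip.vip_map, index=em_index, columns=ex_cols
                 ).to_csv(outdir / "vip_map.csv")
    for which, (ids, y, yhat) in pls_out["_pred"].items():
        pd.DataFrame({"sample_id": ids, "reference_iu_dl": y,
                      "predicted_iu_dl": yhat}
                     ).to_csv(outdir / f"predictions_{which}.csv", index=False)
    report.to_json(outdir / "report.json")


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute the full workflow and return (and optionally write) the report."""
    timings: dict[str, float] = {}

    def timed(name, fn, *args, **kwargs):
        t0 = time.perf_counter()
        out = fn(*args, **kwargs)
        timings[name] = round(time.perf_counter() - t0, 3)
        return out

    stack = timed("input", _load_input, config)
    excised, interped = timed("preprocess", _preprocess, stack,
                              config.scatter_bands)
    parafac_out = timed("parafac", _run_parafac, excised, config)
    pls_out = timed("calibration", _run_pls, interped, config)
    permutation = timed("permutation", _run_permutation,
                        pls_out["_X_cal"], pls_out["_y_cal"],
                        pls_out["a_selected"], config)

    vip = pls_out["_vip"]
    report = RunReport(
        config=config.to_dict(),
        parafac={k: v for k, v in parafac_out.items()
                 if not k.startswith("_")},
        calibration={k: v for k, v in pls_out.items()
                     if not k.startswith("_")},
        vip_peaks=vip.peaks,
        permutation=permutation,
        timings_s=timings,
    )
    if config.outdir:
        _write_artifacts(Path(config.outdir), parafac_out, pls_out, report)
    return report
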