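"""Configuration-driven end-to-end pipeline.

Step I simulates land-cover change (synthetic map pair -> Markov matrix ->
MLP transition potentials -> allocated future map); Step II runs the
species-distribution workflow (synthetic landscape and presences ->
cleaning/rarefaction -> background sampling -> collinearity filter -> AICc
tuning -> replicated fitting -> evaluation -> scenario projection). Every
stage writes plain-text artifacts into the output directory and the run ends
with a JSON manifest sufficient to reproduce the outputs bit-identically.
"""

from __future__ import annotations

import json
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .evaluation import (
    EvaluationReport, auc_band, boyce_index, jackknife_gains, percent_contribution,
)
from .features import FeatureDefinition
from .geodata import clean_and_rarefy, correlation_filter, read_occurrences_csv, sample_background
from .landcover import (
    MLPArch, allocate_change, class_area_report, crosstab_transition,
    demand_from_matrix, scale_matrix, train_transition_mlp,
)
from .model import MaxEntSDM
from .raster import RasterGrid, RasterStack, write_ascii_grid
from .scenario import (
    binarize_and_measure, project_scenario, run_replicates, ten_percentile_threshold,
)
from .selection import CandidateSpec, enumerate_candidates, tune
from .synthetic import (
    SyntheticLandscapeConfig, SyntheticTransitionSpec, SyntheticTruth,
    generate_landcover_pair, generate_raster_stack, sample_presences,
    truth_suitability,
)

STAGES = ("simulate", "landcover", "prepare", "tune", "evaluate", "project", "report")

__all__ = ["PipelineConfig", "run_pipeline", "STAGES"]


@dataclass
class PipelineConfig:
    """Everything one run needs; loadable from YAML."""

    seed: int = 0
    output_dir: str = "maxsdm_run"
    # landscape
    grid_rows: int = 60
    grid_cols: int = 60
    cell_size: float = 1.0
    n_continuous: int = 4
    pairwise_correlation: float = 0.3
    n_landcover_classes: int = 3
    smoothing_sigma: float = 3.0
    # truth: list of {kind, variable(s), weight, knot?, level?}
    truth_weights: list = field(default_factory=lambda: [
        {"kind": "L", "variable": "env1", "weight": 6.0},
        {"kind": "Q", "variable": "env1", "weight": -4.0},
        {"kind": "L", "variable": "env2", "weight": 2.0},
    ])
    n_presences: int = 400
    # preprocessing
    correlation_cutoff: float = 0.85
    n_background: int = 2000
    # tuning
    feature_grid: list = field(default_factory=lambda: ["L", "Q"])
    reg_grid: list = field(default_factory=lambda: [1.0, 2.0])
    # replicates
    n_replicates: int = 5
    train_frac: float = 0.75
    # land-cover simulation
    interval_years: float = 10.0
    horizon_years: float = 35.0
    transition_matrix: list | None = None
    mlp_hidden: int = 10
    mlp_epochs: int = 300
    mlp_learning_rate: float = 0.01
    # scenarios: list of {label, offsets: {layer: additive shift},
    #                     use_future_landcover: bool (default True)}
    scenarios: list = field(default_factory=list)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_dict(self) -> dict:
        from dataclasses import asdict
        return asdict(self)


def _stage_seeds(seed: int) -> dict[str, int]:
    ss = np.random.SeedSequence(seed)
    names = ("landscape", "landcover", "presence", "background", "mlp",
             "allocate", "replicates")
    children = ss.spawn(len(names))
    return {
        n: int(c.generate_state(1)[0] % (2**31)) for n, c in zip(names, children)
    }


def _build_truth(cfg: PipelineConfig, stack: RasterStack) -> SyntheticTruth:
    weights: dict[FeatureDefinition, float] = {}
    for item in cfg.truth_weights:
        kind = item["kind"]
        if kind == "P":
            vars_ = tuple(item["variables"])
        else:
            vars_ = (item["variable"],)
        bounds = tuple(
            (float(stack[v].values[stack.mask].min()),
             float(stack[v].values[stack.mask].max()))
            for v in vars_
        )
        defn = FeatureDefinition(
            kind, vars_, bounds,
            knot=item.get("knot"), level=item.get("level"),
        )
        weights[defn] = float(item["weight"])
    return SyntheticTruth(weights)


def run_pipeline(config: PipelineConfig, until: str | None = None) -> dict:
    """Run the pipeline through stage ``until`` (default: everything).

    Returns the manifest dict (also written to ``manifest.json``). A stage
    failure aborts with the stage name and cause; artifacts written by
    earlier stages are retained.
    """
    if until is not None and until not in STAGES:
        raise ValueError(f"unknown stage {until!r}; choose from {STAGES}")
    stop_at = STAGES.index(until) if until else len(STAGES) - 1
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed)
    manifest: dict = {
        "package": "maxsdm",
        "version": __version__,
        "numpy": np.__version__,
        "config": config.to_dict(),
        "stage_seeds": seeds,
        "artifacts": {},
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    art = manifest["artifacts"]

    def record(name, path):
        art[name] = str(path)

    state: dict = {}

    def stage(name):
        return STAGES.index(name) <= stop_at

    try:
        # ---- Step 0: synthetic landscape -------------------------------
        R = np.full((config.n_continuous, config.n_continuous),
                    config.pairwise_correlation, dtype=float)
        np.fill_diagonal(R, 1.0)
        land_cfg = SyntheticLandscapeConfig(
            grid_rows=config.grid_rows,
            grid_cols=config.grid_cols,
            cell_size=config.cell_size,
            n_continuous=config.n_continuous,
            target_correlations=R,
            n_landcover_classes=config.n_landcover_classes,
            seed=seeds["landscape"],
            smoothing_sigma=config.smoothing_sigma,
        )
        stack = generate_raster_stack(land_cfg)
        state["stack"] = stack
    except Exception as exc:  # pragma: no cover - defensive
        raise RuntimeError(f"stage 'simulate' failed: {exc}") from exc

    # ---- Step I: land-cover simulation ---------------------------------
    if stage("landcover"):
        try:
            K = config.n_landcover_classes
            if config.transition_matrix is not None:
                P = np.asarray(config.transition_matrix, dtype=float)
            else:
                # mild default dynamics: 10% leakage to the next class
                P = np.eye(K) * 0.9
                for i in range(K):
                    P[i, (i + 1) % K] += 0.1
            spec = SyntheticTransitionSpec(
                transition_matrix=P, interval_years=config.interval_years
            )
            drivers = stack.subset(stack.continuous_names)
            t1, t2 = generate_landcover_pair(spec, drivers, seeds["landcover"])
            matrix = crosstab_transition(t1, t2)
            matrix.interval_years = config.interval_years
            scaled = scale_matrix(matrix, config.horizon_years)
            arch = MLPArch(
                hidden=config.mlp_hidden,
                epochs=config.mlp_epochs,
                learning_rate=config.mlp_learning_rate,
                seed=seeds["mlp"],
            )
            potentials = train_transition_mlp(t1, t2, drivers, arch)
            demand = demand_from_matrix(scaled, t2)
            future_lc = allocate_change(t2, demand, potentials, seeds["allocate"])
            state.update(t1=t1, t2=t2, matrix=matrix, scaled=scaled,
                         future_lc=future_lc)
            write_ascii_grid(t1, out / "landcover_t1.asc")
            write_ascii_grid(t2, out / "landcover_t2.asc")
            write_ascii_grid(future_lc, out / "landcover_future.asc")
            matrix.to_frame().to_csv(out / "transition_matrix.csv")
            scaled.to_frame().to_csv(out / "transition_matrix_scaled.csv")
            class_area_report(t2, future_lc).to_csv(
                out / "landcover_area_change.csv", index=False
            )
            for n in ("landcover_t1.asc", "landcover_t2.asc",
                      "landcover_future.asc", "transition_matrix.csv",
                      "transition_matrix_scaled.csv", "landcover_area_change.csv"):
                record(n.rsplit(".", 1)[0], out / n)
            # the SDM's current land-cover layer is the later observed map
            stack = stack.with_layer("landcover", t2)
            state["stack"] = stack
        except Exception as exc:
            raise RuntimeError(f"stage 'landcover' failed: {exc}") from exc

    # ---- simulate presences (needs the final current stack) ------------
    if stage("simulate"):
        try:
            truth = _build_truth(config, stack)
            suit_truth = truth_suitability(stack, truth)
            occ = sample_presences(suit_truth, config.n_presences, seeds["presence"])
            state.update(truth=truth, suit_truth=suit_truth, occ=occ)
            for name, layer in stack.items():
                write_ascii_grid(layer, out / f"layer_{name}.asc")
                record(f"layer_{name}", out / f"layer_{name}.asc")
            write_ascii_grid(suit_truth, out / "truth_suitability.asc")
            record("truth_suitability", out / "truth_suitability.asc")
            occ.to_csv(out / "occurrences.csv")
            record("occurrences", out / "occurrences.csv")
            with open(out / "truth.yaml", "w") as fh:
                yaml.safe_dump(
                    {"weights": config.truth_weights, "seed": config.seed}, fh
                )
            record("truth", out / "truth.yaml")
        except Exception as exc:
            raise RuntimeError(f"stage 'simulate' failed: {exc}") from exc

    # ---- prepare --------------------------------------------------------
    if stage("prepare"):
        try:
            template = stack.template
            occ_clean = clean_and_rarefy(state["occ"], template)
            bg = sample_background(stack, config.n_background, seeds["background"])
            r_occ, c_occ = template.xy_to_rowcol(occ_clean.x, occ_clean.y)
            r_bg, c_bg = template.xy_to_rowcol(bg.x, bg.y)
            rows = np.concatenate([r_occ, r_bg])
            cols = np.concatenate([c_occ, c_bg])
            filt = correlation_filter(
                stack, (rows, cols), cutoff=config.correlation_cutoff
            )
            filt.to_frame().to_csv(out / "variable_filter.csv", index=False)
            record("variable_filter", out / "variable_filter.csv")
            occ_clean.to_csv(out / "occurrences_rarefied.csv")
            record("occurrences_rarefied", out / "occurrences_rarefied.csv")
            bg.to_csv(out / "background.csv")
            record("background", out / "background.csv")
            kept = stack.subset(filt.retained)
            X_occ = kept.table(r_occ, c_occ)
            X_bg = kept.table(r_bg, c_bg)
            state.update(
                occ_clean=occ_clean, bg=bg, filt=filt, kept=kept,
                X_occ=X_occ, X_bg=X_bg,
                cats=tuple(n for n in filt.retained if n in stack.categorical_names),
            )
        except Exception as exc:
            raise RuntimeError(f"stage 'prepare' failed: {exc}") from exc

    # ---- tune -----------------------------------------------------------
    if stage("tune"):
        try:
            X = pd.concat([state["X_occ"], state["X_bg"]], ignore_index=True)
            y = np.r_[np.ones(len(state["X_occ"])), np.zeros(len(state["X_bg"]))]
            candidates = enumerate_candidates(config.feature_grid, config.reg_grid)
            best, table = tune(X, y, candidates, categorical=state["cats"])
            table.to_csv(out / "selection_table.csv", index=False)
            record("selection_table", out / "selection_table.csv")
            state.update(best=best, X=X, y=y)
        except Exception as exc:
            raise RuntimeError(f"stage 'tune' failed: {exc}") from exc

    # ---- evaluate -------------------------------------------------------
    if stage("evaluate"):
        try:
            best: CandidateSpec = state["best"]
            kept = state["kept"]
            X_land = kept.table()
            reps = run_replicates(
                state["X_occ"], state["X_bg"], X_land,
                feature_classes=best.feature_classes,
                reg_multiplier=best.reg_multiplier,
                n_replicates=config.n_replicates,
                train_frac=config.train_frac,
                seed=seeds["replicates"],
                categorical=state["cats"],
            )
            template = kept.template
            rows, cols = kept.valid_rowcol()
            mean_grid = RasterGrid(
                _to_grid(reps.mean_map, template, rows, cols),
                template.mask.copy(), template.origin, template.cell_size,
            )
            write_ascii_grid(mean_grid, out / "suitability_current.asc")
            record("suitability_current", out / "suitability_current.asc")

            r_occ, c_occ = template.xy_to_rowcol(
                state["occ_clean"].x, state["occ_clean"].y
            )
            occ_cell_index = _cell_index(rows, cols, r_occ, c_occ, template.shape)
            occ_suit = reps.mean_map[occ_cell_index]
            tau10 = ten_percentile_threshold(occ_suit)
            current_thr = binarize_and_measure(reps.mean_map, tau10)
            bin_grid = RasterGrid(
                _to_grid(current_thr.binary.astype(float), template, rows, cols),
                template.mask.copy(), template.origin, template.cell_size,
                categorical=True,
            )
            write_ascii_grid(bin_grid, out / "binary_current.asc")
            record("binary_current", out / "binary_current.asc")

            cbi = boyce_index(occ_suit, reps.mean_map).cbi
            mean_test_auc = float(np.nanmean(reps.test_auc))
            report = EvaluationReport(
                auc_train=float(np.mean(reps.train_auc)),
                auc_test=mean_test_auc,
                band=auc_band(mean_test_auc),
                cbi=float(cbi),
                jackknife=jackknife_gains(
                    state["X"], state["y"],
                    feature_classes=best.feature_classes,
                    reg_multiplier=best.reg_multiplier,
                    categorical=state["cats"],
                ),
                contributions=pd.Series(dtype=float),
            )
            final = MaxEntSDM(
                feature_classes=best.feature_classes,
                reg_multiplier=best.reg_multiplier,
                categorical=state["cats"],
            ).fit(state["X"], state["y"])
            report.contributions = percent_contribution(final)
            with open(out / "evaluation.json", "w") as fh:
                json.dump(report.to_dict(), fh, indent=2)
            record("evaluation", out / "evaluation.json")
            report.jackknife.to_csv(out / "jackknife.csv", index=False)
            record("jackknife", out / "jackknife.csv")
            curves = []
            for v in final.feature_names_in_:
                grid_v, suit = final.response_curve(v)
                curves.append(pd.DataFrame(
                    {"variable": v, "value": grid_v, "suitability": suit}
                ))
            pd.concat(curves, ignore_index=True).to_csv(
                out / "response_curves.csv", index=False
            )
            record("response_curves", out / "response_curves.csv")
            (out / "model.lambdas").write_text(final.to_lambdas_text())
            record("model_lambdas", out / "model.lambdas")
            state.update(
                reps=reps, tau10=tau10, current_thr=current_thr,
                final=final, report=report, X_land=X_land,
                rows=rows, cols=cols, template=template,
            )
        except Exception as exc:
            raise RuntimeError(f"stage 'evaluate' failed: {exc}") from exc

    # ---- project --------------------------------------------------------
    if stage("project") and config.scenarios:
        try:
            kept = state["kept"]
            template = state["template"]
            rows, cols = state["rows"], state["cols"]
            results = []
            for sc in config.scenarios:
                label = sc["label"]
                fut = kept
                for layer, shift in (sc.get("offsets") or {}).items():
                    if layer not in fut:
                        raise KeyError(f"scenario {label}: unknown layer {layer!r}")
                    g = fut[layer].copy()
                    g.values = g.values + float(shift)
                    fut = fut.with_layer(layer, g)
                if (
                    sc.get("use_future_landcover", True)
                    and "future_lc" in state
                    and "landcover" in fut
                ):
                    fut = fut.with_layer("landcover", state["future_lc"])
                X_future = fut.table(rows, cols)
                res = project_scenario(
                    state["reps"], X_future, label,
                    state["tau10"], state["current_thr"],
                )
                results.append(res)
                grid = RasterGrid(
                    _to_grid(res.suitability, template, rows, cols),
                    template.mask.copy(), template.origin, template.cell_size,
                )
                write_ascii_grid(grid, out / f"suitability_{label}.asc")
                record(f"suitability_{label}", out / f"suitability_{label}.asc")
                bgrid = RasterGrid(
                    _to_grid(res.thresholded.binary.astype(float), template, rows, cols),
                    template.mask.copy(), template.origin, template.cell_size,
                    categorical=True,
                )
                write_ascii_grid(bgrid, out / f"binary_{label}.asc")
                record(f"binary_{label}", out / f"binary_{label}.asc")
            table = pd.DataFrame(
                {
                    "scenario": [r.label for r in results],
                    "suitable_area_current": state["current_thr"].suitable_count,
                    "suitable_area_future": [r.thresholded.suitable_count for r in results],
                    "percent_change": [r.percent_change for r in results],
                }
            )
            table.to_csv(out / "scenario_changes.csv", index=False)
            record("scenario_changes", out / "scenario_changes.csv")
            state["scenario_results"] = results
        except Exception as exc:
            raise RuntimeError(f"stage 'project' failed: {exc}") from exc

    manifest["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    manifest["_state"] = state  # in-memory extras for library callers
    return manifest


def _to_grid(values: np.ndarray, template, rows, cols) -> np.ndarray:
    out = np.zeros(template.shape)
    out[rows, cols] = values
    return out


def _cell_index(rows, cols, r_q, c_q, shape) -> np.ndarray:
    """Positions of query cells within the valid-cell (row-major) ordering."""
    flat = rows * shape[1] + cols
    lookup = {f: i for i, f in enumerate(flat)}
    q = np.asarray(r_q) * shape[1] + np.asarray(c_q)
    try:
        return np.array([lookup[f] for f in q])
    except KeyError as exc:
        raise ValueError("occurrence cell outside the valid landscape") from exc
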