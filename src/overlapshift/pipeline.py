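"""End-to-end study analogue: simulate/load, screen, fit, select, project, cost.

``run_pipeline`` executes, from one :class:`RunConfig`:

1. grid construction and the >500 m depth mask;
2. covariate simulation for both climate scenarios (or file loading) and
   species simulation from the joint generative model;
3. the pairwise-correlation covariate screen and candidate-subset enumeration;
4. single-species fits over all candidate subsets with DIC ranking and
   relationship classification of the winning smooths (Table-1 analogue);
5. joint fits with DIC ranking and the decisive-difference flag
   (Table-2 analogue);
6. future-scenario projection via the missing-response convention;
7. matched scenario refits for the present/future common spatial trends and
   the ecological-cost tables (Tables-3/4 analogues);
8. the percentage-of-deviance-explained table.

Every random stage derives its seed from the single top-level seed; rerunning
an identical config reproduces all numeric outputs bit-identically.
"""

from __future__ import annotations

import hashlib
import json
import logging
import shutil
import time
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .costs import build_cost_report, reports_to_csv, single_species_costs
from .grid import (LatticeGrid, SpeciesSurface, apply_depth_mask, build_adjacency,
                   build_grid, read_surface, write_surface)
from .inference import InferenceConfig, extract_common_trend, fit, predict_missing
from .model import (ModelSpec, SmoothEffect, deviance_explained,
                    enumerate_candidate_specs, screen_correlations, select_models)
from .simulate import (CovariateField, default_truth, shift_scenario,
                       simulate_covariates, simulate_joint_species, smooth_spatial_field)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "RunManifest", "run_pipeline", "classify_relationship",
           "demo_config"]


@dataclass
class RunConfig:
    """Validated configuration for one pipeline run."""

    seed: int = 0
    output_dir: str = "overlapshift_run"
    n_rows: int = 24
    n_cols: int = 24
    cell_size_km: float = 7.0
    origin_lonlat: tuple = (0.0, 56.0)
    max_depth_m: float = 500.0
    depth_mean_m: float = 250.0
    depth_sd_m: float = 180.0
    covariate_names: tuple = ("PEA", "NPP")
    covariate_range_cells: float = 8.0
    covariate_correlation: list | None = None
    scenario_shifts: dict = field(default_factory=lambda: {
        "PEA": {"mean_shift": 0.5, "pattern_shift_fraction": 0.3},
        "NPP": {"mean_shift": -0.3, "pattern_shift_fraction": 0.3},
    })
    season: str = "summer"
    species_pair: tuple = ("predator", "prey")
    hurdle_species: tuple = ("prey",)
    truth_delta_2: float = 1.0
    truth_z_sd: float = 0.6
    truth_het_sd: float = 0.05
    species_files: dict | None = None       # species -> CSV path (skip simulation)
    covariate_files: dict | None = None     # scenario -> {name -> CSV path}
    correlation_threshold: float = 0.5
    max_set_size: int = 2
    second_best_delta: float = 2.0
    decisive_delta: float = 5.0
    smooth_order: int = 2
    n_bins: int = 25
    contiguity: str = "queen"
    max_opt_evals: int = 60
    n_samples: int = 200
    estimate_hyperparameter_uncertainty: bool = False
    z_crit: float = 1.96
    floor_quantile: float = 0.05
    winds: int = 8

    def __post_init__(self):
        if self.n_rows < 2 or self.n_cols < 2:
            raise ValueError("grid must be at least 2x2")
        if len(self.species_pair) != 2:
            raise ValueError("species_pair must name exactly two species")
        if not self.covariate_names:
            raise ValueError("at least one covariate is required")
        if not 0 < self.correlation_threshold <= 1:
            raise ValueError("correlation_threshold must lie in (0, 1]")
        self.origin_lonlat = tuple(self.origin_lonlat)
        self.covariate_names = tuple(self.covariate_names)
        self.species_pair = tuple(self.species_pair)
        self.hurdle_species = tuple(self.hurdle_species)
        if self.species_files is not None or self.covariate_files is not None:
            if self.species_files is None or self.covariate_files is None:
                raise ValueError("provide both species_files and covariate_files "
                                 "to run on loaded data")
            for scen in ("present", "future"):
                if scen not in self.covariate_files:
                    raise ValueError(f"covariate_files missing scenario {scen!r}")

    @staticmethod
    def from_yaml(path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return RunConfig.from_dict(raw)

    @staticmethod
    def from_dict(raw: dict) -> "RunConfig":
        known = set(RunConfig.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return RunConfig(**raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["origin_lonlat"] = list(self.origin_lonlat)
        d["covariate_names"] = list(self.covariate_names)
        d["species_pair"] = list(self.species_pair)
        d["hurdle_species"] = list(self.hurdle_species)
        return d

    @property
    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class RunManifest:
    config_hash: str
    package_version: str
    seed: int
    stage_seconds: dict
    warnings: list
    files: list

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)


def demo_config(seed: int = 0, output_dir: str = "overlapshift_demo",
                n_rows: int = 24, n_cols: int = 24, **overrides) -> RunConfig:
    """The packaged synthetic demonstration configuration."""
    return RunConfig(seed=seed, output_dir=output_dir,
                     n_rows=n_rows, n_cols=n_cols, **overrides)


def classify_relationship(smooth: SmoothEffect, flat_tol: float = 1e-3,
                          tol_fraction: float = 0.1) -> str:
    """Classify a fitted smooth's shape: pos / neg / opt / asm / none.

    Operates on the posterior-mean curve.  Flat curves (range below
    ``flat_tol``) are "none"; an interior maximum exceeding both endpoints by
    ``tol_fraction`` of the range is "opt"; monotone curves whose terminal
    slope falls below 10% of the maximum slope are asymptotic ("asm");
    otherwise monotone curves are "pos"/"neg" and non-monotone ones fall back
    to the sign of the net change.
    """
    f = np.asarray(smooth.mean, float)
    if f.size < 5:
        raise ValueError("classification needs a smooth with at least 5 bins")
    rng_f = float(f.max() - f.min())
    if rng_f < flat_tol:
        return "none"
    tol = tol_fraction * rng_f
    imax = int(np.argmax(f))
    if 0 < imax < f.size - 1 and f[imax] > f[0] + tol and f[imax] > f[-1] + tol:
        return "opt"
    diffs = np.diff(f)
    drawdown_inc = float(np.max(np.maximum.accumulate(f) - f))
    drawdown_dec = float(np.max(f - np.minimum.accumulate(f)))
    max_slope = float(np.max(np.abs(diffs)))
    terminal_slope = float(np.mean(np.abs(diffs[-2:])))
    if drawdown_inc <= tol:        # monotone increasing
        return "asm" if terminal_slope < 0.1 * max_slope else "pos"
    if drawdown_dec <= tol:        # monotone decreasing
        return "asm" if terminal_slope < 0.1 * max_slope else "neg"
    return "pos" if f[-1] >= f[0] else "neg"


# ---------------------------------------------------------------------------
# pipeline stages
# ---------------------------------------------------------------------------

def _derive_seed(root: int, stage: str) -> int:
    h = hashlib.sha256(f"{root}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


class _StageRunner:
    def __init__(self, outdir: Path):
        self.outdir = outdir
        self.times: dict[str, float] = {}
        self.warnings: list[str] = []
        self.files: list[str] = []

    def run(self, name, fn):
        t0 = time.perf_counter()
        try:
            result = fn()
        except Exception as exc:
            failed = self.outdir / "failed"
            failed.mkdir(parents=True, exist_ok=True)
            for item in list(self.outdir.iterdir()):
                if item.name != "failed":
                    shutil.move(str(item), str(failed / item.name))
            raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") from exc
        self.times[name] = round(time.perf_counter() - t0, 3)
        return result

    def save_csv(self, df: pd.DataFrame, name: str):
        path = self.outdir / name
        df.to_csv(path, index=False, float_format="%.17g")
        self.files.append(name)


def run_pipeline(config: RunConfig) -> RunManifest:
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    runner = _StageRunner(outdir)
    inf_cfg = InferenceConfig(
        seed=_derive_seed(config.seed, "inference"),
        contiguity=config.contiguity, n_bins=config.n_bins,
        max_opt_evals=config.max_opt_evals, n_samples=config.n_samples,
        estimate_hyperparameter_uncertainty=config.estimate_hyperparameter_uncertainty,
    )
    sp1, sp2 = config.species_pair

    # -- stage: grid -----------------------------------------------------
    def stage_grid():
        n = config.n_rows * config.n_cols
        full = build_grid(config.n_rows, config.n_cols, config.origin_lonlat,
                          config.cell_size_km, depth_field=np.full(n, 100.0))
        g = smooth_spatial_field(full, range_cells=6.0, sd=1.0,
                                 seed=_derive_seed(config.seed, "depth"))
        depth = np.clip(config.depth_mean_m + config.depth_sd_m * g, 1.0, None)
        grid = build_grid(config.n_rows, config.n_cols, config.origin_lonlat,
                          config.cell_size_km, depth_field=depth)
        grid = apply_depth_mask(grid, config.max_depth_m)
        adjacency = build_adjacency(grid, config.contiguity)
        if adjacency.isolated.size:
            runner.warnings.append(
                f"{adjacency.isolated.size} isolated cells retained with degree 0")
        return grid, adjacency

    grid, adjacency = runner.run("grid", stage_grid)

    # -- stage: data -----------------------------------------------------
    def stage_data():
        if config.species_files is not None:
            covs = {}
            for scen, files in config.covariate_files.items():
                covs[scen] = {}
                for name, path in files.items():
                    if not Path(path).exists():
                        raise FileNotFoundError(f"missing covariate file: {path}")
                    surf = read_surface(path, grid, name=name, scenario=scen)
                    covs[scen][name] = CovariateField(
                        name=name, season=config.season, scenario=scen,
                        grid=grid, values=surf.values)
            species = {}
            for name, path in config.species_files.items():
                if not Path(path).exists():
                    raise FileNotFoundError(f"missing species file: {path}")
                fam = "hurdle-gamma" if name in config.hurdle_species else "gamma"
                species[name] = read_surface(path, grid, family=fam, name=name)
            return covs, species, None
        corr = (np.asarray(config.covariate_correlation, float)
                if config.covariate_correlation is not None else None)
        present = simulate_covariates(
            grid, config.covariate_names, correlation=corr,
            range_cells=config.covariate_range_cells,
            seed=_derive_seed(config.seed, "covariates"), season=config.season)
        present_map = {f.name: f for f in present}
        future_map = {}
        for name, f in present_map.items():
            shift = config.scenario_shifts.get(name, {})
            future_map[name] = shift_scenario(
                f, mean_shift=shift.get("mean_shift", 0.0),
                pattern_shift_fraction=shift.get("pattern_shift_fraction", 0.0),
                seed=_derive_seed(config.seed, f"shift:{name}"),
                range_cells=config.covariate_range_cells)
        truth = default_truth(
            grid, covariate_names=config.covariate_names,
            species=config.species_pair, hurdle_species=config.hurdle_species,
            delta_2=config.truth_delta_2, z_sd=config.truth_z_sd,
            het_sd=config.truth_het_sd, seed=_derive_seed(config.seed, "truth"))
        species = simulate_joint_species(
            grid, present_map, truth, seed=_derive_seed(config.seed, "species"))
        for name, surf in species.items():
            write_surface(surf, outdir / f"species_{name}.csv")
            runner.files.append(f"species_{name}.csv")
        truth_payload = {
            "intercepts": truth.intercepts,
            "occupancy_intercepts": truth.occupancy_intercepts,
            "delta": truth.delta, "het_sd": truth.het_sd,
            "shapes": truth.shapes, "seed": truth.seed,
            "z": truth.z.tolist(),
        }
        with open(outdir / "truth.json", "w") as fh:
            json.dump(truth_payload, fh)
        runner.files.append("truth.json")
        return {"present": present_map, "future": future_map}, species, truth

    covariates, species_surfaces, truth = runner.run("data", stage_data)
    present_cov = covariates["present"]
    future_cov = covariates["future"]
    cov_values = {k: v.values for k, v in present_cov.items()}

    # -- stage: screen + enumerate --------------------------------------
    def stage_screen():
        corr = screen_correlations(cov_values)
        runner.save_csv(corr.reset_index().rename(columns={"index": "covariate"}),
                        "covariate_correlations.csv")
        subsets = enumerate_candidate_specs(
            cov_values, max_set_size=config.max_set_size,
            correlation_threshold=config.correlation_threshold)
        return subsets

    subsets = runner.run("screen", stage_screen)

    # -- stage: single-species models ------------------------------------
    def stage_single():
        rows = []
        best_fits = {}
        for sname in config.species_pair:
            fam = species_surfaces[sname].family
            entries = []
            for subset in subsets:
                spec = ModelSpec(
                    species=(sname,), covariates=subset,
                    smooth_order={k: config.smooth_order for k in subset},
                    family={sname: fam})
                f = fit(spec, {sname: species_surfaces[sname]},
                        {k: present_cov[k] for k in subset}, inf_cfg,
                        adjacency=adjacency)
                if not f.converged:
                    runner.warnings.append(f"single fit {spec.label} flagged "
                                           "non-converged")
                entries.append((spec, f))
            table = select_models(
                [(s.label, s.covariates, fr.dic) for s, fr in entries],
                second_best_delta=config.second_best_delta,
                decisive_delta=config.decisive_delta)
            by_label = {s.label: (s, fr) for s, fr in entries}
            for _, row in table.iterrows():
                spec, fr = by_label[row["label"]]
                reported = row["is_best"] or row["report_second_best"]
                shapes = {k: classify_relationship(fr.smooths[k])
                          for k in spec.covariates} if reported else {}
                rows.append({
                    "species": sname, "model": row["label"],
                    "covariates": "+".join(spec.covariates),
                    "dic": row["dic"], "delta_dic": row["delta_dic"],
                    "rank": row["rank"], "is_best": row["is_best"],
                    "report_second_best": row["report_second_best"],
                    **{f"shape_{k}": shapes.get(k, "") for k in config.covariate_names},
                })
                if row["is_best"]:
                    best_fits[sname] = (spec, fr)
            for _, fr in entries:
                fr._backend.release()
        runner.save_csv(pd.DataFrame(rows), "single_model_selection.csv")
        return best_fits

    single_best = runner.run("single_models", stage_single)

    # -- stage: joint models ---------------------------------------------
    def stage_joint():
        entries = []
        fam = {s: species_surfaces[s].family for s in config.species_pair}
        for subset in subsets:
            spec = ModelSpec(
                species=config.species_pair, covariates=subset,
                smooth_order={k: config.smooth_order for k in subset},
                family=fam)
            f = fit(spec, {s: species_surfaces[s] for s in config.species_pair},
                    {k: present_cov[k] for k in subset}, inf_cfg,
                    adjacency=adjacency)
            if not f.converged:
                runner.warnings.append(f"joint fit {spec.label} flagged non-converged")
            entries.append((spec, f))
        table = select_models(
            [(s.label, s.covariates, fr.dic) for s, fr in entries],
            second_best_delta=config.second_best_delta,
            decisive_delta=config.decisive_delta)
        runner.save_csv(table.assign(
            covariates=table["covariates"].map(lambda c: "+".join(c))),
            "joint_model_selection.csv")
        best_label = table.loc[table["is_best"], "label"].iloc[0]
        best = next((s, fr) for s, fr in entries if s.label == best_label)
        for s, fr in entries:
            if s.label != best_label:
                fr._backend.release()
        bspec, bfit = best
        runner_up = float(table.loc[table["rank"] == 2, "delta_dic"].iloc[0])
        summary = {
            "label": bspec.label,
            "covariates": list(bspec.covariates),
            "hyperparameters": bfit.hyperparameters,
            "hyperparameter_sd": bfit.hyperparameter_sd,
            "intercepts": {k: list(v) for k, v in bfit.intercepts.items()},
            "occupancy_intercepts": {k: list(v) for k, v in
                                     bfit.occupancy_intercepts.items()},
            "deviance_mean": bfit.deviance_mean,
            "deviance_at_mean": bfit.deviance_at_mean,
            "p_d": bfit.p_d, "dic": bfit.dic,
            "delta_dic_runner_up": runner_up,
            "converged": bfit.converged,
        }
        with open(outdir / "best_joint_fit.json", "w") as fh:
            json.dump(summary, fh, indent=2, default=float)
        runner.files.append("best_joint_fit.json")
        runner.save_csv(extract_common_trend(bfit).to_frame(), "cst_fitted.csv")
        return best

    best_spec, best_fit = runner.run("joint_models", stage_joint)

    # -- stage: predict ---------------------------------------------------
    def stage_predict():
        preds = predict_missing(
            best_fit, {k: future_cov[k] for k in best_spec.covariates},
            seed=_derive_seed(config.seed, "predict"))
        for scen, per_species in preds.items():
            for sname, surf in per_species.items():
                df = surf.to_frame()
                runner.save_csv(df, f"predicted_{sname}_{scen}.csv")
        return preds

    predictions = runner.run("predict", stage_predict)

    # -- stage: common spatial trends (matched scenario refits) -----------
    def stage_cst():
        refit_seed = _derive_seed(config.seed, "cst_refit")
        fixed = dict(best_fit.hyperparameters)
        refit_cfg = replace(inf_cfg, seed=refit_seed, fixed_hyperparameters=fixed,
                            estimate_hyperparameter_uncertainty=False)
        csts = {}
        for scen in ("present", "future"):
            surfaces = {
                s: SpeciesSurface(grid=grid, values=predictions[scen][s].mean,
                                  family="gamma", scenario=scen, name=s)
                for s in config.species_pair
            }
            spec = ModelSpec(
                species=config.species_pair, covariates=best_spec.covariates,
                smooth_order=dict(best_spec.smooth_order),
                family={s: "gamma" for s in config.species_pair})
            cov_map = {k: (present_cov if scen == "present" else future_cov)[k]
                       for k in best_spec.covariates}
            refit = fit(spec, surfaces, cov_map, refit_cfg, adjacency=adjacency)
            if not refit.converged:
                runner.warnings.append(f"{scen} trend refit flagged non-converged")
            csts[scen] = extract_common_trend(refit)
            runner.save_csv(csts[scen].to_frame(), f"cst_{scen}.csv")
            refit._backend.release()
        return csts

    csts = runner.run("cst", stage_cst)

    # -- stage: cost reports ----------------------------------------------
    def stage_costs():
        rows = []
        for sname in config.species_pair:
            metrics = single_species_costs(
                predictions["present"][sname].mean,
                predictions["future"][sname].mean,
                grid, adjacency, z_crit=config.z_crit)
            rows.append({"species": sname, **metrics})
        runner.save_csv(pd.DataFrame(rows), "single_species_costs.csv")

        combined_present = sum(predictions["present"][s].mean
                               for s in config.species_pair)
        combined_future = sum(predictions["future"][s].mean
                              for s in config.species_pair)
        report = build_cost_report(
            pair="+".join(config.species_pair),
            present_density=combined_present, future_density=combined_future,
            present_cst=csts["present"], future_cst=csts["future"],
            grid=grid, adjacency=adjacency, z_crit=config.z_crit,
            floor_quantile=config.floor_quantile)
        runner.warnings.extend(report.warnings)
        reports_to_csv([report], outdir / "joint_cost_report.csv")
        runner.files.append("joint_cost_report.csv")
        return report

    cost_report = runner.run("costs", stage_costs)

    # -- stage: deviance explained ----------------------------------------
    def stage_deviance():
        rows = []
        dev_cfg = replace(inf_cfg, n_samples=100,
                          estimate_hyperparameter_uncertainty=False)
        for sname in config.species_pair:
            fam = species_surfaces[sname].family
            null_spec = ModelSpec(species=(sname,), covariates=(),
                                  family={sname: fam},
                                  include_spatial=False,
                                  include_heterogeneity=False)
            null_fit = fit(null_spec, {sname: species_surfaces[sname]}, {}, dev_cfg)
            null_dev = null_fit.deviance_at_mean
            for cov in config.covariate_names:
                spec = ModelSpec(species=(sname,), covariates=(cov,),
                                 smooth_order={cov: config.smooth_order},
                                 family={sname: fam},
                                 include_spatial=False,
                                 include_heterogeneity=False)
                f = fit(spec, {sname: species_surfaces[sname]},
                        {cov: present_cov[cov]}, dev_cfg)
                pct = deviance_explained(null_dev, f.deviance_at_mean)
                rows.append({"species": sname, "covariate": cov,
                             "null_deviance": null_dev,
                             "reduced_deviance": f.deviance_at_mean,
                             "pct_deviance_explained": pct,
                             "flagged_negative": pct < 0})
        runner.save_csv(pd.DataFrame(rows), "deviance_explained.csv")
        return rows

    runner.run("deviance", stage_deviance)
    best_fit._backend.release()

    from . import __version__
    manifest = RunManifest(
        config_hash=config.config_hash, package_version=__version__,
        seed=config.seed, stage_seconds=runner.times,
        warnings=runner.warnings, files=sorted(set(runner.files)),
    )
    manifest.to_json(outdir / "manifest.json")
    with open(outdir / "config.yaml", "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
    del cost_report, single_best, truth
    return manifest
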