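"""Config-driven orchestration of the full analysis.

Stage order mirrors the field workflow: simulate (or load) trials ->
assemble per-mission plot spectra -> grain-yield retrieval models per
sensor x mission -> biophysical-variable retrieval on the best mission ->
apply the winning models to every replicate (the remotely sensed
phenotypic trait table) -> quantitative genetics (LRT, heritability,
genetic correlation, selection response).

All randomness flows from one root seed split into named per-stage
streams; outputs are plain CSV plus a JSON manifest with file hashes, so
two runs with the same config are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from . import quantgen as qg
from .config import RunConfig
from .metrics import EvalReport
from .retrieval import (apply_model, build_dataset, fit_nonparametric,
                        gpr_uncertainty_summary, search_parametric,
                        split_data)
from .sensors import get_sensor
from .simulate import (TrialDesign, default_genetic_config, forward_reflectance,
                       make_soil_samples, simulate_trial)
from .tables import (plots_to_frame, read_plot_table, read_spectra_table,
                     spectra_to_frame, write_plot_table, write_spectra_table)

log = logging.getLogger(__name__)

STAGES = ("simulate", "spectra", "gy_models", "biophysical", "apply",
          "quantgen")

POOLED = "Pooled"


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


class PipelineRun:
    """Stateful runner: stages communicate through CSV files in outdir."""

    def __init__(self, config: RunConfig):
        self.config = config
        self.outdir = Path(config.outdir)
        self.outdir.mkdir(parents=True, exist_ok=True)
        self.manifest: dict = {
            "config": config.to_dict(),
            "stages": {},
            "warnings": [],
        }

    # -- helpers ----------------------------------------------------------
    def _path(self, name: str) -> Path:
        return self.outdir / name

    def _record(self, stage: str, files: list[Path], t0: float) -> None:
        self.manifest["stages"][stage] = {
            "seconds": round(time.time() - t0, 2),
            "outputs": [{"file": f.name, "sha256": _sha256(f)}
                        for f in files],
        }

    def _need(self, name: str, stage: str) -> Path:
        p = self._path(name)
        if not p.exists():
            raise FileNotFoundError(
                f"stage {stage!r} needs upstream artifact {p}; run the "
                "producing stage first"
            )
        return p

    # -- stages -----------------------------------------------------------
    def stage_simulate(self) -> list[Path]:
        cfg = self.config
        gconf = default_genetic_config()
        seed = cfg.stage_seed("simulate")
        plots = []
        for i, trial in enumerate(cfg.trials):
            design = TrialDesign(trial.trial_id, trial.n_genotypes,
                                 trial.n_replicates)
            plots.extend(simulate_trial(design, gconf, seed + i))
        df = plots_to_frame(plots)
        out = self._path("plots.csv")
        write_plot_table(df, out)
        return [out]

    def stage_spectra(self) -> list[Path]:
        cfg = self.config
        from .tables import frame_to_plots
        plots = frame_to_plots(read_plot_table(self._need("plots.csv",
                                                          "spectra")))
        files = []
        for m in cfg.missions:
            seed = cfg.stage_seed(f"spectra:{m.id}")
            samples = forward_reflectance(
                plots, m.sensor, noise_sd=m.noise_sd, seed=seed,
                mission=m.id, fcover_scale=m.fcover_scale)
            samples += make_soil_samples(
                cfg.n_soil, m.sensor, noise_sd=cfg.soil_noise_sd,
                seed=seed + 1, mission=m.id)
            out = self._path(f"spectra_{m.id}.csv")
            write_spectra_table(spectra_to_frame(samples), out)
            files.append(out)
        return files

    def stage_gy_models(self) -> list[Path]:
        """Grain-yield retrieval per mission: parametric search + ML methods.

        The same random train/validation allocation is reused for every
        model within one mission.  The winning (mission, model) pair is
        chosen by cross-validated nRMSE, so the validation third stays out
        of all selection decisions.
        """
        cfg = self.config
        plots = read_plot_table(self._need("plots.csv", "gy_models"))
        rows = []
        best = None   # (cv_nrmse, mission_id, kind, label)
        for m in cfg.missions:
            spectra = read_spectra_table(
                self._need(f"spectra_{m.id}.csv", "gy_models"))
            sensor = get_sensor(m.sensor)
            data = build_dataset(spectra, plots, "GY")
            split = split_data(len(data), cfg.split_fraction,
                               cfg.stage_seed("split"))
            ranked = search_parametric(
                data, "GY", sensor, split,
                families=cfg.parametric_families,
                k=cfg.cv_folds, seed=cfg.stage_seed(f"cv:{m.id}"))
            par = ranked[0]
            rows.append(self._model_row(m, "parametric", par.label,
                                        par.cv, par.validation))
            if best is None or par.cv.nrmse < best[0]:
                best = (par.cv.nrmse, m.id, "parametric", par.label)
            for method in cfg.ml_methods:
                fit = fit_nonparametric(
                    data, "GY", sensor, split, method,
                    k=cfg.cv_folds, seed=cfg.stage_seed(f"cv:{m.id}"))
                fit.validation = (fit.validation if fit.validation else None)
                rows.append(self._model_row(m, "nonparametric", fit.label,
                                            fit.cv, fit.validation))
                if fit.cv.nrmse < best[0]:
                    best = (fit.cv.nrmse, m.id, "nonparametric", fit.label)
        table = pd.DataFrame(rows)
        out = self._path("gy_model_comparison.csv")
        table.to_csv(out, index=False)
        choice = {"mission": best[1], "kind": best[2], "model": best[3],
                  "cv_nrmse": best[0]}
        choice_path = self._path("best_gy_model.json")
        choice_path.write_text(json.dumps(choice, indent=2))
        return [out, choice_path]

    @staticmethod
    def _model_row(mission, kind: str, label: str, cv: EvalReport,
                   val: EvalReport | None) -> dict:
        row = {"mission": mission.id, "sensor": mission.sensor,
               "stage": mission.stage, "kind": kind, "model": label}
        row.update(cv.as_dict("cv_"))
        if val is not None:
            row.update(val.as_dict("val_"))
        return row

    def stage_biophysical(self) -> list[Path]:
        """Retrieval models for LAI/fAPAR/fCover/LCC on the best mission.

        Ground truth for these variables exists only on the designated
        measurement replicates (default 1 and 2), so training/validation
        uses those plots plus the soil samples.
        """
        cfg = self.config
        with open(self._need("best_gy_model.json", "biophysical")) as fh:
            mission_id = json.load(fh)["mission"]
        mission = next(m for m in cfg.missions if m.id == mission_id)
        sensor = get_sensor(mission.sensor)
        plots = read_plot_table(self._need("plots.csv", "biophysical"))
        spectra = read_spectra_table(
            self._need(f"spectra_{mission_id}.csv", "biophysical"))
        measured = plots[plots["replicate"].isin(cfg.biophysical_replicates)]
        keep = spectra["is_soil"].astype(bool) | spectra["plot_id"].isin(
            measured["plot_id"])
        sub = spectra[keep].reset_index(drop=True)

        rows, choices = [], {}
        for trait in cfg.biophysical_traits:
            data = build_dataset(sub, plots, trait)
            split = split_data(len(data), cfg.split_fraction,
                               cfg.stage_seed("split-bio"))
            best_fit = None
            for method in cfg.ml_methods:
                fit = fit_nonparametric(
                    data, trait, sensor, split, method,
                    k=cfg.cv_folds, seed=cfg.stage_seed(f"cv-bio:{trait}"))
                row = {"mission": mission_id, "trait": trait,
                       "model": fit.label}
                row.update(fit.cv.as_dict("cv_"))
                row.update(fit.validation.as_dict("val_"))
                if fit.method == "gpr":
                    row["val_uncertainty_pct"] = gpr_uncertainty_summary(
                        fit, data.iloc[split.val_idx])
                rows.append(row)
                if best_fit is None or fit.cv.nrmse < best_fit.cv.nrmse:
                    best_fit = fit
            choices[trait] = {"model": best_fit.label,
                              "params": {k: (None if v is None else v)
                                         for k, v in best_fit.params.items()},
                              "cv_nrmse": best_fit.cv.nrmse}
            self._bio_fits = getattr(self, "_bio_fits", {})
            self._bio_fits[trait] = best_fit
        table = pd.DataFrame(rows)
        out = self._path("biophysical_models.csv")
        table.to_csv(out, index=False)
        choice_path = self._path("best_biophysical_models.json")
        choice_path.write_text(json.dumps(
            {"mission": mission_id, "models": choices}, indent=2, default=str))
        return [out, choice_path]

    def stage_apply(self) -> list[Path]:
        """Apply the winning biophysical models to all four replicates."""
        cfg = self.config
        with open(self._need("best_biophysical_models.json", "apply")) as fh:
            mission_id = json.load(fh)["mission"]
        plots = read_plot_table(self._need("plots.csv", "apply"))
        spectra = read_spectra_table(
            self._need(f"spectra_{mission_id}.csv", "apply"))
        veg = spectra[~spectra["is_soil"].astype(bool)].reset_index(drop=True)
        if not hasattr(self, "_bio_fits"):
            # stage run in isolation: refit from the persisted stage inputs
            self.stage_biophysical()
        rspt = plots[["plot_id", "trial_id", "genotype_id",
                      "replicate"]].copy()
        for trait, fit in self._bio_fits.items():
            pred = apply_model(fit, veg)
            rspt = rspt.merge(pred[["plot_id", trait]], on="plot_id")
        out = self._path("rspt.csv")
        rspt.to_csv(out, index=False)
        return [out]

    def stage_quantgen(self) -> list[Path]:
        """Variance components, H2, r_G with yield, and selection response.

        Measured traits (grain yield "MGY" and ground NDVI) come from the
        plot table; the four biophysical traits come from the retrieved
        RSPT table.  Analyses run per trial and pooled (trial and
        replicate-within-trial fixed).
        """
        cfg = self.config
        plots = read_plot_table(self._need("plots.csv", "quantgen"))
        rspt = pd.read_csv(self._need("rspt.csv", "quantgen"))
        merged = plots[["plot_id", "trial_id", "genotype_id", "replicate",
                        "GY", "NDVI"]].rename(columns={"GY": "MGY"})
        merged = merged.merge(
            rspt[["plot_id"] + cfg.biophysical_traits], on="plot_id")
        traits = ["MGY", "NDVI"] + list(cfg.biophysical_traits)
        trials = sorted(merged["trial_id"].unique())

        def obs_for(trait: str, trial: str | None):
            if trial is None:
                return [qg.TraitObservations.from_frame(
                    merged[merged["trial_id"] == t], trait, trial=t)
                    for t in trials]
            return qg.TraitObservations.from_frame(
                merged[merged["trial_id"] == trial], trait, trial=trial)

        groups: list[str | None] = [*trials, None]
        label = lambda t: POOLED if t is None else t

        lrt_rows, h2_rows, fits = [], [], {}
        for grp in groups:
            lrt_row = {"group": label(grp)}
            h2_row = {"group": label(grp)}
            for trait in traits:
                obs = obs_for(trait, grp)
                stat, p = qg.lrt_genotype(obs)
                lrt_row[trait] = stat
                lrt_row[f"{trait}_p"] = p
                vc = qg.fit_one_way_mixed(obs)
                fits[(label(grp), trait)] = vc
                h2_row[trait] = qg.heritability(
                    vc, cfg.heritability_basis).value
            lrt_rows.append(lrt_row)
            h2_rows.append(h2_row)

        rg_rows = []
        for grp in groups:
            row = {"group": label(grp)}
            for trait in traits[1:]:
                try:
                    res = qg.genetic_correlation(obs_for(trait, grp),
                                                 obs_for("MGY", grp))
                    row[trait] = res.r_g
                    row[f"{trait}_p"] = res.p_value
                    if res.out_of_range:
                        self.manifest["warnings"].append(
                            f"|r_G|>1 for {trait} in {label(grp)}")
                except ValueError as exc:
                    row[trait] = np.nan
                    self.manifest["warnings"].append(str(exc))
            rg_rows.append(row)

        basis = cfg.heritability_basis
        sel_rows = []
        vc_gy = fits[(POOLED, "MGY")]
        h2_gy = qg.heritability(vc_gy, basis).value
        r_gy = qg.selection_response(h2_gy, vc_gy.sigma_g)
        sel_rows.append({"parameter": "R", "MGY": r_gy})
        cr_row, eff_row = {"parameter": "CR"}, {"parameter": "CR_over_R"}
        r_row = {"parameter": "R", "MGY": r_gy}
        pooled_rg = {r["group"]: r for r in rg_rows}[POOLED]
        for trait in traits[1:]:
            vc = fits[(POOLED, trait)]
            h2 = qg.heritability(vc, basis).value
            r_row[trait] = qg.selection_response(h2, vc.sigma_g)
            cr = qg.correlated_response(h2, pooled_rg[trait], vc_gy.sigma_g)
            cr_row[trait] = cr
            eff_row[trait] = qg.relative_efficiency(cr, r_gy)
        sel = pd.DataFrame([r_row, cr_row, eff_row])

        outputs = []
        for name, frame in (("lrt.csv", pd.DataFrame(lrt_rows)),
                            ("heritability.csv", pd.DataFrame(h2_rows)),
                            ("genetic_correlation.csv", pd.DataFrame(rg_rows)),
                            ("selection_response.csv", sel)):
            path = self._path(name)
            frame.to_csv(path, index=False)
            outputs.append(path)
        return outputs

    # -- driver -----------------------------------------------------------
    def run_stage(self, name: str) -> list[Path]:
        if name not in STAGES:
            raise ValueError(f"unknown stage {name!r}; stages are {STAGES}")
        t0 = time.time()
        log.info("stage %s: start", name)
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            files = getattr(self, f"stage_{name}")()
        for w in caught:
            self.manifest["warnings"].append(str(w.message))
        self._record(name, files, t0)
        log.info("stage %s: done in %.1fs", name,
                 self.manifest["stages"][name]["seconds"])
        return files

    def run_full(self) -> dict:
        for name in STAGES:
            try:
                self.run_stage(name)
            except Exception:
                self.manifest["failed_stage"] = name
                self._write_manifest()
                log.error("stage %s failed; partial manifest persisted", name)
                raise
        self._write_manifest()
        return self.manifest

    def _write_manifest(self) -> None:
        path = self._path("manifest.json")
        path.write_text(json.dumps(self.manifest, indent=2, default=str))


def run_full(config: RunConfig) -> dict:
    """Execute all stages in order; returns the run manifest."""
    return PipelineRun(config).run_full()


def run_stage(name: str, config: RunConfig) -> list[Path]:
    """Re-run a single stage against the cached upstream artifacts."""
    return PipelineRun(config).run_stage(name)
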