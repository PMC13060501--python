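"""Dataset and configuration I/O, plus the end-to-end analysis pipeline.

The observation table uses a NONMEM-style CSV schema (comma separator,
period decimal, UTF-8, mandatory header): ID, TIME, AMT, DOSE, DV, EVID.
EVID=1 rows are dosing records at TIME=0 with AMT in mg/kg; EVID=0 rows
are observations with DV in ug/mL. Times are hours, doses mg/kg and
concentrations ug/mL at every interface; missing values are not allowed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .design import COLUMNS, PKDataset, default_design, simulate_dataset
from .diagnostics import residual_table
from .estimation import FitResult, FitSettings, fit_model, likelihood_ratio
from .evaluation import bootstrap, vpc
from .nca import exposure_vs_dose
from .params import PopulationParameters
from .params import published_parameters

__all__ = ["read_dataset", "write_dataset", "RunConfig", "read_config",
           "write_config", "run_pipeline"]

log = logging.getLogger("poppk")


def read_dataset(path) -> PKDataset:
    """Read and validate a NONMEM-style CSV observation table.

    Schema violations are reported with 1-based data row numbers (header
    excluded): missing columns, non-numeric cells, missing DV on an
    observation row, or an observation preceding the dosing record.
    """
    raw = pd.read_csv(path, dtype=str, keep_default_na=False,
                      na_values=[""], skip_blank_lines=True)
    missing = [c for c in COLUMNS if c not in raw.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    table = pd.DataFrame(index=raw.index)
    for col in COLUMNS:
        vals = pd.to_numeric(raw[col], errors="coerce")
        bad = vals.isna() & raw[col].notna()
        if bad.any():
            row = int(bad.idxmax()) + 1
            raise ValueError(
                f"{path}: non-numeric value {raw[col][bad.idxmax()]!r} in "
                f"column {col} at data row {row}")
        table[col] = vals
    obs = table["EVID"] == 0
    if table.loc[obs, "DV"].isna().any():
        row = int(table.loc[obs, "DV"].isna().idxmax()) + 1
        raise ValueError(f"{path}: missing DV on observation row {row}")
    if table[COLUMNS].isna().any().any():
        row = int(table[COLUMNS].isna().any(axis=1).idxmax()) + 1
        raise ValueError(f"{path}: missing value at data row {row}")
    for sid, grp in table.groupby("ID", sort=False):
        doses = grp[grp["EVID"] == 1]
        if len(doses) == 0:
            row = int(grp.index[0]) + 1
            raise ValueError(f"{path}: subject {sid} has no dosing record "
                             f"(first seen at data row {row})")
        t_dose = doses["TIME"].min()
        early = grp[(grp["EVID"] == 0) & (grp["TIME"] < t_dose)]
        if len(early):
            row = int(early.index[0]) + 1
            raise ValueError(f"{path}: observation before dose for subject "
                             f"{sid} at data row {row}")
    return PKDataset(table, metadata={"source": str(path)})


def write_dataset(data: PKDataset, path) -> None:
    data.to_csv(path)


@dataclass
class RunConfig:
    """Pipeline configuration: every stochastic stage resolves its seed as
    ``seed + stage offset``, so one global seed reproduces the whole run."""

    seed: int = 1
    out: str = "poppk_run"
    dataset: str | None = None          # path; simulate if None
    parameters: dict = field(default_factory=lambda: published_parameters().to_dict())
    fit: dict = field(default_factory=dict)          # FitSettings overrides
    n_sim_vpc: int = 1000
    n_sim_npde: int = 1000
    B: int = 1000
    n_virtual: int = 1000
    dose_covariate: bool = True
    verbose: bool = False

    STAGE_OFFSETS = {"simulate": 0, "fit": 1, "diagnose": 2, "bootstrap": 3,
                     "vpc": 4, "nca": 5}

    def stage_seed(self, stage: str) -> int:
        return int(self.seed) + self.STAGE_OFFSETS[stage]

    def to_dict(self) -> dict:
        return {
            "seed": self.seed, "out": self.out, "dataset": self.dataset,
            "parameters": self.parameters, "fit": dict(self.fit),
            "n_sim_vpc": self.n_sim_vpc, "n_sim_npde": self.n_sim_npde,
            "B": self.B, "n_virtual": self.n_virtual,
            "dose_covariate": self.dose_covariate, "verbose": self.verbose,
        }

    def settings(self) -> FitSettings:
        return FitSettings(seed=self.stage_seed("fit"), **self.fit)

    def generative_params(self) -> PopulationParameters:
        return PopulationParameters.from_dict(self.parameters)


def read_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return RunConfig(**raw)


def write_config(config: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)


def write_fit(fit: FitResult, path) -> None:
    """Flat key-value table: parameter, estimate, RSE%, fixed flag."""
    frame = fit.params_frame()[["parameter", "estimate", "rse_pct"]].copy()
    frame["fixed"] = False
    extra = pd.DataFrame([
        {"parameter": "dose_median", "estimate": fit.params.dose_median,
         "rse_pct": np.nan, "fixed": True},
        {"parameter": "ofv", "estimate": fit.ofv, "rse_pct": np.nan,
         "fixed": True},
    ])
    pd.concat([frame, extra], ignore_index=True).to_csv(path, index=False)


def run_pipeline(config: RunConfig) -> Path:
    """Run simulate -> fit base -> fit final -> LRT -> diagnostics ->
    bootstrap -> VPC -> NCA, writing a deterministic artifact directory.

    Any stage failure halts the pipeline; artifacts already written are
    retained and run.log records the failing stage. Re-running with the
    same config reproduces every stochastic output bit-for-bit.
    """
    out = Path(config.out)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.DEBUG if config.verbose else logging.INFO)
    stage = "setup"
    try:
        write_config(config, out / "config.yaml")
        params = config.generative_params()
        log.info("seeds: %s", {s: config.stage_seed(s)
                               for s in config.STAGE_OFFSETS})

        stage = "simulate"
        if config.dataset:
            data = read_dataset(config.dataset)
            log.info("loaded dataset %s: %d subjects, %d observations",
                     config.dataset, data.n_subjects, data.n_obs)
        else:
            data = simulate_dataset(default_design(), params,
                                    seed=config.stage_seed("simulate"))
            log.info("simulated default design: %d subjects, %d observations",
                     data.n_subjects, data.n_obs)
        write_dataset(data, out / "dataset.csv")

        stage = "fit"
        settings = config.settings()
        fit_base = fit_model(data, with_dose_covariate=False, settings=settings)
        write_fit(fit_base, out / "fit_base.csv")
        log.info("base fit: OFV=%.3f converged=%s (restarts %s)",
                 fit_base.ofv, fit_base.converged, fit_base.restart_ofvs)
        fit_final = None
        if config.dose_covariate:
            fit_final = fit_model(data, with_dose_covariate=True,
                                  settings=settings)
            write_fit(fit_final, out / "fit_final.csv")
            log.info("final fit: OFV=%.3f converged=%s (restarts %s)",
                     fit_final.ofv, fit_final.converged, fit_final.restart_ofvs)
            delta, significant = likelihood_ratio(fit_base, fit_final)
            (out / "lrt.txt").write_text(
                f"delta_ofv = {delta:.4f}\nsignificant = {significant} "
                f"(cutoff 3.84, 1 df, p < 0.05)\n")
            log.info("LRT: delta OFV %.3f, significant=%s", delta, significant)
        best = fit_final if fit_final is not None else fit_base

        stage = "diagnose"
        res = residual_table(best.params, data, ebes=best.ebes,
                             n_sim=config.n_sim_npde,
                             seed=config.stage_seed("diagnose"))
        res.to_csv(out / "residuals.csv", index=False)
        log.info("diagnostics: %d residual rows", len(res))

        stage = "bootstrap"
        if config.B > 0:
            boot = bootstrap(data, B=config.B, seed=config.stage_seed("bootstrap"),
                             settings=settings,
                             with_dose_covariate=config.dose_covariate)
            boot.summary.to_csv(out / "bootstrap.csv", index=False)
            log.info("bootstrap: %d/%d successful", boot.n_successful, boot.B)
        else:
            log.info("bootstrap skipped (B=0)")

        stage = "vpc"
        vres = vpc(data, best.params, n_sim=config.n_sim_vpc,
                   seed=config.stage_seed("vpc"), stratify_by_dose=True)
        for stratum in vres.bands["stratum"].unique():
            vres.bands[vres.bands["stratum"] == stratum].to_csv(
                out / f"vpc_{stratum}.csv", index=False)
        log.info("vpc: inside-band fraction %.3f",
                 vres.inside_fraction("overall"))

        stage = "nca"
        nca_res = exposure_vs_dose(best.params, n_virtual=config.n_virtual,
                                   seed=config.stage_seed("nca"))
        nca_res.summary.to_csv(out / "nca.csv", index=False)
        log.info("nca: dose-normalised AUC medians %s",
                 nca_res.summary["dn_auc_median"].round(2).tolist())
    except Exception:
        log.exception("pipeline halted at stage %r", stage)
        raise
    finally:
        log.removeHandler(handler)
        handler.close()
    return out
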