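"""Simulation-based model evaluation: nonparametric bootstrap and VPC.

The bootstrap resamples whole animals with replacement, stratified by dose
group so every replicate keeps the design's dose balance, and refits the
model to each replicate. The visual predictive check simulates replicate
datasets under the exact original design (same animals, doses and sampling
times) and overlays the observations on the simulated 5th/50th/95th
percentile bands, overall and per dose group.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import PKDataset
from .diagnostics import simulate_observation_matrix
from .estimation import FitSettings, fit_model
from .likelihood import pack_dataset
from .params import PopulationParameters

__all__ = ["BootstrapResult", "VPCResult", "bootstrap", "vpc", "plot_vpc"]


@dataclass
class BootstrapResult:
    """Percentile summary and per-replicate estimates."""

    summary: pd.DataFrame          # parameter, median, ci_lo, ci_hi
    replicates: pd.DataFrame       # one row per successful replicate
    B: int
    n_successful: int
    n_failed: int

    def ci(self, name: str) -> tuple:
        row = self.summary.set_index("parameter").loc[name]
        return float(row["ci_lo"]), float(row["ci_hi"])


def _stratified_resample(data: PKDataset, rng: np.random.Generator) -> list:
    """Subject IDs resampled with replacement within each dose group."""
    dose_of = data.subject_dose()
    ids = []
    for dose, members in dose_of.groupby(dose_of):
        pool = members.index.to_numpy()
        ids.extend(rng.choice(pool, size=len(pool), replace=True).tolist())
    return ids


def bootstrap(data: PKDataset, B: int = 1000, seed: int = 0,
              settings: FitSettings | None = None,
              with_dose_covariate: bool = True,
              init: PopulationParameters | None = None,
              resampler=None) -> BootstrapResult:
    """Nonparametric bootstrap of the model fit.

    Parameters
    ----------
    B : number of replicates (the study used 1000).
    resampler : optional callable ``(data, rng) -> list of subject IDs``
        replacing the stratified resampler (e.g. identity for checks).
    Failed replicate fits are logged, excluded and counted.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    settings = settings or FitSettings()
    resampler = resampler or _stratified_resample
    rng = np.random.default_rng(seed)
    rows = []
    n_failed = 0
    for b in range(B):
        ids = resampler(data, rng)
        sample = data.subset(ids, relabel=True)
        try:
            fit = fit_model(sample, with_dose_covariate=with_dose_covariate,
                            init=init,
                            settings=settings.replace(seed=settings.seed + b))
            est = fit.estimates()
            if not all(np.isfinite(v) for v in est.values()):
                raise FloatingPointError("non-finite estimate")
            est["replicate"] = b
            est["ofv"] = fit.ofv
            rows.append(est)
        except Exception as exc:   # noqa: BLE001 — any replicate failure counts
            n_failed += 1
            warnings.warn(f"bootstrap replicate {b} failed: {exc}")
    reps = pd.DataFrame(rows)
    params = [c for c in reps.columns if c not in ("replicate", "ofv")]
    summary = pd.DataFrame({
        "parameter": params,
        "median": [reps[p].median() for p in params],
        "ci_lo": [reps[p].quantile(0.025) for p in params],
        "ci_hi": [reps[p].quantile(0.975) for p in params],
        "n_successful": len(reps),
    })
    return BootstrapResult(summary=summary, replicates=reps, B=B,
                           n_successful=len(reps), n_failed=n_failed)


@dataclass
class VPCResult:
    """Percentile bands per stratum and time bin, with observed overlay."""

    bands: pd.DataFrame       # stratum, time, p5, p50, p95, n_obs, n_inside
    observed: pd.DataFrame    # stratum, time, dv
    n_sim: int

    def inside_fraction(self, stratum: str = "overall") -> float:
        sub = self.bands[self.bands["stratum"] == stratum]
        return float(sub["n_inside"].sum() / sub["n_obs"].sum())


def vpc(data: PKDataset, params: PopulationParameters, n_sim: int = 1000,
        seed: int = 0, stratify_by_dose: bool = True,
        bins: list | None = None) -> VPCResult:
    """Visual predictive check under the exact study design.

    Simulates ``n_sim`` replicate datasets (same subjects, doses and
    times), then per stratum and time bin reports the simulated 5th, 50th
    and 95th percentiles of the observation distribution with the observed
    concentrations overlaid. Bins default to the nominal design times; an
    explicit bin-edge list may be given, and empty bins are merged into
    their left neighbour with a warning.
    """
    if n_sim < 100:
        raise ValueError("vpc needs n_sim >= 100")
    pack = pack_dataset(data)
    y_sim = simulate_observation_matrix(params, pack, n_sim, seed)
    obs_mask = pack.mask > 0
    rows = pd.DataFrame({
        "dose": np.repeat(pack.dose, obs_mask.sum(axis=1)),
        "time": pack.t[obs_mask],
        "dv": pack.y[obs_mask],
    })
    sims = y_sim.transpose(0, 2, 1)[obs_mask]  # (n_obs_total, n_sim)

    strata = [("overall", np.ones(len(rows), dtype=bool))]
    if stratify_by_dose:
        strata += [(f"dose_{d:g}", (rows["dose"] == d).to_numpy())
                   for d in np.sort(rows["dose"].unique())]

    def bin_labels(times: np.ndarray) -> np.ndarray:
        if bins is None:
            return times
        edges = np.asarray(bins, dtype=float)
        idx = np.clip(np.digitize(times, edges) - 1, 0, len(edges) - 2)
        counts = np.bincount(idx, minlength=len(edges) - 1)
        for j in np.flatnonzero(counts == 0):
            if j > 0:
                warnings.warn(f"empty time bin {j}; merged with left neighbour")
        centers = 0.5 * (edges[:-1] + edges[1:])
        return centers[idx]

    band_rows = []
    obs_rows = []
    for label, sel in strata:
        t_sel = rows.loc[sel, "time"].to_numpy()
        dv_sel = rows.loc[sel, "dv"].to_numpy()
        sim_sel = sims[sel]
        labels = bin_labels(t_sel)
        for tb in np.unique(labels):
            in_bin = labels == tb
            pooled = sim_sel[in_bin].ravel()
            p5, p50, p95 = np.percentile(pooled, [5, 50, 95])
            dv_bin = dv_sel[in_bin]
            band_rows.append({
                "stratum": label, "time": float(tb),
                "p5": p5, "p50": p50, "p95": p95,
                "n_obs": int(in_bin.sum()),
                "n_inside": int(np.sum((dv_bin >= p5) & (dv_bin <= p95))),
            })
        obs_rows.append(pd.DataFrame({"stratum": label, "time": t_sel,
                                      "dv": dv_sel}))
    bands = pd.DataFrame(band_rows)
    assert np.all((bands["p5"] <= bands["p50"]) & (bands["p50"] <= bands["p95"]))
    return VPCResult(bands=bands, observed=pd.concat(obs_rows, ignore_index=True),
                     n_sim=n_sim)


def plot_vpc(result: VPCResult, stratum: str = "overall", log_scale: bool = True):
    """Median (solid) and 5th/95th (dashed) simulated percentiles with
    observations as points, one panel per call."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    bands = result.bands[result.bands["stratum"] == stratum].sort_values("time")
    obs = result.observed[result.observed["stratum"] == stratum]
    fig, ax = plt.subplots(figsize=(5.5, 4))
    ax.plot(bands["time"], bands["p50"], "-", color="k", label="simulated median")
    ax.plot(bands["time"], bands["p5"], "--", color="k", label="5th/95th")
    ax.plot(bands["time"], bands["p95"], "--", color="k")
    ax.plot(obs["time"], obs["dv"], "o", color="tab:blue", ms=4, alpha=0.7,
            label="observed")
    if log_scale:
        ax.set_yscale("log")
    ax.set_xlabel("time (h)")
    ax.set_ylabel("concentration (ug/mL)")
    ax.set_title(f"VPC — {stratum} (n_sim={result.n_sim})")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    return fig
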