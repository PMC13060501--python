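"""Per-observation residual diagnostics: PWRES, IWRES and NPDE.

Population-weighted residuals and NPDE are computed by Monte-Carlo
simulation of the full model (lognormal IIV plus residual error) rather
than first-order linearisation: per subject the simulated mean and
covariance of the observation vector give a Cholesky decorrelation
``L^-1 (y - mean)``. NPDE follows the rank-based construction: observed
and simulated vectors are decorrelated with the same mean and Cholesky
factor, and each observation's decorrelated value is ranked among the
simulated ones before mapping through the standard-normal quantile.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.linalg import solve_triangular
from scipy.stats import norm

from .design import PKDataset
from .estimation import EBESet, compute_ebes
from .likelihood import Pack, pack_dataset
from .params import DOSE_TO_UG, PopulationParameters

__all__ = ["simulate_observation_matrix", "population_residuals",
           "individual_residuals", "npde", "residual_table", "plot_residuals"]


def simulate_observation_matrix(params: PopulationParameters, pack: Pack,
                                n_sim: int, seed: int) -> np.ndarray:
    """Simulate ``n_sim`` observation vectors per subject, (n, n_sim, m).

    Same generative model as the dataset simulator, including the
    redraw-on-negative rule, so diagnostics are calibrated against the
    generator. Padded cells hold the (positive) structural prediction at
    t = 0 padding times and are never read.
    """
    if seed is None:
        raise ValueError("a seed is required for simulation-based diagnostics")
    rng = np.random.default_rng(seed)
    n, m = pack.y.shape
    eta_cl = rng.normal(0.0, params.omega_cl, size=(n, n_sim))
    eta_v = rng.normal(0.0, params.omega_v, size=(n, n_sim))
    cl_typ = params.cl_pop * (pack.dose / params.dose_median) ** params.beta
    cl = cl_typ[:, None] * np.exp(eta_cl)
    v = params.v_pop * np.exp(eta_v)
    k = cl / v
    f = (pack.dose[:, None] * DOSE_TO_UG / v)[:, :, None] \
        * np.exp(-k[:, :, None] * pack.t[:, None, :])
    eps = rng.standard_normal(f.shape)
    y = f * (1.0 + params.error_b * eps) + params.error_a * eps
    # redraw non-positive draws (proportional error can cross zero)
    for _ in range(200):
        bad = y <= 0
        if not bad.any():
            break
        eps = rng.standard_normal(int(bad.sum()))
        y[bad] = f[bad] * (1.0 + params.error_b * eps) + params.error_a * eps
    return y


def _per_subject_moments(y_sim: np.ndarray, mask_row: np.ndarray):
    """Simulated mean and covariance Cholesky factor for one subject."""
    obs_idx = np.flatnonzero(mask_row)
    sims = y_sim[:, obs_idx]                    # (n_sim, m_i)
    mean = sims.mean(axis=0)
    cov = np.cov(sims, rowvar=False).reshape(len(obs_idx), len(obs_idx))
    try:
        L = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "degenerate simulated covariance; increase n_sim") from exc
    return obs_idx, mean, L


def population_residuals(params: PopulationParameters, data: PKDataset | Pack,
                         n_sim: int = 1000, seed: int = 0,
                         y_sim: np.ndarray | None = None):
    """Population predictions and population-weighted residuals.

    Returns ``(ppred, pwres)`` as Series aligned with the observation rows.
    With no between-animal variability the decorrelation is analytic:
    PWRES = (y - f) / (a + b f).
    """
    pack = data if isinstance(data, Pack) else pack_dataset(data)
    if params.omega_cl == 0 and params.omega_v == 0:
        cl_typ = params.cl_pop * (pack.dose / params.dose_median) ** params.beta
        f = (pack.dose * DOSE_TO_UG / params.v_pop)[:, None] \
            * np.exp(-(cl_typ / params.v_pop)[:, None] * pack.t)
        sd = params.error_a + params.error_b * f
        if np.any((sd == 0) & (pack.mask > 0)):
            raise ZeroDivisionError("zero residual SD at a prediction")
        ppred_vals = f[pack.mask > 0]
        pwres_vals = ((pack.y - f) / sd)[pack.mask > 0]
        idx = pack.obs_rows
        return (pd.Series(ppred_vals, index=idx, name="PPRED"),
                pd.Series(pwres_vals, index=idx, name="PWRES"))
    if n_sim < 500:
        raise ValueError("population residuals need n_sim >= 500")
    if y_sim is None:
        y_sim = simulate_observation_matrix(params, pack, n_sim, seed)
    ppred = np.empty(len(pack.obs_rows))
    pwres = np.empty(len(pack.obs_rows))
    pos = 0
    for i in range(pack.n):
        obs_idx, mean, L = _per_subject_moments(y_sim[i], pack.mask[i])
        d = solve_triangular(L, pack.y[i, obs_idx] - mean, lower=True)
        mi = len(obs_idx)
        ppred[pos:pos + mi] = mean
        pwres[pos:pos + mi] = d
        pos += mi
    idx = pack.obs_rows
    return (pd.Series(ppred, index=idx, name="PPRED"),
            pd.Series(pwres, index=idx, name="PWRES"))


def individual_residuals(ebes: EBESet, data: PKDataset | Pack,
                         params: PopulationParameters) -> pd.Series:
    """IWRES = (y - IPRED) / (a + b * IPRED), aligned with observations."""
    pack = data if isinstance(data, Pack) else pack_dataset(data)
    ipred = ebes.ipred.loc[pack.obs_rows].to_numpy()
    sd = params.error_a + params.error_b * ipred
    if np.any(sd == 0):
        raise ZeroDivisionError("zero residual SD at an individual prediction")
    y = pack.y[pack.mask > 0]
    return pd.Series((y - ipred) / sd, index=pack.obs_rows, name="IWRES")


def npde(params: PopulationParameters, data: PKDataset | Pack,
         n_sim: int = 1000, seed: int = 0,
         y_sim: np.ndarray | None = None) -> pd.Series:
    """Normalized prediction distribution errors.

    Per subject, observed and simulated vectors are decorrelated with the
    simulated mean and Cholesky factor; the prediction discrepancy
    ``pde = (rank + 1/2) / (n_sim + 1)`` (ties get half weight, and the
    offset keeps pde off 0 and 1) maps through the standard-normal
    quantile. Under the true model the NPDE are approximately N(0, 1).
    """
    pack = data if isinstance(data, Pack) else pack_dataset(data)
    if n_sim < 1000 and y_sim is None:
        raise ValueError("npde needs n_sim >= 1000")
    if y_sim is None:
        y_sim = simulate_observation_matrix(params, pack, n_sim, seed)
    n_sim = y_sim.shape[1]
    out = np.empty(len(pack.obs_rows))
    pos = 0
    for i in range(pack.n):
        obs_idx, mean, L = _per_subject_moments(y_sim[i], pack.mask[i])
        d_obs = solve_triangular(L, pack.y[i, obs_idx] - mean, lower=True)
        d_sim = solve_triangular(L, (y_sim[i][:, obs_idx] - mean).T, lower=True)
        less = (d_sim < d_obs[:, None]).sum(axis=1)
        ties = (d_sim == d_obs[:, None]).sum(axis=1)
        pde = (less + 0.5 * ties + 0.5) / (n_sim + 1.0)
        mi = len(obs_idx)
        out[pos:pos + mi] = norm.ppf(pde)
        pos += mi
    return pd.Series(out, index=pack.obs_rows, name="NPDE")


def residual_table(params: PopulationParameters, data: PKDataset,
                   ebes: EBESet | None = None, n_sim: int = 1000,
                   seed: int = 0) -> pd.DataFrame:
    """Full per-observation diagnostic table.

    Columns: subject_id, time, observed, ppred, ipred, pwres, iwres, npde;
    one row per observation, aligned with the dataset's observation rows.
    """
    pack = pack_dataset(data)
    if ebes is None:
        ebes = compute_ebes(params, pack)
    y_sim = simulate_observation_matrix(params, pack, max(n_sim, 1000), seed)
    ppred, pwres = population_residuals(params, pack, n_sim=n_sim, seed=seed,
                                        y_sim=y_sim)
    iwres = individual_residuals(ebes, pack, params)
    np_de = npde(params, pack, n_sim=n_sim, seed=seed, y_sim=y_sim)
    obs = data.observations
    return pd.DataFrame({
        "subject_id": obs["ID"].to_numpy(),
        "time": obs["TIME"].to_numpy(),
        "observed": obs["DV"].to_numpy(),
        "ppred": ppred.loc[obs.index].to_numpy(),
        "ipred": ebes.ipred.loc[obs.index].to_numpy(),
        "pwres": pwres.loc[obs.index].to_numpy(),
        "iwres": iwres.loc[obs.index].to_numpy(),
        "npde": np_de.loc[obs.index].to_numpy(),
    }, index=obs.index)


def plot_residuals(table: pd.DataFrame, kind: str = "pwres"):
    """Residuals vs population prediction and vs time, with a zero line
    and a rolling-median smooth."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(9, 4))
    for ax, xcol, xlab in ((axes[0], "ppred", "population prediction (ug/mL)"),
                           (axes[1], "time", "time (h)")):
        x = table[xcol].to_numpy()
        y = table[kind].to_numpy()
        order = np.argsort(x)
        ax.plot(x, y, "o", ms=4, alpha=0.6)
        ax.axhline(0.0, color="k", lw=1)
        smooth = pd.Series(y[order]).rolling(15, center=True, min_periods=5).median()
        ax.plot(x[order], smooth, color="crimson", lw=1.5)
        ax.set_xlabel(xlab)
        ax.set_ylabel(kind.upper())
    fig.tight_layout()
    return fig
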