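"""Nonlinear mixed-effects estimation: Model and Results objects.

`OneCompartmentModel` holds a dataset and model configuration; `fit()`
maximises an adaptive Gauss-Hermite approximation of the marginal
likelihood over
(CL_pop, V_pop, [beta], omega_CL, omega_V, error params) and returns a
`FitResult` carrying estimates, the information matrix, relative standard
errors, empirical Bayes estimates and convergence metadata — the
statsmodels Model/Results idiom.

Fixed effects are estimated on the log scale and variability parameters on
the log-SD scale, which enforces positivity without bound constraints; the
dose-clearance exponent beta is unconstrained. Optimisation uses
Nelder-Mead with three restarts from jittered initial values (fixed jitter
seeds); the best OFV wins and a spread above one OFV unit between restarts
clears the convergence flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .design import PKDataset
from .likelihood import (Pack, agq_parts, marginal_neg2ll, pack_dataset,
                         find_modes)
from .model import individual_clearance, individual_parameter, predict_concentration
from .params import DOSE_TO_UG, PopulationParameters

__all__ = [
    "FitSettings", "EBESet", "FitResult", "OneCompartmentModel",
    "fit_model", "naive_initial_values", "compute_ebes", "eta_shrinkage",
    "compute_rse", "likelihood_ratio", "LRT_CUTOFF",
]

#: chi-square(1 df) critical value at p = 0.05 for nested-model comparison.
LRT_CUTOFF = 3.84

#: RSE acceptability thresholds (%): fixed effects / random-effect parameters.
RSE_LIMIT_FIXED = 30.0
RSE_LIMIT_RANDOM = 50.0

_FIXED_EFFECTS = ("cl_pop", "v_pop", "beta")


@dataclass(frozen=True)
class FitSettings:
    """Optimiser and likelihood-approximation settings.

    ``final_ofv`` selects how the reported OFV is computed after
    optimisation: ``"is"`` (seeded importance sampling, ``n_is_nodes``
    draws per subject) or ``"objective"`` (the adaptive Gauss-Hermite
    value the optimiser minimised, ``n_agq_nodes`` per dimension).
    """

    final_ofv: str = "is"
    n_is_nodes: int = 1000
    n_agq_nodes: int = 9
    seed: int = 0
    n_restarts: int = 3
    jitter_sd: float = 0.1
    maxiter: int = 900
    xatol: float = 1e-4
    fatol: float = 1e-4
    error_model: str = "proportional"   # "proportional" | "additive" | "combined"

    def __post_init__(self):
        if self.xatol <= 0 or self.fatol <= 0:
            raise ValueError("tolerances must be > 0")
        if self.final_ofv == "is" and self.n_is_nodes < 100:
            raise ValueError("final importance-sampling OFV needs >= 100 nodes")
        if self.error_model not in ("proportional", "additive", "combined"):
            raise ValueError(f"unknown error model {self.error_model!r}")

    def replace(self, **changes) -> "FitSettings":
        return replace(self, **changes)


@dataclass
class EBESet:
    """Posterior-mode random effects and individual predictions.

    ``table`` has one row per subject (ID, DOSE, eta_cl, eta_v, cl_i, v_i);
    ``ipred`` is indexed like the observation rows of the source dataset.
    """

    table: pd.DataFrame
    ipred: pd.Series

    def eta(self, which: str) -> np.ndarray:
        return self.table[f"eta_{which}"].to_numpy()


def compute_ebes(params: PopulationParameters, data: PKDataset | Pack) -> EBESet:
    """Empirical Bayes estimates: per-subject joint posterior modes.

    Maximises p(y_i | eta) p(eta) for each subject at the given population
    parameters (an omega of zero pins the corresponding eta at 0) and
    evaluates the individual predictions at the modes.
    """
    pack = data if isinstance(data, Pack) else pack_dataset(data)
    eta_full, _, _ = find_modes(pack, params)
    cl_i = individual_clearance(params, pack.dose, eta_full[:, 0])
    v_i = individual_parameter(params.v_pop, eta_full[:, 1])
    table = pd.DataFrame({
        "ID": pack.ids,
        "DOSE": pack.dose,
        "eta_cl": eta_full[:, 0],
        "eta_v": eta_full[:, 1],
        "cl_i": cl_i,
        "v_i": v_i,
    })
    k = cl_i / v_i
    f = (pack.dose * DOSE_TO_UG / v_i)[:, None] * np.exp(-k[:, None] * pack.t)
    vals = f[pack.mask > 0]
    ipred = pd.Series(vals, index=pack.obs_rows, name="IPRED")
    return EBESet(table=table, ipred=ipred)


def eta_shrinkage(ebes: EBESet | np.ndarray, omega: float,
                  which: str = "cl", method: str = "sd") -> float:
    """Eta-shrinkage in percent.

    ``method="sd"`` (default): ``100 * (1 - SD(eta_hat) / omega)``;
    ``method="var"``: ``100 * (1 - Var(eta_hat) / omega**2)``. Both
    approach 100 when the individual data carry no information and 0 when
    the EBEs recover the population spread.
    """
    if omega <= 0:
        raise ValueError("shrinkage undefined for omega <= 0")
    eta = ebes.eta(which) if isinstance(ebes, EBESet) else np.asarray(ebes, float)
    if eta.size < 2:
        raise ValueError("shrinkage needs at least two subjects")
    sd = float(np.std(eta, ddof=1))
    if method == "sd":
        return 100.0 * (1.0 - sd / omega)
    if method == "var":
        return 100.0 * (1.0 - (sd / omega) ** 2)
    raise ValueError(f"unknown shrinkage method {method!r}")


@dataclass
class FitResult:
    """Estimates, uncertainty and diagnostics from a fitted model."""

    params: PopulationParameters
    ofv: float
    ofv_objective: float
    param_names: tuple
    fim: np.ndarray | None          # information matrix on the estimation scale
    cov: np.ndarray | None          # 2 * FIM^-1 (estimation scale)
    se: dict | None                 # natural-scale standard errors
    rse: dict | None                # percent
    converged: bool
    n_subjects: int
    n_obs: int
    ebes: EBESet | None = None
    settings: FitSettings | None = None
    model: "OneCompartmentModel | None" = None
    restart_ofvs: tuple = ()
    n_fev: int = 0
    data_fingerprint: tuple | None = None

    @property
    def with_dose_covariate(self) -> bool:
        return "beta" in self.param_names

    @property
    def n_params(self) -> int:
        return len(self.param_names)

    def estimates(self) -> dict:
        d = self.params.to_dict()
        return {name: d[name] for name in self.param_names}

    def eta_shrinkage(self, which: str = "cl", method: str = "sd") -> float:
        omega = getattr(self.params, f"omega_{which}")
        return eta_shrinkage(self.ebes, omega, which=which, method=method)

    def params_frame(self) -> pd.DataFrame:
        rows = []
        est = self.estimates()
        for name in self.param_names:
            rse = self.rse.get(name) if self.rse else np.nan
            limit = RSE_LIMIT_FIXED if name in _FIXED_EFFECTS else RSE_LIMIT_RANDOM
            rows.append({
                "parameter": name,
                "estimate": est[name],
                "se": self.se.get(name) if self.se else np.nan,
                "rse_pct": rse,
                "rse_acceptable": bool(rse < limit) if rse == rse else False,
            })
        return pd.DataFrame(rows)

    def summary(self) -> str:
        lines = [
            "One-compartment IV-bolus population PK model",
            f"  subjects: {self.n_subjects}   observations: {self.n_obs}",
            f"  dose covariate on CL: {self.with_dose_covariate}",
            f"  OFV: {self.ofv:.3f} (objective {self.ofv_objective:.3f})",
            f"  converged: {self.converged}",
            "",
            self.params_frame().to_string(index=False, float_format=lambda v: f"{v:.4g}"),
        ]
        if self.ebes is not None and self.params.omega_cl > 0 and self.params.omega_v > 0:
            lines += ["", "  eta-shrinkage (SD-based): "
                      f"CL {self.eta_shrinkage('cl'):.1f}%  "
                      f"V {self.eta_shrinkage('v'):.1f}%"]
        return "\n".join(lines)

    # -- evaluation hooks (delegate to the dedicated modules) --------------
    def residuals(self, n_sim: int = 1000, seed: int = 0):
        from .diagnostics import residual_table
        return residual_table(self.params, self.model.data, self.ebes,
                              n_sim=n_sim, seed=seed)

    def vpc(self, n_sim: int = 1000, seed: int = 0, stratify_by_dose: bool = True):
        from .evaluation import vpc
        return vpc(self.model.data, self.params, n_sim=n_sim, seed=seed,
                   stratify_by_dose=stratify_by_dose)

    def bootstrap(self, B: int = 1000, seed: int = 0, settings: FitSettings | None = None):
        from .evaluation import bootstrap
        return bootstrap(self.model.data, B=B, seed=seed,
                         settings=settings or self.settings,
                         with_dose_covariate=self.with_dose_covariate)


def naive_initial_values(data: PKDataset, with_dose_covariate: bool,
                         error_model: str = "proportional") -> PopulationParameters:
    """Data-driven, seed-free starting values.

    Pooled log-linear regression of concentration on time within each dose
    group gives a slope (-k) and intercept (log C0) per group, hence
    V = dose/C0 and CL = k V. The typical volume is the geometric mean of
    the group values; CL_pop and beta come from regressing log CL on
    log(dose / reference). Variability terms start at 0.3.
    """
    obs = data.observations
    per_group = []
    for dose, grp in obs.groupby("DOSE"):
        t = grp["TIME"].to_numpy()
        logy = np.log(grp["DV"].to_numpy())
        if len(np.unique(t)) >= 2:
            slope, intercept = np.polyfit(t, logy, 1)
        else:
            continue
        k = max(-slope, 1e-3)
        c0 = float(np.exp(intercept))
        v = dose * DOSE_TO_UG / c0
        per_group.append((dose, k * v, v))
    if not per_group:
        # single usable group: fall back to a global regression
        t = obs["TIME"].to_numpy()
        logy = np.log(obs["DV"].to_numpy())
        slope, intercept = np.polyfit(t, logy, 1)
        k = max(-slope, 1e-3)
        dose = float(obs["DOSE"].median())
        v = dose * DOSE_TO_UG / float(np.exp(intercept))
        per_group = [(dose, k * v, v)]
    doses = np.array([g[0] for g in per_group])
    cls = np.array([g[1] for g in per_group])
    vs = np.array([g[2] for g in per_group])
    v_pop = float(np.exp(np.mean(np.log(vs))))
    dose_median = 3.0
    if with_dose_covariate and len(per_group) >= 2:
        x = np.log(doses / dose_median)
        beta, logcl = np.polyfit(x, np.log(cls), 1)
        cl_pop = float(np.exp(logcl))
        beta = float(np.clip(beta, -2.0, 2.0))
    else:
        cl_pop = float(np.exp(np.mean(np.log(cls))))
        beta = 0.0
    error_a = 0.2 * float(obs["DV"].median()) if error_model != "proportional" else 0.0
    error_b = 0.3 if error_model != "additive" else 0.0
    return PopulationParameters(
        cl_pop=cl_pop, v_pop=v_pop, beta=beta,
        omega_cl=0.3, omega_v=0.3,
        error_a=error_a, error_b=error_b, dose_median=dose_median)


class OneCompartmentModel:
    """Population PK model: IV bolus, first-order elimination, lognormal
    IIV on CL and V, optional power dose covariate on CL.

    Parameters
    ----------
    data : PKDataset
    dose_covariate : bool
        Estimate the power exponent beta linking dose to clearance
        (the final model); ``False`` fixes beta = 0 (the base model).
    error_model : str
        "proportional" (default, the published model), "additive" or
        "combined" residual error.
    """

    def __init__(self, data: PKDataset, dose_covariate: bool = True,
                 error_model: str = "proportional"):
        self.data = data
        self.dose_covariate = bool(dose_covariate)
        self.error_model = error_model
        if self.dose_covariate and len(data.doses) < 2:
            raise ValueError(
                "the dose-clearance exponent is unidentifiable with a single "
                "dose level; use dose_covariate=False")
        self._pack = pack_dataset(data)
        self.param_names = self._make_names()

    @classmethod
    def from_csv(cls, path, **kwargs) -> "OneCompartmentModel":
        return cls(PKDataset.from_csv(path), **kwargs)

    def _make_names(self) -> tuple:
        names = ["cl_pop", "v_pop"]
        if self.dose_covariate:
            names.append("beta")
        names += ["omega_cl", "omega_v"]
        if self.error_model in ("additive", "combined"):
            names.append("error_a")
        if self.error_model in ("proportional", "combined"):
            names.append("error_b")
        return tuple(names)

    # -- parameter-vector transforms --------------------------------------
    def _to_vector(self, p: PopulationParameters) -> np.ndarray:
        d = p.to_dict()
        out = []
        for name in self.param_names:
            v = d[name]
            out.append(v if name == "beta" else np.log(max(v, 1e-10)))
        return np.array(out)

    def _to_params(self, x: np.ndarray) -> PopulationParameters:
        kw = dict(beta=0.0, omega_cl=0.0, omega_v=0.0,
                  error_a=0.0, error_b=0.0, dose_median=3.0)
        for name, v in zip(self.param_names, x):
            kw[name] = v if name == "beta" else float(np.exp(v))
        return PopulationParameters(**kw)

    def loglike_neg2(self, params: PopulationParameters, method: str = "laplace",
                     **kwargs) -> float:
        """OFV at arbitrary parameter values (see `marginal_neg2ll`)."""
        return marginal_neg2ll(params, self._pack, method=method, **kwargs)

    def fit(self, init: PopulationParameters | None = None,
            settings: FitSettings | None = None) -> FitResult:
        settings = settings or FitSettings()
        if init is None:
            init = naive_initial_values(self.data, self.dose_covariate,
                                        settings.error_model)
        x0 = self._to_vector(init)
        pack = self._pack
        eta_cache = [None]
        n_fev = [0]

        def objective(x):
            n_fev[0] += 1
            try:
                p = self._to_params(x)
            except (ValueError, OverflowError):
                return 1e12
            try:
                parts, _, eta_act = agq_parts(pack, p, eta0=eta_cache[0],
                                              n_nodes=settings.n_agq_nodes)
            except FloatingPointError:
                return 1e12
            total = float(np.sum(parts))
            if not np.isfinite(total):
                return 1e12
            eta_cache[0] = eta_act
            return total

        best = None
        restart_ofvs = []
        successes = []
        for r in range(settings.n_restarts):
            if r == 0:
                x_start = x0
            else:
                rng = np.random.default_rng(12345 + r)
                x_start = x0 + rng.normal(0.0, settings.jitter_sd, size=x0.size)
            eta_cache[0] = None
            res = minimize(objective, x_start, method="Nelder-Mead",
                           options=dict(maxiter=settings.maxiter,
                                        maxfev=2 * settings.maxiter,
                                        xatol=settings.xatol,
                                        fatol=settings.fatol))
            # a boundary omega leaves a flat simplex direction that can
            # never satisfy xatol; judge convergence by the objective
            # spread over the final simplex instead
            fvals = res.final_simplex[1]
            settled = bool(res.success) or float(np.ptp(fvals)) < 10.0 * settings.fatol
            restart_ofvs.append(float(res.fun))
            successes.append(settled)
            if best is None or res.fun < best.fun:
                best = res
                best_success = settled
        spread = max(restart_ofvs) - min(restart_ofvs)
        converged = best_success and spread <= 1.0

        params = self._to_params(best.x)
        ofv_objective = float(best.fun)
        if settings.final_ofv == "is":
            ofv = marginal_neg2ll(params, pack, method="is",
                                  n_nodes=settings.n_is_nodes,
                                  seed=settings.seed)
        else:
            ofv = ofv_objective

        fim, cov, se, rse = self._uncertainty(best.x, params,
                                              settings.n_agq_nodes)
        ebes = compute_ebes(params, pack)
        obs = self.data.observations
        fingerprint = (self.data.n_subjects, self.data.n_obs,
                       float(obs["DV"].sum()), float(obs["TIME"].sum()))
        return FitResult(
            params=params, ofv=float(ofv), ofv_objective=ofv_objective,
            param_names=self.param_names, fim=fim, cov=cov, se=se, rse=rse,
            converged=converged, n_subjects=self.data.n_subjects,
            n_obs=self.data.n_obs, ebes=ebes, settings=settings, model=self,
            restart_ofvs=tuple(restart_ofvs), n_fev=n_fev[0],
            data_fingerprint=fingerprint)

    def _uncertainty(self, x: np.ndarray, params: PopulationParameters,
                     n_agq_nodes: int = 9):
        """Finite-difference OFV Hessian on the estimation scale.

        cov = 2 * H^-1 (the OFV is -2 log L). Log-scale parameters have
        RSE% = 100 * SE(log p); beta has RSE% = 100 * SE / |beta|.
        """
        pack = self._pack
        h = 1e-3
        k = x.size

        def f(xx):
            try:
                parts, _, _ = agq_parts(pack, self._to_params(xx),
                                        n_nodes=n_agq_nodes)
                return float(np.sum(parts))
            except (ValueError, FloatingPointError):
                return np.nan

        H = np.empty((k, k))
        f0 = f(x)
        for i in range(k):
            ei = np.zeros(k); ei[i] = h
            H[i, i] = (f(x + ei) - 2.0 * f0 + f(x - ei)) / h ** 2
            for j in range(i + 1, k):
                ej = np.zeros(k); ej[j] = h
                H[i, j] = H[j, i] = (
                    f(x + ei + ej) - f(x + ei - ej)
                    - f(x - ei + ej) + f(x - ei - ej)) / (4.0 * h ** 2)
        if not np.all(np.isfinite(H)):
            return None, None, None, None
        # a variability parameter at its boundary (omega -> 0) leaves a
        # flat or indefinite direction; iteratively drop the flattest
        # directions and invert the well-conditioned submatrix, reporting
        # NaN for the degenerate parameters instead of losing everything
        diag_h = np.diag(H).copy()
        keep = np.ones(k, dtype=bool)
        se_x = np.full(k, np.nan)
        cov = None
        while keep.any():
            sub = H[np.ix_(keep, keep)]
            try:
                cov_sub = 2.0 * np.linalg.inv(sub)
                d = np.diag(cov_sub)
                if np.all(np.isfinite(d)) and np.all(d > 0):
                    se_x[keep] = np.sqrt(d)
                    cov = np.full((k, k), np.nan)
                    cov[np.ix_(keep, keep)] = cov_sub
                    break
            except np.linalg.LinAlgError:
                pass
            flattest = np.argmin(np.where(keep, diag_h, np.inf))
            keep[flattest] = False
        est = params.to_dict()
        se, rse = {}, {}
        for name, s in zip(self.param_names, se_x):
            if name == "beta":
                se[name] = float(s)
                rse[name] = float(100.0 * s / abs(est[name])) if est[name] != 0 else np.inf
            else:
                se[name] = float(est[name] * s)   # delta method from log scale
                rse[name] = float(100.0 * s)
        return H / 2.0, cov, se, rse


def fit_model(data: PKDataset, with_dose_covariate: bool = True,
              init: PopulationParameters | None = None,
              settings: FitSettings | None = None) -> FitResult:
    """Fit the base (beta fixed at 0) or final (beta estimated) model."""
    settings = settings or FitSettings()
    model = OneCompartmentModel(data, dose_covariate=with_dose_covariate,
                                error_model=settings.error_model)
    return model.fit(init=init, settings=settings)


def compute_rse(fit: FitResult) -> pd.DataFrame:
    """RSE (%) per estimated parameter with acceptability flags.

    Fixed effects are flagged above 30%, random-effect and residual-error
    parameters above 50%. Raises if the information matrix was singular,
    naming the weakest direction.
    """
    if fit.rse is None:
        msg = "information matrix is singular or not positive definite"
        if fit.fim is not None:
            w, vec = np.linalg.eigh(fit.fim)
            weakest = fit.param_names[int(np.argmax(np.abs(vec[:, 0])))]
            msg += f"; weakest direction is along {weakest!r}"
        raise np.linalg.LinAlgError(msg)
    return fit.params_frame()


def likelihood_ratio(base: FitResult, final: FitResult):
    """Nested-model likelihood-ratio comparison.

    delta_ofv = OFV(base) - OFV(final); significant at p < 0.05 with one
    degree of freedom when delta_ofv >= 3.84 (boundary inclusive).
    """
    if base.data_fingerprint is not None and final.data_fingerprint is not None \
            and base.data_fingerprint != final.data_fingerprint:
        raise ValueError("base and final fits use different datasets")
    if final.n_params - base.n_params != 1:
        raise ValueError(
            "likelihood-ratio test requires the base model nested in the "
            f"final with exactly one fewer parameter (got {base.n_params} "
            f"vs {final.n_params})")
    delta = base.ofv - final.ofv
    return float(delta), bool(delta >= LRT_CUTOFF)
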