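"""Population and individual parameter containers.

Units follow the per-kg convention used throughout the package: clearance in
mL/h/kg, volume in mL/kg, doses in mg/kg and concentrations in ug/mL (doses
are converted to ug/kg internally, so dose/volume lands directly on the
concentration scale).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace, asdict

__all__ = ["PopulationParameters", "IndividualParameters"]

#: mg/kg -> ug/kg, so that (dose / V[mL/kg]) is in ug/mL.
DOSE_TO_UG = 1000.0


@dataclass(frozen=True)
class PopulationParameters:
    """Fixed effects, random-effect SDs and residual-error parameters.

    Parameters
    ----------
    cl_pop : float
        Typical clearance at the reference dose, mL/h/kg.
    v_pop : float
        Typical volume of distribution, mL/kg.
    beta : float
        Exponent of the power dose-clearance relationship
        ``CL_i = cl_pop * (dose / dose_median)**beta * exp(eta_cl)``;
        0 removes the dose effect.
    omega_cl, omega_v : float
        SDs of the lognormal between-animal random effects on clearance
        and volume (dimensionless, log scale).
    error_a : float
        Additive residual-error SD, ug/mL (0 if unused).
    error_b : float
        Proportional residual-error fraction (0 if unused).
    dose_median : float
        Reference dose of the covariate model, mg/kg.
    """

    cl_pop: float
    v_pop: float
    beta: float = 0.0
    omega_cl: float = 0.0
    omega_v: float = 0.0
    error_a: float = 0.0
    error_b: float = 0.0
    dose_median: float = 3.0

    def __post_init__(self) -> None:
        if self.cl_pop <= 0:
            raise ValueError(f"cl_pop must be > 0, got {self.cl_pop}")
        if self.v_pop <= 0:
            raise ValueError(f"v_pop must be > 0, got {self.v_pop}")
        if self.omega_cl < 0 or self.omega_v < 0:
            raise ValueError("omega_cl and omega_v must be >= 0")
        if self.error_a < 0 or self.error_b < 0:
            raise ValueError("error_a and error_b must be >= 0")
        if self.error_a == 0 and self.error_b == 0:
            raise ValueError("at least one of error_a, error_b must be > 0")
        if self.dose_median <= 0:
            raise ValueError("dose_median must be > 0")

    def replace(self, **changes) -> "PopulationParameters":
        return replace(self, **changes)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PopulationParameters":
        return cls(**{k: float(v) for k, v in d.items()})


def published_parameters() -> PopulationParameters:
    """Final published estimates of the mouse disposition model.

    Typical CL 39.18 mL/h/kg at the 3 mg/kg reference dose, V 53.06 mL/kg,
    dose-clearance exponent -0.30, between-animal SDs 0.058 (CL) and 0.25
    (V) on the log scale, and a 51% proportional residual error.
    """
    return PopulationParameters(
        cl_pop=39.18,
        v_pop=53.06,
        beta=-0.30,
        omega_cl=0.058,
        omega_v=0.25,
        error_a=0.0,
        error_b=0.51,
        dose_median=3.0,
    )


@dataclass(frozen=True)
class IndividualParameters:
    """Realised clearance and volume of one animal.

    ``cl_i`` and ``v_i`` are deterministic functions of the population
    parameters, the administered dose and the random effects.
    """

    eta_cl: float
    eta_v: float
    cl_i: float
    v_i: float
    dose_i: float

    def __post_init__(self) -> None:
        if self.cl_i <= 0 or self.v_i <= 0:
            raise ValueError("cl_i and v_i must be > 0")

    @classmethod
    def from_population(
        cls,
        params: PopulationParameters,
        dose: float,
        eta_cl: float = 0.0,
        eta_v: float = 0.0,
    ) -> "IndividualParameters":
        from .model import individual_clearance, individual_parameter

        return cls(
            eta_cl=eta_cl,
            eta_v=eta_v,
            cl_i=individual_clearance(params, dose, eta_cl),
            v_i=individual_parameter(params.v_pop, eta_v),
            dose_i=dose,
        )
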