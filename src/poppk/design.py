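"""Sparse serial + terminal/destructive sampling designs and the dataset container.

The study this package emulates pooled single IV bolus PK experiments in
female athymic nude mice at 0.3, 1, 3, 5 and 10 mg/kg, mixing serial
sampling (a few draws per animal) with terminal sampling (one draw at
sacrifice), for a total of 121 plasma concentrations from 70 animals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .model import individual_clearance, individual_parameter, predict_concentration
from .params import PopulationParameters

__all__ = ["DoseGroup", "StudyDesign", "PKDataset", "default_design",
           "simulate_dataset", "summarize_dataset"]

#: NONMEM-style flat-table schema used at every I/O boundary.
COLUMNS = ["ID", "TIME", "AMT", "DOSE", "DV", "EVID"]


@dataclass(frozen=True)
class DoseGroup:
    """One dose arm: serial animals share `serial_times`; each terminal
    animal contributes a single sample, times cycling through
    `terminal_times`."""

    dose: float                      # mg/kg
    n_serial: int
    serial_times: tuple              # h, shared by every serial animal
    n_terminal: int
    terminal_times: tuple            # h, cycled across terminal animals
    extra_serial_samples: tuple = () # (subject_index, time) add-ons

    def __post_init__(self):
        if self.dose <= 0:
            raise ValueError("dose must be > 0")
        if any(t <= 0 for t in self.serial_times + self.terminal_times):
            raise ValueError("sampling times must be > 0 (no t=0 records)")

    @property
    def n_subjects(self) -> int:
        return self.n_serial + self.n_terminal

    @property
    def n_obs(self) -> int:
        return (self.n_serial * len(self.serial_times)
                + self.n_terminal + len(self.extra_serial_samples))

    def subject_times(self) -> list:
        """Observation times for each animal in the group, in order."""
        times = []
        for i in range(self.n_serial):
            ts = list(self.serial_times)
            ts += [t for j, t in self.extra_serial_samples if j == i]
            times.append(sorted(ts))
        for i in range(self.n_terminal):
            times.append([self.terminal_times[i % len(self.terminal_times)]])
        return times


@dataclass(frozen=True)
class StudyDesign:
    groups: tuple
    label: str = "design"

    @property
    def n_subjects(self) -> int:
        return sum(g.n_subjects for g in self.groups)

    @property
    def n_obs(self) -> int:
        return sum(g.n_obs for g in self.groups)

    @property
    def doses(self) -> tuple:
        return tuple(g.dose for g in self.groups)


def default_design() -> StudyDesign:
    """The default sparse mouse design: 70 animals, 121 observations.

    Five dose groups (0.3, 1, 3, 5, 10 mg/kg) of 14 animals each: 5 serial
    animals sampled at 0.083, 0.5 and 2 h plus 9 terminal animals sampled
    once at times cycling through 0.25, 1, 3, 6, 8 h. One serial animal in
    the 3 mg/kg group contributes an extra sample at 4 h, bringing the
    total to 121 observations. The window spans roughly 8.5 elimination
    half-lives at the reference dose.
    """
    serial = (0.083, 0.5, 2.0)
    terminal = (0.25, 1.0, 3.0, 6.0, 8.0)
    groups = []
    for dose in (0.3, 1.0, 3.0, 5.0, 10.0):
        extra = ((0, 4.0),) if dose == 3.0 else ()
        groups.append(DoseGroup(dose, 5, serial, 9, terminal, extra))
    return StudyDesign(tuple(groups), label="default-sparse-mouse")


class PKDataset:
    """Flat NONMEM-style observation table with dosing records.

    Columns: ID, TIME (h), AMT (mg/kg on EVID=1 rows, 0 otherwise),
    DOSE (mg/kg, constant within subject), DV (ug/mL on EVID=0 rows,
    0 on dosing rows), EVID (1 dose, 0 observation).
    """

    def __init__(self, table: pd.DataFrame, metadata: dict | None = None):
        self.table = table.reset_index(drop=True)
        self.metadata = dict(metadata or {})
        self.validate()

    # -- accessors ---------------------------------------------------------
    @property
    def observations(self) -> pd.DataFrame:
        return self.table[self.table["EVID"] == 0]

    @property
    def subject_ids(self) -> np.ndarray:
        return self.table["ID"].unique()

    @property
    def n_subjects(self) -> int:
        return self.table["ID"].nunique()

    @property
    def n_obs(self) -> int:
        return int((self.table["EVID"] == 0).sum())

    @property
    def doses(self) -> np.ndarray:
        return np.sort(self.table["DOSE"].unique())

    def subject_dose(self) -> pd.Series:
        """Dose per subject, indexed by ID (order of first appearance)."""
        return self.table.groupby("ID", sort=False)["DOSE"].first()

    def validate(self) -> None:
        missing = [c for c in COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"dataset missing columns: {missing}")
        if self.table[COLUMNS].isna().any().any():
            rows = self.table.index[self.table[COLUMNS].isna().any(axis=1)]
            raise ValueError(f"missing values at rows {list(rows[:5])}")
        obs = self.observations
        for sid, grp in self.table.groupby("ID", sort=False):
            if (grp["EVID"] == 0).sum() < 1:
                raise ValueError(f"subject {sid} has no observation rows")
            if grp["DOSE"].nunique() != 1:
                raise ValueError(f"subject {sid} has non-constant DOSE")
            t = grp.loc[grp["EVID"] == 0, "TIME"].to_numpy()
            if np.any(np.diff(t) <= 0):
                raise ValueError(f"subject {sid} observation times not "
                                 "strictly increasing")
        if np.any(obs["DV"].to_numpy() <= 0):
            raise ValueError("non-positive concentrations in DV")

    # -- I/O ---------------------------------------------------------------
    def to_csv(self, path) -> None:
        self.table[COLUMNS].to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, metadata: dict | None = None) -> "PKDataset":
        from .io import read_dataset
        ds = read_dataset(path)
        ds.metadata.update(metadata or {})
        return ds

    def subset(self, ids: Sequence, relabel: bool = False) -> "PKDataset":
        """Rows of the listed subjects, in the listed order (with
        repetition — bootstrap resamples relabel duplicated animals)."""
        parts = []
        by_id = {sid: grp for sid, grp in self.table.groupby("ID", sort=False)}
        for k, sid in enumerate(ids):
            grp = by_id[sid].copy()
            if relabel:
                grp["ID"] = k + 1
            parts.append(grp)
        return PKDataset(pd.concat(parts, ignore_index=True),
                         metadata={**self.metadata, "subset_of": self.metadata.get("seed")})


def simulate_dataset(design: StudyDesign, params: PopulationParameters,
                     seed: int) -> PKDataset:
    """Simulate an observation table under `design` at `params`.

    Per animal: eta_CL ~ N(0, omega_cl^2), eta_V ~ N(0, omega_v^2);
    concentrations follow the one-compartment model at the design times with
    residual error ``y = f * (1 + b*eps) + a*eps``, eps ~ N(0,1) i.i.d.
    A draw producing y <= 0 is redrawn (possible with a 51% proportional
    CV), which keeps every record positive without a point mass.
    """
    if seed is None:
        raise ValueError("a seed is required: simulation must be reproducible")
    rng = np.random.default_rng(seed)
    rows = []
    sid = 0
    for group in design.groups:
        for times in group.subject_times():
            sid += 1
            eta_cl = rng.normal(0.0, params.omega_cl)
            eta_v = rng.normal(0.0, params.omega_v)
            cl_i = individual_clearance(params, group.dose, eta_cl)
            v_i = individual_parameter(params.v_pop, eta_v)
            rows.append((sid, 0.0, group.dose, group.dose, 0.0, 1))
            for t in times:
                f = predict_concentration(group.dose, cl_i, v_i, t)
                y = -1.0
                while y <= 0:
                    eps = rng.normal()
                    y = f * (1.0 + params.error_b * eps) + params.error_a * eps
                rows.append((sid, t, 0.0, group.dose, y, 0))
    table = pd.DataFrame(rows, columns=COLUMNS)
    return PKDataset(table, metadata={
        "seed": int(seed),
        "design": design.label,
        "generative_parameters": params.to_dict(),
    })


def summarize_dataset(data: PKDataset) -> pd.DataFrame:
    """Per-dose summary: subject and observation counts, time range and
    geometric mean concentration at each nominal time."""
    obs = data.observations
    if len(obs) == 0:
        raise ValueError("empty dataset")
    rows = []
    for dose, grp in obs.groupby("DOSE"):
        gmeans = grp.groupby("TIME")["DV"].apply(
            lambda v: float(np.exp(np.mean(np.log(v)))))
        rows.append({
            "dose": dose,
            "n_subjects": grp["ID"].nunique(),
            "n_obs": len(grp),
            "t_min": grp["TIME"].min(),
            "t_max": grp["TIME"].max(),
            "geomean_by_time": gmeans.to_dict(),
        })
    return pd.DataFrame(rows)
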