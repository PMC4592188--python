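"""Physiological population database and covariate model.

Population knowledge about each varied physiological parameter is stored on
an age x gender grid: mean ``M`` and standard deviation ``S`` per grid
point, a distribution type (normal or lognormal -- for lognormal parameters
``M`` and ``S`` are the mean and SD of the associated normal distribution,
i.e. they live on the log scale), hard physiological bounds, and, for organ
volumes, an allometric body-height exponent ``alpha``.

An individual's parameter vector is predicted from its covariates
(age ``A``, gender ``G``, body height ``H``) and a standardised random
effect ``b``:

*   non-volume parameters:  ``theta = M(A,G) + S(A,G) * b``
*   organ volumes:          ``theta = M(A,G) * r^alpha + S(A,G) * r^alpha * b``

with the height ratio ``r = H / Hbar(A,G)`` against the grid's mean height,
and age scaling of both ``M`` and ``S`` by linear interpolation between grid
ages (no extrapolation).  For lognormal parameters the linear model applies
to ``log(theta)``.  Body weight is defined as the sum of the organ volumes
(unit tissue density), which doubles as the constraint target during
sampling.

The packaged default grid (:func:`default_population_grid`) is a documented
fixture for healthy adults (ages 20-50, both genders) with
literature-plausible means, SDs and bounds; it deliberately does not claim
to reproduce any proprietary database.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from typing import Dict, Mapping, Sequence

import numpy as np
import pandas as pd

from .pbpk import ORGANS, VARIED_FLOW_ORGANS

__all__ = [
    "INDIVIDUAL_PARAMETERS",
    "VOLUME_PARAMETERS",
    "GridEntry",
    "PopulationGrid",
    "IndividualCovariates",
    "AgeOutOfRangeError",
    "default_population_grid",
    "interpolate_population_moments",
    "mean_height",
    "covariate_model",
    "invert_covariate_model",
]

#: The K = 38 individually varied parameters, in canonical order.
VOLUME_PARAMETERS: tuple = tuple(f"volume_{o}" for o in ORGANS)
FLOW_PARAMETERS: tuple = tuple(f"flow_{o}" for o in VARIED_FLOW_ORGANS)
ADME_PARAMETERS: tuple = ("hematocrit", "GET", "ITT", "intP", "specCL", "specTS")
INDIVIDUAL_PARAMETERS: tuple = VOLUME_PARAMETERS + FLOW_PARAMETERS + ADME_PARAMETERS

GENDERS = ("male", "female")


class AgeOutOfRangeError(ValueError):
    """Requested age lies outside the database grid (no extrapolation)."""


@dataclass
class GridEntry:
    """Database record of one physiological parameter."""

    name: str
    distribution: str  # "normal" | "lognormal"
    lower: float  # natural-scale bounds
    upper: float
    alpha: float | None  # allometric height exponent (volumes only)
    age_grid: Dict[str, np.ndarray]  # per gender, strictly increasing years
    M_grid: Dict[str, np.ndarray]  # per gender; log scale if lognormal
    S_grid: Dict[str, np.ndarray]

    def validate(self) -> None:
        if self.distribution not in ("normal", "lognormal"):
            raise ValueError(f"{self.name}: bad distribution {self.distribution!r}")
        if not self.lower < self.upper:
            raise ValueError(f"{self.name}: lower bound must be below upper")
        for g in self.age_grid:
            ages = np.asarray(self.age_grid[g], dtype=float)
            if np.any(np.diff(ages) <= 0):
                raise ValueError(f"{self.name}/{g}: age grid not increasing")
            if np.any(np.asarray(self.S_grid[g]) <= 0):
                raise ValueError(f"{self.name}/{g}: S grid must be positive")
            if len(self.M_grid[g]) != len(ages) or len(self.S_grid[g]) != len(ages):
                raise ValueError(f"{self.name}/{g}: grid length mismatch")


@dataclass
class PopulationGrid:
    """Age/gender-gridded population means, SDs, bounds and scaling exponents."""

    parameters: Dict[str, GridEntry]
    height_age_grid: Dict[str, np.ndarray]
    height_grid: Dict[str, np.ndarray]  # mean body height (cm) per gender

    def validate(self) -> None:
        for entry in self.parameters.values():
            entry.validate()
        for g, ages in self.height_age_grid.items():
            if np.any(np.diff(np.asarray(ages)) <= 0):
                raise ValueError(f"height/{g}: age grid not increasing")

    # -- serialisation ----------------------------------------------------

    def to_csv(self, csv_path, json_path) -> None:
        """One row per parameter x gender x age grid point + JSON sidecar."""
        rows = []
        for name, e in self.parameters.items():
            for g in e.age_grid:
                for a, m, s in zip(e.age_grid[g], e.M_grid[g], e.S_grid[g]):
                    rows.append(dict(parameter=name, gender=g, age=a, M=m, S=s))
        for g in self.height_age_grid:
            for a, h in zip(self.height_age_grid[g], self.height_grid[g]):
                rows.append(dict(parameter="__height__", gender=g, age=a, M=h, S=np.nan))
        pd.DataFrame(rows).to_csv(csv_path, index=False)
        side = {
            name: dict(distribution=e.distribution, lower=e.lower,
                       upper=e.upper, alpha=e.alpha)
            for name, e in self.parameters.items()
        }
        with open(json_path, "w") as fh:
            json.dump(side, fh, indent=1)

    @classmethod
    def from_csv(cls, csv_path, json_path) -> "PopulationGrid":
        df = pd.read_csv(csv_path)
        need = {"parameter", "gender", "age", "M", "S"}
        if not need.issubset(df.columns):
            raise ValueError(f"grid CSV must have columns {sorted(need)}")
        with open(json_path) as fh:
            side = json.load(fh)
        params: Dict[str, GridEntry] = {}
        h_age: Dict[str, np.ndarray] = {}
        h_val: Dict[str, np.ndarray] = {}
        for (name, g), sub in df.groupby(["parameter", "gender"], sort=False):
            sub = sub.sort_values("age")
            if name == "__height__":
                h_age[g] = sub["age"].to_numpy(float)
                h_val[g] = sub["M"].to_numpy(float)
                continue
            if name not in side:
                raise ValueError(f"parameter {name!r} missing from JSON sidecar")
            e = params.get(name)
            if e is None:
                meta = side[name]
                e = params[name] = GridEntry(
                    name=name, distribution=meta["distribution"],
                    lower=meta["lower"], upper=meta["upper"],
                    alpha=meta["alpha"], age_grid={}, M_grid={}, S_grid={})
            e.age_grid[g] = sub["age"].to_numpy(float)
            e.M_grid[g] = sub["M"].to_numpy(float)
            e.S_grid[g] = sub["S"].to_numpy(float)
        grid = cls(parameters=params, height_age_grid=h_age, height_grid=h_val)
        grid.validate()
        return grid


@dataclass(frozen=True)
class IndividualCovariates:
    """One subject's covariates and study-design quantities."""

    age: float  # years
    gender: str
    height: float  # cm
    body_weight: float  # kg
    dose: float  # mg

    def __post_init__(self):
        if self.gender not in GENDERS:
            raise ValueError(f"gender must be one of {GENDERS}")
        if self.height <= 0 or self.body_weight <= 0:
            raise ValueError("height and body weight must be positive")


# --------------------------------------------------------------------------
# Interpolation and the covariate model
# --------------------------------------------------------------------------


def _interp(ages: np.ndarray, values: np.ndarray, age: float,
            what: str) -> float:
    ages = np.asarray(ages, float)
    if not (ages[0] <= age <= ages[-1]):
        raise AgeOutOfRangeError(
            f"age {age} outside grid range [{ages[0]}, {ages[-1]}] for {what}")
    return float(np.interp(age, ages, np.asarray(values, float)))


def interpolate_population_moments(grid: PopulationGrid,
                                   covariates: IndividualCovariates,
                                   parameter: str) -> tuple:
    """(M, S) at the individual's age/gender by linear age interpolation."""
    e = grid.parameters[parameter]
    g = covariates.gender
    m = _interp(e.age_grid[g], e.M_grid[g], covariates.age, parameter)
    s = _interp(e.age_grid[g], e.S_grid[g], covariates.age, parameter)
    return m, s


def mean_height(grid: PopulationGrid, covariates: IndividualCovariates) -> float:
    """Grid mean body height Hbar(A, G) in cm."""
    g = covariates.gender
    return _interp(grid.height_age_grid[g], grid.height_grid[g],
                   covariates.age, "height")


def height_scale(grid: PopulationGrid, covariates: IndividualCovariates,
                 parameter: str) -> float:
    """(H/Hbar)^alpha for height-scaled parameters, 1 otherwise."""
    alpha = grid.parameters[parameter].alpha
    if alpha is None:
        return 1.0
    return (covariates.height / mean_height(grid, covariates)) ** alpha


def covariate_model(grid: PopulationGrid,
                    covariates: IndividualCovariates,
                    b: Mapping[str, float] | Sequence[float],
                    names: Sequence[str] | None = None,
                    warn_out_of_bounds: bool = True) -> Dict[str, float]:
    """Map random effects b_i to the individual parameter vector theta_i.

    Non-volume parameters follow ``M + S*b``; height-scaled parameters
    (those with an allometric exponent) follow ``M*r^a + S*r^a*b``.  For
    lognormal parameters the linear model acts on the log scale and the
    result is exponentiated.  Out-of-bound values are reported via a
    warning but never clipped.
    """
    if names is None:
        names = list(b.keys()) if isinstance(b, Mapping) else list(grid.parameters)
    bvec = ([b[k] for k in names] if isinstance(b, Mapping) else list(b))
    if len(bvec) != len(names):
        raise ValueError("b must have one entry per varied parameter")
    theta: Dict[str, float] = {}
    for name, bi in zip(names, bvec):
        e = grid.parameters[name]
        m, s = interpolate_population_moments(grid, covariates, name)
        r = height_scale(grid, covariates, name)
        x = m * r + s * r * bi
        val = float(np.exp(x)) if e.distribution == "lognormal" else float(x)
        if warn_out_of_bounds and not (e.lower <= val <= e.upper):
            warnings.warn(
                f"covariate model produced out-of-bound {name}={val:.6g} "
                f"(bounds [{e.lower:.6g}, {e.upper:.6g}])", stacklevel=2)
        theta[name] = val
    return theta


def invert_covariate_model(grid: PopulationGrid,
                           covariates: IndividualCovariates,
                           theta: Mapping[str, float]) -> Dict[str, float]:
    """Recover random effects: ``b = (theta - M*r^a) / (S*r^a)``."""
    b: Dict[str, float] = {}
    for name, val in theta.items():
        e = grid.parameters[name]
        m, s = interpolate_population_moments(grid, covariates, name)
        r = height_scale(grid, covariates, name)
        x = np.log(val) if e.distribution == "lognormal" else val
        b[name] = float((x - m * r) / (s * r))
    return b


# --------------------------------------------------------------------------
# Packaged fixture database
# --------------------------------------------------------------------------

# name: (alpha, male means at ages (20, 35, 50) [L], male SD, female factor)
_VOLUME_DB = {
    "muscle": (2.0, (30.0, 29.0, 27.5), 5.0, 0.70),
    "fat": (1.1, (13.0, 15.0, 17.0), 4.5, 1.25),
    "bone": (2.0, (10.3, 10.0, 9.7), 1.5, 0.80),
    "skin": (1.6, (3.3, 3.3, 3.2), 0.50, 0.85),
    "liver": (0.8, (2.40, 2.36, 2.25), 0.45, 0.85),
    "brain": (0.0, (1.45, 1.45, 1.44), 0.13, 0.90),
    "heart": (1.0, (0.35, 0.36, 0.37), 0.06, 0.85),
    "kidney": (0.8, (0.44, 0.44, 0.43), 0.11, 0.85),
    "lung": (1.0, (1.00, 1.00, 1.00), 0.18, 0.85),
    "stomach": (0.75, (0.15, 0.15, 0.15), 0.030, 0.90),
    "small_intestine": (0.75, (0.65, 0.65, 0.65), 0.120, 0.90),
    "large_intestine": (0.75, (0.37, 0.37, 0.37), 0.070, 0.90),
    "pancreas": (0.75, (0.12, 0.12, 0.12), 0.025, 0.90),
    "spleen": (0.75, (0.18, 0.18, 0.18), 0.040, 0.90),
    "gonads": (0.75, (0.035, 0.035, 0.035), 0.008, 0.30),
    "thymus": (0.75, (0.028, 0.025, 0.022), 0.006, 1.00),
    "adrenals": (0.75, (0.014, 0.014, 0.014), 0.003, 1.00),
    "salivary_glands": (0.75, (0.085, 0.085, 0.085), 0.017, 0.90),
    "rest_of_body": (1.0, (9.0, 9.0, 9.0), 1.50, 0.90),
}

# name: (male mean [L/min], female factor); SD is 20 % of the mean
_FLOW_DB = {
    "brain": (0.75, 0.90),
    "heart": (0.24, 0.85),
    "muscle": (1.05, 0.75),
    "bone": (0.30, 0.80),
    "skin": (0.30, 0.85),
    "fat": (0.32, 1.20),
    "kidney": (1.10, 0.85),
    "liver": (0.39, 0.85),  # hepatic artery
    "stomach": (0.060, 0.90),
    "small_intestine": (0.75, 0.90),
    "large_intestine": (0.24, 0.90),
    "pancreas": (0.075, 0.90),
    "spleen": (0.18, 0.90),
}

_AGES = np.array([20.0, 35.0, 50.0])


def default_population_grid() -> PopulationGrid:
    """The packaged adult (20-50 y) fixture database.

    Organ volumes and regional flows are truncated-normal with
    literature-plausible means, CVs of roughly 15-30 % and bounds at
    mean x [0.3, 3]; height scaling of the volumes uses organ-specific
    allometric exponents.  The oral-absorption timing parameters (GET,
    ITT), the intestinal permeability and the two specific clearance rates
    are lognormal; the last three carry wide (two orders of magnitude)
    bounds because they are a priori uninformed.
    """
    params: Dict[str, GridEntry] = {}

    def const(x):
        return np.full(3, float(x))

    for organ, (alpha, means_m, sd_m, f_fac) in _VOLUME_DB.items():
        means_m = np.asarray(means_m, float)
        mid = float(means_m[1])
        params[f"volume_{organ}"] = GridEntry(
            name=f"volume_{organ}", distribution="normal",
            lower=0.3 * mid, upper=3.0 * mid, alpha=alpha,
            age_grid={g: _AGES.copy() for g in GENDERS},
            M_grid={"male": means_m, "female": means_m * f_fac},
            S_grid={"male": const(sd_m), "female": const(sd_m * f_fac)},
        )
    for organ, (mean_m, f_fac) in _FLOW_DB.items():
        params[f"flow_{organ}"] = GridEntry(
            name=f"flow_{organ}", distribution="normal",
            lower=0.3 * mean_m, upper=3.0 * mean_m, alpha=None,
            age_grid={g: _AGES.copy() for g in GENDERS},
            M_grid={"male": const(mean_m), "female": const(mean_m * f_fac)},
            S_grid={"male": const(0.2 * mean_m),
                    "female": const(0.2 * mean_m * f_fac)},
        )
    params["hematocrit"] = GridEntry(
        name="hematocrit", distribution="normal", lower=0.30, upper=0.55,
        alpha=None, age_grid={g: _AGES.copy() for g in GENDERS},
        M_grid={"male": const(0.45), "female": const(0.40)},
        S_grid={g: const(0.03) for g in GENDERS},
    )
    # lognormal parameters: (median, geometric SD as log-SD, lower, upper)
    logn = {
        "GET": (17.25, 0.30, 5.0, 60.0),  # min
        "ITT": (146.4, 0.27, 50.0, 500.0),  # min
        "intP": (3.68e-6, 1.00, 3.68e-8, 3.68e-4),  # dm/min
        "specCL": (0.05, 1.00, 5.0e-4, 5.0),  # 1/min
        "specTS": (0.02, 1.00, 2.0e-4, 2.0),  # 1/min
    }
    for name, (med, lsd, lo, hi) in logn.items():
        params[name] = GridEntry(
            name=name, distribution="lognormal", lower=lo, upper=hi,
            alpha=None, age_grid={g: _AGES.copy() for g in GENDERS},
            M_grid={g: const(np.log(med)) for g in GENDERS},
            S_grid={g: const(lsd) for g in GENDERS},
        )
    grid = PopulationGrid(
        parameters=params,
        height_age_grid={g: _AGES.copy() for g in GENDERS},
        height_grid={"male": np.array([178.0, 177.0, 176.0]),
                     "female": np.array([165.0, 164.0, 163.0])},
    )
    grid.validate()
    return grid
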