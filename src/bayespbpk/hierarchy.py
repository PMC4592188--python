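"""Two-level hierarchical probability model around the PBPK kernel.

Level one describes each individual's plasma concentration data with the
PBPK model under a proportional (relative) error model; level two describes
the spread of the individual physiological parameters across the population
through per-parameter population means ``M`` and standard deviations ``S``,
which themselves carry hyperpriors.

All individual-level parameters are handled on their *sampling scale*:
the natural scale for normally distributed parameters (organ volumes,
flows, hematocrit) and the log scale for lognormally distributed ones
(GET, ITT, intP, specCL, specTS).  On that scale every individual prior is
a truncated normal with covariate-scaled moments, which keeps the whole
hierarchy linear-Gaussian in shape and makes random-effect extraction a
simple standardisation.

The joint parameter vector is laid out flat as::

    [ theta_1 .. theta_N | theta_G | sigma^2 | M | S ]

with ``N`` individuals x ``K`` individual parameters, ``L`` global
substance parameters, giving ``N*K + L + 2K + 1`` scalars (535 for the
12 x 38 + 2 application layout).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Sequence

import numpy as np
from scipy.special import ndtr

from . import pbpk
from .covariates import (
    INDIVIDUAL_PARAMETERS,
    IndividualCovariates,
    PopulationGrid,
    height_scale,
    interpolate_population_moments,
)
from .pbpk import CompoundProperties, PhysiologyVector

__all__ = [
    "GLOBAL_PARAMETERS",
    "ParameterLayout",
    "count_dimension",
    "PriorConfig",
    "PriorCatalogue",
    "build_prior_catalogue",
    "IndividualData",
    "ObservationSet",
    "ErrorModel",
    "log_likelihood_individual",
    "CohortEvaluator",
    "PopulationPKModel",
    "trunc_normal_logpdf",
    "trunc_lognormal_logpdf",
    "covariate_scaling",
    "feasible_volumes",
]

#: Globally estimated substance parameters (theta^G).
GLOBAL_PARAMETERS: tuple = ("lipophilicity", "fraction_unbound")

#: The nine exemplary parameters routinely monitored and reported
#: (absorption/elimination ADME rates and four major organ volumes).
EXEMPLAR_PARAMETERS: tuple = (
    "intP", "specCL", "specTS", "GET", "ITT",
    "volume_fat", "volume_kidney", "volume_liver", "volume_muscle",
)

_LOG2PI = float(np.log(2.0 * np.pi))


# --------------------------------------------------------------------------
# Truncated-density helpers (vectorised)
# --------------------------------------------------------------------------


def _log_trunc_mass(mu, sd, lo, hi):
    z = ndtr((hi - mu) / sd) - ndtr((lo - mu) / sd)
    with np.errstate(divide="ignore"):
        return np.log(np.maximum(z, 0.0))


def trunc_normal_logpdf(x, mu, sd, lo, hi):
    """Log density of a normal truncated to [lo, hi]; -inf outside."""
    x, mu, sd, lo, hi = np.broadcast_arrays(
        *[np.asarray(a, float) for a in (x, mu, sd, lo, hi)])
    out = (-0.5 * _LOG2PI - np.log(sd) - 0.5 * ((x - mu) / sd) ** 2
           - _log_trunc_mass(mu, sd, lo, hi))
    return np.where((x >= lo) & (x <= hi), out, -np.inf)


def trunc_lognormal_logpdf(x, mu_log, sd_log, lo, hi):
    """Log density of a lognormal truncated to natural-scale [lo, hi]."""
    x = np.asarray(x, float)
    with np.errstate(divide="ignore", invalid="ignore"):
        lx = np.log(np.where(x > 0, x, np.nan))
    out = trunc_normal_logpdf(lx, mu_log, sd_log, np.log(lo), np.log(hi))
    return np.where(x > 0, out - np.where(np.isfinite(out), np.log(x), 0.0),
                    -np.inf)


def trunc_invgamma_logpdf(x, a, b, lo, hi):
    """Inverse-gamma(a, scale=b) truncated to [lo, hi]; on SDs directly."""
    from scipy.stats import invgamma

    x = np.asarray(x, float)
    dist = invgamma(a, scale=b)
    mass = dist.cdf(hi) - dist.cdf(lo)
    out = dist.logpdf(x) - np.log(mass)
    return np.where((x >= lo) & (x <= hi), out, -np.inf)


# --------------------------------------------------------------------------
# Parameter layout
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class ParameterLayout:
    """Flat-index bookkeeping for the joint parameter vector."""

    n_individuals: int
    individual_names: tuple = INDIVIDUAL_PARAMETERS
    global_names: tuple = GLOBAL_PARAMETERS

    @property
    def K(self) -> int:
        return len(self.individual_names)

    @property
    def L(self) -> int:
        return len(self.global_names)

    @property
    def dimension(self) -> int:
        return self.n_individuals * self.K + self.L + 2 * self.K + 1

    # -- slices -----------------------------------------------------------

    def individual_slice(self, i: int) -> slice:
        if not 0 <= i < self.n_individuals:
            raise IndexError(f"individual {i} out of range")
        return slice(i * self.K, (i + 1) * self.K)

    @property
    def global_slice(self) -> slice:
        off = self.n_individuals * self.K
        return slice(off, off + self.L)

    @property
    def sigma2_index(self) -> int:
        return self.n_individuals * self.K + self.L

    @property
    def M_slice(self) -> slice:
        off = self.sigma2_index + 1
        return slice(off, off + self.K)

    @property
    def S_slice(self) -> slice:
        off = self.sigma2_index + 1 + self.K
        return slice(off, off + self.K)

    # -- name <-> index bijection ------------------------------------------

    def flat_names(self) -> List[tuple]:
        out: List[tuple] = []
        for i in range(self.n_individuals):
            out += [(nm, "individual", i) for nm in self.individual_names]
        out += [(nm, "global", None) for nm in self.global_names]
        out += [("sigma2", "error", None)]
        out += [(nm, "M", None) for nm in self.individual_names]
        out += [(nm, "S", None) for nm in self.individual_names]
        return out

    def index_of(self, name: str, level: str, subject: int | None = None) -> int:
        if level == "individual":
            return self.individual_slice(subject).start + \
                self.individual_names.index(name)
        if level == "global":
            return self.global_slice.start + self.global_names.index(name)
        if level == "error":
            return self.sigma2_index
        if level == "M":
            return self.M_slice.start + self.individual_names.index(name)
        if level == "S":
            return self.S_slice.start + self.individual_names.index(name)
        raise ValueError(f"unknown level {level!r}")

    def name_of(self, idx: int) -> tuple:
        return self.flat_names()[idx]

    # -- packing -----------------------------------------------------------

    def pack(self, theta: np.ndarray, g: np.ndarray, sigma2: float,
             M: np.ndarray, S: np.ndarray) -> np.ndarray:
        vec = np.empty(self.dimension)
        vec[: self.n_individuals * self.K] = np.asarray(theta).ravel()
        vec[self.global_slice] = g
        vec[self.sigma2_index] = sigma2
        vec[self.M_slice] = M
        vec[self.S_slice] = S
        return vec

    def unpack(self, vec: np.ndarray):
        theta = np.asarray(vec[: self.n_individuals * self.K]).reshape(
            self.n_individuals, self.K)
        return (theta, np.asarray(vec[self.global_slice]),
                float(vec[self.sigma2_index]), np.asarray(vec[self.M_slice]),
                np.asarray(vec[self.S_slice]))

    # -- MH blocks ---------------------------------------------------------

    def blocks(self) -> List[tuple]:
        """Fixed visiting order: individuals, global+sigma2, M halves, S halves."""
        out = []
        for i in range(self.n_individuals):
            sl = self.individual_slice(i)
            out.append((f"individual_{i}", np.arange(sl.start, sl.stop)))
        gl = self.global_slice
        out.append(("global_sigma2",
                    np.r_[np.arange(gl.start, gl.stop), self.sigma2_index]))
        for base, sl in (("M", self.M_slice), ("S", self.S_slice)):
            idx = np.arange(sl.start, sl.stop)
            out.append((f"{base}_0", idx[0::2]))
            out.append((f"{base}_1", idx[1::2]))
        return out


def count_dimension(layout: ParameterLayout) -> int:
    """Total number of scalars: N*K + L + 2K + 1."""
    return layout.dimension


# --------------------------------------------------------------------------
# Prior catalogue
# --------------------------------------------------------------------------


@dataclass
class PriorConfig:
    """Defaults for the prior/hyperprior catalogue.

    ``cv_M``/``cv_S`` are the hyperprior coefficients of variation for
    database-backed parameters; ``uninformed`` lists the parameters absent
    from the physiological database, whose population mean gets a wide
    truncated-uniform hyperprior (+- ``uniform_orders`` orders of magnitude)
    and whose population SD gets a truncated inverse-gamma hyperprior.
    """

    cv_M: float = 0.20
    cv_S: float = 0.50
    uninformed: tuple = ("intP", "specCL", "specTS")
    uniform_orders: float = 2.0
    invgamma_a: float = 1.0
    invgamma_b: float = 0.22
    s_upper_uninformed: float = 1.5
    s_floor_rel: float = 1e-12
    sigma2_bounds: tuple = (1e-6, 1.0)
    global_bounds: Mapping[str, tuple] = field(default_factory=lambda: {
        "lipophilicity": (-2.0, 2.0),
        "fraction_unbound": (0.3, 0.9),
    })
    global_start: Mapping[str, float] = field(default_factory=lambda: {
        "lipophilicity": 0.0,
        "fraction_unbound": 0.6,
    })


@dataclass
class PriorCatalogue:
    """Vectorised prior/hyperprior specification on the sampling scale."""

    names: tuple
    is_log: np.ndarray  # (K,) bool
    x_lower: np.ndarray  # (K,) individual-parameter bounds, sampling scale
    x_upper: np.ndarray
    M_family: tuple  # per k: "truncated_normal" | "truncated_uniform"
    M_mu: np.ndarray
    M_sd: np.ndarray
    M_lower: np.ndarray
    M_upper: np.ndarray
    S_family: tuple  # per k: "truncated_normal" | "inverse_gamma"
    S_mu: np.ndarray  # database S for truncated-normal entries
    S_sd: np.ndarray
    S_lower: np.ndarray
    S_upper: np.ndarray
    invgamma_a: float
    invgamma_b: float
    g_lower: np.ndarray  # (L,) truncated-uniform global bounds
    g_upper: np.ndarray
    g_start: np.ndarray
    sigma2_bounds: tuple

    def hyper_M_logpdf(self, M: np.ndarray) -> np.ndarray:
        M = np.asarray(M, float)
        out = np.empty_like(M)
        tn = np.array([f == "truncated_normal" for f in self.M_family])
        inb = (M >= self.M_lower) & (M <= self.M_upper)
        with np.errstate(invalid="ignore"):
            out[tn] = trunc_normal_logpdf(M[tn], self.M_mu[tn], self.M_sd[tn],
                                          self.M_lower[tn], self.M_upper[tn])
        un = ~tn
        out[un] = -np.log(self.M_upper[un] - self.M_lower[un])
        return np.where(inb, out, -np.inf)

    def hyper_S_logpdf(self, S: np.ndarray) -> np.ndarray:
        S = np.asarray(S, float)
        out = np.empty_like(S)
        tn = np.array([f == "truncated_normal" for f in self.S_family])
        out[tn] = trunc_normal_logpdf(S[tn], self.S_mu[tn], self.S_sd[tn],
                                      self.S_lower[tn], self.S_upper[tn])
        ig = ~tn
        if ig.any():
            out[ig] = trunc_invgamma_logpdf(S[ig], self.invgamma_a,
                                            self.invgamma_b, self.S_lower[ig],
                                            self.S_upper[ig])
        return out

    def sigma2_logpdf(self, sigma2: float) -> float:
        lo, hi = self.sigma2_bounds
        if not (lo <= sigma2 <= hi):
            return -np.inf
        return -float(np.log(sigma2))  # scale-invariant (Jeffreys) prior

    def global_logpdf(self, g: np.ndarray) -> float:
        g = np.asarray(g, float)
        if np.any(g < self.g_lower) or np.any(g > self.g_upper):
            return -np.inf
        return -float(np.sum(np.log(self.g_upper - self.g_lower)))


def build_prior_catalogue(grid: PopulationGrid,
                          reference: IndividualCovariates,
                          config: PriorConfig | None = None) -> PriorCatalogue:
    """Derive the prior catalogue from the database at the cohort's covariates.

    Database-backed parameters get truncated-normal hyperpriors for both M
    (CV ~ ``cv_M``; for lognormal parameters interpreted multiplicatively,
    i.e. an SD of ``log(1 + cv_M)`` on the log-scale mean) and S
    (CV ~ ``cv_S``), truncated at +-2 SD with a small positive floor where
    the band crosses zero.  Uninformed parameters get a truncated-uniform
    hyperprior over +-2 orders of magnitude for M and a truncated
    inverse-gamma(a=1, b=0.22) hyperprior for S.
    """
    cfg = config or PriorConfig()
    names = INDIVIDUAL_PARAMETERS
    K = len(names)
    is_log = np.zeros(K, bool)
    x_lo = np.empty(K)
    x_hi = np.empty(K)
    M_family, S_family = [], []
    M_mu = np.empty(K); M_sd = np.empty(K)
    M_lo = np.empty(K); M_hi = np.empty(K)
    S_mu = np.empty(K); S_sd = np.empty(K)
    S_lo = np.empty(K); S_hi = np.empty(K)
    for k, name in enumerate(names):
        e = grid.parameters[name]
        m0, s0 = interpolate_population_moments(grid, reference, name)
        log = e.distribution == "lognormal"
        is_log[k] = log
        x_lo[k] = np.log(e.lower) if log else e.lower
        x_hi[k] = np.log(e.upper) if log else e.upper
        if name in cfg.uninformed:
            M_family.append("truncated_uniform")
            half = cfg.uniform_orders * np.log(10.0)
            M_mu[k], M_sd[k] = m0, np.nan
            M_lo[k], M_hi[k] = m0 - half, m0 + half
            S_family.append("inverse_gamma")
            S_mu[k], S_sd[k] = s0, np.nan
            S_lo[k] = cfg.s_floor_rel * max(s0, 1.0)
            S_hi[k] = cfg.s_upper_uninformed
        else:
            M_family.append("truncated_normal")
            sd = np.log1p(cfg.cv_M) if log else cfg.cv_M * abs(m0)
            M_mu[k], M_sd[k] = m0, sd
            lo = m0 - 2.0 * sd
            if not log and m0 > 0 and lo <= 0:
                lo = cfg.s_floor_rel * m0
            M_lo[k], M_hi[k] = lo, m0 + 2.0 * sd
            S_family.append("truncated_normal")
            sd_s = cfg.cv_S * s0
            S_mu[k], S_sd[k] = s0, sd_s
            lo_s = s0 - 2.0 * sd_s
            if lo_s <= 0:
                lo_s = cfg.s_floor_rel * s0
            S_lo[k], S_hi[k] = lo_s, s0 + 2.0 * sd_s
    g_lo = np.array([cfg.global_bounds[n][0] for n in GLOBAL_PARAMETERS])
    g_hi = np.array([cfg.global_bounds[n][1] for n in GLOBAL_PARAMETERS])
    g_start = np.array([cfg.global_start[n] for n in GLOBAL_PARAMETERS])
    return PriorCatalogue(
        names=names, is_log=is_log, x_lower=x_lo, x_upper=x_hi,
        M_family=tuple(M_family), M_mu=M_mu, M_sd=M_sd, M_lower=M_lo,
        M_upper=M_hi, S_family=tuple(S_family), S_mu=S_mu, S_sd=S_sd,
        S_lower=S_lo, S_upper=S_hi, invgamma_a=cfg.invgamma_a,
        invgamma_b=cfg.invgamma_b, g_lower=g_lo, g_upper=g_hi,
        g_start=g_start, sigma2_bounds=cfg.sigma2_bounds)


# --------------------------------------------------------------------------
# Observations and likelihood
# --------------------------------------------------------------------------


@dataclass
class IndividualData:
    """One subject's PK observations plus covariates and dose."""

    covariates: IndividualCovariates
    times_h: np.ndarray  # plasma sampling times
    conc: np.ndarray  # mg/L
    urine_time_h: float | None = None
    urine_fraction: float | None = None  # fraction of dose, cumulative
    urine_rel_sd: float = 0.05

    def __post_init__(self):
        self.times_h = np.asarray(self.times_h, float)
        self.conc = np.asarray(self.conc, float)
        if np.any(self.times_h < 0):
            raise ValueError("observation times must be non-negative")
        if len(self.times_h) != len(self.conc):
            raise ValueError("times and concentrations differ in length")

    @property
    def usable(self) -> np.ndarray:
        """Points usable under the proportional error model.

        Pre-dose samples (t = 0) and non-positive concentrations are
        excluded: the model output is exactly zero at dose time and the
        relative error is undefined at zero.
        """
        return (self.conc > 0) & (self.times_h > 0)


@dataclass
class ObservationSet:
    """The cohort's observations."""

    individuals: List[IndividualData]

    @property
    def n(self) -> int:
        return len(self.individuals)

    def __iter__(self):
        return iter(self.individuals)

    def __getitem__(self, i):
        return self.individuals[i]


@dataclass
class ErrorModel:
    """Proportional-error variances: sampled sigma^2 for plasma, a fixed
    relative SD for the single urine endpoint."""

    sigma2: float
    urine_rel_sd: float = 0.05

    def __post_init__(self):
        if self.sigma2 <= 0:
            raise ValueError("sigma2 must be positive")


def log_likelihood_individual(y: np.ndarray, y_model: np.ndarray,
                              sigma2: float,
                              urine_obs: float | None = None,
                              urine_model: float | None = None,
                              urine_rel_sd: float = 0.05) -> float:
    """Proportional-error log likelihood of one individual.

    Each plasma point contributes a normal log density with mean equal to
    the model output and SD equal to ``sigma * y_model``; the optional
    urine endpoint contributes the same form with its fixed relative SD.
    A non-positive model output at an observed point yields ``-inf`` (with
    a warning) so an MH step can reject the proposal.
    """
    y = np.asarray(y, float)
    y_model = np.asarray(y_model, float)
    if np.any(y_model <= 0) or (urine_obs is not None and
                                (urine_model is None or urine_model <= 0)):
        warnings.warn("model output non-positive at an observation point; "
                      "likelihood set to -inf", stacklevel=2)
        return -np.inf
    sd = np.sqrt(sigma2) * y_model
    ll = float(np.sum(-0.5 * _LOG2PI - np.log(sd)
                      - 0.5 * ((y - y_model) / sd) ** 2))
    if urine_obs is not None:
        usd = urine_rel_sd * urine_model
        ll += float(-0.5 * _LOG2PI - np.log(usd)
                    - 0.5 * ((urine_obs - urine_model) / usd) ** 2)
    return ll


class CohortEvaluator:
    """Caches per-individual simulation setups and evaluates the PBPK model.

    For each individual the union of plasma and urine observation times is
    simulated once per parameter proposal; individual evaluations are
    independent of each other (parallelisable by contract).
    """

    def __init__(self, observations: ObservationSet,
                 compound_base: CompoundProperties | None = None,
                 graph: pbpk.CompartmentGraph | None = None,
                 method: str = "expm"):
        self.observations = observations
        self.compound_base = compound_base or pbpk.theophylline()
        self.graph = graph or pbpk.default_graph()
        self.method = method
        self._plans = []
        for ind in observations:
            use = ind.usable
            times = list(ind.times_h[use])
            if ind.urine_time_h is not None:
                times.append(ind.urine_time_h)
            grid_t = np.unique(np.asarray(times, float))
            plasma_idx = np.searchsorted(grid_t, ind.times_h[use])
            urine_idx = (int(np.searchsorted(grid_t, ind.urine_time_h))
                         if ind.urine_time_h is not None else None)
            self._plans.append((grid_t, plasma_idx, urine_idx, use))

    def n_plasma_points(self, i: int) -> int:
        return int(self._plans[i][3].sum())

    def compound(self, g: np.ndarray) -> CompoundProperties:
        return self.compound_base.replace(
            lipophilicity=float(g[0]), fraction_unbound_plasma=float(g[1]))

    def outputs(self, i: int, physiology: PhysiologyVector,
                g: np.ndarray):
        """(plasma concentrations at usable obs times, urine fraction)."""
        ind = self.observations[i]
        grid_t, plasma_idx, urine_idx, _use = self._plans[i]
        res = pbpk.simulate_pk(
            physiology, self.compound(g), pbpk.DoseEvent(ind.covariates.dose),
            grid_t, graph=self.graph, method=self.method)
        conc = res.venous_plasma_conc[plasma_idx]
        urine = (float(res.urinary_fraction[urine_idx])
                 if urine_idx is not None else None)
        return conc, urine

    def log_likelihood(self, i: int, physiology: PhysiologyVector,
                       g: np.ndarray, sigma2: float):
        ind = self.observations[i]
        try:
            conc, urine = self.outputs(i, physiology, g)
        except pbpk.SimulationError as err:  # pragma: no cover - defensive
            warnings.warn(f"simulation failed ({err}); likelihood -inf")
            return -np.inf, (None, None)
        ll = log_likelihood_individual(
            ind.conc[ind.usable], conc, sigma2,
            urine_obs=ind.urine_fraction, urine_model=urine,
            urine_rel_sd=ind.urine_rel_sd)
        return ll, (conc, urine)


# --------------------------------------------------------------------------
# Full population model bundle
# --------------------------------------------------------------------------


def covariate_scaling(grid: PopulationGrid, names: Sequence[str],
                      is_log: np.ndarray, reference: IndividualCovariates,
                      covariates: IndividualCovariates):
    """Affine covariate maps from the sampled population moments (defined at
    the ``reference`` covariates) to one individual's scaled moments:
    ``M_i = a*M + c`` and ``S_i = d*S``.

    Height-scaled (volume) parameters carry ``(H/Hbar)^alpha`` times the
    grid's relative age/gender factor multiplicatively; lognormal
    parameters pick up the grid factor additively on the log scale.
    """
    K = len(names)
    a = np.ones(K)
    c = np.zeros(K)
    d = np.ones(K)
    for k, name in enumerate(names):
        m_i, s_i = interpolate_population_moments(grid, covariates, name)
        m_r, s_r = interpolate_population_moments(grid, reference, name)
        hs = height_scale(grid, covariates, name)
        if is_log[k]:
            c[k] = m_i - m_r
            d[k] = s_i / s_r
        else:
            a[k] = (m_i / m_r) * hs
            d[k] = (s_i / s_r) * hs
    return a, c, d


def feasible_volumes(target: float, mu: np.ndarray, lo: np.ndarray,
                     hi: np.ndarray) -> np.ndarray:
    """A volume vector within [lo, hi] summing exactly to ``target``.

    Starts from the population means rescaled to the target and moves every
    organ proportionally to its remaining slack, which preserves bounds and
    closes the residual in one step.
    """
    if not (lo.sum() <= target <= hi.sum()):
        raise pbpk.InvalidPhysiologyError(
            f"body weight {target} outside feasible range "
            f"[{lo.sum():.3g}, {hi.sum():.3g}]")
    w = np.clip(mu * target / mu.sum(), lo, hi)
    for _ in range(50):
        r = target - w.sum()
        if abs(r) <= 1e-12 * max(1.0, target):
            break
        slack = (hi - w) if r > 0 else (lo - w)
        w = w + slack * (r / slack.sum())
        w = np.clip(w, lo, hi)
    w[np.argmax(hi - lo)] += target - w.sum()  # absorb rounding residue
    return w


class PopulationPKModel:
    """Bundles layout, priors, covariate scaling, data and the PK evaluator.

    Pre-computes the per-individual affine covariate scaling of the sampled
    population moments: ``M_ik = a_ik * M_k + c_ik`` and
    ``S_ik = d_ik * S_k`` where ``a``/``d`` carry the height (and relative
    age/gender grid) scaling for volumes and ``c`` the additive log-scale
    shifts for lognormal parameters.
    """

    def __init__(self, grid: PopulationGrid, observations: ObservationSet,
                 prior_config: PriorConfig | None = None,
                 compound_base: CompoundProperties | None = None,
                 reference: IndividualCovariates | None = None,
                 method: str = "expm"):
        self.grid = grid
        self.observations = observations
        self.layout = ParameterLayout(n_individuals=observations.n)
        self.reference = reference or observations[0].covariates
        self.priors = build_prior_catalogue(grid, self.reference, prior_config)
        self.evaluator = CohortEvaluator(observations, compound_base,
                                         method=method)
        K = self.layout.K
        N = self.layout.n_individuals
        self.scale_a = np.ones((N, K))
        self.shift_c = np.zeros((N, K))
        self.scale_d = np.ones((N, K))
        for i, ind in enumerate(observations):
            (self.scale_a[i], self.shift_c[i],
             self.scale_d[i]) = self.covariate_scaling(ind.covariates)
        vols = [n.startswith("volume_") for n in self.priors.names]
        self.volume_mask = np.array(vols)
        self.body_weights = np.array(
            [ind.covariates.body_weight for ind in observations])

    def covariate_scaling(self, covariates: IndividualCovariates):
        """Affine maps (a, c, d) from sampled (M, S) to one individual's
        covariate-scaled moments: ``M_i = a*M + c``, ``S_i = d*S``."""
        return covariate_scaling(self.grid, self.priors.names,
                                 self.priors.is_log, self.reference,
                                 covariates)

    # -- scale transforms --------------------------------------------------

    def natural(self, x_row: np.ndarray) -> np.ndarray:
        """Sampling scale -> natural scale for one theta^I row."""
        out = np.array(x_row, float)
        out[self.priors.is_log] = np.exp(out[self.priors.is_log])
        return out

    def sampling_scale(self, theta_nat: np.ndarray) -> np.ndarray:
        out = np.array(theta_nat, float)
        out[self.priors.is_log] = np.log(out[self.priors.is_log])
        return out

    def physiology(self, x_row: np.ndarray) -> PhysiologyVector:
        nat = self.natural(x_row)
        return PhysiologyVector(dict(zip(self.priors.names, nat)))

    def scaled_moments(self, M: np.ndarray, S: np.ndarray):
        """Per-individual (N, K) covariate-scaled moments."""
        return (self.scale_a * M[None, :] + self.shift_c,
                self.scale_d * S[None, :])

    # -- prior pieces -------------------------------------------------------

    def theta_logprior(self, X: np.ndarray, M: np.ndarray,
                       S: np.ndarray) -> np.ndarray:
        """(N, K) truncated-normal log densities of theta rows (sampling scale).

        Includes the log-scale Jacobian for lognormal parameters so that the
        density is that of theta on its sampling scale (the scale on which
        the chain moves); truncation bounds are the static parameter bounds.
        """
        mu, sd = self.scaled_moments(M, S)
        return trunc_normal_logpdf(X, mu, sd, self.priors.x_lower[None, :],
                                   self.priors.x_upper[None, :])

    def log_prior(self, vec: np.ndarray) -> float:
        theta, g, sigma2, M, S = self.layout.unpack(vec)
        parts = [
            float(np.sum(self.theta_logprior(theta, M, S))),
            self.priors.global_logpdf(g),
            self.priors.sigma2_logpdf(sigma2),
            float(np.sum(self.priors.hyper_M_logpdf(M))),
            float(np.sum(self.priors.hyper_S_logpdf(S))),
        ]
        return float(sum(parts))

    def log_likelihood(self, vec: np.ndarray) -> float:
        theta, g, sigma2, _M, _S = self.layout.unpack(vec)
        total = 0.0
        for i in range(self.layout.n_individuals):
            ll, _ = self.evaluator.log_likelihood(
                i, self.physiology(theta[i]), g, sigma2)
            total += ll
        return total

    def log_posterior(self, vec: np.ndarray) -> float:
        """Unnormalised log posterior (likelihood x prior, evidence dropped)."""
        lp = self.log_prior(vec)
        if not np.isfinite(lp):
            return -np.inf
        return lp + self.log_likelihood(vec)

    # -- initial state ------------------------------------------------------

    def initial_state(self) -> np.ndarray:
        """Prior-centred start: b = 0 with volumes projected onto the
        body-weight constraint."""
        K = self.layout.K
        N = self.layout.n_individuals
        M0 = self.priors.M_mu.copy()
        S0 = self.priors.S_mu.copy()
        mu, _sd = self.scaled_moments(M0, S0)
        theta = mu.copy()
        vm = self.volume_mask
        lo = self.priors.x_lower[vm]
        hi = self.priors.x_upper[vm]
        for i in range(N):
            theta[i, vm] = feasible_volumes(self.body_weights[i],
                                            mu[i, vm], lo, hi)
        sigma2 = 0.01
        return self.layout.pack(theta, self.priors.g_start.copy(), sigma2,
                                M0, S0)
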