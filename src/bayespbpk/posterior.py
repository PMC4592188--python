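"""Posterior post-processing: random effects, dependency structure,
population generation, correlations and marginal summaries.

The posterior distribution is represented by ``Z`` thinned subsamples of
the full chain.  For each subsample ``z`` the individual parameters are
standardised against that draw's covariate-scaled population moments to
give the posterior random-effects matrix ``b[z]`` (N x K); the population
dependency structure is then the equal-weight Gaussian mixture over the
per-subsample components ``(mean of b[z], covariance of b[z])``.  New
virtual individuals are generated by picking a subsample at random, drawing
a random-effects vector from its (possibly rank-deficient) Gaussian
component and mapping it back through the covariate model with the same
subsample's population moments and global substance parameters -- thereby
propagating hyperparameter uncertainty into population simulations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Sequence, Tuple

import numpy as np
from scipy import stats

from .covariates import IndividualCovariates
from .hierarchy import PopulationPKModel

__all__ = [
    "PosteriorSample",
    "extract_random_effects",
    "fit_dependency_mixture",
    "generate_individual",
    "generate_population",
    "CorrelationDistribution",
    "correlation_analysis",
    "intraindividual_correlation",
    "MarginalSummary",
    "marginal_summaries",
    "population_marginal_draws",
]


@dataclass
class PosteriorSample:
    """Z thinned posterior draws with their chain indices."""

    model: PopulationPKModel
    states: np.ndarray  # (Z, dim)
    indices: np.ndarray | None = None

    def __post_init__(self):
        self.states = np.atleast_2d(np.asarray(self.states, float))

    @property
    def Z(self) -> int:
        return self.states.shape[0]

    # Unpacked views (sampling scale for theta and M)
    @property
    def theta(self) -> np.ndarray:  # (Z, N, K)
        lay = self.model.layout
        return self.states[:, : lay.n_individuals * lay.K].reshape(
            self.Z, lay.n_individuals, lay.K)

    @property
    def globals_(self) -> np.ndarray:  # (Z, L)
        return self.states[:, self.model.layout.global_slice]

    @property
    def sigma2(self) -> np.ndarray:
        return self.states[:, self.model.layout.sigma2_index]

    @property
    def M(self) -> np.ndarray:  # (Z, K)
        return self.states[:, self.model.layout.M_slice]

    @property
    def S(self) -> np.ndarray:
        return self.states[:, self.model.layout.S_slice]

    def theta_natural(self) -> np.ndarray:
        """(Z, N, K) individual parameters on the natural scale."""
        out = self.theta.copy()
        il = self.model.priors.is_log
        out[..., il] = np.exp(out[..., il])
        return out


def extract_random_effects(sample: PosteriorSample) -> np.ndarray:
    """Posterior random effects ``b[z, i, k]`` by inverting the covariate
    model with each draw's own population moments:
    ``b = (theta - M_scaled) / S_scaled`` on the sampling scale."""
    m = sample.model
    mu = (m.scale_a[None] * sample.M[:, None, :] + m.shift_c[None])
    sd = m.scale_d[None] * sample.S[:, None, :]
    if np.any(sd <= 0):
        raise ValueError("non-positive scaled S in posterior draw")
    return (sample.theta - mu) / sd


def fit_dependency_mixture(b: np.ndarray):
    """Equal-weight Gaussian mixture components over subsamples.

    Returns ``(b_bar (Z, K), Sigma (Z, K, K))`` where each component is the
    mean and sample covariance of the N random-effect rows of one
    subsample.  Requires at least two individuals.
    """
    b = np.asarray(b, float)
    if b.ndim != 3 or b.shape[1] < 2:
        raise ValueError("need b of shape (Z, N >= 2, K)")
    bbar = b.mean(axis=1)
    centred = b - bbar[:, None, :]
    n = b.shape[1]
    sigma = np.einsum("zik,zil->zkl", centred, centred) / (n - 1)
    return bbar, sigma


def _component_sqrt(sigma: np.ndarray, rel_tol: float = 1e-10) -> np.ndarray:
    """Spectral square root with small negative eigenvalues clipped to 0."""
    w, U = np.linalg.eigh(sigma)
    w = np.where(w > rel_tol * max(w.max(), 0.0), w, 0.0)
    return U * np.sqrt(w)[None, :]


class GenerationError(RuntimeError):
    pass


def _draw_component(sample, bbar, sigma_sqrt, covariates, rng,
                    max_attempts=100):
    m = sample.model
    pr = m.priors
    a, c, d = m.covariate_scaling(covariates)
    K = len(a)
    for _ in range(max_attempts):
        z = int(rng.integers(sample.Z))
        b = bbar[z] + sigma_sqrt[z] @ rng.standard_normal(K)
        mu = a * sample.M[z] + c
        sd = d * sample.S[z]
        x = mu + sd * b
        if np.all((x >= pr.x_lower) & (x <= pr.x_upper)):
            return x, sample.globals_[z], z
    raise GenerationError(
        f"no in-bounds individual after {max_attempts} attempts; "
        "posterior component variance may exceed the physiological bounds")


def generate_individual(sample: PosteriorSample,
                        covariates: IndividualCovariates,
                        rng: np.random.Generator,
                        bbar: np.ndarray | None = None,
                        sigma: np.ndarray | None = None,
                        max_attempts: int = 100):
    """Generate one new individual parameter vector from the posterior.

    Draws a subsample ``z`` uniformly, a random-effects vector from that
    component's Gaussian (rank-deficient covariances handled spectrally)
    and maps it through the covariate model with the draw's population
    moments.  Returns ``(theta_x (K, sampling scale), theta_G (L,), z)``.
    Out-of-bounds vectors are redrawn up to ``max_attempts`` times.
    """
    if bbar is None or sigma is None:
        b = extract_random_effects(sample)
        bbar, sigma = fit_dependency_mixture(b)
    sqrts = np.stack([_component_sqrt(s) for s in sigma])
    return _draw_component(sample, bbar, sqrts, covariates, rng,
                           max_attempts)


def generate_population(sample: PosteriorSample,
                        covariates: IndividualCovariates | Sequence,
                        n: int, rng: np.random.Generator,
                        max_attempts: int = 100):
    """Generate ``n`` individuals; returns ``(X (n,K), G (n,L), z (n,))``."""
    b = extract_random_effects(sample)
    bbar, sigma = fit_dependency_mixture(b)
    sqrts = np.stack([_component_sqrt(s) for s in sigma])
    covs = (covariates if isinstance(covariates, (list, tuple))
            else [covariates] * n)
    if len(covs) != n:
        raise ValueError("need one covariate record per generated individual")
    K = sample.model.layout.K
    L = sample.model.layout.L
    X = np.empty((n, K))
    G = np.empty((n, L))
    zs = np.empty(n, int)
    for j in range(n):
        X[j], G[j], zs[j] = _draw_component(sample, bbar, sqrts, covs[j],
                                            rng, max_attempts)
    return X, G, zs


# --------------------------------------------------------------------------
# Correlation analysis
# --------------------------------------------------------------------------


@dataclass
class CorrelationDistribution:
    """Distribution over subsamples of one pairwise population correlation."""

    pair: Tuple[str, str]
    values: np.ndarray  # (Z,) correlation across individuals per subsample
    mean: float
    interval: Tuple[float, float]  # 2.5/97.5 percentiles over subsamples
    mean_interval: Tuple[float, float]  # mean of per-subsample Fisher CIs
    p_value: float
    significant: bool

    def __post_init__(self):
        assert np.all(np.abs(self.values) <= 1 + 1e-12)


def _fisher_ci(r: np.ndarray, n: int, alpha: float = 0.05):
    z = np.arctanh(np.clip(r, -1 + 1e-12, 1 - 1e-12))
    half = stats.norm.ppf(1 - alpha / 2) / np.sqrt(n - 3)
    return np.tanh(z - half), np.tanh(z + half)


def correlation_analysis(sample: PosteriorSample,
                         pairs: Sequence[Tuple[str, str]] | None = None,
                         alpha: float = 0.05) -> Dict[Tuple[str, str],
                                                      CorrelationDistribution]:
    """Population-level parameter correlations with their uncertainty.

    For every subsample the Pearson correlation of the posterior random
    effects is computed *across the N individuals*; the distribution of
    these Z values expresses the uncertainty of the population correlation.
    Significance is a two-sided one-sample test of the Fisher-z-transformed
    per-subsample correlations against zero.  Both the subsample-percentile
    interval and the mean of the per-subsample Fisher confidence intervals
    are reported.
    """
    m = sample.model
    names = list(m.priors.names)
    b = extract_random_effects(sample)
    Z, N, K = b.shape
    if N < 3:
        raise ValueError("need at least 3 individuals for correlations")
    if pairs is None:
        pairs = [(names[i], names[j]) for i in range(K) for j in range(i + 1, K)]
    # per-subsample correlation matrices across individuals
    centred = b - b.mean(axis=1, keepdims=True)
    sd = centred.std(axis=1, ddof=1)
    out: Dict[Tuple[str, str], CorrelationDistribution] = {}
    for p, q in pairs:
        i, j = names.index(p), names.index(q)
        cov = np.einsum("zn,zn->z", centred[:, :, i], centred[:, :, j]) / (N - 1)
        with np.errstate(invalid="ignore", divide="ignore"):
            r = cov / (sd[:, i] * sd[:, j])
        r = np.clip(np.nan_to_num(r, nan=0.0), -1.0, 1.0)
        zvals = np.arctanh(np.clip(r, -1 + 1e-12, 1 - 1e-12))
        if np.ptp(zvals) == 0:
            pval = 0.0 if abs(r[0]) > 0 else 1.0
        else:
            pval = float(stats.ttest_1samp(zvals, 0.0).pvalue)
        lo_s, hi_s = np.percentile(r, [2.5, 97.5])
        ci_lo, ci_hi = _fisher_ci(r, N, alpha)
        out[(p, q)] = CorrelationDistribution(
            pair=(p, q), values=r, mean=float(r.mean()),
            interval=(float(lo_s), float(hi_s)),
            mean_interval=(float(ci_lo.mean()), float(ci_hi.mean())),
            p_value=pval, significant=pval < alpha)
    return out


def intraindividual_correlation(sample: PosteriorSample, individual: int,
                                pair: Tuple[str, str]) -> float:
    """Posterior (intraindividual) correlation of two parameters for a fixed
    individual, computed across the autocorrelation-free subsamples."""
    names = list(sample.model.priors.names)
    i, j = names.index(pair[0]), names.index(pair[1])
    draws = sample.theta[:, individual, :]
    return float(np.corrcoef(draws[:, i], draws[:, j])[0, 1])


# --------------------------------------------------------------------------
# Marginal summaries
# --------------------------------------------------------------------------


@dataclass
class MarginalSummary:
    geometric_mean: float
    cv: float  # natural-scale coefficient of variation
    kde_grid: np.ndarray = field(repr=False, default=None)
    kde_density: np.ndarray = field(repr=False, default=None)


def marginal_summaries(values: np.ndarray, lower: float | None = None,
                       upper: float | None = None,
                       n_grid: int = 256) -> MarginalSummary:
    """Geometric mean, natural-scale CV and a boundary-corrected KDE.

    The KDE uses a Gaussian kernel with Silverman bandwidth, reflected at
    the truncation boundaries and renormalised over the bounded support so
    that it integrates to one there.
    """
    x = np.asarray(values, float)
    if np.any(x <= 0):
        raise ValueError("geometric statistics need positive values")
    gm = float(np.exp(np.mean(np.log(x))))
    mean = x.mean()
    cv = float(x.std(ddof=1) / mean) if x.size > 1 else 0.0
    lo = float(lower) if lower is not None else float(x.min())
    hi = float(upper) if upper is not None else float(x.max())
    if hi <= lo:
        hi = lo + max(abs(lo), 1e-12)
    grid = np.linspace(lo, hi, n_grid)
    sd = x.std(ddof=1)
    if sd == 0:
        dens = np.zeros(n_grid)
        dens[np.argmin(np.abs(grid - x[0]))] = 1.0
        dens /= np.trapezoid(dens, grid) or 1.0
    else:
        bw = 0.9 * min(sd, (np.percentile(x, 75) - np.percentile(x, 25)) /
                       1.349 or sd) * x.size ** (-0.2)
        pts = np.concatenate([x, 2 * lo - x, 2 * hi - x])  # boundary mirror
        diff = (grid[:, None] - pts[None, :]) / bw
        dens = np.exp(-0.5 * diff ** 2).sum(axis=1) / (
            x.size * bw * np.sqrt(2 * np.pi))
        dens /= np.trapezoid(dens, grid)
    return MarginalSummary(geometric_mean=gm, cv=cv, kde_grid=grid,
                           kde_density=dens)


def population_marginal_draws(sample: PosteriorSample,
                              covariates: IndividualCovariates, n: int,
                              rng: np.random.Generator) -> np.ndarray:
    """(n, K) natural-scale population draws including hyperparameter
    uncertainty, for marginal prior/posterior comparisons."""
    X, _G, _z = generate_population(sample, covariates, n, rng)
    out = X.copy()
    il = sample.model.priors.is_log
    out[:, il] = np.exp(out[:, il])
    return out
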