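"""Block-wise Metropolis-Hastings sampler for the hierarchical PBPK model.

One iteration visits every block once in a fixed order: the individual
parameter vectors (one block per subject), the global substance parameters
together with the measurement variance, then the population means ``M`` in
two blocks and the population SDs ``S`` in two blocks.  Every scalar of a
block is proposed independently from a truncated normal centred at its
current value, and the acceptance ratio includes the asymmetric
truncated-proposal (Hastings) correction.

Organ volumes are subject to the sum constraint ``sum(V) = body weight``;
they are proposed through a sequential scheme that processes organs in
ascending order of static bound width and tightens each organ's bounds
dynamically against the remaining body weight, assigning the final organ
the exact remainder.  The proposal density of this move (forward and
reverse) is the product of the sequential truncated-normal densities under
their dynamic bounds; the remainder organ contributes no density term.

Proposal scales are adapted only between runs (pre-runs), never within a
run, preserving the Markov property.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Dict, Mapping, Sequence

import numpy as np
from scipy.special import ndtr, ndtri

from .hierarchy import PopulationPKModel, trunc_normal_logpdf
from .pbpk import InvalidPhysiologyError

__all__ = [
    "truncnorm_sample",
    "mh_block_update",
    "run_generic_sampler",
    "sample_organ_volumes",
    "organ_volume_logq",
    "ProposalConfig",
    "SamplerConfig",
    "Chain",
    "PBPKSampler",
    "run_sampler",
    "adapt_proposals",
    "gelman_rubin",
    "thin_subsample",
]

_DEGENERATE_WIDTH = 1e-13
_HALF_LOG2PI = 0.9189385332046727


def _ndtr_s(z: float) -> float:
    return 0.5 * (1.0 + math.erf(z / math.sqrt(2.0)))


def _tn_logpdf_s(x: float, mu: float, sd: float, lo: float, hi: float) -> float:
    """Scalar truncated-normal log density (hot path of the volume sweep)."""
    mass = _ndtr_s((hi - mu) / sd) - _ndtr_s((lo - mu) / sd)
    if mass <= 0.0:
        return -np.inf
    z = (x - mu) / sd
    return -_HALF_LOG2PI - math.log(sd) - 0.5 * z * z - math.log(mass)


def _tn_sample_s(rng, mu: float, sd: float, lo: float, hi: float) -> float:
    a = _ndtr_s((lo - mu) / sd)
    b = _ndtr_s((hi - mu) / sd)
    u = a + (b - a) * rng.random()
    x = mu + sd * float(ndtri(min(max(u, 1e-15), 1.0 - 1e-15)))
    return min(max(x, lo), hi)


def truncnorm_sample(rng: np.random.Generator, mu, sd, lo, hi):
    """Draw from normal(mu, sd) truncated to [lo, hi] (inverse-CDF)."""
    mu, sd, lo, hi = np.broadcast_arrays(
        *[np.asarray(a, float) for a in (mu, sd, lo, hi)])
    a = ndtr((lo - mu) / sd)
    b = ndtr((hi - mu) / sd)
    u = a + (b - a) * rng.random(mu.shape)
    x = mu + sd * ndtri(np.clip(u, 1e-15, 1 - 1e-15))
    return np.clip(x, lo, hi)


# --------------------------------------------------------------------------
# Generic single-block Metropolis-Hastings (used for toy/oracle targets)
# --------------------------------------------------------------------------


def mh_block_update(state: np.ndarray, block: np.ndarray,
                    log_posterior: Callable[[np.ndarray], float],
                    proposal_sd: np.ndarray, lower: np.ndarray,
                    upper: np.ndarray, rng: np.random.Generator,
                    current_logp: float | None = None):
    """One MH update of ``state[block]`` with truncated-normal proposals.

    Returns ``(state, logp, accepted)``.  The acceptance ratio includes the
    Hastings correction for the asymmetric truncated proposal; a NaN
    posterior is treated as ``-inf`` with a warning.
    """
    if current_logp is None:
        current_logp = log_posterior(state)
    cur = state[block]
    sd = np.broadcast_to(np.asarray(proposal_sd, float), cur.shape)
    lo = np.broadcast_to(np.asarray(lower, float), cur.shape)
    hi = np.broadcast_to(np.asarray(upper, float), cur.shape)
    cand = truncnorm_sample(rng, cur, sd, lo, hi)
    prop = state.copy()
    prop[block] = cand
    lp = log_posterior(prop)
    if np.isnan(lp):
        warnings.warn("posterior returned NaN; treated as -inf", stacklevel=2)
        lp = -np.inf
    logq = (float(np.sum(trunc_normal_logpdf(cur, cand, sd, lo, hi)))
            - float(np.sum(trunc_normal_logpdf(cand, cur, sd, lo, hi))))
    if np.log(rng.random()) <= lp - current_logp + logq:
        return prop, lp, True
    return state, current_logp, False


def run_generic_sampler(log_posterior, x0: np.ndarray,
                        blocks: Sequence[np.ndarray], proposal_sd: np.ndarray,
                        lower: np.ndarray, upper: np.ndarray, n_iter: int,
                        rng: np.random.Generator):
    """Block-wise MH over an arbitrary bounded target; returns (samples, acc)."""
    x = np.asarray(x0, float).copy()
    lp = log_posterior(x)
    out = np.empty((n_iter + 1, x.size))
    out[0] = x
    acc = np.zeros(len(blocks))
    for n in range(1, n_iter + 1):
        for j, block in enumerate(blocks):
            x, lp, ok = mh_block_update(x, block, log_posterior,
                                        proposal_sd[block], lower[block],
                                        upper[block], rng, lp)
            acc[j] += ok
        out[n] = x
    return out, acc / max(n_iter, 1)


# --------------------------------------------------------------------------
# Sum-constrained organ-volume proposal
# --------------------------------------------------------------------------


def _volume_sweep(centers, lower, upper, bw, prop_sd, order,
                  rng=None, values=None):
    """Shared engine: sample (rng given) or evaluate (values given).

    Processes organs in ``order``; for each organ the static bounds are
    tightened against the remaining body weight so the sweep always stays
    feasible (upper* uses min -- the feasible reading of the bound pair);
    the final organ is assigned the exact remainder and carries no
    proposal-density term.  Returns (values, log density).
    """
    V = len(centers)
    suffix_lo = np.concatenate([np.cumsum(lower[order][::-1])[::-1], [0.0]])
    suffix_hi = np.concatenate([np.cumsum(upper[order][::-1])[::-1], [0.0]])
    out = np.empty(V) if values is None else np.asarray(values, float)
    logq = 0.0
    rem = bw
    for pos, v in enumerate(order[:-1]):
        lo_d = max(lower[v], rem - suffix_hi[pos + 1])
        hi_d = min(upper[v], rem - suffix_lo[pos + 1])
        if hi_d < lo_d:  # numerical corner; clamp to the feasible point
            lo_d = hi_d = 0.5 * (lo_d + hi_d)
        if hi_d - lo_d <= _DEGENERATE_WIDTH:
            x = 0.5 * (lo_d + hi_d)
            if values is None:
                out[v] = x
        else:
            c = min(max(centers[v], lo_d), hi_d)
            if values is None:
                x = _tn_sample_s(rng, c, prop_sd[v], lo_d, hi_d)
                out[v] = x
            else:
                x = out[v]
                if not (lo_d - 1e-12 <= x <= hi_d + 1e-12):
                    return out, -np.inf
            logq += _tn_logpdf_s(x, c, prop_sd[v], lo_d, hi_d)
        rem -= out[v]
    last = order[-1]
    if values is None:
        out[last] = rem
    return out, logq


def _volume_order(lower: np.ndarray, upper: np.ndarray,
                  names: Sequence[str] | None = None) -> np.ndarray:
    """Ascending static-width order; ties broken by name for determinism."""
    width = upper - lower
    if names is None:
        return np.argsort(width, kind="stable")
    keys = sorted(range(len(width)), key=lambda j: (width[j], names[j]))
    return np.asarray(keys)


def sample_organ_volumes(current: np.ndarray, lower: np.ndarray,
                         upper: np.ndarray, bw: float, prop_sd: np.ndarray,
                         rng: np.random.Generator,
                         order: np.ndarray | None = None,
                         names: Sequence[str] | None = None):
    """Propose a constrained volume vector; returns (candidate, logq_forward).

    The candidate sums to ``bw`` exactly (up to float rounding) and respects
    every static bound.  Raises if ``bw`` lies outside the globally feasible
    range [sum(lower), sum(upper)].
    """
    current = np.asarray(current, float)
    lower = np.asarray(lower, float)
    upper = np.asarray(upper, float)
    if not (lower.sum() <= bw <= upper.sum()):
        raise InvalidPhysiologyError(
            f"body weight {bw} infeasible for bounds "
            f"[{lower.sum():.6g}, {upper.sum():.6g}]")
    if order is None:
        order = _volume_order(lower, upper, names)
    cand, logq = _volume_sweep(current, lower, upper, bw, prop_sd, order,
                               rng=rng)
    return cand, logq


def organ_volume_logq(values: np.ndarray, centers: np.ndarray,
                      lower: np.ndarray, upper: np.ndarray, bw: float,
                      prop_sd: np.ndarray,
                      order: np.ndarray | None = None,
                      names: Sequence[str] | None = None) -> float:
    """Log proposal density of ``values`` under a sweep centred at ``centers``.

    Used for the reverse-move term of the Hastings ratio; the ordering
    depends only on the static bounds, so forward and reverse sweeps visit
    organs identically.
    """
    if order is None:
        order = _volume_order(np.asarray(lower, float),
                              np.asarray(upper, float), names)
    _, logq = _volume_sweep(np.asarray(centers, float),
                            np.asarray(lower, float),
                            np.asarray(upper, float), bw,
                            np.asarray(prop_sd, float), order, values=values)
    return logq


# --------------------------------------------------------------------------
# Configuration, chain container
# --------------------------------------------------------------------------


@dataclass
class ProposalConfig:
    """Per-scalar truncated-normal proposal SDs over the flat state."""

    sd: np.ndarray
    floor: float = 1e-12

    def __post_init__(self):
        self.sd = np.asarray(self.sd, float)
        if np.any(self.sd <= 0):
            raise ValueError("proposal SDs must be positive")


@dataclass
class SamplerConfig:
    """Run configuration of the block-wise sampler.

    ``pre_runs`` are short adaptation runs; after each one the proposal SDs
    are set to ``adapt_fraction x`` the empirical SD of the pre-run chain
    (per block, defaulting to 2.38/sqrt(block dimension)) and the start
    values to the last pre-run state.  ``n_iter`` is the length of the main
    run and ``burn_in`` the number of leading main-run iterations discarded
    by downstream analyses.
    """

    n_iter: int = 4000
    burn_in: int = 1000
    pre_runs: tuple = (300, 500)
    adapt_fraction: float | None = None
    thin_Z: int = 500
    seed: int = 0

    def __post_init__(self):
        if self.burn_in >= self.n_iter:
            raise ValueError("burn_in must be smaller than n_iter")


@dataclass
class Chain:
    """Stored trajectory of the full flat state (one row per iteration)."""

    states: np.ndarray  # (n_stored, dim)
    log_posterior: np.ndarray  # (n_stored,)
    acceptance: Dict[str, float]
    burn_in: int = 0
    seed: int | None = None
    meta: Dict = field(default_factory=dict)

    @property
    def n_iterations(self) -> int:
        return self.states.shape[0]

    def post_burn_in(self) -> np.ndarray:
        return self.states[self.burn_in:]

    def map_state(self) -> np.ndarray:
        """The stored draw with the highest joint posterior density."""
        return self.states[int(np.argmax(self.log_posterior))]

    def save(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as fh:
            fh.create_dataset("states", data=self.states, chunks=True,
                              compression="gzip", compression_opts=1)
            fh.create_dataset("log_posterior", data=self.log_posterior)
            fh.attrs["burn_in"] = self.burn_in
            fh.attrs["seed"] = -1 if self.seed is None else self.seed
            fh.attrs["acceptance"] = json.dumps(self.acceptance)
            fh.attrs["meta"] = json.dumps(self.meta)

    @classmethod
    def load(cls, path) -> "Chain":
        import h5py

        with h5py.File(path, "r") as fh:
            seed = int(fh.attrs["seed"])
            return cls(states=fh["states"][...],
                       log_posterior=fh["log_posterior"][...],
                       acceptance=json.loads(fh.attrs["acceptance"]),
                       burn_in=int(fh.attrs["burn_in"]),
                       seed=None if seed < 0 else seed,
                       meta=json.loads(fh.attrs["meta"]))


# --------------------------------------------------------------------------
# The full-model sampler
# --------------------------------------------------------------------------


class PBPKSampler:
    """Block-wise MH over the full hierarchical state of a
    :class:`~bayespbpk.hierarchy.PopulationPKModel`."""

    def __init__(self, model: PopulationPKModel,
                 proposal: ProposalConfig | None = None,
                 rng: np.random.Generator | int | None = None,
                 recenter: bool = True):
        self.model = model
        self.layout = model.layout
        self.rng = (rng if isinstance(rng, np.random.Generator)
                    else np.random.default_rng(rng))
        self.proposal = proposal or ProposalConfig(self.default_proposal_sd())
        pr = model.priors
        self._vm = model.volume_mask
        self._vol_names = [n for n, m in zip(pr.names, self._vm) if m]
        self._vol_lo = pr.x_lower[self._vm]
        self._vol_hi = pr.x_upper[self._vm]
        self._vol_order = _volume_order(self._vol_lo, self._vol_hi,
                                        self._vol_names)
        self.recenter = recenter
        # the widest-bounded organ absorbs the volume residual of the
        # recentering translation, keeping the body-weight sum exact; wide
        # bounds come with a wide population SD, so the absorbed residual
        # costs the least prior mass there
        widths = pr.x_upper - pr.x_lower
        vol_idx = np.flatnonzero(self._vm)
        self._absorb_k = int(vol_idx[np.argmax(widths[vol_idx])])
        sd0 = np.where(np.isfinite(pr.M_sd), pr.M_sd, pr.S_mu)
        self.recenter_sd = 0.5 * 2.38 / np.sqrt(model.layout.K) * sd0
        self.recenter_sd[self._absorb_k] = 0.0
        # the elimination-invariant shear: when fu moves multiplicatively,
        # the specific clearance levels co-shift on the log scale so the
        # spec * V * fu clearance products stay fixed
        self._clearance_ks = np.array([
            pr.names.index(n) for n in ("specCL", "specTS") if n in pr.names])
        # product-invariant organ-volume/clearance shears: scaling an
        # eliminating organ's volume column multiplicatively while the
        # matching specific rate shifts oppositely on the log scale keeps
        # the spec * V clearance product fixed
        self._shear_pairs = [
            (pr.names.index(v), pr.names.index(r))
            for v, r in (("volume_liver", "specCL"),
                         ("volume_kidney", "specTS"))
            if v in pr.names and r in pr.names]
        self.shear_sd = np.full(len(self._shear_pairs), 0.05)
        try:
            self._fu_index = list(model.layout.global_names).index(
                "fraction_unbound")
        except ValueError:
            self._fu_index = None
        self.recenter_fu_sd = 0.05 if self._fu_index is not None else 0.0
        #: optional Cholesky factor for correlated location proposals
        #: (adapted between runs from the M chain covariance)
        self.recenter_chol: np.ndarray | None = None
        #: per-parameter SD of the log-scale S rescaling component
        self.rescale_sd = np.full(model.layout.K, 0.02)
        self.rescale_sd[self._absorb_k] = 0.0
        self.reset()

    # -- proposal defaults -------------------------------------------------

    def default_proposal_sd(self) -> np.ndarray:
        """Starting proposal SDs scaled to the conditional posterior widths.

        Individual parameters start at a fraction of their (covariate
        scaled) prior SD; the population mean M of a parameter sees N
        individual values, so its conditional width is about S/sqrt(N) (and
        about S/sqrt(2N) for the population SD S itself).  All per-block
        scales carry the classic 2.38/sqrt(d) factor.
        """
        m = self.model
        pr = m.priors
        lay = self.layout
        N = lay.n_individuals
        sd = np.empty(lay.dimension)
        _mu, s_scaled = m.scaled_moments(pr.S_mu, pr.S_mu)
        frac = 2.38 / np.sqrt(lay.K)
        for i in range(N):
            sd[lay.individual_slice(i)] = frac * s_scaled[i] * 0.5
        sd[lay.global_slice] = 0.02 * (pr.g_upper - pr.g_lower)
        sd[lay.sigma2_index] = 0.005
        frac_m = 2.38 / np.sqrt(max(lay.K // 2, 1))
        sd[lay.M_slice] = frac_m * pr.S_mu / np.sqrt(N)
        sd[lay.S_slice] = frac_m * pr.S_mu / np.sqrt(2.0 * N)
        return np.maximum(sd, 1e-12)

    # -- state management --------------------------------------------------

    def reset(self, state: np.ndarray | None = None) -> None:
        vec = (self.model.initial_state() if state is None
               else np.asarray(state, float).copy())
        m = self.model
        self.X, self.g, self.sigma2, self.M, self.S = (
            a.copy() if isinstance(a, np.ndarray) else a
            for a in self.layout.unpack(vec))
        self.ll = np.empty(self.layout.n_individuals)
        for i in range(self.layout.n_individuals):
            self.ll[i], _ = m.evaluator.log_likelihood(
                i, m.physiology(self.X[i]), self.g, self.sigma2)
        self.theta_lp = m.theta_logprior(self.X, self.M, self.S)
        self.hyper_m = m.priors.hyper_M_logpdf(self.M)
        self.hyper_s = m.priors.hyper_S_logpdf(self.S)
        self.accept_counts: Dict[str, int] = {}
        self.try_counts: Dict[str, int] = {}
        self.iteration = 0

    def state_vector(self) -> np.ndarray:
        return self.layout.pack(self.X, self.g, self.sigma2, self.M, self.S)

    def log_posterior_value(self) -> float:
        pr = self.model.priors
        return (float(self.ll.sum()) + float(self.theta_lp.sum())
                + float(self.hyper_m.sum()) + float(self.hyper_s.sum())
                + pr.sigma2_logpdf(self.sigma2) + pr.global_logpdf(self.g))

    def _bump(self, block: str, accepted: bool) -> None:
        self.try_counts[block] = self.try_counts.get(block, 0) + 1
        if accepted:
            self.accept_counts[block] = self.accept_counts.get(block, 0) + 1

    # -- block updates -----------------------------------------------------

    def _update_individual(self, i: int) -> None:
        m = self.model
        pr = m.priors
        lay = self.layout
        sl = lay.individual_slice(i)
        sd = self.proposal.sd[sl]
        cur = self.X[i]
        vm = self._vm
        nv = ~vm
        cand = cur.copy()
        # non-volume scalars: independent truncated normals at static bounds
        cand[nv] = truncnorm_sample(self.rng, cur[nv], sd[nv],
                                    pr.x_lower[nv], pr.x_upper[nv])
        logq = float(np.sum(trunc_normal_logpdf(
            cur[nv], cand[nv], sd[nv], pr.x_lower[nv], pr.x_upper[nv])))
        logq -= float(np.sum(trunc_normal_logpdf(
            cand[nv], cur[nv], sd[nv], pr.x_lower[nv], pr.x_upper[nv])))
        # volumes: sequential constrained sweep + reverse-density term
        bw = m.body_weights[i]
        vols, logq_f = sample_organ_volumes(
            cur[vm], self._vol_lo, self._vol_hi, bw, sd[vm], self.rng,
            order=self._vol_order)
        cand[vm] = vols
        logq_r = organ_volume_logq(cur[vm], vols, self._vol_lo, self._vol_hi,
                                   bw, sd[vm], order=self._vol_order)
        logq += logq_r - logq_f
        lp_row = trunc_normal_logpdf(
            cand, m.scale_a[i] * self.M + m.shift_c[i],
            m.scale_d[i] * self.S, pr.x_lower, pr.x_upper)
        dprior = float(lp_row.sum()) - float(self.theta_lp[i].sum())
        if not np.isfinite(dprior) and not np.isfinite(float(lp_row.sum())):
            self._bump(f"individual_{i}", False)
            return
        ll_new, _ = m.evaluator.log_likelihood(i, m.physiology(cand),
                                               self.g, self.sigma2)
        if np.isnan(ll_new):
            warnings.warn("NaN likelihood treated as -inf", stacklevel=2)
            ll_new = -np.inf
        log_alpha = (ll_new - self.ll[i]) + dprior + logq
        ok = np.log(self.rng.random()) <= log_alpha
        if ok:
            self.X[i] = cand
            self.ll[i] = ll_new
            self.theta_lp[i] = lp_row
        self._bump(f"individual_{i}", ok)

    def _update_global(self) -> None:
        m = self.model
        pr = m.priors
        lay = self.layout
        idx = np.r_[np.arange(lay.global_slice.start, lay.global_slice.stop),
                    lay.sigma2_index]
        sd = self.proposal.sd[idx]
        lo = np.r_[pr.g_lower, pr.sigma2_bounds[0]]
        hi = np.r_[pr.g_upper, pr.sigma2_bounds[1]]
        cur = np.r_[self.g, self.sigma2]
        cand = truncnorm_sample(self.rng, cur, sd, lo, hi)
        logq = float(np.sum(trunc_normal_logpdf(cur, cand, sd, lo, hi))
                     - np.sum(trunc_normal_logpdf(cand, cur, sd, lo, hi)))
        g_new, s2_new = cand[:-1], float(cand[-1])
        ll_new = np.empty_like(self.ll)
        for i in range(lay.n_individuals):
            ll_new[i], _ = m.evaluator.log_likelihood(
                i, m.physiology(self.X[i]), g_new, s2_new)
        dprior = (pr.sigma2_logpdf(s2_new) - pr.sigma2_logpdf(self.sigma2))
        log_alpha = float(ll_new.sum() - self.ll.sum()) + dprior + logq
        ok = np.log(self.rng.random()) <= log_alpha
        if ok:
            self.g, self.sigma2 = g_new, s2_new
            self.ll = ll_new
        self._bump("global_sigma2", ok)

    def _update_population(self, which: str, half: int) -> None:
        m = self.model
        pr = m.priors
        lay = self.layout
        sl = lay.M_slice if which == "M" else lay.S_slice
        cols = np.arange(lay.K)[half::2]
        idx = np.arange(sl.start, sl.stop)[half::2]
        sd = self.proposal.sd[idx]
        if which == "M":
            cur = self.M[cols]
            lo, hi = pr.M_lower[cols], pr.M_upper[cols]
        else:
            cur = self.S[cols]
            lo, hi = pr.S_lower[cols], pr.S_upper[cols]
        cand = truncnorm_sample(self.rng, cur, sd, lo, hi)
        logq = float(np.sum(trunc_normal_logpdf(cur, cand, sd, lo, hi))
                     - np.sum(trunc_normal_logpdf(cand, cur, sd, lo, hi)))
        M_new, S_new = self.M, self.S
        if which == "M":
            M_new = self.M.copy()
            M_new[cols] = cand
            hyper_new = pr.hyper_M_logpdf(M_new)[cols]
            dhyper = float(hyper_new.sum() - self.hyper_m[cols].sum())
        else:
            S_new = self.S.copy()
            S_new[cols] = cand
            hyper_new = pr.hyper_S_logpdf(S_new)[cols]
            dhyper = float(hyper_new.sum() - self.hyper_s[cols].sum())
        lp_cols = trunc_normal_logpdf(
            self.X[:, cols],
            m.scale_a[:, cols] * M_new[cols][None, :] + m.shift_c[:, cols],
            m.scale_d[:, cols] * S_new[cols][None, :],
            pr.x_lower[cols][None, :], pr.x_upper[cols][None, :])
        dprior = float(lp_cols.sum()) - float(self.theta_lp[:, cols].sum())
        log_alpha = dprior + dhyper + logq
        ok = np.isfinite(log_alpha) and \
            np.log(self.rng.random()) <= log_alpha
        if ok:
            if which == "M":
                self.M = M_new
                self.hyper_m[cols] = hyper_new
            else:
                self.S = S_new
                self.hyper_s[cols] = hyper_new
            self.theta_lp[:, cols] = lp_cols
        self._bump(f"{which}_{half}", ok)

    def _update_recenter(self) -> None:
        """Joint translation of (M_k, theta_{.,k}) leaving random effects
        invariant: a funnel-busting move for the centred hierarchy.

        A joint location-scale group move: ``M' = M + delta`` with the
        individual parameters translated along (``theta' = theta + a
        delta``), ``S' = S exp(eps)`` with the random-effect residuals
        rescaled accordingly (``theta' - mu' = (theta - mu) exp(eps)``), so
        the standardised effects ``b`` are invariant under both parts.  Per
        individual the volume component of the move is absorbed by the
        widest-bounded organ so the body-weight sum stays exact.
        Simultaneously the plasma fraction unbound moves multiplicatively
        (``fu' = fu exp(d)``) while the specCL/specTS levels shift by
        ``-d`` on the log scale, keeping the ``spec * V * fu`` clearance
        products invariant — riding the likelihood ridge between the
        global binding parameter and the clearance rates.  The innovation
        is symmetric; the non-unit Jacobian terms are ``(N+1) sum(eps)``
        for the rescaling and ``d`` for the multiplicative fu component.
        The location innovation may be correlated (between-run-adapted
        Cholesky factor) to follow posterior ridges such as
        specTS - kidney volume.
        """
        m = self.model
        pr = m.priors
        N = self.layout.n_individuals
        eta = self.rng.standard_normal(self.layout.K)
        if self.recenter_chol is not None:
            delta = self.recenter_chol @ eta
        else:
            delta = self.recenter_sd * eta
        delta[self._absorb_k] = 0.0
        eps = self.rescale_sd * self.rng.standard_normal(self.layout.K)
        g_new = self.g
        log_jac = float((N + 1) * eps.sum())
        if self._fu_index is not None and self.recenter_fu_sd > 0:
            d_fu = self.recenter_fu_sd * self.rng.standard_normal()
            fu_new = self.g[self._fu_index] * np.exp(d_fu)
            if not (pr.g_lower[self._fu_index] <= fu_new
                    <= pr.g_upper[self._fu_index]):
                self._bump("recenter", False)
                return
            g_new = self.g.copy()
            g_new[self._fu_index] = fu_new
            delta[self._clearance_ks] -= d_fu
            log_jac += d_fu
        # organ-volume/clearance shears: gamma scales the volume column
        # (theta, M, S) multiplicatively, the rate level shifts by -gamma
        gamma = np.zeros(self.layout.K)
        for j, (kv, kr) in enumerate(self._shear_pairs):
            gj = self.shear_sd[j] * self.rng.standard_normal()
            gamma[kv] = gj
            delta[kr] -= gj
            log_jac += (N + 2) * gj
        scale_col = np.exp(gamma)
        M_base = self.M * scale_col
        S_base = self.S * scale_col
        X_base = self.X * scale_col[None, :]
        M_new = M_base + delta
        S_new = S_base * np.exp(eps)
        if (np.any(M_new < pr.M_lower) or np.any(M_new > pr.M_upper)
                or np.any(S_new < pr.S_lower) or np.any(S_new > pr.S_upper)):
            self._bump("recenter", False)
            return
        mu_old = m.scale_a * M_base[None, :] + m.shift_c
        mu_new = m.scale_a * M_new[None, :] + m.shift_c
        X_new = mu_new + (X_base - mu_old) * np.exp(eps)[None, :]
        X_new[:, self._absorb_k] = self.X[:, self._absorb_k]
        moved = X_new - self.X
        X_new[:, self._absorb_k] -= moved[:, self._vm].sum(axis=1)
        if np.any(X_new < pr.x_lower) or np.any(X_new > pr.x_upper):
            self._bump("recenter", False)
            return
        lp_rows = trunc_normal_logpdf(
            X_new, mu_new, m.scale_d * S_new[None, :],
            pr.x_lower[None, :], pr.x_upper[None, :])
        hyper_m_new = pr.hyper_M_logpdf(M_new)
        hyper_s_new = pr.hyper_S_logpdf(S_new)
        ll_new = np.empty_like(self.ll)
        for i in range(N):
            ll_new[i], _ = m.evaluator.log_likelihood(
                i, m.physiology(X_new[i]), g_new, self.sigma2)
        log_alpha = (float(ll_new.sum() - self.ll.sum())
                     + float(lp_rows.sum() - self.theta_lp.sum())
                     + float(hyper_m_new.sum() - self.hyper_m.sum())
                     + float(hyper_s_new.sum() - self.hyper_s.sum())
                     + log_jac)
        ok = np.isfinite(log_alpha) and np.log(self.rng.random()) <= log_alpha
        if ok:
            self.X = X_new
            self.M = M_new
            self.S = S_new
            self.g = g_new
            self.ll = ll_new
            self.theta_lp = lp_rows
            self.hyper_m = hyper_m_new
            self.hyper_s = hyper_s_new
        self._bump("recenter", ok)

    # -- iteration loop ----------------------------------------------------

    def step(self) -> None:
        """One full iteration: every block visited once, fixed order."""
        for i in range(self.layout.n_individuals):
            self._update_individual(i)
        self._update_global()
        for half in (0, 1):
            self._update_population("M", half)
        for half in (0, 1):
            self._update_population("S", half)
        if self.recenter:
            self._update_recenter()
        self.iteration += 1

    def run(self, n_iter: int, burn_in: int = 0,
            meta: Mapping | None = None) -> Chain:
        dim = self.layout.dimension
        states = np.empty((n_iter + 1, dim))
        logp = np.empty(n_iter + 1)
        states[0] = self.state_vector()
        logp[0] = self.log_posterior_value()
        for n in range(1, n_iter + 1):
            self.step()
            states[n] = self.state_vector()
            logp[n] = self.log_posterior_value()
        acc = {k: self.accept_counts.get(k, 0) / v
               for k, v in self.try_counts.items()}
        return Chain(states=states, log_posterior=logp, acceptance=acc,
                     burn_in=burn_in, meta=dict(meta or {}))


def adapt_proposals(segment: np.ndarray, fraction,
                    floor: float = 1e-12) -> ProposalConfig:
    """New proposal SDs = fraction x empirical SD of the chain segment.

    ``fraction`` may be scalar or per-scalar.  Scalars that did not move in
    the segment get the floor (with a warning).
    """
    segment = np.asarray(segment, float)
    if segment.ndim != 2 or segment.shape[0] < 2:
        raise ValueError("segment must be (n >= 2, dim)")
    emp = segment.std(axis=0, ddof=1)
    if np.any(emp <= 0):
        warnings.warn(f"{int(np.sum(emp <= 0))} scalars had zero empirical "
                      "SD; proposal floor applied", stacklevel=2)
    sd = np.maximum(np.asarray(fraction, float) * emp, floor)
    return ProposalConfig(sd=sd, floor=floor)


def _block_fractions(layout, adapt_fraction: float | None) -> np.ndarray:
    frac = np.empty(layout.dimension)
    for name, idx in layout.blocks():
        f = adapt_fraction if adapt_fraction is not None \
            else min(2.38 / np.sqrt(len(idx)), 0.8)
        frac[idx] = f
    return frac


def run_sampler(model: PopulationPKModel,
                config: SamplerConfig | None = None) -> Chain:
    """Pre-runs with proposal adaptation, then the main sampling run.

    After each pre-run the proposal SDs are re-derived from the pre-run
    chain (per block a fraction of the empirical posterior SD, default
    2.38/sqrt(d)) and the start values are set to the last pre-run state;
    no adaptation happens inside a run.  Returns the main-run chain with
    ``config.burn_in`` recorded for downstream analyses.
    """
    cfg = config or SamplerConfig()
    rng = np.random.default_rng(cfg.seed)
    sampler = PBPKSampler(model, rng=rng)
    frac = _block_fractions(model.layout, cfg.adapt_fraction)
    target_acc = 0.234
    acc_scale = np.ones(model.layout.dimension)
    rec_scale = 1.0
    for n_pre in cfg.pre_runs:
        pre = sampler.run(n_pre)
        if sampler.recenter:
            rec_scale = float(np.clip(
                rec_scale * np.exp(2.0 * (pre.acceptance.get("recenter", 0.0)
                                          - target_acc)), 0.05, 3.0))
            M_chain = pre.states[:, model.layout.M_slice]
            m_emp = M_chain.std(axis=0, ddof=1)
            frac_rec = min(2.38 / np.sqrt(model.layout.K), 0.8)
            new_rec = np.maximum(frac_rec * rec_scale * m_emp,
                                 0.1 * sampler.recenter_sd)
            new_rec[sampler._absorb_k] = 0.0
            sampler.recenter_sd = new_rec
            # correlated location proposals along the empirical M ridges
            # (shrunk towards the diagonal; between-run adaptation only)
            C = np.cov(M_chain.T)
            C = 0.7 * C + 0.3 * np.diag(np.diag(C))
            C += np.diag(np.maximum(new_rec, 1e-12) ** 2) * 1e-3
            try:
                L = np.linalg.cholesky(C)
                scale = frac_rec * rec_scale
                L = L * scale
                L[sampler._absorb_k, :] = 0.0
                sampler.recenter_chol = L
            except np.linalg.LinAlgError:
                sampler.recenter_chol = None
            s_emp = np.log(np.maximum(
                pre.states[:, model.layout.S_slice], 1e-300)).std(axis=0,
                                                                  ddof=1)
            new_eps = np.maximum(frac_rec * rec_scale * s_emp,
                                 0.1 * sampler.rescale_sd)
            new_eps[sampler._absorb_k] = 0.0
            sampler.rescale_sd = new_eps
            if sampler._fu_index is not None:
                fu_emp = np.log(pre.states[:, model.layout.global_slice]
                                [:, sampler._fu_index]).std(ddof=1)
                sampler.recenter_fu_sd = max(
                    frac_rec * rec_scale * fu_emp,
                    0.1 * sampler.recenter_fu_sd)
            for j, (kv, _kr) in enumerate(sampler._shear_pairs):
                v_emp = np.log(np.maximum(M_chain[:, kv], 1e-300)).std(ddof=1)
                sampler.shear_sd[j] = max(frac_rec * rec_scale * v_emp,
                                          0.1 * sampler.shear_sd[j])
        # steer every block's scale towards the classic multivariate
        # random-walk acceptance optimum; in a hierarchy the conditional
        # widths are narrower than the marginal chain SDs, so the empirical
        # fraction alone systematically overshoots
        for name, idx in model.layout.blocks():
            acc = pre.acceptance.get(name, 0.0)
            acc_scale[idx] = np.clip(
                acc_scale[idx] * np.exp(2.0 * (acc - target_acc)), 0.05, 3.0)
        prop = adapt_proposals(pre.states, frac * acc_scale)
        # a block that barely moved in a short pre-run must not collapse its
        # proposal scale; keep at least a tenth of the previous SD
        prop.sd = np.maximum(prop.sd, 0.1 * sampler.proposal.sd)
        sampler.proposal = prop
        sampler.reset(pre.states[-1])
    chain = sampler.run(cfg.n_iter, burn_in=cfg.burn_in,
                        meta={"pre_runs": list(cfg.pre_runs),
                              "n_iter": cfg.n_iter})
    chain.seed = cfg.seed
    return chain


# --------------------------------------------------------------------------
# Diagnostics and thinning
# --------------------------------------------------------------------------


def gelman_rubin(samples: np.ndarray,
                 parameters: Sequence[int] | None = None) -> np.ndarray:
    """Split-in-two Gelman-Rubin potential scale reduction factor.

    A single chain (n, p) is split into two equal halves which play the
    role of independent chains in the standard between/within-variance
    formula.  Parameters with zero within-chain variance yield NaN
    (undefined) with a warning.
    """
    x = np.asarray(samples, float)
    if x.ndim == 1:
        x = x[:, None]
    if parameters is not None:
        x = x[:, np.asarray(parameters)]
    n = (x.shape[0] // 2) * 2
    halves = np.stack([x[: n // 2], x[n // 2: n]])  # (2, n/2, p)
    nh = n // 2
    means = halves.mean(axis=1)
    within = halves.var(axis=1, ddof=1)
    W = within.mean(axis=0)
    B = nh * means.var(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        var_plus = (nh - 1) / nh * W + B / nh
        rhat = np.sqrt(var_plus / W)
    if np.any(W <= 0):
        warnings.warn("zero within-chain variance; R-hat undefined (NaN)",
                      stacklevel=2)
        rhat = np.where(W > 0, rhat, np.nan)
    return rhat


def thin_subsample(chain: Chain, Z: int,
                   rng: np.random.Generator | int | None = None):
    """Z uniform draws without replacement from the post-burn-in chain.

    Returns ``(states (Z, dim), indices)`` with indices into the stored
    chain (ascending).
    """
    rng = (rng if isinstance(rng, np.random.Generator)
           else np.random.default_rng(rng))
    post = chain.post_burn_in()
    if Z > post.shape[0]:
        raise ValueError(f"requested {Z} subsamples from a post-burn-in "
                         f"chain of length {post.shape[0]}")
    idx = np.sort(rng.choice(post.shape[0], size=Z, replace=False))
    return post[idx], idx + chain.burn_in
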