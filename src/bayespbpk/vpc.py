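"""Visual predictive checks of population pharmacokinetics.

A VPC replicate simulates the whole experimental setting once: one virtual
parameter set per study individual, simulated at the nominal sampling
times.  Within a replicate the median and the 5th/95th percentiles across
individuals are computed; across many replicates the 95 % confidence band
of each of the three statistics is formed and compared against the same
statistics of the observed data.

Three sources of virtual individuals are supported:

``posterior``
    draws via the posterior dependency mixture (hyperparameter uncertainty
    and random-effect correlations included),
``prior``
    independent draws from the prior population distributions, with a
    lognormal stand-in (geometric SD 1.5) for the a-priori uninformed
    parameters,
``map``
    population parameters fixed at the stored draw with the highest joint
    posterior density, individuals drawn with independent standard-normal
    random effects.

Percentiles are linear-interpolation (type-7) quantiles throughout.
Measurement noise is excluded from the simulations by default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Sequence

import numpy as np
import pandas as pd

from . import pbpk
from .hierarchy import ObservationSet, PopulationPKModel
from .posterior import (
    PosteriorSample,
    _component_sqrt,
    extract_random_effects,
    fit_dependency_mixture,
)

__all__ = ["VpcResult", "observed_statistics", "run_vpc"]

_QUANTS = (5.0, 50.0, 95.0)


@dataclass
class VpcResult:
    """Simulated percentile statistics and their confidence bands."""

    time_h: np.ndarray
    source: str
    statistics: np.ndarray = field(repr=False)  # (n_rep, 3, T): p5, median, p95
    bands: np.ndarray = field(repr=False)  # (3, 2, T): 2.5/97.5 CI per statistic
    n_replicates: int = 0
    n_failed: int = 0
    observed: pd.DataFrame | None = None

    def to_frame(self) -> pd.DataFrame:
        rows = []
        stat_names = ("p5", "median", "p95")
        for s, name in enumerate(stat_names):
            for t, tt in enumerate(self.time_h):
                rows.append(dict(time_h=tt, statistic=name,
                                 lower=self.bands[s, 0, t],
                                 upper=self.bands[s, 1, t],
                                 center=np.median(self.statistics[:, s, t])))
        return pd.DataFrame(rows)

    def plot(self, path=None, log_scale: bool = False):
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(7, 4.5))
        colors = {"p5": "#9ecae1", "median": "#3182bd", "p95": "#9ecae1"}
        for s, name in enumerate(("p5", "median", "p95")):
            ax.fill_between(self.time_h, self.bands[s, 0], self.bands[s, 1],
                            color=colors[name], alpha=0.5,
                            label=f"95% CI of {name}")
        if self.observed is not None:
            for col, style in (("median", "k-"), ("p5", "k--"), ("p95", "k--")):
                ax.plot(self.observed["time_h"], self.observed[col], style,
                        lw=1.2)
        ax.set_xlabel("time [h]")
        ax.set_ylabel("venous plasma concentration [mg/L]")
        if log_scale:
            ax.set_yscale("log")
        ax.set_title(f"VPC ({self.source})")
        ax.legend(loc="best", fontsize=8)
        if path is not None:
            fig.savefig(path, dpi=120, bbox_inches="tight")
            plt.close(fig)
        return fig


def observed_statistics(observations: ObservationSet,
                        nominal_times: Sequence[float]) -> pd.DataFrame:
    """Median and 5/95 percentiles of the observed concentrations, with
    each observation assigned to its nearest nominal time; empty bins are
    omitted with a warning."""
    nominal = np.asarray(nominal_times, float)
    rows: Dict[float, list] = {t: [] for t in nominal}
    for ind in observations:
        use = ind.usable
        for t, y in zip(ind.times_h[use], ind.conc[use]):
            nearest = nominal[np.argmin(np.abs(nominal - t))]
            rows[nearest].append(y)
    recs = []
    for t in nominal:
        vals = np.asarray(rows[t], float)
        if vals.size == 0:
            warnings.warn(f"no observations near nominal time {t} h; "
                          "bin omitted", stacklevel=2)
            continue
        p5, med, p95 = np.percentile(vals, _QUANTS)
        recs.append(dict(time_h=t, p5=p5, median=med, p95=p95, n=vals.size))
    return pd.DataFrame(recs)


def run_vpc(source: str,
            model: PopulationPKModel,
            sample: PosteriorSample | None = None,
            n_replicates: int = 200,
            rng: np.random.Generator | int | None = None,
            nominal_times: Sequence[float] | None = None,
            include_noise: bool = False) -> VpcResult:
    """Run a visual predictive check from the given parameter source.

    Each replicate simulates all study individuals (at their own covariates
    and doses) and records the 5th/50th/95th percentile curves across
    individuals; the band of each statistic is its 2.5/97.5 percentile
    across replicates.  Replicates with failed simulations are excluded
    and counted.
    """
    if source not in ("posterior", "prior", "map"):
        raise ValueError("source must be 'posterior', 'prior' or 'map'")
    rng = (rng if isinstance(rng, np.random.Generator)
           else np.random.default_rng(rng))
    obs = model.observations
    N = obs.n
    if nominal_times is None:
        nominal_times = np.unique(np.concatenate(
            [ind.times_h[ind.usable] for ind in obs]))
        # collapse per-subject jitter onto the shared design
        from .synthetic import THEOPH_NOMINAL_TIMES_H

        nom = np.asarray([t for t in THEOPH_NOMINAL_TIMES_H if t > 0])
        if np.all(np.min(np.abs(nominal_times[:, None] - nom[None, :]),
                         axis=1) < 1.0):
            nominal_times = nom
    times = np.asarray(nominal_times, float)

    pr = model.priors
    names = pr.names
    if source in ("posterior", "map"):
        if sample is None:
            raise ValueError(f"{source!r} VPC needs a posterior sample")
    if source == "posterior":
        b = extract_random_effects(sample)
        bbar, sigma = fit_dependency_mixture(b)
        sqrts = np.stack([_component_sqrt(s) for s in sigma])
    if source == "map" and sample.Z != 1:
        # the caller passes a one-draw sample built from Chain.map_state()
        raise ValueError("map VPC expects a single-draw sample "
                         "(use Chain.map_state())")

    # prior variant: lognormal stand-in spread (geometric SD 1.5) for the
    # a-priori uninformed parameters, database moments otherwise
    uninformed = np.array([f == "truncated_uniform" for f in pr.M_family])
    mu0, sd0 = model.scaled_moments(pr.M_mu, pr.S_mu)
    sd0 = sd0.copy()
    sd0[:, uninformed] = np.log(1.5)

    stats_out = []
    n_failed = 0
    scaling = [model.covariate_scaling(ind.covariates) for ind in obs]
    for rep in range(n_replicates):
        conc = np.empty((N, len(times)))
        try:
            for i, ind in enumerate(obs):
                a, c, d = scaling[i]
                for attempt in range(100):
                    if source == "posterior":
                        z = int(rng.integers(sample.Z))
                        bstar = bbar[z] + sqrts[z] @ rng.standard_normal(
                            model.layout.K)
                        x = a * sample.M[z] + c + d * sample.S[z] * bstar
                        g = sample.globals_[z]
                        s2 = float(sample.sigma2[z])
                    elif source == "map":
                        bstar = rng.standard_normal(model.layout.K)
                        x = a * sample.M[0] + c + d * sample.S[0] * bstar
                        g = sample.globals_[0]
                        s2 = float(sample.sigma2[0])
                    else:
                        x = mu0[i] + sd0[i] * rng.standard_normal(
                            model.layout.K)
                        g = pr.g_start
                        s2 = 0.01
                    if np.all((x >= pr.x_lower) & (x <= pr.x_upper)):
                        break
                else:
                    raise pbpk.SimulationError("no in-bounds draw")
                nat = x.copy()
                nat[pr.is_log] = np.exp(nat[pr.is_log])
                phys = pbpk.PhysiologyVector(dict(zip(names, nat)))
                compound = model.evaluator.compound(g)
                res = pbpk.simulate_pk(phys, compound,
                                       pbpk.DoseEvent(ind.covariates.dose),
                                       times)
                ci = res.venous_plasma_conc
                if include_noise:
                    ci = np.maximum(
                        ci * (1 + np.sqrt(s2) * rng.standard_normal(len(ci))),
                        0.0)
                conc[i] = ci
        except pbpk.SimulationError:
            n_failed += 1
            continue
        stats_out.append(np.percentile(conc, _QUANTS, axis=0))
    if not stats_out:
        raise RuntimeError("all VPC replicates failed")
    stats_arr = np.stack(stats_out)  # (n_ok, 3, T)
    bands = np.percentile(stats_arr, [2.5, 97.5], axis=0)  # (2, 3, T)
    bands = np.moveaxis(bands, 0, 1)  # (3, 2, T)
    observed = observed_statistics(obs, times)
    return VpcResult(time_h=times, source=source, statistics=stats_arr,
                     bands=bands, n_replicates=len(stats_out),
                     n_failed=n_failed, observed=observed)
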