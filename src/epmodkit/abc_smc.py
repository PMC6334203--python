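"""Approximate Bayesian Computation by Sequential Monte Carlo.

Likelihood-free calibration of a simulator against observed summary curves:
parameter particles drawn from a uniform prior are filtered through a
decreasing sequence of distance tolerances. Each generation resamples the
previous population by weight, perturbs with a multivariate Gaussian kernel
(covariance twice the weighted empirical covariance), rejects proposals
outside the prior support, and accepts particles whose simulated summaries
fall within the current tolerance. Importance weights are the prior density
over the kernel mixture density. The tolerance schedule is adaptive: the
next epsilon is the median of the current generation's accepted distances.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict, List, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd

Curves = Mapping[str, np.ndarray]


@dataclass(frozen=True)
class PriorSpec:
    """Independent uniform priors: parameter name -> (lo, hi)."""

    bounds: Dict[str, Tuple[float, float]]

    def __post_init__(self):
        for name, (lo, hi) in self.bounds.items():
            if not lo < hi:
                raise ValueError(f"prior for {name}: need lo < hi, got ({lo}, {hi})")

    @property
    def names(self) -> List[str]:
        return list(self.bounds)

    @property
    def lows(self) -> np.ndarray:
        return np.array([b[0] for b in self.bounds.values()])

    @property
    def highs(self) -> np.ndarray:
        return np.array([b[1] for b in self.bounds.values()])

    @property
    def widths(self) -> np.ndarray:
        return self.highs - self.lows

    def sample(self, rng: np.random.Generator, n: int = 1) -> np.ndarray:
        """(n, d) array of independent uniform draws within the bounds."""
        return rng.uniform(self.lows, self.highs, size=(n, len(self.bounds)))

    def in_support(self, x: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(x)
        return np.all((x >= self.lows) & (x <= self.highs), axis=1)

    def log_density(self) -> float:
        return -float(np.sum(np.log(self.widths)))


@dataclass
class Generation:
    """One accepted population: particles (N, d), distances, normalised weights."""

    particles: np.ndarray
    distances: np.ndarray
    weights: np.ndarray
    epsilon: float
    acceptance_rate: float

    @property
    def ess(self) -> float:
        return float(1.0 / np.sum(self.weights**2))


@dataclass
class PosteriorPopulation:
    """Full ABC-SMC history plus the final weighted particle population."""

    names: List[str]
    generations: List[Generation] = field(default_factory=list)

    @property
    def final(self) -> Generation:
        return self.generations[-1]

    @property
    def epsilons(self) -> np.ndarray:
        return np.array([g.epsilon for g in self.generations])

    @property
    def acceptance_rates(self) -> np.ndarray:
        return np.array([g.acceptance_rate for g in self.generations])

    def weighted_mean(self) -> np.ndarray:
        g = self.final
        return g.weights @ g.particles

    def weighted_sd(self) -> np.ndarray:
        g = self.final
        mu = self.weighted_mean()
        return np.sqrt(g.weights @ (g.particles - mu) ** 2)

    def to_frame(self) -> pd.DataFrame:
        g = self.final
        df = pd.DataFrame(g.particles, columns=self.names)
        df["distance"] = g.distances
        df["weight"] = g.weights
        return df


@dataclass(frozen=True)
class SMCConfig:
    population_size: int = 500
    max_generations: int = 12
    eps0_quantile: float = 0.5
    eps_quantile: float = 0.5  # next epsilon = this quantile of accepted distances
    eps_target: float = 1e-4
    min_acceptance_rate: float = 0.01
    max_proposals_per_gen: int = 2_000_000
    adapt_population: bool = False  # double N when ESS < N/2


def distance(simulated: Curves, observed: Curves) -> float:
    """Mean over curves of the per-curve root-mean-square difference.

    Curves are matched by key and must share their x-grids (equal lengths
    here); zero iff all curves are identical.
    """
    keys = sorted(observed)
    if sorted(simulated) != keys:
        raise ValueError(f"curve sets differ: {sorted(simulated)} vs {keys}")
    total = 0.0
    for k in keys:
        a = np.asarray(simulated[k], dtype=float)
        b = np.asarray(observed[k], dtype=float)
        if a.shape != b.shape:
            raise ValueError(f"curve {k!r}: shape mismatch {a.shape} vs {b.shape}")
        total += float(np.sqrt(np.mean((a - b) ** 2)))
    return total / len(keys)


def _as_curves(out) -> Curves:
    if isinstance(out, Mapping):
        return {k: (v.y if hasattr(v, "y") else np.asarray(v)) for k, v in out.items()}
    return {"curve": np.asarray(out)}


def _kernel_log_mixture(x: np.ndarray, prev: Generation, cov_chol: np.ndarray,
                        log_norm: float) -> float:
    diff = prev.particles - x
    z = np.linalg.solve(cov_chol, diff.T)
    q = np.sum(z * z, axis=0)
    logk = -0.5 * q + log_norm
    m = np.max(logk)
    return float(m + np.log(np.sum(prev.weights * np.exp(logk - m))))


def run_generation(prev: Generation | None, prior: PriorSpec, observed: Curves,
                   epsilon: float, simulate: Callable[[np.ndarray, np.random.Generator], Curves],
                   config: SMCConfig, rng: np.random.Generator,
                   n_particles: int | None = None) -> Generation:
    """Propose/accept until ``n_particles`` particles satisfy distance <= epsilon.

    Generation 0 (``prev is None``) proposes from the prior with uniform
    weights; later generations resample+perturb the previous population.
    """
    n = n_particles or config.population_size
    d = len(prior.names)
    accepted = np.empty((n, d))
    dists = np.empty(n)
    logw = np.empty(n)

    if prev is not None:
        mu = prev.weights @ prev.particles
        cov = 2.0 * np.cov(prev.particles.T, aweights=prev.weights, ddof=0)
        cov = np.atleast_2d(cov) + 1e-12 * np.eye(d) * max(1.0, np.trace(np.atleast_2d(cov)))
        chol = np.linalg.cholesky(cov)
        log_norm = -0.5 * d * np.log(2 * np.pi) - np.sum(np.log(np.diag(chol)))
        log_prior = prior.log_density()

    n_acc = 0
    n_prop = 0
    while n_acc < n:
        if n_prop > config.max_proposals_per_gen:
            raise RuntimeError(
                f"acceptance rate {n_acc / n_prop:.2e} below the configured "
                f"floor at epsilon={epsilon:g}; aborting generation")
        if prev is None:
            theta = prior.sample(rng)[0]
        else:
            idx = rng.choice(len(prev.particles), p=prev.weights)
            theta = prev.particles[idx] + chol @ rng.standard_normal(d)
            n_prop += 1
            if not prior.in_support(theta)[0]:
                continue
        if prev is None:
            n_prop += 1
        dist = distance(_as_curves(simulate(theta, rng)), observed)
        if dist <= epsilon:
            accepted[n_acc] = theta
            dists[n_acc] = dist
            if prev is None:
                logw[n_acc] = 0.0
            else:
                logw[n_acc] = log_prior - _kernel_log_mixture(theta, prev, chol, log_norm)
            n_acc += 1
        rate = n_acc / max(1, n_prop)
        if n_prop >= 200 * n and rate < config.min_acceptance_rate:
            raise RuntimeError(
                f"acceptance rate {rate:.2e} below floor "
                f"{config.min_acceptance_rate} at epsilon={epsilon:g}")

    w = np.exp(logw - np.max(logw))
    w /= np.sum(w)
    return Generation(particles=accepted, distances=dists, weights=w,
                      epsilon=float(epsilon),
                      acceptance_rate=n_acc / max(1, n_prop))


def run_abcsmc(prior: PriorSpec, observed, simulate,
               config: SMCConfig | None = None,
               rng: np.random.Generator | int | None = None) -> PosteriorPopulation:
    """Full ABC-SMC run with adaptive tolerance schedule.

    ``observed`` is a mapping of summary-curve name -> values (SummaryCurve
    objects accepted); ``simulate(theta, rng)`` must return the same keys.
    epsilon_0 is the ``eps0_quantile`` of a pilot set of prior-predictive
    distances; afterwards epsilon_{g+1} is the ``eps_quantile`` of the
    accepted distances. Stops at max generations, the epsilon target, or an
    acceptance-rate floor (recorded, not raised, once one generation exists).
    """
    config = config or SMCConfig()
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    observed = _as_curves(observed)

    # pilot: prior-predictive distances set the initial tolerance
    pilot = prior.sample(rng, config.population_size)
    pilot_d = np.array([distance(_as_curves(simulate(t, rng)), observed)
                        for t in pilot])
    eps = float(np.quantile(pilot_d, config.eps0_quantile))

    pop = PosteriorPopulation(names=prior.names)
    prev: Generation | None = None
    n = config.population_size
    for _ in range(config.max_generations):
        try:
            gen = run_generation(prev, prior, observed, eps, simulate, config,
                                 rng, n_particles=n)
        except RuntimeError:
            if pop.generations:
                break
            raise
        pop.generations.append(gen)
        prev = gen
        if config.adapt_population and gen.ess < n / 2:
            n = 2 * n
        new_eps = float(np.quantile(gen.distances, config.eps_quantile))
        if new_eps <= config.eps_target or gen.acceptance_rate < config.min_acceptance_rate:
            break
        eps = min(new_eps, eps)
    return pop


def posterior_summary(pop: PosteriorPopulation,
                      orig: Mapping[str, float] | None = None,
                      prior: PriorSpec | None = None) -> pd.DataFrame:
    """Per-parameter weighted mean and unweighted min/max of the final
    generation, with optional original-value and prior columns."""
    g = pop.final
    mean = pop.weighted_mean()
    rows = []
    for i, name in enumerate(pop.names):
        row = {"name": name}
        if orig is not None:
            row["orig"] = orig.get(name, np.nan)
        if prior is not None:
            row["prior_lo"], row["prior_hi"] = prior.bounds[name]
        row.update(mean=mean[i], min=float(np.min(g.particles[:, i])),
                   max=float(np.max(g.particles[:, i])))
        rows.append(row)
    return pd.DataFrame(rows)


def posterior_kde(pop: PosteriorPopulation, pair: Sequence[str],
                  grid_size: int = 64, pad: float = 0.15):
    """Weighted Gaussian KDE of a 2-parameter marginal on a regular grid.

    Returns (x_grid, y_grid, density); the density integrates to ~1 on the
    grid. Raises on a zero-variance (degenerate) population.
    """
    from scipy.stats import gaussian_kde

    g = pop.final
    if len(g.particles) < 10:
        raise ValueError("need at least 10 particles for a KDE")
    i, j = (pop.names.index(p) for p in pair)
    pts = g.particles[:, [i, j]].T
    if np.any(np.ptp(pts, axis=1) == 0):
        raise ValueError("degenerate (zero-variance) population; KDE undefined")
    kde = gaussian_kde(pts, weights=g.weights)
    los = pts.min(axis=1) - pad * np.ptp(pts, axis=1)
    his = pts.max(axis=1) + pad * np.ptp(pts, axis=1)
    xg = np.linspace(los[0], his[0], grid_size)
    yg = np.linspace(los[1], his[1], grid_size)
    X, Y = np.meshgrid(xg, yg, indexing="ij")
    dens = kde(np.vstack([X.ravel(), Y.ravel()])).reshape(grid_size, grid_size)
    return xg, yg, dens


def posterior_predictive(pop: PosteriorPopulation, simulate,
                         n_samples: int = 100,
                         rng: np.random.Generator | int | None = None,
                         ci: float = 0.95):
    """Weighted posterior draws pushed through the forward model.

    Returns {curve key: dict(median, lo, hi, samples)} with the pointwise
    median and central ``ci`` interval across the ``n_samples`` simulations.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    g = pop.final
    idx = rng.choice(len(g.particles), size=n_samples, p=g.weights)
    sims = [_as_curves(simulate(g.particles[k], rng)) for k in idx]
    out = {}
    a = (1.0 - ci) / 2.0
    for key in sims[0]:
        stack = np.stack([s[key] for s in sims])
        out[key] = {
            "median": np.median(stack, axis=0),
            "lo": np.quantile(stack, a, axis=0),
            "hi": np.quantile(stack, 1.0 - a, axis=0),
            "samples": stack,
        }
    return out


def sodium_prior(subset: Sequence[str] | None = None) -> PriorSpec:
    """Default uniform priors for the nine inferable sodium-channel
    parameters (optionally a subset, preserving order)."""
    from .sodium_channel import PRIOR_BOUNDS

    names = list(subset) if subset is not None else list(PRIOR_BOUNDS)
    return PriorSpec({n: PRIOR_BOUNDS[n] for n in names})


def sodium_steady_state_simulator(v_grid, fixed: Mapping[str, float] | None = None,
                                  names: Sequence[str] | None = None):
    """Forward model mapping a parameter vector to analytic steady-state
    activation/inactivation summaries on ``v_grid``."""
    from .sodium_channel import ChannelParams, steady_state_curves

    v_grid = np.asarray(v_grid, dtype=float)
    fixed = dict(fixed or {})
    names = list(names) if names is not None else list(sodium_prior().names)

    def simulate(theta: np.ndarray, rng=None):
        params = ChannelParams.from_dict({**fixed, **dict(zip(names, theta))})
        return steady_state_curves(params, v_grid)

    return simulate
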