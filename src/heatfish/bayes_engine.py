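"""Shared Bayesian inference machinery for the hierarchical models.

All models in this package (von Bertalanffy size-at-age, allometric growth,
catch-curve mortality, lognormal mean size/age) share a common structure:
a handful of global parameters plus one or more *latent blocks* of group
effects (cohort, individual, or year) whose units are conditionally
independent given everything else.  The sampler exploits this:

* global scalars are updated one at a time by adaptive random-walk
  Metropolis (proposal scales tuned to ~44% acceptance during warmup);
* each latent block is updated with a single vectorized Metropolis sweep —
  every unit proposes simultaneously and accepts or rejects on its own
  conditional log-density, which is valid because units are conditionally
  independent within a block.

Three independent chains (default) are run from overdispersed starts; the
first half of each chain is discarded as warmup.  Convergence is assessed
with split-R-hat (< 1.1) and model comparison uses PSIS-LOO expected log
pointwise predictive density with Pareto-k diagnostics, both via ``arviz``.

Positive parameters are sampled on the log scale with the stated priors
applied on the natural scale through the change-of-variables Jacobian, so
printed priors stay literal while log-scale likelihood terms remain valid.
"""

from __future__ import annotations

import abc
from dataclasses import dataclass, field
from typing import Callable, Sequence

import arviz as az
import numpy as np
from scipy.linalg import solve_triangular
from scipy.special import gammaln

__all__ = [
    "SamplerConfig",
    "HierarchicalModel",
    "PosteriorSummary",
    "LooResult",
    "sample_posterior",
    "check_convergence",
    "loo_compare",
    "predictive_check",
    "student_t_logpdf",
    "normal_logpdf",
    "half_t_logpdf",
    "gamma_logpdf",
    "chol_from_partial_correlations",
    "partial_correlation_log_prior",
    "mvn_zero_mean_logpdf",
]

RHAT_THRESHOLD = 1.1
PARETO_K_THRESHOLD = 0.7


# ---------------------------------------------------------------------------
# density helpers (vectorized, used inside sampling hot loops)

def student_t_logpdf(x, nu, mu, sigma):
    """Log density of the location-scale Student-t distribution."""
    z = (np.asarray(x) - mu) / sigma
    return (
        gammaln((nu + 1.0) / 2.0)
        - gammaln(nu / 2.0)
        - 0.5 * np.log(nu * np.pi)
        - np.log(sigma)
        - (nu + 1.0) / 2.0 * np.log1p(z * z / nu)
    )


def normal_logpdf(x, mu, sigma):
    z = (np.asarray(x) - mu) / sigma
    return -0.5 * z * z - np.log(sigma) - 0.5 * np.log(2.0 * np.pi)


def half_t_logpdf(x, df, scale):
    """Half-Student-t prior on a positive scale parameter (mode at zero)."""
    x = np.asarray(x)
    return np.where(x > 0, np.log(2.0) + student_t_logpdf(x, df, 0.0, scale), -np.inf)


def gamma_logpdf(x, shape, rate):
    x = np.asarray(x)
    return np.where(
        x > 0,
        shape * np.log(rate) + (shape - 1.0) * np.log(x) - rate * x - gammaln(shape),
        -np.inf,
    )


# ---------------------------------------------------------------------------
# correlation-matrix parametrization (for the MVN group-effect priors)

def chol_from_partial_correlations(z: np.ndarray, dim: int) -> np.ndarray:
    """Cholesky factor of a correlation matrix from canonical partial
    correlations (vine construction); ``z`` has ``dim*(dim-1)/2`` entries in
    (-1, 1) filling the strictly lower triangle row by row."""
    L = np.zeros((dim, dim))
    L[0, 0] = 1.0
    idx = 0
    for i in range(1, dim):
        rem = 1.0
        for j in range(i):
            L[i, j] = z[idx] * np.sqrt(rem)
            rem *= 1.0 - z[idx] ** 2
            idx += 1
        L[i, i] = np.sqrt(rem)
    return L


def partial_correlation_log_prior(y: np.ndarray) -> float:
    """Log prior for unconstrained correlation parameters ``y`` mapped through
    tanh to partial correlations, each uniform on (-1, 1)."""
    t = np.tanh(y)
    return float(np.sum(np.log1p(-t * t)))


def mvn_zero_mean_logpdf(u: np.ndarray, sds: np.ndarray, corr_chol: np.ndarray) -> np.ndarray:
    """Row-wise log density of MVN(0, D L L' D) for ``u`` of shape (n, p)."""
    p = u.shape[1]
    scaled = (u / sds).T  # (p, n)
    w = solve_triangular(corr_chol, scaled, lower=True)
    quad = np.sum(w * w, axis=0)
    logdet = np.sum(np.log(sds)) + np.sum(np.log(np.diag(corr_chol)))
    return -0.5 * quad - logdet - 0.5 * p * np.log(2.0 * np.pi)


# ---------------------------------------------------------------------------
# sampler contract

@dataclass(frozen=True)
class SamplerConfig:
    """Sampling contract: 3 chains, 4000 iterations per chain, first half warmup."""

    chains: int = 3
    iterations: int = 4000
    warmup_frac: float = 0.5
    seed: int = 0
    adapt_decay: float = 0.6  # Robbins-Monro exponent for proposal-scale tuning
    block_sweeps: int = 2  # latent-block Metropolis sweeps per iteration
    thin: int = 1  # keep every thin-th post-warmup iteration

    def __post_init__(self) -> None:
        if self.chains < 2:
            raise ValueError("need at least 2 chains for split-R-hat")
        if not 0.0 < self.warmup_frac < 1.0:
            raise ValueError("warmup fraction must be in (0, 1)")
        if self.iterations < 4:
            raise ValueError("too few iterations")

    @property
    def warmup(self) -> int:
        return int(self.iterations * self.warmup_frac)


class HierarchicalModel(abc.ABC):
    """Interface a model must implement to be sampled.

    State is a dict of parameter name -> value on the *sampling* scale
    (scalars as floats, latent blocks as arrays of shape (n_units,) or
    (n_units, unit_dim)).  Blocks must have conditionally independent units
    given the scalars and the other blocks.
    """

    name: str = "model"
    #: names of scalar parameters on the sampling scale
    scalar_names: Sequence[str] = ()
    #: latent blocks: name -> (n_units, unit_dim); unit_dim 0 means flat vector
    blocks: dict = {}
    n_obs: int = 0

    @abc.abstractmethod
    def init_state(self, rng: np.random.Generator) -> dict:
        """Overdispersed chain-specific initial state."""

    @abc.abstractmethod
    def logp(self, state: dict) -> float:
        """Full log posterior density (up to a constant)."""

    @abc.abstractmethod
    def block_logp_units(self, name: str, state: dict) -> np.ndarray:
        """Per-unit conditional log density contributions for one block."""

    @abc.abstractmethod
    def loglik_pointwise(self, state: dict) -> np.ndarray:
        """Per-observation log likelihood (length n_obs), for LOO."""

    @abc.abstractmethod
    def constrained(self, state: dict) -> dict:
        """Named natural-scale parameter values to store as draws."""


def _block_shape(n_units: int, unit_dim: int) -> tuple:
    return (n_units,) if unit_dim == 0 else (n_units, unit_dim)


class _UnitCovAdapter:
    """Running per-unit covariance of a latent block during warmup, used to
    shape proposals along within-unit posterior ridges (e.g. L_inf vs K)."""

    def __init__(self, n_units: int, p: int):
        self.n = 0
        self.mean = np.zeros((n_units, p))
        self.m2 = np.zeros((n_units, p, p))
        self.chol = np.tile(np.eye(p), (n_units, 1, 1))
        self.p = p

    def update(self, u: np.ndarray) -> None:
        self.n += 1
        delta = u - self.mean
        self.mean += delta / self.n
        self.m2 += np.einsum("ui,uj->uij", delta, u - self.mean)

    def refresh(self) -> None:
        if self.n < 20:
            return
        cov = self.m2 / (self.n - 1)
        cov = cov + 1e-10 * np.trace(cov, axis1=1, axis2=2)[:, None, None] * np.eye(self.p)
        cov = cov + 1e-12 * np.eye(self.p)
        try:
            self.chol = np.linalg.cholesky(cov)
        except np.linalg.LinAlgError:
            pass


class _ScalarCovAdapter:
    """Running covariance of the scalar-parameter vector for a joint
    adaptive-Metropolis move (handles cross-parameter correlations such as
    t0 with the growth coefficients)."""

    def __init__(self, d: int):
        self.n = 0
        self.mean = np.zeros(d)
        self.m2 = np.zeros((d, d))
        self.chol = None
        self.d = d

    def update(self, x: np.ndarray) -> None:
        self.n += 1
        delta = x - self.mean
        self.mean += delta / self.n
        self.m2 += np.outer(delta, x - self.mean)

    def refresh(self) -> None:
        if self.n < max(20, 2 * self.d):
            return
        cov = self.m2 / (self.n - 1) + 1e-12 * np.eye(self.d)
        try:
            self.chol = np.linalg.cholesky(cov)
        except np.linalg.LinAlgError:
            self.chol = None


def _run_chain(
    model: HierarchicalModel,
    config: SamplerConfig,
    seed: np.random.SeedSequence,
    progress: Callable | None = None,
):
    rng = np.random.default_rng(seed)
    state = model.init_state(rng)
    step0 = getattr(model, "step0", {})
    scalar_scales = {n: step0.get(n, 0.1) for n in model.scalar_names}
    block_scales = {
        n: np.full(sh[0], step0.get(n, 0.1)) for n, sh in model.blocks.items()
    }
    block_adapt = {
        n: _UnitCovAdapter(sh[0], sh[1]) for n, sh in model.blocks.items() if sh[1]
    }
    snames = list(model.scalar_names)
    joint_adapt = _ScalarCovAdapter(len(snames))
    joint_scale = 2.38 / np.sqrt(max(len(snames), 1))
    joint_moves = list(getattr(model, "joint_moves", []))
    move_scales = [0.1] * len(joint_moves)
    warmup = config.warmup
    n_save = (config.iterations - warmup + config.thin - 1) // config.thin
    draws: dict[str, list] = {}
    loglik = np.empty((n_save, model.n_obs))
    accept_counts = {n: 0 for n in model.scalar_names}

    cur_logp = model.logp(state)
    if not np.isfinite(cur_logp):
        raise RuntimeError(f"non-finite initial log posterior for {model.name}")

    for it in range(config.iterations):
        gamma = (it + 1) ** (-config.adapt_decay) if it < warmup else 0.0

        # scalar adaptive random-walk Metropolis, one parameter at a time
        for sname in snames:
            prop = dict(state)
            prop[sname] = state[sname] + scalar_scales[sname] * rng.normal()
            lp = model.logp(prop)
            acc = lp - cur_logp > np.log(rng.uniform())
            if acc:
                state, cur_logp = prop, lp
                accept_counts[sname] += 1
            if gamma:
                scalar_scales[sname] *= np.exp(gamma * ((1.0 if acc else 0.0) - 0.44))

        # joint adaptive-Metropolis move over all scalars
        xcur = np.array([state[n] for n in snames])
        joint_adapt.update(xcur)
        if it % 25 == 0 and it < warmup:
            joint_adapt.refresh()
        if joint_adapt.chol is not None:
            xprop = xcur + joint_scale * (joint_adapt.chol @ rng.normal(size=len(snames)))
            prop = dict(state)
            prop.update({n: xprop[i] for i, n in enumerate(snames)})
            lp = model.logp(prop)
            acc = lp - cur_logp > np.log(rng.uniform())
            if acc:
                state, cur_logp = prop, lp
            if gamma:
                joint_scale *= np.exp(gamma * ((1.0 if acc else 0.0) - 0.234))

        # model-specific joint moves (e.g. t0 / growth-coefficient shear)
        for mi, move in enumerate(joint_moves):
            prop, log_h = move(state, rng, move_scales[mi])
            lp = model.logp(prop)
            acc = lp - cur_logp + log_h > np.log(rng.uniform())
            if acc:
                state, cur_logp = prop, lp
            if gamma:
                move_scales[mi] *= np.exp(gamma * ((1.0 if acc else 0.0) - 0.35))

        # vectorized per-unit Metropolis for each latent block
        for _ in range(config.block_sweeps):
            for bname, (n_units, unit_dim) in model.blocks.items():
                cur_units = model.block_logp_units(bname, state)
                u = state[bname]
                step = block_scales[bname]
                noise = rng.normal(size=_block_shape(n_units, unit_dim))
                if unit_dim:
                    ad = block_adapt[bname]
                    shaped = np.einsum("uij,uj->ui", ad.chol, noise)
                    prop_u = u + step[:, None] * shaped
                else:
                    prop_u = u + step * noise
                prop_state = dict(state)
                prop_state[bname] = prop_u
                prop_units = model.block_logp_units(bname, prop_state)
                acc_mask = prop_units - cur_units > np.log(rng.uniform(size=n_units))
                new_u = np.where(acc_mask[:, None] if unit_dim else acc_mask, prop_u, u)
                state = dict(state)
                state[bname] = new_u
                if gamma:
                    target = 0.28 if unit_dim else 0.44
                    block_scales[bname] *= np.exp(gamma * (acc_mask.astype(float) - target))
            cur_logp = model.logp(state)

        if it < warmup:
            for bname, ad in block_adapt.items():
                ad.update(state[bname])
                if it % 25 == 0:
                    ad.refresh()

        if it >= warmup and (it - warmup) % config.thin == 0:
            k = (it - warmup) // config.thin
            for pname, val in model.constrained(state).items():
                draws.setdefault(pname, []).append(np.asarray(val, dtype=float))
            loglik[k] = model.loglik_pointwise(state)
        if progress is not None:
            progress()

    posterior = {n: np.stack(v) for n, v in draws.items()}
    accept_rates = {n: c / config.iterations for n, c in accept_counts.items()}
    return posterior, loglik, accept_rates


@dataclass
class PosteriorSummary:
    """Posterior draws plus medians, credible intervals, and diagnostics."""

    idata: az.InferenceData
    config: SamplerConfig
    model_name: str
    accept_rates: dict = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    def draws(self, name: str) -> np.ndarray:
        """Draws flattened over chains; shape (n_draws, *param_shape)."""
        da = self.idata.posterior[name]
        return da.values.reshape((-1,) + da.values.shape[2:])

    def median(self, name: str):
        return np.median(self.draws(name), axis=0)

    def ci(self, name: str, prob: float = 0.95) -> np.ndarray:
        """Equal-tailed credible interval; shape (2, *param_shape)."""
        a = (1.0 - prob) / 2.0
        return np.quantile(self.draws(name), [a, 1.0 - a], axis=0)

    @property
    def parameter_names(self) -> list:
        return list(self.idata.posterior.data_vars)

    @property
    def rhat(self) -> dict:
        r = az.rhat(self.idata)
        return {v: float(np.nanmax(r[v].values)) for v in r.data_vars}

    @property
    def converged(self) -> bool:
        return all(v < RHAT_THRESHOLD for v in self.rhat.values())

    def percent_difference_draws(self, name_a: str, name_b: str) -> np.ndarray:
        a, b = self.draws(name_a), self.draws(name_b)
        return 100.0 * (a - b) / b


def sample_posterior(
    model: HierarchicalModel,
    config: SamplerConfig | None = None,
) -> PosteriorSummary:
    """Run independent chains and assemble an ``arviz.InferenceData``."""
    config = config or SamplerConfig()
    seeds = np.random.SeedSequence(config.seed).spawn(config.chains)
    chains = [_run_chain(model, config, s) for s in seeds]
    posterior = {
        n: np.stack([c[0][n] for c in chains]) for n in chains[0][0]
    }
    loglik = np.stack([c[1] for c in chains])
    idata = az.from_dict(
        posterior=posterior,
        log_likelihood={"obs": loglik},
    )
    accept = {
        n: float(np.mean([c[2][n] for c in chains])) for n in chains[0][2]
    }
    return PosteriorSummary(
        idata=idata, config=config, model_name=model.name, accept_rates=accept
    )


# ---------------------------------------------------------------------------
# diagnostics

@dataclass
class ConvergenceReport:
    rhat: dict
    passed: bool
    threshold: float = RHAT_THRESHOLD

    def __str__(self) -> str:
        worst = max(self.rhat, key=self.rhat.get)
        status = "PASS" if self.passed else "FAIL"
        return (
            f"convergence {status}: {len(self.rhat)} parameters, "
            f"worst R-hat {self.rhat[worst]:.4f} ({worst})"
        )


def check_convergence(posterior: PosteriorSummary) -> ConvergenceReport:
    """Split-R-hat per parameter; passes iff all are below 1.1."""
    n_chains = posterior.idata.posterior.sizes["chain"]
    if n_chains < 2:
        raise ValueError("split-R-hat needs at least 2 chains")
    rhat = posterior.rhat
    return ConvergenceReport(rhat=rhat, passed=all(v < RHAT_THRESHOLD for v in rhat.values()))


@dataclass
class LooResult:
    """PSIS-LOO comparison of models sharing the same observations."""

    elpd: dict  # model name -> elpd estimate
    se: dict  # model name -> SE of elpd
    diff: dict  # (name_a, name_b) -> elpd_a - elpd_b
    diff_se: dict
    pareto_k: dict  # model name -> per-observation k values
    ranking: list  # best first
    warnings: list = field(default_factory=list)

    @property
    def best(self) -> str:
        return self.ranking[0]


def loo_compare(models: dict) -> LooResult:
    """Compare fitted models by PSIS-LOO elpd (best first).

    ``models`` maps name -> PosteriorSummary; all must have per-observation
    log likelihood over the same observation set.
    """
    if len(models) < 1:
        raise ValueError("need at least one model")
    n_obs = {
        name: m.idata.log_likelihood["obs"].shape[-1] for name, m in models.items()
    }
    if len(set(n_obs.values())) != 1:
        raise ValueError(f"models fitted to different observation sets: {n_obs}")
    loos = {name: az.loo(m.idata, pointwise=True) for name, m in models.items()}
    elpd = {name: float(l.elpd_loo) for name, l in loos.items()}
    se = {name: float(l.se) for name, l in loos.items()}
    pareto_k = {name: np.asarray(l.pareto_k) for name, l in loos.items()}
    warnings = [
        f"{name}: {int(np.sum(k >= PARETO_K_THRESHOLD))} observations with "
        f"Pareto k >= {PARETO_K_THRESHOLD}"
        for name, k in pareto_k.items()
        if np.any(k >= PARETO_K_THRESHOLD)
    ]
    names = list(models)
    diff, diff_se = {}, {}
    for a in names:
        for b in names:
            if a == b:
                continue
            pw = loos[a].loo_i.values - loos[b].loo_i.values
            diff[(a, b)] = float(np.sum(pw))
            diff_se[(a, b)] = float(np.sqrt(len(pw) * np.var(pw)))
    ranking = sorted(names, key=lambda n: elpd[n], reverse=True)
    return LooResult(
        elpd=elpd, se=se, diff=diff, diff_se=diff_se,
        pareto_k=pareto_k, ranking=ranking, warnings=warnings,
    )


@dataclass
class PredictiveCheck:
    statistic_draws: np.ndarray
    observed: float
    tail_prob: float

    @property
    def extreme(self) -> bool:
        return self.tail_prob < 0.05


def predictive_check(statistic_draws: np.ndarray, observed: float) -> PredictiveCheck:
    """Two-sided predictive tail probability of an observed statistic.

    ``statistic_draws`` are values of the statistic computed on datasets
    drawn from the prior- or posterior-predictive distribution.
    """
    draws = np.asarray(statistic_draws, dtype=float)
    if draws.size == 0:
        raise ValueError("empty predictive draws")
    p_hi = float(np.mean(draws >= observed))
    p_lo = float(np.mean(draws <= observed))
    tail = min(1.0, 2.0 * min(p_hi, p_lo))
    return PredictiveCheck(statistic_draws=draws, observed=observed, tail_prob=tail)
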