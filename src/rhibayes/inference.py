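"""Posterior sampling, convergence diagnostics and draw summaries.

The built-in sampler is an adaptive random-walk Metropolis-within-Gibbs
scheme on an unconstrained parameterization:

* ``sigma_r`` is sampled on the log scale;
* the ordered cutpoints are sampled as (first cutpoint, log increments), so
  the ordering constraint holds structurally;
* the random slopes use the non-centered parameterization
  ``r_i = sigma_r * z_i`` with ``z_i ~ Normal(0, 1)`` by default (the
  centered form, sampling ``r_i`` directly, is available for comparison —
  both target the same posterior).

Each sweep updates every global parameter with a scalar Gaussian random-walk
proposal (step sizes adapted toward 44% acceptance during warmup, then
frozen) and then all ``z_i`` jointly with independent per-participant
proposals, which is exact because the ``z_i`` are conditionally independent
given the globals.  Chains are independent, with per-chain random streams
spawned from the master seed, so runs are bitwise reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import arviz as az
import numpy as np
import pandas as pd
from scipy.special import ndtri

from .data_io import AnalysisDataset
from .model import PROB_FLOOR, ModelParameters, PriorConfig, interval_prob

_TARGET_ACCEPT = 0.44  # optimal for one-dimensional random-walk proposals


# ---------------------------------------------------------------------------
# configuration and containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class McmcConfig:
    """Run configuration.

    Defaults follow the study protocol: 4 chains, 4000 iterations per chain
    with the first 2000 discarded as warmup.  ``include_likelihood=False``
    drops the likelihood term so the sampler explores the prior (used for
    prior-recovery checks).
    """

    n_chains: int = 4
    n_iterations: int = 4000
    n_warmup: int = 2000
    seed: int = 0
    parameterization: str = "noncentered"
    include_likelihood: bool = True

    def __post_init__(self) -> None:
        if self.n_chains < 2:
            raise ValueError("at least 2 chains are required (R-hat needs them)")
        if not 0 < self.n_warmup < self.n_iterations:
            raise ValueError("need 0 < n_warmup < n_iterations")
        if self.parameterization not in ("noncentered", "centered"):
            raise ValueError("parameterization must be 'noncentered' or 'centered'")


@dataclass
class PosteriorDraws:
    """Labelled post-warmup draws: array of shape (chains, draws, parameters).

    Parameter naming: ``beta1, beta2, beta3, sigma_r, tau_1..tau_{K-1},
    r_<participant_id>``.
    """

    names: list[str]
    array: np.ndarray  # (n_chains, n_kept, P)

    def __post_init__(self) -> None:
        self.array = np.asarray(self.array, dtype=float)
        if self.array.ndim != 3 or self.array.shape[2] != len(self.names):
            raise ValueError("draws array must be (chains, draws, parameters)")
        self._index = {name: j for j, name in enumerate(self.names)}

    @property
    def n_chains(self) -> int:
        return self.array.shape[0]

    @property
    def n_draws(self) -> int:
        """Total post-warmup draws pooled over chains."""
        return self.array.shape[0] * self.array.shape[1]

    def __contains__(self, name: str) -> bool:
        return name in self._index

    def chains(self, name: str) -> np.ndarray:
        """Draws of one parameter, shape (n_chains, n_kept)."""
        try:
            return self.array[:, :, self._index[name]]
        except KeyError:
            raise KeyError(f"unknown parameter {name!r}") from None

    def get(self, name: str) -> np.ndarray:
        """Pooled draws of one parameter, shape (M,)."""
        return self.chains(name).reshape(-1)

    def matrix(self, names: Sequence[str]) -> np.ndarray:
        """Pooled draws of several parameters, shape (M, len(names))."""
        cols = [self._index[n] for n in names]
        return self.array[:, :, cols].reshape(-1, len(cols))

    def to_frame(self) -> pd.DataFrame:
        n_chains, n_kept, _ = self.array.shape
        frame = pd.DataFrame(self.array.reshape(-1, len(self.names)), columns=self.names)
        frame.insert(0, "iteration", np.tile(np.arange(n_kept), n_chains))
        frame.insert(0, "chain", np.repeat(np.arange(n_chains), n_kept))
        return frame

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "PosteriorDraws":
        frame = pd.read_csv(path)
        if "chain" not in frame.columns or "iteration" not in frame.columns:
            raise ValueError("draws file must have 'chain' and 'iteration' columns")
        names = [c for c in frame.columns if c not in ("chain", "iteration")]
        chains = sorted(frame["chain"].unique())
        blocks = [
            frame.loc[frame["chain"] == c].sort_values("iteration")[names].to_numpy()
            for c in chains
        ]
        return cls(names=names, array=np.stack(blocks, axis=0))


@dataclass(frozen=True)
class IntervalSummary:
    """Posterior median with a credible interval."""

    median: float
    lower: float
    upper: float
    mass: float = 0.95
    interval_type: str = "equal_tailed"


# ---------------------------------------------------------------------------
# the built-in sampler
# ---------------------------------------------------------------------------

def _initial_cutpoints(data: AnalysisDataset) -> np.ndarray:
    """Cutpoints at standard-normal quantiles of pooled category frequencies."""
    counts = np.bincount(
        np.concatenate([data.y_async, data.y_sync]), minlength=data.n_categories + 1
    )[1:]
    total = counts.sum()
    cum = np.cumsum(counts)[:-1] / total
    cum = np.clip(cum, 1.0 / (2 * total), 1.0 - 1.0 / (2 * total))
    tau = ndtri(cum)
    # guard against ties from empty interior categories
    for j in range(1, tau.size):
        if tau[j] <= tau[j - 1]:
            tau[j] = tau[j - 1] + 1e-3
    return tau


class _ChainState:
    """Mutable state of one chain in the unconstrained parameterization."""

    __slots__ = ("g", "z", "g_step", "z_step")

    def __init__(self, g: np.ndarray, z: np.ndarray):
        self.g = g  # [beta1, beta2, beta3, log_sigma, c_1..c_{K-1}]
        self.z = z  # (N,) latent slopes (z_i or r_i depending on parameterization)
        self.g_step = np.full(g.size, -0.7)  # log step sizes
        self.z_step = np.full(z.size, 0.0)


def _run_chain(
    data: AnalysisDataset,
    prior: PriorConfig,
    config: McmcConfig,
    rng: np.random.Generator,
    tau_init: np.ndarray,
) -> np.ndarray:
    """Run one chain; return kept draws (n_kept, 4 + (K-1) + N) on the
    reporting scale (beta1..3, sigma_r, tau, r)."""
    n = data.n_participants
    k1 = data.n_categories - 1
    cia = data.cia
    y0 = data.y_async
    y1 = data.y_sync
    noncentered = config.parameterization == "noncentered"
    with_lik = config.include_likelihood

    def unpack(g: np.ndarray):
        beta1, beta2, beta3, log_sigma = g[:4]
        c = g[4:]
        tau = np.empty(k1)
        tau[0] = c[0]
        if k1 > 1:
            tau[1:] = c[0] + np.cumsum(np.exp(c[1:]))
        return beta1, beta2, beta3, math.exp(log_sigma), tau

    _zeros = np.zeros(n)

    def loglik_parts(beta1, beta2, beta3, sigma, tau, z):
        """(async, sync) per-participant observation log probabilities."""
        if not with_lik:
            return _zeros, _zeros
        tau_pad = np.concatenate(([-np.inf], tau, [np.inf]))
        r = sigma * z if noncentered else z
        eta0 = beta2 * cia
        eta1 = beta1 + r + (beta2 + beta3) * cia
        p0 = interval_prob(tau_pad[y0 - 1] - eta0, tau_pad[y0] - eta0)
        p1 = interval_prob(tau_pad[y1 - 1] - eta1, tau_pad[y1] - eta1)
        return (
            np.log(np.maximum(p0, PROB_FLOOR)),
            np.log(np.maximum(p1, PROB_FLOOR)),
        )

    def global_logprior(g: np.ndarray, z: np.ndarray) -> float:
        """Priors on globals plus transform Jacobians plus, in the centered
        case, the sigma-dependent slope prior."""
        beta1, beta2, beta3, log_sigma, sigma = g[0], g[1], g[2], g[3], math.exp(g[3])
        _, _, _, _, tau = unpack(g)
        total = float(np.sum(prior.coef.logpdf(np.array([beta1, beta2, beta3]))))
        total += float(prior.sigma.logpdf(sigma)) + log_sigma  # log-scale Jacobian
        total += float(np.sum(prior.cutpoint.logpdf(tau)))
        if k1 > 1:
            total += float(np.sum(g[5:]))  # log-increment Jacobian
        if not noncentered:
            total += float(
                np.sum(-0.5 * (z / sigma) ** 2) - n * (g[3] + 0.5 * math.log(2 * math.pi))
            )
        return total

    # -- initialization (retry with fresh jitter if the start is degenerate)
    c_init = np.empty(k1)
    c_init[0] = tau_init[0]
    if k1 > 1:
        c_init[1:] = np.log(np.diff(tau_init))
    state = None
    for _ in range(10):
        g = np.concatenate(([0.0, 0.0, 0.0, 0.0], c_init)) + 0.1 * rng.normal(size=4 + k1)
        z = 0.1 * rng.normal(size=n)
        try:
            beta1, beta2, beta3, sigma, tau = unpack(g)
            ll0, ll1 = loglik_parts(beta1, beta2, beta3, sigma, tau, z)
            lp = global_logprior(g, z)
        except (ValueError, FloatingPointError):
            continue
        if math.isfinite(lp) and np.all(np.isfinite(ll0)) and np.all(np.isfinite(ll1)):
            state = _ChainState(g, z)
            break
    if state is None:
        raise RuntimeError("could not find a finite starting point for the chain")

    lik_scale = 1.0 if with_lik else 0.0
    ll0_sum = float(ll0.sum())
    # ll1 (per-participant sync log-probs) is carried across sweeps for the z update
    target = lik_scale * (ll0_sum + float(ll1.sum())) + lp

    n_kept = config.n_iterations - config.n_warmup
    out = np.empty((n_kept, 4 + k1 + n))
    ng = state.g.size
    z_prior_const = -0.5  # coefficient of z^2 in the standard-normal log pdf

    # Haario-style adaptive-covariance block proposal over the globals:
    # the coefficients trade off against each other (and the cutpoints), so
    # scalar moves alone mix slowly.  Welford accumulators feed an empirical
    # covariance; the block step scale targets the multivariate optimum.
    block_mean = np.zeros(ng)
    block_m2 = np.zeros((ng, ng))
    block_count = 0
    block_logscale = math.log(2.38 / math.sqrt(ng))
    block_chol: np.ndarray | None = None
    _BLOCK_START = 100
    _TARGET_ACCEPT_BLOCK = 0.234

    for it in range(config.n_iterations):
        adapt = it < config.n_warmup
        gamma = (it + 1) ** -0.6 if adapt else 0.0

        # ---- scalar updates of the global parameters -------------------
        for j in range(ng):
            prop = state.g.copy()
            prop[j] += math.exp(state.g_step[j]) * rng.normal()
            b1, b2, b3, sg, tu = unpack(prop)
            pll0, pll1 = loglik_parts(b1, b2, b3, sg, tu, state.z)
            plp = global_logprior(prop, state.z)
            cand = lik_scale * float(pll0.sum() + pll1.sum()) + plp
            log_alpha = cand - target
            accept = math.isfinite(cand) and math.log(rng.uniform()) < log_alpha
            if accept:
                state.g = prop
                ll0_sum = float(pll0.sum())
                ll1 = pll1
                target = cand
            if adapt:
                acc_prob = min(1.0, math.exp(min(0.0, log_alpha))) if math.isfinite(cand) else 0.0
                state.g_step[j] += gamma * (acc_prob - _TARGET_ACCEPT)

        # ---- correlated block update of all globals --------------------
        if adapt:
            block_count += 1
            delta_mean = state.g - block_mean
            block_mean += delta_mean / block_count
            block_m2 += np.outer(delta_mean, state.g - block_mean)
            if block_count > _BLOCK_START and block_count % 50 == 0:
                cov = block_m2 / (block_count - 1) + 1e-8 * np.eye(ng)
                try:
                    block_chol = np.linalg.cholesky(cov)
                except np.linalg.LinAlgError:
                    block_chol = None
        if block_chol is not None:
            prop = state.g + math.exp(block_logscale) * (block_chol @ rng.normal(size=ng))
            b1, b2, b3, sg, tu = unpack(prop)
            pll0, pll1 = loglik_parts(b1, b2, b3, sg, tu, state.z)
            plp = global_logprior(prop, state.z)
            cand = lik_scale * float(pll0.sum() + pll1.sum()) + plp
            log_alpha = cand - target
            if math.isfinite(cand) and math.log(rng.uniform()) < log_alpha:
                state.g = prop
                ll0_sum = float(pll0.sum())
                ll1 = pll1
                target = cand
            if adapt:
                acc_prob = min(1.0, math.exp(min(0.0, log_alpha))) if math.isfinite(cand) else 0.0
                block_logscale += gamma * (acc_prob - _TARGET_ACCEPT_BLOCK)

        # ---- joint vectorized update of the latent slopes --------------
        beta1, beta2, beta3, sigma, tau = unpack(state.g)
        z_prop = state.z + np.exp(state.z_step) * rng.normal(size=n)
        tau_pad = np.concatenate(([-np.inf], tau, [np.inf]))
        if noncentered:
            eta1_prop = beta1 + sigma * z_prop + (beta2 + beta3) * cia
            prior_diff = z_prior_const * (z_prop**2 - state.z**2)
        else:
            eta1_prop = beta1 + z_prop + (beta2 + beta3) * cia
            prior_diff = z_prior_const * (z_prop**2 - state.z**2) / sigma**2
        if with_lik:
            p1 = interval_prob(tau_pad[y1 - 1] - eta1_prop, tau_pad[y1] - eta1_prop)
            ll1_prop = np.log(np.maximum(p1, PROB_FLOOR))
        else:
            ll1_prop = _zeros
        log_alpha_z = lik_scale * (ll1_prop - ll1) + prior_diff
        accept_z = np.log(rng.uniform(size=n)) < log_alpha_z
        if np.any(accept_z):
            state.z = np.where(accept_z, z_prop, state.z)
            ll1 = np.where(accept_z, ll1_prop, ll1)
            # recompute the running target exactly to avoid accumulation drift
            target = lik_scale * (ll0_sum + float(ll1.sum())) + global_logprior(
                state.g, state.z
            )
        if adapt:
            acc_prob_z = np.exp(np.minimum(0.0, log_alpha_z))
            state.z_step += gamma * (acc_prob_z - _TARGET_ACCEPT)

        # ---- record ----------------------------------------------------
        if it >= config.n_warmup:
            beta1, beta2, beta3, sigma, tau = unpack(state.g)
            row = out[it - config.n_warmup]
            row[0], row[1], row[2], row[3] = beta1, beta2, beta3, sigma
            row[4 : 4 + k1] = tau
            row[4 + k1 :] = sigma * state.z if noncentered else state.z

    return out


def sample_posterior(
    data: AnalysisDataset,
    prior: PriorConfig | None = None,
    config: McmcConfig | None = None,
) -> PosteriorDraws:
    """Draw from the posterior of the hierarchical ordered-probit model.

    Chains run sequentially with independent random streams spawned from
    ``config.seed``; identical (data, prior, config) give bitwise identical
    draws.
    """
    prior = prior or PriorConfig()
    config = config or McmcConfig()
    k1 = data.n_categories - 1
    tau_init = _initial_cutpoints(data)
    streams = np.random.SeedSequence(config.seed).spawn(config.n_chains)
    chains = [
        _run_chain(data, prior, config, np.random.default_rng(s), tau_init)
        for s in streams
    ]
    names = (
        ["beta1", "beta2", "beta3", "sigma_r"]
        + [f"tau_{k}" for k in range(1, k1 + 1)]
        + [f"r_{pid}" for pid in data.participants]
    )
    return PosteriorDraws(names=names, array=np.stack(chains, axis=0))


def draws_to_parameters(
    draws: PosteriorDraws, data: AnalysisDataset, index: int
) -> ModelParameters:
    """Materialize one pooled draw as a :class:`ModelParameters` point."""
    flat = draws.matrix(draws.names)[index]
    k1 = data.n_categories - 1
    return ModelParameters(
        beta1=flat[0],
        beta2=flat[1],
        beta3=flat[2],
        sigma_r=flat[3],
        cutpoints=flat[4 : 4 + k1],
        r=flat[4 + k1 :],
    )


# ---------------------------------------------------------------------------
# diagnostics and summaries
# ---------------------------------------------------------------------------

def rhat(draws: PosteriorDraws | np.ndarray, parameter: str | None = None,
         method: str = "rank") -> float:
    """Potential scale reduction factor of one parameter.

    ``method='rank'`` (default) is the rank-normalized split variant
    (delegated to :func:`arviz.rhat`); ``method='split'`` is the classic
    split-chain statistic.  Chains that are all identical and constant are a
    degenerate case and return 1.0 by convention.
    """
    if isinstance(draws, PosteriorDraws):
        if parameter is None:
            raise ValueError("parameter name required with PosteriorDraws input")
        arr = draws.chains(parameter)
    else:
        arr = np.asarray(draws, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2:
        raise ValueError("rhat needs a (chains, draws) array with >= 2 chains")
    if arr.shape[1] < 4:
        raise ValueError("rhat needs at least 4 draws per chain")
    if np.ptp(arr) == 0.0:
        return 1.0
    if method == "rank":
        return float(az.rhat(arr))
    if method != "split":
        raise ValueError("method must be 'rank' or 'split'")
    half = arr.shape[1] // 2
    halves = np.concatenate([arr[:, :half], arr[:, half : 2 * half]], axis=0)
    m, nd = halves.shape
    chain_means = halves.mean(axis=1)
    w = float(np.mean(np.var(halves, axis=1, ddof=1)))
    b = nd * float(np.var(chain_means, ddof=1))
    if w == 0.0:
        return 1.0
    var_hat = (nd - 1) / nd * w + b / nd
    return float(math.sqrt(var_hat / w))


def hpdi(samples, mass: float = 0.95) -> tuple[float, float]:
    """Highest posterior density interval.

    The shortest contiguous window of the sorted sample containing
    ``ceil(mass * M)`` draws; ties in width are broken to the leftmost
    window.
    """
    samples = np.sort(np.asarray(samples, dtype=float).reshape(-1))
    m = samples.size
    if m == 0:
        raise ValueError("hpdi of an empty sample")
    if not 0.0 < mass < 1.0:
        raise ValueError("mass must be in (0, 1)")
    n_keep = min(m, math.ceil(mass * m))
    widths = samples[n_keep - 1 :] - samples[: m - n_keep + 1]
    # leftmost window among (numerically) tied minimal widths
    tol = 8 * np.finfo(float).eps * max(1.0, float(np.abs(samples).max()))
    start = int(np.argmax(widths <= widths.min() + tol))
    return float(samples[start]), float(samples[start + n_keep - 1])


def summarize_vector(
    samples, mass: float = 0.95, interval_type: str = "equal_tailed"
) -> IntervalSummary:
    """Median plus a credible interval of a draw vector."""
    samples = np.asarray(samples, dtype=float).reshape(-1)
    if samples.size == 0:
        raise ValueError("cannot summarize an empty sample")
    med = float(np.median(samples))
    if interval_type == "equal_tailed":
        alpha = (1.0 - mass) / 2.0
        lo, hi = np.quantile(samples, [alpha, 1.0 - alpha])
    elif interval_type == "hpdi":
        lo, hi = hpdi(samples, mass)
    else:
        raise ValueError("interval_type must be 'equal_tailed' or 'hpdi'")
    return IntervalSummary(
        median=med, lower=float(lo), upper=float(hi), mass=mass, interval_type=interval_type
    )


def summarize(
    draws: PosteriorDraws,
    parameter: str,
    mass: float = 0.95,
    interval_type: str = "equal_tailed",
) -> IntervalSummary:
    """Median and credible interval of one named parameter."""
    return summarize_vector(draws.get(parameter), mass=mass, interval_type=interval_type)


@dataclass
class ConvergenceReport:
    """R-hat per parameter with an overall pass/fail flag."""

    threshold: float
    rhats: dict[str, float]
    failures: list[str]
    passed: bool

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "parameter": list(self.rhats),
                "rhat": list(self.rhats.values()),
                "passed": [p not in self.failures for p in self.rhats],
            }
        )


def convergence_report(
    draws: PosteriorDraws,
    threshold: float = 1.1,
    parameters: Sequence[str] | None = None,
    method: str = "rank",
) -> ConvergenceReport:
    """Check the R-hat <= threshold rule for every (requested) parameter.

    An empty parameter subset yields a vacuous pass.
    """
    names = list(draws.names) if parameters is None else list(parameters)
    rhats = {name: rhat(draws, name, method=method) for name in names}
    failures = [name for name, value in rhats.items() if not value <= threshold]
    return ConvergenceReport(
        threshold=threshold, rhats=rhats, failures=failures, passed=not failures
    )
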