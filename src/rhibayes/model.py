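"""Hierarchical ordered-probit model of illusion susceptibility.

The latent ownership intensity of participant ``i`` is

    IHO*_i = (beta1 + r_i) * cond + beta2 * CIA_i + beta3 * cond * CIA_i + e

with ``cond`` coded 0 for asynchronous and 1 for synchronous stroking,
``r_i ~ Normal(0, sigma_r^2)`` a participant-specific random condition slope,
and ``e`` a standard-normal residual (the probit identification: the latent
residual SD is fixed at 1 and is not a free parameter).  The observed rating
is the ordinal category carved out of the latent scale by K-1 strictly
increasing cutpoints: ``Y = k`` iff ``tau_{k-1} < IHO* <= tau_k`` with
``tau_0 = -inf`` and ``tau_K = +inf``.

There is no intercept, fixed or random: the regression equation carries none,
and location on the latent scale is absorbed entirely by the free cutpoints.
``beta1 + beta3*CIA_i + r_i`` is participant ``i``'s illusion susceptibility
(the individual synchrony effect); ``beta3`` is therefore the slope of the
implicit regression of susceptibility on interoceptive accuracy, and ``r_i``
its residual.  CIA enters on its raw 0-1 scale — the standardized
interaction effect is interpreted as the contrast between hypothetical
CIA = 0 and CIA = 1 populations, which requires the raw scale.

Default priors are weakly informative: Normal(0, 2.5) on the coefficients,
half-Cauchy(0, 2.5) on ``sigma_r``, and a heavy-tailed Student-t(3, 0, 2.5)
on each cutpoint (the ordering is enforced structurally by the sampler's
parameterization, not by the prior).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import yaml
from scipy.special import ndtr

from .data_io import AnalysisDataset

#: Floor applied to category probabilities before taking logs.  Documented so
#: that likelihood oracles can apply the same guard.
PROB_FLOOR = 1e-300

_LOG_SQRT_2PI = 0.5 * math.log(2.0 * math.pi)


# ---------------------------------------------------------------------------
# parameters and priors
# ---------------------------------------------------------------------------

@dataclass
class ModelParameters:
    """One point in parameter space.

    ``cutpoints`` has length K-1 and must be strictly increasing; ``r`` has
    one random condition-slope deviation per participant.
    """

    beta1: float
    beta2: float
    beta3: float
    sigma_r: float
    r: np.ndarray
    cutpoints: np.ndarray

    def __post_init__(self) -> None:
        self.r = np.atleast_1d(np.asarray(self.r, dtype=float))
        self.cutpoints = np.atleast_1d(np.asarray(self.cutpoints, dtype=float))
        if self.sigma_r <= 0:
            raise ValueError(f"sigma_r must be positive, got {self.sigma_r}")
        if not np.all(np.diff(self.cutpoints) > 0):
            raise ValueError("cutpoints must be strictly increasing")

    @property
    def n_participants(self) -> int:
        return self.r.size

    @property
    def n_categories(self) -> int:
        return self.cutpoints.size + 1


@dataclass(frozen=True)
class PriorSpec:
    """A univariate prior density, by family name.

    Families ``normal`` and ``student_t`` are location-scale (``df`` used by
    the latter); ``half_cauchy``, ``half_normal``, ``half_t`` and
    ``exponential`` live on the positive half-line with ``scale`` as their
    scale parameter (``loc`` must be 0 for these).
    """

    family: str
    loc: float = 0.0
    scale: float = 2.5
    df: float = 3.0

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise ValueError(f"prior scale must be positive, got {self.scale}")
        known = {"normal", "student_t", "half_cauchy", "half_normal", "half_t", "exponential"}
        if self.family not in known:
            raise ValueError(f"unknown prior family {self.family!r}; choose from {sorted(known)}")
        if self.family.startswith("half") or self.family == "exponential":
            if self.loc != 0.0:
                raise ValueError(f"{self.family} prior must have loc = 0")

    def logpdf(self, x):
        """Elementwise log density (closed forms, vectorized)."""
        x = np.asarray(x, dtype=float)
        s = self.scale
        if self.family == "normal":
            z = (x - self.loc) / s
            return -0.5 * z * z - math.log(s) - _LOG_SQRT_2PI
        if self.family == "student_t":
            v = self.df
            z = (x - self.loc) / s
            const = (
                math.lgamma((v + 1) / 2) - math.lgamma(v / 2)
                - 0.5 * math.log(v * math.pi) - math.log(s)
            )
            return const - 0.5 * (v + 1) * np.log1p(z * z / v)
        # positive half-line families
        out = np.where(x > 0, 0.0, -np.inf)
        with np.errstate(invalid="ignore", divide="ignore"):
            if self.family == "half_cauchy":
                body = math.log(2.0 / (math.pi * s)) - np.log1p((x / s) ** 2)
            elif self.family == "half_normal":
                z = x / s
                body = math.log(2.0) - 0.5 * z * z - math.log(s) - _LOG_SQRT_2PI
            elif self.family == "half_t":
                v = self.df
                z = x / s
                const = (
                    math.log(2.0) + math.lgamma((v + 1) / 2) - math.lgamma(v / 2)
                    - 0.5 * math.log(v * math.pi) - math.log(s)
                )
                body = const - 0.5 * (v + 1) * np.log1p(z * z / v)
            else:  # exponential with scale s (mean s)
                body = -math.log(s) - x / s
        return np.where(x > 0, body, out)


@dataclass(frozen=True)
class PriorConfig:
    """Priors for the three regression coefficients, the random-slope SD and
    the cutpoints."""

    coef: PriorSpec = field(default_factory=lambda: PriorSpec("normal", 0.0, 2.5))
    sigma: PriorSpec = field(default_factory=lambda: PriorSpec("half_cauchy", 0.0, 2.5))
    cutpoint: PriorSpec = field(default_factory=lambda: PriorSpec("student_t", 0.0, 2.5, df=3.0))

    def __post_init__(self) -> None:
        if self.sigma.family in ("normal", "student_t"):
            raise ValueError("sigma prior must be a positive-half-line family")

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        def spec(s: PriorSpec) -> dict:
            d = {"family": s.family, "loc": s.loc, "scale": s.scale}
            if s.family in ("student_t", "half_t"):
                d["df"] = s.df
            return d

        return {"coef": spec(self.coef), "sigma": spec(self.sigma),
                "cutpoint": spec(self.cutpoint)}

    @classmethod
    def from_dict(cls, data: dict) -> "PriorConfig":
        default = cls()
        out = {}
        for name in ("coef", "sigma", "cutpoint"):
            if name in data:
                out[name] = PriorSpec(**data[name])
            else:
                out[name] = getattr(default, name)
        return cls(**out)

    @classmethod
    def from_yaml(cls, path) -> "PriorConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# model mathematics
# ---------------------------------------------------------------------------

def linear_predictor(params: ModelParameters, cia: float, cond: int, i: int) -> float:
    """Latent-scale mean eta for participant ``i`` in one condition.

    eta = (beta1 + r_i) * cond + beta2 * cia + beta3 * cond * cia
    """
    if not 0 <= i < params.n_participants:
        raise IndexError(f"participant index {i} out of range")
    return (params.beta1 + params.r[i]) * cond + params.beta2 * cia + params.beta3 * cond * cia


def category_probs(eta, cutpoints) -> np.ndarray:
    """Ordered-probit category probabilities.

    ``P(Y = k) = Phi(tau_k - eta) - Phi(tau_{k-1} - eta)`` with
    ``tau_0 = -inf`` and ``tau_K = +inf``.  ``eta`` may be a scalar or an
    array; the category axis is last.
    """
    cutpoints = np.asarray(cutpoints, dtype=float)
    if cutpoints.ndim != 1 or not np.all(np.diff(cutpoints) > 0):
        raise ValueError("cutpoints must be a strictly increasing 1-d sequence")
    eta = np.asarray(eta, dtype=float)
    cdf = ndtr(cutpoints - eta[..., None])
    padded = np.concatenate(
        [np.zeros(eta.shape + (1,)), cdf, np.ones(eta.shape + (1,))], axis=-1
    )
    probs = np.diff(padded, axis=-1)
    return np.clip(probs, 0.0, 1.0)


def interval_prob(lo, hi) -> np.ndarray:
    """P(lo < Z <= hi) for standard-normal Z, accurate in both tails.

    A plain ``ndtr(hi) - ndtr(lo)`` loses all relative precision when the
    interval sits in the upper tail (both CDF values near 1); reflecting
    such intervals to the lower tail keeps the error small relative to the
    probability itself.
    """
    lo = np.asarray(lo, dtype=float)
    hi = np.asarray(hi, dtype=float)
    with np.errstate(invalid="ignore"):
        upper = np.nan_to_num(lo + hi, nan=0.0) > 0  # reflect upper-tail intervals
    p = np.where(upper, ndtr(-lo) - ndtr(-hi), ndtr(hi) - ndtr(lo))
    return np.clip(p, 0.0, 1.0)


def _observation_log_probs(params: ModelParameters, data: AnalysisDataset) -> np.ndarray:
    """Log category probability of every observation, shape (2N,)."""
    tau = np.concatenate(([-np.inf], params.cutpoints, [np.inf]))
    eta0 = params.beta2 * data.cia
    eta1 = params.beta1 + params.r + (params.beta2 + params.beta3) * data.cia
    eta = np.concatenate([eta0, eta1])
    y = np.concatenate([data.y_async, data.y_sync])
    p = interval_prob(tau[y - 1] - eta, tau[y] - eta)
    return np.log(np.maximum(p, PROB_FLOOR))


def log_likelihood(params: ModelParameters, data: AnalysisDataset) -> float:
    """Ordered-probit log likelihood over all (participant, condition) cells.

    Category probabilities are floored at :data:`PROB_FLOOR` before the log,
    so the result is finite but very negative when an observed category has
    underflowed probability.
    """
    if params.n_participants != data.n_participants:
        raise ValueError(
            f"parameters sized for {params.n_participants} participants, "
            f"data has {data.n_participants}"
        )
    if params.n_categories != data.n_categories:
        raise ValueError(
            f"parameters imply K={params.n_categories}, data declares K={data.n_categories}"
        )
    return float(_observation_log_probs(params, data).sum())


def log_prior(params: ModelParameters, prior: PriorConfig | None = None) -> float:
    """Joint log prior density at ``params``.

    Sums the coefficient prior over (beta1, beta2, beta3), the SD prior at
    sigma_r, Normal(0, sigma_r) over the random slopes, and the cutpoint
    prior over each cutpoint.  Ordering of the cutpoints is a structural
    constraint (handled by the sampler's parameterization), not part of this
    density.  Returns ``-inf`` when sigma_r is at or below zero.
    """
    prior = prior or PriorConfig()
    if params.sigma_r <= 0:
        return -math.inf
    betas = np.array([params.beta1, params.beta2, params.beta3])
    total = float(np.sum(prior.coef.logpdf(betas)))
    total += float(prior.sigma.logpdf(params.sigma_r))
    z = params.r / params.sigma_r
    total += float(
        np.sum(-0.5 * z * z - math.log(params.sigma_r) - _LOG_SQRT_2PI)
    )
    total += float(np.sum(prior.cutpoint.logpdf(params.cutpoints)))
    return total


def log_posterior(
    params: ModelParameters, data: AnalysisDataset, prior: PriorConfig | None = None
) -> float:
    """Unnormalized log posterior: ``log_likelihood + log_prior``."""
    lp = log_prior(params, prior)
    if not math.isfinite(lp):
        return lp
    return log_likelihood(params, data) + lp
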