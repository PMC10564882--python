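"""Derived quantities: susceptibility, standardized interaction, Bayesian R².

Participant ``i``'s illusion susceptibility is the individual synchrony
effect ``beta1 + beta3 * CIA_i + r_i``, evaluated per posterior draw and
summarized by its median and 95% equal-tailed credible interval; intervals
that exclude zero mark participants who unambiguously experienced (or
resisted) the illusion.

Two effect sizes quantify how much interoceptive accuracy explains of the
between-participant variation in susceptibility:

* standardized beta3 — ``beta3 / sigma_r`` per draw, in the spirit of
  Cohen's d: the standardized difference in mean susceptibility between
  hypothetical populations with CIA = 0 and CIA = 1;
* Bayesian R² — per draw, ``Var(beta3 * CIA_i) / (Var(beta3 * CIA_i) +
  sigma_r^2)``, the proportion of susceptibility variance attributable to
  CIA.  The residual variance is the model's ``sigma_r^2`` (the modeled
  residual-variance reading of the Gelman et al. definition); an alternative
  using the empirical variance of the realized ``r_i`` draws is available
  behind a flag.  Fitted-value variance uses the N-1 denominator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_io import AnalysisDataset
from .inference import (
    ConvergenceReport,
    IntervalSummary,
    PosteriorDraws,
    convergence_report,
    summarize_vector,
)


@dataclass(frozen=True)
class SusceptibilitySummary:
    participant_id: str
    cia: float
    median: float
    lower: float
    upper: float
    includes_zero: bool


@dataclass(frozen=True)
class EffectSummary:
    name: str  # "standardized_beta3" | "bayes_r2"
    median: float
    lower: float
    upper: float
    interval_type: str


def susceptibility_draws(
    draws: PosteriorDraws, data: AnalysisDataset
) -> dict[str, np.ndarray]:
    """Per-participant susceptibility draw vectors.

    ``s_i = beta1 + beta3 * CIA_i + r_i`` evaluated at every pooled draw.
    """
    missing = [p for p in data.participants if f"r_{p}" not in draws]
    if missing:
        raise ValueError(f"draws lack random slopes for participant(s): {missing}")
    beta1 = draws.get("beta1")
    beta3 = draws.get("beta3")
    return {
        pid: beta1 + beta3 * cia_i + draws.get(f"r_{pid}")
        for pid, cia_i in zip(data.participants, data.cia)
    }


def susceptibility_summaries(
    draws: PosteriorDraws, data: AnalysisDataset, mass: float = 0.95
) -> list[SusceptibilitySummary]:
    """Median and equal-tailed interval of susceptibility per participant."""
    vectors = susceptibility_draws(draws, data)
    out = []
    for pid, cia_i in zip(data.participants, data.cia):
        s = summarize_vector(vectors[pid], mass=mass, interval_type="equal_tailed")
        out.append(
            SusceptibilitySummary(
                participant_id=pid,
                cia=float(cia_i),
                median=s.median,
                lower=s.lower,
                upper=s.upper,
                includes_zero=s.lower <= 0.0 <= s.upper,
            )
        )
    return out


def count_includes_zero(
    summaries: list[SusceptibilitySummary],
) -> tuple[int, int, int]:
    """(n intervals including 0, n excluding 0, N)."""
    n_incl = sum(1 for s in summaries if s.includes_zero)
    return n_incl, len(summaries) - n_incl, len(summaries)


def standardized_beta3(draws: PosteriorDraws, mass: float = 0.95) -> EffectSummary:
    """``beta3 / sigma_r`` per draw, median + equal-tailed interval."""
    values = draws.get("beta3") / draws.get("sigma_r")
    s = summarize_vector(values, mass=mass, interval_type="equal_tailed")
    return EffectSummary(
        name="standardized_beta3",
        median=s.median,
        lower=s.lower,
        upper=s.upper,
        interval_type="equal_tailed",
    )


def bayes_r2_draws(
    draws: PosteriorDraws,
    data: AnalysisDataset,
    residual: str = "sigma",
) -> np.ndarray:
    """Per-draw R² values, each in [0, 1].

    ``residual='sigma'`` uses ``sigma_r^2``; ``residual='empirical'`` uses
    the N-1 sample variance of that draw's realized random slopes.
    """
    if data.n_participants < 2:
        raise ValueError("Bayesian R² needs at least 2 participants")
    beta3 = draws.get("beta3")
    v_cia = float(np.var(data.cia, ddof=1))
    v_fit = beta3**2 * v_cia
    if residual == "sigma":
        v_res = draws.get("sigma_r") ** 2
    elif residual == "empirical":
        r = draws.matrix([f"r_{p}" for p in data.participants])
        v_res = np.var(r, axis=1, ddof=1)
    else:
        raise ValueError("residual must be 'sigma' or 'empirical'")
    denom = v_fit + v_res
    with np.errstate(invalid="ignore"):
        r2 = np.where(denom > 0, v_fit / np.where(denom > 0, denom, 1.0), 0.0)
    return r2


def bayes_r2(
    draws: PosteriorDraws,
    data: AnalysisDataset,
    mass: float = 0.95,
    residual: str = "sigma",
) -> EffectSummary:
    """Proportion of susceptibility variance explained by CIA.

    Summarized by the posterior median and the 95% highest-density interval
    (the R² posterior piles up near 0 when the interaction is weak, so the
    equal-tailed interval would be misleading there).
    """
    r2 = bayes_r2_draws(draws, data, residual=residual)
    s = summarize_vector(r2, mass=mass, interval_type="hpdi")
    return EffectSummary(
        name="bayes_r2", median=s.median, lower=s.lower, upper=s.upper,
        interval_type="hpdi",
    )


# ---------------------------------------------------------------------------
# report assembly
# ---------------------------------------------------------------------------

_PARAM_ORDER = ("beta1", "sigma_r", "beta2", "beta3")


@dataclass
class AnalysisReport:
    """Fitted-model summary tables.

    ``parameters``: one row per model parameter (median, 95% CrI);
    ``effects``: standardized beta3 and Bayesian R²;
    ``susceptibility``: one row per participant;
    ``counts``: intervals including/excluding zero;
    ``convergence``: R-hat gate over the reported parameters.
    """

    parameters: pd.DataFrame
    effects: pd.DataFrame
    susceptibility: pd.DataFrame
    counts: tuple[int, int, int]
    convergence: ConvergenceReport

    def write(self, directory) -> None:
        from pathlib import Path

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.parameters.to_csv(directory / "parameters.csv", index=False)
        self.effects.to_csv(directory / "effects.csv", index=False)
        self.susceptibility.to_csv(directory / "susceptibility.csv", index=False)


def make_report(
    draws: PosteriorDraws,
    data: AnalysisDataset,
    mass: float = 0.95,
    rhat_threshold: float = 1.1,
) -> AnalysisReport:
    """Assemble the full results report from posterior draws.

    Emits a warning (without refusing) when any reported parameter fails the
    R-hat gate.
    """
    import warnings

    focal = list(_PARAM_ORDER) + [n for n in draws.names if n.startswith("tau_")]
    conv = convergence_report(draws, threshold=rhat_threshold, parameters=focal)
    if not conv.passed:
        warnings.warn(
            f"R-hat exceeds {rhat_threshold} for: {conv.failures}; "
            "summaries may be unreliable",
            stacklevel=2,
        )

    rows = []
    for name in _PARAM_ORDER:
        s = summarize_vector(draws.get(name), mass=mass)
        rows.append({"parameter": name, "median": s.median, "lower": s.lower,
                     "upper": s.upper, "interval_type": "equal_tailed"})
    parameters = pd.DataFrame(rows)

    eff = [standardized_beta3(draws, mass=mass), bayes_r2(draws, data, mass=mass)]
    effects_frame = pd.DataFrame(
        [
            {"effect": e.name, "median": e.median, "lower": e.lower,
             "upper": e.upper, "interval_type": e.interval_type}
            for e in eff
        ]
    )

    summaries = susceptibility_summaries(draws, data, mass=mass)
    susceptibility = pd.DataFrame(
        [
            {
                "participant": s.participant_id,
                "cia": s.cia,
                "median": s.median,
                "lower": s.lower,
                "upper": s.upper,
                "includes_zero": s.includes_zero,
            }
            for s in summaries
        ]
    )
    return AnalysisReport(
        parameters=parameters,
        effects=effects_frame,
        susceptibility=susceptibility,
        counts=count_includes_zero(summaries),
        convergence=conv,
    )


def plot_susceptibility(summaries: list[SusceptibilitySummary], path=None):
    """Susceptibility vs CIA: medians with 95% interval segments, colored by
    whether the interval includes zero.  Returns the matplotlib figure."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for s in summaries:
        color = "tab:blue" if s.includes_zero else "tab:orange"
        ax.plot([s.cia, s.cia], [s.lower, s.upper], color=color, lw=1.2, alpha=0.8)
        ax.plot(s.cia, s.median, "o", color=color, ms=4)
    ax.axhline(0.0, color="grey", lw=0.8, ls="--")
    ax.set_xlabel("cardiac interoceptive accuracy")
    ax.set_ylabel("illusion susceptibility (latent scale)")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
    return fig
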