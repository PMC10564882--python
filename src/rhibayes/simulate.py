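"""Synthetic data with exactly the generative structure the model assumes.

Each simulated participant gets an interoceptive-accuracy score drawn from a
distribution on [0, 1] (default Beta(5, 2.7), mean ~0.65 — the right-skewed
shape typical of heartbeat-tracking samples), a random condition slope
``r_i ~ Normal(0, sigma_r)``, and one ordinal rating per stimulation
condition: the latent response ``eta + Normal(0, 1)`` is cut into K
categories by the configured cutpoints.  A heartbeat-trial generator inverts
the accuracy formula so the scoring code can be exercised end to end.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_io import AnalysisDataset, HeartbeatTrial

#: Symmetric unit-spaced cutpoints for a 7-category scale.
DEFAULT_CUTPOINTS = (-2.5, -1.5, -0.5, 0.5, 1.5, 2.5)


@dataclass(frozen=True)
class CiaDistribution:
    """Distribution of accuracy scores across participants.

    ``beta`` with shape parameters (a, b); ``uniform`` on [low, high];
    ``point`` is a degenerate point mass (edge-case testing).
    """

    family: str = "beta"
    a: float = 5.0
    b: float = 2.7
    low: float = 0.0
    high: float = 1.0
    value: float = 0.65

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.family == "beta":
            return rng.beta(self.a, self.b, size=n)
        if self.family == "uniform":
            return rng.uniform(self.low, self.high, size=n)
        if self.family == "point":
            return np.full(n, self.value)
        raise ValueError(f"unknown CIA distribution family {self.family!r}")

    @property
    def mean(self) -> float:
        if self.family == "beta":
            return self.a / (self.a + self.b)
        if self.family == "uniform":
            return 0.5 * (self.low + self.high)
        return self.value


@dataclass(frozen=True)
class GeneratorConfig:
    n_participants: int = 50
    beta1: float = 0.5
    beta2: float = 0.25
    beta3: float = 0.33
    sigma_r: float = 2.2
    cutpoints: tuple[float, ...] = DEFAULT_CUTPOINTS
    cia_distribution: CiaDistribution = field(default_factory=CiaDistribution)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 2:
            raise ValueError("need at least 2 participants")
        if self.sigma_r < 0:
            raise ValueError("sigma_r must be non-negative")
        if not all(b > a for a, b in zip(self.cutpoints, self.cutpoints[1:])):
            raise ValueError("cutpoints must be strictly increasing")

    @property
    def n_categories(self) -> int:
        return len(self.cutpoints) + 1


@dataclass
class SimulationTruth:
    """Latent ground truth of one simulated dataset, for recovery checks."""

    config: GeneratorConfig
    r: np.ndarray
    cia: np.ndarray
    eta_async: np.ndarray
    eta_sync: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "participant": [_pid(i) for i in range(self.r.size)],
                "cia": self.cia,
                "r": self.r,
                "eta_async": self.eta_async,
                "eta_sync": self.eta_sync,
            }
        )


def _pid(i: int) -> str:
    return f"p{i + 1:04d}"


def simulate_dataset(
    config: GeneratorConfig | None = None,
) -> tuple[AnalysisDataset, SimulationTruth]:
    """Draw one dataset from the model's own generative process.

    Deterministic under a fixed ``config.seed``.  Returns the dataset
    together with the latent truth (CIA, random slopes, latent-scale means).
    """
    config = config or GeneratorConfig()
    rng = np.random.default_rng(config.seed)
    n = config.n_participants
    cia = config.cia_distribution.sample(n, rng)
    r = config.sigma_r * rng.standard_normal(n) if config.sigma_r > 0 else np.zeros(n)
    eta0 = config.beta2 * cia
    eta1 = (config.beta1 + r) + config.beta2 * cia + config.beta3 * cia
    tau = np.asarray(config.cutpoints)
    latent0 = eta0 + rng.standard_normal(n)
    latent1 = eta1 + rng.standard_normal(n)
    y0 = np.searchsorted(tau, latent0, side="left") + 1
    y1 = np.searchsorted(tau, latent1, side="left") + 1
    data = AnalysisDataset(
        participants=[_pid(i) for i in range(n)],
        cia=cia,
        y_async=y0,
        y_sync=y1,
        n_categories=config.n_categories,
    )
    truth = SimulationTruth(config=config, r=r, cia=cia, eta_async=eta0, eta_sync=eta1)
    return data, truth


def simulate_heartbeat_trials(
    participant_targets: dict[str, float],
    durations: tuple[float, float, float] = (25.0, 35.0, 45.0),
    heart_rate_bpm: float = 72.0,
    seed: int | None = None,
) -> list[HeartbeatTrial]:
    """Heartbeat-tracking trials whose score approximates a target accuracy.

    Recorded counts follow the (constant) heart rate over the three trial
    durations; the reported count on each trial is the integer whose
    per-trial accuracy is closest to the target, preferring the
    under-reporting side on ties.  Because counts are integers, the achieved
    score can differ from the target by at most about ``0.5 / min(recorded)``
    per trial.  ``seed`` is accepted for interface symmetry; the construction
    is deterministic.
    """
    del seed
    if len(durations) != 3:
        raise ValueError("exactly 3 trial durations are required")
    trials: list[HeartbeatTrial] = []
    for pid, target in participant_targets.items():
        if not 0.0 <= target <= 1.0:
            raise ValueError(f"target accuracy for {pid} must be in [0, 1], got {target}")
        for t, dur in enumerate(durations, start=1):
            rec = max(1, round(heart_rate_bpm * dur / 60.0))
            miss = rec * (1.0 - target)  # ideal |recorded - reported|
            best_rep, best_err = None, None
            for d in {math.floor(miss), math.ceil(miss)}:
                for rep in (rec - d, rec + d):  # under-reporting candidate first
                    if rep < 0:
                        continue
                    err = abs((1.0 - abs(rec - rep) / rec) - target)
                    if best_err is None or err < best_err - 1e-15 or (
                        abs(err - best_err) <= 1e-15 and rep < best_rep
                    ):
                        best_rep, best_err = rep, err
            trials.append(
                HeartbeatTrial(
                    participant_id=pid,
                    trial_index=t,
                    duration=float(dur),
                    hb_recorded=rec,
                    hb_reported=int(best_rep),
                )
            )
    return trials
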