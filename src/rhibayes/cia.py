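"""Cardiac interoceptive accuracy (CIA) from the heartbeat tracking task.

Each participant performs three counting trials.  Per-trial accuracy is

    a_t = 1 - |HB_rec,t - HB_rep,t| / HB_rec,t

where ``HB_rec`` is the heartbeat count measured by the recording device and
``HB_rep`` the count the participant reports.  The score is the mean of the
three per-trial accuracies.  Perfect counting gives 1; reporting zero beats
gives 0.  Over-reporting beyond twice the recorded count drives a trial term
below zero — such scores are retained (with a flag) rather than clamped,
because the formula itself does not enforce the nominal [0, 1] range; an
optional clamp is provided for sensitivity analyses.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .data_io import HeartbeatTrial


@dataclass(frozen=True)
class CiaScore:
    participant_id: str
    cia: float
    per_trial_accuracy: tuple[float, float, float]
    out_of_range_flag: bool


def compute_cia(trials: Sequence[HeartbeatTrial], clamp: bool = False) -> CiaScore:
    """Score one participant from exactly three tracking trials.

    Parameters
    ----------
    trials:
        The participant's three :class:`~rhibayes.data_io.HeartbeatTrial`
        records (any order).
    clamp:
        If true, clip the final score into [0, 1] (sensitivity switch); the
        default reports the raw formula value and sets ``out_of_range_flag``
        when it leaves [0, 1].
    """
    if len(trials) != 3:
        raise ValueError(f"CIA requires exactly 3 trials, got {len(trials)}")
    ids = {t.participant_id for t in trials}
    if len(ids) != 1:
        raise ValueError(f"trials belong to several participants: {sorted(ids)}")
    for t in trials:
        if t.hb_recorded < 1:
            raise ValueError(
                f"participant {t.participant_id} trial {t.trial_index}: "
                "hb_recorded must be >= 1"
            )
    accuracy = tuple(
        1.0 - abs(t.hb_recorded - t.hb_reported) / t.hb_recorded for t in trials
    )
    cia = sum(accuracy) / 3.0
    flagged = cia < 0.0 or cia > 1.0
    if clamp:
        cia = min(1.0, max(0.0, cia))
    return CiaScore(
        participant_id=trials[0].participant_id,
        cia=cia,
        per_trial_accuracy=accuracy,  # type: ignore[arg-type]
        out_of_range_flag=flagged,
    )


def score_participants(
    trials: Iterable[HeartbeatTrial], clamp: bool = False
) -> dict[str, CiaScore]:
    """Group a trial table by participant and score everyone with 3 trials.

    Participants with a different trial count are silently excluded here; the
    reader already warns about them when the table is loaded.
    """
    grouped: dict[str, list[HeartbeatTrial]] = {}
    for t in trials:
        grouped.setdefault(t.participant_id, []).append(t)
    return {
        pid: compute_cia(ts, clamp=clamp)
        for pid, ts in sorted(grouped.items())
        if len(ts) == 3
    }
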