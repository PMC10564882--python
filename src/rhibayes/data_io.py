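"""Tabular input/output and dataset assembly.

The analysis consumes two kinds of tables:

* long-format ordinal ratings — one Likert-type rating per participant per
  stimulation condition (0 = asynchronous, 1 = synchronous) per questionnaire
  item; and
* heartbeat-tracking trial tables (or precomputed cardiac interoceptive
  accuracy scores).

Ratings are re-coded internally to categories ``1..K`` by an affine shift from
the instrument's printed scale minimum, so the model dimension (number of
cutpoints) is declared by the caller rather than inferred from whichever
categories happen to be observed.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("rhibayes")

ASYNCHRONOUS = 0
SYNCHRONOUS = 1

#: Default questionnaire item: the ownership statement ("the fake hand was my
#: hand"), the standard single-item measure of illusory hand ownership.
OWNERSHIP_ITEM = 3


class FormatError(ValueError):
    """A required column or field is missing or unparseable."""


class ValidationError(ValueError):
    """The file parsed but its contents violate an invariant."""


# ---------------------------------------------------------------------------
# records
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RatingRecord:
    """One ordinal rating for one participant in one condition.

    ``rating_raw`` is on the instrument's printed scale (e.g. -3..+3);
    ``rating_cat`` is the internal category in ``1..K``.
    """

    participant_id: str
    condition: int  # 0 = asynchronous, 1 = synchronous
    item_id: int
    rating_raw: int
    rating_cat: int


@dataclass(frozen=True)
class HeartbeatTrial:
    """Recorded vs reported heartbeat counts for one tracking trial."""

    participant_id: str
    trial_index: int
    duration: float  # seconds
    hb_recorded: int
    hb_reported: int


@dataclass
class AnalysisDataset:
    """Complete-case dataset ready for model fitting.

    One row per participant: a cardiac interoceptive accuracy score in [0, 1]
    and one ordinal rating (category ``1..K``) per stimulation condition.
    Participants are ordered by identifier so datasets assembled from permuted
    inputs compare equal.
    """

    participants: list[str]
    cia: np.ndarray  # shape (N,)
    y_async: np.ndarray  # shape (N,), categories 1..K
    y_sync: np.ndarray  # shape (N,), categories 1..K
    n_categories: int

    @property
    def n_participants(self) -> int:
        return len(self.participants)

    def __post_init__(self) -> None:
        self.cia = np.asarray(self.cia, dtype=float)
        self.y_async = np.asarray(self.y_async, dtype=int)
        self.y_sync = np.asarray(self.y_sync, dtype=int)
        n = len(self.participants)
        if not (self.cia.shape == self.y_async.shape == self.y_sync.shape == (n,)):
            raise ValidationError("participants, cia and ratings must have equal length")
        if n < 2:
            raise ValidationError(f"need at least 2 complete participants, got {n}")
        if self.n_categories < 3:
            raise ValidationError(f"need at least 3 ordinal categories, got {self.n_categories}")
        for y in (self.y_async, self.y_sync):
            if y.size and (y.min() < 1 or y.max() > self.n_categories):
                raise ValidationError("rating categories must lie in 1..K")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AnalysisDataset):
            return NotImplemented
        return (
            self.participants == other.participants
            and self.n_categories == other.n_categories
            and np.allclose(self.cia, other.cia)
            and np.array_equal(self.y_async, other.y_async)
            and np.array_equal(self.y_sync, other.y_sync)
        )


# ---------------------------------------------------------------------------
# ratings
# ---------------------------------------------------------------------------

_RATING_COLUMNS = ("participant", "condition", "item", "rating")


def _normalize_condition(value: object) -> int:
    """Map a condition label to {0, 1}; 0 = asynchronous."""
    if isinstance(value, str):
        label = value.strip().lower()
        if label.startswith("async"):
            return ASYNCHRONOUS
        if label.startswith("sync"):
            return SYNCHRONOUS
        try:
            value = int(label)
        except ValueError:
            raise ValidationError(f"unrecognized condition label {value!r}") from None
    code = int(value)
    if code not in (0, 1):
        raise ValidationError(f"condition code must be 0 or 1, got {code}")
    return code


def read_ratings(
    path,
    scale_min: int,
    scale_max: int,
    item_filter: int | None = OWNERSHIP_ITEM,
) -> list[RatingRecord]:
    """Read a long-format ratings CSV into :class:`RatingRecord` objects.

    Parameters
    ----------
    path:
        Delimited text file with header columns
        ``participant,condition,item,rating``.
    scale_min, scale_max:
        The printed endpoints of the Likert scale (e.g. -3 and 3 for a
        7-point item, 1 and 11 for an 11-point item).  ``rating_cat`` is
        ``rating - scale_min + 1``.
    item_filter:
        Keep only rows for this item; ``None`` keeps every item.
    """
    if scale_max <= scale_min:
        raise ValueError("scale_max must exceed scale_min")
    frame = pd.read_csv(path)
    missing = [c for c in _RATING_COLUMNS if c not in frame.columns]
    if missing:
        raise FormatError(f"ratings file {path} lacks required column(s): {', '.join(missing)}")
    return ratings_from_frame(frame, scale_min=scale_min, scale_max=scale_max,
                              item_filter=item_filter)


def ratings_from_frame(
    frame: pd.DataFrame,
    scale_min: int,
    scale_max: int,
    item_filter: int | None = OWNERSHIP_ITEM,
    columns: Mapping[str, str] | None = None,
) -> list[RatingRecord]:
    """Build validated rating records from a DataFrame.

    ``columns`` optionally maps the internal names
    ``participant/condition/item/rating`` to the frame's actual column names
    (the adapter hook for external layouts; ``item`` may be omitted there, in
    which case every row is treated as the target item).
    """
    colmap = dict(zip(_RATING_COLUMNS, _RATING_COLUMNS))
    if columns:
        colmap.update(columns)
    records: list[RatingRecord] = []
    out_of_range: list[str] = []
    for row in frame.to_dict("records"):
        item = int(row[colmap["item"]]) if colmap["item"] in row else (item_filter or 0)
        if item_filter is not None and item != item_filter:
            continue
        raw = row[colmap["rating"]]
        try:
            rating = int(raw)
        except (TypeError, ValueError):
            raise FormatError(f"non-integer rating {raw!r}") from None
        if float(raw) != rating:
            raise FormatError(f"non-integer rating {raw!r}")
        pid = str(row[colmap["participant"]])
        if not (scale_min <= rating <= scale_max):
            out_of_range.append(f"participant {pid}, item {item}: rating {rating}")
            continue
        records.append(
            RatingRecord(
                participant_id=pid,
                condition=_normalize_condition(row[colmap["condition"]]),
                item_id=item,
                rating_raw=rating,
                rating_cat=rating - scale_min + 1,
            )
        )
    if out_of_range:
        raise ValidationError(
            "rating(s) outside [%d, %d]: %s" % (scale_min, scale_max, "; ".join(out_of_range))
        )
    keys = [(r.participant_id, r.condition, r.item_id) for r in records]
    dupes = sorted({k for k in keys if keys.count(k) > 1})
    if dupes:
        raise ValidationError(f"duplicate (participant, condition, item) rows: {dupes}")
    return records


def write_ratings(records: Iterable[RatingRecord], path) -> None:
    """Write rating records back to CSV on the raw (printed) scale."""
    frame = pd.DataFrame(
        [
            {
                "participant": r.participant_id,
                "condition": r.condition,
                "item": r.item_id,
                "rating": r.rating_raw,
            }
            for r in records
        ]
    )
    frame.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# heartbeat trials and CIA tables
# ---------------------------------------------------------------------------

_HEARTBEAT_COLUMNS = ("participant", "trial", "duration_s", "hb_recorded", "hb_reported")


def _as_count(value: object, column: str, row_label: str) -> int:
    try:
        out = float(value)
    except (TypeError, ValueError):
        raise FormatError(f"row {row_label}: {column}={value!r} is not a number") from None
    if out != int(out):
        raise FormatError(f"row {row_label}: {column}={value!r} is not an integer count")
    return int(out)


def read_heartbeat_trials(path) -> list[HeartbeatTrial]:
    """Read a heartbeat-tracking trial table.

    Expects columns ``participant,trial,duration_s,hb_recorded,hb_reported``.
    Participants without exactly three trials are flagged with a warning but
    their records are still returned; a recorded count of zero is rejected
    because the accuracy formula divides by it.
    """
    frame = pd.read_csv(path)
    missing = [c for c in _HEARTBEAT_COLUMNS if c not in frame.columns]
    if missing:
        raise FormatError(f"heartbeat file {path} lacks required column(s): {', '.join(missing)}")
    trials: list[HeartbeatTrial] = []
    for idx, row in enumerate(frame.to_dict("records")):
        label = str(idx + 2)  # header is line 1
        rec = _as_count(row["hb_recorded"], "hb_recorded", label)
        rep = _as_count(row["hb_reported"], "hb_reported", label)
        if rec < 1:
            raise ValidationError(
                f"row {label}: hb_recorded must be >= 1 (accuracy divides by it)"
            )
        if rep < 0:
            raise ValidationError(f"row {label}: hb_reported must be non-negative")
        trials.append(
            HeartbeatTrial(
                participant_id=str(row["participant"]),
                trial_index=int(row["trial"]),
                duration=float(row["duration_s"]),
                hb_recorded=rec,
                hb_reported=rep,
            )
        )
    counts: dict[str, int] = {}
    for t in trials:
        counts[t.participant_id] = counts.get(t.participant_id, 0) + 1
    incomplete = sorted(p for p, n in counts.items() if n != 3)
    if incomplete:
        warnings.warn(
            f"participant(s) without exactly 3 heartbeat trials: {incomplete}",
            stacklevel=2,
        )
    return trials


def write_heartbeat_trials(trials: Iterable[HeartbeatTrial], path) -> None:
    frame = pd.DataFrame(
        [
            {
                "participant": t.participant_id,
                "trial": t.trial_index,
                "duration_s": t.duration,
                "hb_recorded": t.hb_recorded,
                "hb_reported": t.hb_reported,
            }
            for t in trials
        ]
    )
    frame.to_csv(path, index=False)


def read_cia(path) -> dict[str, float]:
    """Read precomputed accuracy scores: columns ``participant,cia``."""
    frame = pd.read_csv(path)
    missing = [c for c in ("participant", "cia") if c not in frame.columns]
    if missing:
        raise FormatError(f"CIA file {path} lacks required column(s): {', '.join(missing)}")
    return {str(p): float(c) for p, c in zip(frame["participant"], frame["cia"])}


def write_cia(scores: Mapping[str, float], path) -> None:
    pd.DataFrame(
        {"participant": list(scores.keys()), "cia": list(scores.values())}
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# assembly
# ---------------------------------------------------------------------------

def assemble_dataset(
    ratings: Sequence[RatingRecord],
    cia_scores: Mapping[str, float],
    n_categories: int,
    item_id: int | None = None,
) -> AnalysisDataset:
    """Join ratings with accuracy scores into a complete-case dataset.

    A participant enters the dataset only with a rating in *both* conditions
    and a CIA score (listwise completeness); everyone else is dropped with a
    logged reason.  Participants are sorted by identifier, so the result does
    not depend on input row order.
    """
    by_participant: dict[str, dict[int, RatingRecord]] = {}
    for r in ratings:
        if item_id is not None and r.item_id != item_id:
            continue
        by_participant.setdefault(r.participant_id, {})[r.condition] = r

    participants: list[str] = []
    cia: list[float] = []
    y0: list[int] = []
    y1: list[int] = []
    for pid in sorted(set(by_participant) | set(map(str, cia_scores))):
        conds = by_participant.get(pid, {})
        if ASYNCHRONOUS not in conds or SYNCHRONOUS not in conds:
            logger.info("dropping participant %s: missing condition rating(s)", pid)
            continue
        if pid not in cia_scores:
            logger.info("dropping participant %s: no CIA score", pid)
            continue
        participants.append(pid)
        cia.append(float(cia_scores[pid]))
        y0.append(conds[ASYNCHRONOUS].rating_cat)
        y1.append(conds[SYNCHRONOUS].rating_cat)

    if len(participants) < 2:
        raise ValidationError(
            f"only {len(participants)} complete participant(s); at least 2 required"
        )
    return AnalysisDataset(
        participants=participants,
        cia=np.array(cia),
        y_async=np.array(y0, dtype=int),
        y_sync=np.array(y1, dtype=int),
        n_categories=n_categories,
    )
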