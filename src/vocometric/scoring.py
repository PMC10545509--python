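"""Digit-level scoring of spoken-number responses and per-level aggregation.

Each trial presents a three-digit number; the response is scored by
positional digit match (hundreds, tens, units), 0-3 points per trial.  With
four trials at each vocoding level this yields 12 digit datapoints per level,
aggregated on the log2-channel axis for psychometric fitting.  Clear-speech
trials (no channel axis) are summarised separately.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["score_trial", "aggregate", "PsychometricData", "CLEAR_LEVEL"]

CLEAR_LEVEL = "clear"

TRIAL_COLUMNS = [
    "participant_id", "group", "trial_index", "level",
    "target_digits", "response_digits", "digits_correct",
]


def score_trial(target: str, response: str) -> int:
    """Number of digits reported in the correct position (0-3).

    The target is exactly three digits; the response may be empty or partial.
    Partial responses are left-aligned: a two-digit response is read as
    hundreds+tens, and missing positions score zero.  Non-digit characters
    signal a transcription error.
    """
    if len(target) != 3 or not target.isdigit():
        raise ValueError(f"target must be exactly 3 digits, got {target!r}")
    if response and not response.isdigit():
        raise ValueError(f"response contains non-digit characters: {response!r}")
    if len(response) > 3:
        raise ValueError(f"response longer than 3 digits: {response!r}")
    return sum(t == r for t, r in zip(target, response))


@dataclass(frozen=True)
class PsychometricData:
    """Per-level success counts for one listener.

    ``channels`` are the vocoded levels; ``x`` = log2(channels); ``k`` digits
    correct out of ``n`` presented.  ``k_clear``/``n_clear`` summarise the
    unvocoded trials, which do not enter the curve fit.
    """

    channels: np.ndarray = field(repr=False)
    x: np.ndarray = field(repr=False)
    k: np.ndarray = field(repr=False)
    n: np.ndarray = field(repr=False)
    k_clear: int = 0
    n_clear: int = 0

    def __post_init__(self) -> None:
        if np.any(self.k < 0) or np.any(self.k > self.n):
            raise ValueError("counts must satisfy 0 <= k <= n")

    def to_frame(self, participant: str | None = None) -> pd.DataFrame:
        frame = pd.DataFrame({
            "level": self.channels.astype(int),
            "x_log2": self.x,
            "k": self.k.astype(int),
            "n": self.n.astype(int),
        })
        if participant is not None:
            frame.insert(0, "participant", participant)
        return frame


def aggregate(trials: pd.DataFrame, participant: str) -> PsychometricData:
    """Aggregate one participant's trials into per-level counts.

    ``trials`` follows the trial-table schema (participant_id, level,
    digits_correct, ...); ``level`` is an integer channel count or "clear".
    Each vocoded level contributes k = sum of digits_correct and n = 3 per
    trial.  Requires at least two distinct vocoded levels.
    """
    rows = trials[trials["participant_id"] == participant]
    if rows.empty:
        raise ValueError(f"no trials for participant {participant!r}")
    is_clear = rows["level"].astype(str) == CLEAR_LEVEL
    vocoded = rows[~is_clear]
    if vocoded.empty:
        raise ValueError(f"participant {participant!r} has no vocoded trials")
    channels = vocoded["level"].astype(int)
    if channels.nunique() < 2:
        raise ValueError("need trials at >= 2 distinct vocoded levels")
    by_level = vocoded.groupby(channels).agg(
        k=("digits_correct", "sum"), trials=("digits_correct", "size")
    )
    by_level = by_level.sort_index(ascending=True)
    ch = by_level.index.to_numpy(dtype=float)
    clear_rows = rows[is_clear]
    return PsychometricData(
        channels=ch,
        x=np.log2(ch),
        k=by_level["k"].to_numpy(dtype=float),
        n=3.0 * by_level["trials"].to_numpy(dtype=float),
        k_clear=int(clear_rows["digits_correct"].sum()),
        n_clear=int(3 * len(clear_rows)),
    )
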