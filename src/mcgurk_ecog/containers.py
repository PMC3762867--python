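"""Shared data containers for trial-structured ECoG analyses.

All epoch times are in seconds relative to audio onset (audio onset = 0,
video onset = -1.0).
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

#: Canonical four-alternative phoneme set used throughout.
PHONEMES = ("BA", "GA", "VA", "THA")

#: Task timeline (s, relative to audio onset).
VIDEO_ONSET = -1.0
AUDIO_ONSET = 0.0
AUDIO_END = 0.5

#: One-second analysis intervals used by the information-flow stage.
INTERVALS = {
    "baseline": (-2.0, -1.0),
    "video_only": (-1.0, 0.0),
    "audio_video": (0.0, 1.0),
}

CATEGORIES = ("matched", "mcgurk", "unmatched", "unclassified")


@dataclass
class TrialRecord:
    """Metadata for one audiovisual trial."""

    trial_id: int
    video_phoneme: str
    audio_phoneme: str
    response: str
    category: str = "unclassified"
    audio_onset: float = 0.0

    @property
    def congruent(self) -> bool:
        return self.video_phoneme == self.audio_phoneme

    def with_category(self, category: str) -> "TrialRecord":
        if category not in CATEGORIES:
            raise ValueError(f"unknown category {category!r}")
        return replace(self, category=category)


def trials_to_frame(trials: list[TrialRecord]) -> pd.DataFrame:
    """Tabulate trial metadata (the CSV layout used on disk)."""
    return pd.DataFrame(
        {
            "trial_id": [t.trial_id for t in trials],
            "video_phoneme": [t.video_phoneme for t in trials],
            "audio_phoneme": [t.audio_phoneme for t in trials],
            "response": [t.response for t in trials],
            "category": [t.category for t in trials],
            "audio_onset": [t.audio_onset for t in trials],
        }
    )


def trials_from_frame(df: pd.DataFrame) -> list[TrialRecord]:
    return [
        TrialRecord(
            trial_id=int(r.trial_id),
            video_phoneme=str(r.video_phoneme),
            audio_phoneme=str(r.audio_phoneme),
            response=str(r.response),
            category=str(r.category),
            audio_onset=float(r.audio_onset),
        )
        for r in df.itertuples(index=False)
    ]


@dataclass
class EpochArray:
    """One trial's voltage matrix: time x electrode, in microvolts.

    ``t0`` is the time of the first sample relative to audio onset
    (negative for pre-stimulus coverage).  ``channel_info``, when present,
    is a DataFrame indexed by electrode with optional columns
    ``role`` (posterior/middle/anterior), ``hemisphere`` and ``stg``.
    """

    data: np.ndarray
    fs: float
    t0: float
    channel_info: Optional[pd.DataFrame] = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("epoch data must be 2-D (time x electrode)")
        if not np.isfinite(self.data).all():
            raise ValueError("epoch data contains non-finite values")

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_electrodes(self) -> int:
        return self.data.shape[1]

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_samples) / self.fs

    def time_slice(self, t_lo: float, t_hi: float) -> np.ndarray:
        """Samples with t_lo <= t < t_hi (all electrodes)."""
        i0 = int(np.ceil((t_lo - self.t0) * self.fs - 1e-9))
        i1 = int(np.ceil((t_hi - self.t0) * self.fs - 1e-9))
        i0, i1 = max(i0, 0), min(i1, self.n_samples)
        if i1 <= i0:
            raise ValueError(f"empty time slice [{t_lo}, {t_hi})")
        return self.data[i0:i1]


@dataclass
class Spectrogram:
    """Time x frequency power for one trial and electrode.

    ``times`` are window centers relative to audio onset; ``power`` is in
    uV^2/Hz before normalization and in baseline z-units after.
    """

    power: np.ndarray
    times: np.ndarray
    freqs: np.ndarray
    normalized: bool = False

    def __post_init__(self) -> None:
        self.power = np.asarray(self.power, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        self.freqs = np.asarray(self.freqs, dtype=float)
        if self.power.shape != (self.times.size, self.freqs.size):
            raise ValueError("power shape must be (n_times, n_freqs)")

    def same_grid(self, other: "Spectrogram", tol: float = 1e-9) -> bool:
        return (
            self.times.shape == other.times.shape
            and self.freqs.shape == other.freqs.shape
            and np.allclose(self.times, other.times, atol=tol)
            and np.allclose(self.freqs, other.freqs, atol=tol)
        )


@dataclass
class ConfusionTable:
    """Pairwise classification counts for one electrode (or electrode set).

    Rows index the true label, columns the predicted label, both in the
    order of ``labels``.  Row sums equal the number of test trials with
    that true label, pooled over both cross-validation folds.
    """

    counts: np.ndarray
    labels: tuple[str, str]
    electrode: str = ""
    folds: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.shape != (len(self.labels), len(self.labels)):
            raise ValueError("confusion counts must be square over labels")
        if (self.counts < 0).any():
            raise ValueError("confusion counts must be non-negative")

    @property
    def n_trials(self) -> int:
        return int(self.counts.sum())

    @property
    def accuracy(self) -> float:
        n = self.counts.sum()
        if n == 0:
            raise ValueError("empty confusion table")
        return float(np.trace(self.counts)) / float(n)

    def swapped_labels(self) -> "ConfusionTable":
        """Reinterpret the table with the two true labels exchanged.

        Used when the same predictions are scored against a complementary
        labeling (e.g. audio identity on incongruent within-pair trials).
        """
        return ConfusionTable(
            counts=self.counts[::-1, :].copy(),
            labels=self.labels,
            electrode=self.electrode,
            folds=dict(self.folds),
        )
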