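"""Behavioral categorization, performance scoring, electrode selection.

Stimulus combinations are grouped into three behavioral categories:
matched (video and audio share the phoneme), mcgurk (incongruent and the
video identity is reported more often than chance) and unmatched
(incongruent and the audio identity is reported more often than chance).
"More often than chance" is a one-sided exact binomial test against the
four-alternative chance level.  Electrode selection ranks electrodes by
trial-averaged 75-200 Hz spectral power during the 1000 ms of auditory
stimulus presentation.
"""
from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats as sps

from .containers import EpochArray, TrialRecord
from .spectral import SpectrogramConfig, band_power, multitaper_spectrogram


@dataclass
class CategoryRule:
    chance_level: float = 0.25
    alpha: float = 0.05

    def validate(self) -> None:
        if not 0 < self.chance_level < 1:
            raise ValueError("chance_level must lie in (0, 1)")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")


def categorize_trials(
    trials: list[TrialRecord], rule: CategoryRule | None = None,
    phonemes: tuple[str, ...] | None = None,
) -> list[TrialRecord]:
    """Assign each trial its combination-level behavioral category.

    Order-invariant: categories depend only on per-combination response
    tallies.  Incongruent combinations significant for both attributes
    are resolved by the larger report fraction.
    """
    rule = rule or CategoryRule()
    rule.validate()
    labels = set(phonemes) if phonemes else (
        {t.video_phoneme for t in trials} | {t.audio_phoneme for t in trials}
    )
    for t in trials:
        if t.response not in labels:
            raise ValueError(
                f"trial {t.trial_id}: unknown response label {t.response!r}"
            )

    by_combo: dict[tuple[str, str], list[TrialRecord]] = {}
    for t in trials:
        by_combo.setdefault((t.video_phoneme, t.audio_phoneme), []).append(t)

    combo_category: dict[tuple[str, str], str] = {}
    for (video, audio), ts in by_combo.items():
        if video == audio:
            combo_category[(video, audio)] = "matched"
            continue
        n = len(ts)
        k_video = sum(t.response == video for t in ts)
        k_audio = sum(t.response == audio for t in ts)
        p_video = sps.binomtest(k_video, n, rule.chance_level, alternative="greater").pvalue
        p_audio = sps.binomtest(k_audio, n, rule.chance_level, alternative="greater").pvalue
        sig_video = p_video < rule.alpha
        sig_audio = p_audio < rule.alpha
        if sig_video and sig_audio:
            if k_video > k_audio:
                cat = "mcgurk"
            elif k_audio > k_video:
                cat = "unmatched"
            else:
                cat = "unclassified"
        elif sig_video:
            cat = "mcgurk"
        elif sig_audio:
            cat = "unmatched"
        else:
            cat = "unclassified"
        combo_category[(video, audio)] = cat

    return [
        replace(t, category=combo_category[(t.video_phoneme, t.audio_phoneme)])
        for t in trials
    ]


def performance_by_category(trials: list[TrialRecord]) -> pd.DataFrame:
    """Fraction of trials whose response equals the audio identity, per
    behavioral category.  Categories with no trials are absent."""
    rows = []
    for cat in sorted({t.category for t in trials}):
        ts = [t for t in trials if t.category == cat]
        correct = sum(t.response == t.audio_phoneme for t in ts)
        rows.append(
            {
                "category": cat,
                "n": len(ts),
                "audio_report_fraction": correct / len(ts),
            }
        )
    return pd.DataFrame(rows).set_index("category")


def category_summary(trials: list[TrialRecord]) -> pd.DataFrame:
    """Per-combination tallies behind the categorization (for reports)."""
    by_combo: dict[tuple[str, str], list[TrialRecord]] = {}
    for t in trials:
        by_combo.setdefault((t.video_phoneme, t.audio_phoneme), []).append(t)
    rows = []
    for (video, audio), ts in sorted(by_combo.items()):
        n = len(ts)
        rows.append(
            {
                "video_phoneme": video,
                "audio_phoneme": audio,
                "n": n,
                "video_report_fraction": sum(t.response == video for t in ts) / n,
                "audio_report_fraction": sum(t.response == audio for t in ts) / n,
                "category": ts[0].category,
            }
        )
    return pd.DataFrame(rows)


def _audio_window_power(
    epoch: EpochArray, electrode: int, cfg: SpectrogramConfig,
    band: tuple[float, float], window: tuple[float, float],
) -> float:
    # slice the epoch so that all spectrogram window centers fall inside
    # the audio window; avoids computing the full-epoch spectrogram
    half = cfg.window_s / 2
    data = epoch.time_slice(window[0] - half, window[1] + half)
    sub = EpochArray(data=data, fs=epoch.fs, t0=window[0] - half)
    spec = multitaper_spectrogram(sub, electrode, cfg)
    return band_power(spec, band[0], band[1], window[0], window[1])


def select_electrodes(
    epochs: list[EpochArray],
    n_select: int = 3,
    band: tuple[float, float] = (75.0, 200.0),
    audio_window: tuple[float, float] = (0.0, 1.0),
    spec_cfg: SpectrogramConfig | None = None,
) -> list[int]:
    """Electrodes with the greatest trial-averaged band power in the
    75-200 Hz range during auditory stimulus presentation, rank-ordered.

    When ``channel_info`` carries an ``stg`` flag, only flagged
    electrodes are candidates (the anatomical constraint of the original
    selection).  Ties break toward the lower electrode index.
    """
    if not epochs:
        raise ValueError("no epochs given")
    n_el = epochs[0].n_electrodes
    info = epochs[0].channel_info
    if info is not None and "stg" in info.columns and info["stg"].any():
        candidates = np.flatnonzero(info["stg"].to_numpy())
    else:
        candidates = np.arange(n_el)
    if candidates.size < n_select:
        raise ValueError(
            f"only {candidates.size} candidate electrodes for n_select={n_select}"
        )
    cfg = spec_cfg or SpectrogramConfig()
    power = np.zeros(candidates.size)
    for ep in epochs:
        for j, el in enumerate(candidates):
            power[j] += _audio_window_power(ep, el, cfg, band, audio_window)
    power /= len(epochs)
    order = np.lexsort((candidates, -power))
    return [int(candidates[i]) for i in order[:n_select]]


def electrode_roles(
    selected: list[int], epochs: list[EpochArray] | None = None
) -> dict[str, int]:
    """Map the three selected electrodes to posterior/middle/anterior.

    Uses ``channel_info`` role metadata when present.  Otherwise the
    middle electrode is the one with the largest mean evoked potential
    after audio onset (the physiological marker of the electrode nearest
    primary auditory cortex) and the remaining two keep selection rank
    order (posterior first).
    """
    if len(selected) != 3:
        raise ValueError("role assignment expects exactly 3 electrodes")
    info = epochs[0].channel_info if epochs else None
    if info is not None and "role" in info.columns:
        roles = {str(info.loc[el, "role"]): el for el in selected}
        if set(roles) == {"posterior", "middle", "anterior"}:
            return roles
    if not epochs:
        raise ValueError("need epochs to assign roles physiologically")
    # mean evoked magnitude in the 500 ms after audio onset
    evoked = {
        el: float(
            np.mean(
                [np.abs(ep.time_slice(0.0, 0.5)[:, el]).mean() for ep in epochs]
            )
        )
        for el in selected
    }
    middle = max(evoked, key=evoked.get)
    rest = [el for el in selected if el != middle]
    return {"posterior": rest[0], "middle": middle, "anterior": rest[1]}
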