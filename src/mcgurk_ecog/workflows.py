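"""End-to-end analyses binding the pipeline stages together.

These are the functions the CLI, the examples and the acceptance script
call: simulate (or load) a dataset, preprocess, categorize, select
electrodes, then run the spectral-difference, decoding and
information-tendency analyses.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import infoflow, stats
from .containers import EpochArray, TrialRecord
from .decoding import (
    build_features,
    decode_stimulus_identity,
    mcgurk_dual_decoding,
)
from .experiment import (
    CategoryRule,
    categorize_trials,
    category_summary,
    electrode_roles,
    performance_by_category,
    select_electrodes,
)
from .preprocess import PreprocessConfig, lowpass_downsample, rereference
from .spectral import (
    SpectrogramConfig,
    difference_spectrogram_stat,
    mean_spectrogram,
    multitaper_spectrogram,
    normalize_by_band,
)
from .synth import SimConfig, ground_truth, simulate_dataset

#: Stimulus-free normalization baseline: window centers fully inside the
#: pre-video second (epoch start at -2.0 s, 500 ms windows).
BASELINE = (-1.75, -1.25)


def preprocess_epochs(
    epochs: list[EpochArray], cfg: PreprocessConfig | None = None
) -> list[EpochArray]:
    """Common-average re-reference and, when needed, low-pass +
    downsample each epoch to the target rate."""
    cfg = cfg or PreprocessConfig()
    cfg.validate()
    out = []
    for ep in epochs:
        if ep.fs > cfg.target_fs:
            ep = lowpass_downsample(ep, cfg)
        if cfg.reference == "common_average":
            ep = rereference(ep)
        out.append(ep)
    return out


def mcgurk_difference_analysis(
    epochs: list[EpochArray],
    trials: list[TrialRecord],
    electrodes: list[int],
    spec_cfg: SpectrogramConfig | None = None,
    baseline: tuple[float, float] = BASELINE,
) -> tuple[pd.DataFrame, stats.TestResult]:
    """Difference-spectrogram comparison of illusion vs matched trials.

    For every McGurk-labeled stimulus combination (video v, audio a) and
    every analyzed electrode, the mean baseline-normalized spectrogram
    of its trials is compared (mean |difference| over [-1, 1] s) against
    the matched combination with the same video (v, v) and the one with
    the same audio (a, a).  A smaller same-video than same-audio
    statistic means the illusion-trial representation tracks the video.
    Returns the per-(combo, electrode) table and the Mann-Whitney test
    over the two pooled samples.
    """
    cfg = spec_cfg or SpectrogramConfig()
    norm_specs: dict[int, list] = {}
    for el in electrodes:
        norm_specs[el] = [
            normalize_by_band(multitaper_spectrogram(ep, el, cfg), baseline)
            for ep in epochs
        ]

    def cond_mean(el: int, select) -> object | None:
        idx = [i for i, t in enumerate(trials) if select(t)]
        if not idx:
            return None
        return mean_spectrogram([norm_specs[el][i] for i in idx])

    combos = sorted(
        {
            (t.video_phoneme, t.audio_phoneme)
            for t in trials
            if t.category == "mcgurk"
        }
    )
    rows = []
    for v, a in combos:
        for el in electrodes:
            m_ill = cond_mean(el, lambda t: (t.video_phoneme, t.audio_phoneme) == (v, a))
            m_vid = cond_mean(el, lambda t: (t.video_phoneme, t.audio_phoneme) == (v, v))
            m_aud = cond_mean(el, lambda t: (t.video_phoneme, t.audio_phoneme) == (a, a))
            if m_ill is None or m_vid is None or m_aud is None:
                continue
            rows.append(
                {
                    "video_phoneme": v,
                    "audio_phoneme": a,
                    "electrode": el,
                    "same_video_stat": difference_spectrogram_stat(m_ill, m_vid),
                    "same_audio_stat": difference_spectrogram_stat(m_ill, m_aud),
                }
            )
    table = pd.DataFrame(rows)
    if table.empty:
        raise ValueError("no McGurk combination had matched counterparts")
    test = stats.mannwhitney_diffspec(
        table["same_video_stat"].to_numpy(), table["same_audio_stat"].to_numpy()
    )
    return table, test


@dataclass
class AnalysisResult:
    """Everything the default end-to-end run produces."""

    trials: list[TrialRecord]
    performance: pd.DataFrame
    behavior_tests: list
    selection: list[int]
    roles: dict[str, int]
    diff_table: pd.DataFrame
    diff_test: stats.TestResult
    decoding: dict  # target -> DecodingResult (target-label trained)
    dual_decoding: dict  # target -> DecodingResult (illusion decoder)
    decoding_tests: dict
    tendencies: list
    ground_truth: dict = field(default_factory=dict)

    def tendency_frame(self) -> pd.DataFrame:
        return pd.DataFrame([t.to_row() for t in self.tendencies])


def run_full_analysis(
    cfg: SimConfig | None = None,
    dataset: tuple[list[TrialRecord], list[EpochArray]] | None = None,
    seed: int | None = None,
    variance_kept: float = 0.95,
    spec_cfg: SpectrogramConfig | None = None,
) -> AnalysisResult:
    """Simulate (or accept) a dataset and run every analysis stage."""
    if cfg is None:
        cfg = SimConfig()
    if seed is not None:
        cfg = SimConfig(**{**cfg.__dict__, "seed": seed})
    if dataset is None:
        trials, epochs = simulate_dataset(cfg)
    else:
        trials, epochs = dataset
    epochs = preprocess_epochs(epochs)
    trials = categorize_trials(trials, CategoryRule(chance_level=1.0 / len(cfg.phonemes)))

    performance = performance_by_category(trials)
    groups = {
        cat: np.array(
            [float(t.response == t.audio_phoneme) for t in trials if t.category == cat]
        )
        for cat in performance.index
        if cat != "unclassified"
    }
    behavior_tests = stats.anova_tukey(groups) if len(groups) >= 2 else []

    selection = select_electrodes(epochs)
    roles = electrode_roles(selection, epochs)

    diff_table, diff_test = mcgurk_difference_analysis(
        epochs, trials, selection, spec_cfg=spec_cfg
    )

    features = build_features(epochs, trials, selection)
    decoding = {
        target: decode_stimulus_identity(
            features, trials, target, category="mcgurk",
            variance_kept=variance_kept, seed=cfg.seed,
        )
        for target in ("video", "audio")
    }
    dual = mcgurk_dual_decoding(
        features, trials, variance_kept=variance_kept, seed=cfg.seed
    )
    decoding_tests = {}
    for target, res in dual.items():
        fold_accs = [
            fold["accuracy"]
            for cm in res.confusions.values()
            for fold in cm.folds["per_fold"]
        ]
        if len(fold_accs) >= 5:
            decoding_tests[target] = stats.wilcoxon_vs_chance(np.array(fold_accs))

    tendencies = infoflow.interval_analysis(
        epochs, trials, roles, variance_kept=variance_kept, seed=cfg.seed
    )
    return AnalysisResult(
        trials=trials,
        performance=performance,
        behavior_tests=behavior_tests,
        selection=selection,
        roles=roles,
        diff_table=diff_table,
        diff_test=diff_test,
        decoding=decoding,
        dual_decoding=dual,
        decoding_tests=decoding_tests,
        tendencies=tendencies,
        ground_truth=ground_truth(cfg).to_dict(),
    )


def summary_tables(result: AnalysisResult) -> dict[str, pd.DataFrame]:
    """The CSV-ready tables of an end-to-end run."""
    acc_rows = []
    for kind, res_by_target in (
        ("target_trained", result.decoding),
        ("illusion_decoder", result.dual_decoding),
    ):
        for target, res in res_by_target.items():
            for pair, acc in res.accuracies.items():
                acc_rows.append(
                    {
                        "decoder": kind,
                        "target": target,
                        "pair": "/".join(pair),
                        "accuracy": acc,
                        "n_trials": res.confusions[pair].n_trials,
                    }
                )
    return {
        "performance": result.performance.reset_index(),
        "category_summary": category_summary(result.trials),
        "accuracies": pd.DataFrame(acc_rows),
        "tendencies": result.tendency_frame(),
        "difference_stats": result.diff_table,
    }
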