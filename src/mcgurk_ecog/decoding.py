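"""Pairwise phoneme-identity decoding from voltage and spectrogram features.

The classifier follows a fixed recipe: per-trial features (raw voltage
samples plus log-power spectrogram cells over the selected electrodes,
spanning video onset to the end of the phoneme) are z-scored and
orthogonalized by PCA using statistics of the training fold only,
keeping the minimal number of leading components whose cumulative
explained variance reaches 95%; a two-class linear discriminant with
equal priors and Ledoit-Wolf shrinkage is then fit on the training fold
and applied to the held-out fold.  Folds are interchanged for a twofold
cross-validation and confusion counts pooled.
"""
from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from .containers import ConfusionTable, EpochArray, TrialRecord
from .spectral import SpectrogramConfig, multitaper_spectrogram

#: Feature window: video onset to end of the audio phoneme (s).
FEATURE_WINDOW = (-1.0, 0.5)

#: Spectrogram resolution used for classifier features.  Coarser in time
#: than the display spectrograms: a 50 ms step keeps the feature count
#: tractable while the 500 ms window already smooths over that scale.
FEATURE_SPEC_CFG = SpectrogramConfig(window_s=0.5, step_s=0.05)


@dataclass
class FeatureMatrix:
    """Trials x features, with a catalog mapping columns to their origin."""

    X: np.ndarray
    trial_ids: np.ndarray
    catalog: pd.DataFrame  # columns: electrode, kind, time, frequency

    @property
    def n_trials(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]


def build_features(
    epochs: list[EpochArray] | dict[int, EpochArray],
    trials: list[TrialRecord],
    electrodes: list[int],
    spec_cfg: SpectrogramConfig | None = None,
    window: tuple[float, float] = FEATURE_WINDOW,
) -> FeatureMatrix:
    """Assemble one feature row per trial.

    For each electrode, the row concatenates the voltage trace over
    ``window`` and the unwrapped log-power spectrogram whose analysis
    windows lie fully inside ``window``.  Column order is deterministic:
    electrode-major, voltage before spectrogram cells.
    """
    cfg = spec_cfg or FEATURE_SPEC_CFG
    if isinstance(epochs, dict):
        missing = [t.trial_id for t in trials if t.trial_id not in epochs]
        if missing:
            raise KeyError(f"missing epochs for trial_ids {missing}")
        epoch_list = [epochs[t.trial_id] for t in trials]
    else:
        if len(epochs) != len(trials):
            raise ValueError("epochs and trials must align one-to-one")
        epoch_list = list(epochs)

    t_lo, t_hi = window
    rows = []
    catalog: pd.DataFrame | None = None
    for ep in epoch_list:
        parts = []
        cat_parts = [] if catalog is None else None
        volt_times = None
        for el in electrodes:
            seg = ep.time_slice(t_lo, t_hi)[:, el]
            sub = EpochArray(
                data=ep.time_slice(t_lo, t_hi), fs=ep.fs, t0=t_lo
            )
            spec = multitaper_spectrogram(sub, el, cfg)
            logp = 10.0 * np.log10(spec.power + 1e-20)
            parts.append(seg)
            parts.append(logp.ravel())
            if cat_parts is not None:
                if volt_times is None:
                    volt_times = t_lo + np.arange(seg.size) / ep.fs
                cat_parts.append(
                    pd.DataFrame(
                        {
                            "electrode": el,
                            "kind": "voltage",
                            "time": volt_times,
                            "frequency": np.nan,
                        }
                    )
                )
                tt, ff = np.meshgrid(spec.times, spec.freqs, indexing="ij")
                cat_parts.append(
                    pd.DataFrame(
                        {
                            "electrode": el,
                            "kind": "spectrogram",
                            "time": tt.ravel(),
                            "frequency": ff.ravel(),
                        }
                    )
                )
        if cat_parts is not None:
            catalog = pd.concat(cat_parts, ignore_index=True)
        rows.append(np.concatenate(parts))

    X = np.vstack(rows)
    if catalog is None or X.shape[1] != len(catalog):
        raise RuntimeError("inconsistent feature catalog")
    return FeatureMatrix(
        X=X,
        trial_ids=np.array([t.trial_id for t in trials]),
        catalog=catalog,
    )


# ---------------------------------------------------------------------------
# train-fold-only transform + LDA


def _stratified_two_folds(
    y: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    fold_a, fold_b = [], []
    for label in np.unique(y):
        idx = np.flatnonzero(y == label)
        idx = idx[rng.permutation(idx.size)]
        half = idx.size // 2
        fold_a.extend(idx[:half])
        fold_b.extend(idx[half:])
    return np.sort(fold_a), np.sort(fold_b)


def _fit_fold(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_test: np.ndarray,
    variance_kept: float,
) -> tuple[np.ndarray, dict]:
    """Z-score, PCA and LDA with statistics from the training half only."""
    keep = X_train.std(axis=0) > 0
    n_dropped = int((~keep).sum())
    if n_dropped:
        X_train = X_train[:, keep]
        X_test = X_test[:, keep]
    mu = X_train.mean(axis=0)
    sd = X_train.std(axis=0)
    Ztr = (X_train - mu) / sd
    Zte = (X_test - mu) / sd

    # train-only PCA: minimal leading components reaching the variance goal
    center = Ztr.mean(axis=0)
    U, S, Vt = np.linalg.svd(Ztr - center, full_matrices=False)
    var = S**2
    nonzero = var > var[0] * 1e-12 if var.size else var > 0
    var = var[nonzero]
    Vt = Vt[nonzero]
    cum = np.cumsum(var) / var.sum()
    k = int(np.searchsorted(cum, variance_kept) + 1)
    k = min(k, Vt.shape[0])
    Ptr = (Ztr - center) @ Vt[:k].T
    Pte = (Zte - center) @ Vt[:k].T

    lda = LinearDiscriminantAnalysis(
        solver="lsqr", shrinkage="auto", priors=[0.5, 0.5]
    )
    lda.fit(Ptr, y_train)
    pred = lda.predict(Pte)
    meta = {
        "n_components": k,
        "n_dropped_columns": n_dropped,
        "train_mean_col0": float(mu[0]),
    }
    return pred, meta


def fit_predict_pairwise(
    features: FeatureMatrix | np.ndarray,
    labels: np.ndarray,
    pair: tuple[str, str],
    variance_kept: float = 0.95,
    seed: int = 0,
    electrode: str = "",
) -> ConfusionTable:
    """Twofold cross-validated pairwise classification.

    Returns the confusion table pooled over both folds; ``folds``
    metadata records per-fold component counts, dropped-column counts
    and the training-fold mean of the first feature column (a guard that
    the transform is train-only).
    """
    X = features.X if isinstance(features, FeatureMatrix) else np.asarray(features)
    labels = np.asarray(labels)
    if X.shape[0] != labels.size:
        raise ValueError("features and labels must align")
    sel = np.flatnonzero(np.isin(labels, pair))
    Xp, yp = X[sel], labels[sel]
    for lab in pair:
        if (yp == lab).sum() < 2:
            raise ValueError(f"fewer than 2 trials for label {lab!r}")

    rng = np.random.default_rng(seed)
    fold_a, fold_b = _stratified_two_folds(yp, rng)
    counts = np.zeros((2, 2), dtype=int)
    fold_meta = []
    for train_idx, test_idx in ((fold_a, fold_b), (fold_b, fold_a)):
        if np.unique(yp[train_idx]).size < 2 or np.unique(yp[test_idx]).size < 2:
            raise ValueError("a cross-validation fold contains a single class")
        pred, meta = _fit_fold(
            Xp[train_idx], yp[train_idx], Xp[test_idx], variance_kept
        )
        for true, hat in zip(yp[test_idx], pred):
            counts[pair.index(true), pair.index(hat)] += 1
        meta["accuracy"] = float(np.mean(pred == yp[test_idx]))
        meta["train_rows"] = sel[train_idx].tolist()
        fold_meta.append(meta)
    return ConfusionTable(
        counts=counts,
        labels=tuple(pair),
        electrode=electrode,
        folds={"per_fold": fold_meta, "seed": seed},
    )


# ---------------------------------------------------------------------------
# stimulus-identity decoding


@dataclass
class DecodingResult:
    target: str
    accuracies: dict = field(default_factory=dict)  # pair -> accuracy
    confusions: dict = field(default_factory=dict)  # pair -> ConfusionTable

    @property
    def mean_accuracy(self) -> float:
        if not self.accuracies:
            raise ValueError("no pairs decoded")
        return float(np.mean(list(self.accuracies.values())))

    @property
    def n_pairs(self) -> int:
        return len(self.accuracies)


def _attribute(trials: list[TrialRecord], target: str) -> np.ndarray:
    if target == "video":
        return np.array([t.video_phoneme for t in trials])
    if target == "audio":
        return np.array([t.audio_phoneme for t in trials])
    raise ValueError("target must be 'video' or 'audio'")


def decode_stimulus_identity(
    features: FeatureMatrix,
    trials: list[TrialRecord],
    target: str,
    category: str | None = None,
    variance_kept: float = 0.95,
    seed: int = 0,
) -> DecodingResult:
    """Pairwise decoding of the ``target`` stimulus attribute.

    Runs the twofold pairwise classifier for every unordered label pair
    available after the optional behavioral-category filter; pairs with
    fewer than 2 trials per label are skipped with a warning.
    """
    if features.n_trials != len(trials):
        raise ValueError("features and trials must align")
    mask = np.ones(len(trials), dtype=bool)
    if category is not None:
        mask = np.array([t.category == category for t in trials])
    sub = [t for t, m in zip(trials, mask) if m]
    if not sub:
        raise ValueError(f"no trials left after category filter {category!r}")
    X = features.X[mask]
    y = _attribute(sub, target)
    labels = sorted(np.unique(y))
    if len(labels) < 2:
        raise ValueError("fewer than 2 labels after filtering")

    result = DecodingResult(target=target)
    for i, pair in enumerate(itertools.combinations(labels, 2)):
        if min((y == pair[0]).sum(), (y == pair[1]).sum()) < 2:
            warnings.warn(f"pair {pair} skipped: fewer than 2 trials per label")
            continue
        cm = fit_predict_pairwise(
            X, y, pair, variance_kept=variance_kept, seed=seed + i
        )
        result.accuracies[pair] = cm.accuracy
        result.confusions[pair] = cm
    return result


def mcgurk_dual_decoding(
    features: FeatureMatrix,
    trials: list[TrialRecord],
    variance_kept: float = 0.95,
    seed: int = 0,
) -> dict[str, DecodingResult]:
    """The illusion-condition decoder scored against both attributes.

    For each phoneme pair, McGurk-category trials whose video AND audio
    identities both lie in the pair are classified once, with training
    labels given by the video identity (the attribute driving the
    illusory percept).  The same predictions are scored against the
    video labeling and against the audio labeling; because the two
    labelings are complementary on incongruent within-pair trials, audio
    accuracy is the mirror of video accuracy — the construction behind
    above-chance video decoding coexisting with below-chance audio
    decoding.
    """
    if features.n_trials != len(trials):
        raise ValueError("features and trials must align")
    mask = np.array(
        [t.category == "mcgurk" and not t.congruent for t in trials]
    )
    sub = [t for t, m in zip(trials, mask) if m]
    if not sub:
        raise ValueError("no McGurk-category trials")
    X = features.X[mask]
    video = _attribute(sub, "video")
    audio = _attribute(sub, "audio")
    labels = sorted(set(video) | set(audio))

    out = {
        "video": DecodingResult(target="video"),
        "audio": DecodingResult(target="audio"),
    }
    for i, pair in enumerate(itertools.combinations(labels, 2)):
        in_pair = np.isin(video, pair) & np.isin(audio, pair)
        if min((video[in_pair] == pair[0]).sum(), (video[in_pair] == pair[1]).sum()) < 2:
            warnings.warn(f"pair {pair} skipped: fewer than 2 trials per label")
            continue
        cm_video = fit_predict_pairwise(
            X[in_pair], video[in_pair], pair,
            variance_kept=variance_kept, seed=seed + i,
        )
        cm_audio = cm_video.swapped_labels()
        out["video"].accuracies[pair] = cm_video.accuracy
        out["video"].confusions[pair] = cm_video
        out["audio"].accuracies[pair] = cm_audio.accuracy
        out["audio"].confusions[pair] = cm_audio
    return out
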