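"""Conditional mutual information and directed information tendency.

From each electrode's pairwise confusion table a per-electrode response
channel p(r|s) is estimated; a joint distribution over (stimulus S,
response R_x, response R_y) is assembled as p(s) p(r_x|s) p(r_y|s)
(conditional independence of the two electrodes' decoded responses given
the stimulus — the construction available when only per-electrode
confusion tables are tabulated).  The conditional mutual information

    I(S; R_x | R_y) = sum p(s, x, y) log2 [ p(s, x | y) / (p(s|y) p(x|y)) ]

measures the information R_x carries about S beyond R_y.  The signed
information tendency between adjacent electrodes,

    I(S; R_x | R_y) - I(S; R_y | R_x),

is the net directed transfer from electrode Y to electrode X; with edges
ordered caudal-first, positive values mean caudal-to-rostral transfer.
All quantities are in bits; 0 log 0 is taken as 0 and no pseudocounts
are added by default (an optional additive smoothing exists for very
small trial counts).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .containers import INTERVALS, ConfusionTable, EpochArray, TrialRecord
from .decoding import FeatureMatrix, build_features, fit_predict_pairwise
from .spectral import SpectrogramConfig

EDGES = (("posterior", "middle"), ("middle", "anterior"))


@dataclass
class JointStimulusResponse:
    """Probability tensor over (S, R_x, R_y) with per-axis label sets."""

    p: np.ndarray
    stimulus_labels: tuple[str, ...]
    x_labels: tuple[str, ...]
    y_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=float)
        expected = (
            len(self.stimulus_labels), len(self.x_labels), len(self.y_labels)
        )
        if self.p.shape != expected:
            raise ValueError(f"joint shape {self.p.shape} != labels {expected}")
        if (self.p < 0).any():
            raise ValueError("joint has negative entries")
        if abs(self.p.sum() - 1.0) > 1e-9:
            raise ValueError("joint does not sum to 1")

    def swap_responses(self) -> "JointStimulusResponse":
        return JointStimulusResponse(
            p=np.swapaxes(self.p, 1, 2),
            stimulus_labels=self.stimulus_labels,
            x_labels=self.y_labels,
            y_labels=self.x_labels,
        )


def joint_from_confusions(
    cm_x: ConfusionTable,
    cm_y: ConfusionTable,
    stimulus_prior: np.ndarray | None = None,
    smoothing: float = 0.0,
) -> JointStimulusResponse:
    """Assemble p(s, r_x, r_y) = p(s) p(r_x|s) p(r_y|s) from two
    per-electrode confusion tables over the same label pair.

    The stimulus prior defaults to the empirical true-label frequencies;
    ``smoothing`` adds that many pseudo-counts to every confusion cell.
    """
    if cm_x.labels != cm_y.labels:
        raise ValueError(f"label sets differ: {cm_x.labels} vs {cm_y.labels}")
    cx = cm_x.counts.astype(float) + smoothing
    cy = cm_y.counts.astype(float) + smoothing
    nx = cx.sum(axis=1)
    ny = cy.sum(axis=1)
    if (nx == 0).any() or (ny == 0).any():
        raise ValueError("a stimulus row has zero trials")
    if not np.array_equal(cm_x.counts.sum(axis=1), cm_y.counts.sum(axis=1)):
        raise ValueError("true-label trial counts differ between electrodes")
    px_given_s = cx / nx[:, None]
    py_given_s = cy / ny[:, None]
    if stimulus_prior is None:
        prior = nx / nx.sum()
    else:
        prior = np.asarray(stimulus_prior, dtype=float)
        if prior.size != len(cm_x.labels) or (prior < 0).any():
            raise ValueError("invalid stimulus prior")
        prior = prior / prior.sum()
    p = prior[:, None, None] * px_given_s[:, :, None] * py_given_s[:, None, :]
    return JointStimulusResponse(
        p=p / p.sum(),
        stimulus_labels=cm_x.labels,
        x_labels=cm_x.labels,
        y_labels=cm_y.labels,
    )


def _xlogy2(num: np.ndarray, den: np.ndarray, w: np.ndarray) -> float:
    """sum w * log2(num/den) with the 0 log 0 convention."""
    mask = w > 0
    return float(np.sum(w[mask] * (np.log2(num[mask]) - np.log2(den[mask]))))


def conditional_mutual_information(
    joint: JointStimulusResponse, conditioned: str = "y"
) -> float:
    """I(S; R_x | R_y) in bits (``conditioned='y'``), or I(S; R_y | R_x)
    (``conditioned='x'``).  Non-negative up to floating error."""
    if conditioned == "x":
        return conditional_mutual_information(joint.swap_responses(), "y")
    if conditioned != "y":
        raise ValueError("conditioned must be 'x' or 'y'")
    p = joint.p  # (s, x, y)
    p_y = p.sum(axis=(0, 1))  # (y,)
    p_sy = p.sum(axis=1)  # (s, y)
    p_xy = p.sum(axis=0)  # (x, y)
    # I = sum p(s,x,y) log2 [ p(s,x,y) p(y) / (p(s,y) p(x,y)) ]
    num = p * p_y[None, None, :]
    den = p_sy[:, None, :] * p_xy[None, :, :]
    val = _xlogy2(num, den, p)
    return max(val, 0.0)


def information_tendency(
    cm_x: ConfusionTable,
    cm_y: ConfusionTable,
    stimulus_prior: np.ndarray | None = None,
    smoothing: float = 0.0,
) -> float:
    """Net information transfer from electrode Y to electrode X:
    I(S;R_x|R_y) - I(S;R_y|R_x), in bits.  Antisymmetric in arguments."""
    joint = joint_from_confusions(cm_x, cm_y, stimulus_prior, smoothing)
    return conditional_mutual_information(joint, "y") - conditional_mutual_information(
        joint, "x"
    )


# ---------------------------------------------------------------------------
# interval analysis


@dataclass
class TendencyResult:
    interval: str
    edge: tuple[str, str]  # (source, destination) roles, caudal first
    stimulus_attribute: str
    tendency: float  # bits, mean over label pairs
    per_pair: dict = field(default_factory=dict)  # pair -> bits

    def to_row(self) -> dict:
        return {
            "interval": self.interval,
            "source": self.edge[0],
            "destination": self.edge[1],
            "attribute": self.stimulus_attribute,
            "tendency_bits": self.tendency,
        }


def interval_features(
    epochs: list[EpochArray],
    trials: list[TrialRecord],
    role_to_electrode: dict[str, int],
    intervals: dict[str, tuple[float, float]] | None = None,
    spec_cfg: SpectrogramConfig | None = None,
) -> dict[tuple[str, str], FeatureMatrix]:
    """Per-(interval, role) single-electrode feature matrices."""
    intervals = intervals or INTERVALS
    out = {}
    for name, window in intervals.items():
        for role, el in role_to_electrode.items():
            out[(name, role)] = build_features(
                epochs, trials, [el], spec_cfg=spec_cfg, window=window
            )
    return out


def _pairs(labels: np.ndarray) -> list[tuple[str, str]]:
    import itertools

    return list(itertools.combinations(sorted(np.unique(labels)), 2))


def tendencies_from_features(
    features: dict[tuple[str, str], FeatureMatrix],
    labels_by_attribute: dict[str, np.ndarray],
    edges: tuple = EDGES,
    variance_kept: float = 0.95,
    seed: int = 0,
    smoothing: float = 0.0,
) -> list[TendencyResult]:
    """Tendency per (interval, edge, attribute) from precomputed features.

    Confusion tables are computed per electrode from interval-limited
    features; the per-edge tendency is the mean over label pairs of the
    signed transfer from the caudal to the rostral electrode.
    """
    intervals = sorted({k[0] for k in features}, key=lambda n: list(INTERVALS).index(n) if n in INTERVALS else 99)
    results = []
    for interval in intervals:
        for attribute, labels in labels_by_attribute.items():
            pairs = _pairs(labels)
            # confusion per role per pair, computed once per electrode
            roles = {k[1] for k in features if k[0] == interval}
            cms: dict[str, dict] = {r: {} for r in roles}
            for role in roles:
                fm = features[(interval, role)]
                for i, pair in enumerate(pairs):
                    cms[role][pair] = fit_predict_pairwise(
                        fm, labels, pair,
                        variance_kept=variance_kept,
                        seed=seed + 7919 * i,
                        electrode=role,
                    )
            for edge in edges:
                src, dst = edge
                if src not in cms or dst not in cms:
                    continue
                per_pair = {
                    pair: information_tendency(
                        cms[dst][pair], cms[src][pair], smoothing=smoothing
                    )
                    for pair in pairs
                }
                results.append(
                    TendencyResult(
                        interval=interval,
                        edge=edge,
                        stimulus_attribute=attribute,
                        tendency=float(np.mean(list(per_pair.values()))),
                        per_pair=per_pair,
                    )
                )
    return results


def interval_analysis(
    epochs: list[EpochArray],
    trials: list[TrialRecord],
    role_to_electrode: dict[str, int],
    intervals: dict[str, tuple[float, float]] | None = None,
    edges: tuple = EDGES,
    attributes: tuple[str, ...] = ("video", "audio"),
    variance_kept: float = 0.95,
    seed: int = 0,
    spec_cfg: SpectrogramConfig | None = None,
    smoothing: float = 0.0,
) -> list[TendencyResult]:
    """Directed information tendency per interval, edge and attribute.

    Trials are pooled across behavioral categories (unclassified trials
    are excluded when categories have been assigned).  Epoch support
    must cover every requested interval.
    """
    intervals = intervals or INTERVALS
    for name, (lo, hi) in intervals.items():
        ep = epochs[0]
        if lo < ep.t0 - 1e-9 or hi > ep.t0 + ep.n_samples / ep.fs + 1e-9:
            raise ValueError(f"interval {name!r} [{lo}, {hi}] outside epoch support")
    categorized = [t.category != "unclassified" for t in trials]
    if any(categorized):
        keep = np.array(categorized)
        trials = [t for t, k in zip(trials, keep) if k]
        epochs = [e for e, k in zip(epochs, keep) if k]
    feats = interval_features(epochs, trials, role_to_electrode, intervals, spec_cfg)
    labels = {
        "video": np.array([t.video_phoneme for t in trials]),
        "audio": np.array([t.audio_phoneme for t in trials]),
    }
    labels = {a: labels[a] for a in attributes}
    return tendencies_from_features(
        feats, labels, edges=edges, variance_kept=variance_kept,
        seed=seed, smoothing=smoothing,
    )


def signflip_null_tendencies(
    results: list[TendencyResult],
    n_permutations: int = 2000,
    seed: int = 0,
) -> dict[tuple[str, tuple, str], np.ndarray]:
    """Exchangeability null for the directed tendency.

    Under the no-net-transfer hypothesis the two electrodes of an edge
    are exchangeable, which flips the sign of every per-pair tendency.
    Randomly sign-flipping the per-pair values and re-averaging yields
    the null distribution of the mean tendency with the correct
    estimation-noise spread — unlike a stimulus-label permutation, which
    destroys all stimulus information and therefore understates the
    variance of the tendency when the electrodes are informative.
    Returns, per (interval, edge, attribute), the null means.
    """
    rng = np.random.default_rng(seed)
    out = {}
    for res in results:
        vals = np.array(list(res.per_pair.values()))
        signs = rng.choice([-1.0, 1.0], size=(n_permutations, vals.size))
        out[(res.interval, res.edge, res.stimulus_attribute)] = (
            signs * vals[None, :]
        ).mean(axis=1)
    return out


def permutation_null_tendencies(
    features: dict[tuple[str, str], FeatureMatrix],
    labels_by_attribute: dict[str, np.ndarray],
    n_permutations: int,
    edges: tuple = EDGES,
    variance_kept: float = 0.95,
    seed: int = 0,
) -> dict[tuple[str, tuple, str], np.ndarray]:
    """Null tendencies under joint permutation of the stimulus labels.

    The (video, audio) label assignment is shuffled jointly across
    trials, preserving the stimulus-combination structure while breaking
    any relation to the neural data.  Returns, per (interval, edge,
    attribute), the array of permuted tendencies.
    """
    rng = np.random.default_rng(seed)
    n = next(iter(labels_by_attribute.values())).size
    out: dict[tuple[str, tuple, str], list[float]] = {}
    for p in range(n_permutations):
        perm = rng.permutation(n)
        permuted = {a: lab[perm] for a, lab in labels_by_attribute.items()}
        for res in tendencies_from_features(
            features, permuted, edges=edges,
            variance_kept=variance_kept, seed=seed + 104729 * (p + 1),
        ):
            key = (res.interval, res.edge, res.stimulus_attribute)
            out.setdefault(key, []).append(res.tendency)
    return {k: np.asarray(v) for k, v in out.items()}
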