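"""Conditional mutual information against an independent entropy oracle,
tendency algebra, and convergence of the plug-in estimator."""
from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mcgurk_ecog import (
    ConfusionTable,
    JointStimulusResponse,
    conditional_mutual_information,
    information_tendency,
    joint_from_confusions,
)
from mcgurk_ecog.infoflow import signflip_null_tendencies, interval_analysis
from mcgurk_ecog.containers import TrialRecord, EpochArray


# --- independent oracle: CMI via joint entropies -------------------------

def entropy(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def cmi_oracle(p: np.ndarray) -> float:
    """I(S;Rx|Ry) = H(S,Ry) + H(Rx,Ry) - H(S,Rx,Ry) - H(Ry)."""
    return (
        entropy(p.sum(axis=1).ravel())
        + entropy(p.sum(axis=0).ravel())
        - entropy(p.ravel())
        - entropy(p.sum(axis=(0, 1)))
    )


def random_joint(rng, shape=(2, 2, 2)) -> JointStimulusResponse:
    p = rng.dirichlet(np.ones(np.prod(shape))).reshape(shape)
    return JointStimulusResponse(
        p=p, stimulus_labels=("A", "B"), x_labels=("A", "B"), y_labels=("A", "B")
    )


def make_cm(counts, labels=("A", "B"), electrode="e") -> ConfusionTable:
    return ConfusionTable(counts=np.asarray(counts), labels=labels, electrode=electrode)


class TestConditionalMutualInformation:
    def test_independent_variables_zero(self):
        p = np.full((2, 2, 2), 1 / 8)
        j = JointStimulusResponse(p, ("A", "B"), ("A", "B"), ("A", "B"))
        assert conditional_mutual_information(j) == pytest.approx(0.0, abs=1e-12)

    def test_deterministic_channel_one_bit(self):
        # R_x = S deterministic, R_y independent uniform, S uniform binary
        p = np.zeros((2, 2, 2))
        for s in range(2):
            for y in range(2):
                p[s, s, y] = 0.25
        j = JointStimulusResponse(p, ("A", "B"), ("A", "B"), ("A", "B"))
        assert conditional_mutual_information(j, "y") == pytest.approx(1.0)
        assert conditional_mutual_information(j, "x") == pytest.approx(0.0, abs=1e-12)

    def test_matches_entropy_oracle(self, rng):
        devs = []
        for _ in range(300):
            j = random_joint(rng)
            devs.append(
                abs(conditional_mutual_information(j, "y") - cmi_oracle(j.p))
            )
        assert max(devs) < 1e-10

    def test_nonnegative(self, rng):
        assert all(
            conditional_mutual_information(random_joint(rng), c) >= 0
            for _ in range(100)
            for c in ("x", "y")
        )

    def test_markov_chain_conditional_independence(self, rng):
        """For S -> R_y -> R_x, I(S;R_x|R_y) = 0."""
        for _ in range(20):
            ps = rng.dirichlet([1, 1])
            py_s = rng.dirichlet([1, 1], size=2)
            px_y = rng.dirichlet([1, 1], size=2)
            p = np.einsum("s,sy,yx->sxy", ps, py_s, px_y)
            j = JointStimulusResponse(p, ("A", "B"), ("A", "B"), ("A", "B"))
            assert conditional_mutual_information(j, "y") == pytest.approx(0.0, abs=1e-12)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_chain_rule(self, seed):
        """I(S;Rx,Ry) = I(S;Ry) + I(S;Rx|Ry), all via the entropy oracle
        on one side and the implementation on the other."""
        r = np.random.default_rng(seed)
        j = random_joint(r)
        p = j.p
        i_joint = (
            entropy(p.sum(axis=(1, 2)))
            + entropy(p.sum(axis=0).ravel())
            - entropy(p.ravel())
        )
        i_sy = (
            entropy(p.sum(axis=(1, 2)))
            + entropy(p.sum(axis=(0, 1)))
            - entropy(p.sum(axis=1).ravel())
        )
        lhs = i_joint
        rhs = i_sy + conditional_mutual_information(j, "y")
        assert lhs == pytest.approx(rhs, abs=1e-10)


class TestJointFromConfusions:
    def test_perfect_classifiers_diagonal(self):
        cm = make_cm([[10, 0], [0, 10]])
        j = joint_from_confusions(cm, cm)
        expected = np.zeros((2, 2, 2))
        expected[0, 0, 0] = expected[1, 1, 1] = 0.5
        np.testing.assert_allclose(j.p, expected)

    def test_chance_conditioning_recovers_marginal_mi(self):
        """If R_y is at chance, I(S;R_x|R_y) = I(S;R_x)."""
        cm_x = make_cm([[9, 3], [2, 10]])
        cm_y = make_cm([[6, 6], [6, 6]])
        j = joint_from_confusions(cm_x, cm_y)
        p_sx = j.p.sum(axis=2)
        i_sx = (
            entropy(p_sx.sum(axis=1))
            + entropy(p_sx.sum(axis=0))
            - entropy(p_sx.ravel())
        )
        assert conditional_mutual_information(j, "y") == pytest.approx(i_sx, abs=1e-12)
        assert conditional_mutual_information(j, "x") == pytest.approx(0.0, abs=1e-12)

    def test_symmetric_inputs_symmetric_joint(self):
        cm = make_cm([[8, 2], [2, 8]])
        j = joint_from_confusions(cm, cm, stimulus_prior=np.array([0.5, 0.5]))
        np.testing.assert_allclose(j.p, np.swapaxes(j.p, 1, 2))

    def test_zero_trial_row_rejected(self):
        with pytest.raises(ValueError, match="zero trials"):
            joint_from_confusions(make_cm([[0, 0], [5, 5]]), make_cm([[5, 5], [5, 5]]))

    def test_mismatched_labels_rejected(self):
        with pytest.raises(ValueError, match="label sets"):
            joint_from_confusions(
                make_cm([[5, 5], [5, 5]]),
                make_cm([[5, 5], [5, 5]], labels=("A", "C")),
            )

    def test_mismatched_counts_rejected(self):
        with pytest.raises(ValueError, match="trial counts"):
            joint_from_confusions(
                make_cm([[5, 5], [5, 5]]), make_cm([[4, 4], [5, 5]])
            )


class TestTendency:
    def test_equal_tables_zero(self):
        cm = make_cm([[7, 3], [4, 6]])
        assert information_tendency(cm, cm) == pytest.approx(0.0, abs=1e-12)

    def test_antisymmetry_exact(self, rng):
        n = 10  # both tables share row sums of n trials per stimulus
        for _ in range(20):
            ka, kb = rng.integers(0, n + 1, 2), rng.integers(0, n + 1, 2)
            a = make_cm(np.column_stack([ka, n - ka]))
            b = make_cm(np.column_stack([kb, n - kb]))
            t_xy = information_tendency(a, b)
            t_yx = information_tendency(b, a)
            assert t_xy == pytest.approx(-t_yx, abs=1e-12)

    def test_perfect_vs_chance_equals_marginal_information(self):
        perfect = make_cm([[10, 0], [0, 10]])
        chance = make_cm([[5, 5], [5, 5]])
        t = information_tendency(perfect, chance)
        assert t == pytest.approx(1.0)  # I(S;R_x) for a perfect binary channel

    def test_smoothing_keeps_finite(self):
        cm_a = make_cm([[10, 0], [0, 10]])
        cm_b = make_cm([[10, 0], [10, 0]])
        t = information_tendency(cm_a, cm_b, smoothing=0.5)
        assert np.isfinite(t)


class TestEstimatorConvergence:
    def test_median_error_decreases_with_trials(self, rng):
        """Plug-in CMI from sampled confusion tables converges to the
        analytic CMI of the generating channels as trials grow."""
        acc_x, acc_y = 0.8, 0.7
        px = np.array([[acc_x, 1 - acc_x], [1 - acc_x, acc_x]])
        py = np.array([[acc_y, 1 - acc_y], [1 - acc_y, acc_y]])
        truth_p = 0.5 * np.einsum("sx,sy->sxy", px, py)
        truth = cmi_oracle(truth_p)
        med_errs = []
        for n in (20, 80, 320):
            errs = []
            for _ in range(120):
                cx = np.vstack([rng.multinomial(n, px[s]) for s in range(2)])
                cy = np.vstack([rng.multinomial(n, py[s]) for s in range(2)])
                j = joint_from_confusions(make_cm(cx), make_cm(cy))
                errs.append(abs(conditional_mutual_information(j, "y") - truth))
            med_errs.append(np.median(errs))
        assert med_errs[0] > med_errs[1] > med_errs[2]


class TestIntervalAnalysis:
    def test_interval_outside_epoch_rejected(self, rng):
        trials = [TrialRecord(i, "BA", "BA", "BA") for i in range(4)]
        epochs = [
            EpochArray(data=rng.standard_normal((3500, 3)), fs=1000.0, t0=-2.0)
            for _ in range(4)
        ]
        with pytest.raises(ValueError, match="outside epoch support"):
            interval_analysis(
                epochs, trials, {"posterior": 0, "middle": 1, "anterior": 2},
                intervals={"bad": (-5.0, -4.0)},
            )

    def test_signflip_null_symmetric_and_sized(self):
        from mcgurk_ecog.infoflow import TendencyResult

        res = TendencyResult(
            interval="baseline", edge=("posterior", "middle"),
            stimulus_attribute="video", tendency=0.1,
            per_pair={("A", "B"): 0.2, ("A", "C"): -0.1, ("B", "C"): 0.2},
        )
        null = signflip_null_tendencies([res], n_permutations=500, seed=0)
        vals = null[("baseline", ("posterior", "middle"), "video")]
        assert vals.shape == (500,)
        assert abs(vals.mean()) < 0.02
        assert vals.max() <= (0.2 + 0.1 + 0.2) / 3 + 1e-12
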