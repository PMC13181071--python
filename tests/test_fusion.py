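"""Voting, weighting, rank and logit fusion operators."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from drfuse import (
    FUSION_METHODS,
    InvalidInputError,
    ScorePanel,
    WeightVector,
    average_logits_fuse,
    build_lambda_measure,
    derive_weights,
    fuse,
    hard_vote,
    rank_fuse,
    soft_vote,
    weighted_soft_vote,
)
from .conftest import panel_with_logits


def panel(rows):
    return ScorePanel(np.atleast_2d(np.asarray(rows, dtype=float)))


class TestHardVote:
    @pytest.mark.parametrize(
        "probs, expected",
        [
            ([0.9, 0.8, 0.7, 0.2], 0.75),            # votes (1,1,1,0)
            ([0.9, 0.9, 0.9, 0.9], 1.0),             # unanimous
            ([0.49, 0.50, 0.51, 0.52], 0.75),        # 0.50 votes DR under >= rule
        ],
    )
    def test_vote_fraction(self, probs, expected):
        assert hard_vote(panel(probs)).scores[0] == pytest.approx(expected)

    def test_vote_fraction_lattice(self, small_panel):
        scores = hard_vote(small_panel).scores
        m = small_panel.n_classifiers
        assert np.all(np.isin(np.round(scores * m), np.arange(m + 1)))

    def test_empty_panel_rejected(self):
        with pytest.raises(InvalidInputError):
            ScorePanel(np.empty((0, 4)))


class TestSoftVote:
    def test_mean(self):
        assert soft_vote(panel([0.2, 0.4, 0.6, 0.8])).scores[0] == pytest.approx(0.5)

    def test_idempotent_and_single_classifier(self, rng):
        s = rng.uniform(0, 1, 10)
        same = ScorePanel(np.tile(s[:, None], (1, 5)))
        np.testing.assert_allclose(soft_vote(same).scores, s)
        single = ScorePanel(s[:, None])
        np.testing.assert_allclose(soft_vote(single).scores, s)


class TestWeights:
    def test_uniform(self):
        np.testing.assert_allclose(derive_weights([1, 1, 1, 1]).weights, 0.25)

    def test_backbone_accuracy_weights(self):
        # normalizing four test accuracies near 98% gives near-equal weights
        acc = np.array([98.64, 98.36, 98.36, 98.23])
        w = derive_weights(acc).weights
        np.testing.assert_allclose(w, acc / 393.59, atol=1e-12)
        assert w.sum() == pytest.approx(1.0, abs=1e-12)

    def test_degenerate(self):
        np.testing.assert_allclose(derive_weights([1, 0, 0, 0]).weights, [1, 0, 0, 0])

    def test_all_zero_rejected(self):
        with pytest.raises(InvalidInputError):
            derive_weights([0.0, 0.0])

    def test_unnormalized_weight_vector_rejected(self):
        with pytest.raises(InvalidInputError):
            WeightVector(np.array([0.5, 0.6]))


class TestWeightedSoftVote:
    def test_uniform_reduces_to_soft_vote(self, small_panel):
        w = WeightVector.uniform(small_panel.n_classifiers)
        np.testing.assert_array_equal(
            weighted_soft_vote(small_panel, w).scores, soft_vote(small_panel).scores
        )

    def test_projection(self, small_panel):
        w = WeightVector(np.array([1.0, 0.0, 0.0]))
        np.testing.assert_allclose(
            weighted_soft_vote(small_panel, w).scores, small_panel.probs[:, 0]
        )

    def test_closed_form(self):
        w = WeightVector(np.array([0.3, 0.7]))
        assert weighted_soft_vote(panel([0.2, 0.6]), w).scores[0] == pytest.approx(0.48)

    def test_length_mismatch(self, small_panel):
        with pytest.raises(InvalidInputError):
            weighted_soft_vote(small_panel, WeightVector.uniform(5))


class TestRankFuse:
    def test_single_classifier_preserves_ordering(self, rng):
        s = rng.uniform(0, 1, 15)
        fused = rank_fuse(ScorePanel(s[:, None])).scores
        np.testing.assert_array_equal(np.argsort(fused), np.argsort(s))

    def test_agreeing_classifiers(self):
        p = ScorePanel(np.array([[0.1, 0.2], [0.4, 0.5], [0.6, 0.7], [0.9, 0.95]]))
        np.testing.assert_allclose(rank_fuse(p).scores, [0.25, 0.5, 0.75, 1.0])

    def test_hand_ranks(self):
        p = ScorePanel(np.array([[0.1, 0.2], [0.9, 0.8]]))
        np.testing.assert_allclose(rank_fuse(p).scores, [0.5, 1.0])

    def test_monotone_transform_invariance(self, rng):
        probs = rng.uniform(0, 1, (12, 3))
        base = rank_fuse(ScorePanel(probs)).scores
        transformed = np.column_stack(
            [probs[:, 0] ** 3, 0.2 + 0.8 * probs[:, 1], 1 / (1 + np.exp(-5 * probs[:, 2]))]
        )
        np.testing.assert_allclose(rank_fuse(ScorePanel(transformed)).scores, base)

    def test_identical_columns_give_common_normalized_rank(self, rng):
        s = rng.uniform(0, 1, 9)
        p = ScorePanel(np.tile(s[:, None], (1, 4)))
        from scipy.stats import rankdata

        np.testing.assert_allclose(rank_fuse(p).scores, rankdata(s) / 9)

    def test_tie_handling_uses_average_rank(self):
        p = ScorePanel(np.array([[0.5], [0.5], [0.9]]))
        np.testing.assert_allclose(rank_fuse(p).scores, [0.5, 0.5, 1.0])


class TestAverageLogits:
    def test_identical_logits(self):
        p = panel_with_logits(np.full((3, 4), 0.7))
        np.testing.assert_allclose(average_logits_fuse(p).scores, 0.7, atol=1e-12)

    def test_symmetric_pair(self):
        logits = np.array([[[2.0, 0.0], [0.0, 2.0]]])
        p = ScorePanel(np.array([[0.5, 0.5]]), logits=logits)
        assert average_logits_fuse(p).scores[0] == pytest.approx(0.5)

    def test_softmax_arithmetic(self):
        logits = np.array([[[0.0, 1.0], [2.0, 3.0]]])  # mean pair (1, 2)
        p = ScorePanel(np.array([[0.5, 0.5]]), logits=logits)
        assert average_logits_fuse(p).scores[0] == pytest.approx(
            1 / (1 + np.exp(-1)), abs=1e-6
        )

    def test_missing_logits_rejected(self, rng):
        with pytest.raises(InvalidInputError):
            average_logits_fuse(ScorePanel(rng.uniform(0, 1, (4, 2))))


def _fuse_all(p, measure):
    w = WeightVector.uniform(p.n_classifiers)
    return {m: fuse(p, m, weights=w, measure=measure) for m in FUSION_METHODS}


@settings(max_examples=40, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=2**31 - 1))
def test_raising_one_score_never_lowers_fusion(seed):
    """Every fusion rule is monotone in each classifier's score."""
    rng = np.random.default_rng(seed)
    probs = rng.uniform(0, 1, (6, 3))
    i, j = rng.integers(6), rng.integers(3)
    bumped = probs.copy()
    bumped[i, j] = min(1.0, bumped[i, j] + rng.uniform(0, 1))
    measure = build_lambda_measure(rng.uniform(0.05, 0.5, 3))
    before = _fuse_all(panel_with_logits(probs), measure)
    after = _fuse_all(panel_with_logits(bumped), measure)
    for method in FUSION_METHODS:
        assert after[method].scores[i] >= before[method].scores[i] - 1e-12, method


def test_fused_scores_bounded_by_per_sample_inputs(small_panel, rng):
    """Except for hard voting (vote fraction) and logit averaging, fused
    scores stay within each sample's min/max classifier score."""
    measure = build_lambda_measure(rng.uniform(0.1, 0.6, 3))
    lo = small_panel.probs.min(axis=1) - 1e-12
    hi = small_panel.probs.max(axis=1) + 1e-12
    for method in ("soft", "weighted", "choquet", "sugeno"):
        s = fuse(
            small_panel, method,
            weights=WeightVector.uniform(3), measure=measure,
        ).scores
        assert np.all(s >= lo) and np.all(s <= hi), method


def test_value_idempotency_when_classifiers_agree(rng):
    s = rng.uniform(0, 1, 8)
    p = panel_with_logits(np.tile(s[:, None], (1, 4)))
    measure = build_lambda_measure(np.full(4, 0.2))
    for method in ("soft", "weighted", "choquet", "sugeno", "avg_logits"):
        fused = fuse(p, method, weights=WeightVector.uniform(4), measure=measure)
        np.testing.assert_allclose(fused.scores, s, atol=1e-9, err_msg=method)
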