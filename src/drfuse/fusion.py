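"""Decision-level fusion of binary classifier panels.

Seven aggregation rules over an ``(n, m)`` panel of class-1 probabilities:

* ``hard_vote`` — majority voting on thresholded per-classifier votes;
* ``soft_vote`` — arithmetic mean of probabilities;
* ``weighted_soft_vote`` — convex combination with performance-derived weights;
* ``rank_fuse`` — average of batch-normalized fractional ranks;
* ``choquet_fuse`` — Choquet integral w.r.t. a Sugeno λ-fuzzy measure;
* ``sugeno_fuse`` — Sugeno (max–min) integral w.r.t. the same measure;
* ``average_logits_fuse`` — elementwise logit averaging followed by softmax.

The λ-fuzzy measure assigns each classifier an importance density
``g_i ∈ [0, 1]`` and extends to subsets through

    μ(A ∪ B) = μ(A) + μ(B) + λ·μ(A)·μ(B),

with the interaction parameter λ pinned down by the boundary condition
μ(full set) = 1, i.e. the root of ``1 + λ = Π_i (1 + λ·g_i)`` on (−1, ∞).
λ > 0 (sub-additive densities, Σg < 1) models redundant classifiers;
λ < 0 (Σg > 1) models complementary ones; Σg = 1 recovers an additive
measure and reduces the Choquet integral to a weighted mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, special, stats

from .errors import InvalidInputError
from .panel import ScorePanel

__all__ = [
    "FUSION_METHODS",
    "WeightVector",
    "LambdaMeasure",
    "FusedScores",
    "hard_vote",
    "soft_vote",
    "derive_weights",
    "weighted_soft_vote",
    "rank_fuse",
    "build_lambda_measure",
    "choquet_fuse",
    "sugeno_fuse",
    "average_logits_fuse",
    "density_preset",
    "fuse",
]

FUSION_METHODS = (
    "hard",
    "soft",
    "weighted",
    "rank",
    "choquet",
    "sugeno",
    "avg_logits",
)


@dataclass(frozen=True)
class WeightVector:
    """Nonnegative per-classifier weights summing to one."""

    weights: np.ndarray

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 1 or w.size == 0:
            raise InvalidInputError("weights must be a non-empty vector")
        if np.any(w < 0) or not np.all(np.isfinite(w)):
            raise InvalidInputError("weights must be finite and nonnegative")
        if abs(w.sum() - 1.0) > 1e-9:
            raise InvalidInputError("weights must sum to 1 within 1e-9")
        object.__setattr__(self, "weights", w)

    def __len__(self) -> int:
        return self.weights.size

    @classmethod
    def uniform(cls, m: int) -> "WeightVector":
        return cls(np.full(m, 1.0 / m))


@dataclass(frozen=True)
class FusedScores:
    """Per-sample fused scores with the method tag and optional threshold τ."""

    scores: np.ndarray
    method: str
    sample_ids: tuple = None
    threshold: float = None

    def __post_init__(self):
        s = np.asarray(self.scores, dtype=float)
        if s.ndim != 1 or s.size == 0:
            raise InvalidInputError("scores must be a non-empty vector")
        if not np.all(np.isfinite(s)):
            raise InvalidInputError("fused scores must be finite")
        object.__setattr__(self, "scores", s)
        if self.sample_ids is not None:
            ids = tuple(str(i) for i in self.sample_ids)
            if len(ids) != s.size:
                raise InvalidInputError("sample_ids length does not match scores")
            object.__setattr__(self, "sample_ids", ids)

    def with_threshold(self, tau: float) -> "FusedScores":
        return FusedScores(self.scores, self.method, self.sample_ids, float(tau))

    def __len__(self) -> int:
        return self.scores.size


# --------------------------------------------------------------------------
# Voting-family rules


def hard_vote(panel: ScorePanel, vote_cut: float = 0.5) -> FusedScores:
    """Majority voting: each classifier votes DR iff its probability ≥ vote_cut.

    The fused score is the fraction of positive votes, a value on the lattice
    {0, 1/m, ..., 1}; thresholding the fraction at τ recovers the tunable
    majority rule.
    """
    votes = panel.probs >= vote_cut
    return FusedScores(votes.mean(axis=1), "hard", panel.sample_ids)


def soft_vote(panel: ScorePanel) -> FusedScores:
    """Average-probability voting: unweighted mean of the class-1 probabilities."""
    # same kernel as weighted_soft_vote so the uniform-weight reduction is exact
    uniform = np.full(panel.n_classifiers, 1.0 / panel.n_classifiers)
    return FusedScores((panel.probs * uniform).sum(axis=1), "soft", panel.sample_ids)


def derive_weights(scores_per_classifier) -> WeightVector:
    """Normalize per-classifier performance scores (accuracy, AUC, F1, ...)
    into fusion weights ω_j = Score_j / Σ Score_j."""
    s = np.asarray(scores_per_classifier, dtype=float)
    if s.ndim != 1 or s.size == 0:
        raise InvalidInputError("need a vector of per-classifier scores")
    if np.any(s < 0) or not np.all(np.isfinite(s)):
        raise InvalidInputError("performance scores must be finite and nonnegative")
    total = s.sum()
    if total <= 0:
        raise InvalidInputError("at least one performance score must be positive")
    return WeightVector(s / total)


def weighted_soft_vote(panel: ScorePanel, weights: WeightVector) -> FusedScores:
    """Weighted soft voting: fused score = Σ_j ω_j · p_j (weights sum to one)."""
    if len(weights) != panel.n_classifiers:
        raise InvalidInputError(
            f"{len(weights)} weights for {panel.n_classifiers} classifiers"
        )
    return FusedScores(
        (panel.probs * weights.weights).sum(axis=1), "weighted", panel.sample_ids
    )


def rank_fuse(panel: ScorePanel) -> FusedScores:
    """Rank-based fusion.

    Within the batch, each classifier's probabilities are replaced by their
    fractional ranks (ascending, average rank on ties) normalized to (0, 1]
    by dividing by n; the fused score is the mean normalized rank across
    classifiers. The transform is invariant to any strictly increasing
    rescaling of an individual classifier's scores.
    """
    n = panel.n_samples
    ranks = stats.rankdata(panel.probs, axis=0, method="average") / n
    return FusedScores(ranks.mean(axis=1), "rank", panel.sample_ids)


# --------------------------------------------------------------------------
# Fuzzy-integral rules


@dataclass(frozen=True)
class LambdaMeasure:
    """Sugeno λ-fuzzy measure over a set of m classifiers.

    ``densities[i]`` is μ({i}); subsets are evaluated through the closed
    form μ(S) = (Π_{i∈S}(1 + λ g_i) − 1) / λ (the fixed point of the
    pairwise union rule), degenerating to Σ g_i when λ = 0.
    """

    densities: np.ndarray
    lam: float

    def __post_init__(self):
        g = np.asarray(self.densities, dtype=float)
        object.__setattr__(self, "densities", g)
        object.__setattr__(self, "lam", float(self.lam))

    @property
    def arity(self) -> int:
        return self.densities.size

    def mu(self, subset) -> float:
        """μ_λ(S) for any subset S given as an iterable of classifier indices."""
        idx = np.asarray(sorted(set(int(i) for i in subset)), dtype=int)
        if idx.size == 0:
            return 0.0
        if idx.min() < 0 or idx.max() >= self.arity:
            raise InvalidInputError("subset indices out of range")
        g = self.densities[idx]
        if self.lam == 0.0:
            return float(g.sum())
        return float((np.prod(1.0 + self.lam * g) - 1.0) / self.lam)


def _lambda_identity(lam: float, g: np.ndarray) -> float:
    # f(λ) = Π(1 + g_i λ) − (1 + λ); the non-trivial root fixes μ(N) = 1.
    return np.prod(1.0 + g * lam) - 1.0 - lam


def build_lambda_measure(densities) -> LambdaMeasure:
    """Solve the λ-measure boundary identity and return the measure.

    ``1 + λ = Π_i (1 + λ·g_i)`` has exactly one root on (−1, ∞) besides the
    trivial λ = 0: positive when Σg < 1, negative when Σg > 1. Σg = 1 gives
    the additive measure (λ = 0).
    """
    g = np.asarray(densities, dtype=float)
    if g.ndim != 1 or g.size == 0:
        raise InvalidInputError("need a vector of fuzzy densities")
    if np.any(g < 0) or np.any(g > 1) or not np.all(np.isfinite(g)):
        raise InvalidInputError("fuzzy densities must lie in [0, 1]")
    if np.all(g == 0):
        raise InvalidInputError("at least one fuzzy density must be positive")

    total = g.sum()
    if abs(total - 1.0) <= 1e-9:
        lam = 0.0
    elif total < 1.0:
        if np.count_nonzero(g) < 2:
            raise InvalidInputError(
                "densities summing below 1 need at least two positive entries"
            )
        lo = 1e-9
        hi = 1.0
        while _lambda_identity(hi, g) <= 0:
            hi *= 2.0
            if hi > 1e12:  # pragma: no cover - unreachable for valid densities
                raise InvalidInputError("failed to bracket lambda")
        lam = optimize.brentq(_lambda_identity, lo, hi, args=(g,), xtol=1e-14)
    else:
        lo, hi = -1.0 + 1e-12, -1e-12
        if _lambda_identity(lo, g) <= 0:
            raise InvalidInputError(
                "infeasible densities: no lambda on (-1, 0) attains mu(N) = 1"
            )
        lam = optimize.brentq(_lambda_identity, lo, hi, args=(g,), xtol=1e-15)

    measure = LambdaMeasure(g, lam)
    if abs(measure.mu(range(g.size)) - 1.0) > 1e-6:
        raise InvalidInputError("solved measure violates mu(full set) = 1")
    return measure


def _suffix_measures(panel: ScorePanel, measure: LambdaMeasure):
    """Sort each row ascending; return sorted scores and μ of the upper sets.

    ``mu[:, i]`` is μ(A_i) where A_i holds the classifiers at sorted
    positions i..m−1 (scores ≥ a_i). Built incrementally from the top via
    μ(S ∪ {j}) = μ(S) + g_j + λ·μ(S)·g_j, which is exact for a λ-measure.
    """
    if measure.arity != panel.n_classifiers:
        raise InvalidInputError(
            f"measure arity {measure.arity} != panel width {panel.n_classifiers}"
        )
    order = np.argsort(panel.probs, axis=1, kind="stable")
    a = np.take_along_axis(panel.probs, order, axis=1)
    n, m = a.shape
    mu = np.empty((n, m))
    acc = np.zeros(n)
    for i in range(m - 1, -1, -1):
        gj = measure.densities[order[:, i]]
        acc = acc + gj + measure.lam * acc * gj
        mu[:, i] = acc
    return a, mu


def choquet_fuse(panel: ScorePanel, measure: LambdaMeasure) -> FusedScores:
    """Choquet integral: Σ_i (a_i − a_{i−1}) · μ(A_i) over ascending scores.

    Captures positive/negative interaction among classifiers; with an
    additive measure it collapses to the weighted mean with ω = g.
    """
    a, mu = _suffix_measures(panel, measure)
    increments = np.diff(a, axis=1, prepend=0.0)
    return FusedScores((increments * mu).sum(axis=1), "choquet", panel.sample_ids)


def sugeno_fuse(panel: ScorePanel, measure: LambdaMeasure) -> FusedScores:
    """Sugeno integral: max_i min(a_i, μ(A_i)) over ascending scores.

    A non-compensatory (ordinal) aggregator — it reports a score/importance
    compromise rather than an average, so its output range is typically
    compressed relative to the voting rules.
    """
    a, mu = _suffix_measures(panel, measure)
    return FusedScores(np.minimum(a, mu).max(axis=1), "sugeno", panel.sample_ids)


def average_logits_fuse(panel: ScorePanel) -> FusedScores:
    """Average the raw two-class logit pairs elementwise and apply softmax.

    The fused score is the class-1 softmax probability of the mean logit
    pair; for two classes this equals sigmoid(mean(l1) − mean(l0)).
    """
    if panel.logits is None:
        raise InvalidInputError("average_logits_fuse requires a logit panel")
    avg = panel.logits.mean(axis=1)  # (n, 2)
    scores = special.expit(avg[:, 1] - avg[:, 0])
    return FusedScores(scores, "avg_logits", panel.sample_ids)


# --------------------------------------------------------------------------
# Convenience dispatch


def density_preset(performance_scores, kind: str = "additive", density_sum: float = 0.8):
    """Fuzzy densities from per-classifier performance scores.

    ``additive`` normalizes to Σg = 1 (λ = 0); ``sub-unit`` rescales the
    normalized scores by ``density_sum`` < 1, producing λ > 0 (redundant
    classifiers, a natural prior for near-identical CNN backbones).
    """
    w = derive_weights(performance_scores).weights
    if kind == "additive":
        return w
    if kind == "sub-unit":
        if not 0.0 < density_sum < 1.0:
            raise InvalidInputError("density_sum must lie in (0, 1)")
        return w * density_sum
    raise InvalidInputError(f"unknown density preset {kind!r}")


def fuse(
    panel: ScorePanel,
    method: str,
    *,
    weights: WeightVector = None,
    measure: LambdaMeasure = None,
    vote_cut: float = 0.5,
) -> FusedScores:
    """Dispatch a fusion method by tag (see :data:`FUSION_METHODS`)."""
    if method == "hard":
        return hard_vote(panel, vote_cut)
    if method == "soft":
        return soft_vote(panel)
    if method == "weighted":
        if weights is None:
            weights = WeightVector.uniform(panel.n_classifiers)
        return weighted_soft_vote(panel, weights)
    if method == "rank":
        return rank_fuse(panel)
    if method == "choquet" or method == "sugeno":
        if measure is None:
            raise InvalidInputError(f"{method} fusion requires a LambdaMeasure")
        return (choquet_fuse if method == "choquet" else sugeno_fuse)(panel, measure)
    if method == "avg_logits":
        return average_logits_fuse(panel)
    raise InvalidInputError(f"unknown fusion method {method!r}")
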