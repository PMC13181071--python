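"""Synthetic classifier panels, labels, splits, and fundus-like test images.

The generator emulates the statistical behavior of a bank of near-ceiling
CNN screeners evaluated on a balanced fundus test set: each classifier's
class-1 probability is drawn from a class-conditional Beta distribution
calibrated so that thresholding at 0.5 attains a target
sensitivity/specificity, and classifiers are coupled through a Gaussian
copula with exchangeable correlation ``rho`` (trained CNNs on the same data
err on overlapping subsets of hard cases, so their scores are strongly
correlated rather than independent).

The ``aptos_like`` preset mirrors a 733-sample screening test panel
(372 diseased / 361 healthy, four classifiers, per-classifier sensitivity
0.99 and specificity 0.98 at the 0.5 cut, rho = 0.6).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, special, stats

from .errors import InvalidInputError
from .evaluation import ConfusionMatrix, _as_labels
from .panel import ScorePanel

__all__ = [
    "PanelSpec",
    "aptos_like",
    "simulate_panel",
    "stratified_split",
    "panel_from_confusion",
    "simulate_fundus",
    "field_of_view_mask",
]


def _ceil(x: float) -> int:
    # ceil with protection against float jitter (371.999999996 -> 372, not 373)
    return int(math.ceil(x - 1e-6))


@dataclass(frozen=True)
class PanelSpec:
    """Recipe for a correlated classifier score panel.

    ``beta_pos``/``beta_neg`` give the Beta shape pair of the class-1
    probability for diseased and healthy samples respectively — either one
    ``(a, b)`` pair shared by all classifiers or a per-classifier ``(m, 2)``
    array.
    """

    n: int
    prevalence: float
    m: int
    beta_pos: np.ndarray
    beta_neg: np.ndarray
    rho: float = 0.0
    seed: int = 0
    classifier_ids: tuple = None

    def __post_init__(self):
        if self.n < 2:
            raise InvalidInputError("need at least 2 samples")
        if not 0.0 < self.prevalence < 1.0:
            raise InvalidInputError("prevalence must lie in (0, 1)")
        if self.m < 1:
            raise InvalidInputError("need at least one classifier")
        if not 0.0 <= self.rho < 1.0:
            raise InvalidInputError("rho must lie in [0, 1)")
        for name in ("beta_pos", "beta_neg"):
            shapes = np.atleast_2d(np.asarray(getattr(self, name), dtype=float))
            if shapes.shape == (1, 2):
                shapes = np.repeat(shapes, self.m, axis=0)
            if shapes.shape != (self.m, 2) or np.any(shapes <= 0):
                raise InvalidInputError(f"{name} must be positive (a, b) Beta shapes")
            object.__setattr__(self, name, shapes)
        if self.classifier_ids is not None and len(self.classifier_ids) != self.m:
            raise InvalidInputError("classifier_ids length must equal m")

    @property
    def n_positive(self) -> int:
        return _ceil(self.prevalence * self.n)


def aptos_like(
    n: int = 733,
    m: int = 4,
    sensitivity: float = 0.99,
    specificity: float = 0.98,
    rho: float = 0.6,
    saturation: float = 0.25,
    seed: int = 0,
) -> PanelSpec:
    """Preset emulating a balanced 733-sample screening test panel.

    Class-conditional scores are Beta families pinned to the 0.5 operating
    point: positives ~ Beta(a, saturation) with a solved so
    P(p ≥ 0.5) = sensitivity, negatives ~ Beta(saturation, b) solved so
    P(p < 0.5) = specificity. The outer shape ``saturation`` < 1 piles mass
    against 1 (resp. 0), emulating the saturated softmax outputs of
    well-trained CNNs whose score distributions are strongly bimodal.
    """
    if not 0.0 < sensitivity < 1.0 or not 0.0 < specificity < 1.0:
        raise InvalidInputError("sensitivity/specificity must lie in (0, 1)")
    if saturation <= 0:
        raise InvalidInputError("saturation must be positive")
    from scipy import optimize

    a_pos = optimize.brentq(
        lambda a: stats.beta.cdf(0.5, a, saturation) - (1.0 - sensitivity), 1e-3, 500.0
    )
    b_neg = optimize.brentq(
        lambda b: stats.beta.sf(0.5, saturation, b) - (1.0 - specificity), 1e-3, 500.0
    )
    return PanelSpec(
        n=n,
        prevalence=372.0 / 733.0,
        m=m,
        beta_pos=(a_pos, saturation),
        beta_neg=(saturation, b_neg),
        rho=rho,
        seed=seed,
    )


def simulate_panel(spec: PanelSpec):
    """Draw a (ScorePanel, labels) pair from a :class:`PanelSpec`.

    The positive-class count is deterministic (``ceil(prevalence · n)``);
    per sample, the m classifier scores share a Gaussian-copula latent with
    exchangeable correlation ``rho`` and are mapped through the
    class-appropriate Beta inverse CDF, so each classifier's marginal
    operating point is exact regardless of the coupling. Logit pairs are
    reconstructed as ``(0, logit(p))`` — softmax-equivalent to ``p``.
    """
    rng = np.random.default_rng(spec.seed)
    n, m = spec.n, spec.m
    n_pos = spec.n_positive
    labels = np.zeros(n, dtype=int)
    labels[:n_pos] = 1
    rng.shuffle(labels)

    common = rng.standard_normal((n, 1))
    noise = rng.standard_normal((n, m))
    z = math.sqrt(spec.rho) * common + math.sqrt(1.0 - spec.rho) * noise
    u = stats.norm.cdf(z)

    probs = np.empty((n, m))
    pos = labels == 1
    for j in range(m):
        probs[pos, j] = stats.beta.ppf(u[pos, j], *spec.beta_pos[j])
        probs[~pos, j] = stats.beta.ppf(u[~pos, j], *spec.beta_neg[j])
    probs = np.clip(probs, 0.0, 1.0)

    p_safe = np.clip(probs, 1e-12, 1.0 - 1e-12)
    logits = np.stack([np.zeros_like(probs), special.logit(p_safe)], axis=2)
    panel = ScorePanel(probs, classifier_ids=spec.classifier_ids, logits=logits)
    return panel, labels


def stratified_split(labels, test_fraction: float, seed: int = 0):
    """Per-class random split; the test set takes ceil(fraction · class size).

    Returns sorted (train_indices, test_indices), disjoint and exhaustive.
    With class sizes (1805, 1857) and fraction 0.2 the test set holds
    361 + 372 = 733 samples.
    """
    if not 0.0 <= test_fraction <= 1.0:
        raise InvalidInputError("test_fraction must lie in [0, 1]")
    y = _as_labels(labels)
    rng = np.random.default_rng(seed)
    test_parts = []
    for cls in (0, 1):
        idx = np.flatnonzero(y == cls)
        rng.shuffle(idx)
        test_parts.append(idx[: _ceil(test_fraction * idx.size)])
    test_idx = np.sort(np.concatenate(test_parts)).astype(int)
    train_idx = np.setdiff1d(np.arange(y.size), test_idx)
    return train_idx, test_idx


def panel_from_confusion(cm: ConfusionMatrix, seed: int = 0):
    """Single-classifier panel whose 0.5-threshold evaluation reproduces ``cm``.

    True negatives and false negatives receive scores in [0, 0.5); false
    positives and true positives in [0.5, 1]. Useful for recomputing metric
    rows from published confusion matrices.
    """
    rng = np.random.default_rng(seed)
    lo = lambda k: rng.uniform(0.02, 0.48, k)
    hi = lambda k: rng.uniform(0.52, 0.98, k)
    scores = np.concatenate([lo(cm.tn), hi(cm.fp), lo(cm.fn), hi(cm.tp)])
    labels = np.concatenate(
        [np.zeros(cm.tn + cm.fp, dtype=int), np.ones(cm.fn + cm.tp, dtype=int)]
    )
    perm = rng.permutation(scores.size)
    panel = ScorePanel(scores[perm][:, None], classifier_ids=("clf_1",))
    return panel, labels[perm]


# --------------------------------------------------------------------------
# Fundus-like raster synthesis (CLAHE fixtures)


def field_of_view_mask(height: int, width: int) -> np.ndarray:
    """Boolean circular field-of-view mask shared by all synthetic fundus images."""
    yy, xx = np.mgrid[0:height, 0:width]
    cy, cx = (height - 1) / 2.0, (width - 1) / 2.0
    r = 0.48 * min(height, width)
    return (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2


def simulate_fundus(
    height: int, width: int, contrast_level: float = 1.0, seed: int = 0
) -> np.ndarray:
    """Synthetic low-contrast retina-like RGB image.

    Dark surround, reddish circular field of view with radial shading and
    smooth illumination noise, a bright optic disc, dark curvilinear vessel
    strokes, and small bright/dark blobs standing in for exudates and
    hemorrhages. ``contrast_level`` < 1 compresses the intensity range
    inside the field of view (the regime CLAHE is meant to correct).
    """
    if height < 1 or width < 1:
        raise InvalidInputError("image dimensions must be positive")
    if not 0.0 < contrast_level <= 1.0:
        raise InvalidInputError("contrast_level must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    mask = field_of_view_mask(height, width)
    cy, cx = (height - 1) / 2.0, (width - 1) / 2.0
    r_fov = 0.48 * min(height, width)
    yy, xx = np.mgrid[0:height, 0:width]
    dist = np.sqrt((yy - cy) ** 2 + (xx - cx) ** 2)

    img = np.full((height, width, 3), 6.0)
    shading = 1.0 - 0.35 * np.clip(dist / r_fov, 0, 1) ** 2
    coarse = rng.normal(0.0, 1.0, (height, width))
    illum = 1.0 + 0.08 * ndimage.gaussian_filter(coarse, sigma=max(height, width) / 10)
    base = np.stack([165.0 * shading, 88.0 * shading, 38.0 * shading], axis=2)
    img[mask] = (base * illum[..., None])[mask]

    # optic disc: bright ellipse offset from center
    side = rng.choice((-1.0, 1.0))
    dy, dx = cy + 0.1 * r_fov * rng.normal(), cx + side * 0.55 * r_fov
    disc = np.exp(-(((yy - dy) / (0.16 * r_fov)) ** 2 + ((xx - dx) / (0.2 * r_fov)) ** 2))
    img += disc[..., None] * np.array([75.0, 110.0, 80.0])

    # vessels: dark quadratic arcs radiating from the disc
    t = np.linspace(0.0, 1.0, 4 * max(height, width))
    for _ in range(10):
        ang = rng.uniform(0, 2 * np.pi)
        end = (dy + 1.9 * r_fov * np.sin(ang), dx - side * 1.9 * r_fov * abs(np.cos(ang)))
        ctrl = (
            (dy + end[0]) / 2 + rng.uniform(-0.4, 0.4) * r_fov,
            (dx + end[1]) / 2 + rng.uniform(-0.4, 0.4) * r_fov,
        )
        py = (1 - t) ** 2 * dy + 2 * (1 - t) * t * ctrl[0] + t**2 * end[0]
        px = (1 - t) ** 2 * dx + 2 * (1 - t) * t * ctrl[1] + t**2 * end[1]
        keep = (py >= 0) & (py < height - 1) & (px >= 0) & (px < width - 1)
        iy, ix = py[keep].astype(int), px[keep].astype(int)
        for oy in (0, 1):
            for ox in (0, 1):
                img[iy + oy, ix + ox] *= 0.55
    # lesions: small bright (exudate) and dark (hemorrhage) blobs
    for _ in range(12):
        ang, rad = rng.uniform(0, 2 * np.pi), rng.uniform(0.15, 0.85) * r_fov
        ly, lx = cy + rad * np.sin(ang), cx + rad * np.cos(ang)
        size = rng.uniform(0.01, 0.035) * r_fov + 1.0
        blob = np.exp(-((yy - ly) ** 2 + (xx - lx) ** 2) / (2 * size**2))
        if rng.random() < 0.5:
            img += blob[..., None] * np.array([60.0, 55.0, 20.0])
        else:
            img -= blob[..., None] * np.array([70.0, 50.0, 25.0])

    inside = img[mask]
    img[mask] = inside.mean() + contrast_level * (inside - inside.mean())
    return np.clip(np.round(img), 0, 255).astype(np.uint8)
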