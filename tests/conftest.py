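import numpy as np
import pytest
from scipy import special

from drfuse import ScorePanel, aptos_like, simulate_panel


def panel_with_logits(probs, **kwargs):
    """Build a panel whose logit pairs (0, logit(p)) softmax back to probs."""
    probs = np.asarray(probs, dtype=float)
    safe = np.clip(probs, 1e-12, 1 - 1e-12)
    logits = np.stack([np.zeros_like(probs), special.logit(safe)], axis=2)
    return ScorePanel(probs, logits=logits, **kwargs)


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)


@pytest.fixture
def small_panel(rng):
    return panel_with_logits(rng.uniform(0.0, 1.0, (20, 3)))


@pytest.fixture(scope="session")
def aptos_panel():
    """One 733-sample, 4-classifier correlated panel shared across tests."""
    return simulate_panel(aptos_like(seed=11))


@pytest.fixture(scope="session")
def big_aptos_panel():
    """Large panel for distribution-recovery checks."""
    return simulate_panel(aptos_like(n=10_000, seed=7))
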