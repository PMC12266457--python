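"""Categorical cross-entropy over one-hot per-pixel labels."""

from __future__ import annotations

import numpy as np

_EPS = 1e-12


def categorical_crossentropy(probs: np.ndarray, onehot: np.ndarray) -> float:
    """Mean per-pixel negative log-likelihood of one-hot targets."""
    p = np.clip(probs, _EPS, 1.0)
    ll = np.sum(onehot * np.log(p), axis=-1)
    return float(-np.mean(ll))


def crossentropy_grad_logits(probs: np.ndarray, onehot: np.ndarray) -> np.ndarray:
    """Gradient of the mean cross-entropy w.r.t. pre-softmax logits.

    For softmax + cross-entropy this is (p - y) / n_pixels.
    """
    n = int(np.prod(probs.shape[:-1]))
    return (probs - onehot) / n
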