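"""Performance-weighted mixture of finite-context models with forgetting.

The next-symbol probability is the convex combination

    P(s) = sum_k w_k * P_k(s),

where each ``P_k`` comes from one order-k model and the weights track how
well each model has been predicting recently.  After the symbol at position
n is observed, every weight is updated by

    w_k <- w_k**gamma * P_k(x_n),   then renormalized to sum to 1.

With gamma = 1 this recursion reproduces the exact Bayesian posterior over
models under uniform priors 1/K: the weight of model k is proportional to
the likelihood prod_i P_k(x_i) of the sequence so far.  With gamma < 1 past
likelihood mass decays geometrically, so the mixture progressively forgets
the distant past and adapts to the non-stationary composition of genomic
sequences.

The per-symbol information content of the observed base, -log2 P(x_n) bits,
is the quantity the information profile plots: near 2 bits for unpredictable
DNA, close to 0 inside well-modelled repeats.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np

from .fcm import FcmModel

__all__ = [
    "information_content",
    "MixtureState",
    "PerModelPerformance",
]

#: Smallest weight kept after renormalization (see MixtureState.update_weights).
_WEIGHT_FLOOR = 1e-300


def information_content(probability: float) -> float:
    """Surprise of an outcome with the given probability, in bits.

    ``-log2(p)``; p must lie in (0, 1].  With alpha > 0 every mixture
    probability is strictly positive, so this never sees p == 0.
    """
    if not 0.0 < probability <= 1.0:
        raise ValueError(f"probability must be in (0, 1], got {probability}")
    return -math.log2(probability)


class MixtureState:
    """Weights and forgetting factor for a fixed set of expert models.

    Parameters
    ----------
    models : sequence of FcmModel
        The K experts, typically of increasing order.
    gamma : float
        Forgetting factor in (0, 1].  1 means no forgetting (exact Bayesian
        weights); smaller values emphasize recent performance.

    Invariants: weights start uniform at 1/K, stay strictly positive, and
    sum to 1 after every update.
    """

    __slots__ = ("models", "weights", "gamma", "n")

    def __init__(self, models: Sequence[FcmModel], gamma: float = 0.99):
        if not models:
            raise ValueError("mixture needs at least one model")
        if not 0.0 < gamma <= 1.0:
            raise ValueError(f"gamma must be in (0, 1], got {gamma}")
        self.models = list(models)
        self.gamma = float(gamma)
        self.weights = np.full(len(self.models), 1.0 / len(self.models))
        self.n = 0

    def mix(self, per_model_probs: Sequence[np.ndarray]) -> np.ndarray:
        """Convex combination ``sum_k w_k * P_k`` of per-model 4-vectors."""
        if len(per_model_probs) != len(self.models):
            raise ValueError(
                f"expected {len(self.models)} probability vectors, "
                f"got {len(per_model_probs)}"
            )
        return self.weights @ np.asarray(per_model_probs, dtype=np.float64)

    def update_weights(
        self, per_model_probs: Sequence[np.ndarray], observed: int
    ) -> "MixtureState":
        """Re-weight the experts after observing one symbol.

        ``per_model_probs`` must be the estimates computed for this position
        *before* any count update (causal ordering).  Returns ``self``.
        """
        if len(per_model_probs) != len(self.models):
            raise ValueError(
                f"expected {len(self.models)} probability vectors, "
                f"got {len(per_model_probs)}"
            )
        p_obs = np.array([p[observed] for p in per_model_probs], dtype=np.float64)
        w = self.weights**self.gamma * p_obs
        w /= w.sum()
        # Representability guard: under a sustained extreme likelihood ratio r
        # the recursion's stationary weight is exp(ln r / (1-gamma)), which
        # can pass below the double-precision range and stick at exactly 0,
        # permanently eliminating the expert.  Clamping at 1e-300 keeps every
        # weight positive and recoverable while perturbing the update by far
        # less than its 1e-10 contract.
        self.weights = np.maximum(w, _WEIGHT_FLOOR)
        self.n += 1
        return self


class PerModelPerformance:
    """Running per-symbol information average of each expert, bits/symbol.

    After n symbols, entry k holds ``-(1/n) * sum_i log2 P_k(x_i)`` — the
    code length model k alone would have needed, a diagnostic of how each
    depth is performing on the sequence so far.
    """

    __slots__ = ("avg_info", "n")

    def __init__(self, n_models: int):
        self.avg_info = np.zeros(n_models)
        self.n = 0

    def update(
        self, per_model_probs: Sequence[np.ndarray], observed: int
    ) -> "PerModelPerformance":
        """Fold in the probabilities each model gave the observed symbol."""
        info = np.array(
            [-math.log2(p[observed]) for p in per_model_probs], dtype=np.float64
        )
        self.n += 1
        self.avg_info += (info - self.avg_info) / self.n
        return self
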