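"""Naive reference implementations used as independent oracles.

Everything here is written the slow, obvious way — explicit loops,
contexts as tuples of symbols in plain dictionaries, probabilities from
the defining formulas — and deliberately shares no code with the package's
streaming engine.
"""

from __future__ import annotations

import math

import numpy as np

CODE = {"A": 0, "C": 1, "G": 2, "T": 3}


def naive_profile(seq: str, depths, alphas, gamma: float) -> list[float]:
    """Per-position information of the mixture, by direct evaluation.

    Estimator: P(s|c) = (N(s|c) + a) / (N(c) + 4a), uniform while the
    context is not yet full.  Mixture: sum_k w_k P_k.  Weight recursion:
    w_k <- w_k^gamma * P_k(observed), renormalized.  Non-ACGT positions
    yield NaN and clear the context history.
    """
    K = len(depths)
    counts = [dict() for _ in depths]  # tuple(context) -> [nA,nC,nG,nT]
    w = [1.0 / K] * K
    hist: list[int] = []
    out: list[float] = []
    for ch in seq:
        x = CODE.get(ch.upper(), -1)
        if x < 0:
            out.append(float("nan"))
            hist = []
            continue
        probs = []
        for k in range(K):
            d, a = depths[k], alphas[k]
            if len(hist) >= d:
                ctx = tuple(hist[-d:])
                vec = counts[k].get(ctx, [0, 0, 0, 0])
                p = (vec[x] + a) / (sum(vec) + 4 * a)
            else:
                p = 0.25
            probs.append(p)
        pmix = sum(w[k] * probs[k] for k in range(K))
        out.append(-math.log2(pmix))
        w = [w[k] ** gamma * probs[k] for k in range(K)]
        total = sum(w)
        w = [v / total for v in w]
        for k in range(K):
            d = depths[k]
            if len(hist) >= d:
                ctx = tuple(hist[-d:])
                vec = counts[k].setdefault(ctx, [0, 0, 0, 0])
                vec[x] += 1
        hist.append(x)
    return out


def batch_posterior_log(seq: str, depths, alphas) -> np.ndarray:
    """Posterior model weights after the whole sequence, in log-space.

    Each model accumulates its own log2-likelihood sum log2 P_k(x_i)
    (estimate-then-count, independently of any mixture), and the posterior
    is exp-normalized under uniform priors.  This is the no-forgetting
    batch computation the streaming gamma=1 recursion must reproduce.
    """
    K = len(depths)
    loglik = np.zeros(K)
    counts = [dict() for _ in depths]
    hist: list[int] = []
    for ch in seq:
        x = CODE[ch.upper()]
        for k in range(K):
            d, a = depths[k], alphas[k]
            if len(hist) >= d:
                ctx = tuple(hist[-d:])
                vec = counts[k].get(ctx, [0, 0, 0, 0])
                p = (vec[x] + a) / (sum(vec) + 4 * a)
            else:
                p = 0.25
            loglik[k] += math.log2(p)
            if len(hist) >= d:
                vec = counts[k].setdefault(ctx, [0, 0, 0, 0])
                vec[x] += 1
        hist.append(x)
    # exp-normalize stably
    shifted = loglik - loglik.max()
    post = np.exp2(shifted)
    return post / post.sum()


def random_dna(n: int, seed: int) -> str:
    rng = np.random.default_rng(seed)
    return "".join("ACGT"[c] for c in rng.integers(0, 4, n))
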