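"""Order-k finite-context (Markov) models over the 2-bit DNA alphabet.

A finite-context model of order ``k`` predicts the next base from the ``k``
most recent bases.  Conditional counts ``N(s|c)`` are accumulated while the
sequence is processed and turned into probabilities with the additive
estimator

    P(s|c) = (N(s|c) + alpha) / (N(c) + 4*alpha),

where ``N(c) = sum_s N(s|c)``.  ``alpha`` interpolates between the
maximum-likelihood estimator (alpha -> 0, or N(c) large) and the uniform
distribution (alpha -> inf); ``alpha = 1`` is the Laplace estimator.

Counts are stored sparsely, keyed by the 2-bit packing of the context, so
memory grows with the number of *distinct* contexts actually seen — at most
``min(L, 4**k)`` after ``L`` symbols — never with the dense ``4**k`` state
space (infeasible for k = 16).
"""

from __future__ import annotations

from typing import Iterator, Mapping, Sequence

import numpy as np

__all__ = [
    "SYMBOLS",
    "A",
    "C",
    "G",
    "T",
    "OrderMismatchError",
    "encode",
    "decode",
    "complement_codes",
    "Context",
    "FcmModel",
]

#: Alphabet in 2-bit code order.  A=0, C=1, G=2, T=3; complement is 3 - code.
SYMBOLS = "ACGT"
A, C, G, T = range(4)

# 256-entry lookup: ASCII byte -> 2-bit code, -1 for anything not ACGT/acgt.
_CODE_TABLE = np.full(256, -1, dtype=np.int8)
for _i, _ch in enumerate(SYMBOLS):
    _CODE_TABLE[ord(_ch)] = _i
    _CODE_TABLE[ord(_ch.lower())] = _i


class OrderMismatchError(ValueError):
    """A context of the wrong order was passed to a model."""


def encode(sequence: str) -> np.ndarray:
    """Map a nucleotide string to int8 codes 0-3, with -1 for non-ACGT.

    Case-insensitive.  IUPAC ambiguity codes (N, R, Y, ...) and any other
    character map to -1; downstream stages treat those positions as masked.
    """
    try:
        raw = sequence.encode("ascii")
    except UnicodeEncodeError as exc:
        raise ValueError(f"non-ASCII character in sequence: {exc}") from None
    return _CODE_TABLE[np.frombuffer(raw, dtype=np.uint8)]


def decode(codes: Sequence[int]) -> str:
    """Inverse of :func:`encode`; code -1 becomes ``N``."""
    return "".join("N" if c < 0 else SYMBOLS[c] for c in codes)


def complement_codes(codes: np.ndarray) -> np.ndarray:
    """Watson-Crick complement in code space (A<->T, C<->G); -1 stays -1."""
    out = 3 - codes
    out[codes < 0] = -1
    return out


class Context:
    """The ``k`` most recent symbols, packed 2 bits each into an integer.

    ``packed`` holds the symbols with the most recent one in the lowest two
    bits; pushing a new symbol shifts in 2 bits and drops the oldest 2 bits,
    a constant-time update.
    """

    __slots__ = ("order", "packed")

    def __init__(self, order: int, packed: int = 0):
        if order < 1:
            raise ValueError(f"context order must be >= 1, got {order}")
        if not 0 <= packed < 4**order:
            raise ValueError(f"packed value {packed} out of range for order {order}")
        self.order = order
        self.packed = packed

    @classmethod
    def from_symbols(cls, symbols: Sequence[int]) -> "Context":
        """Build a context from the last ``len(symbols)`` codes (oldest first)."""
        packed = 0
        for s in symbols:
            packed = (packed << 2) | int(s)
        return cls(len(symbols), packed)

    def push(self, symbol: int) -> "Context":
        """Return the context after observing ``symbol`` (0-3)."""
        mask = (1 << (2 * self.order)) - 1
        return Context(self.order, ((self.packed << 2) | int(symbol)) & mask)

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, Context)
            and other.order == self.order
            and other.packed == self.packed
        )

    def __hash__(self) -> int:
        return hash((self.order, self.packed))

    def __repr__(self) -> str:
        syms = [(self.packed >> (2 * i)) & 3 for i in reversed(range(self.order))]
        return f"Context({''.join(SYMBOLS[s] for s in syms)!r})"


class FcmModel:
    """Sparse order-``k`` finite-context model with additive smoothing.

    Parameters
    ----------
    order : int
        Context depth ``k`` (number of conditioning bases).
    alpha : float
        Additive estimator parameter; must be positive.  ``alpha=1`` is the
        Laplace estimator.

    Notes
    -----
    Internally two hash maps are kept: ``(context << 2) | symbol -> N(s|c)``
    and ``context -> N(c)``.  A context never seen yields the uniform
    distribution, because ``N(s|c) = N(c) = 0`` reduces the estimator to
    ``alpha / (4*alpha)``.
    """

    __slots__ = ("order", "alpha", "_counts", "_totals", "_frozen")

    def __init__(self, order: int, alpha: float = 1.0):
        if order < 1:
            raise ValueError(f"model order must be >= 1, got {order}")
        if not alpha > 0:
            raise ValueError(f"alpha must be > 0, got {alpha}")
        self.order = int(order)
        self.alpha = float(alpha)
        self._counts: dict[int, int] = {}
        self._totals: dict[int, int] = {}
        self._frozen = False

    # -- construction helpers -------------------------------------------------

    @classmethod
    def from_counts(
        cls, order: int, alpha: float, counts: Mapping[int, Sequence[int]]
    ) -> "FcmModel":
        """Build a model from ``{packed_context: (nA, nC, nG, nT)}``."""
        model = cls(order, alpha)
        for ctx, vec in counts.items():
            if not 0 <= ctx < 4**order:
                raise ValueError(f"context {ctx} out of range for order {order}")
            if len(vec) != 4 or any(v < 0 for v in vec):
                raise ValueError(f"count vector for context {ctx} must be 4 non-negatives")
            total = 0
            base = ctx << 2
            for s, v in enumerate(vec):
                if v:
                    model._counts[base | s] = int(v)
                total += int(v)
            if total:
                model._totals[ctx] = total
        return model

    # -- core operations ------------------------------------------------------

    def estimate(self, context: Context) -> np.ndarray:
        """Next-symbol probability 4-vector ``P(.|context)``.

        Raises
        ------
        OrderMismatchError
            If ``context.order`` differs from the model order.
        """
        if context.order != self.order:
            raise OrderMismatchError(
                f"context order {context.order} != model order {self.order}"
            )
        total = self._totals.get(context.packed)
        if total is None:
            return np.full(4, 0.25)
        a = self.alpha
        den = total + 4.0 * a
        get = self._counts.get
        base = context.packed << 2
        return np.array(
            [(get(base | s, 0) + a) / den for s in range(4)], dtype=np.float64
        )

    def update(self, context: Context, symbol: int) -> "FcmModel":
        """Record one occurrence of ``symbol`` after ``context``.

        The caller's contract is estimate-then-update: the probability of a
        symbol is computed *before* that symbol is counted.  A frozen model
        ignores updates.  Returns ``self``.
        """
        if context.order != self.order:
            raise OrderMismatchError(
                f"context order {context.order} != model order {self.order}"
            )
        if self._frozen:
            return self
        if not 0 <= symbol <= 3:
            raise ValueError(f"symbol code must be 0-3, got {symbol}")
        key = (context.packed << 2) | symbol
        self._counts[key] = self._counts.get(key, 0) + 1
        self._totals[context.packed] = self._totals.get(context.packed, 0) + 1
        return self

    def freeze(self) -> "FcmModel":
        """Return a model with the same statistics that ignores updates.

        The frozen model shares count storage with the source; the usual
        workflow trains, freezes, and discards the trainable handle.
        """
        frozen = FcmModel.__new__(FcmModel)
        frozen.order = self.order
        frozen.alpha = self.alpha
        frozen._counts = self._counts
        frozen._totals = self._totals
        frozen._frozen = True
        return frozen

    # -- introspection --------------------------------------------------------

    @property
    def frozen(self) -> bool:
        return self._frozen

    @property
    def n_contexts(self) -> int:
        """Number of distinct contexts stored (<= min(symbols seen, 4**k))."""
        return len(self._totals)

    def total_count(self, context: Context) -> int:
        """``N(c)`` for a context (0 if never seen)."""
        if context.order != self.order:
            raise OrderMismatchError(
                f"context order {context.order} != model order {self.order}"
            )
        return self._totals.get(context.packed, 0)

    def iter_counts(self) -> Iterator[tuple[int, tuple[int, int, int, int]]]:
        """Yield ``(packed_context, (nA, nC, nG, nT))`` for stored contexts."""
        get = self._counts.get
        for ctx in sorted(self._totals):
            base = ctx << 2
            yield ctx, tuple(get(base | s, 0) for s in range(4))

    def spawn_empty(self) -> "FcmModel":
        """Fresh trainable model with the same order and alpha."""
        return FcmModel(self.order, self.alpha)

    def __repr__(self) -> str:
        state = "frozen" if self._frozen else "live"
        return (
            f"FcmModel(order={self.order}, alpha={self.alpha}, "
            f"contexts={self.n_contexts}, {state})"
        )
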