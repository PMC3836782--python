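"""Information-profile pipeline: bidirectional scan, min-combine, smooth.

A profile run processes a sequence once per direction.  Each pass streams
left to right; at every valid position the K finite-context models estimate
the next base, the estimates are mixed with the current weights, the
information content -log2 P(observed) is recorded, the weights absorb the
outcome through the forgetting recursion, and only then are the counts
updated (the model never sees the symbol it is predicting).  The reversed
pass repeats this on the reversed sequence with fresh statistics and is
flipped back into genomic coordinates; the final profile takes the
per-position minimum of the two passes, which removes the directional bias
of one-sided context modelling (a repeat's first copy is surprising scanned
forward but predictable scanned backward from its second copy).

Non-ACGT characters (N runs, IUPAC ambiguity codes) are masked: no
estimate, no count update, and the context register is reset so no context
ever spans a gap.  The profile is then low-pass filtered with a Blackman
window — masked positions are excluded from each window placement and the
remaining taps renormalized — and finally subsampled on a fixed grid for
compact genome-browser tracks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy.signal import oaconvolve

from .fcm import FcmModel, complement_codes, encode

__all__ = [
    "DEFAULT_DEPTHS",
    "DEFAULT_GAMMA",
    "DEFAULT_WINDOW",
    "DEFAULT_STEP",
    "default_alphas",
    "ProfileConfig",
    "InformationProfile",
    "ProfileSamples",
    "profile",
    "profile_one_direction",
    "combine_min",
    "blackman_taps",
    "smooth",
    "subsample",
    "conditional_profile",
    "train_models",
]

DEFAULT_DEPTHS = (2, 4, 6, 8, 10, 12, 14, 16)
DEFAULT_GAMMA = 0.99
DEFAULT_WINDOW = 1001
DEFAULT_STEP = 20

#: Direction policies: single direct pass, single reversed pass, or the
#: per-position minimum of both (the default, as published profiles use).
_DIRECTIONS = ("direct", "reversed", "min")
_DIRECTION_ALIASES = {"both": "min", "min_of_both": "min"}


def default_alphas(depths: Sequence[int]) -> dict[int, float]:
    """Default estimator parameter per depth: 1 up to k=12, 1/16 above.

    Deep contexts are sparse — most are seen a handful of times — so a
    smaller alpha lets a few observations move the estimate away from
    uniform quickly, which is what makes k=14/16 models light up on long
    repeats.
    """
    return {d: (1.0 / 16.0 if d >= 14 else 1.0) for d in depths}


@dataclass(frozen=True)
class ProfileConfig:
    """Full parameter set of a profile run.

    Attributes
    ----------
    depths : strictly increasing context orders of the K experts.
    alphas : per-depth estimator parameter; missing depths get the default.
    gamma : forgetting factor in (0, 1].
    window : odd Blackman smoothing length in bp (1 disables smoothing).
    sample_step : subsampling grid step in bp.
    direction : "direct", "reversed" or "min" (minimum of both passes).
    revcomp : if True the reversed pass uses the reverse complement instead
        of the plain reversed character sequence.
    """

    depths: tuple[int, ...] = DEFAULT_DEPTHS
    alphas: Mapping[int, float] | None = None
    gamma: float = DEFAULT_GAMMA
    window: int = DEFAULT_WINDOW
    sample_step: int = DEFAULT_STEP
    direction: str = "min"
    revcomp: bool = False

    def __post_init__(self):
        depths = tuple(int(d) for d in self.depths)
        if not depths or any(d < 1 for d in depths):
            raise ValueError("depths must be positive integers")
        if any(b <= a for a, b in zip(depths, depths[1:])):
            raise ValueError(f"depths must be strictly increasing, got {depths}")
        object.__setattr__(self, "depths", depths)
        alphas = dict(default_alphas(depths))
        if self.alphas:
            for k, a in self.alphas.items():
                if int(k) not in alphas:
                    raise ValueError(f"alpha given for depth {k} not in {depths}")
                if not a > 0:
                    raise ValueError(f"alpha must be > 0, got {a} for depth {k}")
                alphas[int(k)] = float(a)
        object.__setattr__(self, "alphas", alphas)
        if not 0.0 < self.gamma <= 1.0:
            raise ValueError(f"gamma must be in (0, 1], got {self.gamma}")
        if self.window < 1 or self.window % 2 == 0:
            raise ValueError(f"window must be odd and >= 1, got {self.window}")
        if self.sample_step < 1:
            raise ValueError(f"sample_step must be >= 1, got {self.sample_step}")
        direction = _DIRECTION_ALIASES.get(self.direction, self.direction)
        if direction not in _DIRECTIONS:
            raise ValueError(
                f"direction must be one of {_DIRECTIONS} (or 'both'), "
                f"got {self.direction!r}"
            )
        object.__setattr__(self, "direction", direction)

    def make_models(self) -> list[FcmModel]:
        """Fresh, empty experts for one pass."""
        return [FcmModel(d, self.alphas[d]) for d in self.depths]

    def to_dict(self) -> dict:
        return {
            "depths": list(self.depths),
            "alphas": {str(k): v for k, v in sorted(self.alphas.items())},
            "gamma": self.gamma,
            "window": self.window,
            "sample_step": self.sample_step,
            "direction": self.direction,
            "revcomp": self.revcomp,
        }


@dataclass
class InformationProfile:
    """Per-base information values of one sequence, in genomic order.

    ``values[i]`` is the information (bits) of base i; masked (non-ACGT)
    positions hold NaN and are False in ``mask``.  ``direction`` records
    which pass(es) produced the values; ``smoothed_window`` is the Blackman
    length applied, or None for a raw profile.
    """

    sequence_id: str
    values: np.ndarray
    mask: np.ndarray
    config: ProfileConfig | None = None
    direction: str = "min"
    smoothed_window: int | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.shape != self.mask.shape:
            raise ValueError("values and mask must have identical shape")

    def __len__(self) -> int:
        return len(self.values)

    def mean(self) -> float:
        """Mean information over unmasked positions, bits/base."""
        if not self.mask.any():
            return math.nan
        return float(self.values[self.mask].mean())


@dataclass
class ProfileSamples:
    """Profile values on a fixed 1-based grid (positions 1, 1+step, ...).

    Masked grid points carry NaN; writers turn them into track gaps.
    """

    sequence_id: str
    step: int
    positions: np.ndarray
    values: np.ndarray
    sequence_length: int = 0

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.positions.shape != self.values.shape:
            raise ValueError("positions and values must have identical shape")


# ---------------------------------------------------------------------------
# Core streaming pass
# ---------------------------------------------------------------------------


def _scan(
    codes,
    models: Sequence[FcmModel],
    gamma: float,
) -> np.ndarray:
    """One left-to-right pass of the mixture; returns per-position bits.

    ``codes`` is a Python list of int codes (0-3, negative = masked).  The
    models' count tables are read and, unless a model is frozen, updated in
    place.  Per position: estimate -> mix -> record -> update weights ->
    update counts, in that order.  Positions where a model's context is not
    yet full (start of sequence, or after a masked run) get the uniform
    estimate from that model and no count update.

    This loop touches every base of every chromosome, so it is written
    against the models' internal hash maps with pre-bound methods rather
    than through the per-call `estimate`/`update` API; the two are kept
    equivalent by the streaming-vs-reference test suite.
    """
    K = len(models)
    n = len(codes)
    depths = [m.order for m in models]
    alphas = [m.alpha for m in models]
    alpha4 = [4.0 * a for a in alphas]
    masks = [(1 << (2 * d)) - 1 for d in depths]
    counts = [m._counts for m in models]
    totals = [m._totals for m in models]
    cget = [c.get for c in counts]
    tget = [t.get for t in totals]
    train = [not m.frozen for m in models]
    krange = range(K)

    w = [1.0 / K] * K
    p = [0.25] * K
    ctx = [0] * K
    run = 0
    out = [math.nan] * n
    log2 = math.log2

    for i in range(n):
        s = codes[i]
        if s < 0:
            run = 0
            for k in krange:
                ctx[k] = 0
            continue
        # estimate + mix (old weights), and start the weight update
        pmix = 0.0
        if gamma == 1.0:
            for k in krange:
                if run >= depths[k]:
                    c = ctx[k]
                    t = tget[k](c)
                    if t is None:
                        pk = 0.25
                    else:
                        a = alphas[k]
                        pk = (cget[k]((c << 2) | s, 0) + a) / (t + alpha4[k])
                else:
                    pk = 0.25
                p[k] = pk
                wk = w[k]
                pmix += wk * pk
                w[k] = wk * pk
        else:
            for k in krange:
                if run >= depths[k]:
                    c = ctx[k]
                    t = tget[k](c)
                    if t is None:
                        pk = 0.25
                    else:
                        a = alphas[k]
                        pk = (cget[k]((c << 2) | s, 0) + a) / (t + alpha4[k])
                else:
                    pk = 0.25
                p[k] = pk
                wk = w[k]
                pmix += wk * pk
                w[k] = wk**gamma * pk
        out[i] = -log2(pmix)
        # renormalize weights
        tot = 0.0
        for k in krange:
            tot += w[k]
        inv = 1.0 / tot
        for k in krange:
            wk = w[k] * inv
            # same representability guard as MixtureState.update_weights
            w[k] = wk if wk > 1e-300 else 1e-300
        # count update + context shift
        for k in krange:
            d = depths[k]
            if run >= d and train[k]:
                c = ctx[k]
                key = (c << 2) | s
                ck = counts[k]
                ck[key] = ck.get(key, 0) + 1
                tk = totals[k]
                tk[c] = tk.get(c, 0) + 1
            ctx[k] = ((ctx[k] << 2) | s) & masks[k]
        run += 1

    return np.asarray(out, dtype=np.float64)


def _as_codes(sequence) -> np.ndarray:
    if isinstance(sequence, np.ndarray):
        return sequence.astype(np.int8, copy=False)
    if hasattr(sequence, "residues"):  # SequenceRecord
        return encode(sequence.residues)
    return encode(str(sequence))


def _seq_id(sequence, default: str = "seq") -> str:
    return getattr(sequence, "id", default)


def profile_one_direction(
    sequence,
    config: ProfileConfig | None = None,
    pretrained: Sequence[FcmModel] | None = None,
    reverse: bool = False,
) -> InformationProfile:
    """Single-pass profile of a sequence, in genomic coordinates.

    With ``reverse=True`` the pass runs over the reversed (or, if
    ``config.revcomp``, reverse-complemented) sequence and the result is
    flipped back, so values always line up with the input orientation.
    Statistics start empty, or from ``pretrained`` models (which are frozen
    for the duration of the pass: counts stay fixed, weights stay live).
    """
    config = config or ProfileConfig()
    codes = _as_codes(sequence)
    if codes.size == 0:
        raise ValueError("cannot profile an empty sequence")
    if pretrained is not None:
        if tuple(m.order for m in pretrained) != config.depths:
            raise ValueError(
                "pretrained model depths "
                f"{tuple(m.order for m in pretrained)} != config depths "
                f"{config.depths}"
            )
        models = [m.freeze() for m in pretrained]
    else:
        models = config.make_models()
    scan_codes = codes[::-1] if reverse else codes
    if reverse and config.revcomp:
        scan_codes = complement_codes(scan_codes)
    info = _scan(scan_codes.tolist(), models, config.gamma)
    if reverse:
        info = info[::-1]
    return InformationProfile(
        sequence_id=_seq_id(sequence),
        values=info,
        mask=codes >= 0,
        config=config,
        direction="reversed" if reverse else "direct",
    )


def combine_min(
    direct: InformationProfile, reversed_flipped: InformationProfile
) -> InformationProfile:
    """Per-position minimum of the two directional profiles.

    Both profiles must be in genomic coordinates and of equal length; the
    output mask is the AND of the inputs' masks.
    """
    if len(direct) != len(reversed_flipped):
        raise ValueError(
            f"profile lengths differ: {len(direct)} vs {len(reversed_flipped)}"
        )
    mask = direct.mask & reversed_flipped.mask
    values = np.where(
        mask, np.fmin(direct.values, reversed_flipped.values), np.nan
    )
    return InformationProfile(
        sequence_id=direct.sequence_id,
        values=values,
        mask=mask,
        config=direct.config,
        direction="min",
    )


def blackman_taps(window: int) -> np.ndarray:
    """Blackman window of odd length M: 0.42 - 0.5 cos + 0.08 cos(2·).

    The analytic endpoints are exactly 0 (0.42 - 0.5 + 0.08); they are
    clamped to 0.0 here because the floating evaluation leaves a ~1e-17
    residue, negative on some platforms, which would put meaningless
    near-zero weights at the window edges.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError(f"smoothing window must be odd and >= 1, got {window}")
    taps = np.blackman(window)
    if window > 1:
        taps[0] = taps[-1] = 0.0
    return taps


def smooth(info: InformationProfile, window: int | None = None) -> InformationProfile:
    """Low-pass filter with a Blackman window, excluding masked positions.

    The Blackman taps are ``0.42 - 0.5 cos(2 pi m/(M-1)) + 0.08 cos(4 pi
    m/(M-1))`` for m = 0..M-1 (endpoints exactly 0).  At each placement the
    weighted average runs over the unmasked taps only and is renormalized
    to their sum, so edges and track gaps keep the output on the scale of
    the input and constants are preserved.  Masked positions stay masked.
    """
    if window is None:
        window = info.config.window if info.config else DEFAULT_WINDOW
    if window < 1 or window % 2 == 0:
        raise ValueError(f"smoothing window must be odd and >= 1, got {window}")
    if window == 1:
        return replace(info, values=info.values.copy(), smoothed_window=1)
    taps = blackman_taps(window)
    mask_f = info.mask.astype(np.float64)
    num = oaconvolve(np.where(info.mask, info.values, 0.0), taps, mode="same")
    den = oaconvolve(mask_f, taps, mode="same")
    values = np.full(len(info), np.nan)
    valid = info.mask & (den > 0)
    values[valid] = num[valid] / den[valid]
    return replace(info, values=values, smoothed_window=window)


def subsample(info: InformationProfile, step: int | None = None) -> ProfileSamples:
    """Values on the fixed grid 1, 1+step, 1+2*step, ... (1-based).

    Masked grid points are emitted with NaN so that writers can represent
    them as gaps.
    """
    if step is None:
        step = info.config.sample_step if info.config else DEFAULT_STEP
    if step < 1:
        raise ValueError(f"sample step must be >= 1, got {step}")
    idx = np.arange(0, len(info), step)
    return ProfileSamples(
        sequence_id=info.sequence_id,
        step=step,
        positions=idx + 1,
        values=info.values[idx],
        sequence_length=len(info),
    )


def profile(
    sequence,
    config: ProfileConfig | None = None,
    smooth_window: int | None = None,
) -> InformationProfile:
    """Full pipeline for one sequence: directional passes, min, smoothing.

    Each directional pass starts from empty statistics.  The returned
    profile is smoothed with ``config.window`` (override with
    ``smooth_window``; 1 disables smoothing).  Runtime is linear in the
    sequence length; memory is bounded by the number of distinct contexts.
    """
    config = config or ProfileConfig()
    if config.direction in ("direct", "min"):
        fwd = profile_one_direction(sequence, config)
    if config.direction in ("reversed", "min"):
        rev = profile_one_direction(sequence, config, reverse=True)
    if config.direction == "direct":
        combined = fwd
    elif config.direction == "reversed":
        combined = rev
    else:
        combined = combine_min(fwd, rev)
    return smooth(combined, smooth_window if smooth_window is not None else config.window)


def train_models(
    sequence, config: ProfileConfig | None = None, reverse: bool = False
) -> list[FcmModel]:
    """Accumulate counts of all configured depths over a training sequence.

    One streaming pass in the requested orientation; the returned models
    are live (freeze them, or pass them as ``pretrained``, for conditional
    profiling).  Mixture weights produced during training are discarded —
    counts do not depend on them.
    """
    config = config or ProfileConfig()
    codes = _as_codes(sequence)
    if codes.size == 0:
        raise ValueError("cannot train on an empty sequence")
    models = config.make_models()
    scan_codes = codes[::-1] if reverse else codes
    if reverse and config.revcomp:
        scan_codes = complement_codes(scan_codes)
    _scan(scan_codes.tolist(), models, config.gamma)
    return models


def conditional_profile(
    reference,
    target,
    config: ProfileConfig | None = None,
    pretrained: Mapping[str, Sequence[FcmModel]] | None = None,
) -> InformationProfile:
    """Profile of ``target`` using statistics trained on ``reference``.

    The models are trained over the reference (one pass per configured
    direction), frozen, and then run over the target with live mixture
    weights.  Baseline-flat regions mark sequence shared with the
    reference; peaks mark divergence.  Smoothing and the min combination
    follow the ordinary pipeline.  ``pretrained`` (as returned by
    :func:`train_models` per direction, e.g. a loaded model container)
    skips the training pass.
    """
    config = config or ProfileConfig()
    need_fwd = config.direction in ("direct", "min")
    need_rev = config.direction in ("reversed", "min")
    if pretrained is None:
        ref_codes = _as_codes(reference)
        if ref_codes.size == 0:
            raise ValueError("cannot train on an empty reference")
        pretrained = {}
        if need_fwd:
            pretrained["direct"] = train_models(reference, config)
        if need_rev:
            pretrained["reversed"] = train_models(reference, config, reverse=True)
    if need_fwd:
        fwd = profile_one_direction(target, config, pretrained=pretrained["direct"])
    if need_rev:
        rev = profile_one_direction(
            target, config, pretrained=pretrained["reversed"], reverse=True
        )
    if config.direction == "direct":
        combined = fwd
    elif config.direction == "reversed":
        combined = rev
    else:
        combined = combine_min(fwd, rev)
    return smooth(combined, config.window)
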