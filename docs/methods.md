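# Methods

## The information profile

`infoprofile` turns a DNA sequence into a per-base signal of local
complexity.  The signal at position *i* is the information content, in
bits, of base *x_i* under a probabilistic model that has seen only the
sequence up to *i*:

    I(i) = -log2 P(x_i | x_1 ... x_{i-1})

Random, high-entropy DNA costs close to 2 bits per base (four equiprobable
symbols); sequence the model has effectively seen before — tandem repeat
arrays, dispersed transposon copies, segmental duplications — costs far
less.  Plotted along the chromosome, low-information valleys flag
repetitive structure at whatever scale the smoothing window selects.

## The model: a mixture of finite-context experts

The predictor is a convex mixture of K order-k finite-context (Markov)
models, by default K = 8 with depths k = 2, 4, 6, 8, 10, 12, 14, 16.
Each expert estimates the next base from its conditional counts with
additive smoothing:

    P_k(s | c) = (N_k(s|c) + alpha_k) / (N_k(c) + 4 alpha_k)

where N_k(s|c) counts how often symbol s followed context c so far and
N_k(c) = sum_s N_k(s|c).  alpha interpolates between maximum likelihood
and the uniform distribution; alpha = 1 is the Laplace estimator.  Counts
are accumulated *causally*: each base is predicted before it is counted,
so the accounting is exactly the code length an adaptive arithmetic coder
would spend, without producing a bitstream.

The mixture is

    P(s) = sum_k w_k P_k(s),    sum_k w_k = 1,  w_k > 0,

with weights started uniform at 1/K and updated after every observed base
by exponential forgetting:

    w_k  <-  w_k^gamma * P_k(x_i),   renormalized.

With gamma = 1 the recursion is the exact Bayesian posterior over experts
under uniform priors (weight proportional to each model's accumulated
likelihood); with gamma < 1 old evidence decays geometrically with
half-life ~ log(2)/(1-gamma) bases, letting the mixture re-rank its
experts quickly when the sequence's character changes — genomic sequences
are strongly non-stationary, alternating high-entropy stretches (where
shallow models win) with repeats (where the deep models win).

### Default parameters

| parameter | default | meaning / rationale |
|---|---|---|
| depths | 2,4,6,8,10,12,14,16 | shallow experts model composition, deep experts memorize repeats; the published parameterization of the profiles this tool reproduces |
| alpha (k <= 12) | 1 | Laplace estimator; well-populated shallow contexts need no sharpening |
| alpha (k = 14, 16) | 1/16 | deep contexts are seen a handful of times; a small alpha lets a single prior occurrence pull the estimate sharply away from uniform. The exact published value is not legible in the source material; 1/16 follows the authors' related compression work and is configurable (`--alpha`) |
| gamma | 0.99 | forgetting half-life of ~70 bases; no published value exists, chosen as a mild forgetting that adapts within a repeat unit yet keeps megabase-scale stability; configurable (`--gamma`) |
| window | 1,001 bp (odd) | Blackman low-pass for chromosome-scale display; 10,001/100,001 for multi-megabase views |
| sample step | 20 bp | track decimation for browser display |
| direction | min of both | see below |

## Bidirectional processing

One-sided context modelling is direction-biased: the first copy of a
repeat looks random scanned forward, but perfectly predictable scanned
backward from its second copy.  The pipeline therefore runs the scan twice
with independent, fresh statistics — once 5'→3' and once over the reversed
sequence — flips the reversed result back into genomic coordinates, and
takes the per-position minimum.  "Reversed" means the reversed character
sequence, not the reverse complement: the quantity being symmetrized is
the direction of *processing* of one strand.  A `revcomp` option swaps in
the reverse complement for the second pass for users who want strandwise
copy detection instead.

Order of operations in each pass, per position: estimate → mix → record
-log2 P(observed) → update weights → update counts.  The estimator never
sees the symbol it is predicting.

Order of the post-processing: minimum first, then smoothing, then
subsampling.  (Smoothing the minimum, not the minimum of smoothed
profiles.)

## Non-ACGT handling

Any character outside {A,C,G,T} (case-insensitive) masks its position: no
estimate, no information value (NaN), no count update, and the context
register is cleared so that no context ever spans a masked run —
assembly gaps of N must not fabricate phantom contexts.  Masked positions
are excluded from smoothing windows and statistics and come out as track
gaps (a new `fixedStep` block in WIG, omitted intervals in bedGraph).

## Smoothing

The Blackman window w(m) = 0.42 - 0.5 cos(2πm/(M-1)) + 0.08 cos(4πm/(M-1))
is applied as a masked, per-placement-normalized weighted average: at each
position the average runs over the unmasked taps only, divided by their
tap-weight sum.  Consequences: constants are preserved (up to float
rounding, tested at 1e-9 relative), output never leaves the input range,
edges need no padding, and isolated valid positions keep finite values.
The analytic endpoints of the window are exactly 0; the floating
evaluation leaves a ~1e-17 residue (negative on some platforms), which is
clamped to 0 so the zero-endpoint identity holds exactly.  Convolution is
scipy's overlap-add (`oaconvolve`), which switches to FFT for the long
windows (100,001 bp) where direct convolution would dominate runtime.

## Conditional profiles

For comparative analysis the models can be trained over a *reference*
sequence (one full pass per direction), frozen, and then run over a
*target*.  Counts stay fixed; the mixture weights remain live and adapt
along the target, which is what localizes divergence: where the target
matches the reference the deep experts predict almost perfectly and
information is near 0; where it diverges their trained contexts either
vanish (estimates fall back to uniform, 2 bits) or contradict the
observed bases (estimates near 0, information >> 2 bits), so divergent
segments stand out as peaks.  Whether the original method also froze the
weights is not documented; freezing only the counts was chosen because
weight adaptation is precisely the mechanism that makes divergence local
rather than cumulative.

## Complexity contracts

One pass is a single left-to-right scan with O(1) work per model per base:
time is O(K·L) for sequence length L.  Counts live in hash maps keyed by
the 2-bit-packed context, so memory is O(distinct contexts) ≤
sum_k min(L, 4^k) — independent of L once the context spaces saturate,
and never the dense 4^16 ≈ 4.3·10^9 table a flat layout would need.
Counters are plain 64-bit integers with no rescaling; desk-scale sequences
cannot overflow them.

## Numerical choices

- **Warm-up**: for the first k valid positions (after sequence start or a
  masked run) an order-k expert returns the uniform vector and does not
  count; the behaviour at start of sequence is otherwise unspecified and
  this is the simplest well-defined rule.
- **Unseen contexts** yield the uniform distribution (N = 0 in the
  estimator), so mixture probabilities are bounded below by
  w_min·alpha-terms and information values are always finite.
- **Weight representability**: under a sustained likelihood ratio r
  between two experts, the forgetting recursion converges to a stationary
  weight exp(ln r/(1-gamma)); for extreme sustained ratios this passes
  below the double-precision range, and a weight that reaches exactly 0
  can never recover (0^gamma = 0).  After renormalization weights are
  therefore clamped at 1e-300 — twelve orders of magnitude above the
  subnormal range and ~290 below any probability an expert can emit, so
  the update is unchanged at any observable precision, but a suppressed
  expert can always re-enter when the sequence turns in its favour.
- **Ties** in the per-position minimum need no breaking (min is
  symmetric); `argmax` on smoothed profiles returns the first maximum.
- **Degenerate inputs**: empty sequences are rejected; sequences shorter
  than the deepest context simply stay in warm-up (every value 2 bits);
  all-masked sequences produce all-NaN profiles and header-only tracks.

## The synthetic generator

`infoprofile.synthetic` produces the test bed: i.i.d. uniform ACGT
background (optionally an order-m Markov chain with a user transition
matrix, to emulate composition bias), with planted features stamped on
top — tandem repeat arrays (e.g. 50 copies of GGTTAC, the ~300 bp
telomeric scale), dispersed near-identical copies (the ~4.9 kb LTR
retrotransposon scale, with i.i.d. substitution mutations), reverse-
complement copies, homopolymer runs, and N gaps.  Every run is
byte-deterministic for a fixed (spec, seed): a single PCG64 stream drives
background and mutations in feature-list order.  Copies mutate by
substitutions only, keeping truth BED coordinates exact; indels are
deliberately not modelled.

What passing the recovery tests shows — and what it does not: the
generator plants *exact-coordinate, recently-copied* structure on a
memoryless background.  Real genomes add diverged repeat families,
composition gradients, and indel-riddled copies; detection contrast there
will be lower than on these fixtures, and the tests quantify the
mechanism, not genome-wide sensitivity.  Reported problem sizes (200 kb
backgrounds, 10 kb copies, 20 replicates; a 0.5/1/2 Mbp ladder for the
timing contract) were chosen as the smallest scales at which the
megabase-scale claims are meaningfully exercised on a laptop-class single
core.

## Known limitations

- Pure-Python scan loop: ~8 µs/bp on one core (a few minutes per 10 Mbp
  per direction).  The algorithm is linear; the constant is the
  interpreter's.
- No inverted-repeat (reverse-complement) context modelling within a
  single pass; the `revcomp` pass option is a coarse substitute.
- No automatic peak/valley calling or significance model; the output is a
  signal for visual and downstream analysis.
- Model containers serialize counts as JSON; for very deep, very long
  trainings (hundreds of millions of distinct contexts) the container
  becomes large — it is a convenience for conditional workflows, not an
  archival format.
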