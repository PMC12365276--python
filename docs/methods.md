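# Methods

## The polynomial family

The package tabulates fractional-order Tchebichef polynomials
FrTₙᵅ(t) = Tₙ(1 − 2tᵅ) on t ∈ (0, 1), α > 0, three ways:

1. **Closed form** Σₖ βₙ,ₖ t^(αk) with
   βₙ,ₖ = (−1)ᵏ n 2²ᵏ (n+k−1)! / ((n−k)!(2k)!) and β₀,₀ = 1. The
   coefficients are alternating integers that reach ~10³⁵ by n = 30, so
   they are computed in exact integer arithmetic and the degree is capped
   at n = 30; past that the floating-point summation would cancel
   catastrophically anyway. This path is the oracle, not the production
   path.
2. **Plain recurrence** rowₙ₊₁ = (2 − 4tᵅ)·rowₙ − rowₙ₋₁ from rows 1 and
   1 − 2tᵅ.
3. **Normalized recurrence** on the weighted family
   √(w(t)/cₙ)·FrTₙᵅ(t), w(t) = t^(α/2−1)/√(1 − tᵅ), c₀ = 2, cₙ = 1
   (n ≥ 1): the same three-term step with a √c₀ = √2 factor on the n = 1
   step only. Note √w(t) = t^(α/4−1/2)(1 − tᵅ)^(−1/4); the fourth root in
   the second factor follows from w(t) itself and is what the
   implementation uses throughout.

**Grid.** The discretization of t is a free design choice; we use the
midpoint grid t_x = (x + ½)/N, clipped to [ε, 1 − ε] with ε = 10⁻⁶.
Midpoints keep every node strictly inside (0, 1), away from the weight
singularities at both ends, and make the tabulation symmetric. The clip
is a safeguard only — for N ≤ 5·10⁵ no midpoint reaches it.

## Orthogonalization

The tabulated weighted rows are only approximately orthogonal under the
discrete inner product, so an explicit QR step produces the analysis
basis. Two algorithms are provided over the same contract (A = QR,
orthonormal working vectors, upper-triangular R with non-negative
diagonal):

- `classical_gram_schmidt` — every projection coefficient taken against
  the original column; the reference oracle.
- `schwarz_rutishauser` — each column updated sequentially against each
  already-normalized predecessor (subtract, then compute the next inner
  product). Internally the loop is scheduled right-looking: when a column
  is finalized it updates all later columns in one vectorized pass, which
  applies the identical per-column update sequence at BLAS speed.

A column whose post-projection norm falls below 10⁻¹² of its
pre-projection norm raises a rank-deficiency error naming the column;
there is no pivoting or recovery path.

**Why the basis pipeline re-orthogonalizes.** Measured at α = 1 the
tabulated basis matrix has condition ≈ 6·10¹⁶ already at N = 64 and
~10¹⁸ at N = 512: high-degree weighted rows alias on the uniform grid and
become numerically dependent. Any single Gram-Schmidt sweep then loses
orthogonality in proportion to cond(A)·ε_machine — totally, in this
regime. `orthonormalize_basis` therefore runs the Schwarz-Rutishauser
sweep **twice** (the classic "twice is enough" re-orthogonalization),
which restores max|QᵀQ − I| to ~10⁻¹¹ at N = 1024 and makes the
forward/inverse transform pair exact to ~10⁻²⁵ relative MSE. The R
returned is the product of both sweeps' triangular factors. The
single-sweep `schwarz_rutishauser` remains available and is what the
stability comparisons exercise.

## Transforms

Moments are inner products with the rows of the orthonormalized basis;
synthesis is the transpose action. Because Gram-Schmidt is nested, the
order-K basis equals the first K+1 rows of the full-order one, so
truncating a full-order moment set and rebuilding at a lower `max_order`
agree, and truncated reconstruction is the orthogonal projection —
its MSE is non-increasing in K. The 2-D transform is separable on square
inputs (M = Q S Qᵀ, S = Qᵀ M Q) with one shared 1-D basis per axis;
no bivariate family is defined. Full-order factorizations are memoized
per (α, N, n_max, ε) since they are pure functions of the config.

## Watermarking

The embedding rule is quantization index modulation (QIM): a host
coefficient c carrying bit b becomes c′ = Δ·round(c/Δ − b/2) + Δ·b/2, so
the integer lattice carries 0 and the half-offset lattice carries 1, and
blind extraction reads the nearer lattice. QIM was chosen because it is
blind by construction, exact on a clean channel, and exposes one knob
(Δ) trading imperceptibility against robustness. Defaults:

- **Δ** = 0.01 × max|in-band coefficient|, computed at embed time and
  stored in the config for the extractor.
- **Hosts**: zigzag order over anti-diagonals n_lo ≤ i+j ≤ n_hi of the
  2-D moment matrix, DC excluded; default band (1, 8). An optional key
  (seed) shuffles the bit-to-host assignment.
- **FEC**: repetition-3 with majority vote — the simplest forward error
  correction consistent with blind extraction.
- **Capacity**: C = ⌊N/α⌋ raw bits (α here is the embedding-strength /
  spacing parameter, a different knob from the fractional order, which
  the config keeps as a separate field), further capped by the band size
  and divided by the repetition factor.

**Mappings.** `reshape` (default) fills the smallest square row-major
with zero padding and inverts by truncation — lossless, so the clean
round trip is exact. When N is not a perfect square, quantization
perturbs the padding region, which truncation then discards; `embed`
runs a bounded refinement (truncate → re-transform → re-snap, typically
1-3 iterations) until the retained samples are a fixed point of the
extraction pipeline, preserving exactness for padded lengths. `gasf`
(Gramian angular summation field, G[i,j] = cos(φᵢ + φⱼ),
φ = arccos of the min-max-normalized sample) is provided as the
alternative 2-D encoding, but its inverse reads only the diagonal and
discards off-diagonal watermark energy; extraction under it is
best-effort and is tested for well-formedness, not exactness.

## Metrics

MSE, PSNR (referenced to the signal's own peak, +∞ sentinel — serialized
as the string `"inf"` — for an exact match), PRD, BER (XOR rate), and
KLD/JSD. The divergences need distributions the signals do not come
with; the convention here is a 64-bin amplitude histogram over the
shared range of the pair, smoothed by 10⁻¹² per bin and renormalized,
with natural logarithms (units: nats; JSD ≤ ln 2).
`orthonormality_error` is max|QᵀQ − I| — the entrywise Chebyshev norm,
which does not inflate with dimension, so one tolerance is meaningful
from toy to desk-scale matrices.

## Synthetic data

The generators are the test substrate and define the study conditions:

- **ECG**: beats at 60 bpm (2% seeded beat-to-beat jitter), each beat
  five Gaussian bumps on the beat-phase axis (P, Q, R, S, T at phases
  0.18/0.27/0.30/0.33/0.55, amplitudes 0.12/−0.15/1.0/−0.20/0.30 R-peak
  units), plus a 0.05-amplitude 0.3 Hz baseline sine and white noise of
  sd 0.01; 360 Hz sampling.
- **EEG**: five random-frequency, random-phase tones per band with
  powers delta 1.0 / theta 0.5 / alpha 2.0 / beta 0.3 (alpha-dominant,
  as in relaxed wakefulness), over 1/f-shaped noise scaled to sd 0.01;
  256 Hz sampling.

They capture quasi-periodicity, band structure and noise floor — enough
to exercise reconstruction and watermarking — but not pathology, sensor
artifacts, or inter-patient variability, so passing tests demonstrate
numerical correctness of the transforms, not clinical adequacy on real
recordings. Real WFDB/EDF records can be windowed in through the
optional readers.

## Problem sizes

Default verification runs use N ∈ {256, 512, 1024} with 10 seeds per
condition for reconstruction, 50 seeded pairs for watermark round trips,
50 random matrices (8–256 columns) for the QR contract, and 20 seeds per
level for the trend checks — sizes at which every property is stable
across seeds while a full run stays interactive.

## Known limitations

- The analytic closed form is unusable past n ≈ 30 (by design, it
  raises); all production paths use recurrences.
- Near full order the raw basis is numerically rank-deficient; the
  re-orthogonalized Q is an orthonormal basis of the sample space whose
  trailing vectors are no longer accurate polynomial directions. Full-
  order reconstruction is unaffected (any orthonormal Q inverts
  exactly); interpretation of individual high-order moments is not
  meaningful in that regime.
- GASF watermark extraction is best-effort (diagonal-only inverse).
- 2-D transforms handle square inputs only.
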