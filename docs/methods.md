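# Methods

## Overview

`atacnuc` infers nucleosome architecture at base-pair resolution inside
open-chromatin regions from paired-end ATAC-seq fragments. The method rests
on two observations about Tn5 fragmentation of chromatin. First, the
adjusted fragment-size distribution is a mixture of a short, roughly
exponential nucleosome-free component and a structured nucleosomal component
centered near 143 bp. Second, fragments spanning a positioned nucleosome
arrange into a characteristic "V" in the two-dimensional histogram of
fragment size versus midpoint offset from the dyad, because a wrapped
nucleosome protects a minimum span of DNA. Cross-correlating a V-plot
template against per-locus fragment matrices scores every base as a
candidate dyad; a bias-aware background model calibrates those scores.

## Coordinate conventions

Tn5 inserts as a dimer with a 9-bp stagger, so the sequenced fragment ends
are offset from the centers of the two transposase binding sites. All
fragment records store 0-based half-open sequenced coordinates and derive

- `left_center = start + 4`, `right_center = (end - 1) - 4`,
- `adj_size = (end - start) - 8 = right_center - left_center + 1`.

Fragments whose sequenced span is shorter than 9 bp have no valid insertion
centers and are rejected (tallied, not fatal). Even adjusted sizes have a
half-integer midpoint; wherever midpoints are binned (V-plots, occupancy
windows, background matrices) the weight is split 0.5/0.5 across the two
flanking integer positions, which avoids a systematic half-base parity bias.
Exact (chrom, start, end) duplicates are collapsed by default with a flag to
disable, since duplicates dominate shallow PCR libraries; the policy is
exposed rather than hard-coded because it is a library-preparation question,
not a property of the model.

## Fragment-size mixture and occupancy

Sizes below a cutoff (default 115 bp) are treated as purely nucleosome-free
and fit with an exponential after shifting by the minimum observed size.
Two numerical details matter here:

- The fit is the maximum-likelihood estimate of a *truncated* exponential
  (solved by bracketed root finding on the mean identity
  `1/r - T·e^{-rT}/(1-e^{-rT}) = mean`). A naive `rate = 1/mean` on the
  truncated sample is biased by tens of percent when the truncation point is
  comparable to the mean, which it is here.
- Integer size bins stand for continuous intervals `[k, k+1)`, so half a
  base is added to the sample mean before solving (mid-bin continuity
  correction). Without it the recovered rate is ~3% high.

The fitted exponential is extrapolated over the full size range, scaled so
its sub-cutoff mass equals the observed sub-cutoff mass (i.e. assuming all
sub-cutoff fragments are nucleosome-free), and subtracted from the observed
distribution. The clipped positive remainder above the cutoff is the
nucleosomal component; both components are renormalized to sum to one. If
the remainder carries less than 1% of the library mass the fit aborts with
"no nucleosomal mode detectable" — clipped sampling noise alone stays well
under that level at realistic library sizes, while a genuine nucleosomal
mode carries tens of percent.

Occupancy α — the fraction of fragments at a locus drawn from the
nucleosomal component — is the MLE of the two-component mixture likelihood
for fragments whose midpoints fall within ±60 bp of each point of a 5-bp
grid. The log-likelihood is concave in α, so the estimator checks the
boundary gradients and otherwise solves the score equation by bracketed
root finding; a fragment size that is impossible under the current mixture
but possible under the other component forces an infinite gradient and is
handled explicitly. Confidence intervals are 90% profile-likelihood bounds
(log-likelihood drop 1.3528 = χ²₁(0.90)/2), chosen over Wald intervals
because they respect the [0, 1] bounds. Tracks of α and the CI bounds are
smoothed with a truncated Gaussian of 121-bp support and 20-bp sd and
clamped to [0, 1]. In MNase mode the mixture is unavailable (short fragments
are size-selected away) and occupancy is simply the count of fragment
midpoints within 60 bp of a position.

## Tn5 sequence bias

Tn5 contacts ~21 bp around its insertion point. The bias model is a 4×21
PWM over offsets −10..+10 from insertion centers observed in naked genomic
DNA, with a 0.5 pseudocount per cell, stored as log-odds against genome-wide
base frequencies (the raw-frequency/log-odds choice is not forced by the
method; log-odds make a flat model exactly zero, which is convenient for
testing and interpretation). Per-base insertion propensities are
`exp(Σ log-odds)` normalized to mean 1 over the analysed region — only
relative probabilities matter because the background is rescaled by the
observed fragment count. 21-mers containing ambiguous bases get the region
mean.

The fragment-level background matrix B (sizes 105–250 × midpoint offsets
−60..+60, ΣB = 1) multiplies the propensities of the two insertions a
fragment requires with the probability of its size under the library size
distribution. In MNase mode the bias model is disabled (sequence bias of a
processive nuclease is not modelled) and B reduces to `P(size)/121`:
fragments placed at random given the size law.

## V-plot template

The template aggregates (size, offset) weights of fragments around
well-positioned dyads, restricted to sizes 105–250 bp and offsets within
60 bp. Template dyads are filtered for a positioning score in the top 20%
and occupancy > 0.5. The template is symmetrized across the vertical axis,
smoothed with a 2D Gaussian (sd 1 bp, reflective boundary, mass conserved to
1e-6), and row-renormalized so each size row sums to the *target sample's*
nucleosomal fragment-size frequency. The target law is refined from the
data: fragments with midpoints within 60 bp of occupancy-track peaks
(local maxima with α ≥ 0.5, thinned to ≥ 120 bp apart). Rows empty in the
template but carrying target mass are filled uniformly so the row marginals
match the target law exactly; this row renormalization is what lets one
template transfer across samples and species with different size
distributions.

## Signal, background, Z and LLR

With F the fragment matrix at position x (same shape as V) and SumF its
total:

    Signal(x)     = F · V
    Background(x) = (B · V) · SumF
    Normalized(x) = Signal − Background
    var(Background) = SumF · (Σ b_k(1−b_k)v_k² − Σ_{k≠l} b_k b_l v_k v_l)

which is the variance of Σ n_k v_k under n ~ Multinomial(SumF, B). The
cross term is computed through the exact identity
`Σ_{k≠l} b_k b_l v_k v_l = (Σ b v)² − Σ b² v²`, reducing each position to
three inner products; this is pure algebra verified against a multinomial
Monte-Carlo oracle. Z divides the normalized signal by the *standard
deviation* (sqrt of the printed variance): dimensional consistency and the
interpretation of Z > 3 as a ~0.001 one-sided normal tail both require the
standard-normal scale. Per region all terms are computed as row-wise
cross-correlations, so a region of length L costs O(146·L) rather than
O(146·121·L).

The log-likelihood ratio at a candidate compares a multinomial over the
(size, offset) window under `p1 ∝ V∘B + ε` against `p0 ∝ B + ε`
(ε = 1e-9 floors zero cells before normalization). Multinomial rather than
Poisson was chosen because the window's fragment count is conditioned on,
not modelled.

## Calling dyads and NFRs

The normalized signal is smoothed with a mass-normalized truncated Gaussian
of 25-bp total support (sd = 25/6, the conventional support/sd relation;
the sd is otherwise unconstrained); candidates are strict local maxima of
(smoothed + original) where the original normalized signal is positive.
Flat plateaus yield their center (left-of-center on even plateaus). The
nonredundant map is built greedily: highest signal first, then the next
highest not within 120 bp (inclusive: |Δ| ≤ 120 excludes) of any retained
position, ties broken leftmost. Calls are kept when Z > 3 and LLR > 0, both
strict. Candidates that pass the thresholds but lose the greedy pass are
exported as the redundant map; they carry the rotational-positioning
information (satellite positions offset by multiples of ~10 bp).

NFRs: the candidate interval between two adjacent nonredundant calls is the
DNA outside both 147-bp footprints, `[left_dyad + 74, right_dyad − 74)`
(region edges bound terminal candidates). It is emitted when the smoothed
upper 90% occupancy CI dips below `occ_max` (default 0.1) somewhere inside
— a gap hiding an uncalled nucleosome never reaches nucleosome-free
occupancy — and the insertion density of sub-100-bp fragments is at least
`min_insertion_density` (default 0.01/bp), which distinguishes genuine
depletion from absence of data. Defining bounds by the flanking footprints
rather than by the occupancy dip itself avoids the ~20-bp inward blur the
±60-bp estimation window imposes on any threshold crossing.

## Concordance metrics and dinucleotide periodicity

Against a gold-standard dyad set: the distance AUC is the area under the
cumulative distribution of nearest-gold distances within 73 bp, normalized
to [0, 1] (computed exactly as the mean of `(73 − d)/73` over matched
calls); specificity is the fraction of test calls with a gold call within
25 bp; sensitivity the converse; rotational specificity the fraction of
test calls within 1 bp of the redundant gold set. "Within" is inclusive
(≤ d) throughout.

Dinucleotide profiles cover distances 19–60 bp from the dyad, averaged over
both sides; because calls are unstranded the upstream step is read outward,
i.e. reverse-complemented. Each dinucleotide's profile is normalized by its
mean over the window. The power spectral density at 1/10.5 bp — the
helical-twist periodicity of nucleosomal DNA — is the squared modulus of
the direct complex-exponential projection of the mean-centered profile;
1/10.5 does not fall on an integer DFT bin for a 42-point series, so
nearest-bin FFT evaluation would be wrong. Mean-centering prevents DC
leakage into the target frequency.

## Synthetic data generator

The generator emulates the fragment structure the method assumes, not real
chromatin: a single random-sequence chromosome (default 6 kb, GC 0.4);
alternating arrays of planted dyads (165-bp spacing, ≥ 120 bp apart) and
140-bp NFR gaps; nucleosomal fragments with midpoints on a rotational
lattice (offsets 0, ±10, ±20 bp with weights 0.5, 0.2, 0.2, 0.05, 0.05)
plus ±1 bp jitter and sizes from a discretized normal (mean 143, sd 15)
truncated at 117 bp — the V apex, the smallest span a fully wrapped
nucleosome protects; nucleosome-free fragments with midpoints uniform over
the NFR intervals and adjusted sizes 9 + floor(Exp(mean 50)); optionally,
insertion sites drawn through a planted 21-bp preference matrix. All draws
derive from one seed and the planted truth (dyads, lattice, NFRs, α) is
exported so tests compare against stored truth.

What the generator does *not* emulate: PCR duplication, mappability
artifacts, chimeric fragments, sequence-driven nucleosome positioning, and
coupling between fragment size and midpoint offset (real V-plots narrow
with decreasing size; the generator factorizes size and offset). Passing
the recovery tests therefore demonstrates correctness of the estimators
under the model's own assumptions, not performance on real libraries —
where template quality, sequencing depth and bias-model fidelity dominate.

## Problem sizes and reproducibility

Default test and acceptance conditions: 20 planted dyads, 5×10⁴ fragments,
α = 0.7; 10⁴ simulated loci of 200 fragments for null calibration; 20
random (B, V, SumF) instances × 10⁵ multinomial draws for the variance
check; 1000 replicates of 500 fragments for CI coverage. All randomness in
the acceptance script derives from the `--seed` argument; test seeds are
fixed constants. Per-region signal computation is deterministic, and region
results are merged in input order so parallel sharding can never change
output bytes.

## Known limitations

- The free/nucleosomal subtraction rule (scale-to-sub-cutoff-mass, clip,
  renormalize) is one of several defensible reconstructions of the
  size-mixture decomposition; alternatives (joint EM, spline free model)
  would change α slightly in the 115–130 bp overlap zone.
- The mixture is fit once per library; local bias in the size law (e.g.
  GC-rich promoters) is not refit per region.
- Fragments longer than 250 bp and candidate offsets beyond ±60 bp are
  invisible to the template by construction.
- MNase mode inherits the ATAC call machinery but its occupancy is a raw
  midpoint count, not a bounded fraction; NFR calling is therefore not
  offered in MNase mode.
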