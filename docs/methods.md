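# Methods

## Model and assumptions

`kymoclock` assumes a cohort of M fixed samples drawn at unknown phases of
a single periodic process: a wave of gene expression sweeping the
normalized rostro-caudal axis of the PSM once per clock cycle. Snapshots
are treated as exchangeable draws from one cycle — the method neither
estimates the period in hours nor handles cohorts spanning several full
cycles (a target period P ≠ M can be set but is exercised only by
invariants). Profiles are one-dimensional: intensity is averaged over the
full ROI width at each axial bin, so medio-lateral structure is discarded.

## Coordinates and extraction

The axial coordinate of a pixel is the arclength (along the annotated
posterior→anterior polyline) of its orthogonal projection, measured from
the projection of the annotated origin and divided by the per-sample unit
length; 0 is posterior, 1 anterior, and pixels projecting outside [0, 1]
are discarded. Pixel centers sit at integer + 0.5 and ROI membership is
center-in-polygon. Bins are half-open [i/n, (i+1)/n) with the last bin
closed. Empty bins are filled by linear interpolation between non-empty
neighbours (constant extension at the ends) and recorded in profile
metadata; no smoothing beyond this is applied. Background handling is
image-level subtraction with clipping, p ↦ max(p − level, 0), the level
being a scalar summary (mean by default, percentile optional) of the
no-primary control ROI. Z-stacks default to maximum projection, which
preserves thin expression bands; mean and sum are available.

Profile normalization defaults to peak (max = 1), keeping band shape and
making columns commensurable; area normalization (unit trapezoidal
integral) is the alternative. Resampling onto the common matrix grid is
piecewise linear with linear extrapolation from the edge segments, so
affine profiles resample exactly on any grid pair; results are clipped at
zero to preserve the non-negativity contract.

## The ordering objective

The source description defines g through "the autocorrelation function of
the j-th column" of f, but a column is a single sample's spatial profile
and its autocorrelation is unchanged by re-ordering columns — that reading
makes g constant and the minimization vacuous. The only reading under
which re-ordering columns "to obtain a temporally periodic pattern" is
meaningful applies the autocorrelation along the ordered sample axis,
separately for each spatial bin (each row of the permuted matrix); that is
what is implemented, and it is the package's main interpretive commitment.
Similarly, the printed target-autocorrelation formula was not available in
the source text; A_T(k) = cos(2πk/P) is the autocorrelation of any pure
sinusoid of period P samples, the natural target for "one cycle per
cohort", with P exposed as a parameter (default M).

The autocorrelation dialect is circular (wrap-around), mean-removed and
variance-normalized: periodicity enforcement needs the wrap-around, and
normalization makes rows of different amplitude commensurable. Lags run
1..⌊M/2⌋ by default; under circularity longer lags duplicate shorter ones.
Rows whose variance is ≤ `min_row_variance` (default 1e-12, an absolute
tolerance appropriate for max-normalized O(1) intensities) are excluded
and counted: their autocorrelation is undefined and they carry no ordering
signal. Row means and variances are permutation-invariant, so the
evaluator centers, filters and scales rows once; each evaluation of g is a
gather plus one batched multiply-sum.

## Minimization

The search is Metropolis acceptance over permutations with simulated
annealing: proposals reverse a random contiguous segment (better mixing on
permutation spaces than two-element swaps, which are also available),
acceptance probability min(1, exp(−Δg/T)), and T decays geometrically with
cooling factor 0.999 per iteration. The initial temperature "auto" is the
median |Δg| over 100 random swap proposals from the chain's start, so the
schedule adapts to the objective's scale. Five independent chains of
20 000 iterations from seeded random starts are the default; the best-ever
state is returned with a per-iteration trace whose best-so-far column is
globally non-increasing. All randomness derives from one integer seed via
spawned generator streams, so identical configurations reproduce results
exactly. An exhaustive minimizer (guarded at M ≤ 9, override available)
fixes sample 0 at rank 0 and halves the space by reflection — both
reductions are exact because g is invariant under cyclic rotation and
reversal of the ordering — and breaks exact ties by the lexicographically
smallest canonical permutation.

That dihedral invariance means the data determine the ordering only up to
rotation and reflection. Returned orderings are therefore canonicalized:
rotated so the lexicographically smallest sample id has rank 0, and
reflected if the intensity-weighted band centroid drifts
anterior→posterior with increasing rank (the clock wave travels
posterior→anterior). Canonicalization never changes g. Recovery is scored
by `ordering_distance`, the minimum normalized Kendall-tau distance over
all 2M rotations/reflections of one ordering against the other; 0 means
agreement up to the unresolvable symmetry.

## Phase classification

The Phase 1/2/3 call mirrors a judgement made by eye in practice: the
expression band is the set of bins at ≥ 50% of the profile maximum, and
its intensity-weighted centroid c is cut at 1/3 and 2/3 of the axis
(posterior, middle, anterior band). Both the threshold fraction and the
cut-offs are explicit conventions of this package, not measured
quantities; the centroid and the band's fractional width (bins in band /
total bins) are returned so users can apply their own rule.

## Synthetic cohorts

The generator emulates exactly the structure the ordering method assumes:
a traveling signal, one cycle per cohort, with known phases. Band mode
(default) is a Gaussian bump of width 0.1 axis units whose center tracks
phase/2π across the axis — the faithful stress case for a sweeping
expression band; sinusoid mode produces rows that are exact sampled
cosines under grid phases, giving the closed-form zero of g used in tests.
A static linear gradient (anteriorly increasing, Dll1/Notch1-like) and a
constant baseline can be added. Noise is additive Gaussian with standard
deviation `noise_fraction` × amplitude, clipped at zero — the simplest
model consistent with background-subtracted fluorescence; defaults are
amplitude 1, noise fraction 0.1, 100 bins, matching the cohort sizes used
throughout (M = 7 for oracle comparisons, M = 24 for recovery). Paired
cohorts share sample ids, presentation order and phases up to a constant
offset, with independent noise streams per channel, emulating
contralateral halves stained for clock gene and protein.

What passing tests show — and do not. Synthetic cohorts have ideal
geometry: no segmentation error, no axis mis-annotation, no
sample-to-sample variation in wave shape, amplitude or period, no spatial
noise correlation, and phases that tile the cycle evenly. Recovery rates
measured here are therefore upper bounds on real-data performance; the
invariants (symmetry, determinism, oracle equivalence) transfer
unconditionally, the recovery numbers do not.

## Numerical and I/O choices

CSV writers emit floats in shortest round-trip decimal notation and
readers parse with round-trip precision, so tabular round-trips are
value-exact and byte-deterministic across runs; column order is fixed.
The raster kymograph renderer maps values through a matplotlib colormap to
RGB and writes PNG directly (one pixel per rank × bin before integer
upscaling), which keeps re-renders byte-identical; `render_figure`
provides the annotated matplotlib view where byte-stability is not
required. The periodic extension is exact tiling, never resampling, so an
n-cycle extension conserves total intensity ×n bit-exactly. Orderings are
stored both as ranked sample ids and as column indices.

## Problem sizes

Default test and reproduction workloads use cohorts of 7 samples
(exhaustive comparisons, 2 520 effective permutations), 24 samples
(annealed recovery, 10 seeds) and 100-trial separation checks at 50–100
bins — sizes chosen to exercise every code path at desk scale while
matching the cohort magnitudes the method targets.

## Known limitations

- The objective assumes the cohort spans one cycle; heavily non-uniform
  phase sampling or multi-cycle cohorts degrade the cosine target's fit.
- Rotation/reflection ambiguity is resolved only heuristically (band-drift
  direction); cohorts without a clear traveling band keep an arbitrary
  orientation.
- Extraction averages across the full ROI width; curved axes with strongly
  varying ROI width can blur the band.
- The phase classifier is a convention; near the 1/3 and 2/3 boundaries
  labels are sensitive to the threshold fraction.
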