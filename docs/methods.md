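# Methods

This note documents the model behind `wscec`, the parameter choices, the
numerical conventions, and what the synthetic-data tests do and do not
establish.

## Pipeline model

A heartbeat is treated as a short stationary-ish time series whose local
spectral content varies along the beat.  Overlapping windows of length
`l` are summarised by their leading DFT coefficients; the resulting point
cloud in `R^d` traces the beat's trajectory through spectral space.  The
local geometry of that trajectory — how spread out the neighbourhood of
each point is — is captured by the k-nearest-neighbour scatter matrix,
and the scalar curvature of the Bures–Wasserstein metric at that matrix
condenses the neighbourhood's shape into one positive number.  Beats
whose morphology is regular (sharp, repeatable QRS) produce curvature
sequences spread broadly over the admissible range; widened or erratic
complexes concentrate the sequence, and the histogram-dispersion pair
`(cur1, cur2)` quantifies exactly that contrast.

## Curvature conventions

* `Γ_S[Y]` is solved in the eigenbasis of `S` by entrywise division by
  `λ_i + λ_j`.  The same solve is applied to the antisymmetric commutator
  inside the curvature tensor; the eigenbasis formula needs no symmetry
  assumption.
* All eigen-solves symmetrise their input (`(S + Sᵀ)/2`) first.
* **Scalar curvature prefactor.**  The scalar curvature is defined here
  as the full double sum `Σ_{i,j} R(e_i, e_j, e_i, e_j)` over ordered
  pairs of a `g_W`-orthonormal basis of the `n(n+1)/2`-dimensional
  tangent space — the standard Riemannian contraction, implemented
  independently in `scalar_curvature_oracle` (Gram–Schmidt plus brute
  force).  The spectral trace expression
  `tr(UΛ(U+Uᵀ) + (U+Uᵀ)ΛU + (U+Uᵀ)ΛUΛ(U+Uᵀ))`, with eigenvalues sorted
  ascending and `U_{ij} = 1/(λ_i+λ_j)` strictly above the diagonal,
  counts each unordered basis pair once and therefore carries prefactor
  **6**, not 3, to equal the double sum.  The two routes agree to 1e-12
  relative on random SPD(2)/SPD(3) matrices; at the identity in SPD(2)
  both give 3, which matches the O'Neill-submersion value
  `R(X,Y,X,Y) = (3/32)·tr(X[X,Y]Y)` summed over the quotient
  construction of the metric.
* The ceiling `3n(n−1)/λ_min2` was re-verified for this convention on
  20 000 random SPD(3) spectra; it is approached (ratio → 1) as the
  smallest eigenvalue degenerates with the remaining two equal, so the
  bound is tight in order and strict.
* The Gaussian `W²` is a difference of traces; values below `1e-13`
  times the trace scale are snapped to zero, which is the roundoff floor
  of the expression (self-distance would otherwise surface as ~1e-7
  after the square root).

## Dispersion statistic

The histogram has bins `[mj, m(j+1))` for `j = 0 … ⌊b/m⌋`; note the last
bin covers `[b, b+m)`, so "all columns occupied" includes curvatures at
or just above `b`.  `cur1` is the median (mean of central order
statistics for even cardinality) of `U1 = {w : ms ≤ w ≤ b}`.  `cur2`
is pinned to the reading

    ȳ    = (Σ_{j∈U2} y_j) / ⌊b/m⌋          U2 = {j ≥ s+1 : y_j ≠ 0}
    cur2 = sqrt( Σ_{j ≥ s+1} (y_j − ȳ)² / (|U2| − s − 1) )

chosen because it is the unique variant with both documented limits:
with `s = 0` and every column `j ≥ 1` occupied it reduces to the
textbook sample standard deviation of the column heights, and empty
columns shrink the denominator while still contributing `(0 − ȳ)²`
deviations, so `cur2` never falls below the plain column standard
deviation and strictly exceeds it when a column is empty.  A stronger
monotonicity — "emptying a column never decreases `cur2`" — is *false*
(emptying an outlier column legitimately shrinks the spread; random
search finds counterexamples at ~4% rate), so the test suite asserts the
lower-bound form instead.  Degenerate cases (empty `U1`, denominator
≤ 0) flag the beat unclassifiable rather than returning NaN.

## Parameters

| parameter | default | meaning / rationale |
|---|---|---|
| `l` | 10 samples | window length ≈ sharp QRS duration at 360 Hz |
| `τ` | 1 sample | window step |
| `d` | 3 | embedding dimension (a₀, a₁, b₁) |
| scale | `2/l` | makes `(a₁,b₁)` equal the amplitude of a window-commensurate sinusoid; exposed as `embed_scale` because the absolute scale shifts all curvatures and hence the partition boxes |
| `k` | 20 | neighbourhood size; scatter left unnormalised (a 1/k factor would rescale every curvature by k) |
| `m` | 1 | histogram bin width (curvature units) |
| `s` | 0 | histogram offset |
| `ε` | 0.09 | assumed floor on `λ_min2` of the scatters; gives the analytic ceiling `3d(d−1)/ε = 200` |
| `eig_floor` | `1e-8 ×` mean scatter trace (≥ machine eps) | regularisation of rank-deficient scatters, which otherwise send curvature to infinity |
| beat length | 300 samples at 360 Hz | R peak at sample 100, so P and T waves both fit |

The partition of the dispersion plane defaults to the published boxes
(normal `(25,200]×[0,25]`, atrial `(25,90]×(25,∞)`, ventricular
`(10,25]×[0,∞)` with three overlapping sub-boxes, bundle branch block
`[0,10)×[0,∞)` with two, complement unclassified) and can be replaced by
a JSON file; precedence follows the printed order and sub-box overlaps
deliberately yield only the coarse label.

## Preprocessing

Denoising is a 4th-order Butterworth low-pass at 50 Hz applied
forward–backward (zero phase, so peak positions survive).  Records not
at 360 Hz are linearly resampled first.  R-peak detection searches a
QRS-emphasis envelope — the difference of two zero-phase Gaussian
smoothings, a 10 ms kernel matched to the sharp QRS and a 45 ms kernel
that cancels P/T-scale waves — for local maxima above an adaptive
threshold (0.4 × rolling 2-s envelope maximum, floored at 0.25 × the
global maximum so QRS-free tails do not admit noise), with a 200 ms
refractory interval.  The plain raw-trace local search was tried first
and could not localise apexes reliably at the generator's noise level,
and its purely relative threshold failed on records mixing small normal
R waves with large premature-ventricular complexes; the envelope search
keeps the same adaptive-threshold/refractory structure.  On a noise-free
symmetric QRS the envelope apex coincides with the R apex.

## Synthetic data

Beats are sums of Gaussian bumps (P, Q, R, S, T) on a 300-sample grid
with class-specific deltas: bundle-branch-block classes widen the QRS
2.5× and add a second R bump (pronounced for R.B.B.B., shallow for
L.B.B.B.), atrial premature beats shift the P wave 40 ms earlier,
premature ventricular contractions drop the P wave and widen/enlarge the
QRS 1.8×, ventricular flutter is a 5 Hz sinusoid, and the fusion class
averages the normal and flutter templates.  All constants live in one
table; every random draw flows through one integer-seeded generator, so
identical specs give bitwise-identical beats.

**Noise level.**  The default additive broadband noise is 0.3 mV.  This
is not sensor noise alone but the aggregate non-cardiac activity of an
ambulatory recording, and it is the value at which the noise floor of
the kNN scatters is consistent with the pipeline's assumed eigenvalue
floor `ε = 0.09`: baseline windows are noise-dominated, their scatter
eigenvalues scale like `(k−1) · subsample-shrink · (2/l)² · (l/2) · σ²`,
and setting that expression to `ε` gives `σ ≈ 0.3 mV`.  With much
cleaner beats nearly all curvature mass sits far above the ceiling
`b = 200` and the dispersion median degenerates into tail noise.

**What the synthetic tests show.**  Under these conditions the pipeline
reproduces the *ordering* of the transverse dispersion (normal >
widened-QRS classes; flutter lowest) reproducibly across seeded batches.
They do not show that synthetic dispersions land inside the published
partition boxes — those were calibrated on MIT-BIH recordings whose
exact amplitude/scale conventions the generator does not reproduce — nor
anything about rhythm-level phenomena, beat-to-beat correlation, or
electrode artefacts, none of which the generator models.  Recovery of
planted R peaks (≥ 95% within ±3 samples) is asserted for classes with a
single well-defined R apex; double-R bundle-branch-block beats are held
to a ±QRS-width criterion, and flutter-type classes are excluded because
they contain no R apex by construction.

## Problem sizes

The test suite and the acceptance script run entirely on synthetic data:
curvature cross-checks use 100 random matrices per dimension plus a
1000-draw bound sweep; end-to-end checks use 20-beat batches (each beat
is a 289-point cloud, i.e. 289 exact kNN queries and 3×3
eigendecompositions); peak-recovery statistics use 100 ten-beat records.
The whole suite completes in well under a minute on one CPU.

## Known limitations

* Single-lead only; no multi-lead fusion.
* The embedding scale convention is genuinely ambiguous in the source
  formulation (`2/l` adopted, configurable); absolute curvature
  magnitudes — and therefore the partition boxes — move with it.
* The partition is a fixed rectangular calibration, not learned; points
  with `cur1 > 200` fall to unclassified by construction.
* The first sliding window (offset 0) is deliberately not emitted, and
  window count follows `⌊(n−l)/τ⌋ − 1`, matching the source convention
  rather than the maximal window set.
* WFDB-format input is not supported; records are plain numeric series
  (CSV/one-column text) plus a sampling rate.
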