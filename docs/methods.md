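# Methods

## The problem

Two similar processes acting on a surface each produce a direction of
spectral change in peak space. Directly subtracting spectra confounds the
difference between the processes with replicate noise; instead, each
process is summarized by the loading vector of its discriminating
multivariate component, and the two loadings are compared geometrically.
The working assumption is that the loading vectors of similar processes
span a two-dimensional plane in the ~10³-dimensional peak space, so that
one loading can be meaningfully split into a component parallel to the
other (shared chemistry) and an orthogonal remainder (differentiating
chemistry).

## Preprocessing

Input peak tables hold nonnegative summed ion counts, one column per peak,
one row per spectrum. The chain is fixed: remove flagged (saturated)
peaks → Poisson scaling → mean centering.

*Poisson scaling* divides each peak column by the square root of its
across-spectra mean. For counting noise (variance ≈ mean) this equalizes
the noise variance of all peaks at ≈1, preventing intense peaks from
dominating variance-based decompositions through shot noise alone. The
row-wise variant (additionally dividing each spectrum by the square root
of its total counts) is available as `row_scale=True` but off by default;
total-count normalization has little effect on data of this kind. A peak
column with zero mean is a hard error rather than an automatic drop:
silently removing features would desynchronize fitted loadings from the
peak list.

*Back-transformation.* Loadings fitted in scaled space are multiplied by
the per-peak scale factors — inverting the division applied to the data —
and renormalized to unit length. Back-transformed loadings therefore live
in raw count space, where they are directly comparable with per-peak
intensity changes and can be annotated against raw spectra. All
similarities, angles and decompositions in this package operate on
back-transformed, unit-norm loadings; since cosine similarity and
Gram–Schmidt are scale-invariant, the unit normalization is purely a
plotting/comparison convenience.

## Models

**PCA** uses the exact full SVD of the centered matrix (LAPACK, no
whitening). **PLS-DA** is PLS regression (NIPALS) against a single ±1
dummy response — for two classes this spans the same response space as
one-hot coding and yields one natural discriminating direction — with
convergence tolerance 10⁻⁶ and at most 500 iterations; non-convergence is
recorded in provenance, not raised. The per-component "loading" reported
for PLS-DA is the x-rotation (the weight direction mapped to x-space),
treated as directly comparable to a PCA loading. If the two class means
coincide exactly, the x–y covariance is zero and NIPALS has no defined
direction; the fit then returns a degenerate model whose selected
component has a between-within ratio of 0.

**Component selection** emulates the analyst's choice of "the component
that separates my classes": for each component, the between-class sum of
squares of its scores (class-size-weighted squared deviations of class
means from the grand mean) is divided by the within-class sum of squares.
Sums of squares rather than variances are used — monotone-equivalent for
selection and trivial to verify by hand. Ties take the lowest component
index; perfect separation (zero within-SS with distinct means) returns an
infinite sentinel ratio. Sign indeterminacy of SVD/NIPALS directions is
resolved by flipping each loading into the half-space of the reference
direction before similarities are averaged.

## Decomposition and diagnostics

Gram–Schmidt: `parallel = (v1·v2 / v2·v2) v2`, `orthogonal = v1 −
parallel`, with the long-time loading as `v1` projected onto the
short-time loading `v2`. Inputs whose |cosine| exceeds 1 − 10⁻¹² are
flagged degenerate and the orthogonal part is returned as an exact zero
vector. The coplanarity diagnostic
`|θ(ref→v_long) − θ(ref→v_short) − θ(v_short→v_long)|` is ≈0° when the
three directions lie in one plane with the short-time loading between the
reference and the long-time loading — the geometry that licenses
interpreting the 2-D representation. In 2-D plots the reference maps to
(1, 0) and every other vector to (cos θ, sin θ); only angles to the
reference are faithful, since two non-reference vectors need not share a
plane.

Peak ranking reports the k most positive and k most negative coefficients
(ties broken by ascending m/z, tied peaks assigned to the positive list
first so the lists stay disjoint). Ranking is performed on the
unit-normalized decomposition components; normalization does not affect
the order.

## The simulator

The simulator emulates peak tables from pixel-averaged ToF-SIMS spectra:
993 peaks by default, center masses uniform over 1–3661 m/z, base
intensities log-uniform over 10²–10⁶ counts, two classes of 3 spectra
each.

A *mechanism* modifies a uniformly sampled half of the peaks. Each
selected peak increases or decreases with equal probability, at a rate
rᵢ ~ Normal(μ, σ) (clipped at 0, since a negative rate would invert the
monotone direction of the update rules; the clip affects ~3·10⁻⁵ of draws
at the default parameters). Increasing peaks additionally draw an update
factor Fᵢ ~ Uniform(1, 5) bounding their growth. At process time t
(dimensionless extent):

    decrease:  p(t) = p⁰ exp(−rᵢ t)
    increase:  p(t) = p⁰ (1 + Fᵢ (1 − exp(−rᵢ t)))

These rules are the identity at t = 0, monotone in t, keep intensities in
[0, (1+Fᵢ)p⁰], and apply Fᵢ only to increases. They are isolated behind
`apply_mechanism` so alternative kinetics can be swapped in. Default
parameters: mechanism #1 (fast) μ = 1.0, σ = 0.25; mechanism #2 (slow)
μ = 0.2, σ = 0.05 — a ≈5× rate separation — both with F ~ U(1, 5). All
four values are configuration keys.

A *dataset* applies the mechanism(s) sequentially to every initial
spectrum, computes the mean processed spectrum, and draws three
independent Poisson realizations of it as the "artificial" class — so the
artificial spectra carry no one-to-one noise correlation with the
initial spectra.

*Initial spectra* are replicate measurements, and real replicate spectra
of a nominally identical surface agree only to a few percent (sample
heterogeneity, dose and transmission fluctuations). That matters: for a
10⁶-count peak, Poisson noise is 0.1%, so Poisson resampling alone would
make replicates unrealistically identical and leave no within-class
variability for the multivariate methods to contend with. Each synthetic
replicate therefore modulates the base spectrum by a per-peak
multiplicative log-normal factor with CV 3% (`replicate_cv`, a
conservative replicate RSD for this kind of data) before Poisson
sampling. The artificial class is deliberately left Poisson-only: it is
defined as a re-draw of a computed mean spectrum, not as an independent
measurement.

The per-mechanism ground-truth direction is the per-peak mean intensity
change that mechanism contributes at its stage in the chain
(`mechanism_delta` / `chain_deltas`), available exactly because the
changes are computed before they are combined.

## The benchmark

Each Monte-Carlo replicate is a distinct random process: fresh initial
spectra, fresh mechanism(s). The reference ("target") direction is the
PLS-DA loading of a mechanism-#1-only dataset of the same process at
t = 1 (an analytic alternative — the unit-normalized mechanism delta — is
available via `reference="analytic"`). For each requested t, a dataset is
generated, both methods are fit on the preprocessed matrix, the
discriminating component is selected, sign-aligned to the reference, and
scored by cosine similarity; means over replicates are converted to
angles. Replicates that fail to fit are counted and skipped, never
silently dropped. All randomness derives from a single master seed via
counter-mode seed-sequence spawning, making every run bit-reproducible.

Study sizes used by the test suite: 100 replicate datasets per condition
for the single-mechanism recovery and the mechanism-separation studies,
50 for the two-mechanism angle/coplanarity study and for the
permutation-null study (100 label shuffles each). The full suite runs in
well under a minute on one CPU; larger replicate counts (e.g. 1000) are a
single configuration change.

With 3+3 spectra there are only 20 distinct label assignments, so the
permutation null resamples them; the p-value uses the add-one estimator
(1 + #{null ≥ observed}) / (1 + n_permutations).

## Peak-list merging

Peak lists from separate measurements are unified by a relative catch
mass radius (default 200 ppm): the pooled masses are sorted and swept
left-to-right, extending the current cluster while the next peak lies
within the radius of the running cluster mean. Each cluster is
represented by the unweighted mean of its members (no intensity
information is assumed available at merge time; the choice is recorded in
output metadata). A chained cluster can span more than the radius
end-to-end — accepted and documented — but consecutive cluster means
always remain separated by at least the radius, making the operation
idempotent.

## Known limitations

- Only two-class designs; no multi-class discrimination, cross-validated
  component selection, or VIP scores.
- Decomposition handles one pair of loadings at a time; no simultaneous
  orthogonalization across more than two processes.
- The simulator models intensity changes only: no mass-axis effects (peak
  shape, calibration drift, isotopes), no imaging or depth profiling.
- Passing the simulation studies shows the strategy recovers mechanisms
  under Poisson counting noise plus modest multiplicative replicate
  variability with known ground truth; real spectra add effects the
  generator does not emulate (correlated peak families from shared
  fragments, matrix effects, detector saturation), so results on real
  data still require the usual chemical sanity checks.
- Proprietary instrument formats and peak detection from raw spectra are
  out of scope; inputs are delimited peak tables assumed dead-time
  corrected.
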