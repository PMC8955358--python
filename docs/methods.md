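# Methods

## The separation index

Separation between two clusters is quantified by a projection index.
For a unit projection direction *a*, write Δ = |a·(m₂ − m₁)| for the
projected mean gap and σᵢ = √(aᵀΣᵢa) for the projected standard
deviations. The theoretical (Gaussian) index at tail level α is

J(a) = (Δ − z(σ₁+σ₂)) / (Δ + z(σ₁+σ₂)), z = Φ⁻¹(1 − α/2),

and the cluster-pair index J\* is the maximum of J(a) over directions.
Interpretation: the central (1 − α) body of each projected cluster spans
± z σᵢ about its mean, so the numerator is the gap (or overlap, when
negative) between the two bodies and the denominator their joint span.
J\* = 0 when the bodies touch, J\* → 1 as clusters separate, and J\* → −1
as their centers coincide.

**Coverage level.** `coverage_alpha` defaults to 0.05 (z ≈ 1.959964),
the conventional tail level for this index family; all dataset SI values
in the package are on that scale.

**Direction optimisation.** The maximiser satisfies the stationarity
condition a ∝ (Σ₁/σ₁ + Σ₂/σ₂)⁻¹(m₂ − m₁), which the package solves by
fixed-point iteration (change < 1e−10, at most 500 iterations; the start
is the center line). The iteration is verified in tests against a
3600-point angle-grid brute force in 2-D and falls back to that grid,
with a warning, if it ever fails to converge. Equal covariances give the
familiar whitened direction Σ⁻¹d; spherical clusters give the center
line.

**Empirical index.** For sampled (possibly skewed) clouds the Gaussian
quantiles are replaced by sample quantiles of the projected events:
J = (L_hi − U_lo)/(U_hi − L_lo), where lo/hi order the clouds by
projected mean and U/L are the 1 − α/2 and α/2 linear-interpolation
quantiles. The projection is the moment-based optimal direction,
refined in 2-D by a bounded local search over the projection angle
(±0.35 rad, tolerance 1e−6). The estimator is symmetric in its
arguments and converges to the theoretical value for Gaussian clouds as
n grows (checked at n = 10³…10⁵). Clouds need ≥ 20 points and a
full-rank sample covariance.

**Inverting the index.** Dataset construction needs the center distance
δ realising a target J\*. Since J\*(δ) is strictly increasing (a property
test asserts this on random SPD pairs), bisection on δ suffices;
default tolerance 0.005 on J, an order below the 0.1 grid spacing of the
separation series, so nominal SI levels remain well separated.

## Cluster generation

Covariances are drawn as QΛQᵀ with eigenvalues uniform in [1, 5] and Q a
uniformly random rotation (QR of a Gaussian matrix, R-diagonal signs
fixed). This controls the spectrum — hence cluster diameter and
ellipticity — exactly, emulating the spread of shapes seen in real
two-channel cytometry data.

Skew-normal clusters use the selection representation: with correlation
matrix Ω̄ of the scale matrix Ω and shape vector (α, 0), set
δ = Ω̄(α,0)ᵀ/√(1+α²); sample (X₀, X) jointly Gaussian with
cor(X₀, Xⱼ) = δⱼ and keep X when X₀ > 0, else −X. Locations are chosen
so the *theoretical* mean equals the model mean (the skew-normal mean
exceeds its location by ωδ√(2/π)), i.e. centering is a model property,
not a per-sample correction. Left skew mirrors the x-coordinate about
the mean, which guarantees exact distributional symmetry between the two
skew directions and negates skewness exactly.

**Width compensation.** Skewing deflates the x-variance by the factor
1 − 2δ²/π (≈ 0.37 at α = 10). `rescale_to_preskew_width` multiplies
mean-centered x by the inverse square root of that factor, restoring the
variance the cluster would have had unskewed. This is a deterministic,
model-based reading of "restore the pre-skew diameter": a min–max range
match would depend on sample extremes and so vary by replicate. Because
the map is positive-affine, the sample skewness is bit-identical before
and after — the invariance the tests assert at 1e−12.

**Skewness statistic.** The moment ratio g₁ = m₃/m₂^{3/2} (central
sample moments). Small-sample-corrected variants are positive multiples
of g₁, so invariance checks and sign conventions are unaffected; g₁ is
the simplest choice. Closed form for the skew-normal x-marginal:
γ₁ = ((4−π)/2)(δ√(2/π))³/(1 − 2δ²/π)^{3/2}, ≈ 0.5758 at α = 2.5 and
≈ 0.9556 at α = 10.

## Dataset assembly

**Separation family.** k = 2: a random offset direction, center distance
solved for the target index. k = 3: edge lengths of a random triangle
are iteratively re-solved per pair (using each edge's current direction)
and the triangle rebuilt from its side lengths, so all three pairwise
indices land on the target; when the triangle inequality forces an edge
longer, that pair exceeds the target and every cluster's
*nearest-neighbour* SI still equals it. 1000 events per cluster, labels
by generating cluster, nine replicates per SI level by default, SI grid
−0.3…+0.3 in steps of 0.1.

**Skew family.** Two clusters share the same α (mixed-α pairs are out of
scope), each width-compensated. Cluster A sits at lower x, B at higher
x. Orientation fixes which side each skew faces: tail-to-tail has A
left-skewed and B right-skewed, head-to-head the reverse, head-to-tail
both right-skewed; α = 0 is the unskewed control. B's x-shift is then
bisected until the *empirical* index of the assembled pair falls in the
acceptance band [−0.25, −0.15] (measured at the generated n = 1000 per
cluster — there is no closed form for the skew-normal index, so
acceptance mirrors a measure-then-select procedure). The accepted value
is recorded as `measured_si` alongside the construction target; the
manifest carries both so either view of the realised separation is
available.

**Seeds.** Every dataset's RNG seed derives from
(base_seed, family, condition, replicate) via a SeedSequence, so a single
replicate regenerates in isolation, byte-identically.

## File formats

FCS 3.1 files carry a 58-byte HEADER, a "/"-delimited TEXT segment
(values escape the delimiter by doubling) and little-endian float32
row-major list-mode DATA. Float32 is the cytometer convention and loses
nothing here: event values are O(10). The reader additionally accepts
float64 and big-endian data; it refuses other datatypes and reports
truncated DATA segments as errors. Ground truth lives in a sidecar CSV
(`event_index,label`, 0-based, FCS row order) so the event file an
external tool sees is completely standard. The writer is cross-validated
in the test suite against an independently coded minimal parser.

## Evaluation

The difference-to-reference statistic |A − B|/total × 100 compares the
ground-truth cluster-1 count A to the matched output cluster's count B.
"Cluster 1" is fixed deterministically as ground-truth label 1
(generation order). Matching is by optimal assignment on the
contingency table (ties to the smallest reference label); outputs with
more clusters than requested are first merged many-to-one by majority
overlap, with the merge map retained for audit — an automated,
reproducible surrogate for the manual sub-cluster merging such tools
otherwise require. Outputs with *fewer* clusters are still scored via
rectangular assignment (a fully collapsed two-cluster dataset scores
50%); failing to return the requested k is a reported outcome, not a
crash. Summaries use the sample SD (n − 1) and CV = 100·SD/mean; SD is
reported missing (never 0) for single replicates, CV missing when the
mean is 0.

Three-cluster datasets keep equal 1000-event clusters, and reference
fractions are always taken from the ground-truth labels rather than an
assumed percentage.

## Baselines

`kmeans` (k-means++ seeding, Lloyd iterations, emptied centroids
re-seeded at the farthest point, best of 5 restarts by within-cluster
sum of squares) and `gmm_em` (full-covariance EM, k-means
initialisation, covariance regularisation +1e−6·I, convergence at
log-likelihood gain < 1e−6, hard labels by maximum posterior — the
accuracy statistic needs integer counts). Both are deterministic given
their seed. They are stand-ins for the k-means-family and model-based
classes of production tools, not re-implementations of any particular
software; conclusions about named tools require their own outputs, fed
in through the CSV adapter.

## What the synthetic data does and does not show

The generator reproduces controlled separation and skew in two channels
with equal-size, noise-free clusters. Real cytometry data add debris and
doublet events, rare populations, higher-dimensional panels, unequal
population sizes and instrument artefacts — none of which are modelled.
Passing benchmarks here therefore demonstrates correct behaviour with
respect to separation and asymmetry specifically, not performance on
full real-world complexity.

## Problem sizes

Default library conditions (1000 events/cluster, 9 replicates) run in
seconds per condition. The shipped reproduction script uses 3 replicates
per skew condition and the full 9 for the separation envelope; the test
suite uses reduced grids (2–3 replicates, subsets of SI/α levels) for
its end-to-end checks and n = 10⁵ samples for moment checks, sizes at
which every asserted tolerance is comfortably resolved.
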