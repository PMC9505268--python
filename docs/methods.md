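# Methods

This note documents the models, conventions, and numerical choices behind
`texcomplex`, and what the synthetic test bed does and does not establish.

## Color-space decomposition

All transforms accept sRGB arrays in [0, 1] and are deterministic and
shape-preserving. Intensity is the unweighted mean (R+G+B)/3 of the encoded
values — the conventional "intensity image", identical to Ohta's I1, which
the tests exploit as a cross-check. HSV is the standard hexcone on encoded
values with H scaled to [0, 1) and H := 0 on the achromatic axis. YCbCr is
BT.601 full-range on encoded values with the chroma offset removed, so
achromatic pixels map to Cb = Cr = 0 exactly and Y(1,1,1) = 1. I1I2I3 is
Ohta's linear opponent triplet. CIELAB alone linearizes first (IEC
61966-2-1 piecewise gamma), then maps through the sRGB/D65 matrix to XYZ
and to L\*a\*b\* with the D65 2° white — CIELAB is defined on tristimulus
values, while the other spaces are conventionally applied to encoded
values. Channel roles follow the luminance/chrominance split used in the
correlation analysis: Int, V, Y, I1, L\* are luminance; H, S, Cb, Cr, I2,
I3, a\*, b\* are chrominance; R, G, B are raw. H is stored on [0, 1) and
treated as an ordinary (non-circular) quantity by the descriptors.

## First-order descriptors

Global mean and *population* standard deviation (a descriptor of the image,
not an estimate of anything), plus four histogram measures on an
equal-width histogram over the channel's nominal range (256 bins by
default, the 8-bit convention): standardized third and fourth central
moments of the bin-center distribution (kurtosis non-excess; skewness 0 and
kurtosis NaN for a degenerate histogram), energy Σp², and Shannon entropy
in bits with 0·log 0 := 0. Histogram energy and entropy move inversely
over concentration of the value distribution. Rescaling of descriptors to
0–10 for comparability with rank scores happens in the analysis layer, not
here; Pearson correlations are unaffected by it.

## Co-occurrence features

The co-occurrence matrix at (d, θ) holds probabilities of ordered pixel
pairs; pairs leaving the image are dropped (no wrap-around), and each
angle's matrix is normalized independently. Diagonal displacements use the
chessboard offsets (±d, ±d) — this is why counting is implemented here
rather than through `skimage.feature.graycomatrix`, which rounds
d·cos/d·sin offsets (d = 5 at 45° would give offset 4). Quantization is
uniform over the channel's nominal range, 256 levels by default
(configurable; Haralick practice often uses 8–64). Features are energy
Σ P², contrast Σ(i−j)²P, correlation (NaN when a margin is constant),
entropy in base 2, and homogeneity Σ P/(1+(i−j)²) (the inverse difference
moment; a 1+|i−j| variant is available behind a flag). Rotation-invariant
values average the per-angle *features* over the eight 45°-spaced angles,
not the matrices. Since every feature is transpose-invariant and the
matrix at θ+180° is the transpose of the one at θ, the 8-angle mean equals
the 4-angle mean — asserted as a cross-check. The distance sweep
{1, 5, 10, 15, 25, 50, 100, 150, 250} px mirrors the study-scale grid.

## Local binary patterns

N = 8 neighbors on a circle of radius R, neighbor 0 east, counter-clockwise,
bilinear interpolation off the grid. The sign convention is s(x) = 1 for
x ≥ 0 (ties count as 1), so flat regions code as the all-ones uniform
pattern; a small relative guard (1e−9) protects exact ties against bilinear
rounding, which matters only on constant regions. Patterns with at most two
circular transitions are uniform — exactly 58 of the 256 8-bit patterns,
collapsing to 9 rotation-invariant classes by their number of ones; all
others share one catch-all bin (10 bins total). Border pixels within R of
the edge are excluded rather than padded, because padding fabricates
texture. The two single-number features are the mean of the nine uniform
bin frequencies and the non-uniform bin frequency; normalization forces
9·uniform + nonuniform = 1. The vectorized histogram is verified against a
per-pixel brute-force loop and against
`skimage.feature.local_binary_pattern(method="uniform")`.

## Gabor features

g(x,y) = (F²/(πγη))·exp(−F²(x′²/γ² + y′²/η²))·exp(i2πFx′) with (x′, y′)
rotated by θ; γ = η = 0.5 by default. Kernels are sampled on the integer
grid and truncated at 3 envelope standard deviations (σ = γ/(F√2)).
The default bank is the six-frequency {1, 0.7, 0.5, 0.35, 0.25, 0.18} ×
six-orientation {0°…150°} grid of 36 filters; consecutive frequency ratios
are ≈ √2 (half-octave spacing). Energy is the modulus of the complex
convolution response (squared-modulus variant behind a flag), computed with
reflect padding so edges contribute no spurious energy; no DC correction is
applied, because the modulus is carrier-dominated and the std-based feature
is exactly zero on constant images by shift invariance. Rotation-invariant
features average the per-orientation (mean, std) of the energy. Raw feature
magnitudes scale with F² through the kernel normalization, so
frequency-robustness is a statement about *correlations*: across the six
frequencies the correlation of Gabor σ with the complexity scores varies
with a coefficient of variation well under 0.5, peaking at the lowest
frequency.

## Rank scoring and STRESS

VRS is the mean assigned position divided by (T−1); its raw range
[1/(T−1), T/(T−1)] is attained at unanimous first/last placements. Ties
consume a single position value (no fractional mid-ranks). Rescaling is
min–max to [0, 10] per attribute over the analyzed set (an all-equal vector
rescales to 5.0 with a warning). STRESS between score vectors a and b is
100·sqrt(Σ(a−F·b)² / Σ(F·b)²) with the least-squares scale
F = Σab/Σb²; it is zero iff the vectors are positively proportional, and
equals 100·sqrt(1/ρ²−1) for cosine similarity ρ — hence values above 100
are possible for strongly discordant vectors, though rank data in practice
stay inside 0–100. Intra-observer STRESS averages all replicate pairs per
observer, then over the panel; inter-observer STRESS compares each
observer's mean ranks with the leave-one-out panel mean, which avoids
inflating agreement by correlating an observer with a mean containing them.
The viewing-geometry helpers convert pixels to physical extent by linear
scale and compute the visual angle 2·arctan(extent/2/distance).

## Linking statistics

The correlation sweep computes Pearson r (two-sided t-test p) per
(space, channel, feature, parameter) cell against the complexity scores,
flagging constant cells with NaN. PCA of the attribute table is an
eigendecomposition of the *covariance* (not correlation) matrix of the
mean-centered 0–10 columns — the scores share a scale, and standardizing
would discard the attributes' differing spreads; component signs are fixed
so each component's largest-magnitude coefficient is positive. The
weighted-sum complexity model has no intercept (it is a pure weighted sum),
so minimizing the MSE against the observed scores reduces to least squares
through the origin; results carry coefficients, classical standard errors,
MSE, R², r(target, fitted), and the design condition number
(rank-deficiency raises an error naming it). Factor extraction is
maximum-likelihood with a single common factor on standardized measures
(via scikit-learn's EM implementation); loadings are sign-fixed positive
on the dominant measure, and specific variances are floored at 0.005 with
a Heywood flag.

## Synthetic test bed

The generator drives a diagonal sine grating (period = regularity/
repetitiveness scale) blended with band-limited noise (Gaussian white noise
low-pass filtered at σ = 2 px, wrap-around boundaries) on the luminance
plane: blend = √(1−a)·grating + √(2a)·noise with both components at RMS
1/√2, so the blend's power is linear in the randomness amplitude a and the
luminance spread grows strictly monotonically with it — disordered
textures carry more luminance variation, not just rearranged variation. A
noise-free achromatic texture is a pure grating with intensity-channel
standard deviation exactly contrast/(2√2). Chromatic variation adds smooth
noise to the two Ohta opponent planes around the base color with per-pixel
gamut compression *in the opponent plane*, so chroma perturbation never
touches the intensity plane. Latent attributes are: randomness = noise
amplitude, strongness = contrast amplitude, color variation = chroma
amplitude, regularity = 1 − randomness, repetitiveness = grating cycle
count normalized by the maximum resolvable count; latent complexity is the
weighted sum 0.50/0.34/0.41/−0.19/−0.14 of these, and latent homogeneity is
its mirror image. The sampler draws amplitudes independently uniform and
periods log-uniform in [3, size/2].

Simulated observers carry a persistent per-sample bias vector
(sd = σ_inter, their stable idiosyncratic reading of each sample) and fresh
per-replicate noise (sd = σ_intra, same units as the latent score), then
sort by perceived score. The defaults (10 observers, σ_intra = 0.10,
σ_inter = 0.22, two replicate sessions) were chosen so that a default
panel ranking 23 textures shows intra ≈ 23 and inter ≈ 37 STRESS units —
the consistency level of a careful human panel — and are frozen.

### What the benchmark shows — and does not

The end-to-end benchmark (24 textures of 128² px per replicate, 20
replicates; desk-scale sizes chosen so the whole suite runs in seconds)
reproduces the qualitative structure this pipeline is designed to detect:
luminance-channel σ correlates more strongly with the complexity scores
than chrominance-channel σ; global σ, Gabor σ, and CoM entropy form the
top tier of |r| well above the uniform LBP feature; intra-observer STRESS
stays below inter-observer STRESS; and the generating attribute weights
are recovered from rank scores within ±0.08 at 60 samples. Within the top
tier the sample ordering is not asserted — the three measures are
statistically close, and which one leads depends on generator details.

Passing these tests shows the chain is wired correctly and sensitive in
the intended directions. It does not show that the generator's textures
are perceptually faithful to woven textiles: real fabrics have anisotropic,
multi-scale structure, specular sheen, and correlated luminance–chroma
variation that the grating+noise model does not emulate, and real observer
noise need not be Gaussian or additive. Conclusions about real materials
require real images and real panels through the same interfaces.

### Numerical notes

Degenerate inputs are signalled, not silently patched: correlation of a
constant-margin co-occurrence matrix is NaN, kurtosis of a zero-variance
histogram is NaN, STRESS against a zero vector raises, inter-observer
STRESS needs two observers, rank-deficient designs raise with the
condition number. Quantization and histograms clip values into the
channel's nominal range; re-quantizing bin centers is the identity.
Entropies are base 2 throughout. All randomness flows through
`numpy.random.default_rng` seeds carried by the parameter objects, and
pipeline reruns with the same config and seed are byte-identical.

### Known limitations

Rank-order scaling discards metric information, so recovered model weights
are subject to the monotone warp of the rank transform; with the
regularity driver defined as 1 − randomness, the two rank-score columns are
near-collinear and that coefficient pair is the least stable. The H channel
is treated linearly although hue is circular. The correlation sweep's
distance/radius grids must be trimmed for images smaller than the
study-scale 1024² (the pipeline skips and logs infeasible entries).
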