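# Methods

## Detection model

The detector assumes dark-pupil imaging: the pupil is the darkest compact
region in an 8-bit grayscale eye frame. Color frames are first reduced to
Rec. 601 luminance. Two manual constants govern candidate extraction and
both default to the values used throughout the package's evaluation:

| parameter          | default | units | meaning |
|--------------------|---------|-------|---------|
| `threshold`        | 30      | intensity | strict cut: a pixel is candidate-pupil iff intensity < threshold |
| `min_segment_size` | 600     | px    | strict cut: a component is fitted iff its pixel count > min_segment_size |

The strict inequalities are deliberate: threshold 0 always yields an empty
mask, and "bigger than" filtering keeps the size parameter interpretable as
the largest ignorable blob. Connectivity is 8-connected, so diagonal pixel
chains (eyelash shadows) stay single segments. Coordinates are 0-based,
x rightward, y downward; subpixel centers are floats.

### Border extraction and the angle parametrization

Each surviving segment's convex hull is computed from its pixel
coordinates (Qhull). The hull polygon — not just its corner set — is then
sampled at ~1 px arc spacing; the decomposition treats the extracted
border as a curve, and corner-only input is degenerate for compact
rectangular segments (a 4-vertex hull under-determines a 7-coefficient
fit) and unstable for occluded pupils, whose truncation chord carries
almost no hull vertices.

For each border point the geometric angle φ about the reference point
(the arithmetic mean of the border coordinates) is computed as
`atan2(k̄ − y, x − h̄)`, i.e. mathematical y-up orientation despite y-down
storage. The "upward ellipse" model

    x(ω) = h − b·sin ω,      y(ω) = k + a·cos ω

places its ω = 0 point at (h, k + a), straight below the center on screen,
so the model's parametric angle is ω = −φ − π/2 (wrapped to (−π, π]; the
map is its own inverse). The wrap centers ω on the lower half of the
border, where the truncated bases below are most accurate; the poorly
approximated |ω| ≈ π region corresponds to the top of the pupil — the part
an eyelid occludes first, which in practice removes the worst-conditioned
points exactly when occlusion occurs.

### The truncated sinusoidal fit

sin and cos are replaced by their three-term Taylor truncations
Ps(ω) = ω − ω³/3! + ω⁵/5! and Pc(ω) = 1 − ω²/2! + ω⁴/4!, reducing the fit
to one ordinary polynomial least-squares problem per axis:

    x(ω) = c0 + c1·ω + c3·ω³ + c5·ω⁵        (odd, sine-like terms)
    y(ω) = d0 + d2·ω² + d4·ω⁴               (even, cosine-like terms)

Term-wise comparison with the truncated model identifies the ellipse:
h = c0, b = −c1, a = −2·d2, k = d0 − a. The bases span Ps and Pc, so data
generated from the truncated model is recovered exactly (to solver
precision), and the fitted curve passes through (h, k + a) at ω = 0. A fit
whose a or b comes out non-positive is kept for inspection but flagged
inadmissible; absolute-valuing negative amplitudes would promote
pathological segments. Rank-deficient designs (fewer than 4 border points,
fewer than 3 distinct angles, or angle sets too clustered to separate the
monomials) mark the segment non-fittable and it is skipped.

Among admissible fits the pupil is the one minimizing circularity
ρ = max(a, b)/min(a, b); ties (exactly equal ρ) go to the larger source
segment, then the smaller label, making selection fully deterministic. The
whole pipeline contains no randomness: identical frames and configuration
give bit-identical results.

### Known bias, asserted not corrected

On a complete circular border of radius r the truncated bases are poor
near |ω| = π, which biases the fitted center vertically. The test suite
asserts |k̂ − k| ≤ 0.2·r on dense full circles (measured ≈ 0.07·r) rather
than correcting it, keeping the fit faithful to its non-iterative design.
Eyelid occlusion introduces the second bias mode: with the top of the
contour replaced by a chord, the fitted center shifts toward the visible
half, up to ≈ 0.2 of the semi-minor axis at 30% occlusion. Both modes are
visible in the synthetic benchmarks and bound the achievable center error.

## Synthetic eye frames

The generator renders what the detector's intended inputs look like
statistically, not photometrically: a bright sclera field (intensity 190),
an iris disc (90), a dark pupil ellipse (5–20), optionally an eyelid band
that repaints the top fraction of the pupil with iris intensity (the way a
blink truncates the contour), eyelash-like dark bars (aspect ≈ 4) and dark
corner patches, a linear left-to-right illumination ramp, and clamped
Gaussian sensor noise. Rendering is a pure function of the scene spec
including its seed; datasets are byte-reproducible and each dataset writes
a manifest sufficient for exact replay.

Default sampling ranges describe a plausible head-mounted IR geometry at
640 × 480: pupil semi-minor axis 25–60 px, mild ellipticity (vertical
semi-axis up to 1.25× the horizontal — frontal pupils are near-circular,
which is the premise of circularity-based selection), occlusion up to 0.3
in half the frames, one or two distractors in half the frames, ramps up to
30 intensity levels, noise σ = 8. The degraded condition models harsh
outdoor footage: occlusion 0.4 in every frame, ramp 60, noise σ = 20.

What the generator does *not* emulate: corneal glints, IR speckle,
off-axis pupil perspective (projected ellipses here are axis-aligned),
motion blur, and real eyelash texture. Passing the synthetic benchmarks
therefore demonstrates the pipeline's geometric and statistical
correctness under controlled degradation, not field performance on any
particular camera.

## Accuracy criterion

Per-frame detection error is the Euclidean distance e between detected and
reference centers; two-rater annotations are merged by their midpoint
before comparison. The hit/miss criterion fits
f(x) = p₀ + pₛ·exp(−pᵣ·x) to the histogram of e (bin width 1 px by
default, normalized to a density, evaluated at bin centers; at least 4
non-empty bins required) by bounded nonlinear least squares with pᵣ
constrained positive, initialized at p₀ = min density,
pₛ = max − min density, pᵣ = 1/mean(e), tolerances 1e−10, at most 10,000
evaluations. The hit threshold is the x-intercept of the tangent to f at
x = 0, (p₀ + pₛ)/(pᵣ·pₛ); errors strictly below it are hits and the hit
percentage is the detection rate.

Two numerical notes. First, the histogram (rather than a kernel density or
the raw sorted sample) is the fitted object; the bin width is exposed.
Second, when the error sample is not actually decay-shaped (synthetic
clean batches produce a bell around the bias, not a spike at zero) the
optimizer drifts toward the nearly-linear regime pᵣ → 0 with pₛ large: p₀
and pₛ are then individually ill-determined, but the tangent's intercept
p₀ + pₛ and slope −pᵣ·pₛ — and hence the threshold — remain stable. The
threshold, not the raw parameters, is the quantity consumed downstream.

Cliff's delta, δ = (#{xᵢ > yⱼ} − #{xᵢ < yⱼ})/(nₓ·n_y), is computed by
sort-and-count (equivalent to exhaustive enumeration, verified in tests);
reporting uses |δ|. Omnibus and post-hoc rank tests, when wanted, are
delegated to standard statistics libraries and are not re-derived here.

## Gaze calibration

The PCP→PoR map is a 6-parameter affine transform fitted by least squares
to ≥ 3 non-collinear correspondences (5 in the cross protocol: center plus
four arm endpoints, arms 69 cm, viewing distance default 85 cm — the
midpoint of the 80–90 cm protocol range). An affine form is the simplest
map consistent with a "simplified" PoR method; a biquadratic extension
would need more fixation points than the 5-point cross provides and is
deliberately out of scope, as are glint-based and 3-D eye-model methods.
Angular error is arctan(planar offset / viewing distance) in degrees —
planar small-angle geometry, no eye model. With 1 px isotropic pupil
jitter at a plausible 0.16 cm/px gain this yields mean errors well under
half a degree; the synthetic geometry cannot reproduce any specific
hardware's accuracy figure, only the scaling.

## Problem sizes

The shipped benchmarks use 200 frames at default conditions and 150 at the
degraded condition, 10,000 draws for decay-rate recovery, 100 point sets
for the hull oracle, 20 borders for the fit oracle, and 500 simulated
fixations for calibration — sizes at which every quantity is stable to
well within the tolerances asserted, while the whole suite runs in well
under a minute of CPU.

## Limitations

- A global threshold cannot separate a pupil that overlaps a same-intensity
  distractor; the generator deliberately keeps distractors disjoint.
- Circularity-based selection presumes a near-frontal eye; strongly oblique
  viewing angles (projected ellipticity ≫ 1.25) would need the selection
  rule revisited.
- The fitted ellipse is axis-aligned by construction; rotated pupil
  ellipses are absorbed into (a, b) with some center error.
- Per-frame operation only: no temporal smoothing, no blink detection
  beyond the no_pupil status.
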