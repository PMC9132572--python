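# Methods

This note documents the models, parameters, numerical choices, and known
limitations of the package. Everything quantitative stated here is computed
by the test suite or the analysis scripts.

## Synthetic stimuli

An object is a tree of axial segments: a unit-length vertical root plus two
side branches (lengths 0.45–0.75, mostly lateral directions) attached at
random fractional positions. Candidate skeletons are drawn from a pool
(default 12) and the most mutually distinct ones selected by k-means over
pairwise skeletal distances — one representative per cluster — mirroring
how distinct exemplars are chosen from a larger generated family.

Surface forms are radius profiles along each segment,

r(t) = r₀ (1 − taper·t) + (bulge − concavity) sin(πt),

clipped below at a small positive floor, with `end_vertex` forcing r(1)=0
on terminal segments. The linear-taper + half-sine family realizes each of
the four non-accidental properties (taper, positive curvature, negative
curvature, convergence to a vertex) with a single parameter. The default
palette leads with maximally contrasting presets (strong taper + vertex
vs. bulge), so two forms differ in several NAPs at once.

Rendering is deliberately minimal: orthographic projection of the inflated
point samples as a union of filled disks, intensity shaded by local
thickness (silhouette mode by flag), object auto-scaled to 60% of frame
height, rotation palindromic from −30° to +30° and back (60° sweep at
12°/s; at the desk-scale default of 64×64 px this is 60 frames at 6 fps —
the schedule, not the frame rate, matches the full-scale 300-frame/30-fps
configuration, which remains available). What this omits relative to real
rendered 3-D stimuli: shading from lighting, self-occlusion,
perspective, and texture. Consequences are discussed under Limitations.

## Flux-based skeleton extraction

The Euclidean distance transform D is computed with the image border
treated as background. The average outward flux at pixel p is the mean of
⟨∇D(q), n̂(q)⟩ over 8 points q on a circle of radius 1.5 px around p
(central-difference gradient, bilinear interpolation). Away from the
medial axis ∇D is a unit, divergence-free field, so flux ≈ 0; medial
points are sinks with strongly negative flux (≈ −0.6 on a rectangle's
midline, measured).

Thinning removes *simple* pixels — those whose deletion preserves the
number of 8-connected foreground and 4-connected background components in
their 3×3 neighborhood (a 256-entry lookup table) — in order of decreasing
flux, so the least medial pixels go first. A curve endpoint with flux below
the threshold (default −0.4) is anchored as a skeleton endpoint; terminal
branches shorter than `min_branch_length` (default 5 px) are pruned
afterwards. The output is thin (no 2×2 block), a subset of the shape, and
homotopy-equivalent to it. Degenerate shapes thinner than 2 px everywhere
are returned unchanged with a warning flag.

Numerical notes: the flux threshold and branch length are exposed because
the published parameters of flux-based skeletonization algorithms are not
recoverable; the defaults pass the analytic disk/rectangle cases and the
brute-force maximal-inscribed-disk comparison with margin. The brute-force
oracle itself is reliable only on polygonal shapes — on digitized curved
boundaries nearly every interior pixel becomes a "maximal disk" center,
which is precisely the instability pruned skeletons exist to avoid.
"3-pixel Gaussian kernel" blurring is read as σ = 3 px (giving the decoder
a spatially extended target); a kernel-width reading (σ ≈ 1) is available
by argument.

## Stimulus metrics

*Skeletal distance*: symmetrized mean nearest-neighbour distance between
3-D axis point samples after rigid alignment — iterative closest point
(Kabsch updates, 30 iterations, tolerance 1e-10) restarted from the 24
proper rotations of the cube, no scaling. Symmetrization makes the
quantity usable as a premetric for clustering. Whether alignment should
allow scaling is genuinely open; the `align` flag and the unaligned
variant are both exposed.

*Exemplar selection*: classical (Torgerson) multidimensional scaling of the
distance matrix followed by k-means (50 restarts, fixed seed); each
cluster contributes its member nearest the centroid.

*Gabor jets*: 40 zero-DC complex Gabor filters (5 octave-spaced wavelengths
4–64 px at 256², 8 orientations), responses sampled on a 12×12 grid;
magnitude and phase per filter give vectors of length 11520. Images are
mean-centered before filtering so constant images respond exactly zero.
Two videos are compared by a paired t-test across vector elements per
frame pair, p-values averaged over frames (the averaged-p convention is
kept although it is statistically odd; a measured consequence is that the
p-value is *not* monotone in the size of the form difference, since
element-wise changes of both signs cancel in the mean — only detection
vs. identity is a reliable contrast).

## Habituation engine

Backbones are frozen functions of the video: `pixel` (identity),
`skeleton` (binarize → flux skeleton → blur), `flow` (Horn–Schunck
brightness-constancy + smoothness flow on adjacent frame pairs; smoothness
weight 0.001, 100 fixed-point iterations, 5 incremental warping refinements
at a single resolution — at 0.01 without warping the estimator recovers
under a quarter of a 2 px translation, measured), and `conv` (a fixed
random conv + ReLU + pooling layer standing in for pretrained feature
producers; any frame → feature-grid callable plugs in).

The autoencoder compresses to a *global* code: trainable 3×3 conv (16
channels) → ReLU → concatenated global max and average pooling → a
32-dimensional vector, matching the vector-valued (globally pooled)
outputs of object-recognition networks; the decoder is a single transposed
convolution whose 4096-pixel kernel spans the whole frame, i.e. the
reconstruction is a learned combination of 32 template images. This
bottleneck is what makes dishabituation informative: a spatially local
decoder generalizes across skeletons by translation equivariance and
flattens the error structure (measured during development), whereas the
template decoder is necessarily specific to the habituated video.

Reconstruction targets are the backbone's own representation image (for
`pixel` identical to the frame; for `skeleton` the blurred skeleton; for
`flow` the flow image); `conv` backbones reconstruct the raw frame. The
error signal therefore measures how well the *representation* of a test
object is captured by what was learned during habituation.

Training: Adam, learning rate 1e-2, batches of 4 frames in fixed order,
per-epoch error recorded by a post-update evaluation pass. The stopping
rule is shared verbatim with the infant analysis: mean error of the last
four epochs < 50% of the first four, evaluated from epoch 8, cap 100.
The learning rate and batch size are chosen so that the error trace has
plateaued when the criterion fires (it fires at epoch 8 on the default
stimuli): at 1e-3/batch-8 the loss is still halving per epoch at the stop,
which leaves the end-of-habituation reference inconsistent with the frozen
test error (dissimilarity diagonals at ~35% of the end level rather than
~1%, measured) and washes out normalized scores. Shorter videos supply
fewer updates per epoch; tests at 20 frames use batch 2 / lr 0.03 for the
same reason. All engine parameters are config-exposed.

Dissimilarity matrices habituate a fresh state per row and score every
catalog video with frozen weights; entries are test error minus the mean
error of the last four habituation epochs, so diagonals sit near 0 and the
matrix is asymmetric by construction.

## Classification and experiment design

Test responses are normalized by subtracting the end-of-habituation level,
clipped at 0 (negative dishabituation carries no classification signal),
and scored as novel/(novel+familiar), 0.5 when both clip to 0. The
counterbalanced design mirrors the infant experiments: each backbone is
habituated to every (skeleton, form) object; the familiar test object
shares the skeleton but swaps the form, the novel object differs in both.
Each (habituation object × novel skeleton) pair is one resampling unit
(12 units at 3×2); bootstrap CIs are percentile, 5000 iterations. The
surface-form classification task (familiar shares the form, both test
objects swap skeletons) is available as `task="surface_form"`.

## Infant statistics and the synthetic cohort

Looking-time records carry a 500 ms validity rule (invalid trials excluded
everywhere), a 24-trial habituation cap, and 6 alternating test trials
(3 per type, first type counterbalanced). Contrasts: different- vs
same-skeleton test looking, dishabituation per type against the last-four
habituation mean, first-test-trial vs last-habituation-trial discrimination
within each first-trial subgroup (paired), and a Welch test between
subgroups on first-trial looking.

Cohen's d for paired contrasts is t/√n (mean difference over SD of
differences); its CI is a seeded percentile bootstrap over difference
scores (10,000 resamples) — a bootstrap rather than noncentral-t choice,
so printed d-CIs elsewhere are not directly comparable. The JZS Bayes
factor integrates the noncentral-t likelihood against a Cauchy(0, 0.707)
effect-size prior with adaptive quadrature split at the prior mode and the
likelihood peak (absolute tolerance 1e-13); it agrees with an independent
fixed-grid quadrature and with pingouin to at least 4 significant digits.
Sign tests double the smaller exact binomial tail (capped at 1); under the
fair-coin null this coincides with the minimum-likelihood convention,
which is also exposed.

The generator: habituation looking times decay as B·decay^(t−1) with
multiplicative log-normal noise (defaults: baseline 20 s, per-infant
baseline CV 0.25, decay 0.85/trial, noise SD 0.3 on the log scale — a
regime in which most infants habituate between trials 8 and 14), truncated
at the criterion or 24 trials. Test trials center on the infant's observed
end-of-habituation level; different-skeleton trials carry a multiplicative
elevation e^m with m calibrated by root-finding on closed-form log-normal
moments (end-level moments estimated once from a fixed internal
simulation) so the population paired effect size equals the requested
Cohen's d. Calibration on the log scale keeps looking times positive.
What the generator does not emulate: attention drift across trials,
fatigue, trial-order effects, age effects, and any dependence of looking
on actual stimulus content — so passing recovery tests validates the
statistics pipeline, not a model of infant attention.

## Problem sizes

Default experiments run at 64×64 px and 60 frames per video with 3
skeletons × 2 forms; unit tests use 48×48/20-frame catalogs; simulation
tests use 100-seed replications at n = 200 infants. The full-scale
300-frame/256-px configuration is supported by the same code paths.

## Known limitations

- Disk-union rendering has no self-occlusion or shading; silhouettes are
  simpler than rendered meshes, which plausibly *reduces* the pixel
  model's difficulty relative to the original stimuli.
- The skeleton backbone operates frame-by-frame in 2-D; the 3-D skeletal
  distance is used only for stimulus construction and selection.
- Pretrained recognition networks are represented by the adapter interface
  and a random conv extractor only; conclusions about such networks cannot
  be drawn from this package.
- The flow backbone is a classical variational estimator; it underestimates
  large displacements and is evaluated only on small-motion stimuli.
- Classification scores clip negative dishabituation, so the score is
  informative only when at least one test response exceeds the
  end-of-habituation level.
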