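# Methods

This note documents the models, parameter choices and numerical decisions
behind `larvaquant`, and what its synthetic benchmarks do and do not show
about real recordings.

## Behavior video model

The synthetic larva is a capsule — a rectangle of half-width *w* and length
*L* with semicircular caps — bent along a constant-curvature arc. Arc
length is preserved under bending, so the silhouette area has the closed
form *A = 2wL + πw²* regardless of posture, which is what makes end-to-end
area recovery checkable to sub-percent accuracy. A contraction episode
scales the area by a scheduled fractional change (both *w* and *L* scale by
√(1+c)) with linear 0.2 s on/off ramps; the ramp length is a modelling
choice (real CT kinetics are smooth but unspecified) that avoids
single-frame step artifacts. The body crawls at a constant speed with a
random-walk heading, reflects off the image margins, and oscillates a bend
mode (period 1.5 s, amplitude 0.5 rad) so that a moving animal produces
nonzero mobility after stabilization; motion and bending halt inside
scheduled freeze windows.

Gray levels follow dark-field imaging: dim background (20), bright body
(150), Gaussian pixel noise (SD 3, clipped to 8 bits). The body
additionally samples a static, smooth, *bright-skewed* illumination mottle
(|Gaussian field|, SD 8, correlation ~2 px). Two reasons: real larvae have
cuticle/gut texture, and a broad foreground gray-level mode keeps
histogram-based auto-thresholds well conditioned. On a strictly two-level
noisy image, Huang's fuzzy-entropy threshold has a shallow global minimum
just below the foreground mode (trimming the foreground tail tightens the
foreground class mean at almost no entropy cost), which shaves body pixels;
a textured foreground with a sharp lower edge removes that degeneracy. The
rendered frames are honest about this limitation: they emulate contrast,
texture, noise and motion, not photorealistic optics (no PSF, no
anti-aliasing, no multi-animal arenas), so passing tests demonstrate
pipeline correctness, not robustness to every field artifact.

## Segmentation and stabilization

Per frame: auto-threshold (Huang for whole-body segmentation, Moments for
soma detection — both implemented from the ImageJ algorithm definitions,
since scikit-image ships neither), then outlier removal → erosion (disk,
radius 2 px) → outlier removal → dilation (same element). Outlier removal
is symmetric, as in ImageJ's median-style "Remove Outliers": foreground
components smaller than `min_blob_px` (20) are deleted *and* enclosed
background holes smaller than the same bound are filled. Running it before
erosion matters: erosion blows a 1-px pepper hole up to ~20 px, past the
healing bound. If several components survive, the largest is kept and the
frame flagged; empty frames are flagged, and more than 10% empty frames
aborts. Kernel radii are configurable; the defaults are the smallest that
remove speckle without distorting a ~16-px-wide body.

Stabilization translates each frame by the integer-rounded offset that
moves the mask centroid onto the first valid frame's centroid (pure shift,
zero fill). Flagged frames reuse the previous offset. Area is a pixel
count and therefore exactly translation-invariant; mobility (newly
occupied pixels, one-sided set difference) is computed only on stabilized
masks. The one-sided difference follows the printed subtraction
convention; a symmetric-difference variant is available via a flag since
shrink-only motion scores zero one-sided. Invalid frames carry the last
valid value, capped at 5 consecutive fills.

The per-animal immobility flag uses the *stimulus-average* mobility change
(≤ −25%), not an any-frame rule: per-frame new-pixel counts are noisy
enough that any-frame would label essentially every animal immobile.
Immobility *duration* remains the frame-wise time at or below −25%.

## CT scoring

"At or below −10% for at least 0.5 consecutive seconds" is discretized as
≥ `ceil(0.5 × frame_rate)` consecutive frames with an inclusive
comparison; an *n*-frame run lasts *n/frame_rate*. Frame resolution is the
native measurement unit — no sub-frame interpolation. Events are detected
inside the scoring window, and events crossing the stimulus boundary
contribute only their in-window portion to CT duration. CT magnitude is
the mean percent change over the stimulus window, filled frames included
(fills are rare by construction and excluding them would bias long CTs).
The detector is verified against an independent run-length enumeration
oracle on 1,000 random noisy traces — exact agreement, not tolerance.

## CaMPARI ratiometry and Sholl profiles

"Area-normalised intensity" is read as mean intensity per ROI pixel, so the
soma ratio is (mean red)/(mean green) — invariant to common gain. Soma
detection Moments-thresholds the green channel, erodes with a 3-px disk
(stripping dendrites), filters component areas to a configured band, and
dilates back. Sholl annuli are Euclidean-distance shells [r, r+5) at 1-px
steps from the soma centroid, kept overlapping as specified, intersected
with the neuron mask; annuli with fewer than 5 mask pixels are reported
missing rather than averaged over a handful of pixels. Channels are
assumed registered (single-detector two-channel acquisition); no
registration step exists.

## ΔF/F and epoch analysis

ΔF/F is baselined to the mean over the 15 s before the first stimulation
epoch (configurable for the muscle paradigms, which use 45 s / 20 s
baselines). Per epoch the max, time-of-max and trapezoidal AUC are taken
over [onset, offset + 5 s]; the 5 s tail captures responses that peak
after light-off. No photobleaching correction is applied by default.

Two statistical points shaped the design. First, the raw max of a noisy
trace is a biased amplitude estimator (it rides the noise's upper
envelope), so population-level epoch amplitudes should be read from the
trial-averaged trace — the convention used for plotting mean responses —
and `epoch_stats` additionally offers an optional moving-average smoother
for peak reads (default off, so the reported max is the exact sample max).
Second, the trace generator's multiplicative noise is a smooth Gaussian
process (SD 2% of F, correlation time 2 s) rather than white: ROI-averaged
in-vivo fluorescence noise is dominated by slow sources (focus drift,
motion, hemolymph movement), and per-frame shot noise on a many-pixel ROI
mean is comparatively negligible. White noise remains available via
`noise_tau_s = 0`.

Muscle responses are grouped anterior (T1–A1) / central (A2–A5) /
posterior (A6–A8) by segment, and DL/DO, LT, VL/VO by spatial muscle
group. The default muscle-number-to-group mapping follows the standard
larval body-wall nomenclature and is an overridable argument, since group
membership is a nomenclature convention rather than a measurement.

## Phenotype clustering and connectivity

The genotype × 7-metric percent-change matrix mixes seconds and
percentages, so columns are z-scored before embedding/clustering
(`standardize=False` reproduces raw-scale clustering). Percent change from
control is 100·(x − c)/|c|; a zero control falls back to the absolute
difference in points, flagged. t-SNE uses PCA initialisation and a fixed
seed (deterministic by contract), perplexity 5 (~n/4 for ~20 genotypes).
Hierarchical clustering is Euclidean/complete via scipy linkage, cut at
k = 5 by default; merge-height ties resolve by scipy's deterministic
(row-order) pair ordering, cluster ids are renumbered in order of first
appearance, and a Newick export (quoted labels) supports inspecting other
cuts. Percent synaptic input is computed from an edge-list adjacency table;
the behavior correlation is Spearman by default (robust over a small n with
known outliers), Pearson by flag.

## Configuration and reproducibility

`RunConfig` (pydantic, unknown keys rejected) holds every stage parameter
with the assay defaults: −10% / 0.5 s CT, −25% immobility, 5 s baseline +
5 s stimulus, 5-px annuli at 1-px steps, 15 s prestimulus, k = 5. A single
seed fans out to per-stage seeds by stable hashing (all below 2³¹), so
stages re-run independently yet reproducibly; outputs carry the config's
SHA-256 hash.

## Benchmark problem sizes

The end-to-end behavioral benchmark uses 200 larvae (120 in the standalone
reproduction script) at 15 frames/s, 112×112 px, 10 s recordings with one
scheduled episode (onset 2.5–3.5 s, duration 0.5–5 s, depth 20–35%) in
half the cohort — small enough to render and segment in minutes while
leaving duration quantization (1/15 s) well below the 1-frame recovery
tolerance. Ratiometry and ΔF/F recovery use 20 replicate seeds; cluster
recovery uses 100 draws of five centers separated by ≥ 6× the
within-cluster SD.

## Known limitations

Single-animal videos only (no multi-larva tracking or posture analysis);
no optics simulation; channel registration and stack stabilization for
fluorescence input are assumed done upstream (traces or stabilized stacks
in, ROI masks supplied); connectivity is consumed as a table, never
reconstructed. Synthetic benchmarks certify the measurement chain against
known ground truth — they cannot certify segmentation robustness on
footage whose artifacts (shadows, reflections, occlusions) the generator
does not model.
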