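# Methods

This note documents the models behind the three pipelines, the
synthetic-data generators that stand in for raw microscopy, the
numerical choices, and the limits of what the tests demonstrate.

## 1. Single-particle tracking and mobility analysis

### Motion model

A molecule occupies one of three diffusive states — immobile, slow,
fast — and switches between them by a per-frame Markov chain.  In state
*s* the true displacement per frame is Gaussian with per-axis variance
2·D_s·Δt.  Defaults follow the live-cell acquisition the pipeline is
designed for: Δt = 0.032 s, 100 nm pixels, 256×256 field, 2000 frames.
The default state coefficients are the class-representative values
D = (0.003, 0.03, 1.5) µm²/s — the geometric centres of the immobile
[0.001, 0.01) and slow [0.01, 0.1) intervals and the typical fast
coefficient.

Boundary behaviour: steps crossing the nuclear-mask edge are specularly
reflected (the crossing point is found by bisection along the step, the
remaining displacement mirrored across the local tangent obtained from
the gradient of a signed distance field of the mask).  Specular
reflection preserves uniform occupancy — a naive "reverse the step"
rule measurably piles density toward the nucleus centre under fast
diffusion, which is why the geometric version is used.  After
reflection the position is clamped to the pixel-mask definition of
"inside" (nearest pixel true), so mask containment is exact.

Localization error is applied to *reported* positions only
(x_obs = x + N(0, σ_loc)), the standard SPT camera model; it does not
feed back into the dynamics.  Photobleaching truncates each track after
a geometric lifetime (default mean 1/bleach_prob = 100 frames for
movie rendering; the recovery experiments use mean 40 frames, a
realistic JF549 budget).  The camera model renders each visible
molecule as a pixel-integrated 2D Gaussian (erf differences, so the
photon integral is exact), adds a constant background and applies
Poisson shot noise.

Defaults the source acquisition does not determine and that are fixed
here as fixtures: σ_loc = 30 nm, 500 photons/spot, PSF σ = 100 nm,
background 10 photons/px.

### Detection and linking

Detection: local maxima above a fixed intensity threshold inside the
nuclear mask; sub-pixel refinement by least-squares 2D Gaussian fit in
a 7×7 window with an intensity-weighted centroid fallback; detections
closer than one PSF width merge into the brighter one.  The threshold
is a required input; a helper computes mean + k·sd of the masked pixels
(default k = 6).

Linking: greedy global nearest neighbour per frame transition —
candidate (track-end, detection) pairs within the 1.2 µm displacement
cap are processed in ascending distance with ties broken by lower track
id, each end and detection used at most once; ends stay linkable across
one missing frame (gap 1) under the same cap; tracks shorter than five
detections are discarded.  On instances with well-separated particles
this greedy rule provably coincides with the minimal-total-distance
assignment, which the tests verify against an exhaustive matcher.  No
positions are interpolated into gaps.

### Tracklet segmentation

Tracks are partitioned into single-state tracklets by a 3-state
Gaussian hidden Markov model on per-step log squared displacements.
Because r² = (2 D Δt + 2 σ_loc²)·χ²₂ for state D, the emission
parameters need no fitting: mean_s = log(2 D_s Δt + 2 σ_loc²) +
E[log χ²₂] and variance ψ′(1) = π²/6 for every state, with
E[log χ²₂] = log 2 − γ.  The transition prior is sticky (p_stay = 0.94)
and the path is decoded by Viterbi.  Decoded runs shorter than
min_segment_length = 5 frames are merged into the neighbouring run with
the closer emission mean.  A fixed-parameter decoder was chosen over
per-track EM deliberately: per-track EM with ~40 observations and three
components is degenerate and non-deterministic, while the closed-form
emissions make segmentation reproducible and accurate wherever states
are separated (an immobile→fast switch is located within ±2 frames;
immobile/slow borders are soft, which is tolerable because final class
labels come from the MSD fit, not from the decoder).  Steps across a
detection gap are variance-normalized by the frame span.

### Diffusion estimation and classification

For each tracklet of ≥ 10 frames, the time-averaged MSD (all pairs,
gaps excluded) is fit by OLS over the first 4 lags with a free
intercept; D_app = slope/4; the intercept absorbs 4σ_loc².  Negative
slopes are clipped at D_floor = 1e-4 µm²/s and classified immobile, as
are all values below 0.01 (the bins are half-open: immobile < 0.01 ≤
slow < 0.1 ≤ fast).  Four lags is the standard short-lag bias/variance
compromise.  The per-cell immobile fraction is count-weighted
(immobile tracklets / classified tracklets × 100).  Conditions are
compared by a Welch two-sided t-test on per-cell fractions with a
1e-12 variance floor so degenerate zero-variance groups remain
comparable.

At these conditions the classifier confuses immobile↔slow at ~2–4%
per class (fast is essentially never confused), a nearly symmetric
leakage whose net bias on the immobile fraction is below one point.

## 2. SFM morphometry

### Generator

Particles are drawn from an oligomer-class mixture; a class's volume is
V₁ × a multiplier sampled uniformly inside its bin but away from the
bin edges (monomer 0.75–1.35, dimer 1.7–2.7, 3–4mer 3.4–5.3, >tetramer
7–14), so that the few-percent volume loss of thresholded integration
cannot flip a class.  V₁ defaults to 418 nm³ (≈ 1.2 nm³/kDa for a
~380 kDa chain).  Shapes are flat-topped templates with a smooth edge
(protein images as plateau-like blobs): a compact disc whose footprint
radius scales as V^(1/3) (10 nm at V₁); a stadium-shaped rod with axis
ratio 1.8–3.5; and an extended core-plus-three-arms template whose arm
length is solved by bisection so the orientation-averaged template
solidity equals a target (default 0.75).  Template heights are
normalized so Σh·Δx² equals the assigned volume exactly.  Free-RAD51
contaminants are compact 56 nm³ particles.

Tip broadening is volume-preserving Gaussian smoothing (σ = 3 nm,
consistent with a < 10 nm tip radius) rather than geometric dilation,
keeping the volume oracle exact.  Scan artifacts: a background plane
(default 2 nm drop per image width, random orientation), per-scan-line
offsets (σ = 0.15 nm) and white height noise (σ = 0.08 nm).

### Analysis

Flattening estimates the background on particle-free pixels (robust
4-MAD height cut), removes per-line medians, then subtracts a
least-squares plane, iterating twice; the output background median is
zero.  An already-flat field passes through unchanged (idempotence).  Segmentation takes 8-connected components above a height
threshold (default 0.5 nm), discarding components smaller than 10 px or
touching the border.

Per particle: volume = Σ heights × Δx²; area = pixel count × Δx²;
solidity = pixel count / convex-hull area, with the hull computed on
pixel *corner* points (each pixel a unit square) and its area by the
shoelace formula — under this definition a filled rectangle scores
exactly 1 and a plus of five squares scores 5/7.  Pixel-hull solidity
of a digitized disc is 1 − O(1/R) (≈ 0.93 at 24 px diameter), an
inherent staircase effect shared by all pixel-based definitions; the
tests assert that behaviour rather than an idealized 1.  Axis ratio
comes from the second-moment equivalent ellipse (deterministic and
rotation-covariant; minor axis floored at one pixel); rod iff
ratio > 1.5 strictly.

Oligomer classification bins measured volume in units of V₁ at
0.5 / 1.5 / 3 / 6 (geometric midpoints between 1, 2, 4 and 8 chains);
volumes below the exclusion threshold (100 nm³ — above the 56 nm³
RAD51 monomer, below any plausible half-V₁) or below 0.5·V₁ are
excluded from all denominators.  Because thresholded integration loses
a size-dependent few percent of volume into the sub-threshold skirt,
V₁ is a *measured* quantity: `calibrate_monomer_volume` takes the
median of the mode-seeded lowest cluster of measured volumes from a
monomer-rich control set, and the recovery experiments calibrate V₁
this way before classifying condition images, which cancels the
systematic loss.

## 3. Foci quantification

Nuclei: maximum-project the DAPI stack, threshold by iterative minimum
cross-entropy (Li, tolerance 0.5), fill holes, declump touching nuclei
by watershed on the distance transform (peak separation 10 px), drop
border-touching components and those outside plausible area bounds.
EdU gate: integrated per-nucleus EdU intensity strictly above 500 au.

Foci, per nucleus: background and spread are the two-sided 5%-trimmed
mean and sd of the masked projection pixels, with the sd divided by the
truncated-normal shrink factor (≈ 0.79 at 5%) so it estimates the true
σ of Gaussian background — without that correction a focus-free
nucleus yields spurious detections at the k = 2 threshold.  The focus
threshold is background + 2·spread; components of ≥ 4 px (at 132 nm/px,
rejecting sub-diffraction specks) become foci with background-
subtracted integrated intensities.  Estimating background per nucleus
rather than per image respects nucleus-to-nucleus stain differences.
Group summaries report foci per EdU+ nucleus and per-focus intensity,
with fold changes relative to an untreated reference; a Wilcoxon
rank-sum helper compares per-nucleus counts.

The generator places non-overlapping nuclear discs, 3D Gaussian foci
(σ_xy = 1.2 px, σ_z = 1 slice, by default centred on the middle slice,
reflecting autofocus) over a nuclear background, and per-nucleus
uniform EdU at one of two levels; foci keep a minimum separation
(default 5 px) because unresolvably close spots are a single focus to
any intensity-threshold detector.  The EdU channel carries lower noise
than the stain channels: the 500 au gate acts on a maximum projection,
whose noise bias scales with slice count and nucleus area.

## 4. Recovery experiments (`repairscope.experiments`)

The experiments fix the generator ground truth at the characterized
values of the full-length system and measure what the pipelines return:

- Mobility composition: per-cell mixtures with immobile tracklet
  proportion 34% (untreated) or 41% (irradiated), remainder split
  equally between slow and fast; 20 cells × ≥ 300 usable tracklets,
  identity transition matrix so the ground-truth tracklet proportion is
  exact by construction; the reported value is the median per-cell
  immobile percentage after the full segment → MSD → classify → summary
  chain.
- Fast diffusion: pure fast-state tracks at D = 1.5 µm²/s in a
  boundary-free field; mean D_app over ≥ 500 fast-classified tracklets.
- Oligomer mixtures: 10 images × ~35 particles at the full-length
  composition (70% >tetramer) and the +RAD51 composition (74% monomer,
  18% dimer) with 30% free-RAD51 contaminants; V₁ calibrated on a
  4-image monomer control set; percentages among non-excluded
  particles.
- Solidity mode: ≥ 200 extended particles tuned to template solidity
  0.75; modal 0.05-wide bin of the measured solidity histogram.

Problem sizes were chosen so each experiment finishes in seconds to a
minute on one CPU while keeping sampling error well inside the
recovery tolerances (e.g. the median over 20 cells has sd ≈ 0.7
points).

## 5. What the synthetic data does and does not show

The generators reproduce the statistical structure the analyses assume:
Markovian state switching with Gaussian steps, plateau-like particles
with conserved volume, disc nuclei with Gaussian foci.  They omit, by
design: motion blur within the 30 ms integration window, anomalous or
confined sub-diffusion beyond the 3-state switch, optics-accurate PSFs
(no Airy/Gibson–Lanni), AFM tip-shape geometry beyond isotropic
Gaussian broadening, DNA molecules in height images, chromatin texture
in nuclei, and 3D focus structure (quantification is on maximum
projections).  Passing recovery tests therefore demonstrates that the
pipelines are unbiased estimators *under the stated model*, not that
the model captures every property of real cells; on real data the
immobile fraction, volumes and focus counts inherit any mismatch
between these assumptions and the sample.

## 6. Degenerate inputs and tie-breaks

Empty masks, constant images, all-excluded particle sets, groups of
fewer than two cells and sub-3-pixel masks raise `ValueError` rather
than returning silent defaults.  Stationary tracks produce log r² of
the numerical floor (ε = 1e-12 µm²) and decode as immobile.  Linking
ties are broken by lower track id; classification bins are half-open
with sub-floor values mapped to immobile; the Li threshold uses a 0.5
intensity-unit convergence tolerance.  All randomness flows from one
seeded generator per call (`numpy` `default_rng` with per-purpose
streams), so identical parameters and seed give bit-identical output.
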