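# repairscope

Quantitative imaging analysis of the dynamics and molecular architecture
of nuclear DNA-repair proteins (BRCA2-type systems), in three pipelines
that share one package:

1. **Single-particle tracking (SPT)** — detect HaloTag-labelled
   molecules in live-cell movies, link them into tracks, segment each
   track into *immobile / slow / fast* tracklets, and estimate apparent
   diffusion coefficients from MSD slopes.  The per-cell **immobile
   fraction** (percentage of tracklets with
   D_app < 0.01 µm²/s) is the readout of DNA-damage-induced chromatin
   binding.
2. **Scanning-force-microscopy (SFM) morphometry** — flatten height
   images (nm), segment particles, and measure volume
   (V = Σh·Δx², binned in units of a monomer reference volume V₁ into
   monomer / dimer / 3–4mer / >tetramer), **solidity**
   (mask area / convex-hull area; ~1 = globular, lower = extended) and
   rod shape (major/minor axis ratio > 1.5).  Free RAD51 monomers
   (56 nm³) are excluded below a volume threshold.
3. **Nuclear foci quantification** — segment nuclei from DAPI maximum
   projections (minimum cross-entropy threshold + watershed), gate
   S-phase cells by integrated EdU intensity (> 500 au), and detect
   repair-protein foci by robust-background thresholding
   (trimmed mean + 2·sd per nucleus), reporting per-nucleus counts and
   background-subtracted integrated intensities.

The study's raw microscopy is not redistributable, so the
`repairscope.simulate` subpackage generates all three modalities with
known ground truth — 3-state switching Brownian motion rendered through
a camera model (32 ms frames, 100 nm px), height maps of particles with
assigned volume/shape plus scan artifacts (2×2 µm at 512×512 px), and
confocal stacks with nuclei, diffraction-limited foci and EdU labels
(11 slices, 132 nm px) — making every stage testable end to end.

## The model in brief

A tracked molecule switches between three diffusive states by a
per-frame Markov chain; in state *s* its displacements are Gaussian
with per-axis variance 2·D_s·Δt.  Observed squared steps then follow
r² ~ (2 D_s Δt + 2σ_loc²)·χ²₂, so log r² is (approximately) Gaussian
per state — the basis of the 3-state hidden-Markov tracklet segmenter,
decoded by the maximum-likelihood (Viterbi) path.  For each tracklet
(≥ 10 frames), the time-averaged MSD is fit over the first 4 lags with
a free intercept (which absorbs localization error) and
D_app = slope/4; classes are immobile [<0.01), slow [0.01, 0.1) and
fast (≥ 0.1 µm²/s).

## Worked example

```python
import numpy as np
from repairscope.simulate import SPTSimParams, simulate_tracks
from repairscope.mobility import analyze_cell_tracks, compare_conditions

params = SPTSimParams(n_particles=400, n_frames=200, bleach_prob=1/40,
                      transition_matrix=np.eye(3),
                      initial_state_probs=[0.34, 0.33, 0.33], seed=1)
tracks = [t for t in simulate_tracks(params) if len(t) >= 10]
table, summary = analyze_cell_tracks(tracks, cell_id="cell-1")
print(f"{len(table)} tracklets, immobile fraction "
      f"{summary.immobile_fraction:.1f}%")
print(table.groupby("mobility_class")["D_app"].mean().round(4))
```

prints

```
339 tracklets, immobile fraction 37.2%
mobility_class
fast        1.4576
immobile    0.0034
slow        0.0306
Name: D_app, dtype: float64
```

i.e. a synthetic cell generated with 34% immobile tracklets is
recovered at 37.2% (a single cell of ~340 tracklets carries a sampling
sd of about 2.6 points; the median over 20 such cells lands within a
point of the truth), and the class-mean apparent diffusion coefficients
sit at the expected values (the fast class near 1.5 µm²/s; immobile
and slow at their interval centres).  `compare_conditions` then gives
the Welch two-sided t-test between groups of per-cell fractions.

A command-line interface runs the same stages on files
(`repairscope simulate-spt | track | mobility | simulate-sfm | sfm |
simulate-foci | foci | report`), each writing CSV/TIFF outputs plus a
resolved config and a JSON run manifest.

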