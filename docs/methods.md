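# Methods

`vesselfish` implements a pixel-profile decoder for combinatorial
smFISH (100-plex "Molecular Cartography"-style assays) together with
the downstream vascular quantification it feeds: spatial binning of
transcripts, marker-based vessel segmentation, caliber classification
and rank-sum group statistics, plus a separate low-plex (RNAscope-like)
image quantification chain. A synthetic-data module generates every
input the pipeline consumes, so the whole chain is testable without
instrument data.

## Combinatorial coding model

Each gene carries a binary code of length `n_rounds × n_channels`
(default 8 × 2 = 16 slots, round-major, channel-minor order). Codes are
fixed-weight (default 4 on-bits) with minimum pairwise Hamming distance
4, so two codes never share more than two on-bits. A configurable
number of valid codes is reserved as *unused*: decoded signal landing
on them estimates the false-positive rate,

    specificity ratio = (unused hits / n_unused) / (used hits / n_used),

zero on clean data, ≈1 when assignments are random across codes.

Code generation visits candidate codes in a seeded random order and
keeps those respecting the distance constraint. Random visit orders
pack poorly near the combinatorial limit (~100 of the 140 possible
weight-4/distance-4 codes), so when the request exceeds what the random
pass found, the generator falls back to the lexicographic greedy pool —
which attains the 140-code maximum — and draws the requested number
from it with the same seed. Generation is deterministic per seed and
validated (weight, distinctness, pairwise distance) on every call.

## Spot detection

Detection runs per (round, channel) stack:

1. **Per-plane maxima.** Strict local maxima (greater than every
   neighbor within a square radius, default 2 px; −inf boundary padding
   so edge pixels are compared only against real neighbors). Each plane
   keeps at most `floor(slice area in µm² × 0.5)` candidates, brightest
   first. Per candidate we record Babs (pixel value), Bback (median of
   a 3–5 px annulus) and Bperi (mean of the 8-neighbor ring), and
   refine the position to sub-pixel precision with an intensity-weighted
   centroid over a 5×5 window above Bback. Integer-quantized features
   would contribute ±0.5 px noise that dominates the registration error
   budget.
2. **z-linking.** Candidates on adjacent planes within 2 px in xy are
   linked; groups are the transitive closure, and maxima with no
   adjacent-plane neighbor are discarded (a real diffraction-limited
   spot spans several planes).
3. **Iterative margin filter.** A single threshold applied to both
   margins Babs−Bback and Bperi−Bback is tuned by bisection (≤30
   iterations; survival count is monotone in the threshold) until at
   most `floor(volume in µm³ × factor)` groups survive with ≥2 members
   each. Each surviving group emits one feature: its brightest member,
   with a margin-weighted mean plane as the z coordinate.

## Registration

Each round's feature cloud (both channels pooled) is aligned to round 1
by rigid ICP: mutual-nearest-neighbor correspondences alternate with
the closed-form Procrustes (Kabsch) update; iteration stops when the
residual changes by <1e-6 px or after 100 iterations. Two robustness
layers address the fact that different rounds light up different
transcript subsets (two weight-4 codes co-light a given round pair for
only ~20–25 % of spots):

* **Trimming** — only the closest 50 % of mutual-NN pairs enter each
  update, so points present in one cloud only cannot drag the fit.
* **Multi-start** — the pipeline seeds ICP from a coarse grid of
  initial translations (±6 px xy at 3 px steps, ±1 plane) and keeps the
  run with the lowest trimmed RMS, because plain ICP only converges
  from within about half the typical spot spacing.

On noise-free rendered rounds with planted offsets ≤5 px / 3°, the
recovered transforms invert the planted ones to well under 0.1 px / 0.1°
(full overlap) and ~0.1–0.3 px under partial overlap. Stacks are then
resampled by tri-linear interpolation at the inverse transform
(`grid-constant` boundary handling: edge-plane samples interpolate
against the zero fill instead of being zeroed outright; genuinely
out-of-field samples are 0). A round whose images carry almost no spots
(possible in small synthetic panels) keeps the identity transform.

## Decoding

* **Profiles.** Registered stacks are stacked into one 16-vector per
  voxel.
* **Concentration score.** s = n·Σv²/(Σv)², the variance from zero
  normalized by total brightness, scale-invariant with s = 1 for a
  uniform profile and s = n for a one-hot profile; a profile with
  exactly w equal on-bits scores n/w. Default threshold 2 (empty
  profiles removed outright).
* **Code matching.** Cosine similarity between the profile and every
  binary code (used and unused); a pixel is assigned its argmax gene if
  the similarity reaches 0.7 and the argmax is unique, otherwise left
  unassigned. Cosine matching makes assignment invariant to global
  intensity scaling.
* **Grouping.** Same-code voxels form 6-connected components, retained
  if they have ≥2 voxels, every member has a face-adjacent same-group
  neighbor (implied by 6-connectivity at size ≥2, asserted anyway), and
  the bounding box spans ≥2 voxels along ≥2 of the 3 axes — isolated or
  purely linear pixel runs are noise.
* **Localization and validation.** The transcript position is the group
  voxel maximizing summed on-bit intensity. It must be corroborated by
  a strict 26-neighborhood local maximum within 2 px (±1 plane) in at
  least `weight − 1` of the code's on-bit *images*; groups assembled
  over smooth background fail this. The recorded code score is the
  cosine fit at the chosen voxel.

On noise-free, offset-free scenes this chain recovers 100 % of planted
transcripts with ≤1 px position error, exact per-gene count
conservation and zero unused-code hits; with planted offsets the
registered chain matches the offset-free recovery.

## Binning and vessel quantification

Transcript x/y coordinates are assigned to fixed square tiles of pitch
50 px (~7 µm at 0.138 µm/px); tile centroids sit at (i+0.5)·pitch, so
the assignment is nearest-centroid for interior points and
deterministic on boundaries. z is ignored. Bins with fewer than two
expressed genes or fewer than two total counts are dropped; marker
rules then subset bins (e.g. arterial: VWF ≥1 and GJA5 ≥1; vasculature:
any of VWF/MYH11/KCNJ8 >0 and TTN = 0). Gene–gene co-expression across
bins uses Pearson correlation with zero-variance genes dropped and
reported.

Marker-positive bins are grouped into vessels by single-linkage
agglomerative clustering cut at 1.5 × pitch — exactly the
8-neighborhood connected components of the bin lattice. Clusters under
5 bins are removed; survivors are *larger* caliber when they exceed 30
bins, *smaller* otherwise. Per vessel and gene we report the percentage
of bins expressing (count ≥1) and the mean count over expressing bins
only; the mean is flagged undefined when no bin expresses. Group
comparisons use the two-sided Wilcoxon rank-sum test — exact null
enumeration when the smaller group has ≤8 observations and the pooled
sample is tie-free, the tie-corrected normal approximation with
continuity correction otherwise — with Benjamini–Hochberg adjustment
across all genes tested in one comparison run. Because it is not
settled whether vessels or bins are the natural replicates for the
mean-expression contrast, `compare_calibers` treats vessels as
replicates (one value per vessel) and labels the metric; pooled-bin
variants can be formed from the per-bin counts directly.

## RNAscope quantification

Each 8-bit channel passes (1) subtraction of a σ=50 px Gaussian blur of
the raw image with negatives clipped to 0 — the blur estimates smooth
illumination; (2) rolling-ball background subtraction, radius 50 px
(grayscale opening with a ball element, via scikit-image); (3) an
intensity floor: values below 40 are zeroed, so outputs are either 0 or
≥40. The ROI is tiled into square bins with the per-channel maximum
recorded per bin; a bin "expresses" a channel when its max is positive.
For co-expression, ACTA2⁺∧CDH5⁺ double-positive bins are excluded first
and the fraction of ACTA2-only and CDH5-only bins positive for the
target (TINAGL1) is reported, with empty denominators flagged rather
than silently zeroed.

## Synthetic data: what it emulates and what it does not

The generator renders point transcripts as anisotropic 3D Gaussians
(σ 1.2 px lateral / 0.8 plane axial, amplitude 200 on background 10)
into exactly the images of their code's on-bits, applies per-round
rigid offsets to rounds ≥2, and adds constant background with optional
Gaussian read noise and Poisson resampling. Vessel scenes are annular
rings of marker-positive bins: every wall bin gets two pan-EC (VWF) and
two type-marker (GJA5 or ACKR1) transcripts, and the caliber-dependent
gene (SULF1 analogue) is emitted per bin as a Bernoulli draw at rate
0.6 in vessels covering >30 bins and 0.2 otherwise — the planted analogue
of higher SULF1 prevalence in larger arteries. Transcripts keep a 5 px
minimum 3D separation so they remain resolvable after rendering.
RNAscope fixtures are 2D Gaussian blobs with known channel membership,
clipped to 8-bit.

Not emulated: realistic PSFs and chromatic aberration, tissue
autofluorescence and structured background, probe-level efficiency
differences, cell morphology, and optical crowding at densities where
spots overlap within the diffraction limit. Passing tests therefore
demonstrate algorithmic correctness under the stated forward model, not
instrument-level performance on tissue.

## Numerical choices and problem sizes

Ties in candidate brightness break by (z, y, x); bisection uses ≤30
iterations over a bracket guaranteed to satisfy the budget at its upper
end; the decoder's unique-argmax rule breaks cosine ties toward
"unassigned"; BH adjustment caps at 1 and restores input order.
Default analysis sizes used by the test-suite and the acceptance
script: decoding scenes of 192×192×10 px with 100 genes, 20 unused
codes and 200 transcripts; registration clouds of 200 points; vessel
scenes of 4096×4096 px at pitch 50 with ring radii 260/150/55 px
(36/20/4 wall bins — larger, smaller, and sub-threshold decoy);
RNAscope fixtures of 256×256 px. These sizes exercise every decision
boundary (30-bin caliber split, 5-bin minimum, 16-slot profiles) while
keeping a full run in seconds.

## Known limitations

The per-round candidate budget assumes roughly uniform spot density;
strongly clustered scenes can exhaust it locally. The multi-start grid
covers translations up to ±6 px and rotations are recovered only within
ICP's local basin (~3° at these field sizes). Decoding has no
error-correcting bit-flip rescue, so a transcript whose profile is
corrupted in more than one on-bit image is lost rather than rescued.
Vessel caliber is a bin-count proxy, not a lumen measurement in µm.
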