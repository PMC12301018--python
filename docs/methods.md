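# Methods

This note documents the models and estimators in `biofilmquant`, the
assumptions behind them, and the choices made where the design was open.

## The measurement model

A confocal acquisition is a four-dimensional intensity array indexed
`(channel, z, y, x)` with physical voxel size `(dz, dy, dx)` in µm. One
fluorophore reports one biofilm component (Table-style scheme: FITC →
protein, Calcofluor White → polysaccharide, Nile Red → lipid, rhodamine →
all bacteria, propidium iodide → dead bacteria; an optional SYTO 9-like
channel images extracellular DNA separately). The EPS dyes are applied as a
mixture, so EPS components are treated as mutually exclusive per voxel; the
bacterial stains coexist with EPS signal, so bacterial masks may overlap EPS
masks, and the PI (dead) mask is constrained to be a subset of the
all-bacteria mask because PI marks a subpopulation of cells.

Depth is always reported as distance from the substrate (concrete-adjacent)
face. Stacks default to `substrate_at_z0`; the orientation is an explicit,
overridable field because acquisitions do not record it reliably.

## Illumination correction and preprocessing

The pipeline's four stages run in order: shadow correction, grayscale
conversion, segmentation, measurement. Shadow correction defaults to
flat-field division by a fitted second-order polynomial illumination
surface (ten terms in z, y, x), rescaled to the input mean. A global
polynomial is used rather than a windowed smoother because windowed
smoothers are biased at volume boundaries: on a linear gain field a
Gaussian-smoothed copy misestimates the gain within ~2σ of every face,
which is most of a typical stack. The polynomial model captures the classic
vignetting shapes (linear gradients, radial quadratic falloff) exactly and
has no boundary pathology. A grey-opening "rolling ball" subtraction is
available for additive backgrounds. Grayscale conversion (a normalized
weighted channel sum) is exposed for pipeline completeness but the
quantification path segments each channel separately. Denoising offers
median and Gaussian filters with radii in µm, converted per axis to voxels
(rounded half-up) so anisotropic stacks are handled correctly.

## Segmentation and volume estimation

Thresholding supports four methods:

* **manual** — a user threshold, always recorded in the mask's provenance.
* **otsu** — the classic criterion on the full 3D histogram (256 bins after
  min–max scaling). Computed volume-wide, not per slice, so thresholds are
  depth-consistent and depth profiles comparable.
* **half_level** — threshold at the midpoint of the background and
  foreground plateau intensities. Plateaus are estimated away from blurred
  boundaries: a provisional Otsu mask of a 3×3×3-median-filtered copy is
  eroded twice (foreground core) and dilated twice (background ring), and
  the medians of those regions are used. The half level is the
  volume-preserving choice for a symmetric point-spread function on flat
  interfaces.
* **flux** (default) — the threshold is placed at the intensity rank
  matching a photometric volume estimate
  `N̂ = (ΣI − N·bg) / (fg − bg)`, with `bg` the mean of the background ring
  and `fg` the mean of the foreground core. Because convolution with any
  normalized kernel conserves integrated signal and zero-mean noise cancels
  in the sum, `N̂` is immune to the boundary-shift biases that affect all
  threshold counting: Otsu's variance-balancing cut mis-sizes objects by
  5–30 % under realistic blur and noise, and even the half-level cut loses
  `~3σ²/r²` of a convex object's volume to curvature (the half-max
  isosurface of a blurred sphere of radius r shrinks by ~σ²/r).

Component assignment under the multi-stain scheme resolves multi-positive
voxels. With explicit thresholds, each channel is binarized independently
and disputed voxels go to the channel with the higher per-channel z-score
(global mean/sd normalization). With the default flux method the
competition is volume-calibrated: every voxel is provisionally labelled
with the arg-max z-score EPS channel, then each component keeps its
brightest voxels up to its photometric count. This removes a systematic
~2–3 % loss the threshold-and-compete scheme suffers at component contact
interfaces, where both channels' blurred edges cross their thresholds and a
winner-takes-voxel rule shrinks both masks. Recovered volume fractions on
synthetic stacks (64³ voxels, SNR 5, 1-voxel blur) are within ~3 % relative
of truth, and exact in the noiseless unblurred limit.

Constant (e.g. all-zero) channels yield empty masks with a logged warning
when assigned through the scheme; direct `threshold_segment` on a constant
volume raises a documented degenerate-histogram error instead of silently
guessing.

Mask cleanup removes 26-connected objects below a voxel-count floor and
optionally fills enclosed 3D cavities. 26-connectivity is the standard
choice for sparse fluorescent structures.

Known limitations: channel bleed-through biases the flux estimate of the
receiving channel upward by (bleed fraction × source volume) — the
cross-talk checker exists precisely to flag dye pairs where this matters
(Nile Red/PI and Nile Red/rhodamine at a 10 nm margin in the published
scheme); spectral unmixing is out of scope. Isolated objects with radius
comparable to the blur scale are systematically shrunk by any thresholding
method; the PI (dead) channel, whose objects are small and isolated and
which is additionally intersected with the all-bacteria mask, is therefore
the least accurately recovered channel (~15–30 % low under 1-voxel blur).

## Mass budget

With a measured biofilm mass `m` (mg) — a required user input, since
imaging cannot weigh — masses follow from volume fractions:

```
EPS_I  = m · V_I / V
EPS_II = m · (V − V_B) / V
```

Both are enforced as exact identities and are invariant to rescaling all
volumes, so voxel-size errors cancel as long as they are consistent. The
total volume `V` defaults to the union of all component masks
(conservative: only stained voxels count); a per-slice 2D convex envelope
is available to approximate a filled biofilm body including unstained
interstitial space. `V_B` defaults to the all-bacteria mask; a live-only
option subtracts the PI mask. Whether the sum of component masses can
exceed `m` depends on mask overlap: with disjoint EPS masks the sum is
bounded by `m`.

## Depth profiles and layer clustering

Voxels are binned by the depth of their z-center; the default bin width is
10 µm, matching the granularity at which depth enrichment is usually
reported (e.g. a 10–20 µm surface layer). Proportions are normalized
across components within each bin (the stacked-composition view); a
within-component normalization is available to ask *where along depth* a
single component concentrates, and is what the depth-mode recovery checks
use. k-means layer clustering runs on the per-bin composition vectors of
non-empty bins, seeded and restarted deterministically; the feature space
is a documented choice, as composition is the quantity the profile
measures.

## REV analysis

For each cubic subvolume edge length, random axis-aligned subvolumes are
sampled with replacement (seeded) and the coefficient of variation of
their volume fractions computed; the REV size is the smallest size with
cv ≤ 0.05 (default). On a homogeneous Bernoulli(p) mask the cv follows the
binomial closed form `sqrt((1−p)/(p·n_vox))`, which the tests use as an
oracle; on real structured masks the cv decays more slowly, and the REV
size is the scale above which a reported volume fraction stops depending
on where the subvolume was taken.

## Meshes

Iso-surfaces are extracted at 0.5 occupancy by marching cubes on a
zero-padded copy (so boundary-touching objects close), scaled to µm, and
exported as STL/OBJ/PLY. The enclosed volume comes from the watertight
triangulation; for digitized spheres of radius ≥ 10 voxels it agrees with
the voxel count within 5 %, converging as radius grows.

## EEM analysis

EEMs live on the acquisition grid Ex 200–400 nm / Em 220–500 nm at 5 nm
steps. First- and second-order Rayleigh scatter bands (|em − ex| and
|em − 2·ex|, default half-widths 15 nm) are zeroed before detection. Peaks
are 8-neighborhood local maxima with height at least a fraction (default
0.1) of the global maximum; height-relative prominence is used because
instrument units are arbitrary, which also makes detection invariant to
uniform intensity scaling. Classification windows: region A at Ex ∈
[275, 280] and Em ∈ [325, 350] nm; region B within ±5 nm (one grid step,
configurable) of (225, 300) nm, since that peak is conventionally given as
a point coordinate. Only between-condition intensity *ratios* are
reported; a region missing from either condition is reported absent, never
zero.

## Synthetic data generator

The generator exists to make every pipeline stage testable against exact
ground truth. Morphology is deliberately simple: spherical blobs (radius
4 µm ± 30 %, a realistic microcolony scale) are placed with z drawn from a
per-component depth density until each component reaches its target volume
fraction. EPS component truths are kept disjoint; bacterial blobs may
overlap EPS; the dead-bacteria truth is the union of a random subset of
bacterial blobs (whole microcolonies die), keeping PI a strict subset of
all-bacteria. Optics are a bleed matrix (default: 5 % mutual bleed between
the spectrally closest dyes, Nile Red ↔ PI and Nile Red ↔ rhodamine), a
Gaussian blur as PSF proxy, and additive Gaussian noise with
sd = foreground/SNR, applied in that order and clipped at zero. All
randomness flows from one seeded generator per call.

Presets encode the two salinity regimes at 64³ voxels of 1 µm (chosen as a
representative field size; all operations are resolution-agnostic):

* **FQHC** (low salinity): all components uniform over mid-depth
  (16–48 µm), near-equal fractions of 5–8 %.
* **SQHC** (high salinity): bacteria Gaussian(15 µm, 5 µm) — the surface
  layer; extracellular DNA Gaussian(35 µm, 5 µm); protein and
  polysaccharide weighted deep (Gaussian around 45–47 µm); lipid uniform
  over 25–50 µm. Defaults: SNR 5, blur 0.5 µm. The deep protein and
  polysaccharide parameters are illustrative — the regime they emulate is
  described only qualitatively — and are documented as such.

What passing tests do and do not show: the generator exercises
segmentation geometry, depth statistics, cross-talk and the mass algebra,
but its blobs lack real biofilm texture (filaments, intensity gradients,
depth-dependent attenuation, anisotropic PSF). Recovery numbers on
synthetic data are therefore upper bounds on what identical settings would
achieve on real acquisitions, not predictions.

## Numerical conventions

Foreground is `intensity ≥ threshold` everywhere, and thresholds actually
used are recorded in mask provenance and run manifests. Ties in the
z-score competition go to the earlier channel-map entry. Physical radii
convert to voxels by half-up rounding per axis. Empty-input cases are
errors where a quantity would be undefined (total volume of no masks,
meshing an empty mask) and benign no-ops where a valid zero exists (empty
depth profile, empty mask volume). Exit codes in the CLI: 0 success, 2
configuration/validation, 3 data/format, 4 numerical failure.

## Problem sizes

The test suite and the acceptance script use 32³–64³ stacks (plus one 128³
Bernoulli mask for REV), 20-seed replication for depth-pattern recovery,
and 40–60 subvolume samples per REV size — sizes at which the sampling
oracles (binomial cv, 3-sd fraction tolerances) are sharp enough to detect
the biases the estimators are designed to avoid.
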