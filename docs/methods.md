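# Methods

## Data model and conventions

A density map is a 3D scalar grid in `(z, y, x)` index order with an
isotropic voxel spacing `apix` (Å) and an `origin`: the real-space (x, y, z)
position of the **center** of voxel (0, 0, 0), so voxel (k, j, i) sits at
`origin + apix·(i, j, k)`. The voxel containing a point is found by
rounding to the nearest voxel center. Every score below depends on this
convention, so it is fixed package-wide. Only isotropic voxels are
supported; anisotropic cells are rejected on read because all the scoring
formulas assume a single spacing.

CCP4/MRC files are read through gemmi with axis-correspondence words
honoured (permuted section orders are normalized to the internal
convention) and written canonically (MAPC, MAPR, MAPS = 1, 2, 3; mode 2,
little-endian). The origin is taken from the ORIGIN header words, falling
back to `NxSTART·apix` when those are zero. Mode-2 round trips are
bit-exact on float32 data.

Structures are flat atom-record lists. Altlocs keep the highest-occupancy
conformer (first seen on ties); masses come from the element table, with
unknown elements assigned carbon mass under a warning. Cα-RMSD pairs atoms
by (chain, residue) and performs **no superposition**: alternative fits
live in the same map frame, and the raw deviation is precisely what
distinguishes placements. (Whether the original ensemble analyses
superposed first is not documented anywhere we could verify; the
in-one-map setting implies they did not, and that reading is adopted.)

## Map simulation

Each atom contributes an isotropic Gaussian with σ = `sigma_factor` ×
resolution (default sigma factor 0.225, the common convention for
simulated maps) and amplitude proportional to atomic mass; contributions
are summed on the grid and truncated at 3σ (relative truncation error
≤ e^(−4.5) ≈ 1.1% per voxel, bounded in the tests). Grid spacing is
capped at 3.5 Å per pixel unless forced. The default margin around the
structure's bounding box is 2 × resolution, enough that bounded ensemble
perturbations rarely push density off-grid. Mass weighting (rather than
uniform or atomic-number weighting) is this package's choice; scores that
need intensity normalization standardize internally, so no global
rescaling is applied.

For scoring, the probe is blurred **directly on the target's grid**
(`simulate_on_grid`) rather than blurred on its own grid and resampled;
this removes interpolation error from every probe-vs-target comparison.
`resample_on_grid` (trilinear) exists for aligning externally produced
maps.

## Scores

* **CCC** is the Pearson correlation of intensities over the full common
  grid by default — the printed definition sums over all voxels — with an
  optional voxel mask for the background-dominated real-map case. Zero
  variance over the evaluated voxels is an error, not a 0.
* **LAP** applies a 6-neighbour discrete Laplacian (reflective padding)
  to both maps before CCC.
* **MI** uses independent equal-width binning per map over each map's own
  min–max range (20 bins by default) and log base 2, so values are in
  bits; a constant map yields MI = 0. The bin count is the documented
  protocol value; the log base and edge rule are this package's explicit
  choices.
* **SCCC / SMI** need a concrete segment-mask rule: the segment alone is
  blurred at the working resolution on the target grid and thresholded at
  its own volume-based cutoff (1.21 Å³ per Dalton of segment mass); the
  whole-model probe map is then compared with the target over that mask
  only.
* **ENV** binarizes the target at a threshold. Atoms in envelope voxels
  score +1, atoms below threshold or off-grid −2 (protrusion), and every
  envelope voxel with no atom within one voxel (3×3×3 neighbourhood of
  atom-occupied voxels) scores −1 (empty space). The +1/−2/−1 weights are
  configurable defaults: the idea of down/up-weighting is standard, the
  constants are not published.
* **NV / NV-S** compare outward unit normals on the two envelope surfaces.
  A surface voxel is an above-threshold voxel with at least one of its six
  face-neighbours below threshold (out-of-grid counts as below). Normals
  are the negative density gradient, unit-normalized — central differences
  by default, Sobel responses masked above the threshold for NV-S; the
  published normal-estimation variant is not reproducible from available
  descriptions, so this deterministic, oracle-checkable estimator is used
  instead. Zero-gradient surface voxels are dropped. Each target surface
  point is paired with the nearest probe surface point (ties resolved to
  the lowest point index, enforced explicitly rather than left to the
  k-d tree); the score is the mean arccos of the clamped dot products,
  averaged over target surface points only (symmetrizing over both
  surfaces is a plausible alternative not adopted).
* **CD** averages, over probe surface points, the distance to the nearest
  target surface point (k-d tree, verified against the O(n²) scan). It is
  deliberately asymmetric and uses the full surface point set (no
  normal-based dropping).
* Envelope thresholds are derived from molecular mass at 1.21 Å³/Da, the
  standard protein partial specific volume. In ensemble scoring the
  target-side threshold and filtered maps are computed once per run so all
  fits are compared on equal footing.

Ranks follow score polarity (CCC/LAP/MI/ENV/SCCC/SMI descending,
NV/NV-S/CD ascending). Ties receive average fractional ranks, so rank
vectors are a permutation of 1..N exactly when scores are untied — the
generic case for real-valued scores; fractional tied ranks keep the Borda
count order-invariant.

## Ensembles

Local ensembles draw rotation axes and translation directions uniformly
on the sphere, rotation angles uniformly on [0, max_rot] and translation
magnitudes uniformly on [0, max_trans] (defaults 60° and 10 Å), pivoting
at the model's center of mass, and always include the unperturbed fit as
"model 0". Uniform-angle sampling is *not* uniform over SO(3); for a
bounded perturbative search this is immaterial and simplicity wins.
Everything is reproducible from a single integer seed.

## Clustering and consensus

Pairwise Cα-RMSD matrices feed complete-linkage agglomerative clustering
(configurable to single/average). Complete linkage was chosen because it
makes the flat cut interpretable: the cutoff bounds the intra-cluster
diameter. The default cut is the mean pairwise Cα-RMSD of the top-k
(k = 20) fits under a designated score, and by default only those top-k
fits are clustered (clustering the whole ensemble with the top-k-derived
cutoff is available as an option — both readings of the protocol are
defensible). The reported cluster is the non-singleton cluster containing
the best-ranked fit among fits in non-singleton clusters; when every
cluster is a singleton the result is flagged rather than raised.

The Borda count awards N − r points for rank r (best fit N − 1, worst 0);
the alternative N − r + 1 convention is a configurable offset that shifts
totals without reordering. Ties within a score column contribute mean
fractional points; ties in total points break lexicographically by fit id
for determinism. One caveat found while testing: duplicating a *single*
score column doubles that score's weight and **can** change the consensus
order (only duplicating the entire score set is guaranteed neutral) — the
implementation makes no claim otherwise.

## Synthetic fixtures and what they do (not) show

The toy generator builds poly-alanine structures with 5 heavy atoms per
residue on ideal α-helix Cα geometry (rise 1.5 Å, 100°/residue, radius
2.3 Å; backbone/CB placed at plausible bond lengths, not refined
stereochemistry), either as one helix or as two helical domains on a
hinge. The benchmark case blurs a 40-residue helix into a target map
(sigma factor 0.225, apix = min(3.5, resolution/3)) and surrounds the
generating placement with a bounded random ensemble — the same study
design as published local-search benchmarks, scaled to run in seconds
(50 + 1 fits, ~30³ grids at 10 and 20 Å instead of 200-fit ensembles over
crystal structures).

What passing shows: the full pipeline — blur, score, rank, cluster,
consensus — recovers a known placement from bounded decoys, and every
score agrees with an independent brute-force oracle. What it does not
show: behaviour on experimental maps with noise, solvent, segmentation
artifacts or model error; discrimination among *conformations* (as
opposed to placements); or score performance at near-atomic resolution.
Real side chains, B-factors and experimental noise are deliberately out
of scope of the generator.

## Numerical choices

arccos arguments are clamped to [−1, 1]; Sobel/Laplacian edge handling is
reflective to avoid spurious boundary gradients; the volume threshold
returns the n-th largest voxel value (largest density whose enclosed
count reaches the target volume), which makes it exactly reproducible by
sorting; NV drops target points whose probe normal is undefined and
errors only when none remain; all scores are deterministic functions of
their inputs — identical inputs give bit-identical outputs, which the
ensemble tests assert.
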