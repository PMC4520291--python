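# emscore

Assessment of atomic-model fits in 3D electron-microscopy density maps.

At intermediate-to-low resolution (~5–20 Å), placing an atomic model in a
cryo-EM reconstruction is underdetermined: many rigid placements score
similarly, and a single goodness-of-fit number can be misleading. `emscore`
addresses this with three complementary tools:

1. **A family of goodness-of-fit scores** between a target map and a probe
   (the model blurred into a map on the same grid):
   - **CCC** — cross-correlation of voxel intensities over the grid *M*:
     `CCC = Σ_{i∈M}(ρ_i^p − ρ̄^p)(ρ_i^t − ρ̄^t) / [Σ(ρ_i^p − ρ̄^p)² Σ(ρ_i^t − ρ̄^t)²]^{1/2}`
   - **LAP** — CCC of Laplacian-filtered maps (edge-weighted).
   - **MI** — mutual information of the binned intensity distributions
     (20 equal-width bins by default):
     `MI = Σ_{x,y} p(x,y) log₂ [p(x,y) / (p(x)p(y))]`
   - **SCCC / SMI** — CCC / MI restricted to the map region occupied by one
     user-defined structural segment (domain, helix, rigid body), for local
     fit assessment.
   - **ENV** — integer envelope occupancy score: +1 per atom inside the
     thresholded envelope, −2 per protruding atom, −1 per empty envelope
     voxel; higher is better.
   - **NV / NV-S** — mean angle in [0, π] between outward surface-normal
     vectors of the two envelopes, `NV = (1/n) Σ_{i∈v} arccos(a_i·b_i /
     |a_i||b_i|)`; NV-S estimates the normals from 3D Sobel-filtered
     gradients. 0 is a perfect surface match.
   - **CD** — Chamfer distance: mean distance from each probe surface point
     to its nearest target surface point (Å); 0 is best.

   Envelopes come from a volume-based threshold: the density cutoff whose
   enclosed volume matches the molecular volume expected from the model's
   mass (1.21 Å³/Da).

2. **Ensemble generation and Cα-RMSD clustering.** A local ensemble of
   bounded random rigid perturbations (ΔT ≤ 10 Å, ΔΦ ≤ 60° by default)
   around a starting fit ("model 0"), or an externally generated ensemble,
   is scored and hierarchically clustered by Cα-RMSD (complete linkage,
   no superposition — fits share the map frame). The flat cut uses the mean
   pairwise Cα-RMSD of the top-20 fits; the fit of interest is the best
   scorer inside the best non-singleton cluster, because an isolated
   top-scoring fit that no neighbouring placement reproduces is suspect.

3. **Borda-count consensus.** Each of S scores ranks the N fits; rank r
   earns N − r points, and fits are re-ranked by total points, damping the
   idiosyncrasies of any single score.

Everything works on standard formats: CCP4/MRC maps, PDB/mmCIF models,
plain-text segment files, TSV score tables, and residue attribute files
for molecular-graphics coloring.

## Worked example

`examples/local_ensemble_ranking.py` simulates a 10 Å map from a toy
40-residue helix, perturbs the generating placement 30 times within
ΔT ≤ 10 Å / ΔΦ ≤ 60°, and scores all 31 fits:

```
  fit_id    CCC     MI      NV-S  rank_CCC  rank_MI  rank_NV-S
 model_0      1 0.2964 5.809e-09         1        1          1
model_26 0.9821 0.2313    0.3096         2        2          2
 model_4 0.9215 0.1764     0.437         3        3          3
 model_5 0.7996 0.1377     0.563         4        5          4
 model_9 0.7587 0.1411    0.7015         5        4          6

model_0 ranks: CCC=1, MI=1, NV-S=1
```

`model_0` — the placement that generated the map — reaches the ideal
values (CCC = 1, NV-S ≈ 0) and rank 1 under every score; the remaining
ranks order the decoys by how far they strayed. The other examples cover
self-fit scoring (`simulate_and_score.py`), clustering
(`cluster_ensemble.py`, where model 0 lands in the top non-singleton
cluster at the mean-top20 cutoff), consensus (`consensus_ranking.py`) and
per-segment local assessment (`segment_assessment.py`, where displacing
one domain by 5 Å drops that domain's SCCC from 1.000 to 0.083 while the
untouched domain keeps 0.927).

A thin CLI exposes the same workflow for shell pipelines:

```sh
emscore blur --model model.pdb --resolution 10 --out sim.mrc
emscore score --map target.mrc --model model.pdb --ensemble fits.pdb \
              --resolution 10 --scores ccc,mi,nv_s --out scores.tsv
emscore cluster --table scores.tsv --ensemble fits.pdb --score mi --out-prefix cl
emscore consensus --table scores.tsv --scores ccc,mi,nv_s --out-prefix co
```

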