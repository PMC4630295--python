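# phasereg

Draining-vein suppression for complex-valued BOLD fMRI: the **phase
regressor** (PR) and **source-localized phase regressor** (sPR), with the
simulation and phantom machinery needed to validate them.

## The problem

Gradient-echo BOLD is biased toward large draining veins: a vein pools
deoxygenated blood from a wide territory, so the strongest "activation" in a
t-map often sits on a vessel rather than on the responding tissue.  Because
task-related **phase** changes in a gradient-echo acquisition come almost
exclusively from large veins, the phase channel — usually discarded — can be
used to regress the macrovascular component out of the magnitude signal.
This package is for fMRI methodologists and analysts who keep their phase
reconstructions and want vein-suppressed activation maps, ROI sizes and
laterality indices, plus a fully synthetic test bed for the method itself.

## The model

Both suppressors model the macrovascular part of a z-scored magnitude
timecourse S^m as a linear fit of a z-scored phase timecourse S^p and
subtract it:

    S_suppressed(t) = S^m(t) − b₁* · S^p(t)

**PR** minimizes the historical chi-squared loss with the slope in the
denominator,

    L(b₀, b₁) = Σ_t (S^m(t) − b₀ − b₁ S^p(t))² / (σ_m² + b₁ σ_p²),

which has the closed form b₁* = r(√(2 + 2|ρ|) − 1) for z-scored inputs,
where ρ = corr(S^m, S^p) and r = sign(ρ).  Since b₁* ≥ √2 − 1 ≈ 0.414 even
at ρ = 0, PR systematically over-suppresses, and next to a vein (phase
response without magnitude response) it manufactures artifactual activation.

**sPR** replaces this with the unbiased OLS fit — for z-scored series the
slope is simply the correlation — and, crucially, lets the phase regressor
come from the most-correlated voxel k* in the 7-voxel face-adjacent
neighborhood:

    S_sPR(t) = S^m_i(t) − corr(S^m_i, S^p_k*) · S^p_k*(t).

A vein the size of a voxel produces a *symmetric* dipole field whose phase
cancels within the voxel (and an intravascular shift that vanishes at the
magic angle ≈ 54.7°), while the voxels *next to* the vein see a
single-polarity field lobe with a strong phase response.  The neighborhood
source lets sPR suppress exactly those veins whose own phase is silent.

The package also provides: a single-voxel block-design simulator and the
2 × 101 × 101 suppression grid; a physics-based vein phantom
(infinite-cylinder susceptibility field, subvoxel integration with
T2\*-weighted blood/tissue compartments, 4 T defaults); slice-wise homodyne
phase filtering with cubic detrending and z-scoring; pooled-variance
contrast t-maps, threshold/cluster ROI definition, vein-contribution
metrics (N_norm = N_sPR/N_mag, percent vein = (1 − N_norm)·100) and
size/fSNR laterality indices; NIfTI magnitude/phase pair I/O and a CLI.

## Worked example

`examples/01_simulate_regimes.py` simulates the three canonical regimes
(200 seeds each, 14 × 16 s blocks at 1 s sampling) and prints:

```
regime                                   mag t    PR t   sPR t  PR |t|  sPR |t|   (means over 200 seeds)
vein voxel       (mag 5, phase 5)         5.01    0.25    0.51    0.25     0.51
no vein          (mag 5, phase 0)         5.01    3.14    4.93    3.14     4.93
vein-adjacent    (mag 0, phase 4.5)      -0.01    0.02   -0.00    0.71     0.05
```

Row 1: a vein drives both channels and both methods remove the response.
Row 2: with no phase signal there is nothing to suppress — sPR returns
essentially the magnitude t (4.93 vs 5.01) while PR's denominator bias costs
almost 2 t-units.  Row 3: next to a vein PR fabricates |t| ≈ 0.7 activation
(sign set by the noise realization); sPR stays at noise level.

`examples/04_roi_laterality.py` runs the full split-run volume pipeline on a
two-vein phantom (large right vein, small left vein, equal parenchymal
activation strips):

```
hemisphere    N_mag  N_sPR  percent vein
right            51      1           98%
left             17      8           53%

size laterality: +0.50 before suppression, -0.78 after
```

The apparent right-lateralization of the unsuppressed ROI is entirely a
vein-caliber asymmetry; suppression reverses it.  The other examples cover
the full suppression grid and the phantom field model / venogram.

The same operations are scriptable from the shell:

```bash
phasereg simulate-grid --method spr --step 0.1 --seed 1 --out grid.csv
phasereg phantom --kind single --seed 0 --out phantom/
phasereg suppress --train-mag ... --train-phase ... --test-mag ... \
    --test-phase ... --method spr --neighborhood 7 --out out/
phasereg roi-metrics --tmap-mag tmag.nii.gz --tmap-spr tspr.nii.gz --out metrics.csv
```

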