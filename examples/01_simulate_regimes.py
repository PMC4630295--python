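"""Single-voxel suppression in the three canonical fSNR regimes.

Simulates a block-design complex-valued BOLD voxel (14 alternating 16 s
off/on blocks, 1 s sampling, unit-impulse HRF, N(0,1) noise per channel) at
three expected magnitude/phase fSNR combinations, applies the chi-squared
phase regressor (PR) and the OLS source-localized variant (sPR, k* = i), and
prints the realized fSNR statistic of each suppressed timecourse.
"""

import numpy as np

from phasereg import BlockDesign, realized_fsnr, simulate_voxel
from phasereg.block_simulator import suppress_timecourse

design = BlockDesign()          # 224 timepoints

regimes = {
    "vein voxel       (mag 5, phase 5)": (5.0, 5.0),
    "no vein          (mag 5, phase 0)": (5.0, 0.0),
    "vein-adjacent    (mag 0, phase 4.5)": (0.0, 4.5),
}

print(f"{'regime':38s} {'mag t':>7s} {'PR t':>7s} {'sPR t':>7s} "
      f"{'PR |t|':>7s} {'sPR |t|':>8s}   (means over 200 seeds)")
for name, (mf, pf) in regimes.items():
    mag_t, pr_t, spr_t = [], [], []
    for seed in range(200):
        tc = simulate_voxel(mf, pf, design, seed)
        mag_t.append(realized_fsnr(tc.magnitude, design))
        pr_t.append(suppress_timecourse(tc, "pr", design))
        spr_t.append(suppress_timecourse(tc, "spr", design))
    print(f"{name:38s} {np.mean(mag_t):7.2f} {np.mean(pr_t):7.2f} "
          f"{np.mean(spr_t):7.2f} {np.mean(np.abs(pr_t)):7.2f} "
          f"{np.mean(np.abs(spr_t)):8.2f}")

print("""
Reading the rows: with a vein (both channels responsive) both methods
suppress the response toward 0; with no phase signal sPR preserves the
magnitude response while PR's denominator bias over-suppresses it; next to a
vein (phase only) PR manufactures an artifactual response (mean |t| well
above zero; its sign depends on the noise realization) while sPR stays near
zero.""")
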