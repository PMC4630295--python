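"""End-to-end split-run analysis on the two-vein laterality phantom.

Synthesizes two runs of a phantom with a large "right" vein, a small "left"
vein, and one purely parenchymal activation strip per hemisphere; preprocesses
(slice-wise homodyne filtering, cubic detrend, z-score); fits sPR correlations
on run 1 and applies them to run 2; then compares per-hemisphere ROI sizes and
the size-laterality index before and after suppression.
"""

from phasereg import (contrast_tmap, define_roi, laterality, preprocess_series,
                      suppress_volume, vein_contribution)
from phasereg.fixtures import make_laterality_phantom, single_vein_design

design = single_vein_design()
train = preprocess_series(make_laterality_phantom(seed=0)).series
test = preprocess_series(make_laterality_phantom(seed=1000)).series

t_mag = contrast_tmap(test.magnitude, design)
result = suppress_volume(train, test, method="spr", neighborhood=7)
t_spr = contrast_tmap(result.suppressed, design)

rois_mag = define_roi(t_mag, threshold=3.0)
rois_spr = define_roi(t_spr, threshold=3.0)

print(f"{'hemisphere':12s} {'N_mag':>6s} {'N_sPR':>6s} {'percent vein':>13s}")
for hemi in ("right", "left"):
    rm, rs = rois_mag[hemi], rois_spr[hemi]
    vc = vein_contribution(rm, rs)
    print(f"{hemi:12s} {rm.n_voxels:6d} {rs.n_voxels:6d} {vc.percent_vein:12.0f}%")

lat_pre = laterality(rois_mag["right"], rois_mag["left"])
lat_post = laterality(rois_spr["right"], rois_spr["left"])
print(f"\nsize laterality: {lat_pre.size_lat:+.2f} before suppression, "
      f"{lat_post.size_lat:+.2f} after")
print("""
Positive laterality = right-dominant.  The unsuppressed ROI is inflated by
the large right vein; once the vein contribution is regressed out using the
neighboring voxels' phase, the apparent right-lateralization disappears --
the small left vein is below the size sPR can exploit, mirroring how a
vein-size asymmetry masquerades as functional lateralization.""")
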