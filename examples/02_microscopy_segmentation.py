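"""Simulate an LCO microscopy field and quantify the segmented plaques.

Renders a scene with cored, diffuse and coarse-grained plaques, runs the
background-subtraction + Li-threshold segmentation, and prints per-ROI
morphometrics plus the tau-neurite (PHF-1 channel) intensity, which is
planted higher in coarse-grained than in cored plaques.
"""

from plaquemap.microscopy import (
    ChannelImage, rois_to_table, segment_plaques, subtract_background)
from plaquemap.synthio import make_microscopy_scene

scene, truth = make_microscopy_scene(
    counts={"CP": 4, "DP": 3, "CGP": 2}, field_um=(700, 700), rng_seed=7)

lco = ChannelImage(scene.channels["LCO"], truth.px_um, "LCO")
phf1 = ChannelImage(scene.channels["PHF1"], truth.px_um, "PHF1")
rois = segment_plaques(subtract_background(lco, radius_um=50.0))

table = rois_to_table(rois, channels={"PHF1": phf1})
print(f"planted plaques: {len(truth.roi_labels)}, segmented ROIs: {len(rois)}\n")
print(table.round(2).to_string(index=False))
print("\narea_um2 / equiv_diameter_um are the plaque morphometrics;")
print("intensity_per_um2_PHF1 is summed channel intensity over ROI area —")
print("the largest values belong to the multi-cored coarse-grained plaques.")
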