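"""Run the spectral chain on simulated single-plaque ROI spectra.

Simulates ROI-average spectra for cored and diffuse plaques at the study's
technical CV (10%), runs sqrt -> Savitzky-Golay -> SNIP -> TIC -> AUC, and
prints the resulting peptide table with the cored/diffuse fold changes.
A-beta 1-40, 3pE-42 and 11pE-42 are planted threefold higher in cored
plaques; most other peptides are planted equal.
"""

from plaquemap.msiproc import preprocess_roi_spectra
from plaquemap.panel import build_abeta_panel
from plaquemap.synthio import CohortSpec, simulate_roi_spectra

panel = build_abeta_panel()
spec = CohortSpec(groups={"sAD": 6}, seed=11)
spectra, meta = simulate_roi_spectra(spec, plaque_types=("DP", "CP"),
                                     n_plaques_per_type=5)
table = preprocess_roi_spectra(spectra, panel=panel, roi_meta=meta)

medians = table.groupby("plaque_type")[[p.name for p in panel]].median()
print("median normalised AUC per peptide:")
print(medians.T.round(4).to_string())
print("\ncored / diffuse fold change recovered by the chain:")
print((medians.loc["CP"] / medians.loc["DP"]).round(2).to_string())
print("\nvalues near 3 are the planted discriminators; values near 1 the")
print("planted-equal peptides (small deviations reflect the 10% CV).")
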