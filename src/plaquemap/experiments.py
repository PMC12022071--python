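"""Seeded parameter-recovery experiments on synthetic cohorts.

These experiments answer the calibration question behind the analysis: with
the study's noise structure (technical 10%, intra-patient 16%,
inter-patient 18% CV) and realistic ROI counts, does the full spectral +
statistics chain find the peptide contrasts that were planted, and only
those?  They are run across many seeds so the answer is a detection *rate*
rather than a single lucky draw.
"""

from __future__ import annotations

import pandas as pd

from . import msiproc
from . import stats as pstats
from .panel import build_abeta_panel
from .synthio import CohortSpec, simulate_roi_spectra

__all__ = [
    "CP_DP_DISCRIMINATORS",
    "CGP_CP_DISCRIMINATORS",
    "recovery_experiment",
    "recovery_rates",
]

#: Peptides planted to differ between cored and diffuse plaques (fold 3);
#: A-beta 1-42 differs only marginally (fold 1.3) and is scored separately.
CP_DP_DISCRIMINATORS = ("Abeta1-40", "Abeta3pE-42", "Abeta11pE-42")
CP_DP_MARGINAL = ("Abeta1-42",)

#: Planted coarse-grained vs cored contrasts (x-40 species up; x-42
#: species, including A-beta 1-42, down).  Only A-beta 2-42 is neutral.
CGP_CP_DISCRIMINATORS = ("Abeta1-40", "Abeta3pE-40", "Abeta4-40",
                         "Abeta1-42", "Abeta3pE-42", "Abeta5-42",
                         "Abeta11pE-42", "Abeta4-42")


def _non_discriminators(panel_names, contrast):
    planted = set(CP_DP_DISCRIMINATORS) | set(CP_DP_MARGINAL) \
        if contrast == "CP_vs_DP" else set(CGP_CP_DISCRIMINATORS)
    return tuple(n for n in panel_names if n not in planted)


def recovery_experiment(
    n_seeds: int = 50,
    base_seed: int = 0,
    n_patients: int = 12,
    n_plaques_per_type: int = 10,
    mz_step: float = 0.25,
) -> pd.DataFrame:
    """Run the seeded CP-vs-DP / CGP-vs-CP recovery experiment.

    Per seed: simulate ROI spectra for one sporadic-AD-like group
    (``n_patients`` patients, ``n_plaques_per_type`` plaques of each type,
    default CV hierarchy), run the full spectral chain to a PeakTable, then
    per peptide a two-group Kruskal-Wallis/Dunn comparison and per contrast
    an OPLS-DA VIP ranking.  Returns one row per (seed, contrast, peptide)
    with the adjusted p-value, whether the peptide is a planted
    discriminator, and whether the seed's VIP ranking put every planted
    discriminator above every non-discriminator.
    """
    panel = build_abeta_panel()
    names = [p.name for p in panel]
    rows = []
    for i in range(n_seeds):
        spec = CohortSpec(groups={"sAD": n_patients}, seed=base_seed + i)
        spectra, meta = simulate_roi_spectra(
            spec, plaque_types=("DP", "CP", "CGP"),
            n_plaques_per_type=n_plaques_per_type, mz_step=mz_step)
        table = msiproc.preprocess_roi_spectra(spectra, panel=panel,
                                               roi_meta=meta)
        for contrast, (a, b) in (("CP_vs_DP", ("CP", "DP")),
                                 ("CGP_vs_CP", ("CGP", "CP"))):
            sub = table[table.plaque_type.isin((a, b))]
            planted = (CP_DP_DISCRIMINATORS if contrast == "CP_vs_DP"
                       else CGP_CP_DISCRIMINATORS)
            neutral = _non_discriminators(names, contrast)
            # VIP ordering for this contrast
            X = pstats.autoscale(sub[names])
            model = pstats.oplsda_fit(X, sub.plaque_type.to_numpy(),
                                      seed=base_seed + i)
            vip = pstats.vip_scores(model)
            vip_ok = bool(vip[list(planted)].min() > vip[list(neutral)].max())
            for pep in names:
                _, posthoc = pstats.kruskal_dunn({
                    a: sub.loc[sub.plaque_type == a, pep].to_numpy(),
                    b: sub.loc[sub.plaque_type == b, pep].to_numpy()})
                rows.append({
                    "seed": base_seed + i, "contrast": contrast,
                    "peptide": pep, "p_adj": posthoc[0].p_adj,
                    "planted": pep in planted,
                    "marginal": pep in CP_DP_MARGINAL and contrast == "CP_vs_DP",
                    "vip_ranking_correct": vip_ok,
                })
    return pd.DataFrame(rows)


def recovery_rates(results: pd.DataFrame, alpha: float = 0.05) -> dict:
    """Summarise a recovery experiment into per-class detection rates.

    ``planted_detection_rate``: fraction of (seed, planted peptide) pairs
    with adjusted p < alpha.  ``false_positive_rate``: same for
    non-planted, non-marginal peptides.  ``vip_ranking_rate``: fraction of
    seeds whose VIP ranking places all planted discriminators first.
    Rates are percentages.
    """
    out = {}
    for contrast, sub in results.groupby("contrast"):
        planted = sub[sub.planted]
        neutral = sub[~sub.planted & ~sub.marginal]
        per_seed_vip = sub.groupby("seed")["vip_ranking_correct"].first()
        out[contrast] = {
            "planted_detection_rate": 100.0 * (planted.p_adj < alpha).mean(),
            "false_positive_rate": 100.0 * (neutral.p_adj < alpha).mean(),
            "true_negative_rate": 100.0 * (neutral.p_adj >= alpha).mean(),
            "vip_ranking_rate": 100.0 * per_seed_vip.mean(),
            "n_seeds": int(sub.seed.nunique()),
        }
    return out
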