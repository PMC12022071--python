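"""Synthetic scene / datacube / cohort generators: geometry, determinism,
planted effects."""

import numpy as np
import pytest

from plaquemap import synthio
from plaquemap.synthio import (
    CLASS_CODES,
    CohortSpec,
    DEFAULT_TEMPLATES,
    make_cohort,
    make_microscopy_scene,
    make_msi_dataset,
    simulate_roi_spectra,
)


def test_empty_scene_is_blank():
    scene, truth = make_microscopy_scene(counts={}, field_um=(200, 200),
                                         rng_seed=0)
    assert scene.channels["LCO"].max() == 0
    assert truth.roi_labels == []


def test_cgp_diameters_within_reported_interval():
    """20 coarse-grained plaques all fall in the 50-100 um diameter range."""
    _, truth = make_microscopy_scene(counts={"CGP": 20},
                                     field_um=(1500, 1500), px_um=1.0,
                                     rng_seed=3)
    assert len(truth.roi_labels) == 20
    diam = [p.diameter_um for p in truth.plaques]
    assert all(50 <= d <= 100 for d in diam)


@pytest.mark.parametrize("kind,lo,hi", [
    ("CP", 30, 50), ("CGP", 50, 100), ("DP", 50, 100),
])
def test_morphotype_geometry_ranges(kind, lo, hi):
    _, truth = make_microscopy_scene(counts={kind: 10},
                                     field_um=(1200, 1200), px_um=1.0,
                                     rng_seed=7)
    for p in truth.plaques:
        assert lo <= p.diameter_um <= hi


def test_scene_determinism():
    a, _ = make_microscopy_scene(counts={"CP": 3, "DP": 2},
                                 field_um=(400, 400), rng_seed=11)
    b, _ = make_microscopy_scene(counts={"CP": 3, "DP": 2},
                                 field_um=(400, 400), rng_seed=11)
    np.testing.assert_array_equal(a.channels["LCO"], b.channels["LCO"])


def test_infeasible_packing_raises():
    with pytest.raises(RuntimeError, match="could not place"):
        make_microscopy_scene(counts={"CGP": 50}, field_um=(250, 250),
                              rng_seed=0)


def test_cgp_template_invariants():
    tpl = DEFAULT_TEMPLATES["CGP"]
    assert not tpl.has_corona
    assert tpl.n_cores[0] >= 2
    with pytest.raises(ValueError, match="corona"):
        synthio.PlaqueTemplate("CGP", (50, 100), (3, 8), True, {"Abeta1-40": 1.0})


class TestMsiDataset:
    @pytest.fixture(scope="class")
    def noise_free(self, panel):
        scene, truth = make_microscopy_scene(
            counts={"CP": 2, "DP": 2}, field_um=(400, 400), rng_seed=5)
        msi, truth = make_msi_dataset(
            truth, panel, noise_cv=0.0, rng_seed=0, baseline_b0=0.0,
            detector_sigma=0.0, mz_step=1.0)
        return msi, truth

    def test_noise_free_pixel_equals_analytic_sum(self, noise_free, panel):
        """Without noise and baseline, each pixel is the exact Gaussian sum."""
        msi, truth = noise_free
        G = synthio.peak_profile_matrix(panel, msi.mz)
        names = [p.name for p in panel]
        # pick a DP pixel outside any core
        dp_ids = [p.roi_id for p in truth.plaques if p.morphotype == "DP"]
        mask = np.isin(truth.msi_instance_map, dp_ids)
        iy, ix = np.argwhere(mask)[0]
        profile = np.array(
            [DEFAULT_TEMPLATES["DP"].profile[n] for n in names])
        np.testing.assert_allclose(msi.cube[iy, ix], profile @ G, rtol=1e-5,
                                   atol=1e-6)

    def test_peak_fwhm_matches_instrument_resolution(self, noise_free, panel):
        """Measured FWHM of the A-beta 1-42 peak is mz/1000 within one bin."""
        msi, truth = noise_free
        mask = truth.msi_instance_map > 0
        spec = msi.mean_spectrum(mask)
        pep = next(p for p in panel if p.name == "Abeta1-42")
        sel = np.abs(spec.mz - pep.mz_obs) < 30
        mz, inten = spec.mz[sel], spec.intensity[sel]
        half = inten.max() / 2
        above = mz[inten >= half]
        fwhm = above.max() - above.min()
        bin_width = np.diff(spec.mz).mean()
        assert abs(fwhm - pep.mz_obs / 1000.0) <= bin_width

    def test_cp_core_enriched_in_abeta1_40(self, noise_free, panel):
        msi, truth = noise_free
        cp = next(p for p in truth.plaques if p.morphotype == "CP")
        i40 = [p.name for p in panel].index("Abeta1-40")
        G = synthio.peak_profile_matrix(panel, msi.mz)
        apex_bin = int(np.argmax(G[i40]))
        inst = truth.msi_instance_map == cp.roi_id
        core_mask = np.zeros_like(inst)
        # rebuild the core disk from recorded geometry
        ny, nx = inst.shape
        ys, xs = np.mgrid[0:ny, 0:nx]
        cxum, cyum = cp.cores_um[0][:2]
        rr = np.hypot((xs + 0.5) * 10 - cxum, (ys + 0.5) * 10 - cyum)
        core_mask = rr <= cp.cores_um[0][2] / 2
        core_px = inst & core_mask
        halo_px = inst & ~core_mask
        assert core_px.any() and halo_px.any()
        assert (msi.cube[core_px, apex_bin].mean()
                > 2.0 * msi.cube[halo_px, apex_bin].mean())

    def test_empty_panel_rejected(self, noise_free):
        _, truth = noise_free
        with pytest.raises(ValueError, match="panel"):
            make_msi_dataset(truth, panel=[])


def test_planted_fold_change_recovered_with_noise(panel):
    """CP:DP planted fold 3 for A-beta 1-40, 10% CV, 15 ROIs/class ->
    raw AUC ratio within 20% of 3."""
    spec = CohortSpec(groups={"sAD": 15}, technical_cv=0.10,
                      intra_patient_cv=0.0, inter_patient_cv=0.0, seed=21)
    spectra, meta = simulate_roi_spectra(spec, plaque_types=("DP", "CP"),
                                         n_plaques_per_type=1,
                                         baseline_b0=0.0, detector_sigma=0.0)
    pep = next(p for p in panel if p.name == "Abeta1-40")
    aucs = {"CP": [], "DP": []}
    for s in spectra:
        sel = np.abs(s.mz - pep.mz_obs) <= 3 * pep.mz_obs / 1000
        aucs[s.meta["plaque_type"]].append(
            np.trapezoid(s.intensity[sel], s.mz[sel]))
    ratio = np.mean(aucs["CP"]) / np.mean(aucs["DP"])
    assert 0.8 * 3 <= ratio <= 1.2 * 3


def test_noise_free_roi_ratios_exact(panel):
    """With all CVs zero the planted fold changes are recovered exactly."""
    spec = CohortSpec(groups={"sAD": 1}, technical_cv=0.0,
                      intra_patient_cv=0.0, inter_patient_cv=0.0, seed=0)
    spectra, _ = simulate_roi_spectra(spec, plaque_types=("DP", "CP"),
                                      n_plaques_per_type=1,
                                      baseline_b0=0.0, detector_sigma=0.0)
    by_type = {s.meta["plaque_type"]: s for s in spectra}
    for pep in panel:
        sel = np.abs(by_type["CP"].mz - pep.mz_obs) <= 2 * pep.mz_obs / 1000
        a_cp = np.trapezoid(by_type["CP"].intensity[sel], by_type["CP"].mz[sel])
        a_dp = np.trapezoid(by_type["DP"].intensity[sel], by_type["DP"].mz[sel])
        planted = (DEFAULT_TEMPLATES["CP"].profile[pep.name]
                   / DEFAULT_TEMPLATES["DP"].profile[pep.name])
        assert a_cp / a_dp == pytest.approx(planted, rel=0.01)


class TestCohort:
    @pytest.fixture(scope="class")
    def small_spec(self):
        loads = {
            "DP": {"CUAP": 2.0, "sAD": 2.0, "fAD": 1.0},
            "CP": {"CUAP": 1.0, "sAD": 2.0, "fAD": 2.0},
            "CGP": {"CUAP": 0.0, "sAD": 1.0, "fAD": 2.0},
            "CWP": {"CUAP": 0.0, "sAD": 0.0, "fAD": 0.0},
            "CAA": {"CUAP": 0.0, "sAD": 0.0, "fAD": 0.0},
        }
        return CohortSpec(groups={"CUAP": 5, "sAD": 12, "fAD": 6},
                          loads=loads, field_um=(300, 300), mz_step=5.0,
                          seed=42)

    @pytest.fixture(scope="class")
    def cohort(self, small_spec):
        return make_cohort(small_spec)

    def test_cohort_size_matches_group_spec(self, cohort):
        """Groups of 5/12/6 patients give 23 patient bundles."""
        assert len(cohort) == 23
        groups = [b.group for b in cohort]
        assert groups.count("CUAP") == 5
        assert groups.count("sAD") == 12
        assert groups.count("fAD") == 6

    def test_cuap_has_no_cgp_or_caa(self, cohort):
        for b in cohort:
            if b.group == "CUAP":
                kinds = {m for _, m in b.truth.roi_labels}
                assert "CGP" not in kinds and "CAA" not in kinds

    def test_cohort_determinism(self, small_spec):
        from dataclasses import replace

        tiny = replace(small_spec, groups={"CUAP": 1, "sAD": 1, "fAD": 1})
        a = make_cohort(tiny)
        b = make_cohort(tiny)
        for pa, pb in zip(a, b):
            np.testing.assert_array_equal(pa.msi.cube, pb.msi.cube)
            np.testing.assert_array_equal(pa.scene.channels["LCO"],
                                          pb.scene.channels["LCO"])

    def test_every_plaque_once_in_roi_labels(self, cohort):
        for b in cohort:
            ids = [rid for rid, _ in b.truth.roi_labels]
            assert len(ids) == len(set(ids)) == len(b.truth.plaques)


def test_invalid_cv_rejected():
    with pytest.raises(ValueError, match="CV"):
        CohortSpec(technical_cv=1.5)


def test_scene_and_truth_writers(tmp_path):
    """TIFF stack, truth CSV and cohort manifest round-trip basic content."""
    import json

    import pandas as pd
    import tifffile

    scene, truth = make_microscopy_scene(counts={"CP": 2},
                                         field_um=(200, 200), rng_seed=1)
    synthio.write_scene_tiff(scene, tmp_path / "scene.tiff")
    stack = tifffile.imread(tmp_path / "scene.tiff")
    assert stack.shape[0] == 2  # LCO + PHF1 pages
    np.testing.assert_allclose(stack[0], scene.channels["LCO"])

    synthio.write_truth_csv(truth, tmp_path / "truth.csv")
    table = pd.read_csv(tmp_path / "truth.csv")
    assert list(table["class"]) == ["CP", "CP"]
    assert set(table.columns) >= {"roi_id", "center_x_um", "diameter_um"}

    tiny_loads = {"DP": {"sAD": 1.0}, "CP": {"sAD": 1.0}}
    spec = CohortSpec(groups={"sAD": 1}, loads=tiny_loads,
                      field_um=(300, 300), mz_step=10.0, seed=3)
    bundles = make_cohort(spec)
    synthio.write_cohort_manifest(bundles, spec, tmp_path / "manifest.json")
    manifest = json.loads((tmp_path / "manifest.json").read_text())
    assert manifest["groups"] == {"sAD": 1}
    assert len(manifest["patients"]) == 1
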