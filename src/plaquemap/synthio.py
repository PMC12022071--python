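"""Synthetic cohorts: microscopy scenes, MSI datacubes and ROI spectra.

The generators emulate the statistical structure the downstream analysis
assumes, with known ground truth:

* plaque-type-specific image morphology (diffuse blobs, cored plaques with a
  bright compact core and weaker corona, multi-cored coarse-grained plaques
  without corona, cotton-wool blobs, vascular amyloid annuli), with
  morphotype-specific diameter ranges (CP 30-50 um, CGP 50-100 um, DP and
  CWP >= 50 um);
* plaque-type-specific A-beta peptide abundance profiles whose pairwise fold
  changes encode the study's directionality (CP above DP for A-beta 1-40 and
  the pyroglutamated x-42 species; CGP above CP for the x-40 species; CAA
  above CGP for A-beta 1-40 / 3pE-40 and below for x-42);
* Gaussian peak shapes at instrument resolution m/dm = 1000 on a 1500-6000 Da
  axis, a decaying-exponential baseline, multiplicative log-normal abundance
  noise parameterised by CV and an additive detector floor;
* cohort structure: CUAP / sAD / fAD group sizes, plaque-load ordering, and
  the three-level noise hierarchy (technical 10%, intra-patient 16%,
  inter-patient 18% CV by default).

All generators are pure functions of (parameters, seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .containers import MSIDataset, Spectrum
from .panel import DEFAULT_PANEL, AbetaPeptide, build_abeta_panel

__all__ = [
    "MORPHOTYPES",
    "CLASS_CODES",
    "PlaqueTemplate",
    "DEFAULT_TEMPLATES",
    "CohortSpec",
    "PlaquePlacement",
    "SyntheticTruth",
    "Scene",
    "PatientBundle",
    "make_microscopy_scene",
    "make_patch_set",
    "make_msi_dataset",
    "make_cohort",
    "iter_cohort",
    "simulate_roi_spectra",
    "planted_fold_changes",
    "write_scene_tiff",
    "write_truth_csv",
    "write_cohort_manifest",
]

MORPHOTYPES = ("DP", "CP", "CGP", "CWP", "CAA")
CLASS_CODES = {"DP": 1, "CP": 2, "CGP": 3, "CWP": 4, "CAA": 5}

MSI_PITCH_UM = 10.0  # acquisition raster of the linear-mode runs


@dataclass(frozen=True)
class PlaqueTemplate:
    """Geometry and peptide make-up of one plaque morphotype."""

    morphotype: str
    diameter_range_um: tuple[float, float]
    n_cores: tuple[int, int]  # inclusive range; (1, 1) for single-cored
    has_corona: bool
    profile: dict  # peptide name -> relative abundance (arbitrary units)
    core_enrichment: dict = field(default_factory=dict)  # peptide -> core/halo ratio
    phf1_intensity: float = 0.0  # planted tau-neurite channel amplitude

    def __post_init__(self):
        lo, hi = self.diameter_range_um
        if not (0 < lo <= hi):
            raise ValueError(f"{self.morphotype}: bad diameter range {lo}-{hi}")
        if any(v < 0 for v in self.profile.values()):
            raise ValueError(f"{self.morphotype}: abundances must be >= 0")
        if self.morphotype == "CGP":
            if self.has_corona:
                raise ValueError("coarse-grained plaques are devoid of corona")
            if self.n_cores[0] < 2:
                raise ValueError("coarse-grained plaques are multi-cored")


def _default_templates() -> dict:
    # Relative abundances chosen once so that every pairwise contrast the
    # study reports has a planted fold change >= 2 in the stated direction.
    # CP vs DP discriminators: A-beta 1-40, 3pE-42, 11pE-42 (x3), 1-42
    # marginally (x1.3); the remaining peptides are deliberately equal so
    # they act as true negatives in recovery experiments.
    dp = {
        "Abeta1-40": 1.0, "Abeta1-42": 5.0, "Abeta2-42": 1.5,
        "Abeta3pE-40": 0.50, "Abeta3pE-42": 1.0, "Abeta4-40": 0.50,
        "Abeta4-42": 1.0, "Abeta5-42": 1.5, "Abeta11pE-42": 0.5,
    }
    cp = {
        "Abeta1-40": 3.0, "Abeta1-42": 6.5, "Abeta2-42": 1.5,
        "Abeta3pE-40": 0.50, "Abeta3pE-42": 3.0, "Abeta4-40": 0.50,
        "Abeta4-42": 1.0, "Abeta5-42": 1.5, "Abeta11pE-42": 1.5,
    }
    # CGP vs CP: x-40 species elevated (1-40 x2.5, 3pE-40 and 4-40 x4),
    # x-42 species reduced (roughly half); 2-42 left equal.
    cgp = {
        "Abeta1-40": 7.5, "Abeta1-42": 3.0, "Abeta2-42": 1.5,
        "Abeta3pE-40": 2.0, "Abeta3pE-42": 1.5, "Abeta4-40": 2.0,
        "Abeta4-42": 0.5, "Abeta5-42": 0.7, "Abeta11pE-42": 0.7,
    }
    cwp = {
        "Abeta1-40": 2.0, "Abeta1-42": 5.0, "Abeta2-42": 2.5,
        "Abeta3pE-40": 0.40, "Abeta3pE-42": 4.5, "Abeta4-40": 0.40,
        "Abeta4-42": 2.0, "Abeta5-42": 2.5, "Abeta11pE-42": 2.5,
    }
    # CAA vs CGP: 1-40 and 3pE-40 higher still, x-42 species lower.
    caa = {
        "Abeta1-40": 15.0, "Abeta1-42": 1.5, "Abeta2-42": 1.5,
        "Abeta3pE-40": 4.0, "Abeta3pE-42": 0.75, "Abeta4-40": 2.0,
        "Abeta4-42": 0.5, "Abeta5-42": 0.35, "Abeta11pE-42": 0.35,
    }
    return {
        "DP": PlaqueTemplate("DP", (50.0, 90.0), (0, 0), False, dp,
                             phf1_intensity=0.0),
        "CP": PlaqueTemplate("CP", (30.0, 50.0), (1, 1), True, cp,
                             core_enrichment={"Abeta1-40": 3.0},
                             phf1_intensity=50.0),
        "CGP": PlaqueTemplate("CGP", (50.0, 100.0), (3, 8), False, cgp,
                              core_enrichment={}, phf1_intensity=120.0),
        "CWP": PlaqueTemplate("CWP", (50.0, 100.0), (0, 0), False, cwp,
                              phf1_intensity=0.0),
        "CAA": PlaqueTemplate("CAA", (40.0, 80.0), (0, 0), False, caa,
                              phf1_intensity=10.0),
    }


DEFAULT_TEMPLATES = _default_templates()

# Mean plaques per patient per morphotype, by group.  Magnitudes are simulator
# parameters; only the group ordering (DP: CUAP ~ sAD > fAD; CP: CUAP < sAD <
# fAD; CGP: absent in CUAP, fAD > sAD; CAA absent in CUAP) is study-anchored.
DEFAULT_LOADS = {
    "DP": {"CUAP": 6.0, "sAD": 5.0, "fAD": 1.0},
    "CP": {"CUAP": 2.0, "sAD": 4.0, "fAD": 6.0},
    "CGP": {"CUAP": 0.0, "sAD": 2.0, "fAD": 4.0},
    "CWP": {"CUAP": 0.0, "sAD": 0.0, "fAD": 0.0},
    "CAA": {"CUAP": 0.0, "sAD": 1.0, "fAD": 1.0},
}


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a synthetic multi-patient cohort."""

    groups: dict = field(default_factory=lambda: {"CUAP": 5, "sAD": 12, "fAD": 6})
    loads: dict = field(default_factory=lambda: {k: dict(v) for k, v in DEFAULT_LOADS.items()})
    technical_cv: float = 0.10
    intra_patient_cv: float = 0.16
    inter_patient_cv: float = 0.18
    seed: int = 0
    field_um: tuple[float, float] = (600.0, 600.0)
    px_um: float = 0.5
    mz_step: float = 2.0
    panel_names: tuple = DEFAULT_PANEL

    def __post_init__(self):
        for cv in (self.technical_cv, self.intra_patient_cv, self.inter_patient_cv):
            if not (0 <= cv < 1):
                raise ValueError("CVs must lie in [0, 1)")
        if any(n < 1 for n in self.groups.values()):
            raise ValueError("every group needs at least one patient")


@dataclass
class PlaquePlacement:
    """Ground-truth geometry of one generated deposit (um, section coords)."""

    roi_id: int
    morphotype: str
    center_um: tuple[float, float]
    diameter_um: float
    cores_um: list = field(default_factory=list)  # [(cx, cy, diameter), ...]
    vessel_um: np.ndarray | None = None  # (n, 2) polyline for CAA
    annulus_width_um: float = 0.0


@dataclass
class SyntheticTruth:
    """Ground truth of one generated scene / datacube."""

    roi_labels: list  # [(roi_id, morphotype), ...]
    plaques: list  # [PlaquePlacement, ...]
    pixel_class_map: np.ndarray  # microscopy resolution, CLASS_CODES
    instance_map: np.ndarray  # microscopy resolution, roi_id (0 = background)
    field_um: tuple[float, float]
    px_um: float
    planted_fold_changes: dict = field(default_factory=dict)
    transform_true: object = None  # microscopy-um -> MSI-um similarity
    msi_class_map: np.ndarray | None = None
    msi_instance_map: np.ndarray | None = None


@dataclass
class Scene:
    """Multi-channel synthetic microscopy field (grayscale float images)."""

    channels: dict  # tag -> 2-D float32 array
    px_um: float
    field_um: tuple[float, float]


def planted_fold_changes(templates: dict, panel_names=DEFAULT_PANEL) -> dict:
    """Pairwise template fold changes: (peptide, "A_vs_B") -> profile_A/profile_B."""
    out = {}
    types = list(templates)
    for a in types:
        for b in types:
            if a == b:
                continue
            for pep in panel_names:
                pa = templates[a].profile.get(pep, 0.0)
                pb = templates[b].profile.get(pep, 0.0)
                out[(pep, f"{a}_vs_{b}")] = pa / pb if pb > 0 else np.inf
    return out


# ---------------------------------------------------------------------------
# microscopy scene rendering
# ---------------------------------------------------------------------------

def _smooth_noise(shape, sigma_px, rng):
    n = gaussian_filter(rng.uniform(0.0, 1.0, size=shape), sigma_px, mode="reflect")
    lo, hi = n.min(), n.max()
    return (n - lo) / (hi - lo) if hi > lo else np.full(shape, 0.5)

def _radial(shape, cy, cx, px_um):
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    return np.hypot((yy + 0.5) * px_um - cy, (xx + 0.5) * px_um - cx)


def _render_plaque(lco, phf1, cls_map, inst_map, placement, template, px_um, rng):
    """Draw one deposit into the channel images and the truth label maps."""
    cx, cy = placement.center_um
    R = placement.diameter_um / 2.0
    r = _radial(lco.shape, cy, cx, px_um)
    kind = placement.morphotype
    if kind == "DP":
        tex = 0.6 + 0.8 * _smooth_noise(lco.shape, 8.0 / px_um, rng)
        body = 40.0 * np.exp(-((r / (0.60 * R)) ** 2)) * tex
        footprint = r <= R
    elif kind == "CP":
        ccx, ccy, cd = placement.cores_um[0]
        rc = _radial(lco.shape, ccy, ccx, px_um)
        body = 200.0 * np.exp(-((rc / (cd / 2.0)) ** 4))
        body += 80.0 * np.exp(-((r / (0.80 * R)) ** 2))  # corona
        footprint = r <= R
    elif kind == "CGP":
        body = 60.0 * np.exp(-((r / R) ** 8))  # dense fill, sharp edge, no corona
        for gx, gy, gd in placement.cores_um:
            rg = _radial(lco.shape, gy, gx, px_um)
            body += 180.0 * np.exp(-((rg / (gd / 2.0)) ** 4))
        footprint = r <= R
    elif kind == "CWP":
        body = 100.0 * np.exp(-((r / (0.85 * R)) ** 4))
        footprint = r <= R
    elif kind == "CAA":
        w = placement.annulus_width_um
        band = (r >= R - w) & (r <= R)
        body = np.where(band, 150.0, 0.0)
        body = gaussian_filter(body, 2.0 / px_um, mode="reflect")
        footprint = (r >= R - w - 2.0) & (r <= R + 2.0)
    else:  # pragma: no cover
        raise ValueError(f"unknown morphotype {kind!r}")
    lco += body
    if template.phf1_intensity > 0:
        tex = 0.5 + 1.0 * _smooth_noise(lco.shape, 5.0 / px_um, rng)
        phf1 += template.phf1_intensity * tex * np.exp(-((r / (0.75 * R)) ** 4))
    sel = footprint & (cls_map == 0)
    cls_map[sel] = CLASS_CODES[kind]
    inst_map[sel] = placement.roi_id


def _place_plaques(templates, counts, field_um, rng, margin_um=10.0, max_tries=200):
    """Draw non-overlapping placements; raise if packing fails."""
    placements, next_id = [], 1
    order = [t for t in MORPHOTYPES if counts.get(t, 0) > 0]
    for kind in order:
        tpl = templates[kind]
        for _ in range(int(counts[kind])):
            lo, hi = tpl.diameter_range_um
            for attempt in range(max_tries):
                d = rng.uniform(lo, hi)
                R = d / 2.0
                cx = rng.uniform(R + margin_um, field_um[0] - R - margin_um)
                cy = rng.uniform(R + margin_um, field_um[1] - R - margin_um)
                ok = all(
                    np.hypot(cx - p.center_um[0], cy - p.center_um[1])
                    > (d + p.diameter_um) / 2.0 + 2.0
                    for p in placements
                )
                if ok:
                    break
            else:
                raise RuntimeError(
                    f"could not place all requested plaques (placed "
                    f"{len(placements)} of {sum(counts.values())}); "
                    "enlarge the field or reduce counts"
                )
            cores = []
            if kind == "CP":
                cores = [(cx, cy, 0.30 * d)]
            elif kind == "CGP":
                n_gran = rng.integers(tpl.n_cores[0], tpl.n_cores[1] + 1)
                for _ in range(n_gran):
                    ang = rng.uniform(0, 2 * np.pi)
                    rad = rng.uniform(0, 0.70 * R)
                    gd = rng.uniform(8.0, 16.0)
                    cores.append((cx + rad * np.cos(ang), cy + rad * np.sin(ang), gd))
            ann_w = rng.uniform(10.0, 20.0) if kind == "CAA" else 0.0
            vessel = None
            if kind == "CAA":
                ang = rng.uniform(0, 2 * np.pi)
                t = np.linspace(-1.5 * d, 1.5 * d, 25)
                vessel = np.column_stack(
                    [cx + t * np.cos(ang), cy + t * np.sin(ang)]
                )
            placements.append(
                PlaquePlacement(next_id, kind, (cx, cy), d, cores, vessel, ann_w)
            )
            next_id += 1
    return placements


def make_microscopy_scene(
    templates: dict | None = None,
    counts: dict | None = None,
    field_um: tuple[float, float] = (800.0, 800.0),
    px_um: float = 0.5,
    rng_seed: int = 0,
    margin_um: float = 10.0,
) -> tuple[Scene, SyntheticTruth]:
    """Render a synthetic LCO (+ tau-neurite) field with known ground truth.

    Returns a two-channel :class:`Scene` ("LCO", "PHF1") and the matching
    :class:`SyntheticTruth`.  Deterministic for a fixed seed.
    """
    templates = dict(DEFAULT_TEMPLATES if templates is None else templates)
    counts = dict(counts or {})
    if px_um <= 0:
        raise ValueError("px_um must be positive")
    rng = np.random.default_rng(rng_seed)
    shape = (int(round(field_um[1] / px_um)), int(round(field_um[0] / px_um)))
    lco = np.zeros(shape, dtype=np.float64)
    phf1 = np.zeros(shape, dtype=np.float64)
    cls_map = np.zeros(shape, dtype=np.int32)
    inst_map = np.zeros(shape, dtype=np.int32)
    placements = _place_plaques(templates, counts, field_um, rng, margin_um)
    for p in placements:
        _render_plaque(lco, phf1, cls_map, inst_map, p, templates[p.morphotype], px_um, rng)
    scene = Scene(
        channels={"LCO": lco.astype(np.float32), "PHF1": phf1.astype(np.float32)},
        px_um=px_um,
        field_um=tuple(field_um),
    )
    truth = SyntheticTruth(
        roi_labels=[(p.roi_id, p.morphotype) for p in placements],
        plaques=placements,
        pixel_class_map=cls_map,
        instance_map=inst_map,
        field_um=tuple(field_um),
        px_um=px_um,
        planted_fold_changes=planted_fold_changes(templates),
    )
    return scene, truth


def make_patch_set(
    n_per_class: int,
    classes: tuple = ("CGP", "CP", "DP"),
    seed: int = 0,
    patch_um: float = 120.0,
    px_um: float = 1.0,
    noise_sigma: float = 4.0,
    templates: dict | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Single-plaque training patches with labels, one plaque per patch.

    Each patch renders one plaque of the requested morphotype (same
    renderer as the full scenes) into a ``patch_um``-sized field at
    ``px_um`` microns/pixel, adds Gaussian camera noise and a random
    intensity scale, and applies the classifier's preprocessing (grayscale,
    resize, percentile contrast stretch).  Returns ``(patches, labels)``
    with patches shaped ``(n, size, size)`` in [0, 1].
    """
    from .classifier import preprocess_patch

    templates = dict(DEFAULT_TEMPLATES if templates is None else templates)
    rng = np.random.default_rng(seed)
    size = int(round(patch_um / px_um))
    patches, labels = [], []
    for cls in classes:
        tpl = templates[cls]
        lo, hi = tpl.diameter_range_um
        # cap the diameter so the plaque fits the patch with a small margin
        hi = min(hi, 0.8 * patch_um)
        capped = replace(tpl, diameter_range_um=(min(lo, hi), hi))
        local = dict(templates)
        local[cls] = capped
        for _ in range(n_per_class):
            scene, _ = make_microscopy_scene(
                local, {cls: 1}, (patch_um, patch_um), px_um,
                rng_seed=int(rng.integers(0, 2**31 - 1)), margin_um=2.0,
            )
            img = scene.channels["LCO"] * rng.uniform(0.7, 1.3)
            if noise_sigma > 0:
                img = img + rng.normal(0.0, noise_sigma, size=img.shape)
            patches.append(preprocess_patch(img, size))
            labels.append(cls)
    return np.stack(patches), np.asarray(labels)


# ---------------------------------------------------------------------------
# MSI datacube synthesis
# ---------------------------------------------------------------------------

def peak_profile_matrix(panel: list[AbetaPeptide], mz: np.ndarray) -> np.ndarray:
    """(n_peptides, n_bins) unit-apex Gaussians at instrument resolution."""
    fwhm = np.array([p.mz_obs for p in panel]) / 1000.0
    sigma = fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    centers = np.array([p.mz_obs for p in panel])
    return np.exp(
        -((mz[None, :] - centers[:, None]) ** 2) / (2.0 * sigma[:, None] ** 2)
    )


def default_mz_axis(mz_step: float = 1.0) -> np.ndarray:
    return np.arange(1500.0, 6000.0 + 0.5 * mz_step, mz_step)


def exp_baseline(mz: np.ndarray, b0: float = 4.0, lam: float = 1200.0) -> np.ndarray:
    """Smooth matrix-cluster baseline b0 * exp(-(m - 1500)/lambda)."""
    return b0 * np.exp(-(mz - 1500.0) / lam)


def _lognormal_factors(rng, cv, size):
    if cv <= 0:
        return np.ones(size)
    s = np.sqrt(np.log1p(cv * cv))
    return np.exp(rng.normal(-0.5 * s * s, s, size=size))  # unit mean


def _msi_masks(truth: SyntheticTruth, pitch_um: float, transform=None):
    """Rasterise truth geometry onto the MSI grid (class, instance, core)."""
    nx = int(round(truth.field_um[0] / pitch_um))
    ny = int(round(truth.field_um[1] / pitch_um))
    xs = (np.arange(nx) + 0.5) * pitch_um
    ys = (np.arange(ny) + 0.5) * pitch_um
    gx, gy = np.meshgrid(xs, ys)
    if transform is not None:  # MSI pixel centres back into microscopy coords
        pts = np.column_stack([gx.ravel(), gy.ravel()])
        inv = transform.inverse().apply(pts)
        gx = inv[:, 0].reshape(gx.shape)
        gy = inv[:, 1].reshape(gy.shape)
    cls_map = np.zeros((ny, nx), dtype=np.int32)
    inst_map = np.zeros((ny, nx), dtype=np.int32)
    core_map = np.zeros((ny, nx), dtype=bool)
    for p in truth.plaques:
        cx, cy = p.center_um
        r = np.hypot(gx - cx, gy - cy)
        R = p.diameter_um / 2.0
        if p.morphotype == "CAA":
            sel = (r >= R - p.annulus_width_um) & (r <= R)
        else:
            sel = r <= R
        new = sel & (cls_map == 0)
        cls_map[new] = CLASS_CODES[p.morphotype]
        inst_map[new] = p.roi_id
        for ccx, ccy, cd in p.cores_um:
            core_map |= np.hypot(gx - ccx, gy - ccy) <= cd / 2.0
    return cls_map, inst_map, core_map


def make_msi_dataset(
    scene_truth: SyntheticTruth,
    panel: list[AbetaPeptide] | None = None,
    templates: dict | None = None,
    noise_cv: float = 0.10,
    rng_seed: int = 0,
    mz_step: float = 1.0,
    baseline_b0: float = 4.0,
    baseline_lambda: float = 1200.0,
    detector_sigma: float = 0.02,
    pitch_um: float = MSI_PITCH_UM,
    transform=None,
    plaque_scales: dict | None = None,
) -> tuple[MSIDataset, SyntheticTruth]:
    """Synthesise the MSI datacube matching a scene's ground truth.

    Each pixel spectrum is ``sum_p amplitude(pixel, p) * Gaussian(mz_p,
    FWHM = mz_p/1000) + baseline + detector noise``; the per-peptide
    amplitudes carry multiplicative log-normal noise with the requested CV.
    ``plaque_scales`` maps roi_id -> per-peptide multipliers (used by the
    cohort generator to plant patient- and plaque-level variation).

    Returns the dataset and a truth updated with MSI-resolution label maps.
    """
    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")
    panel = list(panel) if panel is not None else build_abeta_panel()
    if not panel:
        raise ValueError("panel must be non-empty")
    templates = dict(DEFAULT_TEMPLATES if templates is None else templates)
    rng = np.random.default_rng(rng_seed)
    cls_map, inst_map, core_map = _msi_masks(scene_truth, pitch_um, transform)
    ny, nx = cls_map.shape
    if ny * nx == 0:
        raise ValueError("scene produces an empty MSI pixel grid")
    mz = default_mz_axis(mz_step)
    G = peak_profile_matrix(panel, mz)
    pep_names = [p.name for p in panel]
    amps = np.zeros((ny, nx, len(panel)))
    for p in scene_truth.plaques:
        tpl = templates[p.morphotype]
        base = np.array([tpl.profile.get(n, 0.0) for n in pep_names])
        if plaque_scales is not None and p.roi_id in plaque_scales:
            base = base * np.asarray(plaque_scales[p.roi_id])
        enrich = np.array([tpl.core_enrichment.get(n, 1.0) for n in pep_names])
        sel = inst_map == p.roi_id
        amps[sel] = base
        amps[sel & core_map] = base * enrich
    amps *= _lognormal_factors(rng, noise_cv, amps.shape)
    cube = amps.reshape(-1, len(panel)) @ G
    cube += exp_baseline(mz, baseline_b0, baseline_lambda)[None, :]
    if detector_sigma > 0:
        cube += rng.normal(0.0, detector_sigma, size=cube.shape)
    cube = np.clip(cube, 0.0, None).reshape(ny, nx, mz.size)
    dataset = MSIDataset(mz=mz, cube=cube, pitch_um=pitch_um,
                         meta={"panel": pep_names})
    truth = replace(scene_truth)
    truth.msi_class_map = cls_map
    truth.msi_instance_map = inst_map
    truth.transform_true = transform
    return dataset, truth


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

@dataclass
class PatientBundle:
    patient_id: str
    group: str
    scene: Scene
    msi: MSIDataset
    truth: SyntheticTruth


def _patient_counts(spec: CohortSpec, group: str, rng) -> dict:
    counts = {}
    for kind in MORPHOTYPES:
        mean = spec.loads.get(kind, {}).get(group, 0.0)
        if group == "CUAP" and kind in ("CGP", "CAA"):
            mean = 0.0  # never present in the unimpaired group
        if mean <= 0:
            counts[kind] = 0
            continue
        n = int(rng.poisson(mean))
        if kind in ("DP", "CP"):
            n = max(n, 1)  # every virtual section shows some plaques
        counts[kind] = n
    return counts


def iter_cohort(spec: CohortSpec, panel=None, templates=None):
    """Yield :class:`PatientBundle` objects one at a time (memory-friendly)."""
    panel = list(panel) if panel is not None else build_abeta_panel(spec.panel_names)
    templates = dict(DEFAULT_TEMPLATES if templates is None else templates)
    master = np.random.default_rng(spec.seed)
    pep_names = [p.name for p in panel]
    for group in spec.groups:
        for i in range(spec.groups[group]):
            pid = f"{group}{i + 1}"
            prng = np.random.default_rng(master.integers(0, 2**31 - 1))
            counts = _patient_counts(spec, group, prng)
            scene, truth = make_microscopy_scene(
                templates, counts, spec.field_um, spec.px_um,
                rng_seed=int(prng.integers(0, 2**31 - 1)),
            )
            patient_fx = _lognormal_factors(prng, spec.inter_patient_cv, len(pep_names))
            scales = {
                p.roi_id: patient_fx
                * _lognormal_factors(prng, spec.intra_patient_cv, len(pep_names))
                for p in truth.plaques
            }
            msi, truth = make_msi_dataset(
                truth, panel, templates,
                noise_cv=spec.technical_cv,
                rng_seed=int(prng.integers(0, 2**31 - 1)),
                mz_step=spec.mz_step,
                plaque_scales=scales,
            )
            yield PatientBundle(pid, group, scene, msi, truth)


def make_cohort(spec: CohortSpec, panel=None, templates=None) -> list:
    """Generate the full cohort as a list of per-patient bundles."""
    return list(iter_cohort(spec, panel, templates))


def simulate_roi_spectra(
    spec: CohortSpec,
    plaque_types: tuple = ("DP", "CP", "CGP"),
    n_plaques_per_type: int = 10,
    panel=None,
    templates=None,
    mz_step: float = 0.25,
    baseline_b0: float = 4.0,
    detector_sigma: float = 0.02,
) -> tuple[list[Spectrum], pd.DataFrame]:
    """Fast path: synthesize ROI-average spectra without spatial rendering.

    Emulates the three-level noise hierarchy directly at the ROI level:
    per-patient peptide abundances jittered with the inter-patient CV,
    per-plaque abundances with the intra-patient CV and each measured
    spectrum with the technical CV.  Used by the statistics
    parameter-recovery experiments where the spatial detour adds nothing.
    """
    panel = list(panel) if panel is not None else build_abeta_panel(spec.panel_names)
    templates = dict(DEFAULT_TEMPLATES if templates is None else templates)
    rng = np.random.default_rng(spec.seed)
    mz = default_mz_axis(mz_step)
    G = peak_profile_matrix(panel, mz)
    base_line = exp_baseline(mz, baseline_b0)
    pep_names = [p.name for p in panel]
    spectra, rows = [], []
    roi_id = 0
    for group, n_pat in spec.groups.items():
        for i in range(n_pat):
            pid = f"{group}{i + 1}"
            patient_fx = _lognormal_factors(rng, spec.inter_patient_cv, len(panel))
            for kind in plaque_types:
                if group == "CUAP" and kind in ("CGP", "CAA"):
                    continue
                profile = np.array(
                    [templates[kind].profile.get(n, 0.0) for n in pep_names]
                )
                for _ in range(n_plaques_per_type):
                    roi_id += 1
                    amp = (
                        profile
                        * patient_fx
                        * _lognormal_factors(rng, spec.intra_patient_cv, len(panel))
                        * _lognormal_factors(rng, spec.technical_cv, len(panel))
                    )
                    inten = amp @ G + base_line
                    if detector_sigma > 0:
                        inten = inten + rng.normal(0, detector_sigma, mz.size)
                    spectra.append(
                        Spectrum(mz, np.clip(inten, 0, None),
                                 {"roi_id": roi_id, "patient": pid,
                                  "group": group, "plaque_type": kind})
                    )
                    rows.append((roi_id, pid, group, kind))
    meta = pd.DataFrame(rows, columns=["roi_id", "patient", "group", "plaque_type"])
    return spectra, meta


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def write_scene_tiff(scene: Scene, path: str) -> None:
    """Write the channel stack as a multi-page TIFF (one page per channel)."""
    import tifffile

    stack = np.stack([scene.channels[k] for k in scene.channels])
    tifffile.imwrite(
        str(path), stack,
        metadata={"channels": list(scene.channels), "px_um": scene.px_um},
    )


def write_truth_csv(truth: SyntheticTruth, path: str) -> None:
    rows = [
        {
            "roi_id": p.roi_id,
            "class": p.morphotype,
            "center_x_um": p.center_um[0],
            "center_y_um": p.center_um[1],
            "diameter_um": p.diameter_um,
        }
        for p in truth.plaques
    ]
    pd.DataFrame(rows).to_csv(str(path), index=False)


def write_cohort_manifest(bundles: list, spec: CohortSpec, path: str) -> None:
    manifest = {
        "groups": dict(spec.groups),
        "seed": spec.seed,
        "technical_cv": spec.technical_cv,
        "intra_patient_cv": spec.intra_patient_cv,
        "inter_patient_cv": spec.inter_patient_cv,
        "patients": [
            {
                "patient_id": b.patient_id,
                "group": b.group,
                "n_plaques": len(b.truth.roi_labels),
                "plaque_types": sorted({m for _, m in b.truth.roi_labels}),
            }
            for b in bundles
        ],
    }
    with open(str(path), "w") as fh:
        json.dump(manifest, fh, indent=2)
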