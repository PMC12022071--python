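"""ROI spectral processing for MALDI-MSI peptide quantification.

The processing chain applied to every ROI-average spectrum, in fixed order:

1. square-root intensity transform (variance stabilisation),
2. Savitzky-Golay smoothing (half-window 10 bins, cubic),
3. SNIP baseline estimation (100 iterations, decreasing window, LLS
   transform) and subtraction,
4. total-ion-count normalisation,
5. MAD noise estimation (scaled by 1.4826 for sigma-consistency),
6. peak detection at SNR > 2,
7. trapezoidal area-under-curve integration in a fixed window around each
   panel peptide (default half-width: one FWHM, m/z / 1000).

The ROI x peptide AUC matrix (:class:`PeakTable` rows) is the unit of all
downstream statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter

from .containers import MSIDataset, Spectrum
from .panel import AbetaPeptide

__all__ = [
    "PreprocessParams",
    "smooth_savgol",
    "snip_baseline",
    "estimate_noise_mad",
    "tic_normalize",
    "detect_peaks",
    "peak_auc",
    "preprocess_spectrum",
    "preprocess_roi_spectra",
    "peaktable_to_long",
]

MAD_SCALE = 1.4826  # makes the MAD a consistent sigma estimator for Gaussians


@dataclass(frozen=True)
class PreprocessParams:
    """Parameters of the ROI spectral chain."""

    sg_half_window: int = 10  # bins; full window 2w+1
    sg_poly_order: int = 3
    snip_iterations: int = 100
    snr_threshold: float = 2.0
    tic_target: float = 1.0
    auc_halfwidth_da: float | None = None  # None -> one FWHM (mz/1000) per peptide

    def __post_init__(self):
        if self.sg_half_window < 1 or self.snip_iterations < 1:
            raise ValueError("window and iteration counts must be >= 1")
        if self.sg_poly_order >= 2 * self.sg_half_window + 1:
            raise ValueError("polynomial order must be below the full window size")
        if self.snr_threshold <= 0:
            raise ValueError("SNR threshold must be positive")


def smooth_savgol(s: Spectrum, half_window: int = 10, poly_order: int = 3) -> Spectrum:
    """Savitzky-Golay least-squares polynomial smoothing.

    Edges are handled by polynomial interpolation of the terminal windows,
    so a polynomial of the filter's order is reproduced exactly over the
    whole spectrum (including the edges).
    """
    window = 2 * half_window + 1
    if window > len(s):
        raise ValueError(
            f"spectrum ({len(s)} bins) shorter than smoothing window ({window})"
        )
    if poly_order >= window:
        raise ValueError("poly_order must be below the window length")
    out = savgol_filter(s.intensity, window_length=window, polyorder=poly_order,
                        mode="interp")
    return s.copy_with(out)


def _lls(v: np.ndarray) -> np.ndarray:
    return np.log(np.log(np.sqrt(v + 1.0) + 1.0) + 1.0)


def _inv_lls(y: np.ndarray) -> np.ndarray:
    return (np.exp(np.exp(y) - 1.0) - 1.0) ** 2 - 1.0


def snip_baseline(s: Spectrum, iterations: int = 100) -> Spectrum:
    """SNIP baseline: LLS transform, decreasing-window clipping, inverse LLS.

    Window width shrinks from ``iterations`` down to 1 (the decreasing,
    statistics-sensitive variant); each pass clips every bin to the mean of
    its two neighbours at the current distance.  The result underestimates
    peaks and tracks smooth baseline structure.
    """
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    v = s.intensity
    if np.any(v < 0):
        raise ValueError("SNIP expects nonnegative intensities (sqrt stage first)")
    y = _lls(v.astype(float))
    n = y.size
    for m in range(min(iterations, n - 1), 0, -1):
        left = np.empty(n)
        right = np.empty(n)
        left[m:] = y[:-m]
        left[:m] = y[0]
        right[:-m] = y[m:]
        right[-m:] = y[-1]
        y = np.minimum(y, 0.5 * (left + right))
    base = np.clip(_inv_lls(y), 0.0, None)
    return s.copy_with(np.minimum(base, v))


def estimate_noise_mad(s: Spectrum) -> float:
    """Noise level as 1.4826 x median absolute deviation of the intensities."""
    if len(s) < 2:
        raise ValueError("need at least two bins to estimate noise")
    v = s.intensity
    return float(MAD_SCALE * np.median(np.abs(v - np.median(v))))


def tic_normalize(s: Spectrum, target: float = 1.0) -> Spectrum:
    """Scale so the total ion count (sum of intensities) equals ``target``."""
    tic = float(s.intensity.sum())
    if tic <= 0:
        raise ValueError(
            f"zero-TIC spectrum (meta={s.meta!r}): cannot normalise"
        )
    return s.copy_with(s.intensity * (target / tic), tic_raw=tic)


def detect_peaks(s: Spectrum, snr_threshold: float = 2.0,
                 noise: float | None = None) -> list[tuple[float, float, float]]:
    """Local maxima with SNR above threshold; near-coincident apexes merged.

    Expects a baseline-subtracted, smoothed spectrum.  Maxima closer than
    one FWHM (apex m/z / 1000) keep only the higher apex.  Returns a list of
    ``(apex_mz, apex_intensity, snr)``.
    """
    v = s.intensity
    if noise is None:
        noise = estimate_noise_mad(s)
    if noise <= 0:
        noise = np.finfo(float).tiny
    idx = np.nonzero((v[1:-1] > v[:-2]) & (v[1:-1] >= v[2:]))[0] + 1
    idx = idx[v[idx] / noise > snr_threshold]
    idx = idx[np.argsort(v[idx])[::-1]]  # strongest first
    kept: list[int] = []
    for i in idx:
        fwhm = s.mz[i] / 1000.0
        if all(abs(s.mz[i] - s.mz[j]) >= fwhm for j in kept):
            kept.append(i)
    kept.sort()
    return [(float(s.mz[i]), float(v[i]), float(v[i] / noise)) for i in kept]


def peak_auc(s: Spectrum, center_mz: float, half_width: float) -> float:
    """Trapezoidal AUC over ``[center - hw, center + hw]`` (negatives clipped)."""
    if half_width <= 0:
        raise ValueError("half_width must be positive")
    sel = (s.mz >= center_mz - half_width) & (s.mz <= center_mz + half_width)
    if sel.sum() < 2:
        raise ValueError(
            f"integration window {center_mz}+-{half_width} covers "
            f"{int(sel.sum())} bin(s); need at least 2"
        )
    return float(np.trapezoid(np.clip(s.intensity[sel], 0.0, None), s.mz[sel]))


def preprocess_spectrum(s: Spectrum, params: PreprocessParams = PreprocessParams()
                        ) -> tuple[Spectrum, float]:
    """Run sqrt -> smoothing -> SNIP subtraction -> TIC on one spectrum.

    The square-root transform stabilises variance for the smoothing and
    baseline stages; because it is nonlinear, the baseline-subtracted
    signal is mapped back to the intensity scale by difference of squares
    (``smoothed^2 - baseline^2``), which is exact for peaks that add on top
    of the baseline.  The TIC normalisation factor is the raw spectrum's
    total ion count, so peptide fold changes between ROIs survive
    normalisation.  Returns the processed spectrum and its MAD noise level.
    """
    raw_tic = float(np.clip(s.intensity, 0.0, None).sum())
    if raw_tic <= 0:
        raise ValueError(f"zero-TIC spectrum (meta={s.meta!r}): cannot normalise")
    stage = s.copy_with(np.sqrt(np.clip(s.intensity, 0.0, None)))
    stage = smooth_savgol(stage, params.sg_half_window, params.sg_poly_order)
    stage = stage.copy_with(np.clip(stage.intensity, 0.0, None))  # SG ringing
    baseline = snip_baseline(stage, params.snip_iterations)
    signal = np.clip(stage.intensity**2 - baseline.intensity**2, 0.0, None)
    stage = stage.copy_with(signal * (params.tic_target / raw_tic),
                            tic_raw=raw_tic)
    noise = estimate_noise_mad(stage)
    return stage, noise


def _roi_average(dataset: MSIDataset, mask: np.ndarray, roi_id) -> Spectrum:
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != dataset.shape:
        raise ValueError(f"ROI {roi_id!r}: mask shape does not match the grid")
    if not mask.any():
        raise ValueError(f"ROI {roi_id!r} covers no MSI pixels")
    spec = dataset.mean_spectrum(mask)
    spec.meta["roi_id"] = roi_id
    return spec


def preprocess_roi_spectra(
    spectra_or_dataset,
    roi_masks: dict | None = None,
    panel: list[AbetaPeptide] = (),
    params: PreprocessParams = PreprocessParams(),
    roi_meta: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Build the ROI x peptide AUC PeakTable.

    Two input forms are accepted: an :class:`MSIDataset` plus
    ``roi_masks`` (roi_id -> boolean pixel mask, averaged per ROI first),
    or a prebuilt list of ROI-average :class:`Spectrum` objects (e.g. from
    :func:`plaquemap.synthio.simulate_roi_spectra`).

    Peptides whose apex SNR falls at or below the threshold are recorded as
    0 and flagged in the companion ``below_noise_<peptide>`` columns.
    ``roi_meta`` (indexed or keyed by ``roi_id``) contributes patient /
    group / plaque-type tags.
    """
    if not panel:
        raise ValueError("panel must be non-empty")
    if isinstance(spectra_or_dataset, MSIDataset):
        if not roi_masks:
            raise ValueError("roi_masks required with an MSIDataset input")
        spectra = [_roi_average(spectra_or_dataset, m, rid)
                   for rid, m in roi_masks.items()]
    else:
        spectra = list(spectra_or_dataset)
    meta_by_roi = {}
    if roi_meta is not None:
        meta_by_roi = roi_meta.set_index("roi_id").to_dict("index")
    rows = []
    for spec in spectra:
        roi_id = spec.meta.get("roi_id")
        processed, noise = preprocess_spectrum(spec, params)
        row = {"roi_id": roi_id}
        row.update(meta_by_roi.get(roi_id, {k: spec.meta[k] for k in
                                            ("patient", "group", "plaque_type")
                                            if k in spec.meta}))
        bin_da = float(np.median(np.diff(processed.mz)))
        for pep in panel:
            hw = params.auc_halfwidth_da or pep.mz_obs / 1000.0
            hw = max(hw, 1.5 * bin_da)  # window must span >= 2 bins
            sel = np.abs(processed.mz - pep.mz_obs) <= hw
            apex = processed.intensity[sel].max() if sel.any() else 0.0
            below = apex / noise <= params.snr_threshold if noise > 0 else apex <= 0
            row[pep.name] = 0.0 if below else peak_auc(processed, pep.mz_obs, hw)
            row[f"below_noise_{pep.name}"] = bool(below)
        rows.append(row)
    return pd.DataFrame(rows)


def peaktable_to_long(table: pd.DataFrame, panel: list[AbetaPeptide]) -> pd.DataFrame:
    """Long-format (one row per ROI x peptide) view of a PeakTable."""
    id_cols = [c for c in table.columns
               if not c.startswith("below_noise_")
               and c not in {p.name for p in panel}]
    long = table.melt(id_vars=id_cols, value_vars=[p.name for p in panel],
                      var_name="peptide", value_name="auc")
    return long
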