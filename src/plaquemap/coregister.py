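"""Microscopy-to-MSI registration, ROI transfer and plaque loads.

Both modalities image the same physical section, so the mapping is modelled
as a similarity transform (isotropic scale + rotation + translation),
estimated from landmark pairs by the closed-form least-squares (Umeyama /
scaled orthogonal Procrustes) solution.  Microscopy plaque ROIs are mapped
through the transform and rasterised onto the 10-um MSI grid with a 50%
pixel-coverage inclusion rule.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "SimilarityTransform",
    "fit_similarity",
    "transfer_rois",
    "plaque_load",
]


@dataclass(frozen=True)
class SimilarityTransform:
    """x' = s R(theta) x + t, all coordinates in um."""

    scale: float = 1.0
    theta: float = 0.0
    tx: float = 0.0
    ty: float = 0.0

    def __post_init__(self):
        if self.scale <= 0:
            raise ValueError("scale must be positive")

    @property
    def matrix(self) -> np.ndarray:
        c, s = np.cos(self.theta), np.sin(self.theta)
        return self.scale * np.array([[c, -s], [s, c]])

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return pts @ self.matrix.T + np.array([self.tx, self.ty])

    def inverse(self) -> "SimilarityTransform":
        inv_scale = 1.0 / self.scale
        c, s = np.cos(-self.theta), np.sin(-self.theta)
        tx, ty = -inv_scale * (c * self.tx - s * self.ty), \
                 -inv_scale * (s * self.tx + c * self.ty)
        return SimilarityTransform(inv_scale, -self.theta, tx, ty)

    def to_json(self, path) -> None:
        import json

        with open(str(path), "w") as fh:
            json.dump({"scale": self.scale, "theta": self.theta,
                       "tx": self.tx, "ty": self.ty}, fh)

    @classmethod
    def from_json(cls, path) -> "SimilarityTransform":
        import json

        with open(str(path)) as fh:
            return cls(**json.load(fh))

    def compose(self, other: "SimilarityTransform") -> "SimilarityTransform":
        """self after other: x -> self(other(x))."""
        m = self.matrix @ other.matrix
        scale = float(np.sqrt(np.abs(np.linalg.det(m))))
        theta = float(np.arctan2(m[1, 0], m[0, 0]))
        t = self.apply(np.array([[other.tx, other.ty]]))[0]
        return SimilarityTransform(scale, theta, float(t[0]), float(t[1]))


def fit_similarity(landmarks_src, landmarks_dst) -> tuple[SimilarityTransform, float]:
    """Least-squares similarity fit (closed-form Umeyama); returns (T, RMS).

    Needs at least two non-coincident landmark pairs.  Reflections are not
    allowed (both modalities view the section from the same side).
    """
    src = np.atleast_2d(np.asarray(landmarks_src, dtype=float))
    dst = np.atleast_2d(np.asarray(landmarks_dst, dtype=float))
    if src.shape != dst.shape or src.shape[0] < 2 or src.shape[1] != 2:
        raise ValueError("need matching lists of >= 2 landmark pairs (x, y)")
    mu_s, mu_d = src.mean(axis=0), dst.mean(axis=0)
    xs, xd = src - mu_s, dst - mu_d
    var_s = (xs**2).sum() / len(src)
    if var_s == 0:
        raise ValueError("degenerate configuration: source landmarks coincide")
    cov = xd.T @ xs / len(src)
    U, D, Vt = np.linalg.svd(cov)
    S = np.eye(2)
    if np.linalg.det(U) * np.linalg.det(Vt) < 0:
        S[1, 1] = -1.0
    R = U @ S @ Vt
    scale = float(np.trace(np.diag(D) @ S) / var_s)
    if scale <= 0:
        raise ValueError("degenerate configuration: nonpositive scale")
    theta = float(np.arctan2(R[1, 0], R[0, 0]))
    t = mu_d - scale * (R @ mu_s)
    T = SimilarityTransform(scale, theta, float(t[0]), float(t[1]))
    rms = float(np.sqrt(((T.apply(src) - dst) ** 2).sum(axis=1).mean()))
    return T, rms


def transfer_rois(
    rois,
    transform: SimilarityTransform,
    grid_shape: tuple[int, int],
    pitch_um: float = 10.0,
    origin_um: tuple[float, float] = (0.0, 0.0),
    coverage: float = 0.5,
    supersample: int = 5,
) -> dict:
    """Rasterise microscopy ROIs onto the MSI pixel grid.

    Each MSI pixel is subdivided into ``supersample**2`` sample points,
    mapped back through the inverse transform into microscopy coordinates,
    and included when at least ``coverage`` of its samples fall inside the
    ROI mask.  ROIs that land (partly) outside the grid are clipped with a
    warning; ROIs with an empty footprint are dropped with a warning.

    ``rois`` is a list of objects with ``pixel_set`` (boolean microscopy
    mask), ``px_um`` and ``label`` attributes (:class:`~plaquemap.microscopy.MicroROI`).
    Returns ``{roi_label: (ny, nx) boolean mask}``.
    """
    ny, nx = grid_shape
    inv = transform.inverse()
    # sample-point offsets within one MSI pixel, in um
    frac = (np.arange(supersample) + 0.5) / supersample
    offx, offy = np.meshgrid(frac * pitch_um, frac * pitch_um)
    masks = {}
    for roi in rois:
        mic_mask = roi.pixel_set
        px_um = roi.px_um
        ys, xs = np.nonzero(mic_mask)
        if ys.size == 0:
            warnings.warn(f"ROI {roi.label}: empty microscopy mask, dropped")
            continue
        # bounding box of the ROI in MSI coordinates limits the raster loop
        corners_um = np.column_stack([(xs + 0.5) * px_um, (ys + 0.5) * px_um])
        proj = transform.apply(corners_um)
        pad = pitch_um
        x0 = int((proj[:, 0].min() - origin_um[0] - pad) // pitch_um)
        x1 = int((proj[:, 0].max() - origin_um[0] + pad) // pitch_um) + 1
        y0 = int((proj[:, 1].min() - origin_um[1] - pad) // pitch_um)
        y1 = int((proj[:, 1].max() - origin_um[1] + pad) // pitch_um) + 1
        clipped = x0 < 0 or y0 < 0 or x1 > nx or y1 > ny
        x0c, x1c = max(x0, 0), min(x1, nx)
        y0c, y1c = max(y0, 0), min(y1, ny)
        mask = np.zeros((ny, nx), dtype=bool)
        for iy in range(y0c, y1c):
            for ix in range(x0c, x1c):
                sx = origin_um[0] + ix * pitch_um + offx
                sy = origin_um[1] + iy * pitch_um + offy
                back = inv.apply(np.column_stack([sx.ravel(), sy.ravel()]))
                jx = np.floor(back[:, 0] / px_um).astype(int)
                jy = np.floor(back[:, 1] / px_um).astype(int)
                ok = (
                    (jx >= 0) & (jx < mic_mask.shape[1])
                    & (jy >= 0) & (jy < mic_mask.shape[0])
                )
                inside = np.zeros(back.shape[0], dtype=bool)
                inside[ok] = mic_mask[jy[ok], jx[ok]]
                if inside.mean() >= coverage:
                    mask[iy, ix] = True
        if clipped and mask.any():
            warnings.warn(f"ROI {roi.label}: clipped at the MSI grid edge")
        if not mask.any():
            warnings.warn(f"ROI {roi.label}: no MSI pixel reaches "
                          f"{coverage:.0%} coverage, dropped")
            continue
        masks[roi.label] = mask
    if not masks:
        raise ValueError("no ROI overlaps the MSI grid")
    return masks


def plaque_load(
    rois_by_type: dict,
    tissue_mask: np.ndarray,
    px_um: float,
) -> pd.DataFrame:
    """Per-type plaque load: count, % area fraction and count per mm^2.

    ``rois_by_type`` maps a morphotype to a list of boolean masks on the
    same grid as ``tissue_mask`` (pixel size ``px_um``).
    """
    tissue_mask = np.asarray(tissue_mask, dtype=bool)
    tissue_px = int(tissue_mask.sum())
    if tissue_px == 0:
        raise ValueError("empty tissue mask")
    tissue_um2 = tissue_px * px_um**2
    tissue_mm2 = tissue_um2 / 1e6
    rows = []
    for kind, masks in rois_by_type.items():
        area_px = sum(int((np.asarray(m, dtype=bool) & tissue_mask).sum())
                      for m in masks)
        rows.append({
            "plaque_type": kind,
            "n_plaques": len(masks),
            "area_fraction_pct": 100.0 * area_px / tissue_px,
            "count_per_mm2": len(masks) / tissue_mm2,
        })
    return pd.DataFrame(rows)
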