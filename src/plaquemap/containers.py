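"""Shared in-memory containers: single spectra and MSI datacubes.

An :class:`MSIDataset` is a rectangular grid of pixels at a fixed pitch
(10 um for the linear-mode acquisitions modelled here), each carrying an
intensity vector on a common m/z axis.  imzML import/export goes through
pyimzml; the in-memory layout is a dense ``(ny, nx, n_bins)`` float32 cube,
which is the convenient shape for spatial smoothing and segmentation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Spectrum", "MSIDataset", "write_imzml", "read_imzml"]


@dataclass
class Spectrum:
    """Paired m/z grid and intensity vector for one pixel or one ROI average."""

    mz: np.ndarray
    intensity: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.ndim != 1 or self.mz.shape != self.intensity.shape:
            raise ValueError("mz and intensity must be 1-D arrays of equal length")
        if self.mz.size >= 2 and not np.all(np.diff(self.mz) > 0):
            raise ValueError("mz grid must be strictly increasing")
        if not np.all(np.isfinite(self.intensity)):
            raise ValueError("intensity contains non-finite values")

    def copy_with(self, intensity: np.ndarray, **meta) -> "Spectrum":
        new_meta = dict(self.meta)
        new_meta.update(meta)
        return Spectrum(self.mz, np.asarray(intensity, dtype=float), new_meta)

    def __len__(self) -> int:
        return self.mz.size


@dataclass
class MSIDataset:
    """Pixel grid of spectra on a common m/z axis.

    ``cube[iy, ix, :]`` is the spectrum of the pixel whose centre sits at
    ``origin_um + (ix + 0.5, iy + 0.5) * pitch_um`` in section coordinates.
    """

    mz: np.ndarray
    cube: np.ndarray  # (ny, nx, n_bins)
    pitch_um: float = 10.0
    origin_um: tuple[float, float] = (0.0, 0.0)
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.mz = np.asarray(self.mz, dtype=float)
        self.cube = np.asarray(self.cube, dtype=np.float32)
        if self.cube.ndim != 3 or self.cube.shape[2] != self.mz.size:
            raise ValueError("cube must be (ny, nx, n_bins) matching the mz axis")
        if self.pitch_um <= 0:
            raise ValueError("pixel pitch must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.cube.shape[:2]

    @property
    def n_pixels(self) -> int:
        return self.cube.shape[0] * self.cube.shape[1]

    def spectrum_at(self, ix: int, iy: int) -> Spectrum:
        return Spectrum(self.mz, self.cube[iy, ix, :], {"pixel": (ix, iy)})

    def mean_spectrum(self, mask: np.ndarray | None = None) -> Spectrum:
        """Average spectrum over ``mask`` (boolean ``(ny, nx)``) or all pixels."""
        if mask is None:
            flat = self.cube.reshape(-1, self.mz.size)
        else:
            mask = np.asarray(mask, dtype=bool)
            if mask.shape != self.shape:
                raise ValueError("mask shape does not match the pixel grid")
            if not mask.any():
                raise ValueError("mask selects no pixels")
            flat = self.cube[mask]
        return Spectrum(self.mz, flat.mean(axis=0, dtype=np.float64))


def write_imzml(dataset: MSIDataset, path: str) -> str:
    """Write a dataset as continuous-mode imzML (+ sibling .ibd)."""
    from pyimzml.ImzMLWriter import ImzMLWriter

    path = str(path)
    if path.lower().endswith(".imzml"):
        path = path[: -len(".imzml")]
    ny, nx = dataset.shape
    with ImzMLWriter(path, mode="continuous") as writer:
        for iy in range(ny):
            for ix in range(nx):
                writer.addSpectrum(
                    dataset.mz, dataset.cube[iy, ix, :].astype(float), (ix + 1, iy + 1)
                )
    return path + ".imzML"


def read_imzml(path: str, pitch_um: float = 10.0) -> MSIDataset:
    """Read an imzML file (continuous or processed) into a dense cube.

    Processed-mode spectra are mapped to the m/z axis of the first spectrum
    by nearest-bin assignment; continuous mode round-trips exactly.
    """
    from pyimzml.ImzMLParser import ImzMLParser

    parser = ImzMLParser(str(path))
    coords = np.asarray(parser.coordinates)[:, :2]
    xs, ys = coords[:, 0], coords[:, 1]
    x0, y0 = xs.min(), ys.min()
    nx, ny = xs.max() - x0 + 1, ys.max() - y0 + 1
    mz0, _ = parser.getspectrum(0)
    mz0 = np.asarray(mz0, dtype=float)
    cube = np.zeros((ny, nx, mz0.size), dtype=np.float32)
    for i, (x, y) in enumerate(zip(xs, ys)):
        mz, inten = parser.getspectrum(i)
        mz = np.asarray(mz, dtype=float)
        inten = np.asarray(inten, dtype=float)
        if mz.size == mz0.size and np.allclose(mz, mz0):
            cube[y - y0, x - x0, :] = inten
        else:  # processed mode: nearest-bin accumulation
            idx = np.clip(np.searchsorted(mz0, mz), 0, mz0.size - 1)
            np.add.at(cube[y - y0, x - x0, :], idx, inten)
    return MSIDataset(mz=mz0, cube=cube, pitch_um=pitch_um)
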