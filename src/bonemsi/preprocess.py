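"""Spectral preprocessing: RMS normalization, mean spectra, noise estimation,
peak picking on the mean spectrum, and ion-image datacube construction.

Peak picking operates on the overall mean spectrum (one shared feature space
for the whole experiment) rather than per pixel; the resulting peak list
defines the columns of the :class:`DataCube` used by all downstream steps.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .io import MSIDataset, ROIMask

__all__ = [
    "PeakList",
    "DataCube",
    "rms_normalize",
    "mean_spectrum",
    "estimate_noise",
    "pick_peaks",
    "build_datacube",
]


@dataclass
class PeakList:
    """Picked peaks: centers (m/z, strictly increasing), apex S/N, apex intensity."""

    centers: np.ndarray
    snr: np.ndarray
    apex: np.ndarray

    def __post_init__(self) -> None:
        self.centers = np.asarray(self.centers, dtype=float)
        self.snr = np.asarray(self.snr, dtype=float)
        self.apex = np.asarray(self.apex, dtype=float)
        if len(self.centers) > 1 and not np.all(np.diff(self.centers) > 0):
            raise ValueError("peak centers must be strictly increasing")

    def __len__(self) -> int:
        return len(self.centers)

    def to_tsv(self, path: str | Path, header_comment: str | None = None) -> None:
        with open(path, "w") as fh:
            if header_comment:
                fh.write(f"# {header_comment}\n")
            fh.write("center_mz\tsnr\tapex\n")
            for c, s, a in zip(self.centers, self.snr, self.apex):
                fh.write(f"{c:.6f}\t{s:.4g}\t{a:.6g}\n")

    @staticmethod
    def from_tsv(path: str | Path) -> "PeakList":
        df = pd.read_csv(path, sep="\t", comment="#")
        return PeakList(df["center_mz"].values, df["snr"].values, df["apex"].values)


@dataclass
class DataCube:
    """Pixels x picked-peaks intensity matrix (ion-image stack)."""

    values: np.ndarray           # (n_pixels, n_peaks), non-negative
    coordinates: np.ndarray      # (n_pixels, 2) of (x, y)
    peak_centers: np.ndarray     # (n_peaks,)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.coordinates = np.asarray(self.coordinates, dtype=int)
        self.peak_centers = np.asarray(self.peak_centers, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D")
        if self.values.shape != (len(self.coordinates), len(self.peak_centers)):
            raise ValueError("values shape inconsistent with coordinates/peaks")
        if np.any(self.values < 0):
            raise ValueError("datacube entries must be non-negative")

    @property
    def n_pixels(self) -> int:
        return self.values.shape[0]

    @property
    def n_peaks(self) -> int:
        return self.values.shape[1]

    @property
    def grid_shape(self) -> tuple[int, int]:
        return (
            int(self.coordinates[:, 1].max()) + 1,
            int(self.coordinates[:, 0].max()) + 1,
        )

    def ion_image(self, peak_index: int, fill: float = 0.0) -> np.ndarray:
        """Spatial map of one peak's intensity (rows x cols)."""
        img = np.full(self.grid_shape, fill, dtype=float)
        img[self.coordinates[:, 1], self.coordinates[:, 0]] = self.values[:, peak_index]
        return img

    def subset_pixels(self, indices: np.ndarray) -> "DataCube":
        return DataCube(self.values[indices], self.coordinates[indices], self.peak_centers)

    def to_tsv(self, path: str | Path, header_comment: str | None = None) -> None:
        with open(path, "w") as fh:
            if header_comment:
                fh.write(f"# {header_comment}\n")
            cols = "\t".join(f"{c:.6f}" for c in self.peak_centers)
            fh.write(f"x\ty\t{cols}\n")
            for (x, y), row in zip(self.coordinates, self.values):
                vals = "\t".join(f"{v:.6g}" for v in row)
                fh.write(f"{x}\t{y}\t{vals}\n")


# ---------------------------------------------------------------------------

def rms_normalize(ds: MSIDataset) -> MSIDataset:
    """Divide each spectrum by its root-mean-square intensity.

    After normalization every non-empty spectrum has RMS exactly 1; the
    operation is idempotent.  All-zero spectra are left unchanged with a
    warning.
    """
    out, n_zero = [], 0
    for inten in ds.intensity_arrays:
        rms = float(np.sqrt(np.mean(np.square(inten)))) if len(inten) else 0.0
        if rms == 0.0:
            n_zero += 1
            out.append(inten.copy())
        else:
            out.append(inten / rms)
    if n_zero:
        warnings.warn(f"rms_normalize: {n_zero} all-zero spectra left unchanged")
    return MSIDataset(
        coordinates=ds.coordinates.copy(),
        mz_arrays=list(ds.mz_arrays),
        intensity_arrays=out,
        mode=ds.mode,
        section_id=ds.section_id,
        group=ds.group,
    )


def _resolve_pixels(
    ds: MSIDataset, mask: ROIMask | np.ndarray | None, labels=None
) -> np.ndarray:
    if mask is None:
        return np.arange(ds.n_pixels)
    if isinstance(mask, ROIMask):
        if labels is None:
            labels = [lb for lb in mask.vocabulary if lb != "background"]
        return mask.pixel_indices(ds, labels)
    mask = np.asarray(mask)
    if mask.dtype == bool:
        return np.flatnonzero(mask)
    return mask.astype(int)


def mean_spectrum(
    ds: MSIDataset,
    mask: ROIMask | np.ndarray | None = None,
    labels: list[str] | None = None,
    axis: np.ndarray | None = None,
    bin_width: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Arithmetic mean spectrum over selected pixels.

    ``mask`` may be an :class:`ROIMask` (with optional ``labels``; default
    all tissue labels), a boolean vector, or an index array.  Continuous-mode
    data are averaged directly on the shared axis; processed-mode spectra are
    first resampled onto a common axis by linear interpolation (an explicit
    ``axis``, or a uniform grid of width ``bin_width`` spanning the data).
    """
    idx = _resolve_pixels(ds, mask, labels)
    if len(idx) == 0:
        raise ValueError("empty pixel selection for mean spectrum")
    if ds.mode == "continuous" and axis is None:
        mz = ds.shared_mz
        mean = np.mean([ds.intensity_arrays[i] for i in idx], axis=0)
        return mz, mean
    if axis is None:
        lo = min(ds.mz_arrays[i][0] for i in idx)
        hi = max(ds.mz_arrays[i][-1] for i in idx)
        if bin_width is None:
            spacing = np.diff(ds.mz_arrays[idx[0]])
            bin_width = float(np.median(spacing)) if len(spacing) else 1.0
        axis = np.arange(lo, hi + bin_width, bin_width)
    acc = np.zeros_like(axis, dtype=float)
    for i in idx:
        acc += np.interp(axis, ds.mz_arrays[i], ds.intensity_arrays[i],
                         left=0.0, right=0.0)
    return axis, acc / len(idx)


def estimate_noise(
    mz: np.ndarray, intensity: np.ndarray, window: float = 1.0
) -> np.ndarray:
    """Per-bin noise level: sliding-window MAD scaled by 1.4826.

    The scaling makes the estimate consistent with the standard deviation for
    Gaussian noise; the median absolute deviation is insensitive to sparse
    peaks inside the window.  ``window`` is in Da.
    """
    mz = np.asarray(mz, dtype=float)
    intensity = np.asarray(intensity, dtype=float)
    if window <= 0:
        raise ValueError("window must be positive")
    if len(mz) > 1:
        min_spacing = float(np.min(np.diff(mz)))
        if window < min_spacing:
            raise ValueError(
                f"window {window} Da smaller than bin spacing {min_spacing:.6g} Da"
            )
    noise = np.empty_like(intensity)
    half = window / 2.0
    lo = np.searchsorted(mz, mz - half, side="left")
    hi = np.searchsorted(mz, mz + half, side="right")
    for i in range(len(mz)):
        seg = intensity[lo[i]:hi[i]]
        med = np.median(seg)
        noise[i] = 1.4826 * np.median(np.abs(seg - med))
    return noise


def pick_peaks(
    mz: np.ndarray,
    intensity: np.ndarray,
    snr_threshold: float = 3.0,
    noise_window: float = 1.0,
    noise: np.ndarray | None = None,
    min_separation_ppm: float = 0.0,
) -> PeakList:
    """Pick local maxima with apex/noise >= ``snr_threshold``.

    The peak center is the apex m/z (no centroid fitting).  Bins whose noise
    estimate is zero only qualify through a small floor tied to the largest
    noise value, so a constant spectrum yields no peaks.  A positive
    ``min_separation_ppm`` merges maxima closer than that distance, keeping
    the most intense apex — use a resolution-matched value (several peak
    widths) to suppress shoulder maxima on profile data.
    """
    mz = np.asarray(mz, dtype=float)
    intensity = np.asarray(intensity, dtype=float)
    if noise is None:
        noise = estimate_noise(mz, intensity, window=noise_window)
    apex_idx, _ = find_peaks(intensity)
    if len(apex_idx) == 0:
        return PeakList(np.array([]), np.array([]), np.array([]))
    floor = max(np.max(noise) * 1e-12, np.finfo(float).tiny)
    local_noise = np.maximum(noise[apex_idx], floor)
    snr = intensity[apex_idx] / local_noise
    keep = snr >= snr_threshold
    centers, snrs, apexes = mz[apex_idx[keep]], snr[keep], intensity[apex_idx[keep]]
    if min_separation_ppm > 0 and len(centers) > 1:
        accepted: list[int] = []
        for i in np.argsort(-apexes):  # strongest first
            if all(
                abs(centers[i] - centers[j]) / centers[j] * 1e6
                >= min_separation_ppm
                for j in accepted
            ):
                accepted.append(i)
        accepted = sorted(accepted)
        centers, snrs, apexes = centers[accepted], snrs[accepted], apexes[accepted]
    return PeakList(centers, snrs, apexes)


def _assign_bins(mz: np.ndarray, centers: np.ndarray, tol_ppm: float) -> np.ndarray:
    """Map each axis bin to its nearest peak window, or -1.

    The extraction window of a center c is [c*(1 - tol), c*(1 + tol)) with
    tol = tol_ppm * 1e-6, half-open on the upper edge; bins falling into two
    overlapping windows go to the nearest center.
    """
    tol = tol_ppm * 1e-6
    nearest = np.clip(np.searchsorted(centers, mz), 0, len(centers) - 1)
    left = np.clip(nearest - 1, 0, len(centers) - 1)
    pick = np.where(
        np.abs(centers[nearest] - mz) <= np.abs(centers[left] - mz), nearest, left
    )
    c = centers[pick]
    inside = (mz >= c * (1.0 - tol)) & (mz < c * (1.0 + tol))
    return np.where(inside, pick, -1)


def build_datacube(
    ds: MSIDataset,
    peaks: PeakList,
    tol_ppm: float = 4.0,
    agg: str = "sum",
) -> DataCube:
    """Extract the ion-image stack: per pixel and peak, the ``sum`` (default)
    or ``max`` of spectral intensities within +/- ``tol_ppm`` of the center."""
    if tol_ppm <= 0:
        raise ValueError("tol_ppm must be positive")
    if agg not in ("sum", "max"):
        raise ValueError("agg must be 'sum' or 'max'")
    centers = peaks.centers
    n_peaks = len(centers)
    tol = tol_ppm * 1e-6
    if n_peaks > 1 and np.any(
        centers[:-1] * (1 + tol) > centers[1:] * (1 - tol)
    ):
        warnings.warn(
            "overlapping extraction windows resolved by nearest-center assignment"
        )
    values = np.zeros((ds.n_pixels, n_peaks), dtype=float)
    if ds.mode == "continuous":
        assign = _assign_bins(ds.shared_mz, centers, tol_ppm)
        mat = ds.intensity_matrix()
        for k in range(n_peaks):
            cols = np.flatnonzero(assign == k)
            if len(cols) == 0:
                continue
            sub = mat[:, cols]
            values[:, k] = sub.sum(axis=1) if agg == "sum" else sub.max(axis=1)
    else:
        for i in range(ds.n_pixels):
            assign = _assign_bins(ds.mz_arrays[i], centers, tol_ppm)
            inten = ds.intensity_arrays[i]
            for k in np.unique(assign[assign >= 0]):
                seg = inten[assign == k]
                values[i, k] = seg.sum() if agg == "sum" else seg.max()
    return DataCube(values, ds.coordinates.copy(), centers.copy())
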