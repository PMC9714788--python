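"""Reading and writing MSI datasets (imzML/ibd) and ROI label masks.

Internal conventions: pixel coordinates are 0-based ``(x, y)`` pairs stored
row-major (sorted by ``(y, x)``); the imzML standard is 1-based, and the
conversion happens at the I/O boundary.  Both imzML binary modes are
supported: *continuous* (one shared m/z axis) and *processed* (per-pixel
axes).
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image
from pyimzml.ImzMLParser import ImzMLParser
from pyimzml.ImzMLWriter import ImzMLWriter

__all__ = [
    "MSIDataset",
    "ROIMask",
    "FormatError",
    "read_imzml",
    "write_imzml",
    "read_roi_mask",
    "write_roi_mask",
    "DEFAULT_VOCABULARY",
]

DEFAULT_VOCABULARY = ("background", "mineralized_bone", "osteoid", "bone_marrow")


class FormatError(ValueError):
    """Raised for malformed imzML/ibd pairs or ROI masks."""


@dataclass
class MSIDataset:
    """Per-pixel mass spectra on a 2-D grid.

    ``coordinates`` is an ``(n_pixels, 2)`` integer array of 0-based
    ``(x, y)`` positions.  ``mz_arrays`` and ``intensity_arrays`` are lists
    of 1-D float arrays, one per pixel; in continuous mode all entries of
    ``mz_arrays`` are views of one shared axis.
    """

    coordinates: np.ndarray
    mz_arrays: list[np.ndarray]
    intensity_arrays: list[np.ndarray]
    mode: str = "processed"
    section_id: str | None = None
    group: str | None = None

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=int)
        self.validate()

    # -- invariants ---------------------------------------------------------
    def validate(self) -> None:
        if self.mode not in ("continuous", "processed"):
            raise FormatError(f"unknown mode {self.mode!r}")
        if len(self.coordinates) == 0:
            raise FormatError("dataset has no pixels")
        if self.coordinates.ndim != 2 or self.coordinates.shape[1] != 2:
            raise FormatError("coordinates must be an (n, 2) array")
        if len({tuple(c) for c in self.coordinates}) != len(self.coordinates):
            raise FormatError("duplicate pixel coordinates")
        if not (
            len(self.mz_arrays) == len(self.intensity_arrays) == len(self.coordinates)
        ):
            raise FormatError("coordinate/spectrum count mismatch")
        for i, (mz, inten) in enumerate(zip(self.mz_arrays, self.intensity_arrays)):
            if len(mz) != len(inten):
                raise FormatError(f"pixel {i}: m/z and intensity lengths differ")
            if len(mz) > 1 and not np.all(np.diff(mz) > 0):
                raise FormatError(f"pixel {i}: m/z axis not strictly increasing")

    # -- basic accessors ----------------------------------------------------
    @property
    def n_pixels(self) -> int:
        return len(self.coordinates)

    @property
    def grid_shape(self) -> tuple[int, int]:
        """(n_rows, n_cols) of the bounding grid."""
        return (
            int(self.coordinates[:, 1].max()) + 1,
            int(self.coordinates[:, 0].max()) + 1,
        )

    @property
    def shared_mz(self) -> np.ndarray:
        if self.mode != "continuous":
            raise FormatError("shared m/z axis only defined in continuous mode")
        return self.mz_arrays[0]

    def intensity_matrix(self) -> np.ndarray:
        """(n_pixels, n_bins) intensity stack; continuous mode only."""
        if self.mode != "continuous":
            raise FormatError("intensity matrix only defined in continuous mode")
        return np.vstack(self.intensity_arrays)

    def sorted_canonical(self) -> "MSIDataset":
        """Return a copy with pixels sorted row-major by (y, x)."""
        order = np.lexsort((self.coordinates[:, 0], self.coordinates[:, 1]))
        return MSIDataset(
            coordinates=self.coordinates[order],
            mz_arrays=[self.mz_arrays[i] for i in order],
            intensity_arrays=[self.intensity_arrays[i] for i in order],
            mode=self.mode,
            section_id=self.section_id,
            group=self.group,
        )

    @staticmethod
    def continuous(
        coordinates: np.ndarray,
        mz: np.ndarray,
        intensities: np.ndarray,
        **kwargs,
    ) -> "MSIDataset":
        """Build a continuous-mode dataset from a shared axis and an
        (n_pixels, n_bins) intensity matrix."""
        mz = np.asarray(mz, dtype=float)
        intensities = np.asarray(intensities, dtype=float)
        return MSIDataset(
            coordinates=coordinates,
            mz_arrays=[mz] * len(intensities),
            intensity_arrays=list(intensities),
            mode="continuous",
            **kwargs,
        )


# ---------------------------------------------------------------------------
# imzML I/O
# ---------------------------------------------------------------------------

def _check_ibd_extent(parser: ImzMLParser, ibd_path: Path) -> None:
    size = os.path.getsize(ibd_path)
    itemsizes = {
        "f": 4, "d": 8, "i": 4, "l": 8,
        np.float32: 4, np.float64: 8, np.int32: 4, np.int64: 8,
    }
    mz_item = itemsizes.get(parser.mzPrecision, 8)
    int_item = itemsizes.get(parser.intensityPrecision, 8)
    for off, length in zip(parser.mzOffsets, parser.mzLengths):
        end = off + length * mz_item
        if end > size:
            raise FormatError(
                f"truncated ibd file {ibd_path}: m/z block ends at byte {end} "
                f"but file has {size} bytes"
            )
    for off, length in zip(parser.intensityOffsets, parser.intensityLengths):
        end = off + length * int_item
        if end > size:
            raise FormatError(
                f"truncated ibd file {ibd_path}: intensity block ends at byte "
                f"{end} but file has {size} bytes"
            )


def read_imzml(path: str | Path, section_id: str | None = None,
               group: str | None = None) -> MSIDataset:
    """Read a paired imzML/ibd file into an :class:`MSIDataset`.

    imzML 1-based pixel indices are shifted to 0-based; pixels are returned
    in canonical (y, x) order regardless of on-disk order.
    """
    path = Path(path)
    ibd = path.with_suffix(".ibd")
    if not path.exists():
        raise FileNotFoundError(path)
    if not ibd.exists():
        raise FileNotFoundError(f"missing binary file {ibd}")
    parser = ImzMLParser(str(path))
    try:
        _check_ibd_extent(parser, ibd)
        mzs, intens = [], []
        for i in range(len(parser.coordinates)):
            mz, inten = parser.getspectrum(i)
            mz = np.asarray(mz, dtype=float)
            if len(mz) > 1 and not np.all(np.diff(mz) > 0):
                raise FormatError(f"pixel {i}: non-monotone m/z axis")
            mzs.append(mz)
            intens.append(np.asarray(inten, dtype=float))
        coords = np.array([(c[0] - 1, c[1] - 1) for c in parser.coordinates])
    finally:
        parser.m.close()
    # shared axis => continuous
    continuous = all(
        len(m) == len(mzs[0]) and np.array_equal(m, mzs[0]) for m in mzs[1:]
    )
    if continuous:
        shared = mzs[0]
        mzs = [shared] * len(mzs)
    ds = MSIDataset(
        coordinates=coords,
        mz_arrays=mzs,
        intensity_arrays=intens,
        mode="continuous" if continuous else "processed",
        section_id=section_id or path.stem,
        group=group,
    )
    return ds.sorted_canonical()


def write_imzml(ds: MSIDataset, path: str | Path) -> None:
    """Write an :class:`MSIDataset` as imzML/ibd with 64-bit encoding.

    Round-trips bit-exactly through :func:`read_imzml`.
    """
    ds.validate()
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with ImzMLWriter(
        str(path),
        mode=ds.mode,
        mz_dtype=np.float64,
        intensity_dtype=np.float64,
    ) as writer:
        for (x, y), mz, inten in zip(
            ds.coordinates, ds.mz_arrays, ds.intensity_arrays
        ):
            writer.addSpectrum(mz, inten, (int(x) + 1, int(y) + 1))


# ---------------------------------------------------------------------------
# ROI masks
# ---------------------------------------------------------------------------

@dataclass
class ROIMask:
    """Label image over the pixel grid of one section.

    ``labels`` is an (n_rows, n_cols) integer image indexing into
    ``vocabulary``; index 0 is conventionally the background label.
    """

    labels: np.ndarray
    vocabulary: tuple[str, ...] = DEFAULT_VOCABULARY
    group: str | None = None
    section_id: str | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.ndim != 2:
            raise FormatError("mask must be a 2-D label image")
        if self.labels.min() < 0 or self.labels.max() >= len(self.vocabulary):
            raise FormatError(
                f"mask labels outside vocabulary of size {len(self.vocabulary)}"
            )

    def index_of(self, label: str) -> int:
        try:
            return self.vocabulary.index(label)
        except ValueError:
            raise KeyError(f"label {label!r} not in vocabulary {self.vocabulary}")

    def label_at(self, x: int, y: int) -> str:
        return self.vocabulary[self.labels[y, x]]

    def pixel_indices(self, ds: MSIDataset, labels: str | list[str]) -> np.ndarray:
        """Indices into ``ds`` pixels whose mask label is in ``labels``."""
        if isinstance(labels, str):
            labels = [labels]
        wanted = {self.index_of(lb) for lb in labels}
        xs, ys = ds.coordinates[:, 0], ds.coordinates[:, 1]
        vals = self.labels[ys, xs]
        return np.flatnonzero(np.isin(vals, list(wanted)))

    def validate_against(self, ds: MSIDataset) -> None:
        nrows, ncols = ds.grid_shape
        if self.labels.shape[0] < nrows or self.labels.shape[1] < ncols:
            raise FormatError(
                f"mask shape {self.labels.shape} smaller than dataset grid "
                f"({nrows}, {ncols})"
            )
        if self.labels.shape[0] > nrows or self.labels.shape[1] > ncols:
            raise FormatError(
                f"mask shape {self.labels.shape} larger than dataset grid "
                f"({nrows}, {ncols})"
            )
        # every non-background labeled pixel must exist in the dataset
        have = {tuple(c) for c in ds.coordinates}
        ys, xs = np.nonzero(self.labels)
        missing = [(x, y) for x, y in zip(xs, ys) if (x, y) not in have]
        if missing:
            raise FormatError(
                f"{len(missing)} labeled mask pixels missing from dataset, "
                f"first {missing[0]}"
            )


def read_roi_mask(
    path: str | Path,
    ds: MSIDataset,
    vocabulary: tuple[str, ...] = DEFAULT_VOCABULARY,
    group: str | None = None,
    section_id: str | None = None,
) -> ROIMask:
    """Read an ROI mask as an 8-bit indexed PNG or an (x, y, label) TSV.

    PNG pixel values index the vocabulary.  TSV rows give 0-based x, y and a
    label name; unlisted pixels are background.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    nrows, ncols = ds.grid_shape
    if path.suffix.lower() == ".png":
        img = np.asarray(Image.open(path).convert("L"), dtype=int)
        labels = img
    else:
        labels = np.zeros((nrows, ncols), dtype=int)
        index = {name: i for i, name in enumerate(vocabulary)}
        with open(path) as fh:
            header = fh.readline().strip().split("\t")
            if header[:3] != ["x", "y", "label"]:
                raise FormatError(f"{path}: expected header x<TAB>y<TAB>label")
            for lineno, line in enumerate(fh, start=2):
                if not line.strip() or line.startswith("#"):
                    continue
                fields = line.rstrip("\n").split("\t")
                x, y, name = int(fields[0]), int(fields[1]), fields[2]
                if name not in index:
                    raise FormatError(
                        f"{path}:{lineno}: label {name!r} outside vocabulary"
                    )
                if not (0 <= x < ncols and 0 <= y < nrows):
                    raise FormatError(
                        f"{path}:{lineno}: pixel ({x}, {y}) outside grid"
                    )
                labels[y, x] = index[name]
    mask = ROIMask(labels, vocabulary, group=group, section_id=section_id)
    mask.validate_against(ds)
    return mask


def write_roi_mask(mask: ROIMask, path: str | Path) -> None:
    """Write a mask as PNG (label indices) or TSV (x, y, label rows)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if path.suffix.lower() == ".png":
        Image.fromarray(mask.labels.astype(np.uint8), mode="L").save(path)
        return
    with open(path, "w") as fh:
        fh.write("x\ty\tlabel\n")
        ys, xs = np.nonzero(mask.labels)
        for y, x in zip(ys, xs):
            fh.write(f"{x}\t{y}\t{mask.vocabulary[mask.labels[y, x]]}\n")
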