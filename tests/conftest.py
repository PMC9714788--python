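"""Shared fixtures: the bundled reference DB and seeded phantom pipelines.

The phantom chains are session-scoped: generating a phantom and running the
preprocessing chain once, then reusing it across test modules, keeps the
suite fast without weakening any assertion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pytest

from bonemsi.db import MetaboliteDB, load_default_db
from bonemsi.preprocess import (
    DataCube,
    PeakList,
    build_datacube,
    mean_spectrum,
    pick_peaks,
    rms_normalize,
)
from bonemsi.synthetic import GroundTruth, PhantomSpec, generate_dataset


@dataclass
class PhantomChain:
    """A generated phantom taken through the preprocessing chain."""

    spec: PhantomSpec
    datasets: list
    truth: GroundTruth
    normalized: list
    peaks: PeakList
    cubes: list[DataCube]

    def peak_to_truth(self) -> np.ndarray:
        """Index of the nearest ground-truth peak for each picked peak."""
        d = np.abs(self.peaks.centers[:, None] - self.truth.mz[None, :])
        return d.argmin(axis=1)

    def true_labels(self, section: int) -> np.ndarray:
        cube = self.cubes[section]
        mask = self.truth.masks[section]
        return mask.labels[cube.coordinates[:, 1], cube.coordinates[:, 0]]


def run_chain(spec: PhantomSpec, db: MetaboliteDB) -> PhantomChain:
    datasets, truth = generate_dataset(spec, db)
    normalized = [rms_normalize(ds) for ds in datasets]
    axis, acc = None, None
    for ds in normalized:
        mz, spectrum = mean_spectrum(ds)
        if axis is None:
            axis, acc = mz, spectrum.copy()
        else:
            acc += np.interp(axis, mz, spectrum, left=0.0, right=0.0)
    peaks = pick_peaks(
        axis, acc / len(normalized), snr_threshold=3.0,
        noise_window=1.0, min_separation_ppm=50.0,
    )
    cubes = [build_datacube(ds, peaks, tol_ppm=4.0) for ds in normalized]
    return PhantomChain(spec, datasets, truth, normalized, peaks, cubes)


@pytest.fixture(scope="session")
def db() -> MetaboliteDB:
    return load_default_db()


@pytest.fixture(scope="session")
def small_phantom(db) -> PhantomChain:
    """32x32 phantom, 60 peaks, 2 sections per group: fast unit-test bed."""
    spec = PhantomSpec(
        n_rows=32, n_cols=32, outer_radius=14.0, ring_width=4.0, seam_width=2.0,
        n_peaks=60, n_sections_per_group=2, n_up=5, n_down=4, seed=11,
    )
    return run_chain(spec, db)


@pytest.fixture(scope="session")
def default_phantom(db) -> PhantomChain:
    """The default study conditions: 64x64, ~300 peaks, 2 groups x 5 sections."""
    return run_chain(PhantomSpec(seed=1), db)
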