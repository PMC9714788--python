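"""Tissue segmentation of MSI datacubes.

Two factorizations are provided:

* **pLSA** — the probabilistic latent semantic (aspect) model
  ``P(pixel, peak) = sum_z P(z) P(pixel|z) P(peak|z)`` fitted by EM with the
  pixel x peak intensities treated as pseudo-counts.  The number of
  components is chosen a priori (tissue compartments plus one background
  component); a background component is identified from off-tissue pixels
  and excluded from peak association.
* **PCA** — mean-centered SVD, as an unsupervised cross-check.

Component order in pLSA is arbitrary; evaluation against ground-truth masks
uses Hungarian matching on the confusion matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment
from sklearn.decomposition import PCA

from .preprocess import DataCube

__all__ = [
    "ComponentModel",
    "fit_plsa",
    "identify_background",
    "assign_peaks",
    "fit_pca",
    "segment_pixels",
    "match_labels",
]

logger = logging.getLogger(__name__)

_EPS = 1e-300


@dataclass
class ComponentModel:
    """Fitted pLSA model.

    ``pixel_given_z`` and ``peak_given_z`` hold the conditional
    distributions as columns (each column sums to 1); ``priors`` is P(z).
    """

    priors: np.ndarray             # (K,)
    pixel_given_z: np.ndarray      # (n_pixels, K)
    peak_given_z: np.ndarray       # (n_peaks, K)
    coordinates: np.ndarray        # (n_pixels, 2)
    peak_centers: np.ndarray       # (n_peaks,)
    ll_trace: np.ndarray = field(default_factory=lambda: np.array([]))
    background: int | None = None
    seed: int | None = None

    @property
    def n_components(self) -> int:
        return len(self.priors)

    def validate(self, atol: float = 1e-9) -> None:
        if abs(self.priors.sum() - 1.0) > atol:
            raise ValueError("priors do not sum to 1")
        for name, mat in (("pixel", self.pixel_given_z), ("peak", self.peak_given_z)):
            err = np.abs(mat.sum(axis=0) - 1.0).max()
            if err > atol:
                raise ValueError(f"{name}-given-z columns drift from 1 by {err:.2e}")
        if len(self.ll_trace) > 1:
            drop = np.diff(self.ll_trace)
            allowed = -1e-9 * np.maximum(np.abs(self.ll_trace[:-1]), 1.0)
            if np.any(drop < allowed):
                raise ValueError("EM log-likelihood decreased")

    def pixel_scores(self) -> np.ndarray:
        """Posterior P(z | pixel), rows summing to 1."""
        num = self.pixel_given_z * self.priors[None, :]
        return num / np.maximum(num.sum(axis=1, keepdims=True), _EPS)

    def reconstruction(self) -> np.ndarray:
        """Model P(pixel, peak) matrix (sums to 1)."""
        return (self.pixel_given_z * self.priors[None, :]) @ self.peak_given_z.T


def _dirichlet_columns(rng: np.random.Generator, n: int, k: int) -> np.ndarray:
    g = rng.gamma(1.0, 1.0, size=(n, k)) + 1e-12
    return g / g.sum(axis=0, keepdims=True)


def fit_plsa(
    cube: DataCube,
    n_components: int,
    seed: int = 0,
    max_iter: int = 500,
    tol: float = 1e-6,
    n_restarts: int = 3,
) -> ComponentModel:
    """Fit the aspect model by EM on non-negative intensities.

    Deterministic given ``seed``: ``n_restarts`` EM runs from independent
    seeded Dirichlet initializations are fitted and the one with the best
    final log-likelihood is returned (the usual guard against EM local
    optima).  Each run stops when the relative log-likelihood change falls
    below ``tol`` or after ``max_iter`` iterations; the log-likelihood is
    non-decreasing across iterations.
    """
    if n_components < 2:
        raise ValueError("n_components must be >= 2 (compartments + background)")
    if n_restarts < 1:
        raise ValueError("n_restarts must be >= 1")
    best: ComponentModel | None = None
    for restart in range(n_restarts):
        model = _fit_plsa_once(
            cube, n_components, seed=seed, restart=restart,
            max_iter=max_iter, tol=tol,
        )
        if best is None or model.ll_trace[-1] > best.ll_trace[-1]:
            best = model
    return best


def _fit_plsa_once(
    cube: DataCube,
    n_components: int,
    seed: int,
    restart: int,
    max_iter: int,
    tol: float,
) -> ComponentModel:
    X = cube.values
    total = X.sum()
    if total <= 0:
        raise ValueError("all-zero datacube")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), restart]))
    k = n_components
    pz = rng.dirichlet(np.ones(k))
    pd_z = _dirichlet_columns(rng, X.shape[0], k)
    pw_z = _dirichlet_columns(rng, X.shape[1], k)

    ll_trace = []
    prev_ll = -np.inf
    for _ in range(max_iter):
        # P(d, w) under the current model
        denom = (pd_z * pz[None, :]) @ pw_z.T          # (n_d, n_w)
        ll = float(np.sum(X * np.log(np.maximum(denom, _EPS))))
        ll_trace.append(ll)
        # combined E+M step
        R = X / np.maximum(denom, _EPS)                # n(d,w) / P(d,w)
        pd_num = (R @ pw_z) * pd_z * pz[None, :]       # (n_d, k)
        pw_num = (R.T @ pd_z) * pw_z * pz[None, :]     # (n_w, k)
        mass = pd_num.sum(axis=0)                      # component masses
        pz = mass / mass.sum()
        pd_z = pd_num / np.maximum(pd_num.sum(axis=0, keepdims=True), _EPS)
        pw_z = pw_num / np.maximum(pw_num.sum(axis=0, keepdims=True), _EPS)
        if prev_ll != -np.inf and abs(ll - prev_ll) <= tol * abs(prev_ll):
            break
        prev_ll = ll

    model = ComponentModel(
        priors=pz,
        pixel_given_z=pd_z,
        peak_given_z=pw_z,
        coordinates=cube.coordinates.copy(),
        peak_centers=cube.peak_centers.copy(),
        ll_trace=np.asarray(ll_trace),
        seed=seed,
    )
    model.validate(atol=1e-9)
    return model


def identify_background(
    model: ComponentModel, background_pixels: np.ndarray | None
) -> int | None:
    """Select the component whose pixel-score mass concentrates on
    off-tissue pixels.

    ``background_pixels`` are dataset pixel indices labeled background in
    the ROI mask.  For each component z the concentration is
    ``sum_{d in background} P(d|z)`` (P(d|z) sums to 1 over pixels); ties
    break to the lowest component index.  Returns ``None`` when no
    background pixels exist.
    """
    if background_pixels is None or len(background_pixels) == 0:
        logger.info("no background pixels in mask; background component unset")
        return None
    conc = model.pixel_given_z[np.asarray(background_pixels, dtype=int)].sum(axis=0)
    return int(np.argmax(conc))


def assign_peaks(
    model: ComponentModel, exclude_background: bool = True
) -> tuple[np.ndarray, dict[int, int]]:
    """Associate each peak with the component maximizing P(peak|z).

    The per-peak loadings are normalized across the considered components
    (all components, or all but the background); the argmax is returned per
    peak together with per-component counts.  Exact ties resolve to the
    lowest component index and are logged.
    """
    comps = np.arange(model.n_components)
    if exclude_background and model.background is not None:
        comps = comps[comps != model.background]
    load = model.peak_given_z[:, comps]
    share = load / np.maximum(load.sum(axis=1, keepdims=True), _EPS)
    best = np.argmax(share, axis=1)
    n_tied = int(np.sum(np.sum(share == share.max(axis=1, keepdims=True), axis=1) > 1))
    if n_tied:
        logger.info("assign_peaks: %d exact ties resolved to lowest index", n_tied)
    labels = comps[best]
    counts = {int(z): int(np.sum(labels == z)) for z in comps}
    return labels, counts


def fit_pca(
    cube: DataCube, n_components: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Column-mean-centered PCA of the datacube.

    Returns (scores, loadings, explained_variance_ratio) with a
    deterministic sign convention: within each component the
    largest-magnitude loading is positive.
    """
    X = cube.values
    if X.shape[0] < 2:
        raise ValueError("PCA needs at least 2 pixels")
    rank = min(X.shape[0] - 1, X.shape[1])
    if n_components > rank:
        raise ValueError(f"n_components {n_components} exceeds rank bound {rank}")
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(X)
    loadings = pca.components_.T                      # (n_peaks, k)
    for j in range(loadings.shape[1]):
        i = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[i, j] < 0:
            loadings[:, j] = -loadings[:, j]
            scores[:, j] = -scores[:, j]
    return scores, loadings, pca.explained_variance_ratio_


def segment_pixels(model: ComponentModel) -> np.ndarray:
    """Per-pixel argmax component as a label image on the dataset grid.

    Off-dataset grid cells are -1; ties resolve to the lowest component
    index.  The background component, when identified, keeps its own label.
    """
    scores = model.pixel_scores()
    labels = np.argmax(scores, axis=1)
    nrows = int(model.coordinates[:, 1].max()) + 1
    ncols = int(model.coordinates[:, 0].max()) + 1
    img = np.full((nrows, ncols), -1, dtype=int)
    img[model.coordinates[:, 1], model.coordinates[:, 0]] = labels
    return img


def match_labels(
    predicted: np.ndarray, truth: np.ndarray
) -> tuple[float, dict[int, int]]:
    """Best-permutation agreement between two label vectors.

    Hungarian assignment on the confusion matrix maps predicted labels to
    truth labels; returns (accuracy, mapping).
    """
    predicted = np.asarray(predicted).ravel()
    truth = np.asarray(truth).ravel()
    if predicted.shape != truth.shape:
        raise ValueError("label vectors must have identical shape")
    pred_ids = np.unique(predicted)
    true_ids = np.unique(truth)
    conf = np.zeros((len(pred_ids), len(true_ids)))
    for i, p in enumerate(pred_ids):
        for j, t in enumerate(true_ids):
            conf[i, j] = np.sum((predicted == p) & (truth == t))
    rows, cols = linear_sum_assignment(-conf)
    mapping = {int(pred_ids[r]): int(true_ids[c]) for r, c in zip(rows, cols)}
    correct = conf[rows, cols].sum()
    return float(correct / len(truth)), mapping
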