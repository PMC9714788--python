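"""Differential statistics between groups and tissue compartments.

Group comparisons use the two-sided Mann-Whitney U test; comparisons across
more than two compartments use the Kruskal-Wallis H test followed by Dunn's
pairwise post hoc test with Benjamini-Hochberg adjustment.  Fold changes are
computed from per-section ROI mean intensities (robust to unequal section
sizes); hypothesis tests are run both pixel-wise (pooling pixels per group,
the primary readout) and on per-section means (pseudoreplication-safe
secondary readout).
"""

from __future__ import annotations

import itertools
import warnings
from math import comb

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .annotation import AnnotationRecord
from .io import ROIMask
from .preprocess import DataCube

__all__ = [
    "mann_whitney",
    "mann_whitney_matrix",
    "kruskal_dunn",
    "bh_adjust",
    "log2_fold_change",
    "volcano_classify",
    "compute_group_stats",
    "class_composition",
    "ora_enrichment",
    "compartment_compare",
    "CORTICAL_LABELS",
]

#: The cortical-bone ROI pools the mineralized shell and the osteoid seam.
CORTICAL_LABELS = ("mineralized_bone", "osteoid")

_EXACT_MAX_N = 16


def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """Rank-sum U of sample ``a`` with midrank ties."""
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    r_a = ranks[: len(a)].sum()
    return float(r_a - len(a) * (len(a) + 1) / 2.0)


def mann_whitney(a, b) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test; returns (U of first sample, p).

    For small samples (n_a + n_b <= 16) the p-value is exact, computed by
    enumerating all group labelings of the pooled values (midranks handle
    ties; the null U distribution is symmetric about n_a*n_b/2, so the
    two-sided p is the |U - mean| tail).  Larger samples use the normal
    approximation with tie and continuity corrections.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be nonempty")
    n_a, n_b = len(a), len(b)
    u_obs = _u_statistic(a, b)
    if n_a + n_b <= _EXACT_MAX_N:
        pooled = np.concatenate([a, b])
        ranks = sps.rankdata(pooled)
        mean_u = n_a * n_b / 2.0
        d_obs = abs(u_obs - mean_u)
        n_total = comb(n_a + n_b, n_a)
        n_extreme = 0
        offset = n_a * (n_a + 1) / 2.0
        for combo in itertools.combinations(range(n_a + n_b), n_a):
            u = ranks[list(combo)].sum() - offset
            if abs(u - mean_u) >= d_obs - 1e-12:
                n_extreme += 1
        return u_obs, n_extreme / n_total
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return float(res.statistic), float(res.pvalue)


def mann_whitney_matrix(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Column-wise two-sided Mann-Whitney test of two (n_obs, n_peaks)
    matrices using the tie- and continuity-corrected normal approximation."""
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic", axis=0)
    return np.asarray(res.statistic, dtype=float), np.asarray(res.pvalue, dtype=float)


def kruskal_dunn(groups: list[np.ndarray]) -> tuple[float, float, pd.DataFrame]:
    """Kruskal-Wallis H test plus Dunn's pairwise post hoc comparisons.

    Returns (H, global chi-square p, pairwise table).  Dunn z-statistics are
    computed on the pooled midranks with the tie correction
    ``T = sum(t^3 - t) / (12 (N-1))``; pairwise two-sided normal p-values are
    Benjamini-Hochberg adjusted across all pairs.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 3:
        raise ValueError("kruskal_dunn needs >= 3 groups; use mann_whitney for 2")
    if any(len(g) == 0 for g in groups):
        raise ValueError("all groups must be nonempty")
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):  # degenerate: every observation tied
        h_stat, p_global = 0.0, 1.0
    else:
        h_stat, p_global = sps.kruskal(*groups)
    n_total = len(pooled)
    ranks = sps.rankdata(pooled)
    sizes = [len(g) for g in groups]
    bounds = np.cumsum([0] + sizes)
    mean_ranks = [
        ranks[bounds[i]:bounds[i + 1]].mean() for i in range(len(groups))
    ]
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts)) / (12.0 * (n_total - 1))
    var_base = n_total * (n_total + 1) / 12.0 - tie_term
    rows = []
    for i, j in itertools.combinations(range(len(groups)), 2):
        se = np.sqrt(var_base * (1.0 / sizes[i] + 1.0 / sizes[j]))
        z = (mean_ranks[i] - mean_ranks[j]) / se if se > 0 else 0.0
        p = 2.0 * sps.norm.sf(abs(z))
        rows.append({"group_i": i, "group_j": j, "z": z, "p": p})
    table = pd.DataFrame(rows)
    table["p_adj"] = bh_adjust(table["p"].values)
    return float(h_stat), float(p_global), table


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, original order preserved."""
    pvals = np.asarray(pvals, dtype=float)
    if pvals.size == 0:
        return pvals.copy()
    if np.any((pvals < 0) | (pvals > 1)) or np.any(np.isnan(pvals)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(pvals, method="fdr_bh")[1]


def log2_fold_change(
    means_a: np.ndarray, means_b: np.ndarray
) -> np.ndarray:
    """log2 of (mean over group-B sections / mean over group-A sections).

    Inputs are (n_sections, n_peaks) matrices of per-section ROI mean
    intensities; group A is the reference.  Peaks with a zero reference mean
    come back NaN with a warning.
    """
    means_a = np.atleast_2d(np.asarray(means_a, dtype=float))
    means_b = np.atleast_2d(np.asarray(means_b, dtype=float))
    ref = means_a.mean(axis=0)
    num = means_b.mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        fc = np.log2(num / ref)
    bad = ~np.isfinite(fc)
    if np.any(bad):
        warnings.warn(f"log2_fold_change undefined for {int(bad.sum())} peaks")
        fc = np.where(bad, np.nan, fc)
    return fc


def volcano_classify(
    stat_table: pd.DataFrame, fc_cut: float = 1.0, alpha: float = 0.05
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Label each peak up/down/ns from fold change and p-value.

    ``up`` requires log2FC >= fc_cut and p < alpha; ``down`` requires
    log2FC <= -fc_cut and p < alpha.  Returns the table with a ``direction``
    column plus summary counts.
    """
    table = stat_table.copy()
    fc = table["log2fc"].values
    p = table["p"].values
    direction = np.full(len(table), "ns", dtype=object)
    with np.errstate(invalid="ignore"):
        direction[(fc >= fc_cut) & (p < alpha)] = "up"
        direction[(fc <= -fc_cut) & (p < alpha)] = "down"
    table["direction"] = direction
    counts = {
        "up": int(np.sum(direction == "up")),
        "down": int(np.sum(direction == "down")),
        "ns": int(np.sum(direction == "ns")),
        "changed": int(np.sum(direction != "ns")),
    }
    return table, counts


def compute_group_stats(
    sections: list[tuple[DataCube, ROIMask]],
    group_a: str,
    group_b: str,
    roi_labels: tuple[str, ...] = CORTICAL_LABELS,
    fc_cut: float = 1.0,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Per-peak differential statistics between two groups of sections.

    For each section the ROI (default: cortical bone = mineralized +
    osteoid) pixels are selected from the mask.  log2 fold changes come from
    per-section ROI means (group B over group A); the primary p-value pools
    ROI pixels per group (pixel-wise Mann-Whitney), with a per-section-mean
    test reported alongside as ``p_section``.
    """
    pixels: dict[str, list[np.ndarray]] = {group_a: [], group_b: []}
    sec_means: dict[str, list[np.ndarray]] = {group_a: [], group_b: []}
    peak_centers = None
    for cube, mask in sections:
        if mask.group not in pixels:
            raise ValueError(
                f"section group {mask.group!r} not in ({group_a!r}, {group_b!r})"
            )
        idx = _mask_indices(cube, mask, roi_labels)
        if len(idx) == 0:
            raise ValueError(f"section {mask.section_id}: empty ROI")
        vals = cube.values[idx]
        pixels[mask.group].append(vals)
        sec_means[mask.group].append(vals.mean(axis=0))
        if peak_centers is None:
            peak_centers = cube.peak_centers
        elif not np.array_equal(peak_centers, cube.peak_centers):
            raise ValueError("sections have inconsistent peak lists")
    if not pixels[group_a] or not pixels[group_b]:
        raise ValueError("both groups need at least one section")

    a_pix = np.vstack(pixels[group_a])
    b_pix = np.vstack(pixels[group_b])
    a_means = np.vstack(sec_means[group_a])
    b_means = np.vstack(sec_means[group_b])

    u_stat, p_pixel = mann_whitney_matrix(a_pix, b_pix)
    fc = log2_fold_change(a_means, b_means)
    if len(a_means) >= 2 and len(b_means) >= 2:
        p_section = np.array([
            mann_whitney(a_means[:, k], b_means[:, k])[1]
            for k in range(a_means.shape[1])
        ])
    else:
        p_section = np.full(a_means.shape[1], np.nan)

    table = pd.DataFrame(
        {
            "peak_mz": peak_centers,
            "log2fc": fc,
            "U": u_stat,
            "p": p_pixel,
            "p_adj": bh_adjust(np.nan_to_num(p_pixel, nan=1.0)),
            "p_section": p_section,
        }
    )
    return volcano_classify(table, fc_cut=fc_cut, alpha=alpha)


def _mask_indices(cube: DataCube, mask: ROIMask, labels) -> np.ndarray:
    if isinstance(labels, str):
        labels = [labels]
    wanted = {mask.index_of(lb) for lb in labels}
    xs, ys = cube.coordinates[:, 0], cube.coordinates[:, 1]
    vals = mask.labels[ys, xs]
    return np.flatnonzero(np.isin(vals, list(wanted)))


def class_composition(
    annotations: list[AnnotationRecord],
    stat_table: pd.DataFrame,
) -> pd.DataFrame:
    """Chemical-class percentages among up- and downregulated annotated peaks.

    Each peak contributes its top-ranked annotation (smallest |ppm|); output
    percentages sum to 100 per direction.
    """
    best: dict[float, AnnotationRecord] = {}
    for a in sorted(annotations, key=lambda r: (r.peak_mz, abs(r.ppm), r.record_id)):
        best.setdefault(a.peak_mz, a)
    rows = []
    for direction in ("up", "down"):
        sub = stat_table[stat_table["direction"] == direction]
        classes = [
            best[mz].chem_class for mz in sub["peak_mz"] if mz in best
        ]
        total = len(classes)
        if total == 0:
            continue
        for cls in sorted(set(classes)):
            rows.append(
                {
                    "direction": direction,
                    "class": cls,
                    "n": classes.count(cls),
                    "percent": 100.0 * classes.count(cls) / total,
                }
            )
    return pd.DataFrame(rows, columns=["direction", "class", "n", "percent"])


def ora_enrichment(
    hit_ids: set[str],
    pathway_sets: dict[str, set[str]],
    background_ids: set[str],
) -> pd.DataFrame:
    """Hypergeometric over-representation of pathways among hit metabolites.

    The enrichment ratio is observed/expected hits:
    ``hits_in_pathway / (pathway_size * |hits| / |background|)``; the
    p-value is the upper-tail hypergeometric probability of at least the
    observed overlap.  Pathways and hits are intersected with the background.
    """
    if not background_ids:
        raise ValueError("empty background")
    hits = set(hit_ids) & set(background_ids)
    m_total = len(background_ids)
    n_hits = len(hits)
    rows = []
    for pathway, members in sorted(pathway_sets.items()):
        members = set(members) & set(background_ids)
        size = len(members)
        if size == 0:
            continue
        k = len(hits & members)
        expected = size * n_hits / m_total
        ratio = k / expected if expected > 0 else 0.0
        p = float(sps.hypergeom.sf(k - 1, m_total, size, n_hits)) if n_hits else 1.0
        rows.append(
            {
                "pathway": pathway,
                "hits": k,
                "size": size,
                "ratio": ratio,
                "p": p,
            }
        )
    df = pd.DataFrame(rows, columns=["pathway", "hits", "size", "ratio", "p"])
    if len(df):
        df["p_adj"] = bh_adjust(df["p"].values)
    else:
        df["p_adj"] = []
    return df


def compartment_compare(
    sections: list[tuple[DataCube, ROIMask]],
    peak_index: int,
    labels: tuple[str, ...] = ("mineralized_bone", "osteoid", "bone_marrow"),
) -> dict:
    """Pixel-intensity comparison of one peak across tissue compartments.

    Returns per-section, per-compartment summaries (median, min, max, n) and
    a test across compartments on pooled pixels: Mann-Whitney for two
    labels, Kruskal-Wallis plus Dunn/BH for more.  Compartments absent from
    a section are omitted with a warning.
    """
    if len(labels) < 2:
        raise ValueError("need at least two compartment labels")
    summaries = []
    pooled: dict[str, list[np.ndarray]] = {lb: [] for lb in labels}
    for cube, mask in sections:
        for lb in labels:
            idx = _mask_indices(cube, mask, lb)
            if len(idx) == 0:
                warnings.warn(
                    f"section {mask.section_id}: no pixels labeled {lb!r}; omitted"
                )
                continue
            vals = cube.values[idx, peak_index]
            pooled[lb].append(vals)
            summaries.append(
                {
                    "section": mask.section_id,
                    "group": mask.group,
                    "label": lb,
                    "n": len(vals),
                    "median": float(np.median(vals)),
                    "min": float(vals.min()),
                    "max": float(vals.max()),
                }
            )
    present = [lb for lb in labels if pooled[lb]]
    if len(present) < 2:
        raise ValueError("fewer than two compartments have pixels")
    samples = [np.concatenate(pooled[lb]) for lb in present]
    result: dict = {"summaries": pd.DataFrame(summaries), "labels": present}
    if len(present) == 2:
        u, p = (
            mann_whitney(samples[0], samples[1])
            if len(samples[0]) + len(samples[1]) <= _EXACT_MAX_N
            else mann_whitney_matrix(samples[0][:, None], samples[1][:, None])
        )
        if isinstance(u, np.ndarray):
            u, p = float(u[0]), float(p[0])
        result.update(test="mann_whitney", U=u, p=p)
    else:
        h, p_global, pairs = kruskal_dunn(samples)
        pairs = pairs.assign(
            label_i=[present[i] for i in pairs["group_i"]],
            label_j=[present[j] for j in pairs["group_j"]],
        )
        result.update(test="kruskal_dunn", H=h, p=p_global, pairwise=pairs)
    return result
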