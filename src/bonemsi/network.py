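"""Spatial correlation metabolic networks.

Ion images of annotated peaks are correlated pixel-by-pixel within an ROI
mask using Spearman's rank correlation.  Candidate edges connect annotated
peaks whose metabolites share at least one pathway; nodes lacking any
correlation with p <= alpha are dropped.  Edge attributes carry rho, its
p-value, |rho| (the layout weight used by force-directed layouts), and the
shared pathway ids; node attributes carry the metabolite name, log2 fold
change, and a label flag for |log2FC| >= 1.  Layout itself is out of scope:
the graph is exported as GraphML for Cytoscape-style tools.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats as sps

from .annotation import AnnotationRecord
from .io import ROIMask
from .preprocess import DataCube

__all__ = ["spatial_spearman", "build_network", "export_graph"]


def spatial_spearman(
    img_i: np.ndarray, img_j: np.ndarray, mask: np.ndarray
) -> tuple[float, float]:
    """Spearman rank correlation of two ion images over masked pixels.

    ``mask`` is a boolean image; at least 3 masked pixels are required.
    Ties get midranks; the p-value uses the t-distribution approximation.
    Constant images have undefined rho and come back (nan, nan) with a
    warning.
    """
    mask = np.asarray(mask, dtype=bool)
    if img_i.shape != img_j.shape or img_i.shape != mask.shape:
        raise ValueError("images and mask must share one grid")
    x = np.asarray(img_i, dtype=float)[mask]
    y = np.asarray(img_j, dtype=float)[mask]
    if len(x) < 3:
        raise ValueError("need at least 3 masked pixels")
    if np.all(x == x[0]) or np.all(y == y[0]):
        warnings.warn("constant image: Spearman rho undefined")
        return float("nan"), float("nan")
    rho, p = sps.spearmanr(x, y)
    return float(rho), float(p)


def _node_table(
    annotations: list[AnnotationRecord], stat_table: pd.DataFrame
) -> pd.DataFrame:
    """Deduplicate annotations to one node per peak (best |ppm| first)."""
    fc_by_mz = dict(zip(stat_table["peak_mz"], stat_table["log2fc"]))
    rows: dict[float, dict] = {}
    for a in sorted(annotations, key=lambda r: (r.peak_mz, abs(r.ppm), r.record_id)):
        if a.peak_mz in rows:
            continue
        rows[a.peak_mz] = {
            "peak_mz": a.peak_mz,
            "id": a.record_id,
            "name": a.name,
            "pathways": frozenset(a.pathways),
            "log2fc": float(fc_by_mz.get(a.peak_mz, np.nan)),
        }
    return pd.DataFrame(sorted(rows.values(), key=lambda r: r["peak_mz"]))


def build_network(
    annotations: list[AnnotationRecord],
    stat_table: pd.DataFrame,
    cube: DataCube,
    mask: ROIMask | np.ndarray,
    roi_labels=("mineralized_bone", "osteoid"),
    alpha: float = 0.05,
    min_abs_rho: float = 0.0,
    label_fc_cut: float = 1.0,
) -> nx.Graph:
    """Build the spatial correlation network within an ROI.

    Candidate edges are pairs of annotated peaks sharing >= 1 pathway; each
    gets the Spearman rho of their ion images over the masked pixels.  Edges
    are kept regardless of rho magnitude (an optional ``min_abs_rho`` floor
    is available for dense pixel-wise data); a node survives only if it has
    at least one correlation with p <= ``alpha``.  Node labels flag
    |log2FC| >= ``label_fc_cut``.
    """
    if not annotations:
        raise ValueError("empty annotation set")
    nodes = _node_table(annotations, stat_table)
    if isinstance(mask, ROIMask):
        wanted = {mask.index_of(lb) for lb in roi_labels}
        bool_mask = np.isin(mask.labels, list(wanted))
    else:
        bool_mask = np.asarray(mask, dtype=bool)

    center_to_col = {c: k for k, c in enumerate(cube.peak_centers)}
    images = {
        row.peak_mz: cube.ion_image(center_to_col[row.peak_mz])
        for row in nodes.itertuples()
        if row.peak_mz in center_to_col
    }
    nodes = nodes[nodes["peak_mz"].isin(images)].reset_index(drop=True)

    edges = []
    significant: set[float] = set()
    recs = list(nodes.itertuples())
    for i in range(len(recs)):
        for j in range(i + 1, len(recs)):
            shared = recs[i].pathways & recs[j].pathways
            if not shared:
                continue
            rho, p = spatial_spearman(
                images[recs[i].peak_mz], images[recs[j].peak_mz], bool_mask
            )
            if not np.isfinite(rho) or abs(rho) < min_abs_rho:
                continue
            edges.append((recs[i].peak_mz, recs[j].peak_mz, rho, p, shared))
            if p <= alpha:
                significant.add(recs[i].peak_mz)
                significant.add(recs[j].peak_mz)

    graph = nx.Graph()
    for row in recs:
        if row.peak_mz not in significant:
            continue
        graph.add_node(
            round(float(row.peak_mz), 6),
            peak_mz=float(row.peak_mz),
            id=row.id,
            name=row.name,
            log2fc=float(row.log2fc),
            labeled=bool(
                np.isfinite(row.log2fc) and abs(row.log2fc) >= label_fc_cut
            ),
            pathways=";".join(sorted(row.pathways)),
        )
    for mz_i, mz_j, rho, p, shared in edges:
        if mz_i in significant and mz_j in significant:
            graph.add_edge(
                round(float(mz_i), 6),
                round(float(mz_j), 6),
                rho=float(rho),
                p=float(p),
                abs_rho=float(abs(rho)),
                shared_pathways=";".join(sorted(shared)),
            )
    return graph


def export_graph(net: nx.Graph, path: str | Path) -> None:
    """Write the network as GraphML (typed node/edge attributes).

    Float attributes survive a round-trip through a generic GraphML reader
    bit-exactly (networkx stores doubles with full repr precision).
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    nx.write_graphml(net, path)


def network_tables(net: nx.Graph) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Node and edge attribute tables for spreadsheet inspection."""
    node_rows = [dict(node=n, **d) for n, d in sorted(net.nodes(data=True))]
    edge_rows = [
        dict(source=u, target=v, **d) for u, v, d in sorted(net.edges(data=True))
    ]
    return pd.DataFrame(node_rows), pd.DataFrame(edge_rows)
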