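"""Spatial Spearman correlations and shared-pathway networks."""

import numpy as np
import networkx as nx
import pandas as pd
import pytest
from scipy import stats as sps

from bonemsi.annotation import AnnotationRecord
from bonemsi.network import (
    build_network,
    export_graph,
    network_tables,
    spatial_spearman,
)
from bonemsi.preprocess import DataCube


def _images(vals_i, vals_j):
    img_i = np.asarray(vals_i, dtype=float).reshape(1, -1)
    img_j = np.asarray(vals_j, dtype=float).reshape(1, -1)
    mask = np.ones_like(img_i, dtype=bool)
    return img_i, img_j, mask


class TestSpatialSpearman:
    def test_self_correlation_is_one(self):
        rng = np.random.default_rng(0)
        img = rng.uniform(0, 10, (5, 5))
        rho, p = spatial_spearman(img, img, np.ones((5, 5), bool))
        assert rho == pytest.approx(1.0)

    def test_rank_invariance_under_monotone_transform(self):
        rng = np.random.default_rng(1)
        img = rng.uniform(0.1, 10, (6, 6))
        mask = np.ones((6, 6), bool)
        for transform in (np.exp, np.sqrt, lambda x: x**3 + 2):
            rho, _ = spatial_spearman(img, transform(img), mask)
            assert rho == pytest.approx(1.0)

    def test_five_pixel_hand_example_vs_rank_pearson_oracle(self):
        x = [3.0, 1.0, 4.0, 1.5, 5.0]
        y = [2.0, 0.5, 2.5, 3.0, 4.0]
        img_i, img_j, mask = _images(x, y)
        rho, p = spatial_spearman(img_i, img_j, mask)
        # oracle: rank both vectors, then Pearson on the ranks
        rx, ry = sps.rankdata(x), sps.rankdata(y)
        rho_oracle = np.corrcoef(rx, ry)[0, 1]
        assert rho == pytest.approx(rho_oracle, abs=1e-12)

    def test_matches_rank_pearson_on_random_masked_images(self):
        rng = np.random.default_rng(2)
        for _ in range(100):
            img_i = rng.uniform(0, 5, (8, 8))
            img_j = rng.uniform(0, 5, (8, 8))
            if rng.random() < 0.5:  # induce ties
                img_i = np.round(img_i)
            mask = rng.random((8, 8)) < 0.6
            if mask.sum() < 3:
                mask[:2, :2] = True
            rho, _ = spatial_spearman(img_i, img_j, mask)
            rx = sps.rankdata(img_i[mask])
            ry = sps.rankdata(img_j[mask])
            assert rho == pytest.approx(np.corrcoef(rx, ry)[0, 1], abs=1e-12)

    def test_constant_image_flagged_nan(self):
        img = np.ones((3, 3))
        other = np.arange(9.0).reshape(3, 3)
        with pytest.warns(UserWarning, match="constant"):
            rho, p = spatial_spearman(img, other, np.ones((3, 3), bool))
        assert np.isnan(rho) and np.isnan(p)

    def test_too_few_pixels_rejected(self):
        img = np.arange(4.0).reshape(2, 2)
        mask = np.zeros((2, 2), bool)
        mask[0, 0] = mask[0, 1] = True
        with pytest.raises(ValueError, match="3"):
            spatial_spearman(img, img, mask)


def _anno(mz, rid, pathways):
    return AnnotationRecord(
        peak_mz=mz, record_id=rid, name=rid.upper(), adduct="M-H",
        theoretical_mz=mz, ppm=0.0, pathways=frozenset(pathways),
        chem_class="x", source="metabolite",
    )


def _toy_cube(columns):
    """columns: dict mz -> 1-D pixel intensity vector (all same length)."""
    mzs = sorted(columns)
    vals = np.column_stack([columns[mz] for mz in mzs])
    n = vals.shape[0]
    coords = np.column_stack([np.arange(n), np.zeros(n, int)])
    return DataCube(vals, coords, np.array(mzs, dtype=float))


def _toy_stat_table(mzs, fcs):
    return pd.DataFrame({"peak_mz": mzs, "log2fc": fcs})


class TestBuildNetwork:
    def _mask_for(self, cube):
        return np.ones(cube.grid_shape, dtype=bool)

    def test_no_shared_pathway_no_edges_no_nodes(self):
        rng = np.random.default_rng(3)
        cube = _toy_cube({100.0: rng.uniform(0, 1, 20), 200.0: rng.uniform(0, 1, 20)})
        annos = [_anno(100.0, "a", {"pw1"}), _anno(200.0, "b", {"pw2"})]
        net = build_network(
            annos, _toy_stat_table([100.0, 200.0], [0.0, 0.0]),
            cube, self._mask_for(cube),
        )
        assert net.number_of_nodes() == 0
        assert net.number_of_edges() == 0

    def test_shared_pathway_with_significant_correlation(self):
        rng = np.random.default_rng(4)
        base = rng.uniform(0, 1, 30)
        cube = _toy_cube({
            100.0: base,
            200.0: base * 2 + rng.normal(0, 0.01, 30).clip(-0.001, 0.001) + 1,
            300.0: rng.uniform(0, 1, 30),
        })
        annos = [
            _anno(100.0, "a", {"pw1"}),
            _anno(200.0, "b", {"pw1"}),
            _anno(300.0, "c", {"pw2"}),
        ]
        net = build_network(
            annos, _toy_stat_table([100.0, 200.0, 300.0], [1.5, -0.2, 0.0]),
            cube, self._mask_for(cube),
        )
        assert net.number_of_nodes() == 2
        assert net.number_of_edges() == 1
        (u, v, attrs), = net.edges(data=True)
        assert attrs["rho"] == pytest.approx(1.0, abs=0.05)
        assert attrs["abs_rho"] == abs(attrs["rho"])
        assert attrs["shared_pathways"] == "pw1"
        assert net.nodes[100.0]["labeled"] is True   # |log2FC| >= 1
        assert net.nodes[200.0]["labeled"] is False

    def test_every_node_has_a_significant_edge(self, small_phantom, db):
        from bonemsi.annotation import annotate_peaks, filter_exogenous
        from bonemsi.stats import compute_group_stats

        chain = small_phantom
        table, _ = compute_group_stats(
            list(zip(chain.cubes, chain.truth.masks)), "WT", "Hyp"
        )
        annos = filter_exogenous(annotate_peaks(chain.peaks, db))
        net = build_network(
            annos, table, chain.cubes[0], chain.truth.masks[0], alpha=0.05
        )
        assert net.number_of_nodes() > 0
        for node in net.nodes:
            assert any(
                net.edges[node, nb]["p"] <= 0.05 for nb in net.neighbors(node)
            )
        # every edge connects metabolites sharing >= 1 pathway
        for _, _, attrs in net.edges(data=True):
            assert attrs["shared_pathways"]

    def test_invariant_under_annotation_order(self, small_phantom, db):
        from bonemsi.annotation import annotate_peaks, filter_exogenous
        from bonemsi.stats import compute_group_stats

        chain = small_phantom
        table, _ = compute_group_stats(
            list(zip(chain.cubes, chain.truth.masks)), "WT", "Hyp"
        )
        annos = filter_exogenous(annotate_peaks(chain.peaks, db))
        net_a = build_network(annos, table, chain.cubes[0], chain.truth.masks[0])
        net_b = build_network(
            list(reversed(annos)), table, chain.cubes[0], chain.truth.masks[0]
        )
        assert set(net_a.nodes) == set(net_b.nodes)
        assert set(map(frozenset, net_a.edges)) == set(map(frozenset, net_b.edges))

    def test_raising_alpha_never_removes_nodes(self, small_phantom, db):
        from bonemsi.annotation import annotate_peaks, filter_exogenous
        from bonemsi.stats import compute_group_stats

        chain = small_phantom
        table, _ = compute_group_stats(
            list(zip(chain.cubes, chain.truth.masks)), "WT", "Hyp"
        )
        annos = filter_exogenous(annotate_peaks(chain.peaks, db))
        previous: set = set()
        for alpha in (0.001, 0.01, 0.05, 0.2):
            net = build_network(
                annos, table, chain.cubes[0], chain.truth.masks[0], alpha=alpha
            )
            assert previous <= set(net.nodes)
            previous = set(net.nodes)

    def test_co_compartment_pairs_correlate_stronger(self, small_phantom, db):
        """Peaks homed in the same compartment colocalize spatially."""
        from bonemsi.network import spatial_spearman

        chain = small_phantom
        cube = chain.cubes[0]
        mask = chain.truth.masks[0]
        home = chain.truth.home_compartments()[chain.peak_to_truth()]
        tissue_mask = mask.labels > 0
        rng = np.random.default_rng(5)
        same, cross = [], []
        idx_by_home = {h: np.flatnonzero(home == h) for h in (0, 1, 2)}
        for h in (0, 1, 2):
            cols = idx_by_home[h]
            for _ in range(10):
                i, j = rng.choice(cols, 2, replace=False)
                rho, _ = spatial_spearman(
                    cube.ion_image(i), cube.ion_image(j), tissue_mask
                )
                same.append(rho)
            other = np.concatenate([idx_by_home[k] for k in (0, 1, 2) if k != h])
            for _ in range(10):
                i = rng.choice(cols)
                j = rng.choice(other)
                rho, _ = spatial_spearman(
                    cube.ion_image(i), cube.ion_image(j), tissue_mask
                )
                cross.append(rho)
        assert np.mean(same) > np.mean(cross)

    def test_empty_annotations_rejected(self, small_phantom):
        with pytest.raises(ValueError, match="empty"):
            build_network(
                [], _toy_stat_table([], []), small_phantom.cubes[0],
                small_phantom.truth.masks[0],
            )


class TestExportGraph:
    def test_empty_network_valid_graphml(self, tmp_path):
        path = tmp_path / "empty.graphml"
        export_graph(nx.Graph(), path)
        back = nx.read_graphml(path)
        assert back.number_of_nodes() == 0

    def test_attribute_round_trip_bit_exact(self, tmp_path):
        net = nx.Graph()
        rho, p = -0.7234567891234567, 0.012345678901234567
        net.add_node("a", name="A", log2fc=1.2345678901, labeled=True,
                     pathways="pw1;pw2")
        net.add_node("b", name="B", log2fc=-0.5, labeled=False, pathways="pw1")
        net.add_edge("a", "b", rho=rho, p=p, abs_rho=abs(rho),
                     shared_pathways="pw1")
        path = tmp_path / "net.graphml"
        export_graph(net, path)
        back = nx.read_graphml(path)
        assert back.edges["a", "b"]["rho"] == rho          # bit-exact float
        assert back.edges["a", "b"]["p"] == p
        assert back.nodes["a"]["log2fc"] == 1.2345678901
        assert back.nodes["a"]["labeled"] is True
        assert back.nodes["a"]["pathways"] == "pw1;pw2"

    def test_network_tables_shapes(self, small_phantom, db):
        from bonemsi.annotation import annotate_peaks, filter_exogenous
        from bonemsi.stats import compute_group_stats

        chain = small_phantom
        table, _ = compute_group_stats(
            list(zip(chain.cubes, chain.truth.masks)), "WT", "Hyp"
        )
        annos = filter_exogenous(annotate_peaks(chain.peaks, db))
        net = build_network(annos, table, chain.cubes[0], chain.truth.masks[0])
        nodes, edges = network_tables(net)
        assert len(nodes) == net.number_of_nodes()
        assert len(edges) == net.number_of_edges()
        if len(edges):
            assert {"rho", "p", "abs_rho", "shared_pathways"} <= set(edges.columns)
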