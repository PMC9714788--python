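"""Nonparametric ROI statistics: Mann-Whitney, Kruskal-Wallis/Dunn, BH,
fold changes, volcano classification, class composition, enrichment."""

import itertools
from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from bonemsi.annotation import AnnotationRecord
from bonemsi.io import ROIMask
from bonemsi.preprocess import DataCube
from bonemsi.stats import (
    bh_adjust,
    class_composition,
    compartment_compare,
    compute_group_stats,
    kruskal_dunn,
    log2_fold_change,
    mann_whitney,
    ora_enrichment,
    volcano_classify,
)


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def brute_force_mw_p(a, b):
    """Two-sided exact Mann-Whitney p by enumerating every labeling; U is
    computed from pairwise comparisons (not ranks) for independence."""
    pooled = np.concatenate([a, b])
    n_a = len(a)

    def u_of(idx_a):
        idx_a = set(idx_a)
        idx_b = [i for i in range(len(pooled)) if i not in idx_a]
        u = 0.0
        for i in idx_a:
            for j in idx_b:
                if pooled[i] > pooled[j]:
                    u += 1.0
                elif pooled[i] == pooled[j]:
                    u += 0.5
        return u

    mean_u = n_a * len(b) / 2.0
    d_obs = abs(u_of(range(n_a)) - mean_u)
    n_extreme = sum(
        abs(u_of(combo) - mean_u) >= d_obs - 1e-12
        for combo in itertools.combinations(range(len(pooled)), n_a)
    )
    return n_extreme / comb(len(pooled), n_a)


def manual_bh(pvals):
    """Textbook step-up: sort ascending, p*(m/rank), cumulative min from the
    largest rank, cap at 1, restore input order."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    adj = np.empty(m)
    running = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        running = min(running, p[i] * m / rank_from_top)
        adj[i] = running
    return adj


def textbook_dunn_z(groups, i, j):
    pooled = np.concatenate(groups)
    n = len(pooled)
    ranks = sps.rankdata(pooled)
    bounds = np.cumsum([0] + [len(g) for g in groups])
    r_i = ranks[bounds[i]:bounds[i + 1]].mean()
    r_j = ranks[bounds[j]:bounds[j + 1]].mean()
    _, counts = np.unique(pooled, return_counts=True)
    tie = np.sum(counts**3 - counts) / (12.0 * (n - 1))
    se = np.sqrt(
        (n * (n + 1) / 12.0 - tie) * (1 / len(groups[i]) + 1 / len(groups[j]))
    )
    return (r_i - r_j) / se


# ---------------------------------------------------------------------------

class TestMannWhitney:
    def test_identical_multisets_give_central_u_and_p_one(self):
        a = [1.0, 2.0, 2.0, 5.0]
        u, p = mann_whitney(a, a)
        assert u == len(a) ** 2 / 2.0
        assert p == 1.0

    def test_complete_separation_small_samples(self):
        u, p = mann_whitney([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        # 2 of the C(6,3)=20 labelings are at least this extreme
        assert p == pytest.approx(0.1)

    def test_agrees_with_enumeration_oracle_on_random_cases(self):
        rng = np.random.default_rng(12)
        for _ in range(30):
            n_a = int(rng.integers(2, 7))
            n_b = int(rng.integers(2, 7))
            a = np.round(rng.normal(0, 1, n_a), 1)  # rounding induces ties
            b = np.round(rng.normal(0.5, 1, n_b), 1)
            _, p = mann_whitney(a, b)
            assert p == pytest.approx(brute_force_mw_p(a, b), abs=1e-12)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])

    def test_large_samples_use_normal_approximation(self):
        rng = np.random.default_rng(13)
        a = rng.normal(0, 1, 100)
        b = rng.normal(1, 1, 100)
        u, p = mann_whitney(a, b)
        ref = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        assert u == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue)


class TestKruskalDunn:
    def test_worked_triple_h_statistic(self):
        # 12/(N(N+1)) * sum(R^2/n) - 3(N+1) with N=9 and rank sums 6, 15, 24
        h, p, _ = kruskal_dunn([np.array([1, 2, 3]), np.array([4, 5, 6]),
                                np.array([7, 8, 9])])
        assert h == pytest.approx(7.2)
        assert p == pytest.approx(float(sps.chi2.sf(7.2, df=2)))

    def test_identical_groups_h_zero_p_one(self):
        g = np.array([3.0, 3.0, 3.0])
        h, p, pairs = kruskal_dunn([g, g, g])
        assert h == pytest.approx(0.0)
        assert np.allclose(pairs["p"], 1.0)
        assert np.allclose(pairs["p_adj"], 1.0)

    def test_dunn_z_matches_textbook_formula(self):
        rng = np.random.default_rng(21)
        groups = [
            np.round(rng.normal(loc, 1, size), 1)
            for loc, size in [(0, 6), (0.8, 5), (2.0, 7), (0.2, 4)]
        ]
        _, _, pairs = kruskal_dunn(groups)
        for row in pairs.itertuples():
            z_ref = textbook_dunn_z(groups, row.group_i, row.group_j)
            assert row.z == pytest.approx(z_ref, abs=1e-10)
            assert row.p == pytest.approx(2 * sps.norm.sf(abs(z_ref)), abs=1e-10)

    def test_pairwise_p_are_bh_adjusted(self):
        rng = np.random.default_rng(22)
        groups = [rng.normal(i, 1, 8) for i in range(4)]
        _, _, pairs = kruskal_dunn(groups)
        np.testing.assert_allclose(
            pairs["p_adj"].values, manual_bh(pairs["p"].values)
        )

    def test_two_groups_redirected(self):
        with pytest.raises(ValueError, match="mann_whitney"):
            kruskal_dunn([np.array([1.0]), np.array([2.0])])


class TestBhAdjust:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.03])[0] == pytest.approx(0.03)

    def test_worked_example(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.04, 0.03, 0.002]), [0.02, 0.04, 0.04, 0.008]
        )

    def test_all_equal_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.2] * 5), [0.2] * 5)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])

    @settings(max_examples=50, derandomize=True)
    @given(
        st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=40)
    )
    def test_matches_manual_step_up_and_dominates_raw(self, pvals):
        adj = bh_adjust(pvals)
        np.testing.assert_allclose(adj, manual_bh(pvals), atol=1e-12)
        assert np.all(adj >= np.asarray(pvals) - 1e-12)
        assert np.all(adj <= 1.0 + 1e-12)
        order = np.argsort(pvals, kind="mergesort")
        assert np.all(np.diff(adj[order]) >= -1e-12)


class TestFoldChange:
    def test_equal_means_zero(self):
        a = np.ones((3, 4))
        assert np.allclose(log2_fold_change(a, a), 0.0)

    def test_doubling_gives_one(self):
        a = np.full((2, 3), 5.0)
        assert np.allclose(log2_fold_change(a, 2 * a), 1.0)

    def test_zero_reference_flagged_nan(self):
        a = np.zeros((2, 1))
        with pytest.warns(UserWarning, match="undefined"):
            fc = log2_fold_change(a, np.ones((2, 1)))
        assert np.isnan(fc[0])

    def test_phantom_recovers_planted_effects(self, small_phantom):
        chain = small_phantom
        table, _ = compute_group_stats(
            list(zip(chain.cubes, chain.truth.masks)), "WT", "Hyp"
        )
        planted = chain.truth.effect_log2[chain.peak_to_truth()]
        err = np.abs(table["log2fc"].values - planted)
        assert np.nanmax(err) <= 0.3


class TestVolcano:
    @pytest.mark.parametrize(
        "fc, p, expected",
        [
            (0.5, 0.001, "ns"),    # below fold-change cutoff
            (1.2, 0.01, "up"),
            (-1.5, 0.001, "down"),
            (2.0, 0.2, "ns"),      # not significant
            (1.0, 0.049, "up"),    # boundary: cutoff is inclusive
        ],
    )
    def test_classification_rules(self, fc, p, expected):
        table = pd.DataFrame({"log2fc": [fc], "p": [p]})
        out, counts = volcano_classify(table)
        assert out["direction"].iloc[0] == expected

    def test_phantom_counts_and_zero_false_positives(self, small_phantom):
        chain = small_phantom
        table, counts = compute_group_stats(
            list(zip(chain.cubes, chain.truth.masks)), "WT", "Hyp"
        )
        planted = chain.truth.effect_log2[chain.peak_to_truth()]
        up_true = set(np.flatnonzero(planted > 0))
        down_true = set(np.flatnonzero(planted < 0))
        assert set(np.flatnonzero(table["direction"] == "up")) == up_true
        assert set(np.flatnonzero(table["direction"] == "down")) == down_true
        assert counts["up"] == chain.spec.n_up
        assert counts["down"] == chain.spec.n_down


def _anno(peak_mz, rid, chem_class, pathways=frozenset()):
    return AnnotationRecord(
        peak_mz=peak_mz, record_id=rid, name=rid, adduct="M-H",
        theoretical_mz=peak_mz, ppm=0.0, pathways=frozenset(pathways),
        chem_class=chem_class, source="metabolite",
    )


class TestClassComposition:
    def test_single_class_is_hundred_percent(self):
        table = pd.DataFrame(
            {"peak_mz": [100.0, 200.0], "direction": ["up", "up"]}
        )
        annos = [_anno(100.0, "a", "Carbohydrates"), _anno(200.0, "b", "Carbohydrates")]
        out = class_composition(annos, table)
        assert list(out["percent"]) == [100.0]

    def test_three_to_one_split(self):
        table = pd.DataFrame(
            {"peak_mz": [1.0, 2.0, 3.0, 4.0], "direction": ["down"] * 4}
        )
        annos = [
            _anno(1.0, "a", "Fatty acids"),
            _anno(2.0, "b", "Fatty acids"),
            _anno(3.0, "c", "Fatty acids"),
            _anno(4.0, "d", "Nucleotides"),
        ]
        out = class_composition(annos, table)
        pct = dict(zip(out["class"], out["percent"]))
        assert pct == {"Fatty acids": 75.0, "Nucleotides": 25.0}

    def test_percentages_sum_to_hundred_per_direction(self, small_phantom, db):
        from bonemsi.annotation import annotate_peaks, filter_exogenous

        chain = small_phantom
        table, _ = compute_group_stats(
            list(zip(chain.cubes, chain.truth.masks)), "WT", "Hyp"
        )
        annos = filter_exogenous(annotate_peaks(chain.peaks, db))
        out = class_composition(annos, table)
        for direction in out["direction"].unique():
            assert out.loc[out["direction"] == direction, "percent"].sum() == (
                pytest.approx(100.0, abs=1e-9)
            )


class TestOraEnrichment:
    def test_worked_ratio(self):
        background = {f"m{i}" for i in range(100)}
        pathway = {f"m{i}" for i in range(10)}
        hits = {f"m{i}" for i in range(5)} | {f"m{i}" for i in range(50, 65)}
        out = ora_enrichment(hits, {"pw": pathway}, background)
        row = out.iloc[0]
        assert row["hits"] == 5
        # 5 observed / (10 * 20/100 expected) = 2.5
        assert row["ratio"] == pytest.approx(2.5)

    def test_hits_equal_background_degenerate(self):
        background = {"a", "b", "c", "d"}
        out = ora_enrichment(
            background, {"pw1": {"a", "b"}, "pw2": {"c"}}, background
        )
        assert np.allclose(out["ratio"], 1.0)
        assert np.allclose(out["p"], 1.0)

    def test_p_matches_hypergeometric_sum_oracle(self):
        background = {f"m{i}" for i in range(12)}
        pathway = {f"m{i}" for i in range(5)}
        hits = {"m0", "m1", "m2", "m7"}
        out = ora_enrichment(hits, {"pw": pathway}, background)
        m_total, size, n_hits, k = 12, 5, 4, 3
        p_oracle = sum(
            comb(size, x) * comb(m_total - size, n_hits - x) / comb(m_total, n_hits)
            for x in range(k, min(size, n_hits) + 1)
        )
        assert out.iloc[0]["p"] == pytest.approx(p_oracle, abs=1e-12)

    def test_ratio_one_when_fractions_match(self):
        background = {f"m{i}" for i in range(20)}
        pathway = {f"m{i}" for i in range(10)}     # half the background
        hits = {"m0", "m15"}                        # one hit inside, one outside
        out = ora_enrichment(hits, {"pw": pathway}, background)
        assert out.iloc[0]["ratio"] == pytest.approx(1.0)

    def test_empty_background_rejected(self):
        with pytest.raises(ValueError):
            ora_enrichment(set(), {"pw": {"a"}}, set())


class TestCompartmentCompare:
    def _toy_sections(self, values_by_label):
        # one 1x6 section: three compartments of two pixels each
        labels = np.array([[1, 1, 2, 2, 3, 3]])
        vals = np.array(
            [values_by_label[1] + values_by_label[2] + values_by_label[3]]
        ).reshape(6, 1)
        coords = np.column_stack([np.arange(6), np.zeros(6, int)])
        cube = DataCube(vals, coords, np.array([100.0]))
        mask = ROIMask(labels, group="WT", section_id="s1")
        return [(cube, mask)]

    def test_identical_compartments_p_one(self):
        sections = self._toy_sections({1: [5.0, 6.0], 2: [5.0, 6.0], 3: [5.0, 6.0]})
        res = compartment_compare(
            sections, 0, labels=("mineralized_bone", "osteoid")
        )
        assert res["test"] == "mann_whitney"
        assert res["p"] == 1.0

    def test_one_pixel_compartment_defined(self):
        sections = self._toy_sections({1: [5.0, 6.0], 2: [7.0, 7.0], 3: [1.0, 2.0]})
        labels = sections[0][1].labels
        labels[0, 1] = 0  # shrink mineralized bone to one pixel
        res = compartment_compare(
            sections, 0, labels=("mineralized_bone", "osteoid", "bone_marrow")
        )
        summ = res["summaries"]
        row = summ[summ["label"] == "mineralized_bone"].iloc[0]
        assert row["n"] == 1
        assert row["median"] == row["min"] == row["max"] == 5.0
        assert res["test"] == "kruskal_dunn"

    def test_absent_label_warns_and_omits(self):
        sections = self._toy_sections({1: [5.0, 6.0], 2: [7.0, 8.0], 3: [1.0, 2.0]})
        labels = sections[0][1].labels
        labels[labels == 3] = 0
        with pytest.warns(UserWarning, match="no pixels"):
            res = compartment_compare(
                sections, 0,
                labels=("mineralized_bone", "osteoid", "bone_marrow"),
            )
        assert res["labels"] == ["mineralized_bone", "osteoid"]

    def test_phantom_ppi_enriched_in_osteoid(self, small_phantom):
        """The pyrophosphate-like peak is osteoid-specific (planted)."""
        chain = small_phantom
        table = chain.truth.peak_table
        ppi_mz = table.loc[table["id"] == "ppi", "mz"].values[0]
        k = int(np.argmin(np.abs(chain.peaks.centers - ppi_mz)))
        res = compartment_compare(
            list(zip(chain.cubes, chain.truth.masks)), k,
            labels=("mineralized_bone", "osteoid"),
        )
        assert res["p"] < 0.01
        summ = res["summaries"]
        med_ost = summ[summ["label"] == "osteoid"]["median"].median()
        med_min = summ[summ["label"] == "mineralized_bone"]["median"].median()
        assert med_ost > med_min
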