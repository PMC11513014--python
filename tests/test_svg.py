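import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from spadom import (
    MGLParams,
    build_knn_graph,
    build_neighborhood,
    calibrate_radius,
    coarse_grained_screen,
    constraint_screen,
    detect_svgs,
    fine_grained_screen,
    morans_i,
)


def _grid(rows, cols):
    r, c = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    return np.column_stack([c.ravel().astype(float), r.ravel().astype(float)])


@pytest.fixture()
def halves():
    """20x20 unit grid split into left/right domains."""
    coords = _grid(20, 20)
    labels = (coords[:, 0] >= 10).astype(int)
    return coords, labels


class TestCalibrateRadius:
    def test_mean_neighbor_count_near_target(self, halves):
        coords, labels = halves
        r = calibrate_radius(coords, labels, target_domain=0, target_mean_neighbors=10)
        # brute-force count at the returned radius
        tgt = coords[labels == 0]
        other = coords[labels == 1]
        counts = [(np.linalg.norm(other - s, axis=1) <= r).sum() for s in tgt]
        assert 9 <= np.mean(counts) <= 11

    def test_saturates_when_target_unreachable(self, halves):
        coords, labels = halves
        with pytest.warns(UserWarning, match="maximal radius"):
            r = calibrate_radius(coords, labels, 0, target_mean_neighbors=10_000)
        assert r >= np.hypot(19, 19)

    def test_scale_equivariance(self, halves):
        coords, labels = halves
        r1 = calibrate_radius(coords, labels, 0, 10)
        r2 = calibrate_radius(coords * 2.0, labels, 0, 10)
        assert r2 == pytest.approx(2.0 * r1, rel=1e-6)


class TestBuildNeighborhood:
    def test_two_domain_membership_rule(self, halves):
        coords, labels = halves
        spec = build_neighborhood(coords, labels, 0, radius=15.0)
        # radius 15 covers >50% of the right half
        assert spec.neighboring_domains == [1]
        spec2 = build_neighborhood(coords, labels, 0, radius=2.0)
        assert spec2.neighboring_domains == []  # only ~20% within radius 2

    def test_exactly_half_is_not_neighboring(self):
        # target at x=0; domain 1 has 4 spots, exactly 2 within radius
        coords = np.array([[0.0, 0], [1.0, 0], [1.0, 1], [5.0, 0], [5.0, 1]])
        labels = np.array([0, 1, 1, 1, 1])
        spec = build_neighborhood(coords, labels, 0, radius=1.5)
        assert 1 not in spec.neighboring_domains

    def test_three_domains_on_line_match_bruteforce(self):
        coords = np.column_stack([np.arange(30, dtype=float), np.zeros(30)])
        labels = np.repeat([0, 1, 2], 10)
        radius = 3.0
        spec = build_neighborhood(coords, labels, 0, radius)
        # brute force: non-target spots within 3.0 of any target spot
        tgt = coords[labels == 0]
        expected = {
            i for i in range(30) if labels[i] != 0
            and min(np.linalg.norm(coords[i] - t) for t in tgt) <= radius
        }
        assert set(spec.neighbor_set) == expected
        assert spec.neighboring_domains == []  # 3/10 of domain 1 only
        assert set(spec.non_neighboring_domains) == {1, 2}

    def test_partition_invariants(self, halves):
        coords, labels = halves
        spec = build_neighborhood(coords, labels, 1, radius=12.0)
        assert 1 not in spec.neighboring_domains
        assert set(spec.neighboring_domains) | set(spec.non_neighboring_domains) == {0}
        assert np.all(labels[spec.neighbor_set] != 1)


class TestFineGrainedScreen:
    def test_identical_expression_not_selected(self, halves):
        coords, labels = halves
        spec = build_neighborhood(coords, labels, 0, 15.0)
        expr = np.full((400, 5), 2.0)
        sel, fc, _, _ = fine_grained_screen(expr, labels, 0, spec)
        assert sel == set() and np.allclose(fc, 1.0)

    def test_threefold_gene_selected(self, halves):
        coords, labels = halves
        spec = build_neighborhood(coords, labels, 0, 15.0)
        expr = np.ones((400, 2))
        expr[labels == 0, 0] = 3.0
        sel, fc, _, _ = fine_grained_screen(expr, labels, 0, spec)
        assert sel == {0}
        assert fc[0] == pytest.approx(3.0, rel=1e-6)

    def test_matches_two_loop_bruteforce(self, halves, rng):
        coords, labels = halves
        spec = build_neighborhood(coords, labels, 0, 15.0)
        expr = rng.gamma(2.0, 1.0, size=(400, 20))
        _, fc, _, _ = fine_grained_screen(expr, labels, 0, spec)
        nbr = np.isin(labels, spec.neighboring_domains)
        for g in range(20):
            num = np.mean([expr[i, g] for i in range(400) if labels[i] == 0])
            den = np.mean([expr[i, g] for i in range(400) if nbr[i]])
            assert abs(fc[g] - num / (den + 1e-9)) < 1e-12

    def test_fold_change_invariant_to_global_rescale(self, halves, rng):
        coords, labels = halves
        spec = build_neighborhood(coords, labels, 0, 15.0)
        expr = rng.gamma(2.0, 1.0, size=(400, 10))
        _, fc1, _, _ = fine_grained_screen(expr, labels, 0, spec)
        _, fc2, _, _ = fine_grained_screen(expr * 37.5, labels, 0, spec)
        np.testing.assert_allclose(fc1, fc2, rtol=1e-7)

    def test_raising_threshold_shrinks_set(self, halves, rng):
        coords, labels = halves
        spec = build_neighborhood(coords, labels, 0, 15.0)
        expr = rng.gamma(2.0, 1.0, size=(400, 50))
        expr[labels == 0] *= rng.uniform(1.0, 3.0, size=50)
        lo, *_ = fine_grained_screen(expr, labels, 0, spec, fc_threshold=1.2)
        hi, *_ = fine_grained_screen(expr, labels, 0, spec, fc_threshold=2.0)
        assert hi <= lo


class TestCoarseGrainedScreen:
    def test_null_selection_rate_controlled(self, rng):
        labels = np.repeat([0, 1, 2], 60)
        expr = rng.gamma(2.0, 1.0, size=(180, 200))  # 200 null genes
        sel, _ = coarse_grained_screen(expr, labels, 0)
        assert len(sel) / 200 <= 0.1

    def test_exclusive_expression_selected(self, rng):
        labels = np.repeat([0, 1], 15)
        expr = np.zeros((30, 3))
        expr[:, 1] = rng.uniform(0.5, 1.5, 30)  # spatially flat gene
        expr[labels == 0, 0] = rng.uniform(2.0, 3.0, 15)  # target-exclusive
        sel, padj = coarse_grained_screen(expr, labels, 0)
        assert 0 in sel and padj[0] < 0.05

    def test_constant_gene_gets_padj_one(self, rng):
        labels = np.repeat([0, 1], 10)
        expr = rng.gamma(2, 1, size=(20, 4))
        expr[:, 2] = 5.0
        _, padj = coarse_grained_screen(expr, labels, 0)
        assert padj[2] == 1.0

    def test_bh_adjusted_nondecreasing_in_sorted_raw_p(self, rng):
        labels = np.repeat([0, 1], 40)
        expr = rng.gamma(2, 1, size=(80, 60))
        expr[labels == 0, :20] *= rng.uniform(1, 2, size=20)
        _, padj = coarse_grained_screen(expr, labels, 0)
        from scipy.stats import mannwhitneyu

        raw = mannwhitneyu(expr[labels == 0], expr[labels == 1],
                           alternative="greater", axis=0).pvalue
        order = np.argsort(raw)
        assert np.all(np.diff(padj[order]) >= -1e-12)

    def test_lower_alpha_shrinks_selection(self, rng):
        labels = np.repeat([0, 1], 50)
        expr = rng.gamma(2, 1, size=(100, 80))
        expr[labels == 0, :30] *= 1.5
        loose, _ = coarse_grained_screen(expr, labels, 0, alpha_fdr=0.1)
        tight, _ = coarse_grained_screen(expr, labels, 0, alpha_fdr=0.01)
        assert tight <= loose


class TestConstraintScreen:
    @pytest.fixture()
    def line3(self):
        coords = np.column_stack([np.arange(30, dtype=float), np.zeros(30)])
        labels = np.repeat([0, 1, 2], 10)
        spec = build_neighborhood(coords, labels, 0, radius=3.0)
        return coords, labels, spec

    def test_equal_means_not_adopted(self, line3):
        _, labels, spec = line3
        expr = np.full((30, 3), 4.0)
        sel, passed = constraint_screen(expr, labels, 0, spec)
        assert sel == set() and not passed.any()

    def test_uniformly_higher_target_passes_all(self, line3):
        _, labels, spec = line3
        expr = np.ones((30, 4))
        expr[labels == 0] = 2.0
        sel, _ = constraint_screen(expr, labels, 0, spec)
        assert sel == {0, 1, 2, 3}

    def test_matches_bruteforce_mean_comparison(self, line3, rng):
        _, labels, spec = line3
        expr = rng.gamma(2, 1, size=(30, 15))
        sel, _ = constraint_screen(expr, labels, 0, spec)
        pooled = np.isin(labels, spec.non_neighboring_domains)
        expected = {
            g for g in range(15)
            if expr[labels == 0, g].mean() > expr[pooled, g].mean()
        }
        assert sel == expected

    def test_no_non_neighboring_domains_passes_all_with_warning(self, rng):
        coords = _grid(6, 6)
        labels = (coords[:, 0] >= 3).astype(int)
        spec = build_neighborhood(coords, labels, 0, radius=10.0)
        assert spec.non_neighboring_domains == []
        expr = rng.gamma(2, 1, size=(36, 5))
        with pytest.warns(UserWarning, match="passes all genes"):
            sel, _ = constraint_screen(expr, labels, 0, spec)
        assert len(sel) == 5


class TestDetectSvgs:
    def test_final_set_is_three_way_intersection(self, small_slide):
        ds = small_slide["ds"]
        report = detect_svgs(ds, small_slide["raw"].labels)
        for d in report.final_sets:
            assert report.final_sets[d] == (
                report.fine_sets[d] & report.coarse_sets[d] & report.constraint_sets[d]
            )
            assert report.final_sets[d] <= report.fine_sets[d]

    def test_planted_markers_recovered(self, small_slide):
        ds = small_slide["ds"]
        report = detect_svgs(ds, small_slide["raw"].labels)
        for d, truth in small_slide["truth_svgs"].items():
            found = report.final_sets[d]
            assert len(found & truth) / len(truth) >= 0.9

    def test_single_domain_rejected(self, small_slide):
        with pytest.raises(ValueError, match="2 domains"):
            detect_svgs(small_slide["ds"], np.zeros(small_slide["ds"].n_spots, dtype=int))

    def test_report_table_consistent_with_sets(self, small_slide):
        ds = small_slide["ds"]
        report = detect_svgs(ds, small_slide["raw"].labels)
        t = report.table
        for d in report.final_sets:
            sub = t[t.domain == d]
            assert set(sub.loc[sub.in_final, "gene"]) == report.final_sets[d]


class TestMoransI:
    def test_smooth_gradient_near_one(self):
        coords = np.column_stack([np.arange(100, dtype=float), np.zeros(100)])
        g = build_knn_graph(coords, k=2)
        assert morans_i(np.arange(100, dtype=float), g) > 0.9

    def test_permutation_null_mean(self, rng):
        n = 100
        coords = np.column_stack([np.arange(n, dtype=float), np.zeros(n)])
        g = build_knn_graph(coords, k=2)
        x = np.arange(n, dtype=float)
        vals = [morans_i(rng.permutation(x), g) for _ in range(300)]
        assert np.mean(vals) == pytest.approx(-1 / (n - 1), abs=0.02)

    def test_checkerboard_negative(self):
        coords = np.column_stack([np.arange(50, dtype=float), np.zeros(50)])
        g = build_knn_graph(coords, k=2)
        x = np.tile([1.0, -1.0], 25)
        assert morans_i(x, g) < 0

    def test_constant_vector_returns_zero_with_warning(self):
        coords = np.column_stack([np.arange(10, dtype=float), np.zeros(10)])
        g = build_knn_graph(coords, k=2)
        with pytest.warns(UserWarning, match="constant"):
            assert morans_i(np.ones(10), g) == 0.0

    def test_matches_bruteforce_double_sum(self, rng):
        coords = rng.uniform(size=(8, 2))
        g = build_knn_graph(coords, k=3)
        x = rng.normal(size=8)
        W = g.row_normalized_adjacency().toarray()
        z = x - x.mean()
        brute = (8 / W.sum()) * sum(
            W[i, j] * z[i] * z[j] for i in range(8) for j in range(8)
        ) / np.sum(z**2)
        np.testing.assert_allclose(morans_i(x, g), brute, atol=1e-10)
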