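"""3D distance statistic: selection policy, normalization, comparisons."""

import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from xistlink import (
    SimulationConfig,
    compare_segments,
    generate_nuclei,
    normalize_tg,
    pairwise_distances,
    rank_candidate_insertion_site,
    two_shortest_average,
)
from xistlink.distance import collect_distance_records, normalize_records
from xistlink.simulate import SEGMENT, XIC, Nucleus, Spot


def _nucleus(segment_pts, xic_pts, segment_id="A"):
    nuc = Nucleus("c1", "TG", 10.0)
    for p in segment_pts:
        nuc.spots.append(Spot("c1", SEGMENT, "unknown", *p, target=segment_id))
    for p in xic_pts:
        nuc.spots.append(Spot("c1", XIC, "unknown", *p))
    return nuc


def _best_two_pair_matching(matrix):
    """Brute-force minimum total weight over all 2-pair matchings with
    distinct rows and columns."""
    m = np.asarray(matrix)
    best = None
    for (r1, r2) in itertools.permutations(range(m.shape[0]), 2):
        for (c1, c2) in itertools.permutations(range(m.shape[1]), 2):
            total = m[r1, c1] + m[r2, c2]
            if best is None or total < best:
                best = total
    return best


class TestPairwise:
    def test_three_four_five(self):
        nuc = _nucleus([(0, 0, 0)], [(3, 4, 0)])
        assert pairwise_distances(nuc, "A")[0, 0] == pytest.approx(5.0)

    def test_coincident_spots_distance_zero(self):
        nuc = _nucleus([(1, 2, 3)], [(1, 2, 3)])
        assert pairwise_distances(nuc, "A")[0, 0] == 0.0

    def test_matches_elementwise_recomputation(self, rng):
        seg = rng.uniform(-5, 5, (4, 3))
        xic = rng.uniform(-5, 5, (3, 3))
        nuc = _nucleus(seg, xic)
        m = pairwise_distances(nuc, "A")
        for i in range(4):
            for j in range(3):
                want = np.sqrt(sum((seg[i, k] - xic[j, k]) ** 2 for k in (2, 0, 1)))
                assert m[i, j] == pytest.approx(want, abs=1e-9)

    def test_missing_channel_errors(self):
        nuc = _nucleus([(0, 0, 0)], [])
        with pytest.raises(ValueError, match="Xic"):
            pairwise_distances(nuc, "A")
        with pytest.raises(ValueError, match="segment"):
            pairwise_distances(_nucleus([], [(0, 0, 0)]), "A")


class TestTwoShortest:
    def test_distinct_entries_simple_matrix(self):
        d1, d2, avg = two_shortest_average(np.array([[1.0, 2.0], [3.0, 4.0]]))
        assert (d1, d2, avg) == (1.0, 4.0, 2.5)  # distinct rows and columns

    def test_policy_difference_on_shared_spot_matrix(self):
        m = np.array([[1.0, 1.1], [1.05, 9.0]])
        assert two_shortest_average(m, require_distinct=True) == (1.0, 9.0, 5.0)
        d1, d2, avg = two_shortest_average(m, require_distinct=False)
        assert (d1, d2) == (1.0, 1.05)
        assert avg == pytest.approx(1.025)

    def test_too_small_matrix_signals_exclusion(self):
        assert two_shortest_average(np.array([[1.0, 2.0]])) is None
        assert two_shortest_average(np.array([[1.0]]), require_distinct=False) is None
        assert two_shortest_average(np.empty((0, 0))) is None

    def test_d1_not_larger_than_d2_and_avg_between(self, rng):
        for _ in range(100):
            m = rng.uniform(0, 10, (4, 4))
            for distinct in (True, False):
                d1, d2, avg = two_shortest_average(m, require_distinct=distinct)
                assert d1 <= d2
                assert d1 <= avg <= d2

    def test_greedy_vs_brute_force_two_pair_matching(self, rng):
        """Greedy equals the optimal 2-pair matching whenever its first
        pick belongs to an optimal matching, and is never better."""
        agree = 0
        for _ in range(300):
            m = rng.uniform(0, 10, (4, 4))
            d1, d2, _ = two_shortest_average(m, require_distinct=True)
            opt = _best_two_pair_matching(m)
            assert d1 + d2 >= opt - 1e-12
            assert d1 == m.min()  # first greedy pick is the global minimum
            i, j = np.unravel_index(np.argmin(m), m.shape)
            rest = np.delete(np.delete(m, i, axis=0), j, axis=1)
            if m.min() + rest.min() <= opt + 1e-12:
                assert d1 + d2 == pytest.approx(opt)
                agree += 1
        assert agree > 250  # discrepancies are rare for random matrices


class TestNormalization:
    def test_subtracts_wt_median(self):
        out = normalize_tg([2.5], [1.0, 2.0, 3.0])
        assert out[0] == pytest.approx(0.5)

    def test_wt_self_normalization_has_zero_median(self, rng):
        wt = rng.uniform(0, 5, 31)
        assert np.median(normalize_tg(wt, wt)) == pytest.approx(0.0)

    @given(st.floats(min_value=-10, max_value=10, allow_nan=False))
    def test_shift_invariance(self, c):
        wt = np.array([1.0, 2.0, 4.0, 8.0])
        tg = np.array([0.5, 3.0, 7.0])
        base = normalize_tg(tg, wt)
        shifted = normalize_tg(tg + c, wt + c)
        np.testing.assert_allclose(shifted, base, atol=1e-9)

    def test_empty_wt_errors(self):
        with pytest.raises(ValueError, match="WT"):
            normalize_tg([1.0], [])


class TestComparisons:
    def test_identical_samples_give_t0_p1(self):
        out = compare_segments({"A": [1.0, 2.0, 3.0], "B": [1.0, 2.0, 3.0]}, "A")
        assert out[0].t_statistic == pytest.approx(0.0)
        assert out[0].p_value == pytest.approx(1.0)

    def test_separated_samples_give_tiny_p(self, rng):
        a = rng.normal(0.0, 0.01, 20)
        b = 10.0 + rng.normal(0.0, 0.01, 20)
        out = compare_segments({"A": a, "B": b}, "A")
        assert out[0].p_value < 1e-3

    def test_zero_variance_degenerate_with_warning(self):
        with pytest.warns(UserWarning, match="degenerate"):
            out = compare_segments({"A": [1.0, 1.0], "B": [2.0, 2.0]}, "A")
        assert out[0].degenerate

    def test_invariant_under_rigid_motion_of_each_nucleus(self, rng):
        from scipy.spatial.transform import Rotation

        seg = rng.uniform(-3, 3, (4, 3))
        xic = rng.uniform(-3, 3, (4, 3))
        base = two_shortest_average(pairwise_distances(_nucleus(seg, xic), "A"))
        rot = Rotation.random(random_state=5).as_matrix()
        shift = np.array([0.3, -1.1, 2.2])
        moved = two_shortest_average(
            pairwise_distances(_nucleus(seg @ rot.T + shift, xic @ rot.T + shift), "A")
        )
        np.testing.assert_allclose(moved, base, atol=1e-9)


class TestRanking:
    def test_orders_by_median(self):
        out = rank_candidate_insertion_site(
            {"A": [0.1, 0.1], "B": [0.5, 0.5], "C": [0.9, 0.9]}
        )
        assert [s for s, _, _ in out] == ["A", "B", "C"]
        assert not any(tied for _, _, tied in out)

    def test_median_tie_ordered_by_id_and_flagged(self):
        out = rank_candidate_insertion_site({"B": [0.5], "A": [0.5], "C": [1.0]})
        assert [s for s, _, _ in out] == ["A", "B", "C"]
        assert out[0][2] and out[1][2] and not out[2][2]

    def test_needs_two_segments(self):
        with pytest.raises(ValueError):
            rank_candidate_insertion_site({"A": [0.1]})


def test_boxplot_helper_writes_a_figure(tmp_path):
    from xistlink.distance import plot_normalized_distances

    out = tmp_path / "box.png"
    plot_normalized_distances({"A": [0.1, 0.2, -0.1], "B": [0.5, 0.6, 0.4]}, str(out))
    assert out.stat().st_size > 0


class TestOnSyntheticCells:
    def test_nearer_segment_wins_comparison_and_ranking(self):
        """Segments 0.25 vs ~60 Mb from the transgene: the nearer one has
        the smaller median normalized distance, significantly so at 50
        cells per genotype."""
        segs = {"near": 135_750_000, "far": 75_500_000}
        cfg = SimulationConfig(seed=31, n_cells_per_genotype=50, segment_positions=segs)
        nuclei = generate_nuclei(cfg, linked=True)
        normalized = {}
        for seg in segs:
            tg_recs, _ = collect_distance_records(nuclei["TG"], seg)
            wt_recs, _ = collect_distance_records(nuclei["WT"], seg)
            normalize_records(tg_recs, wt_recs)
            normalized[seg] = [r.normalized for r in tg_recs]
        assert np.median(normalized["near"]) < np.median(normalized["far"])
        comp = compare_segments(normalized, "near")[0]
        assert comp.p_value < 0.05
        assert rank_candidate_insertion_site(normalized)[0][0] == "near"

    def test_median_normalized_distance_monotone_in_separation(self):
        segs = {"s1": 135_750_000, "s2": 155_500_000, "s3": 75_500_000}
        cfg = SimulationConfig(seed=32, n_cells_per_genotype=100, segment_positions=segs)
        nuclei = generate_nuclei(cfg, linked=True)
        medians = []
        for seg in ("s1", "s2", "s3"):  # separations 0.25, 20, 60 Mb
            tg_recs, _ = collect_distance_records(nuclei["TG"], seg)
            wt_recs, _ = collect_distance_records(nuclei["WT"], seg)
            normalize_records(tg_recs, wt_recs)
            medians.append(np.median([r.normalized for r in tg_recs]))
        assert medians[0] <= medians[1] <= medians[2]
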