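import numpy as np
import pandas as pd
import pytest

from pericentriq import compartments as comp
from pericentriq import metrics as M
from pericentriq import synthetic
from pericentriq.hic_io import Region, balance
from pericentriq.metrics import PsCurve
from conftest import dense_to_matrix


@pytest.fixture(scope="module")
def control_segmentation(default_spec, default_truth, expected_maps, arm_regions):
    ends = {a.name: a.centromeric_end for a in default_spec.arms}
    eigs = [
        comp.compute_eigenvectors(
            expected_maps[1.0],
            arm_regions[name],
            state_track=default_truth.state_track,
            centromeric_end=ends[name],
        )
        for name in arm_regions
    ]
    return comp.call_compartments(eigs, min_len=20_000)


class TestPsCurve:
    def test_planted_exponent_recovered(self, expected_maps, arm_regions):
        curve = M.ps_curve(expected_maps[1.0], arm_regions["armL"])
        slope = M.fit_ps_slope(curve, 10_000, 100_000)
        assert slope == pytest.approx(-1.0, abs=0.05)

    def test_constant_matrix_gives_flat_curve(self):
        dense = np.ones((40, 40))
        np.fill_diagonal(dense, 0)
        m = dense_to_matrix(dense)
        curve = M.ps_curve(m, Region("chr1", 0, 200_000))
        slope = M.fit_ps_slope(curve)
        assert slope == pytest.approx(0.0, abs=1e-9)

    def test_pair_counts_conserve_total_cis_pairs(self):
        n = 30
        rng = np.random.default_rng(4)
        dense = rng.gamma(1.0, size=(n, n))
        dense = np.triu(dense, 1) + np.triu(dense, 1).T
        m = dense_to_matrix(dense)
        curve = M.ps_curve(m, Region("chr1", 0, n * 5000))
        assert curve.n_pairs.sum() == n * (n - 1) // 2

    def test_normalized_curve_sums_to_one(self, expected_maps, arm_regions):
        curve = M.ps_curve(expected_maps[1.0], arm_regions["armL"])
        assert np.nansum(curve.values) == pytest.approx(1.0)

    def test_empty_arm_rejected(self, expected_maps):
        with pytest.raises(ValueError):
            M.ps_curve(expected_maps[1.0], Region("nope", 0, 100_000))


def power_law_curve(exponent, scale=1.0, n_shells=30):
    edges = 1e4 * 10 ** (np.arange(n_shells + 1) / 8)
    mids = np.sqrt(edges[:-1] * edges[1:])
    vals = scale * mids ** exponent
    return PsCurve(
        arm=Region("chr1", 0, 10_000_000),
        shell_edges=edges,
        separations=mids,
        values=vals,
        raw_means=vals,
        n_pairs=np.ones(n_shells),
        norm_factor=1.0,
    )


class TestCurveCrossover:
    def test_closed_form_crossing(self):
        """s^-0.8 and s^-1.2 scaled to cross at s* = 1e5."""
        s_star = 1e5
        a = power_law_curve(-0.8)
        b = power_law_curve(-1.2, scale=s_star ** (-0.8 + 1.2))
        got = M.curve_crossover(a, b)
        assert got is not None
        assert got.first == pytest.approx(s_star, rel=1e-6)

    def test_identical_curves_have_no_crossing(self):
        a = power_law_curve(-1.0)
        assert M.curve_crossover(a, power_law_curve(-1.0)) is None

    def test_constant_factor_offset_has_no_crossing(self):
        a = power_law_curve(-1.0)
        b = power_law_curve(-1.0, scale=3.7)
        assert M.curve_crossover(a, b) is None

    def test_mismatched_shells_rejected(self):
        with pytest.raises(ValueError):
            M.curve_crossover(power_law_curve(-1.0), power_law_curve(-1.0, n_shells=10))


class TestShortLongRatio:
    def test_hand_sum(self):
        n = 500  # 2.5Mb at 5kb
        dense = np.zeros((n, n))
        dense[0, 100] = 30.0  # 0.5 Mb
        dense[0, 400] = 10.0  # 2.0 Mb
        dense = dense + dense.T
        m = dense_to_matrix(dense)
        assert M.short_long_ratio(m, Region("chr1", 0, n * 5000)) == 3.0

    def test_pair_at_exact_cutoff_is_long_range(self):
        n = 300
        dense = np.zeros((n, n))
        dense[0, 200] = 7.0  # exactly 1,000,000 bp
        dense[0, 10] = 21.0
        dense = dense + dense.T
        m = dense_to_matrix(dense)
        assert M.short_long_ratio(m, Region("chr1", 0, n * 5000)) == 3.0

    def test_strictly_decreasing_in_condensin_activity(
        self, expected_maps, arm_regions
    ):
        ratios = [
            M.short_long_ratio(expected_maps[lam], arm_regions["armL"])
            for lam in (0.5, 1.0, 2.0)
        ]
        assert ratios[0] > ratios[1] > ratios[2]

    def test_zero_long_range_signal_rejected(self):
        dense = np.zeros((300, 300))
        dense[0, 1] = 5.0
        dense = dense + dense.T
        with pytest.raises(ValueError, match="long-range"):
            M.short_long_ratio(dense_to_matrix(dense), Region("chr1", 0, 1_500_000))


class TestTransProportion:
    def test_hand_sum(self):
        # two chromosomes of 2 bins each; cis sums 100 each, trans 50
        dense = np.zeros((4, 4))
        dense[0, 1] = 100.0
        dense[2, 3] = 100.0
        dense[1, 2] = 50.0
        dense = dense + dense.T
        m = dense_to_matrix(dense, chrom_split=[("chrA", 2), ("chrB", 2)])
        assert M.trans_proportion(m, "chrA", "chrB") == pytest.approx(1 / 3)

    def test_rows_sum_to_one(self, expected_maps):
        props = M.trans_proportion_matrix(expected_maps[1.0])
        assert np.allclose(props.sum(axis=1), 1.0)

    def test_strictly_decreasing_in_condensin_activity(self, expected_maps):
        vals = [
            M.trans_proportion(expected_maps[lam], "armL", "armR")
            for lam in (0.5, 1.0, 2.0)
        ]
        assert vals[0] > vals[1] > vals[2]

    def test_single_chromosome_rejected(self):
        m = dense_to_matrix(np.ones((4, 4)))
        with pytest.raises(ValueError, match="two chromosomes"):
            M.trans_proportion_matrix(m)

    def test_balanced_input_rejected(self, expected_maps):
        bal = balance(
            synthetic.sample_contacts(expected_maps[1.0], 100_000, 3)
        )
        with pytest.raises(ValueError, match="raw"):
            M.trans_proportion_matrix(bal)


class TestStateInteractionStrength:
    def test_direct_lookup_and_mixed_pair_exclusion(self):
        n = 202  # enough bins for a 500kb separation (100 bins)
        dense = np.zeros((n, n))
        dense[0, 100] = 2.5  # active-active at 500kb
        dense[1, 101] = 4.0  # null-null at 500kb
        dense[2, 102] = 9.0  # active-null: must be excluded
        dense = dense + dense.T
        m = dense_to_matrix(dense)
        track = pd.DataFrame(
            {
                "chrom": ["chr1"] * 6,
                "start": [0, 5000, 10_000, 15_000, 500_000, 505_000],
                "end": [5000, 10_000, 15_000, 500_000, 505_000, n * 5000],
                "state": ["active", "null", "active", "null", "active", "null"],
            }
        )
        out = M.state_interaction_strength(m, track, 500_000)
        assert 2.5 in out["active"]
        assert 4.0 in out["null"]
        assert 9.0 not in np.concatenate([out["active"], out["null"]])

    def test_separation_must_be_grid_aligned(self, expected_maps, default_truth):
        with pytest.raises(ValueError, match="multiple"):
            M.state_interaction_strength(
                expected_maps[1.0], default_truth.state_track, 502_000
            )

    def test_like_with_like_exceeds_cross_on_synthetic(
        self, expected_maps, default_truth
    ):
        """A-A affinity 1.5 vs A-B 0.7 shows up at 500kb separation."""
        out = M.state_interaction_strength(
            expected_maps[1.0], default_truth.state_track, 500_000
        )
        m = expected_maps[1.0]
        states = comp.annotate_bins_with_states(m.bins, default_truth.state_track)
        d = 500_000 // m.bins.resolution
        vals = np.zeros(m.n_bins)
        hit = m.bin2 - m.bin1 == d
        vals[m.bin1[hit]] = m.value[hit]
        i = np.arange(m.n_bins - d)
        cross = (
            (m.bins.chroms[i] == m.bins.chroms[i + d])
            & (states[i] == "active")
            & (states[i + d] != "active")
        )
        assert out["active"].mean() > vals[i[cross]].mean()


class TestCompartmentPairScores:
    def test_exhaustive_bin_pair_oracle_on_toy(self):
        n = 40
        rng = np.random.default_rng(9)
        dense = rng.gamma(1.0, size=(n, n))
        dense = np.triu(dense, 1) + np.triu(dense, 1).T
        m = dense_to_matrix(dense, resolution=25_000)
        from pericentriq.compartments import Compartment, CompartmentSegmentation

        seg = CompartmentSegmentation(
            [
                Compartment(1, "A", "chr1", 0, 250_000, tuple(range(10))),
                Compartment(1, "B", "chr1", 250_000, 500_000, tuple(range(10, 20))),
                Compartment(2, "A", "chr1", 625_000, 1_000_000, tuple(range(25, 40))),
            ],
            min_len=20_000,
        )
        scores = M.compartment_pair_scores(m, seg, min_sep=0, max_sep=10**9)
        assert len(scores) == 3
        by_key = {s.key: s for s in scores}
        oracle = dense[np.ix_(range(10), range(10, 20))].mean()
        assert by_key[("A1", "B1")].mean == pytest.approx(oracle, abs=1e-12)
        oracle2 = dense[np.ix_(range(10), range(25, 40))].mean()
        assert by_key[("A1", "A2")].mean == pytest.approx(oracle2, abs=1e-12)

    def test_separation_window_filter(self, expected_maps, control_segmentation):
        scores = M.compartment_pair_scores(
            expected_maps[1.0], control_segmentation, 500_000, 5_000_000
        )
        assert scores
        for s in scores:
            assert 500_000 <= s.separation <= 5_000_000

    def test_pair_beyond_window_excluded(self):
        """A compartment pair 6Mb apart falls outside the 500kb-5Mb window."""
        from pericentriq.compartments import Compartment, CompartmentSegmentation

        n = 140
        rng = np.random.default_rng(13)
        dense = rng.gamma(1.0, size=(n, n))
        dense = np.triu(dense, 1) + np.triu(dense, 1).T
        m = dense_to_matrix(dense, resolution=50_000)
        seg = CompartmentSegmentation(
            [
                Compartment(1, "A", "chr1", 0, 100_000, (0, 1)),
                Compartment(1, "B", "chr1", 2_000_000, 2_100_000, (40, 41)),
                Compartment(2, "A", "chr1", 6_000_000, 6_100_000, (120, 121)),
            ],
            min_len=20_000,
        )
        keys = {s.key for s in M.compartment_pair_scores(m, seg, 500_000, 5_000_000)}
        assert ("A1", "B1") in keys
        assert ("A1", "A2") not in keys  # 6Mb apart
        wide_keys = {s.key for s in M.compartment_pair_scores(m, seg, 500_000, 10**9)}
        assert ("A1", "A2") in wide_keys

    def test_identical_conditions_give_unit_fold_change(
        self, expected_maps, control_segmentation
    ):
        scores = M.compartment_pair_scores(
            expected_maps[1.0], control_segmentation, 500_000, 5_000_000
        )
        fc = M.fold_change(scores, scores)
        assert all(s.fold_change == pytest.approx(1.0) for s in fc)
        assert all(s.percent_change == pytest.approx(0.0) for s in fc)

    def test_doubling_gives_plus_100_percent(self):
        s1 = [
            M.CompartmentPairScore("A1", "A2", "A", "A", 1e6, 2.0, 4),
        ]
        s0 = [
            M.CompartmentPairScore("A1", "A2", "A", "A", 1e6, 1.0, 4),
        ]
        out = M.fold_change(s1, s0)
        assert out[0].fold_change == pytest.approx(2.0)
        assert out[0].percent_change == pytest.approx(100.0)

    def test_long_range_fold_change_direction(
        self, expected_maps, control_segmentation
    ):
        ctrl = M.compartment_pair_scores(
            expected_maps[1.0], control_segmentation, 500_000, 5_000_000
        )
        for lam, expect_above in ((2.0, True), (0.5, False)):
            kd = M.compartment_pair_scores(
                expected_maps[lam], control_segmentation, 500_000, 5_000_000
            )
            fc = M.fold_change(kd, ctrl)
            folds = [s.fold_change for s in fc if s.separation >= 1_000_000]
            mean_fold = np.mean(folds)
            assert bool(mean_fold > 1.0) is expect_above


class TestScc:
    def make_decay_matrix(self, seed, n=120):
        rng = np.random.default_rng(seed)
        dense = np.zeros((n, n))
        for d in range(1, n):
            dense += np.diag(rng.gamma(2.0, size=n - d) / d, k=d)
        return dense_to_matrix(dense + dense.T)

    def test_self_correlation_is_exactly_one(self):
        m = self.make_decay_matrix(0)
        res = M.scc(m, m, h=2, max_sep=500_000)
        assert res.aggregate == 1.0
        assert all(v == 1.0 for v in res.per_chrom.values())

    def test_shuffled_matrix_decorrelates(self):
        n = 500
        rng = np.random.default_rng(1)
        dense = np.zeros((n, n))
        shuf = np.zeros((n, n))
        for d in range(1, n):
            vals = rng.gamma(2.0, size=n - d) / d
            dense += np.diag(vals, k=d)
            shuf += np.diag(rng.permutation(vals), k=d)
        a = dense_to_matrix(dense + dense.T)
        b = dense_to_matrix(shuf + shuf.T)
        res = M.scc(a, b, h=0, max_sep=2_500_000 // 2)
        assert abs(res.aggregate) < 0.1

    def test_h0_matches_direct_diagonal_oracle(self):
        a = self.make_decay_matrix(2, n=40)
        b = self.make_decay_matrix(3, n=40)
        res = M.scc(a, b, h=0, max_sep=200_000)
        da, db = a.to_dense(), b.to_dense()
        from scipy.stats import rankdata

        num = den = 0.0
        for d in range(1, 200_000 // 5000 + 1):
            x, y = np.diagonal(da, d), np.diagonal(db, d)
            if len(x) < 2 or x.std() == 0 or y.std() == 0:
                continue
            w = len(x) * np.sqrt(np.var(rankdata(x)) * np.var(rankdata(y)))
            num += w * np.corrcoef(x, y)[0, 1]
            den += w
        assert res.aggregate == pytest.approx(num / den, abs=1e-10)

    def test_symmetric_and_bounded(self):
        a = self.make_decay_matrix(4)
        b = self.make_decay_matrix(5)
        r1 = M.scc(a, b, h=3, max_sep=500_000)
        r2 = M.scc(b, a, h=3, max_sep=500_000)
        assert r1.aggregate == pytest.approx(r2.aggregate, abs=1e-12)
        assert -1.0 <= r1.aggregate <= 1.0

    def test_mismatched_bins_rejected(self):
        a = self.make_decay_matrix(6, n=30)
        b = self.make_decay_matrix(6, n=31)
        with pytest.raises(ValueError, match="bin table"):
            M.scc(a, b)
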