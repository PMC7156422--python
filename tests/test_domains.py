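"""Insulation/boundary calling, DI, aggregate maps, RTI, and region rules."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hicreprog import domains, sim
from hicreprog.contacts import ice_normalize
from hicreprog.tracks import SignalTrack

from conftest import matrix_from_values, uniform_matrix


def brute_force_rti(values, t0, t1):
    """Independent RTI enumeration: for each separation, median inside /
    median one-end-inside (partner within one TAD length), median of rows."""
    import statistics

    n = values.shape[0]
    L = t1 - t0
    ratios = []
    for d in range(1, L):
        i_in, i_out = [], []
        for i in range(n - d):
            j = i + d
            a_in = t0 <= i < t1
            b_in = t0 <= j < t1
            if a_in and b_in:
                i_in.append(values[i, j])
            elif a_in != b_in:
                other = j if a_in else i
                if t0 - L <= other < t0 or t1 <= other < t1 + L:
                    i_out.append(values[i, j])
        if not i_in or not i_out:
            continue
        m_out = statistics.median(i_out)
        if m_out == 0:
            continue
        ratios.append(statistics.median(i_in) / m_out)
    return statistics.median(ratios)


class TestInsulationScore:
    def test_uniform_matrix_flat_and_boundary_free(self):
        m = uniform_matrix(60)
        t = domains.insulation_score(m)
        finite = np.isfinite(t.insulation)
        assert np.allclose(t.insulation[finite], 0.0)
        assert len(domains.call_boundaries(t).table) == 0

    def test_single_bin_matches_direct_square_mean(self):
        rng = np.random.default_rng(40)
        a = rng.poisson(20, size=(60, 60)).astype(float)
        vals = a + a.T
        np.fill_diagonal(vals, 0.0)
        m = matrix_from_values(vals)
        t = domains.insulation_score(m)
        w = 10  # 1 Mb / 100 kb
        # independent direct averaging at bin 30, normalized by the
        # chromosome-wide mean of raw square means
        raws = []
        for b in range(w, 60 - w):
            raws.append(vals[b - w: b, b + 1: b + 1 + w].mean())
        expect = np.log2(raws[30 - w] / np.mean(raws))
        assert t.insulation[30] == pytest.approx(expect, rel=1e-12)

    def test_planted_boundary_is_local_minimum(self, tad_map_iced):
        m, truth = tad_map_iced
        t = domains.insulation_score(m)
        for b in truth.boundaries[5:8]:
            window = t.insulation[b - 4: b + 5]
            assert np.nanargmin(window) in (3, 4, 5)

    def test_short_chromosome_is_error(self):
        with pytest.raises(ValueError, match="shorter"):
            domains.insulation_score(uniform_matrix(15))


class TestCallBoundaries:
    def test_monotone_insulation_no_boundaries(self):
        n = 60
        t = domains.InsulationTrack(
            chrom="chr1", resolution=100_000,
            insulation=np.linspace(-1, 1, n),
            delta=np.linspace(-0.5, -0.1, n),  # never crosses downward
            square_size=1_000_000, delta_span=200_000, noise_threshold=0.25,
        )
        assert len(domains.call_boundaries(t).table) == 0

    def test_planted_boundaries_recovered(self, tad_map_iced):
        m, truth = tad_map_iced
        bs = domains.call_boundaries(domains.insulation_score(m))
        called = bs.bins
        true_b = truth.boundaries
        recall = np.mean([np.abs(called - b).min() <= 1 for b in true_b])
        precision = np.mean([np.abs(true_b - c).min() <= 1 for c in called])
        assert recall >= 0.9
        assert precision >= 0.8

    def test_strength_exactly_at_threshold_called(self):
        n = 40
        delta = np.zeros(n)
        delta[:20] = 0.125
        delta[20:] = -0.125  # peak-to-trough exactly 0.25
        t = domains.InsulationTrack(
            chrom="chr1", resolution=100_000,
            insulation=np.zeros(n), delta=delta,
            square_size=1_000_000, delta_span=200_000, noise_threshold=0.25,
        )
        assert len(domains.call_boundaries(t).table) == 1


class TestTadsFromBoundaries:
    def _bset(self, bins, n_bins=100):
        return domains.BoundarySet(
            chrom="chr1", resolution=100_000, n_bins=n_bins,
            table=pd.DataFrame({"bin": bins, "strength": [1.0] * len(bins)}),
        )

    def test_no_boundaries_whole_chromosome(self):
        tads = domains.tads_from_boundaries(self._bset([]))
        assert len(tads) == 1
        assert (tads.iloc[0].start_bin, tads.iloc[0].end_bin) == (0, 100)

    def test_fencepost(self):
        tads = domains.tads_from_boundaries(self._bset([10, 30, 55, 80]))
        assert len(tads) == 5

    def test_random_boundaries_partition_chromosome(self):
        rng = np.random.default_rng(41)
        bins = sorted(rng.choice(np.arange(1, 100), size=12, replace=False))
        tads = domains.tads_from_boundaries(self._bset(list(bins)))
        assert tads.iloc[0].start_bin == 0
        assert tads.iloc[-1].end_bin == 100
        assert (tads["end_bin"].to_numpy()[:-1] == tads["start_bin"].to_numpy()[1:]).all()


class TestDirectionalityIndex:
    def test_symmetric_neighborhood_zero(self):
        m = uniform_matrix(60)
        di = domains.directionality_index(m)
        finite = np.isfinite(di)
        assert np.allclose(di[finite], 0.0)

    def test_hand_evaluated_formula(self):
        # A = 0, B = 40 -> E = 20, DI = +(400/20 + 400/20) = +40
        n = 60
        vals = np.zeros((n, n))
        b = 30
        for j in range(b + 1, b + 21):
            vals[b, j] = vals[j, b] = 2.0
        m = matrix_from_values(vals)
        di = domains.directionality_index(m, window=2_000_000)
        assert di[b] == pytest.approx(40.0)

    def test_sign_pattern_at_tad_edges(self, tad_map_iced):
        m, truth = tad_map_iced
        di = domains.directionality_index(m)
        t0, t1, _ = truth.tad_intervals[8]
        assert di[t0] > 0  # left edge looks downstream
        assert di[t1 - 1] < 0  # right edge looks upstream

    def test_antisymmetry_under_reflection(self):
        rng = np.random.default_rng(42)
        a = rng.poisson(10, size=(60, 60)).astype(float)
        vals = a + a.T
        np.fill_diagonal(vals, 0.0)
        m = matrix_from_values(vals)
        di = domains.directionality_index(m)
        m_flip = matrix_from_values(vals[::-1, ::-1])
        di_flip = domains.directionality_index(m_flip)
        finite = np.isfinite(di)
        assert np.allclose(di[finite], -di_flip[::-1][finite])

    def test_window_larger_than_chromosome_is_error(self):
        with pytest.raises(ValueError, match="window larger"):
            domains.directionality_index(uniform_matrix(10), window=2_000_000)


class TestProfileAtAnchors:
    def test_constant_track_flat_profile(self):
        offs, prof = domains.profile_at_anchors(
            np.full(100, 2.5), 10_000, np.array([300_000, 500_000]), 50_000
        )
        assert np.allclose(prof, 2.5)
        assert offs[0] == -50_000 and offs[-1] == 50_000

    def test_single_anchor_equals_local_slice(self):
        vals = np.arange(100, dtype=float)
        offs, prof = domains.profile_at_anchors(vals, 10_000, np.array([500_000]), 30_000)
        assert np.allclose(prof, vals[47:54])

    def test_matches_brute_force_averaging(self):
        rng = np.random.default_rng(43)
        vals = rng.normal(size=200)
        anchors = np.array([400_000, 900_000, 1_500_000])
        offs, prof = domains.profile_at_anchors(vals, 10_000, anchors, 40_000)
        expect = np.mean(
            [vals[a // 10_000 - 4: a // 10_000 + 5] for a in anchors], axis=0
        )
        assert np.allclose(prof, expect)

    def test_no_usable_anchors_is_error(self):
        with pytest.raises(ValueError, match="usable anchors"):
            domains.profile_at_anchors(np.ones(5), 10_000, np.array([0]), 100_000)


class TestRescaleAggregate:
    def _tads_df(self, spans, res=100_000):
        return pd.DataFrame(
            [
                ("chr1", s * res, e * res, s, e)
                for s, e in spans
            ],
            columns=["chrom", "start", "end", "start_bin", "end_bin"],
        )

    def test_aggregate_mean_is_one(self, tad_map_iced):
        m, truth = tad_map_iced
        tads = self._tads_df([(s, e) for s, e, _ in truth.tad_intervals])
        agg = domains.rescale_aggregate(m, tads)
        assert agg.mean() == pytest.approx(1.0)

    def test_single_tad_equals_own_resampled_submatrix(self):
        rng = np.random.default_rng(44)
        a = rng.poisson(10, size=(80, 80)).astype(float)
        vals = a + a.T
        np.fill_diagonal(vals, 0.0)
        m = matrix_from_values(vals)
        tads = self._tads_df([(30, 50)])
        agg1 = domains.rescale_aggregate(m, tads)
        # averaging over one TAD is that TAD's grid, normalized to mean 1
        assert agg1.mean() == pytest.approx(1.0)
        agg2 = domains.rescale_aggregate(m, pd.concat([tads, tads], ignore_index=True))
        assert np.allclose(agg1, agg2)

    def test_planted_tads_show_center_enrichment(self, tad_map_iced):
        m, truth = tad_map_iced
        tads = self._tads_df([(s, e) for s, e, _ in truth.tad_intervals])
        agg = domains.rescale_aggregate(m, tads, n_grid_tad=20)
        center = agg[15:25, 15:25].mean()  # inner TAD body
        flank = agg[15:25, 0:8].mean()  # TAD rows vs left flank columns
        assert center > flank

    def test_difference_antisymmetry(self):
        rng = np.random.default_rng(45)
        a, b = rng.normal(size=(2, 40, 40))
        assert np.allclose(
            domains.aggregate_difference(a, b), -domains.aggregate_difference(b, a)
        )
        assert np.allclose(domains.aggregate_difference(a, a), 0.0)

    def test_grid_mismatch_is_error(self):
        with pytest.raises(ValueError, match="grids must match"):
            domains.aggregate_difference(np.ones((4, 4)), np.ones((5, 5)))


class TestRelativeTadIntensity:
    def test_uniform_matrix_gives_exactly_one(self):
        m = uniform_matrix(100)
        assert domains.relative_tad_intensity(m, 40, 60) == 1.0

    def test_constant_ratio_two(self):
        n = 100
        vals = np.full((n, n), 3.0)
        np.fill_diagonal(vals, 0.0)
        vals[40:60, 40:60] = 6.0
        np.fill_diagonal(vals[40:60, 40:60], 0.0)
        m = matrix_from_values(vals)
        assert domains.relative_tad_intensity(m, 40, 60) == 2.0

    def test_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(46)
        a = rng.poisson(8, size=(120, 120)).astype(float)
        vals = a + a.T
        np.fill_diagonal(vals, 0.0)
        m = matrix_from_values(vals)
        got = domains.relative_tad_intensity(m, 50, 70)
        expect = brute_force_rti(vals, 50, 70)
        assert got == pytest.approx(expect, abs=1e-12)

    def test_strictly_increasing_in_beta(self):
        rtis = []
        for beta in (0.0, 1.0, 2.0, 4.0):
            vals = []
            for seed in (1, 2, 3):
                p = sim.SimParams(
                    n_bins=200, bin_size=100_000, depth=2e6,
                    tad_intervals=((90, 110, beta),), seed=seed,
                )
                m, _ = sim.simulate_contact_map(p)
                vals.append(domains.relative_tad_intensity(ice_normalize(m), 90, 110))
            rtis.append(np.mean(vals))
        assert rtis[0] < rtis[1] < rtis[2] < rtis[3]

    def test_too_small_tad_is_error(self):
        with pytest.raises(ValueError, match="3 bins"):
            domains.relative_tad_intensity(uniform_matrix(50), 10, 12)


class TestMarkTads:
    def _tads(self):
        return pd.DataFrame(
            {
                "chrom": "chr1",
                "start": [0, 2_000_000],
                "end": [2_000_000, 4_000_000],
                "start_bin": [0, 20],
                "end_bin": [20, 40],
            }
        )

    def test_equal_signal_unmarked(self):
        t = SignalTrack("chr1", 10_000, np.full(400, 5.0))
        flags = domains.mark_tads_by_signal(self._tads(), t, t)
        assert not flags.any()

    def test_enriched_tad_marked(self):
        vals = np.full(400, 5.0)
        chip = vals.copy()
        chip[200:400] *= 2  # second TAD enriched
        flags = domains.mark_tads_by_signal(
            self._tads(),
            SignalTrack("chr1", 10_000, chip),
            SignalTrack("chr1", 10_000, vals),
        )
        assert flags.tolist() == [False, True]

    def test_zero_depth_track_is_error(self):
        t = SignalTrack("chr1", 10_000, np.zeros(400))
        with pytest.raises(ValueError, match="zero-depth"):
            domains.mark_tads_by_signal(self._tads(), t, t)


class TestClassifyReprogramming:
    def test_equal_rti_is_reprogrammed(self):
        assert domains.classify_reprogramming(1.0, 1.0) == "reprogrammed"

    def test_clear_excess_is_unreprogrammed(self):
        assert domains.classify_reprogramming(3.0, 1.0) == "unreprogrammed"

    def test_monotone_in_scnt_rti(self):
        rtis = np.linspace(0.5, 3.0, 20)
        flags = domains.classify_reprogramming(rtis, np.ones(20))
        unrep = flags == "unreprogrammed"
        # once unreprogrammed, stays unreprogrammed as RTI grows
        assert np.all(np.diff(unrep.astype(int)) >= 0)

    def test_nonpositive_reference_is_error(self):
        with pytest.raises(ValueError, match="positive"):
            domains.classify_reprogramming(1.0, 0.0)


class TestRelativeBoundaryDistance:
    def test_on_boundary_zero(self):
        b = np.array([0, 1_000_000, 2_000_000])
        assert domains.relative_boundary_distance((990_000, 1_010_000), b) == 0.0

    def test_tad_center_half(self):
        b = np.array([0, 1_000_000])
        assert domains.relative_boundary_distance((490_000, 510_000), b) == 0.5

    def test_matches_direct_geometry_and_stays_in_range(self):
        rng = np.random.default_rng(47)
        b = np.sort(rng.choice(np.arange(1, 100), size=8, replace=False)) * 1e5
        for _ in range(50):
            mid = rng.uniform(b[0], b[-1])
            got = domains.relative_boundary_distance((mid, mid), b)
            up = b[b <= mid].max() if (b <= mid).any() else b[0]
            down = b[b >= mid].min()
            if up == down:  # exactly on a boundary
                assert got == 0.0
                continue
            expect = min(mid - up, down - mid) / (down - up)
            assert got == pytest.approx(expect)
            assert 0.0 <= got <= 0.5

    def test_outside_all_tads_is_error(self):
        with pytest.raises(ValueError, match="outside"):
            domains.relative_boundary_distance((0, 10), np.array([1e6, 2e6]))

    @settings(deadline=None, derandomize=True)
    @given(
        bounds=st.lists(
            st.integers(min_value=1, max_value=999), min_size=2, max_size=12, unique=True
        ),
        frac=st.floats(min_value=0.0, max_value=1.0),
    )
    def test_always_within_half(self, bounds, frac):
        b = np.sort(np.array(bounds, dtype=float)) * 1e4
        mid = b[0] + frac * (b[-1] - b[0])
        val = domains.relative_boundary_distance((mid, mid), b)
        assert 0.0 <= val <= 0.5


class TestAssignRegions:
    def _df(self, ivs):
        return pd.DataFrame(ivs, columns=["start", "end"])

    def test_region_inside_feature_assigned(self):
        out = domains.assign_regions(self._df([(100, 200)]), self._df([(0, 1000)]))
        assert len(out) == 1

    def test_low_reciprocal_overlap_not_assigned(self):
        # 10% of the region and 10% of the feature
        out = domains.assign_regions(
            self._df([(0, 1000)]), self._df([(900, 1900)])
        )
        assert len(out) == 0

    def test_half_of_feature_only_assigned_either_rule(self):
        # overlap = 50 = 50% of the feature but only 5% of the region
        out = domains.assign_regions(
            self._df([(0, 1000)]), self._df([(950, 1050)])
        )
        assert len(out) == 1
        # under 'both' semantics the same pair fails
        out_both = domains.assign_regions(
            self._df([(0, 1000)]), self._df([(950, 1050)]), mode="both"
        )
        assert len(out_both) == 0

    def test_matches_bedtools_style_brute_force(self):
        rng = np.random.default_rng(48)
        regions = []
        feats = []
        for _ in range(30):
            s = int(rng.integers(0, 10_000))
            regions.append((s, s + int(rng.integers(50, 800))))
            s = int(rng.integers(0, 10_000))
            feats.append((s, s + int(rng.integers(50, 800))))
        out = domains.assign_regions(self._df(regions), self._df(feats), f=0.5)
        got = {(int(r.region_idx), int(r.feature_idx)) for _, r in out.iterrows()}
        expect = set()
        for ri, (rs, re_) in enumerate(regions):
            for fi, (fs, fe) in enumerate(feats):
                ov = min(re_, fe) - max(rs, fs)
                if ov > 0 and (ov / (re_ - rs) >= 0.5 or ov / (fe - fs) >= 0.5):
                    expect.add((ri, fi))
        assert got == expect
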