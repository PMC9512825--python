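import numpy as np
import pandas as pd
import pytest
from scipy import stats

from breakclust.peaks import (AdjustedCurve, GammaNull, adjust_curve,
                              benjamini_hochberg, call_peaks, chi_squared_2x2,
                              count_peak_members, detect_peaks, fit_gamma_null,
                              peak_recurrence_score, single_sample_score)
from breakclust.proximity import ProximityCurve


def curve(positions, values, chrom="chr1"):
    return AdjustedCurve(chrom=chrom, positions=np.asarray(positions, float),
                         values=np.asarray(values, float))


class TestAdjustCurve:
    def _obs(self, pos, smoothed):
        pos = np.asarray(pos, float)
        return ProximityCurve("chr1", pos, smoothed, np.asarray(smoothed),
                              span_alpha=0.2)

    def test_identity_gives_zero(self):
        obs = self._obs([1, 2, 3], np.array([-3.0, -3.5, -4.0]))
        adj = adjust_curve(obs, obs.smoothed)
        assert np.allclose(adj.values, 0.0)

    def test_constant_shift(self, rng):
        sm = -rng.uniform(3, 5, 50)
        obs = self._obs(np.arange(50), sm)
        adj = adjust_curve(obs, sm - 0.7)
        assert np.allclose(adj.values, 0.7)

    def test_random_pair_matches_elementwise_oracle(self, rng):
        sm = -rng.uniform(3, 5, 100)
        exp = -rng.uniform(3, 5, 100)
        obs = self._obs(np.arange(100), sm)
        assert np.allclose(adjust_curve(obs, exp).values, sm - exp)

    def test_misaligned_supports_rejected(self):
        obs = self._obs([1, 2, 3], np.array([-3.0, -3.5, -4.0]))
        with pytest.raises(ValueError):
            adjust_curve(obs, np.zeros(4))


class TestCallPeaks:
    def test_flat_zero_curve_has_no_peaks(self):
        assert call_peaks(curve(np.arange(100), np.zeros(100))) == []

    def test_everywhere_negative_has_no_peaks(self):
        assert call_peaks(curve(np.arange(100), -np.ones(100))) == []

    def test_triangle_region_matches_closed_form(self):
        # apex 1.0 at x=500 over base [0, 1000]: the 75%-of-summit region
        # is [375, 625] with range 250 and area 218.75 (closed form)
        pos = np.arange(0, 1001, dtype=float)
        vals = 1.0 - np.abs(pos - 500) / 500
        pk = call_peaks(curve(pos, vals))
        assert len(pk) == 1
        p = pk[0]
        assert p.start == pytest.approx(375, abs=1)
        assert p.end == pytest.approx(625, abs=1)
        assert p.peak_gr == pytest.approx(250, rel=0.01)
        assert p.peak_area * 1e6 == pytest.approx(218.75, rel=0.01)
        assert p.summit_pos == 500

    def test_two_separated_triangles_in_order(self):
        pos = np.arange(0, 2001, dtype=float)
        v1 = np.clip(1 - np.abs(pos - 400) / 200, 0, None)
        v2 = np.clip(0.5 - np.abs(pos - 1500) / 300, 0, None)
        vals = v1 + v2 - 0.01
        pks = call_peaks(curve(pos, vals))
        assert len(pks) == 2
        assert pks[0].summit_pos < pks[1].summit_pos

    def test_regions_disjoint_inside_excursions(self, rng):
        pos = np.sort(rng.uniform(0, 1e6, 800))
        vals = rng.normal(0, 1, 800)
        pks = call_peaks(curve(pos, vals))
        for a, b in zip(pks, pks[1:]):
            assert a.end <= b.start
        for p in pks:
            assert p.summit_height > 0
            assert p.peak_gr > 0
            assert p.peak_area >= 0


class TestScores:
    def test_prs_worked_example(self):
        prs, sq = peak_recurrence_score(10, 5, 2.0, 1000)
        assert prs == pytest.approx(0.004)
        assert sq == pytest.approx(0.0632456, abs=1e-6)

    def test_prs_collapses_when_every_donor_has_one_sv(self):
        prs, _ = peak_recurrence_score(7, 7, 1.5, 3000)
        assert prs == pytest.approx(1.5 / 3000)

    def test_prs_random_formula_oracle(self, rng):
        for _ in range(100):
            ns, nv = int(rng.integers(1, 50)), int(rng.integers(1, 50))
            a, gr = rng.uniform(0.01, 10), rng.uniform(100, 1e6)
            prs, sq = peak_recurrence_score(ns, nv, a, gr)
            assert prs == (ns / nv) * (a / gr)
            assert sq == np.sqrt(prs)

    def test_prs_error_cases(self):
        with pytest.raises(ValueError):
            peak_recurrence_score(1, 0, 1.0, 100)
        with pytest.raises(ValueError):
            peak_recurrence_score(1, 1, 1.0, 0)

    def test_ssrs_examples_and_oracle(self, rng):
        assert single_sample_score(20, 4) == 5
        with pytest.raises(ValueError):
            single_sample_score(5, 0)
        for _ in range(100):
            nb, ns = int(rng.integers(1, 100)), int(rng.integers(1, 50))
            assert single_sample_score(nb, ns) == nb / ns


class TestGammaNull:
    def test_mle_recovers_shape_within_five_percent(self):
        rng = np.random.default_rng(31)
        x = rng.gamma(2.0, 1.0, size=10_000)
        null = fit_gamma_null(x)
        assert abs(null.shape - 2.0) / 2.0 < 0.05

    def test_largest_value_has_smallest_p(self, rng):
        x = rng.gamma(3, 1, 500)
        null = fit_gamma_null(x)
        p = null.sf(x)
        assert np.argmin(p) == np.argmax(x)

    def test_pit_p_values_are_uniform(self):
        rng = np.random.default_rng(32)
        x = rng.gamma(2.5, 0.8, size=3000)
        null = fit_gamma_null(x)
        assert stats.kstest(null.sf(x), "uniform").pvalue > 0.01

    def test_degenerate_values_rejected(self):
        with pytest.raises(ValueError):
            fit_gamma_null(np.ones(50))

    def test_rate_is_reciprocal_scale(self):
        null = GammaNull(shape=2.0, scale=0.5, n=10)
        assert null.rate == 2.0


class TestBenjaminiHochberg:
    def test_hand_computed_example(self):
        q, flags = benjamini_hochberg([0.001, 0.01, 0.02, 0.9])
        assert np.allclose(q, [0.004, 0.02, 0.0266667, 0.9], atol=1e-6)
        assert flags.tolist() == [True, True, True, False]

    def test_all_ones_flag_nothing(self):
        _, flags = benjamini_hochberg(np.ones(10))
        assert not flags.any()

    def test_single_p_is_identity(self):
        q, _ = benjamini_hochberg([0.01])
        assert q[0] == pytest.approx(0.01)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            benjamini_hochberg([0.5, 1.5])


class TestChiSquared:
    def test_independent_table(self):
        stat, p = chi_squared_2x2([[10, 10], [10, 10]])
        assert stat == 0 and p == 1

    def test_matches_textbook_formula(self, rng):
        for _ in range(50):
            t = rng.integers(1, 50, size=(2, 2)).astype(float)
            stat, _ = chi_squared_2x2(t)
            exp = np.outer(t.sum(1), t.sum(0)) / t.sum()
            assert stat == pytest.approx(np.sum((t - exp) ** 2 / exp))

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            chi_squared_2x2([[0, 0], [1, 2]])


class TestDetectPeaks:
    def _bp(self, positions, donors, svs):
        return pd.DataFrame({"chrom": "chr1", "pos": positions,
                             "donor_id": donors, "sv_id": svs})

    def test_counts_within_region(self):
        pos = np.arange(0, 1001, dtype=float)
        vals = 1.0 - np.abs(pos - 500) / 500
        pk = call_peaks(curve(pos, vals))[0]
        bp = self._bp([400, 450, 500, 800],
                      ["D1", "D1", "D2", "D3"], ["a", "a", "b", "c"])
        counts = count_peak_members(pk, bp)
        assert counts == {"n_smp": 2, "n_sv": 2, "n_bp": 3}

    def test_few_peaks_skip_significance(self, rng):
        pos = np.arange(0, 1001, dtype=float)
        vals = 1.0 - np.abs(pos - 500) / 500
        bp = self._bp([500.0], ["D1"], ["a"])
        out = detect_peaks({"chr1": curve(pos, vals)}, bp)
        assert len(out) == 1
        assert np.isnan(out["p_value"]).all()
        assert not out["recurrent_significant"].any()
        assert out["single_or_two_sample"].all()
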