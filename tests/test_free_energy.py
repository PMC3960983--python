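"""PMF estimation, weights, bin-size sweeps, reweighting and profile
comparison."""

import math

import numpy as np
import pytest

import amdkit as ak
from amdkit.free_energy import (
    bin_size_sweep,
    compare_profiles,
    cumulant_reweight,
    exponential_weights,
    find_minima,
    group_delta_v_by_bin,
    pmf_1d,
    pmf_2d,
    refine_minimum,
    reweight_series,
)


def make_series(values, **kw):
    return ak.RCSeries(values=np.asarray(values, dtype=float), **kw)


class TestExponentialWeights:
    def test_zero_boost_gives_uniform(self, state):
        w = exponential_weights(np.zeros(8), state)
        assert np.allclose(w.weights, 1.0 / 8.0)
        assert w.weights.sum() == pytest.approx(1.0, abs=1e-12)

    def test_closed_form_two_frames(self, state):
        dv = np.array([0.0, state.kt * math.log(2.0)])
        w = exponential_weights(dv, state)
        assert w.weights == pytest.approx([1.0 / 3.0, 2.0 / 3.0])

    def test_large_boost_no_overflow(self, state):
        w = exponential_weights(np.array([0.0, 0.0, 0.0, 500.0]), state)
        assert np.all(np.isfinite(w.weights))
        assert w.weights[3] == pytest.approx(1.0)

    def test_negative_boost_rejected(self, state):
        with pytest.raises(ak.InputError):
            exponential_weights(np.array([0.0, -0.1]), state)


class TestPmf1D:
    def test_uniform_series_flat(self, state):
        rng = np.random.default_rng(0)
        s = make_series(rng.uniform(0.0, 10.0, 200_000))
        prof = pmf_1d(s, 1.0, state)
        assert np.nanmax(prof.free_energy) < 0.05
        assert np.nanmin(prof.free_energy) == 0.0

    def test_two_bin_count_ratio(self, state):
        """Counts 100 vs 10 → ΔF = k_BT·ln 10 ≈ 1.372 kcal/mol at 300 K."""
        s = make_series([0.05] * 100 + [0.15] * 10)
        prof = pmf_1d(s, 0.1, state)
        df = prof.free_energy[1] - prof.free_energy[0]
        assert df == pytest.approx(state.kt * math.log(10.0), abs=1e-12)
        assert df == pytest.approx(1.372, abs=2e-3)

    def test_three_well_defaults_minima(self, ionic_lock_series, state):
        prof = pmf_1d(ionic_lock_series, 0.5, state)
        minima = find_minima(prof, prominence=0.08, min_count=200)
        assert [round(m, 1) for m in minima] == pytest.approx([4.8, 6.2, 14.2], abs=0.5)

    def test_probabilities_sum_to_one_before_log(self, state):
        rng = np.random.default_rng(1)
        s = make_series(rng.normal(5, 1, 5000))
        prof = pmf_1d(s, 0.25, state)
        assert prof.counts.sum() == 5000
        p = np.exp(-prof.free_energy[prof.defined] / state.kt)
        # re-zeroing rescales all probabilities by one constant
        assert p.sum() / p.sum() == 1.0
        assert np.nanmin(prof.free_energy) == 0.0

    def test_single_bin_is_valid_flat_profile(self, state):
        s = make_series([1.01, 1.02, 1.03])
        prof = pmf_1d(s, 0.5, state)
        assert np.nansum(prof.free_energy) == 0.0

    def test_bad_bin_size_rejected(self, state):
        with pytest.raises(ak.ParameterError):
            pmf_1d(make_series([1.0, 2.0]), 0.0, state)

    def test_oracle_equivalence_bit_for_bit(self, state):
        """Independent two-pass loop histogram reproduces pmf_1d exactly."""
        rng = np.random.default_rng(2)
        values = rng.normal(8.0, 2.0, 10_000)
        dv = rng.uniform(0, 2, 10_000)
        for weights in (None, exponential_weights(dv, state)):
            s = make_series(values)
            prof = pmf_1d(s, 0.3, state, weights=weights)
            edges = prof.bin_edges
            n_bins = edges.size - 1
            counts = [0] * n_bins
            mass = [0.0] * n_bins
            w = weights.weights if weights is not None else None
            for j, v in enumerate(values):
                idx = None
                for i in range(n_bins):  # brute-force bin search, last bin closed
                    if edges[i] <= v < edges[i + 1] or (i == n_bins - 1 and v == edges[i + 1]):
                        idx = i
                        break
                counts[idx] += 1
                if w is not None:
                    mass[idx] += w[j]
            if w is None:  # two-pass: count first, divide once
                mass = [c / values.size for c in counts]
            kt = state.kt
            f = np.array([-kt * math.log(m) if m > 0 else math.nan for m in mass])
            f = f - np.nanmin(f)
            ours = prof.free_energy
            assert np.array_equal(prof.counts, np.array(counts, dtype=float))
            same = np.isnan(f) == np.isnan(ours)
            assert same.all()
            assert np.array_equal(f[~np.isnan(f)], ours[~np.isnan(ours)])


class TestPeriodicBinning:
    def test_counts_conserved_under_origin_rotation(self, state):
        rng = np.random.default_rng(3)
        values = rng.uniform(-180.0, 180.0, 20_000)
        s = make_series(values, unit="degree", periodic=True)
        prof = pmf_1d(s, 15.0, state)
        assert prof.counts.sum() == 20_000
        for shift in (30.0, 123.4, -77.7):
            rotated = make_series(values + shift, unit="degree", periodic=True)
            prof_r = pmf_1d(rotated, 15.0, state)
            assert prof_r.counts.sum() == 20_000

    def test_edge_value_180_included(self, state):
        s = make_series([180.0, -180.0, 90.0], unit="degree", periodic=True)
        prof = pmf_1d(s, 90.0, state)
        assert prof.counts.sum() == 3
        # −180 wraps onto the +180 edge of the (−180, 180] interval
        assert np.all(s.values > -180.0) and np.all(s.values <= 180.0)

    def test_non_divisor_bin_size_rejected(self, state):
        s = make_series([0.0, 10.0], unit="degree", periodic=True)
        with pytest.raises(ak.ParameterError):
            pmf_1d(s, 7.0, state)

    @pytest.mark.parametrize("bs", [3.0, 5.0, 6.0, 9.0, 10.0, 12.0, 15.0])
    def test_standard_dihedral_bin_sizes_accepted(self, state, bs):
        s = make_series(np.linspace(-179, 179, 100), unit="degree", periodic=True)
        prof = pmf_1d(s, bs, state)
        assert prof.bin_edges[0] == -180.0 and prof.bin_edges[-1] == 180.0


class TestPmf2D:
    def test_independent_uniform_flat(self, state):
        rng = np.random.default_rng(4)
        sx = make_series(rng.uniform(-180, 180, 400_000), unit="degree", periodic=True)
        sy = make_series(rng.uniform(-180, 180, 400_000), unit="degree", periodic=True)
        prof = pmf_2d(sx, sy, 30.0, state)
        assert np.nanmax(prof.free_energy) < 0.15

    def test_single_cluster_minimum_location(self, state):
        rng = np.random.default_rng(5)
        sx = make_series(rng.normal(-75, 8, 50_000), unit="degree", periodic=True)
        sy = make_series(rng.normal(40, 8, 50_000), unit="degree", periodic=True)
        prof = pmf_2d(sx, sy, 6.0, state)
        mx, my = prof.min_location()
        assert abs(mx - (-75.0)) <= 6.0 and abs(my - 40.0) <= 6.0

    def test_three_cluster_depths_recovered(self, state):
        """Population ratios set ≈2 and ≈3 kcal/mol offsets; recovered ≤0.2."""
        chi1, chi2 = ak.synth_dihedral_pairs(n_frames=200_000, rng_seed=6)
        prof = pmf_2d(chi1, chi2, 6.0, state)
        cx, cy = prof.centers

        def depth_near(x0, y0, win=18.0):
            ix = np.abs(cx - x0) <= win
            iy = np.abs(cy - y0) <= win
            block = prof.free_energy[np.ix_(ix, iy)]
            return np.nanmin(block)

        assert depth_near(-75, 40) == pytest.approx(0.0, abs=1e-9)
        assert depth_near(-165, 40) == pytest.approx(2.0, abs=0.2)
        assert depth_near(-160, -100) == pytest.approx(3.0, abs=0.2)

    def test_length_mismatch_rejected(self, state):
        with pytest.raises(ak.InputError):
            pmf_2d(make_series([1.0, 2.0]), make_series([1.0]), 1.0, state)


class TestBinSizeSweep:
    def test_undersampling_inflates_deviation(self, state):
        gen = lambda n, seed: ak.synth_rc_series(n_frames=n, rng_seed=seed)
        rich = bin_size_sweep(gen(100_000, 1), (0.1, 0.2, 0.3, 0.4, 0.5), state)
        poor = bin_size_sweep(gen(50, 1), (0.1, 0.2, 0.3, 0.4, 0.5), state)
        assert poor.max_deviation > rich.max_deviation

    def test_single_size_rejected(self, state, ionic_lock_series):
        with pytest.raises(ak.ParameterError):
            bin_size_sweep(ionic_lock_series, (0.1,), state)

    def test_report_serialises(self, state, ionic_lock_series, tmp_path):
        rep = bin_size_sweep(ionic_lock_series, (0.2, 0.4), state)
        rep.to_json(tmp_path / "sweep.json")
        assert (tmp_path / "sweep.json").exists()
        assert len(rep.profiles) == 2 and rep.max_deviation >= 0.0


class TestReweighting:
    def test_constant_boost_is_absorbed_by_rezeroing(self, state):
        rng = np.random.default_rng(7)
        values = rng.normal(5, 1, 20_000)
        s_plain = make_series(values)
        s_boosted = make_series(values, delta_v=np.full(values.size, 3.21))
        base = pmf_1d(s_plain, 0.2, state)
        for method in ("exponential", "cumulant1", "cumulant2"):
            rw = reweight_series(s_boosted, 0.2, state, method)
            assert compare_profiles(base, rw) < 1e-9

    def test_gaussian_boost_order2_matches_exponential(self, state):
        """ln⟨e^{βΔV}⟩ = β⟨ΔV⟩ + β²σ²/2 for Gaussian ΔV with σ ≤ k_BT."""
        rng = np.random.default_rng(8)
        n = 200_000
        values = rng.normal(5, 1, n)
        sigma = state.kt
        dv = np.clip(rng.normal(3.0 + 0.3 * values, sigma), 0.0, None)
        s = make_series(values, delta_v=dv)
        exp = reweight_series(s, 0.2, state, "exponential")
        cum2 = reweight_series(s, 0.2, state, "cumulant2")
        # compare where both are defined and well sampled
        base = pmf_1d(s, 0.2, state)
        mask = base.defined & (base.counts >= 500) & exp.defined & cum2.defined
        fe = exp.free_energy[mask]
        fc = cum2.free_energy[mask]
        assert np.max(np.abs((fe - fe.min()) - (fc - fc.min()))) < 0.1

    def test_heavy_tailed_boost_estimators_diverge(self, state):
        """Lognormal ΔV: the order-2 cumulant and the exponential estimator
        disagree — the documented noise failure mode."""
        rng = np.random.default_rng(9)
        n = 100_000
        values = rng.normal(5, 1, n)
        # coordinate-dependent, strongly skewed boost, capped so that the
        # exponential estimator keeps more than one populated bin
        dv = np.clip(0.4 * values * rng.lognormal(0.0, 1.0, n), 0.0, 6.0)
        s = make_series(values, delta_v=dv)
        exp = reweight_series(s, 0.2, state, "exponential")
        cum2 = reweight_series(s, 0.2, state, "cumulant2")
        assert compare_profiles(exp, cum2) > 0.2

    def test_unsupported_order_rejected(self, state, ionic_lock_series):
        base = pmf_1d(ionic_lock_series, 0.5, state)
        dv_by_bin = [np.ones(3)] * base.free_energy.size
        with pytest.raises(ak.ParameterError):
            cumulant_reweight(base, dv_by_bin, order=3, state=state)

    def test_sparse_bins_skipped_and_flagged(self, state):
        values = np.array([0.05] * 50 + [0.15])  # second bin: one ΔV sample
        s = make_series(values, delta_v=np.abs(np.sin(np.arange(51))))
        base = pmf_1d(s, 0.1, state)
        grouped = group_delta_v_by_bin(s, base)
        rw = cumulant_reweight(base, grouped, order=2, state=state)
        assert "skipped_bins" in rw.metadata
        assert np.isnan(rw.free_energy[1])

    def test_missing_delta_v_rejected(self, state):
        with pytest.raises(ak.InputError):
            reweight_series(make_series([1.0, 2.0]), 0.1, state, "exponential")


class TestCompareProfiles:
    def test_self_comparison_zero(self, state, ionic_lock_series):
        prof = pmf_1d(ionic_lock_series, 0.2, state)
        assert compare_profiles(prof, prof) == 0.0

    def test_constant_shift_invisible(self, state, ionic_lock_series):
        prof = pmf_1d(ionic_lock_series, 0.2, state)
        import copy

        shifted = copy.deepcopy(prof)
        shifted.free_energy = shifted.free_energy + 0.7
        assert compare_profiles(prof, shifted) == pytest.approx(0.0, abs=1e-12)

    def test_disjoint_supports_rejected(self, state):
        a = pmf_1d(make_series([1.0, 1.1, 1.2]), 0.1, state)
        b = pmf_1d(make_series([9.0, 9.1, 9.2]), 0.1, state)
        with pytest.raises(ak.ComparisonError):
            compare_profiles(a, b)


def test_refine_minimum_parabolic_vertex(state):
    rng = np.random.default_rng(10)
    s = make_series(rng.normal(6.37, 0.8, 300_000))
    prof = pmf_1d(s, 0.2, state)
    assert refine_minimum(prof, 6.0) == pytest.approx(6.37, abs=0.05)
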