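"""Imaginary-coherence estimators: identities, cluster averaging,
baselining, band/period aggregation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.linalg import hadamard

from betacoh import expected_imcoh, generate_recording
from betacoh.connectivity import (
    BANDS,
    LEFT_M1,
    RIGHT_M1,
    ClusterDef,
    band_period_average,
    band_rows,
    baseline_subtract,
    cluster_imcoh,
    imcoh_across_trials,
    imcoh_within_trial,
    percent_change,
)
from betacoh.preprocess import epoch
from betacoh.synth import MixingModel, OscillatorParams
from betacoh.timefreq import RESTING_GRID_MS, build_bank, make_grid, transform

from .conftest import make_tfr


def _lagged_tfr(lag: float, n_trials: int = 8, n_f: int = 3, n_g: int = 5,
                rng=None):
    """Two channels with a constant phase lag across trials (noise-free)."""
    rng = rng or np.random.default_rng(0)
    theta = rng.uniform(0, 2 * np.pi, size=(n_trials, 1, 1))
    xi = np.exp(1j * np.broadcast_to(theta, (n_trials, n_f, n_g)))
    xj = xi * np.exp(-1j * lag)
    vals = np.stack([xi, xj], axis=1)
    return make_tfr(vals)


class TestAcrossTrials:
    def test_self_coherence_zero(self, rng):
        vals = rng.standard_normal((6, 2, 4, 5)) + 1j * rng.standard_normal((6, 2, 4, 5))
        m = imcoh_across_trials(make_tfr(vals), 0, 0)
        assert np.allclose(m.values, 0.0)

    def test_quadrature_lag_is_one(self):
        m = imcoh_across_trials(_lagged_tfr(np.pi / 2), 0, 1)
        assert np.allclose(m.values, 1.0, atol=1e-12)

    def test_symmetry(self, rng):
        vals = rng.standard_normal((7, 2, 3, 4)) + 1j * rng.standard_normal((7, 2, 3, 4))
        a = imcoh_across_trials(make_tfr(vals), 0, 1).values
        b = imcoh_across_trials(make_tfr(vals), 1, 0).values
        assert np.allclose(a, b)

    def test_needs_two_trials(self, rng):
        vals = rng.standard_normal((1, 2, 3, 4)) * (1 + 0j)
        with pytest.raises(ValueError):
            imcoh_across_trials(make_tfr(vals), 0, 1)

    def test_zero_autospectrum_emits_nan_with_warning(self):
        vals = np.zeros((3, 2, 2, 2), dtype=complex)
        vals[:, 0] = 1.0
        with pytest.warns(RuntimeWarning):
            m = imcoh_across_trials(make_tfr(vals), 0, 1)
        assert np.isnan(m.values).all()

    def test_rescaling_invariance(self, rng):
        vals = rng.standard_normal((9, 2, 3, 4)) + 1j * rng.standard_normal((9, 2, 3, 4))
        scaled = vals.copy()
        scaled[:, 0] *= 7.3
        a = imcoh_across_trials(make_tfr(vals), 0, 1).values
        b = imcoh_across_trials(make_tfr(scaled), 0, 1).values
        assert np.allclose(a, b)

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=30, deadline=None)
    def test_unbaselined_values_in_unit_interval(self, seed):
        r = np.random.default_rng(seed)
        vals = r.standard_normal((5, 2, 3, 4)) + 1j * r.standard_normal((5, 2, 3, 4))
        m = imcoh_across_trials(make_tfr(vals), 0, 1)
        ok = np.isfinite(m.values)
        assert np.all(m.values[ok] >= 0) and np.all(m.values[ok] <= 1)


class TestWithinTrial:
    def test_self_coherence_zero(self, rng):
        vals = rng.standard_normal((4, 1, 3, 6)) + 1j * rng.standard_normal((4, 1, 3, 6))
        v = imcoh_within_trial(make_tfr(vals), 0, 0, (400.0, 520.0))
        assert np.allclose(v, 0.0)

    def test_single_point_window_rejected(self, rng):
        vals = (rng.standard_normal((4, 2, 3, 6)) * (1 + 0j))
        with pytest.raises(ValueError):
            imcoh_within_trial(make_tfr(vals), 0, 1, (400.0, 401.0))

    def test_quadrature_lag_one_per_trial(self):
        # phase advances within trial, lag constant: e^{i w t} vs e^{i(w t - pi/2)}
        n_t, n_f, n_g = 5, 2, 8
        t = np.arange(n_g)
        xi = np.exp(1j * (0.7 * t[None, None, :] + np.arange(n_t)[:, None, None]))
        xj = xi * np.exp(-1j * np.pi / 2)
        tfr = make_tfr(np.stack([xi, xj], axis=1))
        v = imcoh_within_trial(tfr, 0, 1, (400.0, 400.0 + 20.0 * n_g))
        assert np.allclose(v, 1.0)


class TestClusterImcoh:
    def _full_tfr(self, rng, n_trials=6, n_f=2, n_g=4):
        vals = rng.standard_normal((n_trials, 14, n_f, n_g)) \
            + 1j * rng.standard_normal((n_trials, 14, n_f, n_g))
        names = list(LEFT_M1.members) + list(RIGHT_M1.members)
        return make_tfr(vals, ch_names=names)

    def test_overlapping_clusters_rejected(self, rng):
        tfr = self._full_tfr(rng)
        bad = ClusterDef("bad", LEFT_M1.members[:6] + (RIGHT_M1.members[0],))
        with pytest.raises(ValueError):
            cluster_imcoh(tfr, LEFT_M1, bad)

    def test_all_pairs_identical_mean_equals_single_pair(self):
        n_trials = 8
        rng = np.random.default_rng(3)
        theta = rng.uniform(0, 2 * np.pi, size=(n_trials, 1, 1))
        xi = np.exp(1j * np.broadcast_to(theta, (n_trials, 2, 3)))
        vals = np.stack([xi] * 7 + [xi * np.exp(-1j * 1.0)] * 7, axis=1)
        names = list(LEFT_M1.members) + list(RIGHT_M1.members)
        tfr = make_tfr(vals, ch_names=names)
        m = cluster_imcoh(tfr, apply_edge_mask=False)
        single = imcoh_across_trials(tfr, 0, 7)
        assert np.allclose(m.values, single.values)
        assert np.allclose(m.values, abs(np.sin(1.0)), atol=1e-12)

    def test_one_quadrature_pair_among_49_gives_1_over_49(self):
        """Hadamard construction: channel C3 carries +/-1 with sign sequence
        h1, channel C4 carries -i times the same sequence, every other
        channel a different orthogonal +/-1 sequence. Exactly the (C3, C4)
        pair has unit imaginary coherence; all other pairs are exactly 0."""
        H = hadamard(16).astype(float)
        n_trials = 16
        rows = [H[k + 1] for k in range(14)]  # orthogonal, non-constant
        vals = np.empty((n_trials, 14, 1, 2), dtype=complex)
        for c in range(14):
            vals[:, c, 0, :] = rows[c][:, None]
        vals[:, 0, 0, :] = rows[0][:, None]            # C3: real
        vals[:, 7, 0, :] = -1j * rows[0][:, None]      # C4: quadrature partner
        names = list(LEFT_M1.members) + list(RIGHT_M1.members)
        tfr = make_tfr(vals, ch_names=names)
        m = cluster_imcoh(tfr, apply_edge_mask=False)
        assert np.allclose(m.values, 1.0 / 49.0, atol=1e-12)

    def test_cluster_order_symmetry(self, rng):
        tfr = self._full_tfr(rng)
        a = cluster_imcoh(tfr, LEFT_M1, RIGHT_M1, apply_edge_mask=False).values
        b = cluster_imcoh(tfr, RIGHT_M1, LEFT_M1, apply_edge_mask=False).values
        assert np.allclose(a, b)


class TestVolumeConductionAndRecovery:
    def test_zero_lag_leakage_suppressed(self):
        """With full leakage both clusters are zero-lag copies of one shared
        source; across-trial ImCoh at the carrier must stay below 0.05."""
        osc = OscillatorParams(phi=np.pi / 2, kappa=4.0)
        mix = MixingModel(leakage=1.0, snr=1.0)
        rec = generate_recording(("p", "sham", "pre"), "resting", osc, mix,
                                 n_trials=500, seed=21)
        ep = epoch(rec, "resting")
        bank = build_bank()
        k20 = int(np.flatnonzero(bank.freqs == 20.0)[0])
        from betacoh.timefreq import WaveletBank

        sub = WaveletBank(bank.freqs[k20:k20 + 1], bank.cycles[k20:k20 + 1])
        tfr = transform(ep, sub, make_grid(RESTING_GRID_MS))
        m = imcoh_across_trials(tfr, "C3", "C4")
        assert np.nanmean(m.values) < 0.05

    def test_carrier_recovery_within_jackknife_tolerance(self):
        from betacoh.validation import carrier_recovery

        for kappa in (1.0, 4.0):
            r = carrier_recovery(np.pi / 2, kappa, n_trials=300, seed=5)
            assert abs(r["estimate"] - r["expected"]) < 3 * r["se"]
            assert r["expected"] == pytest.approx(expected_imcoh(np.pi / 2, kappa))


class TestBaselineAndAggregation:
    def _map(self, values, grid0=-2000.0):
        from betacoh.connectivity import ImCohMap

        n_f, n_g = values.shape
        return ImCohMap(
            values=values, freqs=np.arange(4.0, 4.0 + n_f),
            grid_ms=grid0 + 20.0 * np.arange(n_g), estimator="across-trial",
        )

    def test_constant_map_baselines_to_zero(self):
        m = self._map(np.full((3, 301), 0.4))
        out = baseline_subtract(m)
        assert np.allclose(out.values, 0.0)

    def test_offset_window_shows_offset(self):
        vals = np.full((2, 301), 0.2)
        grid = -2000.0 + 20.0 * np.arange(301)
        vals[:, grid >= 0] += 0.1
        out = baseline_subtract(self._map(vals))
        assert np.allclose(out.values[:, grid >= 0], 0.1)
        assert np.allclose(out.values[:, grid < -1000.0], 0.0)

    def test_baseline_idempotent(self, rng):
        m = self._map(rng.random((4, 301)))
        once = baseline_subtract(m)
        twice = baseline_subtract(once)
        assert np.allclose(once.values, twice.values)

    def test_missing_baseline_window_rejected(self, rng):
        m = self._map(rng.random((2, 10)), grid0=0.0)
        with pytest.raises(ValueError):
            baseline_subtract(m)

    def test_band_bin_counts(self):
        freqs = np.arange(4.0, 91.0)
        assert len(band_rows(freqs, "beta")) == 18   # 13..30 Hz inclusive
        assert len(band_rows(freqs, "theta")) == 4
        assert len(band_rows(freqs, "alpha")) == 5
        assert len(band_rows(freqs, "gamma")) == 31

    def test_uniform_map_band_average(self):
        vals = np.full((87, 301), 0.37)
        m = self._map(vals)
        for band in BANDS:
            assert band_period_average(m, band, (0.0, 500.0)) == pytest.approx(0.37)

    def test_unknown_band_rejected(self):
        m = self._map(np.zeros((87, 301)))
        with pytest.raises(KeyError):
            band_period_average(m, "delta", (0.0, 500.0))


class TestPercentChange:
    def test_arithmetic(self):
        assert percent_change(0.10, 0.12) == pytest.approx(20.0)
        assert percent_change(-0.10, -0.12) == pytest.approx(-20.0)

    def test_near_zero_reference_flagged(self):
        assert np.isnan(percent_change(0.0, 0.5))
        assert np.isnan(percent_change(1e-12, 0.5))
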