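"""Signed r², band selection, CSP, ratio-of-medians, log-var, NIRS stats."""

import numpy as np
import pytest
from scipy import linalg, signal

from hybridbci.features import (BandSpec, bandpass_epochs, csp_fit,
                                csp_logvar, nirs_mean_slope,
                                ratio_of_medians, select_band,
                                sgn_r2_band_map, signed_r_squared)
from hybridbci.preproc import EpochSet

MA_BL = np.array(["MA", "MA", "BL", "BL"])


class TestSignedRSquared:
    def test_perfect_separation_is_plus_one(self):
        assert signed_r_squared([1, 1, 0, 0], MA_BL) == pytest.approx(1.0)

    def test_reversed_sign(self):
        assert signed_r_squared([0, 0, 1, 1], MA_BL) == pytest.approx(-1.0)

    def test_balanced_overlap_is_zero(self):
        labels = np.array(["MA", "BL", "BL", "MA"])
        assert signed_r_squared([1, 0, 1, 0], labels) == pytest.approx(0.0)

    def test_identical_distributions_zero(self):
        vals = [1.0, 2.0, 1.0, 2.0]
        assert signed_r_squared(vals, MA_BL) == pytest.approx(0.0)

    def test_point_biserial_identity(self):
        """sgn r² = sign(Δm)·Δm²·n1·n0 / (n²·s²_total) (brute-force check)."""
        rng = np.random.default_rng(0)
        vals = rng.normal(size=30)
        labels = np.where(rng.random(30) < 0.5, "MA", "BL")
        if len(set(labels)) < 2:
            labels[0], labels[1] = "MA", "BL"
        y = (labels == "MA")
        n1, n0, n = y.sum(), (~y).sum(), len(y)
        dm = vals[y].mean() - vals[~y].mean()
        s2 = vals.var()
        expected = np.sign(dm) * dm ** 2 * n1 * n0 / (n ** 2 * s2)
        assert signed_r_squared(vals, labels) == pytest.approx(expected)

    def test_errors(self):
        with pytest.raises(ValueError):
            signed_r_squared([1, 2], np.array(["MA", "MA"]))
        with pytest.raises(ValueError):
            signed_r_squared([1, 1, 1, 1], MA_BL)


def _alpha_epochs(n_trials=24, f_hz=10.0, attenuation=0.6, seed=0,
                  n_ch=4, rate=200.0, n_samp=2000):
    """Epochs whose only class difference is amplitude at ``f_hz``."""
    rng = np.random.default_rng(seed)
    labels = np.array((["MA", "BL"] * n_trials)[:n_trials])
    t = np.arange(n_samp) / rate
    data = rng.standard_normal((n_trials, n_ch, n_samp)) * 0.3
    for i, lab in enumerate(labels):
        amp = 1.0 - attenuation * (lab == "MA")
        phase = rng.uniform(0, 2 * np.pi)
        data[i] += amp * np.sin(2 * np.pi * f_hz * t + phase)
    return EpochSet(data, labels, (0.0, 10.0), rate, "EEG")


class TestSelectBand:
    def test_band_contains_discriminative_frequency(self):
        ep = _alpha_epochs()
        band = select_band(ep)
        assert band.f_low <= 10.0 <= band.f_high
        # endpoints snap to the 0.5 Hz grid
        assert band.f_low * 2 == int(band.f_low * 2)
        assert band.f_high * 2 == int(band.f_high * 2)

    def test_zero_effect_falls_back_to_full_range(self):
        rng = np.random.default_rng(1)
        base = rng.standard_normal((6, 3, 1000))
        data = np.concatenate([base, base])        # identical classes
        labels = np.array(["MA"] * 6 + ["BL"] * 6)
        ep = EpochSet(data, labels, (0.0, 5.0), 200.0, "EEG")
        band = select_band(ep)
        assert band.as_tuple() == (4.0, 35.0)

    def test_train_only_no_leakage(self):
        """Changing held-out trials cannot move the selected band."""
        ep = _alpha_epochs(seed=2)
        train = np.arange(16)
        band1 = select_band(ep, train_idx=train)
        tampered = ep.data.copy()
        tampered[16:] = np.random.default_rng(99).normal(
            size=tampered[16:].shape) * 50
        ep2 = EpochSet(tampered, ep.labels, ep.window_s, ep.rate_hz)
        band2 = select_band(ep2, train_idx=train)
        assert band1.as_tuple() == band2.as_tuple()

    def test_requires_trials_per_class(self):
        ep = _alpha_epochs(n_trials=4)
        with pytest.raises(ValueError):
            select_band(ep, train_idx=np.array([0, 1]))


def _two_class_gaussian_epochs(cov1, cov2, n_per_class=30, n_samp=500,
                               seed=0):
    rng = np.random.default_rng(seed)
    n_ch = cov1.shape[0]
    l1 = np.linalg.cholesky(cov1)
    l2 = np.linalg.cholesky(cov2)
    d1 = np.einsum("ij,tjs->tis", l1,
                   rng.standard_normal((n_per_class, n_ch, n_samp)))
    d2 = np.einsum("ij,tjs->tis", l2,
                   rng.standard_normal((n_per_class, n_ch, n_samp)))
    data = np.concatenate([d1, d2])
    labels = np.array(["MA"] * n_per_class + ["BL"] * n_per_class)
    return EpochSet(data, labels, (0.0, 2.5), 200.0, "EEG")


class TestCSP:
    def test_identical_generators_give_half_eigenvalues(self):
        cov = np.eye(3)
        ep = _two_class_gaussian_epochs(cov, cov, seed=3)
        model = csp_fit(ep)
        assert np.allclose(model.eigenvalues, 0.5, atol=0.05)

    def test_analytic_two_channel_case(self):
        """Variances diag(4,1) vs diag(1,4) -> λ = 0.8 and 0.2."""
        ep = _two_class_gaussian_epochs(np.diag([4.0, 1.0]),
                                        np.diag([1.0, 4.0]),
                                        n_per_class=60, n_samp=2000, seed=4)
        model = csp_fit(ep)
        assert model.eigenvalues[0] == pytest.approx(0.8, abs=0.02)
        assert model.eigenvalues[-1] == pytest.approx(0.2, abs=0.02)

    def test_whitening_identity(self):
        ep = _two_class_gaussian_epochs(np.diag([4.0, 1.0, 2.0]),
                                        np.diag([1.0, 4.0, 2.0]), seed=5)
        y = ep.y()
        from hybridbci.features import _class_covariances
        s1, s2 = _class_covariances(ep.data, y)
        model = csp_fit(ep)
        W = model.filters
        assert np.allclose(W.T @ (s1 + s2) @ W, np.eye(3), atol=1e-6)

    def test_eigenvalues_sorted_and_bounded(self):
        ep = _two_class_gaussian_epochs(np.diag([3.0, 1.0, 0.5, 2.0]),
                                        np.eye(4), seed=6)
        model = csp_fit(ep)
        lam = model.eigenvalues
        assert np.all(np.diff(lam) <= 1e-12)
        assert np.all((lam >= 0) & (lam <= 1))

    def test_oracle_whiten_then_rotate_equivalence(self):
        """Generalised-eigen CSP == explicit whiten-then-rotate construction."""
        rng = np.random.default_rng(7)
        for _ in range(20):
            n_ch = rng.integers(2, 7)
            a1 = rng.standard_normal((n_ch, n_ch))
            a2 = rng.standard_normal((n_ch, n_ch))
            s1 = a1 @ a1.T + 0.1 * np.eye(n_ch)
            s2 = a2 @ a2.T + 0.1 * np.eye(n_ch)
            s1 /= np.trace(s1)
            s2 /= np.trace(s2)
            lam, W = linalg.eigh(s1, s1 + s2)
            # oracle: whiten composite, then eigendecompose whitened s1
            d, U = np.linalg.eigh(s1 + s2)
            P = U / np.sqrt(d)
            lam_o, R = np.linalg.eigh(P.T @ s1 @ P)
            assert np.allclose(np.sort(lam), np.sort(lam_o), atol=1e-10)
            W_o = P @ R
            for k in range(n_ch):
                w = W[:, np.argsort(lam)][:, k]
                wo = W_o[:, k]
                cos = abs(w @ wo) / (np.linalg.norm(w) * np.linalg.norm(wo))
                assert cos == pytest.approx(1.0, abs=1e-8)

    def test_too_few_trials(self):
        ep = _two_class_gaussian_epochs(np.eye(2), np.eye(2), n_per_class=1)
        with pytest.raises(ValueError):
            csp_fit(ep)


class TestRatioOfMedians:
    def test_four_to_one(self):
        var = np.array([[4.0], [4.0], [4.0], [1.0], [1.0], [1.0]])
        labels = np.array(["MA"] * 3 + ["BL"] * 3)
        assert ratio_of_medians(var, labels)[0] == pytest.approx(0.8)

    def test_equal_medians_half(self):
        var = np.array([[2.0], [2.0], [2.0], [2.0]])
        assert ratio_of_medians(var, MA_BL)[0] == pytest.approx(0.5)

    def test_outlier_robustness_vs_mean_score(self):
        """One extreme trial moves a mean-based score, not the median one."""
        var = np.array([[1.0], [1.1], [0.9], [1.0], [1.05], [0.95]])
        labels = np.array(["MA"] * 3 + ["BL"] * 3)
        base = ratio_of_medians(var, labels)[0]
        var_out = var.copy()
        var_out[0, 0] = 1000.0                      # median unchanged
        assert ratio_of_medians(var_out, labels)[0] == pytest.approx(
            ratio_of_medians(np.array([[1.1], [1.1], [0.9], [1.0], [1.05],
                                       [0.95]]), labels)[0], abs=0.06)
        m = var_out[:3].mean() / (var_out[:3].mean() + var_out[3:].mean())
        assert abs(m - base) > 0.3                  # the mean score collapses

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            ratio_of_medians(np.ones((3, 2)), np.array(["MA"] * 3))


class TestCspLogvar:
    def _fitted(self):
        ep = _two_class_gaussian_epochs(
            np.diag([4.0, 1.0, 2.0, 3.0, 1.5, 2.5, 0.5]),
            np.diag([1.0, 4.0, 2.0, 0.5, 2.5, 1.5, 3.0]),
            n_per_class=20, seed=8)
        return ep, csp_fit(ep)

    def test_six_features(self):
        ep, model = self._fitted()
        fm = csp_logvar(ep, model)
        assert fm.values.shape == (40, 6)
        assert len(fm.names) == 6
        assert fm.modality == "EEG"

    def test_scaling_shifts_unnormalized_logvar(self):
        ep, model = self._fitted()
        c = 3.0
        f1 = csp_logvar(ep.data, model, labels=ep.labels, normalize=False)
        f2 = csp_logvar(c * ep.data, model, labels=ep.labels,
                        normalize=False)
        assert np.allclose(f2.values - f1.values, 2 * np.log(c), atol=1e-9)

    def test_normalized_logvar_scale_invariant(self):
        ep, model = self._fitted()
        f1 = csp_logvar(ep.data, model, labels=ep.labels)
        f2 = csp_logvar(5.0 * ep.data, model, labels=ep.labels)
        assert np.allclose(f1.values, f2.values, atol=1e-9)

    def test_zero_epoch_is_flagged_error(self):
        ep, model = self._fitted()
        data = ep.data.copy()
        data[0] = 0.0
        with pytest.raises(ValueError, match="constant-zero"):
            csp_logvar(data, model, labels=ep.labels)


class TestNirsMeanSlope:
    def test_constant_series(self):
        data = np.full((5, 9, 63), 2.5)
        ep = EpochSet(data, np.array(["MA", "BL"] * 2 + ["MA"]),
                      (10.0, 15.0), 12.5, "HbO")
        fm = nirs_mean_slope(ep)
        assert fm.values.shape == (5, 18)
        assert np.allclose(fm.values[:, :9], 2.5)
        assert np.allclose(fm.values[:, 9:], 0.0, atol=1e-12)

    def test_linear_series_recovers_slope(self):
        a = 0.73
        t = np.arange(63) / 12.5
        data = np.tile(a * t, (4, 9, 1))
        ep = EpochSet(data, MA_BL, (10.0, 15.0), 12.5, "HbR")
        fm = nirs_mean_slope(ep, "HbR")
        assert np.allclose(fm.values[:, 9:], a, atol=1e-10)

    def test_short_window_rejected(self):
        ep = EpochSet(np.zeros((2, 9, 2)), np.array(["MA", "BL"]),
                      (0.0, 0.16), 12.5, "HbO")
        with pytest.raises(ValueError):
            nirs_mean_slope(ep)


class TestSgnR2BandMap:
    def test_shape_and_columns(self):
        ep = _alpha_epochs(n_ch=10)
        table = sgn_r2_band_map(ep)
        assert table.shape == (10, 5)
        assert list(table.columns) == ["theta", "alpha", "low_beta",
                                       "high_beta", "gamma"]

    def test_alpha_attenuation_shows_negative_alpha_entries(self):
        ep = _alpha_epochs(n_trials=40, attenuation=0.6, seed=9)
        table = sgn_r2_band_map(ep)
        assert (table["alpha"] < 0).all()          # MA < BL at 8-13 Hz
        assert table["gamma"].abs().max() < table["alpha"].abs().min()

    def test_null_data_near_zero(self):
        rng = np.random.default_rng(10)
        data = rng.standard_normal((40, 4, 1000))
        labels = np.array(["MA", "BL"] * 20)
        ep = EpochSet(data, labels, (0.0, 5.0), 200.0, "EEG")
        table = sgn_r2_band_map(ep)
        # permutation 95 % bound for r² with n=40 is ~ 0.1
        assert table.abs().values.max() < 0.25

    def test_band_outside_nyquist_rejected(self):
        ep = _alpha_epochs()
        with pytest.raises(ValueError):
            sgn_r2_band_map(ep, bands={"bad": (30.0, 150.0)})


class TestBandpassEpochs:
    def test_preserves_structure(self):
        ep = _alpha_epochs()
        out = bandpass_epochs(ep, BandSpec(8.0, 13.0))
        assert out.data.shape == ep.data.shape
        assert list(out.labels) == list(ep.labels)
        # narrowband retains the 10 Hz line, kills broadband noise power
        assert out.data.var() < ep.data.var()
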