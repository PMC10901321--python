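"""Noise covariance, the six combination methods, and the decision tree."""

import numpy as np
import pytest

from mcmrs.combine import (
    CombinationContext,
    CombinationWeights,
    NoiseCovariance,
    SensitivityEstimate,
    aoc_combine,
    apply_weights,
    estimate_noise_covariance,
    estimate_sensitivities,
    select_method,
    weights_equal,
    weights_sn2,
    weights_snr,
    wsvd_combine,
)
from mcmrs.core import AcquisitionSet, fid_to_spectrum
from mcmrs.quantify import DampedExponentialModel
from mcmrs.simulate import ArraySpec, make_channels

from conftest import FS, N_POINTS


def noise_scan(rng, n_ch=8, n_pts=4000, chol=None):
    z = (rng.standard_normal((n_ch, n_pts)) + 1j * rng.standard_normal((n_ch, n_pts))) / np.sqrt(2)
    if chol is not None:
        z = chol @ z
    return AcquisitionSet(data=z[:, None, :], sampling_frequency=FS, center_frequency=1e8)


class TestNoiseCovariance:
    def test_iid_noise_gives_identity(self, rng):
        # complex sample covariance at n=4000, 8 channels: expected Frobenius
        # error is sqrt(64/n) ~ 0.13; 0.2 leaves comfortable headroom
        cov = estimate_noise_covariance(None, noise_scan(rng), kind="plain")
        err = np.linalg.norm(cov.matrix - np.eye(8))
        assert err < 0.2

    def test_duplicated_channel_detected(self, rng):
        scan = noise_scan(rng, n_ch=3)
        data = scan.data.copy()
        data[1] = data[0]
        dup = AcquisitionSet(data=data, sampling_frequency=FS, center_frequency=1e8)
        full = estimate_noise_covariance(None, dup, kind="full_correlation")
        assert abs(full.matrix[0, 1]) == pytest.approx(1.0, abs=1e-12)
        plain = estimate_noise_covariance(None, dup, kind="plain")
        assert np.linalg.matrix_rank(plain.matrix, tol=1e-8) < 3

    def test_too_few_samples_rejected(self, rng):
        with pytest.raises(ValueError, match="noise samples"):
            estimate_noise_covariance(None, noise_scan(rng, n_ch=8, n_pts=15))

    def test_spectral_region_estimate_matches_scan_scale(self, rng, clean_fid):
        # white channel noise: spectral-domain covariance over the last bins
        # is N x the time-domain covariance (unnormalised DFT)
        sigma = 2.0
        data = np.stack([clean_fid] * 4) + sigma / np.sqrt(2) * (
            rng.standard_normal((4, N_POINTS)) + 1j * rng.standard_normal((4, N_POINTS))
        )
        acq = AcquisitionSet(data=data[:, None, :], sampling_frequency=FS, center_frequency=1e8)
        cov = estimate_noise_covariance(acq, ("last", 400), kind="plain")
        expected = N_POINTS * sigma**2
        np.testing.assert_allclose(
            np.diag(cov.matrix).real, expected, rtol=0.35
        )

    def test_whitening_normalises_correlated_noise(self, rng):
        # property: whitening with the Cholesky factor of the estimated
        # covariance turns the sample covariance into the identity
        C = np.full((8, 8), 0.3) + 0.7 * np.eye(8)
        chol = np.linalg.cholesky(C)
        scan = noise_scan(rng, chol=chol)
        cov = estimate_noise_covariance(None, scan, kind="plain")
        L = np.linalg.cholesky(cov.matrix)
        # whiten rows of the (points x channels) sample matrix: X @ L^{-H},
        # matching the estimator's C_jk = E[x_j^* x_k] convention
        X = scan.data[:, 0, :].T
        import scipy.linalg

        Xw = scipy.linalg.solve_triangular(L, X.conj().T, lower=True).conj().T
        emp = Xw.conj().T @ Xw / Xw.shape[0]
        assert np.linalg.norm(emp - np.eye(8)) < 0.02


class TestScalarWeights:
    def test_equal_weights(self):
        np.testing.assert_allclose(weights_equal(1).w, [1.0])
        np.testing.assert_allclose(weights_equal(4).w, [0.25] * 4)

    def test_equal_combination_of_identical_channels_reproduces_single(self, clean_fid):
        acq = make_channels(clean_fid, ArraySpec(scale_factors=np.ones(4)), FS)
        combined = weights_equal(4).w @ acq.data[:, 0, :]
        np.testing.assert_allclose(combined, clean_fid, rtol=1e-12)

    def test_snr_weights_proportional_and_normalised(self):
        w = weights_snr([2.0, 1.0]).w
        np.testing.assert_allclose(w, [2 / 3, 1 / 3])
        assert weights_snr([1.0, 0.0, 1.0]).w[1] == 0

    def test_all_zero_snr_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            weights_snr([0.0, 0.0])

    def test_sn2_conjugate_phases_add_constructively(self, clean_fid):
        # channels with phases (0, pi/2): the conjugate weights realign them
        acq_data = np.stack([clean_fid, clean_fid * np.exp(1j * np.pi / 2)])
        w = weights_sn2([(1.0, 0.0), (1.0, np.pi / 2)], [1.0, 1.0])
        combined = w.w @ acq_data
        # pre-normalisation the combined peak would be 2x a single channel;
        # with unit-norm weights the gain is sqrt(2)
        np.testing.assert_allclose(combined, np.sqrt(2) * clean_fid, rtol=1e-12)

    def test_sn2_weight_scales_inversely_with_variance(self):
        w1 = weights_sn2([(1.0, 0.0), (1.0, 0.0)], [1.0, 1.0]).w
        w2 = weights_sn2([(1.0, 0.0), (1.0, 0.0)], [1.0, 2.0]).w
        # doubling channel 2's variance halves its weight relative to channel 1
        assert abs(w2[1] / w2[0]) == pytest.approx(0.5 * abs(w1[1] / w1[0]), rel=1e-12)

    def test_sn2_nonpositive_variance_rejected(self):
        with pytest.raises(ValueError, match="> 0"):
            weights_sn2([(1.0, 0.0)], [0.0])


class TestApplyWeights:
    def test_identity_zero_and_linearity(self, clean_fid, rng):
        spec = fid_to_spectrum(clean_fid, FS)
        assert np.array_equal(
            apply_weights([spec], CombinationWeights(w=[1.0], method="equal")).values,
            spec.values,
        )
        zero = apply_weights(
            [spec, spec], CombinationWeights(w=[0.0, 0.0], method="equal")
        )
        assert not np.any(zero.values)
        w = CombinationWeights(w=rng.standard_normal(2) + 0j, method="equal")
        a = apply_weights([spec, spec], w)
        scaled = spec.copy_with(3.0 * spec.values)
        b = apply_weights([scaled, scaled], w)
        np.testing.assert_allclose(b.values, 3.0 * a.values, rtol=1e-12)

    def test_count_mismatch_rejected(self, clean_fid):
        spec = fid_to_spectrum(clean_fid, FS)
        with pytest.raises(ValueError, match="weights"):
            apply_weights([spec], CombinationWeights(w=[1.0, 1.0], method="equal"))


class TestWsvd:
    def identity_cov(self, n=8):
        return NoiseCovariance(matrix=np.eye(n), n_samples_used=10**6)

    def test_noiseless_rank_one_quality_and_ratio(self, eight_channel_clean, two_peak_model):
        combined, w = wsvd_combine(eight_channel_clean, self.identity_cov())
        assert w.quality == pytest.approx(1.0, abs=1e-12)
        res = DampedExponentialModel(combined, FS).fit(two_peak_model)
        assert res.area_ratio(0, 1) == pytest.approx(1.0, abs=1e-6)

    def test_recovers_conjugate_sensitivities_up_to_phase(self, clean_fid):
        # closed form: for rank-1 data X = fid s^T with identity covariance the
        # leading right singular vector is conj(s)/||s|| up to a global phase
        s = np.array([1.0, 0.8j, -0.5, 0.3 - 0.4j, 0.9, 0.6, 0.7j, 0.93])
        acq = AcquisitionSet(
            data=(s[:, None] * clean_fid[None, :])[:, None, :],
            sampling_frequency=FS,
            center_frequency=1e8,
        )
        _, w = wsvd_combine(acq, self.identity_cov())
        expected = s.conj() / np.linalg.norm(s)
        phase = w.w[0] / expected[0]
        np.testing.assert_allclose(w.w, expected * phase, atol=1e-10)
        assert abs(abs(phase) - 1.0) < 1e-10

    def test_quality_decreases_with_noise_power(self, eight_channel_clean, rng):
        qs = []
        for sigma in (5.0, 20.0, 80.0):
            level_qs = []
            for _ in range(60):
                noise = sigma / np.sqrt(2) * (
                    rng.standard_normal((8, N_POINTS))
                    + 1j * rng.standard_normal((8, N_POINTS))
                )
                acq = AcquisitionSet(
                    data=(eight_channel_clean.data[:, 0, :] + noise)[:, None, :],
                    sampling_frequency=FS,
                    center_frequency=1e8,
                )
                _, w = wsvd_combine(
                    acq, NoiseCovariance(matrix=sigma**2 * np.eye(8), n_samples_used=10**6)
                )
                level_qs.append(w.quality)
            qs.append(np.mean(level_qs))
        assert qs[0] < 1.0
        assert qs[0] > qs[1] > qs[2]

    def test_apodized_weights_applied_to_unapodized_data(self, eight_channel_clean):
        plain, _ = wsvd_combine(eight_channel_clean, self.identity_cov(), apod_lb=0.0)
        apod, _ = wsvd_combine(eight_channel_clean, self.identity_cov(), apod_lb=5.0)
        # noiseless rank-1 data: both estimate the same weights, and the
        # combined FID must NOT carry the apodization decay
        np.testing.assert_allclose(np.abs(apod), np.abs(plain), rtol=1e-8)

    def test_all_zero_data_rejected(self):
        acq = AcquisitionSet(
            data=np.zeros((4, 1, 64), dtype=complex) + 0j,
            sampling_frequency=FS,
            center_frequency=1e8,
        )
        with pytest.raises(ValueError, match="zero"):
            wsvd_combine(acq, self.identity_cov(4))

    def test_singular_covariance_regularized_with_warning(self, eight_channel_clean):
        mat = np.eye(8)
        mat[7, 7] = 0.0
        cov = NoiseCovariance(matrix=mat, n_samples_used=100)
        with pytest.warns(UserWarning, match="ridge"):
            combined, _ = wsvd_combine(eight_channel_clean, cov)
        assert np.all(np.isfinite(combined))


class TestSensitivities:
    def test_scaled_copies_recover_scales(self, clean_fid):
        c = np.array([1.0, 0.8, 0.5, 0.93])
        acq = make_channels(clean_fid, ArraySpec(scale_factors=c), FS)
        sens = estimate_sensitivities(acq)
        ratio = sens.s / sens.s[0]
        np.testing.assert_allclose(ratio.real, c / c[0], rtol=1e-10)
        np.testing.assert_allclose(ratio.imag, 0.0, atol=1e-10)

    def test_channel_phase_rotates_estimate(self, clean_fid):
        phases = np.array([0.0, 0.0, 0.7, 0.0])
        acq = make_channels(
            clean_fid, ArraySpec(scale_factors=np.ones(4), channel_phases=phases), FS
        )
        sens = estimate_sensitivities(acq)
        assert np.angle(sens.s[2] / sens.s[0]) == pytest.approx(0.7, abs=1e-10)

    def test_noisy_estimate_within_five_percent(self, clean_fid, rng):
        c = np.array([1.0, 0.8, 0.7, 0.6, 0.5, 0.65, 0.9, 0.93])
        errs = []
        for _ in range(100):
            noise = 0.35 * (
                rng.standard_normal((8, N_POINTS)) + 1j * rng.standard_normal((8, N_POINTS))
            )
            acq = AcquisitionSet(
                data=(c[:, None] * clean_fid[None, :] + noise)[:, None, :],
                sampling_frequency=FS,
                center_frequency=1e8,
            )
            s = estimate_sensitivities(acq).s
            scale = (s.conj() @ c) / (s.conj() @ s)
            errs.append(np.max(np.abs(s * scale - c) / np.abs(c)))
        assert np.median(errs) < 0.05

    def test_noise_only_flagged_low_confidence(self, rng):
        acq = noise_scan(rng, n_ch=4, n_pts=2048)
        with pytest.warns(UserWarning, match="low-confidence"):
            sens = estimate_sensitivities(acq)
        assert sens.low_confidence


class TestAoc:
    def test_identity_correlation_reduces_to_conjugate_weighting(self):
        s = np.array([1.0, 0.5j, -0.3, 0.8])
        sens = SensitivityEstimate(s=s)
        cov = NoiseCovariance(matrix=np.eye(4), n_samples_used=10**6)
        acq = AcquisitionSet(
            data=np.ones((4, 1, 64), dtype=complex),
            sampling_frequency=FS,
            center_frequency=1e8,
        )
        _, w = aoc_combine(acq, sens, cov)
        expected = s.conj() / np.linalg.norm(s)
        np.testing.assert_allclose(w.w, expected, atol=1e-12)

    def test_beats_random_weight_vectors(self, rng):
        # brute-force optimality oracle on random 4-channel instances:
        # output SNR^2 = |w^T s|^2 / (w^T R w*) for noise covariance R
        for _ in range(10):
            A = rng.standard_normal((4, 4)) + 1j * rng.standard_normal((4, 4))
            R = A @ A.conj().T + 0.1 * np.eye(4)
            s = rng.standard_normal(4) + 1j * rng.standard_normal(4)
            cov = NoiseCovariance(matrix=R, n_samples_used=10**6)
            acq = AcquisitionSet(
                data=np.ones((4, 1, 64), dtype=complex),
                sampling_frequency=FS,
                center_frequency=1e8,
            )
            _, wts = aoc_combine(acq, SensitivityEstimate(s=s), cov)

            def snr2(w):
                gain = abs(w @ s) ** 2
                noise = np.real(w @ R @ w.conj())
                return gain / noise

            best_random = max(
                snr2(v / np.linalg.norm(v))
                for v in (
                    rng.standard_normal((200, 4)) + 1j * rng.standard_normal((200, 4))
                )
            )
            assert snr2(wts.w) >= best_random - 1e-9

    def test_noiseless_rank_one_area_ratio(self, eight_channel_clean, two_peak_model):
        sens = SensitivityEstimate(s=np.array(ArraySpec().sensitivities))
        cov = NoiseCovariance(matrix=np.eye(8), n_samples_used=10**6)
        combined, _ = aoc_combine(eight_channel_clean, sens, cov)
        res = DampedExponentialModel(combined, FS).fit(two_peak_model)
        assert res.area_ratio(0, 1) == pytest.approx(1.0, abs=1e-6)

    def test_dimension_mismatch_rejected(self, eight_channel_clean):
        sens = SensitivityEstimate(s=np.ones(4))
        cov = NoiseCovariance(matrix=np.eye(4), n_samples_used=10**6)
        with pytest.raises(ValueError, match="channel"):
            aoc_combine(eight_channel_clean, sens, cov)


class TestDecisionTree:
    def ctx(self, **kw):
        base = dict(
            has_water_or_prominent_ref=False,
            has_noise_region_or_scan=False,
            channels_correlated=False,
            est_combined_snr=None,
            channels_phased=False,
        )
        base.update(kw)
        return CombinationContext(**base)

    def test_water_plus_noise_info_selects_aoc(self):
        method, why = select_method(
            self.ctx(has_water_or_prominent_ref=True, has_noise_region_or_scan=True)
        )
        assert method == "aoc"
        assert "water" in why

    def test_mid_snr_without_water_selects_apodized_wsvd(self):
        method, why = select_method(
            self.ctx(has_noise_region_or_scan=True, est_combined_snr=20.0)
        )
        assert method == "wsvd_apod"
        assert "15" in why

    def test_high_snr_without_water_selects_wsvd(self):
        method, _ = select_method(
            self.ctx(has_noise_region_or_scan=True, est_combined_snr=50.0)
        )
        assert method == "wsvd"

    def test_reference_only_high_snr_selects_sn2(self):
        method, _ = select_method(
            self.ctx(has_water_or_prominent_ref=True, est_combined_snr=80.0)
        )
        assert method == "sn2"

    def test_nothing_available_falls_back_to_equal(self):
        method, why = select_method(self.ctx())
        assert method == "equal"
        assert "fallback" in why

    def test_always_returns_a_method(self):
        import itertools

        for water, noise, corr, phased, snr in itertools.product(
            [False, True], [False, True], [False, True], [False, True],
            [None, 5.0, 20.0, 50.0, 80.0],
        ):
            method, why = select_method(
                self.ctx(
                    has_water_or_prominent_ref=water,
                    has_noise_region_or_scan=noise,
                    channels_correlated=corr,
                    channels_phased=phased,
                    est_combined_snr=snr,
                )
            )
            assert method in ("equal", "snr", "sn2", "wsvd", "wsvd_apod", "aoc")
            assert isinstance(why, str) and why
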