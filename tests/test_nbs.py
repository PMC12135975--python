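"""Unit tests for the backscattering fixed-window-scan ratio pipeline."""

import numpy as np
import pytest
from scipy import integrate

from crystalkin.core_models import HBAR_UEV_NS
from crystalkin.nbs import (FWSFrame, LinewidthProfile, ResolutionModel,
                            analyze_fws_dataset, convolved_lorentzian,
                            elastic_fraction, fit_gamma_q, gamma_from_ratio,
                            linewidth_profile, lorentzian, nbs_crystal_fraction,
                            ratio_from_gamma, read_fws_frames, subtract_solvent,
                            write_fws_frames)
from crystalkin.synthetic import gen_fws_dataset

RES = ResolutionModel(0.9)


class TestRatioInversion:
    def test_closed_form_algebra(self):
        # R = 5 with offsets (1, 3): gamma^2 = (9 - 5)/(5 - 1) = 1
        assert gamma_from_ratio(5.0, 1.0) == pytest.approx(1.0, abs=1e-12)

    def test_limits(self):
        # R near (omega3/omega1)^2 -> gamma -> 0; R near 1 -> gamma -> inf
        assert gamma_from_ratio(8.9999, 1.0) < 0.02
        assert gamma_from_ratio(1.0001, 1.0) > 100.0

    def test_round_trip_identity_closed_form(self):
        gammas = np.geomspace(0.05, 20.0, 200)
        R = ratio_from_gamma(gammas)
        back = gamma_from_ratio(R, np.ones_like(R))
        np.testing.assert_allclose(back, gammas, rtol=1e-10)

    def test_out_of_window_raises(self):
        with pytest.raises(ValueError):
            gamma_from_ratio(0.5, 1.0)
        with pytest.raises(ValueError):
            gamma_from_ratio(10.0, 1.0)

    def test_out_of_window_nan_mode(self):
        g = gamma_from_ratio(np.array([5.0, 10.0]), np.array([1.0, 1.0]),
                             out_of_window="nan")
        assert np.isfinite(g[0]) and np.isnan(g[1])

    def test_ratio_monotone_decreasing_in_gamma(self):
        gammas = np.geomspace(0.02, 50.0, 300)
        for res in (None, RES):
            r = np.array([ratio_from_gamma(g, resolution=res) for g in gammas])
            assert np.all(np.diff(r) < 0)

    def test_convolved_inversion_recovers_gamma(self):
        # intensities synthesized from a Gaussian-convolved Lorentzian,
        # inverted with the resolution-aware branch
        for g_true in (0.3, 1.0, 2.0, 8.0):
            I1 = convolved_lorentzian(1.0, g_true, RES)
            I3 = convolved_lorentzian(3.0, g_true, RES)
            g = gamma_from_ratio(I1, I3, resolution=RES)
            assert g == pytest.approx(g_true, rel=1e-6)

    def test_closed_form_bias_on_convolved_data(self):
        # applying the pure-Lorentzian formula to resolution-broadened
        # intensities shows a quantifiable bias
        g_true = 2.0
        I1 = convolved_lorentzian(1.0, g_true, RES)
        I3 = convolved_lorentzian(3.0, g_true, RES)
        g_closed = gamma_from_ratio(I1, I3)
        assert abs(g_closed - g_true) > 0.01


def test_voigt_matches_quadrature_oracle():
    # the convolution is evaluated against direct numerical quadrature of
    # the Lorentzian-times-Gaussian integral
    for omega in (0.0, 1.0, 3.0):
        for gamma in (0.2, 1.0, 5.0):
            num, _ = integrate.quad(
                lambda x: lorentzian(omega - x, gamma) * RES(x),
                -np.inf, np.inf, limit=400)
            assert convolved_lorentzian(omega, gamma, RES) == pytest.approx(
                num, rel=1e-8)


class TestGammaQFit:
    def make_profile(self, D=4.0, c=0.3, noise=0.0, seed=None):
        q = np.arange(0.2, 1.901, 0.05)
        gamma = HBAR_UEV_NS * D * q**2 + c
        if noise:
            rng = np.random.default_rng(seed)
            gamma = gamma * (1 + rng.normal(0, noise, q.shape))
        return LinewidthProfile(0.0, q, gamma,
                                np.maximum(noise * gamma, 1e-6))

    def test_exact_recovery(self):
        res = fit_gamma_q(self.make_profile())
        assert res["D"] == pytest.approx(4.0, rel=1e-10)
        assert res["c"] == pytest.approx(0.3, abs=1e-10)

    def test_unit_conversion_hand_check(self):
        # D = 4 A^2/ns at q = 1 1/A contributes hbar*D*q^2 = 2.633 ueV
        assert HBAR_UEV_NS * 4.0 == pytest.approx(2.633, abs=1e-3)

    def test_noisy_recovery(self):
        res = fit_gamma_q(self.make_profile(noise=0.05, seed=2))
        assert res["D"] == pytest.approx(4.0, rel=0.05)
        assert abs(res["c"] - 0.3) < 0.1

    def test_needs_four_points(self):
        q = np.array([0.5, 0.7, 0.9])
        prof = LinewidthProfile(0.0, q, HBAR_UEV_NS * 4 * q**2)
        with pytest.raises(ValueError):
            fit_gamma_q(prof)

    def test_negative_diffusion_flagged(self):
        q = np.arange(0.4, 1.41, 0.1)
        prof = LinewidthProfile(0.0, q, 2.0 - 0.5 * q**2)
        assert "negative-D" in fit_gamma_q(prof)["flags"]


class TestElasticFraction:
    def make_frame(self, elastic, quasi, gamma, counts=None, seed=None):
        q = np.arange(0.2, 1.901, 0.05)
        gamma = np.broadcast_to(gamma, q.shape)
        I0 = elastic * RES(0.0) + quasi * convolved_lorentzian(0.0, gamma, RES)
        I1 = elastic * RES(1.0) + quasi * convolved_lorentzian(1.0, gamma, RES)
        I3 = elastic * RES(3.0) + quasi * convolved_lorentzian(3.0, gamma, RES)
        if counts:
            rng = np.random.default_rng(seed)
            I0, I1, I3 = (rng.poisson(I * counts).astype(float)
                          for I in (I0, I1, I3))
            s0, s1, s3 = (np.sqrt(np.maximum(I, 1)) for I in (I0, I1, I3))
            return FWSFrame(0.0, q, I0, I1, I3, s0, s1, s3), gamma
        return FWSFrame(0.0, q, I0, I1, I3), gamma

    def test_purely_elastic(self):
        frame, gamma = self.make_frame(elastic=1.0, quasi=0.0, gamma=1.5)
        s_fws, c_e, _ = elastic_fraction(frame, gamma, RES)
        np.testing.assert_allclose(s_fws, 0.0, atol=1e-10)
        np.testing.assert_allclose(c_e, frame.I0 / RES(0.0), rtol=1e-10)

    def test_purely_quasielastic(self):
        frame, gamma = self.make_frame(elastic=0.0, quasi=1.0, gamma=1.5)
        s_fws, c_e, _ = elastic_fraction(frame, gamma, RES)
        np.testing.assert_allclose(c_e, 0.0, atol=1e-10)
        np.testing.assert_allclose(s_fws, 1.0, rtol=1e-10)

    def test_mixture_recovery_with_poisson_noise(self):
        frame, gamma = self.make_frame(elastic=0.4, quasi=0.6, gamma=1.5,
                                       counts=1e4, seed=9)
        s_fws, c_e, _ = elastic_fraction(frame, gamma, RES)
        assert np.mean(s_fws) / 1e4 == pytest.approx(0.6, rel=0.05)
        assert np.mean(c_e) / 1e4 == pytest.approx(0.4, rel=0.05)


class TestSolventSubtraction:
    def make(self, scale=1.0):
        q = np.arange(0.2, 1.0, 0.1)
        protein = FWSFrame(0.0, q, 4 * np.ones_like(q), 2 * np.ones_like(q),
                           1 * np.ones_like(q))
        solvent = FWSFrame(0.0, q, 1 * np.ones_like(q),
                           0.5 * np.ones_like(q), 0.2 * np.ones_like(q))
        mix = FWSFrame(0.0, q, protein.I0 + scale * solvent.I0,
                       protein.I1 + scale * solvent.I1,
                       protein.I3 + scale * solvent.I3)
        return protein, solvent, mix

    def test_zero_scale_is_identity(self):
        _, solvent, mix = self.make()
        out = subtract_solvent(mix, solvent, scale=0.0)
        np.testing.assert_allclose(out.I0, mix.I0)

    def test_full_subtraction_of_itself_gives_zero(self):
        _, solvent, _ = self.make()
        out = subtract_solvent(solvent, solvent, scale=1.0)
        assert np.all(out.I0 == 0) and np.all(out.I1 == 0)

    def test_protein_recovered_at_correct_scale(self):
        protein, solvent, mix = self.make(scale=0.9)
        out = subtract_solvent(mix, solvent, scale=0.9)
        np.testing.assert_allclose(out.I0, protein.I0, rtol=1e-12)
        np.testing.assert_allclose(out.I3, protein.I3, rtol=1e-12)

    def test_grid_mismatch_rejected(self):
        _, solvent, mix = self.make()
        other = FWSFrame(0.0, solvent.q + 0.01, solvent.I0, solvent.I1,
                         solvent.I3)
        with pytest.raises(ValueError):
            subtract_solvent(mix, other)


class TestCrystalFraction:
    def test_constant_series_flagged(self):
        t = np.arange(0, 20.0, 1.0)
        q = np.arange(1.0, 1.9, 0.1)
        ce = np.ones((t.size, q.size))
        _, fit = nbs_crystal_fraction(t, ce, q)
        assert "degenerate-normalization" in fit.flags

    def test_container_constant_removed_and_recovery(self):
        rng = np.random.default_rng(5)
        t = np.arange(0, 80.1, 0.5)
        q = np.arange(1.0, 1.85, 0.05)
        sig = 0.5 / (1 + np.exp(-(t - 40.0) / 11.5))
        ce = (0.2 + sig)[:, None] * np.ones(q.size)
        ce = ce + rng.normal(0, 0.03 * 0.5, ce.shape)
        c_nbs, fit = nbs_crystal_fraction(t, ce, q)
        assert c_nbs[-1] == pytest.approx(1.0, abs=1e-12)  # by construction
        assert abs(fit["t0_1"] - 40.0) <= 2 * max(fit.error("t0_1"), 0.5)
        assert abs(fit["dt_1"] - 11.5) <= 2 * max(fit.error("dt_1"), 0.5)

    def test_empty_q_window_rejected(self):
        t = np.arange(0, 10.0, 1.0)
        q = np.array([0.3, 0.5])
        with pytest.raises(ValueError):
            nbs_crystal_fraction(t, np.ones((t.size, q.size)), q)


def test_end_to_end_fws_movie():
    # a full synthetic movie: slowly decreasing D, sigmoidal elastic
    # fraction; the pipeline recovers both generator curves
    frames, truth = gen_fws_dataset(seed=6)
    kin = analyze_fws_dataset(frames)
    D_true = truth.params["D"]
    assert np.median(np.abs(kin.D - D_true) / D_true) < 0.05
    assert kin.D[0] > kin.D[-1]  # slight slowing down, as generated
    assert abs(kin.fit["t0_1"] - 40.0) < 1.0
    assert abs(kin.fit["dt_1"] - 11.48) < 1.0


def test_linewidth_profile_masks_invalid_points():
    q = np.arange(0.2, 1.0, 0.1)
    I1 = np.full_like(q, 2.0)
    I3 = np.full_like(q, 1.0)
    I3[3] = 3.0  # ratio < 1: out of window at this q
    frame = FWSFrame(0.0, q, np.full_like(q, 5.0), I1, I3)
    prof = linewidth_profile(frame)
    assert not prof.valid[3]
    assert np.all(prof.valid[np.arange(q.size) != 3])


def test_fws_csv_round_trip(tmp_path):
    frames, _ = gen_fws_dataset(times_h=[0.0, 1.0], seed=1)
    path = tmp_path / "fws.csv"
    write_fws_frames(path, frames)
    back = read_fws_frames(path)
    assert len(back) == 2
    np.testing.assert_allclose(back[0].I1, frames[0].I1)
    np.testing.assert_allclose(back[1].q, frames[1].q)
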