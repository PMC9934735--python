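"""Diffusion math: schedules, forward/posterior/reverse consistency,
loss, sampling loop contracts, and the variational NLL."""

import numpy as np
import pytest

from gcdiff.diffusion import (NoiseSchedule, NoisySample, diffusion_loss,
                              forward_sample, make_schedule, nll,
                              posterior_params, predict_clean, reverse_step,
                              sample_molecules, transition_coeffs)
from gcdiff.mol import Molecule, SizeDistribution, remove_com


class ZeroModel:
    """Degenerate denoiser predicting zero noise (shape/loop contracts)."""

    vocab = ("H", "C", "N", "O", "F")

    def predict(self, zx, zh, seg, t_frac, cond=None):
        return np.zeros_like(zx), np.zeros_like(zh)


class TestSchedule:
    @pytest.mark.parametrize("kind", ["polynomial", "cosine"])
    def test_variance_preserving_identity(self, kind):
        sch = make_schedule(kind, T=1000)
        assert np.abs(sch.alphas**2 + sch.sigmas**2 - 1).max() < 1e-10

    @pytest.mark.parametrize("kind", ["polynomial", "cosine"])
    def test_endpoints_and_monotonicity(self, kind):
        sch = make_schedule(kind, T=500, precision=1e-5)
        assert sch.alphas[0] >= 1 - 2e-5
        assert sch.alphas[-1] < 0.01
        assert np.all(np.diff(sch.alphas) <= 1e-12)

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            make_schedule("linear", T=10)


class TestTransitions:
    def test_base_case_from_zero(self):
        sch = make_schedule("polynomial", T=100)
        c = transition_coeffs(sch, 0, 40)
        assert c.alpha_ts == pytest.approx(sch.alphas[40] / sch.alphas[0])

    def test_quotient_formula(self):
        # α_t = 0.8, α_s = 0.9 → α_{t|s} = 0.8889
        sch = NoiseSchedule(T=2, alphas=np.array([1.0, 0.9, 0.8]),
                            sigmas=np.sqrt(1 - np.array([1.0, 0.81, 0.64])))
        c = transition_coeffs(sch, 1, 2)
        assert c.alpha_ts == pytest.approx(0.8889, abs=1e-4)

    def test_s_not_less_than_t_rejected(self):
        sch = make_schedule("polynomial", T=10)
        with pytest.raises(ValueError):
            transition_coeffs(sch, 5, 5)

    def test_gaussian_composition_reproduces_closed_form(self):
        """Two-stage noising 0→s→t must match the direct 0→t marginal."""
        sch = make_schedule("polynomial", T=100)
        rng = np.random.default_rng(0)
        s, t = 30, 70
        z0 = 1.7
        c0s = transition_coeffs(sch, 0, s)
        cst = transition_coeffs(sch, s, t)
        c0t = transition_coeffs(sch, 0, t)
        n = 100_000
        zs = c0s.alpha_ts * z0 + c0s.sigma_ts * rng.standard_normal(n)
        zt = cst.alpha_ts * zs + cst.sigma_ts * rng.standard_normal(n)
        se_mean = c0t.sigma_ts / np.sqrt(n)
        assert abs(zt.mean() - c0t.alpha_ts * z0) < 4 * se_mean
        assert abs(zt.std() - c0t.sigma_ts) < 4 * se_mean


class TestForward:
    def _z0(self, rng, n=4, f=6):
        return NoisySample(zx=remove_com(rng.normal(size=(n, 3))),
                           zh=rng.normal(size=(n, f)), t=0)

    def test_moments_match_closed_form(self):
        sch = make_schedule("polynomial", T=100)
        rng = np.random.default_rng(1)
        z0 = self._z0(rng)
        c = transition_coeffs(sch, 0, 60)
        n = 10_000
        draws = np.array([forward_sample(z0, 60, sch, rng)[0].zh
                          for _ in range(n)])
        se_mean = c.sigma_ts / np.sqrt(n)
        se_std = c.sigma_ts / np.sqrt(2 * n)
        assert np.abs(draws.mean(axis=0) - c.alpha_ts * z0.zh).max() < 5 * se_mean
        assert np.abs(draws.std(axis=0) - c.sigma_ts).max() < 5 * se_std

    def test_coordinates_stay_on_subspace(self):
        sch = make_schedule("polynomial", T=50)
        rng = np.random.default_rng(2)
        z0 = self._z0(rng)
        for t in (1, 25, 50):
            zt, (ex, _) = forward_sample(z0, t, sch, rng)
            assert np.abs(zt.zx.mean(axis=0)).max() < 1e-8
            assert np.abs(ex.mean(axis=0)).max() < 1e-10

    def test_uncentered_input_rejected(self):
        with pytest.raises(ValueError):
            NoisySample(zx=np.ones((3, 3)), zh=np.zeros((3, 1)), t=0)


class TestPosterior:
    def test_matches_1d_grid_bayes_oracle(self):
        """Numeric Bayes: prior q(z_s|z_0) × likelihood q(z_t|z_s)."""
        sch = make_schedule("polynomial", T=100)
        s, t = 20, 55
        z0v, ztv = 0.8, -0.4
        grid = np.linspace(-8, 8, 400_001)
        c0s = transition_coeffs(sch, 0, s)
        cst = transition_coeffs(sch, s, t)
        prior = np.exp(-(grid - c0s.alpha_ts * z0v) ** 2
                       / (2 * c0s.sigma_ts**2))
        lik = np.exp(-(ztv - cst.alpha_ts * grid) ** 2 / (2 * cst.sigma_ts**2))
        post = prior * lik
        post /= post.sum()
        mu_oracle = (grid * post).sum()
        sd_oracle = np.sqrt(((grid - mu_oracle) ** 2 * post).sum())

        z0 = NoisySample(zx=np.zeros((1, 3)), zh=np.array([[z0v]]), t=0)
        zt = NoisySample(zx=np.zeros((1, 3)), zh=np.array([[ztv]]), t=t)
        (mu_x, mu_h), sigma = posterior_params(zt, z0, s, t, sch)
        assert mu_h[0, 0] == pytest.approx(mu_oracle, abs=1e-6)
        assert sigma == pytest.approx(sd_oracle, abs=1e-6)

    def test_deterministic_endpoint_when_sigma_s_zero(self):
        sch = NoiseSchedule(T=2, alphas=np.array([1.0, 0.9, 0.6]),
                            sigmas=np.array([0.0, np.sqrt(1 - 0.81),
                                             np.sqrt(1 - 0.36)]))
        z0 = NoisySample(zx=np.zeros((1, 3)), zh=np.array([[2.0]]), t=0)
        zt = NoisySample(zx=np.zeros((1, 3)), zh=np.array([[-1.0]]), t=1)
        (_, mu_h), sigma = posterior_params(zt, z0, 0, 1, sch)
        assert mu_h[0, 0] == pytest.approx(1.0 * 2.0)
        assert sigma == pytest.approx(0.0)

    def test_coefficient_identity_on_equal_inputs(self):
        """μ(z0 = zt = v) = c·v with c from the two weights directly."""
        sch = make_schedule("cosine", T=80)
        s, t = 10, 60
        c = transition_coeffs(sch, s, t)
        c0s = transition_coeffs(sch, 0, s)
        c0t = transition_coeffs(sch, 0, t)
        w0 = c0s.alpha_ts * c.sigma_ts**2 / c0t.sigma_ts**2
        wt = c.alpha_ts * c0s.sigma_ts**2 / c0t.sigma_ts**2
        v = 1.3
        z = NoisySample(zx=np.zeros((1, 3)), zh=np.array([[v]]), t=0)
        zt = NoisySample(zx=np.zeros((1, 3)), zh=np.array([[v]]), t=t)
        (_, mu_h), _ = posterior_params(zt, z, s, t, sch)
        assert mu_h[0, 0] == pytest.approx((w0 + wt) * v, abs=1e-12)


class TestPredictClean:
    def test_inverts_forward_sample_at_machine_precision(self):
        sch = make_schedule("polynomial", T=200)
        rng = np.random.default_rng(3)
        z0 = NoisySample(zx=remove_com(rng.normal(size=(5, 3))),
                         zh=rng.normal(size=(5, 6)), t=0)
        for t in (1, 100, 200):
            zt, eps = forward_sample(z0, t, sch, rng)
            back = predict_clean(zt, eps, t, sch)
            assert np.abs(back.zx - z0.zx).max() < 1e-8
            assert np.abs(back.zh - z0.zh).max() < 1e-8

    def test_scalar_example(self):
        # z_t = 1.0, α = 0.5, σ = 0.8660, ε̂ = 0.2 → z̃_0 = 1.6536
        sch = NoiseSchedule(T=1, alphas=np.array([1.0, 0.5]),
                            sigmas=np.array([0.0, 0.86602540]))
        zt = NoisySample(zx=np.zeros((1, 3)), zh=np.array([[1.0]]), t=1)
        out = predict_clean(zt, (np.zeros((1, 3)), np.array([[0.2]])), 1, sch)
        assert out.zh[0, 0] == pytest.approx(1.6536, abs=1e-4)


class TestReverseStep:
    def test_two_moment_recovery_with_oracle_denoiser(self):
        """Gaussian data + the optimal (posterior-mean) ε̂ oracle: the full
        reverse chain must reproduce the data's first two moments."""
        T = 50
        sch = make_schedule("polynomial", T=T)
        m0, s0 = 0.7, 0.3
        rng = np.random.default_rng(4)

        def eps_opt(z, t):
            c = transition_coeffs(sch, 0, t)
            a, s = c.alpha_ts, c.sigma_ts
            x_post = m0 + (a * s0**2 / (a**2 * s0**2 + s**2)) * (z - a * m0)
            return (z - a * x_post) / s

        n = 4000
        samples = np.empty(n)
        for i in range(n):
            z = NoisySample(zx=np.zeros((1, 3)),
                            zh=rng.standard_normal((1, 1)), t=T)
            for t in range(T, 1, -1):
                e = (np.zeros((1, 3)), eps_opt(z.zh, t))
                z = reverse_step(z, e, t - 1, t, sch, rng)
            z = predict_clean(z, (np.zeros((1, 3)), eps_opt(z.zh, 1)), 1, sch)
            samples[i] = z.zh[0, 0]
        assert abs(samples.mean() - m0) < 4 * s0 / np.sqrt(n)
        assert abs(samples.std() - s0) < 0.03

    def test_noise_free_step_is_posterior_mean(self):
        sch = make_schedule("polynomial", T=20)
        rng = np.random.default_rng(5)
        z0 = NoisySample(zx=remove_com(rng.normal(size=(3, 3))),
                         zh=rng.normal(size=(3, 2)), t=0)
        zt, eps = forward_sample(z0, 10, sch, rng)
        zs = reverse_step(zt, eps, 4, 10, sch, rng, add_noise=False)
        z0t = predict_clean(zt, eps, 10, sch)
        (mu_x, mu_h), _ = posterior_params(zt, z0t, 4, 10, sch)
        assert np.abs(zs.zx - remove_com(mu_x)).max() < 1e-12
        assert np.abs(zs.zh - mu_h).max() < 1e-12
        assert np.abs(zs.zx.mean(axis=0)).max() < 1e-8

    def test_uncentered_eps_hat_rejected(self):
        sch = make_schedule("polynomial", T=20)
        rng = np.random.default_rng(6)
        zt = NoisySample(zx=remove_com(rng.normal(size=(3, 3))),
                         zh=rng.normal(size=(3, 2)), t=10)
        with pytest.raises(ValueError):
            reverse_step(zt, (np.ones((3, 3)), np.zeros((3, 2))), 5, 10,
                         sch, rng)


class TestLoss:
    def test_zero_at_perfect_prediction_and_quadratic(self):
        e = (np.ones((2, 3)), np.ones((2, 4)))
        assert diffusion_loss(e, e) == 0.0
        e2 = (np.zeros((2, 3)), np.ones((2, 4)))
        e4 = (-np.ones((2, 3)), np.ones((2, 4)))
        assert diffusion_loss(e4, e) == pytest.approx(4 * diffusion_loss(e2, e))


class TestSampling:
    def test_fixed_seed_is_bitwise_reproducible(self):
        sch = make_schedule("polynomial", T=20)
        model = ZeroModel()
        a = sample_molecules(model, 3, sch, np.random.default_rng(9),
                             sizes=[3, 4, 5])
        b = sample_molecules(model, 3, sch, np.random.default_rng(9),
                             sizes=[3, 4, 5])
        for ma, mb in zip(a, b):
            assert np.array_equal(ma.coords, mb.coords)
            assert ma.symbols == mb.symbols

    def test_trajectory_stays_on_subspace(self):
        sch = make_schedule("polynomial", T=30)
        coms = []
        sample_molecules(ZeroModel(), 2, sch, np.random.default_rng(1),
                         sizes=[4, 6],
                         callback=lambda t, zx, seg: coms.append(
                             max(abs(zx[seg == i].mean(0)).max()
                                 for i in range(2))))
        assert len(coms) == 30
        assert max(coms) < 1e-8

    def test_invalid_sizes_rejected(self):
        sch = make_schedule("polynomial", T=10)
        with pytest.raises(ValueError):
            sample_molecules(ZeroModel(), 1, sch, np.random.default_rng(0),
                             sizes=[0])


class TestNLL:
    def _mol(self):
        rng = np.random.default_rng(11)
        return Molecule.from_symbols(
            ["C", "H", "N", "O", "F"],
            remove_com(rng.normal(size=(5, 3))))

    def test_size_term_infinite_outside_support(self):
        sch = make_schedule("polynomial", T=10)
        dist = SizeDistribution([4], [1.0])
        assert nll(ZeroModel(), self._mol(), sch, dist) == np.inf

    def test_degenerate_size_distribution_contributes_zero(self):
        """Same seeds, only p(N) differs: the gap must equal −log p."""
        sch = make_schedule("polynomial", T=10)
        mol = self._mol()
        full = nll(ZeroModel(), mol, sch, SizeDistribution([5], [1.0]),
                   rng=np.random.default_rng(0))
        half = nll(ZeroModel(), mol, sch, SizeDistribution([3, 5], [0.5, 0.5]),
                   rng=np.random.default_rng(0))
        assert half - full == pytest.approx(np.log(2.0), abs=1e-10)

    def test_optimal_denoiser_tightens_bound_on_gaussian_toy(self):
        """For Gaussian feature data, the posterior-mean ε̂ must give a
        strictly smaller variational bound than a zero predictor."""
        T = 40
        sch = make_schedule("polynomial", T=T)
        m0, s0 = 0.0, 1.0

        class OptModel(ZeroModel):
            def predict(self, zx, zh, seg, t_frac, cond=None):
                t = int(round(float(t_frac[0]) * T))
                t = max(t, 1)
                c = transition_coeffs(sch, 0, t)
                a, s = c.alpha_ts, c.sigma_ts
                x_post = (a * s0**2 / (a**2 * s0**2 + s**2)) * zh
                return np.zeros_like(zx), (zh - a * x_post) / s

        rng = np.random.default_rng(2)
        mol = self._mol()
        dist = SizeDistribution([5], [1.0])
        b_opt = np.mean([nll(OptModel(), mol, sch, dist, full_sum=True,
                             rng=np.random.default_rng(k))
                         for k in range(5)])
        b_zero = np.mean([nll(ZeroModel(), mol, sch, dist, full_sum=True,
                              rng=np.random.default_rng(k))
                          for k in range(5)])
        assert b_opt < b_zero
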