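"""PPCA fitting, conditional inference and cross-validation."""

import numpy as np
import pytest

from gaitwrench.core import NormalizedCycle
from gaitwrench.ppca import (
    FeatureLayout,
    build_features,
    choose_q,
    compute_scales,
    fit_model,
    infer_grfm,
    loco_cv,
    loso_cv,
    ppca_loglik,
    train_ppca,
)
from gaitwrench.ppca import _conditional  # tested directly against the dense oracle
from gaitwrench.synth import ANGLE_CHANNELS, GeneratorConfig, generate_dataset, normalized_cycles


def _make_cycle(channels, sf=0.6, duration=1.1, subject_id=None):
    n = 101
    ch = {name: np.asarray(v, dtype=float) if np.ndim(v) else np.full(n, float(v))
          for name, v in channels.items()}
    return NormalizedCycle(percent=np.linspace(0, 100, n), channels=ch,
                           stance_fraction=sf, cycle_duration=duration, subject_id=subject_id)


class TestBuildFeatures:
    def test_stacked_dimension_is_channels_times_101_plus_stance(self):
        kin = ["a", "b", "c"]
        grfm = tuple(f"g{i}" for i in range(6))
        layout = FeatureLayout.default(kin, grfm_channels=grfm)
        cycles = [_make_cycle({c: i for i, c in enumerate(kin + list(grfm))}) for _ in range(2)]
        X = build_features(cycles, layout)
        assert X.shape == (2, 9 * 101 + 1)

    def test_missing_channel_raises_with_name(self):
        layout = FeatureLayout.default(["a"], grfm_channels=("g",))
        cyc = _make_cycle({"a": 1.0})  # no grfm channel
        with pytest.raises(KeyError, match="'g'"):
            build_features([cyc], layout)

    def test_permuting_cycles_permutes_rows(self):
        layout = FeatureLayout.default(["a"], grfm_channels=("g",))
        cycles = [_make_cycle({"a": i, "g": -i}) for i in range(4)]
        X = build_features(cycles, layout)
        Xp = build_features(cycles[::-1], layout)
        assert np.array_equal(Xp, X[::-1])


def _data_with_eigenvalues(eigs, n=16, seed=0):
    """Centered data whose sample covariance has exactly these eigenvalues."""
    rng = np.random.default_rng(seed)
    D = len(eigs)
    # orthonormal columns orthogonal to the ones vector, so centering is a no-op
    raw = rng.normal(size=(n, D))
    raw -= raw.mean(axis=0)
    U, _ = np.linalg.qr(raw)
    V, _ = np.linalg.qr(rng.normal(size=(D, D)))
    Xc = U @ np.diag(np.sqrt(n * np.asarray(eigs, dtype=float))) @ V.T
    return Xc + rng.normal(size=D)


class TestTrainPpca:
    def test_sigma2_is_mean_of_discarded_eigenvalues(self):
        X = _data_with_eigenvalues([5.0, 3.0, 2.0, 1.0])
        model = train_ppca(X, q=2)
        assert model.sigma2 == pytest.approx(1.5, abs=1e-10)
        # cross-check against an independent eigendecomposition
        Xc = X - X.mean(axis=0)
        lam = np.sort(np.linalg.eigvalsh(Xc.T @ Xc / len(X)))[::-1]
        assert model.sigma2 == pytest.approx(lam[2:].mean(), abs=1e-10)

    def test_noiseless_low_rank_data_gives_zero_sigma2_and_exact_reconstruction(self, rng):
        n, D, q = 40, 7, 3
        Wtrue = rng.normal(size=(D, q))
        Z = rng.normal(size=(n, q))
        mu = rng.normal(size=D)
        X = Z @ Wtrue.T + mu
        model = train_ppca(X, q=q)
        assert model.sigma2 == pytest.approx(0.0, abs=1e-10)
        scores = np.linalg.pinv(model.W) @ (X - model.mu).T
        recon = (model.W @ scores).T + model.mu
        assert np.allclose(recon, X, atol=1e-8)

    def test_model_covariance_reproduces_top_eigenspace(self):
        X = _data_with_eigenvalues([9.0, 6.0, 1.0, 0.5, 0.25], n=24, seed=3)
        q = 2
        model = train_ppca(X, q=q)
        Xc = X - X.mean(axis=0)
        lam, U = np.linalg.eigh(Xc.T @ Xc / len(X))
        U_top = U[:, np.argsort(lam)[::-1][:q]]
        W_basis, _ = np.linalg.qr(model.W)
        principal_cosines = np.linalg.svd(U_top.T @ W_basis, compute_uv=False)
        assert np.all(np.arccos(np.clip(principal_cosines, -1, 1)) < 1e-8)

    def test_invalid_q_raises(self):
        X = np.random.default_rng(0).normal(size=(5, 4))
        with pytest.raises(ValueError):
            train_ppca(X, q=4)

    def test_nonfinite_input_raises(self):
        X = np.full((5, 4), np.nan)
        with pytest.raises(ValueError, match="finite"):
            train_ppca(X, q=1)

    def test_loglik_nondecreasing_in_q(self, rng):
        X = rng.normal(size=(60, 8)) @ np.diag([3, 2.5, 2, 1.5, 1, 0.8, 0.5, 0.3])
        lls = [ppca_loglik(X, q) for q in range(1, 7)]
        assert np.all(np.diff(lls) >= -1e-9)


class TestConditionalInference:
    def test_matches_dense_gaussian_conditioning_on_random_instances(self, rng):
        """The latent-space conditional equals brute-force conditioning with
        the explicitly assembled D x D covariance, on 100 random models."""
        for _ in range(100):
            D = int(rng.integers(4, 13))
            q = int(rng.integers(1, 4))
            W = rng.normal(size=(D, q))
            sigma2 = float(rng.uniform(0.05, 2.0))
            mu = rng.normal(size=D)
            model = train_ppca(rng.normal(size=(D + 5, D)), q=q)  # container
            model.W, model.sigma2, model.mu = W, sigma2, mu
            n_obs = int(rng.integers(1, D))
            obs_idx = np.sort(rng.choice(D, size=n_obs, replace=False))
            x_obs = rng.normal(size=n_obs)

            mean, var = _conditional(model, obs_idx, x_obs)

            C = W @ W.T + sigma2 * np.eye(D)
            tgt_idx = np.setdiff1d(np.arange(D), obs_idx)
            Coo = C[np.ix_(obs_idx, obs_idx)]
            Cto = C[np.ix_(tgt_idx, obs_idx)]
            Ctt = C[np.ix_(tgt_idx, tgt_idx)]
            dense_mean = mu[tgt_idx] + Cto @ np.linalg.solve(Coo, x_obs - mu[obs_idx])
            dense_cov = Ctt - Cto @ np.linalg.solve(Coo, Cto.T)
            assert np.allclose(mean, dense_mean, atol=1e-9)
            assert np.allclose(var, np.diag(dense_cov), atol=1e-9)

    def test_observing_the_mean_predicts_the_mean(self, small_noisy_cycles, default_layout):
        cycles = [c for cs in small_noisy_cycles.values() for c in cs]
        model = fit_model(cycles, default_layout, q=5)
        obs_idx = model.layout.block_indices(model.layout.observed_blocks)
        mean, _ = _conditional(model, obs_idx, model.mu[obs_idx])
        tgt_idx = np.setdiff1d(np.arange(model.D), obs_idx)
        assert np.array_equal(mean, model.mu[tgt_idx])

    def test_noiseless_identifiability(self, rng):
        """With sigma2 = 0 and full-column-rank observed loadings, data from
        the model is predicted exactly."""
        D, q, n_obs = 10, 3, 6
        W = rng.normal(size=(D, q))
        mu = rng.normal(size=D)
        model = train_ppca(rng.normal(size=(D + 5, D)), q=q)
        model.W, model.sigma2, model.mu = W, 0.0, mu
        z = rng.normal(size=q)
        x = W @ z + mu
        obs_idx = np.arange(n_obs)
        mean, var = _conditional(model, obs_idx, x[obs_idx])
        assert np.allclose(mean, x[n_obs:], atol=1e-8)
        assert np.allclose(var, 0.0)

    def test_prediction_affine_in_observation(self, small_noisy_cycles, default_layout):
        cycles = [c for cs in small_noisy_cycles.values() for c in cs]
        model = fit_model(cycles, default_layout, q=4)
        obs_idx = model.layout.block_indices(model.layout.observed_blocks)
        rng = np.random.default_rng(1)
        x1 = rng.normal(size=len(obs_idx))
        x2 = rng.normal(size=len(obs_idx))
        m1, _ = _conditional(model, obs_idx, x1)
        m2, _ = _conditional(model, obs_idx, x2)
        m_mid, _ = _conditional(model, obs_idx, 0.5 * (x1 + x2))
        assert np.allclose(m_mid, 0.5 * (m1 + m2), atol=1e-9)

    def test_infer_grfm_masks_swing_and_destandardizes(self, small_noisy_cycles, default_layout):
        cycles = [c for cs in small_noisy_cycles.values() for c in cs]
        model = fit_model(cycles, default_layout, q=5)
        cyc = cycles[0]
        pred = infer_grfm(model, cyc)
        swing = pred.percent > cyc.stance_fraction * 100 + 1e-9
        assert np.all(pred.channels["grf_r_y"][swing] == 0.0)
        assert np.all(pred.posterior_sd["grf_r_y"] >= 0.0)
        # roughly reproduces the measured waveform for an in-sample cycle
        stance = ~swing
        err = pred.channels["grf_r_y"][stance] - cyc.channel("grf_r_y")[stance]
        assert np.sqrt(np.mean(err**2)) < 0.1

    def test_untrained_model_rejected(self):
        model = train_ppca(np.random.default_rng(0).normal(size=(10, 6)), q=2)
        with pytest.raises(ValueError, match="layout"):
            infer_grfm(model, np.zeros(3), stance_fraction=0.6)


class TestEmCrossCheck:
    def test_em_fit_agrees_with_closed_form(self, rng):
        """An independently coded EM iteration converges to the same
        covariance as the closed-form eigendecomposition fit."""
        n, D, q = 80, 6, 2
        Wtrue = rng.normal(size=(D, q)) * [2.0, 1.0]
        X = rng.normal(size=(n, q)) @ Wtrue.T + 0.3 * rng.normal(size=(n, D))
        closed = train_ppca(X, q=q)
        mu = X.mean(axis=0)
        Xc = X - mu
        S = Xc.T @ Xc / n
        W = rng.normal(size=(D, q))
        s2 = 1.0
        for _ in range(3000):
            M = W.T @ W + s2 * np.eye(q)
            Minv = np.linalg.inv(M)
            SW = S @ W
            W_new = SW @ np.linalg.inv(s2 * np.eye(q) + Minv @ W.T @ SW)
            s2 = np.trace(S - SW @ Minv @ W_new.T) / D
            W = W_new
        C_em = W @ W.T + s2 * np.eye(D)
        C_cf = closed.W @ closed.W.T + closed.sigma2 * np.eye(D)
        assert np.allclose(C_em, C_cf, atol=1e-6)
        assert s2 == pytest.approx(closed.sigma2, abs=1e-8)


class TestCrossValidation:
    def test_identical_noiseless_subjects_give_zero_rmse(self, noiseless_config, default_layout):
        ds = generate_dataset(noiseless_config)
        cycles = normalized_cycles(ds)
        # with zero latent variance and offsets every cycle equals the
        # subject template; LOSO across lookalike subjects must be exact
        res = loso_cv(cycles, default_layout, q=1)
        assert res.pooled["grf_r_y"]["rmse_mean"] == pytest.approx(0.0, abs=1e-9)

    def test_number_of_folds_equals_number_of_subjects(self, small_noisy_cycles, default_layout):
        res = loso_cv(small_noisy_cycles, default_layout, q=5)
        assert set(res.per_cycle["fold"]) == set(small_noisy_cycles)

    def test_subject_with_zero_cycles_rejected(self, small_noisy_cycles, default_layout):
        broken = dict(small_noisy_cycles)
        broken["empty"] = []
        with pytest.raises(ValueError, match="zero cycles"):
            loso_cv(broken, default_layout, q=2)

    def test_leave_subject_out_is_harder_than_leave_cycles_out(self, small_noisy_cycles, default_layout):
        loso = loso_cv(small_noisy_cycles, default_layout, q="auto")
        loco = loco_cv(small_noisy_cycles, default_layout, q="auto", n_folds=5, seed=0)
        assert loso.pooled["grf_r_y"]["rmse_mean"] > loco.pooled["grf_r_y"]["rmse_mean"]


class TestChooseQ:
    def test_explained_variance_rule(self):
        assert choose_q(np.array([8.0, 1.0, 0.5, 0.5]), explained=0.80) == 1
        assert choose_q(np.array([8.0, 1.0, 0.5, 0.5]), explained=0.90) == 2
        assert choose_q(np.array([8.0, 1.0, 0.5, 0.5]), explained=0.92) == 3
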