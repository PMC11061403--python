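"""Jittered generation, model-based augmentation and the noise baseline."""

import numpy as np
import pytest

from ctmaug.augment import (
    JitterSpec,
    NFTStrategy,
    assemble_training_features,
    jitter_draws,
    nft_augment,
    noise_augment,
)
from ctmaug.fit import FitConfig
from ctmaug.pipeline import (
    FeatureMatrix,
    apply_csp,
    balanced_accuracy,
    bandpass,
    extract_features,
    fit_csp,
    predict,
    train_classifier,
)
from ctmaug.simulate import SimConfig

FAST_FIT = FitConfig(n_steps=1200, burn_in_steps=300, n_chains=1)


class TestJitterDraws:
    def test_draw_count_is_ten_per_factor(self, gains):
        assert len(jitter_draws(gains, JitterSpec(), factor=2)) == 20
        assert len(jitter_draws(gains, JitterSpec(), factor=1)) == 10
        assert len(jitter_draws(gains, JitterSpec(), factor=0.5)) == 5

    def test_zero_scale_reproduces_input(self, gains):
        for d in jitter_draws(gains, JitterSpec(scale=0.0), factor=1):
            assert d.t0 == gains.t0 and d.alpha == gains.alpha

    def test_non_targets_untouched(self, gains):
        for d in jitter_draws(gains, JitterSpec(targets=("t0",)), factor=1,
                              seed=2):
            assert d.alpha == gains.alpha and d.G_ese == gains.G_ese
            assert d.t0 != gains.t0

    def test_sampler_spread_matches_inflated_sigma(self, gains):
        draws = jitter_draws(gains, JitterSpec(targets=("alpha",)), factor=1000,
                             seed=3)
        alphas = np.array([d.alpha for d in draws])
        assert alphas.std(ddof=1) == pytest.approx(1.5 * 14.0, rel=0.02)

    def test_loop_gains_cannot_be_jittered(self):
        with pytest.raises(ValueError):
            JitterSpec(targets=("G_ese",))

    def test_all_draws_pass_stability_screen(self, gains):
        from ctmaug.fit import stability_check
        for d in jitter_draws(gains, JitterSpec(targets=("t0", "gamma_e")),
                              factor=3, seed=4):
            assert stability_check(d)


class TestNoiseAugment:
    def _features(self, rng, n=24):
        vals = np.vstack([rng.normal(1.0, 0.3, (n, 4)),
                          rng.normal(2.0, 0.3, (n, 4))])
        labels = np.array(["L"] * n + ["R"] * n)
        return FeatureMatrix(vals, labels, [f"csp{i}_TP" for i in range(4)])

    def test_count_contract(self, rng):
        f = self._features(rng)
        out = noise_augment(f, factor=2, seed=1)
        assert out.values.shape[0] == 3 * f.values.shape[0]
        assert np.sum(out.labels == "L") == 72

    def test_degenerate_zero_covariance(self):
        vals = np.tile([1.0, 2.0, 3.0, 4.0], (10, 1))
        f = FeatureMatrix(np.vstack([vals, vals + 5]),
                          np.array(["L"] * 10 + ["R"] * 10),
                          [f"f{i}" for i in range(4)])
        out = noise_augment(f, factor=1, seed=0)
        new_l = out.values[20:30]
        np.testing.assert_allclose(new_l, vals, atol=1e-8)

    def test_sampled_covariance_inflated_by_scale(self, rng):
        n, d = 400, 3
        base = rng.multivariate_normal([0, 1, 2],
                                       [[1.0, 0.3, 0.0],
                                        [0.3, 2.0, 0.4],
                                        [0.0, 0.4, 0.5]], size=n)
        f = FeatureMatrix(base, np.array(["L"] * n), ["a", "b", "c"])
        out = noise_augment(f, factor=25, scale=1.5, seed=5)
        drawn = out.values[n:]
        s_feat = np.cov(base, rowvar=False)
        s_drawn = np.cov(drawn, rowvar=False)
        err = np.linalg.norm(s_drawn - 1.5 * s_feat) / np.linalg.norm(1.5 * s_feat)
        assert err < 0.05


class TestNFTAugment:
    @pytest.fixture(scope="class")
    def fixture_split(self, quiet_subject):
        e_bp = bandpass(quiet_subject)
        idx = np.arange(e_bp.n_epochs)
        train = e_bp.select(idx[:36])
        csp = fit_csp(train)
        return train, csp

    @pytest.fixture(scope="class")
    def aug_result(self, fixture_split):
        train, csp = fixture_split
        return nft_augment(train, csp, factor=1.0, spec=None,
                           fit_cfg=FAST_FIT, sim_cfg=SimConfig(), seed=21)

    def test_epoch_count_contract(self, fixture_split, aug_result):
        train, csp = fixture_split
        for cond in np.unique(train.labels):
            n_train = int(np.sum(train.labels == cond))
            assert aug_result.n_epochs(cond) == n_train
            assert set(aug_result.epochs[cond]) == set(range(csp.n_csp))

    def test_reproducible_bit_exact(self, fixture_split):
        train, csp = fixture_split
        a = nft_augment(train, csp, factor=0.25, spec=None,
                        fit_cfg=FAST_FIT, seed=33)
        b = nft_augment(train, csp, factor=0.25, spec=None,
                        fit_cfg=FAST_FIT, seed=33)
        for cond in a.epochs:
            for j in a.epochs[cond]:
                np.testing.assert_array_equal(a.epochs[cond][j],
                                              b.epochs[cond][j])

    def test_artificial_total_power_matches_real(self, fixture_split, aug_result):
        """Band-power calibration keeps the TP feature on the real scale."""
        train, csp = fixture_split
        src = apply_csp(csp, train)
        for cond in np.unique(train.labels):
            real = src.data[src.labels == cond]
            for j in range(csp.n_csp):
                tp_real = np.mean(real[:, j] ** 2)
                tp_art = np.mean(aug_result.epochs[cond][j] ** 2)
                assert tp_art == pytest.approx(tp_real, rel=0.35)

    def test_combined_features_stay_linearly_separable(self, fixture_split,
                                                       aug_result):
        train, csp = fixture_split
        src = apply_csp(csp, train)
        combined = assemble_training_features(src, aug_result, "TP")
        clf = train_classifier(combined)
        acc = balanced_accuracy(combined.labels, predict(clf, combined))
        assert acc > 0.9


class TestAssembly:
    def _fake_aug(self, rng, n_art=24, n_csp=4):
        from ctmaug.augment import AugmentedSources
        eps = {c: {j: rng.standard_normal((n_art, 100)) + 2.0
                   for j in range(n_csp)} for c in ("L", "R")}
        return AugmentedSources(epochs=eps, fs=250.0)

    def _sources(self, rng, n=24):
        from ctmaug.pipeline import EpochSet
        data = rng.standard_normal((2 * n, 4, 100))
        return EpochSet(data, 250.0, np.array(["L"] * n + ["R"] * n))

    def test_row_arithmetic(self, rng):
        src = self._sources(rng)
        fm = assemble_training_features(src, self._fake_aug(rng), "TP")
        assert fm.values.shape == (96, 4)
        assert np.sum(fm.labels == "L") == 48

    def test_none_augmentation_is_identity(self, rng):
        src = self._sources(rng)
        fm = assemble_training_features(src, None, "TP")
        ref = extract_features(src, "TP")
        np.testing.assert_array_equal(fm.values, ref.values)

    def test_epoch_alignment_does_not_change_column_marginals(self, rng):
        src = self._sources(rng)
        aug = self._fake_aug(rng)
        fm1 = assemble_training_features(src, aug, "TP")
        for c in aug.epochs:
            for j in aug.epochs[c]:
                aug.epochs[c][j] = aug.epochs[c][j][rng.permutation(24)]
        fm2 = assemble_training_features(src, aug, "TP")
        np.testing.assert_allclose(np.sort(fm1.values, axis=0),
                                   np.sort(fm2.values, axis=0), rtol=1e-12)

    def test_factor_zero_strategy_returns_real_features(self, rng):
        src = self._sources(rng)
        feats = extract_features(src, "TP")
        strat = NFTStrategy(factor=0.0)
        out = strat.training_features(None, None, src, feats, "TP", 10, 0)
        assert out is feats


class TestJitterPropagation:
    def test_smaller_delay_draws_have_higher_peak_frequency(self, gains):
        """Delay jitter shifts each draw's spectral peak the expected way."""
        from ctmaug.core import analytic_spectrum
        from scipy.stats import spearmanr

        draws = jitter_draws(gains, JitterSpec(targets=("t0",)), factor=4,
                             seed=9)
        t0s, peaks = [], []
        for d in draws:
            ps = analytic_spectrum(d, freqs=np.arange(7.0, 14.0, 0.02))
            t0s.append(d.t0)
            peaks.append(ps.freqs[np.argmax(ps.power)])
        rho = spearmanr(t0s, peaks).statistic
        assert rho < 0
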