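"""Pattern bases, rejection sampling, signal synthesis and dataset contracts."""

import numpy as np
import pytest
from scipy import stats

from synxqsl.dki import DKIParams, NoiseSpec, dki_signal, make_rng
from synxqsl.synthesis import (
    BASIS_VECTORS,
    CENTER_INDEX,
    ParameterRanges,
    SynthesisConfig,
    TrainingDataset,
    basis_matrix,
    expand_to_pattern,
    generate_dataset,
    generate_patterns,
    pattern_from_weights,
    sample_center_params,
    synthesize_sample,
)


class TestBasisSet:
    def test_center_element_zero(self):
        assert np.all(BASIS_VECTORS[:, CENTER_INDEX] == 0)

    def test_mode_selection(self):
        assert basis_matrix(1).shape == (1, 9)
        assert basis_matrix(3).shape == (3, 9)
        assert basis_matrix(6).shape == (6, 9)
        with pytest.raises(ValueError):
            basis_matrix(4)

    def test_flat_basis_is_zero(self):
        assert np.all(basis_matrix(1) == 0)

    def test_horizontal_gradient_basis(self):
        """Weight 0.1 on the second basis shifts D columns by -/0/+ 0.1."""
        center = DKIParams(1000.0, 2.0e-3, 0.2)
        pat = pattern_from_weights(
            center,
            {
                "s0": np.zeros(3),
                "d": np.array([0.0, 0.1e-3, 0.0]),
                "k": np.zeros(3),
            },
        )
        for row in range(3):
            assert pat.d[row, 0] == pytest.approx(1.9e-3)
            assert pat.d[row, 1] == pytest.approx(2.0e-3)
            assert pat.d[row, 2] == pytest.approx(2.1e-3)


class TestCenterSampling:
    def test_constraint_always_satisfied(self, ranges, scheme, rng):
        bound = 3.0 / scheme.b_max
        for _ in range(2000):
            p = sample_center_params(ranges, scheme, rng)
            assert p.D * p.K < bound
            assert 500.0 <= p.S0 <= 8000.0

    def test_unconstrained_d_is_uniform(self, scheme, rng):
        """With K pinned to ~0 the D*K bound is vacuous: D stays uniform."""
        r = ParameterRanges(k=(0.0, 1e-12))
        d = np.array(
            [sample_center_params(r, scheme, rng).D for _ in range(3000)]
        )
        u = (d - 0.2e-3) / (6.0e-3 - 0.2e-3)
        assert stats.kstest(u, "uniform").pvalue > 0.01

    def test_k_marginal_truncated_against_oracle(self, ranges, scheme, rng):
        """K marginal matches a brute-force accept/reject oracle and is no
        longer uniform on [0, 4]."""
        k_pkg = np.array(
            [sample_center_params(ranges, scheme, rng).K for _ in range(4000)]
        )
        oracle_rng = np.random.default_rng(42)
        accepted = []
        while len(accepted) < 4000:
            d = oracle_rng.uniform(0.2e-3, 6.0e-3, 20000)
            k = oracle_rng.uniform(0.0, 4.0, 20000)
            accepted.extend(k[d * k < 3.0 / scheme.b_max][: 4000 - len(accepted)])
        k_oracle = np.asarray(accepted)
        assert stats.ks_2samp(k_pkg, k_oracle).pvalue > 0.01
        assert stats.kstest(k_pkg / 4.0, "uniform").pvalue < 1e-6


class TestPatternExpansion:
    def test_flat_mode_gives_uniform_pattern(self, ranges, scheme, rng):
        center = DKIParams(1000.0, 1.0e-3, 0.5)
        pat = expand_to_pattern(center, 1, ranges, scheme, rng)
        assert np.all(pat.s0 == 1000.0)
        assert np.all(pat.d == 1.0e-3)
        assert np.all(pat.k == 0.5)

    @pytest.mark.parametrize("mode", [1, 3, 6])
    def test_center_preserved_exactly(self, mode, ranges, scheme, rng):
        done = 0
        while done < 50:
            center = sample_center_params(ranges, scheme, rng)
            try:
                pat = expand_to_pattern(
                    center, mode, ranges, scheme, rng, max_attempts=2000
                )
            except RuntimeError:
                continue  # near-boundary centre exhausted its weight budget
            done += 1
            assert pat.s0[1, 1] == center.S0
            assert pat.d[1, 1] == center.D
            assert pat.k[1, 1] == center.K

    @pytest.mark.parametrize("mode", [3, 6])
    def test_all_cells_valid(self, mode, ranges, scheme, rng):
        bound = 3.0 / scheme.b_max
        for _ in range(100):
            center = sample_center_params(ranges, scheme, rng)
            try:
                pat = expand_to_pattern(
                    center, mode, ranges, scheme, rng, max_attempts=2000
                )
            except RuntimeError:
                continue  # near-boundary centre exhausted its weight budget
            cells = pat.cells()
            assert np.all(cells[:, 0] > 0)
            assert np.all(cells[:, 1] > 0)
            assert np.all(cells[:, 2] >= 0)
            assert np.all(cells[:, 1] * cells[:, 2] < bound)

    def test_smaller_mode_embeds_in_larger(self):
        """Zeroing the extra weights of M=6 reproduces the M=3 pattern."""
        center = DKIParams(2000.0, 1.5e-3, 0.3)
        w3 = {
            "s0": np.array([100.0, -50.0, 30.0]),
            "d": np.array([0.0, 0.1e-3, -0.05e-3]),
            "k": np.array([0.0, 0.05, 0.1]),
        }
        w6 = {k: np.concatenate([v, np.zeros(3)]) for k, v in w3.items()}
        p3 = pattern_from_weights(center, w3)
        p6 = pattern_from_weights(center, w6)
        assert np.array_equal(p3.s0, p6.s0)
        assert np.array_equal(p3.d, p6.d)
        assert np.array_equal(p3.k, p6.k)


class TestSampleSynthesis:
    def test_noise_free_flat_features(self, ranges, scheme, rng):
        """sigma=0, flat pattern: nine identical blocks of the closed form."""
        center = DKIParams(3000.0, 1.0e-3, 0.8)
        pat = expand_to_pattern(center, 1, ranges, scheme, rng)
        sample = synthesize_sample(pat, scheme, NoiseSpec(0.0, 4250.0), rng)
        b = scheme.b[1:]
        expected = np.exp(-b * 1.0e-3 + b * b * 1.0e-6 * 0.8 / 6.0)
        feats = sample.features.reshape(9, -1)
        assert np.allclose(feats, expected[None, :], rtol=1e-12)

    def test_features_independent_of_s0(self, scheme, rng):
        """Decay ratios cancel the baseline amplitude exactly."""
        w = {
            "s0": np.zeros(3),
            "d": np.array([0.0, 0.1e-3, 0.05e-3]),
            "k": np.array([0.0, 0.02, -0.03]),
        }
        noise = NoiseSpec(0.0, 4250.0)
        pa = pattern_from_weights(DKIParams(1000.0, 1e-3, 0.5), w)
        pb = pattern_from_weights(DKIParams(7000.0, 1e-3, 0.5), w)
        fa = synthesize_sample(pa, scheme, noise, rng).features
        fb = synthesize_sample(pb, scheme, noise, rng).features
        assert np.allclose(fa, fb, rtol=1e-12)

    def test_rician_bias_matches_oracle(self, ranges, scheme, rng):
        """Noisy decay ratios are biased upward, matching a brute-force
        Monte-Carlo oracle of the same noise model within 3 SE."""
        center = DKIParams(1000.0, 1.0e-3, 0.5)
        pat = expand_to_pattern(center, 1, ranges, scheme, rng)
        noise = NoiseSpec(100.0, 4250.0)
        n = 10_000
        feats = np.stack(
            [synthesize_sample(pat, scheme, noise, rng).features for _ in range(n)]
        )
        j = scheme.n_nonzero - 1  # highest b-value: strongest relative noise
        observed = feats.reshape(n, 9, -1)[:, 4, j]
        clean = dki_signal(scheme.b, params=center)
        oracle_rng = np.random.default_rng(5)
        g0 = oracle_rng.normal(0, noise.sigma, 200_000)
        gj = oracle_rng.normal(0, noise.sigma, 200_000)
        oracle = np.sqrt(clean[j + 1] ** 2 + gj**2) / np.sqrt(clean[0] ** 2 + g0**2)
        clean_ratio = clean[j + 1] / clean[0]
        assert observed.mean() > clean_ratio
        se = np.sqrt(observed.var() / n + oracle.var() / oracle.size)
        assert abs(observed.mean() - oracle.mean()) < 3 * se


class TestDatasetGeneration:
    def test_determinism(self):
        cfg = SynthesisConfig(n=100, mode=6, nr=0.05, seed=7)
        a = generate_dataset(cfg)
        b = generate_dataset(cfg)
        assert np.array_equal(a.signals, b.signals)
        assert np.array_equal(a.target_k, b.target_k)

    def test_noise_free_signals_match_model(self, small_clean_dataset):
        ds = small_clean_dataset
        b = ds.config.scheme.b
        s = ds.signals
        # centre row of every sample must equal the forward model of targets
        d = ds.target_d[:, None]
        k = ds.target_k[:, None]
        s0 = s[:, CENTER_INDEX, 0][:, None]
        expected = s0 * np.exp(-b * d + b * b * d * d * k / 6.0)
        assert np.allclose(s[:, CENTER_INDEX, :], expected, rtol=1e-12)

    def test_feature_lengths(self, small_noisy_dataset):
        assert small_noisy_dataset.features.shape[1] == 54
        assert small_noisy_dataset.center_features.shape[1] == 6

    def test_features_finite_positive(self, small_noisy_dataset):
        f = small_noisy_dataset.features
        assert np.all(np.isfinite(f))
        assert np.all(f > 0)

    def test_center_identity_bulk(self):
        for mode in (1, 3, 6):
            centers, cells = generate_patterns(5000, mode, seed=mode)
            assert np.array_equal(cells[:, CENTER_INDEX, :], centers)

    def test_save_load_round_trip(self, tmp_path, small_noisy_dataset):
        base = tmp_path / "ds"
        small_noisy_dataset.save(base)
        back = TrainingDataset.load(base)
        assert np.array_equal(back.signals, small_noisy_dataset.signals)
        assert back.config == small_noisy_dataset.config

    def test_infeasible_ranges_error(self, scheme):
        bad = ParameterRanges(d=(5.9e-3, 6.0e-3), k=(3.9, 4.0))
        with pytest.raises(RuntimeError):
            sample_center_params(bad, scheme, make_rng(0))
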