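"""Regressor training, grid search and windowed volume inference."""

import numpy as np
import pytest

from synxqsl.dki import dki_signal
from synxqsl.regress import (
    HyperParams,
    HyperparamGrid,
    RegressorModel,
    evaluate,
    extract_window_features,
    grid_search,
    predict_volume,
    train_mlp,
)
from synxqsl.synthesis import ParameterRanges, SynthesisConfig, generate_dataset

TINY = HyperParams(mid_layers=2, units=16, dropout=0.0, epochs=5, batch_size=256)


@pytest.fixture(scope="module")
def tiny_train():
    return generate_dataset(SynthesisConfig(n=1500, mode=6, nr=0.0, seed=21))


@pytest.fixture(scope="module")
def tiny_val():
    return generate_dataset(SynthesisConfig(n=500, mode=6, nr=0.0, seed=22))


class TestTraining:
    def test_seed_reproducibility(self, tiny_train, tiny_val):
        a = train_mlp(tiny_train, TINY, "K", seed=3)
        b = train_mlp(tiny_train, TINY, "K", seed=3)
        assert evaluate(a, tiny_val) == evaluate(b, tiny_val)
        x = tiny_val.features
        assert np.array_equal(a.predict(x), b.predict(x))

    def test_constant_target_regression(self):
        """A dataset whose K is pinned to ~0 is learned as the constant 0."""
        cfg = SynthesisConfig(
            n=2000, mode=1, nr=0.0, seed=31, ranges=ParameterRanges(k=(0.0, 1e-9))
        )
        ds = generate_dataset(cfg)
        held = generate_dataset(
            SynthesisConfig(
                n=300, mode=1, nr=0.0, seed=32, ranges=ParameterRanges(k=(0.0, 1e-9))
            )
        )
        model = train_mlp(ds, HyperParams(2, 16, 0.0, 100, 256), "K", seed=0)
        assert np.max(np.abs(model.predict(held.features))) < 0.05

    def test_window_dimensionality_enforced(self, tiny_train):
        model = train_mlp(tiny_train, TINY, "D", window="synqsl", seed=0)
        assert model.in_dim == 6
        with pytest.raises(ValueError):
            model.predict(np.ones((3, 54)))

    def test_bad_target_rejected(self, tiny_train):
        with pytest.raises(ValueError):
            train_mlp(tiny_train, TINY, "S0", seed=0)

    def test_noise_free_fit_tracks_lsf_oracle(self):
        """On clean flat patterns the regressor approaches the exact map
        recovered by least squares (D in scaled units, RMSE < 0.1)."""
        from synxqsl.lsf import lsf_fit_voxel

        train = generate_dataset(SynthesisConfig(n=10_000, mode=1, nr=0.0, seed=41))
        val = generate_dataset(SynthesisConfig(n=1000, mode=1, nr=0.0, seed=42))
        model = train_mlp(
            train, HyperParams(3, 128, 0.0, 150, 1000), "D", seed=0
        )
        assert evaluate(model, val) < 0.1
        scheme = val.config.scheme
        lsf_d = np.array(
            [
                lsf_fit_voxel(val.signals[i, 4], scheme).D
                for i in range(50)
            ]
        )
        assert np.allclose(lsf_d, val.target_d[:50], rtol=1e-6)

    def test_persistence_round_trip(self, tiny_train, tiny_val, tmp_path):
        model = train_mlp(tiny_train, TINY, "K", seed=3)
        model.save(tmp_path / "m")
        back = RegressorModel.load(tmp_path / "m")
        x = tiny_val.features
        assert np.array_equal(model.predict(x), back.predict(x))
        assert back.hyper == model.hyper
        assert back.train_nr == model.train_nr


class TestGridSearch:
    def test_singleton_grid(self, tiny_train, tiny_val):
        grid = HyperparamGrid(
            mid_layers=(2,), units=(16,), dropout=(0.0,),
            epochs=(5,), batch_size=(256,),
        )
        hyper, model = grid_search(tiny_train, tiny_val, grid, "K")
        assert hyper == HyperParams(2, 16, 0.0, 5, 256)
        assert model.hyper == hyper

    def test_argmin_exhaustiveness(self, tiny_train, tiny_val):
        grid = HyperparamGrid(
            mid_layers=(2,), units=(8, 16), dropout=(0.0,),
            epochs=(3, 6), batch_size=(256,),
        )
        best_hyper, best_model = grid_search(tiny_train, tiny_val, grid, "K", seed=1)
        best_score = evaluate(best_model, tiny_val)
        for hp in grid:
            score = evaluate(train_mlp(tiny_train, hp, "K", seed=1), tiny_val)
            assert best_score <= score + 1e-12

    def test_tie_broken_toward_smaller_model(
        self, tiny_train, tiny_val, monkeypatch
    ):
        """With validation RMSE forced equal, the fewest-weight, lowest-
        dropout configuration wins."""
        import synxqsl.regress as regress

        monkeypatch.setattr(regress, "evaluate", lambda m, d: 1.0)
        grid = HyperparamGrid(
            mid_layers=(2, 3), units=(8, 16), dropout=(0.1, 0.0),
            epochs=(2,), batch_size=(256,),
        )
        hyper, _ = regress.grid_search(tiny_train, tiny_val, grid, "K")
        assert (hyper.mid_layers, hyper.units, hyper.dropout) == (2, 8, 0.0)

    def test_empty_grid(self, tiny_train, tiny_val):
        grid = HyperparamGrid(mid_layers=(), units=(), dropout=(),
                              epochs=(), batch_size=())
        with pytest.raises(ValueError):
            grid_search(tiny_train, tiny_val, grid, "K")


class TestFeatureContract:
    def test_permutation_round_trip(self, tiny_train, tiny_val):
        """A model trained on permuted features applies the recorded
        permutation at inference, leaving predictions self-consistent."""
        rng = np.random.default_rng(0)
        perm = rng.permutation(54)
        model = train_mlp(tiny_train, TINY, "K", seed=3, feature_permutation=perm)
        x = tiny_val.features
        assert np.array_equal(model.predict(x), model.net.predict(x[:, perm]))

    def test_full_grid_default_matches_study_lists(self):
        grid = HyperparamGrid()
        assert grid.mid_layers == (3, 4, 5)
        assert grid.units == (64, 128, 256)
        assert grid.dropout == (0.0, 0.01, 0.1)
        assert grid.epochs == (50, 100, 150)
        assert grid.batch_size == (1000, 10_000, 100_000)
        assert len(grid) == 243


@pytest.fixture(scope="module")
def flat_model():
    ds = generate_dataset(SynthesisConfig(n=4000, mode=1, nr=0.0, seed=51))
    return train_mlp(ds, HyperParams(3, 64, 0.0, 60, 500), "K", seed=0)


@pytest.fixture(scope="module")
def flat_model_q():
    ds = generate_dataset(SynthesisConfig(n=4000, mode=1, nr=0.0, seed=51))
    return train_mlp(
        ds, HyperParams(3, 64, 0.0, 60, 500), "K", window="synqsl", seed=0
    )


class TestVolumeInference:
    def test_uniform_volume_near_truth(self, uniform_volume, scheme, flat_model):
        val = generate_dataset(SynthesisConfig(n=500, mode=1, nr=0.0, seed=52))
        tol = 3 * evaluate(flat_model, val)
        kmap, valid = predict_volume(uniform_volume, scheme, flat_model)
        assert valid.all()
        assert np.max(np.abs(kmap - 0.8)) < tol

    def test_synqsl_uniform_predictions_identical(
        self, uniform_volume, scheme, flat_model_q
    ):
        kmap, _ = predict_volume(uniform_volume, scheme, flat_model_q)
        assert np.all(kmap == kmap.flat[0])

    def test_shape_mismatch_rejected(self, scheme, flat_model):
        with pytest.raises(ValueError):
            predict_volume(np.ones((4, 4, 2, 5)), scheme, flat_model)

    def test_replicate_padding_feature_layout(self, scheme):
        """On a single-slice 3x3 volume the centre voxel sees all nine
        voxels unpadded; a corner voxel sees replicate-padded neighbours."""
        rng = np.random.default_rng(8)
        dwi = rng.uniform(100.0, 1000.0, size=(3, 3, 1, 7))
        feats, valid = extract_window_features(dwi, "synxqsl", b0_eps=0.0)
        assert valid.all()
        ratios = dwi[..., 0, 1:] / dwi[..., 0, :1]  # (3, 3, 6)

        center = np.concatenate(
            [ratios[r, c] for r in range(3) for c in range(3)]
        )
        assert np.allclose(feats[1, 1, 0], center, rtol=1e-12)

        # corner (0,0): replicate padding clamps offsets to the edge
        corner = np.concatenate(
            [
                ratios[max(0, 0 + dy), max(0, 0 + dx)]
                for dy in (-1, 0, 1)
                for dx in (-1, 0, 1)
            ]
        )
        assert np.allclose(feats[0, 0, 0], corner, rtol=1e-12)

    def test_background_guard(self, scheme, flat_model):
        sig = dki_signal(scheme.b, S0=1000.0, D=1.0e-3, K=0.8)
        vol = np.broadcast_to(sig, (5, 5, 1, 7)).copy()
        vol[0, 0] = 0.0  # dead voxel
        kmap, valid = predict_volume(vol, scheme, flat_model)
        assert not valid[0, 0, 0]
        assert kmap[0, 0, 0] == 0.0
        assert valid[2, 2, 0]
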