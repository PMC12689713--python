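"""Desk-reproducible experiment harnesses.

Two experiments are bundled:

* the train/test noise-ratio cross-test — for every training noise ratio
  a D and a K regressor are trained on synthetic X-Q data and evaluated
  on test sets at every noise ratio, yielding an RMSE matrix whose
  diagonal (matched noise) is expected to dominate each column at high
  noise;
* the digital-phantom benchmark — LSF, synQSL and synXQSL (flat / linear
  / quadratic pattern families) estimate D and K maps from one noisy
  phantom DWI volume, scored with signed-error statistics per S0 level
  plus per-map RMSE / SNR / CNR / SSIM.

Both experiments are fully reproducible from their config and a single
base seed; all internal seeds are derived deterministically from it.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dki import D_SCALE, AcquisitionScheme, DEFAULT_SCHEME
from .lsf import lsf_fit_volume
from .metrics import MetricsReport, cnr, signed_error_stats, snr, ssim
from .phantom import PhantomSpec, build_phantom, phantom_dwi
from .regress import (
    DESK_HYPERPARAMS,
    HyperparamGrid,
    HyperParams,
    RegressorModel,
    evaluate,
    grid_search,
    predict_volume,
    train_mlp,
)
from .synthesis import ParameterRanges, SynthesisConfig, generate_dataset

__all__ = [
    "derive_seed",
    "CrossTestConfig",
    "CrossTestResult",
    "run_cross_test",
    "PhantomBenchConfig",
    "run_phantom_benchmark",
]

#: Default noise-ratio levels for the cross-test.
NR_LEVELS = (0.0, 0.001, 0.01, 0.1)


def derive_seed(base: int, *tags) -> int:
    """Stable sub-seed (< 2^31) from a base seed and a tag tuple."""
    text = repr((int(base),) + tags).encode()
    return int.from_bytes(hashlib.sha256(text).digest()[:4], "big") % (2**31)


@dataclass(frozen=True)
class CrossTestConfig:
    nr_levels: tuple[float, ...] = NR_LEVELS
    n_train: int = 100_000
    n_val: int = 10_000
    n_test: int = 10_000
    mode: int = 6
    window: str = "synxqsl"
    targets: tuple[str, ...] = ("D", "K")
    seeds: tuple[int, ...] = (0, 1, 2)
    hyper: HyperParams = DESK_HYPERPARAMS
    grid: HyperparamGrid | None = None  # when set, overrides `hyper`
    ranges: ParameterRanges = field(default_factory=ParameterRanges)
    scheme: AcquisitionScheme = DEFAULT_SCHEME


@dataclass
class CrossTestResult:
    """RMSE indexed by (seed, train NR, test NR) per target parameter.

    D values are in scaled units (x1e-3 mm^2/s); K is dimensionless.
    """

    config: CrossTestConfig
    rmse: dict[str, np.ndarray]
    chosen_hyper: dict[tuple[int, float, str], HyperParams]

    def matrix(self, target: str, seed: int | None = None) -> pd.DataFrame:
        """Train-NR x test-NR matrix for one target (seed-mean if None)."""
        arr = self.rmse[target]
        if seed is None:
            data = arr.mean(axis=0)
        else:
            data = arr[list(self.config.seeds).index(seed)]
        levels = list(self.config.nr_levels)
        return pd.DataFrame(
            data,
            index=pd.Index(levels, name="train_nr"),
            columns=pd.Index(levels, name="test_nr"),
        )


def _train_one(
    train_cfg: SynthesisConfig,
    config: CrossTestConfig,
    target: str,
    fit_seed: int,
) -> RegressorModel:
    train_ds = generate_dataset(train_cfg)
    if config.grid is not None and len(config.grid) > 1:
        val_cfg = SynthesisConfig(
            n=config.n_val,
            mode=train_cfg.mode,
            nr=train_cfg.nr,
            seed=derive_seed(train_cfg.seed, "val"),
            split="validation",
            ranges=train_cfg.ranges,
            scheme=train_cfg.scheme,
        )
        val_ds = generate_dataset(val_cfg)
        _, model = grid_search(
            train_ds, val_ds, config.grid, target,
            window=config.window, seed=fit_seed,
        )
        return model
    hyper = next(iter(config.grid)) if config.grid is not None else config.hyper
    return train_mlp(train_ds, hyper, target, window=config.window, seed=fit_seed)


def run_cross_test(config: CrossTestConfig) -> CrossTestResult:
    """Train at every noise ratio and test against every noise ratio."""
    levels = config.nr_levels
    shape = (len(config.seeds), len(levels), len(levels))
    rmse = {t: np.zeros(shape) for t in config.targets}
    chosen: dict[tuple[int, float, str], HyperParams] = {}
    for s_idx, seed in enumerate(config.seeds):
        tests = {}
        for test_nr in levels:
            tests[test_nr] = generate_dataset(
                SynthesisConfig(
                    n=config.n_test,
                    mode=config.mode,
                    nr=test_nr,
                    seed=derive_seed(seed, "test", test_nr),
                    split="test",
                    ranges=config.ranges,
                    scheme=config.scheme,
                )
            )
        for t_idx, train_nr in enumerate(levels):
            train_cfg = SynthesisConfig(
                n=config.n_train,
                mode=config.mode,
                nr=train_nr,
                seed=derive_seed(seed, "train", train_nr),
                split="train",
                ranges=config.ranges,
                scheme=config.scheme,
            )
            for target in config.targets:
                model = _train_one(
                    train_cfg,
                    config,
                    target,
                    fit_seed=derive_seed(seed, "fit", train_nr, target),
                )
                chosen[(seed, train_nr, target)] = model.hyper
                for e_idx, test_nr in enumerate(levels):
                    rmse[target][s_idx, t_idx, e_idx] = evaluate(
                        model, tests[test_nr]
                    )
    return CrossTestResult(config=config, rmse=rmse, chosen_hyper=chosen)


# ---------------------------------------------------------------------------
# phantom benchmark
# ---------------------------------------------------------------------------

#: Desk-scale phantom grid: the S0 = 320 foreground keeps >= 1e4 voxels
#: while voxelwise LSF over the whole foreground stays in minutes.
DESK_PHANTOM_SHAPE = (96, 96, 36)

METHODS = ("lsf", "synqsl", "synxqsl-m1", "synxqsl-m3", "synxqsl-m6")


@dataclass(frozen=True)
class PhantomBenchConfig:
    spec: PhantomSpec = field(default_factory=PhantomSpec.default)
    sigma: float = 32.0
    train_nr: float = 0.1  # matched to sigma=32 at the S0=320 level
    n_train: int = 100_000
    methods: tuple[str, ...] = METHODS
    hyper: HyperParams = DESK_HYPERPARAMS
    seed: int = 0
    ranges: ParameterRanges = field(default_factory=ParameterRanges)
    scheme: AcquisitionScheme = DEFAULT_SCHEME


def _method_window_mode(method: str) -> tuple[str, int]:
    if method == "synqsl":
        return "synqsl", 1
    if method.startswith("synxqsl-m"):
        return "synxqsl", int(method.split("-m")[1])
    raise ValueError(f"unknown method {method!r}")


def train_method_models(
    config: PhantomBenchConfig,
    methods: tuple[str, ...] | None = None,
) -> dict[tuple[str, str], RegressorModel]:
    """Train the (method, target) regressors a benchmark needs, in-line."""
    methods = methods or tuple(m for m in config.methods if m != "lsf")
    models: dict[tuple[str, str], RegressorModel] = {}
    datasets = {}
    for method in methods:
        window, mode = _method_window_mode(method)
        if mode not in datasets:
            datasets[mode] = generate_dataset(
                SynthesisConfig(
                    n=config.n_train,
                    mode=mode,
                    nr=config.train_nr,
                    seed=derive_seed(config.seed, "bench-train", mode),
                    split="train",
                    ranges=config.ranges,
                    scheme=config.scheme,
                )
            )
        for target in ("D", "K"):
            models[(method, target)] = train_mlp(
                datasets[mode],
                config.hyper,
                target,
                window=window,
                seed=derive_seed(config.seed, "bench-fit", method, target),
            )
    return models


def run_phantom_benchmark(
    config: PhantomBenchConfig,
    models: dict[tuple[str, str], RegressorModel] | None = None,
) -> tuple[MetricsReport, dict[tuple[str, str], np.ndarray]]:
    """Score the configured methods on one noisy phantom realisation.

    Returns the metrics report and the estimated maps keyed by
    (method, parameter).  D statistics are reported in scaled units
    (x1e-3 mm^2/s) to match convention.
    """
    vol = build_phantom(config.spec)
    dwi = phantom_dwi(
        vol, config.scheme, config.sigma, seed=derive_seed(config.seed, "dwi")
    )
    ml_methods = tuple(m for m in config.methods if m != "lsf")
    if models is None and ml_methods:
        models = train_method_models(config, ml_methods)
    maps: dict[tuple[str, str], np.ndarray] = {}
    for method in config.methods:
        if method == "lsf":
            _, d_map, k_map, _ = lsf_fit_volume(dwi, config.scheme)
        else:
            d_map, _ = predict_volume(dwi, config.scheme, models[(method, "D")])
            k_map, _ = predict_volume(dwi, config.scheme, models[(method, "K")])
        maps[(method, "D")] = d_map
        maps[(method, "K")] = k_map

    fg = vol.foreground_mask()
    bg = vol.cnr_background_mask()
    support = vol.support_mask()
    fg_labels = np.where(fg, vol.labels, 0)
    truth = {"D": vol.d * D_SCALE, "K": vol.k}

    err_rows = []
    map_rows = []
    for method in config.methods:
        for param in ("D", "K"):
            est = maps[(method, param)] * (D_SCALE if param == "D" else 1.0)
            for level in vol.s0_levels():
                mask = fg & vol.s0_level_mask(level)
                rms, emin, emax = signed_error_stats(est, truth[param], mask)
                err_rows.append(
                    {
                        "method": method,
                        "parameter": param,
                        "s0_level": level,
                        "rms": rms,
                        "min": emin,
                        "max": emax,
                    }
                )
            rms_all, _, _ = signed_error_stats(est, truth[param], fg)
            map_rows.append(
                {
                    "method": method,
                    "parameter": param,
                    "rmse": rms_all,
                    "snr": snr(est, fg_labels),
                    "cnr": cnr(est, fg, bg),
                    "ssim": ssim(est, truth[param], support),
                }
            )
    report = MetricsReport(
        errors=pd.DataFrame(err_rows), maps=pd.DataFrame(map_rows)
    )
    return report, maps
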