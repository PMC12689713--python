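"""Synthetic X-Q space training-data generation.

Training samples for synXQSL are built entirely from random numbers:

1. a gold-standard (S0, D, K) triple is drawn uniformly within physiological
   ranges, rejected until it satisfies the monotonic-decay bound
   ``D*K < 3/b_max``;
2. the triple is expanded into a 3x3 local parameter pattern by adding a
   random linear combination of fixed basis patterns (flat / linear /
   quadratic families, selected by the number of bases M in {1, 3, 6});
   every basis has a zero centre element, so the centre voxel always keeps
   the gold-standard values;
3. DKI signals are computed at all nine locations for every b-value and
   corrupted with Rician noise, and the regression features are the decay
   ratios E_ij = S_ij / S_i0 (each location normalised by its own noisy
   b=0 value), giving 9N features per sample.

The whole-weight-set is resampled (never clipped) when any of the nine
cells violates positivity or the decay bound, which preserves uniformity
on the accepted region.  Centres sitting essentially on the constraint
boundary can have a vanishing conditional acceptance probability; the
vectorised generator therefore redraws the centre after a bounded weight
budget (see the methods documentation for the distributional effect).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .dki import (
    D_SCALE,
    AcquisitionScheme,
    DKIParams,
    NoiseSpec,
    dki_signal,
    make_rng,
    monotonic_decay_ok,
)

__all__ = [
    "BASIS_VECTORS",
    "basis_matrix",
    "ParameterRanges",
    "LocalPattern",
    "XQSample",
    "SynthesisConfig",
    "TrainingDataset",
    "sample_center_params",
    "pattern_from_weights",
    "expand_to_pattern",
    "synthesize_sample",
    "generate_patterns",
    "generate_dataset",
]

#: Row-major 3x3 basis patterns u1..u6 (centre element always 0).
#: u1 is the flat basis; u2/u3 are in-plane linear gradients; u4..u6 add
#: the quadratic (curvature / saddle) patterns.
BASIS_VECTORS = np.array(
    [
        [0, 0, 0, 0, 0, 0, 0, 0, 0],
        [-1, 0, 1, -1, 0, 1, -1, 0, 1],
        [-1, -1, -1, 0, 0, 0, 1, 1, 1],
        [1, 0, 1, 1, 0, 1, 1, 0, 1],
        [1, 1, 1, 0, 0, 0, 1, 1, 1],
        [1, 0, -1, 0, 0, 0, -1, 0, 1],
    ],
    dtype=float,
)

#: Row-major index of the centre cell of a 3x3 grid.
CENTER_INDEX = 4

#: Cap on rejection-resampling attempts per sample before declaring the
#: configuration infeasible.
MAX_REJECTIONS = 100_000

#: Allowed basis counts: flat, linear, quadratic pattern families.
MODES = (1, 3, 6)
MODE_NAMES = {1: "flat", 3: "linear", 6: "quadratic"}


def basis_matrix(mode: int) -> np.ndarray:
    """The (M, 9) matrix of basis vectors for a pattern mode M in {1, 3, 6}."""
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}, got {mode}")
    return BASIS_VECTORS[:mode]


@dataclass(frozen=True)
class ParameterRanges:
    """Uniform sampling ranges for the DKI parameters and pattern weights.

    Defaults are the study ranges: S0 in [500, 8000], D in [0.2, 6.0]
    (x1e-3 mm^2/s), K in [0, 4], with the joint bound D*K < 3/b_max.
    Weight ranges are per basis: +/-4000 for S0 and +/-0.5 (scaled units)
    for D and K.  All D quantities are stored internally in mm^2/s.
    """

    s0: tuple[float, float] = (500.0, 8000.0)
    d: tuple[float, float] = (0.2e-3, 6.0e-3)
    k: tuple[float, float] = (0.0, 4.0)
    w_s0: tuple[float, float] = (-4000.0, 4000.0)
    w_d: tuple[float, float] = (-0.5e-3, 0.5e-3)
    w_k: tuple[float, float] = (-0.5, 0.5)

    def __post_init__(self) -> None:
        for name in ("s0", "d", "k", "w_s0", "w_d", "w_k"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ValueError(f"range {name} must have min < max, got {lo}, {hi}")

    @property
    def s0_mean(self) -> float:
        """Midpoint of the S0 range, the normaliser for the noise ratio."""
        return 0.5 * (self.s0[0] + self.s0[1])


@dataclass(frozen=True)
class LocalPattern:
    """A 3x3 local pattern of (S0, D, K) with its generating weights.

    Grids are (3, 3) row-major arrays; the centre cell ``[1, 1]`` is the
    sampled gold standard, preserved exactly because every basis pattern
    has a zero centre element.
    """

    s0: np.ndarray
    d: np.ndarray
    k: np.ndarray
    weights: dict[str, np.ndarray]

    @property
    def center(self) -> DKIParams:
        return DKIParams(S0=self.s0[1, 1], D=self.d[1, 1], K=self.k[1, 1])

    def cells(self) -> np.ndarray:
        """(9, 3) array of (S0, D, K) per cell, row-major."""
        return np.stack([self.s0.ravel(), self.d.ravel(), self.k.ravel()], axis=1)


@dataclass(frozen=True)
class XQSample:
    """One noisy X-Q space sample: 9 x (N+1) signals plus targets.

    ``signals[i, j]`` is the (noisy) signal at location i (row-major over
    the 3x3 grid) and b-value index j (j=0 is the baseline).  Features are
    the decay ratios of each location normalised by its own b=0 signal,
    flattened location-major.
    """

    signals: np.ndarray
    target_d: float
    target_k: float
    noise: NoiseSpec

    @property
    def features(self) -> np.ndarray:
        return (self.signals[:, 1:] / self.signals[:, :1]).ravel()


FEATURE_ORDER = "location-major(row-major 3x3), b ascending"


@dataclass(frozen=True)
class SynthesisConfig:
    """Everything needed to regenerate a dataset deterministically."""

    n: int
    mode: int = 6
    nr: float = 0.0
    seed: int = 0
    split: str = "train"
    ranges: ParameterRanges = field(default_factory=ParameterRanges)
    scheme: AcquisitionScheme = None  # type: ignore[assignment]
    bit_generator: str = "mt19937"

    def __post_init__(self) -> None:
        from .dki import DEFAULT_SCHEME

        if self.scheme is None:
            object.__setattr__(self, "scheme", DEFAULT_SCHEME)
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.nr < 0:
            raise ValueError("noise ratio must be >= 0")

    @property
    def noise(self) -> NoiseSpec:
        return NoiseSpec.from_noise_ratio(self.nr, self.ranges.s0_mean)


@dataclass
class TrainingDataset:
    """A generated set of X-Q samples stored columnar.

    ``signals`` has shape (n, 9, N+1); targets are the centre-cell D
    (mm^2/s) and K.  ``features`` returns the full 9N synXQSL feature
    matrix; ``center_features`` the N-dimensional single-voxel (synQSL)
    features of the centre location.
    """

    signals: np.ndarray
    target_d: np.ndarray
    target_k: np.ndarray
    config: SynthesisConfig
    feature_order: str = FEATURE_ORDER

    def __len__(self) -> int:
        return self.signals.shape[0]

    @property
    def features(self) -> np.ndarray:
        s = self.signals
        return (s[:, :, 1:] / s[:, :, :1]).reshape(len(self), -1)

    @property
    def center_features(self) -> np.ndarray:
        s = self.signals[:, CENTER_INDEX]
        return s[:, 1:] / s[:, :1]

    def features_for(self, window: str) -> np.ndarray:
        if window == "synxqsl":
            return self.features
        if window == "synqsl":
            return self.center_features
        raise ValueError("window must be 'synxqsl' or 'synqsl'")

    def targets_for(self, target: str) -> np.ndarray:
        """Regression targets in reporting units (D scaled x1e-3 mm^2/s)."""
        if target == "D":
            return self.target_d * D_SCALE
        if target == "K":
            return self.target_k
        raise ValueError("target must be 'D' or 'K'")

    # -- serialisation ---------------------------------------------------
    def save(self, path: str | Path) -> None:
        path = Path(path)
        np.savez_compressed(
            path.with_suffix(".npz"),
            signals=self.signals,
            target_d=self.target_d,
            target_k=self.target_k,
        )
        meta = asdict(self.config)
        meta["scheme"] = list(self.config.scheme.bvalues)
        meta["feature_order"] = self.feature_order
        path.with_suffix(".json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "TrainingDataset":
        path = Path(path)
        arrays = np.load(path.with_suffix(".npz"))
        meta = json.loads(path.with_suffix(".json").read_text())
        order = meta.pop("feature_order", FEATURE_ORDER)
        meta["scheme"] = AcquisitionScheme(tuple(meta["scheme"]))
        meta["ranges"] = ParameterRanges(
            **{k: tuple(v) for k, v in meta["ranges"].items()}
        )
        cfg = SynthesisConfig(**meta)
        return cls(
            signals=arrays["signals"],
            target_d=arrays["target_d"],
            target_k=arrays["target_k"],
            config=cfg,
            feature_order=order,
        )


# ---------------------------------------------------------------------------
# single-sample operations
# ---------------------------------------------------------------------------


def sample_center_params(
    ranges: ParameterRanges, scheme: AcquisitionScheme, rng: np.random.Generator
) -> DKIParams:
    """Draw one gold-standard triple, rejection-resampled onto D*K < 3/b_max."""
    for _ in range(MAX_REJECTIONS):
        s0 = rng.uniform(*ranges.s0)
        d = rng.uniform(*ranges.d)
        k = rng.uniform(*ranges.k)
        if monotonic_decay_ok(d, k, scheme.b_max):
            return DKIParams(S0=s0, D=d, K=k)
    raise RuntimeError(
        "parameter ranges appear infeasible: no accepted draw in "
        f"{MAX_REJECTIONS} attempts"
    )


def pattern_from_weights(
    center: DKIParams, weights: dict[str, np.ndarray]
) -> LocalPattern:
    """Deterministically build the 3x3 pattern centre + sum_i w_i * u_i.

    ``weights`` maps 's0'/'d'/'k' to length-M weight vectors (M <= 6).
    No validity check is performed here; used both by the random expansion
    and by tests that pin weights by hand.
    """
    grids = {}
    for name, base in (("s0", center.S0), ("d", center.D), ("k", center.K)):
        w = np.asarray(weights[name], dtype=float)
        u = BASIS_VECTORS[: w.size]
        grids[name] = (base + w @ u).reshape(3, 3)
    return LocalPattern(
        s0=grids["s0"],
        d=grids["d"],
        k=grids["k"],
        weights={k: np.asarray(v, dtype=float) for k, v in weights.items()},
    )


def _pattern_valid(pat: LocalPattern, b_max: float) -> bool:
    c = pat.cells()
    s0, d, k = c[:, 0], c[:, 1], c[:, 2]
    return bool(
        np.all(s0 > 0)
        and np.all(d > 0)
        and np.all(k >= 0)
        and np.all(d * k < 3.0 / b_max)
    )


def expand_to_pattern(
    center: DKIParams,
    mode: int,
    ranges: ParameterRanges,
    scheme: AcquisitionScheme,
    rng: np.random.Generator,
    max_attempts: int = MAX_REJECTIONS,
) -> LocalPattern:
    """Expand a centre triple into a valid 3x3 pattern of mode M.

    Weights are drawn independently per parameter and per basis; the whole
    weight set is resampled until all nine cells are physically valid
    (positivity and monotonic decay).  M=1 always yields a flat pattern.
    Centres very close to the D*K bound may exhaust ``max_attempts``
    (their conditional acceptance probability can be arbitrarily small),
    which raises a configuration error.
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}")
    for _ in range(max_attempts):
        weights = {
            "s0": rng.uniform(*ranges.w_s0, size=mode),
            "d": rng.uniform(*ranges.w_d, size=mode),
            "k": rng.uniform(*ranges.w_k, size=mode),
        }
        pat = pattern_from_weights(center, weights)
        if _pattern_valid(pat, scheme.b_max):
            return pat
    raise RuntimeError(
        f"no valid pattern found in {max_attempts} weight resamples; "
        "weight ranges are likely infeasible for this centre"
    )


def synthesize_sample(
    pattern: LocalPattern,
    scheme: AcquisitionScheme,
    noise: NoiseSpec,
    rng: np.random.Generator,
    max_redraws: int = 100,
) -> XQSample:
    """Forward-model all nine cells and apply Rician noise at every (i, j).

    Noise is applied to the b=0 signals too; in the (practically
    unreachable) event a noisy baseline falls below the machine-epsilon
    guard, the noise realisation for the sample is redrawn.
    """
    cells = pattern.cells()
    b = scheme.b
    clean = dki_signal(
        b[np.newaxis, :],
        S0=cells[:, :1],
        D=cells[:, 1:2],
        K=cells[:, 2:3],
    )
    eps = np.finfo(float).eps * float(np.max(clean))
    for _ in range(max_redraws):
        if noise.sigma == 0:
            noisy = clean
        else:
            g = rng.normal(0.0, noise.sigma, size=clean.shape)
            noisy = np.sqrt(clean * clean + g * g)
        if np.all(noisy[:, 0] > eps):
            center = pattern.center
            return XQSample(
                signals=noisy,
                target_d=center.D,
                target_k=center.K,
                noise=noise,
            )
    raise RuntimeError("degenerate sample: baseline signal repeatedly below guard")


# ---------------------------------------------------------------------------
# vectorised dataset generation
# ---------------------------------------------------------------------------


def _sample_centers_batch(
    n: int, ranges: ParameterRanges, b_max: float, rng: np.random.Generator
) -> np.ndarray:
    """(n, 3) accepted centre triples, batch rejection sampling."""
    out = np.empty((n, 3))
    filled = 0
    attempts = 0
    while filled < n:
        need = n - filled
        batch = max(need * 2, 64)
        s0 = rng.uniform(*ranges.s0, size=batch)
        d = rng.uniform(*ranges.d, size=batch)
        k = rng.uniform(*ranges.k, size=batch)
        ok = d * k < 3.0 / b_max
        take = min(int(ok.sum()), need)
        idx = np.nonzero(ok)[0][:take]
        out[filled : filled + take, 0] = s0[idx]
        out[filled : filled + take, 1] = d[idx]
        out[filled : filled + take, 2] = k[idx]
        filled += take
        attempts += batch
        if attempts > MAX_REJECTIONS * max(n, 1) and filled == 0:
            raise RuntimeError("centre parameter ranges appear infeasible")
    return out


#: Weight resampling budget per centre in the vectorised generator; a
#: centre whose conditional acceptance is far below 1/budget is redrawn
#: rather than retried forever (see the methods note on sampling).
WEIGHT_ROUNDS_PER_CENTER = 200

#: Cap on centre-redraw cycles in the vectorised generator.
MAX_CYCLES = 1000


def _generate_joint(
    n: int,
    mode: int,
    ranges: ParameterRanges,
    b_max: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Jointly sample ``n`` valid (centre, pattern) pairs, vectorised.

    Each pending sample gets a fresh accepted centre, then up to
    ``WEIGHT_ROUNDS_PER_CENTER`` whole-weight-set draws; if none yields
    nine valid cells the centre itself is redrawn.  Returns
    ``(centers (n, 3), cells (n, 9, 3))``.
    """
    u = basis_matrix(mode)  # (M, 9)
    bound = 3.0 / b_max
    centers = np.empty((n, 3))
    cells = np.empty((n, 9, 3))
    pending = np.arange(n)
    for _ in range(MAX_CYCLES):
        if pending.size == 0:
            return centers, cells
        centers[pending] = _sample_centers_batch(
            pending.size, ranges, b_max, rng
        )
        local = pending
        for _ in range(WEIGHT_ROUNDS_PER_CENTER):
            m = local.size
            if m == 0:
                break
            w_s0 = rng.uniform(*ranges.w_s0, size=(m, mode))
            w_d = rng.uniform(*ranges.w_d, size=(m, mode))
            w_k = rng.uniform(*ranges.w_k, size=(m, mode))
            c = centers[local]
            s0 = c[:, 0:1] + w_s0 @ u
            d = c[:, 1:2] + w_d @ u
            k = c[:, 2:3] + w_k @ u
            ok = (
                np.all(s0 > 0, axis=1)
                & np.all(d > 0, axis=1)
                & np.all(k >= 0, axis=1)
                & np.all(d * k < bound, axis=1)
            )
            done = local[ok]
            cells[done, :, 0] = s0[ok]
            cells[done, :, 1] = d[ok]
            cells[done, :, 2] = k[ok]
            local = local[~ok]
        pending = local
    raise RuntimeError(
        "pattern sampling did not converge; configuration infeasible"
    )


def generate_patterns(
    n: int,
    mode: int,
    ranges: ParameterRanges | None = None,
    scheme: AcquisitionScheme | None = None,
    rng: np.random.Generator | None = None,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised sampling of n valid local patterns.

    Returns ``(centers, cells)`` with shapes (n, 3) and (n, 9, 3); the
    row-major centre cell ``cells[:, 4, :]`` equals ``centers`` exactly.
    """
    from .dki import DEFAULT_SCHEME

    ranges = ranges or ParameterRanges()
    scheme = scheme or DEFAULT_SCHEME
    if rng is None:
        rng = make_rng(seed)
    return _generate_joint(n, mode, ranges, scheme.b_max, rng)


def generate_dataset(config: SynthesisConfig) -> TrainingDataset:
    """Generate ``config.n`` independent X-Q samples (vectorised, seeded).

    sigma is ``NR x s0_mean`` with ``s0_mean`` the midpoint of the S0
    range.  Identical config (including seed and bit generator) yields a
    byte-identical dataset.
    """
    rng = make_rng(config.seed, config.bit_generator)
    scheme = config.scheme
    noise = config.noise
    centers, cells = _generate_joint(
        config.n, config.mode, config.ranges, scheme.b_max, rng
    )
    b = scheme.b
    clean = cells[:, :, 0:1] * np.exp(
        -b * cells[:, :, 1:2] + b * b * cells[:, :, 1:2] ** 2 * cells[:, :, 2:3] / 6.0
    )
    if noise.sigma > 0:
        g = rng.normal(0.0, noise.sigma, size=clean.shape)
        signals = np.sqrt(clean * clean + g * g)
        eps = np.finfo(float).eps * float(np.max(clean))
        bad = np.nonzero(signals[:, :, 0] <= eps)
        for i, j in zip(*bad):  # pragma: no cover - essentially unreachable
            while signals[i, j, 0] <= eps:
                gg = rng.normal(0.0, noise.sigma)
                signals[i, j, 0] = np.sqrt(clean[i, j, 0] ** 2 + gg * gg)
    else:
        signals = clean
    return TrainingDataset(
        signals=signals,
        target_d=centers[:, 1].copy(),
        target_k=centers[:, 2].copy(),
        config=config,
    )
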