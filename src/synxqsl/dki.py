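"""Diffusional kurtosis imaging (DKI) signal model and Rician noise simulation.

The DKI model describes non-Gaussian water diffusion in tissue.  For an
isotropic acquisition with scalar b-values the signal decays as

    S(b) = S0 * exp(-b*D + b^2 * D^2 * K / 6)

where ``S0`` is the ideal baseline (b=0) signal, ``D`` the diffusion
coefficient (mm^2/s) and ``K`` the dimensionless diffusional kurtosis.
The quadratic term makes the decay non-monotonic for large ``b`` unless
``D*K < 3/b_max``, which is enforced throughout this package.

Magnitude MR images carry Rician noise; in the high-SNR regime the simple
model ``S' = sqrt(S^2 + g^2)`` with ``g ~ N(0, sigma)`` is used here.
Noise levels are parameterised by the noise ratio ``NR = sigma / mean(S0)``.

Internally ``D`` is always stored in mm^2/s; user-facing reports use the
conventional scaled units of 1e-3 mm^2/s (see :data:`D_SCALE`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "D_SCALE",
    "AcquisitionScheme",
    "DKIParams",
    "NoiseSpec",
    "dki_signal",
    "monotonic_decay_ok",
    "add_rician_noise",
    "sigma_for_noise_ratio",
    "noise_ratio",
    "make_rng",
]

#: Multiply an internal D (mm^2/s) by this to get the conventional
#: reporting scale of 1e-3 mm^2/s.  Single conversion point.
D_SCALE = 1.0e3


@dataclass(frozen=True)
class AcquisitionScheme:
    """An ordered list of b-values with a single leading b=0 acquisition.

    Parameters
    ----------
    bvalues
        Diffusion weightings in s/mm^2.  The first entry must be exactly 0
        (the single baseline acquisition); the remaining ``N`` entries must
        be strictly positive and strictly increasing, with ``N >= 2``.
    """

    bvalues: tuple[float, ...]

    def __post_init__(self) -> None:
        b = np.asarray(self.bvalues, dtype=float)
        if b.ndim != 1 or b.size < 3:
            raise ValueError("scheme needs b=0 plus at least 2 non-zero b-values")
        if b[0] != 0.0:
            raise ValueError("first b-value must be 0 (single baseline acquisition)")
        if np.any(b[1:] <= 0.0):
            raise ValueError("non-zero b-values must be strictly positive")
        if np.any(np.diff(b[1:]) <= 0.0):
            raise ValueError("non-zero b-values must be strictly increasing")
        object.__setattr__(self, "bvalues", tuple(float(x) for x in b))

    @property
    def b(self) -> np.ndarray:
        return np.asarray(self.bvalues, dtype=float)

    @property
    def n_nonzero(self) -> int:
        """N, the number of non-zero b-values."""
        return len(self.bvalues) - 1

    @property
    def b_max(self) -> float:
        return self.bvalues[-1]


#: The clinical breast protocol scheme used throughout the experiments
#: (b = 0, 50, 850, 1000, 1500, 2000, 2500 s/mm^2).
DEFAULT_SCHEME = AcquisitionScheme((0.0, 50.0, 850.0, 1000.0, 1500.0, 2000.0, 2500.0))


@dataclass(frozen=True)
class DKIParams:
    """One voxel's (S0, D, K) triple.

    ``D`` is in mm^2/s (internal, unscaled).  ``check_decay_for`` optionally
    enforces the monotonic-decay bound D*K < 3/b_max at construction.
    """

    S0: float
    D: float
    K: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.S0) and np.isfinite(self.D) and np.isfinite(self.K)):
            raise ValueError("non-finite DKI parameters")
        if self.S0 <= 0 or self.D <= 0 or self.K < 0:
            raise ValueError(
                f"invalid DKI parameters S0={self.S0}, D={self.D}, K={self.K}"
            )

    def check_decay(self, b_max: float) -> "DKIParams":
        if not monotonic_decay_ok(self.D, self.K, b_max):
            raise ValueError(
                f"D*K = {self.D * self.K:g} violates monotonic decay bound "
                f"3/b_max = {3.0 / b_max:g}"
            )
        return self


@dataclass(frozen=True)
class NoiseSpec:
    """Rician noise level, tied to its baseline-signal normalisation.

    ``noise_ratio`` (NR) is sigma divided by ``s0_mean``, the mean baseline
    signal of the population the noise is calibrated against.
    """

    sigma: float
    s0_mean: float
    noise_ratio: float = field(init=False)

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.s0_mean <= 0:
            raise ValueError("s0_mean must be > 0")
        object.__setattr__(self, "noise_ratio", self.sigma / self.s0_mean)

    @classmethod
    def from_noise_ratio(cls, nr: float, s0_mean: float) -> "NoiseSpec":
        return cls(sigma=sigma_for_noise_ratio(nr, s0_mean), s0_mean=s0_mean)


def dki_signal(b, params: DKIParams | None = None, *, S0=None, D=None, K=None):
    """Evaluate the DKI signal S0*exp(-b*D + b^2*D^2*K/6).

    Accepts either a :class:`DKIParams` or explicit arrays for ``S0``, ``D``,
    ``K`` (broadcast against ``b``), so the same kernel serves single-voxel
    evaluation and whole-volume forward simulation.
    """
    if params is not None:
        S0, D, K = params.S0, params.D, params.K
    b = np.asarray(b, dtype=float)
    S0 = np.asarray(S0, dtype=float)
    D = np.asarray(D, dtype=float)
    K = np.asarray(K, dtype=float)
    if np.any(b < 0) or not np.all(np.isfinite(b)):
        raise ValueError("b-values must be finite and >= 0")
    if np.any(S0 <= 0) or np.any(D <= 0) or np.any(K < 0):
        raise ValueError("require S0 > 0, D > 0, K >= 0")
    out = S0 * np.exp(-b * D + b * b * D * D * K / 6.0)
    if out.ndim == 0:
        return float(out)
    return out


def monotonic_decay_ok(D, K, b_max) -> bool | np.ndarray:
    """True iff D*K < 3/b_max (strict), the monotonic signal-decay bound.

    d/db [-bD + b^2 D^2 K / 6] = -D + b D^2 K / 3 stays negative on
    [0, b_max] exactly when D*K < 3/b_max.
    """
    b_max = float(b_max)
    if b_max <= 0 or not np.isfinite(b_max):
        raise ValueError("b_max must be positive and finite")
    D = np.asarray(D, dtype=float)
    K = np.asarray(K, dtype=float)
    ok = D * K < 3.0 / b_max
    if ok.ndim == 0:
        return bool(ok)
    return ok


def add_rician_noise(signal, sigma: float, rng: np.random.Generator):
    """Corrupt a signal with the simple Rician model sqrt(S^2 + N(0,sigma)^2).

    A single Gaussian deviate is drawn per signal value.  The output is
    always >= the input and equals it exactly when ``sigma == 0``.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    s = np.asarray(signal, dtype=float)
    if np.any(s < 0):
        raise ValueError("signal must be >= 0")
    if sigma == 0:
        return float(s) if s.ndim == 0 else s.copy()
    g = rng.normal(0.0, sigma, size=s.shape)
    out = np.sqrt(s * s + g * g)
    if out.ndim == 0:
        return float(out)
    return out


def sigma_for_noise_ratio(nr: float, s0_mean: float) -> float:
    """sigma = NR * mean baseline signal."""
    if s0_mean <= 0:
        raise ValueError("s0_mean must be > 0")
    if nr < 0:
        raise ValueError("noise ratio must be >= 0")
    return nr * s0_mean


def noise_ratio(sigma: float, s0_mean: float) -> float:
    """NR = sigma / mean baseline signal; exact inverse of sigma_for_noise_ratio."""
    if s0_mean <= 0:
        raise ValueError("s0_mean must be > 0")
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    return sigma / s0_mean


def make_rng(seed, bit_generator: str = "mt19937") -> np.random.Generator:
    """Seeded generator; Mersenne twister by default, PCG64 selectable."""
    if bit_generator == "mt19937":
        return np.random.Generator(np.random.MT19937(seed))
    if bit_generator == "pcg64":
        return np.random.Generator(np.random.PCG64(seed))
    raise ValueError(f"unknown bit generator {bit_generator!r}")
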