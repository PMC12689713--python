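"""Digital phantom: region-wise constant DKI parameter maps and noisy DWI.

The phantom is a 3D grid (default 128x128x128) split into three equal
slabs, one per baseline-signal level S0 in {240, 320, 400}.  Within each
slab two rows of square boxes vary the remaining parameters: a row of
five boxes sweeps K (including a K=0, D!=0 box that serves as the CNR
background) at fixed D, and a row of three boxes sweeps D at fixed K.
Every (D, K) pairing respects the monotonic-decay bound for the default
b-value scheme (b_max = 2500 s/mm^2).  Everything outside a box is
background (S0 = D = K = 0).

The exact per-region geometry and parameter values are configurable; the
defaults below are the package's own constraint-respecting choices, so
benchmark numbers on this phantom are comparable across methods but are
not tied to any external phantom instance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dki import AcquisitionScheme, make_rng, monotonic_decay_ok

__all__ = [
    "PhantomRegion",
    "PhantomSpec",
    "ParameterVolume",
    "build_phantom",
    "phantom_dwi",
]

S0_LEVELS = (240.0, 320.0, 400.0)
D_LEVELS = (0.5e-3, 1.0e-3, 2.0e-3)
K_LEVELS = (0.0, 0.25, 0.5, 0.75, 1.0)


@dataclass(frozen=True)
class PhantomRegion:
    """An axis-aligned box with constant (S0, D, K)."""

    name: str
    box: tuple[int, int, int, int, int, int]  # x0, x1, y0, y1, z0, z1 (half-open)
    s0: float
    d: float
    k: float

    def slices(self) -> tuple[slice, slice, slice]:
        x0, x1, y0, y1, z0, z1 = self.box
        return slice(x0, x1), slice(y0, y1), slice(z0, z1)

    def n_voxels(self) -> int:
        x0, x1, y0, y1, z0, z1 = self.box
        return max(x1 - x0, 0) * max(y1 - y0, 0) * max(z1 - z0, 0)


@dataclass(frozen=True)
class PhantomSpec:
    """Grid dimensions plus a list of non-overlapping labelled regions."""

    shape: tuple[int, int, int] = (128, 128, 128)
    regions: tuple[PhantomRegion, ...] = ()
    check_decay_bmax: float | None = 2500.0

    def __post_init__(self) -> None:
        for r in self.regions:
            x0, x1, y0, y1, z0, z1 = r.box
            if not (
                0 <= x0 < x1 <= self.shape[0]
                and 0 <= y0 < y1 <= self.shape[1]
                and 0 <= z0 < z1 <= self.shape[2]
            ):
                raise ValueError(f"region {r.name} box outside the grid")
            if r.s0 <= 0 or r.d <= 0 or r.k < 0:
                raise ValueError(f"region {r.name} has non-physical parameters")
            if self.check_decay_bmax is not None and not monotonic_decay_ok(
                r.d, r.k, self.check_decay_bmax
            ):
                raise ValueError(
                    f"region {r.name} violates D*K < 3/b_max at "
                    f"b_max={self.check_decay_bmax}"
                )

    @classmethod
    def from_dict(cls, data: dict) -> "PhantomSpec":
        """Build a spec from a plain mapping (e.g. parsed JSON/YAML).

        Expected keys: ``shape`` (3 ints) and ``regions``, a list of
        mappings with ``name``, ``box`` (x0,x1,y0,y1,z0,z1), ``s0``,
        ``d`` and ``k``; optional ``check_decay_bmax``.
        """
        regions = tuple(
            PhantomRegion(
                name=r["name"],
                box=tuple(int(v) for v in r["box"]),
                s0=float(r["s0"]),
                d=float(r["d"]),
                k=float(r["k"]),
            )
            for r in data.get("regions", ())
        )
        return cls(
            shape=tuple(int(v) for v in data.get("shape", (128, 128, 128))),
            regions=regions,
            check_decay_bmax=data.get("check_decay_bmax", 2500.0),
        )

    @classmethod
    def default(cls, shape: tuple[int, int, int] = (128, 128, 128)) -> "PhantomSpec":
        """The standard layout: 3 S0 slabs x (5 K boxes + 3 D boxes)."""
        nx, ny, nz = shape
        w = max(nx // 8, 2)  # box edge length in-plane
        regions: list[PhantomRegion] = []
        slab = nz // 3
        for si, s0 in enumerate(S0_LEVELS):
            z0, z1 = si * slab, (si + 1) * slab
            # K row: five boxes at fixed D = 1.0e-3, y centred at ny/4
            y0 = max(ny // 4 - w // 2, 0)
            for ki, k in enumerate(K_LEVELS):
                xc = (ki + 1) * nx // 6
                x0 = max(xc - w // 2, 0)
                regions.append(
                    PhantomRegion(
                        name=f"S0{int(s0)}_K{ki}",
                        box=(x0, x0 + w, y0, y0 + w, z0, z1),
                        s0=s0,
                        d=1.0e-3,
                        k=k,
                    )
                )
            # D row: three boxes at fixed K = 0.5, y centred at 3*ny/4
            y0 = min(3 * ny // 4 - w // 2, ny - w)
            for di, d in enumerate(D_LEVELS):
                xc = (di + 1) * nx // 4
                x0 = max(xc - w // 2, 0)
                regions.append(
                    PhantomRegion(
                        name=f"S0{int(s0)}_D{di}",
                        box=(x0, x0 + w, y0, y0 + w, z0, z1),
                        s0=s0,
                        d=d,
                        k=0.5,
                    )
                )
        return cls(shape=shape, regions=tuple(regions))


@dataclass
class ParameterVolume:
    """Ground-truth parameter maps with a region label map.

    Labels: 0 = background, i >= 1 = ``spec.regions[i-1]``.  Mask helpers
    reproduce the benchmark's evaluation regions: foreground (K != 0),
    CNR background (K = 0 and D != 0) and the image support (S0 != 0).
    """

    s0: np.ndarray
    d: np.ndarray
    k: np.ndarray
    labels: np.ndarray
    spec: PhantomSpec
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.s0.shape

    def foreground_mask(self) -> np.ndarray:
        return self.k != 0

    def cnr_background_mask(self) -> np.ndarray:
        return (self.k == 0) & (self.d != 0)

    def support_mask(self) -> np.ndarray:
        return self.s0 != 0

    def s0_level_mask(self, level: float) -> np.ndarray:
        return self.s0 == level

    def s0_levels(self) -> tuple[float, ...]:
        vals = np.unique(self.s0[self.s0 > 0])
        return tuple(float(v) for v in vals)


def build_phantom(spec: PhantomSpec) -> ParameterVolume:
    """Rasterise a spec into deterministic parameter maps; rejects overlaps."""
    s0 = np.zeros(spec.shape)
    d = np.zeros(spec.shape)
    k = np.zeros(spec.shape)
    labels = np.zeros(spec.shape, dtype=np.int32)
    for idx, region in enumerate(spec.regions, start=1):
        sl = region.slices()
        if np.any(labels[sl] != 0):
            raise ValueError(f"region {region.name} overlaps an earlier region")
        labels[sl] = idx
        s0[sl] = region.s0
        d[sl] = region.d
        k[sl] = region.k
    return ParameterVolume(s0=s0, d=d, k=k, labels=labels, spec=spec)


def phantom_dwi(
    vol: ParameterVolume,
    scheme: AcquisitionScheme,
    sigma: float,
    seed: int = 0,
    bit_generator: str = "mt19937",
) -> np.ndarray:
    """Forward-model the phantom into a noisy 4D DWI volume.

    Per voxel the DKI signal is evaluated for every b-value and corrupted
    with Rician noise of the given sigma (background voxels with S0 = 0
    produce pure-noise magnitude signals).  Seed-reproducible.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    b = scheme.b
    d = vol.d[..., None]
    expo = -b * d + b * b * d * d * vol.k[..., None] / 6.0
    clean = vol.s0[..., None] * np.exp(expo)
    clean[vol.s0 == 0] = 0.0
    if sigma == 0:
        return clean
    rng = make_rng(seed, bit_generator)
    g = rng.normal(0.0, sigma, size=clean.shape)
    return np.sqrt(clean * clean + g * g)
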