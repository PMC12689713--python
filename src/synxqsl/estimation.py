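"""Volume-level DKI estimation with a model/results interface.

:class:`DKIVolumeModel` wraps a 4D DWI volume plus its b-value scheme;
``fit`` runs either the conventional least-squares baseline or a pair of
trained regressors (one for D, one for K) and returns a
:class:`DKIFitResults` carrying the parameter maps, validity/convergence
diagnostics and a ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dki import AcquisitionScheme, D_SCALE
from .io import load_volume, read_bvals
from .lsf import lsf_fit_volume
from .regress import RegressorModel, predict_volume

__all__ = ["DKIVolumeModel", "DKIFitResults"]


@dataclass
class DKIFitResults:
    """Estimated DKI parameter maps and their diagnostics.

    ``d`` is in mm^2/s (use ``d_scaled`` for the x1e-3 reporting
    convention).  ``valid`` flags voxels actually estimated; for LSF it is
    additionally the convergence mask.  ``s0`` is None for regressor fits
    (they predict only D or K).
    """

    method: str
    d: np.ndarray
    k: np.ndarray
    valid: np.ndarray
    s0: np.ndarray | None = None
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    @property
    def d_scaled(self) -> np.ndarray:
        return self.d * D_SCALE

    def summary(self) -> pd.DataFrame:
        """Per-parameter statistics over the valid voxels."""
        rows = []
        maps = {"D (x1e-3 mm^2/s)": self.d_scaled, "K": self.k}
        if self.s0 is not None:
            maps["S0"] = self.s0
        for name, arr in maps.items():
            vals = arr[self.valid] if self.valid.any() else np.array([0.0])
            rows.append(
                {
                    "parameter": name,
                    "n_voxels": int(self.valid.sum()),
                    "mean": float(vals.mean()),
                    "sd": float(vals.std()),
                    "min": float(vals.min()),
                    "max": float(vals.max()),
                }
            )
        return pd.DataFrame(rows)


class DKIVolumeModel:
    """A 4D diffusion-weighted volume bound to its acquisition scheme."""

    def __init__(
        self,
        dwi: np.ndarray,
        scheme: AcquisitionScheme,
        affine: np.ndarray | None = None,
    ) -> None:
        dwi = np.asarray(dwi, dtype=float)
        if dwi.ndim != 4:
            raise ValueError("expected a 4D volume (x, y, z, b)")
        if dwi.shape[3] != len(scheme.bvalues):
            raise ValueError("volume frame count does not match the scheme")
        self.dwi = dwi
        self.scheme = scheme
        self.affine = np.eye(4) if affine is None else np.asarray(affine)

    @classmethod
    def from_files(cls, dwi_path, bval_path) -> "DKIVolumeModel":
        data, affine = load_volume(dwi_path)
        return cls(data, read_bvals(bval_path), affine=affine)

    def fit(self, clamp: bool = False) -> DKIFitResults:
        """Voxelwise nonlinear least-squares fit (the LSF baseline)."""
        s0, d, k, conv = lsf_fit_volume(self.dwi, self.scheme, clamp=clamp)
        return DKIFitResults(
            method="lsf", d=d, k=k, valid=conv, s0=s0, affine=self.affine
        )

    def fit_regressor(
        self, d_model: RegressorModel, k_model: RegressorModel
    ) -> DKIFitResults:
        """Apply a trained (D, K) regressor pair voxelwise."""
        if d_model.target != "D" or k_model.target != "K":
            raise ValueError("need one D-target and one K-target model")
        if d_model.window != k_model.window:
            raise ValueError("D and K models use different window modes")
        d, valid = predict_volume(self.dwi, self.scheme, d_model)
        k, _ = predict_volume(self.dwi, self.scheme, k_model)
        return DKIFitResults(
            method=d_model.window, d=d, k=k, valid=valid, affine=self.affine
        )
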