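"""File I/O: FSL-style bval files and NIfTI volumes (via nibabel)."""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np

from .dki import AcquisitionScheme

__all__ = ["read_bvals", "write_bvals", "load_volume", "save_volume"]


def read_bvals(path: str | Path) -> AcquisitionScheme:
    """Read a whitespace-separated bval text file into a scheme."""
    values = [float(tok) for tok in Path(path).read_text().split()]
    return AcquisitionScheme(tuple(values))


def write_bvals(path: str | Path, scheme: AcquisitionScheme) -> None:
    Path(path).write_text(" ".join(f"{b:g}" for b in scheme.bvalues) + "\n")


def load_volume(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Load a NIfTI volume; returns (data, affine)."""
    img = nib.load(str(path))
    return np.asarray(img.get_fdata(), dtype=float), img.affine


def save_volume(path: str | Path, data: np.ndarray, affine: np.ndarray) -> None:
    nib.save(nib.Nifti1Image(np.asarray(data), affine), str(path))
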