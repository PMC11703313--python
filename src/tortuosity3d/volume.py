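"""Labelled 3D volumes and NIfTI I/O.

The pipeline works in world millimetres throughout: voxel indices are 0-based,
coordinates refer to voxel centers, and the mapping to physical space goes
through the 4x4 affine (sform preferred over qform when reading NIfTI, as
nibabel's ``get_fdata``/``affine`` convention already encodes).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

from .errors import InvalidSpecError

log = logging.getLogger(__name__)


@dataclass
class LabelVolume:
    """A 3D integer (or boolean) voxel grid with its voxel-to-world affine.

    Parameters
    ----------
    voxels : ndarray of shape (nx, ny, nz)
        Integer label values (0 = background) or a boolean mask.
    affine : ndarray of shape (4, 4)
        Voxel-index-to-millimetre transform, voxel-center convention.
    """

    voxels: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise InvalidSpecError(
                f"volume must be 3D, got shape {self.voxels.shape}"
            )
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise InvalidSpecError("affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise InvalidSpecError("affine is singular")

    @property
    def spacing(self) -> np.ndarray:
        """Per-axis voxel size in mm (column norms of the linear part)."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def shape(self) -> tuple:
        return self.voxels.shape

    def voxels_to_world(self, idx: np.ndarray) -> np.ndarray:
        """Map (N, 3) voxel indices to (N, 3) world-mm coordinates."""
        idx = np.atleast_2d(np.asarray(idx, dtype=float))
        return idx @ self.affine[:3, :3].T + self.affine[:3, 3]

    def save(self, path) -> None:
        img = nib.Nifti1Image(
            np.asarray(self.voxels, dtype=np.int16), self.affine
        )
        nib.save(img, str(path))

    @classmethod
    def load(cls, path) -> "LabelVolume":
        """Read a NIfTI-1 labelmap, honouring the stored sform/qform."""
        path = Path(path)
        img = nib.load(str(path))
        sform_code = int(img.header["sform_code"])
        which = "sform" if sform_code > 0 else "qform"
        log.info("loaded %s using %s affine", path.name, which)
        data = np.asanyarray(img.dataobj)
        if not np.issubdtype(data.dtype, np.integer):
            data = np.rint(data).astype(np.int32)
        return cls(voxels=data, affine=img.affine)
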