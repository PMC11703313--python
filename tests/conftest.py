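import math

import numpy as np
import pytest

import tortuosity3d as t3d

HELIX_R = 1.0
HELIX_PITCH = 2 * math.pi
HELIX_L = 2 * math.pi * math.sqrt(2.0)  # one turn, r=1, c=1


@pytest.fixture(scope="session")
def helix200():
    """Clean unit helix (r=1 mm, pitch=2*pi mm, 1 turn, kappa=0.5)."""
    return t3d.make_helix(
        t3d.HelixSpec(radius=HELIX_R, pitch=HELIX_PITCH, turns=1, n_points=200)
    )


@pytest.fixture(scope="session")
def voxel_helix():
    """Voxelized helix tube at segmentation-like resolution, with truth."""
    curve = t3d.make_helix(
        t3d.HelixSpec(radius=10.0, pitch=10.0, turns=2, n_points=400)
    )
    vol = t3d.voxelize_tube(curve, tube_radius=1.5, spacing=0.625)
    return vol, curve


@pytest.fixture(scope="session")
def long_helix():
    """Voxelized helix with a long chord (endpoint quantization shifts the
    chord by well under 1%), for flip/permutation invariance checks."""
    curve = t3d.make_helix(
        t3d.HelixSpec(radius=10.0, pitch=40.0, turns=2.5, n_points=500)
    )
    vol = t3d.voxelize_tube(curve, tube_radius=1.5, spacing=0.625)
    return vol, curve


def straight_cylinder(radius_vox=2.5, length_vox=30, spacing=1.0):
    """Axis-aligned filled cylinder mask along x."""
    pad = int(np.ceil(radius_vox)) + 2
    ny = nz = 2 * pad + 1
    vox = np.zeros((length_vox + 2 * pad, ny, nz), dtype=np.int16)
    yy, zz = np.meshgrid(np.arange(ny), np.arange(nz), indexing="ij")
    disk = (yy - pad) ** 2 + (zz - pad) ** 2 <= radius_vox ** 2
    vox[pad:pad + length_vox, disk] = 1
    affine = np.diag([spacing, spacing, spacing, 1.0])
    return t3d.LabelVolume(voxels=vox, affine=affine)


def voxel_ring(radius=8, size=24):
    """Closed one-voxel-wide ring in a single z-slice (loop topology)."""
    vox = np.zeros((size, size, 5), dtype=bool)
    c = size // 2
    theta = np.linspace(0, 2 * np.pi, 2000, endpoint=False)
    ii = np.rint(c + radius * np.cos(theta)).astype(int)
    jj = np.rint(c + radius * np.sin(theta)).astype(int)
    vox[ii, jj, 2] = True
    return t3d.SkeletonMask(voxels=vox, affine=np.eye(4))


def y_skeleton(arm_x=10, arm_y=8, arm_z=3):
    """Y-shaped skeleton: three straight arms meeting at one junction voxel."""
    size = max(arm_x, arm_y, arm_z) + 6
    c = 2
    vox = np.zeros((size, size, size), dtype=bool)
    vox[c, c, c] = True
    vox[c + 1:c + 1 + arm_x, c, c] = True
    vox[c, c + 1:c + 1 + arm_y, c] = True
    vox[c, c, c + 1:c + 1 + arm_z] = True
    return t3d.SkeletonMask(voxels=vox, affine=np.eye(4))


def flip_volume(vol, axis):
    """Flip a volume along one axis, updating the affine to match."""
    vox = np.flip(vol.voxels, axis=axis).copy()
    affine = vol.affine.copy()
    n = vol.voxels.shape[axis]
    affine[:3, 3] += affine[:3, axis] * (n - 1)
    affine[:3, axis] *= -1.0
    return t3d.LabelVolume(voxels=vox, affine=affine)


def permute_volume(vol, perm):
    """Permute volume axes, updating the affine columns to match."""
    vox = np.transpose(vol.voxels, perm).copy()
    affine = vol.affine.copy()
    affine[:3, :3] = affine[:3, :3][:, list(perm)]
    return t3d.LabelVolume(voxels=vox, affine=affine)


METRIC_NAMES = ["aoc", "total_curvature", "mean_squared_curvature",
                "rms_curvature"]


def metric_values(rec):
    return np.array([getattr(rec, m) for m in METRIC_NAMES])
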