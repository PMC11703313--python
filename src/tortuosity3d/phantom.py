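"""Synthetic curves with closed-form curvature, for pipeline validation.

Every downstream stage (skeletonization, spline fitting, metric computation)
is validated against phantoms generated here: helices, circular arcs and
straight lines whose curvature, arc length and tortuosity metrics are known
analytically, optionally perturbed by isotropic Gaussian noise at a controlled
signal-to-noise ratio, and optionally rasterized into binary tube masks so the
full voxel pipeline can run on them exactly as it does on real segmentations.

A circular helix of radius ``r`` and pitch ``p`` (rise per full turn) is

    x(t) = (r cos t, r sin t, c t),   c = p / (2*pi),  t in [0, 2*pi*turns]

with constant curvature ``kappa = r / (r^2 + c^2)`` and arc length per turn
``sqrt((2*pi*r)^2 + p^2)``.  Sampling uniformly in ``t`` is uniform in arc
length, matching the unit-speed parametrization assumed downstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .errors import InvalidSpecError, VoxelizationError
from .volume import LabelVolume

__all__ = [
    "HelixSpec",
    "GroundTruthCurve",
    "make_helix",
    "make_line",
    "make_arc",
    "add_noise",
    "voxelize_tube",
]

#: 26-connectivity structuring element
_STRUCT26 = np.ones((3, 3, 3), dtype=bool)


@dataclass(frozen=True)
class HelixSpec:
    """Parameters of a circular helix phantom.

    Attributes
    ----------
    radius : float
        Helix radius in mm, > 0.
    pitch : float
        Rise per full turn in mm, >= 0 (0 gives a circle).
    turns : float
        Number of revolutions, > 0.
    n_points : int
        Samples along the curve, >= 4.
    noise_sigma : float
        Stddev of isotropic Gaussian coordinate noise in mm, >= 0.
        Mutually exclusive with ``snr``.
    snr : float or None
        Signal-to-noise ratio; sigma is radius / snr.
    seed : int
        Seed for the noise generator.
    """

    radius: float
    pitch: float
    turns: float = 1.0
    n_points: int = 200
    noise_sigma: float = 0.0
    snr: float | None = None
    seed: int = 0

    def __post_init__(self):
        if self.radius <= 0:
            raise InvalidSpecError(f"helix radius must be > 0, got {self.radius}")
        if self.pitch < 0:
            raise InvalidSpecError(f"helix pitch must be >= 0, got {self.pitch}")
        if self.turns <= 0:
            raise InvalidSpecError(f"turns must be > 0, got {self.turns}")
        if self.n_points < 4:
            raise InvalidSpecError(f"n_points must be >= 4, got {self.n_points}")
        if self.noise_sigma < 0:
            raise InvalidSpecError("noise_sigma must be >= 0")
        if self.snr is not None and self.snr <= 0:
            raise InvalidSpecError(f"snr must be > 0, got {self.snr}")
        if self.snr is not None and self.noise_sigma > 0:
            raise InvalidSpecError("give either noise_sigma or snr, not both")


@dataclass
class GroundTruthCurve:
    """An ordered point set with its analytic ground truth.

    ``points`` may be noisy; ``curvature_true``, ``arc_length`` and
    ``metrics_true`` always describe the underlying noiseless curve.
    ``amplitude`` is the characteristic signal scale used to convert an SNR
    into a noise sigma (the radius for helices/arcs, RMS deviation from the
    centroid otherwise).
    """

    points: np.ndarray
    arc_length: float
    curvature_true: np.ndarray
    metrics_true: dict = field(default_factory=dict)
    amplitude: float = 0.0

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float)
        self.curvature_true = np.asarray(self.curvature_true, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise InvalidSpecError("points must have shape (N, 3)")
        if len(self.points) != len(self.curvature_true):
            raise InvalidSpecError("points and curvature_true length mismatch")

    @property
    def n_points(self) -> int:
        return len(self.points)

    @property
    def chord(self) -> float:
        return float(np.linalg.norm(self.points[-1] - self.points[0]))


def _closed_form_metrics(arc_length, chord, kappa):
    """Tortuosity metrics for a constant-curvature curve of length L."""
    L = arc_length
    aoc = L / chord if chord > 1e-12 else math.inf
    return {
        "aoc": aoc,
        "total_curvature": kappa * L,          # kappa_m = int kappa ds
        "mean_squared_curvature": kappa ** 2,  # (1/L) int kappa^2 ds
        "rms_curvature": L * kappa,            # L * sqrt((1/L) int kappa^2 ds)
    }


def make_helix(spec: HelixSpec) -> GroundTruthCurve:
    """Sample a circular helix; add noise afterwards if the spec asks for it."""
    r, p, turns, n = spec.radius, spec.pitch, spec.turns, spec.n_points
    c = p / (2.0 * math.pi)
    t = np.linspace(0.0, 2.0 * math.pi * turns, n)
    points = np.column_stack([r * np.cos(t), r * np.sin(t), c * t])
    kappa = r / (r * r + c * c)
    arc_length = turns * math.sqrt((2.0 * math.pi * r) ** 2 + p ** 2)
    chord = float(np.linalg.norm(points[-1] - points[0]))
    curve = GroundTruthCurve(
        points=points,
        arc_length=arc_length,
        curvature_true=np.full(n, kappa),
        metrics_true=_closed_form_metrics(arc_length, chord, kappa),
        amplitude=r,
    )
    sigma = spec.noise_sigma
    if spec.snr is not None:
        return add_noise(curve, snr=spec.snr, seed=spec.seed)
    if sigma > 0:
        rng = np.random.default_rng(spec.seed)
        curve.points = curve.points + rng.normal(0.0, sigma, curve.points.shape)
    return curve


def make_line(start, end, n_points: int) -> GroundTruthCurve:
    """Evenly spaced points on a straight segment (zero-curvature control)."""
    start = np.asarray(start, dtype=float)
    end = np.asarray(end, dtype=float)
    if n_points < 4:
        raise InvalidSpecError(f"n_points must be >= 4, got {n_points}")
    length = float(np.linalg.norm(end - start))
    if length < 1e-12:
        raise InvalidSpecError("start and end points coincide")
    u = np.linspace(0.0, 1.0, n_points)[:, None]
    points = start + u * (end - start)
    rms_dev = float(np.sqrt(np.mean(np.sum((points - points.mean(0)) ** 2, axis=1))))
    return GroundTruthCurve(
        points=points,
        arc_length=length,
        curvature_true=np.zeros(n_points),
        metrics_true=_closed_form_metrics(length, length, 0.0),
        amplitude=rms_dev,
    )


def make_arc(radius: float, angle: float, n_points: int) -> GroundTruthCurve:
    """Planar circular arc of given radius and opening angle (radians)."""
    if radius <= 0:
        raise InvalidSpecError(f"radius must be > 0, got {radius}")
    if angle <= 0:
        raise InvalidSpecError(f"angle must be > 0, got {angle}")
    if angle > 2.0 * math.pi:
        raise InvalidSpecError("angle must be <= 2*pi")
    if n_points < 4:
        raise InvalidSpecError(f"n_points must be >= 4, got {n_points}")
    t = np.linspace(0.0, angle, n_points)
    points = np.column_stack(
        [radius * np.cos(t), radius * np.sin(t), np.zeros(n_points)]
    )
    arc_length = radius * angle
    chord = 2.0 * radius * math.sin(angle / 2.0)
    return GroundTruthCurve(
        points=points,
        arc_length=arc_length,
        curvature_true=np.full(n_points, 1.0 / radius),
        metrics_true=_closed_form_metrics(arc_length, chord, 1.0 / radius),
        amplitude=radius,
    )


def add_noise(curve: GroundTruthCurve, snr: float, seed: int = 0) -> GroundTruthCurve:
    """Perturb points with isotropic Gaussian noise at a given SNR.

    sigma = amplitude / snr, where amplitude is the curve's characteristic
    signal scale (helix radius, else RMS deviation from the centroid).
    Ground-truth fields are carried over from the clean curve unchanged, and
    the output is deterministic for a fixed seed.
    """
    if snr <= 0:
        raise InvalidSpecError(f"snr must be > 0, got {snr}")
    amplitude = curve.amplitude
    if amplitude <= 0:
        pts = curve.points
        amplitude = float(np.sqrt(np.mean(np.sum((pts - pts.mean(0)) ** 2, axis=1))))
    sigma = amplitude / snr
    rng = np.random.default_rng(seed)
    noisy = curve.points + rng.normal(0.0, sigma, curve.points.shape)
    return GroundTruthCurve(
        points=noisy,
        arc_length=curve.arc_length,
        curvature_true=curve.curvature_true.copy(),
        metrics_true=dict(curve.metrics_true),
        amplitude=curve.amplitude,
    )


def voxelize_tube(
    curve: GroundTruthCurve,
    tube_radius: float,
    spacing=0.625,
    margin: float | None = None,
) -> LabelVolume:
    """Rasterize a curve into a binary tube mask on a regular grid.

    A voxel is foreground iff its center lies within ``tube_radius`` of the
    polyline through ``curve.points`` (voxel-center inclusion, no partial
    volume).  The returned volume carries a diagonal affine built from
    ``spacing`` and is guaranteed to be a single 26-connected component.

    Raises
    ------
    VoxelizationError
        If the curve is empty or the resulting foreground is empty or
        disconnected (tube too thin for the grid).
    """
    if curve.points.size == 0 or len(curve.points) < 2:
        raise VoxelizationError("cannot voxelize an empty or single-point curve")
    spacing = np.broadcast_to(np.asarray(spacing, dtype=float), (3,)).copy()
    if np.any(spacing <= 0):
        raise InvalidSpecError("spacing must be positive")
    if tube_radius < spacing.max():
        raise InvalidSpecError(
            f"tube_radius {tube_radius} below max voxel spacing {spacing.max()}"
        )
    if margin is None:
        margin = 2.0 * tube_radius

    pts = curve.points
    lo = pts.min(axis=0) - tube_radius - margin
    hi = pts.max(axis=0) + tube_radius + margin
    shape = np.maximum(np.ceil((hi - lo) / spacing).astype(int) + 1, 1)

    # densify the polyline so point-to-polyline distance is well approximated
    # by nearest-sample distance (sample step << voxel size)
    seg = np.diff(pts, axis=0)
    seg_len = np.linalg.norm(seg, axis=1)
    step = 0.25 * spacing.min()
    dense = [pts[:1]]
    for i in range(len(seg)):
        n_sub = max(int(np.ceil(seg_len[i] / step)), 1)
        u = np.linspace(0.0, 1.0, n_sub + 1)[1:, None]
        dense.append(pts[i] + u * seg[i])
    dense = np.vstack(dense)

    tree = cKDTree(dense)
    # voxel centers, processed slab by slab to bound memory
    mask = np.zeros(shape, dtype=bool)
    ax = [lo[k] + spacing[k] * np.arange(shape[k]) for k in range(3)]
    yy, zz = np.meshgrid(ax[1], ax[2], indexing="ij")
    for i in range(shape[0]):
        centers = np.column_stack(
            [np.full(yy.size, ax[0][i]), yy.ravel(), zz.ravel()]
        )
        d, _ = tree.query(centers, workers=-1)
        mask[i] = (d <= tube_radius).reshape(shape[1], shape[2])

    if not mask.any():
        raise VoxelizationError("voxelization produced an empty mask")
    n_comp = ndimage.label(mask, structure=_STRUCT26)[1]
    if n_comp != 1:
        raise VoxelizationError(
            f"tube mask is disconnected ({n_comp} components); "
            "increase tube_radius or refine spacing"
        )
    affine = np.eye(4)
    affine[:3, :3] = np.diag(spacing)
    affine[:3, 3] = lo
    return LabelVolume(voxels=mask.astype(np.int16), affine=affine)
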