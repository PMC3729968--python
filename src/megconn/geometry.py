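"""Synthetic sensor/head/atlas geometry.

The head is a single homogeneous conducting sphere; magnetometers sit on a
helmet-like spherical cap outside it, oriented along the outward radial
direction.  ROIs are non-overlapping clusters of source-space voxels on a
shell inside the sphere.  Real studies use subject MRIs and a measured
sensor layout; this module replaces both with a self-contained geometry in
which the sphere lead field is exact and testable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .rsn import cortical_labels

_GOLDEN_ANGLE = np.pi * (3.0 - np.sqrt(5.0))


@dataclass
class SensorArray:
    """Magnetometer layout: positions (m) and unit orientations."""

    channel_ids: tuple[str, ...]
    positions: np.ndarray   # (n, 3) meters
    orientations: np.ndarray  # (n, 3) unit normals

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.orientations = np.asarray(self.orientations, dtype=float)
        n = len(self.channel_ids)
        if len(set(self.channel_ids)) != n:
            raise ValueError("channel_ids must be unique")
        if self.positions.shape != (n, 3) or self.orientations.shape != (n, 3):
            raise ValueError("positions/orientations must be (n_channels, 3)")
        norms = np.linalg.norm(self.orientations, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise ValueError("orientations must have unit norm")

    @property
    def n_channels(self) -> int:
        return len(self.channel_ids)


@dataclass
class HeadModel:
    """Homogeneous conducting sphere."""

    sphere_center: np.ndarray = field(
        default_factory=lambda: np.zeros(3))
    sphere_radius: float = 0.09

    def __post_init__(self) -> None:
        self.sphere_center = np.asarray(self.sphere_center, dtype=float)
        if self.sphere_center.shape != (3,):
            raise ValueError("sphere_center must be a 3-vector")
        if self.sphere_radius <= 0:
            raise ValueError("sphere_radius must be positive")


@dataclass
class ROIAtlas:
    """Labeled source-space voxel clusters, one cluster per ROI.

    Voxel 0 of each ROI is its centroid voxel, used as the representative
    dipole location in forward simulation.
    """

    voxels: dict[str, np.ndarray]  # label -> (k, 3) meters

    def __post_init__(self) -> None:
        self.voxels = {lab: np.atleast_2d(np.asarray(v, dtype=float))
                       for lab, v in self.voxels.items()}
        for lab, v in self.voxels.items():
            if v.ndim != 2 or v.shape[1] != 3 or v.shape[0] < 1:
                raise ValueError(f"ROI {lab!r}: voxels must be (k, 3)")

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(self.voxels)

    @property
    def n_rois(self) -> int:
        return len(self.voxels)

    @property
    def n_voxels(self) -> int:
        return sum(v.shape[0] for v in self.voxels.values())

    def centroid_voxel(self, label: str) -> np.ndarray:
        return self.voxels[label][0]

    def stacked(self) -> tuple[np.ndarray, list[str]]:
        """All voxels stacked into one (n_voxels, 3) array with labels."""
        pos = np.vstack([self.voxels[lab] for lab in self.labels])
        labs = [lab for lab in self.labels
                for _ in range(self.voxels[lab].shape[0])]
        return pos, labs


def _fibonacci_cap(n: int, z_min: float) -> np.ndarray:
    """n roughly-even unit vectors on the spherical cap z >= z_min."""
    k = np.arange(n)
    z = z_min + (1.0 - z_min) * (k + 0.5) / n
    phi = k * _GOLDEN_ANGLE
    rho = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])


def generate_geometry(
    n_channels: int = 151,
    n_rois: int = 78,
    voxels_per_roi: int = 5,
    seed: int = 0,
    *,
    head_radius: float = 0.09,
    sensor_radius: float = 0.12,
    roi_shell_radius: float = 0.07,
    cluster_radius: float = 0.004,
) -> tuple[SensorArray, HeadModel, ROIAtlas]:
    """Generate a sensor helmet, sphere head model and voxel atlas.

    Deterministic given ``seed``.  Raises ``ValueError`` when the requested
    ROI clusters cannot be placed without overlap inside the sphere.
    """
    if n_channels < 8:
        raise ValueError("need at least 8 channels")
    if n_rois < 2:
        raise ValueError("need at least 2 ROIs")
    if voxels_per_roi < 1:
        raise ValueError("need at least 1 voxel per ROI")
    if roi_shell_radius + cluster_radius >= head_radius:
        raise ValueError("geometry infeasible: ROI shell + cluster radius "
                         "exceeds the head sphere radius")

    rng = np.random.default_rng(seed)
    head = HeadModel(np.zeros(3), head_radius)

    # Helmet: spherical cap covering the upper ~70% of the sensor sphere.
    units = _fibonacci_cap(n_channels, z_min=-0.35)
    sensors = SensorArray(
        channel_ids=tuple(f"MEG{idx:03d}" for idx in range(n_channels)),
        positions=sensor_radius * units,
        orientations=units,
    )

    # ROI centroids on an interior shell; reject if clusters would overlap.
    centroids = roi_shell_radius * _fibonacci_cap(n_rois, z_min=-0.9)
    diffs = centroids[:, None, :] - centroids[None, :, :]
    dists = np.linalg.norm(diffs, axis=-1)
    np.fill_diagonal(dists, np.inf)
    if dists.min() <= 2.0 * cluster_radius:
        raise ValueError(
            "geometry infeasible: too many ROIs for the sphere volume "
            f"(min centroid separation {dists.min():.4f} m <= "
            f"{2 * cluster_radius:.4f} m)")

    labels = (cortical_labels() if n_rois == 78
              else tuple(f"ROI_{idx:03d}" for idx in range(n_rois)))

    voxels: dict[str, np.ndarray] = {}
    for lab, cen in zip(labels, centroids):
        pts = [cen]
        for _ in range(voxels_per_roi - 1):
            # random offsets within the cluster ball
            off = rng.normal(size=3)
            off *= (cluster_radius * rng.uniform(0.3, 1.0)
                    / np.linalg.norm(off))
            pts.append(cen + off)
        voxels[lab] = np.array(pts)

    atlas = ROIAtlas(voxels)
    pos, _ = atlas.stacked()
    if np.linalg.norm(pos, axis=1).max() >= head_radius:
        raise ValueError("geometry infeasible: voxel outside head sphere")
    return sensors, head, atlas


def tangential_unit(voxel: np.ndarray, center: np.ndarray) -> np.ndarray:
    """A deterministic unit vector tangential to the sphere at ``voxel``."""
    r = np.asarray(voxel, dtype=float) - np.asarray(center, dtype=float)
    rn = np.linalg.norm(r)
    if rn < 1e-12:
        raise ValueError("tangential orientation undefined at sphere center")
    rhat = r / rn
    ref = np.array([0.0, 0.0, 1.0])
    if abs(rhat @ ref) > 0.999:
        ref = np.array([1.0, 0.0, 0.0])
    t = np.cross(ref, rhat)
    return t / np.linalg.norm(t)
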