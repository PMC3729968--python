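"""Spherical-head lead fields and a SAM-style scalar beamformer.

Forward model: the magnetic field of a current dipole inside a homogeneous
conducting sphere (Sarvas formula).  Radially oriented dipoles are
magnetically silent in this model, so source orientations live in the
tangential plane.

Inverse model: a linearly constrained minimum-variance spatial filter with
unit gain at the target voxel,

    w = C_reg^{-1} l / (l^T C_reg^{-1} l),

where C_reg is the broadband (0.5-48 Hz) data covariance with diagonal
loading, and the scalar source orientation is chosen in the tangential
plane to maximize the pseudo-power 1 / (l(u)^T C_reg^{-1} l(u)) — a 2x2
eigenvalue problem per voxel.  One representative voxel per ROI and band
is then selected by maximum band-limited power.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg as sla

from .bands import BROADBAND, FrequencyBand
from .connectivity import bandpass
from .geometry import HeadModel, ROIAtlas, SensorArray
from .recording import EpochedRecording

MU0 = 4e-7 * np.pi  # vacuum permeability, T m / A


def leadfield_sphere(
    voxel: np.ndarray,
    moment: np.ndarray,
    sensors: SensorArray,
    head: HeadModel,
) -> np.ndarray:
    """Magnetometer gains (T per A m) of a dipole in a conducting sphere.

    Implements the closed-form field of a current dipole with moment
    ``moment`` (A m) at ``voxel`` inside a homogeneous sphere, projected on
    each sensor's orientation.  Linear in the moment; exactly zero for a
    radial moment.
    """
    voxel = np.asarray(voxel, dtype=float)
    moment = np.asarray(moment, dtype=float)
    center = head.sphere_center

    r0 = voxel - center
    r0n = np.linalg.norm(r0)
    if r0n >= head.sphere_radius:
        raise ValueError("dipole must lie strictly inside the sphere")
    if r0n < 1e-9:
        raise ValueError("dipole at the sphere center is silent/invalid")

    r = sensors.positions - center  # (n, 3)
    rn = np.linalg.norm(r, axis=1)
    if np.any(rn <= head.sphere_radius):
        raise ValueError("all sensors must lie outside the sphere")

    a_vec = r - r0
    a = np.linalg.norm(a_vec, axis=1)
    adotr = np.einsum("ij,ij->i", a_vec, r)
    r0dotr = r @ r0

    F = a * (rn * a + rn**2 - r0dotr)
    gradF = ((a**2 / rn + adotr / a + 2.0 * a + 2.0 * rn)[:, None] * r
             - (a + 2.0 * rn + adotr / a)[:, None] * r0[None, :])

    q_x_r0 = np.cross(moment, r0)  # (3,)
    q_x_r0_dot_r = r @ q_x_r0

    B = (MU0 / (4.0 * np.pi * F**2))[:, None] * (
        F[:, None] * q_x_r0[None, :] - q_x_r0_dot_r[:, None] * gradF)
    return np.einsum("ij,ij->i", B, sensors.orientations)


def tangential_basis(voxel: np.ndarray, head: HeadModel) -> np.ndarray:
    """Two orthonormal vectors spanning the tangential plane at ``voxel``."""
    r = np.asarray(voxel, dtype=float) - head.sphere_center
    rn = np.linalg.norm(r)
    if rn < 1e-9:
        raise ValueError("tangential plane undefined at sphere center")
    rhat = r / rn
    ref = np.array([0.0, 0.0, 1.0])
    if abs(rhat @ ref) > 0.999:
        ref = np.array([1.0, 0.0, 0.0])
    e1 = np.cross(ref, rhat)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(rhat, e1)
    return np.vstack([e1, e2])


def compute_covariance(recording: EpochedRecording,
                       band: FrequencyBand = BROADBAND) -> np.ndarray:
    """Data covariance pooled over all concatenated epochs after broadband
    filtering.  Symmetric positive semi-definite by construction."""
    if recording.n_epochs < 2:
        raise ValueError("need at least 2 epochs for the covariance")
    x = bandpass(recording.data, band, recording.fs, axis=1)
    x = x.transpose(0, 2, 1).reshape(recording.n_channels, -1)
    n_samples = x.shape[1]
    if n_samples < recording.n_channels:
        warnings.warn("fewer samples than channels: covariance is rank "
                      "deficient, regularization is mandatory", stacklevel=2)
    x = x - x.mean(axis=1, keepdims=True)
    C = (x @ x.T) / n_samples
    return 0.5 * (C + C.T)


@dataclass
class BeamformerModel:
    """Per-voxel unit-gain spatial filters and their provenance."""

    weights: np.ndarray        # (n_voxels, n_channels)
    orientations: np.ndarray   # (n_voxels, 3) optimized tangential moments
    leadfields: np.ndarray     # (n_voxels, n_channels) at the chosen moment
    voxel_positions: np.ndarray  # (n_voxels, 3)
    covariance: np.ndarray     # (n_channels, n_channels)
    regularization: float
    band_used: FrequencyBand = BROADBAND
    channel_ids: tuple[str, ...] | None = field(default=None)

    @property
    def n_voxels(self) -> int:
        return self.weights.shape[0]

    def unit_gain_error(self) -> np.ndarray:
        """|w^T l - 1| per voxel; the unit-gain contract bounds this by 1e-8."""
        return np.abs(np.einsum("ij,ij->i", self.weights, self.leadfields)
                      - 1.0)


def compute_weights(
    voxel_positions: np.ndarray,
    covariance: np.ndarray,
    sensors: SensorArray,
    head: HeadModel,
    reg_fraction: float = 0.05,
    *,
    band_used: FrequencyBand = BROADBAND,
) -> BeamformerModel:
    """Scalar (SAM-style) beamformer weights for each voxel.

    Diagonal loading: ``C_reg = C + reg_fraction * mean(diag(C)) * I``.
    The source orientation at each voxel is the tangential-plane direction
    maximizing pseudo-power, i.e. the minimal-eigenvalue eigenvector of the
    2x2 matrix ``L^T C_reg^{-1} L`` in the tangential basis.
    """
    voxel_positions = np.atleast_2d(np.asarray(voxel_positions, dtype=float))
    C = np.asarray(covariance, dtype=float)
    if reg_fraction < 0:
        raise ValueError("reg_fraction must be >= 0")
    if not np.allclose(C, C.T, atol=1e-10):
        raise ValueError("covariance must be symmetric")

    n_chan = C.shape[0]
    C_reg = C + reg_fraction * float(np.mean(np.diag(C))) * np.eye(n_chan)
    try:
        cho = sla.cho_factor(C_reg)
    except sla.LinAlgError:
        raise np.linalg.LinAlgError(
            "regularized covariance is singular; increase reg_fraction "
            f"(got reg_fraction={reg_fraction})")

    n_vox = voxel_positions.shape[0]
    weights = np.empty((n_vox, n_chan))
    leadfields = np.empty((n_vox, n_chan))
    orientations = np.empty((n_vox, 3))
    for v, pos in enumerate(voxel_positions):
        basis = tangential_basis(pos, head)
        L2 = np.column_stack([
            leadfield_sphere(pos, basis[0], sensors, head),
            leadfield_sphere(pos, basis[1], sensors, head)])
        CiL = sla.cho_solve(cho, L2)
        G = L2.T @ CiL  # 2x2, SPD for tangential leadfields
        evals, evecs = np.linalg.eigh(G)
        u = evecs[:, 0]  # min eigenvalue -> max pseudo-power
        if u[np.argmax(np.abs(u))] < 0:  # deterministic sign
            u = -u
        l = L2 @ u
        Cil = CiL @ u
        denom = float(l @ Cil)
        if denom <= 0 or not np.isfinite(denom):
            raise np.linalg.LinAlgError(
                f"degenerate pseudo-power at voxel {v}; increase "
                f"reg_fraction (got {reg_fraction})")
        weights[v] = Cil / denom
        leadfields[v] = l
        orientations[v] = u @ basis

    return BeamformerModel(
        weights=weights, orientations=orientations, leadfields=leadfields,
        voxel_positions=voxel_positions, covariance=C,
        regularization=reg_fraction, band_used=band_used,
        channel_ids=sensors.channel_ids)


def reconstruct_voxels(recording: EpochedRecording,
                       model: BeamformerModel) -> np.ndarray:
    """Project sensor data through the weights.

    Returns voxel series of shape (n_voxels, epoch_samples, n_epochs).
    """
    if recording.n_channels != model.weights.shape[1]:
        raise ValueError("channel count mismatch between recording and model")
    if (model.channel_ids is not None and recording.channel_ids is not None
            and model.channel_ids != recording.channel_ids):
        raise ValueError("channel ordering mismatch between recording "
                         "and model")
    return np.einsum("vc,cse->vse", model.weights, recording.data)


@dataclass
class ROITimeSeries:
    """Representative series of one ROI in one band."""

    roi_label: str
    band: FrequencyBand
    samples: np.ndarray  # (epoch_samples, n_epochs), unfiltered
    selected_voxel: int  # index into the atlas' stacked voxel array


def select_roi_voxel(
    voxel_series: np.ndarray,
    atlas: ROIAtlas,
    band: FrequencyBand,
    fs: float,
) -> dict[str, ROITimeSeries]:
    """Pick, per ROI, the member voxel with maximum band power.

    Power is the variance of the band-passed series summed over epochs;
    ties break toward the lowest voxel index.  The returned series is the
    raw (unfiltered) series of the winning voxel.
    """
    voxel_series = np.asarray(voxel_series, dtype=float)
    _, labels_per_voxel = atlas.stacked()
    if voxel_series.shape[0] != len(labels_per_voxel):
        raise ValueError("voxel series count does not match atlas voxels")

    filtered = bandpass(voxel_series, band, fs, axis=1)
    power = filtered.var(axis=1).sum(axis=1)  # variance per epoch, summed

    out: dict[str, ROITimeSeries] = {}
    offset = 0
    for lab in atlas.labels:
        k = atlas.voxels[lab].shape[0]
        if k == 0:
            raise ValueError(f"ROI {lab!r} has no voxels")
        local = int(np.argmax(power[offset:offset + k]))
        sel = offset + local
        out[lab] = ROITimeSeries(roi_label=lab, band=band,
                                 samples=voxel_series[sel],
                                 selected_voxel=sel)
        offset += k
    return out


def roi_band_series(voxel_series: np.ndarray, atlas: ROIAtlas,
                    band: FrequencyBand, fs: float) -> np.ndarray:
    """Stack `select_roi_voxel` output as (n_rois, epoch_samples, n_epochs)
    in atlas label order."""
    sel = select_roi_voxel(voxel_series, atlas, band, fs)
    return np.stack([sel[lab].samples for lab in atlas.labels])
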