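"""Band-limited phase synchronization via the phase-lag index (PLI).

The PLI between two signals is the absolute time-average of the sign of
their wrapped instantaneous phase difference::

    PLI = | < sign( delta_phi ) > |,   delta_phi in (-pi, pi]

It is 0 for a symmetric phase-difference distribution (including exactly
zero lag, the signature of field spread / volume conduction) and 1 for a
consistent non-zero lag.  sign(0) contributes 0, so the PLI of a signal
with itself is exactly 0.

Per-subject processing: ROI series are zero-phase band-pass filtered,
instantaneous phases are taken from the analytic signal per epoch, the PLI
is computed per epoch over all ROI pairs and averaged over epochs (default
5), yielding one symmetric adjacency matrix per band with zero diagonal.
Summaries: node strength (mean off-diagonal row entry), whole-brain mean
(mean node strength = mean over all unordered pairs), and the within-RSN
mean over the N(N-1)/2 pairs of an N-ROI resting-state network.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import signal as sps

from ._kernels import pair_sign_means
from .bands import FrequencyBand


@lru_cache(maxsize=64)
def _design_bandpass(lo: float, hi: float, fs: float) -> np.ndarray:
    """Zero-phase Butterworth band-pass (SOS), designed for <1 dB passband
    ripple and >40 dB stopband attenuation at band edges +/- 25% after
    forward-backward filtering."""
    nyq = fs / 2.0
    if hi >= nyq:
        raise ValueError(f"band edge {hi} Hz at or above Nyquist {nyq} Hz")
    wp = [lo / nyq, hi / nyq]
    ws = [0.75 * lo / nyq, min(1.25 * hi, 0.99 * nyq) / nyq]
    # single-pass specs are halved: filtfilt doubles attenuation in dB
    order, wn = sps.buttord(wp, ws, gpass=0.5, gstop=20.0)
    return sps.butter(order, wn, btype="bandpass", output="sos")


def impulse_response_samples(band: FrequencyBand, fs: float) -> int:
    """Nominal filter impulse-response length: one period of the low edge."""
    return int(np.ceil(fs / band.lo))


def bandpass(x: np.ndarray, band: FrequencyBand, fs: float,
             axis: int = -1) -> np.ndarray:
    """Zero-phase band-pass filter along ``axis``.

    Raises if the epoch is shorter than three filter impulse responses,
    where the transient of the filter would dominate the epoch.
    """
    x = np.asarray(x, dtype=float)
    n = x.shape[axis]
    if n < 3 * impulse_response_samples(band, fs):
        raise ValueError(
            f"epoch of {n} samples too short for band {band.name} at "
            f"fs={fs}: need >= {3 * impulse_response_samples(band, fs)}")
    sos = _design_bandpass(band.lo, band.hi, fs)
    return sps.sosfiltfilt(sos, x, axis=axis)


def instantaneous_phase(x: np.ndarray, axis: int = -1) -> np.ndarray:
    """Phase of the analytic signal, wrapped to (-pi, pi].

    The input must be band-limited for the phase to be meaningful; an
    all-zero input has no defined phase and raises.
    """
    x = np.asarray(x, dtype=float)
    if not np.any(x):
        raise ValueError("phase undefined for all-zero input")
    return np.angle(sps.hilbert(x, axis=axis))


def wrap_phase(p: np.ndarray) -> np.ndarray:
    """Wrap angles to (-pi, pi]."""
    return np.pi - np.mod(np.pi - np.asarray(p), 2.0 * np.pi)


def pli(phase_x: np.ndarray, phase_y: np.ndarray) -> float:
    """PLI between two phase series.

    1-D inputs are a single epoch; 2-D inputs are (n_samples, n_epochs) and
    the per-epoch PLI is averaged over epochs.
    """
    phase_x = np.asarray(phase_x, dtype=float)
    phase_y = np.asarray(phase_y, dtype=float)
    if phase_x.shape != phase_y.shape:
        raise ValueError("phase series must have equal shape")
    d = np.sign(np.sin(phase_x - phase_y))
    if d.ndim == 1:
        return float(abs(d.mean()))
    if d.ndim == 2:
        return float(np.abs(d.mean(axis=0)).mean())
    raise ValueError("phase series must be 1-D or (n_samples, n_epochs)")


@dataclass
class AdjacencyMatrix:
    """Symmetric per-subject, per-band PLI matrix with zero diagonal."""

    values: np.ndarray
    band: FrequencyBand
    labels: tuple[str, ...]
    subject_id: str | None = None
    n_epochs_averaged: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = self.values.shape[0]
        if self.values.shape != (n, n):
            raise ValueError("adjacency must be square")
        if len(self.labels) != n:
            raise ValueError("label count mismatch")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.abs(np.diag(self.values)) > 1e-12):
            raise ValueError("adjacency diagonal must be zero")
        if self.values.min() < -1e-12 or self.values.max() > 1.0 + 1e-12:
            raise ValueError("adjacency entries must lie in [0, 1]")

    @property
    def n_rois(self) -> int:
        return self.values.shape[0]


def edge_trim_samples(band: FrequencyBand, fs: float) -> int:
    """Samples dropped at each epoch edge: 1/(2*lo) seconds, suppressing
    filter and analytic-signal edge transients."""
    return int(np.ceil(fs / (2.0 * band.lo)))


def _pli_matrix_from_phases(phases: np.ndarray) -> np.ndarray:
    """Per-epoch PLI matrix from phases (n_rois, n_samples, n_epochs),
    averaged over epochs."""
    n_rois, _, n_epochs = phases.shape
    acc = np.zeros((n_rois, n_rois))
    for e in range(n_epochs):
        p = phases[:, :, e]
        acc += np.abs(pair_sign_means(np.sin(p), np.cos(p)))
    acc /= n_epochs
    np.fill_diagonal(acc, 0.0)
    return acc


def adjacency(
    roi_series: np.ndarray,
    labels,
    band: FrequencyBand,
    fs: float,
    n_epochs: int = 5,
    *,
    subject_id: str | None = None,
    edge_trim: bool = True,
    prefiltered: bool = False,
) -> AdjacencyMatrix:
    """Band-filtered PLI adjacency from ROI time series.

    Parameters
    ----------
    roi_series
        Array (n_rois, epoch_samples, total_epochs); the first ``n_epochs``
        epochs are used.
    prefiltered
        Skip the band-pass (input already band-limited).
    """
    roi_series = np.asarray(roi_series, dtype=float)
    if roi_series.ndim != 3:
        raise ValueError("roi_series must be (n_rois, n_samples, n_epochs)")
    if roi_series.shape[2] < n_epochs:
        raise ValueError(
            f"need at least {n_epochs} epochs, got {roi_series.shape[2]}")
    x = roi_series[:, :, :n_epochs]
    if not prefiltered:
        x = bandpass(x, band, fs, axis=1)
    phases = instantaneous_phase(x, axis=1)
    if edge_trim:
        k = edge_trim_samples(band, fs)
        if 2 * k >= phases.shape[1]:
            raise ValueError("edge trim leaves no samples")
        phases = phases[:, k:-k, :]
    values = _pli_matrix_from_phases(phases)
    return AdjacencyMatrix(values=values, band=band, labels=tuple(labels),
                           subject_id=subject_id, n_epochs_averaged=n_epochs)


def adjacency_from_phases(phases: np.ndarray, labels, band: FrequencyBand,
                          subject_id: str | None = None) -> AdjacencyMatrix:
    """Adjacency directly from known instantaneous phases (ground-truth
    path of the synthetic generator; no filtering or edge trim)."""
    values = _pli_matrix_from_phases(np.asarray(phases, dtype=float))
    return AdjacencyMatrix(values=values, band=band, labels=tuple(labels),
                           subject_id=subject_id,
                           n_epochs_averaged=phases.shape[2])


def node_strength(A: AdjacencyMatrix | np.ndarray) -> np.ndarray:
    """Mean off-diagonal row entry per ROI (weighted degree)."""
    v = A.values if isinstance(A, AdjacencyMatrix) else np.asarray(A, float)
    n = v.shape[0]
    if n < 2:
        raise ValueError("node strength needs at least 2 ROIs")
    return (v.sum(axis=1) - np.diag(v)) / (n - 1)


def whole_brain_mean(A: AdjacencyMatrix | np.ndarray) -> float:
    """Mean of the node strengths; equals the mean over all unordered
    ROI pairs."""
    return float(node_strength(A).mean())


def rsn_mean_pli(A: AdjacencyMatrix, members) -> float:
    """Mean PLI over the N(N-1)/2 within-network ROI pairs."""
    idx = []
    for lab in members:
        try:
            idx.append(A.labels.index(lab))
        except ValueError:
            raise ValueError(f"RSN member {lab!r} not in adjacency labels")
    if len(idx) < 2:
        raise ValueError("RSN must contain at least 2 ROIs")
    idx = np.asarray(idx)
    sub = A.values[np.ix_(idx, idx)]
    iu = np.triu_indices(len(idx), k=1)
    return float(sub[iu].mean())


def analytic_null_level(m: int) -> float:
    """Expected PLI of independent phases over m samples: the mean absolute
    value of an average of m iid +/-1 signs, ~ sqrt(2 / (pi m))."""
    return float(np.sqrt(2.0 / (np.pi * m)))
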