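"""Coupled narrowband oscillator simulation with known phase-lag structure.

Each ROI carries one narrowband oscillation per analysis band (center
frequency at the band midpoint, with a slow Ornstein-Uhlenbeck phase
wander) plus a broadband 1/f background.  Coupled ROIs share a base phase:
their instantaneous phase difference is a fixed non-zero lag plus von Mises
jitter of configurable concentration, which is exactly the structure the
phase-lag index is designed to detect, and whose expected PLI has a
brute-force Monte-Carlo oracle (`expected_pli`).

This is a phase-imposed coupling model, not Kuramoto dynamics: the phase
relation is constructed directly so that the ground truth is controllable.
The jitter is temporally smoothed through a Gaussian-copula AR(1) process
whose marginal remains von Mises, so that the band-pass/analytic-signal
analysis chain can track the simulated phases.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps
from scipy.special import ndtr

from .bands import FrequencyBand
from .geometry import HeadModel, ROIAtlas, SensorArray, tangential_unit
from .recording import EpochedRecording

_KAPPA_CAP = 1e6  # concentrations above this are treated as jitter-free


@dataclass
class CouplingSpec:
    """Phase coupling between designated ROI pairs in one band.

    ``lag_delta`` is the imposed phase difference in radians, in (-pi, pi];
    ``jitter_kappa`` the von Mises concentration of the phase-difference
    noise (``inf`` = noise-free); ``amplitude_snr`` the power ratio of the
    band oscillations to the 1/f source background.
    """

    band: FrequencyBand
    roi_pairs: list[tuple[str, str]]
    lag_delta: float = np.pi / 2
    jitter_kappa: float = np.inf
    amplitude_snr: float = 2.0

    def __post_init__(self) -> None:
        if not (-np.pi < self.lag_delta <= np.pi):
            raise ValueError("lag_delta must lie in (-pi, pi]")
        if self.jitter_kappa < 0:
            raise ValueError("jitter_kappa must be >= 0")
        if self.amplitude_snr <= 0:
            raise ValueError("amplitude_snr must be positive")


@dataclass
class SourceSimulation:
    """Simulated ROI source signals and their ground-truth band phases."""

    signals: np.ndarray                 # (n_rois, epoch_samples, n_epochs)
    phases: dict[str, np.ndarray]       # band name -> same shape as signals
    labels: tuple[str, ...]
    fs: float
    specs: list[CouplingSpec] = field(default_factory=list)

    @property
    def n_rois(self) -> int:
        return self.signals.shape[0]


def _ou_process(rng: np.random.Generator, n_series: int, n_samples: int,
                fs: float, sigma: float, tau: float) -> np.ndarray:
    """Stationary Ornstein-Uhlenbeck samples, shape (n_series, n_samples)."""
    a = np.exp(-1.0 / (tau * fs))
    w = rng.normal(scale=sigma * np.sqrt(1.0 - a * a),
                   size=(n_series, n_samples))
    z0 = rng.normal(scale=sigma, size=(n_series, 1))
    y, _ = sps.lfilter([1.0], [1.0, -a], w, axis=-1, zi=a * z0)
    return y


def _von_mises_ppf_table(kappa: float, n_grid: int = 8192):
    """Quantile table of the zero-mean von Mises distribution."""
    theta = np.linspace(-np.pi, np.pi, n_grid)
    logpdf = kappa * (np.cos(theta) - 1.0)  # unnormalized, overflow-safe
    pdf = np.exp(logpdf)
    cdf = np.concatenate([[0.0], np.cumsum(0.5 * (pdf[1:] + pdf[:-1])
                                           * np.diff(theta))])
    cdf /= cdf[-1]
    return cdf, theta


def smooth_von_mises(rng: np.random.Generator, kappa: float, n_series: int,
                     n_samples: int, fs: float,
                     tau: float = 0.15) -> np.ndarray:
    """Temporally smooth noise with an exact von Mises(0, kappa) marginal.

    A Gaussian AR(1) process with correlation time ``tau`` (seconds) is
    mapped through its CDF and the von Mises quantile function
    (Gaussian-copula construction), so the marginal is von Mises while
    sample-to-sample changes stay small enough for analytic-signal phase
    tracking.
    """
    if kappa >= _KAPPA_CAP or np.isinf(kappa):
        return np.zeros((n_series, n_samples))
    z = _ou_process(rng, n_series, n_samples, fs, sigma=1.0, tau=tau)
    u = ndtr(z)
    if kappa == 0.0:
        return 2.0 * np.pi * (u - 0.5)
    cdf, theta = _von_mises_ppf_table(kappa)
    return np.interp(u, cdf, theta)


def _one_over_f(rng: np.random.Generator, n_series: int, n_samples: int,
                exponent: float = 1.0) -> np.ndarray:
    """Unit-RMS 1/f^exponent noise via spectral shaping."""
    white = rng.normal(size=(n_series, n_samples))
    spec = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(n_samples)
    scale = np.ones_like(freqs)
    scale[1:] = freqs[1:] ** (-exponent / 2.0)
    scale[0] = 0.0
    x = np.fft.irfft(spec * scale, n=n_samples, axis=-1)
    rms = x.std(axis=-1, keepdims=True)
    return x / rms


def _components(pairs: list[tuple[str, str]]) -> list[list[str]]:
    """Connected components of the pair graph, in first-seen order."""
    adj: dict[str, set[str]] = {}
    order: list[str] = []
    for a, b in pairs:
        if a == b:
            raise ValueError(f"self-coupling of ROI {a!r}")
        for x in (a, b):
            if x not in adj:
                adj[x] = set()
                order.append(x)
        adj[a].add(b)
        adj[b].add(a)
    seen: set[str] = set()
    comps = []
    for root in order:
        if root in seen:
            continue
        comp, queue = [], [root]
        seen.add(root)
        while queue:
            node = queue.pop(0)
            comp.append(node)
            for nb in sorted(adj[node]):
                if nb not in seen:
                    seen.add(nb)
                    queue.append(nb)
        comps.append(comp)
    return comps


def _component_offsets(size: int, lag_delta: float) -> np.ndarray:
    """Phase offsets of a coupled component's members.

    A simple pair realizes ``lag_delta`` exactly.  Larger (cyclic)
    components cannot give every pair the same lag; members are staggered
    over (0.12*pi, 0.88*pi) so that every pairwise lag is non-zero and
    bounded away from 0 and pi.
    """
    if size == 2:
        return np.array([0.0, lag_delta])
    return np.linspace(0.12 * np.pi, 0.88 * np.pi, size) * np.sign(lag_delta)


def simulate_sources(
    atlas: ROIAtlas,
    coupling: list[CouplingSpec],
    n_epochs: int = 5,
    epoch_samples: int = 4096,
    fs: float = 625.0,
    seed: int = 0,
    *,
    wander_sigma: float = 0.8,
    wander_tau: float = 0.4,
    detune_frac: float = 0.7,
    background_exponent: float = 1.0,
    phases_only: bool = False,
) -> SourceSimulation:
    """Simulate per-ROI source series with implanted phase coupling.

    Every ROI receives one oscillation per band named in ``coupling``
    (independent phases unless the ROI belongs to a coupled component in
    that band) plus 1/f background noise.  Each independent oscillator is
    randomly detuned within ``detune_frac`` of the band half-width around
    the band midpoint, so uncoupled phase differences sweep through full
    cycles instead of dwelling; a coupled component shares one detuned
    carrier.  Deterministic given ``seed``.
    """
    if epoch_samples < 256:
        raise ValueError("epoch_samples must be >= 256")
    labels = atlas.labels
    label_set = set(labels)
    by_band: dict[str, list[CouplingSpec]] = {}
    for spec in coupling:
        if spec.band.hi >= fs / 2.0:
            raise ValueError(
                f"band {spec.band.name} exceeds the Nyquist frequency")
        for a, b in spec.roi_pairs:
            for lab in (a, b):
                if lab not in label_set:
                    raise ValueError(f"coupling references unknown ROI "
                                     f"label {lab!r}")
        by_band.setdefault(spec.band.name, []).append(spec)

    rng = np.random.default_rng(seed)
    n_rois = len(labels)
    idx = {lab: i for i, lab in enumerate(labels)}
    m = epoch_samples * n_epochs
    t = np.arange(m) / fs

    bands = []
    for specs in by_band.values():
        if specs[0].band not in bands:
            bands.append(specs[0].band)

    total = np.zeros((n_rois, m))
    phases: dict[str, np.ndarray] = {}
    osc_power = 0.0

    for band in bands:
        specs = by_band[band.name]
        phase = np.empty((n_rois, m))
        coupled: set[int] = set()
        detune = detune_frac * 0.5 * band.width
        for spec in specs:
            for comp in _components(spec.roi_pairs):
                offsets = _component_offsets(len(comp), spec.lag_delta)
                f_c = band.mid + rng.uniform(-detune, detune)
                base = (2.0 * np.pi * f_c * t
                        + _ou_process(rng, 1, m, fs, wander_sigma,
                                      wander_tau)[0]
                        + rng.uniform(0.0, 2.0 * np.pi))
                jitter = smooth_von_mises(rng, spec.jitter_kappa,
                                          len(comp) - 1, m, fs)
                for k, lab in enumerate(comp):
                    i = idx[lab]
                    if i in coupled:
                        raise ValueError(
                            f"ROI {lab!r} coupled twice in band {band.name}")
                    coupled.add(i)
                    p = base + offsets[k]
                    if k > 0:
                        p = p + jitter[k - 1]
                    phase[i] = p
        free = [i for i in range(n_rois) if i not in coupled]
        if free:
            wander = _ou_process(rng, len(free), m, fs, wander_sigma,
                                 wander_tau)
            starts = rng.uniform(0.0, 2.0 * np.pi, size=(len(free), 1))
            f_c = band.mid + rng.uniform(-detune, detune,
                                         size=(len(free), 1))
            phase[free] = 2.0 * np.pi * f_c * t + wander + starts
        if not phases_only:
            total += np.cos(phase)
        osc_power += 0.5
        # wrap to (-pi, pi]
        wrapped = np.pi - np.mod(np.pi - phase, 2.0 * np.pi)
        phases[band.name] = wrapped.reshape(
            n_rois, n_epochs, epoch_samples).transpose(0, 2, 1)

    if bands and not phases_only:
        snr = float(np.mean([s.amplitude_snr for s in coupling]))
        bg_rms = np.sqrt(osc_power / snr)
        total += bg_rms * _one_over_f(rng, n_rois, m, background_exponent)

    signals = total.reshape(n_rois, n_epochs, epoch_samples)
    signals = signals.transpose(0, 2, 1)
    return SourceSimulation(signals=signals, phases=phases, labels=labels,
                            fs=fs, specs=list(coupling))


def project_to_sensors(
    sim: SourceSimulation | np.ndarray,
    atlas: ROIAtlas,
    sensors: SensorArray,
    head: HeadModel,
    snr: float = 5.0,
    seed: int = 0,
    *,
    dipole_moment: float = 1e-8,
) -> EpochedRecording:
    """Forward-project ROI sources to the sensors.

    One dipole per ROI at its centroid voxel with tangential orientation;
    white Gaussian sensor noise scaled so that the ratio of mean sensor
    signal power to noise power equals ``snr`` (``inf`` = noiseless).
    """
    from .beamformer import leadfield_sphere  # local import, avoids cycle

    if not np.isinf(snr) and snr <= 0:
        raise ValueError("snr must be positive (or inf for noiseless)")
    signals = sim.signals if isinstance(sim, SourceSimulation) else \
        np.asarray(sim, dtype=float)
    if signals.ndim != 3 or signals.shape[0] != atlas.n_rois:
        raise ValueError("sources must be (n_rois, epoch_samples, n_epochs)")

    L = np.empty((sensors.n_channels, atlas.n_rois))
    for i, lab in enumerate(atlas.labels):
        vox = atlas.centroid_voxel(lab)
        moment = dipole_moment * tangential_unit(vox, head.sphere_center)
        L[:, i] = leadfield_sphere(vox, moment, sensors, head)

    clean = np.einsum("cr,rse->cse", L, signals)
    if np.isinf(snr):
        data = clean
    else:
        rng = np.random.default_rng(seed)
        sig_power = float(np.mean(clean**2))
        noise_sd = np.sqrt(sig_power / snr)
        data = clean + rng.normal(scale=noise_sd, size=clean.shape)
    fs = sim.fs if isinstance(sim, SourceSimulation) else 625.0
    return EpochedRecording(data=data, fs=fs,
                            channel_ids=sensors.channel_ids)


def expected_pli(
    lag_delta: float,
    kappa: float,
    n_draws: int = 1_000_000,
    seed: int = 0,
    *,
    both_jittered: bool = False,
) -> tuple[float, float]:
    """Brute-force Monte-Carlo oracle for the PLI of a jittered constant lag.

    Draws phase differences ``lag_delta + eta`` with ``eta`` von Mises
    (0, kappa) — or the difference of two independent such draws when both
    pair members carry jitter — and averages ``sign(sin(.))``.  Returns
    (expected PLI, Monte-Carlo standard error of the signed mean).
    """
    rng = np.random.default_rng(seed)
    if kappa >= _KAPPA_CAP or np.isinf(kappa):
        eta = np.zeros(n_draws)
    elif kappa == 0.0:
        eta = rng.uniform(-np.pi, np.pi, n_draws)
    else:
        eta = rng.vonmises(0.0, kappa, n_draws)
        if both_jittered:
            eta = eta - rng.vonmises(0.0, kappa, n_draws)
    s = np.sign(np.sin(lag_delta + eta))
    return float(abs(s.mean())), float(s.std(ddof=1) / np.sqrt(n_draws))
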