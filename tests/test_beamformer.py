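import numpy as np
import pytest

from megconn.bands import ALPHA2, BETA, FrequencyBand
from megconn.beamformer import (compute_covariance, compute_weights,
                                leadfield_sphere, reconstruct_voxels,
                                roi_band_series, select_roi_voxel,
                                tangential_basis)
from megconn.geometry import HeadModel, ROIAtlas, SensorArray, \
    tangential_unit
from megconn.recording import EpochedRecording
from megconn.simulate import CouplingSpec, project_to_sensors, \
    simulate_sources

WIDE = FrequencyBand("wide", 0.5, 90.0)  # permissive band for fs=200 tests


def _radial_sensor_ring(n=24, radius=0.13, seed=0):
    rng = np.random.default_rng(seed)
    pos = rng.normal(size=(n, 3))
    pos *= radius / np.linalg.norm(pos, axis=1, keepdims=True)
    return SensorArray(tuple(f"S{i}" for i in range(n)), pos, pos / radius)


class TestLeadField:
    def test_radial_dipole_is_silent(self, full_geometry):
        sensors, head, atlas = full_geometry
        vox = atlas.centroid_voxel(atlas.labels[10])
        rhat = vox / np.linalg.norm(vox)
        tan = tangential_unit(vox, head.sphere_center)
        g_rad = leadfield_sphere(vox, rhat, sensors, head)
        g_tan = leadfield_sphere(vox, tan, sensors, head)
        assert np.linalg.norm(g_rad) < 1e-12 * np.linalg.norm(g_tan)

    def test_linearity_in_moment(self, full_geometry):
        sensors, head, atlas = full_geometry
        vox = atlas.centroid_voxel(atlas.labels[3])
        m = np.array([1e-8, -2e-8, 0.5e-8])
        assert np.allclose(leadfield_sphere(vox, 2 * m, sensors, head),
                           2 * leadfield_sphere(vox, m, sensors, head),
                           rtol=1e-14)

    def test_against_independent_radial_field_identity(self):
        """For radially oriented magnetometers the sphere's volume currents
        contribute nothing, so the conducting-sphere field must equal the
        free-space dipole field's radial component -- an independent
        closed form."""
        sensors = _radial_sensor_ring()
        head = HeadModel(np.zeros(3), 0.1)
        vox = np.array([0.02, -0.03, 0.05])
        Q = np.array([1e-8, 2e-8, -0.5e-8])
        g = leadfield_sphere(vox, Q, sensors, head)
        a = sensors.positions - vox
        oracle = 1e-7 * np.einsum(
            "ij,ij->i", np.cross(np.broadcast_to(Q, a.shape), a),
            sensors.orientations) / np.linalg.norm(a, axis=1) ** 3
        assert np.max(np.abs(g - oracle)) < 1e-10 * np.max(np.abs(oracle))

    def test_colinear_toy_fixture_is_null_by_symmetry(self):
        sensors = SensorArray(("S0",), np.array([[0.0, 0.0, 0.12]]),
                              np.array([[0.0, 0.0, 1.0]]))
        head = HeadModel(np.zeros(3), 0.1)
        g = leadfield_sphere(np.array([0.0, 0.0, 0.07]),
                             np.array([1e-8, 0.0, 0.0]), sensors, head)
        assert g[0] == 0.0

    def test_dipole_placement_errors(self, full_geometry):
        sensors, head, _ = full_geometry
        m = np.array([1e-8, 0, 0])
        with pytest.raises(ValueError, match="center"):
            leadfield_sphere(np.zeros(3), m, sensors, head)
        with pytest.raises(ValueError, match="inside"):
            leadfield_sphere(np.array([0.0, 0.0, 0.2]), m, sensors, head)


class TestCovariance:
    def _white_recording(self, rng, n_chan=6, sigma=2.0):
        data = sigma * rng.normal(size=(n_chan, 1500, 4))
        return EpochedRecording(data, fs=200.0)

    def test_white_noise_gives_diagonal_covariance(self, rng):
        rec = self._white_recording(rng)
        C = compute_covariance(rec, band=WIDE)
        off = C - np.diag(np.diag(C))
        assert np.abs(off).max() < 0.05 * np.diag(C).mean()
        # broadband filter passes nearly the full white spectrum here
        assert abs(np.diag(C).mean() - 4.0) < 0.5

    def test_rank_one_recording_gives_rank_one_covariance(self, rng):
        s = rng.normal(size=1500 * 4)
        mix = rng.normal(size=6)
        data = np.outer(mix, s).reshape(6, 4, 1500).transpose(0, 2, 1)
        C = compute_covariance(EpochedRecording(data, fs=200.0), band=WIDE)
        ev = np.linalg.eigvalsh(C)
        assert ev[-2] < 1e-10 * ev[-1]

    def test_duplicating_epochs_leaves_covariance_unchanged(self, rng):
        rec = self._white_recording(rng)
        doubled = EpochedRecording(np.concatenate([rec.data, rec.data],
                                                  axis=2), fs=200.0)
        assert np.allclose(compute_covariance(rec, band=WIDE),
                           compute_covariance(doubled, band=WIDE),
                           atol=1e-12)

    def test_single_epoch_rejected(self, rng):
        rec = EpochedRecording(rng.normal(size=(4, 1500, 1)), fs=200.0)
        with pytest.raises(ValueError, match="2 epochs"):
            compute_covariance(rec, band=WIDE)

    def test_fewer_samples_than_channels_warns(self, rng):
        rec = EpochedRecording(rng.normal(size=(350, 150, 2)), fs=200.0)
        with pytest.warns(UserWarning, match="rank"):
            compute_covariance(rec, band=FrequencyBand("hi", 5.0, 90.0))


class TestWeights:
    def test_identity_covariance_closed_form(self, small_geometry):
        sensors, head, atlas = small_geometry
        pos, _ = atlas.stacked()
        model = compute_weights(pos, np.eye(sensors.n_channels), sensors,
                                head, reg_fraction=0.0)
        for v in range(model.n_voxels):
            l = model.leadfields[v]
            assert np.allclose(model.weights[v], l / (l @ l), rtol=1e-10)

    def test_unit_gain_at_every_voxel(self, full_geometry, rng):
        sensors, head, atlas = full_geometry
        pos, _ = atlas.stacked()
        # a generic SPD covariance
        B = rng.normal(size=(sensors.n_channels, sensors.n_channels))
        C = B @ B.T / sensors.n_channels
        model = compute_weights(pos, C, sensors, head, reg_fraction=0.05)
        assert model.unit_gain_error().max() < 1e-8

    def test_rank_deficient_covariance_needs_loading(self, small_geometry):
        sensors, head, atlas = small_geometry
        pos, _ = atlas.stacked()
        u = np.ones(sensors.n_channels)
        C = np.outer(u, u)  # rank 1
        with pytest.raises(np.linalg.LinAlgError, match="reg_fraction"):
            compute_weights(pos, C, sensors, head, reg_fraction=0.0)
        model = compute_weights(pos, C, sensors, head, reg_fraction=0.05)
        assert np.all(np.isfinite(model.weights))
        assert model.unit_gain_error().max() < 1e-8


class TestReconstruction:
    def _single_source_setup(self, geometry, seed=0):
        sensors, head, atlas = geometry
        spec = CouplingSpec(band=ALPHA2,
                            roi_pairs=[(atlas.labels[0], atlas.labels[1])],
                            jitter_kappa=2.0)
        sim = simulate_sources(atlas, [spec], n_epochs=2,
                               epoch_samples=4096, fs=625.0, seed=seed)
        sources = np.zeros_like(sim.signals)
        sources[0] = sim.signals[0]
        rec = project_to_sensors(sources, atlas, sensors, head, snr=np.inf)
        return sensors, head, atlas, sim, rec

    def test_zero_data_reconstructs_to_zero(self, small_geometry):
        sensors, head, atlas = small_geometry
        pos, _ = atlas.stacked()
        model = compute_weights(pos, np.eye(sensors.n_channels), sensors,
                                head)
        rec = EpochedRecording(np.zeros((sensors.n_channels, 512, 2)),
                               fs=625.0)
        assert np.allclose(reconstruct_voxels(rec, model), 0.0)

    def test_noiseless_single_source_round_trip(self, small_geometry):
        sensors, head, atlas, sim, rec = \
            self._single_source_setup(small_geometry)
        C = compute_covariance(rec)
        pos, _ = atlas.stacked()
        model = compute_weights(pos, C, sensors, head, reg_fraction=0.05)
        vox = reconstruct_voxels(rec, model)
        truth = sim.signals[0].ravel()
        est = vox[0].ravel()  # voxel 0 = centroid voxel of ROI 0
        corr = np.corrcoef(truth, est)[0, 1]
        assert abs(corr) >= 0.999

    def test_two_sources_stay_separated(self, small_geometry):
        sensors, head, atlas = small_geometry
        spec = CouplingSpec(band=ALPHA2,
                            roi_pairs=[(atlas.labels[0], atlas.labels[1])],
                            jitter_kappa=1.0)
        sim = simulate_sources(atlas, [spec], n_epochs=2,
                               epoch_samples=4096, fs=625.0, seed=3)
        sources = np.zeros_like(sim.signals)
        sources[0], sources[3] = sim.signals[0], sim.signals[3]
        rec = project_to_sensors(sources, atlas, sensors, head, snr=np.inf)
        pos, _ = atlas.stacked()
        model = compute_weights(pos, compute_covariance(rec), sensors, head)
        vox = reconstruct_voxels(rec, model)
        v0 = atlas.voxels[atlas.labels[0]].shape[0] * 0
        v3 = sum(atlas.voxels[lab].shape[0] for lab in atlas.labels[:3])
        for v_idx, own, other in ((v0, 0, 3), (v3, 3, 0)):
            est = vox[v_idx].ravel()
            c_own = abs(np.corrcoef(est, sources[own].ravel())[0, 1])
            c_other = abs(np.corrcoef(est, sources[other].ravel())[0, 1])
            assert c_own > c_other

    def test_channel_mismatch_rejected(self, small_geometry):
        sensors, head, atlas = small_geometry
        pos, _ = atlas.stacked()
        model = compute_weights(pos, np.eye(sensors.n_channels), sensors,
                                head)
        rec = EpochedRecording(np.zeros((4, 512, 2)), fs=625.0)
        with pytest.raises(ValueError, match="channel"):
            reconstruct_voxels(rec, model)


class TestVoxelSelection:
    def _atlas_one_roi(self, n_vox=3):
        base = np.array([0.0, 0.0, 0.05])
        return ROIAtlas({"only": base + 1e-3 * np.arange(n_vox)[:, None]
                         * np.array([1.0, 0.0, 0.0])})

    def test_single_voxel_roi_selects_it(self):
        atlas = self._atlas_one_roi(1)
        series = np.random.default_rng(0).normal(size=(1, 1024, 2))
        sel = select_roi_voxel(series, atlas, ALPHA2, 625.0)
        assert sel["only"].selected_voxel == 0

    def test_argmax_band_power(self):
        atlas = self._atlas_one_roi(3)
        t = np.arange(1024) / 625.0
        tone = np.sin(2 * np.pi * 11.0 * t)
        series = np.stack([a * np.tile(tone[:, None], (1, 2))
                           for a in (1.0, 2.0, np.sqrt(2.0))])
        sel = select_roi_voxel(series, atlas, ALPHA2, 625.0)
        assert sel["only"].selected_voxel == 1

    def test_selection_can_differ_across_bands(self):
        atlas = self._atlas_one_roi(2)
        t = np.arange(1024) / 625.0
        alpha_tone = np.sin(2 * np.pi * 11.0 * t)
        beta_tone = np.sin(2 * np.pi * 20.0 * t)
        series = np.stack([np.tile(x[:, None], (1, 2))
                           for x in (alpha_tone, beta_tone)])
        sel_a = select_roi_voxel(series, atlas, ALPHA2, 625.0)
        sel_b = select_roi_voxel(series, atlas, BETA, 625.0)
        assert sel_a["only"].selected_voxel == 0
        assert sel_b["only"].selected_voxel == 1

    def test_roi_band_series_order_and_shape(self, small_geometry):
        sensors, head, atlas = small_geometry
        rng = np.random.default_rng(5)
        series = rng.normal(size=(atlas.n_voxels, 1024, 2))
        out = roi_band_series(series, atlas, ALPHA2, 625.0)
        assert out.shape == (atlas.n_rois, 1024, 2)


def test_tangential_basis_orthogonality(small_geometry):
    _, head, atlas = small_geometry
    vox = atlas.centroid_voxel(atlas.labels[0])
    basis = tangential_basis(vox, head)
    r = vox - head.sphere_center
    assert abs(basis[0] @ r) < 1e-12 and abs(basis[1] @ r) < 1e-12
    assert abs(basis[0] @ basis[1]) < 1e-12
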