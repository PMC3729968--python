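import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from megconn._kernels import pair_sign_means, pair_sign_means_numpy
from megconn.bands import ALPHA2, CANONICAL_BANDS, FrequencyBand, get_band
from megconn.connectivity import (AdjacencyMatrix, adjacency,
                                  analytic_null_level, bandpass,
                                  edge_trim_samples, instantaneous_phase,
                                  node_strength, pli, rsn_mean_pli,
                                  whole_brain_mean, wrap_phase)

FS = 625.0
T = np.arange(4096) / FS


class TestBandpass:
    def test_in_band_tone_preserved(self):
        x = np.sin(2 * np.pi * 11.0 * T)
        y = bandpass(x, ALPHA2, FS)
        ratio = y[500:-500].std() / x[500:-500].std()
        assert abs(ratio - 1.0) < 0.05

    def test_out_of_band_tone_rejected_40db(self):
        x = np.sin(2 * np.pi * 25.0 * T)
        y = bandpass(x, ALPHA2, FS)
        atten_db = 20 * np.log10(y[500:-500].std() / x[500:-500].std())
        assert atten_db < -40.0

    def test_zero_in_zero_out(self):
        assert np.allclose(bandpass(np.zeros(4096), ALPHA2, FS), 0.0)

    def test_short_epoch_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            bandpass(np.zeros(100), ALPHA2, FS)

    def test_band_above_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            bandpass(np.zeros(4096), FrequencyBand("bad", 10.0, 400.0), FS)


class TestInstantaneousPhase:
    # a whole number of cycles in the epoch avoids spectral leakage, so the
    # analytic signal is exact away from the edges
    F_EXACT = 64 * FS / 4096  # 9.765625 Hz

    def test_sinusoid_phase_advance(self):
        p = instantaneous_phase(np.sin(2 * np.pi * self.F_EXACT * T))
        dp = wrap_phase(np.diff(p[100:-100]))
        assert np.allclose(dp, 2 * np.pi * self.F_EXACT / FS, atol=1e-3)

    def test_quarter_cycle_offset(self):
        pc = instantaneous_phase(np.cos(2 * np.pi * self.F_EXACT * T))
        ps = instantaneous_phase(np.sin(2 * np.pi * self.F_EXACT * T))
        d = wrap_phase(pc - ps)[100:-100]
        assert np.allclose(d, np.pi / 2, atol=1e-3)

    def test_negation_shifts_phase_by_pi(self):
        x = np.sin(2 * np.pi * 10.0 * T)
        d = np.abs(wrap_phase(instantaneous_phase(-x)
                              - instantaneous_phase(x)))[100:-100]
        assert np.allclose(d, np.pi, atol=1e-6)

    def test_zero_input_rejected(self):
        with pytest.raises(ValueError, match="phase undefined"):
            instantaneous_phase(np.zeros(128))


class TestPli:
    def test_constant_quarter_cycle_lag_gives_one(self):
        px = instantaneous_phase(np.sin(2 * np.pi * 10.0 * T))
        py = instantaneous_phase(np.sin(2 * np.pi * 10.0 * T - np.pi / 2))
        assert pli(px, py) == 1.0

    def test_identical_phases_give_zero(self):
        px = instantaneous_phase(np.sin(2 * np.pi * 10.0 * T))
        assert pli(px, px) == 0.0

    def test_hand_enumerated_sign_sequence(self):
        # signs (+, +, +, -): |(3 - 1) / 4| = 0.5
        dx = np.array([np.pi / 4, np.pi / 4, np.pi / 4, -np.pi / 4])
        assert pli(dx, np.zeros(4)) == 0.5

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="equal shape"):
            pli(np.zeros(4), np.zeros(5))

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_symmetry_range_and_offset_invariance(self, seed):
        r = np.random.default_rng(seed)
        a = r.uniform(-np.pi, np.pi, 257)
        b = r.uniform(-np.pi, np.pi, 257)
        v = pli(a, b)
        assert 0.0 <= v <= 1.0
        assert pli(b, a) == v
        # common phase offset leaves the phase difference unchanged
        off = r.uniform(-np.pi, np.pi)
        assert np.isclose(pli(wrap_phase(a + off), wrap_phase(b + off)), v,
                          atol=1e-12)

    def test_amplitude_rescaling_invariance(self, rng):
        x = rng.normal(size=4096)
        y = rng.normal(size=4096)
        xb, yb = bandpass(x, ALPHA2, FS), bandpass(y, ALPHA2, FS)
        v1 = pli(instantaneous_phase(xb), instantaneous_phase(yb))
        v2 = pli(instantaneous_phase(37.5 * xb),
                 instantaneous_phase(0.004 * yb))
        assert np.isclose(v1, v2, atol=1e-12)


class TestKernels:
    def test_jit_and_numpy_kernels_agree(self, rng):
        p = rng.uniform(-np.pi, np.pi, size=(7, 301))
        s, c = np.sin(p), np.cos(p)
        assert np.allclose(pair_sign_means(s, c),
                           pair_sign_means_numpy(s, c), atol=1e-12)


def _random_adjacency(rng, n):
    v = rng.uniform(0.0, 1.0, size=(n, n))
    v = 0.5 * (v + v.T)
    np.fill_diagonal(v, 0.0)
    return AdjacencyMatrix(values=v, band=ALPHA2,
                           labels=tuple(f"R{k}" for k in range(n)))


class TestAdjacency:
    def test_constant_lag_pair_gives_unit_edge(self):
        x = np.stack([np.sin(2 * np.pi * 11.0 * T),
                      np.sin(2 * np.pi * 11.0 * T - np.pi / 2)])
        series = np.repeat(x[:, :, None], 5, axis=2)
        A = adjacency(series, ("a", "b"), ALPHA2, FS)
        assert A.values[0, 1] == 1.0
        assert A.values[0, 0] == 0.0

    def test_pair_count_combinatorics(self):
        A = _random_adjacency(np.random.default_rng(0), 78)
        iu = np.triu_indices(78, k=1)
        assert len(iu[0]) == 3003

    def test_white_noise_null_level(self, rng):
        series = rng.normal(size=(6, 4096, 5))
        A = adjacency(series, [f"r{k}" for k in range(6)], ALPHA2, FS)
        off = A.values[np.triu_indices(6, k=1)]
        assert off.mean() < 0.2

    def test_too_few_epochs_rejected(self, rng):
        with pytest.raises(ValueError, match="epochs"):
            adjacency(rng.normal(size=(3, 4096, 3)), list("abc"), ALPHA2, FS)

    def test_surrogate_null_matches_analytic_level(self, rng):
        # iid uniform phases: E|mean of m signs| ~ sqrt(2/(pi m))
        m = 2000
        p = rng.uniform(-np.pi, np.pi, size=(40, m))
        signed = pair_sign_means(np.sin(p), np.cos(p))
        observed = np.abs(signed[np.triu_indices(40, k=1)]).mean()
        assert abs(observed - analytic_null_level(m)) \
            < 0.2 * analytic_null_level(m)

    def test_edge_trim_is_half_period_of_low_edge(self):
        assert edge_trim_samples(ALPHA2, FS) == int(np.ceil(FS / 20.0))


class TestSummaries:
    def test_node_strength_constant_matrix(self):
        n = 5
        v = np.full((n, n), 0.3)
        np.fill_diagonal(v, 0.0)
        A = AdjacencyMatrix(v, ALPHA2, tuple("abcde"))
        assert np.allclose(node_strength(A), 0.3)
        assert np.isclose(whole_brain_mean(A), 0.3)

    def test_node_strength_hand_mean(self):
        v = np.array([[0.0, 0.2, 0.4], [0.2, 0.0, 0.6], [0.4, 0.6, 0.0]])
        A = AdjacencyMatrix(v, ALPHA2, ("a", "b", "c"))
        assert np.isclose(node_strength(A)[0], 0.3)

    def test_node_strength_permutation_equivariance(self, rng):
        A = _random_adjacency(rng, 7)
        perm = rng.permutation(7)
        Ap = AdjacencyMatrix(A.values[np.ix_(perm, perm)], ALPHA2,
                             tuple(A.labels[k] for k in perm))
        assert np.allclose(node_strength(Ap), node_strength(A)[perm])
        assert np.isclose(whole_brain_mean(Ap), whole_brain_mean(A))

    def test_whole_brain_equals_pair_enumeration(self, rng):
        A = _random_adjacency(rng, 11)
        pairs = [A.values[i, j] for i in range(11) for j in range(i + 1, 11)]
        assert np.isclose(whole_brain_mean(A), np.mean(pairs), atol=1e-12)

    def test_rsn_mean_hand_case(self):
        v = np.zeros((3, 3))
        v[0, 1] = v[1, 0] = 0.2
        v[0, 2] = v[2, 0] = 0.4
        v[1, 2] = v[2, 1] = 0.6
        A = AdjacencyMatrix(v, ALPHA2, ("a", "b", "c"))
        assert np.isclose(rsn_mean_pli(A, ["a", "b", "c"]), 0.4)

    def test_rsn_equal_to_whole_brain_when_rsn_is_whole_atlas(self, rng):
        A = _random_adjacency(rng, 9)
        assert np.isclose(rsn_mean_pli(A, list(A.labels)),
                          whole_brain_mean(A), atol=1e-12)

    def test_rsn_errors(self, rng):
        A = _random_adjacency(rng, 4)
        with pytest.raises(ValueError, match="at least 2"):
            rsn_mean_pli(A, ["R0"])
        with pytest.raises(ValueError, match="not in adjacency"):
            rsn_mean_pli(A, ["R0", "nope"])

    def test_invalid_adjacency_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            AdjacencyMatrix(np.array([[0.0, 0.1], [0.3, 0.0]]), ALPHA2,
                            ("a", "b"))
        with pytest.raises(ValueError, match="diagonal"):
            AdjacencyMatrix(np.array([[0.5, 0.1], [0.1, 0.0]]), ALPHA2,
                            ("a", "b"))


def test_canonical_band_edges():
    expected = {"delta": (0.5, 4.0), "theta": (4.0, 8.0),
                "alpha1": (8.0, 10.0), "alpha2": (10.0, 13.0),
                "beta": (13.0, 30.0), "gamma": (30.0, 48.0)}
    assert {b.name: (b.lo, b.hi) for b in CANONICAL_BANDS} == expected
    with pytest.raises(KeyError):
        get_band("mu")
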