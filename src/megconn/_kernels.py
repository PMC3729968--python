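"""Inner loops for pairwise phase-lag-index accumulation.

The signed mean of sign(sin(phi_i - phi_j)) over samples is the only O(n^2 m)
computation in the pipeline; it is JIT-compiled with numba when available and
falls back to a blocked numpy implementation otherwise.  Both routes are
exercised against each other in the test suite.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly
    import numba

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False


def pair_sign_means_numpy(sin_p: np.ndarray, cos_p: np.ndarray) -> np.ndarray:
    """Signed mean of sign(sin(phi_i - phi_j)) for all ROI pairs.

    Parameters are ``sin`` and ``cos`` of the phases, shape (n_rois, m).
    Returns an antisymmetric (n_rois, n_rois) matrix of signed means.
    """
    n, m = sin_p.shape
    out = np.zeros((n, n))
    for i in range(n):
        # sin(phi_i - phi_j) = sin_i cos_j - cos_i sin_j, broadcast over j
        d = sin_p[i] * cos_p - cos_p[i] * sin_p
        out[i] = np.sign(d).mean(axis=1)
    return out


if _HAVE_NUMBA:

    @numba.njit(cache=True, fastmath=True)
    def _pair_sign_means_jit(sin_p, cos_p):  # pragma: no cover - compiled
        n, m = sin_p.shape
        out = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                acc = 0.0
                for t in range(m):
                    d = sin_p[i, t] * cos_p[j, t] - cos_p[i, t] * sin_p[j, t]
                    # branchless sign: vectorizable, sign(0) contributes 0
                    acc += (d > 0.0) - (d < 0.0)
                v = acc / m
                out[i, j] = v
                out[j, i] = -v
        return out

    def pair_sign_means(sin_p: np.ndarray, cos_p: np.ndarray) -> np.ndarray:
        return _pair_sign_means_jit(
            np.ascontiguousarray(sin_p), np.ascontiguousarray(cos_p))

else:  # pragma: no cover

    pair_sign_means = pair_sign_means_numpy
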