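"""Canonical frequency bands used throughout the pipeline.

The six classical bands of resting-state M/EEG analysis are fixed here:
delta 0.5-4 Hz, theta 4-8 Hz, alpha1 8-10 Hz, alpha2 10-13 Hz,
beta 13-30 Hz and gamma 30-48 Hz.  Beamformer weights are computed from
broadband (0.5-48 Hz) data; band-specific filtering happens only at the
voxel-selection and connectivity stages.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class FrequencyBand:
    """A named frequency band [lo, hi] in Hz."""

    name: str
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not (0.0 < self.lo < self.hi):
            raise ValueError(f"invalid band {self.name}: need 0 < lo < hi, "
                             f"got lo={self.lo}, hi={self.hi}")

    @property
    def mid(self) -> float:
        """Band midpoint in Hz (center frequency of synthetic oscillations)."""
        return 0.5 * (self.lo + self.hi)

    @property
    def width(self) -> float:
        return self.hi - self.lo


DELTA = FrequencyBand("delta", 0.5, 4.0)
THETA = FrequencyBand("theta", 4.0, 8.0)
ALPHA1 = FrequencyBand("alpha1", 8.0, 10.0)
ALPHA2 = FrequencyBand("alpha2", 10.0, 13.0)
BETA = FrequencyBand("beta", 13.0, 30.0)
GAMMA = FrequencyBand("gamma", 30.0, 48.0)

#: The six canonical analysis bands, in ascending frequency order.
CANONICAL_BANDS: tuple[FrequencyBand, ...] = (
    DELTA, THETA, ALPHA1, ALPHA2, BETA, GAMMA)

#: Broadband range used for the data covariance / beamformer weights.
BROADBAND = FrequencyBand("broadband", 0.5, 48.0)

_BY_NAME = {b.name: b for b in CANONICAL_BANDS + (BROADBAND,)}


def get_band(name: str) -> FrequencyBand:
    """Look up a canonical band by name."""
    try:
        return _BY_NAME[name]
    except KeyError:
        raise KeyError(f"unknown band {name!r}; known: {sorted(_BY_NAME)}")
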