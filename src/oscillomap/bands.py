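"""Frequency-band definitions for band-limited envelope analysis.

The canonical resting-state bands used throughout the package: delta
(1-4 Hz), theta (4-8 Hz), alpha (8-13 Hz), beta (13-30 Hz) and three
20-Hz-wide gamma windows (40-60, 60-80, 80-100 Hz).
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class BandDefinition:
    """A named frequency band [f_lo, f_hi] in Hz.

    Invariant: 0 < f_lo < f_hi, and f_hi must lie strictly below the
    Nyquist frequency of any recording the band is applied to (checked
    at filter time, not here, since the band does not know the rate).
    """

    name: str
    f_lo: float
    f_hi: float

    def __post_init__(self) -> None:
        if not (0 < self.f_lo < self.f_hi):
            raise ValueError(
                f"band {self.name!r}: require 0 < f_lo < f_hi, "
                f"got ({self.f_lo}, {self.f_hi})"
            )

    def validate_for_fs(self, fs: float) -> None:
        """Raise ValueError if the band is incompatible with sampling rate fs."""
        if self.f_hi >= fs / 2:
            raise ValueError(
                f"band {self.name!r}: f_hi={self.f_hi} Hz is at or above "
                f"the Nyquist frequency ({fs / 2} Hz for fs={fs} Hz)"
            )


DELTA = BandDefinition("delta", 1.0, 4.0)
THETA = BandDefinition("theta", 4.0, 8.0)
ALPHA = BandDefinition("alpha", 8.0, 13.0)
BETA = BandDefinition("beta", 13.0, 30.0)
GAMMA1 = BandDefinition("gamma1", 40.0, 60.0)
GAMMA2 = BandDefinition("gamma2", 60.0, 80.0)
GAMMA3 = BandDefinition("gamma3", 80.0, 100.0)

#: The seven default analysis bands, low to high.
DEFAULT_BANDS: tuple[BandDefinition, ...] = (
    DELTA, THETA, ALPHA, BETA, GAMMA1, GAMMA2, GAMMA3,
)

_BY_NAME = {b.name: b for b in DEFAULT_BANDS}


def band_by_name(name: str) -> BandDefinition:
    """Look up one of the default bands by name."""
    try:
        return _BY_NAME[name]
    except KeyError:
        raise KeyError(
            f"unknown band {name!r}; known: {sorted(_BY_NAME)}"
        ) from None
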