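"""Wavenumber axis for hyperspectral absorbance cubes.

Quantum-cascade-laser infrared microscopes sample the fingerprint region on a
fixed grid of wavenumbers (cm^-1).  The axis is the spectral coordinate shared
by every pixel of a cube; all band lookups (Amide I, paraffin, phosphate...)
go through nearest-channel resolution on this grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidArgumentError

#: Default acquisition span of the instrument emulated by the phantom (cm^-1).
DEFAULT_LO = 952.0
DEFAULT_HI = 1800.0
#: Default spectral depth (number of wavenumber channels).
DEFAULT_N_CHANNELS = 213


@dataclass(frozen=True)
class WavenumberAxis:
    """Strictly increasing vector of wavenumbers in cm^-1."""

    values: np.ndarray = field(
        default_factory=lambda: np.linspace(DEFAULT_LO, DEFAULT_HI, DEFAULT_N_CHANNELS)
    )

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 1 or values.size < 2:
            raise InvalidArgumentError("axis needs at least two wavenumbers")
        if not np.all(np.diff(values) > 0):
            raise InvalidArgumentError("wavenumbers must be strictly increasing")
        object.__setattr__(self, "values", values)

    def __len__(self) -> int:
        return int(self.values.size)

    @property
    def lo(self) -> float:
        return float(self.values[0])

    @property
    def hi(self) -> float:
        return float(self.values[-1])

    def nearest_channel(self, wavenumber: float) -> int:
        """Index of the channel closest to ``wavenumber``.

        Raises if the requested position lies outside the axis span: a band
        centre off the grid is a configuration error, not a rounding issue.
        """
        if not (self.lo <= wavenumber <= self.hi):
            raise InvalidArgumentError(
                f"wavenumber {wavenumber} outside axis span [{self.lo}, {self.hi}]"
            )
        return int(np.argmin(np.abs(self.values - wavenumber)))

    def channel_slice(self, lo: float, hi: float) -> slice:
        """Channel slice covering [lo, hi], bounds resolved to nearest channels."""
        if lo >= hi:
            raise InvalidArgumentError("band window requires lo < hi")
        i = self.nearest_channel(lo)
        j = self.nearest_channel(hi)
        return slice(i, j + 1)


def generate_axis(lo: float, hi: float, n: int) -> WavenumberAxis:
    """Evenly spaced axis of ``n`` wavenumbers from ``lo`` to ``hi`` inclusive."""
    if n < 2:
        raise InvalidArgumentError("axis needs n >= 2 channels")
    if lo >= hi:
        raise InvalidArgumentError("axis requires lo < hi")
    return WavenumberAxis(np.linspace(float(lo), float(hi), int(n)))
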