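"""In-memory container for one hyperspectral chemical image."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .axis import WavenumberAxis
from .errors import InvalidArgumentError


@dataclass
class HyperCube:
    """One chemical image: an H x W x B absorbance array plus its axis.

    ``meta`` carries sample identifiers (image id, class, treatment, animal)
    so a cube is self-describing when written to disk.
    """

    absorbance: np.ndarray
    axis: WavenumberAxis
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        arr = np.asarray(self.absorbance, dtype=float)
        if arr.ndim != 3:
            raise InvalidArgumentError("absorbance must be H x W x B")
        if arr.shape[2] != len(self.axis):
            raise InvalidArgumentError(
                f"spectral depth {arr.shape[2]} does not match axis length {len(self.axis)}"
            )
        if not np.all(np.isfinite(arr)):
            raise InvalidArgumentError("absorbance contains non-finite values")
        self.absorbance = arr

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.absorbance.shape  # type: ignore[return-value]

    @property
    def n_values(self) -> int:
        """Total number of datapoints in the cube (H * W * B)."""
        return int(self.absorbance.size)
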