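"""Spectral preprocessing: rubber-band baseline, tissue mask, normalisation.

The pipeline converts a raw absorbance cube into tissue spectra suitable for
multiple-instance learning, in this fixed order:

1. rubber-band baseline correction per spectrum (lower convex-hull envelope
   subtracted, removing scattering drift),
2. tissue mask: fixed absorbance threshold (default 0.1) at the channel
   nearest the Amide I peak (default 1654 cm^-1),
3. background spectra replaced by zero-vectors so the spatial dimensions of
   the image are preserved,
4. vector (unit L2) normalisation of the remaining tissue spectra, removing
   thickness variation.

The lower convex hull is computed with an Andrew monotone-chain scan over the
(wavenumber, absorbance) points; collinear points are kept on the hull.  The
baseline is the hull linearly interpolated between its vertices, so the
corrected spectrum is non-negative and exactly zero at hull-contact channels,
and adding any affine function of wavenumber to the input leaves the output
unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .axis import WavenumberAxis
from .cube import HyperCube
from .errors import InvalidArgumentError

DEFAULT_THRESHOLD = 0.1
AMIDE_I_PEAK = 1654.0


@dataclass
class TissueMask:
    """Boolean tissue map from thresholding one absorbance channel."""

    keep: np.ndarray
    threshold: float = DEFAULT_THRESHOLD
    peak_wavenumber: float = AMIDE_I_PEAK

    def __post_init__(self) -> None:
        if self.threshold <= 0:
            raise InvalidArgumentError("threshold must be positive")
        self.keep = np.asarray(self.keep, dtype=bool)

    @property
    def n_tissue(self) -> int:
        return int(self.keep.sum())


@dataclass
class PreprocessedCube:
    """Baseline-corrected, masked, vector-normalised cube.

    Background rows are exact zero-vectors; every tissue spectrum has unit
    Euclidean norm.
    """

    spectra: np.ndarray
    axis: WavenumberAxis
    mask: TissueMask
    provenance: tuple[str, ...] = ()
    meta: dict[str, Any] = field(default_factory=dict)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.spectra.shape  # type: ignore[return-value]


def _lower_hull_indices(x: list[float], y: list[float]) -> list[int]:
    """Andrew monotone-chain lower hull of points sorted by x.

    Collinear points are kept on the hull (pop only on a strict clockwise
    turn); they do not change the interpolated envelope.
    """
    hull: list[int] = []
    for i in range(len(x)):
        while len(hull) >= 2:
            i1, i2 = hull[-2], hull[-1]
            cross = (x[i2] - x[i1]) * (y[i] - y[i1]) - (y[i2] - y[i1]) * (x[i] - x[i1])
            if cross < 0.0:
                hull.pop()
            else:
                break
        hull.append(i)
    return hull


def rubberband_baseline(
    spectrum: np.ndarray, axis: WavenumberAxis, return_baseline: bool = False
):
    """Subtract the lower convex-hull envelope from one spectrum.

    Returns the corrected spectrum (and optionally the baseline itself).
    """
    y = np.asarray(spectrum, dtype=float)
    if y.ndim != 1 or y.size != len(axis):
        raise InvalidArgumentError("spectrum length must match axis length")
    if y.size < 2:
        raise InvalidArgumentError("rubber-band correction needs at least 2 channels")
    if not np.all(np.isfinite(y)):
        raise InvalidArgumentError("spectrum contains non-finite values")
    x = axis.values
    idx = _lower_hull_indices(x.tolist(), y.tolist())
    baseline = np.interp(x, x[idx], y[idx])
    corrected = y - baseline
    # Clip the ~1e-16 negatives left by interpolation round-off.
    np.maximum(corrected, 0.0, out=corrected)
    corrected[idx] = 0.0
    if return_baseline:
        return corrected, baseline
    return corrected


def _rubberband_flat(flat: np.ndarray, axis: WavenumberAxis) -> np.ndarray:
    """Baseline-correct each row of a (K, B) matrix in place-efficient form."""
    x = axis.values
    xl = x.tolist()
    out = np.empty_like(flat)
    for k in range(flat.shape[0]):
        yk = flat[k]
        idx = _lower_hull_indices(xl, yk.tolist())
        baseline = np.interp(x, x[idx], yk[idx])
        row = yk - baseline
        np.maximum(row, 0.0, out=row)
        row[idx] = 0.0
        out[k] = row
    return out


def tissue_mask(
    cube: HyperCube,
    threshold: float = DEFAULT_THRESHOLD,
    peak: float = AMIDE_I_PEAK,
) -> TissueMask:
    """Threshold the channel nearest ``peak``: keep pixels with A >= threshold.

    Expects a baseline-corrected cube; the mask depends only on the single
    peak channel.
    """
    ch = cube.axis.nearest_channel(peak)
    keep = cube.absorbance[:, :, ch] >= threshold
    return TissueMask(keep=keep, threshold=threshold, peak_wavenumber=peak)


def vector_normalize(spectrum: np.ndarray) -> np.ndarray:
    """Scale a spectrum to unit Euclidean norm; the zero vector stays zero."""
    y = np.asarray(spectrum, dtype=float)
    norm = float(np.linalg.norm(y))
    if norm == 0.0:
        return y.copy()
    return y / norm


def preprocess_cube(
    cube: HyperCube,
    threshold: float = DEFAULT_THRESHOLD,
    peak: float = AMIDE_I_PEAK,
) -> PreprocessedCube:
    """Run the full pipeline: baseline -> mask -> zero-fill -> normalise."""
    H, W, B = cube.shape
    flat = _rubberband_flat(cube.absorbance.reshape(H * W, B), cube.axis)
    corrected = HyperCube(flat.reshape(H, W, B), cube.axis, dict(cube.meta))
    mask = tissue_mask(corrected, threshold=threshold, peak=peak)

    keep_flat = mask.keep.ravel()
    flat[~keep_flat] = 0.0
    kept = flat[keep_flat]
    norms = np.linalg.norm(kept, axis=1, keepdims=True)
    norms[norms == 0.0] = 1.0
    flat[keep_flat] = kept / norms

    return PreprocessedCube(
        spectra=flat.reshape(H, W, B),
        axis=cube.axis,
        mask=mask,
        provenance=("rubberband_baseline", "tissue_mask", "zero_fill", "vector_normalize"),
        meta=dict(cube.meta),
    )


def auc_image(cube: HyperCube) -> np.ndarray:
    """Per-pixel trapezoidal integral of absorbance over the full axis span.

    This is the greyscale morphology image attention maps are overlaid on.
    """
    if cube.shape[2] < 2:
        raise InvalidArgumentError("AUC needs at least 2 channels")
    return np.trapezoid(cube.absorbance, cube.axis.values, axis=2)
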