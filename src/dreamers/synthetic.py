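"""Phantom QCL-IR cohort generator with planted ground truth.

Real infrared chemical-imaging cohorts of patient-derived xenograft tissue are
rarely shareable, so every downstream stage of this package is exercised on a
synthetic phantom whose salient pixels, discriminative bands and protein
endpoints are known by construction.  A phantom image is built as

* a spatially contiguous tissue region (thresholded smooth Gaussian random
  field) on a near-zero background,
* a base tissue spectrum made of Gaussian absorption bands (Amide I/II/III,
  nucleic-acid phosphate, CH deformation) with per-image amplitude jitter
  emulating biological variability,
* a salient sub-region whose pixels additionally carry class-discriminative
  bands (phosphate stretch near 965 cm^-1 for one class, lipid/RNA carbonyl
  near 1727 cm^-1 for the other) and treatment-specific amide shifts,
* paraffin contaminant bands at 1464 and 1373 cm^-1 on every pixel (sections
  are not dewaxed), a smooth scattering-like baseline drift, and additive
  Gaussian noise.

Protein endpoints (Bim, Puma) are drawn as a linear function of the planted
Amide-I integral of each image's salient region plus calibrated noise, so the
cohort-level Pearson correlation approaches a configurable target.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .axis import WavenumberAxis
from .cube import HyperCube
from .errors import InvalidArgumentError, WriteError

#: (centre cm^-1, Gaussian sigma cm^-1, amplitude in absorbance units)
Peak = tuple[float, float, float]

DEFAULT_TREATMENTS: tuple[str, ...] = ("FOLFOX", "ABT199", "COMBO", "VEHICLE")

#: Base absorption bands present in every tissue pixel.
BASE_TISSUE_PEAKS: tuple[Peak, ...] = (
    (1654.0, 25.0, 0.60),  # Amide I
    (1544.0, 20.0, 0.35),  # Amide II
    (1240.0, 40.0, 0.18),  # Amide III
    (1080.0, 25.0, 0.12),  # nu-PO2 nucleic-acid backbone
    (1452.0, 15.0, 0.08),  # CH2/CH3 deformation
)

#: Class-discriminative bands carried only by salient pixels.
DEFAULT_CLASS_EFFECTS: dict[int, tuple[Peak, ...]] = {
    0: ((965.0, 10.0, 0.6),),   # phosphate stretch region
    1: ((1727.0, 12.0, 0.6),),  # carbonyl stretch region
}

#: Treatment-specific amide shifts (apoptosis-like protein-band changes),
#: carried by salient pixels on top of the class effect.
DEFAULT_TREATMENT_EFFECTS: dict[str, tuple[Peak, ...]] = {
    "FOLFOX": ((1654.0, 25.0, 0.10),),
    "ABT199": ((1654.0, 25.0, 0.25), (1240.0, 40.0, 0.15)),
    "COMBO": ((1654.0, 25.0, 0.35), (1240.0, 40.0, 0.20)),
    "VEHICLE": (),
}

#: Paraffin wax contaminant bands (centre, sigma, relative amplitude).
PARAFFIN_BANDS: tuple[tuple[float, float, float], ...] = (
    (1464.0, 9.0, 1.0),
    (1373.0, 9.0, 0.62),
)

#: Peaks have compact support: truncated at +/- 5 sigma so planted effects are
#: exactly zero outside their band windows (the clipped tail is < 4e-6 amp).
PEAK_TRUNCATION_SIGMA = 5.0

#: Window (cm^-1) of the planted band integral that protein endpoints track.
PROTEIN_BAND_WINDOW: tuple[float, float] = (1600.0, 1700.0)
PROTEIN_NAMES: tuple[str, ...] = ("bim", "puma")

# Sub-stream tags so label choices never perturb shared random draws.
_STREAM_LAYOUT, _STREAM_JITTER, _STREAM_BASELINE, _STREAM_NOISE = 1, 2, 3, 4
_STREAM_PROTEIN = 999983


@dataclass(frozen=True)
class BaselineParams:
    """Maximum amplitudes of the smooth per-pixel baseline drift components."""

    offset: float = 0.03
    slope: float = 0.03
    curvature: float = 0.02

    def __post_init__(self) -> None:
        if min(self.offset, self.slope, self.curvature) < 0:
            raise InvalidArgumentError("baseline amplitudes must be >= 0")

    @property
    def is_zero(self) -> bool:
        return self.offset == self.slope == self.curvature == 0.0


@dataclass(frozen=True)
class BandEffects:
    """Per-class and per-treatment Gaussian peak deltas on salient pixels."""

    class_effects: dict[int, tuple[Peak, ...]] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_EFFECTS)
    )
    treatment_effects: dict[str, tuple[Peak, ...]] = field(
        default_factory=lambda: dict(DEFAULT_TREATMENT_EFFECTS)
    )

    def windows(self, n_sigma: float = PEAK_TRUNCATION_SIGMA) -> list[tuple[float, float]]:
        """Wavenumber windows (centre +/- n_sigma * sigma) of every effect band."""
        out = []
        for peaks in list(self.class_effects.values()) + list(self.treatment_effects.values()):
            for c, w, _ in peaks:
                out.append((c - n_sigma * w, c + n_sigma * w))
        return out


@dataclass(frozen=True)
class PhantomSpec:
    """Recipe for one synthetic QCL-IR cohort."""

    height: int = 64
    width: int = 64
    axis: WavenumberAxis = field(default_factory=WavenumberAxis)
    n_models: int = 2
    treatments: tuple[str, ...] = DEFAULT_TREATMENTS
    images_per_cell: int = 5
    mice_per_cell: int = 5
    tissue_fraction: float = 0.5
    salient_fraction: float = 0.15
    band_effects: BandEffects = field(default_factory=BandEffects)
    baseline_params: BaselineParams = field(default_factory=BaselineParams)
    paraffin_amplitude: float = 0.15
    noise_sd: float = 0.01
    amplitude_jitter: float = 0.15
    protein_corr: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.height < 1 or self.width < 1:
            raise InvalidArgumentError("image dimensions must be >= 1")
        if not (0 < self.tissue_fraction <= 1):
            raise InvalidArgumentError("tissue_fraction must be in (0, 1]")
        if not (0 < self.salient_fraction <= 1):
            raise InvalidArgumentError("salient_fraction must be in (0, 1]")
        if not self.treatments:
            raise InvalidArgumentError("treatments must be non-empty")
        if self.n_models < 1:
            raise InvalidArgumentError("n_models must be >= 1")
        if self.images_per_cell < 1 or self.mice_per_cell < 1:
            raise InvalidArgumentError("images_per_cell and mice_per_cell must be >= 1")
        if self.paraffin_amplitude < 0 or self.noise_sd < 0 or self.amplitude_jitter < 0:
            raise InvalidArgumentError("amplitudes must be >= 0")
        if not (-1.0 <= self.protein_corr <= 1.0):
            raise InvalidArgumentError("protein_corr must lie in [-1, 1]")
        missing = [c for c in range(self.n_models) if c not in self.band_effects.class_effects]
        if missing:
            raise InvalidArgumentError(f"band_effects missing class effects for {missing}")

    @property
    def n_images(self) -> int:
        return self.n_models * len(self.treatments) * self.images_per_cell


@dataclass
class GroundTruth:
    """Planted truth for one phantom image."""

    tissue_mask_true: np.ndarray
    salient_mask_true: np.ndarray
    class_label: int
    treatment_label: str
    animal_id: str
    protein_levels: dict[str, float] = field(default_factory=dict)
    #: Noiseless Amide-I integral of the salient mean spectrum; the quantity
    #: the protein endpoints are calibrated against.
    planted_band_integral: float = 0.0


@dataclass
class Cohort:
    """A generated phantom cohort: cubes, manifest and planted truth."""

    cubes: list[HyperCube]
    manifest: pd.DataFrame
    ground_truths: list[GroundTruth]


def _gaussian(axis: WavenumberAxis, centre: float, sigma: float, amp: float) -> np.ndarray:
    z = (axis.values - centre) / sigma
    out = amp * np.exp(-0.5 * z**2)
    out[np.abs(z) > PEAK_TRUNCATION_SIGMA] = 0.0
    return out


def _peak_sum(axis: WavenumberAxis, peaks: Sequence[Peak], scales=None) -> np.ndarray:
    out = np.zeros(len(axis))
    for i, (c, w, a) in enumerate(peaks):
        s = 1.0 if scales is None else scales[i]
        out += _gaussian(axis, c, w, a * s)
    return out


def _top_fraction_mask(score: np.ndarray, n_keep: int) -> np.ndarray:
    """Boolean mask of the n_keep highest-scoring entries of a 2D field."""
    flat = score.ravel()
    mask = np.zeros(flat.size, dtype=bool)
    if n_keep > 0:
        mask[np.argpartition(flat, -n_keep)[-n_keep:]] = True
    return mask.reshape(score.shape)


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(stream)]))


def generate_cube(
    spec: PhantomSpec,
    class_label: int,
    treatment_label: str,
    animal_id: str = "m0",
    seed: int = 0,
) -> tuple[HyperCube, GroundTruth]:
    """Generate one phantom image and its planted ground truth.

    All stochastic components are drawn from sub-streams keyed only by
    ``seed``, so two cubes generated with the same seed but different class
    labels differ exactly (and only) in the class-effect band channels of the
    salient pixels.
    """
    if class_label not in range(spec.n_models):
        raise InvalidArgumentError(f"unknown class label {class_label!r}")
    if treatment_label not in spec.treatments:
        raise InvalidArgumentError(f"unknown treatment {treatment_label!r}")

    H, W, B = spec.height, spec.width, len(spec.axis)
    axis = spec.axis

    # Spatial layout: contiguous blobs from smoothed Gaussian random fields,
    # thresholded to the exact planted pixel counts.
    rng_layout = _rng(seed, _STREAM_LAYOUT)
    sigma_px = max(2.0, min(H, W) / 8.0)
    tissue_field = gaussian_filter(rng_layout.standard_normal((H, W)), sigma=sigma_px)
    n_tissue = int(round(spec.tissue_fraction * H * W))
    n_tissue = max(1, n_tissue)
    tissue = _top_fraction_mask(tissue_field, n_tissue)

    salient_field = gaussian_filter(rng_layout.standard_normal((H, W)), sigma=sigma_px)
    n_salient = max(1, int(round(spec.salient_fraction * n_tissue)))
    scores = np.where(tissue, salient_field, -np.inf)
    salient = _top_fraction_mask(scores, n_salient)

    # Per-image biological variability of the base band amplitudes.
    rng_jitter = _rng(seed, _STREAM_JITTER)
    jit = rng_jitter.standard_normal(len(BASE_TISSUE_PEAKS))
    scales = np.clip(1.0 + spec.amplitude_jitter * jit, 0.0, None)

    base = _peak_sum(axis, BASE_TISSUE_PEAKS, scales)
    class_eff = _peak_sum(axis, spec.band_effects.class_effects[class_label])
    treat_eff = _peak_sum(axis, spec.band_effects.treatment_effects.get(treatment_label, ()))

    cube = np.zeros((H, W, B))
    cube[tissue] += base
    cube[salient] += class_eff + treat_eff

    if spec.paraffin_amplitude > 0:
        paraffin = sum(
            _gaussian(axis, c, w, spec.paraffin_amplitude * rel) for c, w, rel in PARAFFIN_BANDS
        )
        cube += paraffin

    bp = spec.baseline_params
    rng_base = _rng(seed, _STREAM_BASELINE)
    if not bp.is_zero:
        t = (axis.values - axis.lo) / (axis.hi - axis.lo)
        off = bp.offset * _smooth_unit_field(rng_base, H, W, sigma_px)
        slp = bp.slope * _smooth_unit_field(rng_base, H, W, sigma_px)
        crv = bp.curvature * _smooth_unit_field(rng_base, H, W, sigma_px)
        cube += (
            off[:, :, None]
            + slp[:, :, None] * t[None, None, :]
            + crv[:, :, None] * (4.0 * (t[None, None, :] - 0.5) ** 2)
        )

    if spec.noise_sd > 0:
        rng_noise = _rng(seed, _STREAM_NOISE)
        cube += rng_noise.normal(0.0, spec.noise_sd, size=(H, W, B))

    # Planted (noiseless) Amide-I integral of the salient mean spectrum.
    sl = axis.channel_slice(*PROTEIN_BAND_WINDOW)
    salient_mean = base + class_eff + treat_eff
    planted = float(np.trapezoid(salient_mean[sl], axis.values[sl]))

    meta = {
        "class": int(class_label),
        "treatment": treatment_label,
        "animal_id": animal_id,
        "seed": int(seed),
    }
    gt = GroundTruth(
        tissue_mask_true=tissue,
        salient_mask_true=salient,
        class_label=int(class_label),
        treatment_label=treatment_label,
        animal_id=animal_id,
        planted_band_integral=planted,
    )
    return HyperCube(cube, axis, meta), gt


def _smooth_unit_field(rng: np.random.Generator, H: int, W: int, sigma: float) -> np.ndarray:
    """Smooth random field rescaled to [0, 1]."""
    f = gaussian_filter(rng.standard_normal((H, W)), sigma=sigma)
    lo, hi = f.min(), f.max()
    if hi == lo:
        return np.zeros((H, W))
    return (f - lo) / (hi - lo)


def generate_cohort(spec: PhantomSpec, out_dir: str | Path | None = None) -> Cohort:
    """Generate a full phantom cohort.

    The default spec mirrors a 2-class x 4-treatment x 5-image design
    (40 images, 20 per class).  Animal identifiers are unique within each
    (class, treatment) cell and never shared across classes.  When ``out_dir``
    is given every cube is written to HDF5 and the manifest records the path;
    otherwise cubes stay in memory and ``path`` is empty.
    """
    from . import io as _io  # local import: io depends on cube, not on us

    cubes: list[HyperCube] = []
    gts: list[GroundTruth] = []
    rows: list[dict] = []

    idx = 0
    for c in range(spec.n_models):
        for t in spec.treatments:
            animals = [f"m{c}_{t}_{k}" for k in range(spec.mice_per_cell)]
            for i in range(spec.images_per_cell):
                animal = animals[i % spec.mice_per_cell]
                child = int(
                    np.random.SeedSequence([spec.seed, idx]).generate_state(1)[0] % (2**31)
                )
                cube, gt = generate_cube(spec, c, t, animal_id=animal, seed=child)
                image_id = f"img{idx:03d}_c{c}_{t}"
                cube.meta["image_id"] = image_id
                cubes.append(cube)
                gts.append(gt)
                rows.append(
                    {
                        "image_id": image_id,
                        "path": "",
                        "class": c,
                        "treatment": t,
                        "animal_id": animal,
                    }
                )
                idx += 1

    # Protein endpoints: linear in the planted Amide-I integral plus noise
    # calibrated so the population correlation equals protein_corr.
    planted = np.array([g.planted_band_integral for g in gts])
    sd = planted.std()
    z = (planted - planted.mean()) / sd if sd > 0 else np.zeros_like(planted)
    rng = _rng(spec.seed, _STREAM_PROTEIN)
    r = spec.protein_corr
    for name in PROTEIN_NAMES:
        eps = rng.standard_normal(len(gts))
        levels = r * z + np.sqrt(max(0.0, 1.0 - r * r)) * eps
        for g, row, v in zip(gts, rows, levels):
            g.protein_levels[name] = float(v)
            row[name] = float(v)

    manifest = pd.DataFrame(rows)

    if out_dir is not None:
        out = Path(out_dir)
        try:
            out.mkdir(parents=True, exist_ok=True)
        except OSError as e:  # pragma: no cover - filesystem dependent
            raise WriteError(out, str(e)) from e
        for cube, row in zip(cubes, manifest.itertuples()):
            path = out / f"{row.image_id}.h5"
            try:
                _io.write_cube(path, cube)
            except OSError as e:
                raise WriteError(path, str(e)) from e
            manifest.loc[row.Index, "path"] = str(path)
        manifest.to_csv(out / "manifest.csv", index=False)

    return Cohort(cubes=cubes, manifest=manifest, ground_truths=gts)
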