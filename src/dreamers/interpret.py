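"""Attention saliency and per-wavenumber gradient attributions.

Two complementary views of a trained model's reasoning:

* **Attention**: the pooling weights a_k of each bag, min-max normalised to
  [0, 1], rendered as a 2D saliency map over the source image, and used to
  filter the top-attended fraction of spectra for downstream analysis.
* **Expected gradients**: per-wavenumber attribution of the instance-level
  class score.  For an instance x, background samples b and path positions
  alpha ~ U(0, 1), the attribution of channel i is the average of
  (x_i - b_i) * d f_c / d x_i evaluated at b + alpha (x - b) — a sampled
  form of integrated gradients with a background distribution, summarised per
  class as mean |attribution| (importance) and signed mean (direction).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .axis import WavenumberAxis
from .errors import InvalidArgumentError, NumericError
from .mil import Bag, MilAttentionModel

DEFAULT_TOP_FRACTION = 0.05
DEFAULT_N_SAMPLES = 64
DEFAULT_BACKGROUND_SIZE = 512
DEFAULT_INSTANCES_PER_BAG = 2000


@dataclass
class AttentionResult:
    """Attention view of one bag: raw weights, [0,1] map, top spectra."""

    raw: np.ndarray
    normalized: np.ndarray
    map: np.ndarray
    top_indices: np.ndarray
    top_spectra: np.ndarray


@dataclass
class AttributionSummary:
    """Per-class, per-wavenumber expected-gradients summary."""

    wavenumbers: np.ndarray
    mean_abs: np.ndarray       # (n_classes, B) importance
    signed_mean: np.ndarray    # (n_classes, B) direction of effect
    ranking: np.ndarray        # (n_classes, B) channel indices, descending importance


def normalize_attention(raw: np.ndarray) -> np.ndarray:
    """Min-max normalise attention weights to [0, 1].

    A constant vector maps to all zeros: a flat attention field carries no
    saliency.
    """
    raw = np.asarray(raw, dtype=float)
    if np.any(raw < 0):
        raise InvalidArgumentError("attention weights must be non-negative")
    if not np.all(np.isfinite(raw)):
        raise InvalidArgumentError("attention weights must be finite")
    lo, hi = raw.min(), raw.max()
    if hi == lo:
        return np.zeros_like(raw)
    return (raw - lo) / (hi - lo)


def attention_map(
    normalized: np.ndarray, index_map: np.ndarray, height: int, width: int
) -> np.ndarray:
    """Scatter per-instance values onto the (H, W) grid; unmapped pixels = 0."""
    normalized = np.asarray(normalized, dtype=float)
    idx = np.asarray(index_map, dtype=int)
    if idx.shape != (normalized.size, 2):
        raise InvalidArgumentError("index_map must pair one (row, col) per instance")
    if idx.size and (
        idx.min() < 0 or idx[:, 0].max() >= height or idx[:, 1].max() >= width
    ):
        raise InvalidArgumentError("index_map entries outside the image")
    img = np.zeros((height, width))
    img[idx[:, 0], idx[:, 1]] = normalized
    return img


def top_fraction(
    raw: np.ndarray, spectra: np.ndarray, fraction: float = DEFAULT_TOP_FRACTION
) -> tuple[np.ndarray, np.ndarray]:
    """Indices and spectra of the ceil(fraction * K) highest-attention instances.

    Rows are ordered by descending weight; ties at the cut keep the smaller
    instance index.
    """
    raw = np.asarray(raw, dtype=float)
    spectra = np.asarray(spectra, dtype=float)
    if raw.size == 0:
        raise InvalidArgumentError("empty bag")
    if not (0 < fraction <= 1):
        raise InvalidArgumentError("fraction must be in (0, 1]")
    if spectra.shape[0] != raw.size:
        raise InvalidArgumentError("spectra rows must match weights")
    n_keep = int(np.ceil(fraction * raw.size))
    # stable sort on (-weight, index): deterministic tie handling
    order = np.lexsort((np.arange(raw.size), -raw))
    idx = order[:n_keep]
    return idx, spectra[idx]


def attend_bag(
    model: MilAttentionModel,
    bag: Bag,
    height: int,
    width: int,
    fraction: float = DEFAULT_TOP_FRACTION,
) -> AttentionResult:
    """Full attention read-out of one bag through a trained model."""
    _, a = model.forward(bag)
    normalized = normalize_attention(a)
    amap = attention_map(normalized, bag.index_map, height, width)
    idx, spectra = top_fraction(a, bag.instances, fraction)
    return AttentionResult(
        raw=a, normalized=normalized, map=amap, top_indices=idx, top_spectra=spectra
    )


def gradient_attributions(
    model: MilAttentionModel,
    bags: list[Bag],
    background: np.ndarray,
    n_samples: int = DEFAULT_N_SAMPLES,
    instances_per_bag: int = DEFAULT_INSTANCES_PER_BAG,
    axis: WavenumberAxis | None = None,
    seed: int = 0,
    batch_size: int = 8192,
) -> AttributionSummary:
    """Expected-gradients attribution per input wavenumber per class.

    ``background`` is a sample of instances (conventionally drawn from the
    validation bags).  For runtime, at most ``instances_per_bag`` instances
    per bag are explained (seed-subsampled); attention-heavy pixels are rare,
    so explained instances are drawn uniformly from the tissue (non-zero)
    rows when any exist.
    """
    background = np.asarray(background, dtype=float)
    if background.ndim != 2 or background.shape[0] < 1:
        raise InvalidArgumentError("background must be a non-empty instance matrix")
    for k, v in model.params.items():
        if not np.all(np.isfinite(v)):
            raise NumericError(f"model parameter {k} is non-finite")

    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 23]))
    explained: list[np.ndarray] = []
    for bag in bags:
        X = bag.instances
        nz = np.flatnonzero(np.any(X != 0.0, axis=1))
        pool = nz if nz.size else np.arange(X.shape[0])
        if pool.size > instances_per_bag:
            pool = rng.choice(pool, size=instances_per_bag, replace=False)
        explained.append(X[np.sort(pool)])
    X = np.concatenate(explained, axis=0)
    N, B = X.shape
    C = model.config.n_classes

    mean_abs = np.zeros((C, B))
    signed = np.zeros((C, B))
    for start in range(0, N, max(1, batch_size // n_samples)):
        xb = X[start : start + max(1, batch_size // n_samples)]
        nb = xb.shape[0]
        b_idx = rng.integers(0, background.shape[0], size=(nb, n_samples))
        alphas = rng.random((nb, n_samples))
        bg = background[b_idx]                      # (nb, S, B)
        diff = xb[:, None, :] - bg                  # (nb, S, B)
        pts = (bg + alphas[:, :, None] * diff).reshape(nb * n_samples, B)
        for c in range(C):
            g = model.instance_input_gradients(pts, c).reshape(nb, n_samples, B)
            attr = (g * diff).mean(axis=1)          # (nb, B)
            mean_abs[c] += np.abs(attr).sum(axis=0)
            signed[c] += attr.sum(axis=0)
    mean_abs /= N
    signed /= N

    ranking = np.argsort(-mean_abs, axis=1, kind="stable")
    wn = axis.values if axis is not None else np.arange(B, dtype=float)
    return AttributionSummary(
        wavenumbers=wn, mean_abs=mean_abs, signed_mean=signed, ranking=ranking
    )


def expected_gradients_single(
    model: MilAttentionModel,
    x: np.ndarray,
    background: np.ndarray,
    class_idx: int,
    n_samples: int = 256,
    seed: int = 0,
) -> np.ndarray:
    """Expected-gradients attribution vector for one instance (test utility)."""
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 29]))
    background = np.atleast_2d(np.asarray(background, dtype=float))
    b_idx = rng.integers(0, background.shape[0], size=n_samples)
    alphas = rng.random(n_samples)
    bg = background[b_idx]
    diff = x[None, :] - bg
    pts = bg + alphas[:, None] * diff
    g = model.instance_input_gradients(pts, class_idx)
    return (g * diff).mean(axis=0)


def rank_report(
    summary: AttributionSummary,
    band_annotations: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Per-class ranked wavenumber table with optional band annotations.

    Annotations outside the axis span are flagged in the ``note`` column
    rather than silently dropped.
    """
    band_annotations = band_annotations or {}
    lo, hi = float(summary.wavenumbers.min()), float(summary.wavenumbers.max())
    span = summary.wavenumbers[-1] - summary.wavenumbers[0]
    half_step = span / max(1, len(summary.wavenumbers) - 1) / 2.0

    rows = []
    for c in range(summary.mean_abs.shape[0]):
        for rank, ch in enumerate(summary.ranking[c]):
            wn = float(summary.wavenumbers[ch])
            labels, notes = [], []
            for name, centre in band_annotations.items():
                if not (lo <= centre <= hi):
                    if rank == 0:
                        labels.append(name)
                        notes.append(f"annotation {centre} cm^-1 outside axis span")
                    continue
                if abs(wn - centre) <= half_step:
                    labels.append(name)
            rows.append(
                {
                    "class": c,
                    "rank": rank,
                    "wavenumber": wn,
                    "mean_abs_attribution": float(summary.mean_abs[c, ch]),
                    "signed_mean_attribution": float(summary.signed_mean[c, ch]),
                    "band": ";".join(labels),
                    "note": ";".join(notes),
                }
            )
    return pd.DataFrame(rows)


def save_attention_overlay(
    path, attention_img: np.ndarray, morphology_img: np.ndarray
) -> None:
    """PNG overlay: greyscale AUC morphology background, colour attention."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 4))
    ax.imshow(morphology_img, cmap="gray")
    masked = np.ma.masked_where(attention_img <= 0, attention_img)
    im = ax.imshow(masked, cmap="inferno", alpha=0.7, vmin=0, vmax=1)
    fig.colorbar(im, ax=ax, fraction=0.046)
    ax.set_axis_off()
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
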