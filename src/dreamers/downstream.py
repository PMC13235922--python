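"""Downstream analysis of salient spectra: clustering and band correlations.

Top-attended spectra are standard-scaled, embedded to 2D with UMAP (grid
search over neighbourhood size, minimum distance and metric), clustered with
k-means, and scored against ground-truth labels with normalised mutual
information NMI(U, V) = I(U, V) / sqrt(H(U) H(V)) (natural logs, plug-in
estimates from the contingency table).

Separately, amide band integrals and peak ratios computed from each image's
salient mean spectrum are correlated (Pearson) with protein endpoints, one
table per chemotherapy-sensitivity group.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans
from sklearn.preprocessing import StandardScaler

from .axis import WavenumberAxis
from .errors import InvalidArgumentError

#: Denominators smaller than this yield a flagged missing value, not infinity.
RATIO_EPS = 1e-12


@dataclass(frozen=True)
class UmapGrid:
    """UMAP parameter grid plus the k of the downstream k-means."""

    n_neighbors: tuple[int, ...] = (5, 10, 20, 40, 80)
    min_dist: tuple[float, ...] = (0.1, 0.25, 0.5)
    metrics: tuple[str, ...] = ("euclidean", "cosine", "manhattan")
    k: int = 7
    random_state: int = 0

    def __post_init__(self) -> None:
        if not (self.n_neighbors and self.min_dist and self.metrics):
            raise InvalidArgumentError("grid axes must be non-empty")
        if self.k < 2:
            raise InvalidArgumentError("k must be >= 2")

    def cells(self):
        return itertools.product(self.n_neighbors, self.min_dist, self.metrics)


@dataclass(frozen=True)
class BandDefinition:
    """Integration window [lo, hi] in cm^-1."""

    name: str
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if self.lo >= self.hi:
            raise InvalidArgumentError(f"band {self.name}: lo must be < hi")


@dataclass(frozen=True)
class PeakRatio:
    """Ratio of absorbances at two nearest-channel peak positions."""

    name: str
    numerator: float
    denominator: float


#: Protein-related amide bands.
DEFAULT_BANDS: tuple[BandDefinition, ...] = (
    BandDefinition("amide_i", 1600.0, 1700.0),
    BandDefinition("amide_ii", 1540.0, 1560.0),
    BandDefinition("amide_iii", 1200.0, 1350.0),
)

#: Peak ratios; positions beyond the amide pair follow common literature
#: assignments for cellular IR spectra (DNA/RNA phosphate, lipid carbonyl).
DEFAULT_RATIOS: tuple[PeakRatio, ...] = (
    PeakRatio("amide_i_ii", 1658.0, 1544.0),
    PeakRatio("amide_i_dna_po4", 1658.0, 970.0),
    PeakRatio("amide_i_nucleic_po2", 1658.0, 1080.0),
    PeakRatio("amide_i_lipid_co", 1658.0, 1740.0),
    PeakRatio("amide_i_rna_uracil", 1658.0, 996.0),
)


def standard_scale(features: np.ndarray) -> np.ndarray:
    """Column-wise standardisation to mean 0, population sd 1.

    Constant columns map to zero.
    """
    X = np.asarray(features, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise InvalidArgumentError("standard_scale needs an N x B matrix with N >= 2")
    return StandardScaler().fit_transform(X)


def nmi(labels_true, labels_pred) -> float:
    """Normalised mutual information with geometric-mean normalisation.

    Computed from the contingency table with natural logarithms.  If either
    partition has zero entropy the score is 1 when the partitions are
    identical up to relabelling and 0 otherwise.
    """
    u = np.asarray(labels_true).ravel()
    v = np.asarray(labels_pred).ravel()
    if u.size != v.size:
        raise InvalidArgumentError("label vectors must have equal length")
    if u.size == 0:
        raise InvalidArgumentError("label vectors must be non-empty")
    n = u.size
    _, ui = np.unique(u, return_inverse=True)
    _, vi = np.unique(v, return_inverse=True)
    table = np.zeros((ui.max() + 1, vi.max() + 1))
    np.add.at(table, (ui, vi), 1.0)
    pij = table / n
    pi = pij.sum(axis=1)
    pj = pij.sum(axis=0)
    hu = -np.sum(pi[pi > 0] * np.log(pi[pi > 0]))
    hv = -np.sum(pj[pj > 0] * np.log(pj[pj > 0]))
    if hu == 0.0 or hv == 0.0:
        # degenerate partition(s): identical up to relabelling iff both are
        # single-cluster (a constant partition matches any constant partition)
        same = (hu == 0.0) and (hv == 0.0)
        return 1.0 if same else 0.0
    nz = pij > 0
    mi = float(np.sum(pij[nz] * (np.log(pij[nz]) - np.log(np.outer(pi, pj)[nz]))))
    return float(mi / np.sqrt(hu * hv))


def umap_kmeans(
    spectra: np.ndarray,
    n_neighbors: int,
    min_dist: float,
    metric: str = "euclidean",
    k: int = 7,
    random_state: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """2D UMAP embedding followed by k-means clustering (10 restarts).

    Deterministic for a fixed ``random_state``.
    """
    import umap  # heavy import kept local

    X = np.asarray(spectra, dtype=float)
    if X.shape[0] <= n_neighbors:
        raise InvalidArgumentError(
            f"need more than n_neighbors={n_neighbors} samples, got {X.shape[0]}"
        )
    reducer = umap.UMAP(
        n_components=2,
        n_neighbors=n_neighbors,
        min_dist=min_dist,
        metric=metric,
        random_state=random_state,
    )
    embedding = reducer.fit_transform(X)
    km = KMeans(n_clusters=k, n_init=10, random_state=random_state)
    labels = km.fit_predict(embedding)
    return embedding, labels


def umap_grid_search(
    spectra: np.ndarray, labels_true, grid: UmapGrid
) -> tuple[dict, float, pd.DataFrame]:
    """Evaluate every grid cell by the NMI of its k-means labels vs truth.

    Returns (best params, best NMI, full results table).  Ties resolve to
    smaller n_neighbors, then smaller min_dist, then metric name order.
    """
    rows = []
    for nn, md, metric in grid.cells():
        _, labels = umap_kmeans(
            spectra, n_neighbors=nn, min_dist=md, metric=metric,
            k=grid.k, random_state=grid.random_state,
        )
        rows.append(
            {"n_neighbors": nn, "min_dist": md, "metric": metric,
             "nmi": nmi(labels_true, labels)}
        )
    results = pd.DataFrame(rows)
    best_score = results["nmi"].max()
    tied = results[results["nmi"] == best_score]
    best = min(
        tied.to_dict("records"),
        key=lambda r: (r["n_neighbors"], r["min_dist"], r["metric"]),
    )
    params = {k: best[k] for k in ("n_neighbors", "min_dist", "metric")}
    return params, float(best_score), results


def integrate_band(
    spectrum: np.ndarray, band: BandDefinition, axis: WavenumberAxis
) -> float:
    """Trapezoidal integral of the spectrum over the band window.

    The channels nearest each bound are included.
    """
    sl = axis.channel_slice(band.lo, band.hi)
    y = np.asarray(spectrum, dtype=float)
    return float(np.trapezoid(y[sl], axis.values[sl]))


def band_metrics(
    spectra_by_image: dict[str, np.ndarray],
    axis: WavenumberAxis,
    bands: tuple[BandDefinition, ...] = DEFAULT_BANDS,
    ratios: tuple[PeakRatio, ...] = DEFAULT_RATIOS,
) -> pd.DataFrame:
    """Band integrals and peak ratios per image (rows indexed by image id).

    ``spectra_by_image`` maps image id -> representative (e.g. salient-mean)
    spectrum.  A denominator below the epsilon guard yields NaN plus a flag
    column ``<name>_missing`` = True rather than infinity.
    """
    rows = {}
    for image_id, spectrum in spectra_by_image.items():
        y = np.asarray(spectrum, dtype=float)
        row: dict[str, float | bool] = {}
        for band in bands:
            row[band.name] = integrate_band(y, band, axis)
        for ratio in ratios:
            num = float(y[axis.nearest_channel(ratio.numerator)])
            den = float(y[axis.nearest_channel(ratio.denominator)])
            if abs(den) < RATIO_EPS:
                row[ratio.name] = np.nan
                row[f"{ratio.name}_missing"] = True
            else:
                row[ratio.name] = num / den
                row[f"{ratio.name}_missing"] = False
        rows[image_id] = row
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "image_id"
    return out


def pearson_correlate(
    metrics: pd.DataFrame,
    proteins: pd.DataFrame,
    group_key: str = "class",
    min_pairs: int = 3,
) -> dict[object, pd.DataFrame]:
    """Sample Pearson r between every spectral metric and protein, per group.

    ``proteins`` must share the image index with ``metrics`` and contain the
    grouping column plus one column per protein.  Pairs with missing values
    are dropped pairwise; cells with fewer than ``min_pairs`` complete pairs
    are reported as NaN.  Each cell also records the n used.
    """
    if group_key not in proteins.columns:
        raise InvalidArgumentError(f"protein table missing group column {group_key!r}")
    metric_cols = [c for c in metrics.columns if not c.endswith("_missing")]
    protein_cols = [c for c in proteins.columns if c != group_key]
    joined = metrics[metric_cols].join(proteins, how="inner")
    if joined.empty:
        raise InvalidArgumentError("metrics and protein tables share no image ids")

    tables: dict[object, pd.DataFrame] = {}
    for group, sub in joined.groupby(group_key):
        r = pd.DataFrame(index=metric_cols, columns=protein_cols, dtype=float)
        n = pd.DataFrame(index=metric_cols, columns=protein_cols, dtype=int)
        for mc in metric_cols:
            for pc in protein_cols:
                pair = sub[[mc, pc]].dropna()
                n.loc[mc, pc] = len(pair)
                if len(pair) < min_pairs or pair[mc].nunique() < 2 or pair[pc].nunique() < 2:
                    r.loc[mc, pc] = np.nan
                else:
                    r.loc[mc, pc] = float(stats.pearsonr(pair[mc], pair[pc])[0])
        table = r.copy()
        table.columns = pd.MultiIndex.from_product([["r"], protein_cols])
        for pc in protein_cols:
            table[("n", pc)] = n[pc]
        tables[group] = table
    return tables
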