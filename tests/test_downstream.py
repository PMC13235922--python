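"""Scaling, NMI, UMAP + k-means clustering and band-ratio correlations."""

import numpy as np
import pandas as pd
import pytest

from dreamers import InvalidArgumentError, generate_axis
from dreamers.downstream import (
    BandDefinition,
    PeakRatio,
    UmapGrid,
    band_metrics,
    integrate_band,
    nmi,
    pearson_correlate,
    standard_scale,
    umap_grid_search,
    umap_kmeans,
)


class TestStandardScale:
    def test_two_point_column(self):
        out = standard_scale(np.array([[1.0], [3.0]]))
        np.testing.assert_allclose(out.ravel(), [-1.0, 1.0])

    def test_constant_column_maps_to_zero(self):
        out = standard_scale(np.array([[2.0, 1.0], [2.0, 3.0]]))
        np.testing.assert_allclose(out[:, 0], 0.0)

    def test_moments(self, rng):
        out = standard_scale(rng.normal(3, 7, size=(100, 5)))
        np.testing.assert_allclose(out.mean(axis=0), 0.0, atol=1e-9)
        np.testing.assert_allclose(out.std(axis=0), 1.0, atol=1e-9)

    def test_single_row_rejected(self):
        with pytest.raises(InvalidArgumentError):
            standard_scale(np.ones((1, 3)))


def brute_force_nmi(u, v):
    """Plug-in NMI from explicit probability loops (independent oracle)."""
    import math

    n = len(u)
    uu, vv = sorted(set(u)), sorted(set(v))
    mi = 0.0
    for a in uu:
        for b in vv:
            nij = sum(1 for x, y in zip(u, v) if x == a and y == b)
            if nij == 0:
                continue
            pij = nij / n
            pi = sum(1 for x in u if x == a) / n
            pj = sum(1 for y in v if y == b) / n
            mi += pij * math.log(pij / (pi * pj))
    hu = -sum(
        (sum(1 for x in u if x == a) / n) * math.log(sum(1 for x in u if x == a) / n)
        for a in uu
    )
    hv = -sum(
        (sum(1 for y in v if y == b) / n) * math.log(sum(1 for y in v if y == b) / n)
        for b in vv
    )
    if hu == 0.0 or hv == 0.0:
        return 1.0 if (hu == 0.0 and hv == 0.0) else 0.0
    return mi / math.sqrt(hu * hv)


class TestNmi:
    def test_identical_partitions(self):
        assert nmi([0, 0, 1, 1, 2], [5, 5, 3, 3, 9]) == pytest.approx(1.0)

    def test_independent_partitions(self):
        assert nmi([0, 0, 1, 1], [0, 1, 0, 1]) == pytest.approx(0.0, abs=1e-15)

    def test_matches_brute_force_and_sklearn(self, rng):
        from sklearn.metrics import normalized_mutual_info_score

        for _ in range(30):
            u = rng.integers(0, 4, size=30)
            v = rng.integers(0, 3, size=30)
            got = nmi(u, v)
            assert got == pytest.approx(brute_force_nmi(list(u), list(v)), abs=1e-12)
            assert got == pytest.approx(
                normalized_mutual_info_score(u, v, average_method="geometric"), abs=1e-9
            )

    def test_symmetry_relabelling_bounds(self, rng):
        u = rng.integers(0, 3, size=40)
        v = rng.integers(0, 5, size=40)
        assert nmi(u, v) == pytest.approx(nmi(v, u), abs=1e-12)
        relabel = (u + 1) % 3
        assert nmi(relabel, v) == pytest.approx(nmi(u, v), abs=1e-12)
        assert 0.0 <= nmi(u, v) <= 1.0

    def test_degenerate_entropy_convention(self):
        assert nmi([1, 1, 1], [2, 2, 2]) == 1.0
        assert nmi([1, 1, 1], [0, 1, 2]) == 0.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(InvalidArgumentError):
            nmi([0, 1], [0, 1, 2])


class TestUmapKmeans:
    def test_separated_blobs_recovered(self, rng):
        centers = rng.normal(scale=20, size=(4, 10))
        X = np.concatenate([c + rng.normal(size=(50, 10)) for c in centers])
        labels_true = np.repeat(np.arange(4), 50)
        _, labels = umap_kmeans(X, n_neighbors=15, min_dist=0.1, k=4, random_state=0)
        assert nmi(labels_true, labels) >= 0.95

    def test_deterministic(self, rng):
        X = rng.normal(size=(60, 8))
        _, l1 = umap_kmeans(X, n_neighbors=10, min_dist=0.2, k=3, random_state=7)
        _, l2 = umap_kmeans(X, n_neighbors=10, min_dist=0.2, k=3, random_state=7)
        np.testing.assert_array_equal(l1, l2)

    def test_too_few_samples_rejected(self, rng):
        with pytest.raises(InvalidArgumentError):
            umap_kmeans(rng.normal(size=(5, 4)), n_neighbors=10, min_dist=0.1)


@pytest.fixture(scope="module")
def blobs():
    rng = np.random.default_rng(3)
    centers = rng.normal(scale=15, size=(3, 8))
    X = np.concatenate([c + rng.normal(size=(40, 8)) for c in centers])
    return X, np.repeat(np.arange(3), 40)


class TestUmapGridSearch:
    def test_product_rule_and_argmax_contract(self, blobs):
        X, y = blobs
        grid = UmapGrid(
            n_neighbors=(5, 10), min_dist=(0.1,), metrics=("euclidean",), k=3
        )
        params, best, results = umap_grid_search(X, y, grid)
        assert len(results) == 2 * 1 * 1
        assert best == results["nmi"].max()
        assert best >= results["nmi"].min()
        assert params["n_neighbors"] in (5, 10)

    def test_single_cell_grid(self, blobs):
        X, y = blobs
        grid = UmapGrid(n_neighbors=(10,), min_dist=(0.25,), metrics=("cosine",), k=3)
        params, _, results = umap_grid_search(X, y, grid)
        assert len(results) == 1
        assert params == {"n_neighbors": 10, "min_dist": 0.25, "metric": "cosine"}


class TestIntegrateBand:
    def test_constant_over_amide_i_window(self, axis):
        area = integrate_band(np.ones(len(axis)), BandDefinition("amide_i", 1600, 1700), axis)
        assert area == pytest.approx(100.0)

    def test_zero_spectrum(self, axis):
        assert integrate_band(np.zeros(len(axis)), BandDefinition("b", 1600, 1700), axis) == 0.0

    def test_narrow_gaussian_analytic(self, axis):
        amp, sigma, c = 0.8, 12.0, 1300.0
        y = amp * np.exp(-0.5 * ((axis.values - c) / sigma) ** 2)
        area = integrate_band(y, BandDefinition("g", 1200, 1400), axis)
        assert area == pytest.approx(amp * sigma * np.sqrt(2 * np.pi), rel=1e-3)

    def test_linearity_and_adjacent_additivity(self, axis, rng):
        y1, y2 = rng.random(len(axis)), rng.random(len(axis))
        b = BandDefinition("b", 1200, 1400)
        assert integrate_band(2 * y1 + y2, b, axis) == pytest.approx(
            2 * integrate_band(y1, b, axis) + integrate_band(y2, b, axis)
        )
        left = BandDefinition("l", 1200, 1300)
        right = BandDefinition("r", 1300, 1400)
        assert integrate_band(y1, left, axis) + integrate_band(y1, right, axis) == pytest.approx(
            integrate_band(y1, b, axis)
        )

    def test_band_outside_span_rejected(self, axis):
        with pytest.raises(InvalidArgumentError):
            integrate_band(np.zeros(len(axis)), BandDefinition("x", 200, 400), axis)


class TestBandMetrics:
    def test_peak_ratio_division(self, axis):
        y = np.zeros(len(axis))
        y[axis.nearest_channel(1658)] = 0.4
        y[axis.nearest_channel(1544)] = 0.2
        table = band_metrics({"img": y}, axis, bands=(), ratios=(PeakRatio("r", 1658, 1544),))
        assert table.loc["img", "r"] == pytest.approx(2.0)
        assert not table.loc["img", "r_missing"]

    def test_zero_denominator_flagged(self, axis):
        y = np.zeros(len(axis))
        y[axis.nearest_channel(1658)] = 0.4
        table = band_metrics({"img": y}, axis, bands=(), ratios=(PeakRatio("r", 1658, 1544),))
        assert np.isnan(table.loc["img", "r"])
        assert bool(table.loc["img", "r_missing"])

    def test_noiseless_phantom_recovers_planted_ratio(self, axis):
        # two planted Gaussian bands; the peak ratio equals the amplitude ratio
        a1, a2 = 0.6, 0.3
        y = a1 * np.exp(-0.5 * ((axis.values - 1656) / 25) ** 2)
        y += a2 * np.exp(-0.5 * ((axis.values - 1544) / 20) ** 2)
        table = band_metrics(
            {"img": y}, axis, bands=(), ratios=(PeakRatio("r", 1656, 1544),)
        )
        expected = (a1 + a2 * np.exp(-0.5 * ((1656 - 1544) / 20) ** 2)) / (
            a2 + a1 * np.exp(-0.5 * ((1544 - 1656) / 25) ** 2)
        )
        assert table.loc["img", "r"] == pytest.approx(expected, rel=1e-3)


class TestPearsonCorrelate:
    def _tables(self, metric):
        metrics = pd.DataFrame({"m": metric}, index=[f"i{j}" for j in range(len(metric))])
        proteins = pd.DataFrame(
            {
                "class": 0,
                "bim": np.arange(len(metric), dtype=float),
            },
            index=metrics.index,
        )
        return metrics, proteins

    def test_perfect_linear_relations(self):
        x = np.arange(6, dtype=float)
        m, p = self._tables(2 * x + 1)
        r = pearson_correlate(m, p)[0]
        assert r[("r", "bim")].iloc[0] == pytest.approx(1.0)
        m, p = self._tables(-x)
        r = pearson_correlate(m, p)[0]
        assert r[("r", "bim")].iloc[0] == pytest.approx(-1.0)

    def test_affine_invariance(self, rng):
        x = rng.normal(size=30)
        noise = rng.normal(size=30)
        y = x + 0.5 * noise
        m1, p1 = self._tables(y)
        p1["bim"] = x
        base = pearson_correlate(m1, p1)[0][("r", "bim")].iloc[0]
        m2 = m1 * 7.0 + 3.0
        scaled = pearson_correlate(m2, p1)[0][("r", "bim")].iloc[0]
        assert scaled == pytest.approx(base, abs=1e-12)

    def test_too_few_pairs_missing(self):
        m, p = self._tables(np.array([1.0, np.nan, np.nan, np.nan, 2.0]))
        r = pearson_correlate(m, p)[0]
        assert np.isnan(r[("r", "bim")].iloc[0])
        assert r[("n", "bim")].iloc[0] == 2
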