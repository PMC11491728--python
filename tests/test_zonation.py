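"""Correlation matrices, PC1 stress index, orientation and quantile zones."""

import numpy as np
import pytest
from scipy import stats

import stresszones as sz
from stresszones.climatology import CountRaster, CountStack, get_variable, sweep_thresholds
from stresszones.errors import DegenerateInputError
from stresszones.grids import GridSpec
from stresszones.zonation import (
    StressIndexRaster,
    classify_quantiles,
    correlation_matrix,
    orient_stress,
    pca_first_component,
)

from conftest import make_stack


def counts_from_layers(layers, thresholds=None, variable="tmin", n_days=None):
    """Wrap explicit integer layers as a CountStack for testing."""
    layers = np.asarray(layers)
    n_t, rows, cols = layers.shape
    if thresholds is None:
        thresholds = list(range(n_t))
    if n_days is None:
        n_days = int(layers.max()) + 1
    grid = GridSpec.from_extent((0, 0, float(cols), float(rows)), (rows, cols))
    mask = np.ones((rows, cols), dtype=bool)
    var = get_variable(variable)
    rasters = [
        CountRaster(variable=var, threshold=float(t), grid=grid,
                    counts=layers[i].astype(np.int16), mask=mask, n_days=n_days)
        for i, t in enumerate(thresholds)
    ]
    return CountStack(variable=var, thresholds=[float(t) for t in thresholds], rasters=rasters)


# --- correlation ------------------------------------------------------------

def test_layer_with_itself_and_with_negation():
    base = np.arange(9).reshape(1, 3, 3)
    cm = correlation_matrix(counts_from_layers(np.vstack([base, base]), n_days=10))
    assert cm.r[0, 1] == pytest.approx(1.0)
    flipped = base.max() - base  # pixelwise reversal -> perfect anticorrelation
    cm2 = correlation_matrix(counts_from_layers(np.vstack([base, flipped]), n_days=10))
    assert cm2.r[0, 1] == pytest.approx(-1.0)


def test_correlation_matches_direct_formula_on_listed_values():
    a = np.array([[1, 4, 2], [0, 3, 5], [2, 2, 1]], dtype=float)
    b = np.array([[2, 3, 1], [1, 5, 4], [0, 2, 2]], dtype=float)
    cm = correlation_matrix(counts_from_layers(np.stack([a, b]), n_days=6))
    x, y = a.ravel(), b.ravel()
    cov = ((x - x.mean()) * (y - y.mean())).sum() / (len(x) - 1)
    want = cov / (x.std(ddof=1) * y.std(ddof=1))
    assert cm.r[0, 1] == pytest.approx(want)
    assert np.allclose(cm.r, cm.r.T) and np.allclose(np.diag(cm.r), 1.0)


def test_zero_variance_layer_excluded_with_warning():
    varying = np.arange(9).reshape(3, 3)
    flat = np.full((3, 3), 4)
    stack = counts_from_layers(np.stack([varying, flat]), n_days=10)
    with pytest.warns(UserWarning, match="zero-variance"):
        cm = correlation_matrix(stack)
    assert cm.labels == [("tmin", 0.0)]
    assert cm.excluded == [("tmin", 1.0)]


def test_correlation_decay_with_threshold_distance(tmin_counts):
    """Neighbouring thresholds correlate more strongly than distant ones."""
    cm = correlation_matrix(tmin_counts)
    t = np.array([t for _, t in cm.labels])
    dist = np.abs(t[:, None] - t[None, :])
    pairs = np.triu_indices(len(t), k=1)
    mean_r_by_d = {}
    for d, r in zip(dist[pairs], cm.r[pairs]):
        mean_r_by_d.setdefault(d, []).append(r)
    ds = sorted(mean_r_by_d)
    means = [np.mean(mean_r_by_d[d]) for d in ds]
    rho = stats.spearmanr([-d for d in ds], means).statistic
    assert rho >= 0.8


# --- PCA --------------------------------------------------------------------

def test_rank_one_stack_explains_all_variance():
    base = np.arange(12).reshape(3, 4)
    stack = counts_from_layers(np.stack([base, 2 * base]), n_days=30)
    index = pca_first_component(stack)
    assert index.explained_variance_fraction == pytest.approx(1.0)


def test_pc1_matches_eigendecomposition_oracle():
    rng = np.random.default_rng(5)
    layers = rng.integers(0, 20, size=(4, 4, 5))
    stack = counts_from_layers(layers, n_days=20)
    index = pca_first_component(stack)

    X = layers.reshape(4, -1).T.astype(float)
    Z = (X - X.mean(0)) / X.std(0, ddof=1)
    evals, evecs = np.linalg.eigh(np.cov(Z, rowvar=False))
    want = Z @ evecs[:, -1]
    got = index.pc1.ravel()
    agree = np.allclose(got, want, atol=1e-8) or np.allclose(got, -want, atol=1e-8)
    assert agree
    assert index.explained_variance_fraction == pytest.approx(evals[-1] / evals.sum())


def test_pca_is_deterministic(tmin_counts):
    a = pca_first_component(tmin_counts)
    b = pca_first_component(tmin_counts)
    assert np.array_equal(a.pc1, b.pc1, equal_nan=True)


def test_all_constant_stack_is_degenerate():
    stack = counts_from_layers(np.full((3, 3, 3), 7), n_days=10)
    with pytest.raises(DegenerateInputError):
        pca_first_component(stack)


# --- orientation ------------------------------------------------------------

def _oriented_pair(tmin_counts):
    index = pca_first_component(tmin_counts)
    return index, orient_stress(index, tmin_counts)


def test_orientation_makes_stress_high_where_suitable_days_scarce(tmin_counts):
    _, oriented = _oriented_pair(tmin_counts)
    mean_counts = tmin_counts.to_array().mean(axis=0)[oriented.mask]
    r = np.corrcoef(oriented.pc1[oriented.mask], mean_counts)[0, 1]
    assert r < 0
    assert oriented.oriented


def test_orientation_is_idempotent_and_flips_positive_case(tmin_counts):
    index, oriented = _oriented_pair(tmin_counts)
    again = orient_stress(oriented, tmin_counts)
    assert np.array_equal(again.pc1, oriented.pc1, equal_nan=True)
    flipped = StressIndexRaster(
        variable=index.variable, grid=index.grid, pc1=-oriented.pc1,
        mask=index.mask, explained_variance_fraction=index.explained_variance_fraction,
    )
    assert np.array_equal(
        orient_stress(flipped, tmin_counts).pc1, oriented.pc1, equal_nan=True
    )


def test_zones_invariant_to_pca_sign(tmin_counts):
    """The eigen-solver's arbitrary PC1 sign never changes the zone raster."""
    index, _ = _oriented_pair(tmin_counts)
    neg = StressIndexRaster(
        variable=index.variable, grid=index.grid, pc1=-index.pc1,
        mask=index.mask, explained_variance_fraction=index.explained_variance_fraction,
    )
    za = classify_quantiles(orient_stress(index, tmin_counts))
    zb = classify_quantiles(orient_stress(neg, tmin_counts))
    assert np.array_equal(za.classes, zb.classes)


# --- quantile classification ------------------------------------------------

def index_from_values(values, mask=None):
    values = np.asarray(values, dtype=float)
    grid = GridSpec.from_extent((0, 0, values.shape[1], values.shape[0]), values.shape)
    if mask is None:
        mask = np.ones(values.shape, dtype=bool)
    return StressIndexRaster(
        variable="tmin", grid=grid, pc1=values, mask=mask,
        explained_variance_fraction=1.0, oriented=True,
    )


def test_five_classes_of_twenty_pixels_each():
    idx = index_from_values(np.arange(1, 101, dtype=float).reshape(10, 10))
    zones = classify_quantiles(idx, k=5)
    counts = zones.zone_counts()
    assert counts == {z: 20 for z in range(1, 6)}
    assert zones.classes[idx.pc1 == 100] == 5
    assert zones.classes[idx.pc1 == 1] == 1


def test_median_split_on_four_values():
    idx = index_from_values(np.array([[1.0, 2.0], [3.0, 4.0]]))
    zones = classify_quantiles(idx, k=2)
    assert zones.classes.tolist() == [[1, 1], [2, 2]]


def test_constant_index_is_degenerate():
    idx = index_from_values(np.full((3, 3), 2.5))
    with pytest.raises(DegenerateInputError):
        classify_quantiles(idx, k=5)


def test_equal_area_within_one_pixel_without_ties():
    rng = np.random.default_rng(23)
    for n, k in ((101, 5), (97, 4), (64, 3)):
        rows = 1
        vals = rng.permutation(np.linspace(0, 1, n)).reshape(rows, n)
        zones = classify_quantiles(index_from_values(vals), k=k)
        counts = list(zones.zone_counts().values())
        assert len(counts) == k
        assert all(n // k <= c <= -(-n // k) for c in counts)


def test_class_one_has_more_suitable_days_than_class_five(tmin_counts, tmin_zones):
    mean_counts = tmin_counts.to_array().mean(axis=0)
    m1 = mean_counts[tmin_zones.classes == 1].mean()
    m5 = mean_counts[tmin_zones.classes == 5].mean()
    assert m1 > m5
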