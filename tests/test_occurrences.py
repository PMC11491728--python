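"""Occurrence cleaning, spatial thinning and zone annotation."""

import numpy as np
import pandas as pd
import pytest

import stresszones as sz
from stresszones.errors import GeoreferenceError, SchemaError
from stresszones.occurrences import (
    annotate_zones,
    clean_occurrences,
    haversine_km,
    thin_occurrences,
)


def occ_table(points, species="Quercus testensis"):
    return pd.DataFrame(
        [{"species": species, "longitude": x, "latitude": y} for x, y in points]
    )


def test_exact_duplicates_keep_first():
    table = occ_table([(-95.0, 35.0), (-95.0, 35.0), (-94.0, 35.5)])
    out = clean_occurrences(table, drop_outliers=False)
    assert out["status"].tolist() == ["kept", "dropped_duplicate", "kept"]


def test_missing_and_zero_coordinates_are_flagged():
    table = occ_table([(np.nan, 35.0), (0.0, 0.0), (-94.0, 35.5)])
    out = clean_occurrences(table, drop_outliers=False)
    assert out["status"].tolist() == ["dropped_missing", "dropped_zero", "kept"]


def test_points_outside_extent_are_flagged():
    table = occ_table([(-95.0, 35.0), (-80.0, 35.0)])
    out = clean_occurrences(table, extent=(-100, 30, -90, 40), drop_outliers=False)
    assert out["status"].tolist() == ["kept", "dropped_outside"]


def test_darwin_core_aliases_accepted():
    table = pd.DataFrame(
        {"scientificName": ["A"], "decimalLongitude": [-95.0], "decimalLatitude": [35.0]}
    )
    out = clean_occurrences(table)
    assert out.loc[0, "status"] == "kept"
    assert {"species", "longitude", "latitude"} <= set(out.columns)


def test_missing_columns_raise_schema_error():
    with pytest.raises(SchemaError):
        clean_occurrences(pd.DataFrame({"species": ["A"], "longitude": [1.0]}))


def reference_outlier_rule(lon, lat, multiplier=1.5):
    """Independent restatement of the centroid-IQR rule, iterated."""
    keep = np.ones(len(lon), dtype=bool)
    while True:
        d = haversine_km(lon[keep], lat[keep], lon[keep].mean(), lat[keep].mean())
        q1, q3 = np.quantile(d, [0.25, 0.75])
        out = d > q3 + multiplier * (q3 - q1)
        if not out.any():
            return keep
        idx = np.flatnonzero(keep)
        keep[idx[out]] = False


def test_far_point_dropped_as_cloud_outlier():
    rng = np.random.default_rng(2)
    lon = -95.0 + rng.normal(0, 0.05, 100)
    lat = 35.0 + rng.normal(0, 0.05, 100)
    lon = np.append(lon, -95.0 + 5.0)  # ~10x the cluster scale away
    lat = np.append(lat, 35.0)
    out = clean_occurrences(occ_table(zip(lon, lat)))
    assert out["status"].iloc[-1] == "dropped_outlier"
    want_keep = reference_outlier_rule(lon, lat)
    assert np.array_equal(out["status"] == "kept", want_keep)


def test_cleaning_conserves_records_and_is_idempotent():
    rng = np.random.default_rng(4)
    pts = [(float(x), float(y)) for x, y in rng.normal([-95, 35], 0.5, (60, 2))]
    pts += [(0.0, 0.0), (np.nan, 1.0), pts[0], (-80.0, 35.0)]
    table = occ_table(pts)
    once = clean_occurrences(table, extent=(-100, 30, -90, 40))
    assert len(once) == len(table)
    assert set(once["status"]) <= set(sz.occurrences.STATUS_VALUES)
    twice = clean_occurrences(once, extent=(-100, 30, -90, 40))
    pd.testing.assert_series_equal(once["status"], twice["status"])


# --- thinning ---------------------------------------------------------------

def test_two_close_points_thin_to_one():
    table = clean_occurrences(occ_table([(-95.0, 35.0), (-95.0, 35.045)]), drop_outliers=False)
    out = thin_occurrences(table, 20.0, seed=0)
    assert sorted(out["status"]) == ["dropped_thinned", "kept"]


def test_distant_points_all_survive_thinning():
    table = clean_occurrences(occ_table([(-95, 35), (-94, 35), (-93, 35)]), drop_outliers=False)
    out = thin_occurrences(table, 20.0, seed=0)
    assert (out["status"] == "kept").all()


@pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
def test_no_kept_pair_within_thinning_distance(seed):
    rng = np.random.default_rng(100 + seed)
    pts = rng.normal([-95, 35], 0.3, (80, 2))
    table = clean_occurrences(occ_table([tuple(p) for p in pts]), drop_outliers=False)
    out = thin_occurrences(table, 15.0, seed=seed)
    kept = out[out["status"] == "kept"]
    lon = kept["longitude"].to_numpy()
    lat = kept["latitude"].to_numpy()
    for i in range(len(kept)):
        d = haversine_km(lon, lat, lon[i], lat[i])
        d[i] = np.inf
        assert d.min() >= 15.0
    # and every dropped record is within distance of some kept one
    dropped = out[out["status"] == "dropped_thinned"]
    for _, r in dropped.iterrows():
        d = haversine_km(lon, lat, r["longitude"], r["latitude"])
        assert d.min() < 15.0


def test_haversine_agrees_with_sklearn():
    from sklearn.metrics.pairwise import haversine_distances

    pts = np.radians([[35.0, -95.0], [36.2, -93.4]])
    want = haversine_distances(pts)[0, 1] * 6371.0088
    got = haversine_km(-95.0, 35.0, -93.4, 36.2)
    assert got == pytest.approx(want, rel=1e-9)


# --- zone annotation --------------------------------------------------------

def test_point_at_pixel_center_gets_that_label(tmin_zones):
    g = tmin_zones.grid
    r, c = 3, 4
    lon = g.x_min + (c + 0.5) * g.dx
    lat = g.y_max - (r + 0.5) * g.dy
    table = clean_occurrences(occ_table([(lon, lat)]), drop_outliers=False)
    out = annotate_zones(table, {"tmin": tmin_zones})
    assert out.loc[0, "zone_tmin"] == tmin_zones.classes[r, c]


def test_nodata_pixel_yields_missing_label(tmin_zones):
    import copy

    zr = copy.deepcopy(tmin_zones)
    zr.mask[0, 0] = False
    g = zr.grid
    lon, lat = g.x_min + 0.5 * g.dx, g.y_max - 0.5 * g.dy
    table = clean_occurrences(occ_table([(lon, lat)]), drop_outliers=False)
    out = annotate_zones(table, {"tmin": zr})
    assert np.isnan(out.loc[0, "zone_tmin"])


def test_batch_annotation_matches_pointwise_lookup(tmin_zones):
    occ = sz.generate_occurrences(tmin_zones, sz.OccurrenceSimConfig(n_points=200, seed=8))
    table = clean_occurrences(occ, drop_outliers=False)
    out = annotate_zones(table, {"tmin": tmin_zones})
    g = tmin_zones.grid
    for _, rec in out.iterrows():
        row = int(np.floor((g.y_max - rec["latitude"]) / g.dy))
        col = int(np.floor((rec["longitude"] - g.x_min) / g.dx))
        assert rec["zone_tmin"] == tmin_zones.classes[row, col]


def test_crs_mismatch_rejected(tmin_zones):
    import dataclasses
    import copy

    other = copy.deepcopy(tmin_zones)
    other.grid = dataclasses.replace(other.grid, crs="EPSG:5070")
    table = clean_occurrences(occ_table([(-95.0, 35.0)]), drop_outliers=False)
    with pytest.raises(GeoreferenceError):
        annotate_zones(table, {"tmin": tmin_zones, "tmax": other})
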