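"""Chi-square zone-preference tests against area-proportional expectations.

For one species and one climate dimension, observed occurrence counts
per stress zone are compared with the counts expected if occurrences
fell proportionally to zone area (optionally restricted to the species'
accessible area M).  An overall Pearson chi-square (df = zones - 1)
tests departure from the null; each zone also gets a 1-df zone-vs-rest
chi-square, and a zone is labelled *preferred* iff that test is
significant and observed exceeds expected.  Zones with no significant
difference, or a significant deficit, are *not preferred*.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InfeasibleConfigurationError, NoDataError

__all__ = [
    "ZonePreferenceResult",
    "zone_area_proportions",
    "chi_square_preference",
    "summarize_species",
    "concentration_shares",
]


@dataclass
class ZonePreferenceResult:
    """Observed vs expected zone occupancy and per-zone preference labels."""

    species: str
    variable: str
    zones: list[int]
    observed: np.ndarray
    expected: np.ndarray
    overall_chi2: float
    overall_df: int
    overall_p: float
    per_zone_chi2: np.ndarray
    per_zone_p: np.ndarray
    labels: list[str]  # "preferred" / "not_preferred" per zone
    n: int
    alpha: float
    correction: str
    domain: str = "full_extent"

    @property
    def preferred_zones(self) -> list[int]:
        return [z for z, lab in zip(self.zones, self.labels) if lab == "preferred"]

    @property
    def concentrated_zone(self):
        """Preferred zone with the largest observed/expected ratio, or None."""
        best, best_ratio = None, -np.inf
        for z, lab, o, e in zip(self.zones, self.labels, self.observed, self.expected):
            if lab != "preferred":
                continue
            ratio = np.inf if e == 0 else o / e
            if ratio > best_ratio:
                best, best_ratio = z, ratio
        return best

    def to_row(self) -> dict:
        row = {
            "species": self.species,
            "variable": self.variable,
            "n": self.n,
            "domain": self.domain,
            "overall_chi2": self.overall_chi2,
            "overall_df": self.overall_df,
            "overall_p": self.overall_p,
            "concentrated_zone": self.concentrated_zone,
        }
        for z, o, e, p, lab in zip(self.zones, self.observed, self.expected, self.per_zone_p, self.labels):
            row[f"obs_{z}"] = int(o)
            row[f"exp_{z}"] = float(e)
            row[f"p_{z}"] = float(p)
            row[f"label_{z}"] = lab
        return row


def zone_area_proportions(zones, domain=None) -> dict[int, float]:
    """Area (valid-pixel) share of each stress zone, optionally within M.

    ``domain`` is a shapely geometry in the raster's CRS; a pixel counts
    toward the domain iff its center falls inside.  Proportions sum to 1.
    """
    mask = zones.mask.copy()
    if domain is not None:
        import shapely

        lon, lat = zones.grid.cell_centers()
        inside = shapely.contains_xy(domain, lon.ravel(), lat.ravel()).reshape(mask.shape)
        mask &= inside
        if not mask.any():
            raise InfeasibleConfigurationError("accessible area intersects no valid pixel")
    labels = zones.classes[mask]
    total = labels.size
    return {z: int((labels == z).sum()) / total for z in range(1, zones.k + 1)}


def _holm(pvals: np.ndarray) -> np.ndarray:
    from statsmodels.stats.multitest import multipletests

    return multipletests(pvals, method="holm")[1]


def chi_square_preference(
    observed,
    proportions,
    species: str = "",
    variable: str = "",
    alpha: float = 0.05,
    correction: str = "none",
    domain: str = "full_extent",
) -> ZonePreferenceResult:
    """Test observed zone occupancy against area-proportional expectations.

    Parameters
    ----------
    observed
        Mapping zone -> count, or an array over zones 1..k.
    proportions
        Mapping zone -> expected share of occurrences (summing to 1), or
        an aligned array; zones with zero expectation *and* zero
        observation are excluded from the statistic.
    correction
        Multiple-testing correction across per-zone tests: "none"
        (default) or "holm".
    """
    if isinstance(observed, dict):
        zones = sorted(observed)
        obs = np.array([observed[z] for z in zones], dtype=float)
    else:
        obs = np.asarray(observed, dtype=float)
        zones = list(range(1, len(obs) + 1))
    if isinstance(proportions, dict):
        props = np.array([proportions.get(z, 0.0) for z in zones], dtype=float)
    else:
        props = np.asarray(proportions, dtype=float)
    if len(props) != len(obs):
        raise ValueError("observed and proportions must cover the same zones")
    if not np.isclose(props.sum(), 1.0, atol=1e-6):
        raise ValueError("proportions must sum to 1")
    n = obs.sum()
    if n <= 0:
        raise NoDataError("no occurrences to test")

    include = ~((props == 0) & (obs == 0))
    if ((props == 0) & (obs > 0)).any():
        warnings.warn(
            "zone with zero expected area has observed occurrences; statistic is infinite",
            stacklevel=2,
        )
    zones_i = [z for z, inc in zip(zones, include) if inc]
    obs_i = obs[include]
    props_i = props[include]
    exp_i = n * props_i

    with np.errstate(divide="ignore", invalid="ignore"):
        terms = (obs_i - exp_i) ** 2 / exp_i
    terms = np.where((exp_i == 0) & (obs_i > 0), np.inf, terms)
    chi2 = float(terms.sum())
    df = len(zones_i) - 1
    overall_p = float(stats.chi2.sf(chi2, df)) if df > 0 else 1.0

    # per-zone 1-df zone-vs-rest tests
    pz_chi2 = np.empty(len(zones_i))
    for j, (o, e) in enumerate(zip(obs_i, exp_i)):
        if e == 0 or e == n:
            pz_chi2[j] = np.inf if o != e else 0.0
            continue
        pz_chi2[j] = (o - e) ** 2 / e + ((n - o) - (n - e)) ** 2 / (n - e)
    pz_p = stats.chi2.sf(pz_chi2, 1)

    if correction == "holm":
        pz_p_adj = _holm(pz_p)
    elif correction == "none":
        pz_p_adj = pz_p
    else:
        raise ValueError(f"unknown correction policy {correction!r}")

    labels = [
        "preferred" if (p < alpha and o > e) else "not_preferred"
        for p, o, e in zip(pz_p_adj, obs_i, exp_i)
    ]
    return ZonePreferenceResult(
        species=species,
        variable=variable,
        zones=zones_i,
        observed=obs_i.astype(int),
        expected=exp_i,
        overall_chi2=chi2,
        overall_df=df,
        overall_p=overall_p,
        per_zone_chi2=pz_chi2,
        per_zone_p=pz_p_adj,
        labels=labels,
        n=int(n),
        alpha=alpha,
        correction=correction,
        domain=domain,
    )


def counts_by_zone(table: pd.DataFrame, dimension: str, k: int = 5) -> dict[int, int]:
    """Tally kept, annotated records per zone for one climate dimension."""
    col = f"zone_{dimension}"
    kept = table[(table["status"] == "kept") & table[col].notna()]
    counts = kept[col].astype(int).value_counts()
    return {z: int(counts.get(z, 0)) for z in range(1, k + 1)}


def summarize_species(results) -> pd.DataFrame:
    """One row per species x climate dimension, mmc2-style.

    Each row carries n, per-zone observed/expected/p/label columns and
    the *concentrated* zone: the preferred zone with the largest
    observed/expected ratio (missing if no zone is preferred).
    """
    results = list(results)
    if not results:
        raise NoDataError("no preference results to summarize")
    return pd.DataFrame([r.to_row() for r in results])


def concentration_shares(summary: pd.DataFrame, variable: str, k: int = 5) -> dict[int, float]:
    """Share of species whose concentrated zone is z, for one dimension.

    Species with no preferred zone are excluded from the denominator of
    no zone; shares are over all species tested for that dimension.
    """
    sub = summary[summary["variable"] == variable]
    if len(sub) == 0:
        raise NoDataError(f"no results for variable {variable!r}")
    return {
        z: float((sub["concentrated_zone"] == z).mean()) for z in range(1, k + 1)
    }
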