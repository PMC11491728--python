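"""Threshold-correlation matrices, PC1 stress indices and equal-area zones.

Counts of suitable days at neighbouring thresholds are strongly
correlated and decay smoothly with threshold distance, so no single
threshold is privileged.  Each climate dimension's threshold sweep is
therefore reduced to its first principal component (columns standardized
over valid pixels), oriented so that higher scores mean *fewer* suitable
days (more stress), and cut into five equal-area classes at the 1/5 ...
4/5 empirical quantiles, class 1 = least stress, class 5 = most stress.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .climatology import CountStack
from .errors import DegenerateInputError, UnresolvedOrientationError
from .grids import GridSpec, Raster

__all__ = [
    "CorrelationMatrix",
    "StressIndexRaster",
    "StressZoneRaster",
    "correlation_matrix",
    "pca_first_component",
    "orient_stress",
    "classify_quantiles",
]

log = logging.getLogger(__name__)


@dataclass
class CorrelationMatrix:
    """Pearson correlations among (variable, threshold) count layers."""

    labels: list[tuple[str, float]]
    r: np.ndarray
    excluded: list[tuple[str, float]] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        names = [f"{v}@{t:g}" for v, t in self.labels]
        return pd.DataFrame(self.r, index=names, columns=names)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path)

    def plot_heatmap(self, path=None):
        """Optional Fig-style circle-free heatmap of the matrix."""
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(6, 5))
        im = ax.imshow(self.r, vmin=-1, vmax=1, cmap="RdBu_r")
        names = [f"{v}@{t:g}" for v, t in self.labels]
        ax.set_xticks(range(len(names)), names, rotation=90, fontsize=5)
        ax.set_yticks(range(len(names)), names, fontsize=5)
        fig.colorbar(im, ax=ax, label="Pearson r")
        fig.tight_layout()
        if path is not None:
            fig.savefig(path, dpi=150)
            plt.close(fig)
        return fig


@dataclass
class StressIndexRaster:
    """Continuous PC1 stress score per valid pixel."""

    variable: str
    grid: GridSpec
    pc1: np.ndarray          # float, NaN where invalid
    mask: np.ndarray
    explained_variance_fraction: float
    oriented: bool = False   # True once the more-stress = higher-score sign is fixed

    def as_raster(self) -> Raster:
        return Raster(grid=self.grid, values=self.pc1, mask=self.mask)


@dataclass
class StressZoneRaster:
    """Five-class (generally k-class) equal-area categorization of PC1."""

    variable: str
    grid: GridSpec
    classes: np.ndarray      # int8; 0 where invalid
    mask: np.ndarray
    class_breaks: np.ndarray  # k-1 interior quantile cut points
    k: int = 5

    def zone_counts(self) -> dict[int, int]:
        vals, counts = np.unique(self.classes[self.mask], return_counts=True)
        return {int(v): int(c) for v, c in zip(vals, counts)}

    def as_raster(self) -> Raster:
        return Raster(grid=self.grid, values=self.classes, mask=self.mask)


def _stack_columns(stack: CountStack) -> tuple[np.ndarray, np.ndarray]:
    """Valid-pixel matrix (n_valid, n_thresholds) and the valid mask."""
    mask = stack.mask
    cols = np.stack([r.counts[mask].astype(float) for r in stack.rasters], axis=1)
    return cols, mask


def correlation_matrix(stacks) -> CorrelationMatrix:
    """Pairwise Pearson r over valid pixels across all supplied layers.

    Accepts one CountStack or a sequence of them; all must share grid
    and mask.  Zero-variance layers are excluded with a warning and
    recorded in the result's ``excluded`` metadata.
    """
    if isinstance(stacks, CountStack):
        stacks = [stacks]
    stacks = list(stacks)
    if not stacks:
        raise DegenerateInputError("no count stacks supplied")
    g0, m0 = stacks[0].grid, stacks[0].mask
    columns, labels = [], []
    for s in stacks:
        if not s.grid.same_grid(g0) or not np.array_equal(s.mask, m0):
            raise DegenerateInputError("count stacks must share grid and mask")
        data, _ = _stack_columns(s)
        for j, t in enumerate(s.thresholds):
            columns.append(data[:, j])
            labels.append((s.variable.name, float(t)))
    X = np.stack(columns, axis=1)
    sd = X.std(axis=0)
    keep = sd > 0
    excluded = [lab for lab, k in zip(labels, keep) if not k]
    if excluded:
        warnings.warn(
            f"excluding {len(excluded)} zero-variance layer(s) from the correlation matrix",
            stacklevel=2,
        )
    labels = [lab for lab, k in zip(labels, keep) if k]
    if not labels:
        raise DegenerateInputError("all layers have zero variance")
    r = np.corrcoef(X[:, keep], rowvar=False)
    r = np.atleast_2d(r)
    return CorrelationMatrix(labels=labels, r=r, excluded=excluded)


def pca_first_component(stack: CountStack) -> StressIndexRaster:
    """First principal component of the standardized threshold sweep.

    Rows are valid pixels, columns are thresholds; each column is scaled
    to zero mean and unit variance over valid pixels before the
    decomposition (zero-variance columns are dropped with a warning), so
    the PCA operates on the correlation structure of the sweep.  The
    sign of the returned scores is the solver's; apply
    :func:`orient_stress` before classification.
    """
    if len(stack.thresholds) < 2:
        raise DegenerateInputError("need at least 2 thresholds for a PCA")
    X, mask = _stack_columns(stack)
    if X.shape[0] < 3:
        raise DegenerateInputError("need at least 3 valid pixels for a PCA")
    sd = X.std(axis=0, ddof=1)
    keep = sd > 0
    if not keep.any():
        raise DegenerateInputError("all threshold layers are constant; no variation to summarize")
    if not keep.all():
        warnings.warn(
            f"dropping {(~keep).sum()} zero-variance threshold layer(s) before PCA",
            stacklevel=2,
        )
        X, sd = X[:, keep], sd[keep]
    Z = (X - X.mean(axis=0)) / sd
    pca = PCA(n_components=1, svd_solver="full")
    scores = pca.fit_transform(Z)[:, 0]
    pc1 = np.full(stack.grid.shape, np.nan)
    pc1[mask] = scores
    return StressIndexRaster(
        variable=stack.variable.name,
        grid=stack.grid,
        pc1=pc1,
        mask=mask,
        explained_variance_fraction=float(pca.explained_variance_ratio_[0]),
    )


def orient_stress(index: StressIndexRaster, stack: CountStack) -> StressIndexRaster:
    """Fix the PC1 sign so higher scores mean more stress.

    Stress is operationalized as scarcity of suitable days: the oriented
    score correlates *negatively* with the mean suitable-day count
    across thresholds.  Idempotent; raises if the correlation is zero
    (caller must then choose the sign explicitly).
    """
    mean_counts = stack.to_array().astype(float).mean(axis=0)[index.mask]
    scores = index.pc1[index.mask]
    r = np.corrcoef(scores, mean_counts)[0, 1]
    if not np.isfinite(r) or r == 0:
        raise UnresolvedOrientationError(
            "PC1 is uncorrelated with mean suitable-day counts; set the sign explicitly"
        )
    pc1 = -index.pc1 if r > 0 else index.pc1.copy()
    return StressIndexRaster(
        variable=index.variable,
        grid=index.grid,
        pc1=pc1,
        mask=index.mask,
        explained_variance_fraction=index.explained_variance_fraction,
        oriented=True,
    )


def classify_quantiles(index: StressIndexRaster, k: int = 5) -> StressZoneRaster:
    """Cut the stress index into ``k`` equal-area classes.

    Interior breaks are the j/k empirical inverse-CDF (type-1) quantiles
    of PC1 over valid pixels, j = 1..k-1; values tied with a break go to
    the lower class.  Class k holds the highest scores (most stress).
    """
    if k < 2:
        raise DegenerateInputError("need k >= 2 classes")
    scores = index.pc1[index.mask]
    if np.unique(scores).size < k:
        raise DegenerateInputError(
            f"only {np.unique(scores).size} distinct index values; cannot form {k} classes"
        )
    breaks = np.quantile(scores, [j / k for j in range(1, k)], method="inverted_cdf")
    classes = np.zeros(index.grid.shape, dtype=np.int8)
    classes[index.mask] = 1 + np.searchsorted(breaks, scores, side="left").astype(np.int8)
    # a value exactly equal to a break belongs to the lower class
    return StressZoneRaster(
        variable=index.variable,
        grid=index.grid,
        classes=classes,
        mask=index.mask,
        class_breaks=np.asarray(breaks, dtype=float),
        k=k,
    )
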