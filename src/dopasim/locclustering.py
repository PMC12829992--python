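"""Density-based clustering of single-molecule localisation tables.

Super-resolution (dSTORM) imaging yields tables of fitted emitter positions
(x, y in nm).  The percent-clustered statistic runs DBSCAN with a
neighbourhood radius and core-point threshold and reports the percentage of
localisations assigned to any cluster (non-noise).  A parameter scan maps
that statistic over a (radius, min_points) grid and region differences are
assessed with Welch's unequal-variance t-test, with images as the unit of
analysis.

Because the neighbourhood parameter is quoted sometimes as a radius and
sometimes as a diameter in the imaging literature, the API takes an
explicit ``radius_nm`` everywhere.

``synth_localisations`` generates clustered-plus-background point patterns
(isotropic Gaussian clusters over complete spatial randomness) with ground-
truth labels, so the analysis is testable without any microscopy data.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dfield

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.cluster import DBSCAN

from .errors import ParameterError

__all__ = [
    "LocalisationTable",
    "ClusterScanResult",
    "read_localisations",
    "percent_clustered",
    "parameter_scan",
    "region_compare",
    "synth_localisations",
]


@dataclass
class LocalisationTable:
    """Emitter positions (nm) from one image, with an optional label."""

    points: np.ndarray            # (n, 2) x, y in nm
    label: str = ""
    truth: np.ndarray | None = None  # generator ground truth (-1 background)

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 2)
        if len(self.points) < 1:
            raise ParameterError("localisation table needs at least one point")
        if not np.all(np.isfinite(self.points)):
            raise ParameterError("localisation coordinates must be finite")

    @property
    def n(self) -> int:
        return len(self.points)

    def clustered_fraction_truth(self) -> float:
        """Ground-truth clustered percentage (synthetic tables only)."""
        if self.truth is None:
            raise ParameterError("table has no ground-truth labels")
        return 100.0 * float(np.mean(self.truth >= 0))


def read_localisations(path, x_col: str | int = "x", y_col: str | int = "y",
                       label: str = "", sep: str | None = None) -> LocalisationTable:
    """Read a plain-text localisation table (whitespace or comma delimited).

    Column selection is by header name or integer position; coordinates are
    taken to be nm.
    """
    df = pd.read_csv(path, sep=sep, engine="python")
    cols = []
    for c in (x_col, y_col):
        cols.append(df.columns[c] if isinstance(c, int) else c)
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ParameterError(
            f"columns {missing} not found in {list(df.columns)}")
    return LocalisationTable(df[cols].to_numpy(dtype=float), label=label)


def percent_clustered(table: LocalisationTable, radius_nm: float,
                      min_points: int) -> float:
    """Percentage of localisations assigned to any DBSCAN cluster.

    ``radius_nm`` is the neighbourhood (eps) radius and ``min_points`` the
    core-point threshold (neighbourhood count including the point itself).
    """
    if radius_nm <= 0:
        raise ParameterError("radius must be positive")
    if min_points < 2:
        raise ParameterError("min_points must be at least 2")
    labels = DBSCAN(eps=radius_nm, min_samples=min_points).fit_predict(table.points)
    return 100.0 * float(np.mean(labels >= 0))


@dataclass
class ClusterScanResult:
    """Percent-clustered over a (radius, min_points) grid, per region."""

    radii_nm: np.ndarray
    min_points: np.ndarray
    per_region: dict = dfield(default_factory=dict)  # region -> (r, m, image)
    region_means: dict = dfield(default_factory=dict)  # region -> (r, m)
    difference: np.ndarray | None = None             # second minus first

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for region, grid in self.region_means.items():
            for i, r in enumerate(self.radii_nm):
                for j, m in enumerate(self.min_points):
                    rows.append({"region": region, "radius_nm": r,
                                 "min_points": int(m),
                                 "percent_clustered": grid[i, j]})
        return pd.DataFrame(rows)


def parameter_scan(tables_by_region: dict, radii_nm, min_points_grid) -> ClusterScanResult:
    """Scan percent-clustered over radius and min_points for each region.

    ``tables_by_region`` maps region name -> list of tables (images).  With
    exactly two regions the per-cell mean difference (second minus first,
    in iteration order) is also returned.
    """
    radii = np.asarray(radii_nm, dtype=float)
    mins = np.asarray(min_points_grid, dtype=int)
    if not tables_by_region or any(not v for v in tables_by_region.values()):
        raise ParameterError("every region needs at least one table")
    res = ClusterScanResult(radii, mins)
    for region, tables in tables_by_region.items():
        grid = np.zeros((len(radii), len(mins), len(tables)))
        for k, tab in enumerate(tables):
            for i, r in enumerate(radii):
                for j, m in enumerate(mins):
                    grid[i, j, k] = percent_clustered(tab, r, int(m))
        res.per_region[region] = grid
        res.region_means[region] = grid.mean(axis=2)
    names = list(tables_by_region)
    if len(names) == 2:
        res.difference = res.region_means[names[1]] - res.region_means[names[0]]
    return res


def region_compare(values_a, values_b):
    """Welch's unequal-variance two-sample t-test on per-image percentages.

    Returns ``(t, p)`` with a two-sided p-value.  Two identical degenerate
    groups give t = 0, p = 1.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ParameterError("need at least two values per group")
    if a.std() == 0 and b.std() == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return float(np.inf) * np.sign(a.mean() - b.mean()), 0.0
    t, p = sps.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


def synth_localisations(n_clusters: int = 3, cluster_sigma_nm: float = 15.0,
                        points_per_cluster: int = 100,
                        background_per_um2: float = 25.0,
                        field_size_um: float = 2.0, seed=0,
                        label: str = "synthetic") -> LocalisationTable:
    """Synthetic clustered-plus-background localisation pattern.

    ``n_clusters`` isotropic Gaussian clusters (sd ``cluster_sigma_nm``) at
    uniform random centres, over a complete-spatial-randomness background of
    the given intensity.  Ground-truth labels are kept (cluster index, or -1
    for background).
    """
    if min(n_clusters, points_per_cluster) < 0 or cluster_sigma_nm < 0 \
            or background_per_um2 < 0 or field_size_um <= 0:
        raise ParameterError("generator parameters must be non-negative")
    rng = np.random.default_rng(seed)
    size_nm = field_size_um * 1e3
    pts = []
    truth = []
    centres = rng.random((n_clusters, 2)) * size_nm
    for k in range(n_clusters):
        p = centres[k] + rng.normal(0.0, cluster_sigma_nm,
                                    size=(points_per_cluster, 2))
        pts.append(np.mod(p, size_nm))
        truth.append(np.full(points_per_cluster, k))
    n_bg = rng.poisson(background_per_um2 * field_size_um**2)
    pts.append(rng.random((n_bg, 2)) * size_nm)
    truth.append(np.full(n_bg, -1))
    pts = np.concatenate(pts) if pts else np.zeros((0, 2))
    truth = np.concatenate(truth).astype(int)
    if len(pts) == 0:
        raise ParameterError("generator produced no points")
    return LocalisationTable(pts, label=label, truth=truth)
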