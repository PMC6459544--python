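"""Per-embryo spatial pattern statistics.

Everything here operates on a single embryo's cell table (the columns of
:data:`epipattern.synthetic.CELL_COLUMNS`) together with its
:class:`~epipattern.geometry.EmbryoGeometry`.  Statistics that are undefined
for a given embryo (too few progenitors, empty compartments) are reported as
NaN rather than raising, so cohort summaries degrade gracefully; the
lower-level operations raise typed errors where the contract demands it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .errors import EstimationError, IntegrityError, ParameterError
from .geometry import EmbryoGeometry

__all__ = [
    "CompartmentCounts",
    "SpacingStats",
    "ClusterStats",
    "AnalysisConfig",
    "compartment_counts",
    "cell_density",
    "density_display",
    "estimate_mean_diameter",
    "normalized_nearest_spacing",
    "domain_angle",
    "connected_pairs",
    "decompose_clusters",
    "summarize_embryo",
    "summarize_cohort",
    "SUMMARY_STATISTICS",
]


@dataclass(frozen=True)
class CompartmentCounts:
    """Counts of the four (dlc, p63) compartments with their BrdU+ subcounts.

    ``n_p63`` is the total of p63+ cells and always equals
    ``n_kerat + n_iono``; ``n_mislabel`` (dlc+ p63-) sits outside it.
    """

    n_p63: int
    n_kerat: int
    n_iono: int
    n_mislabel: int
    n_p63_brdu: int
    n_kerat_brdu: int
    n_iono_brdu: int
    n_mislabel_brdu: int


@dataclass(frozen=True)
class SpacingStats:
    """Normalized nearest-neighbour spacing of progenitors in the central area."""

    n_used: int
    mean_norm_spacing: float
    values: tuple[float, ...] = field(default=())

    @property
    def defined(self) -> bool:
        return self.n_used > 0 and math.isfinite(self.mean_norm_spacing)


@dataclass(frozen=True)
class ClusterStats:
    """Connected-pair and cluster decomposition of the progenitor pattern.

    A pair is *connected* when the centre distance is strictly less than
    ``threshold`` mean cell diameters; clusters are connected components of
    the pair graph, an isolated progenitor being a cluster of size 1.
    ``max_cluster`` is 0 when there are no progenitors.
    """

    threshold: float
    n_connected_pairs: int
    pct_cells_in_pairs: float
    cluster_sizes: tuple[int, ...]
    max_cluster: int


@dataclass(frozen=True)
class AnalysisConfig:
    """Tunable parameters of the analysis layer."""

    central_fraction: float = 0.40
    pair_threshold: float = 1.25
    diameter_estimator: str = "recorded"  # or "nearest_neighbor"
    diameter_scope: str = "dlc"  # or "all": which cells define the mean diameter

    def __post_init__(self) -> None:
        if not (0.0 < self.central_fraction <= 1.0):
            raise ParameterError("central_fraction must lie in (0, 1]")
        if self.pair_threshold <= 0.0:
            raise ParameterError("pair_threshold must be positive")
        if self.diameter_estimator not in ("recorded", "nearest_neighbor"):
            raise ParameterError(
                f"unknown diameter_estimator {self.diameter_estimator!r}"
            )
        if self.diameter_scope not in ("dlc", "all"):
            raise ParameterError(f"unknown diameter_scope {self.diameter_scope!r}")


# ---------------------------------------------------------------------------
# compartments and densities


def compartment_counts(cells: pd.DataFrame) -> CompartmentCounts:
    """Partition one embryo's cells by (dlc, p63) flag with BrdU+ subcounts.

    Raises
    ------
    IntegrityError
        If ``cell_id`` values are duplicated within the table.
    """
    if len(cells) and "cell_id" in cells.columns and cells["cell_id"].duplicated().any():
        dup = cells.loc[cells["cell_id"].duplicated(), "cell_id"].iloc[0]
        raise IntegrityError(f"duplicate cell_id {dup!r} within embryo")
    if len(cells) == 0:
        return CompartmentCounts(0, 0, 0, 0, 0, 0, 0, 0)
    dlc = cells["dlc"].to_numpy(dtype=bool)
    p63 = cells["p63"].to_numpy(dtype=bool)
    brdu = cells["brdu"].to_numpy(dtype=bool)
    kerat = ~dlc & p63
    iono = dlc & p63
    mis = dlc & ~p63
    return CompartmentCounts(
        n_p63=int(p63.sum()),
        n_kerat=int(kerat.sum()),
        n_iono=int(iono.sum()),
        n_mislabel=int(mis.sum()),
        n_p63_brdu=int((p63 & brdu).sum()),
        n_kerat_brdu=int((kerat & brdu).sum()),
        n_iono_brdu=int((iono & brdu).sum()),
        n_mislabel_brdu=int((mis & brdu).sum()),
    )


def cell_density(count: int, area: float) -> float:
    """Cells per square micrometre: ``count / area``.

    Raises
    ------
    ParameterError
        If ``area <= 0``.
    """
    if not (area > 0.0):
        raise ParameterError(f"area must be positive, got {area!r}")
    if count < 0:
        raise ParameterError("count must be non-negative")
    return count / area


def density_display(density: float) -> str:
    """Render a density using the conventional 1e-4 cells/um^2 scale."""
    return f"{density * 1e4:.2f} cells um^-2 x 10^-4"


def estimate_mean_diameter(
    cells: pd.DataFrame, method: str = "recorded"
) -> float:
    """Mean cell diameter of one embryo, micrometres.

    ``method="recorded"`` averages the recorded per-cell diameters.
    ``method="nearest_neighbor"`` averages nearest-neighbour centre distances
    over all cells — a fallback for data lacking diameter annotations.
    """
    if len(cells) == 0:
        raise EstimationError("cannot estimate mean diameter of an empty table")
    if method == "recorded":
        return float(cells["diameter_um"].mean())
    if method == "nearest_neighbor":
        if len(cells) < 2:
            raise EstimationError("nearest-neighbour estimator needs >= 2 cells")
        xy = cells[["x_um", "y_um"]].to_numpy(dtype=float)
        d, _ = cKDTree(xy).query(xy, k=2)
        return float(d[:, 1].mean())
    raise ParameterError(f"unknown diameter estimator {method!r}")


# ---------------------------------------------------------------------------
# spacing and domain angle


def _dlc_table(cells: pd.DataFrame) -> pd.DataFrame:
    return cells.loc[cells["dlc"].astype(bool)]


def normalized_nearest_spacing(
    cells: pd.DataFrame,
    geometry: EmbryoGeometry,
    central_fraction: float = 0.40,
    mean_diameter: float | None = None,
    diameter_scope: str = "dlc",
) -> SpacingStats:
    """Nearest-neighbour spacing of central progenitors, in cell diameters.

    Focal cells are dlc+ cells whose distance from the centroid is at most
    ``central_fraction * radius`` (i.e. within ``central_fraction`` of the
    embryo diameter, measured across the centre).  Each focal cell's nearest
    dlc+ neighbour may lie anywhere in the embryo.  Distances are divided by
    the embryo's mean cell diameter (mean over dlc+ cells by default, over
    all cells with ``diameter_scope="all"``, or the explicit
    ``mean_diameter`` when given).

    Returns a :class:`SpacingStats` whose ``mean_norm_spacing`` is NaN when
    fewer than two dlc+ cells exist or no focal cell lies in the central area.
    """
    dlc = _dlc_table(cells)
    if len(dlc) < 2:
        return SpacingStats(n_used=0, mean_norm_spacing=float("nan"))
    if mean_diameter is None:
        scope = dlc if diameter_scope == "dlc" else cells
        mean_diameter = float(scope["diameter_um"].mean())
    if not (mean_diameter > 0.0):
        raise ParameterError("mean diameter must be positive")
    xy = dlc[["x_um", "y_um"]].to_numpy(dtype=float)
    r_c = np.hypot(xy[:, 0] - geometry.centroid[0], xy[:, 1] - geometry.centroid[1])
    focal = r_c <= central_fraction * geometry.radius
    if not focal.any():
        return SpacingStats(n_used=0, mean_norm_spacing=float("nan"))
    d, _ = cKDTree(xy).query(xy[focal], k=2)
    norm = d[:, 1] / mean_diameter
    return SpacingStats(
        n_used=int(focal.sum()),
        mean_norm_spacing=float(norm.mean()),
        values=tuple(float(v) for v in norm),
    )


def domain_angle(cells: pd.DataFrame, geometry: EmbryoGeometry) -> float:
    """Angular width (degrees) of the smallest arc containing all dlc+ cells.

    Positions are converted to polar angles about the embryo centroid; the
    returned width is 360 minus the largest angular gap between consecutive
    cells, which handles wrap-around.  A single dlc+ cell gives 0 degrees; no
    dlc+ cells give NaN.
    """
    dlc = _dlc_table(cells)
    if len(dlc) == 0:
        return float("nan")
    if len(dlc) == 1:
        return 0.0
    theta = np.sort(
        geometry.angles(dlc["x_um"].to_numpy(float), dlc["y_um"].to_numpy(float))
    )
    gaps = np.diff(theta)
    wrap = 2.0 * math.pi - (theta[-1] - theta[0])
    max_gap = max(float(gaps.max(initial=0.0)), wrap)
    return math.degrees(2.0 * math.pi - max_gap)


# ---------------------------------------------------------------------------
# pairs and clusters


def _pair_list(
    xy: np.ndarray, cutoff: float
) -> list[tuple[int, int]]:
    """Unordered index pairs with centre distance strictly below ``cutoff``."""
    if len(xy) < 2:
        return []
    pairs = cKDTree(xy).query_pairs(cutoff, output_type="ndarray")
    if len(pairs) == 0:
        return []
    d = np.hypot(*(xy[pairs[:, 0]] - xy[pairs[:, 1]]).T)
    keep = d < cutoff  # query_pairs uses <=; the definition is strict
    return [tuple(p) for p in pairs[keep]]


class _DisjointSet:
    """Minimal union-find with path compression."""

    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[ri] = rj


def connected_pairs(
    cells: pd.DataFrame, mean_diameter: float, threshold: float = 1.25
) -> ClusterStats:
    """Count connected dlc+ pairs (centre distance < threshold diameters).

    ``pct_cells_in_pairs`` is the percentage of dlc+ cells with at least one
    connected neighbour.  Cluster fields are filled in as well (see
    :func:`decompose_clusters`); both views share one computation.
    """
    return decompose_clusters(cells, mean_diameter, threshold)


def decompose_clusters(
    cells: pd.DataFrame, mean_diameter: float, threshold: float = 1.25
) -> ClusterStats:
    """Decompose the dlc+ pattern into clusters of contiguous pairs.

    Clusters are connected components of the graph whose edges join dlc+
    cells at centre distance strictly less than ``threshold * mean_diameter``;
    an isolated dlc+ cell is a cluster of size 1.
    """
    if not (mean_diameter > 0.0):
        raise ParameterError("mean_diameter must be positive")
    if threshold <= 0.0:
        raise ParameterError("threshold must be positive")
    dlc = _dlc_table(cells)
    n = len(dlc)
    if n == 0:
        return ClusterStats(threshold, 0, 0.0, (), 0)
    xy = dlc[["x_um", "y_um"]].to_numpy(dtype=float)
    pairs = _pair_list(xy, threshold * mean_diameter)
    dsu = _DisjointSet(n)
    in_pair = np.zeros(n, dtype=bool)
    for i, j in pairs:
        dsu.union(i, j)
        in_pair[i] = in_pair[j] = True
    roots = [dsu.find(i) for i in range(n)]
    sizes: dict[int, int] = {}
    for r in roots:
        sizes[r] = sizes.get(r, 0) + 1
    cluster_sizes = tuple(sorted(sizes.values(), reverse=True))
    return ClusterStats(
        threshold=float(threshold),
        n_connected_pairs=len(pairs),
        pct_cells_in_pairs=100.0 * float(in_pair.sum()) / n,
        cluster_sizes=cluster_sizes,
        max_cluster=max(cluster_sizes) if cluster_sizes else 0,
    )


# ---------------------------------------------------------------------------
# per-embryo summary

#: Statistic columns of the per-embryo summary table (everything numeric).
SUMMARY_STATISTICS = [
    "n_p63",
    "n_kerat",
    "n_iono",
    "n_mislabel",
    "n_p63_brdu",
    "n_kerat_brdu",
    "n_iono_brdu",
    "pct_p63_brdu",
    "pct_kerat_brdu",
    "pct_iono_brdu",
    "density_p63",
    "density_kerat",
    "density_iono",
    "mean_diameter_um",
    "mean_norm_spacing",
    "n_spacing_used",
    "domain_angle_deg",
    "n_connected_pairs",
    "pct_cells_in_pairs",
    "n_clusters",
    "max_cluster",
]


def _pct(sub: int, total: int) -> float:
    return 100.0 * sub / total if total > 0 else float("nan")


def summarize_embryo(
    cells: pd.DataFrame,
    geometry: EmbryoGeometry,
    config: AnalysisConfig = AnalysisConfig(),
) -> dict:
    """Compute every per-embryo statistic as one flat record.

    Undefined statistics (empty compartments, <2 progenitors) are NaN.
    """
    counts = compartment_counts(cells)
    area = geometry.counting_area
    if len(cells) > 0:
        mean_d_all = estimate_mean_diameter(cells, config.diameter_estimator)
        dlc = _dlc_table(cells)
        if config.diameter_scope == "dlc" and len(dlc) > 0:
            if config.diameter_estimator == "recorded":
                mean_d = float(dlc["diameter_um"].mean())
            else:
                mean_d = mean_d_all
        else:
            mean_d = mean_d_all
    else:
        mean_d = float("nan")
    spacing = normalized_nearest_spacing(
        cells,
        geometry,
        central_fraction=config.central_fraction,
        mean_diameter=mean_d if math.isfinite(mean_d) and mean_d > 0 else None,
        diameter_scope=config.diameter_scope,
    )
    if math.isfinite(mean_d) and mean_d > 0:
        clusters = decompose_clusters(cells, mean_d, config.pair_threshold)
    else:
        clusters = ClusterStats(config.pair_threshold, 0, 0.0, (), 0)
    return {
        "n_p63": counts.n_p63,
        "n_kerat": counts.n_kerat,
        "n_iono": counts.n_iono,
        "n_mislabel": counts.n_mislabel,
        "n_p63_brdu": counts.n_p63_brdu,
        "n_kerat_brdu": counts.n_kerat_brdu,
        "n_iono_brdu": counts.n_iono_brdu,
        "pct_p63_brdu": _pct(counts.n_p63_brdu, counts.n_p63),
        "pct_kerat_brdu": _pct(counts.n_kerat_brdu, counts.n_kerat),
        "pct_iono_brdu": _pct(counts.n_iono_brdu, counts.n_iono),
        "density_p63": cell_density(counts.n_p63, area),
        "density_kerat": cell_density(counts.n_kerat, area),
        "density_iono": cell_density(counts.n_iono, area),
        "mean_diameter_um": mean_d,
        "mean_norm_spacing": spacing.mean_norm_spacing,
        "n_spacing_used": spacing.n_used,
        "domain_angle_deg": domain_angle(cells, geometry),
        "n_connected_pairs": clusters.n_connected_pairs,
        "pct_cells_in_pairs": clusters.pct_cells_in_pairs,
        "n_clusters": len(clusters.cluster_sizes),
        "max_cluster": clusters.max_cluster,
    }


def summarize_cohort(
    cells: pd.DataFrame,
    geometries: pd.DataFrame,
    config: AnalysisConfig = AnalysisConfig(),
) -> pd.DataFrame:
    """One summary row per embryo in the cohort tables.

    ``geometries`` must contain one row per embryo_id appearing in ``cells``
    (embryos with a geometry but no cells yield all-zero/NaN rows).
    """
    from .geometry import EmbryoGeometry as EG

    rows = []
    for _, g in geometries.iterrows():
        geom = EG(
            centroid=(float(g["cx_um"]), float(g["cy_um"])),
            radius=float(g["radius_um"]),
            sector_center=float(g["sector_center_rad"]),
            sector_halfwidth=float(g["sector_halfwidth_rad"]),
            counting_area=float(g["area_um2"]),
        )
        sub = cells.loc[cells["embryo_id"] == g["embryo_id"]]
        rec = summarize_embryo(sub, geom, config)
        rec["embryo_id"] = g["embryo_id"]
        rec["condition"] = sub["condition"].iloc[0] if len(sub) else ""
        rows.append(rec)
    cols = ["embryo_id", "condition"] + SUMMARY_STATISTICS
    return pd.DataFrame(rows, columns=cols) if rows else pd.DataFrame(columns=cols)
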