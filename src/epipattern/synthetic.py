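"""Synthetic embryo cohorts: packed epithelium, progenitor selection, S-phase labels.

The generator emulates the statistical structure of ventral epidermal cell
mosaics in early fish embryos:

* a near-confluent monolayer of stem cells (``p63``-positive) packed into the
  ventral counting sector by dart-throwing with a hard minimum centre-to-centre
  distance;
* a sparse set of progenitors (``dlc``-positive) chosen by sequential
  short-range inhibition (a Matern type-III-like thinning on the discrete cell
  mosaic), restricted to a ventral progenitor domain, with an optional chained
  co-selection channel that produces contiguous progenitor clusters;
* independent Bernoulli S-phase (``brdu``) labels per compartment, and a rare
  mislabel channel that records a progenitor as ``p63``-negative.

All randomness flows through :class:`numpy.random.Generator` (PCG64).
Per-embryo streams are keyed by ``(seed, condition, embryo index)`` so cohorts
are reproducible and extensible without perturbing earlier embryos.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field, asdict, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import PackingError, ParameterError
from .geometry import (
    DEFAULT_GEOMETRY,
    EmbryoGeometry,
    angular_distance,
    sample_in_sector,
)

__all__ = [
    "ConditionPreset",
    "CohortConfig",
    "CELL_COLUMNS",
    "GEOMETRY_COLUMNS",
    "pack_epithelium",
    "select_progenitors",
    "assign_brdu",
    "generate_embryo",
    "generate_cohort",
    "default_presets",
]

#: Column order of the canonical cell table.
CELL_COLUMNS = [
    "embryo_id",
    "cell_id",
    "x_um",
    "y_um",
    "diameter_um",
    "p63",
    "dlc",
    "brdu",
    "condition",
]

#: Column order of the canonical geometry table.
GEOMETRY_COLUMNS = [
    "embryo_id",
    "cx_um",
    "cy_um",
    "radius_um",
    "sector_center_rad",
    "sector_halfwidth_rad",
    "area_um2",
]

#: Contact distance (in units of mean cell diameter) used for chained
#: co-selection; matches the connected-pair threshold of the analysis layer.
CONTACT_DIAMETERS = 1.25

#: Fractional minimum centre-to-centre spacing of the packed epithelium, in
#: units of the effective cell diameter.
PACKING_FRACTION_OF_DIAMETER = 0.9


@dataclass(frozen=True)
class ConditionPreset:
    """Generative parameters of one experimental condition.

    Parameters are expressed in the units the analysis layer estimates them
    in, so that every parameter is recoverable from the generated patterns.

    Attributes
    ----------
    name : str
        Condition label recorded on every generated cell.
    n_stem_mean : float
        Expected number of stem (p63+) cells in the counting sector; the
        realized count is Poisson-distributed about this mean.
    diameter_mean : float
        Baseline cell diameter, micrometres.
    diameter_scale : float
        Multiplicative diameter change of this condition (1.0 = baseline).
    domain_scale : float
        Multiplicative change of the progenitor-domain angular half-width.
    inhibition_radius : float
        Short-range inhibition radius, in units of the mean cell diameter.
    p_select : float
        Probability that a visited, uninhibited candidate becomes dlc+.
    p_cluster : float
        Probability that a newly selected dlc+ cell co-selects one contacting
        neighbour (chains with geometric decay at this ratio).
    brdu_rate_keratinocyte, brdu_rate_ionocyte : float
        Bernoulli S-phase label rates for dlc-/dlc+ cells respectively.
    mislabel_rate : float
        Probability that a dlc+ cell is recorded p63-negative.
    domain_halfwidth : float
        Baseline angular half-width (radians) of the progenitor domain, before
        ``domain_scale`` is applied.
    domain_radius_frac : float
        Radial extent of the progenitor domain as a fraction of the embryo
        radius.
    diameter_cv : float
        Coefficient of variation of the multiplicative per-cell diameter
        noise (must be <= 0.05).
    packing : str
        ``"hex_jitter"`` (default): jittered hexagonal packing, emulating the
        near-regular geometry of a confluent monolayer; ``"dart"``: random
        sequential dart-throwing with rejection.  Both enforce the same hard
        minimum centre-to-centre distance.
    """

    name: str
    n_stem_mean: float
    diameter_mean: float = 11.0
    diameter_scale: float = 1.0
    domain_scale: float = 1.0
    inhibition_radius: float = 1.3
    p_select: float = 1.0
    p_cluster: float = 0.0
    brdu_rate_keratinocyte: float = 0.873
    brdu_rate_ionocyte: float = 0.725
    mislabel_rate: float = 0.002
    domain_halfwidth: float = 1.0
    domain_radius_frac: float = 0.38
    diameter_cv: float = 0.03
    packing: str = "hex_jitter"

    def __post_init__(self) -> None:
        if self.packing not in ("hex_jitter", "dart"):
            raise ParameterError(f"unknown packing mode {self.packing!r}")
        probs = {
            "p_select": self.p_select,
            "p_cluster": self.p_cluster,
            "brdu_rate_keratinocyte": self.brdu_rate_keratinocyte,
            "brdu_rate_ionocyte": self.brdu_rate_ionocyte,
            "mislabel_rate": self.mislabel_rate,
        }
        for key, value in probs.items():
            if not (0.0 <= value <= 1.0):
                raise ParameterError(f"{key} must lie in [0, 1], got {value!r}")
        for key in ("diameter_scale", "domain_scale", "inhibition_radius",
                    "diameter_mean"):
            if not (getattr(self, key) > 0.0):
                raise ParameterError(f"{key} must be positive")
        if not (self.n_stem_mean >= 0.0):
            raise ParameterError("n_stem_mean must be non-negative")
        if not (0.0 < self.domain_halfwidth <= math.pi):
            raise ParameterError("domain_halfwidth must lie in (0, pi]")
        if not (0.0 < self.domain_radius_frac <= 1.0):
            raise ParameterError("domain_radius_frac must lie in (0, 1]")
        if not (0.0 <= self.diameter_cv <= 0.05):
            raise ParameterError("diameter_cv must lie in [0, 0.05]")

    @property
    def effective_diameter(self) -> float:
        return self.diameter_mean * self.diameter_scale

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ConditionPreset":
        unknown = set(d) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise ParameterError(f"unknown preset keys: {sorted(unknown)}")
        return cls(**d)


@dataclass(frozen=True)
class CohortConfig:
    """A seeded cohort: a set of presets, each replicated over n embryos."""

    presets: Sequence[ConditionPreset]
    n_embryos_per_condition: int = 20
    seed: int = 0
    geometry: EmbryoGeometry = field(default=DEFAULT_GEOMETRY)

    def __post_init__(self) -> None:
        if self.n_embryos_per_condition < 0:
            raise ParameterError("n_embryos_per_condition must be >= 0")
        if int(self.seed) < 0:
            raise ParameterError("seed must be a non-negative integer")
        names = [p.name for p in self.presets]
        if len(names) != len(set(names)):
            raise ParameterError("preset names must be unique")


def default_presets() -> list[ConditionPreset]:
    """Bundled demonstration presets for five conditions.

    Counts, labelling rates and scale factors follow the published group
    means for a wild-type-like baseline, two mutant dosages, a knockdown and
    an overexpression condition.
    """
    wt = ConditionPreset(name="wt", n_stem_mean=1222.5)
    return [
        wt,
        replace(wt, name="het", n_stem_mean=1062.3, brdu_rate_keratinocyte=0.773),
        replace(
            wt,
            name="hom",
            n_stem_mean=935.0,
            brdu_rate_keratinocyte=0.647,
            brdu_rate_ionocyte=0.547,
        ),
        replace(wt, name="mo", diameter_scale=1.052, domain_scale=0.879),
        replace(
            wt,
            name="oe",
            diameter_scale=0.921,
            domain_scale=1.363,
            p_cluster=0.6,
        ),
    ]


# ---------------------------------------------------------------------------
# packing


def _hex_packing_bound(area: float, min_dist: float) -> float:
    """Theoretical maximum number of points with pairwise distance >= min_dist
    in a region of the given area (hexagonal close packing, boundary ignored)."""
    return 2.0 * area / (math.sqrt(3.0) * min_dist * min_dist)


class _Grid:
    """Uniform hash grid for O(1) minimum-distance checks during packing."""

    def __init__(self, cell_size: float):
        self.h = cell_size
        self.cells: dict[tuple[int, int], list[tuple[float, float]]] = {}

    def _key(self, x: float, y: float) -> tuple[int, int]:
        return (int(math.floor(x / self.h)), int(math.floor(y / self.h)))

    def ok(self, x: float, y: float, min_dist: float) -> bool:
        ki, kj = self._key(x, y)
        m2 = min_dist * min_dist
        for i in range(ki - 1, ki + 2):
            for j in range(kj - 1, kj + 2):
                for (px, py) in self.cells.get((i, j), ()):
                    dx = px - x
                    dy = py - y
                    if dx * dx + dy * dy < m2:
                        return False
        return True

    def add(self, x: float, y: float) -> None:
        self.cells.setdefault(self._key(x, y), []).append((x, y))


def pack_epithelium(
    geometry: EmbryoGeometry,
    preset: ConditionPreset,
    rng: np.random.Generator,
    *,
    max_attempts_per_cell: int = 2000,
) -> pd.DataFrame:
    """Pack a Poisson-distributed number of stem cells into the counting sector.

    The realized cell count is Poisson-distributed about ``n_stem_mean``.
    Cells honour a hard minimum centre-to-centre distance of
    ``0.9 * effective diameter`` (effective diameter =
    ``diameter_mean * diameter_scale``).  Two packing modes exist:

    * ``"hex_jitter"`` (default): cells sit on a randomly oriented hexagonal
      lattice, randomly thinned to the target count, with per-cell uniform
      jitter bounded so the minimum distance is preserved — the near-regular
      geometry of a confluent monolayer;
    * ``"dart"``: random sequential placement with rejection (a Matern-III /
      RSA-like disordered mosaic).

    Each cell's recorded diameter is the effective diameter perturbed by
    multiplicative Gaussian noise with CV ``preset.diameter_cv``.

    Returns a cell table (columns :data:`CELL_COLUMNS` minus identity columns)
    with every cell flagged p63+, dlc-, brdu-.

    Raises
    ------
    PackingError
        If the requested expected count exceeds the hexagonal close-packing
        bound for the sector area, if the lattice cannot host the realized
        count, or if the dart thrower exhausts its retry cap.
    """
    d_eff = preset.effective_diameter
    min_dist = PACKING_FRACTION_OF_DIAMETER * d_eff
    bound = _hex_packing_bound(geometry.counting_area, min_dist)
    if preset.n_stem_mean > bound:
        raise PackingError(
            f"expected count {preset.n_stem_mean:.1f} exceeds the close-packing "
            f"bound {bound:.1f} for area {geometry.counting_area:.3g} um^2 at "
            f"minimum spacing {min_dist:.3g} um"
        )
    n = int(rng.poisson(preset.n_stem_mean))
    if preset.packing == "hex_jitter":
        xs, ys = _place_hex_jitter(geometry, n, min_dist, rng)
    else:
        xs, ys = _place_dart(
            geometry, n, min_dist, rng, max_attempts_per_cell=max_attempts_per_cell
        )
    noise = 1.0 + rng.normal(0.0, preset.diameter_cv, size=n)
    diam = d_eff * np.clip(noise, 0.5, 1.5)
    return pd.DataFrame(
        {
            "x_um": xs,
            "y_um": ys,
            "diameter_um": diam,
            "p63": np.ones(n, dtype=bool),
            "dlc": np.zeros(n, dtype=bool),
            "brdu": np.zeros(n, dtype=bool),
        }
    )


#: Target site surplus of the jittered hexagonal lattice over the expected
#: cell count; the surplus absorbs Poisson count fluctuations as vacancies.
_HEX_SITE_MARGIN = 1.15


def _place_hex_jitter(
    geometry: EmbryoGeometry,
    n: int,
    min_dist: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Thinned, jittered hexagonal lattice clipped to the counting sector."""
    area = geometry.counting_area
    # lattice constant giving ~_HEX_SITE_MARGIN * n sites in the sector
    target_sites = max(float(n) * _HEX_SITE_MARGIN, 1.0)
    a = math.sqrt(2.0 * area / (math.sqrt(3.0) * target_sites))
    if a < min_dist:
        raise PackingError(
            f"lattice constant {a:.3g} um below the minimum spacing "
            f"{min_dist:.3g} um: density infeasible for jittered-hex packing"
        )
    jitter = 0.5 * (a - min_dist)
    # axial lattice covering the disc, random global rotation and phase
    span = int(math.ceil(geometry.radius / (a * 0.5))) + 2
    i, j = np.meshgrid(np.arange(-span, span + 1), np.arange(-span, span + 1))
    px = (i + 0.5 * j).ravel() * a
    py = (j * (math.sqrt(3.0) / 2.0)).ravel() * a
    phi = rng.uniform(0.0, 2.0 * math.pi)
    ox, oy = rng.uniform(-0.5, 0.5, size=2) * a
    c, s = math.cos(phi), math.sin(phi)
    x = c * (px + ox) - s * (py + oy) + geometry.centroid[0]
    y = s * (px + ox) + c * (py + oy) + geometry.centroid[1]
    inside = geometry.contains(x, y)
    x, y = x[inside], y[inside]
    if n > len(x):
        raise PackingError(
            f"realized count {n} exceeds the {len(x)} available lattice sites"
        )
    keep = rng.choice(len(x), size=n, replace=False)
    # uniform jitter in a disc of radius `jitter` preserves the minimum distance
    r = jitter * np.sqrt(rng.uniform(0.0, 1.0, size=n))
    th = rng.uniform(0.0, 2.0 * math.pi, size=n)
    jx = x[keep] + r * np.cos(th)
    jy = y[keep] + r * np.sin(th)
    # a jittered cell that would leave the sector stays on its lattice site
    out = ~geometry.contains(jx, jy)
    jx[out] = x[keep][out]
    jy[out] = y[keep][out]
    return jx, jy


def _place_dart(
    geometry: EmbryoGeometry,
    n: int,
    min_dist: float,
    rng: np.random.Generator,
    *,
    max_attempts_per_cell: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Random sequential placement with rejection below ``min_dist``."""
    xs = np.empty(n)
    ys = np.empty(n)
    grid = _Grid(cell_size=min_dist)
    placed = 0
    attempts = 0
    cap = max_attempts_per_cell * max(n, 1)
    # draw candidate points in blocks to amortize RNG overhead
    block = max(256, n)
    while placed < n:
        pts = sample_in_sector(geometry, block, rng)
        for x, y in pts:
            attempts += 1
            if grid.ok(x, y, min_dist):
                xs[placed] = x
                ys[placed] = y
                grid.add(x, y)
                placed += 1
                if placed == n:
                    break
            if attempts >= cap:
                raise PackingError(
                    f"placed only {placed}/{n} cells after {attempts} attempts; "
                    "density too close to the jamming limit"
                )
    return xs, ys


# ---------------------------------------------------------------------------
# progenitor selection


def select_progenitors(
    cells: pd.DataFrame,
    preset: ConditionPreset,
    rng: np.random.Generator,
    geometry: EmbryoGeometry | None = None,
) -> pd.DataFrame:
    """Mark a subset of stem cells dlc+ by sequential short-range inhibition.

    Candidate cells (those inside the progenitor domain when a geometry is
    supplied, all cells otherwise) are visited in a random order; a visited
    cell becomes dlc+ with probability ``p_select`` iff no already-selected
    cell lies within ``inhibition_radius`` mean diameters.  After each
    selection, with probability ``p_cluster`` one uniformly chosen contacting
    neighbour (within ``1.25`` mean diameters) is co-selected, bypassing the
    inhibition check; co-selection chains with geometric decay.

    With ``p_cluster = 0`` the dlc+ set satisfies a hard-core constraint at
    the inhibition radius.

    Returns a copy of ``cells`` with the ``dlc`` column updated.
    """
    if preset.inhibition_radius <= 0.0:
        raise ParameterError("inhibition_radius must be positive")
    out = cells.copy()
    n = len(out)
    if n == 0 or preset.p_select == 0.0:
        return out
    xy = out[["x_um", "y_um"]].to_numpy(dtype=float)
    mean_d = float(out["diameter_um"].mean())
    r_inh = preset.inhibition_radius * mean_d
    r_contact = CONTACT_DIAMETERS * mean_d

    if geometry is not None:
        dx = xy[:, 0] - geometry.centroid[0]
        dy = xy[:, 1] - geometry.centroid[1]
        theta = np.arctan2(dy, dx)
        in_angle = angular_distance(theta, geometry.sector_center) <= (
            preset.domain_halfwidth * preset.domain_scale
        )
        in_radius = np.hypot(dx, dy) <= preset.domain_radius_frac * geometry.radius
        eligible = in_angle & in_radius
    else:
        eligible = np.ones(n, dtype=bool)

    from scipy.spatial import cKDTree

    tree = cKDTree(xy)
    selected = np.zeros(n, dtype=bool)
    sel_xy: list[np.ndarray] = []

    def inhibited(i: int) -> bool:
        if not sel_xy:
            return False
        pts = np.asarray(sel_xy)
        d2 = np.sum((pts - xy[i]) ** 2, axis=1)
        return bool(np.any(d2 < r_inh * r_inh))

    def co_select_chain(i: int) -> None:
        cur = i
        while rng.random() < preset.p_cluster:
            nbrs = [
                j
                for j in tree.query_ball_point(xy[cur], r_contact)
                if j != cur and not selected[j] and eligible[j]
            ]
            if not nbrs:
                return
            nxt = nbrs[int(rng.integers(len(nbrs)))]
            selected[nxt] = True
            sel_xy.append(xy[nxt])
            cur = nxt

    order = rng.permutation(np.flatnonzero(eligible))
    for i in order:
        if selected[i] or inhibited(int(i)):
            continue
        if rng.random() < preset.p_select:
            selected[i] = True
            sel_xy.append(xy[i])
            if preset.p_cluster > 0.0:
                co_select_chain(int(i))

    out["dlc"] = selected
    return out


# ---------------------------------------------------------------------------
# labelling


def assign_brdu(
    cells: pd.DataFrame, preset: ConditionPreset, rng: np.random.Generator
) -> pd.DataFrame:
    """Assign independent Bernoulli S-phase labels and apply the mislabel channel.

    Each dlc- p63+ cell is brdu+ with probability ``brdu_rate_keratinocyte``;
    each dlc+ cell with probability ``brdu_rate_ionocyte``.  Additionally each
    dlc+ cell has its p63 flag cleared with probability ``mislabel_rate``,
    producing the rare dlc+ p63- class.
    """
    out = cells.copy()
    n = len(out)
    if n == 0:
        return out
    dlc = out["dlc"].to_numpy(dtype=bool)
    p63 = out["p63"].to_numpy(dtype=bool)
    u = rng.uniform(size=n)
    brdu = np.where(dlc, u < preset.brdu_rate_ionocyte,
                    p63 & (u < preset.brdu_rate_keratinocyte))
    mis = dlc & (rng.uniform(size=n) < preset.mislabel_rate)
    out["brdu"] = brdu
    out["p63"] = p63 & ~mis
    return out


# ---------------------------------------------------------------------------
# cohorts


def _embryo_rng(seed: int, condition: str, index: int) -> np.random.Generator:
    """Deterministic per-embryo stream keyed by (seed, condition, index)."""
    key = zlib.crc32(condition.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(seed), key, int(index)]))


def generate_embryo(
    geometry: EmbryoGeometry,
    preset: ConditionPreset,
    rng: np.random.Generator,
    embryo_id: str,
) -> pd.DataFrame:
    """Generate one embryo: pack, select progenitors, label."""
    cells = pack_epithelium(geometry, preset, rng)
    cells = select_progenitors(cells, preset, rng, geometry=geometry)
    cells = assign_brdu(cells, preset, rng)
    cells.insert(0, "embryo_id", embryo_id)
    cells.insert(1, "cell_id", np.arange(len(cells)))
    cells["condition"] = preset.name
    return cells[CELL_COLUMNS]


def generate_cohort(config: CohortConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate the full cohort described by ``config``.

    Returns ``(cells, geometries)``: a cell table over all embryos and one
    geometry row per embryo.  Identical configs produce identical tables.
    """
    g = config.geometry
    cell_frames: list[pd.DataFrame] = []
    geo_rows: list[dict] = []
    for preset in config.presets:
        for i in range(config.n_embryos_per_condition):
            embryo_id = f"{preset.name}_{i:03d}"
            rng = _embryo_rng(config.seed, preset.name, i)
            cell_frames.append(generate_embryo(g, preset, rng, embryo_id))
            geo_rows.append(
                {
                    "embryo_id": embryo_id,
                    "cx_um": g.centroid[0],
                    "cy_um": g.centroid[1],
                    "radius_um": g.radius,
                    "sector_center_rad": g.sector_center,
                    "sector_halfwidth_rad": g.sector_halfwidth,
                    "area_um2": g.counting_area,
                }
            )
    if cell_frames:
        cells = pd.concat(cell_frames, ignore_index=True)
    else:
        cells = pd.DataFrame(
            {c: pd.Series(dtype=t) for c, t in zip(
                CELL_COLUMNS,
                [str, int, float, float, float, bool, bool, bool, str],
            )}
        )
    geoms = pd.DataFrame(geo_rows, columns=GEOMETRY_COLUMNS)
    return cells, geoms
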