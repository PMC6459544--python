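import math

import numpy as np
import pandas as pd
import pytest

from epipattern.errors import EstimationError, IntegrityError, ParameterError
from epipattern.geometry import make_geometry
from epipattern.patterns import (
    AnalysisConfig,
    cell_density,
    compartment_counts,
    connected_pairs,
    decompose_clusters,
    density_display,
    domain_angle,
    estimate_mean_diameter,
    normalized_nearest_spacing,
    summarize_embryo,
)

from conftest import cells_from_arrays


GEOM = make_geometry(radius=100.0)


# ---------------------------------------------------------------------------
# brute-force oracles


def brute_nearest(xy):
    d = np.sqrt(((xy[:, None, :] - xy[None, :, :]) ** 2).sum(-1))
    np.fill_diagonal(d, np.inf)
    return d.min(axis=1)


def brute_pairs(xy, cutoff):
    out = []
    for i in range(len(xy)):
        for j in range(i + 1, len(xy)):
            if math.dist(xy[i], xy[j]) < cutoff:
                out.append((i, j))
    return out


def brute_clusters(xy, cutoff):
    # transitive closure over the connected-pair relation
    n = len(xy)
    labels = list(range(n))
    changed = True
    while changed:
        changed = False
        for i, j in brute_pairs(xy, cutoff):
            lo = min(labels[i], labels[j])
            for k in (i, j):
                if labels[k] != lo:
                    labels[k] = lo
                    changed = True
    sizes = {}
    for l in labels:
        sizes[l] = sizes.get(l, 0) + 1
    return sorted(sizes.values(), reverse=True)


# ---------------------------------------------------------------------------
# compartments


class TestCompartments:
    def test_hand_enumeration(self):
        cells = cells_from_arrays(
            [(0, 0), (5, 0), (10, 0)],
            p63=[True, True, False],
            dlc=[False, True, True],
            brdu=[True, False, True],
        )
        c = compartment_counts(cells)
        assert (c.n_p63, c.n_kerat, c.n_iono, c.n_mislabel) == (2, 1, 1, 1)
        assert (c.n_kerat_brdu, c.n_iono_brdu, c.n_mislabel_brdu) == (1, 0, 1)

    def test_empty(self):
        c = compartment_counts(cells_from_arrays(np.empty((0, 2))))
        assert c.n_p63 == c.n_kerat == c.n_iono == c.n_mislabel == 0

    def test_conservation_invariant(self):
        rng = np.random.default_rng(0)
        cells = cells_from_arrays(
            rng.uniform(-50, 50, (200, 2)),
            p63=rng.random(200) < 0.9,
            dlc=rng.random(200) < 0.2,
            brdu=rng.random(200) < 0.5,
        )
        c = compartment_counts(cells)
        assert c.n_p63 == c.n_kerat + c.n_iono

    def test_duplicate_cell_id_raises(self):
        cells = cells_from_arrays([(0, 0), (5, 0)])
        cells.loc[1, "cell_id"] = 0
        with pytest.raises(IntegrityError):
            compartment_counts(cells)


class TestDensity:
    def test_simple(self):
        assert cell_density(10, 1e5) == pytest.approx(1.0e-4)

    def test_zero_count(self):
        assert cell_density(0, 123.0) == 0.0

    def test_matches_reported_scale(self):
        assert cell_density(57, 2.7e5) == pytest.approx(2.11e-4, rel=0.005)

    def test_invalid_area(self):
        with pytest.raises(ParameterError):
            cell_density(1, 0.0)

    def test_display_helper(self):
        assert density_display(2.13e-4) == "2.13 cells um^-2 x 10^-4"


class TestMeanDiameter:
    def test_arithmetic_mean(self):
        cells = cells_from_arrays([(0, 0), (20, 0), (40, 0)], diameter=[10, 12, 14])
        assert estimate_mean_diameter(cells) == pytest.approx(12.0)

    def test_empty_raises(self):
        with pytest.raises(EstimationError):
            estimate_mean_diameter(cells_from_arrays(np.empty((0, 2))))

    def test_nn_estimator_single_cell_raises(self):
        with pytest.raises(EstimationError):
            estimate_mean_diameter(
                cells_from_arrays([(0, 0)]), method="nearest_neighbor"
            )

    def test_nn_estimator_on_grid(self):
        xy = [(i * 7.0, j * 7.0) for i in range(5) for j in range(5)]
        cells = cells_from_arrays(xy)
        assert estimate_mean_diameter(
            cells, method="nearest_neighbor"
        ) == pytest.approx(7.0)


# ---------------------------------------------------------------------------
# spacing


class TestSpacing:
    def test_two_cells_unit_spacing(self):
        d = 10.0
        cells = cells_from_arrays([(0, 0), (d, 0)], diameter=d)
        s = normalized_nearest_spacing(cells, GEOM)
        assert s.mean_norm_spacing == pytest.approx(1.0)
        assert s.n_used == 2

    def test_three_collinear_hand_geometry(self):
        d = 10.0
        cells = cells_from_arrays([(0, 0), (1.3 * d, 0), (3 * d, 0)], diameter=d)
        s = normalized_nearest_spacing(cells, GEOM, central_fraction=1.0)
        assert sorted(s.values) == pytest.approx([1.3, 1.3, 1.7])
        assert s.mean_norm_spacing == pytest.approx(4.3 / 3)

    def test_fewer_than_two_progenitors_flagged(self):
        s = normalized_nearest_spacing(cells_from_arrays([(0, 0)]), GEOM)
        assert s.n_used == 0 and math.isnan(s.mean_norm_spacing)

    def test_focal_restriction_but_neighbors_anywhere(self):
        d = 10.0
        # one central cell, nearest neighbor outside the central region
        cells = cells_from_arrays([(0, 0), (70, 0)], diameter=d)
        s = normalized_nearest_spacing(cells, GEOM, central_fraction=0.4)
        assert s.n_used == 1
        assert s.mean_norm_spacing == pytest.approx(7.0)

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(5)
        xy = rng.uniform(-60, 60, (120, 2))
        cells = cells_from_arrays(xy, diameter=8.0)
        s = normalized_nearest_spacing(cells, GEOM, central_fraction=1.0)
        expected = brute_nearest(xy) / 8.0
        assert s.n_used == 120
        assert np.allclose(sorted(s.values), sorted(expected))

    def test_zero_mean_diameter_rejected(self):
        cells = cells_from_arrays([(0, 0), (5, 0)])
        with pytest.raises(ParameterError):
            normalized_nearest_spacing(cells, GEOM, mean_diameter=0.0)


class TestDomainAngle:
    def test_single_cell_zero(self):
        assert domain_angle(cells_from_arrays([(5, 5)]), GEOM) == 0.0

    def test_no_progenitors_nan(self):
        cells = cells_from_arrays([(5, 5)], dlc=False)
        assert math.isnan(domain_angle(cells, GEOM))

    def test_hand_geometry_60_degrees(self):
        a, b = math.radians(10), math.radians(70)
        cells = cells_from_arrays(
            [(50 * math.cos(a), 50 * math.sin(a)), (30 * math.cos(b), 30 * math.sin(b))]
        )
        assert domain_angle(cells, GEOM) == pytest.approx(60.0)

    def test_wraparound(self):
        angles = [350.0, 5.0, 10.0]
        xy = [(40 * math.cos(math.radians(t)), 40 * math.sin(math.radians(t)))
              for t in angles]
        assert domain_angle(cells_from_arrays(xy), GEOM) == pytest.approx(20.0)

    def test_wraparound_matches_bruteforce_scan(self):
        rng = np.random.default_rng(9)
        theta = rng.uniform(0, 2 * math.pi, 25)
        xy = np.c_[40 * np.cos(theta), 40 * np.sin(theta)]
        got = domain_angle(cells_from_arrays(xy), GEOM)
        # brute force: minimal arc over all candidate start angles
        best = 360.0
        for start in theta:
            rel = np.degrees(np.mod(theta - start, 2 * math.pi))
            best = min(best, rel.max())
        assert got == pytest.approx(best)


# ---------------------------------------------------------------------------
# pairs and clusters


class TestPairsClusters:
    def test_single_cell(self):
        s = connected_pairs(cells_from_arrays([(0, 0)]), mean_diameter=10.0)
        assert s.n_connected_pairs == 0 and s.pct_cells_in_pairs == 0.0

    def test_boundary_is_strict(self):
        d = 10.0
        cells = cells_from_arrays([(0, 0), (1.25 * d, 0)], diameter=d)
        s = connected_pairs(cells, mean_diameter=d)
        assert s.n_connected_pairs == 0
        just_inside = cells_from_arrays([(0, 0), (1.25 * d - 1e-9, 0)], diameter=d)
        assert connected_pairs(just_inside, mean_diameter=d).n_connected_pairs == 1

    def test_collinear_triple(self):
        d = 10.0
        cells = cells_from_arrays([(0, 0), (1.0 * d, 0), (2.2 * d, 0)], diameter=d)
        s = decompose_clusters(cells, mean_diameter=d)
        assert s.n_connected_pairs == 2
        assert s.pct_cells_in_pairs == pytest.approx(100.0)
        assert s.cluster_sizes == (3,)
        assert s.max_cluster == 3

    def test_two_separated_pairs(self):
        d = 10.0
        cells = cells_from_arrays(
            [(0, 0), (d, 0), (100, 0), (100 + d, 0)], diameter=d
        )
        s = decompose_clusters(cells, mean_diameter=d)
        assert s.cluster_sizes == (2, 2)
        assert s.max_cluster == 2

    def test_isolated_cell_is_cluster_of_one(self):
        s = decompose_clusters(cells_from_arrays([(0, 0)]), mean_diameter=10.0)
        assert s.cluster_sizes == (1,) and s.max_cluster == 1

    def test_sizes_sum_to_n_progenitors(self):
        rng = np.random.default_rng(2)
        xy = rng.uniform(-80, 80, (60, 2))
        s = decompose_clusters(cells_from_arrays(xy, diameter=9.0), mean_diameter=9.0)
        assert sum(s.cluster_sizes) == 60

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(5):
            xy = rng.uniform(-60, 60, (80, 2))
            d = rng.uniform(5, 15)
            cells = cells_from_arrays(xy, diameter=d)
            s = decompose_clusters(cells, mean_diameter=d)
            cutoff = 1.25 * d
            assert s.n_connected_pairs == len(brute_pairs(xy, cutoff))
            assert list(s.cluster_sizes) == brute_clusters(xy, cutoff)

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(11)
        xy = rng.uniform(-60, 60, (70, 2))
        cells = cells_from_arrays(xy, diameter=10.0)
        prev_pairs, prev_max = -1, -1
        for thr in (0.5, 1.0, 1.25, 2.0, 4.0):
            s = decompose_clusters(cells, mean_diameter=10.0, threshold=thr)
            assert s.n_connected_pairs >= prev_pairs
            assert s.max_cluster >= prev_max
            prev_pairs, prev_max = s.n_connected_pairs, s.max_cluster


# ---------------------------------------------------------------------------
# invariances


class TestInvariances:
    def _random_cells(self, seed, n=60):
        rng = np.random.default_rng(seed)
        theta = rng.uniform(0, 2 * math.pi, n)
        r = 90 * np.sqrt(rng.uniform(0, 1, n))
        xy = np.c_[r * np.cos(theta), r * np.sin(theta)]
        return cells_from_arrays(xy, diameter=rng.uniform(8, 12, n))

    def test_scale_invariance(self):
        cells = self._random_cells(21)
        k = 3.7
        scaled = cells.copy()
        scaled[["x_um", "y_um", "diameter_um"]] *= k
        geom_s = make_geometry(radius=100.0 * k)
        a = summarize_embryo(cells, GEOM)
        b = summarize_embryo(scaled, geom_s)
        for key in ("mean_norm_spacing", "domain_angle_deg", "n_connected_pairs",
                    "pct_cells_in_pairs", "max_cluster", "n_clusters"):
            assert a[key] == pytest.approx(b[key]), key

    def test_rotation_invariance(self):
        cells = self._random_cells(22)
        phi = 1.234
        rot = cells.copy()
        c, s = math.cos(phi), math.sin(phi)
        x, y = cells.x_um.to_numpy(), cells.y_um.to_numpy()
        rot["x_um"] = c * x - s * y
        rot["y_um"] = s * x + c * y
        a = summarize_embryo(cells, GEOM)
        b = summarize_embryo(rot, GEOM)
        for key in ("mean_norm_spacing", "domain_angle_deg", "n_connected_pairs",
                    "max_cluster"):
            assert a[key] == pytest.approx(b[key]), key


# ---------------------------------------------------------------------------
# summary


class TestSummarize:
    def test_empty_embryo(self):
        s = summarize_embryo(cells_from_arrays(np.empty((0, 2))), GEOM)
        assert s["n_p63"] == 0
        assert math.isnan(s["mean_norm_spacing"])
        assert math.isnan(s["domain_angle_deg"])

    def test_density_is_count_over_area(self):
        cells = self_cells = cells_from_arrays(
            [(0, 0), (20, 0), (40, 0)], dlc=[True, True, False]
        )
        s = summarize_embryo(cells, GEOM)
        assert s["density_iono"] == s["n_iono"] / GEOM.counting_area

    def test_compositional_equivalence(self):
        rng = np.random.default_rng(33)
        xy = rng.uniform(-70, 70, (80, 2))
        cells = cells_from_arrays(
            xy, diameter=10.0, dlc=rng.random(80) < 0.3, brdu=rng.random(80) < 0.5
        )
        cfg = AnalysisConfig()
        s = summarize_embryo(cells, GEOM, cfg)
        # recompute each statistic by direct calls
        counts = compartment_counts(cells)
        assert s["n_iono"] == counts.n_iono
        dlc_d = cells.loc[cells.dlc, "diameter_um"].mean()
        sp = normalized_nearest_spacing(
            cells, GEOM, cfg.central_fraction, mean_diameter=dlc_d
        )
        assert s["mean_norm_spacing"] == pytest.approx(sp.mean_norm_spacing)
        cl = decompose_clusters(cells, dlc_d, cfg.pair_threshold)
        assert s["max_cluster"] == cl.max_cluster
        assert s["domain_angle_deg"] == pytest.approx(domain_angle(cells, GEOM))
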