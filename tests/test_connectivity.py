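"""Friction surfaces, cost-weighted distance and corridor construction."""

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import Polygon, box

from movescape.connectivity import (
    FrictionSurface,
    build_corridors,
    cost_weighted_distance,
    crop_corridors,
    extract_cores,
    friction_from_surface,
    mosaic_minimum,
    no_roads_surface,
    normalized_corridor,
    pair_cores,
    prediction_surface,
)
from movescape.models import DesignSpec, FittedModel
from movescape.simulate import generate_landscape, true_selection_model

from conftest import brute_dijkstra_cwd, make_raster


def model_from(beta: dict) -> FittedModel:
    names = list(beta)
    return FittedModel(
        beta=pd.Series(beta, dtype=float),
        se=pd.Series(np.nan, index=names),
        loglik=np.nan,
        vcov=pd.DataFrame(np.nan, index=names, columns=names),
        model_kind="ground_truth",
        spec=DesignSpec(continuous={n: False for n in names}, intercept=False, standardize=False),
        stats={"mu": {}, "sd": {}, "levels": {}},
        terms={n: {"columns": [n], "kind": "continuous"} for n in names},
    )


def friction_of(values, cell_size=250.0):
    return FrictionSurface(make_raster(values, cell_size=cell_size))


class TestPredictionSurface:
    def test_zero_beta_all_ones(self, small_stack):
        m = model_from({"dem": 0.0})
        s = prediction_surface(m, small_stack)
        assert np.allclose(s.values, 1.0)

    def test_two_by_two_arithmetic(self):
        from movescape.raster import LandscapeStack

        layer = make_raster([[0.0, 1.0], [1.0, 0.0]])
        stack = LandscapeStack({"v": layer})
        s = prediction_surface(model_from({"v": 1.0}), stack)
        assert np.allclose(np.sort(np.unique(s.values)), [np.exp(-1), 1.0])

    def test_monotone_in_covariates(self, small_stack):
        m = model_from({"canopy": 0.5, "ndvi_summer": 0.5})
        s = prediction_surface(m, small_stack)
        c, n = small_stack["canopy"].values, small_stack["ndvi_summer"].values
        i = np.unravel_index(np.argmax(c + n), c.shape)
        j = np.unravel_index(np.argmin(c + n), c.shape)
        assert s.values[i] > s.values[j]

    def test_missing_layer_reported(self, small_stack):
        with pytest.raises(KeyError, match="no landscape layer"):
            prediction_surface(model_from({"not_a_layer": 1.0}), small_stack)


class TestFriction:
    def test_floor_and_complement(self):
        surf = make_raster([[1.0, 0.0, 0.4]])
        fr = friction_from_surface(surf, epsilon=1e-6)
        assert fr.raster.values[0, 0] == pytest.approx(1e-6)
        assert fr.raster.values[0, 1] == pytest.approx(1.0)
        assert fr.raster.values[0, 2] + surf.values[0, 2] == pytest.approx(1.0)


class TestNoRoadsSurface:
    def test_model_without_road_terms_identical(self, small_stack):
        m = model_from({"canopy": 0.4})
        a = prediction_surface(m, small_stack)
        b = no_roads_surface(m, small_stack)
        assert np.array_equal(a.values, b.values, equal_nan=True)

    def test_no_roads_at_least_actual_near_road(self, small_config, small_stack):
        tm = true_selection_model(small_stack, {"dist_highway": 2.0, "canopy": 0.2})
        a = prediction_surface(tm, small_stack)
        n = no_roads_surface(tm, small_stack)
        near = small_stack["dist_highway"].values < 500
        # raw-score monotonicity survives each surface's own renormalization
        # here because the maximising cell is far from roads in both
        assert (n.values[near] >= a.values[near] - 1e-12).all()


class TestExtractCores:
    def test_single_block(self):
        vals = np.zeros((10, 10))
        vals[2:7, 2:7] = 1.0
        cores = extract_cores(make_raster(vals), quantile=0.75)
        assert len(cores) == 1
        assert cores[0].area == pytest.approx(25 * 250.0**2)

    def test_two_blocks(self):
        vals = np.zeros((12, 12))
        vals[1:4, 1:4] = 1.0
        vals[8:11, 8:11] = 1.0
        cores = extract_cores(make_raster(vals), quantile=0.9)
        assert len(cores) == 2

    def test_uniform_raster_warns_all_qualify(self):
        with pytest.warns(UserWarning, match="degenerate"):
            cores = extract_cores(make_raster(np.ones((5, 5))), quantile=0.75)
        assert sum(c.area for c in cores) == pytest.approx(25 * 250.0**2)


class TestPairCores:
    def test_distance_rules(self):
        a = box(0, 0, 1000, 1000)
        b = box(100_000, 0, 101_000, 1000)  # 99 km away
        assert pair_cores([a], [b], max_km=80) == []
        c = box(500, 500, 1500, 1500)  # overlaps a
        pairs = pair_cores([a], [c], max_km=80)
        assert pairs[0][2] == 0.0
        d = box(81_000, 0, 82_000, 1000)  # exactly 80 km edge-to-edge
        assert len(pair_cores([a], [d], max_km=80)) == 1


class TestCostWeightedDistance:
    def test_unit_friction_neighbours(self):
        fr = friction_of(np.ones((3, 3)))
        cwd = cost_weighted_distance(fr, [4])  # centre cell
        assert cwd.values[1, 2] == pytest.approx(250.0)
        assert cwd.values[0, 0] == pytest.approx(250.0 * np.sqrt(2))

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_heapq_dijkstra(self, seed):
        rng = np.random.default_rng(seed)
        f = rng.uniform(0.1, 1.0, size=(8, 8))
        fr = friction_of(f)
        src = [(0, 0), (3, 4)]
        cwd = cost_weighted_distance(fr, [r * 8 + c for r, c in src])
        oracle = brute_dijkstra_cwd(f, 250.0, src)
        assert np.allclose(cwd.values, oracle, atol=1e-9)

    def test_triangle_property(self):
        rng = np.random.default_rng(3)
        f = rng.uniform(0.1, 1.0, size=(8, 8))
        via = (4, 4)
        d_a = brute_dijkstra_cwd(f, 250.0, [(0, 0)])
        d_b = brute_dijkstra_cwd(f, 250.0, [via])
        assert (d_a <= d_a[via] + d_b + 1e-9).all()

    def test_doubling_friction_doubles_cwd(self):
        rng = np.random.default_rng(4)
        f = rng.uniform(0.1, 1.0, size=(8, 8))
        c1 = cost_weighted_distance(friction_of(f), [0])
        c2 = cost_weighted_distance(friction_of(2 * f), [0])
        assert np.allclose(c2.values, 2 * c1.values)

    def test_nodata_source_rejected(self):
        f = np.ones((4, 4))
        f[0, 0] = np.nan
        with pytest.raises(ValueError):
            cost_weighted_distance(friction_of(f), [0])


class TestNormalizedCorridor:
    def test_identities_random(self):
        rng = np.random.default_rng(5)
        f = rng.uniform(0.1, 1.0, size=(9, 9))
        fr = friction_of(f)
        ca = cost_weighted_distance(fr, [0])
        cb = cost_weighted_distance(fr, [80])
        lcd, nlcc = normalized_corridor(ca, cb)
        assert np.nanmin(nlcc.values) == pytest.approx(0.0)
        assert (nlcc.values >= -1e-9).all()
        assert lcd == pytest.approx(np.nanmin(ca.values + cb.values))

    def test_uniform_3x3_matches_oracle(self):
        f = np.ones((3, 3))
        fr = friction_of(f)
        ca = cost_weighted_distance(fr, [0])
        cb = cost_weighted_distance(fr, [8])
        lcd, nlcc = normalized_corridor(ca, cb)
        oa = brute_dijkstra_cwd(f, 250.0, [(0, 0)])
        ob = brute_dijkstra_cwd(f, 250.0, [(2, 2)])
        assert np.allclose(nlcc.values, oa + ob - np.min(oa + ob))
        # the diagonal is the least-cost path
        assert nlcc.values[1, 1] == pytest.approx(0.0)

    def test_linearity_under_friction_scaling(self):
        rng = np.random.default_rng(6)
        f = rng.uniform(0.2, 1.0, size=(8, 8))
        out = []
        for scale in (1.0, 2.0):
            fr = friction_of(scale * f)
            ca = cost_weighted_distance(fr, [0])
            cb = cost_weighted_distance(fr, [63])
            out.append(normalized_corridor(ca, cb))
        assert out[1][0] == pytest.approx(2 * out[0][0])
        assert np.allclose(out[1][1].values, 2 * out[0][1].values)

    def test_disjoint_regions_rejected(self):
        f = np.ones((3, 3))
        f[:, 1] = np.nan  # wall
        fr = friction_of(f)
        ca = cost_weighted_distance(fr, [0])
        cb = cost_weighted_distance(fr, [2])
        with pytest.raises(ValueError, match="reachable"):
            normalized_corridor(ca, cb)


class TestMosaicAndCrop:
    def test_single_input_identity(self):
        r = make_raster(np.arange(9.0).reshape(3, 3))
        assert np.array_equal(mosaic_minimum([r]).values, r.values)

    def test_cellwise_min_and_nodata_rule(self):
        a = make_raster([[1.0, np.nan], [5.0, 2.0]])
        b = make_raster([[3.0, 4.0], [np.nan, 1.0]])
        m = mosaic_minimum([a, b])
        assert m.values[0, 0] == 1.0 and m.values[0, 1] == 4.0
        assert m.values[1, 0] == 5.0 and m.values[1, 1] == 1.0

    def test_permutation_invariance(self):
        rng = np.random.default_rng(7)
        rs = [make_raster(rng.uniform(size=(5, 5))) for _ in range(4)]
        m1 = mosaic_minimum(rs)
        m2 = mosaic_minimum(rs[::-1])
        assert np.array_equal(m1.values, m2.values)

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValueError):
            mosaic_minimum([make_raster(np.ones((3, 3))), make_raster(np.ones((4, 4)))])

    def test_crop_inclusive(self):
        m = make_raster([[1.0, 2.0, 3.0]])
        out = crop_corridors(m, 2.0)
        assert out.values[0, 0] == 1.0 and out.values[0, 1] == 2.0
        assert np.isnan(out.values[0, 2])

    def test_crop_infinite_unchanged(self):
        m = make_raster([[1.0, 5.0]])
        assert np.array_equal(crop_corridors(m, np.inf).values, m.values)

    def test_crop_all_above_warns(self):
        with pytest.warns(UserWarning):
            out = crop_corridors(make_raster([[10.0, 20.0]]), 5.0)
        assert np.isnan(out.values).all()


class TestBuildCorridors:
    def test_road_scenario_reduces_corridor_area(self, small_config, small_stack):
        """With strongly negative road coefficients the corridor area within
        a fixed CWD budget cannot exceed the no-roads counterfactual's."""
        tm = true_selection_model(
            small_stack, {"canopy": 0.05, "dist_highway": 3.0, "dist_gravel": 1.0}
        )
        fa = friction_from_surface(prediction_surface(tm, small_stack))
        fn = friction_from_surface(no_roads_surface(tm, small_stack), scenario="no_roads")
        cores_w = extract_cores(
            prediction_surface(true_selection_model(small_stack, small_config.beta_rsf_winter), small_stack),
            min_cells=30,
        )
        cores_s = extract_cores(
            prediction_surface(true_selection_model(small_stack, small_config.beta_rsf_summer), small_stack),
            min_cells=30,
        )
        cut = 2000.0
        cs = build_corridors(fa, cores_w, cores_s, cwd_cutoff=cut)
        cn = build_corridors(fn, cores_w, cores_s, cwd_cutoff=cut)
        area_a = np.isfinite(cs.cropped().values).sum()
        area_n = np.isfinite(cn.cropped().values).sum()
        assert area_a <= area_n
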