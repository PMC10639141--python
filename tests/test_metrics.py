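import numpy as np
import pytest

import oracles
from forestagb.metrics import (
    DemGrid,
    MetricConfig,
    PointCloud,
    aih_percentiles,
    clip_to_plot,
    density_metrics,
    extract_features,
    height_percentiles,
    moment_metrics,
    normalize_heights,
)
from forestagb.synthetic import (
    PlotInventory,
    SimConfig,
    TreeRecord,
    denormalize_cloud,
    simulate_point_cloud,
    tilted_dem,
)


def _cloud(z, normalized=True, rng=None):
    z = np.asarray(z, dtype=float)
    rng = rng or np.random.default_rng(0)
    return PointCloud(
        x=rng.uniform(0, 40, z.size), y=rng.uniform(0, 40, z.size), z=z, normalized=normalized
    )


class TestHeightPercentiles:
    def test_single_point_every_percentile_equal(self):
        vals = height_percentiles(np.array([7.0]), [10, 50, 95])
        assert all(v == 7.0 for v in vals.values())

    def test_median_of_five(self):
        assert height_percentiles(np.arange(3.0, 8.0), [50])["H_p50"] == 5.0

    def test_p100_is_max(self):
        z = np.array([2.5, 9.0, 4.0])
        assert height_percentiles(z, [100])["H_p100"] == 9.0

    def test_nondecreasing_in_p(self, rng):
        z = rng.uniform(2, 30, 200)
        vals = list(height_percentiles(z, [1, 25, 50, 75, 99]).values())
        assert vals == sorted(vals)


class TestAIH:
    def test_uniform_heights_all_equal(self):
        vals = aih_percentiles(np.full(9, 6.0), [10, 50, 90])
        assert all(v == 6.0 for v in vals.values())

    def test_three_point_hand_case(self):
        # cumulative sums 3, 7, 12 against thresholds 3 (25%) and 6 (50%)
        out = aih_percentiles(np.array([3.0, 4.0, 5.0]), [25, 50])
        assert out["AIH_p25"] == 3.0
        assert out["AIH_p50"] == 4.0

    def test_p100_is_max(self):
        assert aih_percentiles(np.array([3.0, 4.0, 5.0]), [100])["AIH_p100"] == 5.0


class TestMoments:
    def test_constant_sample_degenerate_dispersion(self):
        out = moment_metrics(np.full(5, 4.2))
        assert out["H_std"] == 0.0 and out["H_mad"] == 0.0
        assert out["H_sqrt"] == pytest.approx(out["H_mean"])

    def test_two_point_hand_case(self):
        out = moment_metrics(np.array([3.0, 5.0]))
        assert out["H_mean"] == 4.0
        assert out["H_sqrt"] == pytest.approx(np.sqrt(17.0))

    def test_kurtosis_of_large_normal_sample_near_three(self, rng):
        z = rng.normal(10.0, 1.0, 200_000)
        assert moment_metrics(z)["H_curt"] == pytest.approx(3.0, abs=0.1)

    def test_single_point_flags_dispersion_missing(self):
        out = moment_metrics(np.array([7.0]))
        assert np.isnan(out["H_std"]) and np.isnan(out["H_curt"])
        assert out["H_mean"] == 7.0


class TestDensities:
    def test_all_below_cutoff_gives_zeros(self):
        out = density_metrics(np.array([0.1, 0.5, 1.9]), cutoff=2.0)
        assert list(out.values()) == [0.0] * 10

    def test_uniform_layers_each_about_a_tenth(self, rng):
        z = rng.uniform(2.0001, 30.0, 100_000)
        out = density_metrics(z, cutoff=2.0)
        assert list(out.values()) == pytest.approx([0.1] * 10, abs=0.01)

    def test_default_arity_is_ten(self, rng):
        out = density_metrics(rng.uniform(0, 20, 100), cutoff=2.0)
        assert len(out) == 10

    def test_sum_equals_above_fraction_exactly(self, rng):
        z = rng.uniform(0, 25, 500)
        out = density_metrics(z, cutoff=2.0, denominator="all")
        assert sum(out.values()) == pytest.approx(np.mean(z > 2.0), abs=1e-12)
        out2 = density_metrics(z, cutoff=2.0, denominator="above_cutoff")
        assert sum(out2.values()) == pytest.approx(1.0, abs=1e-12)


class TestBruteForceAgreement:
    """Every metric family vs. the loop-based oracle on 100 random small clouds."""

    def test_all_families(self, rng):
        percentiles = [5, 25, 50, 75, 95]
        for _ in range(100):
            n = int(rng.integers(2, 51))
            z = rng.uniform(0.0, 30.0, n)
            above = z[z > 2.0]
            if above.size >= 2:
                hp = height_percentiles(above, percentiles)
                for p in percentiles:
                    assert hp[f"H_p{p}"] == pytest.approx(
                        oracles.percentile_linear(above.tolist(), p), rel=1e-9
                    )
                ap = aih_percentiles(above, percentiles)
                for p in percentiles:
                    assert ap[f"AIH_p{p}"] == pytest.approx(
                        oracles.aih(above.tolist(), p), rel=1e-9
                    )
                mm = moment_metrics(above)
                ref = oracles.moments(above.tolist())
                for key, val in ref.items():
                    assert mm[key] == pytest.approx(val, rel=1e-9), key
            for denom in ("all", "above_cutoff"):
                dm = density_metrics(z, 2.0, 10, denom)
                ref_d = oracles.densities(z.tolist(), 2.0, 10, denom)
                assert list(dm.values()) == pytest.approx(ref_d, rel=1e-9, abs=1e-12)


class TestNormalization:
    def test_flat_dem_identity(self, rng):
        cloud = _cloud(rng.uniform(0, 20, 50), normalized=False)
        dem = DemGrid(values=np.zeros((5, 5)), x0=-1.0, y0=-1.0, cell_size=12.0)
        out = normalize_heights(cloud, dem)
        assert out.normalized
        np.testing.assert_allclose(out.z, cloud.z)

    def test_constant_offset(self, rng):
        cloud = _cloud(np.full(20, 715.0), normalized=False)
        dem = DemGrid(values=np.full((4, 4), 700.0), x0=-1.0, y0=-1.0, cell_size=15.0)
        np.testing.assert_allclose(normalize_heights(cloud, dem).z, 15.0)

    def test_tilted_plane_round_trip_recovers_truth(self, rng):
        plot = PlotInventory(
            plot_id="p", side_length=40.0,
            trees=(TreeRecord("larch", 25.0, 20.0, 20.0, 20.0),),
        )
        config = SimConfig(n_plots=1, seed=5)
        truth = simulate_point_cloud(plot, config, rng=np.random.default_rng(5))
        grid, x0, y0, cs = tilted_dem(plot)
        raw = denormalize_cloud(truth, (grid, x0, y0, cs))
        recovered = normalize_heights(raw, DemGrid(values=grid, x0=x0, y0=y0, cell_size=cs))
        np.testing.assert_allclose(recovered.z, truth.z, atol=1e-6)

    def test_points_outside_dem_error_reports_count(self):
        cloud = PointCloud(x=np.array([100.0, 0.5]), y=np.array([100.0, 0.5]),
                           z=np.array([1.0, 2.0]))
        dem = DemGrid(values=np.zeros((3, 3)), x0=0.0, y0=0.0, cell_size=1.0)
        with pytest.raises(ValueError, match="1 point"):
            normalize_heights(cloud, dem)

    def test_double_normalization_rejected(self, rng):
        cloud = _cloud(rng.uniform(0, 5, 10), normalized=True)
        dem = DemGrid(values=np.zeros((3, 3)), x0=0.0, y0=0.0, cell_size=30.0)
        with pytest.raises(ValueError, match="already"):
            normalize_heights(cloud, dem)


class TestClip:
    def test_full_cover_is_identity(self, rng):
        cloud = _cloud(rng.uniform(0, 10, 30))
        out = clip_to_plot(cloud, [(-1, -1), (41, -1), (41, 41), (-1, 41)])
        assert len(out) == len(cloud)

    def test_disjoint_polygon_empty(self, rng):
        cloud = _cloud(rng.uniform(0, 10, 30))
        out = clip_to_plot(cloud, [(100, 100), (110, 100), (110, 110), (100, 110)])
        assert len(out) == 0

    def test_unit_square_hand_points(self):
        cloud = PointCloud(
            x=np.array([0.5, 0.0, 1.0, 1.5, -0.1]),
            y=np.array([0.5, 0.0, 1.0, 0.5, 0.5]),
            z=np.zeros(5),
        )
        square = [(0, 0), (1, 0), (1, 1), (0, 1)]
        out = clip_to_plot(cloud, square)
        expected = [
            oracles.point_in_polygon(x, y, square) for x, y in zip(cloud.x, cloud.y)
        ]
        assert len(out) == sum(expected) == 3

    def test_degenerate_polygon_rejected(self, rng):
        with pytest.raises(ValueError):
            clip_to_plot(_cloud(np.zeros(3)), [(0, 0), (1, 1), (2, 2)])


class TestExtractFeatures:
    def test_default_registry_has_56_metrics(self, rng):
        cloud = _cloud(rng.uniform(0, 25, 2000))
        vec = extract_features(cloud)
        assert len(vec) == 56

    def test_deterministic_on_identical_clouds(self, rng):
        z = rng.uniform(0, 25, 500)
        a = extract_features(_cloud(z)).values
        b = extract_features(_cloud(z)).values
        assert a == b

    def test_height_metrics_scale_and_densities_do_not(self, rng):
        z = rng.uniform(3, 25, 2000)  # keep everything above the cutoff after scaling
        base = extract_features(_cloud(z)).values
        scaled = extract_features(_cloud(2.0 * z)).values
        for name in base:
            if name.startswith(("H_p", "AIH_p")) or name in ("H_mean", "H_sqrt", "H_median"):
                assert scaled[name] == pytest.approx(2.0 * base[name], rel=1e-6), name
        # density ratios are exactly scale-free once the cutoff scales too
        # (the layers span [cutoff, max z], so the partition is homothetic)
        scaled_cut = extract_features(_cloud(2.0 * z), MetricConfig(height_cutoff=4.0)).values
        for i in range(1, 11):
            assert scaled_cut[f"d{i}"] == pytest.approx(base[f"d{i}"], abs=1e-12)

    def test_unnormalized_or_empty_cloud_rejected(self, rng):
        with pytest.raises(ValueError, match="normalized"):
            extract_features(_cloud(np.ones(5), normalized=False))
        empty = PointCloud(x=np.array([]), y=np.array([]), z=np.array([]), normalized=True)
        with pytest.raises(ValueError, match="empty"):
            extract_features(empty)

    def test_invariant_order_relations(self, rng):
        vec = extract_features(_cloud(rng.uniform(0, 25, 3000))).values
        assert vec["H_min"] <= vec["H_median"] <= vec["H_max"]
        ps = [vec[f"H_p{p}"] for p in (1, 25, 50, 75, 99)]
        assert ps == sorted(ps)
        aihs = [vec[f"AIH_p{p}"] for p in (1, 25, 50, 75, 99)]
        assert aihs == sorted(aihs)
        dsum = sum(vec[f"d{i}"] for i in range(1, 11))
        assert dsum <= 1.0 + 1e-12
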