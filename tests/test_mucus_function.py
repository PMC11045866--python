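"""Mucus growth rate and bead-penetrability quantification."""

import numpy as np
import pandas as pd
import pytest

from mucoflow.mucus_function import (
    BeadCloud,
    bead_distances,
    distance_distribution,
    growth_rate,
    mucus_surface,
    penetrability,
    penetrability_per_mouse,
)


def thickness_frame(t0_sites, t45_sites, mouse="m1"):
    rows = []
    for site, v in enumerate(t0_sites, 1):
        rows.append((mouse, site, 0.0, v))
    for site, v in enumerate(t45_sites, 1):
        rows.append((mouse, site, 45.0, v))
    return pd.DataFrame(rows, columns=["mouse_id", "site", "time_min",
                                       "thickness_um"])


class TestGrowthRate:
    def test_two_um_per_min(self):
        frame = thickness_frame([80] * 5, [170] * 5)
        assert growth_rate(frame)["m1"] == pytest.approx(2.0)

    def test_no_change_is_zero(self):
        frame = thickness_frame([90] * 5, [90] * 5)
        assert growth_rate(frame)["m1"] == 0.0

    def test_sitewise_hand_values(self):
        frame = thickness_frame([100, 110, 90, 105, 95],
                                [190, 200, 180, 195, 185])
        assert growth_rate(frame)["m1"] == pytest.approx(2.0)

    def test_linear_in_uniform_late_shift(self):
        base = thickness_frame([100, 110, 90, 105, 95],
                               [190, 200, 180, 195, 185])
        shifted = base.copy()
        late = shifted["time_min"] == 45.0
        shifted.loc[late, "thickness_um"] += 45.0  # +1 um/min
        assert growth_rate(shifted)["m1"] == pytest.approx(
            growth_rate(base)["m1"] + 1.0
        )

    def test_single_timepoint_rejected(self):
        frame = thickness_frame([80] * 5, [])
        with pytest.raises(ValueError, match="two timepoints"):
            growth_rate(frame)


def flat_cloud(z_values, z0=0.0, mouse="m1", image="i1"):
    n = len(z_values)
    beads = pd.DataFrame({
        "x_um": np.linspace(0, 100, n),
        "y_um": np.linspace(0, 100, n),
        "z_um": z_values,
    })
    return BeadCloud(image, mouse, beads, epithelium=z0)


class TestBeadDistances:
    def test_flat_plane(self):
        cloud = flat_cloud([12.0, 0.0, 30.0])
        np.testing.assert_allclose(bead_distances(cloud), [12.0, 0.0, 30.0])

    def test_tilted_plane_hand_geometry(self, rng):
        a, b, c = 0.1, -0.05, 20.0
        x = rng.uniform(0, 100, 20)
        y = rng.uniform(0, 100, 20)
        d_true = rng.uniform(0, 50, 20)
        beads = pd.DataFrame({"x_um": x, "y_um": y,
                              "z_um": a * x + b * y + c + d_true})
        cloud = BeadCloud("i", "m", beads, epithelium=(a, b, c))
        np.testing.assert_allclose(bead_distances(cloud), d_true, atol=1e-10)

    def test_gridded_surface_interpolation(self):
        # bilinear-compatible height field sampled on a grid
        xs, ys = np.meshgrid(np.arange(0, 101, 10), np.arange(0, 101, 10))
        grid = pd.DataFrame({
            "x_um": xs.ravel(), "y_um": ys.ravel(),
            "h_um": 5.0 + 0.2 * xs.ravel(),
        })
        beads = pd.DataFrame({"x_um": [15.0], "y_um": [35.0], "z_um": [30.0]})
        cloud = BeadCloud("i", "m", beads, epithelium=grid)
        assert bead_distances(cloud)[0] == pytest.approx(30 - (5 + 3), abs=1e-9)

    def test_bead_outside_grid_rejected(self):
        grid = pd.DataFrame({"x_um": [0, 10, 0, 10], "y_um": [0, 0, 10, 10],
                             "h_um": [1.0, 1.0, 1.0, 1.0]})
        beads = pd.DataFrame({"x_um": [50.0], "y_um": [50.0], "z_um": [5.0]})
        cloud = BeadCloud("i", "m", beads, epithelium=grid)
        with pytest.raises(ValueError, match="domain"):
            bead_distances(cloud)

    def test_translation_invariance(self, rng):
        z = rng.uniform(0, 100, 60)
        d0 = bead_distances(flat_cloud(z, z0=0.0))
        d1 = bead_distances(flat_cloud(z + 37.0, z0=37.0))
        np.testing.assert_allclose(d0, d1, atol=1e-10)


class TestMucusSurface:
    def test_single_occupied_bin(self):
        d = np.full(100, 62.0)
        assert mucus_surface(d) == pytest.approx(62.5)

    def test_taller_far_mode_wins(self):
        d = np.concatenate([np.full(60, 12.0), np.full(80, 92.0)])
        assert mucus_surface(d) == pytest.approx(92.5)

    def test_tie_broken_toward_lumen(self):
        d = np.concatenate([np.full(50, 12.0), np.full(50, 92.0)])
        assert mucus_surface(d) == pytest.approx(92.5)

    def test_too_few_beads_recommends_fixed_surface(self):
        with pytest.raises(ValueError, match="surface"):
            mucus_surface(np.full(10, 50.0))

    def test_planted_surface_recovered_within_one_bin(self):
        from mucoflow.synthetic_data import SimConfig, gen_bead_cloud

        hits = 0
        n_seeds = 50
        for seed in range(n_seeds):
            cloud, _ = gen_bead_cloud(SimConfig(seed=seed), 700)
            est = mucus_surface(bead_distances(cloud))
            hits += abs(est - 120.0) <= 5.0
        assert hits >= int(0.95 * n_seeds)


class TestPenetrability:
    def test_all_beads_far_gives_zero(self):
        d = np.concatenate([np.full(100, 50.0), np.full(100, 92.0)])
        cloud = flat_cloud(d)
        res = penetrability(cloud, surface_um=95.0)
        assert res.fraction_within_zone == 0.0

    def test_all_beads_close_gives_one(self):
        cloud = flat_cloud(np.full(100, 5.0))
        res = penetrability(cloud, surface_um=100.0)
        assert res.fraction_within_zone == 1.0
        assert res.n_beads_in_mucus == 100

    def test_negative_and_above_surface_excluded(self):
        z = np.concatenate([[-5.0, -1.0], np.full(50, 5.0), [120.0, 130.0]])
        cloud = flat_cloud(z)
        res = penetrability(cloud, surface_um=100.0)
        assert res.n_beads_negative == 2
        assert res.n_beads_above_surface == 2
        assert res.n_beads_in_mucus == 50

    def test_fraction_invariant_to_z_translation(self, rng):
        z = rng.uniform(0, 119, 400)
        r0 = penetrability(flat_cloud(z), surface_um=120.0)
        r1 = penetrability(flat_cloud(z + 55.0, z0=55.0), surface_um=120.0)
        assert r0.fraction_within_zone == pytest.approx(r1.fraction_within_zone)

    def test_fraction_decreases_with_penetration_depth(self):
        from mucoflow.mucus_function import penetrability as pen
        from mucoflow.synthetic_data import SimConfig, gen_bead_cloud

        means = []
        for lam in (10.0, 30.0, 90.0):
            vals = []
            for seed in range(20):
                cloud, _ = gen_bead_cloud(
                    SimConfig(seed=seed, bead_lambda=lam), 600
                )
                vals.append(pen(cloud).fraction_within_zone)
            means.append(np.mean(vals))
        assert means[0] > means[1] > means[2]

    def test_per_mouse_mean_over_images(self):
        r1 = penetrability(flat_cloud(np.full(100, 5.0), image="a"),
                           surface_um=100.0)
        r2 = penetrability(flat_cloud(np.full(100, 50.0), image="b"),
                           surface_um=100.0)
        per = penetrability_per_mouse([r1, r2])
        assert per["m1"] == pytest.approx(0.5)


class TestDistanceDistribution:
    def test_single_bead(self):
        cloud = flat_cloud(np.full(60, 7.0))
        res = penetrability(cloud, surface_um=50.0)
        table = distance_distribution([res])
        assert table.loc["m1", "median_um"] == 7.0
        assert table.loc["m1", "q1_um"] == 7.0

    def test_uniform_1_to_100(self):
        cloud = flat_cloud(np.arange(1.0, 101.0))
        res = penetrability(cloud, surface_um=200.0)
        table = distance_distribution([res])
        assert table.loc["m1", "median_um"] == pytest.approx(50.5)

    def test_pooled_quartiles_linear_interpolation(self):
        c1 = flat_cloud(np.array([1.0, 2.0, 3.0] * 20), image="a")
        c2 = flat_cloud(np.array([4.0, 5.0] * 30), image="b")
        r1 = penetrability(c1, surface_um=10.0)
        r2 = penetrability(c2, surface_um=10.0)
        table = distance_distribution([r1, r2])
        pooled = np.concatenate([[1.0, 2.0, 3.0] * 20, [4.0, 5.0] * 30])
        q1, med, q3 = np.percentile(pooled, [25, 50, 75])
        assert table.loc["m1", "q1_um"] == pytest.approx(q1)
        assert table.loc["m1", "median_um"] == pytest.approx(med)
        assert table.loc["m1", "q3_um"] == pytest.approx(q3)

    def test_group_pooling_requires_map(self):
        cloud = flat_cloud(np.full(60, 7.0))
        res = penetrability(cloud, surface_um=50.0)
        with pytest.raises(ValueError, match="group"):
            distance_distribution([res], by="group")
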