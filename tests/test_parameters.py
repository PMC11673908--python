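"""Cluster statistics, geometry parameters and the Balance Index."""

import numpy as np
import pytest

from cyclogait import (
    balance_index,
    calibrate_bi_scale,
    cluster_stats,
    compute_parameters,
    geometry_parameters,
    healthy_template,
)
from cyclogait.errors import CalibrationError, ClusteringError
from cyclogait.parameters import PARAM_NAMES


def template_clusters(template=None, offset=(0.0, 0.0), scale=1.0):
    """Degenerate two-point clusters sitting exactly at the template means."""
    means = (template or healthy_template()).cluster_means()
    off = np.asarray(offset)
    return {lab: np.vstack([m, m]) * scale + off for lab, m in means.items()}


class TestClusterStats:
    def test_identical_points_have_zero_scatter(self):
        s = cluster_stats([[0.3, 0.4]] * 5, "A_L")
        assert s.sigma_x == s.sigma_y == s.area == 0.0
        assert s.mean == pytest.approx([0.3, 0.4])

    def test_hand_computed_square(self):
        # var of {0,0,2,2} with n-1 denominator = 4/3
        s = cluster_stats([(0, 0), (0, 2), (2, 0), (2, 2)])
        assert s.sigma_x == pytest.approx(1.1547, abs=1e-4)
        assert s.sigma_y == pytest.approx(1.1547, abs=1e-4)
        assert s.area == pytest.approx(4.0 / 3.0)

    def test_area_scales_quadratically(self, rng):
        pts = rng.normal(size=(30, 2))
        k = 2.5
        assert cluster_stats(pts * k).area == pytest.approx(k**2 * cluster_stats(pts).area)

    def test_fewer_than_two_points_is_error(self):
        with pytest.raises(ClusteringError):
            cluster_stats([[1.0, 2.0]])


class TestBalanceIndex:
    def test_zero_scatter_gives_zero_bi_and_na_percents(self):
        with pytest.warns(UserWarning, match="percent"):
            res = balance_index(template_clusters())
        assert res.bi_raw == 0.0 and res.bi == 0.0
        assert all(np.isnan(v) for v in res.percent.values())

    def test_quadratic_scaling_and_percent_sum(self, rng):
        clusters = {lab: rng.normal(size=(8, 2)) for lab in template_clusters()}
        res = balance_index(clusters)
        k = 3.0
        scaled = balance_index({lab: pts * k for lab, pts in clusters.items()})
        assert scaled.bi_raw == pytest.approx(k**2 * res.bi_raw, rel=1e-12)
        assert sum(res.percent.values()) == pytest.approx(100.0, abs=1e-9)

    def test_missing_cluster_named_in_error(self):
        clusters = template_clusters()
        del clusters["C_RL"]
        with pytest.raises(ClusteringError, match="C_RL"):
            balance_index(clusters)

    def test_monte_carlo_matches_planted_sigma_products(self):
        # 10 000 strides of Gaussian scatter: BI within 2% of sum of planted areas
        rng = np.random.default_rng(7)
        sigmas = {lab: (0.01 + 0.002 * i, 0.02 - 0.001 * i) for i, lab in enumerate(template_clusters())}
        clusters = {
            lab: rng.normal([0.0, 0.5], sigmas[lab], size=(10_000, 2)) for lab in sigmas
        }
        planted = sum(sx * sy for sx, sy in sigmas.values())
        assert balance_index(clusters).bi_raw == pytest.approx(planted, rel=0.02)


class TestCalibrateBiScale:
    def test_raw_threshold_half_gives_scale_200(self):
        # optimal threshold = midpoint of the separation gap = 0.5
        assert calibrate_bi_scale([0.6, 0.7], [0.3, 0.4]) == pytest.approx(200.0)

    def test_gap_midpoint_from_brute_force_example(self):
        assert calibrate_bi_scale([2.0, 3.0], [0.5, 1.0]) == pytest.approx(100.0 / 1.5)

    def test_identical_groups_is_calibration_error(self):
        with pytest.raises(CalibrationError):
            calibrate_bi_scale([1.0, 1.0], [1.0, 1.0])

    def test_calibrated_threshold_sits_at_100(self, rng):
        from cyclogait.cohort_stats import optimal_threshold, roc_curve

        d = rng.lognormal(1.0, 0.5, size=40)
        h = rng.lognormal(0.0, 0.5, size=50)
        scale = calibrate_bi_scale(d, h)
        thr, _ = optimal_threshold(roc_curve(d * scale, h * scale))
        assert thr == pytest.approx(100.0, rel=1e-9)


class TestGeometryParameters:
    def test_template_geometry_recovered_exactly(self):
        tpl = healthy_template()
        geom = geometry_parameters(template_clusters(tpl))
        assert geom["AB"] == pytest.approx(0.027, abs=1e-12)
        assert geom["BC"] == pytest.approx(0.288, abs=1e-12)
        assert geom["Ra"] == pytest.approx(0.288 / 0.027, rel=1e-9)
        assert geom["ap_B"] == pytest.approx(0.810)
        assert geom["ap_C"] == pytest.approx(0.564, abs=1e-12)

    def test_colinear_ratio(self):
        clusters = template_clusters()
        # place A, B and the C markers on one vertical line: AB=0.1, BC=0.3
        for lab, y in (("A_L", 1.0), ("A_R", 1.0), ("B_L", 0.9), ("B_R", 0.9),
                       ("C_LR", 0.6), ("C_RL", 0.6)):
            clusters[lab] = np.array([[0.0, y]] * 2)
        geom = geometry_parameters(clusters)
        assert geom["Ra"] == pytest.approx(3.0)

    def test_pythagorean_distance(self):
        clusters = template_clusters()
        clusters["A_L"] = np.array([[0.0, 4.0]] * 2)
        clusters["B_L"] = np.array([[3.0, 0.0]] * 2)
        clusters["A_R"] = np.array([[0.0, 4.0]] * 2)
        clusters["B_R"] = np.array([[3.0, 0.0]] * 2)
        assert geometry_parameters(clusters)["AB"] == pytest.approx(5.0)

    def test_zero_ab_makes_ra_undefined(self):
        clusters = template_clusters()
        clusters["A_L"] = clusters["B_L"].copy()
        clusters["A_R"] = clusters["B_R"].copy()
        with pytest.raises(ZeroDivisionError, match="Ra"):
            geometry_parameters(clusters)


class TestInvariances:
    def test_translation_leaves_distances_and_bi_unchanged(self, rng):
        clusters = {lab: rng.normal(m, 0.01, size=(6, 2))
                    for lab, m in healthy_template().cluster_means().items()}
        base = compute_parameters(clusters)
        moved = compute_parameters({lab: pts + [0.3, -0.2] for lab, pts in clusters.items()})
        for name in ("AE", "BD", "AB", "BC", "CD", "DE", "Ra", "Rp", "BI"):
            assert getattr(moved, name) == pytest.approx(getattr(base, name), rel=1e-9)
        assert moved.ap_A == pytest.approx(base.ap_A - 0.2, rel=1e-9)

    def test_scaling_laws(self, rng):
        clusters = {lab: rng.normal(m, 0.01, size=(6, 2))
                    for lab, m in healthy_template().cluster_means().items()}
        k = 1.7
        base = compute_parameters(clusters)
        scaled = compute_parameters({lab: pts * k for lab, pts in clusters.items()})
        assert scaled.AB == pytest.approx(k * base.AB, rel=1e-12)
        assert scaled.Ra == pytest.approx(base.Ra, rel=1e-12)
        assert scaled.Rp == pytest.approx(base.Rp, rel=1e-12)
        assert scaled.BI == pytest.approx(k**2 * base.BI, rel=1e-12)

    def test_distance_chain_does_not_sum_to_gait_line(self):
        # markers are not colinear, so AB + BD + DE != AE
        geom = geometry_parameters(template_clusters())
        assert geom["AB"] + geom["BD"] + geom["DE"] != pytest.approx(geom["AE"], rel=1e-3)

    def test_parameter_vector_has_all_fifteen_names(self):
        vec = compute_parameters(template_clusters(scale=2.0, offset=(0.01, 0.0)))
        assert list(vec.to_series().index) == PARAM_NAMES
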