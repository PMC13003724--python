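import numpy as np
import pytest

from aawss.mesh import cylinder_profile, make_vessel_mesh
from aawss.metrics import CycleSpec, HemodynamicFields, compute_fields
from aawss.risk import (DEFAULT_BINS, BELOW_RANGE, RiskThresholds,
                        bin_parameter, extract_patches, jaccard,
                        joint_risk_mask, roi_summary)
from aawss.synth import LesionSpec, synth_wss_series
from aawss.waveform import make_waveform


def make_fields(mesh, tawss, osi, ecap, rrt):
    n = mesh.n_nodes
    full = lambda v: np.full(n, float(v)) if np.isscalar(v) else np.asarray(v)
    return HemodynamicFields(mesh=mesh, tawss=full(tawss), osi=full(osi),
                             ecap=full(ecap), rrt=full(rrt),
                             undefined_osi=np.zeros(n, bool),
                             infinite_rrt=np.zeros(n, bool))


class TestBinParameter:
    def test_interior_value(self):
        labels, over = bin_parameter([0.3], DEFAULT_BINS["tawss"])
        assert labels[0] == "0-0.5"
        assert not over[0]

    def test_boundary_goes_to_upper_bin(self):
        labels, _ = bin_parameter([0.35], DEFAULT_BINS["osi"])
        assert labels[0] == "0.35-0.5"

    def test_top_bin_closed_and_overflow_flagged(self):
        labels, over = bin_parameter([30.0, 40.0], DEFAULT_BINS["rrt"])
        assert list(labels) == ["24-30", "24-30"]
        assert list(over) == [False, True]

    def test_below_range_labeled(self):
        labels, _ = bin_parameter([10.0], DEFAULT_BINS["rrt"])
        assert labels[0] == BELOW_RANGE


class TestJointMask:
    def test_consistent_quadruple_inside_criterion(self, tiny_mesh):
        # quadruple satisfying ECAP = OSI/TAWSS, RRT = 1/((1-2 OSI) TAWSS)
        f = make_fields(tiny_mesh, 0.23, 0.42, 0.42 / 0.23,
                        1 / ((1 - 0.84) * 0.23))
        assert joint_risk_mask(f).all()

    def test_ecap_below_range_excluded(self, tiny_mesh):
        f = make_fields(tiny_mesh, 0.30, 0.40, 0.40 / 0.30, 25.0)
        assert not joint_risk_mask(f).any()  # ECAP 1.33 < 1.6

    def test_mask_equals_brute_force_and_of_conditions(self, tiny_mesh):
        rng = np.random.default_rng(0)
        n = tiny_mesh.n_nodes
        f = make_fields(tiny_mesh, rng.uniform(0, 1, n),
                        rng.uniform(0, 0.5, n), rng.uniform(0, 2.5, n),
                        rng.uniform(10, 40, n))
        mask = joint_risk_mask(f)
        brute = np.array([
            0 <= f.tawss[i] <= 0.5 and 0.35 <= f.osi[i] <= 0.5
            and 1.6 <= f.ecap[i] <= 2.0 and 24 <= f.rrt[i] <= 30
            for i in range(n)])
        assert np.array_equal(mask, brute)

    def test_flagged_nodes_always_false(self, tiny_mesh):
        f = make_fields(tiny_mesh, 0.23, 0.42, 1.83, 27.0)
        flagged = HemodynamicFields(
            mesh=f.mesh, tawss=f.tawss, osi=f.osi, ecap=f.ecap, rrt=f.rrt,
            undefined_osi=np.ones(tiny_mesh.n_nodes, bool),
            infinite_rrt=np.zeros(tiny_mesh.n_nodes, bool))
        assert not joint_risk_mask(flagged).any()


class TestPatches:
    def test_empty_mask_zero_patches(self, cyl_mesh):
        rmap = extract_patches(np.zeros(cyl_mesh.n_nodes, bool), cyl_mesh)
        assert rmap.patches == [] and rmap.dropped == []

    def test_single_triangle_forms_one_patch(self, cyl_mesh):
        mask = np.zeros(cyl_mesh.n_nodes, bool)
        tri = cyl_mesh.triangles[0]
        mask[tri] = True
        rmap = extract_patches(mask, cyl_mesh, min_area=0.0)
        assert len(rmap.patches) == 1
        assert set(rmap.patches[0]["nodes"]) == set(tri.tolist())
        assert rmap.patches[0]["area_m2"] == pytest.approx(
            cyl_mesh.node_areas[tri].sum())

    def test_partition_of_mask_before_min_area_filter(self, cyl_mesh):
        rng = np.random.default_rng(1)
        mask = rng.random(cyl_mesh.n_nodes) < 0.3
        rmap = extract_patches(mask, cyl_mesh, min_area=0.0)
        all_nodes = np.concatenate([p["nodes"] for p in rmap.patches])
        assert sorted(all_nodes.tolist()) == sorted(
            np.flatnonzero(mask).tolist())
        assert len(all_nodes) == len(set(all_nodes.tolist()))

    def test_patches_sorted_by_area_descending(self, cyl_mesh):
        mask = np.zeros(cyl_mesh.n_nodes, bool)
        mask[:40] = True    # big band
        mask[500:503] = True  # small cluster
        rmap = extract_patches(mask, cyl_mesh, min_area=0.0)
        areas = [p["area_m2"] for p in rmap.patches]
        assert areas == sorted(areas, reverse=True)

    def test_min_area_moves_speckle_to_dropped(self, cyl_mesh):
        mask = np.zeros(cyl_mesh.n_nodes, bool)
        mask[0] = True
        rmap = extract_patches(mask, cyl_mesh, min_area=25e-6)
        assert rmap.patches == []
        assert len(rmap.dropped) == 1


@pytest.fixture(scope="module")
def planted():
    mesh = make_vessel_mesh(cylinder_profile(0.012), 0.12, 32, 48)
    wave = make_waveform("generic_aortic", cycles=3)
    lesions = [
        LesionSpec(center=(0.012, 0.0, 0.035), geodesic_radius=0.01),
        LesionSpec(center=(-0.012, 0.0, 0.09), geodesic_radius=0.01),
    ]
    series = synth_wss_series(mesh, wave, base_tawss=1.5,
                              lesions=lesions, seed=5)
    fields = compute_fields(series)
    return mesh, series, fields


class TestEndToEnd:
    def test_two_disjoint_lesions_recovered_as_two_patches(self, planted):
        mesh, series, fields = planted
        mask = joint_risk_mask(fields)
        rmap = extract_patches(mask, mesh, fields)
        assert len(rmap.patches) == 2
        gts = series.ground_truth["lesions"]
        # match patches to ground truth by best overlap
        for gt in gts:
            best = max(rmap.patches,
                       key=lambda p: jaccard(p["nodes"], gt["nodes"]))
            assert jaccard(best["nodes"], gt["nodes"]) >= 0.9

    def test_roi_summary_returns_planted_bins(self, planted):
        _, series, fields = planted
        gt = series.ground_truth["lesions"][0]
        bins = roi_summary(fields, gt["nodes"])
        assert bins == {"tawss": "0-0.5", "osi": "0.35-0.5",
                        "ecap": "1.6-2", "rrt": "24-30"}

    def test_roi_straddling_background_takes_majority_bins(self, planted):
        mesh, series, fields = planted
        gt = series.ground_truth["lesions"][0]
        lesion_nodes = gt["nodes"]
        bg = np.setdiff1d(np.arange(mesh.n_nodes), np.concatenate(
            [g["nodes"] for g in series.ground_truth["lesions"]]))
        # ~70/30 lesion/background by node count (areas are near-uniform)
        n_bg = max(1, int(len(lesion_nodes) * 0.4))
        roi = np.r_[lesion_nodes, bg[:n_bg]]
        assert roi_summary(fields, roi)["tawss"] == "0-0.5"

    def test_empty_roi_rejected(self, planted):
        _, _, fields = planted
        with pytest.raises(ValueError, match="empty"):
            roi_summary(fields, np.array([], dtype=int))


def test_healthy_uniform_tube_has_empty_joint_mask(cyl_mesh):
    wave = make_waveform("generic_aortic", cycles=3)
    series = synth_wss_series(cyl_mesh, wave, base_tawss=1.5, seed=0)
    fields = compute_fields(series)
    assert not joint_risk_mask(fields).any()


def test_thresholds_validate_joint_bin_membership():
    with pytest.raises(ValueError, match="joint"):
        RiskThresholds(joint={"tawss": (0.0, 0.7), "osi": (0.35, 0.5),
                              "ecap": (1.6, 2.0), "rrt": (24.0, 30.0)})
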