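import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from vasotherm.domain import Material, VoxelGrid
from vasotherm.errors import CouplingError
from vasotherm.fixtures import make_three_layer_toy
from vasotherm.soi import (
    Mollifier,
    build_coupling_map,
    calibrate_constant,
    load_coupling_json,
    mollifier_value,
    save_coupling_json,
)

T = int(Material.TISSUE)


def tissue_grid(shape, spacing=(1e-3, 1e-3, 1e-3)):
    return VoxelGrid(shape, spacing, np.full(shape, T, dtype=np.int8))


class TestMollifierValue:
    def test_compact_support_boundary_and_beyond(self):
        m = Mollifier(epsilon=2e-3, C=1.0)
        assert mollifier_value(np.array([2e-3, 0.0, 0.0]), m) == 0.0
        assert mollifier_value(np.array([3e-3, 0.0, 0.0]), m) == 0.0

    def test_center_value(self):
        # at r = 0 the bump is exp(-1), scaled by C / eps^n
        m = Mollifier(epsilon=2e-3, C=3.5)
        expected = 3.5 / (2e-3) ** 3 * math.exp(-1.0)
        assert mollifier_value(np.zeros(3), m) == pytest.approx(expected, rel=1e-14)

    def test_half_radius_ratio(self):
        # eta(0.5)/eta(0) = exp(1/(0.25-1) + 1) = exp(-1/3)
        m = Mollifier(epsilon=1e-2, C=1.0)
        ratio = (mollifier_value(np.array([5e-3, 0, 0]), m)
                 / mollifier_value(np.zeros(3), m))
        assert ratio == pytest.approx(math.exp(-1.0 / 3.0), rel=1e-12)

    @given(st.floats(0.0, 0.99), st.floats(0.001, 0.99))
    def test_radially_decreasing(self, f1, gap):
        m = Mollifier(epsilon=1e-2, C=1.0)
        f2 = min(f1 + gap, 1.0)
        v1 = mollifier_value(np.array([f1 * 1e-2, 0, 0]), m)
        v2 = mollifier_value(np.array([0, f2 * 1e-2, 0]), m)
        assert v1 >= v2  # radially symmetric, non-increasing in |r|


class TestCalibration:
    def test_discrete_normalization_exact(self):
        grid = tissue_grid((7, 7, 3))
        pos = grid.centers()[grid.linear_index(3, 3, 1)]
        eps = 3.2e-3
        C = calibrate_constant(grid, pos, eps)
        m = Mollifier(eps, C)
        centers = grid.centers()
        total = sum(
            mollifier_value(centers[i] - pos, m) * grid.voxel_volume
            for i in range(grid.n_voxels)
        )
        assert total == pytest.approx(1.0, abs=1e-12)

    def test_single_voxel_soi_weight_is_one(self):
        grid = tissue_grid((3, 3, 1))
        pos = grid.centers()[grid.linear_index(1, 1, 0)]
        C = calibrate_constant(grid, pos, 0.9e-3)  # below spacing: only itself
        m = Mollifier(0.9e-3, C)
        w = mollifier_value(np.zeros(3), m) * grid.voxel_volume
        assert w == pytest.approx(1.0, abs=1e-14)

    def test_halving_voxel_volume_doubles_C(self):
        big = tissue_grid((5, 5, 1), spacing=(1e-3, 1e-3, 2e-3))
        small = tissue_grid((5, 5, 1), spacing=(1e-3, 1e-3, 1e-3))
        # same in-plane centers; z-centers differ but the displacement to a
        # terminal placed at each grid's own plane is identical
        eps = 2.5e-3
        C_big = calibrate_constant(big, big.centers()[big.linear_index(2, 2, 0)], eps)
        C_small = calibrate_constant(
            small, small.centers()[small.linear_index(2, 2, 0)], eps)
        assert C_small == pytest.approx(2.0 * C_big, rel=1e-12)

    def test_empty_soi_raises(self):
        grid = tissue_grid((3, 3, 3))
        with pytest.raises(CouplingError, match="empty"):
            calibrate_constant(grid, (-10e-3, -10e-3, -10e-3), 1e-3)


class TestCouplingMap:
    def test_weights_sum_to_one_and_decrease_with_distance(self, toy_problem):
        from vasotherm.soi import build_coupling_map

        cm = build_coupling_map(
            toy_problem.grid, toy_problem.arterial, toy_problem.venous,
            toy_problem.epsilon,
        )
        centers = toy_problem.grid.centers()
        for (kind, tid), (idx, w) in cm.weights.items():
            assert w.sum() == pytest.approx(1.0, abs=1e-12)
            assert np.all(w >= 0)
            tree = toy_problem.arterial if kind == "artery" else toy_problem.venous
            pos = tree.nodes[tid].position
            d = np.linalg.norm(centers[idx] - pos, axis=1)
            assert np.all(d < cm.epsilon)
            order = np.argsort(d)
            # non-increasing in distance, up to round-off on near-ties
            assert np.all(np.diff(w[order]) <= 1e-12)

    def test_full_coverage_on_toy(self, toy_problem):
        cm = build_coupling_map(
            toy_problem.grid, toy_problem.arterial, toy_problem.venous,
            toy_problem.epsilon,
        )
        assert cm.coverage["arterial_source_fraction"] == 1.0
        assert cm.coverage["venous_sink_fraction"] == 1.0

    def test_translation_invariance(self):
        """Shifting terminal and voxel centers together leaves the
        normalized weights unchanged (only relative geometry matters)."""
        spacing = (1e-3, 1e-3, 1e-3)
        grid = tissue_grid((12, 12, 1), spacing)
        eps = 2.7e-3  # support fully interior at both placements
        pos1 = grid.centers()[grid.linear_index(4, 4, 0)] + np.array([2e-4, -1e-4, 0.0])
        pos2 = pos1 + np.array([2e-3, 1e-3, 0.0])  # shift by whole voxels
        from vasotherm.soi import _raw_quadrature

        idx1, raw1 = _raw_quadrature(grid, pos1, eps, grid.tissue_linear)
        idx2, raw2 = _raw_quadrature(grid, pos2, eps, grid.tissue_linear)
        np.testing.assert_allclose(
            np.sort(raw1 / raw1.sum()), np.sort(raw2 / raw2.sum()), atol=1e-13
        )

    def test_tiny_epsilon_on_terminal_voxel_center(self):
        prob = make_three_layer_toy(10, 10, 2)
        tid = prob.arterial.terminals[0]
        # place epsilon below half the min spacing: SoI would be empty
        with pytest.raises(CouplingError, match=tid):
            build_coupling_map(prob.grid, prob.arterial, prob.venous, 20e-6)

    def test_json_round_trip(self, toy_problem, tmp_path):
        cm = build_coupling_map(
            toy_problem.grid, toy_problem.arterial, toy_problem.venous,
            toy_problem.epsilon,
        )
        path = tmp_path / "coupling.json"
        save_coupling_json(cm, path)
        back = load_coupling_json(path)
        assert back.terminals() == cm.terminals()
        for key in cm.terminals():
            np.testing.assert_array_equal(back.weights[key][0], cm.weights[key][0])
            np.testing.assert_allclose(back.weights[key][1], cm.weights[key][1],
                                       rtol=1e-15)
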