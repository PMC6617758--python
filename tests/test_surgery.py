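"""Cut-plane parameterization and component placement."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

import tkabalance as tk
from tkabalance import ParameterError, SurgicalParams


class TestSurgicalParams:
    def test_neutral_plan(self, anatomy):
        p = tk.neutral_params(anatomy)
        assert p.vv_femur == 0.0
        assert p.vv_tibia == 0.0
        assert p.ext_rot_femur == 0.0
        assert p.post_slope == 3.0
        assert p.gap == anatomy.implant_thickness == 26.0

    def test_out_of_range_warns_not_fails(self):
        with pytest.warns(UserWarning):
            SurgicalParams(vv_tibia=8.0)

    def test_round_trip(self):
        p = SurgicalParams(vv_femur=1, vv_tibia=-2, ext_rot_femur=3,
                           post_slope=4, gap=22)
        assert SurgicalParams.from_dict(p.to_dict()) == p


class TestCutPlanes:
    def test_zero_rotation_normals_parallel_to_mechanical_axis(self, model):
        with pytest.warns(UserWarning):  # slope 0 is outside the sweep range
            p = SurgicalParams(post_slope=0.0)
        cuts = tk.compute_cut_planes(p, model)
        u = model.hip_center_femur - model.knee_center_femur
        u /= np.linalg.norm(u)
        assert abs(cuts.femoral_normal @ u + 1) < 1e-9   # points distally
        assert abs(cuts.tibial_normal @ [0, 1, 0] - 1) < 1e-9

    def test_tibial_varus_rotation_magnitude(self, model):
        with pytest.warns(UserWarning):
            p = SurgicalParams(vv_tibia=3.0, post_slope=0.0)
        cuts = tk.compute_cut_planes(p, model)
        ang = np.degrees(np.arccos(np.clip(cuts.tibial_normal @ [0, 1, 0], -1, 1)))
        assert ang == pytest.approx(3.0, abs=1e-9)

    def test_sequential_rotations_match_composed_matrix_oracle(self, model):
        p = SurgicalParams(vv_tibia=2.0, post_slope=5.0)
        cuts = tk.compute_cut_planes(p, model)
        oracle = (Rotation.from_rotvec(np.deg2rad(2.0) * np.array([1.0, 0, 0]))
                  * Rotation.from_rotvec(np.deg2rad(5.0) * np.array([0.0, 0, 1]))
                  ).apply([0.0, 1.0, 0.0])
        assert np.allclose(cuts.tibial_normal, oracle, atol=1e-12)


class TestPlacement:
    def test_neutral_is_deterministic_fixed_point(self, model, anatomy):
        p = tk.neutral_params(anatomy)
        cuts = tk.compute_cut_planes(p, model)
        a = tk.place_components(cuts, p, model)
        b = tk.place_components(cuts, p, model)
        assert np.allclose(a.placement.rotation, b.placement.rotation, atol=0)
        assert np.allclose(a.placement.translation, b.placement.translation,
                           atol=0)
        La = a.ligament_lengths(0.0)
        Lb = b.ligament_lengths(0.0)
        for name in La:
            assert La[name] == pytest.approx(Lb[name], abs=1e-12)

    def test_gap_increase_lengthens_both_ligaments(self, model, anatomy):
        p = tk.neutral_params(anatomy)
        m0 = tk.place_components(tk.compute_cut_planes(p, model), p, model)
        p2 = p.replace(gap=p.gap + 2.0)
        m2 = tk.place_components(tk.compute_cut_planes(p2, model), p2, model)
        L0, L2 = m0.ligament_lengths(0.0), m2.ligament_lengths(0.0)
        assert L2["MCL"] > L0["MCL"]
        assert L2["LCL"] > L0["LCL"]

    def test_gap_monotonicity_over_sweep_range(self, model, anatomy):
        p = tk.neutral_params(anatomy)
        for name in ("MCL", "LCL"):
            prev = -np.inf
            for gap in np.arange(18.0, 29.0, 2.0):
                pg = p.replace(gap=gap)
                m = tk.place_components(tk.compute_cut_planes(pg, model), pg, model)
                L = m.ligament_lengths(0.0)[name]
                assert L >= prev
                prev = L

    def test_lowering_medial_plateau_stretches_mcl(self, model, anatomy):
        """The frontal-plane cut rotation that lowers the medial tibial
        plateau (relative to the femur) lengthens the MCL and shortens
        the LCL; checked against a brute-force attachment-distance
        oracle."""
        p = tk.neutral_params(anatomy)
        placed = {}
        for vv in (-3.0, 0.0, 3.0):
            pv = p.replace(vv_tibia=vv)
            placed[vv] = tk.place_components(
                tk.compute_cut_planes(pv, model), pv, model)
        # medial plateau sample point, tibia frame (left knee: medial = +Z)
        plateau = np.array([0.0, 0.0, 40.0])
        heights = {vv: m.placement.apply(plateau)[1] for vv, m in placed.items()}
        lowering = min((-3.0, 3.0), key=lambda vv: heights[vv])
        raising = -lowering

        def oracle_lengths(m):
            # direct attachment-distance recomputation
            anat = m.anatomy
            T = m.placement
            o = anat.mcl_origin
            via_w = T.apply(anat.mcl_via)
            ins_w = T.apply(anat.mcl_insertion)
            mcl = np.linalg.norm(via_w - o) + np.linalg.norm(ins_w - via_w)
            lcl = np.linalg.norm(T.apply(anat.lcl_insertion) - anat.lcl_origin)
            return mcl, lcl

        mcl_low, lcl_low = oracle_lengths(placed[lowering])
        mcl_0, lcl_0 = oracle_lengths(placed[0.0])
        mcl_hi, lcl_hi = oracle_lengths(placed[raising])
        assert mcl_low > mcl_0 > mcl_hi
        assert lcl_low < lcl_0 < lcl_hi
        # model's own lengths agree with the oracle
        assert placed[lowering].ligament_lengths(0.0)["MCL"] == pytest.approx(
            mcl_low, abs=1e-9)

    def test_frontal_plane_antisymmetry(self, model, anatomy):
        p = tk.neutral_params(anatomy)
        grads = {}
        for name in ("MCL", "LCL"):
            L = []
            for vv in np.arange(-3.0, 4.0, 1.0):
                pv = p.replace(vv_tibia=vv)
                m = tk.place_components(tk.compute_cut_planes(pv, model), pv, model)
                L.append(m.ligament_lengths(0.0)[name])
            diffs = np.diff(L)
            assert np.all(diffs > 0) or np.all(diffs < 0)
            grads[name] = np.sign(diffs[0])
        assert grads["MCL"] == -grads["LCL"]

    def test_external_rotation_leaves_extension_placement(self, model, anatomy):
        """Femoral external rotation acts about the mechanical axis, so
        the full-extension tibia placement is unchanged; only the hinge
        (hence flexed poses) differs."""
        p = tk.neutral_params(anatomy)
        m0 = tk.place_components(tk.compute_cut_planes(p, model), p, model)
        p6 = p.replace(ext_rot_femur=6.0)
        m6 = tk.place_components(tk.compute_cut_planes(p6, model), p6, model)
        L0, L6 = m0.ligament_lengths(0.0), m6.ligament_lengths(0.0)
        assert L0["MCL"] == pytest.approx(L6["MCL"], abs=1e-9)
        Lf0, Lf6 = m0.ligament_lengths(60.0), m6.ligament_lengths(60.0)
        assert abs(Lf0["MCL"] - Lf6["MCL"]) > 0.05

    def test_nonpositive_gap_rejected(self, model, anatomy):
        p = tk.neutral_params(anatomy)
        with pytest.warns(UserWarning):
            bad = p.replace(gap=-1.0)
        cuts = tk.compute_cut_planes(bad, model)
        with pytest.raises(ParameterError):
            tk.place_components(cuts, bad, model)
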