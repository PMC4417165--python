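"""Base-frame fitting, helical decomposition, chi conformers, globals."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from mmdna import (
    analyze_structure,
    analyze_trajectory,
    build_duplex,
    chi_state,
    fiber_b_table,
    fit_base_frame,
    global_descriptors,
    inter_bp_params,
    intra_bp_params,
    sequence_for,
)
from mmdna.bases import RING_ATOMS, STANDARD_BASES, standard_coords
from mmdna.frames import BaseFrame, classify_chi, pair_frame
from mmdna.simulate import EnsembleSpec, sample_trajectory
from mmdna.structure import Trajectory


def _atoms_dict(base, R=np.eye(3), t=np.zeros(3)):
    return {n: R @ xyz + t for n, xyz in STANDARD_BASES[base].items()}


class TestFitBaseFrame:
    def test_planted_rigid_motion_recovered_exactly(self):
        R = Rotation.from_euler("zyx", [31, -14, 77], degrees=True).as_matrix()
        t = np.array([2.0, -1.0, 5.5])
        frame = fit_base_frame(_atoms_dict("G", R, t), "G")
        assert np.allclose(frame.rotation, R, atol=1e-10)
        assert np.allclose(frame.origin, t, atol=1e-10)
        assert frame.rms_fit == pytest.approx(0.0, abs=1e-10)

    def test_noisy_fit_matches_independent_oracle(self, rng):
        """Under sigma = 0.01 A isotropic noise the fitted rotation equals
        an independent least-squares superposition (scipy align_vectors)
        and stays within 1 deg of the planted rotation.  The out-of-plane
        axes of a planar ring are the poorly conditioned directions, so the
        angular error is dominated by them (~0.2 deg typical at this
        noise)."""
        R = Rotation.from_euler("zyx", [10, 40, -30], degrees=True).as_matrix()
        ref = standard_coords("A", RING_ATOMS["A"])
        worst = 0.0
        for _ in range(20):
            atoms = _atoms_dict("A", R, np.zeros(3))
            noisy = {n: xyz + rng.normal(scale=0.01, size=3)
                     for n, xyz in atoms.items()}
            frame = fit_base_frame(noisy, "A")
            obs = np.array([noisy[n] for n in RING_ATOMS["A"]])
            oracle, _ = Rotation.align_vectors(obs - obs.mean(0),
                                               ref - ref.mean(0))
            assert np.allclose(frame.rotation, oracle.as_matrix(), atol=1e-8)
            delta = Rotation.from_matrix(frame.rotation.T @ R)
            worst = max(worst, np.degrees(np.linalg.norm(delta.as_rotvec())))
        assert worst < 1.0

    def test_two_atoms_underdetermined(self):
        atoms = {n: STANDARD_BASES["A"][n] for n in ("N9", "C8")}
        with pytest.raises(ValueError, match=">= 3"):
            fit_base_frame(atoms, "A")

    def test_unknown_base_rejected(self):
        with pytest.raises(ValueError, match="unknown base"):
            fit_base_frame(_atoms_dict("A"), "X")

    def test_emitted_rotations_are_proper(self, rng, at_control):
        from conftest import random_table
        st = build_duplex(at_control, random_table(rng))
        an = analyze_structure(st)
        for R in an.pair_rot[0]:
            assert abs(np.linalg.det(R) - 1.0) < 1e-8
            assert np.max(np.abs(R @ R.T - np.eye(3))) < 1e-8


class TestPairDecomposition:
    def test_identity_pair_gives_zeros(self):
        w = BaseFrame(origin=np.zeros(3), rotation=np.eye(3))
        c = w.flipped()  # flipping back inside the decomposition -> identity
        p = intra_bp_params(w, c)
        assert np.allclose(p.as_array(), 0.0, atol=1e-12)

    @pytest.mark.parametrize("col,value", [(5, 10.0), (0, 1.0), (3, -25.0),
                                           (1, -0.8)])
    def test_single_planted_parameter_roundtrips(self, col, value, at_control):
        tab = fiber_b_table(13)
        tab.intra[6, col] = value
        an = analyze_structure(build_duplex(at_control, tab))
        expected = np.zeros(6)
        expected[col] = value
        assert np.allclose(an.intra[0, 6], expected, atol=1e-9)

    def test_fiber_step_parameters(self, fiber_structure):
        an = analyze_structure(fiber_structure)
        assert np.allclose(an.inter[0],
                           np.tile([0, 0, 3.38, 0, 0, 36.0], (12, 1)),
                           atol=1e-9)

    def test_identical_pair_frames_give_zero_step(self):
        f = BaseFrame(origin=np.array([1.0, 2.0, 3.0]),
                      rotation=Rotation.from_euler(
                          "z", 25, degrees=True).as_matrix())
        p = inter_bp_params(f, f)
        assert np.allclose(p.as_array(), 0.0, atol=1e-12)

    def test_non_orthonormal_frame_rejected(self):
        with pytest.raises(ValueError, match="orthonormal"):
            BaseFrame(origin=np.zeros(3), rotation=np.eye(3) * 1.001)


class TestChi:
    @pytest.mark.parametrize("chi,conf", [
        (-117.0, "anti"), (60.0, "syn"), (-75.0, "high-anti"),
        (150.0, "anti"), (100.0, "other"), (-30.0, "high-anti"),
    ])
    def test_bin_classification(self, chi, conf):
        assert classify_chi(chi) == conf

    def test_builder_realises_requested_chi(self, at_control):
        tab = fiber_b_table(13)
        tab.chi[:, 0] = -117.0
        tab.chi[:, 1] = 60.0
        st = build_duplex(at_control, tab)
        topo = st.topology
        for i in (0, 6, 12):
            res = topo.watson(i)
            atoms = {a: st.coords[res.atom_index(a)] for a in res.atom_names}
            state = chi_state(atoms, res.base)
            assert state.chi == pytest.approx(-117.0, abs=1e-8)
            assert state.conformer == "anti"
            res = topo.crick(i)
            atoms = {a: st.coords[res.atom_index(a)] for a in res.atom_names}
            state = chi_state(atoms, res.base)
            assert state.chi == pytest.approx(60.0, abs=1e-8)
            assert state.conformer == "syn"

    def test_missing_atom_rejected(self):
        atoms = _atoms_dict("A")  # no O4'
        with pytest.raises(ValueError, match="chi atom"):
            chi_state(atoms, "A")


class TestGlobalDescriptors:
    def _pair_frames(self, structure):
        an = analyze_structure(structure)
        return [BaseFrame(origin=an.pair_org[0, i], rotation=an.pair_rot[0, i])
                for i in range(an.n_pairs)]

    def test_straight_build_has_zero_bend(self, fiber_structure):
        g = global_descriptors(self._pair_frames(fiber_structure))
        assert g.helical_bend == pytest.approx(0.0, abs=1e-6)

    def test_single_central_roll_bends_by_that_angle(self, at_control):
        """Rotation-composition oracle: one 20 deg roll kink between two
        straight arms separates their axes by 20 deg."""
        tab = fiber_b_table(13)
        tab.inter[6, 4] = 20.0
        g = global_descriptors(
            self._pair_frames(build_duplex(at_control, tab)))
        assert g.helical_bend == pytest.approx(20.0, abs=0.5)

    def test_total_twist_full_range(self, fiber_structure):
        g = global_descriptors(self._pair_frames(fiber_structure),
                               step_range=(0, 12))
        assert g.total_twist == pytest.approx(432.0, abs=1e-9)

    def test_default_range_excludes_terminal_pairs(self, fiber_structure):
        g = global_descriptors(self._pair_frames(fiber_structure))
        assert g.step_range == (1, 11)
        assert g.total_twist == pytest.approx(360.0, abs=1e-9)

    def test_bend_bounds_on_random_builds(self, rng, at_control):
        from conftest import random_table
        for _ in range(10):
            st = build_duplex(at_control, random_table(rng, rot=40.0))
            g = global_descriptors(self._pair_frames(st))
            assert 0.0 <= g.helical_bend <= 180.0

    def test_too_few_steps_rejected(self, fiber_structure):
        with pytest.raises(ValueError, match="steps"):
            global_descriptors(self._pair_frames(fiber_structure),
                               step_range=(5, 7))


class TestAnalyzeTrajectory:
    def test_identical_frames_have_zero_sd(self, fiber_structure):
        traj = Trajectory(fiber_structure.topology,
                          np.repeat(fiber_structure.coords[None], 5, axis=0))
        an = analyze_trajectory(traj)
        s = an.summary()
        assert np.allclose(s["sd"].to_numpy(), 0.0, atol=1e-9)

    def test_gaussian_ensemble_mean_within_3_se(self):
        """Sampled means agree with the planted table to 3 SE."""
        seq = sequence_for("f1", "A", "A")
        tab = fiber_b_table(13)
        var = np.zeros(6 * 13 + 6 * 12)
        tw_col = 6 * 13 + 5 * 6 + 5  # twist of step 5
        var[tw_col] = 16.0
        spec = EnsembleSpec(sequence=seq, table=tab, covariance=var,
                            n_frames=800, seed=21)
        an = analyze_trajectory(sample_trajectory(spec))
        se = 4.0 / np.sqrt(800)
        assert abs(an.inter[:, 5, 5].mean() - 36.0) <= 3 * se

    def test_topology_mismatch_rejected(self, fiber_structure):
        topo = fiber_structure.topology
        bad = np.repeat(fiber_structure.coords[None], 2, axis=0)[:, :-1, :]
        with pytest.raises(Exception):
            analyze_trajectory(Trajectory(topo, bad))

    def test_chi_conformer_fractions_sum_to_one(self, fiber_structure):
        traj = Trajectory(fiber_structure.topology,
                          fiber_structure.coords[None])
        an = analyze_trajectory(traj)
        f = an.chi_conformer_fractions()
        sums = f.groupby(["strand", "pair"])["fraction"].sum()
        assert np.allclose(sums.to_numpy(), 1.0)
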