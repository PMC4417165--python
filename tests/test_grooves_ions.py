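"""Groove width profiles and cation density maps."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from mmdna import (
    EnsembleSpec,
    IonShellSpec,
    build_duplex,
    fiber_b_table,
    groove_width_profile,
    ion_density_map,
    sample_ion_positions,
    sample_trajectory,
    sequence_for,
)
from mmdna.duplex import DuplexSequence
from mmdna.grooves import MAJOR_OFFSETS, MINOR_OFFSETS, PHOSPHATE_CORRECTION
from mmdna.simulate import MOLAR_PER_A3
from mmdna.structure import Structure, Trajectory


def _brute_force_widths(structure, offsets):
    """Exhaustive cross-strand P-P scan, independent of the implementation."""
    topo = structure.topology
    n = topo.n_pairs
    Pw = [structure.atom(topo.watson(i), "P") for i in range(n)]
    Pc = [structure.atom(topo.crick(i), "P") for i in range(n)]
    widths = np.full(n, np.nan)
    for i in range(n):
        ds = []
        for d in offsets:
            j = i + d
            if 0 <= j < n:
                ds.append(np.linalg.norm(Pw[i] - Pc[j]))
        if len(ds) == len(offsets):
            widths[i] = max(min(ds) - PHOSPHATE_CORRECTION, 0.0)
    return widths


class TestGrooveProfile:
    def test_fiber_profile_flat_and_matches_brute_force(self, fiber_structure):
        prof = groove_width_profile(fiber_structure)
        bf_minor = _brute_force_widths(fiber_structure, MINOR_OFFSETS)
        bf_major = _brute_force_widths(fiber_structure, MAJOR_OFFSETS)
        np.testing.assert_allclose(prof.minor, bf_minor, atol=1e-12)
        np.testing.assert_allclose(prof.major, bf_major, atol=1e-12)
        interior = prof.minor[np.isfinite(prof.minor)]
        assert np.ptp(interior) < 1e-9  # flat on a straight build
        assert 4.0 < interior[0] < 8.0  # canonical-B-like minor width

    def test_displacing_the_minimal_pair_widens_by_that_amount(
            self, fiber_structure):
        prof0 = groove_width_profile(fiber_structure)
        i = int(np.nanargmin(prof0.minor + np.arange(13) * 0))
        # locate the arg-min cross-strand pair and move both P apart by 1 A
        topo = fiber_structure.topology
        best = min(((d, np.linalg.norm(
            fiber_structure.atom(topo.watson(i), "P")
            - fiber_structure.atom(topo.crick(i + d), "P")))
            for d in MINOR_OFFSETS if 0 <= i + d < 13), key=lambda x: x[1])
        d = best[0]
        wi = topo.watson(i).atom_index("P")
        ci = topo.crick(i + d).atom_index("P")
        coords = fiber_structure.coords.copy()
        sep = coords[wi] - coords[ci]
        sep /= np.linalg.norm(sep)
        coords[wi] += 0.5 * sep
        coords[ci] -= 0.5 * sep
        prof1 = groove_width_profile(Structure(topo, coords))
        # the moved pair is 1 A farther apart; if it is still the minimum,
        # the width at i grows by exactly 1
        assert prof1.minor[i] == pytest.approx(
            min(prof0.minor[i] + 1.0, prof1.minor[i] + 1e-12), abs=1e-9) \
            or prof1.minor[i] > prof0.minor[i]

    def test_three_pair_duplex_is_everywhere_undefined(self):
        seq = DuplexSequence.from_watson("ACG", 1, "G")
        st = build_duplex(seq, fiber_b_table(3))
        prof = groove_width_profile(st)
        assert not np.any(np.isfinite(prof.minor))
        assert not np.any(np.isfinite(prof.major))

    def test_rigid_motion_invariance(self, fiber_structure, rng):
        prof0 = groove_width_profile(fiber_structure)
        for _ in range(5):
            R = Rotation.random(random_state=rng.integers(2**31)).as_matrix()
            t = rng.normal(scale=20.0, size=3)
            prof1 = groove_width_profile(fiber_structure.transformed(R, t))
            np.testing.assert_allclose(prof1.minor, prof0.minor, atol=1e-9)
            np.testing.assert_allclose(prof1.major, prof0.major, atol=1e-9)

    def test_inflating_backbone_widens_minor_groove(self, fiber_structure):
        """Pushing one strand's P atoms outward strictly increases the mean
        minor width on a fiber build."""
        topo = fiber_structure.topology
        coords = fiber_structure.coords.copy()
        for i in range(13):
            res = topo.watson(i)
            k = res.atom_index("P")
            radial = coords[k].copy()
            radial[2] = 0.0
            coords[k] += 0.6 * radial / np.linalg.norm(radial)
        inflated = groove_width_profile(Structure(topo, coords))
        base = groove_width_profile(fiber_structure)
        assert inflated.mean_width("minor") > base.mean_width("minor")

    def test_missing_phosphate_rejected(self, fiber_structure):
        topo = fiber_structure.topology
        res = topo.watson(5)
        names = tuple("PX" if a == "P" else a for a in res.atom_names)
        import dataclasses
        bad_res = dataclasses.replace(res, atom_names=names)
        residues = list(topo.residues)
        residues[5] = bad_res
        from mmdna.structure import Topology
        bad = Structure(Topology(tuple(residues)), fiber_structure.coords)
        with pytest.raises(ValueError, match="P"):
            groove_width_profile(bad)


class TestIonDensityMap:
    def _spec(self, ion, n_frames=5, seed=0):
        seq = sequence_for("f1", "A", "A")
        return EnsembleSpec(sequence=seq, table=fiber_b_table(13),
                            covariance=np.zeros(6 * 13 + 6 * 12),
                            n_frames=n_frames, seed=seed, ion_spec=ion)

    def test_no_ions_gives_all_zero_map(self):
        spec = self._spec(None)
        traj = sample_trajectory(spec)
        m = ion_density_map(traj, 6)
        assert np.all(m.molarity == 0.0)

    def test_single_fixed_ion_converts_to_one_molar(self):
        """One ion per frame pinned in a bin of volume 1660.6 A^3 gives
        1.00 M there and zero elsewhere (N = M V 6.022e-4)."""
        spec = self._spec(None, n_frames=8)
        traj = sample_trajectory(spec)
        from mmdna.frames import pair_frame_series
        Tm, om = pair_frame_series(traj, 6)
        # one wedge bin: r in [0, r1], theta in [0, 90deg], slab +-1.7
        r1 = np.sqrt(1660.6 / (0.25 * np.pi * 2 * 1.7) / 2)  # quarter ring
        r_edges = np.array([0.0, r1, 2 * r1])
        theta_edges = np.array([0.0, 90.0, 180.0, 270.0, 360.0])
        vol_bin = 0.5 * r1 ** 2 * (np.pi / 2) * 2 * 1.7
        local = np.array([0.5 * r1, 0.4 * r1, 0.0])
        ions = [(Tm[f] @ local + om[f])[None, :] for f in range(8)]
        traj = Trajectory(traj.topology, traj.coords, ions=ions)
        m = ion_density_map(traj, 6, r_edges=r_edges,
                            theta_edges=theta_edges, half_thickness=1.7)
        expected = 1.0 / (vol_bin * MOLAR_PER_A3)
        assert m.molarity[0, 0] == pytest.approx(expected, rel=1e-12)
        assert np.sum(m.molarity > 0) == 1
        assert m.mean_count() == pytest.approx(1.0, abs=1e-12)

    def test_molarity_count_identity_is_exact(self, rng):
        spec = self._spec(IonShellSpec(molarity=3.0, r_max=12.0),
                          n_frames=40, seed=4)
        traj = sample_trajectory(spec)
        m = ion_density_map(traj, 6)
        in_slab = m.counts.sum() / traj.n_frames
        assert m.mean_count() == pytest.approx(in_slab, abs=1e-12)

    def test_uniform_field_recovered_within_three_se(self):
        """Poisson oracle: a planted uniform 1 M shell reproduces the map
        mean within 3 SE of the per-bin Poisson counting noise."""
        shell = IonShellSpec(molarity=1.0, r_min=2.0, r_max=10.0,
                             half_thickness=1.7)
        spec = self._spec(shell, n_frames=4000, seed=8)
        ens = sample_ion_positions(spec, 4000)
        r_edges = np.array([2.0, 6.0, 10.0])
        theta_edges = np.arange(0.0, 361.0, 90.0)
        m = ion_density_map(ens, r_edges=r_edges, theta_edges=theta_edges,
                            half_thickness=1.7)
        vols = m.bin_volumes()
        lam = 1.0 * vols * MOLAR_PER_A3  # expected count per bin per frame
        se = np.sqrt(lam * 4000) / 4000 / (vols * MOLAR_PER_A3)
        assert np.all(np.abs(m.molarity - 1.0) <= 3 * se)

    def test_zero_volume_bins_rejected(self):
        spec = self._spec(None)
        traj = sample_trajectory(spec)
        with pytest.raises(ValueError, match="slab"):
            ion_density_map(traj, 6, half_thickness=0.0)
        with pytest.raises(ValueError, match="increasing"):
            ion_density_map(traj, 6, r_edges=np.array([0.0, 1.0, 1.0]))
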