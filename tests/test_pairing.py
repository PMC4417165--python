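"""Hydrogen bonds, pairing-scheme occupancies and breathing statistics."""

import numpy as np
import pytest

from mmdna import (
    HBondCriteria,
    breathing_analysis,
    build_duplex,
    detect_hbonds,
    fiber_b_table,
    load_scheme_catalog,
    scheme_occupancies,
    sequence_for,
)
from mmdna.pairing import (
    STATE_CLOSED,
    STATE_OPEN_MAJOR,
    pair_hbonds,
)
from mmdna.structure import Trajectory

from conftest import (
    GG_SCHEME_C_INTRA,
    GG_SCHEME_W_INTRA,
    GT_WOBBLE_INTRA,
    OPENED_INTRA,
)


def _structure_with_lesion_intra(w, c, intra, env="f1"):
    seq = sequence_for(env, w, c)
    tab = fiber_b_table(13)
    if intra is not None:
        tab.intra[6] = intra
    return seq, build_duplex(seq, tab)


def _mixture_trajectory(w, c, intra_by_frame, env="f1"):
    seq = sequence_for(env, w, c)
    frames = []
    topo = None
    for intra in intra_by_frame:
        tab = fiber_b_table(13)
        tab.intra[6] = intra
        st = build_duplex(seq, tab)
        topo = st.topology
        frames.append(st.coords)
    return Trajectory(topo, np.stack(frames))


class TestDetectHbonds:
    def test_canonical_pairs_form_their_watson_crick_bonds(self):
        _, st = _structure_with_lesion_intra("A", "T", None, env="f2")
        hb = pair_hbonds(st, 6)
        atoms = {(h.donor[2], h.acceptor[2]) for h in hb}
        assert atoms == {("N6", "O4"), ("N3", "N1")}
        for h in hb:
            assert 2.5 < h.distance <= 3.5
            assert h.angle >= 135.0

    def test_distance_cutoff_excludes_far_contacts(self):
        # stretch the pair apart: N...O beyond 3.5 A disappears
        _, st = _structure_with_lesion_intra("A", "T", OPENED_INTRA, env="f2")
        assert pair_hbonds(st, 6) == []

    def test_angle_cutoff_is_applied(self):
        """Tightening theta_min above the actual bond angles removes
        bonds; loosening it keeps them."""
        _, st = _structure_with_lesion_intra("A", "T", None, env="f2")
        strict = pair_hbonds(st, 6, HBondCriteria(theta_min=179.0))
        loose = pair_hbonds(st, 6, HBondCriteria(theta_min=90.0))
        assert strict == []
        assert len(loose) >= 2

    def test_deterministic_order(self):
        _, st = _structure_with_lesion_intra("G", "C", None)
        assert detect_hbonds(st) == detect_hbonds(st)

    def test_wobble_geometry_forms_wobble_bonds(self):
        _, st = _structure_with_lesion_intra("G", "T", GT_WOBBLE_INTRA)
        atoms = {(h.donor[0], h.donor[2], h.acceptor[0], h.acceptor[2])
                 for h in pair_hbonds(st, 6)}
        assert ("A", "N1", "B", "O2") in atoms
        assert ("B", "N3", "A", "O6") in atoms


class TestSchemeOccupancies:
    def test_all_catalogs_load_and_validate(self):
        for w in "ACGT":
            for c in "ACGT":
                cat = load_scheme_catalog(w, c)
                assert cat.schemes

    def test_canonical_ensemble_is_fully_watson_crick(self):
        seq = sequence_for("f2", "A", "T")
        st = build_duplex(seq, fiber_b_table(13))
        traj = Trajectory(st.topology, np.repeat(st.coords[None], 4, axis=0))
        fractions, labels, prom = scheme_occupancies(traj, 6)
        assert fractions["AT_WC"] == 1.0
        assert fractions["unassigned"] == 0.0
        assert prom == 1
        assert set(labels) == {"AT_WC"}

    def test_seventy_thirty_mixture_recovered_exactly(self):
        """70% wobble-geometry frames, 30% opened frames -> occupancies
        0.70 / 0.30 by construction."""
        frames = [GT_WOBBLE_INTRA] * 7 + [OPENED_INTRA] * 3
        traj = _mixture_trajectory("G", "T", frames)
        fractions, labels, _ = scheme_occupancies(traj, 6)
        assert fractions["GT_wobble"] == pytest.approx(0.70)
        assert fractions["unassigned"] == pytest.approx(0.30)
        assert sum(fractions.values()) == pytest.approx(1.0, abs=1e-12)

    def test_mirrored_gg_schemes_recovered_within_binomial_error(self, rng):
        """A 50/50 Bernoulli mixture of the two mirrored G-G poses comes
        back symmetric within 3 binomial SE."""
        n = 400
        draws = rng.random(n) < 0.5
        frames = [GG_SCHEME_W_INTRA if d else GG_SCHEME_C_INTRA
                  for d in draws]
        traj = _mixture_trajectory("G", "G", frames)
        fractions, _, _ = scheme_occupancies(traj, 6)
        se = np.sqrt(0.25 / n)
        assert abs(fractions["GG_N1_O6_w"] - 0.5) <= 3 * se
        assert abs(fractions["GG_N1_O6_c"] - 0.5) <= 3 * se
        assert fractions["unassigned"] == 0.0

    def test_fractions_sum_to_one(self, rng):
        frames = [GT_WOBBLE_INTRA if rng.random() < 0.6 else OPENED_INTRA
                  for _ in range(30)]
        traj = _mixture_trajectory("G", "T", frames)
        fractions, _, _ = scheme_occupancies(traj, 6)
        assert sum(fractions.values()) == pytest.approx(1.0, abs=1e-12)

    def test_empty_trajectory_rejected(self):
        seq = sequence_for("f1", "G", "T")
        st = build_duplex(seq, fiber_b_table(13))
        traj = Trajectory(st.topology, st.coords[None][:0])
        with pytest.raises(ValueError, match="empty"):
            scheme_occupancies(traj, 6)


class TestBreathing:
    def test_run_length_example(self):
        """[C x5, O+ x3, C x2, O+ x2, C x8] -> 25% occupancy, 2
        transitions, mean residence 2.5 ps (dt = 1 ps), all major."""
        opening = np.zeros(20)
        opening[5:8] = 60.0
        opening[10:12] = 60.0
        tr = breathing_analysis(opening, frame_dt=1.0, reference=0.0,
                                threshold=45.0, min_frames=2)
        s = tr.summary()
        assert s["all"]["occupancy_pct"] == pytest.approx(25.0)
        assert s["all"]["n_transitions"] == 2
        assert s["all"]["mean_residence_time"] == pytest.approx(2.5)
        assert s["minor"]["occupancy_pct"] == 0.0
        assert s["major"]["n_transitions"] == 2

    def test_constant_series_never_breathes(self):
        tr = breathing_analysis(np.full(50, 3.0), reference=3.0)
        assert tr.occupancy_pct() == 0.0
        assert tr.n_transitions() == 0

    def test_single_frame_spikes_are_suppressed_by_hysteresis(self):
        opening = np.zeros(30)
        opening[10] = 90.0  # one frame only: below min_frames=2
        tr = breathing_analysis(opening, reference=0.0, min_frames=2)
        assert tr.occupancy_pct() == 0.0

    def test_direction_follows_excursion_sign(self):
        opening = np.zeros(20)
        opening[3:6] = 80.0
        opening[12:15] = -80.0
        tr = breathing_analysis(opening, reference=0.0)
        assert tr.n_transitions(STATE_OPEN_MAJOR) == 1
        assert tr.summary()["minor"]["n_transitions"] == 1

    def test_rle_summary_matches_brute_force_scan(self, rng):
        """Occupancy, transitions and residences from run-length encoding
        equal a per-frame brute-force scan on random binary series."""
        for _ in range(200):
            n = int(rng.integers(4, 120))
            raw = rng.random(n) < rng.uniform(0.1, 0.9)
            opening = np.where(raw, 90.0, 0.0)
            tr = breathing_analysis(opening, reference=0.0, threshold=45.0,
                                    min_frames=2)
            # brute force: mark frames open when in a >= 2-long raw run
            open_bf = np.zeros(n, dtype=bool)
            i = 0
            while i < n:
                if raw[i]:
                    j = i
                    while j < n and raw[j]:
                        j += 1
                    if j - i >= 2:
                        open_bf[i:j] = True
                    i = j
                else:
                    i += 1
            assert tr.occupancy_pct() == pytest.approx(
                100.0 * open_bf.sum() / n)
            trans_bf = int(np.sum(np.diff(
                np.concatenate([[0], open_bf.astype(int)])) == 1))
            assert tr.n_transitions() == trans_bf
            res_bf = []
            i = 0
            while i < n:
                if open_bf[i]:
                    j = i
                    while j < n and open_bf[j]:
                        j += 1
                    res_bf.append(j - i)
                    i = j
                else:
                    i += 1
            assert sorted(tr.residence_frames().tolist()) == sorted(res_bf)

    def test_planted_recall_and_false_positives(self, rng):
        """Amplitude >= 2x threshold with window >= min_frames: 100%
        recall; amplitude <= 0.5x threshold on noise sigma = threshold/6:
        no false positives."""
        thr = 45.0
        n = 2000
        noise = rng.normal(0.0, thr / 6.0, n)
        detected = 0
        for start in (100, 700, 1500):
            series = noise.copy()
            series[start:start + 10] += 2 * thr
            tr = breathing_analysis(series, reference=0.0, threshold=thr,
                                    min_frames=2)
            if np.all(tr.states[start:start + 10] != STATE_CLOSED):
                detected += 1
        assert detected == 3
        weak = noise.copy()
        weak[300:310] += 0.5 * thr
        tr = breathing_analysis(weak, reference=0.0, threshold=thr,
                                min_frames=2)
        assert tr.occupancy_pct() == 0.0

    def test_short_series_rejected(self):
        with pytest.raises(ValueError, match="shorter"):
            breathing_analysis(np.array([1.0]), min_frames=2)
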