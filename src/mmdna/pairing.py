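"""Hydrogen-bond detection, pairing-scheme classification and breathing.

The reduced-atom model carries no hydrogens, so donor geometry is judged
through idealized in-plane hydrogens constructed from the donor's bonding
environment (sp2 amines: two H at 120 deg from the attached ring atom; ring
N-H: one H opposite the ring-neighbour bisector).  A candidate donor to
acceptor contact is a hydrogen bond when the heavy-atom distance is at most
``d_max`` (default 3.5 A) and the angle at the constructed hydrogen is at
least ``theta_min`` (default 135 deg).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import yaml

from . import bases
from .structure import Residue, Structure, Trajectory

__all__ = [
    "HBondCriteria",
    "HBondObservation",
    "PairingScheme",
    "SchemeCatalog",
    "load_scheme_catalog",
    "detect_hbonds",
    "pair_hbonds",
    "scheme_occupancies",
    "BreathingTrace",
    "breathing_analysis",
]

N_H_BOND = 1.01  # idealized N-H length, A


@dataclass(frozen=True)
class HBondCriteria:
    d_max: float = 3.5
    theta_min: float = 135.0

    def __post_init__(self):
        if self.d_max <= 0 or not (0 <= self.theta_min <= 180):
            raise ValueError("invalid hydrogen-bond criteria")


@dataclass(frozen=True)
class HBondObservation:
    """One detected hydrogen bond (heavy-atom geometry, implicit H)."""

    donor: tuple[str, int, str]  # chain, residue number, atom
    acceptor: tuple[str, int, str]
    distance: float
    angle: float  # at the idealized hydrogen, deg


@dataclass(frozen=True)
class PairingScheme:
    """A named hydrogen-bonding topology across the two lesion bases.

    Bonds are "X:atom > Y:atom" donor -> acceptor strings with X, Y in
    {W, C} (lesion-pair Watson / Crick base; sugar O4' acceptors allowed).
    """

    scheme_id: str
    bonds: tuple[tuple[str, str, str, str], ...]  # (d_strand, d_atom, a_strand, a_atom)
    annotation: str = ""

    @classmethod
    def from_strings(cls, scheme_id: str, bonds: list[str],
                     annotation: str = "") -> "PairingScheme":
        parsed = []
        for b in bonds:
            try:
                left, right = (s.strip() for s in b.split(">"))
                ds, da = (s.strip() for s in left.split(":"))
                as_, aa = (s.strip() for s in right.split(":"))
            except ValueError:
                raise ValueError(f"malformed bond spec {b!r}") from None
            if ds not in "WC" or as_ not in "WC":
                raise ValueError(f"bond strands must be W or C: {b!r}")
            parsed.append((ds, da, as_, aa))
        if not parsed:
            raise ValueError(f"scheme {scheme_id} has no bonds")
        return cls(scheme_id, tuple(parsed), annotation)


@dataclass
class SchemeCatalog:
    """Ordered pairing schemes for one lesion base combination."""

    watson_base: str
    crick_base: str
    schemes: list[PairingScheme] = field(default_factory=list)

    def validate(self):
        for s in self.schemes:
            for ds, da, as_, aa in s.bonds:
                db = self.watson_base if ds == "W" else self.crick_base
                ab = self.watson_base if as_ == "W" else self.crick_base
                if da != bases.SUGAR_ACCEPTOR and da not in bases.DONORS[db]:
                    raise ValueError(
                        f"{s.scheme_id}: {da} is not a donor of {db}")
                ok_acc = aa == bases.SUGAR_ACCEPTOR or aa in bases.ACCEPTORS[ab]
                if not ok_acc:
                    raise ValueError(
                        f"{s.scheme_id}: {aa} is not an acceptor of {ab}")
        return self


def load_scheme_catalog(watson_base: str, crick_base: str) -> SchemeCatalog:
    """Load the shipped (editable) catalog for a lesion base combination."""
    name = f"{watson_base}{crick_base}.yaml"
    path = resources.files("mmdna").joinpath(f"data/schemes/{name}")
    raw = yaml.safe_load(path.read_text())
    schemes = [
        PairingScheme.from_strings(d["id"], d["bonds"], d.get("annotation", ""))
        for d in raw["schemes"]
    ]
    return SchemeCatalog(watson_base, crick_base, schemes).validate()


# ---------------------------------------------------------------------------
# hydrogen-bond geometry


def _plane_normal(coords: np.ndarray) -> np.ndarray:
    c = coords - coords.mean(axis=0)
    _, _, vt = np.linalg.svd(c)
    return vt[2]


def _rotate_about(v: np.ndarray, axis: np.ndarray, deg: float) -> np.ndarray:
    a = np.deg2rad(deg)
    axis = axis / np.linalg.norm(axis)
    return (v * np.cos(a) + np.cross(axis, v) * np.sin(a)
            + axis * np.dot(axis, v) * (1 - np.cos(a)))


def _donor_hydrogens(structure: Structure, res: Residue,
                     donor_atom: str) -> list[np.ndarray]:
    """Idealized in-plane hydrogen positions for one donor."""
    kind, ante = bases.DONORS[res.base][donor_atom]
    D = structure.atom(res, donor_atom)
    ring = np.array([structure.atom(res, a) for a in bases.RING_ATOMS[res.base]])
    normal = _plane_normal(ring)
    if kind == "amine":
        C = structure.atom(res, ante)
        u = (C - D) / np.linalg.norm(C - D)
        return [D + N_H_BOND * _rotate_about(u, normal, s * 120.0)
                for s in (+1, -1)]
    x1 = structure.atom(res, ante[0])
    x2 = structure.atom(res, ante[1])
    u1 = (x1 - D) / np.linalg.norm(x1 - D)
    u2 = (x2 - D) / np.linalg.norm(x2 - D)
    bis = u1 + u2
    bis /= np.linalg.norm(bis)
    return [D - N_H_BOND * bis]


def _acceptors_of(res: Residue) -> list[str]:
    acc = [a for a in bases.ACCEPTORS[res.base] if a in res.atom_names]
    if bases.SUGAR_ACCEPTOR in res.atom_names:
        acc.append(bases.SUGAR_ACCEPTOR)
    return acc


def detect_hbonds(structure: Structure,
                  residue_pairs: list[tuple[Residue, Residue]] | None = None,
                  criteria: HBondCriteria = HBondCriteria()
                  ) -> list[HBondObservation]:
    """All donor->acceptor contacts satisfying the geometric criteria.

    ``residue_pairs`` restricts the scan to ordered residue pairs (donor
    residue, acceptor residue); by default every distinct residue pair of
    the structure is scanned both ways.  Output order is deterministic
    (donor chain, number, atom, then acceptor).
    """
    residues = structure.topology.residues
    if residue_pairs is None:
        residue_pairs = [(a, b) for a in residues for b in residues if a != b]
    out = []
    for dres, ares in residue_pairs:
        if dres.base not in bases.DONORS:
            raise ValueError(f"unknown residue type {dres.base!r}")
        for datom in bases.DONORS[dres.base]:
            if datom not in dres.atom_names:
                continue
            D = structure.atom(dres, datom)
            hydrogens = _donor_hydrogens(structure, dres, datom)
            for aatom in _acceptors_of(ares):
                A = structure.atom(ares, aatom)
                dist = float(np.linalg.norm(A - D))
                if dist > criteria.d_max or dist <= 0.0:
                    continue
                best = 0.0
                for H in hydrogens:
                    v1 = D - H
                    v2 = A - H
                    c = np.dot(v1, v2) / (np.linalg.norm(v1)
                                          * np.linalg.norm(v2))
                    ang = float(np.degrees(np.arccos(np.clip(c, -1, 1))))
                    best = max(best, ang)
                if best >= criteria.theta_min:
                    out.append(HBondObservation(
                        donor=(dres.chain, dres.number, datom),
                        acceptor=(ares.chain, ares.number, aatom),
                        distance=dist, angle=best))
    out.sort(key=lambda h: (h.donor, h.acceptor))
    return out


def pair_hbonds(structure: Structure, mm_position: int,
                criteria: HBondCriteria = HBondCriteria()
                ) -> list[HBondObservation]:
    """Hydrogen bonds between the two bases of one pair (both directions)."""
    topo = structure.topology
    w = topo.watson(mm_position)
    c = topo.crick(mm_position)
    return detect_hbonds(structure, [(w, c), (c, w)], criteria)


def scheme_occupancies(traj: Trajectory, mm_position: int,
                       catalog: SchemeCatalog | None = None,
                       criteria: HBondCriteria = HBondCriteria(),
                       promiscuity_threshold: float = 0.05):
    """Per-scheme occupancy fractions at the lesion pair.

    Each frame is labelled by the first catalog scheme whose bonds are all
    formed; among fully formed schemes ties break toward the scheme with
    more bonds, then catalog order.  Frames matching no scheme fall into
    the ``unassigned`` sink.  Returns ``(fractions dict, per-frame labels,
    promiscuity)`` where promiscuity counts schemes above the reportable
    threshold.
    """
    if traj.n_frames == 0:
        raise ValueError("empty trajectory")
    topo = traj.topology
    wres = topo.watson(mm_position)
    cres = topo.crick(mm_position)
    if catalog is None:
        catalog = load_scheme_catalog(wres.base, cres.base)
    labels = []
    for f in range(traj.n_frames):
        st = traj.frame(f)
        formed = {
            (h.donor[0], h.donor[2], h.acceptor[0], h.acceptor[2])
            for h in detect_hbonds(st, [(wres, cres), (cres, wres)], criteria)
        }
        # translate chain IDs to lesion-pair strand codes
        chain_code = {wres.chain: "W", cres.chain: "C"}
        formed = {(chain_code[a], b, chain_code[c], d) for a, b, c, d in formed}
        best = None
        for k, scheme in enumerate(catalog.schemes):
            if all(b in formed for b in scheme.bonds):
                key = (-len(scheme.bonds), k)
                if best is None or key < best[0]:
                    best = (key, scheme.scheme_id)
        labels.append("unassigned" if best is None else best[1])
    n = len(labels)
    fractions = {s.scheme_id: labels.count(s.scheme_id) / n
                 for s in catalog.schemes}
    fractions["unassigned"] = labels.count("unassigned") / n
    promiscuity = sum(f >= promiscuity_threshold
                      for sid, f in fractions.items() if sid != "unassigned")
    return fractions, labels, promiscuity


# ---------------------------------------------------------------------------
# breathing

STATE_CLOSED, STATE_OPEN_MAJOR, STATE_OPEN_MINOR = 0, 1, 2
STATE_NAMES = {0: "closed", 1: "open_major", 2: "open_minor"}


@dataclass
class BreathingTrace:
    """Per-frame open/closed state of one pair plus run-length summaries.

    ``states`` codes: 0 closed, 1 open toward the major groove, 2 open
    toward the minor groove.  Occupancies are percentages of all frames;
    transitions count closed -> open boundaries; residence times are per
    open event, in frames and in time units (``frame_dt`` per frame).
    """

    states: np.ndarray
    frame_dt: float
    threshold: float
    reference: float
    min_frames: int

    @property
    def n_frames(self) -> int:
        return self.states.size

    def _events(self, direction: int | None = None):
        s = self.states
        is_open = (s != STATE_CLOSED) if direction is None else (s == direction)
        if not is_open.any():
            return []
        padded = np.concatenate([[False], is_open, [False]])
        d = np.diff(padded.astype(int))
        starts = np.nonzero(d == 1)[0]
        stops = np.nonzero(d == -1)[0]
        return list(zip(starts, stops))

    def occupancy_pct(self, direction: int | None = None) -> float:
        s = self.states
        is_open = (s != STATE_CLOSED) if direction is None else (s == direction)
        return 100.0 * float(is_open.sum()) / self.n_frames

    def n_transitions(self, direction: int | None = None) -> int:
        return len(self._events(direction))

    def residence_frames(self, direction: int | None = None) -> np.ndarray:
        return np.array([b - a for a, b in self._events(direction)], dtype=int)

    def summary(self) -> dict:
        out = {"n_frames": int(self.n_frames), "frame_dt": self.frame_dt,
               "threshold": self.threshold, "reference": self.reference,
               "min_frames": self.min_frames}
        for key, direction in (("all", None), ("major", STATE_OPEN_MAJOR),
                               ("minor", STATE_OPEN_MINOR)):
            res = self.residence_frames(direction)
            out[key] = {
                "occupancy_pct": self.occupancy_pct(direction),
                "n_transitions": self.n_transitions(direction),
                "mean_residence_frames": float(res.mean()) if res.size else 0.0,
                "max_residence_frames": int(res.max()) if res.size else 0,
                "mean_residence_time": float(res.mean() * self.frame_dt)
                if res.size else 0.0,
                "max_residence_time": float(res.max() * self.frame_dt)
                if res.size else 0.0,
            }
        return out


def breathing_analysis(opening: np.ndarray, frame_dt: float = 1.0,
                       reference: float = 0.0, threshold: float = 45.0,
                       min_frames: int = 2) -> BreathingTrace:
    """Classify a per-frame opening series into breathing states.

    A frame is open when its opening deviates from ``reference`` by more
    than ``threshold`` degrees as part of a run of at least ``min_frames``
    consecutive above-threshold frames (hysteresis against single-frame
    noise).  The excursion sign sets the direction: positive opening
    deviations expose the bases toward the major groove.
    """
    opening = np.asarray(opening, dtype=float)
    if opening.ndim != 1:
        raise ValueError("opening must be a 1-D series")
    if opening.size < min_frames:
        raise ValueError("series shorter than min_frames")
    if frame_dt <= 0 or threshold <= 0 or min_frames < 1:
        raise ValueError("frame_dt, threshold and min_frames must be positive")
    if not np.all(np.isfinite(opening)):
        raise ValueError("opening series contains non-finite values")
    dev = opening - reference
    raw = np.abs(dev) > threshold
    states = np.zeros(opening.size, dtype=np.int8)
    padded = np.concatenate([[False], raw, [False]])
    d = np.diff(padded.astype(int))
    for a, b in zip(np.nonzero(d == 1)[0], np.nonzero(d == -1)[0]):
        if b - a >= min_frames:
            mean_dev = dev[a:b].mean()
            states[a:b] = STATE_OPEN_MAJOR if mean_dev > 0 else STATE_OPEN_MINOR
    return BreathingTrace(states=states, frame_dt=frame_dt,
                          threshold=threshold, reference=reference,
                          min_frames=min_frames)
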