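"""Lightweight structure and trajectory containers plus multi-model PDB I/O.

Chain A is the Watson strand and chain B the Crick strand, both numbered
1..N in their own 5'->3' direction, so Crick residue j (0-based) pairs with
Watson residue N-1-j.  Monatomic cations ride along as HETATM records
(residue/element NA, K or MG).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import gemmi
import numpy as np

__all__ = ["Residue", "Topology", "Structure", "Trajectory",
           "write_pdb", "read_pdb"]

ION_NAMES = ("NA", "K", "MG")


@dataclass(frozen=True)
class Residue:
    chain: str
    number: int  # 1-based within its chain
    base: str
    atom_names: tuple[str, ...]
    offset: int  # index of first atom in the flat coordinate array

    @property
    def n_atoms(self) -> int:
        return len(self.atom_names)

    def atom_index(self, name: str) -> int:
        try:
            return self.offset + self.atom_names.index(name)
        except ValueError:
            raise KeyError(
                f"atom {name!r} not in {self.chain}{self.number} ({self.base})"
            ) from None


@dataclass(frozen=True)
class Topology:
    residues: tuple[Residue, ...]

    @property
    def n_atoms(self) -> int:
        last = self.residues[-1]
        return last.offset + last.n_atoms

    @property
    def n_pairs(self) -> int:
        return len(self.residues) // 2

    def watson(self, pair_index: int) -> Residue:
        return self.residues[pair_index]

    def crick(self, pair_index: int) -> Residue:
        """Crick residue paired with Watson pair_index."""
        n = self.n_pairs
        # chain B residues are stored 5'->3' after all of chain A
        return self.residues[n + (n - 1 - pair_index)]

    def chain_residues(self, chain: str) -> list[Residue]:
        return [r for r in self.residues if r.chain == chain]


@dataclass
class Structure:
    topology: Topology
    coords: np.ndarray  # (n_atoms, 3)
    ions: np.ndarray | None = None  # (n_ions, 3)
    ion_name: str = "NA"

    def atom(self, residue: Residue, name: str) -> np.ndarray:
        return self.coords[residue.atom_index(name)]

    def transformed(self, R: np.ndarray, t: np.ndarray) -> "Structure":
        """Rigidly moved copy (used by invariance checks)."""
        ions = None if self.ions is None else self.ions @ R.T + t
        return Structure(self.topology, self.coords @ R.T + t, ions,
                         self.ion_name)


@dataclass
class Trajectory:
    topology: Topology
    coords: np.ndarray  # (n_frames, n_atoms, 3)
    ions: list[np.ndarray] | None = None  # per frame, (n_ions_f, 3)
    ion_name: str = "NA"
    frame_dt: float = 1.0  # time between frames, arbitrary units
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must be (n_frames, n_atoms, 3)")
        if self.coords.shape[1] != self.topology.n_atoms:
            raise ValueError(
                f"coords carry {self.coords.shape[1]} atoms but the "
                f"topology declares {self.topology.n_atoms}")
        if self.ions is not None and len(self.ions) != self.coords.shape[0]:
            raise ValueError("ion frames do not match coordinate frames")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    def frame(self, i: int) -> Structure:
        ions = None if self.ions is None else self.ions[i]
        return Structure(self.topology, self.coords[i], ions, self.ion_name)

    def __iter__(self):
        return (self.frame(i) for i in range(self.n_frames))


def _check_topology_match(topology: Topology, other: Topology):
    if topology != other:
        raise ValueError("frames have mismatching topologies")


def write_pdb(path, traj: Trajectory | Structure):
    """Write a (multi-model) PDB; one MODEL per frame, ions as HETATM."""
    if isinstance(traj, Structure):
        traj = Trajectory(traj.topology, traj.coords[None],
                          None if traj.ions is None else [traj.ions],
                          traj.ion_name)
    st = gemmi.Structure()
    st.name = "mmdna"
    for f in range(traj.n_frames):
        model = gemmi.Model(f + 1)
        chains: dict[str, gemmi.Chain] = {}
        serial = 1
        for res in traj.topology.residues:
            ch = chains.get(res.chain)
            if ch is None:
                ch = gemmi.Chain(res.chain)
                chains[res.chain] = ch
            g_res = gemmi.Residue()
            g_res.name = "D" + res.base
            g_res.seqid = gemmi.SeqId(res.number, " ")
            for k, name in enumerate(res.atom_names):
                a = gemmi.Atom()
                a.name = name
                a.serial = serial
                serial += 1
                x, y, z = traj.coords[f, res.offset + k]
                a.pos = gemmi.Position(x, y, z)
                a.element = gemmi.Element("P" if name == "P" else name[0])
                a.occ = 1.0
                g_res.add_atom(a)
            ch.add_residue(g_res)
        ions = None if traj.ions is None else traj.ions[f]
        if ions is not None and len(ions) > 0:
            ich = gemmi.Chain("I")
            for k, xyz in enumerate(ions):
                g_res = gemmi.Residue()
                g_res.name = traj.ion_name
                g_res.seqid = gemmi.SeqId(k + 1, " ")
                g_res.het_flag = "H"
                a = gemmi.Atom()
                a.name = traj.ion_name
                a.serial = serial
                serial += 1
                a.pos = gemmi.Position(*xyz)
                a.element = gemmi.Element(traj.ion_name.capitalize())
                a.occ = 1.0
                g_res.add_atom(a)
                ich.add_residue(g_res)
            chains["I"] = ich
        for ch in chains.values():
            model.add_chain(ch)
        st.add_model(model)
    doc = st.make_pdb_string()
    with open(path, "w") as fh:
        fh.write(doc)


def read_pdb(path, frame_dt: float = 1.0) -> Trajectory:
    """Read a multi-model PDB written by this package (or compatible)."""
    st = gemmi.read_structure(str(path))
    if len(st) == 0:
        raise ValueError(f"no models in {path}")
    residues: list[Residue] = []
    offset = 0
    first = st[0]
    for ch in first:
        for res in ch:
            name = res.name.strip()
            if name in ION_NAMES:
                continue
            base = name[-1]  # DA/DC/DG/DT (or A/C/G/T)
            atom_names = tuple(a.name for a in res)
            residues.append(Residue(ch.name, res.seqid.num, base,
                                    atom_names, offset))
            offset += len(atom_names)
    topology = Topology(tuple(residues))
    n_atoms = topology.n_atoms
    coords = np.empty((len(st), n_atoms, 3))
    ions: list[np.ndarray] = []
    ion_name = "NA"
    any_ions = False
    for f, model in enumerate(st):
        idx = 0
        frame_ions = []
        for ch in model:
            for res in ch:
                if res.name.strip() in ION_NAMES:
                    ion_name = res.name.strip()
                    for a in res:
                        frame_ions.append([a.pos.x, a.pos.y, a.pos.z])
                    continue
                for a in res:
                    coords[f, idx] = [a.pos.x, a.pos.y, a.pos.z]
                    idx += 1
        if idx != n_atoms:
            raise ValueError(f"model {f + 1} atom count {idx} != {n_atoms}")
        if frame_ions:
            any_ions = True
        ions.append(np.asarray(frame_ions, dtype=float).reshape(-1, 3))
    return Trajectory(topology, coords, ions if any_ions else None,
                      ion_name, frame_dt)
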