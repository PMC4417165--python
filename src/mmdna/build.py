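"""Rebuild atomic duplexes from helical coordinates.

The builder and the analyser share one mid-frame parameter convention, so a
built structure analysed with :mod:`mmdna.frames` returns the input table to
numerical precision (the round-trip contract).
"""

from __future__ import annotations

import numpy as np

from . import bases
from ._rotations import FLIP_X, internal_to_cartesian, mid_frame_split, step_compose
from .duplex import DuplexSequence
from .params import ParameterTable
from .structure import Residue, Structure, Topology

__all__ = ["build_duplex", "pair_frames_from_table", "duplex_topology"]


def duplex_topology(seq: DuplexSequence) -> Topology:
    """Reduced-atom topology for a duplex: chain A Watson, chain B Crick."""
    residues = []
    offset = 0
    for i, b in enumerate(seq.watson):
        names = tuple(bases.base_atom_names(b))
        residues.append(Residue("A", i + 1, b, names, offset))
        offset += len(names)
    for j, b in enumerate(seq.crick):
        names = tuple(bases.base_atom_names(b))
        residues.append(Residue("B", j + 1, b, names, offset))
        offset += len(names)
    return Topology(tuple(residues))


def pair_frames_from_table(table: ParameterTable):
    """Propagate pair frames along the helix from the step parameters.

    Returns ``(rotations (N,3,3), origins (N,3))``; the first pair frame is
    the identity at the origin.
    """
    n = table.n_pairs
    T = np.empty((n, 3, 3))
    o = np.empty((n, 3))
    T[0] = np.eye(3)
    o[0] = 0.0
    for i in range(n - 1):
        T[i + 1], o[i + 1], _, _ = step_compose(table.inter[i], T[i], o[i])
    return T, o


def _place_nucleotide(base: str, R: np.ndarray, origin: np.ndarray,
                      chi: float) -> np.ndarray:
    std_names = list(bases.STANDARD_BASES[base].keys())
    coords = bases.standard_coords(base) @ R.T + origin
    named = dict(zip(std_names, coords))
    o4p = internal_to_cartesian(
        named[bases.CHI_REF_ATOM[base]],
        named[bases.GLYCOSIDIC_N[base]],
        named["C1'"],
        bases.O4P_BOND, bases.O4P_ANGLE, chi,
    )
    p = R @ bases.P_OFFSET + origin
    return np.vstack([coords, o4p, p])


def build_duplex(seq: DuplexSequence, table: ParameterTable) -> Structure:
    """Atomic duplex realising a helical-parameter table exactly.

    Pair frames are chained from the step parameters; within each pair the
    intra parameters are split symmetrically about the pair frame, the Watson
    base taking the forward half and the (flipped) Crick base the backward
    half.  Per-nucleotide glycosidic torsions come from ``table.chi``.
    """
    if table.n_pairs != len(seq):
        raise ValueError(
            f"table is for {table.n_pairs} pairs, sequence has {len(seq)}"
        )
    topo = duplex_topology(seq)
    Tp, op = pair_frames_from_table(table)
    n = len(seq)
    watson_xyz = [None] * n
    crick_xyz = [None] * n
    for i in range(n):
        T1, o1, T2, o2 = mid_frame_split(table.intra[i], Tp[i], op[i])
        wb, cb = seq.pair(i)
        R_c = T1 @ FLIP_X  # undo the strand-flip convention
        watson_xyz[i] = _place_nucleotide(wb, T2, o2, table.chi[i, 0])
        crick_xyz[i] = _place_nucleotide(cb, R_c, o1, table.chi[i, 1])
    # chain A is Watson 5'->3'; chain B is Crick 5'->3' = pairs N-1..0
    blocks = watson_xyz + [crick_xyz[n - 1 - j] for j in range(n)]
    return Structure(topo, np.vstack(blocks))
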