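"""Groove geometry from cross-strand phosphate separations.

The width of a groove at a position is the minimum cross-strand P-P
distance over a fixed register window, minus twice the phosphate group
radius (5.8 A in total), floored at zero.  The register windows were fixed
against a straight fiber-like build, where the minor-groove P-P minimum
(~11.7 A) sits at cross-strand offsets -3/-2 and the major-groove one
(~17.2 A) at +3/+4.  Positions whose window runs off either strand end are
flagged undefined (NaN), never zero-filled.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .structure import Structure

__all__ = ["GrooveProfile", "groove_width_profile",
           "PHOSPHATE_CORRECTION", "MINOR_OFFSETS", "MAJOR_OFFSETS"]

PHOSPHATE_CORRECTION = 5.8  # A, summed phosphate-group radii
MINOR_OFFSETS = (-3, -2)
MAJOR_OFFSETS = (3, 4)
METHOD_TAG = "cross-strand-P-min"


@dataclass
class GrooveProfile:
    """Per-position minor and major groove widths (A; NaN = undefined)."""

    minor: np.ndarray
    major: np.ndarray
    method: str = METHOD_TAG

    @property
    def n_positions(self) -> int:
        return self.minor.size

    def defined(self, groove: str = "minor") -> np.ndarray:
        return np.isfinite(getattr(self, groove))

    def mean_width(self, groove: str = "minor") -> float:
        vals = getattr(self, groove)
        return float(np.nanmean(vals)) if np.any(np.isfinite(vals)) else np.nan

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "position": np.arange(self.n_positions),
            "minor_width": self.minor,
            "major_width": self.major,
            "method": self.method,
        })


def _phosphates(structure: Structure):
    topo = structure.topology
    n = topo.n_pairs
    Pw = np.empty((n, 3))
    Pc = np.empty((n, 3))
    for i in range(n):
        try:
            Pw[i] = structure.atom(topo.watson(i), "P")
            Pc[i] = structure.atom(topo.crick(i), "P")
        except KeyError:
            raise ValueError(
                f"missing P (pseudo-)atom at pair {i}; groove widths need "
                "phosphates on both strands") from None
    return Pw, Pc


def groove_width_profile(structure: Structure,
                         minor_offsets: tuple[int, ...] = MINOR_OFFSETS,
                         major_offsets: tuple[int, ...] = MAJOR_OFFSETS,
                         correction: float = PHOSPHATE_CORRECTION
                         ) -> GrooveProfile:
    """Minor/major groove width at every pair position of one snapshot.

    At Watson position i the minor width is
    ``min_d |P_w(i) - P_c(i+d)| - correction`` over the minor offset window
    (``P_c(j)`` is the phosphate of the Crick residue paired with Watson
    position j), floored at 0; the major width uses its own window.
    """
    Pw, Pc = _phosphates(structure)
    n = Pw.shape[0]
    out = {}
    for name, offsets in (("minor", minor_offsets), ("major", major_offsets)):
        widths = np.full(n, np.nan)
        for i in range(n):
            js = [i + d for d in offsets]
            if any(j < 0 or j >= n for j in js):
                continue  # window does not fit: undefined, flagged as NaN
            dmin = min(float(np.linalg.norm(Pw[i] - Pc[j])) for j in js)
            widths[i] = max(dmin - correction, 0.0)
        out[name] = widths
    return GrooveProfile(minor=out["minor"], major=out["major"])
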