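"""Helical-parameter containers.

Intra-base-pair coordinates: shear, stretch, stagger (A), buckle, propeller,
opening (deg).  Inter-base-pair (step) coordinates: shift, slide, rise (A),
tilt, roll, twist (deg).  Translations come first in every 6-vector.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "INTRA_NAMES",
    "INTER_NAMES",
    "IntraBpParams",
    "InterBpParams",
    "ParameterTable",
    "fiber_b_table",
    "DEFAULT_CHI",
    "FIBER_RISE",
    "FIBER_TWIST",
]

INTRA_NAMES = ("shear", "stretch", "stagger", "buckle", "propeller", "opening")
INTER_NAMES = ("shift", "slide", "rise", "tilt", "roll", "twist")

#: fiber-like B-form defaults
FIBER_RISE = 3.38
FIBER_TWIST = 36.0
DEFAULT_CHI = -117.0


def _check_angles(values, names):
    for name, v in zip(names[3:], np.asarray(values)[..., 3:].T):
        v = np.atleast_1d(v)
        if np.any(v <= -180.0) or np.any(v > 180.0):
            raise ValueError(f"{name} outside (-180, 180]")


@dataclass(frozen=True)
class IntraBpParams:
    shear: float
    stretch: float
    stagger: float
    buckle: float
    propeller: float
    opening: float

    def as_array(self) -> np.ndarray:
        return np.array([self.shear, self.stretch, self.stagger,
                         self.buckle, self.propeller, self.opening])

    @classmethod
    def from_array(cls, a) -> "IntraBpParams":
        return cls(*(float(v) for v in a))


@dataclass(frozen=True)
class InterBpParams:
    shift: float
    slide: float
    rise: float
    tilt: float
    roll: float
    twist: float

    def as_array(self) -> np.ndarray:
        return np.array([self.shift, self.slide, self.rise,
                         self.tilt, self.roll, self.twist])

    @classmethod
    def from_array(cls, a) -> "InterBpParams":
        return cls(*(float(v) for v in a))


@dataclass
class ParameterTable:
    """Full helical coordinate set of an N-pair duplex.

    ``intra``: (N, 6) per-pair parameters; ``inter``: (N-1, 6) per-step
    parameters; ``chi``: (N, 2) glycosidic torsion targets (deg), column 0
    Watson, column 1 Crick.
    """

    intra: np.ndarray
    inter: np.ndarray
    chi: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        self.intra = np.array(self.intra, dtype=float)
        self.inter = np.array(self.inter, dtype=float)
        n = self.n_pairs
        if n < 2:
            raise ValueError("a duplex table needs at least 2 pairs")
        if self.intra.shape != (n, 6) or self.inter.shape != (n - 1, 6):
            raise ValueError(
                f"malformed table: intra {self.intra.shape}, "
                f"inter {self.inter.shape}"
            )
        if self.chi is None:
            self.chi = np.full((n, 2), DEFAULT_CHI)
        self.chi = np.array(self.chi, dtype=float)
        if self.chi.shape != (n, 2):
            raise ValueError("chi must be (n_pairs, 2)")
        _check_angles(self.intra, INTRA_NAMES)
        _check_angles(self.inter, INTER_NAMES)
        if np.any(self.inter[:, 2] <= 0):
            raise ValueError("rise must be positive for B-like builds")

    @property
    def n_pairs(self) -> int:
        return self.intra.shape[0]

    def copy(self) -> "ParameterTable":
        return ParameterTable(self.intra.copy(), self.inter.copy(),
                              self.chi.copy())

    def stacked(self) -> np.ndarray:
        """Flat parameter vector: all intra rows then all inter rows."""
        return np.concatenate([self.intra.ravel(), self.inter.ravel()])

    @classmethod
    def from_stacked(cls, vec: np.ndarray, n_pairs: int,
                     chi=None) -> "ParameterTable":
        vec = np.asarray(vec, dtype=float)
        n_intra = n_pairs * 6
        intra = vec[:n_intra].reshape(n_pairs, 6)
        inter = vec[n_intra:].reshape(n_pairs - 1, 6)
        return cls(intra, inter, chi)

    def to_frame(self) -> pd.DataFrame:
        """Tidy view: one row per (position, parameter)."""
        rows = []
        for i in range(self.n_pairs):
            for j, name in enumerate(INTRA_NAMES):
                rows.append(("intra", i, name, self.intra[i, j]))
        for i in range(self.n_pairs - 1):
            for j, name in enumerate(INTER_NAMES):
                rows.append(("inter", i, name, self.inter[i, j]))
        return pd.DataFrame(rows, columns=["kind", "index", "parameter",
                                           "value"])


def fiber_b_table(n_pairs: int, rise: float = FIBER_RISE,
                  twist: float = FIBER_TWIST,
                  chi: float = DEFAULT_CHI) -> ParameterTable:
    """Straight fiber-like B-DNA table: all parameters zero except rise/twist."""
    intra = np.zeros((n_pairs, 6))
    inter = np.zeros((n_pairs - 1, 6))
    inter[:, 2] = rise
    inter[:, 5] = twist
    return ParameterTable(intra, inter, np.full((n_pairs, 2), float(chi)))
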