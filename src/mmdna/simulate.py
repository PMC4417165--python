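"""Synthetic duplex ensembles with fully known ground truth.

This module stands in for molecular-dynamics sampling: snapshots are built
from helical-parameter vectors drawn from a multivariate normal around a
mean table, optionally with planted base-pair breathing excursions and a
cation field of known molarity.  Every random draw derives from one master
seed expanded per frame through a counter, so identical specs give
bit-identical ensembles.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .build import build_duplex, duplex_topology, pair_frames_from_table
from .duplex import DuplexSequence
from .params import INTER_NAMES, INTRA_NAMES, ParameterTable
from .structure import Trajectory

__all__ = [
    "MOLAR_PER_A3",
    "DEFAULT_FLUCTUATION_SD",
    "BreathingEvent",
    "IonShellSpec",
    "IonFieldSpec",
    "IonEnsemble",
    "EnsembleSpec",
    "default_covariance",
    "sample_parameter_vectors",
    "sample_trajectory",
    "sample_ion_positions",
]

logger = logging.getLogger(__name__)

#: ions per cubic angstrom per molar (Avogadro * 1e-27)
MOLAR_PER_A3 = 6.022e-4

#: study-condition per-parameter fluctuation SDs for a B-DNA duplex at 298 K
#: (A for translations, deg for rotations)
DEFAULT_FLUCTUATION_SD = {
    "shear": 0.30, "stretch": 0.15, "stagger": 0.40,
    "buckle": 9.0, "propeller": 8.0, "opening": 4.0,
    "shift": 0.50, "slide": 0.50, "rise": 0.30,
    "tilt": 3.5, "roll": 5.5, "twist": 5.0,
}

_OPENING_COL = INTRA_NAMES.index("opening")
_RISE_COL = INTER_NAMES.index("rise")


@dataclass(frozen=True)
class BreathingEvent:
    """A planted opening excursion: pair ``pair`` is pushed out of its mean
    opening by ``amplitude`` degrees (positive toward the major groove) for
    frames ``start`` <= f < ``stop``."""

    pair: int
    start: int
    stop: int
    amplitude: float
    direction: str = "major"

    def __post_init__(self):
        if self.direction not in ("major", "minor"):
            raise ValueError("direction must be 'major' or 'minor'")
        if self.stop <= self.start:
            raise ValueError("empty breathing window")

    @property
    def signed_amplitude(self) -> float:
        s = 1.0 if self.direction == "major" else -1.0
        return s * abs(self.amplitude)


@dataclass(frozen=True)
class IonShellSpec:
    """Uniform cation molarity in a cylindrical shell around the duplex axis
    at the chosen base-pair plane (r in [r_min, r_max] A, |z| <= half_thickness)."""

    molarity: float
    r_min: float = 0.0
    r_max: float = 16.0
    half_thickness: float = 1.7
    center_position: int | None = None  # default: lesion pair

    def __post_init__(self):
        if self.molarity < 0:
            raise ValueError("molarity must be >= 0")
        if not (0 <= self.r_min < self.r_max) or self.half_thickness <= 0:
            raise ValueError("degenerate or unbounded shell")

    @property
    def volume(self) -> float:
        return float(np.pi * (self.r_max ** 2 - self.r_min ** 2)
                     * 2 * self.half_thickness)


@dataclass(frozen=True)
class IonFieldSpec:
    """Per-bin cation molarity over a radial x angular grid in the base-pair
    plane slab; ``molarity`` has shape (n_r, n_theta)."""

    r_edges: tuple[float, ...]
    theta_edges: tuple[float, ...]  # degrees, covering [0, 360]
    molarity: np.ndarray
    half_thickness: float = 1.7
    center_position: int | None = None

    def __post_init__(self):
        m = np.asarray(self.molarity, dtype=float)
        if np.any(m < 0):
            raise ValueError("molarity must be >= 0")
        if m.shape != (len(self.r_edges) - 1, len(self.theta_edges) - 1):
            raise ValueError("molarity grid does not match bin edges")
        object.__setattr__(self, "molarity", m)

    def bin_volumes(self) -> np.ndarray:
        r = np.asarray(self.r_edges)
        th = np.deg2rad(np.asarray(self.theta_edges))
        ring = 0.5 * (r[1:] ** 2 - r[:-1] ** 2)
        return np.outer(ring, np.diff(th)) * 2 * self.half_thickness


@dataclass
class IonEnsemble:
    """Per-frame cation coordinate sets (lab frame) plus the generating
    cylindrical system used as ground truth."""

    frames: list[np.ndarray]
    center_rotation: np.ndarray
    center_origin: np.ndarray
    spec: IonShellSpec | IonFieldSpec

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def mean_count(self) -> float:
        return float(np.mean([len(f) for f in self.frames]))


@dataclass
class EnsembleSpec:
    """Everything needed to generate a synthetic duplex ensemble.

    ``covariance`` applies to the stacked parameter vector (all intra rows,
    then all inter rows; see :meth:`ParameterTable.stacked`) and may be a
    full PSD matrix, a 1-D vector of per-entry variances, or None for the
    study-condition defaults.
    """

    sequence: DuplexSequence
    table: ParameterTable
    covariance: np.ndarray | None = None
    n_frames: int = 100
    seed: int = 0
    planted_breathing: list[BreathingEvent] = field(default_factory=list)
    ion_spec: IonShellSpec | IonFieldSpec | None = None
    frame_dt: float = 1.0
    max_resample: int = 20

    def __post_init__(self):
        if self.table.n_pairs != len(self.sequence):
            raise ValueError("table/sequence dimension mismatch")
        if self.n_frames <= 0:
            raise ValueError("n_frames must be positive")
        for ev in self.planted_breathing:
            if not (0 <= ev.start < ev.stop <= self.n_frames):
                raise ValueError(f"breathing window {ev} outside [0, n_frames)")
            if not (0 <= ev.pair < self.table.n_pairs):
                raise ValueError(f"breathing pair {ev.pair} out of range")

    @property
    def n_entries(self) -> int:
        n = self.table.n_pairs
        return 6 * n + 6 * (n - 1)

    def variance_vector(self) -> np.ndarray | None:
        """Diagonal variances, or None if a full covariance was supplied."""
        if self.covariance is None:
            n = self.table.n_pairs
            sds = [DEFAULT_FLUCTUATION_SD[p] for p in INTRA_NAMES] * n + \
                  [DEFAULT_FLUCTUATION_SD[p] for p in INTER_NAMES] * (n - 1)
            return np.asarray(sds) ** 2
        cov = np.asarray(self.covariance, dtype=float)
        if cov.ndim == 1:
            if np.any(cov < 0):
                raise ValueError("negative variances")
            return cov
        return None

    def cholesky(self) -> np.ndarray | None:
        """Lower Cholesky factor of a full covariance (None if diagonal)."""
        if self.variance_vector() is not None:
            return None
        cov = np.asarray(self.covariance, dtype=float)
        if cov.shape != (self.n_entries, self.n_entries):
            raise ValueError(f"covariance must be {self.n_entries} square")
        if np.max(np.abs(cov - cov.T)) > 1e-10:
            raise ValueError("covariance must be symmetric")
        w = np.linalg.eigvalsh(cov)
        if w[0] < -1e-10 * max(1.0, w[-1]):
            raise ValueError("covariance is not positive semidefinite")
        jitter = 1e-12 * max(1.0, float(w[-1]))
        return np.linalg.cholesky(cov + jitter * np.eye(cov.shape[0]))

    def content_hash(self) -> str:
        """Stable hash of the generating conditions (for run manifests)."""
        payload = {
            "watson": self.sequence.watson,
            "crick": self.sequence.crick,
            "mm_position": self.sequence.mm_position,
            "intra": self.table.intra.tolist(),
            "inter": self.table.inter.tolist(),
            "chi": self.table.chi.tolist(),
            "covariance": None if self.covariance is None
            else np.asarray(self.covariance).tolist(),
            "n_frames": self.n_frames,
            "seed": self.seed,
            "breathing": [(e.pair, e.start, e.stop, e.amplitude, e.direction)
                          for e in self.planted_breathing],
            "frame_dt": self.frame_dt,
        }
        blob = json.dumps(payload, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


def default_covariance(n_pairs: int) -> np.ndarray:
    """Study-condition diagonal variances for an ``n_pairs`` duplex."""
    sds = [DEFAULT_FLUCTUATION_SD[p] for p in INTRA_NAMES] * n_pairs + \
          [DEFAULT_FLUCTUATION_SD[p] for p in INTER_NAMES] * (n_pairs - 1)
    return np.asarray(sds) ** 2


def _frame_rng(seed: int, frame: int, attempt: int = 0) -> np.random.Generator:
    return np.random.default_rng([seed & 0x7FFFFFFF, frame, attempt])


def sample_parameter_vectors(spec: EnsembleSpec) -> tuple[np.ndarray, int]:
    """Draw the per-frame stacked parameter vectors.

    Returns ``(vectors (n_frames, d), n_resampled)``.  Frames whose sampled
    geometry is degenerate (any rise <= 0) are redrawn from a fresh
    counter-keyed substream; the count of redraws is reported and warned.
    """
    mean = spec.table.stacked()
    d = mean.size
    var = spec.variance_vector()
    L = spec.cholesky() if var is None else None
    sd = None if var is None else np.sqrt(var)
    n = spec.table.n_pairs
    rise_idx = 6 * n + np.arange(n - 1) * 6 + _RISE_COL
    out = np.empty((spec.n_frames, d))
    n_resampled = 0
    for f in range(spec.n_frames):
        for attempt in range(spec.max_resample + 1):
            rng = _frame_rng(spec.seed, f, attempt)
            z = rng.standard_normal(d)
            vec = mean + (sd * z if L is None else L @ z)
            if np.all(vec[rise_idx] > 0):
                break
            n_resampled += 1
        else:
            raise RuntimeError(
                f"frame {f}: geometry still degenerate after "
                f"{spec.max_resample} resamples"
            )
        out[f] = vec
    # planted breathing overrides the opening of the target pair
    for ev in spec.planted_breathing:
        col = 6 * ev.pair + _OPENING_COL
        base = spec.table.intra[ev.pair, _OPENING_COL]
        out[ev.start:ev.stop, col] = base + ev.signed_amplitude
    if n_resampled:
        warnings.warn(f"resampled {n_resampled} degenerate draws (rise <= 0)",
                      stacklevel=2)
        logger.info("resampled %d degenerate draws", n_resampled)
    return out, n_resampled


def sample_trajectory(spec: EnsembleSpec) -> Trajectory:
    """Generate the synthetic ensemble as an atomic trajectory.

    Each frame is built from its own parameter vector; chi targets follow
    the mean table.  The returned trajectory carries the spec hash, seed and
    resample count in its metadata.
    """
    vectors, n_resampled = sample_parameter_vectors(spec)
    topo = duplex_topology(spec.sequence)
    coords = np.empty((spec.n_frames, topo.n_atoms, 3))
    for f in range(spec.n_frames):
        table = ParameterTable.from_stacked(vectors[f], spec.table.n_pairs,
                                            chi=spec.table.chi)
        coords[f] = build_duplex(spec.sequence, table).coords
    ions = None
    if spec.ion_spec is not None:
        ion_ens = sample_ion_positions(spec, spec.n_frames)
        ions = ion_ens.frames
    return Trajectory(
        topology=topo, coords=coords, ions=ions, frame_dt=spec.frame_dt,
        metadata={
            "seed": spec.seed,
            "spec_hash": spec.content_hash(),
            "n_resampled": n_resampled,
            "mm_position": spec.sequence.mm_position,
        },
    )


def _center_frame(spec: EnsembleSpec, center_position: int | None):
    pos = center_position
    if pos is None:
        pos = spec.sequence.mm_position
    T, o = pair_frames_from_table(spec.table)
    return T[pos], o[pos]


def sample_ion_positions(spec: EnsembleSpec, frame_count: int) -> IonEnsemble:
    """Per-frame cation coordinates from a Poisson point process.

    The intensity in every bin is molarity x bin volume x 6.022e-4 ions/A^3/M;
    positions are uniform within their bin, expressed in the cylindrical
    system of the mean-structure pair frame at the chosen center position
    (z along the local helix axis, theta = 0 at the major-groove center).
    """
    ion_spec = spec.ion_spec
    if ion_spec is None:
        raise ValueError("spec has no ion field")
    Tm, om = _center_frame(spec, ion_spec.center_position)
    frames: list[np.ndarray] = []
    if isinstance(ion_spec, IonShellSpec):
        lam = ion_spec.molarity * ion_spec.volume * MOLAR_PER_A3
        r0sq, r1sq = ion_spec.r_min ** 2, ion_spec.r_max ** 2
        for f in range(frame_count):
            rng = _frame_rng(spec.seed, f, 10_000)
            k = rng.poisson(lam)
            r = np.sqrt(rng.uniform(r0sq, r1sq, k))
            th = rng.uniform(0.0, 2 * np.pi, k)
            z = rng.uniform(-ion_spec.half_thickness,
                            ion_spec.half_thickness, k)
            local = np.column_stack([r * np.cos(th), r * np.sin(th), z])
            frames.append(local @ Tm.T + om)
    else:
        vols = ion_spec.bin_volumes()
        lam = ion_spec.molarity * vols * MOLAR_PER_A3
        r_edges = np.asarray(ion_spec.r_edges)
        th_edges = np.deg2rad(np.asarray(ion_spec.theta_edges))
        for f in range(frame_count):
            rng = _frame_rng(spec.seed, f, 10_000)
            counts = rng.poisson(lam)
            pts = []
            for (i, j), k in np.ndenumerate(counts):
                if k == 0:
                    continue
                r = np.sqrt(rng.uniform(r_edges[i] ** 2,
                                        r_edges[i + 1] ** 2, k))
                th = rng.uniform(th_edges[j], th_edges[j + 1], k)
                z = rng.uniform(-ion_spec.half_thickness,
                                ion_spec.half_thickness, k)
                pts.append(np.column_stack([r * np.cos(th),
                                            r * np.sin(th), z]))
            local = (np.vstack(pts) if pts else np.empty((0, 3)))
            frames.append(local @ Tm.T + om)
    return IonEnsemble(frames=frames, center_rotation=Tm, center_origin=om,
                       spec=ion_spec)
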