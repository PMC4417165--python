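"""Base reference frames and helical-parameter analysis.

The engine fits the idealized base geometry onto each observed base by
least-squares rigid superposition, then decomposes pairs and steps with the
symmetric mid-frame scheme shared with the builder.  Per-trajectory driving
is vectorised across frames.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import bases
from ._rotations import (
    FLIP_X,
    dihedral_batch,
    kabsch,
    kabsch_batch,
    step_decompose,
    step_decompose_batch,
)
from .params import INTER_NAMES, INTRA_NAMES, IntraBpParams, InterBpParams
from .structure import Structure, Trajectory

__all__ = [
    "BaseFrame",
    "ChiState",
    "GlobalDescriptors",
    "CHI_BINS",
    "classify_chi",
    "fit_base_frame",
    "intra_bp_params",
    "pair_frame",
    "inter_bp_params",
    "chi_state",
    "global_descriptors",
    "analyze_trajectory",
    "TrajectoryAnalysis",
]


@dataclass(frozen=True)
class BaseFrame:
    """Orthonormal frame of one base: origin (A) and rotation matrix whose
    columns are x (major-groove edge), y (sugar side), z (stack normal)."""

    origin: np.ndarray
    rotation: np.ndarray
    rms_fit: float = 0.0

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=float)
        if abs(np.linalg.det(R) - 1.0) > 1e-8 or \
                np.max(np.abs(R @ R.T - np.eye(3))) > 1e-8:
            raise ValueError("rotation is not a proper orthonormal matrix")

    def flipped(self) -> "BaseFrame":
        """Frame after the 180 deg strand-flip about its own x axis."""
        return BaseFrame(self.origin, self.rotation @ FLIP_X, self.rms_fit)


#: glycosidic-torsion conformer bins (deg, half-open intervals (lo, hi])
CHI_BINS = {
    "anti": ((120.0, 180.0), (-180.0, -90.0)),
    "high-anti": ((-90.0, -30.0),),
    "syn": ((-30.0, 90.0),),
}


def classify_chi(chi: float) -> str:
    for name, intervals in CHI_BINS.items():
        for lo, hi in intervals:
            if lo < chi <= hi:
                return name
    return "other"


@dataclass(frozen=True)
class ChiState:
    chi: float
    conformer: str


@dataclass(frozen=True)
class GlobalDescriptors:
    helical_bend: float  # deg, in [0, 180]
    total_twist: float  # deg, summed over the included steps
    step_range: tuple[int, int]  # half-open [start, stop) of included steps


def fit_base_frame(atoms: dict[str, np.ndarray], base_type: str) -> BaseFrame:
    """Least-squares frame of one base from labelled heavy-atom coordinates.

    ``atoms`` maps atom names to positions; the ring atoms present for
    ``base_type`` are superposed (rotation + translation, no scaling) onto
    the idealized geometry.  At least three non-collinear matched atoms are
    required.
    """
    if base_type not in bases.RING_ATOMS:
        raise ValueError(f"unknown base type {base_type!r}")
    names = [n for n in bases.RING_ATOMS[base_type] if n in atoms]
    if len(names) < 3:
        raise ValueError(
            f"need >= 3 ring atoms to fit a {base_type} frame, got {len(names)}"
        )
    obs = np.array([atoms[n] for n in names], dtype=float)
    ref = bases.standard_coords(base_type, names)
    spread = np.linalg.svd(obs - obs.mean(0), compute_uv=False)
    if spread[1] < 1e-6:
        raise ValueError("ring atoms are collinear; frame is underdetermined")
    R, t, rms = kabsch(ref, obs, return_rms=True)
    return BaseFrame(origin=t, rotation=R, rms_fit=rms)


def _decompose_pair(frame_w: BaseFrame, frame_c: BaseFrame):
    flipped = frame_c.flipped()
    return step_decompose(flipped.rotation, flipped.origin,
                          frame_w.rotation, frame_w.origin)


def intra_bp_params(frame_w: BaseFrame, frame_c: BaseFrame) -> IntraBpParams:
    """Six intra-pair coordinates of a Watson/Crick base-frame pair.

    The Crick frame is flipped 180 deg about the pair x axis before the
    symmetric mid-frame decomposition; the six numbers describe the Watson
    base relative to the flipped Crick base (shear, stretch, stagger in A;
    buckle, propeller, opening in deg).
    """
    p, _, _ = _decompose_pair(frame_w, frame_c)
    return IntraBpParams.from_array(p)


def pair_frame(frame_w: BaseFrame, frame_c: BaseFrame) -> BaseFrame:
    """Mid-frame of a base pair (the per-pair origin of step parameters)."""
    _, Tm, om = _decompose_pair(frame_w, frame_c)
    return BaseFrame(origin=om, rotation=Tm,
                     rms_fit=max(frame_w.rms_fit, frame_c.rms_fit))


def inter_bp_params(pair_i: BaseFrame, pair_j: BaseFrame) -> InterBpParams:
    """Six step coordinates between consecutive pair frames."""
    p, _, _ = step_decompose(pair_i.rotation, pair_i.origin,
                             pair_j.rotation, pair_j.origin)
    return InterBpParams.from_array(p)


def chi_state(atoms: dict[str, np.ndarray], base_type: str) -> ChiState:
    """Glycosidic torsion and conformer of one nucleotide.

    chi is O4'-C1'-N9-C4 for purines and O4'-C1'-N1-C2 for pyrimidines.
    """
    names = bases.CHI_ATOMS[base_type]
    try:
        pts = [np.asarray(atoms[n], dtype=float) for n in names]
    except KeyError as e:
        raise ValueError(f"missing chi atom {e} for base {base_type}") from None
    chi = float(dihedral_batch(*pts))
    return ChiState(chi=chi, conformer=classify_chi(chi))


def _bend_from_axes(mid_z: np.ndarray) -> np.ndarray:
    """Angle (deg) between the mean local helix axes of the first and last
    three steps of the included window; ``mid_z`` is (..., n_steps, 3)."""
    w = min(3, mid_z.shape[-2])
    u = mid_z[..., :w, :].mean(axis=-2)
    v = mid_z[..., -w:, :].mean(axis=-2)
    c = np.sum(u * v, axis=-1) / (
        np.linalg.norm(u, axis=-1) * np.linalg.norm(v, axis=-1))
    return np.degrees(np.arccos(np.clip(c, -1.0, 1.0)))


def default_step_range(n_pairs: int) -> tuple[int, int]:
    """Included steps: those between pairs 1..n-2 (outermost pair at each
    end excluded against end fraying)."""
    return (1, n_pairs - 2)


def global_descriptors(pair_frames: list[BaseFrame],
                       step_range: tuple[int, int] | None = None
                       ) -> GlobalDescriptors:
    """Helical bend and total twist of one snapshot from its pair frames.

    The bend is the angle between the mean local helix axes (mid-step frame
    z) of the first three and last three included steps; the total twist is
    the sum of step twists over ``step_range`` (half-open step indices,
    default excluding the outermost pair at each end).
    """
    n = len(pair_frames)
    if step_range is None:
        step_range = default_step_range(n)
    start, stop = step_range
    if not (0 <= start < stop <= n - 1):
        raise ValueError(f"invalid step range {step_range} for {n} pairs")
    if stop - start < 3:
        raise ValueError(
            "need >= 3 included steps for the two terminal axis windows"
        )
    twists = []
    mid_z = []
    for i in range(start, stop):
        p, Tm, _ = step_decompose(
            pair_frames[i].rotation, pair_frames[i].origin,
            pair_frames[i + 1].rotation, pair_frames[i + 1].origin)
        twists.append(p[5])
        mid_z.append(Tm[:, 2])
    bend = float(_bend_from_axes(np.asarray(mid_z)))
    return GlobalDescriptors(helical_bend=bend,
                             total_twist=float(np.sum(twists)),
                             step_range=(start, stop))


# ---------------------------------------------------------------------------
# trajectory driver


@dataclass
class TrajectoryAnalysis:
    """Per-frame helical coordinate series of one trajectory.

    Arrays: ``intra`` (F, N, 6), ``inter`` (F, N-1, 6), ``chi`` (F, N, 2)
    (column 0 Watson, 1 Crick), ``bend``/``total_twist`` (F,), pair frames
    ``pair_rot`` (F, N, 3, 3) / ``pair_org`` (F, N, 3) and mid-step frames.
    """

    intra: np.ndarray
    inter: np.ndarray
    chi: np.ndarray
    bend: np.ndarray
    total_twist: np.ndarray
    pair_rot: np.ndarray
    pair_org: np.ndarray
    step_rot: np.ndarray
    step_org: np.ndarray
    fit_rms: np.ndarray
    step_range: tuple[int, int]
    frame_dt: float = 1.0
    metadata: dict = field(default_factory=dict)

    @property
    def n_frames(self) -> int:
        return self.intra.shape[0]

    @property
    def n_pairs(self) -> int:
        return self.intra.shape[1]

    def intra_series(self, parameter: str) -> np.ndarray:
        return self.intra[:, :, INTRA_NAMES.index(parameter)]

    def inter_series(self, parameter: str) -> np.ndarray:
        return self.inter[:, :, INTER_NAMES.index(parameter)]

    def opening_series(self, pair_index: int) -> np.ndarray:
        return self.intra[:, pair_index, INTRA_NAMES.index("opening")]

    def chi_conformer_fractions(self) -> pd.DataFrame:
        """Occupancy of chi conformer bins per nucleotide."""
        rows = []
        for strand, col in (("W", 0), ("C", 1)):
            for i in range(self.n_pairs):
                vals = self.chi[:, i, col]
                labels = [classify_chi(v) for v in vals]
                for conf in list(CHI_BINS) + ["other"]:
                    frac = labels.count(conf) / len(labels)
                    rows.append((strand, i, conf, frac))
        return pd.DataFrame(rows, columns=["strand", "pair", "conformer",
                                           "fraction"])

    def summary(self) -> pd.DataFrame:
        """Tidy per-position means and SDs of every helical coordinate."""
        rows = []
        for j, name in enumerate(INTRA_NAMES):
            for i in range(self.n_pairs):
                v = self.intra[:, i, j]
                rows.append(("intra", i, name, v.mean(), v.std(ddof=1)))
        for j, name in enumerate(INTER_NAMES):
            for i in range(self.n_pairs - 1):
                v = self.inter[:, i, j]
                rows.append(("inter", i, name, v.mean(), v.std(ddof=1)))
        for name, v in (("helical_bend", self.bend),
                        ("total_twist", self.total_twist)):
            rows.append(("global", -1, name, v.mean(), v.std(ddof=1)))
        return pd.DataFrame(rows, columns=["kind", "index", "parameter",
                                           "mean", "sd"])

    def to_frame(self) -> pd.DataFrame:
        """Long-form per-frame table (frame, kind, index, parameter, value)."""
        recs = []
        F, N = self.intra.shape[:2]
        frames = np.arange(F)
        for j, name in enumerate(INTRA_NAMES):
            for i in range(N):
                recs.append(pd.DataFrame({
                    "frame": frames, "kind": "intra", "index": i,
                    "parameter": name, "value": self.intra[:, i, j]}))
        for j, name in enumerate(INTER_NAMES):
            for i in range(N - 1):
                recs.append(pd.DataFrame({
                    "frame": frames, "kind": "inter", "index": i,
                    "parameter": name, "value": self.inter[:, i, j]}))
        return pd.concat(recs, ignore_index=True)


def base_frames_batch(traj: Trajectory):
    """Fit Watson and Crick base frames for every pair of every frame.

    Returns rotations (F, N, 2, 3, 3), origins (F, N, 2, 3) and fit RMS
    (F, N, 2); axis 2 is strand (0 Watson, 1 Crick).
    """
    topo = traj.topology
    n = topo.n_pairs
    F = traj.n_frames
    rot = np.empty((F, n, 2, 3, 3))
    org = np.empty((F, n, 2, 3))
    rms = np.empty((F, n, 2))
    for s, getter in enumerate((topo.watson, topo.crick)):
        by_type: dict[str, list[int]] = {}
        for i in range(n):
            by_type.setdefault(getter(i).base, []).append(i)
        for base, idx in by_type.items():
            ring = bases.RING_ATOMS[base]
            cols = np.array([[getter(i).atom_index(a) for a in ring]
                             for i in idx])  # (k, n_ring)
            obs = traj.coords[:, cols, :]  # (F, k, n_ring, 3)
            R, t, r = kabsch_batch(bases.ring_coords(base), obs)
            rot[:, idx, s] = R
            org[:, idx, s] = t
            rms[:, idx, s] = r
    return rot, org, rms


def pair_frame_series(traj: Trajectory, position: int):
    """Pair frame of one position for every frame: (F, 3, 3), (F, 3).

    Cheaper than a full analysis when only one pair's frame is needed
    (e.g. to anchor the cylindrical system of an ion map).
    """
    topo = traj.topology
    rot = np.empty((traj.n_frames, 2, 3, 3))
    org = np.empty((traj.n_frames, 2, 3))
    for s, res in enumerate((topo.watson(position), topo.crick(position))):
        ring = bases.RING_ATOMS[res.base]
        cols = np.array([res.atom_index(a) for a in ring])
        R, t, _ = kabsch_batch(bases.ring_coords(res.base),
                               traj.coords[:, cols, :])
        rot[:, s] = R
        org[:, s] = t
    flip_c = rot[:, 1] @ FLIP_X
    _, Tm, om = step_decompose_batch(flip_c, org[:, 1], rot[:, 0], org[:, 0])
    return Tm, om


def analyze_trajectory(traj: Trajectory,
                       step_range: tuple[int, int] | None = None
                       ) -> TrajectoryAnalysis:
    """Full helical-coordinate series for a trajectory.

    Fits all base frames, decomposes intra-pair and step parameters with the
    shared mid-frame scheme, computes per-nucleotide chi and the global
    descriptors of every snapshot.
    """
    topo = traj.topology
    n = topo.n_pairs
    if n < 2:
        raise ValueError("trajectory must contain a duplex of >= 2 pairs")
    rot, org, rms = base_frames_batch(traj)
    flip_c = rot[:, :, 1] @ FLIP_X
    intra, Tp, op = step_decompose_batch(flip_c, org[:, :, 1],
                                         rot[:, :, 0], org[:, :, 0])
    inter, Ts, os_ = step_decompose_batch(Tp[:, :-1], op[:, :-1],
                                          Tp[:, 1:], op[:, 1:])
    # chi for both strands
    F = traj.n_frames
    chi = np.empty((F, n, 2))
    for s, getter in enumerate((topo.watson, topo.crick)):
        pts = np.empty((4, F, n, 3))
        for i in range(n):
            res = getter(i)
            names = bases.CHI_ATOMS[res.base]
            for k, a in enumerate(names):
                pts[k, :, i] = traj.coords[:, res.atom_index(a)]
        chi[:, :, s] = dihedral_batch(pts[0], pts[1], pts[2], pts[3])
    explicit_range = step_range is not None
    if step_range is None:
        step_range = default_step_range(n)
    start, stop = step_range
    feasible = 0 <= start < stop <= n - 1 and stop - start >= 3
    if not feasible and explicit_range:
        raise ValueError(f"invalid step range {step_range} for {n} pairs")
    twist_col = INTER_NAMES.index("twist")
    if feasible:
        total_twist = inter[:, start:stop, twist_col].sum(axis=1)
        bend = _bend_from_axes(Ts[:, start:stop, :, 2])
    else:  # duplex too short for global descriptors; local series still valid
        total_twist = np.full(F, np.nan)
        bend = np.full(F, np.nan)
    return TrajectoryAnalysis(
        intra=intra, inter=inter, chi=chi, bend=bend,
        total_twist=total_twist, pair_rot=Tp, pair_org=op,
        step_rot=Ts, step_org=os_, fit_rms=rms, step_range=(start, stop),
        frame_dt=traj.frame_dt, metadata=dict(traj.metadata),
    )


def analyze_structure(structure: Structure,
                      step_range: tuple[int, int] | None = None
                      ) -> TrajectoryAnalysis:
    """Single-snapshot convenience wrapper around :func:`analyze_trajectory`."""
    traj = Trajectory(structure.topology, structure.coords[None])
    return analyze_trajectory(traj, step_range=step_range)
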