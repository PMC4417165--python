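"""Radial-angular cation density maps at a base-pair plane.

Cations are binned in the cylindrical system of the local pair frame at a
chosen position: z along the local helix axis, theta = 0 along the pair x
axis, which points at the major-groove center.  Counts accumulated over
frames convert to molarity through the bin volume and the Avogadro factor
6.022e-4 ions per cubic angstrom per molar; the conversion is exactly
invertible, so the stored map always reproduces the mean ion count.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .frames import pair_frame_series
from .simulate import MOLAR_PER_A3, IonEnsemble
from .structure import Trajectory

__all__ = ["IonDensityMap", "ion_density_map", "default_r_edges",
           "default_theta_edges"]


def default_r_edges() -> np.ndarray:
    """0..16 A in 0.5 A rings."""
    return np.arange(0.0, 16.0 + 1e-9, 0.5)


def default_theta_edges() -> np.ndarray:
    """0..360 deg in 10 deg sectors."""
    return np.arange(0.0, 360.0 + 1e-9, 10.0)


@dataclass
class IonDensityMap:
    """Cation molarity on a radial x angular grid in a base-pair slab."""

    r_edges: np.ndarray
    theta_edges: np.ndarray  # deg
    half_thickness: float
    molarity: np.ndarray  # (n_r, n_theta), M
    counts: np.ndarray  # raw accumulated counts
    frame_count: int
    center_position: int

    def bin_volumes(self) -> np.ndarray:
        r = np.asarray(self.r_edges)
        th = np.deg2rad(np.asarray(self.theta_edges))
        ring = 0.5 * (r[1:] ** 2 - r[:-1] ** 2)
        return np.outer(ring, np.diff(th)) * 2 * self.half_thickness

    def mean_count(self) -> float:
        """Mean in-slab ion count per frame implied by the stored map."""
        return float(np.sum(self.molarity * self.bin_volumes() * MOLAR_PER_A3))

    def to_frame(self) -> pd.DataFrame:
        r_mid = 0.5 * (self.r_edges[:-1] + self.r_edges[1:])
        th_mid = 0.5 * (self.theta_edges[:-1] + self.theta_edges[1:])
        rr, tt = np.meshgrid(r_mid, th_mid, indexing="ij")
        return pd.DataFrame({
            "r_mid": rr.ravel(), "theta_mid": tt.ravel(),
            "molarity": self.molarity.ravel(),
            "count": self.counts.ravel(),
        })

    def render(self, ax=None, vmax: float | None = 5.0):
        """Polar heatmap; color clipping is presentation-only."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(subplot_kw={"projection": "polar"})
        th = np.deg2rad(self.theta_edges)
        mesh = ax.pcolormesh(th, self.r_edges, self.molarity,
                             vmin=0.0, vmax=vmax, cmap="jet")
        ax.figure.colorbar(mesh, ax=ax, label="molarity (M)")
        return ax


def ion_density_map(traj: Trajectory | IonEnsemble, center_position: int = -1,
                    r_edges=None, theta_edges=None,
                    half_thickness: float = 1.7,
                    pair_frames=None) -> IonDensityMap:
    """Accumulate a cation molarity map over a trajectory.

    ``traj`` is either an atomic trajectory carrying ion records (pair
    frames fitted from coordinates frame by frame unless ``pair_frames``
    supplies precomputed ``(rotations (F,3,3), origins (F,3))``) or a bare
    :class:`IonEnsemble`, binned in its own fixed generating frame.
    """
    if isinstance(traj, IonEnsemble):
        F = traj.n_frames
        ion_frames = traj.frames
        Tm = np.broadcast_to(traj.center_rotation, (F, 3, 3))
        om = np.broadcast_to(traj.center_origin, (F, 3))
    else:
        F = traj.n_frames
        ion_frames = traj.ions
        if pair_frames is None:
            Tm, om = pair_frame_series(traj, center_position)
        else:
            Tm, om = pair_frames
    if F == 0:
        raise ValueError("no frames")
    r_edges = default_r_edges() if r_edges is None else np.asarray(r_edges, float)
    theta_edges = (default_theta_edges() if theta_edges is None
                   else np.asarray(theta_edges, float))
    if np.any(np.diff(r_edges) <= 0) or np.any(np.diff(theta_edges) <= 0):
        raise ValueError("bin edges must be strictly increasing")
    if half_thickness <= 0:
        raise ValueError("zero-volume slab")
    counts = np.zeros((r_edges.size - 1, theta_edges.size - 1))
    for f in range(F):
        ions = None if ion_frames is None else ion_frames[f]
        if ions is None or len(ions) == 0:
            continue
        local = (np.asarray(ions) - om[f]) @ Tm[f]
        keep = np.abs(local[:, 2]) <= half_thickness
        if not keep.any():
            continue
        r = np.hypot(local[keep, 0], local[keep, 1])
        th = np.degrees(np.arctan2(local[keep, 1], local[keep, 0])) % 360.0
        h, _, _ = np.histogram2d(r, th, bins=(r_edges, theta_edges))
        counts += h
    r = r_edges
    ring = 0.5 * (r[1:] ** 2 - r[:-1] ** 2)
    vols = np.outer(ring, np.diff(np.deg2rad(theta_edges))) * 2 * half_thickness
    molarity = counts / F / (vols * MOLAR_PER_A3)
    return IonDensityMap(r_edges=r_edges, theta_edges=theta_edges,
                         half_thickness=half_thickness, molarity=molarity,
                         counts=counts, frame_count=F,
                         center_position=center_position)
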