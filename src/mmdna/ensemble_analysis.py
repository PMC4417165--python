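"""Ensemble-level summaries: average structure and RMSd, cluster
representatives, harmonic stiffness constants and series correlations.

Stiffness follows equipartition for a harmonic degree of freedom: a series
with thermal variance Var(x) at temperature T has force constant
k = k_B T / Var(x) (kcal/mol per squared unit of x), so softer distributions
mean smaller constants.  Only scalar (univariate) constants are computed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from ._rotations import kabsch_batch
from .structure import Topology, Trajectory

__all__ = [
    "KB_KCAL_MOL_K",
    "EnsembleSummary",
    "StiffnessSet",
    "rmsd_and_average",
    "pairwise_rmsd",
    "cluster_representative",
    "stiffness_constants",
    "stiffness_from_series",
    "series_correlations",
    "interior_atom_indices",
]

KB_KCAL_MOL_K = 1.987204259e-3  # Boltzmann constant, kcal/mol/K


def interior_atom_indices(topology: Topology, trim: int = 1) -> np.ndarray:
    """Atom indices of the interior pairs (``trim`` pairs dropped per end),
    the default selection against end fraying."""
    n = topology.n_pairs
    keep = set(range(trim, n - trim))
    idx = []
    for i in keep:
        for res in (topology.watson(i), topology.crick(i)):
            idx.extend(range(res.offset, res.offset + res.n_atoms))
    return np.array(sorted(idx), dtype=int)


@dataclass
class EnsembleSummary:
    """Average structure (on the analysed selection), per-frame RMSd (A),
    optional cluster labels and the representative frame index."""

    average_coords: np.ndarray
    rmsd: np.ndarray
    selection: np.ndarray
    cluster_labels: np.ndarray | None = None
    representative: int | None = None
    n_iterations: int = 0


def _align_to(ref: np.ndarray, coords: np.ndarray):
    """Superpose each frame of ``coords`` (F,n,3) onto ``ref`` (n,3).

    Returns aligned coordinates and the per-frame RMSd.
    """
    R, t, rms = kabsch_batch(ref, coords)
    # R maps ref -> frame; the inverse maps the frame onto ref
    aligned = np.einsum("fij,fnj->fni", np.swapaxes(R, 1, 2),
                        coords - t[:, None, :])
    return aligned, rms


def rmsd_and_average(traj: Trajectory, selection: np.ndarray | None = None,
                     tol: float = 1e-6, max_iter: int = 200
                     ) -> EnsembleSummary:
    """Iterative average structure and the RMSd of every frame to it.

    The average is refined by repeated superposition-to-mean until the mean
    displacement between successive averages drops below ``tol`` (A); the
    RMSd series is evaluated after optimal rigid superposition of each
    frame onto the converged average.
    """
    if traj.n_frames < 2:
        raise ValueError("averaging needs at least 2 frames")
    sel = (np.arange(traj.coords.shape[1]) if selection is None
           else np.asarray(selection, dtype=int))
    coords = traj.coords[:, sel, :]
    mean = coords[0].copy()
    n_it = 0
    for n_it in range(1, max_iter + 1):
        aligned, _ = _align_to(mean, coords)
        new_mean = aligned.mean(axis=0)
        shift = float(np.mean(np.linalg.norm(new_mean - mean, axis=1)))
        mean = new_mean
        if shift < tol:
            break
    _, rms = _align_to(mean, coords)
    return EnsembleSummary(average_coords=mean, rmsd=rms, selection=sel,
                           n_iterations=n_it)


def pairwise_rmsd(traj: Trajectory, selection: np.ndarray | None = None
                  ) -> np.ndarray:
    """Symmetric matrix of pairwise RMSd after optimal superposition."""
    sel = (np.arange(traj.coords.shape[1]) if selection is None
           else np.asarray(selection, dtype=int))
    coords = traj.coords[:, sel, :]
    F = coords.shape[0]
    D = np.zeros((F, F))
    for i in range(F - 1):
        _, _, rms = kabsch_batch(coords[i], coords[i + 1:])
        D[i, i + 1:] = rms
        D[i + 1:, i] = rms
    return D


def cluster_representative(traj: Trajectory, cutoff: float,
                           selection: np.ndarray | None = None
                           ) -> EnsembleSummary:
    """Average-linkage clustering at an RMSd cutoff; medoid of the largest
    cluster is the representative snapshot.

    Ties on cluster size resolve toward the cluster containing the lowest
    frame index; ties on the medoid's summed RMSd resolve toward the lowest
    frame index.
    """
    if traj.n_frames == 0:
        raise ValueError("empty trajectory")
    sel = (np.arange(traj.coords.shape[1]) if selection is None
           else np.asarray(selection, dtype=int))
    if traj.n_frames == 1:
        return EnsembleSummary(average_coords=traj.coords[0, sel],
                               rmsd=np.zeros(1), selection=sel,
                               cluster_labels=np.zeros(1, dtype=int),
                               representative=0)
    D = pairwise_rmsd(traj, sel)
    Z = linkage(squareform(D, checks=False), method="average")
    labels = fcluster(Z, t=cutoff, criterion="distance")
    sizes = {c: int(np.sum(labels == c)) for c in np.unique(labels)}
    max_size = max(sizes.values())
    candidates = [c for c, s in sizes.items() if s == max_size]
    winner = min(candidates,
                 key=lambda c: int(np.nonzero(labels == c)[0][0]))
    members = np.nonzero(labels == winner)[0]
    summed = D[np.ix_(members, members)].sum(axis=1)
    representative = int(members[np.lexsort((members, summed))[0]])
    avg = rmsd_and_average(traj, sel) if traj.n_frames >= 2 else None
    return EnsembleSummary(
        average_coords=avg.average_coords, rmsd=avg.rmsd, selection=sel,
        cluster_labels=labels, representative=representative,
        n_iterations=avg.n_iterations)


@dataclass
class StiffnessSet:
    """Univariate harmonic force constants from thermal fluctuations.

    Units: kcal/mol/deg^2 for angular series (bend, opening) and
    kcal/mol/A^2 for the minor groove width.  Zero-variance series carry an
    infinite constant and a degeneracy flag.
    """

    k_bend: float
    k_opening: float
    k_minw: float
    temperature: float
    variances: dict = field(default_factory=dict)
    degenerate: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "k_bend": self.k_bend, "k_opening": self.k_opening,
            "k_minw": self.k_minw, "temperature": self.temperature,
            "variances": dict(self.variances),
            "degenerate": dict(self.degenerate),
        }


def stiffness_from_series(series: np.ndarray, temperature: float = 298.0
                          ) -> tuple[float, float, bool]:
    """(force constant, variance, degenerate?) for one fluctuation series."""
    series = np.asarray(series, dtype=float)
    if series.size < 2:
        raise ValueError("need at least 2 samples")
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    var = float(series.var(ddof=1))
    if var == 0.0:
        return float("inf"), 0.0, True
    return KB_KCAL_MOL_K * temperature / var, var, False


def stiffness_constants(bend: np.ndarray, opening: np.ndarray,
                        minw: np.ndarray, temperature: float = 298.0
                        ) -> StiffnessSet:
    """Stiffness constants for global bend, lesion-pair opening and minor
    groove width (k = k_B T / Var)."""
    out = {}
    var = {}
    degen = {}
    for name, s in (("bend", bend), ("opening", opening), ("minw", minw)):
        k, v, flag = stiffness_from_series(s, temperature)
        out[name] = k
        var[name] = v
        degen[name] = flag
    return StiffnessSet(k_bend=out["bend"], k_opening=out["opening"],
                        k_minw=out["minw"], temperature=temperature,
                        variances=var, degenerate=degen)


def _fisher_lee(x: np.ndarray, y: np.ndarray) -> float:
    """Circular-circular correlation (Fisher-Lee), O(n) form."""
    x = np.deg2rad(x)
    y = np.deg2rad(y)
    n = x.size
    A = np.sum(np.cos(x) * np.cos(y))
    B = np.sum(np.sin(x) * np.sin(y))
    C = np.sum(np.cos(x) * np.sin(y))
    D = np.sum(np.sin(x) * np.cos(y))
    E = np.sum(np.cos(2 * x))
    Fv = np.sum(np.sin(2 * x))
    G = np.sum(np.cos(2 * y))
    H = np.sum(np.sin(2 * y))
    denom = np.sqrt((n ** 2 - E ** 2 - Fv ** 2) * (n ** 2 - G ** 2 - H ** 2))
    if denom == 0:
        return np.nan
    return float(4 * (A * B - C * D) / denom)


def _circular_linear(theta: np.ndarray, x: np.ndarray) -> float:
    """Mardia circular-linear association in [0, 1]."""
    th = np.deg2rad(theta)
    c, s = np.cos(th), np.sin(th)
    if np.std(x) == 0 or np.std(c) == 0 or np.std(s) == 0:
        return np.nan
    rxc = np.corrcoef(x, c)[0, 1]
    rxs = np.corrcoef(x, s)[0, 1]
    rcs = np.corrcoef(c, s)[0, 1]
    r2 = (rxc ** 2 + rxs ** 2 - 2 * rxc * rxs * rcs) / (1 - rcs ** 2)
    return float(np.sqrt(max(r2, 0.0)))


def series_correlations(series: dict[str, np.ndarray],
                        circular: set[str] | None = None) -> pd.DataFrame:
    """Correlation matrix of named series.

    Pearson for linear-linear pairs, Fisher-Lee for circular-circular and
    the Mardia coefficient (unsigned) for mixed pairs; ``circular`` names
    the angle-valued series.  Zero-variance series yield NaN entries.
    """
    circular = circular or set()
    names = list(series)
    arrays = {k: np.asarray(v, dtype=float) for k, v in series.items()}
    lengths = {v.size for v in arrays.values()}
    if len(lengths) != 1:
        raise ValueError("all series must have equal length")
    if lengths.pop() < 3:
        raise ValueError("need n >= 3")
    M = np.full((len(names), len(names)), np.nan)
    for i, a in enumerate(names):
        for j, b in enumerate(names):
            if j < i:
                continue
            xa, xb = arrays[a], arrays[b]
            if a in circular and b in circular:
                r = _fisher_lee(xa, xb)
            elif a not in circular and b not in circular:
                if np.std(xa) == 0 or np.std(xb) == 0:
                    r = np.nan if i != j else 1.0
                else:
                    r = float(np.corrcoef(xa, xb)[0, 1])
            else:
                th, lin = (xa, xb) if a in circular else (xb, xa)
                r = _circular_linear(th, lin)
            M[i, j] = M[j, i] = r
    return pd.DataFrame(M, index=names, columns=names)
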