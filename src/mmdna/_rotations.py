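"""Low-level rigid-body math shared by the builder and the analysers.

Everything here works in Cartesian angstroms and degrees. Rotation matrices
act on column vectors (``R @ v``); frames are (rotation, origin) pairs whose
columns are the frame axes expressed in lab coordinates.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "wrap_angle",
    "rot_z",
    "rot_y",
    "euler_zyz",
    "from_euler_zyz",
    "step_decompose",
    "step_compose",
    "euler_zyz_batch",
    "step_decompose_batch",
    "dihedral_batch",
    "mid_frame_split",
    "dihedral",
    "angle_between",
    "internal_to_cartesian",
    "kabsch",
    "kabsch_batch",
    "FLIP_X",
]

# 180 deg rotation about x: the strand-flip operator applied to Crick frames
FLIP_X = np.diag([1.0, -1.0, -1.0])


def wrap_angle(a):
    """Wrap angles (deg) into (-180, 180]."""
    w = -((-np.asarray(a, dtype=float) + 180.0) % 360.0 - 180.0)
    return w


def rot_z(deg: float) -> np.ndarray:
    r = np.deg2rad(deg)
    c, s = np.cos(r), np.sin(r)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def rot_y(deg: float) -> np.ndarray:
    r = np.deg2rad(deg)
    c, s = np.cos(r), np.sin(r)
    return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])


def euler_zyz(R: np.ndarray) -> tuple[float, float, float]:
    """Decompose ``R = Rz(a) @ Ry(b) @ Rz(g)`` with b in [0, 180).

    Returns angles in degrees. At the b -> 0 degeneracy only a+g is
    determined; a is set to 0 so downstream hinge phases vanish cleanly.
    """
    sb = float(np.hypot(R[0, 2], R[1, 2]))
    b = np.degrees(np.arctan2(sb, R[2, 2]))
    if sb < 1e-9:
        a = 0.0
        # R reduces to Rz(a+g) (b=0) or Rz(a-g)·Ry(180) (b=180, pathological)
        g = np.degrees(np.arctan2(R[1, 0], R[0, 0]))
    else:
        a = np.degrees(np.arctan2(R[1, 2], R[0, 2]))
        g = np.degrees(np.arctan2(R[2, 1], -R[2, 0]))
    return a, b, g


def from_euler_zyz(a: float, b: float, g: float) -> np.ndarray:
    return rot_z(a) @ rot_y(b) @ rot_z(g)


def step_decompose(T1, o1, T2, o2):
    """Mid-frame (CEHS-style) six-parameter decomposition of frame 2 vs frame 1.

    Returns ``(params, Tm, om)`` where params are
    (dx, dy, dz, tilt, roll, twist): translations of origin 2 relative to
    origin 1 expressed in the mid frame (A), and the hinge/twist angles (deg).
    The same routine serves intra-pair parameters (frame 1 = flipped Crick,
    frame 2 = Watson; params read shear, stretch, stagger, buckle, propeller,
    opening) and step parameters (consecutive pair frames).
    """
    R = T1.T @ T2
    a, b, g = euler_zyz(R)
    # a and g are each defined mod 360; pick the branch whose twist a+g lies
    # in (-180, 180] (shifting g by 360 flips the hinge phase by 180 and the
    # mid-frame x/y axes with it, keeping the decomposition self-consistent)
    if a + g > 180.0:
        g -= 360.0
    elif a + g <= -180.0:
        g += 360.0
    twist = a + g
    if np.hypot(R[0, 2], R[1, 2]) < 1e-6:
        # near-zero hinge: a and g are separately ill-conditioned but the
        # in-plane block gives their sum to O(b^2)
        twist = float(wrap_angle(np.degrees(np.arctan2(R[1, 0], R[0, 0]))))
    phi = 0.5 * (g - a)
    gamma = b
    tilt = gamma * np.sin(np.deg2rad(phi))
    roll = gamma * np.cos(np.deg2rad(phi))
    Tm = T1 @ rot_z(a) @ rot_y(0.5 * b) @ rot_z(phi)
    om = 0.5 * (np.asarray(o1) + np.asarray(o2))
    t = Tm.T @ (np.asarray(o2) - np.asarray(o1))
    params = np.array([t[0], t[1], t[2], tilt, roll, twist])
    return params, Tm, om


def step_compose(params, T1, o1):
    """Inverse of :func:`step_decompose`: place frame 2 from frame 1.

    Returns ``(T2, o2, Tm, om)``.
    """
    dx, dy, dz, tilt, roll, twist = (float(v) for v in params)
    gamma = float(np.hypot(tilt, roll))
    phi = np.degrees(np.arctan2(tilt, roll))
    a = 0.5 * twist - phi
    g = 0.5 * twist + phi
    T2 = T1 @ rot_z(a) @ rot_y(gamma) @ rot_z(g)
    Tm = T1 @ rot_z(a) @ rot_y(0.5 * gamma) @ rot_z(phi)
    o2 = np.asarray(o1, dtype=float) + Tm @ np.array([dx, dy, dz])
    om = 0.5 * (np.asarray(o1) + o2)
    return T2, o2, Tm, om


def mid_frame_split(params, Tm, om):
    """Place the two frames whose mid-frame decomposition equals ``params``.

    Given the target mid frame (Tm, om) and the six parameters, return
    ``(T1, o1, T2, o2)``.  Used by the builder to realise intra-pair
    parameters symmetrically about a pair frame.
    """
    dx, dy, dz, tilt, roll, twist = (float(v) for v in params)
    gamma = float(np.hypot(tilt, roll))
    phi = np.degrees(np.arctan2(tilt, roll))
    a = 0.5 * twist - phi
    g = 0.5 * twist + phi
    M = rot_z(a) @ rot_y(0.5 * gamma) @ rot_z(phi)
    T1 = Tm @ M.T
    T2 = T1 @ rot_z(a) @ rot_y(gamma) @ rot_z(g)
    half = 0.5 * (Tm @ np.array([dx, dy, dz]))
    o1 = np.asarray(om, dtype=float) - half
    o2 = np.asarray(om, dtype=float) + half
    return T1, o1, T2, o2


def _rot_z_batch(deg: np.ndarray) -> np.ndarray:
    r = np.deg2rad(np.asarray(deg, dtype=float))
    c, s = np.cos(r), np.sin(r)
    out = np.zeros(r.shape + (3, 3))
    out[..., 0, 0] = c
    out[..., 0, 1] = -s
    out[..., 1, 0] = s
    out[..., 1, 1] = c
    out[..., 2, 2] = 1.0
    return out


def _rot_y_batch(deg: np.ndarray) -> np.ndarray:
    r = np.deg2rad(np.asarray(deg, dtype=float))
    c, s = np.cos(r), np.sin(r)
    out = np.zeros(r.shape + (3, 3))
    out[..., 0, 0] = c
    out[..., 0, 2] = s
    out[..., 1, 1] = 1.0
    out[..., 2, 0] = -s
    out[..., 2, 2] = c
    return out


def euler_zyz_batch(R: np.ndarray):
    """Vectorised :func:`euler_zyz` over stacked matrices (..., 3, 3)."""
    sb = np.hypot(R[..., 0, 2], R[..., 1, 2])
    b = np.degrees(np.arctan2(sb, R[..., 2, 2]))
    degen = sb < 1e-9
    a = np.where(degen, 0.0,
                 np.degrees(np.arctan2(R[..., 1, 2], R[..., 0, 2])))
    g = np.where(degen,
                 np.degrees(np.arctan2(R[..., 1, 0], R[..., 0, 0])),
                 np.degrees(np.arctan2(R[..., 2, 1], -R[..., 2, 0])))
    return a, b, g


def step_decompose_batch(T1, o1, T2, o2):
    """Vectorised :func:`step_decompose` over stacks of frames."""
    R = np.swapaxes(T1, -1, -2) @ T2
    a, b, g = euler_zyz_batch(R)
    # branch choice as in step_decompose: twist in (-180, 180]
    g = g - 360.0 * (a + g > 180.0) + 360.0 * (a + g <= -180.0)
    twist = a + g
    small = np.hypot(R[..., 0, 2], R[..., 1, 2]) < 1e-6
    if np.any(small):  # near-zero hinge: use the well-conditioned sum
        direct = wrap_angle(np.degrees(np.arctan2(R[..., 1, 0],
                                                  R[..., 0, 0])))
        twist = np.where(small, direct, twist)
    phi = 0.5 * (g - a)
    gamma = b
    tilt = gamma * np.sin(np.deg2rad(phi))
    roll = gamma * np.cos(np.deg2rad(phi))
    Tm = T1 @ _rot_z_batch(a) @ _rot_y_batch(0.5 * b) @ _rot_z_batch(phi)
    om = 0.5 * (o1 + o2)
    t = np.einsum("...ji,...j->...i", Tm, o2 - o1)
    params = np.stack([t[..., 0], t[..., 1], t[..., 2],
                       tilt, roll, twist], axis=-1)
    return params, Tm, om


def dihedral_batch(p0, p1, p2, p3):
    """Vectorised signed torsion (deg) over stacked points (..., 3)."""
    b0 = p0 - p1
    b1 = p2 - p1
    b2 = p3 - p2
    b1n = b1 / np.linalg.norm(b1, axis=-1, keepdims=True)
    v = b0 - np.sum(b0 * b1n, axis=-1, keepdims=True) * b1n
    w = b2 - np.sum(b2 * b1n, axis=-1, keepdims=True) * b1n
    x = np.sum(v * w, axis=-1)
    y = np.sum(np.cross(b1n, v) * w, axis=-1)
    return wrap_angle(np.degrees(np.arctan2(y, x)))


def dihedral(p0, p1, p2, p3) -> float:
    """Signed torsion p0-p1-p2-p3 in degrees, in (-180, 180]."""
    b0 = np.asarray(p0) - np.asarray(p1)
    b1 = np.asarray(p2) - np.asarray(p1)
    b2 = np.asarray(p3) - np.asarray(p2)
    b1n = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1n) * b1n
    w = b2 - np.dot(b2, b1n) * b1n
    x = np.dot(v, w)
    y = np.dot(np.cross(b1n, v), w)
    return float(wrap_angle(np.degrees(np.arctan2(y, x))))


def angle_between(u, v) -> float:
    """Unsigned angle between two vectors in degrees, in [0, 180]."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    c = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def internal_to_cartesian(a, b, c, bond: float, angle_deg: float,
                          torsion_deg: float) -> np.ndarray:
    """Place atom d with |c-d| = bond, angle(b,c,d) = angle, torsion(a,b,c,d).

    Natural-extension reference frame construction; used to realise requested
    glycosidic torsions when placing the pseudo-O4' atom.
    """
    a, b, c = (np.asarray(p, dtype=float) for p in (a, b, c))
    ang = np.deg2rad(angle_deg)
    tor = np.deg2rad(torsion_deg)
    d_local = bond * np.array([
        -np.cos(ang),
        np.sin(ang) * np.cos(tor),
        np.sin(ang) * np.sin(tor),
    ])
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    M = np.column_stack([bc, m, n])
    return c + M @ d_local


def kabsch(ref: np.ndarray, obs: np.ndarray, return_rms: bool = False):
    """Optimal rigid superposition of ``ref`` onto ``obs`` (no scaling).

    Returns ``(R, t)`` with ``R @ ref_i + t ~= obs_i`` in the least-squares
    sense (proper rotation, det +1), optionally with the fit RMS.
    """
    ref = np.asarray(ref, dtype=float)
    obs = np.asarray(obs, dtype=float)
    rc = ref.mean(axis=0)
    oc = obs.mean(axis=0)
    H = (ref - rc).T @ (obs - oc)
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = oc - R @ rc
    if not return_rms:
        return R, t
    rms = float(np.sqrt(np.mean(np.sum((obs - (ref - rc) @ R.T - oc) ** 2,
                                       axis=1))))
    return R, t, rms


def kabsch_batch(ref: np.ndarray, obs: np.ndarray):
    """Vectorised Kabsch: ``ref`` (n,3) against ``obs`` (..., n, 3).

    Returns stacked rotations (..., 3, 3), translations (..., 3) and fit RMS
    (...,).  Used to fit every base frame of every snapshot in one shot.
    """
    ref = np.asarray(ref, dtype=float)
    obs = np.asarray(obs, dtype=float)
    rc = ref.mean(axis=0)
    oc = obs.mean(axis=-2)
    refc = ref - rc
    obsc = obs - oc[..., None, :]
    H = np.einsum("ni,...nj->...ij", refc, obsc)
    U, S, Vt = np.linalg.svd(H)
    det = np.linalg.det(np.swapaxes(Vt, -1, -2) @ np.swapaxes(U, -1, -2))
    D = np.zeros(H.shape)
    D[..., 0, 0] = 1.0
    D[..., 1, 1] = 1.0
    D[..., 2, 2] = np.sign(det)
    R = np.swapaxes(Vt, -1, -2) @ D @ np.swapaxes(U, -1, -2)
    t = oc - np.einsum("...ij,j->...i", R, rc)
    fit = np.einsum("...ij,nj->...ni", R, refc) + oc[..., None, :]
    rms = np.sqrt(np.mean(np.sum((obs - fit) ** 2, axis=-1), axis=-1))
    return R, t, rms
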