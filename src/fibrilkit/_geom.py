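"""Low-level vector geometry shared by the builder and the analysis suite.

Internal module: internal-coordinate (NeRF) atom placement, dihedral/angle
measurement, rigid-body superposition, amide-hydrogen reconstruction and the
Kabsch-Sander hydrogen-bond energy used for secondary-structure assignment.
All coordinates are in Angstrom, all angles in degrees unless noted.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "unit",
    "wrap_angle",
    "bond_angle",
    "dihedral",
    "place_atom",
    "rotation_matrix",
    "kabsch_rotation",
    "reconstruct_amide_hydrogens",
    "ks_hbond_energy",
]


def unit(v: np.ndarray) -> np.ndarray:
    """Return v scaled to unit length (last-axis norm)."""
    n = np.linalg.norm(v, axis=-1, keepdims=True)
    if np.any(n == 0):
        raise ValueError("cannot normalize zero-length vector")
    return v / n


def wrap_angle(a):
    """Wrap angle(s) in degrees into (-180, 180]."""
    a = np.asarray(a, dtype=float)
    out = -((-a + 180.0) % 360.0 - 180.0)
    return out if out.ndim else float(out)


def bond_angle(p0, p1, p2) -> float:
    """Angle at p1 spanned by p0 and p2, degrees in [0, 180]."""
    u = unit(np.asarray(p0, float) - p1)
    w = unit(np.asarray(p2, float) - p1)
    return float(np.degrees(np.arccos(np.clip(np.dot(u, w), -1.0, 1.0))))


def dihedral(p0, p1, p2, p3) -> float:
    """Signed torsion p0-p1-p2-p3 in degrees, IUPAC convention (trans = 180)."""
    p0, p1, p2, p3 = (np.asarray(p, float) for p in (p0, p1, p2, p3))
    b0 = p1 - p0
    b1 = p2 - p1
    b2 = p3 - p2
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    m1 = np.cross(n1, unit(b1))
    x = np.dot(n1, n2)
    y = np.dot(m1, n2)
    return float(wrap_angle(np.degrees(np.arctan2(y, x))))


def place_atom(a, b, c, bond: float, angle: float, torsion: float) -> np.ndarray:
    """NeRF placement: position D with |CD|=bond, angle(B,C,D)=angle and
    dihedral(A,B,C,D)=torsion (degrees)."""
    a, b, c = (np.asarray(p, float) for p in (a, b, c))
    ang = np.radians(angle)
    tor = np.radians(torsion)
    d_local = np.array(
        [
            -bond * np.cos(ang),
            bond * np.sin(ang) * np.cos(tor),
            -bond * np.sin(ang) * np.sin(tor),
        ]
    )
    bc = unit(c - b)
    n = unit(np.cross(b - a, bc))
    m = np.cross(n, bc)
    frame = np.column_stack([bc, m, n])
    return c + frame @ d_local


def rotation_matrix(axis, angle_deg: float) -> np.ndarray:
    """Rotation about `axis` (through the origin) by `angle_deg`, right-handed."""
    ax = unit(np.asarray(axis, float))
    t = np.radians(angle_deg)
    ct, st = np.cos(t), np.sin(t)
    x, y, z = ax
    cross = np.array([[0, -z, y], [z, 0, -x], [-y, x, 0]])
    return ct * np.eye(3) + st * cross + (1 - ct) * np.outer(ax, ax)


def kabsch_rotation(mobile: np.ndarray, target: np.ndarray):
    """Optimal rigid superposition of `mobile` onto `target` (both (N,3)).

    Returns (R, t) with target ~= mobile @ R.T + t, proper rotation only.
    """
    mobile = np.asarray(mobile, float)
    target = np.asarray(target, float)
    mc = mobile.mean(axis=0)
    tc = target.mean(axis=0)
    H = (mobile - mc).T @ (target - tc)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = tc - R @ mc
    return R, t


# --- hydrogen-bond machinery -------------------------------------------------

_NH_BOND = 1.01  # amide N-H length, Angstrom


def reconstruct_amide_hydrogens(n_xyz, ca_xyz, c_prev_xyz, has_prev):
    """Geometric amide-H positions (bisector convention).

    H sits on the external bisector of C(i-1)-N(i)-CA(i).  Residues without a
    preceding peptide bond (chain starts) get NaN; callers must also exclude
    prolines, which carry no amide H.
    """
    n_xyz = np.asarray(n_xyz, float)
    ca_xyz = np.asarray(ca_xyz, float)
    c_prev_xyz = np.asarray(c_prev_xyz, float)
    has_prev = np.asarray(has_prev, bool)
    h = np.full_like(n_xyz, np.nan)
    if np.any(has_prev):
        u1 = unit(n_xyz[has_prev] - c_prev_xyz[has_prev])
        u2 = unit(n_xyz[has_prev] - ca_xyz[has_prev])
        h[has_prev] = n_xyz[has_prev] + _NH_BOND * unit(u1 + u2)
    return h


_KS_Q1Q2_F = 0.084 * 332.0  # partial charges times electrostatic factor, kcal/mol*A


def ks_hbond_energy(n_xyz, h_xyz, c_xyz, o_xyz):
    """Kabsch-Sander electrostatic H-bond energy matrix, kcal/mol.

    Entry (i, j) is the energy of donor i (N-H) against acceptor j (C=O):
    E = 0.084 * 332 * (1/r_ON + 1/r_CH - 1/r_OH - 1/r_CN).  Donors with NaN
    hydrogens give +inf rows (no bond possible).
    """
    n_xyz = np.asarray(n_xyz, float)
    h_xyz = np.asarray(h_xyz, float)
    c_xyz = np.asarray(c_xyz, float)
    o_xyz = np.asarray(o_xyz, float)

    def dist(a, b):
        d = a[:, None, :] - b[None, :, :]
        return np.linalg.norm(d, axis=-1)

    with np.errstate(invalid="ignore", divide="ignore"):
        e = _KS_Q1Q2_F * (
            1.0 / dist(n_xyz, o_xyz)
            + 1.0 / dist(h_xyz, c_xyz)
            - 1.0 / dist(h_xyz, o_xyz)
            - 1.0 / dist(n_xyz, c_xyz)
        )
    e[~np.isfinite(e)] = np.inf
    # DSSP-style clamp: overlapping atoms must not yield runaway energies
    return np.maximum(e, -9.9)
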