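"""Independent brute-force oracles used only by the tests.

Each oracle takes a different computational route than the library:
superposition via the quaternion eigenvector method, dihedrals via the
raw normal-vector atan2 formula, contacts and region totals via direct
enumeration.
"""

from __future__ import annotations

import numpy as np


def quaternion_superpose_rmsd(mobile: np.ndarray, reference: np.ndarray) -> float:
    """Optimal-superposition RMSD via the Horn quaternion method."""
    x = np.asarray(mobile, float) - np.mean(mobile, axis=0)
    y = np.asarray(reference, float) - np.mean(reference, axis=0)
    n = x.shape[0]
    M = x.T @ y
    Sxx, Sxy, Sxz = M[0]
    Syx, Syy, Syz = M[1]
    Szx, Szy, Szz = M[2]
    K = np.array([
        [Sxx + Syy + Szz, Syz - Szy, Szx - Sxz, Sxy - Syx],
        [Syz - Szy, Sxx - Syy - Szz, Sxy + Syx, Szx + Sxz],
        [Szx - Sxz, Sxy + Syx, -Sxx + Syy - Szz, Syz + Szy],
        [Sxy - Syx, Szx + Sxz, Syz + Szy, -Sxx - Syy + Szz],
    ])
    lam = np.linalg.eigvalsh(K)[-1]
    msd = max((np.sum(x ** 2) + np.sum(y ** 2) - 2.0 * lam) / n, 0.0)
    return float(np.sqrt(msd))


def quaternion_rotation(mobile: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Optimal rotation matrix from the same quaternion eigenproblem."""
    x = np.asarray(mobile, float) - np.mean(mobile, axis=0)
    y = np.asarray(reference, float) - np.mean(reference, axis=0)
    M = x.T @ y
    Sxx, Sxy, Sxz = M[0]
    Syx, Syy, Syz = M[1]
    Szx, Szy, Szz = M[2]
    K = np.array([
        [Sxx + Syy + Szz, Syz - Szy, Szx - Sxz, Sxy - Syx],
        [Syz - Szy, Sxx - Syy - Szz, Sxy + Syx, Szx + Sxz],
        [Szx - Sxz, Sxy + Syx, -Sxx + Syy - Szz, Syz + Szy],
        [Sxy - Syx, Szx + Sxz, Syz + Szy, -Sxx - Syy + Szz],
    ])
    w, v = np.linalg.eigh(K)
    q0, q1, q2, q3 = v[:, -1]
    return np.array([
        [q0*q0 + q1*q1 - q2*q2 - q3*q3, 2*(q1*q2 - q0*q3), 2*(q1*q3 + q0*q2)],
        [2*(q1*q2 + q0*q3), q0*q0 - q1*q1 + q2*q2 - q3*q3, 2*(q2*q3 - q0*q1)],
        [2*(q1*q3 - q0*q2), 2*(q2*q3 + q0*q1), q0*q0 - q1*q1 - q2*q2 + q3*q3],
    ])


def dihedral_normals(p1, p2, p3, p4) -> float:
    """Dihedral (degrees) via plane normals and atan2, IUPAC sign."""
    p1, p2, p3, p4 = (np.asarray(p, float) for p in (p1, p2, p3, p4))
    b1, b2, b3 = p2 - p1, p3 - p2, p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m1 = np.cross(n1, b2 / np.linalg.norm(b2))
    x = np.dot(n1, n2)
    y = np.dot(m1, n2)
    ang = -float(np.degrees(np.arctan2(y, x)))
    return 180.0 if ang <= -180.0 + 1e-12 else ang


def brute_force_contacts(coords: np.ndarray, threshold: float) -> np.ndarray:
    """All-pairs strict-< adjacency matrix by explicit double loop."""
    n = coords.shape[0]
    adj = np.zeros((n, n), dtype=bool)
    for i in range(n):
        for j in range(n):
            if i != j:
                d = float(np.sqrt(np.sum((coords[i] - coords[j]) ** 2)))
                adj[i, j] = d < threshold
    return adj


def enumerate_region_total(ranges, merge: bool) -> int:
    """Residue count of ranges by explicit enumeration."""
    if merge:
        seen = set()
        for r in ranges:
            for s in range(r.start, r.end + 1):
                seen.add((r.chain_id, s))
        return len(seen)
    return sum(r.end - r.start + 1 for r in ranges)
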