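"""Independent oracles used by the test suite.

These deliberately avoid the code paths they check: the quaternion
eigenvalue method and a sampled-rotation brute force for the optimal
superposition RMSD, plain dynamic programming for global alignment scores,
and exhaustive string enumeration for insertion degeneracy.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.transform import Rotation


def quaternion_rmsd(P: np.ndarray, Q: np.ndarray) -> float:
    """Optimal superposition RMSD via the Horn quaternion eigenvalue method."""
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    Pc = P - P.mean(axis=0)
    Qc = Q - Q.mean(axis=0)
    M = Pc.T @ Qc
    Sxx, Sxy, Sxz = M[0]
    Syx, Syy, Syz = M[1]
    Szx, Szy, Szz = M[2]
    K = np.array(
        [
            [Sxx + Syy + Szz, Syz - Szy, Szx - Sxz, Sxy - Syx],
            [Syz - Szy, Sxx - Syy - Szz, Sxy + Syx, Szx + Sxz],
            [Szx - Sxz, Sxy + Syx, -Sxx + Syy - Szz, Syz + Szy],
            [Sxy - Syx, Szx + Sxz, Syz + Szy, -Sxx - Syy + Szz],
        ]
    )
    lam = np.linalg.eigvalsh(K)[-1]
    sq = (Pc * Pc).sum() + (Qc * Qc).sum() - 2.0 * lam
    return float(np.sqrt(max(sq, 0.0) / P.shape[0]))


def brute_force_rotation_rmsd(P: np.ndarray, Q: np.ndarray) -> float:
    """Optimal RMSD by grid search over sampled rotations with refinement."""
    Pc = np.asarray(P, float) - np.asarray(P, float).mean(axis=0)
    Qc = np.asarray(Q, float) - np.asarray(Q, float).mean(axis=0)
    n = Pc.shape[0]

    def batch_rmsd(eulers: np.ndarray) -> np.ndarray:
        mats = Rotation.from_euler("zyz", eulers).as_matrix()  # (k,3,3)
        moved = np.einsum("kij,nj->kni", mats, Pc)
        d = moved - Qc[None]
        return np.sqrt((d * d).sum(axis=(1, 2)) / n)

    center = np.array([0.0, np.pi / 2, 0.0])
    widths = np.array([np.pi, np.pi / 2, np.pi])
    steps = 14
    best_val = np.inf
    for _ in range(10):
        axes = [np.linspace(c - w, c + w, steps) for c, w in zip(center, widths)]
        grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
        vals = batch_rmsd(grid)
        k = int(np.argmin(vals))
        if vals[k] < best_val:
            best_val = float(vals[k])
            center = grid[k]
        widths = widths * (2.5 / steps)
    return best_val


def nw_linear_gap_score(a: str, b: str, sub, gap: float) -> float:
    """Global-alignment optimum under a linear gap penalty (plain DP)."""
    n, m = len(a), len(b)
    M = np.full((n + 1, m + 1), -np.inf)
    M[0, :] = np.arange(m + 1) * gap
    M[:, 0] = np.arange(n + 1) * gap
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            M[i, j] = max(
                M[i - 1, j - 1] + sub[a[i - 1], b[j - 1]],
                M[i - 1, j] + gap,
                M[i, j - 1] + gap,
            )
    return float(M[n, m])


def pairing_score(a: str, b: str, pairs, sub, gap: float) -> float:
    """Score of an alignment reconstructed from its matched columns."""
    matched = sum(sub[a[i], b[j]] for i, j in pairs)
    n_gap_cols = (len(a) - len(pairs)) + (len(b) - len(pairs))
    return float(matched + gap * n_gap_cols)


def brute_force_insertion_products(sequence: str, residue: str = "A") -> set[str]:
    """Every distinct product of inserting ``residue`` at each internal site."""
    return {
        sequence[:i] + residue + sequence[i:] for i in range(1, len(sequence))
    }


def random_rigid_transform(rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """A uniformly random proper rotation and a random translation."""
    R = Rotation.random(random_state=np.random.RandomState(rng.integers(2**31))).as_matrix()
    t = rng.normal(scale=10.0, size=3)
    return R, t
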