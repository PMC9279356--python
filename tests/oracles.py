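"""Independent numerical oracles used only by the test suite.

These deliberately avoid the code paths they check: RMSD via the
quaternion (Davenport) eigenvalue method plus direct optimisation, SASA
via Shrake-Rupley point sampling.
"""

import numpy as np


def quaternion_rmsd(mobile: np.ndarray, reference: np.ndarray) -> float:
    """Minimum RMSD over proper rotations via the quaternion eigen method."""
    P = mobile - mobile.mean(axis=0)
    Q = reference - reference.mean(axis=0)
    M = P.T @ Q
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
    n = mobile.shape[0]
    sq = ((P**2).sum() + (Q**2).sum() - 2.0 * lam) / n
    return float(np.sqrt(max(sq, 0.0)))


def optimizer_rmsd(mobile: np.ndarray, reference: np.ndarray, n_starts: int = 8) -> float:
    """Brute-force RMSD minimisation over quaternion-parametrised rotations."""
    from scipy.optimize import minimize

    P = mobile - mobile.mean(axis=0)
    Q = reference - reference.mean(axis=0)
    n = mobile.shape[0]

    def rot(q):
        q = q / np.linalg.norm(q)
        w, x, y, z = q
        return np.array(
            [
                [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
                [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
                [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
            ]
        )

    def cost(q):
        return ((P @ rot(q).T - Q) ** 2).sum() / n

    rng = np.random.default_rng(1234)
    best = np.inf
    for _ in range(n_starts):
        q0 = rng.normal(size=4)
        res = minimize(cost, q0, method="Nelder-Mead",
                       options={"xatol": 1e-12, "fatol": 1e-16, "maxiter": 5000})
        best = min(best, res.fun)
    return float(np.sqrt(max(best, 0.0)))


def shrake_rupley_sasa(
    coords: np.ndarray,
    radii: np.ndarray,
    probe: float = 1.4,
    n_points: int = 1000,
    seed: int = 0,
) -> np.ndarray:
    """Numerical per-sphere SASA by uniform point sampling (test oracle)."""
    rng = np.random.default_rng(seed)
    pts = rng.normal(size=(n_points, 3))
    pts /= np.linalg.norm(pts, axis=1, keepdims=True)
    R = radii + probe
    n = coords.shape[0]
    out = np.zeros(n)
    for i in range(n):
        surf = coords[i] + R[i] * pts
        free = np.ones(n_points, dtype=bool)
        for j in range(n):
            if j == i:
                continue
            d = np.linalg.norm(surf - coords[j], axis=1)
            free &= d >= R[j]
        out[i] = free.mean() * 4.0 * np.pi * R[i] ** 2
    return out
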