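"""Deterministic unit-vector direction sets on the sphere.

Used for diffusion gradient schemes, spherical-harmonic quadrature,
non-negativity constraint grids, and the tracking direction codebook.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "fibonacci_hemisphere",
    "fibonacci_sphere",
    "electrostatic_directions",
    "sign_balanced",
]


def fibonacci_sphere(n: int) -> np.ndarray:
    """``n`` quasi-uniform points on the full unit sphere (golden-spiral)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    i = np.arange(n, dtype=float)
    phi = (1.0 + np.sqrt(5.0)) / 2.0
    z = 1.0 - (2.0 * i + 1.0) / n
    theta = 2.0 * np.pi * i / phi
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    pts = np.stack([r * np.cos(theta), r * np.sin(theta), z], axis=1)
    return pts / np.linalg.norm(pts, axis=1, keepdims=True)


def fibonacci_hemisphere(n: int) -> np.ndarray:
    """``n`` quasi-uniform points on the upper (z >= 0) hemisphere."""
    pts = fibonacci_sphere(2 * n)
    upper = pts[pts[:, 2] >= 0.0]
    if upper.shape[0] < n:  # boundary ties; top up from the reflected half
        extra = -pts[pts[:, 2] < 0.0]
        upper = np.vstack([upper, extra])
    return upper[:n]


def _antipodal_energy_grad(v: np.ndarray) -> tuple[float, np.ndarray]:
    # Coulomb energy over all pairs +/-v_i, +/-v_j (antipodally symmetric).
    n = v.shape[0]
    d_minus = v[:, None, :] - v[None, :, :]
    d_plus = v[:, None, :] + v[None, :, :]
    eye = np.eye(n, dtype=bool)
    r_m = np.linalg.norm(d_minus, axis=2)
    r_p = np.linalg.norm(d_plus, axis=2)
    r_m[eye] = np.inf
    np.clip(r_m, 1e-9, None, out=r_m)
    np.clip(r_p, 1e-9, None, out=r_p)
    energy = 0.5 * np.sum(1.0 / r_m) + 0.5 * np.sum(1.0 / r_p[~eye]) + np.sum(
        1.0 / r_p[eye]
    )
    grad = -np.sum(d_minus / r_m[..., None] ** 3, axis=1)
    grad -= np.sum(d_plus / r_p[..., None] ** 3, axis=1)
    return float(energy), grad


_ELECTROSTATIC_CACHE: dict = {}


def electrostatic_directions(n: int, n_iter: int = 200, lr: float = 5e-3) -> np.ndarray:
    """Antipodally-symmetric electrostatic-repulsion layout of ``n`` directions.

    Starts from a deterministic Fibonacci hemisphere and runs projected
    gradient descent on the Coulomb energy of the +/- point pairs; fully
    deterministic for fixed ``n`` (and cached, since the optimization is
    O(n_iter * n^2)).
    """
    key = (n, n_iter, lr)
    if key in _ELECTROSTATIC_CACHE:
        return _ELECTROSTATIC_CACHE[key].copy()
    v = fibonacci_hemisphere(n).copy()
    step = lr / max(n, 1)
    prev_e = np.inf
    for _ in range(n_iter):
        e, g = _antipodal_energy_grad(v)
        if e > prev_e:
            step *= 0.5
        prev_e = e
        # project gradient onto the tangent plane, step, renormalize
        g_t = g - np.sum(g * v, axis=1, keepdims=True) * v
        v = v - step * g_t
        v /= np.linalg.norm(v, axis=1, keepdims=True)
    _ELECTROSTATIC_CACHE[key] = v
    return v.copy()


def sign_balanced(directions: np.ndarray) -> np.ndarray:
    """Flip alternate directions so the set straddles both hemispheres.

    Antipodally-symmetric sampling schemes are conventionally stored with
    mixed signs so the mean direction is close to zero; flipping every other
    vector is a deterministic way to achieve that.
    """
    out = directions.copy()
    out[1::2] *= -1.0
    return out
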