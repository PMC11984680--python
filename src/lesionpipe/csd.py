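"""Tissue response estimation and single-shell 3-tissue constrained
spherical deconvolution (SS3T-CSD).

The decomposition models the diffusion signal in each voxel as the sum of an
anisotropic intracellular compartment (ICA, white-matter-like, expressed as a
fiber orientation distribution convolved with a white-matter response), an
isotropic intracellular compartment (ICI, gray-matter-like) and an isotropic
extracellular compartment (ECI, CSF-like free water).  Signal fractions are
the b0-equivalent contribution of each compartment, normalized to sum to one.

Spherical harmonics are real, even-order only (diffusion signal is antipodally
symmetric), ordered by ascending ``l`` with ``m`` running ``-l..l`` within each
degree (MRtrix coefficient ordering).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy.optimize import nnls
from scipy.special import lpmv

from ._sphere import electrostatic_directions
from .errors import InvalidSpecError, MissingTissueError

__all__ = [
    "SHBasis",
    "ResponseSet",
    "FODField",
    "TissueFractionField",
    "SS3TOptions",
    "sh_basis",
    "sh_n_coeffs",
    "sh_degrees",
    "estimate_responses",
    "fit_ss3t",
    "fit_ss3t_volume",
    "signal_fractions",
    "fod_amplitude",
]


# --------------------------------------------------------------------------
# real even spherical harmonics
# --------------------------------------------------------------------------

def sh_n_coeffs(lmax: int) -> int:
    """Number of even real SH coefficients up to ``lmax``."""
    return (lmax + 1) * (lmax + 2) // 2


def sh_degrees(lmax: int) -> tuple[np.ndarray, np.ndarray]:
    """Per-column ``(l, m)`` arrays for the even real SH basis."""
    ls, ms = [], []
    for l in range(0, lmax + 1, 2):
        for m in range(-l, l + 1):
            ls.append(l)
            ms.append(m)
    return np.asarray(ls), np.asarray(ms)


def _real_sh_matrix(directions: np.ndarray, lmax: int) -> np.ndarray:
    directions = np.atleast_2d(np.asarray(directions, dtype=float))
    norms = np.linalg.norm(directions, axis=1)
    if np.any(norms < 1e-12):
        raise InvalidSpecError("zero-norm direction in SH evaluation")
    u = directions / norms[:, None]
    cos_t = np.clip(u[:, 2], -1.0, 1.0)
    phi = np.arctan2(u[:, 1], u[:, 0])
    ls, ms = sh_degrees(lmax)
    out = np.empty((u.shape[0], ls.size))
    from math import factorial

    for j, (l, m) in enumerate(zip(ls, ms)):
        am = abs(m)
        norm = np.sqrt(
            (2 * l + 1) / (4.0 * np.pi) * factorial(l - am) / factorial(l + am)
        )
        p = lpmv(am, l, cos_t)
        if m == 0:
            out[:, j] = norm * p
        elif m > 0:
            out[:, j] = np.sqrt(2.0) * norm * p * np.cos(m * phi)
        else:
            out[:, j] = np.sqrt(2.0) * norm * p * np.sin(am * phi)
    return out


@dataclass(frozen=True)
class SHBasis:
    """Real, even-order, antipodally symmetric SH basis sampled at directions."""

    lmax: int
    directions: np.ndarray
    matrix: np.ndarray

    @property
    def n_coeffs(self) -> int:
        return sh_n_coeffs(self.lmax)


def sh_basis(directions: np.ndarray, lmax: int) -> SHBasis:
    """Evaluate the even real SH basis at unit ``directions``.

    Raises :class:`InvalidSpecError` for odd ``lmax``.
    """
    if lmax < 0 or lmax % 2 != 0:
        raise InvalidSpecError(f"lmax must be even and non-negative, got {lmax}")
    directions = np.atleast_2d(np.asarray(directions, dtype=float))
    return SHBasis(lmax=lmax, directions=directions,
                   matrix=_real_sh_matrix(directions, lmax))


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------

@dataclass
class ResponseSet:
    """Per-tissue, per-shell response functions on b0-normalized signal.

    ``wm`` maps shell b-value to the zonal (m=0) SH coefficients of the
    axially symmetric white-matter kernel aligned with +z; ``gm`` and ``csf``
    map shell b-value to the isotropic mean signal.  b0 amplitudes are stored
    per tissue (1.0 when responses are estimated on b0-normalized data).
    """

    shells: tuple[float, ...]
    wm: dict[float, np.ndarray]
    gm: dict[float, float]
    csf: dict[float, float]
    wm_b0: float = 1.0
    gm_b0: float = 1.0
    csf_b0: float = 1.0
    lmax: int = 8

    def __post_init__(self) -> None:
        bs = sorted(self.shells)
        csf_vals = [self.csf_b0] + [self.csf[b] for b in bs]
        if np.any(np.diff(csf_vals) > 1e-9):
            raise InvalidSpecError("CSF response must decrease with b-value")
        for b in bs:
            if self.wm[b][0] <= 0:
                raise InvalidSpecError("WM l=0 response coefficient must be positive")


@dataclass
class FODField:
    """Grid of even-SH FOD coefficients with its affine and fit mask."""

    coeffs: np.ndarray  # (X, Y, Z, n_coeffs)
    affine: np.ndarray
    lmax: int
    mask: np.ndarray | None = None

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.coeffs.shape[:3]


@dataclass
class TissueFractionField:
    """Per-voxel signal fractions (f_ECI, f_ICI, f_ICA), each in [0, 1].

    Voxels outside ``mask`` hold NaN and are excluded from statistics.
    """

    f_eci: np.ndarray
    f_ici: np.ndarray
    f_ica: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    mask: np.ndarray | None = None

    def stack(self) -> np.ndarray:
        """(X, Y, Z, 3) array ordered (f_ECI, f_ICI, f_ICA)."""
        return np.stack([self.f_eci, self.f_ici, self.f_ica], axis=-1)

    def check_simplex(self, atol: float = 1e-6) -> bool:
        m = self.mask if self.mask is not None else np.isfinite(self.f_eci)
        s = self.f_eci[m] + self.f_ici[m] + self.f_ica[m]
        return bool(np.all(np.abs(s - 1.0) <= atol))


# --------------------------------------------------------------------------
# response estimation
# --------------------------------------------------------------------------

def _rotation_to_z(v: np.ndarray) -> np.ndarray:
    """Rotation matrix R with R @ v = +z (v unit)."""
    v = v / np.linalg.norm(v)
    z = np.array([0.0, 0.0, 1.0])
    c = float(np.dot(v, z))
    if c > 1.0 - 1e-12:
        return np.eye(3)
    if c < -1.0 + 1e-12:
        return np.diag([1.0, -1.0, -1.0])
    axis = np.cross(v, z)
    s = np.linalg.norm(axis)
    axis = axis / s
    k = np.array([
        [0.0, -axis[2], axis[1]],
        [axis[2], 0.0, -axis[0]],
        [-axis[1], axis[0], 0.0],
    ])
    return np.eye(3) + s * k + (1.0 - c) * (k @ k)


def principal_fiber_direction(signal: np.ndarray, directions: np.ndarray) -> np.ndarray:
    """Dominant fiber axis of a single-fiber diffusion signal.

    Uses the leading eigenvector of the log-signal-weighted direction
    second-moment; the signal attenuates fastest along the fiber, so the
    axis of maximal attenuation is the fiber direction.
    """
    w = -np.log(np.clip(signal, 1e-6, None))
    w = np.clip(w, 0.0, None)
    m = (directions * w[:, None]).T @ directions
    vals, vecs = np.linalg.eigh(m)
    return vecs[:, -1]


def estimate_responses(dwi, tissue_masks: Mapping[str, np.ndarray],
                       lmax: int = 8) -> ResponseSet:
    """Estimate WM/GM/CSF response functions from labelled voxels.

    ``dwi`` is a :class:`~lesionpipe.phantom.DWIDataset`; ``tissue_masks``
    must provide nonempty boolean volumes under keys ``"wm"`` (single-fiber
    white matter), ``"gm"`` and ``"csf"``.  Signals are normalized per voxel
    by the mean b0 before estimation, so all b0 amplitudes are 1.
    """
    gtab = dwi.gtab
    data = np.asarray(dwi.data, dtype=float)
    for name in ("wm", "gm", "csf"):
        if name not in tissue_masks or not np.any(tissue_masks[name]):
            raise MissingTissueError(f"empty or missing tissue mask: {name!r}")

    b0 = data[..., gtab.b0_mask].mean(axis=-1)
    shells = gtab.shell_bvalues

    def _norm_signals(mask: np.ndarray) -> np.ndarray:
        vox = data[mask]
        denom = b0[mask][:, None]
        if np.any(denom <= 0):
            raise MissingTissueError("non-positive b0 signal inside tissue mask")
        return vox / denom

    wm_sig = _norm_signals(np.asarray(tissue_masks["wm"], dtype=bool))
    gm_sig = _norm_signals(np.asarray(tissue_masks["gm"], dtype=bool))
    csf_sig = _norm_signals(np.asarray(tissue_masks["csf"], dtype=bool))

    ls, ms = sh_degrees(lmax)
    zonal_cols = np.flatnonzero(ms == 0)
    wm_resp: dict[float, np.ndarray] = {}
    outer = max(shells)
    outer_idx = gtab.shell_mask(outer)
    outer_dirs = gtab.bvecs[outer_idx]

    per_shell_fits: dict[float, list[np.ndarray]] = {b: [] for b in shells}
    for sig in wm_sig:
        fiber = principal_fiber_direction(sig[outer_idx], outer_dirs)
        rot = _rotation_to_z(fiber)
        for b in shells:
            idx = gtab.shell_mask(b)
            dirs_rot = gtab.bvecs[idx] @ rot.T
            bz = _real_sh_matrix(dirs_rot, lmax)[:, zonal_cols]
            r, *_ = np.linalg.lstsq(bz, sig[idx], rcond=None)
            per_shell_fits[b].append(r)
    for b in shells:
        wm_resp[b] = np.mean(per_shell_fits[b], axis=0)

    gm_resp = {b: float(gm_sig[:, gtab.shell_mask(b)].mean()) for b in shells}
    csf_resp = {b: float(csf_sig[:, gtab.shell_mask(b)].mean()) for b in shells}
    return ResponseSet(shells=tuple(sorted(shells)), wm=wm_resp, gm=gm_resp,
                       csf=csf_resp, lmax=lmax)


# --------------------------------------------------------------------------
# constrained least squares (active set on hard inequality constraints)
# --------------------------------------------------------------------------

class _LDPSolver:
    """Exact solver for min ||a x - s||^2 subject to g x >= -eps.

    The full-column-rank system is reduced through its QR factorization to a
    least-distance problem, which the Lawson-Hanson transformation turns into
    a single non-negative least-squares solve (deterministic active set).
    Factorizations depend only on ``a``/``g`` and are cached, so per-voxel
    work is one small NNLS.
    """

    def __init__(self, a: np.ndarray, g: np.ndarray, eps: float = 1e-4):
        from scipy.linalg import qr, solve_triangular

        q, r = qr(a, mode="economic")
        if np.abs(np.diag(r)).min() < 1e-10 * np.abs(np.diag(r)).max():
            raise InvalidSpecError("rank-deficient deconvolution system "
                                   "(too few directions for lmax?)")
        self._q = q
        self._r = r
        self._c = solve_triangular(r, g.T, trans="T").T  # g @ inv(r)
        self._eps = float(eps)
        self._solve_tri = solve_triangular

    def solve(self, s: np.ndarray) -> np.ndarray:
        b = self._q.T @ s
        # least distance: min ||z|| s.t. c z >= d - c b,  z = y - b
        d = -self._eps - self._c @ b
        if np.all(d <= 1e-12):  # unconstrained optimum already feasible
            return self._solve_tri(self._r, b)
        e = np.vstack([self._c.T, d[None, :]])
        f = np.zeros(e.shape[0])
        f[-1] = 1.0
        u, _ = nnls(e, f)
        r = e @ u - f
        if abs(r[-1]) < 1e-12:
            raise InvalidSpecError("infeasible constraint set in deconvolution")
        z = -r[:-1] / r[-1]
        return self._solve_tri(self._r, z + b)


def constrained_lstsq(a: np.ndarray, s: np.ndarray, g: np.ndarray,
                      eps: float = 1e-4, max_iter: int = 60) -> np.ndarray:
    """min ||a x - s||^2 subject to g x >= -eps (exact, deterministic)."""
    return _LDPSolver(a, g, eps).solve(s)


# --------------------------------------------------------------------------
# SS3T fit
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SS3TOptions:
    """Solver options for :func:`fit_ss3t`."""

    n_constraint_dirs: int = 300
    eps: float = 1e-4
    l0_anchor: float = 30.0     # weight of the anisotropy anchor row
    shell: float | None = None  # outermost shell when None
    normalize_b0: bool = True
    rician_correction: bool = True  # second-moment magnitude debiasing


class _SS3TOperator:
    """Precomputed forward/constraint matrices shared across voxels."""

    def __init__(self, gtab, responses: ResponseSet, lmax: int,
                 options: SS3TOptions):
        if lmax % 2 != 0:
            raise InvalidSpecError("lmax must be even")
        self.gtab = gtab
        self.responses = responses
        self.lmax = lmax
        self.options = options
        shell = options.shell if options.shell is not None else max(gtab.shell_bvalues)
        if shell not in responses.wm:
            raise InvalidSpecError(f"no response for shell b={shell}")
        self.shell = shell

        b0_idx = np.flatnonzero(gtab.b0_mask)
        sh_idx = np.flatnonzero(gtab.shell_mask(shell))
        if b0_idx.size == 0:
            raise InvalidSpecError("gradient table has no b=0 measurements")
        n_coef = sh_n_coeffs(lmax)
        if sh_idx.size < n_coef:
            raise InvalidSpecError(
                f"shell has {sh_idx.size} directions; lmax={lmax} needs >= {n_coef}"
            )
        self.rows = np.concatenate([b0_idx, sh_idx])
        self.n_b0 = b0_idx.size

        ls, _ = sh_degrees(lmax)
        r = responses.wm[shell]
        l_even = np.arange(0, lmax + 1, 2)
        r_full = np.zeros(l_even.size)
        r_full[: r.size] = r[: l_even.size]
        conv = np.sqrt(4.0 * np.pi / (2 * ls + 1))
        r_per_col = r_full[ls // 2]
        y_shell = _real_sh_matrix(gtab.bvecs[sh_idx], lmax)
        a_fod_shell = y_shell * (conv * r_per_col)[None, :]
        a_fod_b0 = np.zeros((self.n_b0, n_coef))
        a_fod_b0[:, 0] = np.sqrt(4.0 * np.pi) * responses.wm_b0
        self.a_fod = np.vstack([a_fod_b0, a_fod_shell])

        self.gm_col = np.concatenate([
            np.full(self.n_b0, responses.gm_b0),
            np.full(sh_idx.size, responses.gm[shell]),
        ])
        self.csf_col = np.concatenate([
            np.full(self.n_b0, responses.csf_b0),
            np.full(sh_idx.size, responses.csf[shell]),
        ])

        cdirs = electrostatic_directions(options.n_constraint_dirs)
        self.g_amp = _real_sh_matrix(cdirs, lmax)
        self.n_coef = n_coef

        # joint system: FOD coefficients + (w_ICI, w_ECI), plus one anchor
        # row tying the FOD l=0 term to the anisotropy-implied WM fraction.
        # The single shell leaves {flat FOD, GM, CSF} degenerate (two
        # isotropic equations, three unknowns); the anchor resolves it by
        # requiring the WM compartment to carry no more isotropic signal
        # than its l=2 content implies for a single-fiber kernel.
        a_joint = np.column_stack([self.a_fod, self.gm_col, self.csf_col])
        anchor = np.zeros((1, n_coef + 2))
        anchor[0, 0] = np.sqrt(options.l0_anchor) * np.sqrt(4.0 * np.pi)
        self.a_joint = np.vstack([a_joint, anchor])
        g = np.zeros((self.g_amp.shape[0] + 2, n_coef + 2))
        g[:-2, :n_coef] = self.g_amp
        g[-2, n_coef] = 1.0
        g[-1, n_coef + 1] = 1.0
        self.g_joint = g
        self._solver = _LDPSolver(self.a_joint, self.g_joint, options.eps)

        # projector extracting the l=2 SH content of the shell signal, used
        # to estimate the WM fraction from anisotropic content alone:
        # for a single fiber, ||s_l||_2 = |r_l| * f_ICA for every even l >= 2
        pinv_y = np.linalg.pinv(y_shell)
        self._p2 = pinv_y[(ls >= 2) & (ls <= 2)]
        self._r2 = abs(float(r_full[1])) if r_full.size > 1 else 0.0

    # -- per-voxel pieces ------------------------------------------------
    def prepare(self, signal: np.ndarray) -> np.ndarray:
        signal = np.asarray(signal, dtype=float)
        if signal.shape[0] != len(self.gtab):
            raise InvalidSpecError("signal length does not match gradient table")
        s = signal[self.rows]
        b0_vals = signal[self.gtab.b0_mask]
        if self.options.normalize_b0:
            b0 = b0_vals.mean()
            if b0 <= 0:
                raise InvalidSpecError("non-positive b0 signal")
            s = s / b0
            b0_vals = b0_vals / b0
        if self.options.rician_correction and b0_vals.size >= 3:
            # magnitude (Rician) floor debiasing: E[M^2] = S^2 + 2 sigma^2,
            # with sigma estimated from the b0 replicates; exact no-op for
            # noiseless data (sigma_hat = 0)
            sigma2 = float(np.var(b0_vals, ddof=1))
            if sigma2 > 0:
                s = np.sqrt(np.clip(s * s - 2.0 * sigma2, 0.0, None))
        return s

    def anchor_value(self, s: np.ndarray) -> float:
        """Anisotropy-implied WM weight from the shell's l=2 content."""
        if self._r2 <= 1e-12:
            return 0.0
        w = float(np.linalg.norm(self._p2 @ s[self.n_b0:])) / self._r2
        return min(w, 1.5)

    def rhs_for(self, s: np.ndarray) -> np.ndarray:
        anchor = np.sqrt(self.options.l0_anchor) * self.anchor_value(s)
        return np.concatenate([s, [anchor]])

    def solve_prepared(self, s: np.ndarray
                       ) -> tuple[np.ndarray, tuple[float, float, float]]:
        x = self._solver.solve(self.rhs_for(s))
        return self.unpack(x)

    def unpack(self, x: np.ndarray) -> tuple[np.ndarray, tuple[float, float, float]]:
        c = x[: self.n_coef]
        w_ici = max(0.0, float(x[self.n_coef]))
        w_eci = max(0.0, float(x[self.n_coef + 1]))
        w_ica = max(0.0, self.responses.wm_b0 * np.sqrt(4.0 * np.pi) * float(c[0]))
        return c, (w_ica, self.responses.gm_b0 * w_ici,
                   self.responses.csf_b0 * w_eci)

    def fit(self, signal: np.ndarray
            ) -> tuple[np.ndarray, tuple[float, float, float]]:
        return self.solve_prepared(self.prepare(signal))


def fit_ss3t(dwi_voxel: np.ndarray, gtab, responses: ResponseSet,
             lmax: int = 8, options: SS3TOptions | None = None
             ) -> tuple[np.ndarray, tuple[float, float, float]]:
    """Single-voxel SS3T-CSD fit.

    Returns ``(fod_coefficients, (w_ICA, w_ICI, w_ECI))`` where the weights
    are b0-equivalent compartment contributions.  Fits the b0 measurements
    plus the outermost shell as one convex quadratic program: white-matter
    FOD coefficients (amplitude >= -eps on a dense direction set) plus
    non-negative isotropic GM/CSF weights, with a tiny ridge on the FOD l=0
    term that resolves the single-shell isotropic degeneracy in favor of the
    isotropic compartments.
    """
    op = _SS3TOperator(gtab, responses, lmax, options or SS3TOptions())
    return op.fit(np.asarray(dwi_voxel, dtype=float))


def fit_ss3t_volume(dwi, responses: ResponseSet, mask: np.ndarray | None = None,
                    lmax: int = 8, options: SS3TOptions | None = None
                    ) -> tuple[FODField, np.ndarray]:
    """Fit SS3T-CSD over all ``mask`` voxels of a DWI dataset.

    Returns the FOD field and a ``(X, Y, Z, 3)`` weight array ordered
    ``(w_ICA, w_ICI, w_ECI)`` (NaN outside the mask).
    """
    options = options or SS3TOptions()
    op = _SS3TOperator(dwi.gtab, responses, lmax, options)
    data = np.asarray(dwi.data, dtype=float)
    if mask is None:
        mask = dwi.brain_mask
    mask = np.asarray(mask, dtype=bool)
    shape = data.shape[:3]
    coeffs = np.zeros(shape + (op.n_coef,), dtype=float)
    weights = np.full(shape + (3,), np.nan)

    vox = np.argwhere(mask)
    signals = data[mask]
    # vectorized b0 normalization + batch unconstrained warm solve; only
    # voxels violating a constraint go through the per-voxel QP
    b0 = signals[:, dwi.gtab.b0_mask].mean(axis=1)
    good = b0 > 0
    s_all = signals[:, op.rows] / np.where(b0 > 0, b0, 1.0)[:, None]
    if options.rician_correction and int(dwi.gtab.b0_mask.sum()) >= 3:
        b0_norm = signals[:, dwi.gtab.b0_mask] / np.where(b0 > 0, b0, 1.0)[:, None]
        sigma2 = np.var(b0_norm, axis=1, ddof=1)
        s_all = np.sqrt(np.clip(s_all ** 2 - 2.0 * sigma2[:, None], 0.0, None))
    if op._r2 > 1e-12:
        anchors = np.minimum(
            np.linalg.norm(s_all[:, op.n_b0:] @ op._p2.T, axis=1) / op._r2, 1.5)
    else:
        anchors = np.zeros(s_all.shape[0])
    rhs = np.hstack([s_all,
                     (np.sqrt(options.l0_anchor) * anchors)[:, None]])
    x0_all, *_ = np.linalg.lstsq(op.a_joint, rhs.T, rcond=None)
    x0_all = x0_all.T
    viol = (op.g_joint @ x0_all.T < -options.eps).any(axis=0)

    for i, idx in enumerate(vox):
        if not good[i]:
            continue
        if viol[i]:
            c, w = op.unpack(op._solver.solve(rhs[i]))
        else:
            c, w = op.unpack(x0_all[i])
        coeffs[tuple(idx)] = c
        weights[tuple(idx)] = w
    fod = FODField(coeffs=coeffs, affine=np.asarray(dwi.affine, dtype=float),
                   lmax=lmax, mask=mask)
    return fod, weights


def signal_fractions(weights: np.ndarray, affine: np.ndarray | None = None,
                     mask: np.ndarray | None = None) -> TissueFractionField:
    """Normalize ``(w_ICA, w_ICI, w_ECI)`` weights to signal fractions.

    ``weights`` has shape ``(..., 3)``; all-zero or non-finite voxels are set
    to missing (NaN) and dropped from the returned mask.
    """
    w = np.asarray(weights, dtype=float)
    if w.shape[-1] != 3:
        raise InvalidSpecError("weights must have a trailing axis of length 3")
    if np.any(w[np.isfinite(w)] < 0):
        raise InvalidSpecError("compartment weights must be non-negative")
    total = w.sum(axis=-1)
    valid = np.isfinite(total) & (total > 0)
    if mask is not None:
        valid &= np.asarray(mask, dtype=bool)
    frac = np.full_like(w, np.nan)
    frac[valid] = w[valid] / total[valid][..., None]
    return TissueFractionField(
        f_eci=frac[..., 2], f_ici=frac[..., 1], f_ica=frac[..., 0],
        affine=np.eye(4) if affine is None else np.asarray(affine, dtype=float),
        mask=valid,
    )


def fod_amplitude(fod_voxel: np.ndarray, directions: np.ndarray,
                  clip: bool = True) -> np.ndarray:
    """FOD amplitude along ``directions`` (clipped at 0 for sampling use)."""
    fod_voxel = np.asarray(fod_voxel, dtype=float)
    lmax = _lmax_from_ncoef(fod_voxel.shape[-1])
    amp = _real_sh_matrix(directions, lmax) @ fod_voxel
    return np.clip(amp, 0.0, None) if clip else amp


def _lmax_from_ncoef(n: int) -> int:
    lmax = 0
    while sh_n_coeffs(lmax) < n:
        lmax += 2
    if sh_n_coeffs(lmax) != n:
        raise InvalidSpecError(f"{n} is not a valid even-SH coefficient count")
    return lmax


def zonal_response_from_kernel(kernel, bval: float, lmax: int,
                               n_quad: int = 4096) -> np.ndarray:
    """Zonal SH coefficients of an axially symmetric kernel ``kernel(cos_t, b)``.

    Numerical quadrature oracle used for validating estimated responses.
    """
    from numpy.polynomial.legendre import leggauss

    t, w = leggauss(n_quad)
    ls = np.arange(0, lmax + 1, 2)
    out = np.empty(ls.size)
    vals = kernel(t, bval)
    for i, l in enumerate(ls):
        norm = np.sqrt((2 * l + 1) / (4.0 * np.pi))
        from numpy.polynomial.legendre import Legendre

        pl = Legendre.basis(l)(t)
        out[i] = 2.0 * np.pi * norm * np.sum(w * vals * pl)
    return out
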