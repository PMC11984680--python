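"""Whole-volume probabilistic tractography on an FOD field.

Streamlines grow bidirectionally from random in-mask seeds; at each step the
next direction is sampled proportionally to the FOD amplitude (evaluated on
trilinearly interpolated SH coefficients) over a dense precomputed direction
codebook restricted to a cone around the incoming direction.  Amplitudes
below the cutoff are rejected; a streamline terminates when no direction in
the cone survives, when it exits the mask, or at the maximum length, and is
discarded when shorter than the minimum length.

Voxel visitation uses an exact segment-voxel traversal with the half-open
convention: voxel ``(i, j, k)`` is the box ``[i, i+1)`` per axis in grid
units (grid coordinate = world point mapped through the inverse affine, with
voxel centers at half-integers).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from ._sphere import electrostatic_directions
from .csd import FODField, _real_sh_matrix
from .errors import InvalidSpecError, TrackingError

__all__ = [
    "Streamline",
    "Tractogram",
    "TrackingParams",
    "seed_points",
    "propagate_streamline",
    "generate_tractogram",
    "sift_filter",
    "track_density_map",
    "streamline_voxels",
    "tractogram_voxel_pairs",
]


@dataclass
class Streamline:
    """Ordered polyline in world mm with its fixed step size."""

    points: np.ndarray  # (n, 3)
    step_size: float

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))

    @property
    def length(self) -> float:
        return (self.points.shape[0] - 1) * self.step_size

    def __len__(self) -> int:
        return self.points.shape[0]


@dataclass
class Tractogram:
    """A set of streamlines with grid provenance."""

    streamlines: list[Streamline]
    affine: np.ndarray
    seed_count: int = 0
    rng_seed: int | None = None

    def __len__(self) -> int:
        return len(self.streamlines)

    def lengths(self) -> np.ndarray:
        return np.array([s.length for s in self.streamlines])


@dataclass(frozen=True)
class TrackingParams:
    step_size: float = 0.65          # mm
    max_angle_per_step: float = 30.0  # degrees
    fod_amplitude_cutoff: float = 0.05
    min_length: float = 2.6          # mm
    max_length: float = 250.0        # mm
    target_count: int = 20000
    n_codebook: int = 512            # full-sphere sampling directions

    def __post_init__(self) -> None:
        if self.min_length < 0:
            raise InvalidSpecError("min_length must be >= 0")
        if not 0.0 < self.max_angle_per_step < 90.0:
            raise InvalidSpecError("max_angle_per_step must be in (0, 90)")
        if self.step_size <= 0 or self.max_length <= 0:
            raise InvalidSpecError("step and max length must be positive")


# --------------------------------------------------------------------------
# seeding
# --------------------------------------------------------------------------

def seed_points(mask: np.ndarray, affine: np.ndarray, n: int,
                rng: np.random.Generator) -> np.ndarray:
    """``n`` world-mm points uniform over the union of in-mask voxel volumes."""
    mask = np.asarray(mask, dtype=bool)
    vox = np.argwhere(mask)
    if vox.shape[0] == 0:
        raise InvalidSpecError("empty seeding mask")
    pick = rng.integers(0, vox.shape[0], size=n)
    # uniform inside the half-open voxel box [i, i+1) in grid units,
    # i.e. index-space offset in [-0.5, 0.5)
    offs = rng.random((n, 3)) - 0.5
    idx_coords = vox[pick] + offs
    return idx_coords @ np.asarray(affine, dtype=float)[:3, :3].T + affine[:3, 3]


# --------------------------------------------------------------------------
# propagation
# --------------------------------------------------------------------------

class _Codebook:
    """Dense direction set with SH matrix and cone adjacency."""

    def __init__(self, lmax: int, n_dirs: int, max_angle_deg: float):
        half = electrostatic_directions(n_dirs // 2)
        self.dirs = np.vstack([half, -half])
        self.n = self.dirs.shape[0]
        self.antipode = np.concatenate([
            np.arange(self.n // 2) + self.n // 2,
            np.arange(self.n // 2),
        ])
        self.y = _real_sh_matrix(self.dirs, lmax)
        cos_max = np.cos(np.deg2rad(max_angle_deg))
        self.cone = (self.dirs @ self.dirs.T) >= cos_max


_CODEBOOK_CACHE: dict[tuple[int, int, float], _Codebook] = {}


def _get_codebook(lmax: int, n_dirs: int, max_angle: float) -> _Codebook:
    key = (lmax, n_dirs, round(max_angle, 6))
    if key not in _CODEBOOK_CACHE:
        _CODEBOOK_CACHE[key] = _Codebook(lmax, n_dirs, max_angle)
    return _CODEBOOK_CACHE[key]


def _trilinear_coeffs(coeffs: np.ndarray, idx_coords: np.ndarray) -> np.ndarray:
    """Trilinear interpolation of SH coefficient volumes at index coords."""
    shape = np.asarray(coeffs.shape[:3])
    x = np.clip(idx_coords, 0.0, shape - 1.0 - 1e-9)
    i0 = np.floor(x).astype(np.intp)
    i0 = np.minimum(i0, shape - 2)
    f = x - i0
    out = np.zeros((idx_coords.shape[0], coeffs.shape[3]))
    for dx in (0, 1):
        wx = f[:, 0] if dx else 1.0 - f[:, 0]
        for dy in (0, 1):
            wy = f[:, 1] if dy else 1.0 - f[:, 1]
            for dz in (0, 1):
                wz = f[:, 2] if dz else 1.0 - f[:, 2]
                w = wx * wy * wz
                out += w[:, None] * coeffs[i0[:, 0] + dx, i0[:, 1] + dy,
                                           i0[:, 2] + dz]
    return out


def _voxel_of(idx_coords: np.ndarray) -> np.ndarray:
    """Voxel index under the half-open convention (round-half-up of index)."""
    return np.floor(idx_coords + 0.5).astype(np.intp)


class _Tracker:
    def __init__(self, fod: FODField, mask: np.ndarray, params: TrackingParams):
        self.fod = fod
        self.mask = np.asarray(mask, dtype=bool)
        self.params = params
        self.inv_affine = np.linalg.inv(np.asarray(fod.affine, dtype=float))
        self.cb = _get_codebook(fod.lmax, params.n_codebook,
                                params.max_angle_per_step)
        self.max_steps = int(np.floor(params.max_length / params.step_size))

    def _to_index(self, pts_mm: np.ndarray) -> np.ndarray:
        return pts_mm @ self.inv_affine[:3, :3].T + self.inv_affine[:3, 3]

    def _in_mask(self, idx_coords: np.ndarray) -> np.ndarray:
        v = _voxel_of(idx_coords)
        shape = self.mask.shape
        ok = np.all((v >= 0) & (v < shape), axis=1)
        out = np.zeros(v.shape[0], dtype=bool)
        vv = v[ok]
        out[ok] = self.mask[vv[:, 0], vv[:, 1], vv[:, 2]]
        return out

    def _sample(self, weights: np.ndarray, rng: np.random.Generator
                ) -> tuple[np.ndarray, np.ndarray]:
        """Sample one codebook index per row proportional to ``weights``."""
        tot = weights.sum(axis=1)
        alive = tot > 0
        r = rng.random(weights.shape[0]) * np.where(alive, tot, 1.0)
        idx = (np.cumsum(weights, axis=1) < r[:, None]).sum(axis=1)
        idx = np.minimum(idx, weights.shape[1] - 1)
        return idx, alive

    def _grow(self, seeds_mm: np.ndarray, dir_idx: np.ndarray,
              rng: np.random.Generator, max_steps: np.ndarray
              ) -> tuple[np.ndarray, np.ndarray]:
        """Grow one half per seed.

        Returns ``(points, counts)``: a ``(n, max, 3)`` buffer of grown points
        (seed excluded) and the number of valid points per seed.
        """
        n = seeds_mm.shape[0]
        cap = int(max_steps.max(initial=0))
        buf = np.empty((n, max(cap, 1), 3))
        counts = np.zeros(n, dtype=int)
        pos = seeds_mm.copy()
        cur = dir_idx.copy()
        alive = cur >= 0
        step = self.params.step_size
        while np.any(alive):
            act = np.flatnonzero(alive)
            nxt = pos[act] + step * self.cb.dirs[cur[act]]
            idxc = self._to_index(nxt)
            inm = self._in_mask(idxc)
            alive[act[~inm]] = False
            act = act[inm]
            if act.size == 0:
                break
            buf[act, counts[act]] = nxt[inm]
            counts[act] += 1
            pos[act] = nxt[inm]
            over = counts[act] >= max_steps[act]
            alive[act[over]] = False
            act = act[~over]
            if act.size == 0:
                break
            c = _trilinear_coeffs(self.fod.coeffs, self._to_index(pos[act]))
            amp = c @ self.cb.y.T
            w = np.where(self.cb.cone[cur[act]]
                         & (amp >= self.params.fod_amplitude_cutoff), amp, 0.0)
            idx, ok = self._sample(w, rng)
            cur[act] = idx
            alive[act[~ok]] = False
        return buf, counts

    def propagate(self, seeds_mm: np.ndarray, rng: np.random.Generator
                  ) -> list[np.ndarray | None]:
        """Bidirectional propagation of a batch of seeds.

        Returns one ``(n, 3)`` point array per accepted seed, ``None`` for
        rejected ones (too short or dead seed).
        """
        seeds_mm = np.atleast_2d(np.asarray(seeds_mm, dtype=float))
        n = seeds_mm.shape[0]
        idxc = self._to_index(seeds_mm)
        inm = self._in_mask(idxc)
        c = _trilinear_coeffs(self.fod.coeffs, idxc)
        amp = c @ self.cb.y.T
        w = np.where(amp >= self.params.fod_amplitude_cutoff, amp, 0.0)
        w[~inm] = 0.0
        d0, alive = self._sample(w, rng)
        d0 = np.where(alive, d0, -1)

        # split the step budget between the two halves
        budget = np.full(n, self.max_steps)
        fwd, n_fwd = self._grow(seeds_mm, d0, rng, budget)
        back, n_back = self._grow(seeds_mm,
                                  np.where(d0 >= 0, self.cb.antipode[d0], -1),
                                  rng, budget - n_fwd)
        out: list[np.ndarray | None] = []
        min_pts = int(np.ceil(self.params.min_length / self.params.step_size)) + 1
        for i in range(n):
            if d0[i] < 0 or n_back[i] + 1 + n_fwd[i] < min_pts:
                out.append(None)
                continue
            out.append(np.vstack([back[i, : n_back[i]][::-1],
                                  seeds_mm[i][None, :],
                                  fwd[i, : n_fwd[i]]]))
        return out


def propagate_streamline(fod_field: FODField, seed: Sequence[float],
                         params: TrackingParams, rng: np.random.Generator,
                         mask: np.ndarray | None = None) -> Streamline | None:
    """Grow one bidirectional streamline from ``seed`` (world mm).

    Returns ``None`` when the streamline is rejected (final length below
    ``params.min_length`` or the seed has no super-threshold FOD amplitude).
    """
    if mask is None:
        mask = fod_field.mask if fod_field.mask is not None else np.ones(
            fod_field.grid_shape, dtype=bool)
    tracker = _Tracker(fod_field, mask, params)
    res = tracker.propagate(np.asarray(seed, dtype=float)[None, :], rng)[0]
    return None if res is None else Streamline(points=res,
                                               step_size=params.step_size)


def generate_tractogram(fod_field: FODField, mask: np.ndarray,
                        params: TrackingParams,
                        rng: np.random.Generator | int) -> Tractogram:
    """Seed and propagate until ``params.target_count`` accepted streamlines.

    Raises :class:`TrackingError` when the acceptance rate stays below 1e-4
    after 10x the target number of attempts (degenerate FOD field).
    """
    if isinstance(rng, (int, np.integer)):
        rng_seed: int | None = int(rng)
        rng = np.random.default_rng(rng)
    else:
        rng_seed = None
    mask = np.asarray(mask, dtype=bool)
    tracker = _Tracker(fod_field, mask, params)
    target = params.target_count
    accepted: list[Streamline] = []
    attempts = 0
    # over-seed each round: the grow loop's step cost is batch-width
    # amortized, so fewer, wider rounds are much cheaper
    batch = int(min(max(1024, 2 * target), 8192))
    while len(accepted) < target:
        seeds = seed_points(mask, fod_field.affine, batch, rng)
        results = tracker.propagate(seeds, rng)
        for r in results:
            if r is not None:
                accepted.append(Streamline(points=r, step_size=params.step_size))
                if len(accepted) == target:
                    break
        attempts += batch
        if attempts >= 10 * target and len(accepted) < max(1, 1e-4 * attempts):
            raise TrackingError(
                f"acceptance rate {len(accepted)}/{attempts} below 1e-4; "
                "degenerate FOD field?"
            )
    return Tractogram(streamlines=accepted[:target],
                      affine=np.asarray(fod_field.affine, dtype=float),
                      seed_count=attempts, rng_seed=rng_seed)


# --------------------------------------------------------------------------
# exact segment-voxel traversal
# --------------------------------------------------------------------------

def _to_grid_units(points_mm: np.ndarray, affine: np.ndarray) -> np.ndarray:
    """World mm -> corner-based grid units (voxel (i,j,k) = [i, i+1)^3)."""
    inv = np.linalg.inv(np.asarray(affine, dtype=float))
    return points_mm @ inv[:3, :3].T + inv[:3, 3] + 0.5


def _segments_to_voxels(a: np.ndarray, b: np.ndarray,
                        owner: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Voxels traversed by segments a->b (grid units), labelled by owner.

    Exact: each segment is subdivided so no piece spans more than one integer
    plane per axis; plane-crossing parameters then split each piece into
    sub-intervals whose midpoints identify every traversed voxel.
    """
    delta = b - a
    m = np.floor(np.max(np.abs(delta), axis=1)).astype(np.intp) + 1
    total = int(m.sum())
    seg_id = np.repeat(np.arange(a.shape[0]), m)
    # k-th piece index within each segment
    k = np.arange(total) - np.repeat(np.cumsum(m) - m, m)
    frac0 = k / m[seg_id]
    frac1 = (k + 1) / m[seg_id]
    pa = a[seg_id] + frac0[:, None] * delta[seg_id]
    pb = a[seg_id] + frac1[:, None] * delta[seg_id]
    d = pb - pa

    ts = np.ones((total, 5))
    ts[:, 0] = 0.0
    for ax in range(3):
        lo = np.minimum(pa[:, ax], pb[:, ax])
        hi = np.maximum(pa[:, ax], pb[:, ax])
        plane = np.floor(hi)
        crosses = (plane > lo) & (np.abs(d[:, ax]) > 1e-12)
        t = np.where(crosses, (plane - pa[:, ax]) / np.where(d[:, ax] != 0,
                                                            d[:, ax], 1.0), 1.0)
        ts[:, ax + 1] = np.clip(t, 0.0, 1.0)
    ts.sort(axis=1)
    mids = 0.5 * (ts[:, :-1] + ts[:, 1:])  # (total, 4)
    pts = pa[:, None, :] + mids[:, :, None] * d[:, None, :]
    vox = np.floor(pts.reshape(-1, 3)).astype(np.int64)
    own = np.repeat(owner[seg_id], 4)
    return own, vox


def streamline_voxels(points_mm: np.ndarray, affine: np.ndarray,
                      grid_shape: Sequence[int] | None = None) -> np.ndarray:
    """Unique voxel indices traversed by one streamline polyline."""
    points_mm = np.atleast_2d(np.asarray(points_mm, dtype=float))
    g = _to_grid_units(points_mm, affine)
    if g.shape[0] == 1:
        vox = np.floor(g).astype(np.int64)
    else:
        _, vox = _segments_to_voxels(g[:-1], g[1:],
                                     np.zeros(g.shape[0] - 1, dtype=np.int64))
    vox = np.unique(vox, axis=0)
    if grid_shape is not None:
        shp = np.asarray(grid_shape)
        vox = vox[np.all((vox >= 0) & (vox < shp), axis=1)]
    return vox


def tractogram_voxel_pairs(tractogram: Tractogram,
                           grid_shape: Sequence[int]
                           ) -> tuple[np.ndarray, np.ndarray]:
    """Unique (streamline index, flat voxel index) visitation pairs."""
    owners = []
    starts = []
    all_pts = []
    for i, s in enumerate(tractogram.streamlines):
        all_pts.append(s.points)
        starts.append(s.points.shape[0])
    if not all_pts:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    g = _to_grid_units(np.vstack(all_pts), tractogram.affine)
    n_pts = np.asarray(starts)
    ends = np.cumsum(n_pts)
    begins = ends - n_pts
    seg_a, seg_b, seg_owner = [], [], []
    for i, (b0, e0) in enumerate(zip(begins, ends)):
        if e0 - b0 >= 2:
            seg_a.append(g[b0:e0 - 1])
            seg_b.append(g[b0 + 1:e0])
            seg_owner.append(np.full(e0 - b0 - 1, i, dtype=np.int64))
    if not seg_a:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    own, vox = _segments_to_voxels(np.vstack(seg_a), np.vstack(seg_b),
                                   np.concatenate(seg_owner))
    shp = np.asarray(grid_shape)
    ok = np.all((vox >= 0) & (vox < shp), axis=1)
    own, vox = own[ok], vox[ok]
    flat = np.ravel_multi_index((vox[:, 0], vox[:, 1], vox[:, 2]), tuple(grid_shape))
    pair = own * int(np.prod(grid_shape)) + flat
    upair = np.unique(pair)
    return upair // int(np.prod(grid_shape)), upair % int(np.prod(grid_shape))


def track_density_map(tractogram: Tractogram,
                      grid_shape: Sequence[int]) -> np.ndarray:
    """Per-voxel count of distinct streamlines traversing each voxel."""
    _, flat = tractogram_voxel_pairs(tractogram, grid_shape)
    td = np.bincount(flat, minlength=int(np.prod(grid_shape)))
    return td.reshape(tuple(grid_shape)).astype(np.int64)


# --------------------------------------------------------------------------
# SIFT-style pruning
# --------------------------------------------------------------------------

def sift_filter(tractogram: Tractogram, fod_field: FODField, keep_count: int,
                return_trace: bool = False):
    """Greedily prune streamlines so density matches FOD magnitude.

    Cost = sum over mask voxels of ``(mu * TD(v) - A(v))**2`` with ``A`` the
    FOD l=0 amplitude and ``mu`` refit (least squares) after every removal;
    each removal deletes the streamline whose removal most decreases the
    cost.  Returns the kept subset in original order (and the cost trace when
    ``return_trace``).
    """
    if keep_count <= 0:
        raise InvalidSpecError("keep_count must be positive")
    n = len(tractogram)
    if keep_count > n:
        raise InvalidSpecError(f"keep_count {keep_count} exceeds tractogram size {n}")
    grid_shape = fod_field.grid_shape
    mask = (fod_field.mask if fod_field.mask is not None
            else np.ones(grid_shape, dtype=bool)).reshape(-1)
    owners, vox_flat = tractogram_voxel_pairs(tractogram, grid_shape)
    in_mask = mask[vox_flat]
    owners, vox_flat = owners[in_mask], vox_flat[in_mask]

    a_amp = (fod_field.coeffs[..., 0] / np.sqrt(4.0 * np.pi)).reshape(-1)
    a_amp = np.where(mask, np.clip(a_amp, 0.0, None), 0.0)

    td = np.bincount(vox_flat, minlength=mask.size).astype(float)
    n_vox_per = np.bincount(owners, minlength=n).astype(float)
    removed = np.zeros(n, dtype=bool)
    trace = []

    order = np.argsort(owners, kind="stable")
    owners_s, vox_s = owners[order], vox_flat[order]

    def mu_fit() -> float:
        denom = float(np.sum(td[mask] ** 2))
        return float(np.sum(a_amp[mask] * td[mask]) / denom) if denom > 0 else 0.0

    def cost(mu: float) -> float:
        r = mu * td[mask] - a_amp[mask]
        return float(r @ r)

    mu = mu_fit()
    trace.append(cost(mu))
    for _ in range(n - keep_count):
        r_v = mu * td - a_amp
        s_per = np.bincount(owners_s, weights=r_v[vox_s], minlength=n)
        delta = mu * mu * n_vox_per - 2.0 * mu * s_per
        delta[removed] = np.inf
        worst = int(np.argmin(delta))
        removed[worst] = True
        sel = owners_s == worst
        np.subtract.at(td, vox_s[sel], 1.0)
        mu = mu_fit()
        trace.append(cost(mu))

    kept = [s for i, s in enumerate(tractogram.streamlines) if not removed[i]]
    out = Tractogram(streamlines=kept, affine=tractogram.affine,
                     seed_count=tractogram.seed_count,
                     rng_seed=tractogram.rng_seed)
    return (out, np.asarray(trace)) if return_trace else out
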