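"""Synthetic diffusion phantoms, WMH lesion masks, and a two-timepoint cohort.

The forward signal model is a three-compartment mixture per voxel: an axially
symmetric tensor ("zeppelin") for the intracellular anisotropic compartment
and mono-exponential isotropic decay for the intracellular isotropic (GM-like)
and extracellular isotropic (CSF-like) compartments.  Noise, when requested,
is Rician: the magnitude of the noiseless signal plus complex Gaussian noise,
with SNR defined on the b=0 signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from ._sphere import electrostatic_directions, sign_balanced
from .csd import TissueFractionField
from .errors import InvalidSpecError

__all__ = [
    "GradientTable",
    "Diffusivities",
    "BundleSpec",
    "LesionSpec",
    "RegionSpec",
    "PhantomSpec",
    "PhantomGroundTruth",
    "DWIDataset",
    "CohortEffectSpec",
    "make_gradient_table",
    "simulate_voxel_signal",
    "build_phantom",
    "generate_cohort",
    "default_phantom_spec",
]

_SHELL_TOL = 50.0  # s/mm^2; bvals within this of each other share a shell


# --------------------------------------------------------------------------
# gradient table
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class GradientTable:
    """Diffusion gradient scheme: b-values and unit direction vectors.

    b=0 entries carry a zero direction vector.  Shells are identified by
    clustering b-values to within +/-50 s/mm^2.
    """

    bvals: np.ndarray
    bvecs: np.ndarray

    def __post_init__(self) -> None:
        bvals = np.asarray(self.bvals, dtype=float)
        bvecs = np.asarray(self.bvecs, dtype=float)
        object.__setattr__(self, "bvals", bvals)
        object.__setattr__(self, "bvecs", bvecs)
        if bvals.ndim != 1 or bvecs.shape != (bvals.size, 3):
            raise InvalidSpecError("bvals must be (N,), bvecs (N, 3)")
        if np.any(bvals < 0):
            raise InvalidSpecError("b-values must be non-negative")
        norms = np.linalg.norm(bvecs, axis=1)
        nz = ~self.b0_mask
        if np.any(np.abs(norms[nz] - 1.0) > 1e-6):
            raise InvalidSpecError("non-b0 bvecs must be unit vectors")

    def __len__(self) -> int:
        return int(self.bvals.size)

    @property
    def b0_mask(self) -> np.ndarray:
        return self.bvals < _SHELL_TOL

    @property
    def shell_bvalues(self) -> tuple[float, ...]:
        """Representative (mean) b-value per nonzero shell, ascending."""
        nz = np.sort(self.bvals[~self.b0_mask])
        if nz.size == 0:
            return ()
        shells: list[list[float]] = [[nz[0]]]
        for b in nz[1:]:
            if b - shells[-1][-1] <= _SHELL_TOL:
                shells[-1].append(b)
            else:
                shells.append([b])
        return tuple(float(np.mean(s)) for s in shells)

    def shell_mask(self, bval: float) -> np.ndarray:
        return (~self.b0_mask) & (np.abs(self.bvals - bval) <= _SHELL_TOL)


def make_gradient_table(n_b0: int, n_dirs_per_shell: int,
                        shell_bvals: Sequence[float]) -> GradientTable:
    """Deterministic multi-shell gradient scheme.

    ``n_b0`` zero entries followed by one electrostatic-repulsion layout of
    ``n_dirs_per_shell`` antipodally-symmetric unit directions per shell.
    """
    shell_bvals = list(shell_bvals)
    if len(set(shell_bvals)) != len(shell_bvals):
        raise InvalidSpecError("shell b-values must be distinct")
    if any(b <= 0 for b in shell_bvals):
        raise InvalidSpecError("shell b-values must be positive")
    if n_dirs_per_shell < 6:
        raise InvalidSpecError("need at least 6 directions per shell")
    if n_b0 < 0:
        raise InvalidSpecError("n_b0 must be non-negative")
    dirs = sign_balanced(electrostatic_directions(n_dirs_per_shell))
    bvals = [0.0] * n_b0
    bvecs = [np.zeros(3)] * n_b0
    for b in shell_bvals:
        bvals.extend([float(b)] * n_dirs_per_shell)
        bvecs.extend(dirs)
    return GradientTable(bvals=np.asarray(bvals), bvecs=np.asarray(bvecs))


# --------------------------------------------------------------------------
# forward model
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Diffusivities:
    """Compartment diffusivities in mm^2/s."""

    d_csf: float = 3.0e-3
    d_gm: float = 0.8e-3
    d_ax: float = 1.7e-3
    d_rad: float = 0.2e-3


def simulate_voxel_signal(gtab: GradientTable,
                          fractions: Sequence[float],
                          fiber_dir: Sequence[float] | None,
                          diffusivities: Diffusivities = Diffusivities(),
                          snr: float = np.inf,
                          rng: np.random.Generator | None = None) -> np.ndarray:
    """Noisy three-compartment signal for one voxel, S(b=0) = 1 noiseless.

    ``fractions`` is ``(f_ECI, f_ICI, f_ICA)`` and must sum to 1.
    """
    f_eci, f_ici, f_ica = (float(f) for f in fractions)
    if min(f_eci, f_ici, f_ica) < -1e-12 or abs(f_eci + f_ici + f_ica - 1.0) > 1e-9:
        raise InvalidSpecError("fractions must be non-negative and sum to 1")
    if f_ica > 0 and fiber_dir is None:
        raise InvalidSpecError("fiber_dir required when f_ICA > 0")
    d = diffusivities
    b = gtab.bvals
    s = f_eci * np.exp(-b * d.d_csf) + f_ici * np.exp(-b * d.d_gm)
    if f_ica > 0:
        v = np.asarray(fiber_dir, dtype=float)
        v = v / np.linalg.norm(v)
        cos2 = (gtab.bvecs @ v) ** 2
        s = s + f_ica * np.exp(-b * ((d.d_ax - d.d_rad) * cos2 + d.d_rad))
    if np.isinf(snr):
        return s
    if snr <= 0:
        raise InvalidSpecError("snr must be positive")
    if rng is None:
        raise InvalidSpecError("rng required for finite SNR")
    sigma = 1.0 / snr  # relative to the unit b0 signal
    n1 = rng.normal(0.0, sigma, size=s.shape)
    n2 = rng.normal(0.0, sigma, size=s.shape)
    return np.sqrt((s + n1) ** 2 + n2 ** 2)


# --------------------------------------------------------------------------
# phantom geometry
# --------------------------------------------------------------------------

def _check_fractions(fr: Sequence[float], what: str) -> tuple[float, float, float]:
    fr = tuple(float(x) for x in fr)
    if len(fr) != 3 or min(fr) < 0 or abs(sum(fr) - 1.0) > 1e-9:
        raise InvalidSpecError(
            f"{what} fractions must be 3 non-negative values summing to 1: {fr}"
        )
    return fr


@dataclass(frozen=True)
class BundleSpec:
    """Straight-or-curved fiber bundle: centerline control points (mm),
    radius (mm), and the tissue fractions inside the bundle."""

    centerline: np.ndarray  # (K, 3) mm
    radius: float
    fractions: tuple[float, float, float] = (0.02, 0.03, 0.95)  # (ECI, ICI, ICA)

    def __post_init__(self) -> None:
        object.__setattr__(self, "centerline",
                           np.atleast_2d(np.asarray(self.centerline, dtype=float)))
        if self.centerline.shape[0] < 2:
            raise InvalidSpecError("bundle centerline needs >= 2 control points")
        if self.radius <= 0:
            raise InvalidSpecError("bundle radius must be positive")
        _check_fractions(self.fractions, "bundle")


@dataclass(frozen=True)
class LesionSpec:
    """Spherical lesion: center (mm), radius (mm), lesion fractions.

    ``in_wmh_mask=False`` makes a "sham" lesion: its microstructure is
    altered but it is not labelled as WMH (used by the cohort generator to
    keep whole-phantom composition identical across subjects).
    """

    center: tuple[float, float, float]
    radius: float
    fractions: tuple[float, float, float] = (0.45, 0.35, 0.20)
    in_wmh_mask: bool = True

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise InvalidSpecError("lesion radius must be positive")
        _check_fractions(self.fractions, "lesion")


@dataclass(frozen=True)
class RegionSpec:
    """Axis-aligned background box (mm bounds) with homogeneous fractions."""

    fractions: tuple[float, float, float]
    lo: tuple[float, float, float] | None = None  # None = whole grid
    hi: tuple[float, float, float] | None = None

    def __post_init__(self) -> None:
        _check_fractions(self.fractions, "region")


@dataclass(frozen=True)
class PhantomSpec:
    """Full description of one synthetic diffusion acquisition."""

    grid_shape: tuple[int, int, int] = (20, 20, 20)
    voxel_size: float = 1.7
    bundles: tuple[BundleSpec, ...] = ()
    background_tissue: Mapping[str, RegionSpec] = field(
        default_factory=lambda: {"default": RegionSpec(fractions=(1.0, 0.0, 0.0))}
    )
    lesions: tuple[LesionSpec, ...] = ()
    diffusivities: Diffusivities = Diffusivities()
    snr: float = np.inf
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.grid_shape) != 3 or any(s <= 0 for s in self.grid_shape):
            raise InvalidSpecError("grid_shape must be 3 positive ints")
        if self.voxel_size <= 0:
            raise InvalidSpecError("voxel_size must be positive")
        if self.snr <= 0:
            raise InvalidSpecError("snr must be positive (or infinity)")
        extent = np.asarray(self.grid_shape) * self.voxel_size
        for les in self.lesions:
            c = np.asarray(les.center)
            if np.any(c - les.radius < 0) or np.any(c + les.radius > extent):
                raise InvalidSpecError(
                    f"lesion at {les.center} r={les.radius} exceeds grid extent {extent}"
                )

    @property
    def affine(self) -> np.ndarray:
        """Grid-to-world (RAS mm) affine; voxel center i is at (i + 0.5) * size."""
        aff = np.diag([self.voxel_size] * 3 + [1.0])
        aff[:3, 3] = 0.5 * self.voxel_size
        return aff


@dataclass
class PhantomGroundTruth:
    """Exact per-voxel truth recorded while rasterizing a phantom."""

    true_fractions: TissueFractionField
    fiber_direction: np.ndarray  # (X, Y, Z, 3); NaN where no fiber
    wmh_mask: np.ndarray
    tissue_masks: dict[str, np.ndarray]  # 'wm' (single-fiber), 'gm', 'csf'


@dataclass
class DWIDataset:
    """Gridded diffusion signal with its gradient table and affine."""

    data: np.ndarray  # (X, Y, Z, N)
    gtab: GradientTable
    affine: np.ndarray
    brain_mask: np.ndarray

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    @property
    def voxel_volume(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3])))


def _voxel_centers(spec: PhantomSpec) -> np.ndarray:
    idx = np.indices(spec.grid_shape).reshape(3, -1).T.astype(float)
    return (idx + 0.5) * spec.voxel_size


def _dist_to_polyline(points: np.ndarray, line: np.ndarray
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Min distance from each point to a polyline, and the local unit tangent."""
    best_d = np.full(points.shape[0], np.inf)
    best_t = np.zeros((points.shape[0], 3))
    for a, b in zip(line[:-1], line[1:]):
        ab = b - a
        denom = float(ab @ ab)
        if denom == 0:
            continue
        t = np.clip(((points - a) @ ab) / denom, 0.0, 1.0)
        proj = a + t[:, None] * ab
        d = np.linalg.norm(points - proj, axis=1)
        closer = d < best_d
        best_d[closer] = d[closer]
        best_t[closer] = ab / np.sqrt(denom)
    return best_d, best_t


def build_phantom(spec: PhantomSpec) -> tuple[DWIDataset, PhantomGroundTruth]:
    """Rasterize a phantom spec into a DWI dataset plus exact ground truth.

    Layering: background regions (in declaration order) -> bundles -> lesions.
    Voxels covered by several bundles get the fraction-sum renormalized and
    the fiber direction of the bundle with the largest local ICA fraction.
    """
    gtab = make_gradient_table(10, 64, [1500.0, 3000.0])
    return build_phantom_with_gtab(spec, gtab)


def build_phantom_with_gtab(spec: PhantomSpec, gtab: GradientTable
                            ) -> tuple[DWIDataset, PhantomGroundTruth]:
    shape = tuple(spec.grid_shape)
    n_vox = int(np.prod(shape))
    centers = _voxel_centers(spec)
    fractions = np.zeros((n_vox, 3))  # (ECI, ICI, ICA)
    fiber = np.full((n_vox, 3), np.nan)
    region_id = np.full(n_vox, -1)

    # background regions, declaration order, later boxes override earlier
    extent = np.asarray(shape) * spec.voxel_size
    for rid, (name, reg) in enumerate(spec.background_tissue.items()):
        lo = np.zeros(3) if reg.lo is None else np.asarray(reg.lo, dtype=float)
        hi = extent if reg.hi is None else np.asarray(reg.hi, dtype=float)
        inside = np.all((centers >= lo) & (centers < hi), axis=1)
        fractions[inside] = reg.fractions
        region_id[inside] = rid
        if reg.fractions[2] > 0:
            raise InvalidSpecError(
                f"background region {name!r} has f_ICA > 0 but no orientation"
            )

    # bundles: sum fractions then renormalize; direction of largest-ICA bundle
    in_any_bundle = np.zeros(n_vox, dtype=bool)
    bundle_accum = np.zeros((n_vox, 3))
    best_ica = np.zeros(n_vox)
    for bun in spec.bundles:
        d, tang = _dist_to_polyline(centers, bun.centerline)
        inside = d <= bun.radius
        in_any_bundle |= inside
        bundle_accum[inside] += np.asarray(bun.fractions)
        stronger = inside & (bun.fractions[2] > best_ica)
        fiber[stronger] = tang[stronger]
        best_ica[stronger] = bun.fractions[2]
    if np.any(in_any_bundle):
        tot = bundle_accum[in_any_bundle].sum(axis=1, keepdims=True)
        fractions[in_any_bundle] = bundle_accum[in_any_bundle] / tot

    # lesions override everything inside their sphere
    wmh = np.zeros(n_vox, dtype=bool)
    for les in spec.lesions:
        d = np.linalg.norm(centers - np.asarray(les.center), axis=1)
        inside = d <= les.radius
        if les.in_wmh_mask:
            wmh |= inside
        fractions[inside] = les.fractions
        needs_dir = inside & (np.asarray(les.fractions)[2] > 0)
        if np.any(needs_dir & ~np.isfinite(fiber[:, 0])):
            raise InvalidSpecError(
                "lesion with f_ICA > 0 outside any bundle has no orientation"
            )

    fiber[fractions[:, 2] <= 0] = np.nan

    # simulate signals; voxels sharing (fractions, fiber) reuse one noiseless
    # profile, with Rician noise applied per voxel afterwards when requested
    rng = np.random.default_rng(spec.seed)
    keys = np.concatenate([fractions, np.nan_to_num(fiber, nan=2.0)], axis=1)
    uniq, inv = np.unique(keys.round(12), axis=0, return_inverse=True)
    profiles = np.empty((uniq.shape[0], len(gtab)))
    for k in range(uniq.shape[0]):
        i = int(np.flatnonzero(inv == k)[0])
        fd = fiber[i] if np.isfinite(fiber[i, 0]) else None
        profiles[k] = simulate_voxel_signal(gtab, fractions[i], fd,
                                            spec.diffusivities)
    data = profiles[inv]
    if not np.isinf(spec.snr):
        sigma = 1.0 / spec.snr
        n1 = rng.normal(0.0, sigma, size=data.shape)
        n2 = rng.normal(0.0, sigma, size=data.shape)
        data = np.sqrt((data + n1) ** 2 + n2 ** 2)

    # ground-truth tissue masks
    single_fiber = in_any_bundle & ~wmh & (fractions[:, 2] >= 0.7)
    gm_like = (~in_any_bundle) & ~wmh & (fractions[:, 1] >= 0.5)
    csf_like = (~in_any_bundle) & ~wmh & (fractions[:, 0] >= 0.9)
    mask3 = lambda flat: flat.reshape(shape)

    affine = spec.affine
    truth = PhantomGroundTruth(
        true_fractions=TissueFractionField(
            f_eci=mask3(fractions[:, 0]).copy(),
            f_ici=mask3(fractions[:, 1]).copy(),
            f_ica=mask3(fractions[:, 2]).copy(),
            affine=affine, mask=np.ones(shape, dtype=bool),
        ),
        fiber_direction=fiber.reshape(shape + (3,)),
        wmh_mask=mask3(wmh).copy(),
        tissue_masks={
            "wm": mask3(single_fiber).copy(),
            "gm": mask3(gm_like).copy(),
            "csf": mask3(csf_like).copy(),
        },
    )
    dwi = DWIDataset(
        data=data.reshape(shape + (len(gtab),)),
        gtab=gtab, affine=affine,
        brain_mask=np.ones(shape, dtype=bool),
    )
    return dwi, truth


def default_phantom_spec(grid_shape: tuple[int, int, int] = (20, 20, 20),
                         voxel_size: float = 1.7,
                         bundle_fractions: tuple[float, float, float] = (0.02, 0.03, 0.95),
                         lesion_radius: float | None = None,
                         lesion_fractions: tuple[float, float, float] = (0.45, 0.35, 0.20),
                         snr: float = np.inf,
                         seed: int = 0) -> PhantomSpec:
    """Straight z-axis bundle through a CSF background with a GM slab.

    When ``lesion_radius`` is given, a spherical WMH is centered on the
    bundle at the grid midpoint.
    """
    extent = np.asarray(grid_shape) * voxel_size
    cx, cy, cz = extent / 2.0
    bundle = BundleSpec(
        centerline=np.array([[cx, cy, 0.0], [cx, cy, extent[2]]]),
        radius=max(2.0 * voxel_size, 0.17 * extent[0]),
        fractions=bundle_fractions,
    )
    background = {
        "csf": RegionSpec(fractions=(1.0, 0.0, 0.0)),
        "gm": RegionSpec(fractions=(0.05, 0.95, 0.0),
                         lo=(0.0, 0.0, 0.0),
                         hi=(0.25 * extent[0], extent[1], extent[2])),
    }
    lesions: tuple[LesionSpec, ...] = ()
    if lesion_radius is not None:
        lesions = (LesionSpec(center=(cx, cy, cz), radius=lesion_radius,
                              fractions=lesion_fractions),)
    return PhantomSpec(grid_shape=tuple(grid_shape), voxel_size=voxel_size,
                       bundles=(bundle,), background_tissue=background,
                       lesions=lesions, snr=snr, seed=seed)


def cohort_phantom_spec(grid_shape: tuple[int, int, int],
                        voxel_size: float,
                        lesioned_eci: float,
                        center_eci: float,
                        lesion_radius: float,
                        gm_eci: float = 0.05,
                        snr: float = np.inf,
                        seed: int = 0) -> PhantomSpec:
    """Two-bundle cohort phantom with an exactly-null whole-phantom mean.

    The lesioned bundle carries free-water fraction ``lesioned_eci`` and
    hosts a spherical WMH whose tissue is continuous with the bundle (the
    WMH is a geometric label, so lesion size never changes composition); a
    mirrored control bundle carries ``2*center_eci - lesioned_eci``, making
    the whole-phantom mean composition identical for every subject by
    construction.
    """
    extent = np.asarray(grid_shape) * voxel_size
    ex, ey, ez = extent
    radius = 0.18 * float(ex)
    x1, x2 = 0.26 * ex, 0.74 * ex
    mirror_eci = float(np.clip(2.0 * center_eci - lesioned_eci, 0.005, 0.5))
    lesion_radius = float(np.clip(lesion_radius, 0.6 * voxel_size,
                                  min(radius, x1 - 1e-6)))
    bundles = (
        BundleSpec(centerline=np.array([[x1, ey / 2, 0.0], [x1, ey / 2, ez]]),
                   radius=radius,
                   fractions=_bundle_fractions_for(lesioned_eci)),
        BundleSpec(centerline=np.array([[x2, ey / 2, 0.0], [x2, ey / 2, ez]]),
                   radius=radius,
                   fractions=_bundle_fractions_for(mirror_eci)),
    )
    background = {
        "csf": RegionSpec(fractions=(1.0, 0.0, 0.0)),
        "gm": RegionSpec(fractions=(gm_eci, 1.0 - gm_eci, 0.0),
                         lo=(0.0, 0.0, 0.0), hi=(ex, 0.18 * ey, ez)),
    }
    lesions = (LesionSpec(center=(x1, ey / 2, ez / 2), radius=lesion_radius,
                          fractions=_bundle_fractions_for(lesioned_eci)),)
    return PhantomSpec(grid_shape=tuple(grid_shape), voxel_size=voxel_size,
                       bundles=bundles, background_tissue=background,
                       lesions=lesions, snr=snr, seed=seed)


# --------------------------------------------------------------------------
# cohort generation
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortEffectSpec:
    """Planted effect structure for the synthetic two-timepoint cohort.

    Cross-sectional: greater age-adjusted epigenetic age (AgeAccelGrim)
    increases WMH volume and the bundle (perilesional) free-water fraction.
    Longitudinal: follow-up lesion radius and bundle free-water fraction grow
    at a rate proportional to AgeAccelGrim, while whole-phantom background
    composition drifts identically for everyone (a deliberately null
    whole-brain interaction).  Follow-up retention is an independent
    Bernoulli draw (missing completely at random by construction).
    """

    grimage_intercept: float = 5.0
    grimage_age_slope: float = 0.85
    grimage_sex_effect: float = 3.0     # added for males
    grimage_sd: float = 3.5
    male_prob: float = 0.31             # 30 of 98 in the reference cohort
    brain_volume_mean: float = 1.1e6    # mm^3
    brain_volume_sd: float = 5.0e4
    brain_volume_accel_slope: float = -4.0e3
    wmh_volume_base: float = 80.0       # mm^3 (desk-scale grids are small)
    wmh_volume_accel_slope: float = 8.0
    wmh_volume_sd: float = 10.0
    wmh_volume_min: float = 40.0
    roi_eci_base: float = 0.08
    roi_eci_accel_slope: float = 5.0e-3     # per year of AgeAccelGrim (baseline)
    roi_eci_change_rate: float = 5.0e-3     # per year of AgeAccelGrim (follow-up)
    roi_eci_noise_sd: float = 4.0e-3
    global_drift_eci: float = 0.01          # identical for all subjects
    gm_eci_noise_sd: float = 0.03           # per-scan background variability
    lesion_growth_rate: float = 0.08        # mm radius per year of AgeAccelGrim
    retention_prob: float = 41.0 / 98.0
    grid_shape: tuple[int, int, int] = (12, 12, 12)
    voxel_size: float = 1.7
    snr: float = np.inf

    def __post_init__(self) -> None:
        for name in ("grimage_sd", "brain_volume_sd", "wmh_volume_sd",
                     "roi_eci_noise_sd"):
            if getattr(self, name) < 0:
                raise InvalidSpecError(f"{name} must be non-negative")
        if not 0.0 <= self.retention_prob <= 1.0:
            raise InvalidSpecError("retention_prob must be in [0, 1]")


def _bundle_fractions_for(eci: float) -> tuple[float, float, float]:
    eci = float(np.clip(eci, 0.01, 0.5))
    ici = 0.03
    return (eci, ici, 1.0 - eci - ici)


def generate_cohort(n_subjects: int,
                    effects: CohortEffectSpec | None = None,
                    seed: int = 0):
    """Synthesize the cohort table plus per-subject phantom spec pairs.

    Returns ``(cohort, specs)`` where ``cohort`` is a pandas DataFrame with
    one row per subject per timepoint and ``specs`` maps subject id to the
    ``(baseline, followup)`` :class:`PhantomSpec` pair.  Deterministic for a
    fixed seed.
    """
    import pandas as pd

    from .stats import age_accel

    if n_subjects < 10:
        raise InvalidSpecError("need at least 10 subjects")
    eff = effects or CohortEffectSpec()
    rng = np.random.default_rng(seed)

    age = rng.uniform(58.0, 81.0, size=n_subjects)
    sex_male = rng.random(n_subjects) < eff.male_prob
    grim = (eff.grimage_intercept + eff.grimage_age_slope * age
            + eff.grimage_sex_effect * sex_male
            + rng.normal(0.0, eff.grimage_sd, n_subjects))
    accel = age_accel(grim, age)
    brain_vol = (eff.brain_volume_mean + eff.brain_volume_accel_slope * accel
                 + rng.normal(0.0, eff.brain_volume_sd, n_subjects))
    wmh_vol = (eff.wmh_volume_base + eff.wmh_volume_accel_slope * accel
               + rng.normal(0.0, eff.wmh_volume_sd, n_subjects))
    wmh_vol = np.clip(wmh_vol, eff.wmh_volume_min, None)
    retained = rng.random(n_subjects) < eff.retention_prob

    extent = np.asarray(eff.grid_shape) * eff.voxel_size
    max_lesion_radius = 0.18 * float(extent[0])

    # bundle free-water centers per timepoint: the follow-up center drifts
    # identically for every subject (the deliberately null whole-phantom
    # change); subject deviations from the center are mirrored by the
    # control bundle inside cohort_phantom_spec, so the whole-phantom mean
    # composition carries no AgeAccelGrim interaction by construction.
    c_base = eff.roi_eci_base
    c_follow = eff.roi_eci_base + eff.global_drift_eci

    rows = []
    specs: dict[str, tuple[PhantomSpec, PhantomSpec]] = {}
    for i in range(n_subjects):
        sid = f"sub-{i + 1:03d}"
        eci_noise = rng.normal(0.0, eff.roi_eci_noise_sd, size=2)
        eci_base = float(np.clip(
            c_base + eff.roi_eci_accel_slope * accel[i] + eci_noise[0],
            0.015, 0.45))
        eci_follow = float(np.clip(
            eci_base + eff.global_drift_eci
            + eff.roi_eci_change_rate * accel[i] + eci_noise[1],
            0.015, 0.45))
        r_base = float(np.clip((3.0 * wmh_vol[i] / (4.0 * np.pi)) ** (1.0 / 3.0),
                               0.9 * eff.voxel_size, max_lesion_radius))
        r_follow = float(np.clip(
            r_base + np.clip(0.05 + eff.lesion_growth_rate * accel[i], 0.0, 1.5),
            0.9 * eff.voxel_size, max_lesion_radius))
        sub_seed = int(rng.integers(0, 2 ** 31 - 1))
        # accel-independent background variability (keeps the whole-phantom
        # null honest: the residual it creates dominates rasterization and
        # fit-nonlinearity crumbs)
        gm_eci = np.clip(0.05 + rng.normal(0.0, eff.gm_eci_noise_sd, size=2),
                         0.01, 0.30)
        spec_b = cohort_phantom_spec(
            grid_shape=eff.grid_shape, voxel_size=eff.voxel_size,
            lesioned_eci=eci_base, center_eci=c_base,
            lesion_radius=r_base, gm_eci=float(gm_eci[0]),
            snr=eff.snr, seed=sub_seed,
        )
        spec_f = cohort_phantom_spec(
            grid_shape=eff.grid_shape, voxel_size=eff.voxel_size,
            lesioned_eci=eci_follow, center_eci=c_follow,
            lesion_radius=r_follow, gm_eci=float(gm_eci[1]),
            snr=eff.snr, seed=sub_seed + 1,
        )
        specs[sid] = (spec_b, spec_f)

        for tp, a in (("baseline", age[i]), ("followup", age[i] + 2.0)):
            rows.append({
                "subject_id": sid,
                "timepoint": tp,
                "age_years": float(a),
                "sex": "M" if sex_male[i] else "F",
                "grimage_years": float(grim[i]),
                "age_accel_grim": float(accel[i]),
                "total_brain_volume": float(brain_vol[i] - (2.0e3 if tp == "followup" else 0.0)),
                "wmh_volume": float(wmh_vol[i] if tp == "baseline"
                                    else 4.0 / 3.0 * np.pi * r_follow ** 3),
                "retained_at_followup": bool(retained[i]),
            })
    cohort = pd.DataFrame(rows)
    return cohort, specs
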