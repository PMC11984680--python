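"""Pipeline orchestration: config, per-scan processing, cohort analysis.

``run_pipeline`` drives phantom generation (or ingest), microstructure
fitting, tractography, lesionometry and statistics in order, writing each
stage's outputs before the next begins and recording lineage in a manifest.
A single global seed deterministically derives per-stage, per-subject
sub-seeds, so results cannot depend on execution order.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import csd as csd_mod
from . import io as io_mod
from . import lesionometry as les_mod
from . import stats as stats_mod
from . import tracking as trk_mod
from .errors import InvalidSpecError, LesionPipeError
from .phantom import CohortEffectSpec, PhantomSpec, build_phantom, generate_cohort

__all__ = [
    "CSDConfig", "PipelineConfig", "RunManifest",
    "derive_seed", "process_scan", "measure_cohort", "analyze_cohort",
    "run_pipeline",
]


def derive_seed(global_seed: int, *labels) -> int:
    """Stable per-stage/per-subject sub-seed from the global seed."""
    key = ":".join([str(global_seed), *map(str, labels)])
    return int.from_bytes(hashlib.blake2b(key.encode(), digest_size=8).digest(),
                          "big") % (2 ** 63)


@dataclass(frozen=True)
class CSDConfig:
    lmax: int = 8
    n_constraint_dirs: int = 300
    l0_anchor: float = 30.0

    def options(self) -> csd_mod.SS3TOptions:
        return csd_mod.SS3TOptions(n_constraint_dirs=self.n_constraint_dirs,
                                   l0_anchor=self.l0_anchor)


@dataclass
class PipelineConfig:
    """Validated configuration for a full synthetic-cohort run.

    Every stage's parameters are constructed (and therefore validated)
    when the config is built, before any stage executes.
    """

    seed: int = 0
    out_dir: str = "lesionpipe_out"
    n_subjects: int = 98
    effects: CohortEffectSpec = field(default_factory=CohortEffectSpec)
    csd: CSDConfig = field(default_factory=CSDConfig)
    tracking: trk_mod.TrackingParams = field(
        default_factory=lambda: trk_mod.TrackingParams(target_count=2000))
    sift_keep: int | None = 400   # None disables pruning
    min_tracts: int = 10
    models: tuple[str, ...] = ("baseline", "longitudinal", "missingness")
    write_volumes: bool = True    # per-scan NIfTI/TCK outputs

    def __post_init__(self) -> None:
        if self.min_tracts < 1:
            raise InvalidSpecError("min_tracts must be >= 1")
        if self.sift_keep is not None and not (
                0 < self.sift_keep <= self.tracking.target_count):
            raise InvalidSpecError("sift_keep must be in (0, target_count]")
        unknown = set(self.models) - {"baseline", "longitudinal", "missingness"}
        if unknown:
            raise InvalidSpecError(f"unknown models: {sorted(unknown)}")

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict[str, Any]:
        d = asdict(self)
        d["effects"] = asdict(self.effects)
        d["csd"] = asdict(self.csd)
        d["tracking"] = asdict(self.tracking)
        d["models"] = list(self.models)
        for key in ("grid_shape",):
            d["effects"][key] = list(d["effects"][key])
        return d

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "PipelineConfig":
        d = dict(d)
        eff = dict(d.pop("effects", {}))
        if "grid_shape" in eff:
            eff["grid_shape"] = tuple(eff["grid_shape"])
        if "snr" in eff and eff["snr"] in ("inf", None):
            eff["snr"] = np.inf
        d["effects"] = CohortEffectSpec(**eff)
        d["csd"] = CSDConfig(**d.pop("csd", {}))
        d["tracking"] = trk_mod.TrackingParams(**d.pop("tracking", {}))
        d["models"] = tuple(d.get("models", ("baseline", "longitudinal",
                                             "missingness")))
        return cls(**d)

    def to_yaml(self, path) -> None:
        d = self.to_dict()
        if np.isinf(d["effects"]["snr"]):
            d["effects"]["snr"] = "inf"
        with io_mod.atomic_write(path) as tmp:
            tmp.write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class RunManifest:
    """Lineage record of one pipeline run."""

    config_hash: str
    software_version: str
    global_seed: int
    stage_seeds: dict[str, int] = field(default_factory=dict)
    files: dict[str, str] = field(default_factory=dict)  # path -> sha256
    started: str = ""
    finished: str = ""

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    def checksums(self) -> dict[str, str]:
        return dict(self.files)


# --------------------------------------------------------------------------
# per-scan processing
# --------------------------------------------------------------------------

def reference_responses(effects: CohortEffectSpec,
                        csd_cfg: CSDConfig) -> csd_mod.ResponseSet:
    """Cohort-common response functions from a clean reference phantom.

    A single response set shared across subjects and timepoints keeps the
    compartment decomposition comparable between scans (a subject's own
    perilesional white matter would otherwise absorb their planted free-water
    elevation into the response itself).
    """
    from .phantom import default_phantom_spec

    ref = default_phantom_spec(grid_shape=effects.grid_shape,
                               voxel_size=effects.voxel_size,
                               bundle_fractions=(0.0, 0.0, 1.0))
    dwi, truth = build_phantom(ref)
    return csd_mod.estimate_responses(dwi, truth.tissue_masks,
                                      lmax=csd_cfg.lmax)


def process_scan(spec: PhantomSpec,
                 csd_cfg: CSDConfig,
                 tracking: trk_mod.TrackingParams,
                 sift_keep: int | None,
                 min_tracts: int,
                 seed: int,
                 responses: csd_mod.ResponseSet | None = None
                 ) -> dict[str, float]:
    """Phantom -> microstructure -> tractogram -> lesionometry for one scan.

    Returns the per-scan measurement row (volumes, whole-brain and ROI
    fraction means, lesion load).  ROI statistics are NaN when the ROI is
    empty; ``roi_empty`` flags the condition.  ``responses`` defaults to
    per-scan estimation from the phantom's own tissue masks.
    """
    dwi, truth = build_phantom(spec)
    if responses is None:
        responses = csd_mod.estimate_responses(dwi, truth.tissue_masks,
                                               lmax=csd_cfg.lmax)
    fod, weights = csd_mod.fit_ss3t_volume(dwi, responses, dwi.brain_mask,
                                           lmax=csd_cfg.lmax,
                                           options=csd_cfg.options())
    fractions = csd_mod.signal_fractions(weights, affine=dwi.affine,
                                         mask=dwi.brain_mask)
    tractogram = trk_mod.generate_tractogram(fod, dwi.brain_mask, tracking,
                                             np.random.default_rng(seed))
    if sift_keep is not None and sift_keep < len(tractogram):
        tractogram = trk_mod.sift_filter(tractogram, fod, sift_keep)

    wmh = les_mod.LesionMask(mask=truth.wmh_mask, affine=dwi.affine)
    subset = les_mod.select_lesioned_streamlines(tractogram, wmh)
    roi = les_mod.build_lesionometry_roi(subset, wmh, min_tracts=min_tracts)
    row: dict[str, float] = {
        "wmh_volume_mm3": wmh.volume_mm3,
        "roi_volume_mm3": roi.volume_mm3,
        "n_lesioned_tracts": float(len(subset)),
        "mask_volume_mm3": float(dwi.brain_mask.sum()) * dwi.voxel_volume,
    }
    m = dwi.brain_mask & fractions.mask
    for name, vol in (("eci", fractions.f_eci), ("ici", fractions.f_ici),
                      ("ica", fractions.f_ica)):
        row[f"global_f_{name}"] = float(vol[m].mean())
    if roi.is_empty:
        row.update(roi_empty=1.0, roi_f_eci=np.nan, roi_f_ici=np.nan,
                   roi_f_ica=np.nan, lesion_load=np.nan)
    else:
        les_mod.roi_statistics(roi, fractions)
        row.update(
            roi_empty=0.0,
            roi_f_eci=roi.mean_f_eci,
            roi_f_ici=roi.mean_f_ici,
            roi_f_ica=roi.mean_f_ica,
            lesion_load=les_mod.lesion_load(wmh, roi),
        )
    return row


def measure_cohort(cohort: pd.DataFrame,
                   specs: Mapping[str, tuple[PhantomSpec, PhantomSpec]],
                   config: PipelineConfig) -> pd.DataFrame:
    """Run the imaging pipeline on every scan of the cohort.

    Non-retained subjects are not scanned at follow-up; their follow-up rows
    are dropped (listwise deletion happens downstream).
    """
    responses = reference_responses(config.effects, config.csd)
    rows = []
    for _, rec in cohort.iterrows():
        sid, tp = rec["subject_id"], rec["timepoint"]
        if tp == "followup" and not rec["retained_at_followup"]:
            continue
        spec = specs[sid][0 if tp == "baseline" else 1]
        seed = derive_seed(config.seed, "scan", sid, tp)
        meas = process_scan(spec, config.csd, config.tracking,
                            config.sift_keep, config.min_tracts, seed,
                            responses=responses)
        rows.append({**rec.to_dict(), **meas})
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# cohort-level models
# --------------------------------------------------------------------------

def analyze_cohort(measured: pd.DataFrame,
                   models: tuple[str, ...] = ("baseline", "longitudinal",
                                              "missingness")) -> dict[str, Any]:
    """The study's planned models on a measured cohort table.

    Baseline GLMs control for age at scan, sex and a volumetric term (whole
    brain, WMH volume or ROI volume as appropriate); longitudinal models are
    change-score fits on complete pairs controlling for sex, baseline age and
    total brain volume.  No multiple-testing correction is applied (nominal
    p-values, as reported).
    """
    import logging

    from .errors import DegenerateDesignError

    log = logging.getLogger("lesionpipe.stats")
    out: dict[str, Any] = {}
    base = measured[measured["timepoint"] == "baseline"].reset_index(drop=True)

    def _try(name, fn):
        # smoke-scale runs may lack the df for some models; record and go on
        try:
            out[name] = fn()
        except DegenerateDesignError as exc:
            log.warning("model %s skipped: %s", name, exc)

    if "baseline" in models:
        _try("wmh_volume~accel", lambda: stats_mod.fit_glm(
            base["wmh_volume_mm3"],
            {"age_accel_grim": base["age_accel_grim"],
             "age": base["age_years"], "sex": base["sex"],
             "total_brain_volume": base["total_brain_volume"]},
            term_of_interest="age_accel_grim"))
        bb = base[base["roi_empty"] == 0]
        for frac in ("eci", "ici", "ica"):
            _try(f"roi_f_{frac}~accel", lambda frac=frac: stats_mod.fit_glm(
                bb[f"roi_f_{frac}"],
                {"age_accel_grim": bb["age_accel_grim"],
                 "age": bb["age_years"], "sex": bb["sex"],
                 "roi_volume": bb["roi_volume_mm3"]},
                term_of_interest="age_accel_grim"))
        _try("lesion_load~accel", lambda: stats_mod.fit_glm(
            bb["lesion_load"],
            {"age_accel_grim": bb["age_accel_grim"], "age": bb["age_years"],
             "sex": bb["sex"], "total_brain_volume": bb["total_brain_volume"]},
            term_of_interest="age_accel_grim"))

    if "longitudinal" in models:
        fol = measured[measured["timepoint"] == "followup"]
        pairs = base.merge(fol, on="subject_id", suffixes=("_b", "_f"))
        pairs = pairs[(pairs["roi_empty_b"] == 0) & (pairs["roi_empty_f"] == 0)]
        cov = {"age_accel_grim": pairs["age_accel_grim_b"],
               "sex": pairs["sex_b"], "age_baseline": pairs["age_years_b"],
               "total_brain_volume": pairs["total_brain_volume_b"]}
        for scope in ("roi", "global"):
            for frac in ("eci", "ici", "ica"):
                col = f"{scope}_f_{frac}"
                _try(f"long_{col}~accel",
                     lambda col=col: stats_mod.longitudinal_model(
                         pairs[f"{col}_b"], pairs[f"{col}_f"], cov,
                         term_of_interest="age_accel_grim"))

    if "missingness" in models:
        out["missingness"] = stats_mod.missingness_tests(measured)
    return out


def results_frame(results: Mapping[str, Any]) -> pd.DataFrame:
    """Tidy TSV-ready table of every fitted model term."""
    rows = []
    for name, res in results.items():
        if isinstance(res, stats_mod.GLMResult):
            t = res[res.term_of_interest]
            rows.append({"model": name, "term": res.term_of_interest,
                         "estimate": t["coef"], "statistic": t["t"],
                         "stat_type": "t", "df": t["df"], "p": t["p"]})
        elif isinstance(res, stats_mod.LongitudinalResult):
            rows.append({"model": name, "term": res.term,
                         "estimate": res.estimate, "statistic": res.F_statistic,
                         "stat_type": "F", "df": res.df_denominator,
                         "p": res.p_value})
        elif isinstance(res, pd.DataFrame):
            for _, r in res.iterrows():
                rows.append({"model": name, "term": r["variable"],
                             "estimate": np.nan, "statistic": r["t_statistic"],
                             "stat_type": "t", "df": r["df"], "p": r["p"]})
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# full run
# --------------------------------------------------------------------------

def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute phantom -> csd -> tracking -> lesionometry -> stats.

    Each stage's outputs are written before the next stage begins; any stage
    failure aborts with the stage name and offending input in the message.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_dict = _json_safe(config.to_dict())
    cfg_dict.pop("out_dir", None)  # output location is not part of identity
    cfg_yaml = yaml.safe_dump(cfg_dict, sort_keys=True)
    manifest = RunManifest(
        config_hash=hashlib.sha256(cfg_yaml.encode()).hexdigest(),
        software_version=_version(),
        global_seed=config.seed,
        started=time.strftime("%Y-%m-%dT%H:%M:%S"),
    )

    def record(path: Path) -> None:
        manifest.files[str(path.relative_to(out))] = io_mod.sha256_file(path)

    import logging

    log = logging.getLogger("lesionpipe.pipeline")
    try:
        stage = "phantom"
        log.info("[phantom] generating cohort of %d subjects", config.n_subjects)
        cohort_seed = derive_seed(config.seed, "cohort")
        manifest.stage_seeds["cohort"] = cohort_seed
        cohort, specs = generate_cohort(config.n_subjects, config.effects,
                                        seed=cohort_seed)
        config.to_yaml(out / "config.yaml")
        record(out / "config.yaml")
        io_mod.write_tsv(out / "cohort.tsv", cohort)
        record(out / "cohort.tsv")

        stage = "imaging"
        log.info("[imaging] csd + tracking + lesionometry per scan")
        measured = _measure_and_write(cohort, specs, config, out, manifest,
                                      record)
        io_mod.write_tsv(out / "measurements.tsv", measured)
        record(out / "measurements.tsv")

        stage = "stats"
        log.info("[stats] fitting models: %s", ", ".join(config.models))
        results = analyze_cohort(measured, config.models)
        io_mod.write_tsv(out / "model_results.tsv", results_frame(results))
        record(out / "model_results.tsv")
        _write_report(out / "report.txt", results)
        record(out / "report.txt")
    except LesionPipeError as exc:
        raise LesionPipeError(f"stage {stage!r} failed: {exc}") from exc

    manifest.finished = time.strftime("%Y-%m-%dT%H:%M:%S")
    with io_mod.atomic_write(out / "manifest.json") as tmp:
        tmp.write_text(manifest.to_json())
    return manifest


def _measure_and_write(cohort, specs, config, out: Path, manifest, record):
    rows = []
    for _, rec in cohort.iterrows():
        sid, tp = rec["subject_id"], rec["timepoint"]
        if tp == "followup" and not rec["retained_at_followup"]:
            continue
        spec = specs[sid][0 if tp == "baseline" else 1]
        seed = derive_seed(config.seed, "scan", sid, tp)
        manifest.stage_seeds[f"scan:{sid}:{tp}"] = seed
        if config.write_volumes:
            row = _process_and_write(spec, config, seed, out / sid / tp, record)
        else:
            row = process_scan(spec, config.csd, config.tracking,
                               config.sift_keep, config.min_tracts, seed)
        rows.append({**rec.to_dict(), **row})
    return pd.DataFrame(rows)


def _process_and_write(spec, config, seed, scan_dir: Path, record):
    scan_dir.mkdir(parents=True, exist_ok=True)
    dwi, truth = build_phantom(spec)
    io_mod.write_nifti(scan_dir / "dwi.nii", dwi.data, dwi.affine)
    io_mod.write_bvals_bvecs(scan_dir / "bvals", scan_dir / "bvecs", dwi.gtab)
    io_mod.write_nifti(scan_dir / "wmh.nii", truth.wmh_mask, dwi.affine)
    responses = csd_mod.estimate_responses(dwi, truth.tissue_masks,
                                           lmax=config.csd.lmax)
    fod, weights = csd_mod.fit_ss3t_volume(dwi, responses, dwi.brain_mask,
                                           lmax=config.csd.lmax,
                                           options=config.csd.options())
    io_mod.write_nifti(scan_dir / "fod.nii", fod.coeffs, dwi.affine)
    fractions = csd_mod.signal_fractions(weights, affine=dwi.affine,
                                         mask=dwi.brain_mask)
    for name, vol in (("eci", fractions.f_eci), ("ici", fractions.f_ici),
                      ("ica", fractions.f_ica)):
        io_mod.write_nifti(scan_dir / f"f_{name}.nii", vol, dwi.affine)
    tractogram = trk_mod.generate_tractogram(fod, dwi.brain_mask,
                                             config.tracking,
                                             np.random.default_rng(seed))
    if config.sift_keep is not None and config.sift_keep < len(tractogram):
        tractogram = trk_mod.sift_filter(tractogram, fod, config.sift_keep)
    io_mod.write_tck(scan_dir / "tracks.tck", tractogram)

    wmh = les_mod.LesionMask(mask=truth.wmh_mask, affine=dwi.affine)
    subset = les_mod.select_lesioned_streamlines(tractogram, wmh)
    roi = les_mod.build_lesionometry_roi(subset, wmh, config.min_tracts)
    io_mod.write_nifti(scan_dir / "roi.nii", roi.mask, dwi.affine)
    for f in ("dwi.nii", "bvals", "bvecs", "wmh.nii", "fod.nii", "f_eci.nii",
              "f_ici.nii", "f_ica.nii", "tracks.tck", "roi.nii"):
        record(scan_dir / f)

    row: dict[str, float] = {
        "wmh_volume_mm3": wmh.volume_mm3,
        "roi_volume_mm3": roi.volume_mm3,
        "n_lesioned_tracts": float(len(subset)),
        "mask_volume_mm3": float(dwi.brain_mask.sum()) * dwi.voxel_volume,
    }
    m = dwi.brain_mask & fractions.mask
    for name, vol in (("eci", fractions.f_eci), ("ici", fractions.f_ici),
                      ("ica", fractions.f_ica)):
        row[f"global_f_{name}"] = float(vol[m].mean())
    if roi.is_empty:
        row.update(roi_empty=1.0, roi_f_eci=np.nan, roi_f_ici=np.nan,
                   roi_f_ica=np.nan, lesion_load=np.nan)
    else:
        les_mod.roi_statistics(roi, fractions)
        row.update(roi_empty=0.0, roi_f_eci=roi.mean_f_eci,
                   roi_f_ici=roi.mean_f_ici, roi_f_ica=roi.mean_f_ica,
                   lesion_load=les_mod.lesion_load(wmh, roi))
    return row


def _write_report(path: Path, results: Mapping[str, Any]) -> None:
    lines = ["lesionpipe model report",
             "sex coding: F=0, M=1",
             "note: nominal p-values, no multiple-testing correction", ""]
    frame = results_frame(results)
    lines.append(frame.to_string(index=False))
    with io_mod.atomic_write(path) as tmp:
        tmp.write_text("\n".join(lines) + "\n")


def _json_safe(obj):
    if isinstance(obj, dict):
        return {k: _json_safe(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_json_safe(v) for v in obj]
    if isinstance(obj, float) and np.isinf(obj):
        return "inf"
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def _version() -> str:
    from . import __version__

    return __version__
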