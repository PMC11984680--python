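"""File formats: NIfTI volumes, FSL bvals/bvecs, TCK tractograms, TSV tables.

All writers go through an atomic write helper: content lands in a
``<name>.partial`` file that is renamed into place only on success, so a
failed run never leaves a truncated file without a marker.
"""

from __future__ import annotations

import hashlib
import os
from contextlib import contextmanager
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .errors import AlignmentError, FormatError
from .phantom import GradientTable
from .tracking import Streamline, Tractogram

__all__ = [
    "read_nifti", "write_nifti",
    "read_bvals_bvecs", "write_bvals_bvecs",
    "read_tck", "write_tck",
    "read_tsv", "write_tsv",
    "sha256_file", "check_affines_match", "atomic_write",
]


@contextmanager
def atomic_write(path: str | os.PathLike):
    """Yield a temporary ``.partial`` path, renamed to ``path`` on success."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tmp = path.with_name(path.name + ".partial")
    try:
        yield tmp
        os.replace(tmp, path)
    except BaseException:
        # leave the .partial marker behind for post-mortem inspection
        raise


def sha256_file(path: str | os.PathLike) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def check_affines_match(a: np.ndarray, b: np.ndarray, atol: float = 1e-5) -> None:
    if not np.allclose(a, b, atol=atol):
        raise AlignmentError("affine mismatch between paired volumes")


# -- NIfTI ------------------------------------------------------------------

def write_nifti(path: str | os.PathLike, data: np.ndarray, affine: np.ndarray,
                dtype=np.float32) -> None:
    arr = np.asarray(data)
    if arr.dtype == bool:
        dtype = np.uint8
    img = nib.Nifti1Image(arr.astype(dtype), np.asarray(affine))
    with atomic_write(path) as tmp:
        tmp.write_bytes(img.to_bytes())


def read_nifti(path: str | os.PathLike) -> tuple[np.ndarray, np.ndarray]:
    img = nib.load(str(path))
    return np.asarray(img.get_fdata()), np.asarray(img.affine)


# -- FSL bvals / bvecs ------------------------------------------------------

def write_bvals_bvecs(bvals_path: str | os.PathLike,
                      bvecs_path: str | os.PathLike,
                      gtab: GradientTable) -> None:
    with atomic_write(bvals_path) as tmp:
        np.savetxt(tmp, gtab.bvals[None, :], fmt="%.6g")
    with atomic_write(bvecs_path) as tmp:
        np.savetxt(tmp, gtab.bvecs.T, fmt="%.9g")


def read_bvals_bvecs(bvals_path: str | os.PathLike,
                     bvecs_path: str | os.PathLike) -> GradientTable:
    bvals = np.loadtxt(bvals_path).reshape(-1)
    bvecs = np.loadtxt(bvecs_path)
    if bvecs.ndim != 2 or 3 not in bvecs.shape:
        raise FormatError("bvecs must be a 3xN (or Nx3) table")
    if bvecs.shape[0] == 3 and bvecs.shape[1] != 3:
        bvecs = bvecs.T
    elif bvecs.shape[1] != 3:
        bvecs = bvecs.T
    if bvecs.shape[0] != bvals.size:
        raise FormatError(
            f"bvals has {bvals.size} entries but bvecs has {bvecs.shape[0]}")
    return GradientTable(bvals=bvals, bvecs=bvecs)


# -- TCK (MRtrix streamline format, via nibabel) ----------------------------

def write_tck(path: str | os.PathLike, tractogram: Tractogram) -> None:
    from nibabel.streamlines import Tractogram as NibTractogram
    from nibabel.streamlines.tck import TckFile

    nt = NibTractogram([s.points for s in tractogram.streamlines],
                       affine_to_rasmm=np.eye(4))
    with atomic_write(path) as tmp:
        TckFile(nt).save(str(tmp))


def read_tck(path: str | os.PathLike, affine: np.ndarray,
             step_size: float | None = None) -> Tractogram:
    from nibabel.streamlines import load as nib_load
    from nibabel.streamlines.tck import TckFile

    try:
        tck = nib_load(str(path))
    except Exception as exc:  # malformed header
        raise FormatError(f"cannot read TCK file {path}: {exc}") from exc
    if not isinstance(tck, TckFile):
        raise FormatError(f"{path} is not a TCK file")
    streamlines = []
    for pts in tck.tractogram.streamlines:
        pts = np.asarray(pts, dtype=float)
        if step_size is None:
            seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
            ss = float(np.median(seg)) if seg.size else 0.0
        else:
            ss = step_size
        streamlines.append(Streamline(points=pts, step_size=ss))
    return Tractogram(streamlines=streamlines,
                      affine=np.asarray(affine, dtype=float))


# -- TSV --------------------------------------------------------------------

def write_tsv(path: str | os.PathLike, frame: pd.DataFrame) -> None:
    with atomic_write(path) as tmp:
        frame.to_csv(tmp, sep="\t", index=False)


def read_tsv(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
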