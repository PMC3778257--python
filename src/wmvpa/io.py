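"""Readers and writers: NIfTI volumes, cohort directories, result tables.

A cohort directory holds one ``.nii.gz`` per subject, a ``clinical.csv``
with the subject covariates (including the outcome label), and optionally
the generating ``spec.json``. Every artifact-writing helper also appends
to a manifest (input hashes, configuration echo, package versions) so a
run can be reproduced from its outputs alone.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .synthetic import CohortSpec
from .volumes import SubjectVolume

__all__ = [
    "save_volume", "load_volume", "save_mask", "load_mask",
    "write_cohort", "read_cohort", "write_manifest",
]


def _affine(voxel_size_mm) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = voxel_size_mm
    return aff


def save_volume(volume: SubjectVolume, path) -> None:
    img = nib.Nifti1Image(volume.data.astype(np.float32), _affine(volume.voxel_size_mm))
    nib.save(img, str(path))


def load_volume(path, subject_id: str, label: int) -> SubjectVolume:
    img = nib.load(str(path))
    voxel_size = tuple(float(z) for z in img.header.get_zooms()[:3])
    return SubjectVolume(
        data=np.asarray(img.dataobj, dtype=float),
        voxel_size_mm=voxel_size,
        subject_id=subject_id,
        label=label,
    )


def save_mask(mask: np.ndarray, voxel_size_mm, path) -> None:
    img = nib.Nifti1Image(mask.astype(np.uint8), _affine(voxel_size_mm))
    nib.save(img, str(path))


def load_mask(path) -> np.ndarray:
    img = nib.load(str(path))
    return np.asarray(img.dataobj) > 0


def write_cohort(volumes: list[SubjectVolume], clinical: pd.DataFrame,
                 out_dir, spec: CohortSpec | None = None) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for v in volumes:
        save_volume(v, out / f"{v.subject_id}.nii.gz")
    clinical.to_csv(out / "clinical.csv", index=False)
    if spec is not None:
        (out / "spec.json").write_text(json.dumps(spec.to_dict(), indent=2))
    return out


def read_cohort(cohort_dir) -> tuple[list[SubjectVolume], pd.DataFrame]:
    """Load a cohort directory written by :func:`write_cohort`."""
    d = Path(cohort_dir)
    csv = d / "clinical.csv"
    if not csv.exists():
        raise FileNotFoundError(f"no clinical.csv in {d}")
    clinical = pd.read_csv(csv)
    volumes = []
    for _, row in clinical.iterrows():
        sid = str(row["subject_id"])
        path = d / f"{sid}.nii.gz"
        if not path.exists():
            raise FileNotFoundError(f"missing volume for subject {sid}: {path}")
        volumes.append(load_volume(path, sid, int(row["label"])))
    return volumes, clinical


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(out_dir, config: dict, inputs: list = ()) -> Path:
    """Record configuration, input hashes and versions next to the artifacts."""
    import wmvpa
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "config": config,
        "inputs": {str(p): _sha256(Path(p)) for p in inputs},
        "versions": {
            "wmvpa": wmvpa.__version__,
            "numpy": np.__version__,
            "nibabel": nib.__version__,
            "pandas": pd.__version__,
        },
    }
    path = out / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return path
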