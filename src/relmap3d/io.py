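"""NIfTI and tabular I/O for phantoms, atlases, maps and visit tables."""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .lrp import RelevanceMap
from .phantoms import Phantom, SyntheticAtlas


def save_nifti(data: np.ndarray, path, dtype=np.float32) -> None:
    img = nib.Nifti1Image(np.asarray(data, dtype=dtype), affine=np.eye(4))
    nib.save(img, str(path))


def load_nifti(path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).get_fdata())


def save_cohort(cohort: list[Phantom], outdir) -> Path:
    """Volumes as .nii.gz plus a participants.tsv metadata sidecar."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for p in cohort:
        save_nifti(p.volume, outdir / f"{p.subject_id}.nii.gz")
        save_nifti(p.lesion_mask.astype(np.uint8), outdir / f"{p.subject_id}_lesion.nii.gz",
                   dtype=np.uint8)
        rows.append(p.metadata())
    pd.DataFrame(rows).to_csv(outdir / "participants.tsv", sep="\t", index=False)
    return outdir


def load_cohort(indir) -> list[Phantom]:
    indir = Path(indir)
    meta = pd.read_csv(indir / "participants.tsv", sep="\t")
    cohort = []
    for _, row in meta.iterrows():
        vol = load_nifti(indir / f"{row.subject_id}.nii.gz").astype(np.float32)
        lesion = load_nifti(indir / f"{row.subject_id}_lesion.nii.gz").astype(bool)
        cohort.append(Phantom(volume=vol, label=int(row.label), lesion_mask=lesion,
                              subject_id=str(row.subject_id), site=str(row.site),
                              age=float(row.age), sex=str(row.sex)))
    return cohort


def save_atlas(atlas: SyntheticAtlas, path, names_path=None) -> None:
    save_nifti(atlas.labels, path, dtype=np.int16)
    if names_path is not None:
        Path(names_path).write_text(json.dumps(atlas.names, indent=2))


def load_atlas(path, names_path=None) -> SyntheticAtlas:
    labels = load_nifti(path).astype(np.int32)
    if names_path is not None:
        names = {int(k): v for k, v in json.loads(Path(names_path).read_text()).items()}
    else:
        names = {int(k): f"region_{int(k):02d}" for k in np.unique(labels) if k > 0}
    return SyntheticAtlas(labels=labels, names=names)


def save_map(m: RelevanceMap, path, sidecar=None) -> None:
    """Relevance map as NIfTI with a JSON sidecar carrying provenance."""
    save_nifti(m.data, path)
    if sidecar is not None:
        meta = {k: v for k, v in m.meta.items()
                if isinstance(v, (int, float, str, list, type(None)))}
        Path(sidecar).write_text(json.dumps(meta, indent=2))


def save_visits(visits: pd.DataFrame, path) -> None:
    visits.to_csv(path, sep="\t", index=False)


def load_visits(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
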