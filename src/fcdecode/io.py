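"""Reading and writing the pipeline's on-disk formats.

NIfTI volumes go through nibabel with a diagonal affine built from the voxel
size (the pipeline supports no shear or rotation; voxel indices are 0-based
and world coordinates are index x voxel size). Tabular formats are TSV;
gene sets use the GMT convention (set name, description, then member ids,
tab-separated); the cohort manifest is JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from fcdecode.synthetic import SyntheticCohort
from fcdecode.types import BoldSeries, NuisanceSet, Parcellation


def _affine(voxel_size_mm) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = voxel_size_mm
    return aff


def save_bold(series: BoldSeries, path) -> None:
    img = nib.Nifti1Image(series.data.astype(np.float32), _affine(series.voxel_size_mm))
    img.header.set_zooms(tuple(series.voxel_size_mm) + (series.tr_seconds,))
    nib.save(img, str(path))


def load_bold(path, brain_mask: np.ndarray | None = None) -> BoldSeries:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj, dtype=float)
    zooms = img.header.get_zooms()
    if brain_mask is None:
        brain_mask = np.ones(data.shape[:3], dtype=bool)
    return BoldSeries(
        data=data,
        voxel_size_mm=tuple(float(z) for z in zooms[:3]),
        tr_seconds=float(zooms[3]) if len(zooms) > 3 else 1.0,
        brain_mask=brain_mask,
    )


def save_mask(mask: np.ndarray, voxel_size_mm, path) -> None:
    nib.save(nib.Nifti1Image(mask.astype(np.uint8), _affine(voxel_size_mm)), str(path))


def load_mask(path) -> np.ndarray:
    return np.asanyarray(nib.load(str(path)).dataobj) > 0


def save_labels(labels: np.ndarray, voxel_size_mm, path) -> None:
    nib.save(nib.Nifti1Image(labels.astype(np.int32), _affine(voxel_size_mm)), str(path))


def load_parcellation(path) -> Parcellation:
    labels = np.asanyarray(nib.load(str(path)).dataobj).astype(np.int32)
    return Parcellation(labels=labels)


def save_map(values: np.ndarray, voxel_size_mm, path) -> None:
    nib.save(nib.Nifti1Image(values.astype(np.float32), _affine(voxel_size_mm)), str(path))


def save_motion(motion: np.ndarray, path) -> None:
    """Six numeric columns, one row per retained volume, no header."""
    np.savetxt(str(path), motion, delimiter="\t", fmt="%.8g")


def load_motion(path) -> np.ndarray:
    out = np.loadtxt(str(path), delimiter="\t")
    if out.ndim == 1:
        out = out[None, :]
    return out


def save_expression_tsv(matrix, path) -> None:
    matrix.to_frame().rename_axis("gene_id").to_csv(str(path), sep="\t")


def load_expression_tsv(path, normalized: bool = False):
    from fcdecode.decoding import ExpressionMatrix

    df = pd.read_csv(str(path), sep="\t", index_col=0)
    return ExpressionMatrix(
        gene_ids=list(df.index.astype(str)),
        region_labels=list(df.columns.astype(str)),
        energies=df.to_numpy(dtype=float),
        normalized=normalized,
    )


def save_gmt(annotations: dict[str, list[str]], path) -> None:
    with open(path, "w") as fh:
        for name, members in annotations.items():
            fh.write("\t".join([name, "synthetic"] + list(members)) + "\n")


def load_gmt(path) -> dict[str, list[str]]:
    out: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 3:
                out[parts[0]] = parts[2:]
    return out


def load_gene_list(path) -> list[str]:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def save_gene_list(genes, path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g}\n")


def save_cohort(cohort: SyntheticCohort, outdir) -> dict:
    """Write a full synthetic cohort to disk and return its manifest.

    Layout: one ``<subject>_bold.nii.gz`` + ``<subject>_motion.tsv`` per
    subject, shared ``parcellation.nii.gz`` / ``brain_mask.nii.gz`` /
    ``ventricle_mask.nii.gz``, and ``manifest.json`` mapping subject ids to
    group labels and file paths.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    vs = cohort.subjects[0].series.voxel_size_mm
    save_labels(cohort.parcellation.labels, vs, outdir / "parcellation.nii.gz")
    save_mask(cohort.subjects[0].series.brain_mask, vs, outdir / "brain_mask.nii.gz")
    save_mask(cohort.ventricle_mask, vs, outdir / "ventricle_mask.nii.gz")
    manifest: dict = {
        "seed": cohort.config.rng_seed if cohort.config else None,
        "tr_seconds": float(cohort.subjects[0].series.tr_seconds),
        "parcellation": "parcellation.nii.gz",
        "brain_mask": "brain_mask.nii.gz",
        "ventricle_mask": "ventricle_mask.nii.gz",
        "subjects": {},
    }
    for subj in cohort.subjects:
        bold_name = f"{subj.subject_id}_bold.nii.gz"
        motion_name = f"{subj.subject_id}_motion.tsv"
        save_bold(subj.series, outdir / bold_name)
        save_motion(subj.nuisance.motion_traces, outdir / motion_name)
        manifest["subjects"][subj.subject_id] = {
            "group": subj.group,
            "bold": bold_name,
            "motion": motion_name,
        }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


def load_manifest(outdir) -> dict:
    with open(Path(outdir) / "manifest.json") as fh:
        return json.load(fh)
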