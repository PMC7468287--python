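"""Readers and writers for every on-disk artifact.

Volumes, label images and displacement fields are NIfTI-1 (``.nii`` /
``.nii.gz``); expression tables are TSV; contrast reports are CSV; all
configuration is YAML.  Fields follow the NIfTI vector convention: a 5-D
image of shape ``(nx, ny, nz, 1, 3)`` whose last axis holds the (x, y, z)
displacement components in mm.

Readers validate and reject rather than silently coerce: a 4-D image is a
dimensionality error, a 2-component "field" is a format error, duplicate
expression keys are an integrity error.
"""

from __future__ import annotations

import os
from typing import Iterable

import nibabel as nib
import numpy as np
import pandas as pd

from .core import DisplacementField, LabelVolume, VolumeGrid
from .errors import DimensionalityError, FormatError, IntegrityError

__all__ = [
    "read_volume",
    "write_volume",
    "read_labels",
    "write_labels",
    "read_field",
    "write_field",
    "read_expression",
    "write_expression",
    "write_contrast_report",
    "EXPRESSION_COLUMNS",
    "LAYERS",
]

#: Required columns of an expression TSV, in canonical order.
EXPRESSION_COLUMNS = ["gene_id", "specimen_id", "region", "layer", "value"]

#: Transient laminar compartments of the fetal cortex sampled per region:
#: subpial granular zone, marginal zone, cortical plate, subplate.
LAYERS = ["SG", "MZ", "CP", "SP"]


def _affine(spacing, origin) -> np.ndarray:
    aff = np.eye(4)
    aff[:3, :3] = np.diag(spacing)
    aff[:3, 3] = origin
    return aff


def _load_nifti(path):
    try:
        img = nib.load(os.fspath(path))
    except Exception as exc:  # nibabel raises several classes for bad files
        raise FormatError(f"cannot read NIfTI file {path}: {exc}") from exc
    return img

def _grid_meta(img):
    aff = img.affine
    spacing = np.sqrt((aff[:3, :3] ** 2).sum(axis=0))
    origin = aff[:3, 3].copy()
    return spacing, origin


def read_volume(path) -> VolumeGrid:
    """Read a 3-D scalar NIfTI volume."""
    img = _load_nifti(path)
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise DimensionalityError(f"expected a 3-D volume, got ndim={data.ndim} in {path}")
    spacing, origin = _grid_meta(img)
    return VolumeGrid(np.asarray(data, dtype=np.float64), spacing, origin)


def write_volume(vol: VolumeGrid, path) -> None:
    img = nib.Nifti1Image(np.asarray(vol.values, dtype=np.float64), _affine(vol.spacing, vol.origin))
    nib.save(img, os.fspath(path))


def read_labels(path, label_dict: dict[str, int]) -> LabelVolume:
    """Read an integer segmentation; ``label_dict`` supplies the name -> id map."""
    img = _load_nifti(path)
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise DimensionalityError(f"expected a 3-D label image, got ndim={data.ndim} in {path}")
    if not np.allclose(data, np.round(data)):
        raise FormatError(f"label image {path} contains non-integer values")
    spacing, origin = _grid_meta(img)
    return LabelVolume(np.asarray(np.round(data), dtype=np.int32), dict(label_dict), spacing, origin)


def write_labels(lab: LabelVolume, path) -> None:
    img = nib.Nifti1Image(np.asarray(lab.labels, dtype=np.int16), _affine(lab.spacing, lab.origin))
    nib.save(img, os.fspath(path))


def read_field(path) -> DisplacementField:
    """Read a displacement field stored with the NIfTI 5th-dimension vector
    convention (or a plain ``(nx, ny, nz, 3)`` 4-D image)."""
    img = _load_nifti(path)
    data = np.asanyarray(img.dataobj)
    if data.ndim == 5:
        if data.shape[3] != 1 or data.shape[4] != 3:
            raise FormatError(
                f"vector NIfTI must have shape (nx, ny, nz, 1, 3), got {data.shape} in {path}"
            )
        data = data[:, :, :, 0, :]
    elif data.ndim == 4:
        if data.shape[3] != 3:
            raise FormatError(f"field must carry 3 components, got {data.shape[3]} in {path}")
    else:
        raise DimensionalityError(f"expected a 4-D/5-D vector image, got ndim={data.ndim}")
    spacing, origin = _grid_meta(img)
    return DisplacementField(np.asarray(data, dtype=np.float64), spacing, origin)


def write_field(field: DisplacementField, path) -> None:
    data = field.vectors[:, :, :, np.newaxis, :]  # (nx, ny, nz, 1, 3)
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float64), _affine(field.spacing, field.origin))
    img.header.set_intent("vector")
    nib.save(img, os.fspath(path))


def read_expression(path) -> pd.DataFrame:
    """Read a layered regional expression TSV.

    Columns: gene_id, specimen_id, region, layer, value (linear-scale,
    non-negative).  The (gene, specimen, region, layer) key must be unique.
    """
    try:
        df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "specimen_id": str,
                                                "region": str, "layer": str})
    except Exception as exc:
        raise FormatError(f"cannot parse expression TSV {path}: {exc}") from exc
    missing = [c for c in EXPRESSION_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"expression TSV {path} lacks columns {missing}")
    return validate_expression(df[EXPRESSION_COLUMNS])


def validate_expression(df: pd.DataFrame) -> pd.DataFrame:
    bad_layers = set(df["layer"].unique()) - set(LAYERS)
    if bad_layers:
        raise IntegrityError(f"unknown layers {sorted(bad_layers)}; expected {LAYERS}")
    if (df["value"] < 0).any():
        n = int((df["value"] < 0).sum())
        raise IntegrityError(f"{n} negative expression values")
    key = ["gene_id", "specimen_id", "region", "layer"]
    if df.duplicated(subset=key).any():
        dup = df[df.duplicated(subset=key, keep=False)].iloc[0]
        raise IntegrityError(
            "duplicate expression key "
            f"({dup['gene_id']}, {dup['specimen_id']}, {dup['region']}, {dup['layer']})"
        )
    return df.reset_index(drop=True)


def write_expression(df: pd.DataFrame, path) -> None:
    df[EXPRESSION_COLUMNS].to_csv(path, sep="\t", index=False)


def write_contrast_report(result, path) -> None:
    """Write a contrast selection as CSV, layers in SG/MZ/CP/SP order and
    rows by descending fold change within each layer.

    ``result`` is a :class:`morphogrowth.transcriptome.ContrastResult`.
    An empty selection yields a header-only file.
    """
    frames = []
    for layer in LAYERS:
        block = result.layers.get(layer)
        if block is None:
            continue
        sel = block.table[block.table["selected"]].copy()
        sel.insert(0, "layer", layer)
        frames.append(sel.sort_values("fold_change", ascending=False))
    cols = ["layer", "gene_id", "target_mean", "contrast_mean", "fold_change", "rank"]
    if frames:
        out = pd.concat(frames, ignore_index=True)[cols]
    else:
        out = pd.DataFrame(columns=cols)
    out.to_csv(path, index=False)
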