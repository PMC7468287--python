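"""Displacement-magnitude heat maps and arrow (quiver) renderings.

Figures are assertion-free artifacts: the arrays behind every rendering
are also exported as CSV so tests and downstream analysis work on numbers,
never on pixels.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Literal

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .core import DisplacementField, LabelVolume, VolumeGrid, check_same_grid

__all__ = ["SliceSpec", "magnitude_map", "arrow_plot", "slice_vectors"]

#: Axis index orthogonal to each anatomical plane (arrays are (x, y, z)).
_PLANE_AXIS = {"sagittal": 0, "coronal": 1, "axial": 2}


@dataclass(frozen=True)
class SliceSpec:
    """A rendered orthogonal slice: plane, index, arrow stride and an
    optional magnitude colour range (mm)."""

    plane: Literal["axial", "coronal", "sagittal"] = "coronal"
    index: int = 0
    stride: int = 4
    vmax: float | None = None

    def validate(self, shape) -> None:
        if self.plane not in _PLANE_AXIS:
            raise ValueError(f"unknown plane {self.plane!r}")
        axis = _PLANE_AXIS[self.plane]
        if not (0 <= self.index < shape[axis]):
            raise ValueError(
                f"slice index {self.index} out of range for {self.plane} axis of size {shape[axis]}"
            )
        if self.stride < 1:
            raise ValueError("stride must be >= 1")


def magnitude_map(fld: DisplacementField) -> VolumeGrid:
    """Per-voxel Euclidean norm |u(x)| in mm (the heat-map quantity)."""
    return VolumeGrid(fld.magnitude(), fld.spacing.copy(), fld.origin.copy())


def slice_vectors(fld: DisplacementField, labels: LabelVolume, spec: SliceSpec) -> pd.DataFrame:
    """The numeric content of an arrow plot: one row per stride-subsampled
    in-mask voxel of the slice, with its in-plane position (mm), label,
    in-plane displacement components and 3-D magnitude."""
    check_same_grid(fld, labels, "field/labels")
    spec.validate(fld.shape)
    axis = _PLANE_AXIS[spec.plane]
    in_plane = [d for d in range(3) if d != axis]

    sl = [slice(None)] * 3
    sl[axis] = spec.index
    vec = fld.vectors[tuple(sl)]
    lab = labels.labels[tuple(sl)]

    rows = []
    for i in range(0, lab.shape[0], spec.stride):
        for k in range(0, lab.shape[1], spec.stride):
            if lab[i, k] == 0:
                continue
            idx3 = [0, 0, 0]
            idx3[axis] = spec.index
            idx3[in_plane[0]], idx3[in_plane[1]] = i, k
            pos = labels.origin + labels.spacing * np.asarray(idx3)
            rows.append({
                "pos_h_mm": pos[in_plane[0]],
                "pos_v_mm": pos[in_plane[1]],
                "label": int(lab[i, k]),
                "u_h_mm": float(vec[i, k, in_plane[0]]),
                "u_v_mm": float(vec[i, k, in_plane[1]]),
                "magnitude_mm": float(np.linalg.norm(vec[i, k])),
            })
    return pd.DataFrame(rows, columns=["pos_h_mm", "pos_v_mm", "label",
                                       "u_h_mm", "u_v_mm", "magnitude_mm"])


def arrow_plot(fld: DisplacementField, labels: LabelVolume, spec: SliceSpec,
               out_path, export_path=None) -> pd.DataFrame:
    """Write a quiver-over-heat-map figure for one slice and return (and
    optionally export) the sampled vectors behind it.

    Deterministic for fixed inputs.  The heat map is the in-slice
    displacement magnitude; arrows are drawn at stride-subsampled in-mask
    voxels.
    """
    data = slice_vectors(fld, labels, spec)
    axis = _PLANE_AXIS[spec.plane]
    in_plane = [d for d in range(3) if d != axis]

    sl = [slice(None)] * 3
    sl[axis] = spec.index
    mag = magnitude_map(fld).values[tuple(sl)]

    fig, ax = plt.subplots(figsize=(6, 6))
    extent = [
        fld.origin[in_plane[0]],
        fld.origin[in_plane[0]] + fld.spacing[in_plane[0]] * (mag.shape[0] - 1),
        fld.origin[in_plane[1]],
        fld.origin[in_plane[1]] + fld.spacing[in_plane[1]] * (mag.shape[1] - 1),
    ]
    ax.imshow(mag.T, origin="lower", cmap="hot", vmax=spec.vmax,
              extent=extent, interpolation="nearest")
    if len(data):
        ax.quiver(data["pos_h_mm"], data["pos_v_mm"], data["u_h_mm"], data["u_v_mm"],
                  color="white", angles="xy", scale_units="xy", scale=0.5, width=0.004)
    ax.set_xlabel("mm")
    ax.set_ylabel("mm")
    ax.set_title(f"{spec.plane} slice {spec.index}: displacement (mm)")
    fig.savefig(os.fspath(out_path), dpi=120)
    plt.close(fig)
    if export_path is not None:
        data.to_csv(os.fspath(export_path), index=False)
    return data
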