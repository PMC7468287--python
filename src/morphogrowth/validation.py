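"""Registration validation by warped-segmentation overlap.

The multiclass Dice similarity coefficient scores, per label L,
``2 |A_L ∩ B_L| / (|A_L| + |B_L|)`` and averages over foreground labels
(macro averaging: each label counts equally regardless of size; a
voxel-weighted average is available as an option).  Background is
excluded — its overlap would inflate scores meaninglessly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence

import numpy as np
import pandas as pd

from .core import DisplacementField, GrowthSeries, LabelVolume, check_same_grid
from .errors import PipelineError
from .registration import warp_labels

__all__ = ["DiceReport", "multiclass_dice", "validate_registration"]


@dataclass
class DiceReport:
    """Per-label Dice plus the macro average over foreground labels
    present in either input."""

    per_label: Dict[str, float]
    macro: float
    weighted: float
    counts_a: Dict[str, int]
    counts_b: Dict[str, int]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"region": k, "dice": v,
             "voxels_a": self.counts_a.get(k, 0), "voxels_b": self.counts_b.get(k, 0)}
            for k, v in self.per_label.items()
        ]
        return pd.DataFrame(rows)


def multiclass_dice(a: LabelVolume, b: LabelVolume) -> DiceReport:
    """Multiclass Dice between two segmentations on the same grid.

    Labels absent from both inputs are excluded; a label present in only
    one input scores 0.  Exactly symmetric in its arguments.
    """
    check_same_grid(a, b, "label volumes")
    names = {**{v: k for k, v in b.label_dict.items()},
             **{v: k for k, v in a.label_dict.items()}}
    per_label, counts_a, counts_b = {}, {}, {}
    ids = sorted(set(np.unique(a.labels)) | set(np.unique(b.labels)) - {0})
    scores = []
    weights = []
    for lid in ids:
        if lid == 0:
            continue
        sel_a = a.labels == lid
        sel_b = b.labels == lid
        na, nb = int(sel_a.sum()), int(sel_b.sum())
        if na + nb == 0:
            continue
        dice = 2.0 * int((sel_a & sel_b).sum()) / (na + nb)
        name = names.get(lid, str(lid))
        per_label[name] = dice
        counts_a[name], counts_b[name] = na, nb
        scores.append(dice)
        weights.append(na + nb)
    if not scores:
        raise ValueError("no foreground labels present in either input")
    return DiceReport(
        per_label=per_label,
        macro=float(np.mean(scores)),
        weighted=float(np.average(scores, weights=weights)),
        counts_a=counts_a,
        counts_b=counts_b,
    )


def validate_registration(series: GrowthSeries,
                          fields: Sequence[DisplacementField]) -> pd.DataFrame:
    """Score every consecutive week pair of a series.

    Each field maps week ``k`` onto week ``k+1`` in the resampling sense,
    so warping the *later* segmentation through it propagates it back onto
    the earlier week's grid (the analog of warping the oldest-week
    segmentation to the desired week); the warped labels are scored
    against the week-``k`` segmentation.
    """
    if len(fields) != series.n_weeks - 1:
        raise PipelineError("validation", f"need {series.n_weeks - 1} fields, got {len(fields)}")
    rows = []
    for k, fld in enumerate(fields):
        warped = warp_labels(series.labels[k + 1], fld)
        report = multiclass_dice(warped, series.labels[k])
        row = {"pair": f"{k}->{k + 1}", "macro_dice": report.macro,
               "weighted_dice": report.weighted}
        row.update({f"dice_{name}": v for name, v in report.per_label.items()})
        rows.append(row)
    return pd.DataFrame(rows)
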