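"""Synthetic growing-brain phantoms and layered expression tables.

The imaging phantom is a minimal geometry that exhibits the morphology of
interest: an ellipsoidal "hemisphere" with a lateral wedge-shaped
indentation (the open fissure) separating a frontal/parietal lip above
from a temporal lip below, with the insula at the indentation floor.
Week-to-week change is an analytically defined stationary velocity field

* a global radial expansion term calibrated so one week multiplies the
  object volume by ``1 + global_growth_per_week``,
* an opercular convergence term that pushes the upper lip inferiorly and
  the lower lip superiorly toward the fissure plane, with magnitude
  decaying smoothly away from the fissure and into the interior,
* an optional excess-growth term concentrated in the opercular shells.

The weekly transformation is the exponential of this velocity field,
computed by scaling and squaring, so the ground truth is diffeomorphic by
construction and its Jacobian determinant is a valid oracle for every
downstream morphometry stage.  Week ``k`` images are produced by
evaluating the analytic week-0 scene at back-transported grid points
(``exp(-v)`` applied ``k`` times), so labels stay crisp at every week.

The expression generator emulates a two-specimen, four-layer regional
microarray: log-normal baseline intensities for ~35,000 genes with a
planted multiplicative fold increase for a chosen number of genes per
layer, applied in the target (opercular) regions only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Sequence, Tuple

import numpy as np
import pandas as pd

from .core import DisplacementField, GrowthSeries, LabelVolume, VolumeGrid
from .fieldops import exp_velocity, jacobian_det_array, sample_vectors
from .io import LAYERS, validate_expression

__all__ = [
    "PhantomSpec",
    "ExpressionSpec",
    "PHANTOM_LABELS",
    "OPERCULAR_LABELS",
    "generate_phantom",
    "generate_expression",
]

#: Label ids of the phantom segmentation (background = 0, implicit).
PHANTOM_LABELS: Dict[str, int] = {
    "interior": 1,
    "insula": 2,
    "frontal_operculum": 3,
    "parietal_operculum": 4,
    "temporal_operculum": 5,
}

OPERCULAR_LABELS = ("frontal_operculum", "parietal_operculum", "temporal_operculum")


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of the growing-phantom generator.

    ``global_growth_per_week`` is the fractional object-volume growth per
    week (0.06 = 6 %); ``opercular_excess_growth`` is the extra fractional
    growth planted in the opercular shells; ``convergence_amplitude_mm``
    is the peak closing speed of the opercular lips in mm per week.
    """

    grid_shape: Tuple[int, int, int] = (48, 48, 48)
    spacing_mm: Tuple[float, float, float] = (1.0, 1.0, 1.0)
    n_weeks: int = 3
    global_growth_per_week: float = 0.06
    opercular_excess_growth: float = 0.04
    convergence_amplitude_mm: float = 1.5
    noise_sd: float = 0.01
    seed: int = 0

    def validate(self) -> None:
        if any(s < 16 for s in self.grid_shape):
            raise ValueError(f"grid_shape must be >= 16 per axis, got {self.grid_shape}")
        if self.n_weeks < 2:
            raise ValueError(f"n_weeks must be >= 2, got {self.n_weeks}")
        if self.global_growth_per_week <= -1:
            raise ValueError("global_growth_per_week must exceed -1")
        if self.convergence_amplitude_mm < 0:
            raise ValueError("convergence_amplitude_mm must be >= 0")
        if self.opercular_excess_growth <= -1:
            raise ValueError("opercular_excess_growth must exceed -1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


class _Scene:
    """Analytic week-0 geometry plus the weekly velocity field.

    All geometric parameters are in mm and derived from the grid's
    physical extent so the phantom scales with resolution.
    """

    def __init__(self, spec: PhantomSpec):
        shape = np.asarray(spec.grid_shape, dtype=float)
        self.spacing = np.asarray(spec.spacing_mm, dtype=float)
        self.origin = np.zeros(3)
        extent = (shape - 1) * self.spacing
        self.center = self.origin + extent / 2.0
        half = extent / 2.0
        # Ellipsoid radii leave head-room for several weeks of growth.
        self.radii = np.array([0.68 * half[0], 0.76 * half[1], 0.62 * half[2]])
        self.x_in = 0.25 * self.radii[0]          # fissure depth (wedge apex)
        self.g0 = 0.22 * self.radii[2]            # wedge half-gap at the surface
        self.w_y = 0.55 * self.radii[1]           # anterior-posterior fissure extent
        self.spec = spec

    # -- geometry -----------------------------------------------------

    def _local(self, pts):
        rel = pts - self.center
        return rel[..., 0], rel[..., 1], rel[..., 2]

    def _half_gap(self, xp):
        return self.g0 * np.clip(xp - self.x_in, 0.0, None) / (self.radii[0] - self.x_in)

    def labels(self, pts: np.ndarray) -> np.ndarray:
        xp, dy, dz = self._local(pts)
        e = (xp / self.radii[0]) ** 2 + (dy / self.radii[1]) ** 2 + (dz / self.radii[2]) ** 2
        half_gap = self._half_gap(xp)
        in_wedge = (xp > self.x_in) & (np.abs(dz) < half_gap) & (np.abs(dy) < self.w_y)
        inside = (e < 1.0) & ~in_wedge
        near_fissure = np.abs(dy) < self.w_y

        insula = (
            inside
            & near_fissure
            & (xp > self.x_in - 3.0)
            & (xp <= self.x_in + 3.0)
            & (np.abs(dz) <= 3.5)
        )
        operc = (
            inside
            & near_fissure
            & (xp > self.x_in + 3.0)
            & (np.abs(dz) <= half_gap + 4.5)
            & ~insula
        )
        out = np.zeros(pts.shape[:-1], dtype=np.int32)
        out[inside] = PHANTOM_LABELS["interior"]
        out[insula] = PHANTOM_LABELS["insula"]
        out[operc & (dz > 0) & (dy <= 0)] = PHANTOM_LABELS["frontal_operculum"]
        out[operc & (dz > 0) & (dy > 0)] = PHANTOM_LABELS["parietal_operculum"]
        out[operc & (dz <= 0)] = PHANTOM_LABELS["temporal_operculum"]
        return out

    def intensity(self, pts: np.ndarray) -> np.ndarray:
        """Smooth label-correlated intensity: registration needs gradients,
        realism is not the goal."""
        xp, dy, dz = self._local(pts)
        e = (xp / self.radii[0]) ** 2 + (dy / self.radii[1]) ** 2 + (dz / self.radii[2]) ** 2
        body = np.sqrt(np.clip(1.0 - e, 0.0, None))
        band = np.exp(-((e - 0.80) ** 2) / (2 * 0.006))  # bright cortical ribbon
        half_gap = self._half_gap(xp)
        soft_wedge = (
            _sigmoid((half_gap - np.abs(dz)) / 0.8)
            * _sigmoid((xp - self.x_in) / 0.8)
            * _sigmoid((self.w_y - np.abs(dy)) / 1.5)
        )
        # Smooth parenchymal texture, advected with the anatomy; real tissue
        # contrast is what makes week-to-week correspondence observable away
        # from boundaries.
        texture = 1.0 + 0.45 * (
            np.sin(0.55 * xp + 1.0) * np.sin(0.48 * dy + 2.0)
            + np.sin(0.42 * dy) * np.sin(0.60 * dz + 1.5)
            + np.sin(0.52 * dz + 0.5) * np.sin(0.45 * xp)
        ) / 1.5
        return (0.4 * body + 0.8 * band) * texture * (1.0 - 0.95 * soft_wedge)

    # -- motion -------------------------------------------------------

    def velocity(self, pts: np.ndarray) -> np.ndarray:
        """Weekly velocity with the radial coefficient calibrated so the
        total object-volume growth per week equals ``global_growth_per_week``
        (the convergence/excess terms contribute volume too; the radial
        term absorbs the difference)."""
        spec = self.spec
        local = self._structured_velocity(pts)
        excess_growth = self._excess_volume_growth(pts, local)
        a = (np.log1p(spec.global_growth_per_week) - np.log1p(excess_growth)) / 3.0
        return a * (pts - self.center) + local

    def _excess_volume_growth(self, pts, local_velocity) -> float:
        """Fractional object-volume growth produced by the non-radial terms
        alone, measured as the mean Jacobian of their exponential over the
        week-0 object mask."""
        if not np.any(local_velocity):
            return 0.0
        u = exp_velocity(local_velocity, self.spacing, self.origin)
        j = jacobian_det_array(u, self.spacing)
        mask = self.labels(pts) > 0
        return float(j[mask].mean()) - 1.0

    def _structured_velocity(self, pts: np.ndarray) -> np.ndarray:
        """Convergence + opercular excess terms (no global expansion)."""
        spec = self.spec
        xp, dy, dz = self._local(pts)
        rel = pts - self.center
        v = np.zeros_like(rel)

        q = _sigmoid((xp - (self.x_in + 4.0)) / 1.5)
        r = np.exp(-(dy**2) / (2 * self.w_y**2))

        if spec.convergence_amplitude_mm > 0:
            # Odd closing profile about the fissure plane: the lips move
            # toward it and the compression is confined to the open gap,
            # decaying smoothly away from the plane.
            sig_t, sig_env = 1.5, 4.0
            profile = np.tanh(dz / sig_t) * np.exp(-(dz**2) / (2 * sig_env**2))
            dd = np.linspace(0, 4 * sig_env, 2001)
            peak = float(np.max(np.tanh(dd / sig_t) * np.exp(-(dd**2) / (2 * sig_env**2))))
            v[..., 2] = v[..., 2] - spec.convergence_amplitude_mm * q * r * profile / peak

        # Opercular-shell growth.  Closing is produced by differential
        # growth of the lips, not rigid motion, so the convergence
        # amplitude contributes shell growth too (2 %/week per mm/week of
        # closing speed) on top of the explicitly requested excess.
        eps_c = (np.log1p(spec.opercular_excess_growth) / 3.0
                 + 0.02 / 3.0 * spec.convergence_amplitude_mm)
        if eps_c != 0:
            shell = np.exp(-((np.abs(dz) - 5.0) ** 2) / (2 * 3.5**2))
            v += (eps_c * q * r * shell)[..., np.newaxis] * rel

        return v


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))


def generate_phantom(spec: PhantomSpec) -> GrowthSeries:
    """Generate the weekly phantom series with ground-truth pair fields.

    Returns a :class:`GrowthSeries` whose ``true_fields[k]`` is the
    displacement of the diffeomorphism mapping week ``k`` anatomy onto
    week ``k+1`` anatomy (Jacobian > 1 where tissue grows).  Raises
    ``ValueError`` if the requested convergence amplitude makes the
    analytic field fold (non-positive Jacobian): such a spec is
    non-physical.
    """
    spec.validate()
    scene = _Scene(spec)
    spacing, origin = scene.spacing, scene.origin

    axes = [origin[d] + spacing[d] * np.arange(spec.grid_shape[d]) for d in range(3)]
    grid_pts = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1)

    v = scene.velocity(grid_pts)
    u_fwd = exp_velocity(v, spacing, origin)
    min_j = float(jacobian_det_array(u_fwd, spacing).min())
    if min_j <= 0:
        raise ValueError(
            f"phantom spec folds: min Jacobian of the weekly transform is {min_j:.4f} <= 0; "
            "reduce convergence_amplitude_mm"
        )
    u_bwd = exp_velocity(-v, spacing, origin)

    rng = np.random.default_rng(spec.seed)
    volumes, labels = [], []
    pts = grid_pts
    for week in range(spec.n_weeks):
        if week > 0:
            # one more backward week: exp(-k v) applied incrementally
            pts = pts + sample_vectors(u_bwd, spacing, origin, pts)
        lab = scene.labels(pts)
        img = scene.intensity(pts)
        if spec.noise_sd > 0:
            img = img + rng.normal(0.0, spec.noise_sd, size=img.shape)
        volumes.append(VolumeGrid(img, spacing.copy(), origin.copy()))
        labels.append(LabelVolume(lab, dict(PHANTOM_LABELS), spacing.copy(), origin.copy()))

    true_fields = [
        DisplacementField(u_fwd.copy(), spacing.copy(), origin.copy())
        for _ in range(spec.n_weeks - 1)
    ]
    return GrowthSeries(volumes, labels, true_fields)


# ---------------------------------------------------------------------------
# Expression tables
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ExpressionSpec:
    """Parameters of the synthetic layered expression table.

    Defaults emulate a prenatal regional microarray: ~35,000 genes, two
    specimens, four transient cortical layers, opercular target regions
    contrasted against the insula, with `planted_gene_count` genes per
    layer overexpressed in the target regions by a fold drawn uniformly
    from ``planted_fold_range``.
    """

    n_genes: int = 35_000
    n_specimens: int = 2
    layers: Tuple[str, ...] = tuple(LAYERS)
    target_regions: Tuple[str, ...] = OPERCULAR_LABELS
    contrast_regions: Tuple[str, ...] = ("insula",)
    planted_gene_count: int = 40
    planted_fold_range: Tuple[float, float] = (15.0, 25.0)
    baseline_log_mean: float = 1.5
    baseline_log_sd: float = 1.0
    sample_log_sd: float = 0.4
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 1 or self.n_specimens < 1:
            raise ValueError("need at least one gene and one specimen")
        if self.planted_gene_count < 0:
            raise ValueError("planted_gene_count must be >= 0")
        if self.planted_gene_count * len(self.layers) > self.n_genes:
            raise ValueError("cannot plant more genes than exist across layers")
        if self.planted_fold_range[0] <= 1 or self.planted_fold_range[1] < self.planted_fold_range[0]:
            raise ValueError("planted folds must be > 1 and the range non-empty")
        if set(self.target_regions) & set(self.contrast_regions):
            raise ValueError("target and contrast regions must be disjoint")
        if not self.target_regions or not self.contrast_regions:
            raise ValueError("target and contrast region sets must be non-empty")


def generate_expression(spec: ExpressionSpec) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Generate the expression table and the planted truth.

    Returns ``(table, truth)``: the table has one row per
    (gene, specimen, region, layer) with strictly positive linear-scale
    values; the truth lists (gene_id, layer, planted_fold) for every
    planted gene, for recovery tests.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)

    regions = list(spec.target_regions) + list(spec.contrast_regions)
    G, S, R, L = spec.n_genes, spec.n_specimens, len(regions), len(spec.layers)
    width = max(5, len(str(G - 1)))
    gene_ids = np.array([f"G{i:0{width}d}" for i in range(G)])

    # Per-gene baseline (wide, between-gene) times per-sample variability
    # (narrow, between-region/specimen): the gene effect dominates, as in
    # real regional microarrays, so null fold changes stay near 1.
    baseline = rng.lognormal(mean=spec.baseline_log_mean, sigma=spec.baseline_log_sd,
                             size=(G, 1, 1, 1))
    values = baseline * rng.lognormal(mean=0.0, sigma=spec.sample_log_sd,
                                      size=(G, S, R, L))

    n_target = len(spec.target_regions)
    truth_rows = []
    if spec.planted_gene_count > 0:
        chosen = rng.choice(G, size=spec.planted_gene_count * L, replace=False)
        for li, layer in enumerate(spec.layers):
            genes = chosen[li * spec.planted_gene_count:(li + 1) * spec.planted_gene_count]
            folds = rng.uniform(*spec.planted_fold_range, size=genes.size)
            values[genes, :, :n_target, li] *= folds[:, np.newaxis, np.newaxis]
            for g, f in zip(genes, folds):
                truth_rows.append((gene_ids[g], layer, float(f)))

    table = pd.DataFrame(
        {
            "gene_id": np.repeat(gene_ids, S * R * L),
            "specimen_id": np.tile(np.repeat([f"specimen_{s+1}" for s in range(S)], R * L), G),
            "region": np.tile(np.repeat(regions, L), G * S),
            "layer": np.tile(list(spec.layers), G * S * R),
            "value": values.reshape(-1),
        }
    )
    truth = pd.DataFrame(truth_rows, columns=["gene_id", "layer", "planted_fold"])
    return validate_expression(table), truth
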