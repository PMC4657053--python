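"""Derivation of per-cell-type gene weight vectors from a lineage compendium.

A raw reference matrix (genes x arrays, log-scale intensities) is turned into
up- and down-regulated weight vectors in five steps:

1. median-normalize each gene across cell types (absolute -> relative);
2. z-transform each column; collapse replicate arrays of the same cell type
   by mean z-score, then z-transform again;
3. split each column into up (z > 0) and down (z < 0) subsets;
4. convert z-scores to -log10 one-sided normal tail probabilities and trim
   values above 10;
5. scale everything by the single global maximum so weights lie in [0, 1].
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .containers import (
    ChannelMode,
    ExpressionMatrix,
    LineageWeightSet,
    ReplicateMap,
    ValidationError,
)

#: transformed weights above this are trimmed (step 4); -log10 p = 10
#: corresponds to |z| of roughly 6.4
TRIM_THRESHOLD = 10.0


def median_normalize_across_celltypes(m: ExpressionMatrix) -> ExpressionMatrix:
    """Subtract each gene's across-column median, making values relative.

    Input values are log-scale intensities, so relative expression is a
    difference, not a ratio. Requires at least two columns; relative
    expression against a single column is undefined.
    """
    if m.n_columns < 2:
        raise ValidationError(
            "median normalization needs >= 2 columns; relative expression "
            "against a single column is undefined"
        )
    med = m.data.median(axis=1)
    return m.with_values(m.data.sub(med, axis=0))


def z_transform_columns(m: ExpressionMatrix) -> ExpressionMatrix:
    """Standardize each column to mean 0, sample sd 1 (ddof=1)."""
    sd = m.data.std(axis=0, ddof=1)
    dead = sd[~(sd > 0)]
    if len(dead):
        raise ValidationError(
            f"zero-variance column(s) cannot be z-transformed: {dead.index.tolist()[:5]}"
        )
    return m.with_values((m.data - m.data.mean(axis=0)) / sd)


def collapse_replicates(m: ExpressionMatrix, reps: ReplicateMap) -> ExpressionMatrix:
    """Average replicate columns per cell type, then re-z-transform.

    Input must already be z-transformed; the mean of replicate z-scores is
    taken per gene and each resulting cell-type column is renormalized so it
    again follows ~N(0, 1).
    """
    reps.validate_against(m)
    collapsed = pd.DataFrame(
        {ct: m.data[list(cols)].mean(axis=1) for ct, cols in reps.groups.items()},
        index=m.data.index,
    )
    return z_transform_columns(ExpressionMatrix(collapsed, m.channel_mode))


def split_up_down(z: ExpressionMatrix) -> tuple[ExpressionMatrix, ExpressionMatrix]:
    """Split z-scores into up (z clipped below at 0) and down (clipped above).

    ``up + down`` reconstructs ``z`` exactly; each entry is nonzero in at
    most one subset.
    """
    up = z.with_values(z.data.clip(lower=0.0))
    down = z.with_values(z.data.clip(upper=0.0))
    return up, down


def weights_from_z(
    up: ExpressionMatrix,
    down: ExpressionMatrix,
    trim: float = TRIM_THRESHOLD,
    scale: str = "global",
) -> LineageWeightSet:
    """Convert split z-scores to trimmed, scaled -log10 p-value weights.

    Up-subset entries use the upper-tail standard-normal probability of z,
    down-subset entries the lower tail (stored as a positive magnitude).
    Entries zeroed by the split stay at weight 0 — non-regulated genes carry
    no weight. Values above ``trim`` are clamped, then both subsets are
    divided by one maximum: the global maximum over the whole weight set by
    default (``scale="global"``), or each cell type's own maximum
    (``scale="per_celltype"``).
    """
    if scale not in ("global", "per_celltype"):
        raise ValidationError(f"unknown scale mode {scale!r}")
    zu = up.data.to_numpy()
    zd = down.data.to_numpy()
    if not (zu > 0).any() and not (zd < 0).any():
        raise ValidationError("no differential genes anywhere: all z-scores are zero")

    wu = np.zeros_like(zu)
    mask = zu > 0
    # norm.sf(z) == norm.cdf(-z); -log10 via logsf for numerical range
    wu[mask] = -stats.norm.logsf(zu[mask]) / np.log(10)
    wd = np.zeros_like(zd)
    mask = zd < 0
    wd[mask] = -stats.norm.logcdf(zd[mask]) / np.log(10)

    np.clip(wu, None, trim, out=wu)
    np.clip(wd, None, trim, out=wd)

    if scale == "global":
        scale_max = float(max(wu.max(), wd.max()))
        wu /= scale_max
        wd /= scale_max
    else:
        per_ct = np.maximum(wu.max(axis=0), wd.max(axis=0))
        if (per_ct <= 0).any():
            bad = up.column_ids[int(np.argmin(per_ct))]
            raise ValidationError(f"cell type {bad!r} has no differential genes")
        wu /= per_ct
        wd /= per_ct
        scale_max = float(per_ct.max())

    return LineageWeightSet(
        pd.DataFrame(wu, index=up.data.index, columns=up.data.columns),
        pd.DataFrame(wd, index=down.data.index, columns=down.data.columns),
        scale_max=scale_max,
    )


def build_weights(
    raw: ExpressionMatrix,
    reps: ReplicateMap | None = None,
    trim: float = TRIM_THRESHOLD,
    scale: str = "global",
) -> LineageWeightSet:
    """Run the full five-step preparation on a raw reference matrix.

    When ``reps`` is None each column is treated as its own cell type
    (replicate collapsing still re-z-transforms, which is then a no-op up to
    numerical precision).
    """
    if raw.channel_mode is not ChannelMode.REFERENCE:
        raise ValidationError(
            f"reference preparation expects channel_mode 'reference', got "
            f"{raw.channel_mode.value!r}"
        )
    if reps is None:
        reps = ReplicateMap({c: [c] for c in raw.column_ids})
    rel = median_normalize_across_celltypes(raw)
    z = z_transform_columns(rel)
    z = collapse_replicates(z, reps)
    up, down = split_up_down(z)
    return weights_from_z(up, down, trim=trim, scale=scale)
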