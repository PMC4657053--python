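"""Patient expression preparation: probeset collapse, channel handling,
gene-namespace harmonization and per-patient ranking."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import (
    ChannelMode,
    ExpressionMatrix,
    LineageWeightSet,
    PatientRanking,
    ProbesetMatrix,
    ValidationError,
)


def collapse_probesets(pm: ProbesetMatrix) -> ExpressionMatrix:
    """Represent each gene by its probeset with the highest mean intensity.

    The mean is taken across all sample columns; ties keep the probeset that
    appears first in input order. Probesets without a gene mapping are
    dropped.
    """
    if not pm.probeset_to_gene:
        raise ValidationError("empty probeset-to-gene mapping")
    mapped = [ps for ps in pm.data.index if ps in pm.probeset_to_gene]
    if not mapped:
        raise ValidationError("no probeset in the matrix has a gene mapping")
    sub = pm.data.loc[mapped]
    genes = pd.Series([pm.probeset_to_gene[ps] for ps in mapped], index=sub.index)
    means = sub.mean(axis=1)
    keep: dict[str, str] = {}
    best: dict[str, float] = {}
    for ps in sub.index:  # input order; strict > keeps the first on ties
        g = genes[ps]
        if g not in keep or means[ps] > best[g]:
            keep[g] = ps
            best[g] = means[ps]
    out = sub.loc[list(keep.values())]
    out.index = list(keep.keys())
    return ExpressionMatrix(out, pm.channel_mode)


def prepare_one_channel(m: ExpressionMatrix) -> ExpressionMatrix:
    """log2(x + 1) then per-gene median-centering across samples.

    Absolute intensities become relative expression between patients; output
    row medians are 0.
    """
    if m.channel_mode is not ChannelMode.ONE_CHANNEL:
        raise ValidationError(
            f"expected one_channel data, got {m.channel_mode.value!r}"
        )
    if (m.values < 0).any():
        bad = m.data.index[(m.values < 0).any(axis=1)][:5].tolist()
        raise ValidationError(f"negative intensities in one-channel rows {bad}")
    logged = np.log2(m.data + 1.0)
    centered = logged.sub(logged.median(axis=1), axis=0)
    return ExpressionMatrix(centered, ChannelMode.ONE_CHANNEL)


def prepare_two_channel(m: ExpressionMatrix) -> ExpressionMatrix:
    """Two-channel log-ratios are already relative: identity pass-through."""
    if m.channel_mode is not ChannelMode.TWO_CHANNEL:
        raise ValidationError(
            f"expected two_channel data, got {m.channel_mode.value!r}"
        )
    return m


def prepare_patients(m: ExpressionMatrix) -> ExpressionMatrix:
    """Dispatch to the channel-appropriate preparation."""
    if m.channel_mode is ChannelMode.ONE_CHANNEL:
        return prepare_one_channel(m)
    if m.channel_mode is ChannelMode.TWO_CHANNEL:
        return prepare_two_channel(m)
    raise ValidationError("patient matrices must be one_channel or two_channel")


def harmonize_genes(
    ref: LineageWeightSet, pat: ExpressionMatrix
) -> tuple[LineageWeightSet, ExpressionMatrix]:
    """Restrict both inputs to their shared genes, matched case-insensitively.

    Murine symbols (Title-case) match human symbols (UPPER-case) by simple
    case folding; no homology expansion. Output gene order follows the
    reference, and is identical in both returned objects.
    """
    ref_upper = {g.upper(): g for g in ref.gene_ids}
    pat_upper = {g.upper(): g for g in pat.gene_ids}
    shared = [u for u in (g.upper() for g in ref.gene_ids) if u in pat_upper]
    if not shared:
        top_ref = ref.gene_ids[:5]
        top_pat = pat.gene_ids[:5]
        raise ValidationError(
            "no shared gene symbols between reference and patient data; "
            f"reference starts {top_ref}, patients start {top_pat}"
        )
    ref_out = ref.subset([ref_upper[u] for u in shared])
    pat_out = ExpressionMatrix(
        pat.data.loc[[pat_upper[u] for u in shared]], pat.channel_mode
    )
    return ref_out, pat_out


def rank_patient(pat: ExpressionMatrix, patient_id: str) -> PatientRanking:
    """Sort one patient's genes by decreasing expression.

    Ties keep input gene order (stable sort). Genes with a missing value for
    this patient are dropped from this patient's ranking only.
    """
    if patient_id not in pat.data.columns:
        raise ValidationError(f"unknown patient id {patient_id!r}")
    col = pat.data[patient_id]
    col = col[np.isfinite(col.to_numpy())]
    order = np.argsort(-col.to_numpy(), kind="stable")
    return PatientRanking(
        genes=[col.index[i] for i in order],
        values=col.to_numpy()[order],
        patient_id=patient_id,
    )
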