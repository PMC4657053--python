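"""Lineage similarity scoring.

A patient's genes are ranked by decreasing expression; against a cell type's
weight vector w in [0, 1]^n the foreground and background running sums

    f(i) = sum_{j<=i} |g_j| w_j / sum_j |g_j| w_j
    b(i) = sum_{j<=i} |g_j| (1 - w_j) / sum_j |g_j| (1 - w_j)

are compared through d(i) = f(i) - b(i). The signed maximum deviation
(pre-LSS) is positive when highly expressed patient genes carry high
weights, i.e. when the patient profile is concordant with the cell type's
regulated genes. Each pre-LSS is normalized by the mean |pre-LSS| under
permutation of the gene labels in the ranked list, giving LSS_up and
LSS_dn; two-channel data combine them as LSS = LSS_up - LSS_dn, one-channel
data use LSS_up alone (the down subset is dominated by cross-hybridization
noise on absolute-intensity platforms).

Expression magnitudes enter as |g_j|: for two-channel log-ratios the sign
already determines rank position, and magnitude weighting keeps f and b
monotone in [0, 1].
"""

from __future__ import annotations

import hashlib
import logging

import numpy as np
import pandas as pd

from .containers import (
    ChannelMode,
    ExpressionMatrix,
    LineageWeightSet,
    LSSResult,
    PatientRanking,
    RunningSums,
    ValidationError,
    _coerce_mode,
)

logger = logging.getLogger(__name__)

try:  # fused permutation-null kernel; numpy chunked path is the fallback
    import numba

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

DEFAULT_N_PERM = 1000

#: deviations smaller than this in magnitude are numerical noise (e.g. the
#: exact cancellation f == b under a constant weight vector) and snap to 0
DEVIATION_EPS = 1e-12


def _signed_max_deviation(a: np.ndarray, w: np.ndarray, strict: bool = True) -> np.ndarray:
    """Pre-LSS for stacked weight vectors.

    Parameters
    ----------
    a : (n,) magnitudes of the ranked expression values (non-negative).
    w : (..., n) weight vectors along the last (gene) axis, aligned to the
        ranking; leading axes stack cell types and/or permutations.
    strict : if True, a zero foreground or background denominator raises;
        if False (permutation evaluation) the affected entry scores 0.

    Returns
    -------
    (...) signed maximum deviations; ties |max d| == |min d| return the
    positive branch.
    """
    # background terms |g|(1-w) = |g| - |g|w, so the background cumsum is the
    # (weight-free) magnitude cumsum minus the foreground cumsum
    cf = np.cumsum(a * w, axis=-1)
    cum_a = np.cumsum(a)
    tot_f = cf[..., -1]
    tot_b = cum_a[-1] - tot_f
    bad = (tot_f <= 0) | (tot_b <= 0)
    if bad.any():
        if strict:
            raise ValidationError(
                "degenerate weight vector: foreground or background running "
                "sum has zero total weight"
            )
        tot_f = np.where(tot_f <= 0, 1.0, tot_f)
        tot_b = np.where(tot_b <= 0, 1.0, tot_b)
    cb = cum_a - cf
    cb /= tot_b[..., None]
    cf /= tot_f[..., None]
    cf -= cb
    d = cf
    d_plus = np.maximum(d.max(axis=-1), 0.0)
    d_minus = np.minimum(d.min(axis=-1), 0.0)
    d_plus = np.where(d_plus < DEVIATION_EPS, 0.0, d_plus)
    d_minus = np.where(d_minus > -DEVIATION_EPS, 0.0, d_minus)
    out = np.where(np.abs(d_plus) >= np.abs(d_minus), d_plus, d_minus)
    if bad.any():
        out = np.where(bad, 0.0, out)
    return out


def _null_abs_sums_loop(
    a: np.ndarray,
    cum_a: np.ndarray,
    w_genes_first: np.ndarray,
    perms: np.ndarray,
    eps: float,
) -> np.ndarray:
    """Sum of |pre-LSS| over permutations for K stacked weight vectors.

    ``w_genes_first`` is (n, K); each permutation realigns weights to the
    fixed sorted magnitudes ``a``. Uses the identity
    d(i) = cf(i) * (1/tot_f + 1/tot_b) - cum_a(i) / tot_b and the fact that
    |pre-LSS| = max_i |d(i)|, so everything happens in one fused pass with
    no large temporaries. Degenerate (zero-total) vectors contribute 0.
    """
    n_perm, n = perms.shape
    k_vec = w_genes_first.shape[1]
    acc = np.zeros(k_vec)
    tot = np.zeros(k_vec)
    s1 = np.zeros(k_vec)
    s2 = np.zeros(k_vec)
    cf = np.zeros(k_vec)
    best = np.zeros(k_vec)
    tot_a = cum_a[n - 1]
    for p in range(n_perm):
        for k in range(k_vec):
            tot[k] = 0.0
        for i in range(n):
            ai = a[i]
            row = perms[p, i]
            for k in range(k_vec):
                tot[k] += ai * w_genes_first[row, k]
        for k in range(k_vec):
            tf = tot[k]
            tb = tot_a - tf
            if tf <= 0.0 or tb <= 0.0:
                s1[k] = 0.0
                s2[k] = 0.0
            else:
                s1[k] = 1.0 / tf + 1.0 / tb
                s2[k] = 1.0 / tb
            cf[k] = 0.0
            best[k] = 0.0
        for i in range(n):
            ai = a[i]
            row = perms[p, i]
            ca = cum_a[i]
            for k in range(k_vec):
                cf[k] += ai * w_genes_first[row, k]
                d = cf[k] * s1[k] - ca * s2[k]
                if d < 0.0:
                    d = -d
                if d > best[k]:
                    best[k] = d
        for k in range(k_vec):
            if best[k] > eps:
                acc[k] += best[k]
    return acc


if _HAVE_NUMBA:
    _null_abs_sums = numba.njit(cache=True, nogil=True)(_null_abs_sums_loop)
else:  # pragma: no cover

    def _null_abs_sums(a, cum_a, w_genes_first, perms, eps):
        out = np.zeros(w_genes_first.shape[1])
        for start in range(0, perms.shape[0], 64):
            block = perms[start : start + 64]
            out += np.abs(
                _signed_max_deviation(
                    a, np.ascontiguousarray(w_genes_first.T)[:, block], strict=False
                )
            ).sum(axis=1)
        return out


def running_sums(r: PatientRanking, w: np.ndarray) -> RunningSums:
    """Foreground/background weighted cumulative distributions.

    ``w`` must be aligned to ``r``'s gene order and lie in [0, 1].
    """
    w = np.asarray(w, dtype=float)
    if w.shape != (len(r),):
        raise ValidationError(
            f"weight vector length {w.shape} does not match ranking length {len(r)}"
        )
    if w.min() < 0 or w.max() > 1:
        raise ValidationError("weights must lie in [0, 1]")
    a = np.abs(r.values)
    cf = np.cumsum(a * w)
    cb = np.cumsum(a * (1.0 - w))
    if cf[-1] <= 0:
        raise ValidationError("all foreground terms |g_j|*w_j are zero")
    if cb[-1] <= 0:
        raise ValidationError("all background terms |g_j|*(1-w_j) are zero")
    return RunningSums(f=cf / cf[-1], b=cb / cb[-1])


def pre_lss(rs: RunningSums) -> float:
    """Signed maximum deviation between foreground and background.

    With d(i) = f(i) - b(i): returns max(0, max d) if its magnitude is at
    least that of min(0, min d), else the latter. Positive values mean
    concordance with the weight vector's regulated direction.
    """
    d = rs.f - rs.b
    d_plus = max(d.max(), 0.0)
    d_minus = min(d.min(), 0.0)
    if d_plus < DEVIATION_EPS:
        d_plus = 0.0
    if d_minus > -DEVIATION_EPS:
        d_minus = 0.0
    return float(d_plus if abs(d_plus) >= abs(d_minus) else d_minus)


def permutation_null(
    r: PatientRanking, w: np.ndarray, n_perm: int, seed: int
) -> float:
    """Mean |pre-LSS| when gene labels of the ranked list are permuted.

    Each permutation shuffles the alignment between the weight vector and
    the fixed, sorted expression magnitudes. Deterministic under ``seed``.
    """
    if n_perm < 1:
        raise ValidationError("n_perm must be >= 1")
    w = np.asarray(w, dtype=float)
    if w.shape != (len(r),):
        raise ValidationError("weight vector length does not match ranking")
    a = np.abs(r.values)
    rng = np.random.default_rng(seed)
    n = len(r)
    total = 0.0
    chunk = max(1, min(n_perm, int(2_000_000 / max(n, 1))))
    done = 0
    while done < n_perm:
        b = min(chunk, n_perm - done)
        perms = np.argsort(rng.random((b, n)), axis=1)
        total += np.abs(_signed_max_deviation(a, w[perms], strict=False)).sum()
        done += b
    return total / n_perm


def _combine(
    lss_up: float, lss_dn: float, channel_mode: ChannelMode
) -> float:
    if channel_mode is ChannelMode.TWO_CHANNEL:
        return lss_up - lss_dn
    return lss_up


def _safe_ratio(p: float, null_mean: float, label: str) -> float:
    """pLSS / null-mean with the degenerate 0/0 case defined as 0."""
    if null_mean > 0:
        return p / null_mean
    if p == 0.0 and null_mean == 0.0:
        return 0.0
    raise ValidationError(
        f"non-positive permutation null mean ({null_mean}) for {label} with "
        f"nonzero pre-LSS {p}"
    )


def normalize_and_combine(
    plss_up: float,
    plss_dn: float,
    null_up: float,
    null_dn: float,
    channel_mode: ChannelMode | str,
    patient_id: str = "",
    cell_type: str = "",
    n_permutations: int = DEFAULT_N_PERM,
    seed: int = 0,
) -> LSSResult:
    """Divide pre-LSS values by their permutation-null means and combine.

    Two-channel: LSS = LSS_up - LSS_dn. One-channel: LSS = LSS_up.
    """
    channel_mode = _coerce_mode(channel_mode)
    lss_up = _safe_ratio(plss_up, null_up, "up subset")
    lss_dn = _safe_ratio(plss_dn, null_dn, "down subset")
    return LSSResult(
        patient_id=patient_id,
        cell_type=cell_type,
        plss_up=plss_up,
        plss_dn=plss_dn,
        null_mean_abs_up=null_up,
        null_mean_abs_dn=null_dn,
        lss_up=lss_up,
        lss_dn=lss_dn,
        lss=_combine(lss_up, lss_dn, channel_mode),
        n_permutations=n_permutations,
        seed=seed,
    )


LONG_COLUMNS = [
    "patient_id",
    "cell_type",
    "pLSS_up",
    "pLSS_dn",
    "null_mean_abs_up",
    "null_mean_abs_dn",
    "LSS_up",
    "LSS_dn",
    "LSS",
    "n_perm",
    "seed",
]


def score_all(
    weights: LineageWeightSet,
    patients: ExpressionMatrix,
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 17,
    progress: bool = False,
) -> pd.DataFrame:
    """Score every (patient, cell type) pair; returns a long-format frame.

    Inputs must be gene-harmonized: identical gene order up to case. Each
    patient gets an independent RNG stream spawned from ``seed`` by patient
    index, so results do not depend on evaluation order and the same
    permutations serve all cell types of that patient (one permutation of
    the ranked gene list scrambles every weight column identically).
    """
    if n_perm < 1:
        raise ValidationError("n_perm must be >= 1")
    wg = [g.upper() for g in weights.gene_ids]
    pg = [g.upper() for g in patients.gene_ids]
    if wg != pg:
        raise ValidationError(
            "weights and patients are not gene-harmonized (order-identical "
            "symbols required); run harmonize_genes first"
        )
    if patients.channel_mode is ChannelMode.REFERENCE:
        raise ValidationError("patient matrix cannot have channel_mode 'reference'")

    wu = weights.up.to_numpy()
    wd = weights.down.to_numpy()
    n_ct = wu.shape[1]
    cell_types = weights.cell_types
    vals_all = patients.data.to_numpy()

    rows: list[list] = []
    for k, pid in enumerate(patients.column_ids):
        vals = vals_all[:, k]
        finite = np.flatnonzero(np.isfinite(vals))
        if finite.size == 0:
            raise ValidationError(f"patient {pid!r}: no finite expression values")
        order = finite[np.argsort(-vals[finite], kind="stable")]
        a = np.abs(vals[order])
        # up and down subsets stack so one pass serves both cell-type blocks
        w_both = np.concatenate([wu[order], wd[order]], axis=1)  # (n, 2C)
        try:
            p_both = _signed_max_deviation(
                a, np.ascontiguousarray(w_both.T), strict=True
            )
        except ValidationError as exc:
            raise ValidationError(f"patient {pid!r}: {exc}") from exc
        p_up, p_dn = p_both[:n_ct], p_both[n_ct:]

        # RNG stream keyed to the patient's identity, not its column
        # position: permuting input columns only permutes output rows
        pid_key = int.from_bytes(
            hashlib.sha256(str(pid).encode()).digest()[:4], "little"
        )
        rng = np.random.default_rng(np.random.SeedSequence([seed, pid_key]))
        n = order.size
        cum_a = np.cumsum(a)
        null_both = np.zeros(2 * n_ct)
        chunk = max(1, min(n_perm, int(2_000_000 / max(n, 1))))
        done = 0
        while done < n_perm:
            b = min(chunk, n_perm - done)
            perms = np.argsort(rng.random((b, n)), axis=1)
            null_both += _null_abs_sums(a, cum_a, w_both, perms, DEVIATION_EPS)
            done += b
        null_both /= n_perm
        null_up, null_dn = null_both[:n_ct], null_both[n_ct:]

        for c in range(n_ct):
            try:
                lss_up = _safe_ratio(float(p_up[c]), float(null_up[c]), "up subset")
                lss_dn = _safe_ratio(float(p_dn[c]), float(null_dn[c]), "down subset")
            except ValidationError as exc:
                raise ValidationError(
                    f"patient {pid!r}, cell type {cell_types[c]!r}: {exc}"
                ) from exc
            rows.append(
                [
                    pid,
                    cell_types[c],
                    float(p_up[c]),
                    float(p_dn[c]),
                    float(null_up[c]),
                    float(null_dn[c]),
                    lss_up,
                    lss_dn,
                    _combine(lss_up, lss_dn, patients.channel_mode),
                    n_perm,
                    seed,
                ]
            )
        if progress and (k + 1) % 25 == 0:
            logger.info("scored %d/%d patients", k + 1, len(patients.column_ids))

    return pd.DataFrame(rows, columns=LONG_COLUMNS)


def scores_wide(long: pd.DataFrame) -> pd.DataFrame:
    """Pivot a long-format score frame to patients x cell types."""
    wide = long.pivot(index="patient_id", columns="cell_type", values="LSS")
    # preserve first-appearance order on both axes
    wide = wide.loc[
        pd.unique(long["patient_id"]), pd.unique(long["cell_type"])
    ]
    wide.index.name = "patient_id"
    wide.columns.name = None
    return wide
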