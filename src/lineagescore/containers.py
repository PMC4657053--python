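"""Core data containers shared across the pipeline.

Expression data is carried as a pandas DataFrame (genes as rows, samples or
cell types as columns) wrapped with channel-mode metadata, because every
downstream operation — normalization, replicate collapsing, ranking — is a
row- or column-wise DataFrame transform.
"""

from __future__ import annotations

import enum
import json
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd


class ValidationError(ValueError):
    """Raised when user-supplied input violates a documented contract."""


class ChannelMode(str, enum.Enum):
    """Array platform semantics of an expression matrix.

    ``one_channel``: absolute intensities (log-transform + median-centering
    required before scoring; only the up-subset score is interpretable).
    ``two_channel``: log-ratios, already relative between samples.
    ``reference``: a cell-lineage compendium destined for weight derivation.
    """

    ONE_CHANNEL = "one_channel"
    TWO_CHANNEL = "two_channel"
    REFERENCE = "reference"


def _coerce_mode(mode: "ChannelMode | str") -> ChannelMode:
    if isinstance(mode, ChannelMode):
        return mode
    try:
        return ChannelMode(str(mode))
    except ValueError:
        raise ValidationError(
            f"unknown channel mode {mode!r}; expected one of "
            f"{[m.value for m in ChannelMode]}"
        ) from None


@dataclass
class ExpressionMatrix:
    """Genes x columns real-valued expression matrix.

    Parameters
    ----------
    data : pandas.DataFrame
        Rows indexed by unique gene symbols, columns by sample / cell-type
        labels, float-valued and finite.
    channel_mode : ChannelMode or str
        Platform semantics (see :class:`ChannelMode`).
    """

    data: pd.DataFrame
    channel_mode: ChannelMode = ChannelMode.TWO_CHANNEL

    def __post_init__(self) -> None:
        self.channel_mode = _coerce_mode(self.channel_mode)
        if not isinstance(self.data, pd.DataFrame):
            raise ValidationError("ExpressionMatrix.data must be a DataFrame")
        if self.data.shape[0] == 0 or self.data.shape[1] == 0:
            raise ValidationError("expression matrix is empty")
        idx = self.data.index.astype(str)
        if idx.duplicated().any():
            dups = sorted(idx[idx.duplicated()].unique()[:5])
            raise ValidationError(f"duplicate gene identifiers: {dups}")
        if (idx == "").any():
            raise ValidationError("empty gene identifier in matrix index")
        values = self.data.to_numpy(dtype=float, copy=False)
        if np.isinf(values).any():
            bad = self.data.index[np.isinf(values).any(axis=1)][:5].tolist()
            raise ValidationError(f"infinite expression values in rows {bad}")
        # Reference compendia must be complete; patient matrices may carry
        # missing cells, which are dropped per-patient at ranking time.
        if self.channel_mode is ChannelMode.REFERENCE and np.isnan(values).any():
            bad = self.data.index[np.isnan(values).any(axis=1)][:5].tolist()
            raise ValidationError(f"missing values in reference rows {bad}")
        self.data = self.data.astype(float)
        self.data.index = idx

    @property
    def gene_ids(self) -> list[str]:
        return self.data.index.tolist()

    @property
    def column_ids(self) -> list[str]:
        return [str(c) for c in self.data.columns]

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_columns(self) -> int:
        return self.data.shape[1]

    def with_values(self, values: np.ndarray | pd.DataFrame) -> "ExpressionMatrix":
        """Return a copy carrying new values with the same labels and mode."""
        if isinstance(values, pd.DataFrame):
            df = values
        else:
            df = pd.DataFrame(values, index=self.data.index, columns=self.data.columns)
        return ExpressionMatrix(df, self.channel_mode)


@dataclass
class ReplicateMap:
    """Partition of matrix columns into cell-type replicate groups."""

    groups: Mapping[str, Sequence[str]]

    def __post_init__(self) -> None:
        seen: dict[str, str] = {}
        for ct, cols in self.groups.items():
            if len(cols) == 0:
                raise ValidationError(f"replicate group {ct!r} is empty")
            for c in cols:
                if c in seen:
                    raise ValidationError(
                        f"column {c!r} assigned to both {seen[c]!r} and {ct!r}"
                    )
                seen[c] = ct
        self.groups = {ct: list(cols) for ct, cols in self.groups.items()}

    @property
    def cell_types(self) -> list[str]:
        return list(self.groups)

    def validate_against(self, m: ExpressionMatrix) -> None:
        cols = set(m.column_ids)
        mapped = {c for cs in self.groups.values() for c in cs}
        missing = sorted(mapped - cols)
        if missing:
            raise ValidationError(f"replicate map references absent columns: {missing[:5]}")
        unmapped = sorted(cols - mapped)
        if unmapped:
            raise ValidationError(f"columns not covered by replicate map: {unmapped[:5]}")

    @classmethod
    def infer(cls, column_ids: Sequence[str], suffix_regex: str = r"#\d+$") -> "ReplicateMap":
        """Group columns by stripping a trailing replicate suffix (default ``#<n>``)."""
        pat = re.compile(suffix_regex)
        groups: dict[str, list[str]] = {}
        for c in column_ids:
            groups.setdefault(pat.sub("", c), []).append(c)
        return cls(groups)


@dataclass
class LineageWeightSet:
    """Per-cell-type up/down gene weight vectors on a common [0, 1] scale.

    ``up`` and ``down`` are genes x cell-types DataFrames; a weight is
    -log10 of a one-sided normal tail probability of the collapsed z-score,
    trimmed at 10 and divided by one global maximum, so that strongly
    differential genes carry weight near 1 and non-regulated genes carry 0.
    Down-subset weights are stored as positive magnitudes; direction lives in
    the subset label.
    """

    up: pd.DataFrame
    down: pd.DataFrame
    scale_max: float | None = None

    def __post_init__(self) -> None:
        if not self.up.index.equals(self.down.index) or not self.up.columns.equals(
            self.down.columns
        ):
            raise ValidationError("up/down weight matrices must share labels")
        for name, df in (("up", self.up), ("down", self.down)):
            v = df.to_numpy(dtype=float)
            if not np.isfinite(v).all():
                raise ValidationError(f"non-finite {name} weights")
            if v.min() < 0 or v.max() > 1 + 1e-12:
                raise ValidationError(f"{name} weights outside [0, 1]")

    @property
    def gene_ids(self) -> list[str]:
        return self.up.index.tolist()

    @property
    def cell_types(self) -> list[str]:
        return [str(c) for c in self.up.columns]

    def validate_complementarity(self) -> None:
        """Check that no gene is both up- and down-weighted for a cell type."""
        overlap = (self.up.to_numpy() > 0) & (self.down.to_numpy() > 0)
        if overlap.any():
            gi, ci = np.argwhere(overlap)[0]
            raise ValidationError(
                f"gene {self.up.index[gi]!r} carries both up and down weight "
                f"for cell type {self.up.columns[ci]!r}"
            )

    def subset(self, genes: Sequence[str]) -> "LineageWeightSet":
        return LineageWeightSet(self.up.loc[genes], self.down.loc[genes], self.scale_max)

    def to_dir(self, path: str | Path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        self.up.to_csv(path / "weights_up.tsv", sep="\t", index_label="gene")
        self.down.to_csv(path / "weights_down.tsv", sep="\t", index_label="gene")
        meta = {"scale_max": self.scale_max, "n_genes": len(self.up), "n_celltypes": self.up.shape[1]}
        (path / "weights_meta.json").write_text(json.dumps(meta, indent=2) + "\n")

    @classmethod
    def from_dir(cls, path: str | Path) -> "LineageWeightSet":
        path = Path(path)
        up = pd.read_csv(path / "weights_up.tsv", sep="\t", index_col="gene")
        down = pd.read_csv(path / "weights_down.tsv", sep="\t", index_col="gene")
        meta_path = path / "weights_meta.json"
        scale_max = None
        if meta_path.exists():
            scale_max = json.loads(meta_path.read_text()).get("scale_max")
        return cls(up, down, scale_max)


@dataclass
class ProbesetMatrix:
    """Probeset-level expression with a (possibly many-to-one) gene mapping."""

    data: pd.DataFrame
    probeset_to_gene: Mapping[str, str]
    channel_mode: ChannelMode = ChannelMode.ONE_CHANNEL

    def __post_init__(self) -> None:
        self.channel_mode = _coerce_mode(self.channel_mode)
        if self.data.index.duplicated().any():
            raise ValidationError("duplicate probeset identifiers")
        for ps, g in self.probeset_to_gene.items():
            if not g:
                raise ValidationError(f"probeset {ps!r} maps to an empty symbol")


@dataclass
class PatientRanking:
    """One patient's genes ordered by decreasing expression."""

    genes: list[str]
    values: np.ndarray
    patient_id: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.genes) != len(self.values):
            raise ValidationError("ranking genes/values length mismatch")
        if np.any(np.diff(self.values) > 1e-12):
            raise ValidationError("ranking values must be non-increasing")

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class RunningSums:
    """Foreground/background weighted cumulative distributions over a ranking."""

    f: np.ndarray
    b: np.ndarray

    def __post_init__(self) -> None:
        self.f = np.asarray(self.f, dtype=float)
        self.b = np.asarray(self.b, dtype=float)
        if self.f.shape != self.b.shape:
            raise ValidationError("foreground/background length mismatch")


@dataclass
class LSSResult:
    """Scores for one (patient, cell type) pair."""

    patient_id: str
    cell_type: str
    plss_up: float
    plss_dn: float
    null_mean_abs_up: float
    null_mean_abs_dn: float
    lss_up: float
    lss_dn: float
    lss: float
    n_permutations: int
    seed: int


@dataclass
class AssocResult:
    """Cox proportional-hazards association of one cell type's score."""

    cell_type: str
    coef: float
    hr: float
    ci_low: float
    ci_high: float
    wald_p: float
    adj_p: float = float("nan")
    n: int = 0
    n_events: int = 0
    converged: bool = True


REQUIRED_CLINICAL_COLUMNS = ("sample_id", "time", "event")


@dataclass
class ClinicalTable:
    """Survival outcomes plus optional covariates, indexed by sample id.

    ``time`` is in whatever unit the source table uses (recorded in
    ``time_unit``); ``event`` is 1 for an observed death, 0 for censoring.
    Any further columns are carried as candidate covariates.
    """

    data: pd.DataFrame
    time_unit: str = "unspecified"

    def __post_init__(self) -> None:
        df = self.data
        for col in ("time", "event"):
            if col not in df.columns:
                raise ValidationError(f"clinical table missing required column {col!r}")
        if df.index.duplicated().any():
            dups = df.index[df.index.duplicated()][:5].tolist()
            raise ValidationError(f"duplicate sample ids: {dups}")
        times = df["time"].to_numpy(dtype=float)
        bad = np.flatnonzero(~(np.isfinite(times) & (times > 0)))
        if bad.size:
            raise ValidationError(
                f"non-positive or missing survival time at row {bad[0] + 1} "
                f"(sample {df.index[bad[0]]!r})"
            )
        events = df["event"].to_numpy(dtype=float)
        bad = np.flatnonzero(~np.isin(events, (0.0, 1.0)))
        if bad.size:
            raise ValidationError(
                f"event indicator must be 0 or 1; offending row {bad[0] + 1} "
                f"(sample {df.index[bad[0]]!r}, value {df['event'].iloc[bad[0]]!r})"
            )
        df = df.copy()
        df["time"] = times
        df["event"] = events.astype(int)
        df.index = df.index.astype(str)
        self.data = df

    @property
    def sample_ids(self) -> list[str]:
        return self.data.index.tolist()

    @property
    def covariate_columns(self) -> list[str]:
        return [c for c in self.data.columns if c not in ("time", "event")]

    def subset(self, sample_ids: Sequence[str]) -> "ClinicalTable":
        return ClinicalTable(self.data.loc[list(sample_ids)], self.time_unit)
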