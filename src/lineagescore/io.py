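"""Readers, writers, run configuration and the end-to-end pipeline.

TSV is the canonical interchange format: expression matrices are written
genes-as-rows with a header of sample labels, clinical tables carry
``sample_id``, ``time``, ``event`` plus free covariate columns, and every
pipeline run emits a JSON manifest (seed, config hash, package version) so
identical manifests imply identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .containers import (
    ChannelMode,
    ClinicalTable,
    ExpressionMatrix,
    LineageWeightSet,
    ReplicateMap,
    ValidationError,
    _coerce_mode,
)
from .lineage_prep import build_weights
from .lss import score_all, scores_wide
from .patient_prep import harmonize_genes, prepare_patients
from .survival import assoc_table, cox_univariate_all, dichotomize_lss, km_logrank

logger = logging.getLogger(__name__)


def read_expression_tsv(path: str | Path, channel_mode: ChannelMode | str) -> ExpressionMatrix:
    """Read a genes x columns TSV (first column identifiers, header row).

    Duplicate identifiers are rejected with their row numbers; non-numeric
    cells are reported with their location. Parsing is locale-independent
    (C-locale decimal points).
    """
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"expression file not found: {path}")
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    except Exception as exc:  # ragged rows, encoding problems
        raise ValidationError(f"{path}: cannot parse TSV: {exc}") from exc
    if df.shape[1] == 0:
        raise ValidationError(f"{path}: no data columns")
    dup = df.index.duplicated(keep=False)
    if dup.any():
        rows = [i + 2 for i in np.flatnonzero(dup)][:5]  # +2: header + 1-based
        names = sorted(set(df.index[dup]))[:5]
        raise ValidationError(
            f"{path}: duplicate gene identifier(s) {names} at file rows {rows}"
        )
    try:
        num = df.apply(pd.to_numeric, axis=0)
    except (ValueError, TypeError):
        for col in df.columns:
            conv = pd.to_numeric(df[col], errors="coerce")
            bad = conv.isna() & df[col].notna()
            if bad.any():
                i = int(np.flatnonzero(bad)[0])
                raise ValidationError(
                    f"{path}: non-numeric cell {df[col].iloc[i]!r} at row "
                    f"{i + 2}, column {col!r}"
                ) from None
        raise
    return ExpressionMatrix(num, channel_mode)


def write_expression_tsv(m: ExpressionMatrix, path: str | Path, label: str = "gene") -> None:
    m.data.to_csv(Path(path), sep="\t", index_label=label)


def read_replicate_map(path: str | Path) -> ReplicateMap:
    """Read a two-column (column_id, cell_type) TSV."""
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"replicate map not found: {path}")
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns[:2]) != ["column_id", "cell_type"]:
        raise ValidationError(
            f"{path}: expected header 'column_id\\tcell_type', got {list(df.columns)}"
        )
    groups: dict[str, list[str]] = {}
    for _, row in df.iterrows():
        groups.setdefault(row["cell_type"], []).append(row["column_id"])
    return ReplicateMap(groups)


def read_clinical_tsv(path: str | Path, time_unit: str = "unspecified") -> ClinicalTable:
    """Read and validate a clinical TSV with sample_id, time, event columns.

    Unknown columns are preserved as candidate covariates; missing covariate
    cells are allowed, missing time/event are not.
    """
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"clinical file not found: {path}")
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in ("sample_id", "time", "event") if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing required column(s) {missing}")
    for col in ("time", "event"):
        na = df[col].isna()
        if na.any():
            raise ValidationError(
                f"{path}: missing {col} at file row {int(np.flatnonzero(na)[0]) + 2}"
            )
    df = df.set_index("sample_id")
    try:
        return ClinicalTable(df, time_unit=time_unit)
    except ValidationError as exc:
        raise ValidationError(f"{path}: {exc}") from exc


@dataclass
class RunConfig:
    """End-to-end pipeline configuration.

    Either ``weights_dir`` (pre-built weight set) or ``lineages_path``
    (+ optional ``replicate_map_path``) must be provided. ``clinical_path``
    is required only when the association stage is requested.
    """

    patients_path: str
    out_dir: str
    channel_mode: ChannelMode | str = ChannelMode.TWO_CHANNEL
    weights_dir: str | None = None
    lineages_path: str | None = None
    replicate_map_path: str | None = None
    clinical_path: str | None = None
    associate: bool = True
    n_perm: int = 1000
    seed: int = 17
    covariates: list[str] = field(default_factory=list)
    adjustment: str = "bh"
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        self.channel_mode = _coerce_mode(self.channel_mode)
        if self.n_perm < 1:
            raise ValidationError("n_perm must be >= 1")
        if self.adjustment != "bh":
            raise ValidationError(f"unsupported adjustment method {self.adjustment!r}")
        if not self.weights_dir and not self.lineages_path:
            raise ValidationError("provide weights_dir or lineages_path")

    def validate_paths(self) -> None:
        """Pre-flight existence check for every referenced input path."""
        checks = [("patients", self.patients_path)]
        if self.weights_dir:
            checks.append(("weights", self.weights_dir))
        if self.lineages_path:
            checks.append(("lineages", self.lineages_path))
        if self.replicate_map_path:
            checks.append(("replicate map", self.replicate_map_path))
        if self.associate:
            if not self.clinical_path:
                raise ValidationError(
                    "association requested but no clinical_path configured"
                )
            checks.append(("clinical", self.clinical_path))
        for label, p in checks:
            if not Path(p).exists():
                raise ValidationError(f"{label} input does not exist: {p}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["channel_mode"] = self.channel_mode.value
        return d

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text())
        if not isinstance(doc, dict):
            raise ValidationError(f"{path}: run config must be a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ValidationError(f"{path}: unknown config fields {sorted(unknown)}")
        return cls(**doc)


def _config_hash(cfg: RunConfig) -> str:
    payload = json.dumps(cfg.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def run_pipeline(cfg: RunConfig) -> dict[str, Path]:
    """Execute prep -> harmonize -> score -> associate and write artifacts.

    Returns a mapping of artifact names to paths. All inputs are validated
    before any stage runs; any stage failure aborts with the stage named in
    the error message.
    """
    logging.basicConfig(level=cfg.log_level)
    cfg.validate_paths()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    stage = "prep"
    try:
        if cfg.weights_dir:
            weights = LineageWeightSet.from_dir(cfg.weights_dir)
        else:
            raw = read_expression_tsv(cfg.lineages_path, ChannelMode.REFERENCE)
            reps = (
                read_replicate_map(cfg.replicate_map_path)
                if cfg.replicate_map_path
                else ReplicateMap.infer(raw.column_ids)
            )
            weights = build_weights(raw, reps)
        patients_raw = read_expression_tsv(cfg.patients_path, cfg.channel_mode)
        patients = prepare_patients(patients_raw)

        stage = "harmonize"
        weights, patients = harmonize_genes(weights, patients)
        logger.info(
            "harmonized to %d genes, %d cell types, %d patients",
            len(patients.gene_ids),
            len(weights.cell_types),
            len(patients.column_ids),
        )

        stage = "score"
        long = score_all(weights, patients, n_perm=cfg.n_perm, seed=cfg.seed)
        wide = scores_wide(long)

        artifacts: dict[str, Path] = {}
        long_path = out / "lss_long.tsv"
        wide_path = out / "lss_matrix.tsv"
        long.to_csv(long_path, sep="\t", index=False)
        wide.to_csv(wide_path, sep="\t")
        artifacts["lss_long"] = long_path
        artifacts["lss_matrix"] = wide_path

        if cfg.associate:
            stage = "associate"
            clin = read_clinical_tsv(cfg.clinical_path)
            shared = [s for s in wide.index if s in set(clin.sample_ids)]
            if not shared:
                raise ValidationError("no samples shared with clinical table")
            results = cox_univariate_all(wide.loc[shared], clin.subset(shared))
            table = assoc_table(results)
            assoc_path = out / "associations.tsv"
            table.to_csv(assoc_path, sep="\t", index=False)
            artifacts["associations"] = assoc_path

            top = table.dropna(subset=["adj_p"])
            if len(top):
                ct = top.iloc[0]["cell_type"]
                try:
                    threshold, labels = dichotomize_lss(
                        wide.loc[shared, ct].to_numpy()
                    )
                    curves, logrank_p = km_logrank(
                        pd.Series(labels, index=shared), clin.subset(shared)
                    )
                    km_path = out / f"km_{ct}.tsv"
                    km_df = pd.concat(
                        [c.assign(group=g) for g, c in curves.items()],
                        ignore_index=True,
                    )
                    km_df.attrs["logrank_p"] = logrank_p
                    km_df.to_csv(km_path, sep="\t", index=False)
                    (out / f"km_{ct}.json").write_text(
                        json.dumps(
                            {
                                "cell_type": str(ct),
                                "threshold": threshold,
                                "logrank_p": logrank_p,
                            },
                            indent=2,
                        )
                        + "\n"
                    )
                    artifacts["km_curves"] = km_path
                except ValidationError as exc:
                    logger.warning("KM export skipped for %s: %s", ct, exc)

        manifest = {
            "package": "lineagescore",
            "version": __version__,
            "seed": cfg.seed,
            "n_perm": cfg.n_perm,
            "config": cfg.to_dict(),
            "config_hash": _config_hash(cfg),
            "artifacts": {k: str(v.name) for k, v in artifacts.items()},
        }
        manifest_path = out / "manifest.json"
        manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
        artifacts["manifest"] = manifest_path
        return artifacts
    except ValidationError as exc:
        raise ValidationError(f"[stage: {stage}] {exc}") from exc
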