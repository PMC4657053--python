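"""Model/Results front door for the scoring and association pipeline.

``LineageSimilarityModel`` holds harmonized weights + patient data and its
``fit`` runs the permutation-normalized scoring, returning ``LSSResults``.
``SurvivalAssociationModel`` holds a score matrix + clinical table and its
``fit`` runs the Cox screen (optionally covariate-adjusted), returning
``AssociationResults`` with estimates, confidence intervals and a summary
table. Simulation-based fixtures come from :mod:`lineagescore.simulate`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import (
    ChannelMode,
    ClinicalTable,
    ExpressionMatrix,
    LineageWeightSet,
    ReplicateMap,
    ValidationError,
)
from .lineage_prep import build_weights
from .lss import DEFAULT_N_PERM, score_all, scores_wide
from .patient_prep import harmonize_genes, prepare_patients
from .survival import (
    assoc_table,
    cox_multivariate,
    cox_univariate_all,
    dichotomize_lss,
    km_logrank,
)


@dataclass
class LSSResults:
    """Fitted lineage similarity scores.

    Attributes
    ----------
    long : tidy frame with one row per (patient, cell type).
    wide : patients x cell types matrix of final LSS values.
    """

    long: pd.DataFrame
    wide: pd.DataFrame
    channel_mode: ChannelMode
    n_perm: int
    seed: int

    def summary(self) -> str:
        """Per-cell-type location/spread of the fitted scores."""
        stats = self.wide.agg(["mean", "std", "min", "max"]).T
        lines = [
            "Lineage Similarity Score fit",
            "=" * 60,
            f"patients: {self.wide.shape[0]}   cell types: {self.wide.shape[1]}",
            f"channel mode: {self.channel_mode.value}   "
            f"permutations: {self.n_perm}   seed: {self.seed}",
            "-" * 60,
            stats.round(3).to_string(),
        ]
        return "\n".join(lines)

    def to_tsv(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.long.to_csv(out / "lss_long.tsv", sep="\t", index=False)
        self.wide.to_csv(out / "lss_matrix.tsv", sep="\t")


class LineageSimilarityModel:
    """Scores patient expression profiles against a lineage weight set.

    Parameters
    ----------
    weights : LineageWeightSet
        Up/down gene weights per cell type (see lineage_prep).
    patients : ExpressionMatrix
        Channel-prepared patient matrix. Gene harmonization against the
        weights happens at construction.
    prepare : bool
        When True (default) the channel-appropriate preparation
        (log + median-centering for one-channel data) is applied first.
    """

    def __init__(
        self,
        weights: LineageWeightSet,
        patients: ExpressionMatrix,
        prepare: bool = True,
    ) -> None:
        if prepare:
            patients = prepare_patients(patients)
        self.weights, self.patients = harmonize_genes(weights, patients)
        self.channel_mode = patients.channel_mode

    @classmethod
    def from_reference(
        cls,
        reference: ExpressionMatrix,
        patients: ExpressionMatrix,
        replicate_map: ReplicateMap | None = None,
        prepare: bool = True,
    ) -> "LineageSimilarityModel":
        """Build weights from a raw reference compendium, then construct."""
        return cls(build_weights(reference, replicate_map), patients, prepare=prepare)

    def fit(
        self, n_perm: int = DEFAULT_N_PERM, seed: int = 17, progress: bool = False
    ) -> LSSResults:
        long = score_all(
            self.weights, self.patients, n_perm=n_perm, seed=seed, progress=progress
        )
        return LSSResults(
            long=long,
            wide=scores_wide(long),
            channel_mode=self.channel_mode,
            n_perm=n_perm,
            seed=seed,
        )


@dataclass
class AssociationResults:
    """Fitted Cox associations between scores and survival."""

    table: pd.DataFrame
    clinical: ClinicalTable
    scores: pd.DataFrame
    covariates: list[str] = field(default_factory=list)

    def summary(self) -> str:
        cols = ["cell_type", "coef", "hr", "ci_low", "ci_high", "wald_p", "adj_p"]
        shown = self.table[cols].copy()
        lines = [
            "Cox proportional-hazards association"
            + (f" (adjusted for {', '.join(self.covariates)})" if self.covariates else ""),
            "=" * 72,
            f"samples: {self.table['n'].max()}   "
            f"events: {self.table['n_events'].max()}   "
            f"cell types tested: {len(self.table)}",
            "-" * 72,
            shown.round(4).to_string(index=False),
        ]
        return "\n".join(lines)

    def significant(self, alpha: float = 0.05) -> pd.DataFrame:
        return self.table[self.table["adj_p"] < alpha]

    def kaplan_meier(self, cell_type: str):
        """Dichotomize one cell type's scores and compare survival curves.

        Returns (threshold, labels, curves, logrank_p).
        """
        if cell_type not in self.scores.columns:
            raise ValidationError(f"unknown cell type {cell_type!r}")
        shared = [s for s in self.scores.index if s in set(self.clinical.sample_ids)]
        vals = self.scores.loc[shared, cell_type].to_numpy()
        threshold, labels = dichotomize_lss(vals)
        curves, p = km_logrank(
            pd.Series(labels, index=shared), self.clinical.subset(shared)
        )
        return threshold, labels, curves, p


class SurvivalAssociationModel:
    """Associates a patients x cell-types score matrix with survival.

    ``fit()`` runs the univariate Cox screen across all cell types with one
    Benjamini-Hochberg pass; when ``covariates`` are given, each cell type
    is additionally fitted with those adjustment terms and the adjusted
    estimates replace the univariate ones in the results table (BH is still
    applied across all cell types at once).
    """

    def __init__(
        self,
        scores: pd.DataFrame,
        clinical: ClinicalTable,
        covariates: list[str] | None = None,
    ) -> None:
        shared = [s for s in scores.index if s in set(clinical.sample_ids)]
        if not shared:
            raise ValidationError("no samples shared between scores and clinical table")
        self.scores = scores.loc[shared]
        self.clinical = clinical.subset(shared)
        self.covariates = list(covariates or [])

    def fit(self) -> AssociationResults:
        from .survival import bh_adjust

        if not self.covariates:
            results = cox_univariate_all(self.scores, self.clinical)
            table = assoc_table(results)
        else:
            results = []
            for ct in self.scores.columns:
                results.append(
                    cox_multivariate(
                        self.scores[ct],
                        self.clinical,
                        covariates=self.covariates,
                        cell_type=str(ct),
                    )
                )
            adj = bh_adjust([r.wald_p for r in results])
            for r, a in zip(results, adj):
                r.adj_p = float(a)
            table = assoc_table(results)
        return AssociationResults(
            table=table,
            clinical=self.clinical,
            scores=self.scores,
            covariates=self.covariates,
        )
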