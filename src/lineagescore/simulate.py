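"""Synthetic lineage compendia and patient cohorts with planted ground truth.

The generator emulates the structure the scoring pipeline consumes: a
reference compendium of cell types with replicate arrays, where each cell
type owns disjoint up- and down-regulated gene modules shifted by
``effect_z`` standard deviations on a Gaussian background; and a patient
cohort whose expression blends one planted cell type's mean profile with
noise according to a per-patient mixing coefficient alpha in [0, 1], and
whose exponential survival hazard scales as exp(beta * alpha). Recovering
alpha through the score, and beta through the Cox screen, is the pipeline's
end-to-end correctness check.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import (
    ChannelMode,
    ClinicalTable,
    ExpressionMatrix,
    ReplicateMap,
    ValidationError,
    _coerce_mode,
)


@dataclass
class SimConfig:
    """Study conditions for the synthetic compendium and cohort.

    Expression is on log scale throughout (post-RMA / log-ratio semantics).
    ``effect_z`` is the module mean shift in units of ``noise_sd``;
    ``alpha_a``/``alpha_b`` parameterize the Beta distribution of the
    per-patient mixing coefficient; ``beta`` is the planted log-hazard per
    unit alpha on an exponential baseline.
    """

    n_genes: int = 2000
    n_celltypes: int = 20
    n_replicates_per_celltype: int = 3
    module_size: int = 40
    effect_z: float = 3.0
    noise_sd: float = 1.0
    n_patients: int = 200
    channel_mode: ChannelMode = ChannelMode.TWO_CHANNEL
    alpha_a: float = 2.0
    alpha_b: float = 2.0
    beta: float = 1.5
    baseline_hazard: float = 0.1
    censor_rate: float = 0.3
    confounded_covariates: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        self.channel_mode = _coerce_mode(self.channel_mode)
        for name in (
            "n_genes",
            "n_celltypes",
            "n_replicates_per_celltype",
            "module_size",
            "n_patients",
        ):
            if getattr(self, name) < 1:
                raise ValidationError(f"{name} must be a positive integer")
        if 2 * self.module_size > self.n_genes:
            raise ValidationError("module_size * 2 exceeds n_genes")
        if 2 * self.module_size * self.n_celltypes > self.n_genes:
            raise ValidationError(
                "disjoint up/down modules for all cell types are impossible: "
                f"2 * {self.module_size} * {self.n_celltypes} > {self.n_genes} genes"
            )
        if self.effect_z <= 0 or self.noise_sd <= 0 or self.baseline_hazard <= 0:
            raise ValidationError("effect_z, noise_sd, baseline_hazard must be > 0")
        if self.alpha_a <= 0 or self.alpha_b <= 0:
            raise ValidationError("alpha distribution parameters must be > 0")
        if not 0 <= self.censor_rate < 1:
            raise ValidationError("censor_rate must lie in [0, 1)")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["channel_mode"] = self.channel_mode.value
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValidationError(f"unknown simulation config fields: {sorted(unknown)}")
        return cls(**d)


@dataclass
class SimTruth:
    """Ground truth of a simulated compendium/cohort pair."""

    planted_celltype: str
    alpha: np.ndarray = field(default_factory=lambda: np.zeros(0))
    module_genes_up: dict[str, list[str]] = field(default_factory=dict)
    module_genes_down: dict[str, list[str]] = field(default_factory=dict)
    true_beta: float = 0.0
    mean_profiles: pd.DataFrame | None = None


def _gene_ids(n: int) -> list[str]:
    return [f"G{i:05d}" for i in range(1, n + 1)]


def _celltype_ids(n: int) -> list[str]:
    return [f"CT{i:02d}" for i in range(1, n + 1)]


def simulate_lineages(cfg: SimConfig) -> tuple[ExpressionMatrix, ReplicateMap, SimTruth]:
    """Simulate a replicate-structured reference compendium.

    Each cell type receives disjoint up/down modules of ``module_size``
    genes with mean shift +/- ``effect_z * noise_sd``; replicate columns
    share the cell-type mean with independent N(0, noise_sd) noise.
    Deterministic under ``cfg.seed``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    genes = _gene_ids(cfg.n_genes)
    cts = _celltype_ids(cfg.n_celltypes)
    assignment = rng.permutation(cfg.n_genes)
    shift = cfg.effect_z * cfg.noise_sd
    mean_profiles = np.zeros((cfg.n_genes, cfg.n_celltypes))
    mod_up: dict[str, list[str]] = {}
    mod_dn: dict[str, list[str]] = {}
    pos = 0
    for c, ct in enumerate(cts):
        up_idx = assignment[pos : pos + cfg.module_size]
        pos += cfg.module_size
        dn_idx = assignment[pos : pos + cfg.module_size]
        pos += cfg.module_size
        mean_profiles[up_idx, c] = shift
        mean_profiles[dn_idx, c] = -shift
        mod_up[ct] = [genes[i] for i in sorted(up_idx)]
        mod_dn[ct] = [genes[i] for i in sorted(dn_idx)]

    cols: dict[str, np.ndarray] = {}
    groups: dict[str, list[str]] = {}
    for c, ct in enumerate(cts):
        groups[ct] = []
        for r in range(1, cfg.n_replicates_per_celltype + 1):
            name = f"{ct}#{r}"
            cols[name] = mean_profiles[:, c] + rng.normal(
                0.0, cfg.noise_sd, cfg.n_genes
            )
            groups[ct].append(name)

    matrix = ExpressionMatrix(
        pd.DataFrame(cols, index=genes), ChannelMode.REFERENCE
    )
    truth = SimTruth(
        planted_celltype=cts[0],
        module_genes_up=mod_up,
        module_genes_down=mod_dn,
        true_beta=cfg.beta,
        mean_profiles=pd.DataFrame(mean_profiles, index=genes, columns=cts),
    )
    return matrix, ReplicateMap(groups), truth


def _calibrate_censoring(
    times: np.ndarray, u: np.ndarray, censor_rate: float
) -> np.ndarray:
    """Uniform(0, c_max) censoring times with c_max set so the realized
    censoring fraction matches the target.

    A sample is censored iff C_i < T_i, i.e. c_max * u_i < T_i; choosing
    c_max as the (1 - rate) quantile of T_i / u_i hits the target exactly up
    to integer rounding.
    """
    if censor_rate <= 0:
        return np.full_like(times, np.inf)
    ratio = times / u
    c_max = float(np.quantile(ratio, 1.0 - censor_rate))
    return u * c_max


def simulate_cohort(
    cfg: SimConfig, truth: SimTruth
) -> tuple[ExpressionMatrix, ClinicalTable]:
    """Simulate a patient cohort tied to a planted cell type.

    Patient i draws alpha_i ~ Beta(alpha_a, alpha_b); expression is
    alpha_i * (planted mean profile) + N(0, noise_sd) per gene. Survival
    time is exponential with hazard baseline_hazard * exp(beta * alpha_i),
    censored by an independent uniform time calibrated to ``censor_rate``.
    Two-channel cohorts are median-centered per gene; one-channel cohorts
    are exponentiated to positive intensities around a baseline of 2^7.
    """
    if truth.mean_profiles is None:
        raise ValidationError("truth object lacks mean profiles; run simulate_lineages")
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 2]))
    n = cfg.n_patients
    alpha = rng.beta(cfg.alpha_a, cfg.alpha_b, n)
    mu = truth.mean_profiles[truth.planted_celltype].to_numpy()
    expr = alpha[None, :] * mu[:, None] + rng.normal(
        0.0, cfg.noise_sd, (cfg.n_genes, n)
    )
    patients = [f"P{i:04d}" for i in range(1, n + 1)]
    genes = truth.mean_profiles.index

    if cfg.channel_mode is ChannelMode.TWO_CHANNEL:
        expr = expr - np.median(expr, axis=1, keepdims=True)
    elif cfg.channel_mode is ChannelMode.ONE_CHANNEL:
        expr = np.power(2.0, expr + 7.0)
    else:
        raise ValidationError("cohort channel_mode must be one_channel or two_channel")
    pat = ExpressionMatrix(
        pd.DataFrame(expr, index=genes, columns=patients), cfg.channel_mode
    )

    hazard = cfg.baseline_hazard * np.exp(cfg.beta * alpha)
    times = rng.exponential(1.0 / hazard)
    u = rng.uniform(size=n)
    censor_times = _calibrate_censoring(times, u, cfg.censor_rate)
    observed = np.minimum(times, censor_times)
    event = (times <= censor_times).astype(int)

    if cfg.confounded_covariates:
        age = 40.0 + 30.0 * alpha + rng.normal(0.0, 5.0, n)
        flt3_p = np.clip(alpha, 0.05, 0.95)
    else:
        age = rng.normal(55.0, 10.0, n)
        flt3_p = np.full(n, 0.3)
    flt3 = np.where(rng.uniform(size=n) < flt3_p, "mutated", "wildtype")
    fab = rng.choice([f"M{i}" for i in range(6)], size=n)

    clin = ClinicalTable(
        pd.DataFrame(
            {
                "time": np.maximum(observed, 1e-9),
                "event": event,
                "age": age,
                "fab": fab,
                "flt3": flt3,
            },
            index=pd.Index(patients, name="sample_id"),
        ),
        time_unit="arbitrary",
    )
    truth.alpha = alpha
    return pat, clin


def write_fixture_bundle(cfg: SimConfig, out_dir: str | Path) -> dict[str, Path]:
    """Write a self-contained input bundle: lineage TSV, replicate map,
    patient TSV, clinical TSV and a truth JSON recording the config."""
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise ValidationError(f"cannot create output directory {out}: {exc}") from exc
    lineages, reps, truth = simulate_lineages(cfg)
    patients, clin = simulate_cohort(cfg, truth)

    paths = {
        "lineages": out / "lineages.tsv",
        "replicates": out / "replicates.tsv",
        "patients": out / "patients.tsv",
        "clinical": out / "clinical.tsv",
        "truth": out / "truth.json",
    }
    # expression written at 1e-4 resolution: far below the simulated noise,
    # short decimal reprs that round-trip exactly through the TSV readers
    lineages.data.round(4).to_csv(paths["lineages"], sep="\t", index_label="gene")
    pd.DataFrame(
        [(col, ct) for ct, cols in reps.groups.items() for col in cols],
        columns=["column_id", "cell_type"],
    ).to_csv(paths["replicates"], sep="\t", index=False)
    patients.data.round(4).to_csv(paths["patients"], sep="\t", index_label="gene")
    clin.data.to_csv(paths["clinical"], sep="\t", index_label="sample_id")
    truth_doc = {
        "config": cfg.to_dict(),
        "planted_celltype": truth.planted_celltype,
        "alpha": truth.alpha.tolist(),
        "module_genes_up": truth.module_genes_up,
        "module_genes_down": truth.module_genes_down,
        "true_beta": truth.true_beta,
    }
    paths["truth"].write_text(json.dumps(truth_doc, indent=2) + "\n")
    return paths
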