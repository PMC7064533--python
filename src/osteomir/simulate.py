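"""Synthetic osteosarcoma cohorts with the structure the pipeline assumes.

The generator emulates the joint structure of a prognostic-biomarker study:
a small miRNA profile whose log-expression carries proportional-hazards
effects on recurrence-free survival, independent uniform censoring, a
metastasis-at-diagnosis covariate, a pathologic-necrosis class whose odds of
being suboptimal rise with the latent risk, mRNA targets negatively
correlated with their regulator miRNAs, CpG methylation correlated with
miRNA expression, and gene-drug association plus cell-line IC50 tables with
planted "active" drugs that must survive the staged pharmacogenomic filter.

Survival times are exponential (constant baseline hazard) with per-sample
hazard ``baseline_hazard * exp(sum_g beta_g * z_gs)`` where ``z_gs`` is the
standardized profile expression — the standard Cox form, with a closed-form
sampler.  Ground-truth labels (latent risk, true effect signs, planted
drugs) ride along for parameter-recovery tests.

All randomness flows from a single seed through deterministically spawned
per-table substreams, so a fixed seed gives bit-identical cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.special import expit

from .matrix import ExpressionMatrix, write_matrix
from .genesets import GeneTargetMap


class ConfigError(ValueError):
    pass


@dataclass
class SimulationConfig:
    """Data-generating parameters of a synthetic cohort.

    Defaults describe a mid-size single-cohort study: 150 patients, a
    five-miRNA profile with per-feature log-hazard 0.5 on standardized
    expression, a baseline hazard of 0.01 events/month (median ~70 months at
    zero risk) and 10 years of uniform accrual/censoring.
    """

    n_samples: int = 150
    n_profile_features: int = 5
    n_noise_features: int = 45
    log_hazard_effects: tuple[float, ...] | float = 0.5
    baseline_hazard: float = 0.01  # events per month
    censor_window: float = 120.0  # months
    metastasis_prob: float = 0.25
    necrosis_link: float = 1.0  # log-odds of suboptimal necrosis per unit latent risk
    target_regulation: float = 0.5  # expected |negative| miRNA->target correlation
    methyl_rho: float = 0.35  # expected miRNA-CpG (M-value) correlation
    n_drugs: int = 30
    n_active_drugs: int = 3
    n_cell_lines: int = 15
    seed: int = 0
    # table-shape parameters (not varied by the core analyses)
    targets_per_mirna_expansive: int = 10
    targets_per_mirna_restrictive: int = 3
    n_background_genes: int = 100
    cpgs_per_mirna: int = 9

    def __post_init__(self) -> None:
        for name in ("n_samples", "n_profile_features", "n_noise_features",
                     "n_drugs", "n_active_drugs", "n_cell_lines"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be > 0")
        if self.baseline_hazard <= 0:
            raise ConfigError("baseline_hazard must be > 0")
        if self.censor_window <= 0:
            raise ConfigError("censor_window must be > 0")
        if not 0.0 <= self.metastasis_prob <= 1.0:
            raise ConfigError("metastasis_prob must lie in [0, 1]")
        if abs(self.methyl_rho) > 1.0:
            raise ConfigError("methyl_rho must satisfy |rho| <= 1")
        if not 0.0 <= self.target_regulation <= 1.0:
            raise ConfigError("target_regulation must lie in [0, 1]")
        if self.n_active_drugs > self.n_drugs:
            raise ConfigError("n_active_drugs cannot exceed n_drugs")
        if np.isscalar(self.log_hazard_effects):
            self.log_hazard_effects = tuple(
                [float(self.log_hazard_effects)] * self.n_profile_features
            )
        else:
            self.log_hazard_effects = tuple(float(b) for b in self.log_hazard_effects)
        if len(self.log_hazard_effects) != self.n_profile_features:
            raise ConfigError("log_hazard_effects must have one entry per profile feature")

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path, "rt", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_yaml(self, path) -> None:
        data = asdict(self)
        data["log_hazard_effects"] = list(self.log_hazard_effects)
        with open(path, "wt", encoding="utf-8") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


@dataclass
class SyntheticCohort:
    """All tables of a simulated cohort plus the generating ground truth."""

    clinical: pd.DataFrame
    mirna: ExpressionMatrix
    mrna: ExpressionMatrix
    methylation: ExpressionMatrix  # beta space
    cpg_annotation: pd.DataFrame  # probe_id, feature_id, locus
    target_map: GeneTargetMap
    drug_assoc: pd.DataFrame
    ic50: pd.DataFrame
    truth: dict
    config: SimulationConfig

    @property
    def profile_features(self) -> list[str]:
        return list(self.truth["true_signs"].index)

    def write_dir(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.clinical.to_csv(out / "clinical.tsv", sep="\t", index=False)
        write_matrix(self.mirna, out / "mirna_log2.tsv")
        write_matrix(self.mrna, out / "mrna_log2.tsv")
        write_matrix(self.methylation, out / "methylation_beta.tsv")
        self.cpg_annotation.to_csv(out / "cpg_annotation.tsv", sep="\t", index=False)
        self.target_map.write_tsv(out / "target_map.tsv")
        self.drug_assoc.to_csv(out / "drug_associations.tsv", sep="\t", index=False)
        self.ic50.to_csv(out / "drug_sensitivity.tsv", sep="\t", index=False)
        pd.DataFrame(
            {"sample_id": self.truth["latent_risk"].index,
             "latent_risk": self.truth["latent_risk"].to_numpy()}
        ).to_csv(out / "truth_latent_risk.tsv", sep="\t", index=False)


def _standardize(rows: np.ndarray) -> np.ndarray:
    mu = rows.mean(axis=1, keepdims=True)
    sd = rows.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return (rows - mu) / sd


def simulate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Draw a full synthetic cohort from a configuration."""
    streams = np.random.SeedSequence(config.seed).spawn(7)
    rng_expr, rng_surv, rng_clin, rng_mrna, rng_meth, rng_drug, rng_ic50 = (
        np.random.default_rng(s) for s in streams
    )
    n = config.n_samples
    samples = [f"OS-{i + 1:03d}" for i in range(n)]
    profile_ids = [f"mir-prof-{i + 1:02d}" for i in range(config.n_profile_features)]
    noise_ids = [f"mir-noise-{i + 1:03d}" for i in range(config.n_noise_features)]

    # --- miRNA log-expression: per-feature baseline ~ N(8, 1), unit noise SD
    all_ids = profile_ids + noise_ids
    baselines = rng_expr.normal(8.0, 1.0, size=len(all_ids))
    values = baselines[:, None] + rng_expr.normal(0.0, 1.0, size=(len(all_ids), n))
    mirna = ExpressionMatrix(pd.DataFrame(values, index=all_ids, columns=samples), "log2norm")

    # --- exponential proportional-hazards survival with uniform censoring
    betas = np.asarray(config.log_hazard_effects)
    z_profile = _standardize(values[: len(profile_ids)])
    latent_risk = betas @ z_profile
    hazard = config.baseline_hazard * np.exp(latent_risk)
    event_time = rng_surv.exponential(1.0 / hazard)
    censor_time = rng_surv.uniform(0.0, config.censor_window, size=n)
    time = np.minimum(event_time, censor_time)
    time = np.maximum(time, 1e-3)  # guard the (measure-zero) zero-duration draw
    event = (event_time <= censor_time).astype(int)

    metastasis = rng_clin.binomial(1, config.metastasis_prob, size=n)
    centered_risk = latent_risk - latent_risk.mean()
    p_subopt = expit(config.necrosis_link * centered_risk)
    necrosis = np.where(rng_clin.uniform(size=n) < p_subopt, "suboptimal", "optimal")
    clinical = pd.DataFrame(
        {
            "sample_id": samples,
            "time_months": time,
            "event": event,
            "metastasis": metastasis,
            "necrosis": necrosis,
            "endpoint": "RFS",
        }
    )

    # --- mRNA targets: negatively coupled to their regulator miRNA
    expansive: dict[str, set[str]] = {}
    restrictive: dict[str, set[str]] = {}
    gene_rows = []
    gene_ids: list[str] = []
    tr = config.target_regulation
    resid = np.sqrt(max(0.0, 1.0 - tr * tr))
    for i, mirna_id in enumerate(profile_ids):
        genes = [
            f"tgt-{mirna_id}-{t + 1:02d}" for t in range(config.targets_per_mirna_expansive)
        ]
        expansive[mirna_id] = set(genes)
        restrictive[mirna_id] = set(genes[: config.targets_per_mirna_restrictive])
        for gene in genes:
            gene_ids.append(gene)
            gene_rows.append(-tr * z_profile[i] + resid * rng_mrna.normal(size=n))
    for b in range(config.n_background_genes):
        gene_ids.append(f"bg-gene-{b + 1:03d}")
        gene_rows.append(rng_mrna.normal(size=n))
    mrna_values = 6.0 + np.asarray(gene_rows)
    mrna = ExpressionMatrix(
        pd.DataFrame(mrna_values, index=gene_ids, columns=samples), "log2norm"
    )
    target_map = GeneTargetMap(expansive=expansive, restrictive=restrictive)

    # --- methylation: M-values coupled to regulator miRNA, reported as beta
    rho = config.methyl_rho
    m_resid = np.sqrt(max(0.0, 1.0 - rho * rho))
    probe_rows, probe_ids, annot_rows = [], [], []
    for i, mirna_id in enumerate(profile_ids):
        for c in range(config.cpgs_per_mirna):
            probe = f"cg-{mirna_id}-{c + 1:02d}"
            probe_ids.append(probe)
            annot_rows.append((probe, mirna_id, "14q32"))
            center = rng_meth.normal(-1.0, 0.5)
            probe_rows.append(
                center + rho * z_profile[i] + m_resid * rng_meth.normal(size=n)
            )
    m_values = np.asarray(probe_rows)
    beta_values = 1.0 / (1.0 + np.power(2.0, -m_values))
    methylation = ExpressionMatrix(
        pd.DataFrame(beta_values, index=probe_ids, columns=samples), "beta"
    )
    cpg_annotation = pd.DataFrame(annot_rows, columns=["probe_id", "feature_id", "locus"])

    # --- gene-drug associations and IC50 tables with planted active drugs
    drug_ids = [f"drug-{d + 1:02d}" for d in range(config.n_drugs)]
    active = drug_ids[: config.n_active_drugs]
    network_22 = sorted(target_map.union("expansive"))
    network_5 = sorted(target_map.union("restrictive"))
    assoc_rows = []
    for drug in drug_ids:
        if drug in active:
            # >= 3 distinct broad-network genes, >= 1 of them in the core network
            core_gene = rng_drug.choice(network_5)
            others = rng_drug.choice(
                [g for g in network_22 if g != core_gene], size=3, replace=False
            )
            for gene in [core_gene, *others]:
                coef = rng_drug.uniform(0.30, 0.60) * rng_drug.choice([-1.0, 1.0])
                p = 10.0 ** rng_drug.uniform(-6.0, -3.5)
                assoc_rows.append((drug, gene, coef, p))
        else:
            # inert: either sub-threshold effect size or non-significant p
            genes = rng_drug.choice(network_22, size=4, replace=False)
            weak_effect = rng_drug.uniform() < 0.5
            for gene in genes:
                if weak_effect:
                    coef = rng_drug.uniform(0.02, 0.20) * rng_drug.choice([-1.0, 1.0])
                    p = 10.0 ** rng_drug.uniform(-6.0, -1.0)
                else:
                    coef = rng_drug.uniform(0.30, 0.60) * rng_drug.choice([-1.0, 1.0])
                    p = rng_drug.uniform(0.05, 1.0)
                assoc_rows.append((drug, gene, coef, p))
    drug_assoc = pd.DataFrame(
        assoc_rows, columns=["drug_id", "gene_id", "coefficient", "p"]
    )

    cell_lines = [f"OS-line-{c + 1:02d}" for c in range(config.n_cell_lines)]
    ic50_rows = []
    for line in cell_lines:
        ic50_rows.append(("cisplatin", line, float(np.exp(rng_ic50.normal(np.log(8.0), 0.2)))))
    for drug in drug_ids:
        if drug in active:
            med = rng_ic50.uniform(0.05, 1.0)
            sigma = 0.3
        else:
            med = rng_ic50.uniform(15.0, 50.0)
            sigma = 0.3
        for line in cell_lines:
            ic50_rows.append((drug, line, float(np.exp(rng_ic50.normal(np.log(med), sigma)))))
    ic50 = pd.DataFrame(ic50_rows, columns=["drug_id", "cell_line_id", "ic50"])

    truth = {
        "latent_risk": pd.Series(latent_risk, index=samples),
        "true_signs": pd.Series(
            [1 if b >= 0 else -1 for b in betas], index=profile_ids, dtype=int
        ),
        "planted_drugs": active,
        "log_hazard_effects": pd.Series(betas, index=profile_ids),
    }
    return SyntheticCohort(
        clinical=clinical,
        mirna=mirna,
        mrna=mrna,
        methylation=methylation,
        cpg_annotation=cpg_annotation,
        target_map=target_map,
        drug_assoc=drug_assoc,
        ic50=ic50,
        truth=truth,
        config=config,
    )
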