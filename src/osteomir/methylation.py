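"""Differential methylation, miRNA-CpG correlation, methylation clustering.

All tests run in M space (logit2 of the beta fraction); beta-space inputs
are converted first because beta values are heteroskedastic near the
boundaries.  Differential methylation between two expression-defined patient
groups uses a per-probe Welch t-test with BH FDR reported alongside the
unadjusted p-values.  The link between the prognostic miRNAs and their
annotated CpG sites is assessed by Spearman rank correlation, and
methylation-based patient stratification reuses the clustering, R-index and
log-rank machinery, with a half-variance-filter rerun as a robustness check.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .matrix import ExpressionMatrix
from .normalize import beta_to_m, variance_filter
from .risk import ClusterAssignment, RIndexResult, hier_cluster, r_index
from .survival import LogRankResult, SurvivalData, logrank
from .genesets import bh_fdr


class MethylationError(ValueError):
    pass


@dataclass
class CpGAnnotation:
    """Maps methylation probes to the feature (miRNA) and locus they tag."""

    table: pd.DataFrame  # columns: probe_id, feature_id, locus

    def __post_init__(self) -> None:
        if self.table["probe_id"].duplicated().any():
            dups = self.table.loc[self.table["probe_id"].duplicated(), "probe_id"].tolist()
            raise MethylationError(f"duplicate probe id(s): {dups}")

    @classmethod
    def read_tsv(cls, path) -> "CpGAnnotation":
        return cls(pd.read_csv(path, sep="\t", dtype=str))

    def probes_for(self, feature_id: str) -> list[str]:
        mask = self.table["feature_id"] == feature_id
        return self.table.loc[mask, "probe_id"].tolist()

    @property
    def probe_ids(self) -> list[str]:
        return self.table["probe_id"].tolist()


def _ensure_m(matrix: ExpressionMatrix) -> ExpressionMatrix:
    if matrix.space == "M":
        return matrix
    if matrix.space == "beta":
        return beta_to_m(matrix)
    raise MethylationError(f"expected beta or M values, got {matrix.space!r}")


def differential_methylation(
    m_matrix: ExpressionMatrix,
    groups: pd.Series,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-probe Welch t-test of M-values between two patient groups.

    Returns mean difference (group1 - group2, M units), t, p and BH q per
    probe; the frame's ``attrs`` carry the count of probes with unadjusted
    p < alpha and the fraction hypermethylated in group 1.
    """
    matrix = _ensure_m(m_matrix)
    groups = pd.Series(groups)
    labels = groups.dropna().unique()
    if len(labels) != 2:
        raise MethylationError(f"need exactly two groups, got {list(labels)}")
    g1 = [s for s in matrix.sample_ids if groups.get(s) == labels[0]]
    g2 = [s for s in matrix.sample_ids if groups.get(s) == labels[1]]
    if len(g1) < 2 or len(g2) < 2:
        raise MethylationError("each group needs >= 2 samples")
    a = matrix.data[g1].to_numpy()
    b = matrix.data[g2].to_numpy()
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = stats.ttest_ind(a, b, axis=1, equal_var=False)
    t = np.where(np.isnan(t), 0.0, t)
    p = np.where(np.isnan(p), 1.0, p)
    diff = a.mean(axis=1) - b.mean(axis=1)
    out = pd.DataFrame(
        {"mean_diff": diff, "t": t, "p": p, "bh_q": bh_fdr(p)},
        index=matrix.feature_ids,
    )
    out.attrs["group1"] = labels[0]
    out.attrs["group2"] = labels[1]
    out.attrs["n_significant"] = int((out["p"] < alpha).sum())
    out.attrs["fraction_hyper_group1"] = float((diff > 0).mean())
    return out


def mirna_cpg_correlation(
    mirna_expr: ExpressionMatrix,
    m_matrix: ExpressionMatrix,
    annotation: CpGAnnotation,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Spearman correlation between each miRNA and its annotated CpG probes.

    Returns (per-pair frame with rho and p, per-miRNA summary with the count
    of significant probes, the median rho over significant probes and its
    range).  Constant vectors leave rho undefined and are flagged.
    """
    matrix = _ensure_m(m_matrix)
    shared = [s for s in mirna_expr.sample_ids if s in matrix.sample_ids]
    if len(shared) < 5:
        raise MethylationError("need >= 5 shared samples for rank correlation")
    pairs = []
    for mirna in mirna_expr.feature_ids:
        probes = [p for p in annotation.probes_for(mirna) if p in matrix.data.index]
        x = mirna_expr.data.loc[mirna, shared].to_numpy()
        for probe in probes:
            y = matrix.data.loc[probe, shared].to_numpy()
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                pairs.append((mirna, probe, float("nan"), float("nan"), True))
                continue
            rho, p = stats.spearmanr(x, y)
            pairs.append((mirna, probe, float(rho), float(p), False))
    per_pair = pd.DataFrame(
        pairs, columns=["mirna", "probe_id", "rho", "p", "undefined"]
    )
    summaries = []
    for mirna, sub in per_pair.groupby("mirna", sort=True):
        sig = sub[(sub["p"] < alpha) & (~sub["undefined"])]
        summaries.append(
            (
                mirna,
                len(sub),
                len(sig),
                float(sig["rho"].median()) if len(sig) else float("nan"),
                float(sig["rho"].min()) if len(sig) else float("nan"),
                float(sig["rho"].max()) if len(sig) else float("nan"),
            )
        )
    summary = pd.DataFrame(
        summaries,
        columns=["mirna", "n_probes", "n_significant", "median_rho", "min_rho", "max_rho"],
    )
    return per_pair, summary


@dataclass
class MethylationSurvivalResult:
    clusters: ClusterAssignment
    logrank: LogRankResult
    r_index: RIndexResult
    robust_clusters: ClusterAssignment  # after dropping 50% least-variant probes
    robust_logrank: LogRankResult
    robust_agreement: float  # fraction of samples keeping their partition side


def methylation_cluster_survival(
    m_matrix: ExpressionMatrix,
    probe_subset: list[str],
    clinical: pd.DataFrame,
    k: int = 2,
    n_perturbations: int = 50,
    noise_sd_factor: float = 0.5,
    seed: int = 0,
) -> MethylationSurvivalResult:
    """Cluster patients on CpG probes, test survival, and check robustness.

    The robustness rerun removes the 50% least-variant probes and reclusters;
    agreement is the best label-matching fraction of samples assigned to the
    same side of the partition.
    """
    matrix = _ensure_m(m_matrix)
    sub = matrix.subset_features(probe_subset)
    clusters = hier_cluster(sub, k=k)
    ridx = r_index(sub, k=k, n_perturbations=n_perturbations,
                   noise_sd_factor=noise_sd_factor, seed=seed)
    clin = clinical.set_index("sample_id").loc[clusters.labels.index]
    surv = SurvivalData.from_clinical(clin.reset_index(), group=clusters.labels.to_numpy())
    lr = logrank(surv)

    robust_matrix = variance_filter(sub, 0.50)
    robust = hier_cluster(robust_matrix, k=k)
    robust_surv = SurvivalData.from_clinical(clin.reset_index(), group=robust.labels.to_numpy())
    robust_lr = logrank(robust_surv)
    agreement = _partition_agreement(clusters.labels, robust.labels)
    return MethylationSurvivalResult(clusters, lr, ridx, robust, robust_lr, agreement)


def _partition_agreement(a: pd.Series, b: pd.Series) -> float:
    """Max over label permutations of the per-sample agreement fraction."""
    from itertools import permutations

    b = b.reindex(a.index)
    labels_b = sorted(b.unique())
    best = 0.0
    for perm in permutations(sorted(a.unique())):
        if len(perm) != len(labels_b):
            break
        mapping = dict(zip(labels_b, perm))
        best = max(best, float((a == b.map(mapping)).mean()))
    return best
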