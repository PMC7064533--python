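"""Risk stratification: signed-average scoring, clustering and concordance.

The signed-average score is a deliberately simple prognostic index: per-sample
mean of profile-feature expression weighted +1 or -1 by each feature's
hazard-ratio direction, dichotomized at the cohort median.  Its appeal is
robustness — no coefficients are fitted, so nothing can overfit when the
profile is carried to a new cohort or platform.

Unsupervised stratification uses agglomerative clustering of samples with
centered-correlation distance (1 - Pearson) and average linkage, and the
stability of a partition is quantified with the R-index: the fraction of
originally co-clustered sample pairs that remain co-clustered after Gaussian
noise perturbation and reclustering.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

from .matrix import ExpressionMatrix

logger = logging.getLogger(__name__)


class RiskError(ValueError):
    pass


@dataclass
class RiskProfile:
    """Ordered profile features with +/-1 direction weights."""

    feature_ids: list[str]
    signs: list[int]
    source: str = ""

    def __post_init__(self) -> None:
        if len(self.feature_ids) != len(self.signs):
            raise RiskError("feature_ids and signs must have equal length")
        if any(s not in (1, -1) for s in self.signs):
            raise RiskError("signs must be +1 or -1")

    @classmethod
    def read_tsv(cls, path, source: str = "") -> "RiskProfile":
        table = pd.read_csv(path, sep="\t")
        return cls(
            feature_ids=table["feature_id"].astype(str).tolist(),
            signs=table["sign"].astype(int).tolist(),
            source=source or str(path),
        )

    def write_tsv(self, path) -> None:
        pd.DataFrame({"feature_id": self.feature_ids, "sign": self.signs}).to_csv(
            path, sep="\t", index=False
        )


@dataclass
class RiskScore:
    """Per-sample signed-average score with median dichotomization."""

    scores: pd.Series
    cutpoint: float
    groups: pd.Series  # "high" / "low"; samples exactly at the median go low
    dropped_features: list[str] = field(default_factory=list)


@dataclass
class ClusterAssignment:
    labels: pd.Series  # per-sample cluster label in 1..k
    k: int
    linkage: str = "average"
    distance: str = "centered correlation"


@dataclass
class RIndexResult:
    r: float
    n_perturbations: int
    noise_sd: float
    per_perturbation: list[float]


@dataclass
class ConcordanceResult:
    contingency: pd.DataFrame
    chi2: float
    chi2_p: float
    fisher_p: float | None  # exact two-sided, 2x2 tables only
    cramers_v: float  # NaN when undefined (single-category labelling)


def signed_average_score(
    matrix: ExpressionMatrix,
    profile: RiskProfile,
    standardize: bool = True,
) -> RiskScore:
    """Signed-average risk score S_s = mean_g w_g * x_gs, median-split.

    Features are z-scored per feature before averaging when ``standardize``
    is on (the default) so that no single high-variance feature dominates.
    Profile features absent from the matrix are dropped with a warning;
    higher score means predicted-poorer outcome under the sign convention.
    Samples whose score equals the median are assigned to the low group.
    """
    present = [f for f in profile.feature_ids if f in matrix.data.index]
    dropped = [f for f in profile.feature_ids if f not in matrix.data.index]
    if dropped:
        logger.warning("signed_average_score: dropping absent feature(s) %s", dropped)
        warnings.warn(f"profile features not in matrix, dropped: {dropped}", stacklevel=2)
    if not present:
        raise RiskError("no profile feature present in the matrix")
    signs = pd.Series(
        [s for f, s in zip(profile.feature_ids, profile.signs) if f in present],
        index=present,
        dtype=float,
    )
    sub = matrix.data.loc[present]
    if standardize:
        mu = sub.mean(axis=1)
        sd = sub.std(axis=1, ddof=1)
        zero = sd[sd == 0].index.tolist()
        if zero:
            raise RiskError(f"cannot z-score constant feature(s): {zero}")
        sub = sub.sub(mu, axis=0).div(sd, axis=0)
    scores = sub.mul(signs, axis=0).mean(axis=0)
    cutpoint = float(scores.median())
    groups = pd.Series(np.where(scores > cutpoint, "high", "low"), index=scores.index)
    return RiskScore(scores=scores, cutpoint=cutpoint, groups=groups, dropped_features=dropped)


def _sample_distance(data: pd.DataFrame) -> np.ndarray:
    """Condensed 1 - Pearson distance between sample columns."""
    d = pdist(data.to_numpy().T, metric="correlation")
    if np.any(~np.isfinite(d)):
        raise RiskError(
            "correlation distance undefined (constant sample over the feature subset)"
        )
    return d


def hier_cluster(
    matrix: ExpressionMatrix,
    feature_subset: list[str] | None = None,
    k: int = 2,
) -> ClusterAssignment:
    """Average-linkage agglomerative clustering of samples.

    Distance between samples is 1 - Pearson correlation over the chosen
    feature subset (centered correlation).  Zero-variance features are
    dropped with a warning; the tree is cut to exactly ``k`` clusters.
    """
    data = matrix.data if feature_subset is None else matrix.subset_features(feature_subset).data
    variances = data.var(axis=1, ddof=0)
    flat = variances[variances == 0].index.tolist()
    if flat:
        logger.warning("hier_cluster: dropping zero-variance feature(s) %s", flat)
        warnings.warn(f"zero-variance features dropped: {flat}", stacklevel=2)
        data = data.drop(index=flat)
    if data.shape[0] == 0:
        raise RiskError("no feature with nonzero variance")
    n_samples = data.shape[1]
    if k > n_samples:
        raise RiskError(f"k={k} exceeds the {n_samples} samples")
    dist = _sample_distance(data)
    tree = linkage(dist, method="average")
    labels = fcluster(tree, t=k, criterion="maxclust")
    return ClusterAssignment(labels=pd.Series(labels, index=data.columns), k=k)


def _copair_matrix(labels: np.ndarray) -> np.ndarray:
    return labels[:, None] == labels[None, :]


def r_index(
    matrix: ExpressionMatrix,
    feature_subset: list[str] | None = None,
    k: int = 2,
    n_perturbations: int = 50,
    noise_sd_factor: float = 0.5,
    seed: int = 0,
) -> RIndexResult:
    """Cluster-reproducibility R-index under Gaussian noise perturbation.

    Each perturbation adds i.i.d. Gaussian noise with SD equal to
    ``noise_sd_factor`` times the pooled within-feature SD, reclusters at the
    same ``k``, and records the fraction of sample pairs co-clustered in the
    original partition that are still co-clustered.  R is the mean of those
    fractions; a factor of zero reproduces the data exactly and gives R = 1.
    """
    if n_perturbations < 1:
        raise RiskError("n_perturbations must be >= 1")
    data = matrix.data if feature_subset is None else matrix.subset_features(feature_subset).data
    pooled_var = float(data.var(axis=1, ddof=1).mean())
    if pooled_var == 0:
        raise RiskError("all features have zero variance")
    noise_sd = noise_sd_factor * np.sqrt(pooled_var)
    base = hier_cluster(ExpressionMatrix(data, matrix.space), k=k)
    base_labels = base.labels.to_numpy()
    base_pairs = _copair_matrix(base_labels)
    iu = np.triu_indices(len(base_labels), 1)
    together = base_pairs[iu]
    if not together.any():
        raise RiskError("original partition has no co-clustered pair")
    rng = np.random.default_rng(seed)
    agreements: list[float] = []
    for _ in range(n_perturbations):
        noisy = data + rng.normal(0.0, noise_sd, size=data.shape)
        pert = hier_cluster(ExpressionMatrix(noisy, matrix.space), k=k)
        pert_pairs = _copair_matrix(pert.labels.to_numpy())[iu]
        agreements.append(float(pert_pairs[together].mean()))
    return RIndexResult(
        r=float(np.mean(agreements)),
        n_perturbations=n_perturbations,
        noise_sd=float(noise_sd),
        per_perturbation=agreements,
    )


COMPOSITE_RULE = {
    ("low", "optimal"): "very_favorable",
    ("high", "suboptimal"): "very_unfavorable",
    ("low", "suboptimal"): "intermediate",
    ("high", "optimal"): "intermediate",
}


def composite_classify(risk_group: str, necrosis: str) -> str:
    """Composite prognostic group from risk profile and pathologic necrosis.

    Low-risk profile with optimal chemoresponse (>= 90% tumor necrosis) is
    very favorable; high-risk with suboptimal response is very unfavorable;
    the two mixed combinations form a single intermediate group.
    """
    key = (risk_group, necrosis)
    if key not in COMPOSITE_RULE:
        raise RiskError(
            f"composite_classify expects risk in {{high,low}} and necrosis in "
            f"{{optimal,suboptimal}}, got {key}"
        )
    return COMPOSITE_RULE[key]


def composite_classify_samples(risk_groups: pd.Series, necrosis: pd.Series) -> pd.Series:
    """Vectorized composite classification; samples missing either input are
    excluded (and logged)."""
    shared = risk_groups.index.intersection(necrosis.index)
    ok = [
        s for s in shared
        if pd.notna(risk_groups[s]) and pd.notna(necrosis[s])
    ]
    skipped = sorted((set(risk_groups.index) | set(necrosis.index)) - set(ok))
    if len(ok) < len(shared):
        logger.warning("composite: excluded samples with missing inputs: %s", skipped)
    return pd.Series(
        [composite_classify(risk_groups[s], necrosis[s]) for s in ok], index=ok
    )


def concordance(labels_a: pd.Series, labels_b: pd.Series) -> ConcordanceResult:
    """Classification concordance: chi-square, Fisher (2x2) and Cramer's V.

    The chi-square entering V carries no continuity correction (the standard
    convention for V); Fisher's exact two-sided p is reported for 2x2 tables
    as the significance measure.  Degenerate single-category labellings leave
    V undefined (NaN).
    """
    labels_a, labels_b = pd.Series(labels_a), pd.Series(labels_b)
    if not labels_a.index.equals(labels_b.index):
        labels_b = labels_b.reindex(labels_a.index)
        if labels_b.isna().any():
            raise RiskError("both labelings must cover the same samples")
    table = pd.crosstab(labels_a, labels_b)
    n = int(table.to_numpy().sum())
    r, c = table.shape
    if min(r, c) < 2:
        return ConcordanceResult(table, 0.0, 1.0, None, float("nan"))
    chi2, chi2_p, _, _ = stats.chi2_contingency(table, correction=False)
    fisher_p = None
    if table.shape == (2, 2):
        _, fisher_p = stats.fisher_exact(table, alternative="two-sided")
        fisher_p = float(fisher_p)
    v = float(np.sqrt(chi2 / (n * (min(r, c) - 1))))
    return ConcordanceResult(table, float(chi2), float(chi2_p), fisher_p, v)
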