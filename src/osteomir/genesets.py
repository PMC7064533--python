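"""Gene-set survival association by functional class scoring (LS/KS tests).

A gene set (here: the experimentally supported mRNA targets of a prognostic
miRNA) is scored against a survival endpoint by first computing a univariate
Cox score-test p-value for every measured gene, then summarizing the set's
p-values with two statistics:

* LS = mean of -ln(p) over the set (large when the set is collectively
  associated with outcome),
* KS = the maximal exceedance of the set's ordered p-values below the
  uniform line, max_i (i/k - p_(i)), floored at zero.

Significance comes from a permutation null: random gene sets of the same
size drawn without replacement from all measured genes, with the add-one
rule p = (1 + #{null >= observed}) / (1 + n_perm) so a permutation p can
never be exactly zero.

The module also provides EASE-penalized hypergeometric pathway enrichment
against user-supplied GMT collections and Benjamini-Hochberg FDR control.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .matrix import ExpressionMatrix
from .normalize import variance_filter
from .survival import SurvivalData, cox_score_test

MIN_USABLE_SET = 5  # sets below this are reported "too small", not scored


class GeneSetError(ValueError):
    pass


@dataclass
class GeneTargetMap:
    """miRNA -> target-gene sets at two evidence tiers.

    The restrictive tier demands targeted experimental evidence of the
    miRNA/mRNA interaction and must be a subset of the expansive tier.
    """

    expansive: dict[str, set[str]]
    restrictive: dict[str, set[str]]

    def __post_init__(self) -> None:
        for mirna, restr in self.restrictive.items():
            expa = self.expansive.get(mirna, set())
            if not restr <= expa:
                raise GeneSetError(
                    f"restrictive targets of {mirna} are not a subset of expansive"
                )

    @classmethod
    def read_tsv(cls, path) -> "GeneTargetMap":
        """Read (mirna_id, gene_id, tier) rows; tier is expansive|restrictive.

        A restrictive row implies expansive membership.
        """
        table = pd.read_csv(path, sep="\t", dtype=str)
        expansive: dict[str, set[str]] = {}
        restrictive: dict[str, set[str]] = {}
        for _, row in table.iterrows():
            mirna, gene, tier = row["mirna_id"], row["gene_id"], row["tier"]
            expansive.setdefault(mirna, set()).add(gene)
            restrictive.setdefault(mirna, set())
            if tier == "restrictive":
                restrictive[mirna].add(gene)
            elif tier != "expansive":
                raise GeneSetError(f"unknown evidence tier {tier!r}")
        return cls(expansive=expansive, restrictive=restrictive)

    def write_tsv(self, path) -> None:
        rows = []
        for mirna, genes in sorted(self.expansive.items()):
            restr = self.restrictive.get(mirna, set())
            for gene in sorted(genes):
                rows.append((mirna, gene, "restrictive" if gene in restr else "expansive"))
        pd.DataFrame(rows, columns=["mirna_id", "gene_id", "tier"]).to_csv(
            path, sep="\t", index=False
        )

    def union(self, tier: str, mirnas=None) -> set[str]:
        sets = self.restrictive if tier == "restrictive" else self.expansive
        keys = sets.keys() if mirnas is None else mirnas
        out: set[str] = set()
        for m in keys:
            out |= sets.get(m, set())
        return out


@dataclass
class GeneSetResult:
    name: str
    set_size: int
    ls: float
    ks: float
    p_ls: float
    p_ks: float
    n_perm: int
    seed: int
    too_small: bool = False


def per_gene_pvalues(matrix: ExpressionMatrix, survival: SurvivalData) -> pd.DataFrame:
    """Univariate Cox score-test p per gene against the survival endpoint.

    Returns a frame indexed by gene with columns p, chi2, sign and a
    ``constant`` flag; constant genes carry no information and get p = 1.
    """
    if matrix.shape[1] != survival.n:
        raise GeneSetError("matrix samples must match survival data")
    records = []
    values = matrix.data.to_numpy()
    for i, gene in enumerate(matrix.feature_ids):
        x = values[i]
        if np.ptp(x) == 0:
            records.append((gene, 1.0, 0.0, 1, True))
            continue
        chi2, p, sign = cox_score_test(survival.time, survival.event, x)
        records.append((gene, p, chi2, sign, False))
    return pd.DataFrame(
        records, columns=["gene", "p", "chi2", "sign", "constant"]
    ).set_index("gene")


def _clamp_pvals(pvals: np.ndarray) -> np.ndarray:
    pvals = np.asarray(pvals, dtype=float)
    if np.any(pvals <= 0):
        warnings.warn("p-values <= 0 clamped to machine minimum", stacklevel=3)
        pvals = np.maximum(pvals, np.finfo(float).tiny)
    if np.any(pvals > 1):
        raise GeneSetError("p-values must not exceed 1")
    return pvals


def ls_stat(pvals) -> float:
    """LS statistic: mean of -ln(p) over the set."""
    pvals = _clamp_pvals(pvals)
    if pvals.size == 0:
        raise GeneSetError("LS needs at least one p-value")
    return float(np.mean(-np.log(pvals)))


def ks_stat(pvals) -> float:
    """KS statistic: max_i (i/k - p_(i)) over ascending-sorted p, floored at 0.

    One-sided toward small p — only enrichment of small p-values counts.
    """
    pvals = np.sort(_clamp_pvals(pvals))
    if pvals.size == 0:
        raise GeneSetError("KS needs at least one p-value")
    k = pvals.size
    ranks = np.arange(1, k + 1) / k
    return float(max(0.0, np.max(ranks - pvals)))


def permutation_pvalue(
    geneset: set[str] | list[str],
    all_gene_pvals: pd.Series,
    n_perm: int = 1000,
    seed: int = 0,
    name: str = "",
) -> GeneSetResult:
    """Permutation p-values for a gene set's LS and KS statistics.

    The null is random gene sets of the same size sampled without replacement
    from every measured gene; p = (1 + #{null >= observed}) / (1 + n_perm).
    """
    if n_perm < 100:
        raise GeneSetError("n_perm must be >= 100")
    all_gene_pvals = pd.Series(all_gene_pvals)
    if len(set(geneset)) > len(all_gene_pvals):
        raise GeneSetError("gene set larger than the measured gene universe")
    genes = [g for g in geneset if g in all_gene_pvals.index]
    missing = set(geneset) - set(genes)
    if missing:
        warnings.warn(f"gene set members not measured, dropped: {sorted(missing)}", stacklevel=2)
    k = len(genes)
    if k > len(all_gene_pvals):
        raise GeneSetError("gene set larger than the measured gene universe")
    if k < MIN_USABLE_SET:
        return GeneSetResult(name, k, float("nan"), float("nan"), float("nan"),
                             float("nan"), n_perm, seed, too_small=True)
    observed = all_gene_pvals.loc[genes].to_numpy()
    obs_ls = ls_stat(observed)
    obs_ks = ks_stat(observed)
    universe = _clamp_pvals(all_gene_pvals.to_numpy())
    rng = np.random.default_rng(seed)
    # vectorized null: one row of sampled indices per permutation
    null_ls = np.empty(n_perm)
    null_ks = np.empty(n_perm)
    ranks = np.arange(1, k + 1) / k
    for b in range(n_perm):
        draw = universe[rng.choice(len(universe), size=k, replace=False)]
        null_ls[b] = -np.log(draw).mean()
        null_ks[b] = max(0.0, np.max(ranks - np.sort(draw)))
    p_ls = (1 + int(np.sum(null_ls >= obs_ls))) / (1 + n_perm)
    p_ks = (1 + int(np.sum(null_ks >= obs_ks))) / (1 + n_perm)
    return GeneSetResult(name, k, obs_ls, obs_ks, p_ls, p_ks, n_perm, seed)


def random_set_control(
    all_gene_pvals: pd.Series,
    candidate: GeneSetResult,
    n_sets: int = 10,
    set_size: int = 44,
    n_perm: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Score random gene sets as a specificity control for a candidate set.

    Draws ``n_sets`` random sets of ``set_size`` genes, runs the full
    permutation machinery on each, and reports where the candidate's LS/KS
    p-values rank within the control distribution.
    """
    all_gene_pvals = pd.Series(all_gene_pvals)
    if set_size > len(all_gene_pvals):
        raise GeneSetError("set_size exceeds the measured gene universe")
    rng = np.random.default_rng(seed)
    rows = []
    genes = all_gene_pvals.index.to_numpy()
    for i in range(n_sets):
        members = rng.choice(genes, size=set_size, replace=False)
        res = permutation_pvalue(
            list(members), all_gene_pvals, n_perm=n_perm,
            seed=int(rng.integers(2**31 - 1)), name=f"random_{i + 1}",
        )
        rows.append((res.name, res.set_size, res.ls, res.ks, res.p_ls, res.p_ks))
    control = pd.DataFrame(rows, columns=["name", "set_size", "ls", "ks", "p_ls", "p_ks"])
    control.attrs["candidate_p_ls"] = candidate.p_ls
    control.attrs["candidate_p_ks"] = candidate.p_ks
    control.attrs["n_controls_below_candidate_ls"] = int((control["p_ls"] <= candidate.p_ls).sum())
    return control


def geneset_survival_analysis(
    matrix: ExpressionMatrix,
    survival: SurvivalData,
    target_map: GeneTargetMap,
    tier: str = "expansive",
    n_perm: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Score every miRNA's target set at one evidence tier against survival.

    The expansive-tier analysis first removes the 20% lowest-variance genes
    to reduce statistical noise; the restrictive tier runs unfiltered.  Sets
    with fewer than five usable genes are reported as too small.
    """
    if tier not in ("expansive", "restrictive"):
        raise GeneSetError(f"unknown tier {tier!r}")
    work = variance_filter(matrix, 0.20) if tier == "expansive" else matrix
    pvals = per_gene_pvalues(work, survival)["p"]
    sets = target_map.expansive if tier == "expansive" else target_map.restrictive
    rows = []
    rng = np.random.default_rng(seed)
    for mirna in sorted(sets):
        res = permutation_pvalue(
            sets[mirna], pvals, n_perm=n_perm,
            seed=int(rng.integers(2**31 - 1)), name=mirna,
        )
        rows.append(
            (mirna, tier, res.set_size, res.ls, res.ks, res.p_ls, res.p_ks, res.too_small)
        )
    return pd.DataFrame(
        rows,
        columns=["mirna", "tier", "set_size", "ls", "ks", "p_ls", "p_ks", "too_small"],
    )


def read_gmt(path) -> dict[str, set[str]]:
    """Read a GMT pathway collection (name, description, genes...)."""
    pathways: dict[str, set[str]] = {}
    with open(path, "rt", encoding="utf-8") as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            pathways[parts[0]] = set(parts[2:])
    return pathways


def ease_enrichment(
    gene_list: set[str] | list[str],
    background: set[str] | list[str],
    pathway_collection: dict[str, set[str]],
) -> pd.DataFrame:
    """EASE-penalized hypergeometric pathway enrichment with BH FDR.

    For each pathway the one-sided hypergeometric upper-tail p is computed on
    the 2x2 overlap table with the overlap cell decremented by one — the
    conservative EASE-score variant, so single-gene overlaps can never be
    significant (overlap of 0 or 1 gives p = 1).
    """
    background = set(background)
    if not background:
        raise GeneSetError("background gene universe is empty")
    gene_list = set(gene_list)
    if not gene_list <= background:
        raise GeneSetError("gene_list must be a subset of the background")
    n_bg = len(background)
    n_list = len(gene_list)
    rows = []
    for name in sorted(pathway_collection):
        members = pathway_collection[name] & background
        overlap = len(gene_list & members)
        if overlap <= 1:
            p = 1.0
        else:
            # P(X >= overlap - 1), X ~ Hypergeom(N=n_bg, K=|pathway|, n=n_list)
            p = float(stats.hypergeom.sf(overlap - 2, n_bg, len(members), n_list))
        rows.append((name, len(members), overlap, min(p, 1.0)))
    result = pd.DataFrame(rows, columns=["pathway", "pathway_size", "overlap", "ease_p"])
    result["bh_q"] = bh_fdr(result["ease_p"].to_numpy()) if len(result) else []
    return result


def bh_fdr(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone)."""
    pvals = np.asarray(pvals, dtype=float)
    if np.any((pvals < 0) | (pvals > 1)):
        raise GeneSetError("p-values must lie in [0, 1]")
    if pvals.size == 0:
        return pvals
    return multipletests(pvals, method="fdr_bh")[1]
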