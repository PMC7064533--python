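"""Staged pharmacogenomic drug screen against miRNA target networks.

The screen starts from gene-drug predictive associations (standardized
regression coefficient + p-value per drug/gene pair, as exported from a
pharmacogenomic database) and narrows the drug list in three stages:

1. association filter — keep pairs with |coefficient| > 0.25 and p < 0.001
   (strict inequalities; a relaxed mode uses 0.15 / 0.05),
2. network rule — keep drugs hitting at least three distinct genes of the
   broad (22-miRNA) target network and at least one gene of the core
   (5-miRNA) network,
3. sensitivity rule — among surviving drugs with IC50 measurements in
   osteosarcoma cell lines, keep those whose median IC50 does not exceed the
   median IC50 of a clinically active reference drug (cisplatin by default),
   ranked ascending by median IC50.

Each stage only removes drugs, so loosening any threshold can never shrink
the surviving set.
"""

from __future__ import annotations

import importlib.resources
import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


class PharmacoError(ValueError):
    pass


@dataclass(frozen=True)
class DrugFilterConfig:
    """Thresholds of the staged screen (defaults = the stringent mode)."""

    coef_threshold: float = 0.25
    p_threshold: float = 0.001
    min_hits_22: int = 3
    min_hits_5: int = 1
    top_n_targets: int = 20
    reference_drug: str = "cisplatin"
    limited_evidence_max_lines: int = 3

    def __post_init__(self) -> None:
        if self.coef_threshold <= 0 or self.p_threshold <= 0:
            raise PharmacoError("thresholds must be > 0")
        if self.min_hits_22 < 0 or self.min_hits_5 < 0:
            raise PharmacoError("min hit counts must be >= 0")

    def relaxed(self) -> "DrugFilterConfig":
        """The slightly relaxed but still robust mode (0.15 / 0.05)."""
        return replace(self, coef_threshold=0.15, p_threshold=0.05)


def rank_top_targets(
    per_gene_rfs_p: pd.Series,
    target_map,
    tier: str = "expansive",
    top_n: int = 20,
) -> dict[str, list[str]]:
    """Per miRNA, the top-``top_n`` target genes by survival-association p.

    Genes are ordered by ascending p with ties broken by gene id; miRNAs with
    fewer available targets keep them all, and miRNAs with no measured target
    are skipped with a log entry.
    """
    per_gene_rfs_p = pd.Series(per_gene_rfs_p)
    sets = target_map.expansive if tier == "expansive" else target_map.restrictive
    ranked: dict[str, list[str]] = {}
    for mirna in sorted(sets):
        genes = sorted(g for g in sets[mirna] if g in per_gene_rfs_p.index)
        missing = sets[mirna] - set(genes)
        if missing:
            logger.info("rank_top_targets: %s targets without p-values excluded: %s",
                        mirna, sorted(missing))
        if not genes:
            logger.warning("rank_top_targets: %s has no measured target, skipped", mirna)
            continue
        genes.sort(key=lambda g: (per_gene_rfs_p[g], g))
        ranked[mirna] = genes[:top_n]
    return ranked


def filter_associations(assoc: pd.DataFrame, config: DrugFilterConfig) -> pd.DataFrame:
    """Stage 1: keep rows with |coefficient| > threshold and p < threshold.

    Both inequalities are strict, so an association exactly at a threshold is
    excluded.
    """
    required = {"drug_id", "gene_id", "coefficient", "p"}
    if not required <= set(assoc.columns):
        raise PharmacoError(f"association table needs columns {sorted(required)}")
    mask = (assoc["coefficient"].abs() > config.coef_threshold) & (
        assoc["p"] < config.p_threshold
    )
    return assoc.loc[mask].copy()


def select_drugs(
    hits: pd.DataFrame,
    network_22_genes: set[str],
    network_5_genes: set[str],
    config: DrugFilterConfig,
) -> pd.DataFrame:
    """Stage 2: the network hit rule, counting distinct genes per drug.

    A drug is retained iff it hits at least ``min_hits_22`` distinct genes of
    the broad network and ``min_hits_5`` of the core network.  Returns a
    per-drug frame with hit counts, the median coefficient magnitude over the
    drug's passing associations, and the pass flag.
    """
    if not network_22_genes or not network_5_genes:
        raise PharmacoError("both gene networks must be nonempty")
    rows = []
    for drug, sub in hits.groupby("drug_id", sort=True):
        genes = set(sub["gene_id"])
        h22 = len(genes & network_22_genes)
        h5 = len(genes & network_5_genes)
        rows.append(
            (
                drug,
                h22,
                h5,
                float(sub["coefficient"].abs().median()),
                h22 >= config.min_hits_22 and h5 >= config.min_hits_5,
            )
        )
    return pd.DataFrame(
        rows, columns=["drug_id", "hits_22", "hits_5", "median_coefficient", "passes_network"]
    )


def rank_by_ic50(
    drugs: list[str],
    sensitivity: pd.DataFrame,
    config: DrugFilterConfig | None = None,
) -> pd.DataFrame:
    """Stage 3: median-IC50 ranking against the reference drug.

    Median IC50 (midpoint interpolation for even counts) is taken per drug
    over its available cell lines to blunt outliers.  Drugs with no
    measurements are flagged ``no sensitivity data`` and excluded from the
    pass decision; drugs measured in at most three cell lines are flagged
    limited-evidence.  The final list is the drugs whose median does not
    exceed the reference drug's median, sorted ascending.
    """
    config = config or DrugFilterConfig()
    required = {"drug_id", "cell_line_id", "ic50"}
    if not required <= set(sensitivity.columns):
        raise PharmacoError(f"sensitivity table needs columns {sorted(required)}")
    if (sensitivity["ic50"] <= 0).any() or ~np.isfinite(sensitivity["ic50"]).all():
        raise PharmacoError("IC50 values must be positive and finite")
    ref = sensitivity.loc[sensitivity["drug_id"] == config.reference_drug, "ic50"]
    if ref.empty:
        raise PharmacoError(
            f"reference drug {config.reference_drug!r} has no IC50 measurement"
        )
    ref_median = float(ref.median())
    rows = []
    for drug in drugs:
        values = sensitivity.loc[sensitivity["drug_id"] == drug, "ic50"]
        if values.empty:
            rows.append((drug, float("nan"), 0, False, False, "no sensitivity data"))
            continue
        med = float(values.median())
        n = int(len(values))
        flag = "limited evidence" if n <= config.limited_evidence_max_lines else ""
        rows.append((drug, med, n, True, med <= ref_median, flag))
    report = pd.DataFrame(
        rows,
        columns=["drug_id", "median_ic50", "n_cell_lines", "has_data", "passes_ic50", "flag"],
    )
    report.attrs["reference_drug"] = config.reference_drug
    report.attrs["reference_median_ic50"] = ref_median
    return report.sort_values(
        ["median_ic50", "drug_id"], na_position="last"
    ).reset_index(drop=True)


def run_drug_screen(
    assoc: pd.DataFrame,
    sensitivity: pd.DataFrame | None,
    network_22_genes: set[str],
    network_5_genes: set[str],
    config: DrugFilterConfig | None = None,
) -> pd.DataFrame:
    """Full staged screen; one row per drug with all stage flags.

    ``passes_stage1`` = at least one association surviving the coefficient/p
    filter; ``passes_stage2`` additionally satisfies the network hit rule;
    ``passes_stage3`` additionally has sensitivity data with median IC50 at
    or below the reference drug.  Stage flags are nested by construction.
    """
    config = config or DrugFilterConfig()
    hits = filter_associations(assoc, config)
    network = select_drugs(hits, network_22_genes, network_5_genes, config)
    report = network.rename(columns={"passes_network": "passes_stage2"})
    report["passes_stage1"] = True  # every row here had >= 1 passing association
    all_drugs = pd.Index(sorted(assoc["drug_id"].unique()))
    report = report.set_index("drug_id").reindex(all_drugs)
    report["hits_22"] = report["hits_22"].fillna(0).astype(int)
    report["hits_5"] = report["hits_5"].fillna(0).astype(int)
    report["passes_stage1"] = report["passes_stage1"].eq(True).astype(bool)
    report["passes_stage2"] = report["passes_stage2"].eq(True).astype(bool)
    report["passes_stage3"] = False
    report["median_ic50"] = float("nan")
    report["n_cell_lines"] = 0
    report["flag"] = ""
    if sensitivity is not None:
        stage2 = report.index[report["passes_stage2"]].tolist()
        ic50 = rank_by_ic50(stage2, sensitivity, config).set_index("drug_id")
        report.loc[ic50.index, "median_ic50"] = ic50["median_ic50"]
        report.loc[ic50.index, "n_cell_lines"] = ic50["n_cell_lines"]
        report.loc[ic50.index, "flag"] = ic50["flag"]
        report.loc[ic50.index, "passes_stage3"] = ic50["passes_ic50"] & ic50["has_data"]
        report.attrs.update(ic50.attrs)
    report = report.reset_index().rename(columns={"index": "drug_id"})
    report = report.sort_values(
        ["passes_stage3", "median_ic50", "drug_id"],
        ascending=[False, True, True],
        na_position="last",
    ).reset_index(drop=True)
    report["final_rank"] = np.where(
        report["passes_stage3"], np.arange(1, len(report) + 1), 0
    )
    return report


def published_drug_screen() -> pd.DataFrame:
    """The published osteosarcoma drug-screen summary shipped with the package.

    One row per drug with its class, median IC50 across osteosarcoma cell
    lines (micromolar) and median regression coefficient; the three
    ``comparative`` rows (methotrexate, etoposide, cisplatin) are standard
    chemotherapeutics listed for reference only, cisplatin serving as the
    sensitivity threshold.
    """
    with importlib.resources.files("osteomir.data").joinpath(
        "published_drug_screen.tsv"
    ).open("rt") as fh:
        return pd.read_csv(fh, sep="\t")


def published_final_selection(config: DrugFilterConfig | None = None) -> pd.DataFrame:
    """Re-run the final IC50 selection stage on the published screen summary.

    Rebuilds a sensitivity table from the published per-drug median IC50
    column (each median standing in for the drug's cell-line measurements)
    and applies the cisplatin-referenced selection to the candidate drugs.
    """
    config = config or DrugFilterConfig()
    table = published_drug_screen()
    sensitivity = pd.DataFrame(
        {
            "drug_id": table["name"],
            "cell_line_id": "published_median",
            "ic50": table["median_ic50_um"],
        }
    )
    candidates = table.loc[table["role"] == "candidate", "name"].tolist()
    report = rank_by_ic50(candidates, sensitivity, config)
    return report[report["passes_ic50"]].reset_index(drop=True)
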