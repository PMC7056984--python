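"""Dosage-compensation ratios and expression breadth.

Dosage compensation is quantified as ratios of median expression between
the X chromosome and autosomes within a tissue, and between tissues
within a chromosome class: X_Ts/A_Ts, X_Ov/A_Ov and analogues for the
gonadectomised soma (GTM/GTF). The autosomal side is by default the
median of the nine per-autosome medians ("median_of_medians"), with a
pooled-gene alternative; Mann-Whitney p-values always compare the pooled
gene-level distributions. Genes without a chromosome assignment are
excluded from these analyses.

Expression breadth counts, per gene, the tissues whose average FPKM
exceeds a floor (strictly greater than 1 FPKM by default); the class
summary reports the fraction of genes expressed in all four tissues.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .expression import TISSUES
from .stats import mwu_test, sign_test

logger = logging.getLogger(__name__)


def chrom_median_expression(
    tissue_avgs: pd.DataFrame,
    gene_map: pd.Series,
    tissue: str,
) -> pd.Series:
    """Median tissue-average FPKM per chromosome (unmapped genes excluded)."""
    if tissue not in tissue_avgs.columns:
        raise ValueError(f"missing tissue {tissue}")
    chrom = gene_map.reindex(tissue_avgs.index).fillna("unmapped")
    keep = chrom != "unmapped"
    grouped = tissue_avgs.loc[keep, tissue].groupby(chrom[keep]).median()
    return grouped


@dataclass
class DosageReport:
    medians: pd.DataFrame  # chromosome x tissue medians
    ratios: dict[str, float]
    mwu_p: dict[str, float]
    aggregation: str = "median_of_medians"
    extras: dict = field(default_factory=dict)


def _x_and_a(values: pd.Series, chrom: pd.Series) -> tuple[np.ndarray, np.ndarray]:
    on_x = chrom == "X"
    auto = (~on_x) & (chrom != "unmapped")
    return values[on_x].to_numpy(float), values[auto].to_numpy(float)


def dosage_ratios(
    tissue_avgs: pd.DataFrame,
    gene_map: pd.Series,
    aggregation: str = "median_of_medians",
) -> DosageReport:
    """All eight dosage ratios with MWU p-values.

    The A-side summary is either the median of per-autosome medians
    (default) or the median over pooled autosomal genes. Within-tissue
    X/A comparisons get an MWU p on X vs pooled-autosome gene values;
    between-tissue comparisons (e.g. X_Ts/X_Ov) on the two tissues' gene
    values within the chromosome class.
    """
    if aggregation not in ("median_of_medians", "pooled_genes"):
        raise ValueError(f"unknown aggregation {aggregation!r}")
    for t in TISSUES:
        if t not in tissue_avgs.columns:
            raise ValueError(f"missing tissue {t}")
    chrom = gene_map.reindex(tissue_avgs.index).fillna("unmapped")
    mapped = chrom != "unmapped"
    medians = (
        tissue_avgs.loc[mapped]
        .groupby(chrom[mapped])
        .median()
        .loc[:, list(TISSUES)]
    )
    if "X" not in medians.index or len(medians.index) < 2:
        raise ValueError("need medians for X and at least one autosome")

    def a_side(tissue: str) -> float:
        if aggregation == "median_of_medians":
            return float(medians.loc[medians.index != "X", tissue].median())
        vals = tissue_avgs.loc[mapped & (chrom != "X"), tissue]
        return float(vals.median())

    x_med = {t: float(medians.loc["X", t]) for t in TISSUES}
    a_med = {t: a_side(t) for t in TISSUES}

    ratios: dict[str, float] = {}
    pvals: dict[str, float] = {}
    # within-tissue X vs A
    for t, name in (("TS", "X_Ts/A_Ts"), ("OV", "X_Ov/A_Ov"),
                    ("GTM", "X_GTM/A_GTM"), ("GTF", "X_GTF/A_GTF")):
        x_vals, a_vals = _x_and_a(tissue_avgs[t], chrom)
        ratios[name] = x_med[t] / a_med[t]
        pvals[name] = mwu_test(x_vals, a_vals)
    # between-tissue within chromosome class
    x_mask = chrom == "X"
    a_mask = mapped & ~x_mask
    for (t1, t2), name, mask in (
        (("TS", "OV"), "X_Ts/X_Ov", x_mask),
        (("TS", "OV"), "A_Ts/A_Ov", a_mask),
        (("GTM", "GTF"), "X_GTM/X_GTF", x_mask),
        (("GTM", "GTF"), "A_GTM/A_GTF", a_mask),
    ):
        num = x_med[t1] if mask is x_mask else a_med[t1]
        den = x_med[t2] if mask is x_mask else a_med[t2]
        ratios[name] = num / den
        pvals[name] = mwu_test(
            tissue_avgs.loc[mask, t1], tissue_avgs.loc[mask, t2]
        )
    return DosageReport(medians=medians, ratios=ratios, mwu_p=pvals,
                        aggregation=aggregation)


def expression_breadth(
    tissue_avgs: pd.DataFrame, threshold: float = 1.0
) -> pd.Series:
    """Per-gene count of tissues with average FPKM strictly above the
    threshold."""
    return (tissue_avgs[list(TISSUES)] > threshold).sum(axis=1)


@dataclass
class BreadthSummary:
    label: str
    n: int
    fraction_all_tissues: float


def summarize_breadth(
    breadth: pd.Series, calls: pd.DataFrame, class_col: str = "gonad_class"
) -> list[BreadthSummary]:
    """Fraction of each class expressed in all four tissues."""
    out = []
    for label, idx in calls.groupby(class_col).groups.items():
        b = breadth.reindex(idx).dropna()
        frac = float((b == 4).mean()) if len(b) else float("nan")
        out.append(BreadthSummary(str(label), int(len(b)), frac))
    return out


def unbiased_direction_fraction(
    tissue_avgs: pd.DataFrame,
    calls: pd.DataFrame,
    gene_map: pd.Series,
    chromosome: str = "X",
) -> tuple[int, int, float]:
    """Among gonad-unbiased genes on a chromosome, how many are
    male-higher (testis average above ovary average)?

    Returns (n_higher_in_male, n_total, sign-test p against 0.5).
    """
    chrom = gene_map.reindex(tissue_avgs.index).fillna("unmapped")
    unbiased = calls.index[calls["gonad_class"] == "unbiased"]
    sel = tissue_avgs.loc[
        tissue_avgs.index.intersection(unbiased)[
            chrom.loc[tissue_avgs.index.intersection(unbiased)] == chromosome
        ]
    ]
    n_total = int(len(sel))
    if n_total == 0:
        return 0, 0, float("nan")
    n_male = int((sel["TS"] > sel["OV"]).sum())
    return n_male, n_total, sign_test(n_male, n_total)
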