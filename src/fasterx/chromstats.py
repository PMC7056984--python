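"""X-versus-autosome comparisons of dN/dS stratified by sex-bias class.

For each stratum (all genes; ovary-, testis-, gonad-unbiased; GT-female-,
GT-male-, GT-unbiased) the X-linked and pooled-autosomal gene sets are
summarised by their median dN/dS with a percentile-bootstrap confidence
interval, and compared through the ratio of medians (or means) and a
Mann-Whitney U test. Genes without a chromosome assignment are pooled
with the autosomes by default (the annotation's unmapped scaffolds are
overwhelmingly autosomal), with a flag to exclude them instead. Genes
whose omega is undefined (dS = 0) are excluded from omega summaries and
counted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stats import bootstrap_median_ci, mwu_test

logger = logging.getLogger(__name__)


@dataclass
class ChromosomeSummary:
    stratum: str
    group: str  # "X" or "A"
    n: int
    median: float
    mean: float
    ci_low: float
    ci_high: float


@dataclass
class RatioResult:
    name: str
    numerator_stat: float
    denominator_stat: float
    ratio: float
    statistic_kind: str
    mwu_p: float


def split_x_autosome(
    values: pd.Series,
    chromosomes: pd.Series,
    exclude_unmapped: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Split a per-gene series into X-linked and (pooled) autosomal arrays."""
    chrom = chromosomes.reindex(values.index).fillna("unmapped")
    on_x = chrom == "X"
    if exclude_unmapped:
        auto = ~on_x & (chrom != "unmapped")
    else:
        auto = ~on_x
    return values[on_x].to_numpy(float), values[auto].to_numpy(float)


def xa_ratio(
    x_values,
    a_values,
    statistic: str = "median",
    name: str = "X/A",
) -> RatioResult:
    """Ratio of a summary statistic between X and autosomal gene sets.

    Computed at full precision from the unrounded statistics; the MWU
    p-value compares the underlying gene-level distributions.
    """
    x = np.asarray(x_values, dtype=float)
    a = np.asarray(a_values, dtype=float)
    if x.size == 0 or a.size == 0:
        raise ValueError("both strata must be nonempty")
    stat = np.median if statistic == "median" else np.mean
    if statistic not in ("median", "mean"):
        raise ValueError("statistic must be 'median' or 'mean'")
    num = float(stat(x))
    den = float(stat(a))
    if den == 0.0:
        raise ValueError("autosomal statistic is zero: ratio undefined")
    return RatioResult(
        name=name,
        numerator_stat=num,
        denominator_stat=den,
        ratio=num / den,
        statistic_kind=statistic,
        mwu_p=mwu_test(x, a),
    )


#: (stratum label, contrast column, class value) — None matches all genes
STRATA: list[tuple[str, str | None, str | None]] = [
    ("all genes", None, None),
    ("ovary-biased", "gonad_class", "ovary-biased"),
    ("testis-biased", "gonad_class", "testis-biased"),
    ("gonad-unbiased", "gonad_class", "unbiased"),
    ("GT-female-biased", "gt_class", "GT-female-biased"),
    ("GT-male-biased", "gt_class", "GT-male-biased"),
    ("GT-unbiased", "gt_class", "unbiased"),
]


def stratified_dnds_table(
    dnds: pd.DataFrame,
    gene_map: pd.Series,
    calls: pd.DataFrame,
    n_boot: int = 1000,
    seed: int = 0,
    exclude_unmapped: bool = False,
) -> tuple[list[ChromosomeSummary], list[RatioResult]]:
    """Per-stratum X and autosome summaries plus X/A ratio results.

    ``dnds`` must contain an ``omega`` column indexed by gene (NaN where
    undefined); ``gene_map`` maps gene -> chromosome; ``calls`` carries
    ``gonad_class`` and ``gt_class`` columns. A gene biased in both
    contrasts contributes to both contrasts' strata. Empty strata yield
    n = 0 rows with NaN statistics.
    """
    omega = dnds["omega"]
    n_undef = int(omega.isna().sum())
    if n_undef:
        logger.info("%d genes with undefined omega (dS = 0) excluded", n_undef)
    omega = omega.dropna()
    summaries: list[ChromosomeSummary] = []
    ratios: list[RatioResult] = []
    for i, (label, col, value) in enumerate(STRATA):
        if col is None:
            sel = omega
        else:
            in_class = calls.index[calls[col] == value]
            sel = omega.loc[omega.index.intersection(in_class)]
        x, a = split_x_autosome(sel, gene_map, exclude_unmapped=exclude_unmapped)
        for group, vals in (("X", x), ("A", a)):
            if vals.size == 0:
                logger.warning("empty stratum %s/%s", label, group)
                summaries.append(
                    ChromosomeSummary(label, group, 0, np.nan, np.nan,
                                      np.nan, np.nan)
                )
                continue
            med, lo, hi = bootstrap_median_ci(
                vals, n_boot=n_boot, seed=seed + i
            )
            summaries.append(
                ChromosomeSummary(label, group, int(vals.size), med,
                                  float(vals.mean()), lo, hi)
            )
        if x.size and a.size:
            ratios.append(
                xa_ratio(x, a, "median", name=f"X/A_dN/dS({label})")
            )
    return summaries, ratios


def summaries_frame(summaries: list[ChromosomeSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (s.stratum, s.group, s.n, s.median, s.mean, s.ci_low, s.ci_high)
            for s in summaries
        ],
        columns=["stratum", "group", "n", "median", "mean", "ci_low", "ci_high"],
    )


def ratios_frame(ratios: list[RatioResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (r.name, r.numerator_stat, r.denominator_stat, r.ratio,
             r.statistic_kind, r.mwu_p)
            for r in ratios
        ],
        columns=["name", "x_stat", "a_stat", "ratio", "statistic", "mwu_p"],
    )
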