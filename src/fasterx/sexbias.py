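"""Differential expression between tissue pairs and sex-bias classification.

A gene is sex-biased for a contrast (testis vs ovary, or gonadectomised
male vs female soma) when its average FPKM differs at least twofold
between the two tissues, the negative-binomial test gives p < 0.05, and
the higher of the two tissue averages is at least 1 FPKM. All other genes
are unbiased. P-values are unadjusted by default, with optional
Benjamini-Hochberg correction behind a flag.

The test is an in-package negative-binomial Wald test: median-of-ratios
size factors, gene-wise method-of-moments dispersions shrunk toward a
mean-dispersion trend, and a Wald statistic on the log fold change. It
approximates, rather than reproduces bit-for-bit, the shrinkage-based
DE packages commonly used for such designs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

CONTRASTS = {"gonad": ("OV", "TS"), "gtsoma": ("GTF", "GTM")}
# prior weight (pseudo-genes) pulling gene-wise dispersions to the trend;
# with two replicates per group the gene-wise estimate has ~2 df, so the
# trend dominates, as it should
_PRIOR_WEIGHT = 10.0


@dataclass
class SexBiasCall:
    gene_id: str
    contrast: str
    label: str  # female-biased / male-biased / unbiased
    fold_change: float
    p_value: float
    avg_f: float
    avg_m: float


def size_factors(counts: np.ndarray) -> np.ndarray:
    """Median-of-ratios size factors over genes with nonzero geometric mean."""
    logc = np.log(counts, out=np.full(counts.shape, -np.inf), where=counts > 0)
    log_geo = logc.mean(axis=1)
    usable = np.isfinite(log_geo)
    if not usable.any():
        raise ValueError("no gene has nonzero counts in every sample")
    ratios = logc[usable] - log_geo[usable, None]
    sf = np.exp(np.median(ratios, axis=0))
    return sf / np.exp(np.mean(np.log(sf)))


def _trend_dispersion(mean: np.ndarray, disp: np.ndarray) -> np.ndarray:
    """Fit alpha(mu) = a0 + a1/mu to gene-wise dispersions (robust, two
    rounds of trimming) and evaluate it at each gene's mean."""
    ok = (mean > 0) & (disp > 1e-8)
    if ok.sum() < 10:
        fallback = float(np.median(disp[disp > 0])) if (disp > 0).any() else 0.01
        return np.full_like(mean, max(fallback, 1e-8))
    x = 1.0 / mean[ok]
    y = disp[ok]
    keep = np.ones(len(y), dtype=bool)
    a0, a1 = np.median(y), 0.0
    for _ in range(2):
        A = np.vstack([np.ones(keep.sum()), x[keep]]).T
        coef, *_ = np.linalg.lstsq(A, y[keep], rcond=None)
        a0, a1 = coef
        resid = y - (a0 + a1 * x)
        cut = 3.0 * np.median(np.abs(resid)) + 1e-12
        keep = np.abs(resid) < cut
        if keep.sum() < 10:
            break
    fitted = a0 + a1 / np.maximum(mean, 1e-8)
    return np.clip(fitted, 1e-8, None)


def nb_two_group_test(
    counts_group1: np.ndarray,
    counts_group2: np.ndarray,
    library_sizes: np.ndarray | None = None,
) -> np.ndarray:
    """Two-sided NB Wald p-values for equal means, vectorised over genes.

    ``counts_group1``/``counts_group2`` are (genes x replicates) integer
    arrays. Size factors are median-of-ratios over the combined matrix
    unless ``library_sizes`` (per sample, ordered group1 then group2) is
    given, in which case factors are proportional to it. All-zero genes
    get p = 1.0.
    """
    g1 = np.atleast_2d(np.asarray(counts_group1, dtype=float))
    g2 = np.atleast_2d(np.asarray(counts_group2, dtype=float))
    if g1.shape[1] < 2 or g2.shape[1] < 2:
        logger.warning("fewer than 2 replicates per group: test is degenerate")
    combined = np.hstack([g1, g2])
    if library_sizes is not None:
        sf = np.asarray(library_sizes, dtype=float)
        sf = sf / np.exp(np.mean(np.log(sf)))
    else:
        sf = size_factors(combined)
    n1 = g1.shape[1]
    q1 = g1 / sf[None, :n1]
    q2 = g2 / sf[None, n1:]
    mu1 = q1.mean(axis=1)
    mu2 = q2.mean(axis=1)
    mu = np.hstack([q1, q2]).mean(axis=1)

    # gene-wise method-of-moments dispersion from within-group variability
    var_w = (q1.var(axis=1, ddof=1) * (n1 - 1)
             + q2.var(axis=1, ddof=1) * (q2.shape[1] - 1)) / max(
        n1 + q2.shape[1] - 2, 1
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        disp_gene = np.where(mu > 0, (var_w - mu) / mu**2, 0.0)
    disp_gene = np.clip(disp_gene, 0.0, 10.0)
    disp_trend = _trend_dispersion(mu, disp_gene)
    w = max(n1 + g2.shape[1] - 2, 1)
    disp = (w * disp_gene + _PRIOR_WEIGHT * disp_trend) / (w + _PRIOR_WEIGHT)

    # Wald statistic on log(mu2/mu1); delta-method variance of log group
    # means under NB(mu, disp): Var(log muhat) ~ (1/mu + disp) / n
    eps = 0.5  # stabilises the log for very low means
    lfc = np.log(mu2 + eps) - np.log(mu1 + eps)
    se2 = (1.0 / np.maximum(mu1, eps) + disp) / n1 + (
        1.0 / np.maximum(mu2, eps) + disp
    ) / g2.shape[1]
    z = lfc / np.sqrt(se2)
    p = 2.0 * stats.norm.sf(np.abs(z))
    allzero = (g1.sum(axis=1) + g2.sum(axis=1)) == 0
    if allzero.any():
        logger.info("%d all-zero genes reported with p = 1.0", allzero.sum())
        p[allzero] = 1.0
    return np.clip(p, 0.0, 1.0)


def classify_sex_bias(
    avg_fpkm_f: float,
    avg_fpkm_m: float,
    p_value: float,
    fold: float = 2.0,
    alpha: float = 0.05,
    fpkm_floor: float = 1.0,
) -> str:
    """Three-way label from the two tissue averages and the test p-value.

    A zero denominator makes the fold change infinite, which counts as
    passing the fold threshold if the other criteria hold.
    """
    if avg_fpkm_f < 0 or avg_fpkm_m < 0:
        raise ValueError("tissue-average FPKM must be nonnegative")
    if p_value >= alpha or max(avg_fpkm_f, avg_fpkm_m) < fpkm_floor:
        return "unbiased"
    if avg_fpkm_f >= fold * avg_fpkm_m and avg_fpkm_f > 0:
        return "female-biased"
    if avg_fpkm_m >= fold * avg_fpkm_f and avg_fpkm_m > 0:
        return "male-biased"
    return "unbiased"


def classify_contrast(
    tissue_avgs: pd.DataFrame,
    counts: pd.DataFrame,
    contrast: str,
    fold: float = 2.0,
    alpha: float = 0.05,
    fpkm_floor: float = 1.0,
    adjust_p: bool = False,
) -> pd.DataFrame:
    """Classify every gene for one contrast.

    ``tissue_avgs`` holds tissue-average FPKM (columns TS, OV, GTM, GTF);
    ``counts`` the raw count matrix with ``TISSUE_rep`` columns. Returns a
    frame with columns label, fold_change, p_value, avg_f, avg_m indexed
    by gene. Class names follow the contrast (ovary-/testis-biased for the
    gonad, GT-female-/GT-male-biased for the soma).
    """
    if contrast not in CONTRASTS:
        raise ValueError(f"unknown contrast {contrast!r}")
    f_tis, m_tis = CONTRASTS[contrast]
    f_cols = [c for c in counts.columns if c.rsplit("_", 1)[0] == f_tis]
    m_cols = [c for c in counts.columns if c.rsplit("_", 1)[0] == m_tis]
    p = nb_two_group_test(counts[f_cols].to_numpy(), counts[m_cols].to_numpy())
    if adjust_p:
        from scipy.stats import false_discovery_control

        p = false_discovery_control(p, method="bh")
    avg_f = tissue_avgs[f_tis].to_numpy()
    avg_m = tissue_avgs[m_tis].to_numpy()
    labels = [
        classify_sex_bias(f, m, pv, fold=fold, alpha=alpha, fpkm_floor=fpkm_floor)
        for f, m, pv in zip(avg_f, avg_m, p)
    ]
    female_name = "ovary-biased" if contrast == "gonad" else "GT-female-biased"
    male_name = "testis-biased" if contrast == "gonad" else "GT-male-biased"
    rename = {"female-biased": female_name, "male-biased": male_name}
    with np.errstate(divide="ignore", invalid="ignore"):
        fc = np.maximum(avg_f, avg_m) / np.minimum(avg_f, avg_m)
    return pd.DataFrame(
        {
            "label": [rename.get(l, l) for l in labels],
            "fold_change": fc,
            "p_value": p,
            "avg_f": avg_f,
            "avg_m": avg_m,
        },
        index=tissue_avgs.index,
    )


def summarize_class_fractions(calls: pd.DataFrame, universe=None) -> pd.DataFrame:
    """Counts and percentages per class for one contrast's calls."""
    if universe is not None:
        calls = calls.loc[calls.index.intersection(universe)]
    n = len(calls)
    rows = []
    for label, cnt in calls["label"].value_counts().items():
        rows.append({"label": label, "n": int(cnt),
                     "percent": 100.0 * cnt / n if n else float("nan")})
    return pd.DataFrame(rows, columns=["label", "n", "percent"])
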