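"""Read-count to FPKM conversion, replicate QC, and per-tissue averaging.

FPKM here is reads per kilobase of coding sequence per million mapped
reads, with the library size taken as the per-sample column sum of counts
over the CDS set (reads were mapped to CDS, not the genome) and gene
length taken as the CDS length used for mapping.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

TISSUES = ("TS", "OV", "GTM", "GTF")


def fpkm(counts, gene_length_nt, library_size):
    """FPKM = counts x 1e9 / (library_size x gene_length_nt).

    Accepts scalars or aligned arrays. No pseudocounts are added.
    """
    library_size = np.asarray(library_size, dtype=float)
    gene_length_nt = np.asarray(gene_length_nt, dtype=float)
    if np.any(library_size <= 0):
        raise ValueError("library size must be positive")
    if np.any(gene_length_nt <= 0):
        raise ValueError("gene length must be positive")
    return np.asarray(counts, dtype=float) * 1e9 / (library_size * gene_length_nt)


def fpkm_matrix(counts: pd.DataFrame, gene_length_nt: pd.Series) -> pd.DataFrame:
    """Per-sample FPKM for a genes x samples count matrix.

    ``gene_length_nt`` is aligned on the count matrix index; missing
    lengths raise.
    """
    lengths = gene_length_nt.reindex(counts.index)
    if lengths.isna().any():
        missing = list(counts.index[lengths.isna()][:5])
        raise ValueError(f"missing CDS length for genes {missing}")
    lib = counts.sum(axis=0)
    vals = fpkm(
        counts.to_numpy(dtype=float),
        lengths.to_numpy(dtype=float)[:, None],
        lib.to_numpy(dtype=float)[None, :],
    )
    return pd.DataFrame(vals, index=counts.index, columns=counts.columns)


def _tissue_of(sample: str) -> str:
    return sample.rsplit("_", 1)[0]


def replicate_concordance(fpkm_table: pd.DataFrame, tissue: str) -> float:
    """Spearman correlation of the first two replicates of a tissue.

    Returns NaN (and logs a QC failure) when either replicate vector is
    constant, which leaves the rank correlation undefined.
    """
    cols = [c for c in fpkm_table.columns if _tissue_of(c) == tissue]
    if len(cols) < 2:
        raise ValueError(f"tissue {tissue} has fewer than 2 replicates")
    x, y = fpkm_table[cols[0]], fpkm_table[cols[1]]
    if x.nunique() <= 1 or y.nunique() <= 1:
        logger.warning("QC failure: constant replicate vector for %s", tissue)
        return float("nan")
    rho = stats.spearmanr(x, y).statistic
    return float(rho)


def qc_all_tissues(fpkm_table: pd.DataFrame, warn_below: float = 0.91
                   ) -> dict[str, float]:
    """Replicate concordance per tissue, warning below the QC threshold."""
    out = {}
    for t in TISSUES:
        rho = replicate_concordance(fpkm_table, t)
        out[t] = rho
        if not np.isfinite(rho) or rho < warn_below:
            logger.warning("replicate concordance for %s is %.3f (< %.2f)",
                           t, rho, warn_below)
    return out


def average_replicates(fpkm_table: pd.DataFrame) -> pd.DataFrame:
    """Arithmetic mean FPKM per gene per tissue (columns TS, OV, GTM, GTF)."""
    by_tissue = {}
    for t in TISSUES:
        cols = [c for c in fpkm_table.columns if _tissue_of(c) == t]
        if not cols:
            raise ValueError(f"missing tissue {t} in FPKM table")
        if len(cols) == 1:
            logger.warning("tissue %s has a single replicate", t)
        by_tissue[t] = fpkm_table[cols].mean(axis=1)
    return pd.DataFrame(by_tissue)
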