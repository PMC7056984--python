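"""End-to-end orchestration: files in, tables out.

``run_all`` executes the stages in dependency order — (optional)
simulation, CDS validation, reciprocal-best-hit orthology, codon
alignment + dN/dS, FPKM, sex-bias classification, X-vs-autosome dN/dS
stratification, dosage/breadth — writing every intermediate as plain TSV
so each stage is independently auditable, plus a JSON run manifest with
the full configuration and per-stage record counts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import align, chromstats, dnds, dosage, expression, orthology, sexbias
from .simulate import CodonSimParams, ExprSimParams, FixtureParams, emit_fixture_bundle

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All thresholds and switches of one pipeline run.

    Defaults are the analysis' canonical values: e-value ceiling 1e-6,
    dN/dS retention bound 1.5, minimum alignment length 33 aa, twofold
    change at alpha 0.05 with a 1-FPKM floor for sex bias, breadth floor
    1 FPKM, 1000 bootstrap replicates.
    """

    out_dir: str = "results/run"
    cds_a: str = ""
    cds_b: str = ""
    gene_map: str = ""
    counts: str = ""
    fwd_hits: str = ""
    rev_hits: str = ""

    evalue_max: float = 1e-6
    max_d: float = 1.5
    min_aa: int = 33
    fold: float = 2.0
    alpha: float = 0.05
    fpkm_floor: float = 1.0
    breadth_threshold: float = 1.0
    n_boot: int = 1000
    seed: int = 0

    exclude_unmapped: bool = False
    disable_block_filter: bool = False
    aggregation: str = "median_of_medians"
    dnds_method: str = "yn00"
    universe: str = "orthologs"  # or "all" for expression analyses

    simulate: bool = False
    sim_n_genes: int = 500
    sim_n_codons: int = 300
    sim_kappa: float = 2.0
    sim_omega: float = 0.2
    sim_omega_log_sd: float = 0.5
    sim_branch_length: float = 0.15
    sim_x_omega_multiplier: float = 1.0
    sim_male_x_dosage_factor: float = 1.0
    sim_fold_change: float = 8.0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class RunResult:
    config: RunConfig
    stage_counts: dict[str, int] = field(default_factory=dict)
    tables: dict[str, pd.DataFrame] = field(default_factory=dict)
    scalars: dict[str, float] = field(default_factory=dict)
    manifest_path: Path | None = None


def _config_hash(cfg: RunConfig) -> str:
    return hashlib.sha256(
        json.dumps(cfg.to_dict(), sort_keys=True).encode()
    ).hexdigest()[:12]


def _write(df: pd.DataFrame, path: Path, cfg_hash: str, index: bool = False) -> None:
    with open(path, "w") as fh:
        fh.write(f"# fasterx 0.1.0 config={cfg_hash}\n")
        df.to_csv(fh, sep="\t", index=index)


class StageError(RuntimeError):
    def __init__(self, stage: str, msg: str):
        super().__init__(f"stage '{stage}' failed: {msg}")
        self.stage = stage


def _simulate_stage(cfg: RunConfig, out: Path) -> None:
    fix_dir = out / "fixtures"
    codon_p = CodonSimParams(
        n_codons=cfg.sim_n_codons,
        kappa=cfg.sim_kappa,
        omega=cfg.sim_omega,
        branch_length=cfg.sim_branch_length,
        seed=cfg.seed,
    )
    expr_p = ExprSimParams(
        n_genes=cfg.sim_n_genes,
        male_X_dosage_factor=cfg.sim_male_x_dosage_factor,
        fold_change=cfg.sim_fold_change,
        seed=cfg.seed + 1,
    )
    fix_p = FixtureParams(
        x_omega_multiplier=cfg.sim_x_omega_multiplier,
        base_omega=cfg.sim_omega,
        omega_log_sd=cfg.sim_omega_log_sd,
    )
    paths = emit_fixture_bundle(codon_p, expr_p, fix_dir, fix_p)
    cfg.cds_a = str(paths["species_a.fasta"])
    cfg.cds_b = str(paths["species_b.fasta"])
    cfg.gene_map = str(paths["gene_map.tsv"])
    cfg.counts = str(paths["counts.tsv"])
    cfg.fwd_hits = str(paths["fwd_hits.tsv"])
    cfg.rev_hits = str(paths["rev_hits.tsv"])


def compute_dnds_table(
    pairs: list[orthology.OrthologPair],
    seqs_a: dict[str, str],
    seqs_b: dict[str, str],
    method: str = "yn00",
    max_d: float = 1.5,
    min_aa: int = 33,
    disable_block_filter: bool = False,
) -> pd.DataFrame:
    """Align each ortholog pair, filter, estimate dN/dS, apply retention."""
    estimator = dnds.dnds_yn00 if method == "yn00" else dnds.dnds_ng86
    rows = []
    for p in pairs:
        try:
            aln = align.align_codon_pair(
                seqs_a[p.gene_a], seqs_b[p.gene_b], p.gene_a, p.gene_b
            )
        except (ValueError, KeyError) as exc:
            logger.warning("pair %s-%s dropped: %s", p.gene_a, p.gene_b, exc)
            continue
        aln = align.strip_gaps(aln)
        if not disable_block_filter:
            aln = align.filter_divergent_blocks(aln)
        if aln.n_codons == 0:
            logger.warning("pair %s-%s dropped: empty after filtering",
                           p.gene_a, p.gene_b)
            continue
        est = estimator(aln)
        rows.append(
            {
                "gene_a": p.gene_a,
                "gene_b": p.gene_b,
                "n_codons": aln.n_codons,
                "S_sites": est.S_sites,
                "N_sites": est.N_sites,
                "kappa": est.kappa,
                "dN": est.dN,
                "dS": est.dS,
                "omega": est.omega if est.omega is not None else np.nan,
                "method": est.method,
                "retained": dnds.retain_pair(est, aln, max_d=max_d, min_aa=min_aa),
            }
        )
    return pd.DataFrame(rows)


def run_all(config: RunConfig) -> RunResult:
    """Run every stage; returns tables, stage counts and headline scalars."""
    cfg = dataclasses.replace(config)
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result = RunResult(config=cfg)
    counts_log = result.stage_counts

    if cfg.simulate:
        _simulate_stage(cfg, out)
    cfg_hash = _config_hash(cfg)

    # --- orthology ---------------------------------------------------------
    stage = "orthologs"
    try:
        recs_a = orthology.filter_valid_cds(
            orthology.read_fasta_records(cfg.cds_a, "A"), min_aa=cfg.min_aa
        )
        recs_b = orthology.filter_valid_cds(
            orthology.read_fasta_records(cfg.cds_b, "B"), min_aa=cfg.min_aa
        )
        seqs_a = {r.gene_id: r.sequence for r in orthology.longest_valid_per_gene(recs_a)}
        seqs_b = {r.gene_id: r.sequence for r in orthology.longest_valid_per_gene(recs_b)}
        counts_log["genes_a"] = len(recs_a)
        counts_log["genes_b"] = len(recs_b)
        counts_log["valid_cds_a"] = len(seqs_a)
        counts_log["valid_cds_b"] = len(seqs_b)
        pairs = orthology.reciprocal_best_hits(
            orthology.read_blast6(cfg.fwd_hits),
            orthology.read_blast6(cfg.rev_hits),
            evalue_max=cfg.evalue_max,
        )
        pairs = [p for p in pairs if p.gene_a in seqs_a and p.gene_b in seqs_b]
        counts_log["ortholog_pairs"] = len(pairs)
        orthology.write_pairs(pairs, out / "orthologs.tsv")
    except (OSError, ValueError, KeyError) as exc:
        raise StageError(stage, str(exc)) from exc

    # --- alignment + dN/dS -------------------------------------------------
    stage = "align-dnds"
    try:
        dnds_df = compute_dnds_table(
            pairs, seqs_a, seqs_b,
            method=cfg.dnds_method, max_d=cfg.max_d, min_aa=cfg.min_aa,
            disable_block_filter=cfg.disable_block_filter,
        )
        counts_log["retained_pairs"] = int(dnds_df["retained"].sum()) if len(dnds_df) else 0
        _write(dnds_df, out / "dnds.tsv", cfg_hash)
    except (ValueError, KeyError) as exc:
        raise StageError(stage, str(exc)) from exc

    # --- expression --------------------------------------------------------
    stage = "fpkm"
    try:
        counts_df = pd.read_csv(cfg.counts, sep="\t", index_col=0, comment="#")
        gene_map_df = pd.read_csv(cfg.gene_map, sep="\t", comment="#")
        gene_map = gene_map_df.set_index("gene_id")["chromosome"]
        lengths = gene_map_df.set_index("gene_id")["cds_length_nt"]
        fpkm_df = expression.fpkm_matrix(counts_df, lengths)
        expression.qc_all_tissues(fpkm_df)
        tissue_avgs = expression.average_replicates(fpkm_df)
        counts_log["expressed_genes"] = int(len(tissue_avgs))
        _write(tissue_avgs, out / "fpkm_tissue_avg.tsv", cfg_hash, index=True)
    except (OSError, ValueError, KeyError) as exc:
        raise StageError(stage, str(exc)) from exc

    # --- sex-bias classification ------------------------------------------
    stage = "classify"
    try:
        gonad = sexbias.classify_contrast(
            tissue_avgs, counts_df, "gonad",
            fold=cfg.fold, alpha=cfg.alpha, fpkm_floor=cfg.fpkm_floor,
        )
        gtsoma = sexbias.classify_contrast(
            tissue_avgs, counts_df, "gtsoma",
            fold=cfg.fold, alpha=cfg.alpha, fpkm_floor=cfg.fpkm_floor,
        )
        calls = pd.DataFrame(
            {"gonad_class": gonad["label"], "gt_class": gtsoma["label"]}
        )
        for name, df in (("gonad", gonad), ("gtsoma", gtsoma)):
            counts_log[f"biased_{name}"] = int((df["label"] != "unbiased").sum())
            _write(df, out / f"calls_{name}.tsv", cfg_hash, index=True)
    except (ValueError, KeyError) as exc:
        raise StageError(stage, str(exc)) from exc

    # --- X vs autosome dN/dS ----------------------------------------------
    stage = "xstats"
    try:
        dnds_retained = (
            dnds_df[dnds_df["retained"]].set_index("gene_a")
            if len(dnds_df)
            else pd.DataFrame(columns=["omega"])
        )
        summaries, ratios = chromstats.stratified_dnds_table(
            dnds_retained, gene_map, calls,
            n_boot=cfg.n_boot, seed=cfg.seed,
            exclude_unmapped=cfg.exclude_unmapped,
        )
        _write(chromstats.summaries_frame(summaries), out / "xa_summaries.tsv",
               cfg_hash)
        _write(chromstats.ratios_frame(ratios), out / "xa_ratios.tsv", cfg_hash)
        for r in ratios:
            result.scalars[r.name] = r.ratio
    except (ValueError, KeyError) as exc:
        raise StageError(stage, str(exc)) from exc

    # --- dosage + breadth --------------------------------------------------
    stage = "dosage"
    try:
        universe = (
            tissue_avgs.loc[tissue_avgs.index.intersection(dnds_retained.index)]
            if cfg.universe == "orthologs" and len(dnds_retained)
            else tissue_avgs
        )
        report = dosage.dosage_ratios(universe, gene_map,
                                      aggregation=cfg.aggregation)
        _write(report.medians, out / "chrom_tissue_medians.tsv", cfg_hash,
               index=True)
        ratio_df = pd.DataFrame(
            {"name": list(report.ratios), "ratio": list(report.ratios.values()),
             "mwu_p": [report.mwu_p[k] for k in report.ratios]}
        )
        _write(ratio_df, out / "dosage_ratios.tsv", cfg_hash)
        result.scalars.update(report.ratios)

        breadth = dosage.expression_breadth(universe, cfg.breadth_threshold)
        b_sum = dosage.summarize_breadth(
            breadth, calls.loc[calls.index.intersection(universe.index)]
        )
        _write(
            pd.DataFrame(
                [(b.label, b.n, b.fraction_all_tissues) for b in b_sum],
                columns=["class", "n", "fraction_all_tissues"],
            ),
            out / "breadth.tsv", cfg_hash,
        )
        n_male, n_tot, p_sign = dosage.unbiased_direction_fraction(
            universe, calls, gene_map
        )
        result.scalars["x_unbiased_male_higher_fraction"] = (
            n_male / n_tot if n_tot else float("nan")
        )
        result.scalars["x_unbiased_sign_p"] = p_sign
    except (ValueError, KeyError) as exc:
        raise StageError(stage, str(exc)) from exc

    result.tables = {
        "dnds": dnds_df,
        "tissue_avgs": tissue_avgs,
        "calls": calls,
        "xa_summaries": chromstats.summaries_frame(summaries),
        "xa_ratios": chromstats.ratios_frame(ratios),
        "dosage_medians": report.medians,
        "dosage_ratios": ratio_df,
    }

    manifest = {
        "config": cfg.to_dict(),
        "config_hash": cfg_hash,
        "stage_counts": counts_log,
        "scalars": {k: (None if not np.isfinite(v) else v)
                    for k, v in result.scalars.items()},
    }
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    result.manifest_path = manifest_path
    logger.info("run complete: %s", counts_log)
    return result
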