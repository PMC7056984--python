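"""Synthetic-data generation for the whole pipeline.

Three generators cover every input the analysis consumes:

* codon-sequence ortholog pairs evolved from a common ancestor under an
  MG94xHKY codon substitution process with known omega and kappa
  (Markov jump / Gillespie simulation per codon along each branch);
* negative-binomial read-count matrices for the four-tissue, replicated
  expression design (testis, ovary, gonadectomised male and female soma),
  with planted sex-bias classes, X-linked ovary-bias enrichment and a
  male-X dosage factor;
* a fixture bundle writer that emits CDS FASTA files for two species, a
  gene-to-chromosome map, a counts table, a truth table and forward/
  reverse 12-column tabular similarity files (with configurable decoys),
  so the pipeline can run end to end from files.

All randomness flows through explicit seeds; no global RNG state is used.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .codons import (
    CODON_INDEX,
    GENETIC_CODE,
    SENSE_CODONS,
    is_transition,
    sense_neighbors,
)

TISSUES = ("TS", "OV", "GTM", "GTF")
MALE_TISSUES = frozenset({"TS", "GTM"})
CHROMOSOMES = ("X",) + tuple(f"LG{i}" for i in range(2, 11))

GONAD_CLASSES = ("ovary-biased", "testis-biased", "unbiased")
GT_CLASSES = ("GT-female-biased", "GT-male-biased", "unbiased")


def _uniform_codon_frequencies() -> np.ndarray:
    return np.full(len(SENSE_CODONS), 1.0 / len(SENSE_CODONS))


@dataclass
class CodonSimParams:
    """Parameters of one simulated ortholog pair.

    ``branch_length`` is the expected number of substitutions per codon
    along each of the two branches from the common ancestor (so total
    divergence is twice this value).
    """

    n_codons: int = 300
    kappa: float = 2.0
    omega: float = 0.2
    branch_length: float = 0.3
    codon_frequencies: np.ndarray = field(default_factory=_uniform_codon_frequencies)
    seed: int = 0

    def validate(self) -> None:
        if self.n_codons <= 0:
            raise ValueError("n_codons must be positive")
        if self.kappa < 0 or self.omega < 0 or self.branch_length < 0:
            raise ValueError("kappa, omega and branch_length must be >= 0")
        freqs = np.asarray(self.codon_frequencies, dtype=float)
        if freqs.shape != (len(SENSE_CODONS),):
            raise ValueError(
                f"codon_frequencies must have {len(SENSE_CODONS)} entries "
                "(sense codons only)"
            )
        if np.any(freqs < 0) or abs(freqs.sum() - 1.0) > 1e-9:
            raise ValueError("codon_frequencies must be a probability vector")


def _mg94_neighbor_tables(
    kappa: float, omega: float, pi: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Jump-process tables for the MG94xHKY model.

    Returns (targets, rates, total_rate_per_codon) where ``targets`` and
    ``rates`` are (61, 9) arrays padded with -1/0, and rates are scaled so
    that the stationary mean substitution rate is one per codon per unit
    time. Position-specific nucleotide frequencies are derived from the
    stationary codon frequencies.
    """
    pos_freq = np.zeros((3, 4))
    nt_idx = {nt: i for i, nt in enumerate("TCAG")}
    for codon, p in zip(SENSE_CODONS, pi):
        for pos in range(3):
            pos_freq[pos, nt_idx[codon[pos]]] += p
    targets = np.full((len(SENSE_CODONS), 9), -1, dtype=np.int64)
    rates = np.zeros((len(SENSE_CODONS), 9))
    for i, codon in enumerate(SENSE_CODONS):
        for k, (nb, pos, ts, syn) in enumerate(sense_neighbors(codon)):
            r = pos_freq[pos, nt_idx[nb[pos]]]
            if ts:
                r *= kappa
            if not syn:
                r *= omega
            targets[i, k] = CODON_INDEX[nb]
            rates[i, k] = r
    total = rates.sum(axis=1)
    mean_rate = float(np.dot(pi, total))
    if mean_rate > 0:
        rates /= mean_rate
        total = total / mean_rate
    return targets, rates, total


def _evolve_branch(
    states: np.ndarray,
    t: float,
    targets: np.ndarray,
    rates: np.ndarray,
    total: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Evolve codon states for time t by per-codon Gillespie jumps."""
    states = states.copy()
    remaining = np.full(states.shape, float(t))
    active = np.ones(states.shape, dtype=bool)
    while active.any():
        idx = np.flatnonzero(active)
        tot = total[states[idx]]
        waits = np.where(
            tot > 0,
            rng.exponential(1.0, size=idx.size) / np.where(tot > 0, tot, 1.0),
            np.inf,
        )
        jumped = waits < remaining[idx]
        remaining[idx] -= np.where(jumped, waits, remaining[idx])
        active[idx[~jumped]] = False
        jump_idx = idx[jumped]
        for j in jump_idx:  # few events per call: rare-substitution regime
            s = states[j]
            p = rates[s] / total[s]
            states[j] = targets[s, rng.choice(9, p=p)]
    return states


def simulate_codon_pair(params: CodonSimParams) -> tuple[str, str, str, float]:
    """Simulate one ortholog pair.

    Returns (ancestral CDS, descendant A, descendant B, true omega). The
    ancestor is drawn from the stationary codon distribution and the two
    descendants evolve independently for ``branch_length`` expected
    substitutions per codon each. No stop codons are ever produced.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    pi = np.asarray(params.codon_frequencies, dtype=float)
    targets, rates, total = _mg94_neighbor_tables(params.kappa, params.omega, pi)
    anc = rng.choice(len(SENSE_CODONS), size=params.n_codons, p=pi)
    desc_a = _evolve_branch(anc, params.branch_length, targets, rates, total, rng)
    desc_b = _evolve_branch(anc, params.branch_length, targets, rates, total, rng)

    def to_seq(states: np.ndarray) -> str:
        return "".join(SENSE_CODONS[s] for s in states)

    return to_seq(anc), to_seq(desc_a), to_seq(desc_b), params.omega


@dataclass
class ExprSimParams:
    """Parameters of the synthetic four-tissue expression experiment.

    Class fractions mirror the observed composition of the beetle data:
    ovary-biased genes are strongly enriched on the X chromosome relative
    to autosomes, testis-biased genes are not, and a male-X dosage factor
    multiplies the expression of X-linked genes in male tissues.
    """

    n_genes: int = 500
    n_chromosomes: int = 10
    x_gene_fraction: float = 0.056
    ovary_bias_fraction_X: float = 0.54
    ovary_bias_fraction_A: float = 0.16
    testis_bias_fraction: float = 0.12
    gt_female_bias_fraction: float = 0.05
    gt_male_bias_fraction: float = 0.05
    fold_change: float = 8.0
    male_X_dosage_factor: float = 1.0
    nb_dispersion: float = 0.05
    mean_log_expression: float = 5.0
    sd_log_expression: float = 1.5
    n_replicates: int = 2
    seed: int = 0

    def validate(self) -> None:
        fracs = [
            self.x_gene_fraction,
            self.ovary_bias_fraction_X,
            self.ovary_bias_fraction_A,
            self.testis_bias_fraction,
            self.gt_female_bias_fraction,
            self.gt_male_bias_fraction,
        ]
        if any(not (0.0 <= f <= 1.0) for f in fracs):
            raise ValueError("all class fractions must lie in [0, 1]")
        if self.fold_change < 1.0:
            raise ValueError("fold_change must be >= 1")
        if self.male_X_dosage_factor <= 0.0:
            raise ValueError("male_X_dosage_factor must be positive")
        if self.nb_dispersion < 0.0:
            raise ValueError("nb_dispersion must be >= 0")
        if self.n_genes < 0 or self.n_chromosomes < 2:
            raise ValueError("n_genes must be >= 0 with >= 2 chromosomes")
        if self.n_replicates < 2:
            warnings.warn(
                "fewer than 2 replicates per tissue: the differential "
                "expression test will be degenerate",
                stacklevel=2,
            )


def sample_columns(n_replicates: int = 2) -> list[str]:
    return [f"{t}_{r}" for t in TISSUES for r in range(1, n_replicates + 1)]


def simulate_expression(params: ExprSimParams) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate the count matrix and its planted truth table.

    Returns (counts, truth). ``counts`` has one row per gene and one
    column per sample (``TS_1``, ``TS_2``, ``OV_1``, ...); ``truth``
    records each gene's chromosome and planted gonad / GT-soma class.
    Biased genes have the favoured tissue's mean multiplied by
    ``fold_change``; X-linked genes have male-tissue means multiplied by
    ``male_X_dosage_factor``; counts are negative binomial with common
    dispersion.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    n = params.n_genes
    gene_ids = [f"g{i:05d}" for i in range(1, n + 1)]

    is_x = rng.random(n) < params.x_gene_fraction
    autosomes = [f"LG{i}" for i in range(2, params.n_chromosomes + 1)]
    chrom = np.where(is_x, "X", rng.choice(autosomes, size=n))

    p_ov = np.where(is_x, params.ovary_bias_fraction_X, params.ovary_bias_fraction_A)
    u = rng.random(n)
    gonad_class = np.full(n, "unbiased", dtype=object)
    gonad_class[u < p_ov] = "ovary-biased"
    gonad_class[(u >= p_ov) & (u < p_ov + params.testis_bias_fraction)] = (
        "testis-biased"
    )
    v = rng.random(n)
    gt_class = np.full(n, "unbiased", dtype=object)
    gt_class[v < params.gt_female_bias_fraction] = "GT-female-biased"
    gt_class[
        (v >= params.gt_female_bias_fraction)
        & (v < params.gt_female_bias_fraction + params.gt_male_bias_fraction)
    ] = "GT-male-biased"

    base = rng.lognormal(params.mean_log_expression, params.sd_log_expression, n)
    mean = {t: base.copy() for t in TISSUES}
    # plant the bias as a symmetric geometric split so the favoured tissue's
    # mean is fold_change x the disfavoured one while the gene's overall
    # level stays at baseline
    up = math.sqrt(params.fold_change)
    for tissue, other, cls, labels in (
        ("OV", "TS", gonad_class, ("ovary-biased", "testis-biased")),
        ("GTF", "GTM", gt_class, ("GT-female-biased", "GT-male-biased")),
    ):
        f_sel = cls == labels[0]
        m_sel = cls == labels[1]
        mean[tissue][f_sel] *= up
        mean[other][f_sel] /= up
        mean[other][m_sel] *= up
        mean[tissue][m_sel] /= up
    for t in MALE_TISSUES:
        mean[t][is_x] *= params.male_X_dosage_factor

    cols = sample_columns(params.n_replicates)
    counts = np.empty((n, len(cols)), dtype=np.int64)
    disp = params.nb_dispersion
    for j, col in enumerate(cols):
        mu = mean[col.rsplit("_", 1)[0]]
        if disp > 0:
            # NB with Var = mu + disp * mu^2, via gamma-Poisson mixture
            lam = rng.gamma(shape=1.0 / disp, scale=mu * disp)
            counts[:, j] = rng.poisson(lam)
        else:
            counts[:, j] = rng.poisson(mu)

    counts_df = pd.DataFrame(counts, index=pd.Index(gene_ids, name="gene_id"),
                             columns=cols)
    truth = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "chromosome": chrom,
            "gonad_class": gonad_class,
            "gt_class": gt_class,
            # the means actually planted, after the dosage factor; recovery
            # tests stratify on these because the dosage factor itself
            # shifts male/female expression ratios of X-linked genes
            **{f"true_mean_{t}": mean[t] for t in TISSUES},
        }
    ).set_index("gene_id")
    return counts_df, truth


# ---------------------------------------------------------------------------
# Fixture bundle
# ---------------------------------------------------------------------------


@dataclass
class FixtureParams:
    """Controls for the on-disk fixture bundle."""

    n_decoys: int = 10
    decoy_tied_evalue: bool = False
    x_omega_multiplier: float = 1.0
    base_omega: float = 0.2
    omega_log_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.n_decoys < 0:
            raise ValueError("n_decoys must be >= 0")


def _fake_hit_scores(identity: float, aln_len_nt: int) -> tuple[float, float]:
    """Deterministic e-value / bit-score surrogates from percent identity.

    Monotone in identity and length so that true pairs always outscore
    their shuffled decoys; no search engine is run.
    """
    bits = 2.0 * aln_len_nt * max(identity, 0.05)
    evalue = min(1e3 * math.exp(-math.log(2.0) * bits / 4.0), 10.0)
    return evalue, bits


def _identity(a: str, b: str) -> float:
    same = sum(1 for x, y in zip(a, b) if x == y)
    return same / len(a) if a else 0.0


def _shuffle_codons(seq: str, rng: np.random.Generator) -> str:
    codons = [seq[i : i + 3] for i in range(3, len(seq), 3)]  # keep ATG
    rng.shuffle(codons)
    return seq[:3] + "".join(codons)


BLAST6_COLUMNS = [
    "query", "subject", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


def emit_fixture_bundle(
    codon_params: CodonSimParams,
    expr_params: ExprSimParams,
    out_dir: str | Path,
    fixture_params: FixtureParams | None = None,
) -> dict[str, Path]:
    """Write a complete synthetic input set for the pipeline.

    Per gene of the expression design, one ortholog pair is simulated with
    ``codon_params`` (gene-specific omega optionally scaled on the X
    chromosome and jittered lognormally), written as species-A and
    species-B CDS FASTA with a leading ATG and trailing stop codon added.
    Similarity files contain the true pair per gene plus shuffled-codon
    decoy hits with strictly weaker scores (optionally sharing the true
    hit's e-value to exercise bit-score tie-breaking).

    Returns a dict of logical name -> written path.
    """
    fixture_params = fixture_params or FixtureParams()
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create fixture directory {out}: {exc}") from exc

    counts, truth = simulate_expression(expr_params)
    gene_ids = list(truth.index)
    rng = np.random.default_rng(
        np.random.default_rng(codon_params.seed).integers(2**31)
    )

    seq_a: dict[str, str] = {}
    seq_b: dict[str, str] = {}
    true_omega: dict[str, float] = {}
    for k, gid in enumerate(gene_ids):
        omega = fixture_params.base_omega
        if fixture_params.omega_log_sd > 0:
            omega *= float(
                np.exp(rng.normal(0.0, fixture_params.omega_log_sd))
            )
        if truth.loc[gid, "chromosome"] == "X":
            omega *= fixture_params.x_omega_multiplier
        p = CodonSimParams(
            n_codons=codon_params.n_codons,
            kappa=codon_params.kappa,
            omega=omega,
            branch_length=codon_params.branch_length,
            codon_frequencies=codon_params.codon_frequencies,
            seed=int(rng.integers(2**31)),
        )
        _, a, b, _ = simulate_codon_pair(p)
        # frame the CDS the way annotation pipelines deliver them
        seq_a[gid] = "ATG" + a + "TAA"
        seq_b[gid] = "ATG" + b + "TAA"
        true_omega[gid] = omega

    paths: dict[str, Path] = {}

    def write_fasta(name: str, seqs: dict[str, str], suffix: str) -> None:
        path = out / name
        with open(path, "w") as fh:
            for gid, seq in seqs.items():
                fh.write(f">{gid}{suffix}\n")
                for i in range(0, len(seq), 60):
                    fh.write(seq[i : i + 60] + "\n")
        paths[name] = path

    write_fasta("species_a.fasta", seq_a, "")
    write_fasta("species_b.fasta", {g: s for g, s in seq_b.items()}, "_b")

    gene_map = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "chromosome": [truth.loc[g, "chromosome"] for g in gene_ids],
            "cds_length_nt": [len(seq_a[g]) for g in gene_ids],
        }
    )
    gene_map.to_csv(out / "gene_map.tsv", sep="\t", index=False)
    paths["gene_map.tsv"] = out / "gene_map.tsv"

    counts.to_csv(out / "counts.tsv", sep="\t")
    paths["counts.tsv"] = out / "counts.tsv"

    truth_out = truth.copy()
    truth_out["true_omega"] = [true_omega[g] for g in truth_out.index]
    truth_out.to_csv(out / "truth.tsv", sep="\t")
    paths["truth.tsv"] = out / "truth.tsv"

    fwd_rows: list[list] = []
    rev_rows: list[list] = []
    decoy_genes = (
        list(rng.choice(gene_ids, size=min(fixture_params.n_decoys, len(gene_ids)),
                        replace=False))
        if fixture_params.n_decoys and gene_ids
        else []
    )
    for gid in gene_ids:
        a, b = seq_a[gid], seq_b[gid]
        ident = _identity(a, b)
        ev, bits = _fake_hit_scores(ident, len(a))
        n_mm = round(len(a) * (1 - ident))
        fwd_rows.append([gid, f"{gid}_b", round(100 * ident, 2), len(a), n_mm, 0,
                         1, len(a), 1, len(b), ev, round(bits, 1)])
        rev_rows.append([f"{gid}_b", gid, round(100 * ident, 2), len(b), n_mm, 0,
                         1, len(b), 1, len(a), ev, round(bits, 1)])
    for gid in decoy_genes:
        decoy = _shuffle_codons(seq_b[gid], rng)
        others = [g for g in gene_ids if g != gid]
        if not others:
            continue
        target = str(rng.choice(others))
        ident = _identity(seq_a[target], decoy)
        ev, bits = _fake_hit_scores(ident, len(decoy))
        true_ev = next(r[10] for r in fwd_rows if r[0] == target)
        true_bits = next(r[11] for r in fwd_rows if r[0] == target)
        if fixture_params.decoy_tied_evalue:
            ev, bits = true_ev, max(true_bits - 10.0, 1.0)
        n_mm = round(len(decoy) * (1 - ident))
        fwd_rows.append([target, f"{gid}_b", round(100 * ident, 2), len(decoy),
                         n_mm, 0, 1, len(decoy), 1, len(decoy), ev,
                         round(bits, 1)])

    for name, rows in (("fwd_hits.tsv", fwd_rows), ("rev_hits.tsv", rev_rows)):
        pd.DataFrame(rows, columns=BLAST6_COLUMNS).to_csv(
            out / name, sep="\t", index=False, header=False
        )
        paths[name] = out / name
    return paths
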