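"""CDS validity filtering and reciprocal-best-hit ortholog identification.

The ortholog definition is operational: a cross-species gene pair is an
ortholog when each gene is the other's best similarity-search match
(lowest e-value, bit score breaking ties) in both search directions and
both directions pass the e-value ceiling. The search itself is external;
this module consumes 12-column tabular output from any engine.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .codons import GENETIC_CODE, STOP_CODONS

logger = logging.getLogger(__name__)

VALID_NT = frozenset("ACGT")


@dataclass
class CdsRecord:
    """One gene's coding sequence with validity status."""

    gene_id: str
    sequence: str
    species: str = ""
    chromosome: str = "unmapped"
    valid: bool = False
    reason: str = ""


@dataclass(frozen=True)
class SearchHit:
    query: str
    subject: str
    evalue: float
    bitscore: float


@dataclass(frozen=True)
class OrthologPair:
    gene_a: str
    gene_b: str
    evalue_fwd: float
    evalue_rev: float
    bitscore_fwd: float
    bitscore_rev: float


def check_cds(sequence: str, min_aa: int = 33) -> tuple[bool, str]:
    """Apply the CDS validity rules to one sequence.

    Valid means: starts with ATG, length a multiple of three, contains
    only unambiguous A/C/G/T, has no internal stop codon, and encodes at
    least ``min_aa`` amino acids (a terminal stop codon, when present,
    does not count toward the length).
    """
    seq = sequence.upper()
    if not seq:
        return False, "empty sequence"
    if set(seq) - VALID_NT:
        return False, "ambiguous nucleotide"
    if len(seq) % 3:
        return False, "length not a codon multiple"
    if not seq.startswith("ATG"):
        return False, "no start codon"
    codons = [seq[i : i + 3] for i in range(0, len(seq), 3)]
    n_aa = len(codons) - 1 if codons[-1] in STOP_CODONS else len(codons)
    if any(c in STOP_CODONS for c in codons[:-1]):
        return False, "internal stop"
    if n_aa < min_aa:
        return False, f"shorter than {min_aa} aa"
    return True, ""


def filter_valid_cds(records: list[CdsRecord], min_aa: int = 33) -> list[CdsRecord]:
    """Set validity and rejection reason on each record (in place) and return them."""
    for rec in records:
        rec.valid, rec.reason = check_cds(rec.sequence, min_aa=min_aa)
    n_ok = sum(r.valid for r in records)
    logger.info("CDS filter: %d of %d records valid", n_ok, len(records))
    return records


def longest_valid_per_gene(records: list[CdsRecord]) -> list[CdsRecord]:
    """Among valid records sharing a gene ID, keep the longest CDS.

    Ties on length resolve to the lexicographically first sequence so the
    choice is deterministic.
    """
    best: dict[str, CdsRecord] = {}
    for rec in records:
        if not rec.valid:
            continue
        cur = best.get(rec.gene_id)
        if (
            cur is None
            or len(rec.sequence) > len(cur.sequence)
            or (len(rec.sequence) == len(cur.sequence)
                and rec.sequence < cur.sequence)
        ):
            best[rec.gene_id] = rec
    return [best[g] for g in sorted(best)]


def collapse_hsps(hits: list[SearchHit]) -> list[SearchHit]:
    """Keep, per (query, subject) pair, the best HSP: lowest e-value, then
    highest bit score."""
    best: dict[tuple[str, str], SearchHit] = {}
    for h in hits:
        if h.evalue < 0:
            raise ValueError(f"negative e-value for {h.query}->{h.subject}")
        key = (h.query, h.subject)
        cur = best.get(key)
        if cur is None or (h.evalue, -h.bitscore) < (cur.evalue, -cur.bitscore):
            best[key] = h
    return list(best.values())


def best_hit_per_query(hits: list[SearchHit]) -> dict[str, SearchHit]:
    """Best subject per query: minimal e-value, ties broken by maximal bit
    score, then by lexicographic subject order (logged, since the data no
    longer discriminates)."""
    hits = collapse_hsps(hits)
    best: dict[str, SearchHit] = {}
    for h in hits:
        cur = best.get(h.query)
        if cur is None:
            best[h.query] = h
            continue
        key_new = (h.evalue, -h.bitscore, h.subject)
        key_cur = (cur.evalue, -cur.bitscore, cur.subject)
        if key_new < key_cur:
            if h.evalue == cur.evalue and h.bitscore == cur.bitscore:
                logger.warning(
                    "query %s: full tie between %s and %s resolved "
                    "lexicographically",
                    h.query, h.subject, cur.subject,
                )
            best[h.query] = h
    return best


def reciprocal_best_hits(
    fwd_hits: list[SearchHit],
    rev_hits: list[SearchHit],
    evalue_max: float = 1e-6,
) -> list[OrthologPair]:
    """Reciprocal best hits below the e-value ceiling, sorted by gene_a.

    A pair (a, b) is reported iff b is a's best forward match, a is b's
    best reverse match, and both directions have e-value < ``evalue_max``.
    The ceiling is applied to the final reciprocal pair (both directions),
    not to the candidate hit lists.
    """
    fwd_best = best_hit_per_query(fwd_hits)
    rev_best = best_hit_per_query(rev_hits)
    pairs = []
    for a, fh in fwd_best.items():
        rh = rev_best.get(fh.subject)
        if rh is None or rh.subject != a:
            continue
        if fh.evalue < evalue_max and rh.evalue < evalue_max:
            pairs.append(
                OrthologPair(
                    gene_a=a,
                    gene_b=fh.subject,
                    evalue_fwd=fh.evalue,
                    evalue_rev=rh.evalue,
                    bitscore_fwd=fh.bitscore,
                    bitscore_rev=rh.bitscore,
                )
            )
    pairs.sort(key=lambda p: p.gene_a)
    return pairs


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

BLAST6_NAMES = [
    "query", "subject", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


def read_blast6(path: str | Path) -> list[SearchHit]:
    """Read 12-column tabular similarity-search output."""
    try:
        df = pd.read_csv(path, sep="\t", names=BLAST6_NAMES, comment="#")
    except pd.errors.EmptyDataError:
        return []
    return [
        SearchHit(str(r.query), str(r.subject), float(r.evalue), float(r.bitscore))
        for r in df.itertuples(index=False)
    ]


def write_pairs(pairs: list[OrthologPair], path: str | Path) -> None:
    pd.DataFrame(
        [
            (p.gene_a, p.gene_b, p.evalue_fwd, p.evalue_rev,
             p.bitscore_fwd, p.bitscore_rev)
            for p in pairs
        ],
        columns=["gene_a", "gene_b", "evalue_fwd", "evalue_rev",
                 "bitscore_fwd", "bitscore_rev"],
    ).to_csv(path, sep="\t", index=False)


def read_fasta_records(path: str | Path, species: str = "") -> list[CdsRecord]:
    """Read a CDS FASTA into records (ID = first token of the header)."""
    from Bio import SeqIO

    return [
        CdsRecord(gene_id=rec.id, sequence=str(rec.seq).upper(), species=species)
        for rec in SeqIO.parse(str(path), "fasta")
    ]
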