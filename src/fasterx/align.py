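"""Codon-aware pairwise alignment and alignment filtering.

Ortholog pairs are aligned at the protein level with a deterministic
global (Needleman-Wunsch, affine-gap, BLOSUM62) aligner and back-translated
so that gaps occur only in whole-codon units. Columns containing gaps are
then removed, and highly divergent segments are masked with a windowed
amino-acid-identity filter that retains only conserved blocks of a minimum
length (a two-sequence analogue of classic conserved-block trimming).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from Bio.Align import PairwiseAligner, substitution_matrices

from .codons import GENETIC_CODE, translate

logger = logging.getLogger(__name__)

GAP_CODON = "---"


@dataclass
class CodonAlignment:
    """Aligned codon columns of one ortholog pair.

    ``columns`` holds (codon_a, codon_b) pairs; a codon may be the gap
    codon ``---`` before gap stripping. ``n_codons_prefilter`` records the
    column count before any filtering, for audit.
    """

    gene_a: str
    gene_b: str
    columns: list[tuple[str, str]]
    n_codons_prefilter: int = field(default=0)

    def __post_init__(self) -> None:
        if self.n_codons_prefilter == 0:
            self.n_codons_prefilter = len(self.columns)

    @property
    def n_codons(self) -> int:
        return len(self.columns)

    def seqs(self) -> tuple[str, str]:
        a = "".join(c for c, _ in self.columns)
        b = "".join(c for _, c in self.columns)
        return a, b


def _make_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -0.5
    return aligner


_ALIGNER = _make_aligner()


def align_codon_pair(
    cds_a: str, cds_b: str, gene_a: str = "a", gene_b: str = "b"
) -> CodonAlignment:
    """Globally align two coding sequences codon-by-codon.

    The translated proteins are aligned (terminal stop codons, if present,
    are dropped first) and the alignment is back-translated onto the
    nucleotide sequences, so indels are whole codons.

    Raises ``ValueError`` if either sequence is not a clean in-frame CDS.
    """
    codons_a = _clean_codons(cds_a, gene_a)
    codons_b = _clean_codons(cds_b, gene_b)
    prot_a = "".join(GENETIC_CODE[c] for c in codons_a)
    prot_b = "".join(GENETIC_CODE[c] for c in codons_b)
    aln = _ALIGNER.align(prot_a, prot_b)[0]
    cols: list[tuple[str, str]] = []
    ia = ib = 0
    for sa, sb in zip(aln[0], aln[1]):
        ca = GAP_CODON if sa == "-" else codons_a[ia]
        cb = GAP_CODON if sb == "-" else codons_b[ib]
        if sa != "-":
            ia += 1
        if sb != "-":
            ib += 1
        cols.append((ca, cb))
    return CodonAlignment(gene_a, gene_b, cols)


def _clean_codons(cds: str, gene: str) -> list[str]:
    cds = cds.upper()
    if len(cds) < 3 or len(cds) % 3:
        raise ValueError(f"{gene}: CDS length {len(cds)} not a codon multiple")
    codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
    if GENETIC_CODE.get(codons[-1]) == "*":
        codons = codons[:-1]
    prot = "".join(GENETIC_CODE.get(c, "X") for c in codons)
    if "*" in prot or "X" in prot:
        raise ValueError(f"{gene}: internal stop or ambiguous codon in CDS")
    return codons


def strip_gaps(alignment: CodonAlignment) -> CodonAlignment:
    """Remove every column containing a gap in either sequence."""
    cols = [
        (a, b) for a, b in alignment.columns if a != GAP_CODON and b != GAP_CODON
    ]
    return CodonAlignment(
        alignment.gene_a, alignment.gene_b, cols, alignment.n_codons_prefilter
    )


def filter_divergent_blocks(
    alignment: CodonAlignment,
    window: int = 12,
    min_identity: float = 0.5,
    min_block: int = 10,
    max_nonconserved: int = 8,
) -> CodonAlignment:
    """Drop codon columns inside highly divergent segments.

    A column is flagged divergent when the amino-acid identity of the
    length-``window`` window centred on it falls below ``min_identity``,
    or when it sits in a run of more than ``max_nonconserved`` consecutive
    non-identical columns. After removal, surviving runs of consecutive
    columns shorter than ``min_block`` are removed too, so only conserved
    blocks remain. The input must be gap-free.
    """
    cols = alignment.columns
    n = len(cols)
    if n == 0:
        return alignment
    ident = [GENETIC_CODE[a] == GENETIC_CODE[b] for a, b in cols]
    half = window // 2
    keep = []
    for i in range(n):
        lo = max(0, i - half)
        hi = min(n, lo + window)
        lo = max(0, hi - window)
        frac = sum(ident[lo:hi]) / (hi - lo)
        keep.append(frac >= min_identity)
    # long contiguous mismatch runs go regardless of window context
    i = 0
    while i < n:
        if ident[i]:
            i += 1
            continue
        j = i
        while j < n and not ident[j]:
            j += 1
        if j - i > max_nonconserved:
            for k in range(i, j):
                keep[k] = False
        i = j
    # enforce minimum block length on the retained runs
    out: list[tuple[str, str]] = []
    i = 0
    while i < n:
        if not keep[i]:
            i += 1
            continue
        j = i
        while j < n and keep[j]:
            j += 1
        if j - i >= min_block:
            out.extend(cols[i:j])
        i = j
    if len(out) < n:
        logger.debug(
            "%s-%s: block filter removed %d of %d codon columns",
            alignment.gene_a,
            alignment.gene_b,
            n - len(out),
            n,
        )
    return CodonAlignment(
        alignment.gene_a, alignment.gene_b, out, alignment.n_codons_prefilter
    )
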