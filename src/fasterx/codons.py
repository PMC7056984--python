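"""Genetic-code tables and codon-level combinatorics.

Everything downstream of pairwise divergence estimation (NG86 counting,
the YN00-style estimator, and the codon substitution simulator) shares the
tables built here: the standard nuclear genetic code, per-position
degeneracy classes, single-nucleotide codon neighbourhoods, and the
enumeration of minimal mutational pathways between codon pairs.

Pathways that pass through a stop codon are excluded everywhere, following
the classic counting convention.
"""

from __future__ import annotations

from functools import lru_cache
from itertools import permutations

NUCLEOTIDES = "TCAG"

# Standard nuclear genetic code, indexed by codon string.
GENETIC_CODE: dict[str, str] = {}
_AA = (
    "FFLLSSSSYY**CC*W"
    "LLLLPPPPHHQQRRRR"
    "IIIMTTTTNNKKSSRR"
    "VVVVAAAADDEEGGGG"
)
_i = 0
for _n1 in NUCLEOTIDES:
    for _n2 in NUCLEOTIDES:
        for _n3 in NUCLEOTIDES:
            GENETIC_CODE[_n1 + _n2 + _n3] = _AA[_i]
            _i += 1

STOP_CODONS = frozenset(c for c, aa in GENETIC_CODE.items() if aa == "*")
SENSE_CODONS: tuple[str, ...] = tuple(
    sorted(c for c in GENETIC_CODE if c not in STOP_CODONS)
)
CODON_INDEX = {c: i for i, c in enumerate(SENSE_CODONS)}

PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")


def translate(seq: str) -> str:
    """Translate an in-frame nucleotide string; stops become '*'."""
    return "".join(GENETIC_CODE[seq[i : i + 3]] for i in range(0, len(seq) - 2, 3))


def is_transition(a: str, b: str) -> bool:
    return (a in PURINES and b in PURINES) or (a in PYRIMIDINES and b in PYRIMIDINES)


def codon_diffs(c1: str, c2: str) -> tuple[int, ...]:
    """Positions (0-2) at which two codons differ."""
    return tuple(i for i in range(3) if c1[i] != c2[i])


@lru_cache(maxsize=None)
def sense_neighbors(codon: str) -> tuple[tuple[str, int, bool, bool], ...]:
    """All sense codons one nucleotide away.

    Returns tuples (neighbor, position, is_transition, is_synonymous).
    """
    out = []
    aa = GENETIC_CODE[codon]
    for pos in range(3):
        for nt in NUCLEOTIDES:
            if nt == codon[pos]:
                continue
            nb = codon[:pos] + nt + codon[pos + 1 :]
            if nb in STOP_CODONS:
                continue
            out.append(
                (nb, pos, is_transition(codon[pos], nt), GENETIC_CODE[nb] == aa)
            )
    return tuple(out)


@lru_cache(maxsize=None)
def position_degeneracy(codon: str) -> tuple[int, int, int]:
    """Degeneracy class (0, 2 or 4) of each position of a sense codon.

    A position is 4-fold if every nucleotide substitution there is
    synonymous, 0-fold if every substitution is nonsynonymous (changes to
    stop codons count as nonsynonymous), 2-fold otherwise.
    """
    aa = GENETIC_CODE[codon]
    out = []
    for pos in range(3):
        syn = 0
        for nt in NUCLEOTIDES:
            if nt == codon[pos]:
                continue
            nb = codon[:pos] + nt + codon[pos + 1 :]
            if GENETIC_CODE[nb] == aa:
                syn += 1
        out.append({0: 0, 3: 4}.get(syn, 2))
    return tuple(out)


@lru_cache(maxsize=None)
def ng86_site_fractions(codon: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) site counts of one codon, NG86 style.

    Each position contributes fractionally according to the proportion of
    its three possible changes that are synonymous; changes to stop codons
    are counted as nonsynonymous opportunities (classic NG86 convention).
    """
    aa = GENETIC_CODE[codon]
    s = 0.0
    for pos in range(3):
        syn = 0
        for nt in NUCLEOTIDES:
            if nt == codon[pos]:
                continue
            nb = codon[:pos] + nt + codon[pos + 1 :]
            if nb not in STOP_CODONS and GENETIC_CODE[nb] == aa:
                syn += 1
        s += syn / 3.0
    return s, 3.0 - s


# A pathway step: (from_codon, to_codon, is_transition, is_synonymous)
Step = tuple[str, str, bool, bool]


@lru_cache(maxsize=None)
def minimal_pathways(c1: str, c2: str) -> tuple[tuple[Step, ...], ...]:
    """All minimal mutational pathways between two sense codons.

    Each pathway applies the differing positions in some order; orderings
    whose intermediate codons are stop codons are discarded.
    """
    diffs = codon_diffs(c1, c2)
    paths = []
    for order in permutations(diffs):
        cur = c1
        steps: list[Step] = []
        ok = True
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if nxt in STOP_CODONS:
                ok = False
                break
            steps.append(
                (
                    cur,
                    nxt,
                    is_transition(cur[pos], c2[pos]),
                    GENETIC_CODE[cur] == GENETIC_CODE[nxt],
                )
            )
            cur = nxt
        if ok:
            paths.append(tuple(steps))
    return tuple(paths)


@lru_cache(maxsize=None)
def ng86_diff_counts(c1: str, c2: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) difference counts between two codons.

    Minimal pathways are weighted equally (the NG86 definition); pathways
    through stop codons are excluded. If every pathway crosses a stop the
    differences are counted as nonsynonymous.
    """
    if c1 == c2:
        return 0.0, 0.0
    paths = minimal_pathways(c1, c2)
    ndiff = len(codon_diffs(c1, c2))
    if not paths:  # all orderings stop-crossing: treat as nonsynonymous
        return 0.0, float(ndiff)
    sd = nd = 0.0
    w = 1.0 / len(paths)
    for path in paths:
        for _, _, _, syn in path:
            if syn:
                sd += w
            else:
                nd += w
    return sd, nd
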