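"""Pairwise dN/dS estimation.

Two estimators are provided:

* ``dnds_ng86`` — classic Nei-Gojobori (1986) counting. Synonymous and
  nonsynonymous site fractions are averaged over the two sequences,
  differences are partitioned by equal weighting over all minimal
  mutational pathways (stop-crossing pathways excluded), and the
  Jukes-Cantor correction turns proportions into distances.

* ``dnds_yn00`` — a Yang-Nielsen (2000) style estimator. Codon usage is
  estimated from the data (F3x4), the transition/transversion ratio kappa
  is estimated from fourfold-degenerate and nondegenerate sites, site and
  difference counting is weighted by kappa, codon frequencies and the
  current omega, and transition/transversion-aware (K80-type) distance
  corrections are applied separately to synonymous and nonsynonymous
  sites. Pathway weights depend on omega, so the estimate is iterated to
  convergence.

dN and dS below 0 are impossible by construction; dS saturation (p >= 3/4
under the correction in use) flags the estimate as not converged.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field

from .align import CodonAlignment
from .codons import (
    CODON_INDEX,
    NUCLEOTIDES,
    SENSE_CODONS,
    codon_diffs,
    is_transition,
    minimal_pathways,
    ng86_diff_counts,
    ng86_site_fractions,
    position_degeneracy,
    sense_neighbors,
)

MAX_ITER = 100
TOL = 1e-6


@dataclass
class DnDsEstimate:
    """Per-pair divergence estimate.

    ``omega`` is None when dS = 0 (undefined ratio); ``converged`` is
    False when a distance correction saturated or the YN00 iteration hit
    the iteration cap.
    """

    dN: float
    dS: float
    omega: float | None
    kappa: float
    S_sites: float
    N_sites: float
    method: str
    converged: bool = True
    n_codons: int = 0
    iterations: int = field(default=0)


def _jukes_cantor(p: float) -> tuple[float, bool]:
    """JC69 distance for a proportion of differing sites; flags saturation."""
    if p <= 0.0:
        return 0.0, True
    if p >= 0.75:
        return float("inf"), False
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0), True


def _check_alignment(alignment: CodonAlignment) -> list[tuple[str, str]]:
    if alignment.n_codons == 0:
        raise ValueError("empty alignment: no codon columns to estimate from")
    for a, b in alignment.columns:
        if a not in CODON_INDEX or b not in CODON_INDEX:
            raise ValueError(f"non-sense codon column ({a}, {b}) in alignment")
    return alignment.columns


def dnds_ng86(alignment: CodonAlignment) -> DnDsEstimate:
    """Nei-Gojobori (1986) dN/dS on a gap-free codon alignment."""
    cols = _check_alignment(alignment)
    S = N = 0.0
    Sd = Nd = 0.0
    for a, b in cols:
        sa, na = ng86_site_fractions(a)
        sb, nb = ng86_site_fractions(b)
        S += 0.5 * (sa + sb)
        N += 0.5 * (na + nb)
        sd, nd = ng86_diff_counts(a, b)
        Sd += sd
        Nd += nd
    pS = Sd / S if S > 0 else 0.0
    pN = Nd / N if N > 0 else 0.0
    dS, ok_s = _jukes_cantor(pS)
    dN, ok_n = _jukes_cantor(pN)
    omega = (dN / dS) if (dS > 0 and math.isfinite(dS)) else None
    return DnDsEstimate(
        dN=dN,
        dS=dS,
        omega=omega,
        kappa=1.0,
        S_sites=S,
        N_sites=N,
        method="NG86",
        converged=ok_s and ok_n,
        n_codons=len(cols),
    )


# ---------------------------------------------------------------------------
# YN00-style estimator
# ---------------------------------------------------------------------------


def _f3x4(cols: list[tuple[str, str]]) -> dict[str, float]:
    """F3x4 codon frequencies from both sequences of the alignment."""
    pos_counts = [Counter(), Counter(), Counter()]
    for a, b in cols:
        for codon in (a, b):
            for i in range(3):
                pos_counts[i][codon[i]] += 1
    pos_freq = []
    for i in range(3):
        tot = sum(pos_counts[i].values())
        pos_freq.append({nt: pos_counts[i][nt] / tot for nt in NUCLEOTIDES})
    raw = {
        c: pos_freq[0][c[0]] * pos_freq[1][c[1]] * pos_freq[2][c[2]]
        for c in SENSE_CODONS
    }
    z = sum(raw.values())
    return {c: v / z for c, v in raw.items()}


def _k80_from_pq(P: float, Q: float) -> tuple[float, float] | None:
    """K80 transition (A) and transversion (B) distances, or None if saturated."""
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0.0 or w2 <= 0.0:
        return None
    A = 0.5 * math.log(1.0 / w1) - 0.25 * math.log(1.0 / w2)
    B = 0.5 * math.log(1.0 / w2)
    return A, B


def estimate_kappa(cols: list[tuple[str, str]]) -> float:
    """Kappa from fourfold-degenerate and nondegenerate codon positions.

    Positions whose degeneracy class (0-fold or 4-fold) agrees between the
    two codons of a column are pooled per class; a K80 kappa is computed
    per class and the two are combined weighted by site counts. Falls back
    to 1.0 when neither class yields a usable estimate.
    """
    counts = {0: [0, 0, 0], 4: [0, 0, 0]}  # class -> [n_sites, ts, tv]
    for a, b in cols:
        dega = position_degeneracy(a)
        degb = position_degeneracy(b)
        for pos in range(3):
            cls = dega[pos]
            if cls not in (0, 4) or degb[pos] != cls:
                continue
            counts[cls][0] += 1
            if a[pos] != b[pos]:
                if is_transition(a[pos], b[pos]):
                    counts[cls][1] += 1
                else:
                    counts[cls][2] += 1
    num = den = 0.0
    for cls in (0, 4):
        n, ts, tv = counts[cls]
        if n < 10:
            continue
        res = _k80_from_pq(ts / n, tv / n)
        if res is None:
            continue
        A, B = res
        if B <= 0:
            continue
        kappa_cls = 2.0 * A / B
        if kappa_cls <= 0 or not math.isfinite(kappa_cls):
            continue
        num += kappa_cls * n
        den += n
    return num / den if den > 0 else 1.0


def _weighted_sites(
    cols: list[tuple[str, str]], kappa: float, pi: dict[str, float]
) -> tuple[float, float]:
    """Kappa- and frequency-weighted synonymous/nonsynonymous site counts."""
    cache: dict[str, tuple[float, float]] = {}

    def per_codon(codon: str) -> tuple[float, float]:
        if codon in cache:
            return cache[codon]
        syn_w = tot_w = 0.0
        for nb, _pos, ts, syn in sense_neighbors(codon):
            w = (kappa if ts else 1.0) * pi[nb]
            tot_w += w
            if syn:
                syn_w += w
        s = 3.0 * syn_w / tot_w if tot_w > 0 else 0.0
        cache[codon] = (s, 3.0 - s)
        return cache[codon]

    S = N = 0.0
    for a, b in cols:
        sa, na = per_codon(a)
        sb, nb = per_codon(b)
        S += 0.5 * (sa + sb)
        N += 0.5 * (na + nb)
    return S, N


def _weighted_diffs(
    pair_counts: Counter,
    kappa: float,
    omega: float,
    pi: dict[str, float],
) -> tuple[float, float, float, float]:
    """Pathway-weighted difference counts split by type.

    Returns (syn transitions, syn transversions, nonsyn transitions,
    nonsyn transversions). Each minimal pathway between a codon pair is
    weighted by the product over its steps of
    (kappa if transition) x (omega if nonsynonymous) x pi(target codon),
    mirroring how a codon model scores multi-hit pathways; weights are
    normalised per codon pair.
    """
    sts = stv = nts = ntv = 0.0
    for (a, b), n in pair_counts.items():
        if a == b:
            continue
        paths = minimal_pathways(a, b)
        ndiff = len(codon_diffs(a, b))
        if not paths:  # every ordering crosses a stop: count as nonsynonymous
            nts += n * 0.0
            ntv += n * float(ndiff)
            continue
        weights = []
        for path in paths:
            w = 1.0
            for _, to, ts, syn in path:
                w *= (kappa if ts else 1.0) * (1.0 if syn else omega) * pi[to]
            weights.append(w)
        z = sum(weights)
        if z <= 0.0:
            weights = [1.0] * len(paths)
            z = float(len(paths))
        for path, w in zip(paths, weights):
            frac = n * w / z
            for _, _, ts, syn in path:
                if syn and ts:
                    sts += frac
                elif syn:
                    stv += frac
                elif ts:
                    nts += frac
                else:
                    ntv += frac
    return sts, stv, nts, ntv


def _k80_distance(ts: float, tv: float, n_sites: float) -> tuple[float, bool]:
    """K80 distance from transition/transversion counts over n_sites."""
    if n_sites <= 0:
        return 0.0, True
    P = ts / n_sites
    Q = tv / n_sites
    if P + Q <= 0:
        return 0.0, True
    res = _k80_from_pq(P, Q)
    if res is None:
        # saturated under K80; fall back to JC on the pooled proportion
        d, ok = _jukes_cantor(P + Q)
        return d, False if not ok else False
    A, B = res
    return A + B, True


def dnds_yn00(alignment: CodonAlignment) -> DnDsEstimate:
    """YN00-style dN/dS accounting for transition bias and codon usage."""
    cols = _check_alignment(alignment)
    pair_counts = Counter(cols)
    pi = _f3x4(cols)
    kappa = estimate_kappa(cols)

    omega = 1.0
    dN = dS = 0.0
    converged = False
    ok = True
    it = 0
    for it in range(1, MAX_ITER + 1):
        S, N = _weighted_sites(cols, kappa, pi)
        sts, stv, nts, ntv = _weighted_diffs(pair_counts, kappa, omega, pi)
        dS_new, ok_s = _k80_distance(sts, stv, S)
        dN_new, ok_n = _k80_distance(nts, ntv, N)
        ok = ok_s and ok_n
        if abs(dS_new - dS) < TOL and abs(dN_new - dN) < TOL:
            dS, dN = dS_new, dN_new
            converged = True
            break
        dS, dN = dS_new, dN_new
        omega = dN / dS if dS > 0 and math.isfinite(dS) else 1.0
    omega_out = (dN / dS) if (dS > 0 and math.isfinite(dS)) else None
    return DnDsEstimate(
        dN=dN,
        dS=dS,
        omega=omega_out,
        kappa=kappa,
        S_sites=S,
        N_sites=N,
        method="YN00",
        converged=converged and ok,
        n_codons=len(cols),
        iterations=it,
    )


def retain_pair(
    estimate: DnDsEstimate,
    alignment: CodonAlignment,
    max_d: float = 1.5,
    min_aa: int = 33,
) -> bool:
    """Retention filter: dN and dS each below ``max_d`` and the filtered
    alignment at least ``min_aa`` codons long."""
    return (
        math.isfinite(estimate.dN)
        and math.isfinite(estimate.dS)
        and estimate.dN < max_d
        and estimate.dS < max_d
        and alignment.n_codons >= min_aa
    )
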