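"""Pairwise coding-sequence comparison and dN/dS estimation.

Two estimators are provided.  The primary one follows the Yang-Nielsen
(2000) approximate method: F3x4 codon frequencies, kappa estimated from
fourfold-degenerate and nondegenerate sites with a K80 correction, site
counting weighted by kappa and target-codon frequency, and separate
K80-type multiple-hit corrections for the synonymous and nonsynonymous
classes.  Multi-hit codon pairs average over all mutational pathways that
avoid stop codons, with equal pathway weights.  ``dnds_ng86`` is an
independent Nei-Gojobori (1986) implementation used as a cross-check, not
as the primary route.

Codon alignments are protein-guided: proteins are aligned and gaps are
back-propagated, so frames survive by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations, product
from typing import Callable

import numpy as np

from ._align import global_protein_alignment
from .seq_core import SequenceError, translate

BASES = "TCAG"
CODONS = ["".join(c) for c in product(BASES, repeat=3)]
STOPS = {"TAA", "TAG", "TGA"}
SENSE_CODONS = [c for c in CODONS if c not in STOPS]
_AA = {c: translate(c + "TAA") or "*" for c in CODONS}
_TRANSITIONS = {frozenset("AG"), frozenset("CT")}


def _is_transition(a: str, b: str) -> bool:
    return frozenset((a, b)) in _TRANSITIONS


class SaturationWarningError(RuntimeError):
    pass


@dataclass
class CodonAlignment:
    """Two gap-aligned CDSs with equal length and preserved frames."""

    seq_a: str
    seq_b: str

    def __post_init__(self) -> None:
        if len(self.seq_a) != len(self.seq_b):
            raise ValueError("aligned sequences differ in length")
        if len(self.seq_a) % 3:
            raise ValueError("alignment length not a multiple of 3")
        for s in (self.seq_a, self.seq_b):
            if len(s.replace("-", "")) % 3:
                raise ValueError("gaps break the reading frame")

    def codon_columns(self) -> list[tuple[str, str]]:
        return [(self.seq_a[i:i + 3], self.seq_b[i:i + 3])
                for i in range(0, len(self.seq_a), 3)]

    def classify_columns(self) -> list[str]:
        out = []
        for ca, cb in self.codon_columns():
            if "-" in ca or "-" in cb:
                out.append("gapped")
            elif ca == cb:
                out.append("identical")
            else:
                out.append("substituted")
        return out


@dataclass
class DnDsResult:
    dN: float
    dS: float
    kappa: float
    S: float
    N: float
    saturated: bool = False

    @property
    def ratio(self) -> float | None:
        """dN/dS; None when dS = 0 (reported as 'dS = 0', never a number)."""
        if self.dS <= 0:
            return None
        return self.dN / self.dS


def align_codons(cds_a: str, cds_b: str,
                 msa_engine: Callable[[str, str], tuple[str, str]] | None = None
                 ) -> CodonAlignment:
    """Protein-guided codon alignment of two CDSs.

    Trailing stop codons are dropped before alignment; an internal stop is
    an error.  ``msa_engine`` may override the pairwise protein aligner.
    """
    seqs = []
    prots = []
    for cds in (cds_a, cds_b):
        cds = cds.upper()
        if len(cds) % 3:
            raise SequenceError("CDS length not a multiple of 3")
        if cds[-3:] in STOPS:
            cds = cds[:-3]
        prot = translate(cds + "TAA")
        if "*" in prot:
            raise SequenceError("internal stop codon")
        seqs.append(cds)
        prots.append(prot)
    if msa_engine is None:
        pa, pb = global_protein_alignment(prots[0], prots[1])
    else:
        pa, pb = msa_engine(prots[0], prots[1])
    out = ["", ""]
    pos = [0, 0]
    for col in range(len(pa)):
        for k, row in enumerate((pa, pb)):
            if row[col] == "-":
                out[k] += "---"
            else:
                out[k] += seqs[k][3 * pos[k]:3 * pos[k] + 3]
                pos[k] += 1
    return CodonAlignment(out[0], out[1])


def count_differences(aln: CodonAlignment) -> tuple[int, int, int]:
    """(nucleotide substitutions, gapped bases, amino-acid substitutions)."""
    nt_subs = nt_gaps = aa_subs = 0
    for ca, cb in aln.codon_columns():
        for x, y in zip(ca, cb):
            if x == "-" or y == "-":
                nt_gaps += 1
            elif x != y:
                nt_subs += 1
        if "-" not in ca and "-" not in cb and ca != cb:
            if _AA[ca] != _AA[cb]:
                aa_subs += 1
    return nt_subs, nt_gaps, aa_subs


# ---------------------------------------------------------------------------
# shared counting machinery

def _pathway_counts(ca: str, cb: str) -> tuple[float, float, float, float]:
    """Average (syn_ts, syn_tv, nonsyn_ts, nonsyn_tv) difference counts over
    all stop-free mutational pathways between two codons (equal weights)."""
    diff = [i for i in range(3) if ca[i] != cb[i]]
    if not diff:
        return 0.0, 0.0, 0.0, 0.0
    totals = np.zeros(4)
    n_paths = 0
    for order in permutations(diff):
        cur = ca
        steps = []
        ok = True
        for pos in order:
            nxt = cur[:pos] + cb[pos] + cur[pos + 1:]
            if nxt in STOPS:
                ok = False
                break
            syn = _AA[cur] == _AA[nxt]
            ts = _is_transition(cur[pos], cb[pos])
            steps.append((syn, ts))
            cur = nxt
        if ok:
            n_paths += 1
            for syn, ts in steps:
                idx = (0 if syn else 2) + (0 if ts else 1)
                totals[idx] += 1
    if n_paths == 0:
        # all pathways pass through stops; fall back to ignoring the ban
        for order in permutations(diff):
            cur = ca
            for pos in order:
                nxt = cur[:pos] + cb[pos] + cur[pos + 1:]
                syn = _AA[cur] == _AA.get(nxt, "*")
                ts = _is_transition(cur[pos], cb[pos])
                idx = (0 if syn else 2) + (0 if ts else 1)
                totals[idx] += 1
                cur = nxt
            n_paths += 1
    return tuple(totals / n_paths)


def _k80_correct(P: float, Q: float) -> tuple[float, float, float]:
    """K80 distance split into transition/transversion parts.

    Returns (d, a_part, b_part); raises SaturationWarningError when the
    log arguments collapse.
    """
    w1 = 1 - 2 * P - Q
    w2 = 1 - 2 * Q
    if w1 <= 0 or w2 <= 0:
        raise SaturationWarningError("distance saturated")
    a = -0.5 * math.log(w1) + 0.25 * math.log(w2)
    b = -0.25 * math.log(w2)
    return a + 2 * b, a, b


def _pairs(aln: CodonAlignment) -> list[tuple[str, str]]:
    return [(ca, cb) for ca, cb in aln.codon_columns()
            if "-" not in ca and "-" not in cb
            and ca not in STOPS and cb not in STOPS]


def _f3x4(pairs: list[tuple[str, str]]) -> dict[str, float]:
    """F3x4 codon frequencies pooled over both sequences."""
    pos_freq = np.zeros((3, 4))
    for ca, cb in pairs:
        for c in (ca, cb):
            for p in range(3):
                pos_freq[p, BASES.index(c[p])] += 1
    pos_freq /= pos_freq.sum(axis=1, keepdims=True)
    freqs = {}
    for c in SENSE_CODONS:
        freqs[c] = (pos_freq[0, BASES.index(c[0])]
                    * pos_freq[1, BASES.index(c[1])]
                    * pos_freq[2, BASES.index(c[2])])
    total = sum(freqs.values())
    return {c: f / total for c, f in freqs.items()}


def _estimate_kappa(pairs: list[tuple[str, str]]) -> float:
    """kappa from fourfold-degenerate and nondegenerate sites (K80 per
    class, counts-weighted combination); falls back to 2 when undefined."""
    def degeneracy(codon: str, pos: int) -> int:
        aa = _AA[codon]
        n = 0
        for b in BASES:
            alt = codon[:pos] + b + codon[pos + 1:]
            if alt not in STOPS and _AA[alt] == aa:
                n += 1
        return n  # includes the codon itself

    classes = {0: [0, 0, 0], 4: [0, 0, 0]}  # class -> [sites, ts, tv]
    for ca, cb in pairs:
        for p in range(3):
            da, db = degeneracy(ca, p), degeneracy(cb, p)
            for cls, want in ((0, 1), (4, 4)):
                if da == want and db == want:
                    classes[cls][0] += 1
                    if ca[p] != cb[p]:
                        if _is_transition(ca[p], cb[p]):
                            classes[cls][1] += 1
                        else:
                            classes[cls][2] += 1
    ests, weights = [], []
    for cls, (n, ts, tv) in classes.items():
        if n < 10:
            continue
        P, Q = ts / n, tv / n
        try:
            _, a, b = _k80_correct(P, Q)
        except SaturationWarningError:
            continue
        if b > 1e-9:
            ests.append(a / b / 2)
            weights.append(n)
    if not ests:
        return 2.0
    kappa = float(np.average(ests, weights=weights))
    return min(max(kappa, 0.1), 50.0)


def _site_counts(pairs: list[tuple[str, str]], kappa: float,
                 freqs: dict[str, float]) -> tuple[float, float]:
    """Mutation-opportunity counts of synonymous (S) and nonsynonymous (N)
    sites, weighted by kappa and F3x4 target-codon frequencies, averaged
    over the observed codons of both sequences."""
    cache: dict[str, tuple[float, float]] = {}

    def per_codon(codon: str) -> tuple[float, float]:
        if codon in cache:
            return cache[codon]
        s = n = 0.0
        for p in range(3):
            wsum = syn = 0.0
            for b in BASES:
                if b == codon[p]:
                    continue
                alt = codon[:p] + b + codon[p + 1:]
                if alt in STOPS:
                    continue
                w = (kappa if _is_transition(codon[p], b) else 1.0)
                w *= freqs.get(alt, 1e-6)
                wsum += w
                if _AA[alt] == _AA[codon]:
                    syn += w
            if wsum > 0:
                s += syn / wsum
                n += 1 - syn / wsum
        cache[codon] = (s, n)
        return s, n

    S = N = 0.0
    for ca, cb in pairs:
        for c in (ca, cb):
            s, n = per_codon(c)
            S += s / 2
            N += n / 2
    return S, N


def dnds_yn00(aln: CodonAlignment) -> DnDsResult:
    """Yang-Nielsen style dN/dS for one aligned CDS pair.

    Requires at least 30 comparable codon columns; dS > 3 sets the
    saturated flag.
    """
    pairs = _pairs(aln)
    if len(pairs) < 30:
        raise ValueError(f"only {len(pairs)} comparable codons (< 30)")
    freqs = _f3x4(pairs)
    kappa = _estimate_kappa(pairs)
    S, N = _site_counts(pairs, kappa, freqs)
    syn_ts = syn_tv = non_ts = non_tv = 0.0
    for ca, cb in pairs:
        sts, stv, nts, ntv = _pathway_counts(ca, cb)
        syn_ts += sts
        syn_tv += stv
        non_ts += nts
        non_tv += ntv
    sat = False
    if syn_ts + syn_tv == 0:
        dS = 0.0
    else:
        try:
            dS, _, _ = _k80_correct(syn_ts / S, syn_tv / S)
        except SaturationWarningError:
            dS, sat = 3.0, True
    if non_ts + non_tv == 0:
        dN = 0.0
    else:
        try:
            dN, _, _ = _k80_correct(non_ts / N, non_tv / N)
        except SaturationWarningError:
            dN, sat = 3.0, True
    if dS > 3.0:
        sat = True
    return DnDsResult(dN=dN, dS=dS, kappa=kappa, S=S, N=N, saturated=sat)


def dnds_ng86(aln: CodonAlignment) -> DnDsResult:
    """Nei-Gojobori (1986) estimator: unweighted site counting, equal
    pathway averaging, Jukes-Cantor correction.  Cross-check route."""
    pairs = _pairs(aln)
    if len(pairs) < 30:
        raise ValueError(f"only {len(pairs)} comparable codons (< 30)")

    def per_codon(codon: str) -> float:
        s = 0.0
        for p in range(3):
            nalt = syn = 0
            for b in BASES:
                if b == codon[p]:
                    continue
                alt = codon[:p] + b + codon[p + 1:]
                if alt in STOPS:
                    continue
                nalt += 1
                if _AA[alt] == _AA[codon]:
                    syn += 1
            if nalt:
                s += syn / nalt
        return s

    S = sum(per_codon(ca) / 2 + per_codon(cb) / 2 for ca, cb in pairs)
    N = 3 * len(pairs) - S
    Sd = Nd = 0.0
    for ca, cb in pairs:
        sts, stv, nts, ntv = _pathway_counts(ca, cb)
        Sd += sts + stv
        Nd += nts + ntv

    def jc(p: float) -> float:
        arg = 1 - 4 * p / 3
        if arg <= 0:
            raise SaturationWarningError("saturated")
        return -0.75 * math.log(arg)

    sat = False
    try:
        dS = jc(Sd / S) if Sd else 0.0
    except SaturationWarningError:
        dS, sat = 3.0, True
    try:
        dN = jc(Nd / N) if Nd else 0.0
    except SaturationWarningError:
        dN, sat = 3.0, True
    if dS > 3.0:
        sat = True
    return DnDsResult(dN=dN, dS=dS, kappa=1.0, S=S, N=N, saturated=sat)
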