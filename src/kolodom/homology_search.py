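"""Desk-scale local similarity search standing in for tblastn/blastn/blastp.

The engine is word-seeded gapped Smith-Waterman: exact word seeds locate
candidate windows on the target, full affine-gap local DP is run inside each
window, and additional non-overlapping HSPs are recovered by masking and
recursing.  E-values follow the Karlin-Altschul form
``E = K * m * n * exp(-lambda * S)`` with fixed per-mode constants; they are
monotone in the raw score, which is all the pipeline's cutoffs (1e-5 for
protein modes, 1e-100 for nucleotide) require.  Reproducing NCBI BLAST
statistics bit-exactly is a non-goal.

An adapter for externally produced 12-column BLAST tabular hits lets
real-genome runs reuse e.g. NCBI BLAST output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from ._align import (
    BLOSUM62,
    _sw_affine,
    encode_nucleotide,
    encode_protein,
    nt_score_matrix,
)
from .seq_core import GenomeAssembly, Interval, reverse_complement, translate

MODES = ("prot_vs_translated_nuc", "nuc_vs_nuc", "prot_vs_prot")

#: default e-value cutoffs: 1e-5 for translated/protein searches, 1e-100 for
#: nucleotide searches against the source genome.
DEFAULT_CUTOFFS = {
    "prot_vs_translated_nuc": 1e-5,
    "nuc_vs_nuc": 1e-100,
    "prot_vs_prot": 1e-5,
}


@dataclass(frozen=True)
class SearchConfig:
    """Scoring and seeding constants (documented, overridable)."""

    word_prot: int = 5
    word_nuc: int = 12
    prot_gap_open: float = 11.0
    prot_gap_ext: float = 1.0
    nt_match: float = 2.0
    nt_mismatch: float = -3.0
    nt_gap_open: float = 5.0
    nt_gap_ext: float = 2.0
    # Karlin-Altschul constants; gapped BLOSUM62-11/1 and +2/-3-5/2 regimes
    ka_lambda_prot: float = 0.267
    ka_k_prot: float = 0.041
    ka_lambda_nuc: float = 0.625
    ka_k_nuc: float = 0.41
    seed_cluster_gap: int = 1200  # positions between seed clusters before splitting
    diag_band: int = 16  # diagonal width within which seeds co-cluster
    min_cluster_seeds: int = 3  # seed-count rule: sparse random seeds are ignored
    window_pad: int = 200  # window margin around a seed cluster

    def ka(self, mode: str) -> tuple[float, float]:
        if mode == "nuc_vs_nuc":
            return self.ka_lambda_nuc, self.ka_k_nuc
        return self.ka_lambda_prot, self.ka_k_prot


DEFAULT_CONFIG = SearchConfig()


@dataclass(frozen=True)
class Hsp:
    """One high-scoring segment pair."""

    query_id: str
    subject: Interval
    query_span: tuple[int, int]
    score: float
    bitscore: float
    evalue: float
    mode: str

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise ValueError("negative e-value")


@dataclass
class HitRegion:
    """Adjacent HSPs of one query merged into a single hit region."""

    subject: Interval
    member_hsps: list[Hsp] = field(default_factory=list)


@dataclass(frozen=True)
class _Subject:
    """One searchable sequence with instructions to lift local coordinates
    back to the genome."""

    seq: str
    contig: str
    strand: str
    frame: int  # 0..2 for translated frames; -1 for untranslated
    contig_len: int


def _subjects_for(target, mode: str) -> list[_Subject]:
    if isinstance(target, GenomeAssembly):
        contigs = target.contigs
    elif isinstance(target, dict):
        contigs = target
    else:
        raise TypeError("target must be a GenomeAssembly or a name->seq dict")
    subs: list[_Subject] = []
    for name, seq in contigs.items():
        L = len(seq)
        if mode == "prot_vs_prot":
            subs.append(_Subject(seq, name, "+", -1, L))
        elif mode == "nuc_vs_nuc":
            subs.append(_Subject(seq, name, "+", -1, L))
            subs.append(_Subject(reverse_complement(seq), name, "-", -1, L))
        elif mode == "prot_vs_translated_nuc":
            rc = reverse_complement(seq)
            for frame in range(3):
                for strand, s in (("+", seq), ("-", rc)):
                    tail = s[frame:]
                    tail = tail[: len(tail) - len(tail) % 3]
                    if tail:
                        subs.append(_Subject(_frame_translate(tail), name,
                                             strand, frame, L))
        else:
            raise ValueError(f"unknown mode {mode!r}")
    return subs


def _frame_translate(seq: str) -> str:
    """Frame translation keeping stops as '*' and N-codons as 'X'."""
    from Bio.Seq import Seq

    prot = str(Seq(seq).translate())
    return prot


def _lift(sub: _Subject, ts: int, te: int, mode: str) -> Interval:
    """Subject-local half-open span -> genomic Interval."""
    if mode == "prot_vs_prot":
        return Interval(sub.contig, ts, te, "+")
    if mode == "nuc_vs_nuc":
        if sub.strand == "+":
            return Interval(sub.contig, ts, te, "+")
        return Interval(sub.contig, sub.contig_len - te, sub.contig_len - ts, "-")
    # translated: aa coords -> nt coords on the searched strand
    nts, nte = sub.frame + 3 * ts, sub.frame + 3 * te
    if sub.strand == "+":
        return Interval(sub.contig, nts, nte, "+")
    return Interval(sub.contig, sub.contig_len - nte, sub.contig_len - nts, "-")


class Searcher:
    """Reusable word index over one target for one search mode."""

    def __init__(self, target, mode: str, config: SearchConfig = DEFAULT_CONFIG):
        if mode not in MODES:
            raise ValueError(f"unknown mode {mode!r}")
        self.mode = mode
        self.config = config
        self.word = config.word_nuc if mode == "nuc_vs_nuc" else config.word_prot
        self.subjects = _subjects_for(target, mode)
        seen: dict[str, int] = {}
        for s in self.subjects:
            seen[s.contig] = s.contig_len
        self.total_len = sum(seen.values())
        self.index: dict[str, list[tuple[int, int]]] = {}
        for si, sub in enumerate(self.subjects):
            seq = sub.seq
            for p in range(len(seq) - self.word + 1):
                w = seq[p:p + self.word]
                if "N" in w or "X" in w or "*" in w:
                    continue
                self.index.setdefault(w, []).append((si, p))

    # -- scoring helpers -------------------------------------------------
    def _score_matrix(self, q: np.ndarray, t: np.ndarray) -> np.ndarray:
        if self.mode == "nuc_vs_nuc":
            base = nt_score_matrix(self.config.nt_match, self.config.nt_mismatch)
        else:
            base = BLOSUM62
        return base[q][:, t]

    def _gaps(self) -> tuple[float, float]:
        if self.mode == "nuc_vs_nuc":
            return self.config.nt_gap_open, self.config.nt_gap_ext
        return self.config.prot_gap_open, self.config.prot_gap_ext

    def _encode(self, seq: str) -> np.ndarray:
        if self.mode == "nuc_vs_nuc":
            return encode_nucleotide(seq)
        return encode_protein(seq)

    def _evalue(self, score: float, m: int) -> float:
        lam, k = self.config.ka(self.mode)
        return k * m * max(self.total_len, 1) * math.exp(-lam * score)

    def min_score(self, m: int, cutoff: float) -> float:
        lam, k = self.config.ka(self.mode)
        return (math.log(k * m * max(self.total_len, 1)) - math.log(cutoff)) / lam

    # -- search ----------------------------------------------------------
    def search(self, query_id: str, query: str, evalue_cutoff: float | None = None
               ) -> list[Hsp]:
        if evalue_cutoff is None:
            evalue_cutoff = DEFAULT_CUTOFFS[self.mode]
        if evalue_cutoff <= 0:
            raise ValueError("cutoff must be > 0")
        query = query.upper()
        alphabet = set("ACGTN") if self.mode == "nuc_vs_nuc" else None
        if alphabet is not None and not set(query) <= alphabet:
            raise ValueError("nucleotide query contains non-ACGTN characters")
        if not self.subjects or not query:
            return []
        m = len(query)
        min_score = self.min_score(m, evalue_cutoff)
        seeds: dict[int, list[tuple[int, int]]] = {}
        for qp in range(m - self.word + 1):
            for si, tp in self.index.get(query[qp:qp + self.word], ()):
                seeds.setdefault(si, []).append((tp - qp, tp))
        eq = self._encode(query)
        go, ge = self._gaps()
        hsps: list[Hsp] = []
        pad = self.config.window_pad + self.word
        for si, diag_pos in seeds.items():
            sub = self.subjects[si]
            # cluster seeds within a diagonal band and a position gap; the
            # two-hit rule drops lone random seeds so windows stay local
            diag_pos.sort()
            clusters: list[list[tuple[int, int]]] = []
            cur: list[tuple[int, int]] = []
            for dg, tp in diag_pos:
                if (cur and (dg - cur[-1][0] > self.config.diag_band
                             or abs(tp - cur[-1][1]) >
                             self.config.seed_cluster_gap)):
                    clusters.append(cur)
                    cur = []
                cur.append((dg, tp))
            if cur:
                clusters.append(cur)
            et = self._encode(sub.seq)
            for cl in clusters:
                if len(cl) < self.config.min_cluster_seeds:
                    continue
                tmin = min(tp for _, tp in cl)
                tmax = max(tp for _, tp in cl)
                ws = max(0, tmin - pad)
                we = min(len(sub.seq), tmax + pad)
                self._hsps_in_window(query_id, eq, et, sub, ws, we, go, ge,
                                     min_score, m, hsps)
        hsps = self._dedup(hsps)
        hsps.sort(key=lambda h: (h.evalue, h.subject.contig, h.subject.start))
        return [h for h in hsps if h.evalue < evalue_cutoff]

    def _hsps_in_window(self, query_id, eq, et, sub, ws, we, go, ge,
                        min_score, m, out, depth=0):
        if we - ws < self.word or depth > 6:
            return
        S = self._score_matrix(eq, et[ws:we])
        score, qs, qe, ts, te = _sw_affine(S, go, ge)
        if score < min_score or qe <= qs:
            return
        iv = _lift(sub, ws + ts, ws + te, self.mode)
        out.append(Hsp(query_id, iv, (int(qs), int(qe)), float(score),
                       bitscore=self._bitscore(score),
                       evalue=self._evalue(score, m), mode=self.mode))
        self._hsps_in_window(query_id, eq, et, sub, ws, ws + ts, go, ge,
                             min_score, m, out, depth + 1)
        self._hsps_in_window(query_id, eq, et, sub, ws + te, we, go, ge,
                             min_score, m, out, depth + 1)

    def _bitscore(self, score: float) -> float:
        lam, k = self.config.ka(self.mode)
        return (lam * score - math.log(k)) / math.log(2)

    @staticmethod
    def _dedup(hsps: list[Hsp]) -> list[Hsp]:
        """Drop HSPs mostly contained in a better-scoring one."""
        kept: list[Hsp] = []
        for h in sorted(hsps, key=lambda x: -x.score):
            redundant = False
            for k in kept:
                if (k.subject.contig == h.subject.contig
                        and k.subject.strand == h.subject.strand):
                    ov = (min(k.subject.end, h.subject.end)
                          - max(k.subject.start, h.subject.start))
                    if ov > 0.5 * len(h.subject):
                        redundant = True
                        break
            if not redundant:
                kept.append(h)
        return kept


def search(query: str, target, mode: str, evalue_cutoff: float | None = None,
           query_id: str = "query", config: SearchConfig = DEFAULT_CONFIG
           ) -> list[Hsp]:
    """One-shot convenience wrapper around :class:`Searcher`."""
    return Searcher(target, mode, config).search(query_id, query, evalue_cutoff)


def merge_hit_regions(hsps: list[Hsp], query_len: int) -> list[HitRegion]:
    """Cluster HSPs of one query into hit regions.

    HSPs on the same contig and strand join one region transitively whenever
    the gap between their subject intervals is smaller than the query length
    (0 when they overlap).  Strands never merge: a transposase CDS lies on
    one strand.
    """
    if query_len <= 0:
        raise ValueError("query_len must be positive")
    groups: dict[tuple[str, str], list[Hsp]] = {}
    for h in hsps:
        groups.setdefault((h.subject.contig, h.subject.strand), []).append(h)
    regions: list[HitRegion] = []
    for (contig, strand), members in sorted(groups.items()):
        members.sort(key=lambda h: (h.subject.start, h.subject.end))
        cur = [members[0]]
        cur_end = members[0].subject.end
        for h in members[1:]:
            if max(0, h.subject.start - cur_end) < query_len:
                cur.append(h)
                cur_end = max(cur_end, h.subject.end)
            else:
                regions.append(_region(contig, strand, cur))
                cur = [h]
                cur_end = h.subject.end
        regions.append(_region(contig, strand, cur))
    regions.sort(key=lambda r: (r.subject.contig, r.subject.start))
    return regions


def _region(contig: str, strand: str, members: list[Hsp]) -> HitRegion:
    start = min(h.subject.start for h in members)
    end = max(h.subject.end for h in members)
    return HitRegion(Interval(contig, start, end, strand), list(members))


# ---------------------------------------------------------------------------
# BLAST tabular (outfmt-6 style) adapter

_TAB_COLS = 12


def read_tabular_hits(path, mode: str) -> list[Hsp]:
    """Read 12-column BLAST tabular hits (qseqid sseqid pident length
    mismatch gapopen qstart qend sstart send evalue bitscore).

    Coordinates are 1-based inclusive; ``sstart > send`` marks a minus-strand
    hit.  Malformed rows raise with the offending line number.
    """
    out: list[Hsp] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != _TAB_COLS:
                raise ValueError(f"line {ln}: expected {_TAB_COLS} columns, "
                                 f"got {len(parts)}")
            try:
                qid, sid = parts[0], parts[1]
                qstart, qend = int(parts[6]), int(parts[7])
                sstart, send = int(parts[8]), int(parts[9])
                evalue, bitscore = float(parts[10]), float(parts[11])
            except ValueError as exc:
                raise ValueError(f"line {ln}: {exc}") from None
            if sstart <= send:
                iv = Interval(sid, sstart - 1, send, "+")
            else:
                iv = Interval(sid, send - 1, sstart, "-")
            out.append(Hsp(qid, iv, (qstart - 1, qend), score=bitscore,
                           bitscore=bitscore, evalue=evalue, mode=mode))
    return out


def write_tabular_hits(path, hsps: list[Hsp]) -> None:
    with open(path, "w") as fh:
        for h in hsps:
            if h.subject.strand == "+":
                ss, se = h.subject.start + 1, h.subject.end
            else:
                ss, se = h.subject.end, h.subject.start + 1
            fh.write("\t".join(map(str, [
                h.query_id, h.subject.contig, "100.00",
                h.query_span[1] - h.query_span[0], 0, 0,
                h.query_span[0] + 1, h.query_span[1], ss, se,
                f"{h.evalue:.3g}", f"{h.bitscore:.1f}"])) + "\n")
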