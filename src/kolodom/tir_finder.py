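"""Full-length element reconstruction around repetitive transposase CDSs.

Copies of one subfamily share the transposon body (TIR to TIR) and diverge
into unrelated host flanks beyond it.  Element boundaries are therefore
change points in cross-copy flank identity: walking outward from the CDS,
mean pairwise identity stays high inside the element and collapses to the
~25% background level outside.  The boundary estimator is a CUSUM argmax —
the outermost offset maximizing the cumulative excess of per-position
identity over ``drop_threshold``, taking the first index attaining the
maximum — which is exact when flanks differ right at the element edge and
stays within a few bases under realistic copy divergence.

Terminal validation mirrors the published convention: both TIRs are read
5'->3' inward (the right one reverse-complemented), so an intact element
shows two TIRs starting AG and is flanked by a duplicated TTAA target site.
"""

from __future__ import annotations

from dataclasses import dataclass

from .seq_core import GenomeAssembly, Interval, dotplot_matches, reverse_complement

DEFAULT_TIR_LEN = 16
DEFAULT_WINDOW = 50
DEFAULT_DROP = 0.5
MIN_FLANK = 15_000
TSD = "TTAA"


class BoundaryUndetermined(RuntimeError):
    """Raised when boundaries cannot be inferred (e.g. a single copy)."""


@dataclass
class FlankedCopy:
    """One subfamily copy: its CDS locus plus the CDS-oriented sequence with
    flanks (``seq[cds_start:cds_end]`` is the CDS on the + strand of seq)."""

    cds_locus: Interval
    seq: str
    cds_start: int
    cds_end: int


@dataclass
class FullLengthElement:
    cds_name: str
    element: Interval
    length: int
    tir_left: str
    tir_right: str
    tsd_left: str
    tsd_right: str
    terminal_ok: bool
    tsd_ok: bool
    tir_similarity: int = 0  # word-12 matches between the two TIR reads

    def __post_init__(self) -> None:
        if len(self.tir_left) != len(self.tir_right):
            raise ValueError("TIR lengths differ")
        if len(self.tir_left) < 10:
            raise ValueError("TIR shorter than 10 bp")


def _identity_track(seqs: list[str]) -> list[float]:
    """Per-position mean pairwise identity across equal-direction strings of
    possibly different lengths (truncated to the shortest)."""
    n = min(len(s) for s in seqs)
    k = len(seqs)
    out = []
    for i in range(n):
        match = total = 0
        for a in range(k):
            for b in range(a + 1, k):
                total += 1
                if seqs[a][i] == seqs[b][i]:
                    match += 1
        out.append(match / total)
    return out


def _cusum_boundary(track: list[float], drop_threshold: float,
                    window: int) -> int:
    """Offset of the identity change point: first argmax of the cumulative
    sum of (identity - drop_threshold), scanned outward from the CDS."""
    best = cum = 0.0
    best_i = 0
    for i, m in enumerate(track):
        cum += m - drop_threshold
        if cum > best + 1e-12:
            best = cum
            best_i = i + 1
    return best_i


def find_element_boundaries(copies: list[FlankedCopy], min_copies: int = 2,
                            window: int = DEFAULT_WINDOW,
                            drop_threshold: float = DEFAULT_DROP
                            ) -> tuple[int, int]:
    """(left_offset, right_offset) of the shared element relative to the CDS
    (bases upstream of cds_start, bases downstream of cds_end).

    Requires at least ``min_copies`` copies; one copy cannot define a
    boundary and raises :class:`BoundaryUndetermined`.
    """
    if len(copies) < max(2, min_copies):
        raise BoundaryUndetermined(
            f"{len(copies)} copies; boundaries need at least {max(2, min_copies)}")
    lefts = [c.seq[:c.cds_start][::-1] for c in copies]  # outward-reading
    rights = [c.seq[c.cds_end:] for c in copies]
    left_off = _cusum_boundary(_identity_track(lefts), drop_threshold, window)
    right_off = _cusum_boundary(_identity_track(rights), drop_threshold, window)
    return left_off, right_off


def validate_termini(element_seq: str, left_flank4: str, right_flank4: str,
                     tir_len: int = DEFAULT_TIR_LEN
                     ) -> tuple[str, str, bool, bool, int]:
    """Check the terminal structure of a reconstructed element.

    Returns (tir_left, tir_right, terminal_ok, tsd_ok, tir_similarity);
    tir_right is read inward on the reverse strand so both TIR strings of an
    intact element begin AG; tsd_ok requires both 4 bp flanks to equal TTAA.
    """
    if len(element_seq) < 2 * tir_len:
        raise ValueError("element shorter than twice the TIR length")
    tir_left = element_seq[:tir_len]
    tir_right = reverse_complement(element_seq[-tir_len:])
    terminal_ok = tir_left.startswith("AG") and tir_right.startswith("AG")
    tsd_ok = left_flank4 == TSD and right_flank4 == TSD
    similarity = len(dotplot_matches(tir_left, tir_right, 12)) if tir_len >= 12 \
        else 0
    return tir_left, tir_right, terminal_ok, tsd_ok, similarity


def _refine_tsd(seq: str, es: int, ee: int, tsd: str = TSD,
                max_shift: int = 12) -> tuple[int, int]:
    """Snap raw boundaries to the target-site duplication.

    The TSD is host sequence duplicated at insertion, so every copy carries
    it and cross-copy identity alone cannot exclude it from the element.
    Each boundary slides inward to the smallest shift placing an intact TSD
    just outside; a side without a TSD (a mutated target site) borrows the
    other side's shift, since the identity overshoot is symmetric.
    """
    k = len(tsd)
    ls = next((s for s in range(max_shift + 1)
               if seq[es + s - k:es + s] == tsd), None)
    rs = next((s for s in range(max_shift + 1)
               if seq[ee - s:ee - s + k] == tsd), None)
    if ls is None and rs is None:
        return es, ee
    if ls is None:
        ls = rs
    if rs is None:
        rs = ls
    return es + ls, ee - rs


def extract_flanked_copies(cds_loci: list[Interval], genome: GenomeAssembly,
                           flank: int = MIN_FLANK) -> list[FlankedCopy]:
    """Cut each CDS with up to ``flank`` bp of genomic context (to contig
    ends), oriented so the CDS reads forward."""
    out = []
    for locus in cds_loci:
        contig = genome.contigs[locus.contig]
        s = max(0, locus.start - flank)
        e = min(len(contig), locus.end + flank)
        seq = contig[s:e]
        cs, ce = locus.start - s, locus.end - s
        if locus.strand == "-":
            seq = reverse_complement(seq)
            cs, ce = len(seq) - ce, len(seq) - cs
        out.append(FlankedCopy(locus, seq, cs, ce))
    return out


def reconstruct_full_length(cds_name: str, cds_locus: Interval,
                            genome: GenomeAssembly,
                            subfamily_loci: list[Interval],
                            min_copies: int = 2, window: int = DEFAULT_WINDOW,
                            drop_threshold: float = DEFAULT_DROP,
                            tir_len: int = DEFAULT_TIR_LEN
                            ) -> FullLengthElement | None:
    """Reconstruct the full-length element containing one repetitive CDS.

    ``subfamily_loci`` are the CDS loci of all intact copies of the
    subfamily (including ``cds_locus``).  Returns None when boundaries are
    undetermined.
    """
    copies = extract_flanked_copies(subfamily_loci, genome)
    try:
        left_off, right_off = find_element_boundaries(copies, min_copies,
                                                      window, drop_threshold)
    except BoundaryUndetermined:
        return None
    target = next(c for c in copies if c.cds_locus == cds_locus)
    es = target.cds_start - left_off
    ee = target.cds_end + right_off
    es, ee = _refine_tsd(target.seq, es, ee)
    if es < 4 or ee > len(target.seq) - 4:
        return None
    element_seq = target.seq[es:ee]
    lf4 = target.seq[es - 4:es]
    rf4 = target.seq[ee:ee + 4]
    tl, tr, term_ok, tsd_ok, sim = validate_termini(element_seq, lf4, rf4,
                                                    tir_len)
    # lift element span back to forward-genome coordinates
    contig_len = len(genome.contigs[cds_locus.contig])
    offset = max(0, cds_locus.start - MIN_FLANK)
    if cds_locus.strand == "+":
        g_start, g_end = offset + es, offset + ee
    else:
        flank_len = len(target.seq)
        g_start = offset + flank_len - ee
        g_end = offset + flank_len - es
    element = Interval(cds_locus.contig, g_start, min(g_end, contig_len),
                       cds_locus.strand)
    return FullLengthElement(cds_name, element, ee - es, tl, tr, lf4, rf4,
                             term_ok, tsd_ok, sim)
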