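"""Stage 1: from query transposase proteins to trimmed prospective CDSs.

Hit regions from the forward translated search are widened by 1800 bp
flanks, the longest ORF (>= 1800 bp, stop codon included) in each region
becomes a candidate, candidates are verified by a backward protein search
against the query set (homologous to at least five queries), deduplicated
by locus overlap, serially named by descending ORF length, and finally
start-trimmed so translation initiation sites align across the family.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, Sequence

from . import homology_search as hs
from ._align import progressive_align
from .seq_core import GenomeAssembly, Interval, Orf, find_orfs, translate

MIN_ORF_NT = 1800
DEFAULT_FLANK = 1800
BACKWARD_MIN_HITS = 5


@dataclass
class ProspectiveCDS:
    """A trimmed candidate transposase CDS.

    ``longest_orf_nt`` and ``trimmed_nt`` both include the stop codon, the
    convention under which a 2352 bp CDS encodes a 783-residue protein.
    """

    name: str
    locus: Interval
    longest_orf_nt: int
    trimmed_nt: int
    cds: str
    protein: str
    trim_flagged: bool = False

    def __post_init__(self) -> None:
        if self.trimmed_nt > self.longest_orf_nt:
            raise ValueError("trimmed CDS longer than its source ORF")
        if len(self.cds) != self.trimmed_nt:
            raise ValueError("cds length disagrees with trimmed_nt")
        if translate(self.cds) != self.protein:
            raise ValueError("cds does not translate to protein")


def extract_candidate_regions(regions: Sequence[hs.HitRegion],
                              genome: GenomeAssembly,
                              flank: int = DEFAULT_FLANK) -> list[Interval]:
    """Widen hit regions by ``flank`` bp each side, clip to contig bounds and
    union overlapping widened intervals on the same contig and strand."""
    widened: dict[tuple[str, str], list[tuple[int, int]]] = {}
    for r in regions:
        iv = r.subject
        L = len(genome.contigs[iv.contig])
        widened.setdefault((iv.contig, iv.strand), []).append(
            (max(0, iv.start - flank), min(L, iv.end + flank)))
    out: list[Interval] = []
    for (contig, strand), spans in sorted(widened.items()):
        spans.sort()
        cs, ce = spans[0]
        for s, e in spans[1:]:
            if s <= ce:
                ce = max(ce, e)
            else:
                out.append(Interval(contig, cs, ce, strand))
                cs, ce = s, e
        out.append(Interval(contig, cs, ce, strand))
    out.sort(key=lambda iv: (iv.contig, iv.start))
    return out


def call_longest_orf(region_seq: str, region: Interval,
                     min_nt: int = MIN_ORF_NT) -> Orf | None:
    """Longest qualifying ORF in a region, lifted to genome coordinates.

    Both strands of the extracted fragment are searched (the fragment is
    given in forward-genome orientation).  Ties break by leftmost genomic
    start, then '+' strand.  Returns None when every ORF is shorter than
    ``min_nt``.
    """
    orfs = find_orfs(region_seq, min_nt, contig=region.contig)
    if not orfs:
        return None
    lifted = [Orf(Interval(region.contig, region.start + o.locus.start,
                           region.start + o.locus.end, o.locus.strand),
                  o.nt_length, o.protein) for o in orfs]
    lifted.sort(key=lambda o: (-o.nt_length, o.locus.start, o.locus.strand))
    return lifted[0]


def backward_verify(candidate_protein: str, query_proteins: dict[str, str],
                    evalue_cutoff: float = 1e-5,
                    min_hits: int = BACKWARD_MIN_HITS) -> bool:
    """True iff the candidate hits at least ``min_hits`` distinct queries in
    a protein-vs-protein search below the cutoff."""
    if not query_proteins:
        raise ValueError("empty query set")
    hits = hs.search(candidate_protein, query_proteins, "prot_vs_prot",
                     evalue_cutoff, query_id="candidate")
    return len({h.subject.contig for h in hits}) >= min_hits


def dedup_candidates(candidates: list[ProspectiveCDS],
                     min_overlap: float = 0.5) -> list[ProspectiveCDS]:
    """Collapse candidates whose loci overlap >= ``min_overlap`` of the
    shorter locus, keeping the longer ORF (multiple queries hit one locus)."""
    kept: list[ProspectiveCDS] = []
    for c in sorted(candidates, key=lambda c: -c.longest_orf_nt):
        dup = False
        for k in kept:
            if k.locus.contig == c.locus.contig:
                ov = (min(k.locus.end, c.locus.end)
                      - max(k.locus.start, c.locus.start))
                if ov >= min_overlap * min(len(k.locus), len(c.locus)):
                    dup = True
                    break
        if not dup:
            kept.append(c)
    return kept


def trim_to_majority_start(candidates: list[ProspectiveCDS],
                           msa_engine: Callable[[dict[str, str]], dict[str, str]]
                           = progressive_align) -> list[ProspectiveCDS]:
    """Align candidate proteins and trim excess 5' sequence so translation
    initiation sites sit in the modal alignment column.

    A candidate starting before the majority column is cut back to the
    methionine whose aligned position is nearest at-or-after that column;
    a candidate with no such methionine is left untrimmed and flagged.
    """
    if len(candidates) < 3:
        raise ValueError("need at least 3 candidates to define a majority start")
    msa = msa_engine({c.name: c.protein for c in candidates})
    start_col: dict[str, int] = {}
    res_cols: dict[str, list[int]] = {}
    for name, row in msa.items():
        cols = [i for i, ch in enumerate(row) if ch != "-"]
        res_cols[name] = cols
        start_col[name] = cols[0]
    counts: dict[int, int] = {}
    for col in start_col.values():
        counts[col] = counts.get(col, 0) + 1
    majority = max(counts.items(), key=lambda kv: (kv[1], -kv[0]))[0]
    out: list[ProspectiveCDS] = []
    for c in candidates:
        if start_col[c.name] >= majority:
            out.append(c)
            continue
        cols = res_cols[c.name]
        met_cols = [(cols[i], i) for i, aa in enumerate(c.protein) if aa == "M"]
        eligible = [(col, i) for col, i in met_cols if col >= majority]
        if not eligible:
            out.append(replace(c, trim_flagged=True))
            continue
        _, res_idx = min(eligible, key=lambda t: t[0])
        new_cds = c.cds[3 * res_idx:]
        start, end = c.locus.start, c.locus.end
        if c.locus.strand == "+":
            start += 3 * res_idx
        else:
            end -= 3 * res_idx
        out.append(replace(c, locus=Interval(c.locus.contig, start, end,
                                             c.locus.strand),
                           trimmed_nt=len(new_cds), cds=new_cds,
                           protein=c.protein[res_idx:]))
    return out


def discover_cds(query_proteins: dict[str, str], genome: GenomeAssembly,
                 forward_cutoff: float = 1e-5, backward_cutoff: float = 1e-5,
                 flank: int = DEFAULT_FLANK, min_orf_nt: int = MIN_ORF_NT,
                 min_backward_hits: int = BACKWARD_MIN_HITS,
                 msa_engine: Callable = progressive_align,
                 searcher: hs.Searcher | None = None,
                 config: hs.SearchConfig = hs.DEFAULT_CONFIG
                 ) -> list[ProspectiveCDS]:
    """Full discovery stage for one genome.

    Candidates are named ``<species_tag><serial>`` ordered by descending
    longest-ORF length, mirroring the serial naming of the locus tables.
    """
    if searcher is None:
        searcher = hs.Searcher(genome, "prot_vs_translated_nuc", config)
    all_regions: list[hs.HitRegion] = []
    for qname, qprot in query_proteins.items():
        hsps = searcher.search(qname, qprot, forward_cutoff)
        all_regions.extend(hs.merge_hit_regions(hsps, 3 * len(qprot)))
    regions = extract_candidate_regions(all_regions, genome, flank)
    candidates: list[ProspectiveCDS] = []
    for region in regions:
        seq = genome.contigs[region.contig][region.start:region.end]
        orf = call_longest_orf(seq, region, min_orf_nt)
        if orf is None:
            continue
        if not backward_verify(orf.protein, query_proteins, backward_cutoff,
                               min_backward_hits):
            continue
        cds = genome.fetch(orf.locus)
        candidates.append(ProspectiveCDS(
            name="", locus=orf.locus, longest_orf_nt=orf.nt_length,
            trimmed_nt=orf.nt_length, cds=cds, protein=orf.protein))
    candidates = dedup_candidates(candidates)
    candidates.sort(key=lambda c: (-c.longest_orf_nt, c.locus.contig,
                                   c.locus.start))
    named = [replace(c, name=f"{genome.species_tag}{i + 1}")
             for i, c in enumerate(candidates)]
    if len(named) >= 3:
        named = trim_to_majority_start(named, msa_engine)
    return named
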