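"""Sequence primitives shared by every pipeline stage.

Coordinates are 0-based half-open internally; report writers convert to the
1-based inclusive ``Chr05:4592573..4595167(-)`` style used throughout the
locus tables.  Open reading frames are measured *including* the stop codon,
so a 2352 bp CDS encodes a 783-residue protein; the protein string never
carries the terminal stop.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
_COMPLEMENT = str.maketrans("ACGTNRYSWKMBDHVacgtnryswkmbdhv",
                            "TGCANYRSWMKVHDBtgcanyrswmkvhdb")
_IUPAC = frozenset("ACGTNRYSWKMBDHV")

CONTIG_CLASSES = ("diploid_chr", "tetraploid_L", "tetraploid_S", "scaffold")


class SequenceError(ValueError):
    """Raised for malformed nucleotide input (bad alphabet, broken frame)."""


@dataclass(frozen=True)
class Interval:
    """Strand-aware 0-based half-open genomic interval."""

    contig: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"bad interval [{self.start},{self.end})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"bad strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "Interval") -> bool:
        return (self.contig == other.contig
                and self.start < other.end and other.start < self.end)

    def gap_to(self, other: "Interval") -> int:
        """Gap in bp between two intervals on the same contig (0 if they touch
        or overlap)."""
        if self.contig != other.contig:
            raise ValueError("intervals on different contigs")
        return max(0, max(self.start, other.start) - min(self.end, other.end))

    def to_locus_string(self) -> str:
        """Render 1-based inclusive, e.g. ``Chr05:4592573..4595167(-)``."""
        return f"{self.contig}:{self.start + 1}..{self.end}({self.strand})"

    @classmethod
    def from_locus_string(cls, text: str) -> "Interval":
        m = re.fullmatch(r"(.+):(\d+)\.\.(\d+)\(([+-−])\)", text.strip())
        if m is None:
            raise ValueError(f"unparseable locus {text!r}")
        contig, start, end, strand = m.groups()
        strand = "-" if strand in ("-", "−") else "+"
        return cls(contig, int(start) - 1, int(end), strand)


@dataclass
class GenomeAssembly:
    """Named contigs plus a chromosome-class label per contig.

    Classes distinguish diploid chromosomes, the L/S homeologous chromosomes
    of an allotetraploid, and unplaced scaffolds.
    """

    contigs: dict[str, str]
    contig_class: dict[str, str]
    species_tag: str = ""

    def __post_init__(self) -> None:
        self.contigs = {name: seq.upper() for name, seq in self.contigs.items()}
        for name in self.contigs:
            cls = self.contig_class.get(name)
            if cls not in CONTIG_CLASSES:
                raise ValueError(f"contig {name!r} has class {cls!r}")

    def fetch(self, iv: Interval) -> str:
        """Forward-strand slice; reverse-complemented when iv is on '-'."""
        seq = self.contigs[iv.contig][iv.start:iv.end]
        return reverse_complement(seq) if iv.strand == "-" else seq

    def total_length(self) -> int:
        return sum(len(s) for s in self.contigs.values())


@dataclass(frozen=True)
class Orf:
    """An ATG->stop open reading frame; nt_length counts the stop codon."""

    locus: Interval
    nt_length: int
    protein: str

    def __post_init__(self) -> None:
        if self.nt_length % 3:
            raise ValueError("ORF length not a multiple of 3")
        if self.nt_length != 3 * (len(self.protein) + 1):
            raise ValueError("ORF length inconsistent with protein length")


def reverse_complement(seq: str) -> str:
    for ch in set(seq.upper()):
        if ch not in _IUPAC:
            raise SequenceError(f"non-IUPAC character {ch!r}")
    return seq.translate(_COMPLEMENT)[::-1]


def translate(cds: str) -> str:
    """Translate a CDS with the standard code.

    A trailing stop codon is dropped; internal stops are rendered ``*`` so a
    broken frame stays visible.  Length must be a multiple of 3.
    """
    cds = cds.upper()
    if len(cds) % 3:
        raise SequenceError(f"CDS length {len(cds)} not a multiple of 3")
    prot = str(Seq(cds).translate())
    if prot.endswith("*"):
        prot = prot[:-1]
    return prot


def _scan_frame(seq: str, offset: int, min_nt_len: int) -> Iterator[tuple[int, int, str]]:
    """Yield (start, end, protein) for ATG->stop spans in one forward frame.

    A codon containing N kills the ORF(s) crossing it (assembly gaps are not
    guessed through).
    """
    n = len(seq)
    open_starts: list[int] = []
    for pos in range(offset, n - 2, 3):
        codon = seq[pos:pos + 3]
        if "N" in codon:
            open_starts.clear()
            continue
        if codon in STOP_CODONS:
            end = pos + 3
            for s in open_starts:
                if end - s >= min_nt_len:
                    yield s, end, translate(seq[s:end])
            open_starts.clear()
        elif codon == "ATG":
            open_starts.append(pos)


def find_orfs(seq: str, min_nt_len: int, contig: str = "") -> list[Orf]:
    """All ATG->stop ORFs of length >= min_nt_len in all six frames.

    Results are sorted by descending length, then leftmost genomic start,
    then '+' strand first — the tie-break used by longest-ORF calling.
    """
    if min_nt_len < 3 or min_nt_len % 3:
        raise ValueError("min_nt_len must be >= 3 and divisible by 3")
    seq = seq.upper()
    out: list[Orf] = []
    for frame in range(3):
        for s, e, prot in _scan_frame(seq, frame, min_nt_len):
            out.append(Orf(Interval(contig, s, e, "+"), e - s, prot))
    rc = reverse_complement(seq)
    n = len(seq)
    for frame in range(3):
        for s, e, prot in _scan_frame(rc, frame, min_nt_len):
            out.append(Orf(Interval(contig, n - e, n - s, "-"), e - s, prot))
    out.sort(key=lambda o: (-o.nt_length, o.locus.start, o.locus.strand))
    return out


def dotplot_matches(a: str, b: str, word: int) -> list[tuple[int, int]]:
    """Exact word matches between two sequences: all (i, j) with
    a[i:i+word] == b[j:j+word].

    Word-size defaults elsewhere in the pipeline are 12 (nucleotide) and 5
    (protein).
    """
    if word < 1:
        raise ValueError("word must be >= 1")
    index: dict[str, list[int]] = {}
    for j in range(len(b) - word + 1):
        index.setdefault(b[j:j + word], []).append(j)
    hits = [(i, j)
            for i in range(len(a) - word + 1)
            for j in index.get(a[i:i + word], ())]
    hits.sort()
    return hits


# ---------------------------------------------------------------------------
# File I/O

def read_fasta(path) -> dict[str, str]:
    """Multi-record FASTA -> ordered name->sequence map (uppercased)."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path, sequences: dict[str, str], width: int = 70) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="")
               for name, seq in sequences.items()]
    SeqIO.write(records, str(path), "fasta-2line" if width == 0 else "fasta")


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    name: str
    interval: Interval


def read_gene_models(path) -> list[GeneModel]:
    """GFF3 reader restricted to gene/mRNA features (ID and Name attributes).

    mRNA features are only used when no gene parent provides the locus.
    """
    import gffutils

    db = gffutils.create_db(str(path), dbfn=":memory:", force=True,
                            merge_strategy="create_unique", keep_order=True)
    out: list[GeneModel] = []
    seen_gene_ids: set[str] = set()
    for ftype in ("gene", "mRNA"):
        for feat in db.features_of_type(ftype):
            if ftype == "mRNA":
                parents = feat.attributes.get("Parent", [])
                if any(p in seen_gene_ids for p in parents):
                    continue
            gid = feat.attributes.get("ID", [feat.id])[0]
            name = feat.attributes.get("Name", [gid])[0]
            iv = Interval(feat.seqid, feat.start - 1, feat.end,
                          feat.strand if feat.strand in "+-" else "+")
            out.append(GeneModel(gid, name, iv))
            if ftype == "gene":
                seen_gene_ids.add(gid)
    return out


def write_bed(path, intervals: Iterable[tuple[str, Interval]]) -> None:
    """BED6 output (name per interval)."""
    with open(path, "w") as fh:
        for name, iv in intervals:
            fh.write(f"{iv.contig}\t{iv.start}\t{iv.end}\t{name}\t0\t"
                     f"{iv.strand}\n")


def write_gene_models(path, models: Iterable[GeneModel], source: str = "kolodom") -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in models:
            iv = m.interval
            fh.write(f"{iv.contig}\t{source}\tgene\t{iv.start + 1}\t{iv.end}\t.\t"
                     f"{iv.strand}\t.\tID={m.gene_id};Name={m.name}\n")
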