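"""Stage 2: truncated-copy counting and repetitiveness classification.

A prospective CDS is searched (nucleotide mode, e-value < 1e-100) against
its own genome; merged hit regions that do not overlap any prospective CDS
locus are its closely related truncated copies.  Zero copies means
nonrepetitive — the signature of an anciently domesticated transposase.
A gene whose only copies are the degraded homeolog on the partner
chromosome, a tandem neighbour, or an apparent assembly artifact is
"semi-nonrepetitive"; anything else is repetitive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

from . import homology_search as hs
from .cds_discovery import ProspectiveCDS
from .seq_core import GenomeAssembly, Interval

DEFAULT_NT_CUTOFF = 1e-100
DEFAULT_NEIGHBORHOOD_BP = 50_000
SUSPECT_CONTIG_BP = 1000


class RepClass(str, Enum):
    NONREPETITIVE = "nonrepetitive"
    SEMI_NONREPETITIVE = "semi_nonrepetitive"
    REPETITIVE = "repetitive"


class SemiReason(str, Enum):
    HOMEOLOGOUS_CHROMOSOME = "homeologous_chromosome"
    NEIGHBORHOOD = "neighborhood"
    SUSPECT_ASSEMBLY = "suspect_assembly"


@dataclass
class CopyProfile:
    cds_name: str
    truncated_hits: list[hs.HitRegion] = field(default_factory=list)
    rep_class: RepClass | None = None
    semi_reason: SemiReason | None = None

    @property
    def n_truncated(self) -> int:
        return len(self.truncated_hits)


def count_truncated_copies(cds: ProspectiveCDS, genome: GenomeAssembly,
                           all_cds: list[ProspectiveCDS],
                           evalue_cutoff: float = DEFAULT_NT_CUTOFF,
                           searcher: hs.Searcher | None = None) -> CopyProfile:
    """Count closely related truncated copies of one prospective CDS.

    Merged nucleotide hit regions overlapping (>= 1 bp) *any* prospective
    CDS locus — including the query's own — are discarded; the remainder are
    the truncated copies.
    """
    if searcher is None:
        searcher = hs.Searcher(genome, "nuc_vs_nuc")
    hsps = searcher.search(cds.name, cds.cds, evalue_cutoff)
    regions = hs.merge_hit_regions(hsps, len(cds.cds))
    loci = [c.locus for c in all_cds]
    truncated = [r for r in regions
                 if not any(r.subject.overlaps(iv) for iv in loci)]
    return CopyProfile(cds.name, truncated)


def _partner_chromosomes(contig: str, homeology: dict[str, list[str]]) -> set[str]:
    """All contigs homeologous to ``contig`` under the pair map."""
    partners: set[str] = set()
    for dip, tets in homeology.items():
        if contig == dip:
            partners.update(tets)
        elif contig in tets:
            partners.add(dip)
            partners.update(t for t in tets if t != contig)
    return partners


def classify_repetitiveness(profile: CopyProfile,
                            loci: dict[str, Interval],
                            homeology: dict[str, list[str]],
                            neighborhood_bp: int = DEFAULT_NEIGHBORHOOD_BP,
                            paralog_groups: dict[str, list[str]] | None = None,
                            contig_lengths: dict[str, int] | None = None
                            ) -> CopyProfile:
    """Fill in the repetitiveness class of a counted profile.

    semi-nonrepetitive requires every hit to be explainable as (a) the
    degraded homeolog on the partner chromosome, (b) a tandem duplicate
    within ``neighborhood_bp`` of the CDS or of a phylogenetically grouped
    paralog, or (c) an apparent assembly artifact spanning an entire very
    short contig.  A CDS on an unplaced scaffold cannot use rule (a).
    """
    if profile.n_truncated == 0:
        profile.rep_class = RepClass.NONREPETITIVE
        profile.semi_reason = None
        return profile
    own = loci[profile.cds_name]
    partners = _partner_chromosomes(own.contig, homeology)
    near_loci = [own]
    if paralog_groups:
        for member in paralog_groups.get(profile.cds_name, ()):
            if member in loci and member != profile.cds_name:
                near_loci.append(loci[member])
    reasons: list[SemiReason] = []
    for region in sorted(profile.truncated_hits,
                         key=lambda r: (r.subject.contig, r.subject.start)):
        iv = region.subject
        if iv.contig in partners:
            reasons.append(SemiReason.HOMEOLOGOUS_CHROMOSOME)
            continue
        if any(iv.contig == nl.contig
               and nl.gap_to(iv) <= neighborhood_bp for nl in near_loci):
            reasons.append(SemiReason.NEIGHBORHOOD)
            continue
        if contig_lengths is not None:
            clen = contig_lengths.get(iv.contig)
            if (clen is not None and clen < SUSPECT_CONTIG_BP
                    and iv.start == 0 and iv.end == clen):
                reasons.append(SemiReason.SUSPECT_ASSEMBLY)
                continue
        profile.rep_class = RepClass.REPETITIVE
        profile.semi_reason = None
        return profile
    profile.rep_class = RepClass.SEMI_NONREPETITIVE
    profile.semi_reason = reasons[0]
    return profile


def rep_class_from_count(n_truncated: int, semi_evidence: bool) -> RepClass:
    """Classification when only a copy count and curated semi evidence are
    available (the locus-table fixture transcription: the asterisk marks
    genes whose hits were all homeolog/tandem/artifact cases)."""
    if n_truncated == 0:
        return RepClass.NONREPETITIVE
    return RepClass.SEMI_NONREPETITIVE if semi_evidence else RepClass.REPETITIVE
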