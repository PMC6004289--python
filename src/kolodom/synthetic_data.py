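"""Seeded simulator of diploid + allotetraploid genome fixtures.

The generator emulates the study design every pipeline stage needs, without
any download: multi-chromosome assemblies (one diploid genome, one
tetraploid genome with homeologous L/S chromosome pairs) carrying

* domesticated ortholog sets — single-copy transposase genes present as a
  diploid gene plus L/S homeologs, embedded in cassettes of shared
  orthologous neighbour genes (synteny truth);
* active repetitive families — full-length elements (TIRs starting AG,
  TTAA target-site duplication written at insertion) with intact and
  truncated dispersed copies;
* decayed fossils that no discovery stage should call.

All transposases descend from one deep ancestral protein carrying the five
Kolobok motifs (DDE, H2CH, C2CH, PWF, AVPTIF) at fixed residue positions,
so candidate proteins align and motif anchor columns are well defined.
Sequence evolution is codon substitution only (Goldman-Yang style rates:
transversion 1, transition kappa, nonsynonymous multiplied by omega; stop
codons forbidden); intact active copies keep their motif codons, modelling
the functional constraint on a transposase that still transposes.

Background sequence is i.i.d. nucleotide at a configurable GC content.
Truth tables list every planted CDS locus, truncated-copy locus, element
span, cluster membership and the expected repetitiveness class and status.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import expm

from .seq_core import GeneModel, GenomeAssembly, Interval, reverse_complement, translate
from .selection_dnds import BASES, SENSE_CODONS, STOPS, _AA, _is_transition

# codon machinery -----------------------------------------------------------

_CODON_IDX = {c: i for i, c in enumerate(SENSE_CODONS)}

#: preferred codon per amino acid used when planting consensus residues
_AA_CODON = {}
for _c in SENSE_CODONS:
    _AA_CODON.setdefault(_AA[_c], _c)

#: the 20 consensus motif residues in field order
MOTIF_CONSENSUS = "DDEHHCHCCCHPWFAVPTIF"


def _codon_rate_matrix(omega: float, kappa: float) -> np.ndarray:
    n = len(SENSE_CODONS)
    Q = np.zeros((n, n))
    for i, ci in enumerate(SENSE_CODONS):
        for p in range(3):
            for b in BASES:
                if b == ci[p]:
                    continue
                cj = ci[:p] + b + ci[p + 1:]
                if cj in STOPS:
                    continue
                j = _CODON_IDX[cj]
                r = kappa if _is_transition(ci[p], b) else 1.0
                if _AA[ci] != _AA[cj]:
                    r *= omega
                Q[i, j] = r
    np.fill_diagonal(Q, -Q.sum(axis=1))
    # scale: one expected substitution per codon per unit time (uniform freqs)
    rate = -np.mean(np.diag(Q))
    return Q / rate if rate > 0 else Q


def mutate_codon_sequence(cds: str, t: float, omega: float, kappa: float,
                          seed: int) -> str:
    """Evolve a CDS for time ``t`` (expected substitutions per codon) under
    a Goldman-Yang style codon model.  Deterministic per seed; the trailing
    stop codon, if present, is preserved unchanged."""
    if t < 0 or omega < 0 or kappa < 0:
        raise ValueError("t, omega, kappa must be >= 0")
    cds = cds.upper()
    if len(cds) % 3:
        raise ValueError("CDS length not a multiple of 3")
    tail = ""
    if cds[-3:] in STOPS:
        cds, tail = cds[:-3], cds[-3:]
    if t == 0:
        return cds + tail
    rng = np.random.default_rng(seed)
    P = expm(_codon_rate_matrix(omega, kappa) * t)
    P = np.clip(P, 0, None)
    P /= P.sum(axis=1, keepdims=True)
    out = []
    for i in range(0, len(cds), 3):
        idx = _CODON_IDX[cds[i:i + 3]]
        out.append(SENSE_CODONS[rng.choice(len(SENSE_CODONS), p=P[idx])])
    return "".join(out) + tail


# configuration -------------------------------------------------------------

@dataclass
class FamilySpec:
    kind: str  # domesticated_ortholog_set | active_family | fossil
    cds_length: int = 2352  # includes the stop codon; multiple of 3, >= 1800
    genome: str = "diploid"  # host genome for active/fossil families
    chromosome_pair: int = 1  # 1-based index into the contig plan
    n_intact: int = 3
    n_truncated: int = 4
    truncation_range: tuple[int, int] = (450, 1500)
    tir: str = "AGGTCAGCATTGACCC"  # left TIR; starts AG per the superfamily
    tsd: str = "TTAA"
    t: float = 0.3
    omega: float = 0.2
    kappa: float = 2.0

    def __post_init__(self) -> None:
        if self.cds_length < 1800 or self.cds_length % 3:
            raise ValueError("cds_length must be >= 1800 and a multiple of 3")
        if self.kind == "active_family" and not self.tir.startswith("AG"):
            raise ValueError("active-family TIR must start AG")


@dataclass
class SimConfig:
    seed: int = 0
    n_chromosome_pairs: int = 2
    contig_length: int = 100_000
    gc: float = 0.40
    background_gene_every: int = 9_000  # host gene-model density per contig
    n_neighbor_genes: int = 3  # per side of each domesticated gene
    neighbor_gene_len: int = 450
    neighbor_spacing: int = 250
    n_queries: int = 8
    query_t_range: tuple[float, float] = (0.3, 0.7)
    deep_t: float = 0.8  # divergence of each family ancestor from the root
    element_pad: int = 900  # internal element sequence flanking the CDS
    families: list[FamilySpec] = field(default_factory=lambda: [
        FamilySpec("domesticated_ortholog_set", 2352, chromosome_pair=1),
        FamilySpec("domesticated_ortholog_set", 2202, chromosome_pair=2),
        FamilySpec("active_family", 2352, genome="diploid", n_intact=3,
                   n_truncated=4, t=0.01),
        FamilySpec("active_family", 2250, genome="tetraploid", n_intact=2,
                   n_truncated=3, t=0.01,
                   tir="AGGAGTTCAGTCAACC"),
        FamilySpec("fossil", 2100, genome="diploid"),
    ])


@dataclass
class SimResult:
    diploid: GenomeAssembly
    tetraploid: GenomeAssembly
    gene_models: dict[str, list[GeneModel]]  # 'diploid' / 'tetraploid'
    queries: dict[str, str]  # query transposase proteins
    reference_name: str  # query whose motif positions anchor extraction
    motif_positions: list[int]  # 20 residue indices in the reference protein
    homeology_map: dict[str, list[str]]
    truth_genes: pd.DataFrame
    truth_truncated: pd.DataFrame
    truth_elements: pd.DataFrame


# sequence helpers ----------------------------------------------------------

def _random_nt(rng: np.random.Generator, n: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=n, p=p)])


def _motif_residue_positions(protein_len: int) -> list[int]:
    """Fixed fractional layout of the 20 motif residues within a protein."""
    fracs = [0.30, 0.34, 0.38,              # DDE (spread, as in the family)
             0.50, 0.52, 0.54, 0.56,        # H2CH
             0.64, 0.655, 0.67, 0.685,      # C2CH
             0.73, 0.75, 0.77]              # PWF
    pos = [int(f * protein_len) for f in fracs]
    avptif_start = int(0.85 * protein_len)
    pos += list(range(avptif_start, avptif_start + 6))  # AVPTIF is contiguous
    if len(set(pos)) != 20:
        raise ValueError("protein too short for the motif layout")
    return pos


def _fix_start(cds: str) -> str:
    """Restore the initiation codon (absolutely constrained in any gene the
    discovery stage should treat as an intact ORF)."""
    return "ATG" + cds[3:]


def _plant_motifs(cds: str, positions: list[int]) -> str:
    """Overwrite motif codons with consensus-residue codons."""
    body = cds[:-3] if cds[-3:] in STOPS else cds
    codons = [body[i:i + 3] for i in range(0, len(body), 3)]
    for res_pos, aa in zip(positions, MOTIF_CONSENSUS):
        codons[res_pos] = _AA_CODON[aa]
    tail = cds[len(body):]
    return "".join(codons) + tail


def _random_cds(rng: np.random.Generator, nt_len: int) -> str:
    """ATG ... stop CDS of ``nt_len`` with no internal stops."""
    n_codons = nt_len // 3
    inner = [SENSE_CODONS[i] for i in
             rng.choice(len(SENSE_CODONS), size=n_codons - 2)]
    return "ATG" + "".join(inner) + "TAA"


class _ContigBuilder:
    """Plans insertions into an i.i.d. background and assembles the contig,
    resolving final coordinates."""

    def __init__(self, rng: np.random.Generator, name: str, length: int,
                 gc: float):
        self.rng = rng
        self.name = name
        self.bg = _random_nt(rng, length, gc)
        self.inserts: list[tuple[int, str, object]] = []

    def place(self, seq: str, meta: object, min_sep: int = 6000) -> None:
        """Reserve a background position, re-drawing on conflict.

        ``min_sep`` background bases must separate insertions so that the
        1800 bp candidate-region flanks of neighbouring planted genes can
        never fuse into one extraction region.
        """
        for _ in range(200):
            pos = int(self.rng.integers(5000, len(self.bg) - 5000))
            if all(abs(pos - p) >= min_sep for p, _, _ in self.inserts):
                self.inserts.append((pos, seq, meta))
                return
        raise RuntimeError("could not place insertion without overlap")

    def build(self) -> tuple[str, list[tuple[object, int, int]]]:
        parts = []
        placed = []
        prev = 0
        offset = 0
        for pos, seq, meta in sorted(self.inserts, key=lambda x: x[0]):
            parts.append(self.bg[prev:pos])
            start = pos + offset
            parts.append(seq)
            placed.append((meta, start, start + len(seq)))
            offset += len(seq)
            prev = pos
        parts.append(self.bg[prev:])
        return "".join(parts), placed


# main generator ------------------------------------------------------------

def simulate_genomes(cfg: SimConfig) -> SimResult:
    """Build both genomes, gene models, queries and truth tables."""
    rng = np.random.default_rng(cfg.seed)
    seed_pool = iter(rng.integers(0, 2**31 - 1, size=10000).tolist())

    deep_cds = _random_cds(rng, 2352)
    motif_pos = _motif_residue_positions(2352 // 3 - 1)
    deep_cds = _plant_motifs(deep_cds, motif_pos)

    # query set: diverged relatives of the deep ancestor (motifs retained)
    queries: dict[str, str] = {}
    for qi in range(cfg.n_queries):
        tq = float(rng.uniform(*cfg.query_t_range))
        qcds = mutate_codon_sequence(deep_cds, tq, 0.5, 2.0, next(seed_pool))
        qcds = _fix_start(_plant_motifs(qcds, motif_pos))
        queries[f"query{qi + 1}"] = translate(qcds)
    reference_name = "query1"

    dip_names = [f"Chr{i}" for i in range(1, cfg.n_chromosome_pairs + 1)]
    tet_names = [f"chr{i}{s}" for i in range(1, cfg.n_chromosome_pairs + 1)
                 for s in ("L", "S")]
    homeology = {f"Chr{i}": [f"chr{i}L", f"chr{i}S"]
                 for i in range(1, cfg.n_chromosome_pairs + 1)}
    builders = {name: _ContigBuilder(rng, name, cfg.contig_length, cfg.gc)
                for name in dip_names + tet_names}

    truth_genes = []
    truth_trunc = []
    truth_elems = []
    gene_cassettes: dict[str, list[tuple[str, str]]] = {"diploid": [],
                                                        "tetraploid": []}

    def family_ancestor(spec: FamilySpec) -> str:
        """Family founder derived from the deep ancestor at the family's CDS
        length (3'-truncated before the stop when shorter)."""
        cds = mutate_codon_sequence(deep_cds, cfg.deep_t, 0.5, spec.kappa,
                                    next(seed_pool))
        cds = _fix_start(_plant_motifs(cds, motif_pos))
        if spec.cds_length < len(cds):
            cds = cds[:spec.cds_length - 3] + "TAA"
        return cds

    def cassette(spec_idx: int, cds: str, genome_key: str, suffix: str
                 ) -> tuple[str, list[tuple[str, int, int]], tuple[int, int]]:
        """Neighbour-gene cassette with the CDS in the middle.  Returns the
        sequence, gene sub-spans (name, start, end) and the CDS sub-span."""
        parts: list[str] = []
        genes: list[tuple[str, int, int]] = []
        pos = 0

        def add(seq: str, gname: str | None = None):
            nonlocal pos
            if gname is not None:
                genes.append((gname, pos, pos + len(seq)))
            parts.append(seq)
            pos += len(seq)

        n = cfg.n_neighbor_genes
        for j in range(n):
            add(_random_nt(rng, cfg.neighbor_gene_len, cfg.gc),
                f"F{spec_idx}n{j + 1}{suffix}")
            add(_random_nt(rng, cfg.neighbor_spacing, cfg.gc))
        cds_span = (pos, pos + len(cds))
        add(cds)
        for j in range(n, 2 * n):
            add(_random_nt(rng, cfg.neighbor_spacing, cfg.gc))
            add(_random_nt(rng, cfg.neighbor_gene_len, cfg.gc),
                f"F{spec_idx}n{j + 1}{suffix}")
        return "".join(parts), genes, cds_span

    for fi, spec in enumerate(cfg.families, start=1):
        anc = family_ancestor(spec)
        pair = spec.chromosome_pair
        if spec.kind == "domesticated_ortholog_set":
            dip = _fix_start(mutate_codon_sequence(anc, spec.t, spec.omega,
                                                   spec.kappa,
                                                   next(seed_pool)))
            ls_anc = mutate_codon_sequence(anc, spec.t / 2, spec.omega,
                                           spec.kappa, next(seed_pool))
            lv_l = _fix_start(mutate_codon_sequence(ls_anc, spec.t / 2,
                                                    spec.omega, spec.kappa,
                                                    next(seed_pool)))
            lv_s = _fix_start(mutate_codon_sequence(ls_anc, spec.t / 2,
                                                    spec.omega, spec.kappa,
                                                    next(seed_pool)))
            placements = [(f"Chr{pair}", "diploid", "", dip),
                          (f"chr{pair}L", "tetraploid", ".L", lv_l),
                          (f"chr{pair}S", "tetraploid", ".S", lv_s)]
            for contig, genome_key, suffix, cds in placements:
                seq, genes, cds_span = cassette(fi, cds, genome_key, suffix)
                meta = ("cassette", fi, genome_key, genes, cds_span, spec)
                builders[contig].place(seq, meta)
        elif spec.kind == "active_family":
            pad5 = _random_nt(rng, cfg.element_pad, cfg.gc)
            pad3 = _random_nt(rng, cfg.element_pad, cfg.gc)
            tir_l = spec.tir
            # right TIR: a similar (not identical) inverted terminal repeat
            tir_r = spec.tir[:6] + _random_nt(rng, 2, 0.5) + spec.tir[8:]
            host = dip_names if spec.genome == "diploid" else tet_names
            copy_contigs: list[str] = []
            for ci in range(spec.n_intact):
                cds = mutate_codon_sequence(anc, spec.t, spec.omega,
                                            spec.kappa, next(seed_pool))
                cds = _fix_start(_plant_motifs(cds, motif_pos))
                element = (tir_l + pad5 + cds + pad3
                           + reverse_complement(tir_r))
                strand = "+" if rng.random() < 0.5 else "-"
                ins = element if strand == "+" else reverse_complement(element)
                ins = spec.tsd + ins + spec.tsd
                contig = host[int(rng.integers(len(host)))]
                copy_contigs.append(contig)
                meta = ("element", fi, spec.genome, strand, len(tir_l),
                        len(pad5), len(cds), spec)
                builders[contig].place(ins, meta)
            # interspersal guarantee: each intact copy must see at least one
            # truncated copy outside its own neighbourhood and off its
            # homeologous partner chromosome, or it would not look
            # repetitive at all — the family signature the study keys on
            partner_of = {}
            for i in range(1, cfg.n_chromosome_pairs + 1):
                partner_of[f"chr{i}L"] = f"chr{i}S"
                partner_of[f"chr{i}S"] = f"chr{i}L"
            forced: list[str] = []
            for contig in copy_contigs:
                banned = {contig, partner_of.get(contig, "")}
                ok_contigs = [c for c in host if c not in banned]
                if not any(c in ok_contigs for c in forced):
                    forced.append(ok_contigs[int(rng.integers(len(ok_contigs)))])
            frag_contigs = forced + [host[int(rng.integers(len(host)))]
                                     for _ in range(max(0, spec.n_truncated
                                                        - len(forced)))]
            for contig in frag_contigs[:max(spec.n_truncated, len(forced))]:
                lo, hi = spec.truncation_range
                flen = int(rng.integers(lo, hi + 1))
                start = int(rng.integers(0, len(anc) - flen))
                frag = mutate_codon_sequence(anc, spec.t, spec.omega,
                                             spec.kappa,
                                             next(seed_pool))[start:start + flen]
                if rng.random() < 0.5:
                    frag = reverse_complement(frag)
                builders[contig].place(frag, ("fragment", fi, spec.genome, spec))
        elif spec.kind == "fossil":
            decayed = list(mutate_codon_sequence(anc, 1.2, 1.0, spec.kappa,
                                                 next(seed_pool)))
            # additional unconstrained point decay (stops allowed)
            for i in range(len(decayed)):
                if rng.random() < 0.15:
                    decayed[i] = "ACGT"[int(rng.integers(4))]
            frag = "".join(decayed)[:1500]
            host = dip_names if spec.genome == "diploid" else tet_names
            contig = host[int(rng.integers(len(host)))]
            builders[contig].place(frag, ("fossil", fi, spec.genome, spec))
        else:
            raise ValueError(f"unknown family kind {spec.kind!r}")

    contigs: dict[str, str] = {}
    contig_class: dict[str, str] = {}
    gene_models: dict[str, list[GeneModel]] = {"diploid": [], "tetraploid": []}
    for name, builder in builders.items():
        seq, placed = builder.build()
        contigs[name] = seq
        if name.startswith("Chr"):
            contig_class[name] = "diploid_chr"
        else:
            contig_class[name] = ("tetraploid_L" if name.endswith("L")
                                  else "tetraploid_S")
        genome_key_of_contig = "diploid" if name.startswith("Chr") else "tetraploid"
        # background host gene models at regular spacing keep neighbour
        # windows local; names are contig-specific (no cross-genome sharing)
        occupied = [(s - 2000, e + 2000) for _, s, e in placed]
        gi = 0
        for p in range(4000, len(seq) - 4000, cfg.background_gene_every):
            if any(s <= p <= e or s <= p + cfg.neighbor_gene_len <= e
                   for s, e in occupied):
                continue
            gi += 1
            gene_models[genome_key_of_contig].append(GeneModel(
                f"{name}.bg{gi}", f"{name}bg{gi}",
                Interval(name, p, p + cfg.neighbor_gene_len, "+")))
        for meta, start, end in placed:
            kind = meta[0]
            if kind == "cassette":
                _, fi, genome_key, genes, cds_span, spec = meta
                for gname, gs, ge in genes:
                    gene_models[genome_key].append(GeneModel(
                        f"{name}.{gname}", gname,
                        Interval(name, start + gs, start + ge, "+")))
                cs, ce = cds_span
                truth_genes.append(dict(
                    family=f"F{fi}", kind="domesticated", genome=genome_key,
                    contig=name, start=start + cs, end=start + ce, strand="+",
                    cluster=f"F{fi}", expected_rep_class="nonrepetitive",
                    expected_status="ancient_domestication"))
            elif kind == "element":
                _, fi, genome_key, strand, tir_len, pad5, cds_len, spec = meta
                tsd = len(spec.tsd)
                el_start, el_end = start + tsd, end - tsd
                if strand == "+":
                    cds_start = el_start + tir_len + pad5
                    cds_end = cds_start + cds_len
                else:
                    cds_end = el_end - tir_len - pad5
                    cds_start = cds_end - cds_len
                truth_genes.append(dict(
                    family=f"F{fi}", kind="active", genome=genome_key,
                    contig=name, start=cds_start, end=cds_end, strand=strand,
                    cluster="", expected_rep_class="repetitive",
                    expected_status="currently_active"))
                truth_elems.append(dict(
                    family=f"F{fi}", genome=genome_key, contig=name,
                    start=el_start, end=el_end, strand=strand,
                    tir_left=spec.tir, tsd=spec.tsd))
            elif kind == "fragment":
                _, fi, genome_key, spec = meta
                truth_trunc.append(dict(family=f"F{fi}", genome=genome_key,
                                        contig=name, start=start, end=end))
            elif kind == "fossil":
                _, fi, genome_key, spec = meta
                truth_trunc.append(dict(family=f"F{fi}", genome=genome_key,
                                        contig=name, start=start, end=end))

    dip = GenomeAssembly({n: contigs[n] for n in dip_names},
                         {n: contig_class[n] for n in dip_names}, "Dt")
    tet = GenomeAssembly({n: contigs[n] for n in tet_names},
                         {n: contig_class[n] for n in tet_names}, "Lt")
    return SimResult(
        diploid=dip, tetraploid=tet, gene_models=gene_models,
        queries=queries, reference_name=reference_name,
        motif_positions=motif_pos, homeology_map=homeology,
        truth_genes=pd.DataFrame(truth_genes),
        truth_truncated=pd.DataFrame(truth_trunc),
        truth_elements=pd.DataFrame(truth_elems),
    )
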