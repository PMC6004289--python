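"""Seeded Smith-Waterman search, hit-region merging, tabular adapter."""

import random

import pytest
from Bio import Align
from Bio.Align import substitution_matrices

from kolodom import homology_search as hs
from kolodom._align import smith_waterman_nucleotide, smith_waterman_protein
from kolodom.seq_core import Interval, reverse_complement

from .conftest import encode_protein_as_cds, make_genome, random_dna, random_protein


def _biopython_local_score(a, b, protein=True):
    if protein:
        al = Align.PairwiseAligner(
            mode="local",
            substitution_matrix=substitution_matrices.load("BLOSUM62"),
            open_gap_score=-12, extend_gap_score=-1)
    else:
        al = Align.PairwiseAligner(mode="local", match_score=2,
                                   mismatch_score=-3,
                                   open_gap_score=-7, extend_gap_score=-2)
    return al.score(a, b)


class TestSmithWaterman:
    @pytest.mark.parametrize("seed", range(6))
    def test_protein_score_equals_dp_oracle(self, seed):
        """Full-DP local alignment score matches an independent aligner on
        pairs up to 200 residues."""
        rng = random.Random(seed)
        a = random_protein(rng, rng.randint(50, 200))
        core = a[10:10 + rng.randint(30, len(a) - 20)]
        b = list(core)
        for _ in range(len(b) // 8):
            b[rng.randrange(len(b))] = rng.choice("ACDEFGHIKLMNPQRSTVWY")
        b = "".join(b)
        score, _, _ = smith_waterman_protein(a, b)
        assert score == pytest.approx(_biopython_local_score(a, b), abs=1e-6)

    @pytest.mark.parametrize("seed", range(4))
    def test_nucleotide_score_equals_dp_oracle(self, seed):
        rng = random.Random(100 + seed)
        a = random_dna(rng, 180)
        b = list(a[20:150])
        for _ in range(10):
            b[rng.randrange(len(b))] = rng.choice("ACGT")
        b = "".join(b)
        score, _, _ = smith_waterman_nucleotide(a, b)
        assert score == pytest.approx(_biopython_local_score(a, b, False),
                                      abs=1e-6)


class TestSearch:
    def test_exact_translated_copy_found_as_single_region(self):
        rng = random.Random(7)
        prot = random_protein(rng, 700)
        nt = encode_protein_as_cds(rng, prot)
        bg = random_dna(rng, 100_000)
        genome = make_genome({"c1": bg[:40_000] + nt + bg[40_000:]})
        hits = hs.search(prot, genome, "prot_vs_translated_nuc", 1e-5)
        regions = hs.merge_hit_regions(hits, 3 * len(prot))
        covering = [r for r in regions
                    if r.subject.start <= 40_000
                    and r.subject.end >= 40_000 + len(nt)]
        assert len(covering) == 1
        assert covering[0].subject.strand == "+"

    def test_minus_strand_copy_mapped_back(self):
        rng = random.Random(8)
        cds = random_dna(rng, 2400)
        bg = random_dna(rng, 60_000)
        genome = make_genome(
            {"c1": bg[:20_000] + reverse_complement(cds) + bg[20_000:]})
        hits = hs.search(cds, genome, "nuc_vs_nuc", 1e-100)
        assert any(h.subject.strand == "-" and h.subject.start == 20_000
                   and h.subject.end == 20_000 + 2400 for h in hits)

    def test_diverged_copies_recovered(self):
        """Several >=90%-identity planted copies yield that many merged
        regions; pure-random background yields none."""
        rng = random.Random(9)
        cds = random_dna(rng, 2100)
        pieces, planted = [], []
        bg = random_dna(rng, 120_000)
        offset = 0
        cursor = 0
        for pos in (15_000, 50_000, 90_000):
            copy = list(cds)
            for _ in range(len(copy) // 12):  # ~92% identity
                copy[rng.randrange(len(copy))] = rng.choice("ACGT")
            copy = "".join(copy)
            pieces.append(bg[cursor:pos])
            planted.append(pos + offset)
            pieces.append(copy)
            offset += len(copy)
            cursor = pos
        pieces.append(bg[cursor:])
        genome = make_genome({"c1": "".join(pieces)})
        hits = hs.search(cds, genome, "nuc_vs_nuc", 1e-100)
        regions = hs.merge_hit_regions(hits, len(cds))
        starts = sorted(r.subject.start for r in regions)
        assert len(regions) == 3
        for want, got in zip(sorted(planted), starts):
            assert abs(want - got) <= 25

    def test_empty_target(self):
        assert hs.search("MKV" * 50, {}, "prot_vs_prot", 1e-5) == []

    def test_invalid_nucleotide_query(self):
        with pytest.raises(ValueError):
            hs.search("MKVF", {"s": "ACGT" * 100}, "nuc_vs_nuc", 1e-5)


def _mk_hsp(contig, start, end, strand="+", qid="q"):
    return hs.Hsp(qid, Interval(contig, start, end, strand), (0, 10),
                  100.0, 50.0, 1e-30, "nuc_vs_nuc")


class TestMergeHitRegions:
    def test_gap_below_query_length_merges(self):
        hsps = [_mk_hsp("c", 1000, 1500), _mk_hsp("c", 2000, 2400)]
        assert len(hs.merge_hit_regions(hsps, 2352)) == 1

    def test_gap_above_query_length_splits(self):
        hsps = [_mk_hsp("c", 1000, 1500), _mk_hsp("c", 4500, 4900)]
        assert len(hs.merge_hit_regions(hsps, 2352)) == 2

    def test_strands_never_merge(self):
        hsps = [_mk_hsp("c", 1000, 1500, "+"), _mk_hsp("c", 1600, 1900, "-")]
        assert len(hs.merge_hit_regions(hsps, 2352)) == 2

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_transitive_closure_oracle(self, seed):
        rng = random.Random(seed)
        qlen = 500
        hsps = []
        for _ in range(50):
            start = rng.randrange(0, 30_000)
            hsps.append(_mk_hsp(rng.choice("ab"), start,
                                start + rng.randrange(50, 400),
                                rng.choice("+-")))
        regions = hs.merge_hit_regions(hsps, qlen)

        # oracle: brute-force union-find over the pairwise gap predicate
        parent = list(range(len(hsps)))

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for i in range(len(hsps)):
            for j in range(i + 1, len(hsps)):
                a, b = hsps[i].subject, hsps[j].subject
                if (a.contig == b.contig and a.strand == b.strand
                        and a.gap_to(b) < qlen):
                    parent[find(i)] = find(j)
        n_components = len({find(i) for i in range(len(hsps))})
        assert len(regions) == n_components
        # each region spans exactly its members
        for r in regions:
            assert r.subject.start == min(h.subject.start for h in r.member_hsps)
            assert r.subject.end == max(h.subject.end for h in r.member_hsps)

    def test_idempotent(self):
        rng = random.Random(11)
        hsps = [_mk_hsp("c", s, s + 200)
                for s in sorted(rng.sample(range(0, 20_000, 100), 20))]
        once = hs.merge_hit_regions(hsps, 700)
        again = hs.merge_hit_regions(
            [h for r in once for h in r.member_hsps], 700)
        assert [(r.subject.start, r.subject.end) for r in once] == \
               [(r.subject.start, r.subject.end) for r in again]


class TestTabular:
    def test_minus_strand_convention(self, tmp_path):
        p = tmp_path / "hits.tsv"
        p.write_text("q\ts\t95.0\t100\t5\t0\t1\t100\t200\t101\t1e-30\t180\n")
        (h,) = hs.read_tabular_hits(p, "nuc_vs_nuc")
        assert h.subject == Interval("s", 100, 200, "-")
        assert h.query_span == (0, 100)

    def test_empty_file(self, tmp_path):
        p = tmp_path / "empty.tsv"
        p.write_text("")
        assert hs.read_tabular_hits(p, "nuc_vs_nuc") == []

    def test_malformed_row_reports_line_number(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("q\ts\t95.0\t100\t5\t0\t1\t100\t200\t101\t1e-30\t180\n"
                     "q\ts\tnot-enough-columns\n")
        with pytest.raises(ValueError, match="line 2"):
            hs.read_tabular_hits(p, "nuc_vs_nuc")

    def test_round_trip(self, tmp_path):
        hsps = [_mk_hsp("s1", 100, 300, "+"), _mk_hsp("s2", 500, 900, "-")]
        p = tmp_path / "rt.tsv"
        hs.write_tabular_hits(p, hsps)
        back = hs.read_tabular_hits(p, "nuc_vs_nuc")
        assert [(h.subject, h.query_span) for h in back] == \
               [(h.subject, h.query_span) for h in hsps]
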