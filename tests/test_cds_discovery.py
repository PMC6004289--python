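"""Candidate region extraction, longest-ORF calling, backward
verification and start-codon trimming."""

import random

import pytest

from kolodom import homology_search as hs
from kolodom.cds_discovery import (
    ProspectiveCDS,
    backward_verify,
    call_longest_orf,
    dedup_candidates,
    extract_candidate_regions,
    trim_to_majority_start,
)
from kolodom.seq_core import Interval, find_orfs, translate

from .conftest import encode_protein_as_cds, make_genome, random_dna, random_protein


def _region(contig, start, end, strand="+"):
    return hs.HitRegion(Interval(contig, start, end, strand), [])


class TestExtractCandidateRegions:
    def test_widening(self):
        genome = make_genome({"c": "A" * 100_000})
        (iv,) = extract_candidate_regions([_region("c", 5000, 6000)], genome)
        assert (iv.start, iv.end) == (3200, 7800)

    def test_clipping_at_contig_edge(self):
        genome = make_genome({"c": "A" * 100_000})
        (iv,) = extract_candidate_regions([_region("c", 500, 900)], genome)
        assert (iv.start, iv.end) == (0, 2700)

    def test_overlapping_widened_regions_union(self):
        genome = make_genome({"c": "A" * 100_000})
        out = extract_candidate_regions(
            [_region("c", 5000, 6000), _region("c", 7000, 8000)], genome)
        assert len(out) == 1
        assert (out[0].start, out[0].end) == (3200, 9800)

    def test_strands_kept_separate(self):
        genome = make_genome({"c": "A" * 100_000})
        out = extract_candidate_regions(
            [_region("c", 5000, 6000, "+"), _region("c", 5500, 6500, "-")],
            genome)
        assert len(out) == 2


class TestCallLongestOrf:
    def _embed(self, rng, cds, at, total=12_000):
        bg = random_dna(rng, total)
        return bg[:at] + cds + bg[at:]

    def test_longest_wins(self):
        rng = random.Random(0)
        long_cds = "ATG" + encode_protein_as_cds(rng, random_protein(rng, 782)) + "TAA"
        short_cds = "ATG" + encode_protein_as_cds(rng, random_protein(rng, 298)) + "TAA"
        seq = self._embed(rng, long_cds + random_dna(rng, 500) + short_cds, 3000)
        orf = call_longest_orf(seq, Interval("c", 50_000, 50_000 + len(seq)))
        assert orf is not None
        assert orf.nt_length >= 2352

    def test_short_orfs_rejected(self):
        rng = random.Random(1)
        cds = "ATG" + encode_protein_as_cds(rng, random_protein(rng, 597)) + "TAA"
        assert len(cds) == 1797
        # stops in all three frames stop the ORF from borrowing upstream codons
        seq = self._embed(rng, "TAATAATAA" + cds, 4000)
        assert call_longest_orf(seq, Interval("c", 0, len(seq))) is None

    def test_coordinates_lifted_to_genome(self):
        rng = random.Random(2)
        prot = random_protein(rng, 700)
        cds = "ATG" + encode_protein_as_cds(rng, prot) + "TAA"
        seq = self._embed(rng, cds, 5000)
        orf = call_longest_orf(seq, Interval("c", 30_000, 30_000 + len(seq)))
        assert orf.locus.start == 35_000
        assert orf.locus.end == 35_000 + len(cds)

    @pytest.mark.parametrize("seed", range(3))
    def test_equals_max_over_find_orfs(self, seed):
        rng = random.Random(seed + 10)
        seq = random_dna(rng, 6000)
        got = call_longest_orf(seq, Interval("c", 0, len(seq)), min_nt=90)
        all_orfs = find_orfs(seq, 90)
        if not all_orfs:
            assert got is None
        else:
            best = min(all_orfs, key=lambda o: (-o.nt_length, o.locus.start,
                                                o.locus.strand))
            assert got.nt_length == best.nt_length
            assert (got.locus.start, got.locus.end) == \
                   (best.locus.start, best.locus.end)


class TestBackwardVerify:
    def test_candidate_matching_near_identical_queries(self):
        rng = random.Random(3)
        base = random_protein(rng, 600)
        queries = {}
        for i in range(10):
            q = list(base)
            for _ in range(30):
                q[rng.randrange(len(q))] = rng.choice("ACDEFGHIKLMNPQRSTVWY")
            queries[f"q{i}"] = "".join(q)
        assert backward_verify(base, queries) is True

    def test_shuffled_protein_fails(self):
        rng = random.Random(4)
        base = random_protein(rng, 600)
        queries = {f"q{i}": random_protein(rng, 600) for i in range(10)}
        shuffled = list(base)
        rng.shuffle(shuffled)
        assert backward_verify("".join(shuffled), queries) is False

    def test_empty_query_set_is_error(self):
        with pytest.raises(ValueError):
            backward_verify("MKV" * 100, {})


def _candidate(name, protein, rng, extra_nt=0, contig="c", start=10_000,
               strand="+"):
    cds = encode_protein_as_cds(rng, protein) + "TAA"
    return ProspectiveCDS(name, Interval(contig, start, start + len(cds),
                                         strand),
                          len(cds) + extra_nt if extra_nt else len(cds),
                          len(cds), cds, protein)


class TestTrimToMajorityStart:
    def test_excess_5prime_trimmed(self):
        rng = random.Random(5)
        core = "M" + random_protein(rng, 700).replace("M", "L")
        extended = "M" + random_protein(rng, 29).replace("M", "L") + core
        cands = [_candidate(f"g{i}", core, rng) for i in range(3)]
        long_cand = _candidate("g3", extended, rng)
        out = trim_to_majority_start(cands + [long_cand])
        trimmed = next(c for c in out if c.name == "g3")
        assert trimmed.trimmed_nt == long_cand.trimmed_nt - 90
        assert trimmed.protein == core
        # locus start moves by 90 on the plus strand
        assert trimmed.locus.start == long_cand.locus.start + 90

    def test_already_aligned_unchanged(self):
        rng = random.Random(6)
        prot = "M" + random_protein(rng, 600)
        cands = [_candidate(f"g{i}", prot, rng) for i in range(4)]
        out = trim_to_majority_start(cands)
        assert [c.cds for c in out] == [c.cds for c in cands]

    def test_trimming_preserves_frame_and_stop(self):
        rng = random.Random(7)
        core = "M" + random_protein(rng, 500).replace("M", "V")
        cands = [_candidate(f"g{i}", core, rng) for i in range(3)]
        ext = _candidate("gx", "M" + "LIV" * 7 + core, rng)
        out = trim_to_majority_start(cands + [ext])
        for c in out:
            assert len(c.cds) % 3 == 0
            assert c.cds[-3:] in ("TAA", "TAG", "TGA")
            assert translate(c.cds) == c.protein

    def test_no_atg_after_majority_flags_candidate(self):
        rng = random.Random(8)
        core = "M" + random_protein(rng, 400).replace("M", "T")
        cands = [_candidate(f"g{i}", core, rng) for i in range(3)]
        # starts before the majority column but has no later methionine
        odd = _candidate("gx", "W" + "Q" * 15 + core[1:], rng)
        out = trim_to_majority_start(cands + [odd])
        flagged = next(c for c in out if c.name == "gx")
        assert flagged.trim_flagged
        assert flagged.cds == odd.cds

    def test_requires_three_candidates(self):
        rng = random.Random(9)
        prot = "M" + random_protein(rng, 100)
        with pytest.raises(ValueError):
            trim_to_majority_start([_candidate("a", prot, rng),
                                    _candidate("b", prot, rng)])


class TestDedup:
    def test_overlapping_candidates_collapse_to_longer(self):
        rng = random.Random(10)
        long_p = "M" + random_protein(rng, 700)
        short_p = "M" + random_protein(rng, 650)
        a = _candidate("a", long_p, rng, start=10_000)
        b = _candidate("b", short_p, rng, start=10_300)
        out = dedup_candidates([a, b])
        assert [c.name for c in out] == ["a"]

    def test_distant_candidates_kept(self):
        rng = random.Random(11)
        a = _candidate("a", "M" + random_protein(rng, 600), rng, start=10_000)
        b = _candidate("b", "M" + random_protein(rng, 600), rng, start=50_000)
        assert len(dedup_candidates([a, b])) == 2
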