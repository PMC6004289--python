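"""Shared fixtures: random-sequence helpers and one session-scoped
synthetic genome pair reused by the slower integration tests."""

from __future__ import annotations

import itertools
import random

import pytest

from kolodom.seq_core import GenomeAssembly


AA20 = "ACDEFGHIKLMNPQRSTVWY"


def random_protein(rng: random.Random, n: int) -> str:
    return "".join(rng.choice(AA20) for _ in range(n))


def random_dna(rng: random.Random, n: int) -> str:
    return "".join(rng.choice("ACGT") for _ in range(n))


_CODONS_FOR: dict[str, list[str]] = {}
for _c in ("".join(t) for t in itertools.product("ACGT", repeat=3)):
    from kolodom.seq_core import translate

    _CODONS_FOR.setdefault(translate(_c + "TAA") or "*", []).append(_c)


def encode_protein_as_cds(rng: random.Random, protein: str) -> str:
    """Back-translate a protein with random synonymous codon choices."""
    return "".join(rng.choice(_CODONS_FOR[aa]) for aa in protein)


@pytest.fixture(scope="session")
def sim():
    """One deterministic synthetic diploid + tetraploid genome pair."""
    from kolodom.synthetic_data import SimConfig, simulate_genomes

    return simulate_genomes(SimConfig(seed=2024))


@pytest.fixture(scope="session")
def pipeline_result(sim):
    """The full pipeline run once on the session genomes."""
    from kolodom.pipeline_cli import run_pipeline

    return run_pipeline(
        sim.diploid, sim.tetraploid, sim.queries,
        gene_models=sim.gene_models, homeology_map=sim.homeology_map,
        reference_protein=sim.queries[sim.reference_name],
        reference_motif_positions=sim.motif_positions)


def make_genome(contigs: dict[str, str], cls: str = "diploid_chr",
                tag: str = "T") -> GenomeAssembly:
    return GenomeAssembly(contigs, {n: cls for n in contigs}, tag)
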