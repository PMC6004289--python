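"""Curated fixture transcriptions of the published result tables.

These ship as explicit TSVs so tests and the table-reproduction mode run
without any genome download.  The motif table is stored pre-split into its
five fields: a handful of rows (Tr3, Tr34, Tr35, Tr37, Tr38) carry irregular
gap characters in the source and are curated with '-' fill — all of them are
non-conserved under any parse, so none of the printed counts depend on the
curation.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import pandas as pd

from .copy_profile import RepClass, rep_class_from_count
from .motif_scan import Flag, MotifProfile
from .seq_core import Interval

_FLAGS = {"": Flag.NONE, "+": Flag.PLUS, "++": Flag.PLUSPLUS}

STATUS_STRINGS = ("currently active", "active?",
                  "ancient domestication", "domestication?")


def _read(name: str) -> pd.DataFrame:
    with resources.files("kolodom.data").joinpath(name).open() as fh:
        df = pd.read_csv(fh, sep="\t", dtype=str, keep_default_na=False)
    return df.apply(lambda col: col.str.strip())


def load_locus_table() -> pd.DataFrame:
    """Per-gene locus, ORF/CDS lengths, truncated-copy count and curated
    semi-nonrepetitive evidence; adds the derived repetitiveness class."""
    df = _read("table1_loci.tsv")
    df["longest_orf_nt"] = df["longest_orf_nt"].astype(int)
    df["trimmed_nt"] = df["trimmed_nt"].astype(int)
    df["n_truncated"] = df["n_truncated"].astype(int)
    df["semi_evidence"] = df["semi_evidence"].astype(int).astype(bool)
    df["rep_class"] = [
        rep_class_from_count(n, s).value
        for n, s in zip(df["n_truncated"], df["semi_evidence"])
    ]
    return df


def load_motif_table() -> tuple[list[MotifProfile], dict[str, str], dict[str, Flag]]:
    """Motif profiles, species map, and the printed conservation flags."""
    df = _read("table2_motifs.tsv")
    profiles = [MotifProfile(r.name, r.dde, r.h2ch, r.c2ch, r.pwf, r.avptif)
                for r in df.itertuples(index=False)]
    species_of = dict(zip(df["name"], df["species"]))
    printed = {r.name: _FLAGS[r.flag] for r in df.itertuples(index=False)}
    return profiles, species_of, printed


def load_cluster_table() -> pd.DataFrame:
    """Ortholog subfamilies D1-D9 with synteny verdicts."""
    df = _read("table3_clusters.tsv")
    df["synteny_ok"] = df["synteny_ok"].astype(int).astype(bool)
    df["members"] = df["members"].str.split(",")
    return df


def load_status_table() -> pd.DataFrame:
    """Per-gene divergence columns and the printed presumptive status."""
    df = _read("table4_status.tsv")
    assert set(df["status"]) <= set(STATUS_STRINGS)
    return df


def load_element_table() -> pd.DataFrame:
    """Reconstructed full-length elements: loci, lengths, TIR and TSD
    strings."""
    df = _read("table5_elements.tsv")
    df["length"] = df["length"].astype(int)
    return df


def load_homeology_map() -> dict[str, list[str]]:
    """Diploid chromosome -> [L, S] homeologous tetraploid chromosomes."""
    df = _read("homeology_xenopus.tsv")
    return {r.diploid: [r.tetraploid_L, r.tetraploid_S] for r in df.itertuples()}


def read_homeology_map(path) -> dict[str, list[str]]:
    """Read a homeology map from a user-supplied TSV (same three columns)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    return {r.diploid: [r.tetraploid_L, r.tetraploid_S] for r in df.itertuples()}


def cluster_membership() -> tuple[dict[str, str], dict[str, bool]]:
    """gene -> cluster id and gene -> cluster synteny flag."""
    df = load_cluster_table()
    cid: dict[str, str] = {}
    ok: dict[str, bool] = {}
    for r in df.itertuples():
        for m in r.members:
            cid[m] = r.cluster_id
            ok[m] = bool(r.synteny_ok)
    return cid, ok
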