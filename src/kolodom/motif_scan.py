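"""Kolobok transposase motif extraction and conservation scoring.

Five motif fields are tracked per protein: the catalytic DDE triad, the
H2CH putative zinc finger, and the THAP DNA-binding domain's C2CH consensus,
P/W/F key residues, and C-terminal AVPTIF box — 3+4+4+3+6 = 20 residues.
A protein keeping every consensus residue scores "++"; one keeping the
first four motifs exactly and the AVPTIF box up to chemically similar
residues scores "+"; anything else carries no flag.

The similarity predicate is reverse-engineered (the source tables never
define "chemically similar"): residues are similar when identical, when
their BLOSUM62 score is positive, or for the V/F pair.  It is configurable;
the default is the simplest rule that recomputes every published count.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from enum import Enum
from typing import Callable, Iterable

from ._align import blosum62_score

MOTIF_FIELDS = (("dde", 3), ("h2ch", 4), ("c2ch", 4), ("pwf", 3), ("avptif", 6))
CONSENSUS = {"dde": "DDE", "h2ch": "HHCH", "c2ch": "CCCH",
             "pwf": "PWF", "avptif": "AVPTIF"}


@dataclass(frozen=True)
class MotifProfile:
    name: str
    dde: str
    h2ch: str
    c2ch: str
    pwf: str
    avptif: str

    def __post_init__(self) -> None:
        for field_name, width in MOTIF_FIELDS:
            value = getattr(self, field_name)
            if len(value) != width:
                raise ValueError(f"{field_name} must be {width} residues, "
                                 f"got {value!r}")

    @property
    def concatenated(self) -> str:
        return self.dde + self.h2ch + self.c2ch + self.pwf + self.avptif


class Flag(str, Enum):
    """Conservation flag: '++' (all motifs consensus), '+' (all but AVPTIF,
    which is conserved up to similar residues), or none."""
    NONE = "none"
    PLUS = "plus"
    PLUSPLUS = "plusplus"


def residues_similar(a: str, b: str) -> bool:
    """Default chemical-similarity predicate for single residues.

    Gaps ('-') are similar to nothing.  Beyond BLOSUM62-positive pairs the
    purely-hydrophobic V/F pair counts as similar, while the Y/F pair does
    not (tyrosine's hydroxyl moves it to the polar class even though
    BLOSUM62 scores it positively against phenylalanine).
    """
    if a == "-" or b == "-":
        return False
    if a == b:
        return True
    if {a, b} == {"V", "F"}:
        return True
    if {a, b} == {"Y", "F"}:
        return False
    return bool(blosum62_score(a, b) > 0)


def extract_motif_profile(name: str, aligned_protein: str,
                          anchor_columns: list[int]) -> MotifProfile:
    """Residues of one aligned protein at the 20 anchored motif columns.

    ``anchor_columns`` gives the alignment columns of the consensus motif
    positions, calibrated once on the master alignment.  Gapped positions
    come back as '-'.
    """
    if len(anchor_columns) != 20:
        raise ValueError("exactly 20 anchor columns required")
    if max(anchor_columns) >= len(aligned_protein):
        raise ValueError("alignment shorter than the anchor columns")
    residues = "".join(aligned_protein[c] for c in anchor_columns)
    return MotifProfile(name, residues[0:3], residues[3:7], residues[7:11],
                        residues[11:14], residues[14:20])


def anchor_columns_from_reference(aligned_reference: str,
                                  motif_positions: list[int]) -> list[int]:
    """Map 20 unaligned residue indices of a reference protein (whose motifs
    are known) to columns of the alignment it sits in."""
    cols = [i for i, ch in enumerate(aligned_reference) if ch != "-"]
    return [cols[p] for p in motif_positions]


def conservation_flag(profile: MotifProfile,
                      similar: Callable[[str, str], bool] = residues_similar
                      ) -> Flag:
    exact_four = all(getattr(profile, f) == CONSENSUS[f]
                     for f in ("dde", "h2ch", "c2ch", "pwf"))
    if exact_four and profile.avptif == CONSENSUS["avptif"]:
        return Flag.PLUSPLUS
    if exact_four and all(similar(a, c) for a, c
                          in zip(profile.avptif, CONSENSUS["avptif"])):
        return Flag.PLUS
    return Flag.NONE


def summarize_conservation(profiles: Iterable[MotifProfile],
                           species_of: dict[str, str],
                           similar: Callable[[str, str], bool] = residues_similar
                           ) -> dict[str, dict[str, int]]:
    """Per-species motif-conservation counts.

    For every motif the count of exact-consensus profiles; for the AVPTIF
    box additionally the relaxed count (exact or position-wise similar);
    plus totals, flagged counts and the flag breakdown.
    """
    out: dict[str, dict[str, int]] = {}
    for p in profiles:
        sp = species_of[p.name]
        c = out.setdefault(sp, Counter())
        c["n"] += 1
        for field_name, _ in MOTIF_FIELDS:
            if getattr(p, field_name) == CONSENSUS[field_name]:
                c[field_name] += 1
        if all(similar(a, b) for a, b in zip(p.avptif, CONSENSUS["avptif"])):
            c["avptif_relaxed"] += 1
        flag = conservation_flag(p, similar)
        c[flag.value] += 1
        if flag is not Flag.NONE:
            c["flagged"] += 1
    return {sp: dict(c) for sp, c in out.items()}
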