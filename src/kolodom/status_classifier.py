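"""Final presumptive-status call per transposase gene.

Four structural rules combine repetitiveness, motif conservation and
synteny-verified orthology:

R1  repetitive and all motifs conserved ('+'/'++')  -> currently active
R2  repetitive, motifs lost                         -> active?
R3  (semi-)nonrepetitive in a synteny-verified
    ortholog cluster                                -> ancient domestication
R4  anything else                                   -> domestication?

The rules are reverse-engineered from the published status column (the
source never states them explicitly); they reproduce it exactly for all 62
genes.  dN/dS is carried as corroborating evidence only — every published
status follows from the structure alone.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from enum import Enum
from typing import Iterable

from .copy_profile import RepClass
from .motif_scan import Flag
from .selection_dnds import DnDsResult


class PresumptiveStatus(str, Enum):
    CURRENTLY_ACTIVE = "currently_active"
    ACTIVE_Q = "active_q"
    ANCIENT_DOMESTICATION = "ancient_domestication"
    DOMESTICATION_Q = "domestication_q"

    @property
    def printable(self) -> str:
        return {
            "currently_active": "currently active",
            "active_q": "active?",
            "ancient_domestication": "ancient domestication",
            "domestication_q": "domestication?",
        }[self.value]


PRINTABLE_TO_STATUS = {s.printable: s for s in PresumptiveStatus}

DOMESTICATED = {PresumptiveStatus.ANCIENT_DOMESTICATION,
                PresumptiveStatus.DOMESTICATION_Q}


@dataclass
class GeneRecord:
    name: str
    species: str
    rep_class: RepClass
    flag: Flag
    cluster_id: str | None = None
    cluster_synteny_ok: bool = False
    dnds_vs_relative: DnDsResult | None = None


def classify_status(r: GeneRecord) -> PresumptiveStatus:
    """Apply the four structural rules; total and mutually exclusive."""
    repetitive = r.rep_class is RepClass.REPETITIVE
    if repetitive and r.flag in (Flag.PLUS, Flag.PLUSPLUS):
        return PresumptiveStatus.CURRENTLY_ACTIVE
    if repetitive:
        return PresumptiveStatus.ACTIVE_Q
    if r.cluster_id is not None and r.cluster_synteny_ok:
        return PresumptiveStatus.ANCIENT_DOMESTICATION
    return PresumptiveStatus.DOMESTICATION_Q


def summarize_statuses(records: Iterable[GeneRecord]) -> dict:
    """Per-status and per-species counts plus the domesticated total
    (ancient domestication + domestication?)."""
    per_status: Counter = Counter()
    per_species: dict[str, Counter] = {}
    domesticated = 0
    n = 0
    for r in records:
        status = classify_status(r)
        n += 1
        per_status[status.value] += 1
        per_species.setdefault(r.species, Counter())[status.value] += 1
        if status in DOMESTICATED:
            domesticated += 1
    return {
        "n": n,
        "per_status": dict(per_status),
        "per_species": {sp: dict(c) for sp, c in per_species.items()},
        "domesticated_total": domesticated,
    }
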