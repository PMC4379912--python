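"""In-silico restriction-site (RFLP) typing at coding-region marker sites."""

from __future__ import annotations

import re
from dataclasses import dataclass

from Bio.Data.IUPACData import ambiguous_dna_values

from .reference import MT_LENGTH, ReferenceSequence

PRESENT = "present"
ABSENT = "absent"
UNTYPED = "untyped"

#: half-width of the sequence window inspected around the anchor
WINDOW = 10


@dataclass(frozen=True)
class RflpSite:
    """A labeled restriction site: anchor position + enzyme recognition motif."""

    label: str
    anchor: int
    recognition: str  # IUPAC codes allowed

    def __post_init__(self) -> None:
        if len(self.recognition) < 4:
            raise ValueError("recognition sequence must be >= 4 bp")
        if not 1 <= self.anchor <= MT_LENGTH:
            raise ValueError(f"anchor {self.anchor} outside [1, {MT_LENGTH}]")


#: the coding-region marker panel (enzyme recognition motifs:
#: HhaI GCGC, AluI AGCT, HinfI GANTC, HpaI GTTAAC, AccI GTMKAC)
PANEL = (
    RflpSite("4831HhaI", 4831, "GCGC"),
    RflpSite("5176AluI", 5176, "AGCT"),
    RflpSite("9820HinfI", 9820, "GANTC"),
    RflpSite("12406HpaI", 12406, "GTTAAC"),
    RflpSite("13262AluI", 13262, "AGCT"),
    RflpSite("14465AccI", 14465, "GTMKAC"),
)


def iupac_regex(motif: str) -> re.Pattern[str]:
    parts = []
    for c in motif.upper():
        vals = ambiguous_dna_values[c]
        parts.append(c if len(vals) == 1 else f"[{vals}]")
    return re.compile("".join(parts))


def insilico_rflp(
    sample: str,
    site: RflpSite,
    reference: ReferenceSequence,
    offset: int = 1,
) -> str:
    """Type one restriction site on a reference-aligned sample sequence.

    ``sample`` is aligned to reference coordinates starting at 1-based
    ``offset`` (default: a full-genome sequence).  Returns ``present`` if the
    IUPAC-expanded recognition motif occurs in the +/-10 bp window overlapping
    the anchor position, ``absent`` otherwise, and ``untyped`` when the window
    is not fully covered by A/C/G/T sample bases.
    """
    lo = site.anchor - WINDOW
    hi = site.anchor + WINDOW
    start_idx = lo - offset
    end_idx = hi - offset + 1
    if start_idx < 0 or end_idx > len(sample):
        return UNTYPED
    window = sample[start_idx:end_idx].upper()
    if set(window) - set("ACGT"):
        return UNTYPED
    pat = iupac_regex(site.recognition)
    anchor_idx = site.anchor - lo  # index of anchor within window
    for m in pat.finditer(window):
        if m.start() <= anchor_idx < m.end():
            return PRESENT
    return ABSENT


def rflp_profile(sample: str, reference: ReferenceSequence, offset: int = 1) -> dict[str, str]:
    """Type the whole marker panel; returns label -> present/absent/untyped."""
    return {s.label: insilico_rflp(sample, s, reference, offset) for s in PANEL}
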