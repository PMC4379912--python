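"""Reference sequence model: 16,569-bp circular mtDNA coordinate frame.

Coordinates throughout the package are 1-based and inclusive.  The control
region is the circular span 16024-576; covered ranges may wrap (a range
``16024-407`` means 16024..16569 followed by 1..407).
"""

from __future__ import annotations

import functools
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator, Sequence

from Bio import SeqIO
from Bio.Data import CodonTable
from Bio.Seq import Seq

MT_LENGTH = 16569
CONTROL_REGION = (16024, 576)  # circular span
CODING_REGION = (577, 16023)

_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_PURINES = frozenset("AG")
_PYRIMIDINES = frozenset("CT")

#: vertebrate mitochondrial genetic code
_MT_TABLE = CodonTable.unambiguous_dna_by_id[2]


def transition_partner(base: str) -> str:
    """Return the transition partner (A<->G, C<->T) of ``base``."""
    return _TRANSITION[base.upper()]


def is_transition(a: str, b: str) -> bool:
    a, b = a.upper(), b.upper()
    return (a in _PURINES and b in _PURINES) or (a in _PYRIMIDINES and b in _PYRIMIDINES)


@dataclass(frozen=True)
class Feature:
    """An annotated genome feature (gene) on the reference."""

    name: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    kind: str  # protein | tRNA | rRNA
    strand: str  # H | L

    def __post_init__(self) -> None:
        if not (1 <= self.start <= MT_LENGTH and 1 <= self.end <= MT_LENGTH):
            raise ValueError(f"feature {self.name} outside [1, {MT_LENGTH}]")
        if self.kind not in ("protein", "tRNA", "rRNA"):
            raise ValueError(f"unknown feature kind {self.kind!r}")
        if self.strand not in ("H", "L"):
            raise ValueError(f"unknown strand {self.strand!r}")

    def __contains__(self, position: int) -> bool:
        return self.start <= position <= self.end


class ReferenceSequence:
    """The reference sequence plus its gene annotation.

    Provides base lookup, feature lookup and codon translation for the
    functional classification of substitutions.
    """

    def __init__(self, bases: str, features: Sequence[Feature]):
        bases = bases.upper()
        if len(bases) != MT_LENGTH:
            raise ValueError(f"reference must be exactly {MT_LENGTH} bp, got {len(bases)}")
        if set(bases) - set("ACGT"):
            raise ValueError("reference bases must be over {A,C,G,T}")
        self.bases = bases
        self.features = tuple(features)
        # per-position feature index (positions can fall in >1 feature)
        self._by_pos: dict[int, list[Feature]] = {}
        for f in self.features:
            for pos in range(f.start, f.end + 1):
                self._by_pos.setdefault(pos, []).append(f)

    def base_at(self, position: int) -> str:
        """Base at a 1-based position (circular: position wraps mod length)."""
        return self.bases[(position - 1) % MT_LENGTH]

    def features_at(self, position: int) -> list[Feature]:
        return self._by_pos.get(position, [])

    @staticmethod
    def in_control_region(position: int) -> bool:
        return position >= CONTROL_REGION[0] or position <= CONTROL_REGION[1]

    # --- codon machinery -------------------------------------------------

    def codon_at(self, position: int, feature: Feature) -> tuple[str, int]:
        """Return (codon, offset-in-codon) for ``position`` inside a protein gene.

        For H-strand genes codons read 5'->3' from the gene start; for the
        light-strand gene the coding sequence is the reverse complement read
        from the gene end.  Trailing incomplete codons are completed from the
        downstream genomic sequence (they are completed by polyadenylation in
        the mature transcript).
        """
        if feature.kind != "protein":
            raise ValueError("codon_at requires a protein feature")
        if position not in feature:
            raise ValueError("position outside feature")
        if feature.strand == "H":
            idx = position - feature.start
            offset = idx % 3
            start = position - offset
            codon = "".join(self.base_at(start + i) for i in range(3))
        else:
            idx = feature.end - position
            offset = idx % 3
            start = position + offset  # codon runs start, start-1, start-2 on L strand
            codon = str(
                Seq("".join(self.base_at(start - i) for i in range(3))).complement()
            )
        return codon, offset

    def translate_codon(self, codon: str) -> str:
        if codon in _MT_TABLE.stop_codons:
            return "*"
        return _MT_TABLE.forward_table[codon]

    def amino_acid_change(
        self, position: int, derived: str, feature: Feature
    ) -> tuple[str, str]:
        """(reference aa, derived aa) for substituting ``derived`` at ``position``."""
        codon, offset = self.codon_at(position, feature)
        if feature.strand == "L":
            derived = str(Seq(derived).complement())
        new = codon[:offset] + derived + codon[offset + 1 :]
        return self.translate_codon(codon), self.translate_codon(new)


# --- circular interval helpers -------------------------------------------


def positions_in(intervals: Iterable[tuple[int, int]]) -> Iterator[int]:
    """Yield every position of a list of (possibly wrapping) 1-based intervals."""
    for start, end in intervals:
        if start <= end:
            yield from range(start, end + 1)
        else:  # wraps through the origin
            yield from range(start, MT_LENGTH + 1)
            yield from range(1, end + 1)


def interval_contains(intervals: Iterable[tuple[int, int]], position: int) -> bool:
    for start, end in intervals:
        if start <= end:
            if start <= position <= end:
                return True
        elif position >= start or position <= end:
            return True
    return False


def _data_text(name: str) -> str:
    return resources.files("mtphylogeo").joinpath("data", name).read_text()


def parse_annotation(text: str) -> list[Feature]:
    features = []
    for line in text.splitlines():
        if not line.strip() or line.startswith("#") or line.startswith("Name\t"):
            continue
        name, start, end, kind, strand = line.split("\t")
        features.append(Feature(name, int(start), int(end), kind, strand))
    return features


@functools.lru_cache(maxsize=4)
def load_reference(
    fasta_path: str | None = None, annotation_path: str | None = None
) -> ReferenceSequence:
    """Load the bundled (or a user-supplied) reference and gene table."""
    if fasta_path is not None:
        record = next(SeqIO.parse(fasta_path, "fasta"))
        bases = str(record.seq)
    else:
        lines = _data_text("reference.fasta").splitlines()
        bases = "".join(l.strip() for l in lines if not l.startswith(">"))
    ann_text = (
        Path(annotation_path).read_text()
        if annotation_path is not None
        else _data_text("gene_annotation.tsv")
    )
    return ReferenceSequence(bases, parse_annotation(ann_text))
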