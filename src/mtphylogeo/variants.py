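"""Reference-relative mutation notation, variant calling and filtering.

Token grammar (phylotree-style, 1-based reference coordinates):

* ``16172``          transition (derived base = transition partner of reference)
* ``16183C``         substitution to the given base (kind from purine/pyrimidine rule)
* ``16193.1C``       insertion of C after 16193, ordinal 1 (``+`` form normalized)
* ``8281d``          deletion of position 8281
* ``8281-8289d``     ranged deletion, expands to one deletion per position
* ``@10398``         back (reverse) mutation: derived state equals the reference

Leading reference-base letters (``A73G`` style) are accepted and validated.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .reference import (
    MT_LENGTH,
    ReferenceSequence,
    interval_contains,
    is_transition,
    positions_in,
    transition_partner,
)

_TOKEN_RE = re.compile(
    r"^(?P<back>@)?(?P<lead>[ACGT])?(?P<pos>\d+)"
    r"(?:\.(?P<ins>\d+))?(?P<suffix>[ACGTd])?$",
    re.IGNORECASE,
)
_RANGE_RE = re.compile(r"^(?P<a>\d+)-(?P<b>\d+)(?:d|del)$", re.IGNORECASE)
_PLUS_RE = re.compile(r"^(?P<pos>\d+)\+(?P<bases>[ACGT]+)$", re.IGNORECASE)

DELETION = "deletion"
INSERTION = "insertion"
TRANSITION = "transition"
TRANSVERSION = "transversion"


class MutationError(ValueError):
    """Malformed or inconsistent mutation token."""


@dataclass(frozen=True, order=True)
class Mutation:
    """A single reference-relative change.

    ``ref`` is empty for insertions; ``derived`` is empty for deletions.
    ``insertion_index`` is the ordinal of a ``.N`` insertion (0 if none).
    """

    position: int
    insertion_index: int = 0
    ref: str = ""
    derived: str = ""
    kind: str = TRANSITION
    back_mutation: bool = False

    def __post_init__(self) -> None:
        if not 1 <= self.position <= MT_LENGTH:
            raise MutationError(f"position {self.position} outside [1, {MT_LENGTH}]")
        if self.kind == INSERTION and self.insertion_index < 1:
            raise MutationError("insertion requires insertion_index >= 1")
        if self.kind != INSERTION and self.insertion_index != 0:
            raise MutationError("insertion_index only valid for insertions")
        if self.back_mutation and self.ref and self.derived != self.ref:
            raise MutationError("back mutation must restore the reference base")
        if self.kind in (TRANSITION, TRANSVERSION) and self.ref and self.derived:
            ti = is_transition(self.ref, self.derived)
            if ti != (self.kind == TRANSITION):
                raise MutationError(
                    f"kind {self.kind} inconsistent with {self.ref}->{self.derived}"
                )

    @property
    def is_substitution(self) -> bool:
        return self.kind in (TRANSITION, TRANSVERSION)

    @property
    def key(self) -> tuple[int, int, str]:
        """Identity used for matching mutations across profiles/motifs."""
        return (self.position, self.insertion_index, self.derived if not self.back_mutation else "@")


def parse_mutation_token(token: str, reference: ReferenceSequence) -> list[Mutation]:
    """Parse one token into mutations (a ranged deletion expands to several).

    Raises :class:`MutationError` on malformed tokens, positions outside the
    genome, or a substitution to the reference base without ``@``.
    """
    token = token.strip()
    if not token:
        raise MutationError("empty token")
    m = _RANGE_RE.match(token)
    if m:
        a, b = int(m.group("a")), int(m.group("b"))
        if not (1 <= a <= b <= MT_LENGTH):
            raise MutationError(f"bad deletion range {token!r}")
        return [
            Mutation(position=p, ref=reference.base_at(p), derived="", kind=DELETION)
            for p in range(a, b + 1)
        ]
    m = _PLUS_RE.match(token)
    if m:  # "+": normalized to .N form
        pos = int(m.group("pos"))
        return [
            Mutation(position=pos, insertion_index=i + 1, derived=b.upper(), kind=INSERTION)
            for i, b in enumerate(m.group("bases"))
        ]
    m = _TOKEN_RE.match(token)
    if not m:
        raise MutationError(f"malformed token {token!r}")
    pos = int(m.group("pos"))
    if not 1 <= pos <= MT_LENGTH:
        raise MutationError(f"position {pos} outside [1, {MT_LENGTH}]")
    back = bool(m.group("back"))
    lead = (m.group("lead") or "").upper()
    ins = m.group("ins")
    suffix = m.group("suffix") or ""
    refbase = reference.base_at(pos)

    if ins is not None:
        idx = int(ins)
        if idx < 1 or not suffix or suffix.lower() == "d":
            raise MutationError(f"malformed insertion token {token!r}")
        if back:
            raise MutationError("back-mutation insertions are not supported")
        return [Mutation(position=pos, insertion_index=idx, derived=suffix.upper(), kind=INSERTION)]

    if suffix.lower() == "d":
        if back:
            raise MutationError("back-mutation deletions are not supported")
        return [Mutation(position=pos, ref=refbase, derived="", kind=DELETION)]

    if lead and lead != refbase:
        raise MutationError(
            f"token {token!r}: leading base {lead} does not match reference {refbase}"
        )

    if back:
        derived = suffix.upper() if suffix else refbase
        if derived != refbase:
            raise MutationError(f"back mutation {token!r} must restore reference {refbase}")
        return [
            Mutation(
                position=pos, ref=refbase, derived=refbase, kind=TRANSITION, back_mutation=True
            )
        ]

    derived = suffix.upper() if suffix else transition_partner(refbase)
    if derived == refbase:
        raise MutationError(f"token {token!r}: derived equals reference without '@'")
    kind = TRANSITION if is_transition(refbase, derived) else TRANSVERSION
    return [Mutation(position=pos, ref=refbase, derived=derived, kind=kind)]


def parse_tokens(tokens: str | list[str], reference: ReferenceSequence) -> list[Mutation]:
    """Parse a whitespace-separated token string (or list) into mutations."""
    if isinstance(tokens, str):
        tokens = tokens.split()
    out: list[Mutation] = []
    for t in tokens:
        out.extend(parse_mutation_token(t, reference))
    return out


def format_mutation(m: Mutation) -> str:
    """Inverse of :func:`parse_mutation_token` for a single mutation."""
    if m.kind == INSERTION:
        return f"{m.position}.{m.insertion_index}{m.derived}"
    if m.kind == DELETION:
        return f"{m.position}d"
    if m.back_mutation:
        return f"@{m.position}"
    if m.kind == TRANSITION and (not m.ref or m.derived == transition_partner(m.ref)):
        return str(m.position)  # bare form: derived is the forced transition partner
    return f"{m.position}{m.derived}"


def format_mutations(muts: list[Mutation]) -> list[str]:
    """Format mutations, compacting runs of consecutive deletions to ``a-bd``."""
    out: list[str] = []
    i = 0
    muts = sorted(muts, key=lambda m: (m.position, m.insertion_index))
    while i < len(muts):
        m = muts[i]
        if m.kind == DELETION:
            j = i
            while (
                j + 1 < len(muts)
                and muts[j + 1].kind == DELETION
                and muts[j + 1].position == muts[j].position + 1
            ):
                j += 1
            if j > i:
                out.append(f"{m.position}-{muts[j].position}d")
            else:
                out.append(f"{m.position}d")
            i = j + 1
        else:
            out.append(format_mutation(m))
            i += 1
    return out


@dataclass
class VariantProfile:
    """A sample's reference-relative mutations plus its sequenced range(s)."""

    sample_id: str
    covered: list[tuple[int, int]] = field(default_factory=list)
    mutations: list[Mutation] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[tuple[int, int]] = set()
        for m in self.mutations:
            if not self.covers(m.position):
                raise ValueError(
                    f"{self.sample_id}: mutation at {m.position} outside covered ranges"
                )
            k = (m.position, m.insertion_index)
            if k in seen:
                raise ValueError(f"{self.sample_id}: duplicate mutation at {k}")
            seen.add(k)

    def covers(self, position: int) -> bool:
        return interval_contains(self.covered, position)

    @property
    def keys(self) -> frozenset[tuple[int, int, str]]:
        return frozenset(m.key for m in self.mutations)

    def tokens(self) -> list[str]:
        return format_mutations(self.mutations)


FULL_COVERAGE = [(1, MT_LENGTH)]

# --- functional classification -------------------------------------------

SYNONYMOUS = "s"
NONSYNONYMOUS = "ns"
TRNA = "t"
RRNA = "r"
NONCODING = "nc"
CONTROL = "control"
INDEL = "indel"


def classify_mutation_function(m: Mutation, reference: ReferenceSequence) -> str:
    """Functional class of a mutation: s/ns/t/r/nc, control, or indel.

    Substitutions in the control region (16024-576) are labeled ``control``;
    indels are labeled ``indel`` (their s/ns status is undefined).  Positions
    inside more than one protein gene are nonsynonymous if the amino acid
    changes in any reading frame.
    """
    if not m.is_substitution:
        return INDEL
    if reference.in_control_region(m.position):
        return CONTROL
    feats = reference.features_at(m.position)
    proteins = [f for f in feats if f.kind == "protein"]
    if proteins:
        for f in proteins:
            aa_ref, aa_new = reference.amino_acid_change(m.position, m.derived, f)
            if aa_ref != aa_new:
                return NONSYNONYMOUS
        return SYNONYMOUS
    if any(f.kind == "tRNA" for f in feats):
        return TRNA
    if any(f.kind == "rRNA" for f in feats):
        return RRNA
    return NONCODING


# --- exclusion filter -----------------------------------------------------


def apply_exclusion_filter(profile: VariantProfile) -> VariantProfile:
    """Drop hypermutable/length-polymorphic sites conventionally disregarded.

    Removed: indels in 303-315, AC indels in 515-522, transversions 16182C
    and 16183C, any C insertion at 16193, and any variant at 16519.  All
    other mutations are preserved in order.
    """
    kept = []
    for m in profile.mutations:
        if m.position == 16519:
            continue
        if not m.is_substitution and 303 <= m.position <= 315:
            continue
        if not m.is_substitution and 515 <= m.position <= 522:
            continue
        if m.kind == TRANSVERSION and m.derived == "C" and m.position in (16182, 16183):
            continue
        if m.kind == INSERTION and m.position == 16193 and m.derived == "C":
            continue
        kept.append(m)
    return VariantProfile(profile.sample_id, list(profile.covered), kept)


# --- variant calling ------------------------------------------------------

_AMBIGUOUS = set("RYSWKMBDHVN")


def call_variants(
    sample: str,
    covered: list[tuple[int, int]],
    reference: ReferenceSequence,
    sample_id: str = "sample",
) -> VariantProfile:
    """Diff a sample sequence against the reference over ``covered``.

    The sample is either the same length as the covered span (aligned;
    ``-`` marks deletions) or a plain sequence of different length, in which
    case a pairwise diff is computed.  Indels are normalized to their
    3'-most equivalent placement.  Positions with ambiguity codes are
    treated as uncovered and removed from the profile's covered ranges.
    """
    if not covered:
        raise ValueError("covered interval empty")
    sample = sample.upper()
    bad = set(sample) - set("ACGT-") - _AMBIGUOUS
    if bad:
        raise ValueError(f"non-IUPAC characters in sample: {sorted(bad)}")
    ref_positions = list(positions_in(covered))
    ref_seq = "".join(reference.base_at(p) for p in ref_positions)

    ins_muts: list[Mutation] = []
    if len(sample) == len(ref_positions):
        aligned = sample
    else:
        aligned, ins_muts = _align_to_reference(
            sample.replace("-", ""), ref_seq, ref_positions
        )

    muts: list[Mutation] = []
    uncovered: set[int] = set()
    for i, pos in enumerate(ref_positions):
        c = aligned[i]
        if c == "-":
            muts.append(Mutation(position=pos, ref=reference.base_at(pos), derived="", kind=DELETION))
        elif c in _AMBIGUOUS:
            uncovered.add(pos)
        elif c != reference.base_at(pos):
            rb = reference.base_at(pos)
            kind = TRANSITION if is_transition(rb, c) else TRANSVERSION
            muts.append(Mutation(position=pos, ref=rb, derived=c, kind=kind))
    muts.extend(ins_muts)
    muts = _normalize_indels(muts, reference)
    new_covered = _subtract_positions(covered, uncovered)
    muts = [m for m in muts if interval_contains(new_covered, m.position)]
    muts.sort(key=lambda m: (m.position, m.insertion_index))
    return VariantProfile(sample_id, new_covered, muts)


def _align_to_reference(
    sample: str, ref_seq: str, ref_positions: list[int]
) -> tuple[str, list[Mutation]]:
    """Pairwise diff of near-identical sequences via difflib opcodes.

    Returns a string the same length as ``ref_seq`` with '-' at deleted
    positions, plus the insertion mutations (anchored to the reference
    position after which they occur).
    """
    import difflib

    sm = difflib.SequenceMatcher(a=ref_seq, b=sample, autojunk=False)
    out = []
    ins: list[tuple[int, str]] = []  # (ref index after which, bases)
    for tag, i1, i2, j1, j2 in sm.get_opcodes():
        if tag == "equal":
            out.append(sample[j1:j2])
        elif tag == "replace":
            # align positionally; length mismatch handled as sub + indel
            n = min(i2 - i1, j2 - j1)
            out.append(sample[j1 : j1 + n])
            if (i2 - i1) > n:
                out.append("-" * ((i2 - i1) - n))
            elif (j2 - j1) > n:
                ins.append((i2 - 1, sample[j1 + n : j2]))
        elif tag == "delete":
            out.append("-" * (i2 - i1))
        elif tag == "insert":
            ins.append((i1 - 1, sample[j1:j2]))
    ins_muts = [
        Mutation(
            position=ref_positions[max(idx, 0)],
            insertion_index=k + 1,
            derived=b,
            kind=INSERTION,
        )
        for idx, bases in ins
        for k, b in enumerate(bases)
    ]
    return "".join(out), ins_muts


def _normalize_indels(muts: list[Mutation], reference: ReferenceSequence) -> list[Mutation]:
    """Shift indels to their 3'-most equivalent placement.

    A deletion run a..b slides right while base(a) == base(b+1); an
    insertion after p slides right while its first base equals base(p+1),
    rotating the inserted string.
    """
    subs = [m for m in muts if m.is_substitution]
    dels = sorted((m for m in muts if m.kind == DELETION), key=lambda m: m.position)
    inss = sorted(
        (m for m in muts if m.kind == INSERTION),
        key=lambda m: (m.position, m.insertion_index),
    )
    out: list[Mutation] = list(subs)

    # group consecutive deletions into runs
    i = 0
    while i < len(dels):
        j = i
        while j + 1 < len(dels) and dels[j + 1].position == dels[j].position + 1:
            j += 1
        a, b = dels[i].position, dels[j].position
        while b + 1 <= MT_LENGTH and reference.base_at(a) == reference.base_at(b + 1):
            a += 1
            b += 1
        out.extend(
            Mutation(position=p, ref=reference.base_at(p), derived="", kind=DELETION)
            for p in range(a, b + 1)
        )
        i = j + 1

    # group insertions by anchor
    by_anchor: dict[int, list[Mutation]] = {}
    for m in inss:
        by_anchor.setdefault(m.position, []).append(m)
    for anchor, group in by_anchor.items():
        bases = "".join(m.derived for m in sorted(group, key=lambda m: m.insertion_index))
        pos = anchor
        while pos + 1 <= MT_LENGTH and bases[0] == reference.base_at(pos + 1):
            bases = bases[1:] + bases[0]
            pos += 1
        out.extend(
            Mutation(position=pos, insertion_index=k + 1, derived=b, kind=INSERTION)
            for k, b in enumerate(bases)
        )
    return out


def _subtract_positions(
    covered: list[tuple[int, int]], drop: set[int]
) -> list[tuple[int, int]]:
    """Remove individual positions from covered intervals (keeps wrap form)."""
    if not drop:
        return list(covered)
    out: list[tuple[int, int]] = []
    for start, end in covered:
        spans = [(start, MT_LENGTH), (1, end)] if start > end else [(start, end)]
        for s, e in spans:
            cur = s
            for p in sorted(x for x in drop if s <= x <= e):
                if p > cur:
                    out.append((cur, p - 1))
                cur = p + 1
            if cur <= e:
                out.append((cur, e))
    return out


def mutate_sequence(reference: ReferenceSequence, muts: list[Mutation]) -> str:
    """Apply substitutions/indels to the full reference sequence (test helper)."""
    seq: list[str] = list(reference.bases)
    inserts: dict[int, list[Mutation]] = {}
    for m in muts:
        if m.is_substitution:
            seq[m.position - 1] = m.derived if not m.back_mutation else m.ref
        elif m.kind == DELETION:
            seq[m.position - 1] = ""
        else:
            inserts.setdefault(m.position, []).append(m)
    for pos, group in sorted(inserts.items(), reverse=True):
        bases = "".join(
            g.derived for g in sorted(group, key=lambda g: g.insertion_index)
        )
        seq[pos - 1] = seq[pos - 1] + bases
    return "".join(seq)


# --- variant table TSV ----------------------------------------------------


def _parse_range(text: str) -> list[tuple[int, int]]:
    out = []
    for part in text.split(";"):
        part = part.strip()
        if not part:
            continue
        a, b = part.split("-")
        out.append((int(a), int(b)))
    return out


def read_variant_table(path: str, reference: ReferenceSequence) -> list[VariantProfile]:
    """Read the tab-separated variant table (SampleID / Range / Variants)."""
    profiles = []
    with open(path, encoding="utf-8") as fh:
        header = None
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            if header is None:
                header = line.split("\t")
                if header[:3] != ["SampleID", "Range", "Variants"]:
                    raise ValueError("variant table must have header SampleID\\tRange\\tVariants")
                continue
            fields = line.split("\t")
            sample_id, rng = fields[0], fields[1]
            tokens = fields[2] if len(fields) > 2 else ""
            profiles.append(
                VariantProfile(sample_id, _parse_range(rng), parse_tokens(tokens, reference))
            )
    return profiles


def write_variant_table(profiles: list[VariantProfile], path: str) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("SampleID\tRange\tVariants\n")
        for p in profiles:
            rng = ";".join(f"{a}-{b}" for a, b in p.covered)
            fh.write(f"{p.sample_id}\t{rng}\t{' '.join(p.tokens())}\n")
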