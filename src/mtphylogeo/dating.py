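"""Founder-age (TMRCA) estimation from rooted genealogies via the rho statistic.

rho is the mean number of mutations from the clade root to its sampled tips;
its standard error is computed from branch mutation counts weighted by the
squared number of subtended tips.  Ages follow fixed molecular clocks, one
mutation per 2,585 / 7,884 / 18,845 years for the complete-genome,
coding-synonymous and HVS-I-transition mutation classes respectively.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from ._util import round_half_up
from .reference import ReferenceSequence, load_reference
from .variants import (
    Mutation,
    SYNONYMOUS,
    TRANSITION,
    VariantProfile,
    apply_exclusion_filter,
    classify_mutation_function,
)

COMPLETE_GENOME = "complete_genome"
CODING_SYNONYMOUS = "coding_synonymous"
HVS_TRANSITIONS = "hvs_transitions"

HVS_WINDOW = (16090, 16365)


@dataclass(frozen=True)
class ClockRate:
    """A mutation-class-specific clock: years per accumulated mutation."""

    mutation_class: str
    years_per_mutation: float

    def __post_init__(self) -> None:
        if self.years_per_mutation <= 0:
            raise ValueError("rate must be positive")


CLOCKS: dict[str, ClockRate] = {
    COMPLETE_GENOME: ClockRate(COMPLETE_GENOME, 2585.0),
    CODING_SYNONYMOUS: ClockRate(CODING_SYNONYMOUS, 7884.0),
    HVS_TRANSITIONS: ClockRate(HVS_TRANSITIONS, 18845.0),
}


def filter_mutations_for_clock(
    muts: list[Mutation], clock: ClockRate, reference: ReferenceSequence | None = None
) -> list[Mutation]:
    """Keep only the mutations counted by the given clock.

    complete_genome: all substitutions (indels excluded); coding_synonymous:
    synonymous coding substitutions; hvs_transitions: transitions inside
    16090-16365.  Callers should apply the exclusion filter first.
    """
    if clock.mutation_class == COMPLETE_GENOME:
        return [m for m in muts if m.is_substitution]
    if clock.mutation_class == CODING_SYNONYMOUS:
        reference = reference or load_reference()
        return [
            m
            for m in muts
            if m.is_substitution
            and classify_mutation_function(m, reference) == SYNONYMOUS
        ]
    if clock.mutation_class == HVS_TRANSITIONS:
        lo, hi = HVS_WINDOW
        return [
            m
            for m in muts
            if m.kind == TRANSITION and not m.back_mutation and lo <= m.position <= hi
        ]
    raise ValueError(f"unknown clock class {clock.mutation_class!r}")


class GenealogyTree:
    """A rooted genealogy with per-branch mutation counts.

    Nodes are arbitrary hashable ids; each non-root node has a parent and an
    integer mutation count on the branch above it.
    """

    def __init__(self, root: str = "root"):
        self.root = root
        self.parent: dict[str, str] = {}
        self.branch_mutations: dict[str, int] = {}
        self.children: dict[str, list[str]] = {root: []}

    def add_node(self, name: str, parent: str, mutations: int) -> None:
        if name in self.children:
            raise ValueError(f"duplicate node {name!r}")
        if parent not in self.children:
            raise ValueError(f"unknown parent {parent!r}")
        if mutations < 0 or int(mutations) != mutations:
            raise ValueError("branch mutation count must be a non-negative integer")
        self.parent[name] = parent
        self.branch_mutations[name] = int(mutations)
        self.children[name] = []
        self.children[parent].append(name)

    @property
    def tips(self) -> list[str]:
        return [n for n, ch in self.children.items() if not ch and n != self.root]

    @property
    def n_tips(self) -> int:
        return len(self.tips)

    def subtended_tips(self, node: str) -> int:
        """Number of tips below (or at) ``node`` (the n_b of the branch above it)."""
        if not self.children[node]:
            return 0 if node == self.root else 1
        return sum(self.subtended_tips(c) for c in self.children[node])

    def tip_path_length(self, tip: str) -> int:
        total = 0
        cur = tip
        while cur != self.root:
            total += self.branch_mutations[cur]
            cur = self.parent[cur]
        return total

    @classmethod
    def star(cls, tip_mutation_counts: list[int]) -> "GenealogyTree":
        g = cls()
        for i, l in enumerate(tip_mutation_counts):
            g.add_node(f"tip{i}", g.root, l)
        return g


def compute_rho(g: GenealogyTree) -> float:
    """Mean root-to-tip mutation count (= sum_b l_b n_b / N)."""
    tips = g.tips
    if not tips:
        raise ValueError("genealogy has no tips")
    return sum(g.tip_path_length(t) for t in tips) / len(tips)


def saillard_sigma(g: GenealogyTree) -> float:
    """Standard error of rho: sqrt(sum_b l_b n_b^2) / N."""
    tips = g.tips
    if not tips:
        raise ValueError("genealogy has no tips")
    n = len(tips)
    total = 0
    for node in g.parent:  # every branch (above each non-root node)
        nb = g.subtended_tips(node)
        total += g.branch_mutations[node] * nb * nb
    return math.sqrt(total) / n


def rho_to_age(rho: float, sigma: float, clock: ClockRate) -> tuple[float, float]:
    """Convert (rho, sigma) to (age, age sigma) in kya, half-up at 2 decimals."""
    if rho < 0 or sigma < 0:
        raise ValueError("rho and sigma must be non-negative")
    age = rho * clock.years_per_mutation / 1000.0
    age_sigma = sigma * clock.years_per_mutation / 1000.0
    return round_half_up(age, 2), round_half_up(age_sigma, 2)


@dataclass
class RhoEstimate:
    """A Table-style dating row for one haplogroup under one clock."""

    haplogroup: str
    n: int
    rho: float
    sigma: float
    clock: ClockRate
    age_kya: float
    age_sigma_kya: float
    n_excluded: int = 0

    @property
    def rho_2dp(self) -> float:
        return round_half_up(self.rho, 2)

    @property
    def sigma_2dp(self) -> float:
        return round_half_up(self.sigma, 2)


def date_haplogroup(
    profiles: list[VariantProfile],
    root_profile: VariantProfile,
    clock: ClockRate,
    reference: ReferenceSequence | None = None,
    genealogy: GenealogyTree | None = None,
    haplogroup: str = "",
) -> RhoEstimate:
    """Estimate the TMRCA of a clade from its member profiles.

    Without a supplied genealogy, a star genealogy is assumed: each tip
    attaches to the root with branch length equal to the clock-filtered
    mutation distance between the profile and the clade root haplotype.
    Profiles with no covered clock-eligible sites are excluded (counted in
    ``n_excluded``).  Heteroplasmic/uncertain states are not represented in
    profiles and are therefore ignored.
    """
    if not profiles:
        raise ValueError("no profiles to date")
    reference = reference or load_reference()
    n_excluded = 0
    if genealogy is None:
        root_keys = {m.key: m for m in apply_exclusion_filter(root_profile).mutations}
        lengths = []
        for p in profiles:
            if not _covers_clock_sites(p, clock):
                n_excluded += 1
                continue
            p_f = apply_exclusion_filter(p)
            p_keys = {m.key: m for m in p_f.mutations}
            diff = [p_keys[k] for k in p_keys.keys() - root_keys.keys()]
            diff += [root_keys[k] for k in root_keys.keys() - p_keys.keys()]
            lengths.append(len(filter_mutations_for_clock(diff, clock, reference)))
        if not lengths:
            raise ValueError("all profiles excluded by the clock filter")
        genealogy = GenealogyTree.star(lengths)
    rho = compute_rho(genealogy)
    sigma = saillard_sigma(genealogy)
    age, age_sigma = rho_to_age(rho, sigma, clock)
    return RhoEstimate(
        haplogroup=haplogroup,
        n=genealogy.n_tips,
        rho=rho,
        sigma=sigma,
        clock=clock,
        age_kya=age,
        age_sigma_kya=age_sigma,
        n_excluded=n_excluded,
    )


def _covers_clock_sites(profile: VariantProfile, clock: ClockRate) -> bool:
    if clock.mutation_class == HVS_TRANSITIONS:
        lo, hi = HVS_WINDOW
        return any(profile.covers(p) for p in range(lo, hi + 1))
    return bool(profile.covered)


def write_estimates_tsv(estimates: list[RhoEstimate], path: str) -> None:
    """Write dating rows in a table layout (one row per haplogroup/clock)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("Haplogroup\tClock\tN\tRho\tSigma\tAge_kya\tAgeSigma_kya\tExcluded\n")
        for e in estimates:
            fh.write(
                f"{e.haplogroup}\t{e.clock.mutation_class}\t{e.n}\t"
                f"{e.rho_2dp:.2f}\t{e.sigma_2dp:.2f}\t"
                f"{e.age_kya:.2f}\t{e.age_sigma_kya:.2f}\t{e.n_excluded}\n"
            )


def genealogy_from_newick(text: str) -> GenealogyTree:
    """Parse a Newick string whose branch lengths are integer mutation counts."""
    import dendropy

    tree = dendropy.Tree.get(data=text, schema="newick")
    g = GenealogyTree()
    counter = [0]

    def name_of(node) -> str:
        if node.taxon is not None and node.taxon.label:
            return node.taxon.label
        if node.label:
            return node.label
        counter[0] += 1
        return f"_internal{counter[0]}"

    root = tree.seed_node
    mapping = {id(root): g.root}
    for node in root.preorder_iter():
        if node is root:
            continue
        name = name_of(node)
        length = int(round(node.edge.length or 0))
        g.add_node(name, mapping[id(node.parent_node)], length)
        mapping[id(node)] = name
    return g
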