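"""Motif-based haplogroup classification against a rooted clade tree.

A haplogroup tree is a rooted tree of named clades; each non-root node
carries the motif of defining mutations on the branch leading to it.  A
profile is scored against every node's *cumulative* motif (root-to-node,
with back mutations cancelling earlier occurrences of the same position),
restricted to the profile's sequenced ranges.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

from .reference import ReferenceSequence, load_reference
from .variants import Mutation, VariantProfile, parse_tokens

ANCESTRY_LABELS = ("EastEurasian", "SouthAsian", "WestEurasian", "Other", "Unassigned")
UNASSIGNED = "Unassigned"


@dataclass
class HaplogroupNode:
    name: str
    parent: str  # empty for root
    motif_tokens: list[str] = field(default_factory=list)
    ancestry: str = ""
    motif: list[Mutation] = field(default_factory=list)  # parsed branch motif


class HaplogroupTree:
    """Validated rooted tree of haplogroup definitions."""

    def __init__(self, nodes: list[HaplogroupNode]):
        self.nodes: dict[str, HaplogroupNode] = {}
        roots = []
        for n in nodes:
            if n.name in self.nodes:
                raise ValueError(f"duplicate haplogroup name {n.name!r}")
            self.nodes[n.name] = n
            if not n.parent:
                roots.append(n.name)
        if len(roots) != 1:
            raise ValueError(f"tree must have exactly one root, found {roots}")
        self.root = roots[0]
        for n in self.nodes.values():
            if n.parent and n.parent not in self.nodes:
                raise ValueError(f"node {n.name!r} has missing parent {n.parent!r}")
            if n.parent and not n.motif:
                raise ValueError(f"non-root node {n.name!r} has empty motif")
        # cycle check / depth computation
        self._depth: dict[str, int] = {}
        for name in self.nodes:
            seen = set()
            d = 0
            cur = name
            while self.nodes[cur].parent:
                if cur in seen:
                    raise ValueError(f"cycle detected at {cur!r}")
                seen.add(cur)
                cur = self.nodes[cur].parent
                d += 1
            self._depth[name] = d

    def __contains__(self, name: str) -> bool:
        return name in self.nodes

    def __iter__(self):
        return iter(self.nodes.values())

    def depth(self, name: str) -> int:
        return self._depth[name]

    def path(self, name: str) -> list[str]:
        """Names from root to ``name`` inclusive."""
        out = []
        cur = name
        while True:
            out.append(cur)
            p = self.nodes[cur].parent
            if not p:
                break
            cur = p
        return out[::-1]

    def subtree(self, name: str) -> set[str]:
        out = {name}
        changed = True
        while changed:
            changed = False
            for n in self.nodes.values():
                if n.parent in out and n.name not in out:
                    out.add(n.name)
                    changed = True
        return out

    def path_motif(self, name: str) -> list[Mutation]:
        """Cumulative defining mutations root -> node.

        Back-mutation tokens cancel the earlier occurrence of the same
        position; a back mutation with nothing to cancel is dropped (the
        expected state is then simply the reference).
        """
        if name not in self.nodes:
            raise KeyError(name)
        cache = getattr(self, "_motif_cache", None)
        if cache is None:
            cache = self._motif_cache = {}
        if name in cache:
            return list(cache[name])
        acc: dict[tuple[int, int], Mutation] = {}
        for node_name in self.path(name):
            for m in self.nodes[node_name].motif:
                if m.back_mutation:
                    acc.pop((m.position, m.insertion_index), None)
                else:
                    acc[(m.position, m.insertion_index)] = m
        out = [acc[k] for k in sorted(acc)]
        cache[name] = out
        return list(out)

    def ancestry_of(self, name: str) -> str:
        """Nearest explicit ancestry label on the root path; 'Other' if none."""
        for node_name in reversed(self.path(name)):
            if self.nodes[node_name].ancestry:
                return self.nodes[node_name].ancestry
        return "Other"

    def defining_positions(self) -> set[int]:
        """Every position used in any branch motif (for private-site avoidance)."""
        out = set()
        for n in self.nodes.values():
            out.update(m.position for m in n.motif)
        return out


def load_haplogroup_tree(
    path: str | None = None, reference: ReferenceSequence | None = None
) -> HaplogroupTree:
    """Load a haplogroup tree TSV (bundled fixture tree by default)."""
    reference = reference or load_reference()
    if path is None:
        text = resources.files("mtphylogeo").joinpath("data", "haplogroups.tsv").read_text()
    else:
        with open(path, encoding="utf-8") as fh:
            text = fh.read()
    nodes = []
    header_seen = False
    for line in text.splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        if not header_seen:
            if line.split("\t")[0] != "Name":
                raise ValueError("haplogroup tree file must start with a Name/Parent/Motif header")
            header_seen = True
            continue
        fields = line.split("\t")
        fields += [""] * (4 - len(fields))
        name, parent, motif_text, ancestry = fields[:4]
        if ancestry and ancestry not in ANCESTRY_LABELS:
            raise ValueError(f"unknown ancestry label {ancestry!r}")
        tokens = motif_text.split()
        nodes.append(
            HaplogroupNode(
                name=name,
                parent=parent,
                motif_tokens=tokens,
                ancestry=ancestry,
                motif=parse_tokens(tokens, reference),
            )
        )
    return HaplogroupTree(nodes)


@dataclass
class AssignmentResult:
    """Outcome of scoring a profile against the haplogroup tree."""

    sample_id: str
    haplogroup: str  # best name, or "Unassigned"
    co_optimal: list[str]  # all argmax names (tie reporting)
    score: float
    matched: int
    expected_in_range: int
    conflicts: int  # expected-in-range motif mutations absent from the profile
    ancestry: str

    @property
    def unambiguous(self) -> bool:
        return self.haplogroup != UNASSIGNED and len(self.co_optimal) == 1


def assign_haplogroup(
    profile: VariantProfile, tree: HaplogroupTree, w_miss: float = 1.0
) -> AssignmentResult:
    """Assign a profile to the best-scoring haplogroup.

    Score of a node = matched cumulative-motif mutations (restricted to the
    profile's covered ranges) minus ``w_miss`` times the covered-but-absent
    ones.  Ties are broken by more matches, fewer misses, shallower depth,
    then name; all co-optimal nodes are reported.  A best score <= 0 yields
    ``Unassigned``.
    """
    if not tree.nodes:
        raise ValueError("empty haplogroup tree")
    keys = profile.keys
    rows = []
    for node in tree:
        motif = tree.path_motif(node.name)
        in_range = [m for m in motif if profile.covers(m.position)]
        matched = sum(1 for m in in_range if m.key in keys)
        missing = len(in_range) - matched
        score = matched - w_miss * missing
        rows.append((score, matched, missing, node.name))
    best_score = max(r[0] for r in rows)
    co = [r for r in rows if r[0] == best_score]
    co.sort(key=lambda r: (-r[1], r[2], tree.depth(r[3]), r[3]))
    score, matched, missing, name = co[0]
    if best_score <= 0:
        return AssignmentResult(
            sample_id=profile.sample_id,
            haplogroup=UNASSIGNED,
            co_optimal=[r[3] for r in co],
            score=best_score,
            matched=matched,
            expected_in_range=matched + missing,
            conflicts=missing,
            ancestry=UNASSIGNED,
        )
    return AssignmentResult(
        sample_id=profile.sample_id,
        haplogroup=name,
        co_optimal=[r[3] for r in co],
        score=score,
        matched=matched,
        expected_in_range=matched + missing,
        conflicts=missing,
        ancestry=tree.ancestry_of(name),
    )


def summarize_ancestry(
    assignments: list[AssignmentResult],
) -> dict[str, tuple[int, float]]:
    """Counts and half-up 2-decimal percentages per macro-ancestry label."""
    from ._util import round_half_up

    if not assignments:
        raise ValueError("no assignments to summarize")
    counts: dict[str, int] = {}
    for a in assignments:
        counts[a.ancestry] = counts.get(a.ancestry, 0) + 1
    total = len(assignments)
    return {
        label: (c, round_half_up(100.0 * c / total, 2))
        for label, c in sorted(counts.items())
    }
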