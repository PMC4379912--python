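"""Seeded synthetic-data generators for every pipeline stage.

All generators draw from a single explicitly seeded NumPy RNG stream per
call and are bit-reproducible given (seed, parameters).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dating import (
    CLOCKS,
    COMPLETE_GENOME,
    CODING_SYNONYMOUS,
    HVS_TRANSITIONS,
    HVS_WINDOW,
    ClockRate,
    GenealogyTree,
)
from .haplogroups import HaplogroupTree
from .popstats import FrequencyTable
from .reference import CODING_REGION, MT_LENGTH, ReferenceSequence, load_reference, transition_partner
from .spatial import GeoPoint
from .variants import (
    FULL_COVERAGE,
    Mutation,
    SYNONYMOUS,
    TRANSITION,
    VariantProfile,
    classify_mutation_function,
    is_transition,
)

#: sites conventionally disregarded (kept out of simulated private variation)
_EXCLUDED_POSITIONS = frozenset(
    set(range(303, 316)) | set(range(515, 523)) | {16182, 16183, 16193, 16519}
)


@dataclass
class SimulationConfig:
    """Bundle of generator parameters; seed is mandatory."""

    seed: int
    n_tips: int = 10
    lam: float = 2.0
    clock: str = COMPLETE_GENOME
    topology: str = "star"  # star | bifurcating
    n_populations: int = 4
    n_per_population: int = 50
    cline_slope: float = 0.0
    private_rate: float = 1.0

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if self.lam < 0:
            raise ValueError("lam must be >= 0")


_eligible_cache: dict[tuple[int, str], list[int]] = {}


def clock_eligible_positions(
    clock_class: str, reference: ReferenceSequence | None = None
) -> list[int]:
    """Positions where a transition is counted by the given clock."""
    reference = reference or load_reference()
    key = (id(reference), clock_class)
    if key in _eligible_cache:
        return _eligible_cache[key]
    if clock_class == HVS_TRANSITIONS:
        pos = [p for p in range(HVS_WINDOW[0], HVS_WINDOW[1] + 1)]
    elif clock_class == COMPLETE_GENOME:
        pos = list(range(1, MT_LENGTH + 1))
    elif clock_class == CODING_SYNONYMOUS:
        pos = []
        for p in range(CODING_REGION[0], CODING_REGION[1] + 1):
            m = _transition_at(p, reference)
            if classify_mutation_function(m, reference) == SYNONYMOUS:
                pos.append(p)
    else:
        raise ValueError(f"unknown clock class {clock_class!r}")
    pos = [p for p in pos if p not in _EXCLUDED_POSITIONS]
    _eligible_cache[key] = pos
    return pos


def _transition_at(position: int, reference: ReferenceSequence) -> Mutation:
    ref = reference.base_at(position)
    return Mutation(position=position, ref=ref, derived=transition_partner(ref), kind=TRANSITION)


def simulate_star_genealogy(
    cfg: SimulationConfig,
    reference: ReferenceSequence | None = None,
    root_profile: VariantProfile | None = None,
) -> tuple[GenealogyTree, list[VariantProfile]]:
    """Star genealogy: each tip gets Poisson(lam) private transitions.

    Private sites are drawn uniformly (without replacement per tip) from the
    clock-eligible positions, avoiding the excluded sites and the root
    haplotype's own variant positions.
    """
    reference = reference or load_reference()
    rng = np.random.default_rng(cfg.seed)
    eligible = clock_eligible_positions(cfg.clock, reference)
    root_muts = list(root_profile.mutations) if root_profile else []
    taken = {m.position for m in root_muts}
    pool = np.array([p for p in eligible if p not in taken])
    if cfg.lam > len(pool):
        raise ValueError("lam exceeds the number of distinct eligible positions")
    g = GenealogyTree()
    profiles = []
    for i in range(cfg.n_tips):
        k = rng.poisson(cfg.lam)
        if k > len(pool):
            raise ValueError("drawn mutation count exhausts eligible positions")
        sites = rng.choice(pool, size=k, replace=False)
        muts = root_muts + [_transition_at(int(p), reference) for p in sorted(sites)]
        g.add_node(f"tip{i}", g.root, int(k))
        profiles.append(VariantProfile(f"S{i + 1}", list(FULL_COVERAGE), muts))
    return g, profiles


def simulate_tree_genealogy(cfg: SimulationConfig) -> GenealogyTree:
    """Random bifurcating (Yule-style) genealogy with Poisson branch counts.

    Branch mutation counts are Poisson with mean proportional to an
    exponential branch duration times ``lam`` (so expectations are
    branch-proportional); subtended tip counts follow from the topology.
    """
    if cfg.n_tips < 2:
        raise ValueError("need >= 2 tips")
    rng = np.random.default_rng(cfg.seed)
    g = GenealogyTree()
    # grow a Yule topology: repeatedly split a uniformly chosen active lineage
    next_id = [0]

    def fresh() -> str:
        next_id[0] += 1
        return f"n{next_id[0]}"

    active = []
    for _ in range(2):
        name = fresh()
        g.add_node(name, g.root, 0)
        active.append(name)
    while len(active) < cfg.n_tips:
        parent = active.pop(rng.integers(len(active)))
        for _ in range(2):
            name = fresh()
            g.add_node(name, parent, 0)
            active.append(name)
    for node in g.parent:
        duration = rng.exponential(1.0)
        g.branch_mutations[node] = int(rng.poisson(cfg.lam * duration))
    return g


def redraw_branch_mutations(
    g: GenealogyTree, means: dict[str, float], rng: np.random.Generator
) -> GenealogyTree:
    """Fresh Poisson draw of branch counts on a fixed topology (for sigma tests)."""
    out = GenealogyTree(g.root)
    for node in _preorder(g):
        out.add_node(node, g.parent[node], int(rng.poisson(means[node])))
    return out


def _preorder(g: GenealogyTree) -> list[str]:
    order = []
    stack = [g.root]
    while stack:
        cur = stack.pop()
        for ch in g.children[cur]:
            order.append(ch)
            stack.append(ch)
    return order


def simulate_population_frequencies(
    cfg: SimulationConfig,
    profiles: np.ndarray | None = None,
    haplogroups: list[str] | None = None,
    cline_haplogroup: int = 0,
    groups: dict[str, str] | None = None,
) -> FrequencyTable:
    """Multinomial per-population haplogroup counts with an optional cline.

    ``profiles`` is a (n_populations, H) matrix of frequency profiles (a
    single shared profile may be given as a 1-D vector).  A positive
    ``cline_slope`` adds a linear increase of ``cline_haplogroup``'s
    frequency along longitude (renormalizing the rest), and populations are
    laid out west-to-east on a transect.
    """
    rng = np.random.default_rng(cfg.seed)
    if profiles is None:
        profiles = np.full(4, 0.25)
    profiles = np.atleast_2d(np.asarray(profiles, dtype=float))
    if profiles.shape[0] == 1:
        profiles = np.repeat(profiles, cfg.n_populations, axis=0)
    if profiles.shape[0] != cfg.n_populations:
        raise ValueError("profile dimension mismatch")
    if not np.allclose(profiles.sum(axis=1), 1.0):
        raise ValueError("profiles must be simplex points")
    n_h = profiles.shape[1]
    if haplogroups is None:
        haplogroups = [f"HG{i + 1}" for i in range(n_h)]
    lons = np.linspace(90.0, 110.0, cfg.n_populations)
    lats = np.full(cfg.n_populations, 20.0)
    counts = np.zeros((cfg.n_populations, n_h), dtype=int)
    pops = [f"Pop{i + 1}" for i in range(cfg.n_populations)]
    for i in range(cfg.n_populations):
        p = profiles[i].copy()
        if cfg.cline_slope:
            t = (lons[i] - lons[0]) / (lons[-1] - lons[0])
            delta = cfg.cline_slope * t
            p[cline_haplogroup] = np.clip(p[cline_haplogroup] + delta, 0.0, 1.0)
            rest = [j for j in range(n_h) if j != cline_haplogroup]
            rest_sum = p[rest].sum()
            if rest_sum > 0:
                p[rest] *= (1.0 - p[cline_haplogroup]) / rest_sum
        counts[i] = rng.multinomial(cfg.n_per_population, p / p.sum())
    return FrequencyTable(
        populations=pops,
        haplogroups=list(haplogroups),
        counts=counts,
        groups=dict(groups or {}),
        coordinates={pops[i]: (float(lats[i]), float(lons[i])) for i in range(cfg.n_populations)},
    )


def fixture_sequences_for_haplogroup(
    tree: HaplogroupTree,
    name: str,
    n: int = 1,
    private_lam: float = 0.0,
    seed: int = 0,
    reference: ReferenceSequence | None = None,
    covered: list[tuple[int, int]] | None = None,
    id_prefix: str | None = None,
) -> list[VariantProfile]:
    """Profiles carrying the cumulative motif of a clade plus private noise.

    Private mutations are Poisson(private_lam) transitions at positions away
    from every defining site of the whole tree (and the excluded sites), so
    round-trip classification stays unambiguous.
    """
    if name not in tree:
        raise KeyError(f"unknown clade {name!r}")
    reference = reference or load_reference()
    rng = np.random.default_rng(seed)
    motif = tree.path_motif(name)
    avoid = tree.defining_positions() | _EXCLUDED_POSITIONS
    pool = np.array([p for p in range(1, MT_LENGTH + 1) if p not in avoid])
    covered = covered or list(FULL_COVERAGE)
    prefix = id_prefix or name
    out = []
    for i in range(n):
        k = rng.poisson(private_lam) if private_lam > 0 else 0
        sites = rng.choice(pool, size=k, replace=False) if k else []
        muts = list(motif) + [_transition_at(int(p), reference) for p in sorted(sites)]
        out.append(VariantProfile(f"{prefix}_{i + 1}", list(covered), muts))
    return out
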