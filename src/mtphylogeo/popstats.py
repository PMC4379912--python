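"""Population-level statistics over haplogroup frequency tables.

Covers principal components analysis of frequency profiles, the
Bhattacharyya-type frequency distance 1 - sum(sqrt(x*y)), hierarchical
AMOVA with Phi fixation indices and permutation significance, and
constrained weighted-least-squares admixture proportion estimation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .haplogroups import AssignmentResult, UNASSIGNED


@dataclass
class FrequencyTable:
    """Populations x haplogroups count matrix with optional metadata."""

    populations: list[str]
    haplogroups: list[str]
    counts: np.ndarray  # shape (P, H), integers
    groups: dict[str, str] = field(default_factory=dict)
    coordinates: dict[str, tuple[float, float]] = field(default_factory=dict)  # lat, lon

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.populations), len(self.haplogroups)):
            raise ValueError("counts shape does not match labels")
        if (self.counts < 0).any():
            raise ValueError("negative counts")
        if (self.n == 0).any():
            raise ValueError("population with zero individuals")

    @property
    def n(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def frequencies(self) -> np.ndarray:
        return self.counts / self.n[:, None]

    def row(self, population: str) -> np.ndarray:
        try:
            i = self.populations.index(population)
        except ValueError:
            raise KeyError(f"unknown population {population!r}") from None
        return self.frequencies[i]

    # --- population CSV dialect ------------------------------------------

    @classmethod
    def from_csv(cls, path: str) -> "FrequencyTable":
        df = pd.read_csv(path, comment="#")
        meta = ["Population", "Group", "Lat", "Lon", "n"]
        hgs = [c for c in df.columns if c not in meta]
        counts = df[hgs].to_numpy(dtype=int)
        t = cls(
            populations=list(df["Population"].astype(str)),
            haplogroups=hgs,
            counts=counts,
            groups={
                str(r.Population): str(r.Group)
                for r in df.itertuples()
                if "Group" in df.columns and not pd.isna(r.Group)
            },
            coordinates={
                str(r.Population): (float(r.Lat), float(r.Lon))
                for r in df.itertuples()
                if {"Lat", "Lon"} <= set(df.columns)
                and not pd.isna(r.Lat)
                and not pd.isna(r.Lon)
            },
        )
        if "n" in df.columns and not (df["n"].to_numpy() == counts.sum(axis=1)).all():
            raise ValueError("declared n does not match haplogroup counts")
        return t

    def to_csv(self, path: str) -> None:
        df = pd.DataFrame(self.counts, columns=self.haplogroups)
        df.insert(0, "n", self.n)
        df.insert(0, "Lon", [self.coordinates.get(p, (np.nan, np.nan))[1] for p in self.populations])
        df.insert(0, "Lat", [self.coordinates.get(p, (np.nan, np.nan))[0] for p in self.populations])
        df.insert(0, "Group", [self.groups.get(p, "") for p in self.populations])
        df.insert(0, "Population", self.populations)
        df.to_csv(path, index=False)


def build_frequency_table(
    assignments: list[tuple[str, AssignmentResult]]
) -> FrequencyTable:
    """Tabulate (population label, assignment) pairs into a FrequencyTable.

    Unassigned samples form an explicit ``Unassigned`` column.
    """
    if not assignments:
        raise ValueError("no assignments")
    pops = sorted({p for p, _ in assignments})
    hgs = sorted({a.haplogroup for _, a in assignments} - {UNASSIGNED})
    if any(a.haplogroup == UNASSIGNED for _, a in assignments):
        hgs.append(UNASSIGNED)
    counts = np.zeros((len(pops), len(hgs)), dtype=int)
    for pop, a in assignments:
        counts[pops.index(pop), hgs.index(a.haplogroup)] += 1
    return FrequencyTable(pops, hgs, counts)


# --- PCA ------------------------------------------------------------------


@dataclass
class PcaResult:
    scores: np.ndarray  # (P, k)
    loadings: np.ndarray  # (H, k)
    percent_variance: np.ndarray  # (k,), of the total variance
    components: int


def pca_frequencies(
    table: FrequencyTable, n_components: int = 2, scale: bool = False
) -> PcaResult:
    """PCA of the column-mean-centered frequency matrix via SVD.

    ``scale=True`` additionally divides columns by their standard deviation
    (correlation-mode); the default matches covariance-mode PCA on
    frequencies, which share a scale.
    """
    if len(table.populations) < 2:
        raise ValueError("PCA needs >= 2 populations")
    x = table.frequencies.copy()
    x -= x.mean(axis=0)
    if scale:
        sd = x.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        x /= sd
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    lam = s**2
    total = lam.sum()
    k = min(n_components, len(s))
    pct = np.zeros(k) if total == 0 else 100.0 * lam[:k] / total
    return PcaResult(
        scores=u[:, :k] * s[:k],
        loadings=vt[:k].T,
        percent_variance=pct,
        components=k,
    )


# --- frequency distance ---------------------------------------------------


def nei_da(table: FrequencyTable, pop_a: str, pop_b: str) -> float:
    """Frequency distance 1 - sum_h sqrt(x_h * y_h), in [0, 1]."""
    x, y = table.row(pop_a), table.row(pop_b)
    return float(1.0 - np.sqrt(x * y).sum())


# --- AMOVA ----------------------------------------------------------------


@dataclass
class AmovaResult:
    sigma_among_groups: float
    sigma_among_pops: float
    sigma_within: float
    percent: tuple[float, float, float]
    phi_ct: float
    phi_sc: float
    phi_st: float
    p_ct: float
    p_sc: float
    p_st: float
    permutations: int
    seed: int
    ss: tuple[float, float, float]  # among-groups, among-pops-within, within
    df: tuple[int, int, int]

    @property
    def total_variance(self) -> float:
        return self.sigma_among_groups + self.sigma_among_pops + self.sigma_within


def _amova_components(
    counts: np.ndarray, group_index: list[list[int]]
) -> tuple[float, float, float, tuple[float, float, float], tuple[int, int, int]]:
    """Variance components from per-population haplogroup counts.

    Individuals carry a 0/1 distance (different haplogroup = 1), so every
    sum of squared pairwise distances reduces to counts: for a pool S,
    sum_{i<j in S} d_ij = (n_S^2 - sum_h C_h(S)^2) / 2.
    """
    n_p = counts.sum(axis=1).astype(float)
    n_tot = n_p.sum()
    pooled = counts.sum(axis=0)

    def ssd(pool_counts: np.ndarray) -> float:
        n = pool_counts.sum()
        return float(n * n - (pool_counts.astype(float) ** 2).sum()) / (2.0 * n)

    ssd_total = ssd(pooled)
    ssd_wp = sum(ssd(counts[i]) for i in range(counts.shape[0]))
    ssd_wg = 0.0
    for idx in group_index:
        ssd_wg += ssd(counts[idx].sum(axis=0))
    ssd_ap = ssd_wg - ssd_wp
    ssd_ag = ssd_total - ssd_wg

    n_groups = len(group_index)
    n_pops = counts.shape[0]
    df_ag = n_groups - 1
    df_ap = n_pops - n_groups
    df_wp = int(n_tot) - n_pops
    if df_ag < 1 or df_ap < 1 or df_wp < 1:
        raise ValueError("degenerate AMOVA design")

    # expected-mean-square coefficients (unbalanced design)
    n_g = np.array([n_p[idx].sum() for idx in group_index])
    sum_np2_over_ng = sum(
        (n_p[idx] ** 2).sum() / n_p[idx].sum() for idx in group_index
    )
    n1 = (n_tot - sum_np2_over_ng) / df_ap
    n2 = (sum_np2_over_ng - (n_p**2).sum() / n_tot) / df_ag
    n3 = (n_tot - (n_g**2).sum() / n_tot) / df_ag

    ms_wp = ssd_wp / df_wp
    ms_ap = ssd_ap / df_ap
    ms_ag = ssd_ag / df_ag
    sigma_c = ms_wp
    sigma_b = (ms_ap - sigma_c) / n1
    sigma_a = (ms_ag - sigma_c - n2 * sigma_b) / n3
    return sigma_a, sigma_b, sigma_c, (ssd_ag, ssd_ap, ssd_wp), (df_ag, df_ap, df_wp)


def _phis(sa: float, sb: float, sc: float) -> tuple[float, float, float]:
    tot = sa + sb + sc
    phi_ct = sa / tot if tot else 0.0
    phi_st = (sa + sb) / tot if tot else 0.0
    phi_sc = sb / (sb + sc) if (sb + sc) else 0.0
    return phi_ct, phi_sc, phi_st


def amova(
    table: FrequencyTable,
    grouping: dict[str, str],
    permutations: int = 1000,
    seed: int | None = None,
) -> AmovaResult:
    """Two-level AMOVA on haplogroup profiles with permutation p-values.

    Distances between individuals default to 0/1 (same/different
    haplogroup).  Significance: Phi_CT permutes populations across groups,
    Phi_SC permutes individuals across populations within groups, Phi_ST
    permutes individuals across everything; p = (hits + 1) / (perms + 1).
    """
    if seed is None:
        raise ValueError("seed is required for the permutation test")
    groups = sorted({grouping[p] for p in table.populations})
    if len(groups) < 2:
        raise ValueError("AMOVA needs >= 2 groups")
    counts = table.counts.astype(int)
    pop_group = [groups.index(grouping[p]) for p in table.populations]
    group_index = [
        [i for i, g in enumerate(pop_group) if g == gi] for gi in range(len(groups))
    ]
    sa, sb, sc, ss, df = _amova_components(counts, group_index)
    phi_ct, phi_sc, phi_st = _phis(sa, sb, sc)

    rng = np.random.default_rng(seed)
    n_pops, n_h = counts.shape
    n_p = counts.sum(axis=1)
    group_sizes = [len(ix) for ix in group_index]

    hits_ct = hits_sc = hits_st = 0
    for _ in range(permutations):
        # Phi_CT: shuffle whole populations among groups
        perm = rng.permutation(n_pops)
        gi = []
        start = 0
        for size in group_sizes:
            gi.append(list(perm[start : start + size]))
            start += size
        a, b, c, _, _ = _amova_components(counts, gi)
        if _phis(a, b, c)[0] >= phi_ct - 1e-12:
            hits_ct += 1

        # Phi_SC: shuffle individuals among populations within each group
        counts_sc = np.zeros_like(counts)
        for idx in group_index:
            pool = np.repeat(np.arange(n_h), counts[idx].sum(axis=0))
            rng.shuffle(pool)
            start = 0
            for i in idx:
                part = pool[start : start + n_p[i]]
                counts_sc[i] = np.bincount(part, minlength=n_h)
                start += n_p[i]
        a, b, c, _, _ = _amova_components(counts_sc, group_index)
        if _phis(a, b, c)[1] >= phi_sc - 1e-12:
            hits_sc += 1

        # Phi_ST: shuffle individuals across all populations
        pool = np.repeat(np.arange(n_h), counts.sum(axis=0))
        rng.shuffle(pool)
        counts_st = np.zeros_like(counts)
        start = 0
        for i in range(n_pops):
            counts_st[i] = np.bincount(pool[start : start + n_p[i]], minlength=n_h)
            start += n_p[i]
        a, b, c, _, _ = _amova_components(counts_st, group_index)
        if _phis(a, b, c)[2] >= phi_st - 1e-12:
            hits_st += 1

    tot = sa + sb + sc
    pct = (
        (100 * sa / tot, 100 * sb / tot, 100 * sc / tot) if tot else (0.0, 0.0, 0.0)
    )
    return AmovaResult(
        sigma_among_groups=sa,
        sigma_among_pops=sb,
        sigma_within=sc,
        percent=pct,
        phi_ct=phi_ct,
        phi_sc=phi_sc,
        phi_st=phi_st,
        p_ct=(hits_ct + 1) / (permutations + 1),
        p_sc=(hits_sc + 1) / (permutations + 1),
        p_st=(hits_st + 1) / (permutations + 1),
        permutations=permutations,
        seed=seed,
        ss=ss,
        df=df,
    )


# --- WLS admixture --------------------------------------------------------


@dataclass
class AdmixtureEstimate:
    parental_populations: list[str]
    proportions: np.ndarray
    residual_ss: float
    non_unique: bool = False


def wls_admixture(
    hybrid: np.ndarray,
    parental: np.ndarray,
    parental_names: list[str] | None = None,
    weights: np.ndarray | None = None,
) -> AdmixtureEstimate:
    """Weighted least-squares admixture proportions.

    Minimizes sum_h w_h (f_h - sum_p m_p f_ph)^2 subject to sum(m) = 1 and
    m >= 0; the equality is enforced by substitution and non-negativity by
    active-set clipping with re-solution.  A rank-deficient parental matrix
    is flagged ``non_unique`` (one minimizer is still returned).
    """
    hybrid = np.asarray(hybrid, dtype=float)
    parental = np.asarray(parental, dtype=float)
    n_par, n_h = parental.shape
    if n_par < 2:
        raise ValueError("need >= 2 parental populations")
    if hybrid.shape != (n_h,):
        raise ValueError("hybrid and parental panels differ")
    if parental_names is None:
        parental_names = [f"P{i + 1}" for i in range(n_par)]
    w = np.ones(n_h) if weights is None else np.asarray(weights, dtype=float)
    sw = np.sqrt(w)

    non_unique = np.linalg.matrix_rank(parental) < n_par

    def solve(active: list[int]) -> np.ndarray:
        # substitute m_last = 1 - sum(others) over the active set
        base = active[-1]
        others = active[:-1]
        y = sw * (hybrid - parental[base])
        if not others:
            m = np.zeros(n_par)
            m[base] = 1.0
            return m
        x = (parental[others] - parental[base]).T * sw[:, None]
        beta, *_ = np.linalg.lstsq(x, y, rcond=None)
        m = np.zeros(n_par)
        m[others] = beta
        m[base] = 1.0 - beta.sum()
        return m

    active = list(range(n_par))
    for _ in range(n_par):
        m = solve(active)
        neg = [i for i in active if m[i] < -1e-12]
        if not neg:
            break
        worst = min(neg, key=lambda i: m[i])
        active = [i for i in active if i != worst]
    m = np.clip(m, 0.0, None)
    total = m.sum()
    m = m / total if total > 0 else np.full(n_par, 1.0 / n_par)
    resid = hybrid - m @ parental
    return AdmixtureEstimate(
        parental_populations=list(parental_names),
        proportions=m,
        residual_ss=float((w * resid**2).sum()),
        non_unique=bool(non_unique),
    )
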