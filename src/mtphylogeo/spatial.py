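"""Moran's I correlograms over great-circle distance classes."""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np

EARTH_RADIUS_KM = 6371.0


class GeoPoint(NamedTuple):
    lat: float
    lon: float


def _validate(p: GeoPoint) -> None:
    if not (-90.0 <= p.lat <= 90.0) or not (-180.0 <= p.lon <= 180.0):
        raise ValueError(f"invalid coordinates {p}")


def great_circle_distance(a: GeoPoint, b: GeoPoint) -> float:
    """Haversine distance in kilometres (mean Earth radius 6,371 km)."""
    a, b = GeoPoint(*a), GeoPoint(*b)
    _validate(a)
    _validate(b)
    la1, lo1, la2, lo2 = map(math.radians, (a.lat, a.lon, b.lat, b.lon))
    h = (
        math.sin((la2 - la1) / 2) ** 2
        + math.cos(la1) * math.cos(la2) * math.sin((lo2 - lo1) / 2) ** 2
    )
    return 2 * EARTH_RADIUS_KM * math.asin(min(1.0, math.sqrt(h)))


def pairwise_distances(points: Sequence[GeoPoint]) -> np.ndarray:
    n = len(points)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = great_circle_distance(points[i], points[j])
    return d


def make_distance_classes(
    points: Sequence[GeoPoint], k: int, mode: str = "equal_width"
) -> np.ndarray:
    """Class boundaries over (0, max pairwise distance], length k+1.

    ``equal_width`` splits the range evenly; ``equal_count`` uses quantiles
    of the pairwise distance distribution so classes hold similar numbers
    of pairs.
    """
    if len(points) < 2:
        raise ValueError("need >= 2 points")
    if k < 1:
        raise ValueError("k must be >= 1")
    d = pairwise_distances(points)
    upper = d[np.triu_indices(len(points), k=1)]
    dmax = upper.max()
    if dmax == 0:
        raise ValueError("all points identical")
    if mode == "equal_width":
        return np.linspace(0.0, dmax, k + 1)
    if mode == "equal_count":
        qs = np.quantile(upper, np.linspace(0, 1, k + 1))
        qs[0], qs[-1] = 0.0, dmax
        return qs
    raise ValueError(f"unknown mode {mode!r}")


@dataclass
class CorrelogramResult:
    boundaries: np.ndarray  # length k+1; class c = (b[c], b[c+1]]
    morans_i: list[float | None]  # None for empty classes
    n_pairs: list[int]
    p_values: list[float | None]
    expected: float  # -1/(n-1)
    permutations: int
    seed: int


def morans_i(values: np.ndarray, weights: np.ndarray) -> float:
    """Moran's I for a binary (or general) spatial weight matrix."""
    x = np.asarray(values, dtype=float)
    n = len(x)
    z = x - x.mean()
    denom = (z**2).sum()
    if denom == 0:
        raise ValueError("constant values: Moran's I undefined")
    w_sum = weights.sum()
    if w_sum == 0:
        raise ValueError("empty weight matrix")
    return float(n / w_sum * (weights * np.outer(z, z)).sum() / denom)


def morans_i_correlogram(
    values: Sequence[float],
    points: Sequence[GeoPoint],
    k: int = 5,
    permutations: int = 999,
    seed: int | None = None,
    mode: str = "equal_width",
    boundaries: np.ndarray | None = None,
) -> CorrelogramResult:
    """Per-distance-class Moran's I with two-sided permutation p-values.

    Weights are binary per class: w_ij = 1 iff the great-circle distance of
    the pair falls in the class.  p-values use the add-one rule
    (b + 1) / (m + 1) on |I - E| exceedances under random relabeling.
    """
    if seed is None:
        raise ValueError("seed is required for the permutation test")
    x = np.asarray(values, dtype=float)
    n = len(x)
    if n < 3:
        raise ValueError("need >= 3 locations")
    if len(points) != n:
        raise ValueError("values and points differ in length")
    if np.all(x == x[0]):
        raise ValueError("constant values: Moran's I undefined")
    d = pairwise_distances(points)
    if boundaries is None:
        boundaries = make_distance_classes(points, k, mode)
    boundaries = np.asarray(boundaries, dtype=float)
    k = len(boundaries) - 1
    expected = -1.0 / (n - 1)
    rng = np.random.default_rng(seed)

    result_i: list[float | None] = []
    result_p: list[float | None] = []
    n_pairs: list[int] = []
    iu = np.triu_indices(n, k=1)
    for c in range(k):
        lo, hi = boundaries[c], boundaries[c + 1]
        mask = (d > lo) & (d <= hi)
        np.fill_diagonal(mask, False)
        pairs = int(mask[iu].sum())
        n_pairs.append(pairs)
        if pairs == 0:
            result_i.append(None)
            result_p.append(None)
            continue
        w = mask.astype(float)
        obs = morans_i(x, w)
        stat = abs(obs - expected)
        hits = 0
        for _ in range(permutations):
            perm = rng.permutation(x)
            if abs(morans_i(perm, w) - expected) >= stat - 1e-15:
                hits += 1
        result_i.append(obs)
        result_p.append((hits + 1) / (permutations + 1))
    return CorrelogramResult(
        boundaries=boundaries,
        morans_i=result_i,
        n_pairs=n_pairs,
        p_values=result_p,
        expected=expected,
        permutations=permutations,
        seed=seed,
    )


def write_correlogram_tsv(result: CorrelogramResult, path: str) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("ClassLow_km\tClassHigh_km\tPairs\tMoransI\tExpected\tP\n")
        for c in range(len(result.boundaries) - 1):
            i = result.morans_i[c]
            p = result.p_values[c]
            fh.write(
                f"{result.boundaries[c]:.3f}\t{result.boundaries[c + 1]:.3f}\t"
                f"{result.n_pairs[c]}\t"
                f"{'NA' if i is None else f'{i:.6f}'}\t"
                f"{result.expected:.6f}\t"
                f"{'NA' if p is None else f'{p:.4f}'}\n"
            )
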