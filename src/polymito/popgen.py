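"""Isolation-by-distance statistics: K2P distances, great-circle distances,
and the Mantel permutation test.

The Kimura 2-parameter distance separates transition (P) and transversion (Q)
proportions over sites where both sequences carry an unambiguous base
(pairwise deletion):

    d = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q)

A saturated pair (log argument <= 0) is reported as NaN.  The Mantel test
correlates the strictly-lower-triangle entries of two distance matrices and
assesses significance by permuting the labels of one matrix.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GeoPoint",
    "DistanceMatrix",
    "MantelResult",
    "k2p",
    "k2p_matrix",
    "haversine_km",
    "geographic_matrix",
    "mantel",
]

EARTH_RADIUS_KM = 6371.0

_PURINES = {"A", "G"}
_PYRIMIDINES = {"C", "T"}
_BASES = {"A", "C", "G", "T"}


class GeoPoint(NamedTuple):
    lat: float
    lon: float


@dataclass(frozen=True)
class DistanceMatrix:
    """Labelled symmetric distance matrix with zero diagonal (NaN = missing)."""

    labels: tuple
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1] or v.shape[0] != len(self.labels):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(np.diag(v), 0.0, equal_nan=False):
            raise ValueError("diagonal must be zero")
        if not np.allclose(v, v.T, equal_nan=True):
            raise ValueError("matrix must be symmetric")
        with np.errstate(invalid="ignore"):
            if np.any(v[~np.isnan(v)] < 0):
                raise ValueError("distances must be non-negative")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "labels", tuple(self.labels))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def condensed(self) -> np.ndarray:
        """Strictly-lower-triangle entries, row-major."""
        i, j = np.tril_indices(len(self.labels), -1)
        return self.values[i, j]


@dataclass(frozen=True)
class MantelResult:
    r: float
    r_squared: float
    p_value: float
    n_permutations: int
    tail: str
    seed: int | None


def k2p(a: str, b: str) -> float:
    """Kimura 2-parameter distance between two aligned sequences.

    Sites where either base is not in {A,C,G,T} are dropped (pairwise
    deletion).  Returns NaN on saturation; raises when lengths differ or no
    comparable sites remain.
    """
    if len(a) != len(b):
        raise ValueError(f"aligned sequences must have equal length ({len(a)} != {len(b)})")
    a, b = a.upper(), b.upper()
    n = ts = tv = 0
    for x, y in zip(a, b):
        if x not in _BASES or y not in _BASES:
            continue
        n += 1
        if x == y:
            continue
        if (x in _PURINES) == (y in _PURINES):
            ts += 1
        else:
            tv += 1
    if n == 0:
        raise ValueError("no comparable sites (pairwise deletion removed everything)")
    P, Q = ts / n, tv / n
    arg1, arg2 = 1.0 - 2.0 * P - Q, 1.0 - 2.0 * Q
    if arg1 <= 0 or arg2 <= 0:
        return math.nan
    return -0.5 * math.log(arg1) - 0.25 * math.log(arg2)


def k2p_matrix(seqs: Sequence[tuple[str, str]]) -> DistanceMatrix:
    """Pairwise K2P distances over (label, aligned sequence) pairs."""
    labels = [s[0] for s in seqs]
    n = len(labels)
    if n < 2:
        raise ValueError("need at least two sequences")
    v = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            v[i, j] = v[j, i] = k2p(seqs[i][1], seqs[j][1])
    return DistanceMatrix(tuple(labels), v)


def haversine_km(p1: GeoPoint, p2: GeoPoint) -> float:
    """Great-circle distance (Earth radius 6371.0 km)."""
    for p in (p1, p2):
        if abs(p[0]) > 90 or abs(p[1]) > 180:
            raise ValueError(f"invalid coordinates {p}")
    lat1, lon1, lat2, lon2 = map(math.radians, (p1[0], p1[1], p2[0], p2[1]))
    dlat, dlon = lat2 - lat1, lon2 - lon1
    h = math.sin(dlat / 2) ** 2 + math.cos(lat1) * math.cos(lat2) * math.sin(dlon / 2) ** 2
    return 2 * EARTH_RADIUS_KM * math.asin(min(1.0, math.sqrt(h)))


def geographic_matrix(points: Sequence[tuple[str, GeoPoint]]) -> DistanceMatrix:
    labels = [p[0] for p in points]
    n = len(labels)
    v = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            v[i, j] = v[j, i] = haversine_km(points[i][1], points[j][1])
    return DistanceMatrix(tuple(labels), v)


def mantel(
    d1: DistanceMatrix,
    d2: DistanceMatrix,
    n_perm: int = 9999,
    seed: int | None = None,
    tail: str = "greater",
) -> MantelResult:
    """Mantel permutation test between two labelled distance matrices.

    r is the Pearson correlation of the strictly-lower-triangle entries; the
    p-value is (1 + #{permutations with r* >= r}) / (1 + n_perm) for the
    one-tailed 'greater' alternative (|r*| >= |r| for 'two-sided').  Labels of
    the second matrix are aligned to the first before testing; permutations
    are applied to the first matrix's labels and are reproducible via ``seed``.
    """
    if tail not in ("greater", "two-sided"):
        raise ValueError("tail must be 'greater' or 'two-sided'")
    if sorted(d1.labels) != sorted(d2.labels):
        raise ValueError("matrices must share the same label set")
    n = len(d1.labels)
    if n < 4:
        raise ValueError("Mantel test needs at least 4 labels")

    order = [d2.labels.index(l) for l in d1.labels]
    m1 = d1.values
    m2 = d2.values[np.ix_(order, order)]

    tri_i, tri_j = np.tril_indices(n, -1)
    x = m1[tri_i, tri_j]
    y = m2[tri_i, tri_j]
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant distance matrix: correlation undefined")

    def _pearson(a: np.ndarray, b: np.ndarray) -> np.ndarray:
        a = a - a.mean(axis=-1, keepdims=True)
        b = b - b.mean()
        num = a @ b
        den = np.sqrt((a * a).sum(axis=-1) * (b * b).sum())
        return num / den

    r = float(_pearson(x[None, :], y)[0])

    rng = np.random.default_rng(seed)
    perms = np.array([rng.permutation(n) for _ in range(n_perm)])
    xp = m1[perms[:, tri_i], perms[:, tri_j]]  # (n_perm, n_pairs)
    r_star = _pearson(xp, y)
    if tail == "greater":
        hits = int(np.sum(r_star >= r))
    else:
        hits = int(np.sum(np.abs(r_star) >= abs(r)))
    p = (1 + hits) / (1 + n_perm)
    return MantelResult(
        r=r, r_squared=r * r, p_value=p, n_permutations=n_perm, tail=tail, seed=seed
    )
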