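"""Spatial similarity of country species lists.

Compositional dissimilarity between countries is the Jaccard distance of
their species sets; geographic distance is the great-circle distance between
country centroids.  Their association is tested with the Mantel permutation
test, and resolved by distance class with a Mantel correlogram (progressive
Holm correction across classes).

Sign convention: the correlogram tests *dissimilarity* against distance-class
membership, so positive spatial structure at short distances (nearby
countries sharing more species) appears as a negative Mantel r in the first
classes.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import AlignmentError, MycocheckError

EARTH_RADIUS_KM = 6371.0
_EPS = 1e-12


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distances/dissimilarities between labelled items."""

    labels: list[str]
    values: np.ndarray
    kind: str = "generic"  # e.g. jaccard_dissimilarity, geographic_km

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if v.shape != (n, n):
            raise ValueError(f"matrix shape {v.shape} does not match {n} labels")
        if not np.allclose(v, v.T, atol=1e-9):
            raise ValueError("matrix must be symmetric")
        if not np.allclose(np.diag(v), 0.0, atol=1e-9):
            raise ValueError("diagonal must be zero")
        if (v < -1e-9).any():
            raise ValueError("distances must be nonnegative")
        if self.kind == "jaccard_dissimilarity" and (v > 1 + 1e-9).any():
            raise ValueError("jaccard dissimilarity must lie in [0, 1]")
        self.values = v

    @property
    def n(self) -> int:
        return len(self.labels)

    def condensed(self) -> np.ndarray:
        """Lower-triangle entries, row-major (the Mantel test's vector view)."""
        i, j = np.tril_indices(self.n, k=-1)
        return self.values[i, j]

    def reorder(self, labels: Sequence[str]) -> "DistanceMatrix":
        if set(labels) != set(self.labels):
            raise AlignmentError("cannot reorder: label sets differ")
        idx = [self.labels.index(l) for l in labels]
        return DistanceMatrix(list(labels), self.values[np.ix_(idx, idx)], self.kind)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index_label="label")

    @classmethod
    def read_csv(cls, path: str | Path, kind: str = "generic") -> "DistanceMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(list(df.columns), df.to_numpy(dtype=float), kind)


def jaccard_matrix(species_sets: Mapping[str, set]) -> DistanceMatrix:
    """Pairwise Jaccard dissimilarity 1 - |A∩B| / |A∪B| between species sets."""
    labels = sorted(species_sets)
    if len(labels) < 2:
        raise MycocheckError("need at least two species sets")
    for label in labels:
        if not species_sets[label]:
            raise MycocheckError(f"species set for {label!r} is empty")
    n = len(labels)
    v = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        a, b = species_sets[labels[i]], species_sets[labels[j]]
        d = 1.0 - len(a & b) / len(a | b)
        v[i, j] = v[j, i] = d
    return DistanceMatrix(labels, v, "jaccard_dissimilarity")


def haversine_km(lat1: float, lon1: float, lat2: float, lon2: float,
                 radius_km: float = EARTH_RADIUS_KM) -> float:
    """Great-circle distance between two points in decimal degrees."""
    for lat in (lat1, lat2):
        if not -90.0 <= lat <= 90.0:
            raise ValueError(f"latitude {lat} outside [-90, 90]")
    for lon in (lon1, lon2):
        if not -180.0 <= lon <= 180.0:
            raise ValueError(f"longitude {lon} outside [-180, 180]")
    p1, p2 = math.radians(lat1), math.radians(lat2)
    dphi = math.radians(lat2 - lat1)
    dlmb = math.radians(lon2 - lon1)
    h = math.sin(dphi / 2) ** 2 + math.cos(p1) * math.cos(p2) * math.sin(dlmb / 2) ** 2
    return 2 * radius_km * math.asin(min(1.0, math.sqrt(h)))


def geo_distance_matrix(
    centroids: Mapping[str, tuple[float, float]],
    radius_km: float = EARTH_RADIUS_KM,
) -> DistanceMatrix:
    """Great-circle distance matrix (km) from per-label (lat, lon) centroids."""
    labels = sorted(centroids)
    n = len(labels)
    v = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        (la1, lo1), (la2, lo2) = centroids[labels[i]], centroids[labels[j]]
        v[i, j] = v[j, i] = haversine_km(la1, lo1, la2, lo2, radius_km)
    return DistanceMatrix(labels, v, "geographic_km")


def read_centroids(path: str | Path) -> dict[str, tuple[float, float]]:
    """Centroid CSV (columns country, lat, lon) -> {country: (lat, lon)}."""
    df = pd.read_csv(path)
    if not {"country", "lat", "lon"}.issubset(df.columns):
        raise MycocheckError("centroid table needs columns country, lat, lon")
    return {str(r["country"]): (float(r["lat"]), float(r["lon"]))
            for _, r in df.iterrows()}


@dataclass
class MantelResult:
    """Standardized Mantel statistic with its permutation p-value."""

    r_M: float
    p_perm: float
    n_perm: int
    seed: int | None
    tail: str
    degenerate: bool = False  # a zero-variance input; r=0, p=1 by contract

    def __repr__(self) -> str:
        return (f"MantelResult(r_M={self.r_M:.4f}, p={self.p_perm:.4g}, "
                f"n_perm={self.n_perm}, tail={self.tail!r})")


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc, yc = x - x.mean(), y - y.mean()
    return float(xc @ yc / math.sqrt((xc @ xc) * (yc @ yc)))


def _count_extreme(r_perm: np.ndarray, r_obs: float, tail: str) -> int:
    if tail == "greater":
        return int((r_perm >= r_obs - _EPS).sum())
    if tail == "less":
        return int((r_perm <= r_obs + _EPS).sum())
    if tail == "two-sided":
        return int((np.abs(r_perm) >= abs(r_obs) - _EPS).sum())
    raise ValueError(f"unknown tail {tail!r}")


def _permutation_indices(n: int, n_perm: int, exhaustive: bool,
                         seed: int | None) -> np.ndarray:
    if exhaustive:
        perms = [p for p in itertools.permutations(range(n))
                 if p != tuple(range(n))]
        return np.array(perms, dtype=np.intp)
    rng = np.random.default_rng(seed)
    return np.array([rng.permutation(n) for _ in range(n_perm)], dtype=np.intp)


def mantel_test(
    d1: DistanceMatrix,
    d2: DistanceMatrix,
    n_perm: int = 999,
    seed: int | None = None,
    tail: str = "greater",
    exhaustive: bool = False,
) -> MantelResult:
    """Mantel permutation test between two distance matrices.

    r_M is the Pearson correlation of the lower-triangle entries; the null is
    built by jointly permuting the rows and columns of ``d2``.  For
    tail="greater", p = (1 + #{r_perm >= r_obs}) / (n_perm + 1), giving a
    p-value resolution of exactly 1/(n_perm + 1).  ``exhaustive=True``
    enumerates all n! - 1 non-identity relabelings instead (small n only).

    A zero-variance matrix yields r_M = 0, p = 1 (degenerate-input contract).
    """
    if d1.labels != d2.labels:
        if set(d1.labels) == set(d2.labels):
            d2 = d2.reorder(d1.labels)
        else:
            raise AlignmentError("distance matrices have different labels")
    if not exhaustive and n_perm < 99:
        raise ValueError("n_perm must be >= 99 (or use exhaustive=True)")
    n = d1.n
    i_idx, j_idx = np.tril_indices(n, k=-1)
    x = d1.values[i_idx, j_idx]
    y = d2.values[i_idx, j_idx]
    if x.std() < _EPS or y.std() < _EPS:
        return MantelResult(0.0, 1.0, 0, seed, tail, degenerate=True)
    r_obs = _pearson(x, y)

    perms = _permutation_indices(n, n_perm, exhaustive, seed)
    y_perm = d2.values[perms[:, i_idx], perms[:, j_idx]]  # (B, n_pairs)
    yc = y_perm - y_perm.mean(axis=1, keepdims=True)
    xc = x - x.mean()
    denom = np.sqrt((xc @ xc) * (yc * yc).sum(axis=1))
    r_perm = (yc @ xc) / denom
    n_eff = len(perms)
    p = (1 + _count_extreme(r_perm, r_obs, tail)) / (n_eff + 1)
    return MantelResult(r_obs, float(p), n_eff, seed, tail)


def _holm(p: np.ndarray) -> np.ndarray:
    """Holm step-down adjusted p-values."""
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(1.0, running)
    return adj


@dataclass
class CorrelogramClass:
    lower_km: float
    upper_km: float
    n_pairs: int
    r_M: float
    p: float
    p_corrected: float = float("nan")
    all_labels_involved: bool = True


@dataclass
class Correlogram:
    """Mantel r per geographic distance class, with progressive correction."""

    classes: list[CorrelogramClass]
    n_perm: int
    seed: int | None
    correction: str
    tail: str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "class_lower_km": c.lower_km, "class_upper_km": c.upper_km,
            "n_pairs": c.n_pairs, "r": c.r_M, "p": c.p,
            "p_corrected": c.p_corrected,
            "all_labels_involved": c.all_labels_involved,
        } for c in self.classes])

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def sturges_classes(n_pairs: int) -> int:
    """Sturges' rule for the number of distance classes."""
    return int(math.ceil(math.log2(n_pairs))) + 1


def mantel_correlogram(
    d1: DistanceMatrix,
    d_geo: DistanceMatrix,
    n_classes: int | None = None,
    n_perm: int = 999,
    seed: int | None = None,
    tail: str = "two-sided",
    correction: str = "holm_progressive",
) -> Correlogram:
    """Mantel correlogram of ``d1`` against geographic distance classes.

    Distances are cut into ``n_classes`` equal-width bins (Sturges' rule by
    default) spanning the observed range.  Each class is tested by a Mantel
    test of ``d1`` against the binary membership matrix of that class
    (1 where the pair's distance falls in the class).  P-values are corrected
    progressively in increasing distance order: the k-th class's corrected p
    is its Holm-adjusted value among the first k classes.  Classes with no
    pairs are dropped with a warning; classes whose pairs do not touch every
    label are flagged.
    """
    if d1.labels != d_geo.labels:
        if set(d1.labels) == set(d_geo.labels):
            d_geo = d_geo.reorder(d1.labels)
        else:
            raise AlignmentError("distance matrices have different labels")
    n = d1.n
    i_idx, j_idx = np.tril_indices(n, k=-1)
    dist = d_geo.values[i_idx, j_idx]
    n_pairs = len(dist)
    if n_classes is None:
        n_classes = sturges_classes(n_pairs)
    edges = np.linspace(dist.min(), dist.max(), n_classes + 1)
    edges[-1] += _EPS  # right-closed final bin

    classes: list[CorrelogramClass] = []
    for c in range(n_classes):
        in_class = (dist >= edges[c]) & (dist < edges[c + 1])
        if c == n_classes - 1:
            in_class |= np.isclose(dist, edges[-1] - _EPS)
        if not in_class.any():
            warnings.warn(f"distance class [{edges[c]:.1f}, {edges[c + 1]:.1f}) "
                          "has no pairs; dropped", stacklevel=2)
            continue
        member = np.zeros((n, n))
        member[i_idx[in_class], j_idx[in_class]] = 1.0
        member += member.T
        dm_member = DistanceMatrix(d1.labels, member, "class_membership")
        res = mantel_test(d1, dm_member, n_perm=n_perm, seed=seed, tail=tail)
        touched = set(i_idx[in_class]) | set(j_idx[in_class])
        classes.append(CorrelogramClass(
            float(edges[c]), float(min(edges[c + 1], dist.max())),
            int(in_class.sum()), res.r_M, res.p_perm,
            all_labels_involved=(len(touched) == n)))

    if correction == "holm_progressive":
        ps = np.array([c.p for c in classes])
        for k in range(len(classes)):
            classes[k].p_corrected = float(_holm(ps[: k + 1])[k])
    elif correction == "none":
        for c in classes:
            c.p_corrected = c.p
    else:
        raise ValueError(f"unknown correction {correction!r}")
    return Correlogram(classes, n_perm, seed, correction, tail)
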