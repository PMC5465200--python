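"""Between-population distances and low-dimensional ordinations.

Nei's standard genetic distance is computed from haplogroup-frequency rows;
geographic distances are great-circle kilometres; MDS is metric stress
majorization (SMACOF) initialized from the classical Torgerson solution so
the embedding is deterministic, with Kruskal stress-1 reported; PCA is an
eigendecomposition of the covariance of centered frequency rows.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from ystr.data_io import PopulationMeta
from ystr.haplogroups import FrequencyTable

EARTH_RADIUS_KM = 6371.0


@dataclass
class DistanceMatrix:
    labels: list[str]
    d: np.ndarray
    kind: str = "nei_genetic"  # nei_genetic | geographic_km | mds_configuration

    def validate(self) -> None:
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape mismatch")
        if not np.allclose(self.d, self.d.T, equal_nan=True):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.d), 0.0):
            raise ValueError("diagonal must be zero")
        finite = self.d[np.isfinite(self.d)]
        if np.any(finite < -1e-12):
            raise ValueError("distances must be non-negative")

    def upper_triangle(self) -> np.ndarray:
        iu = np.triu_indices(len(self.labels), k=1)
        return self.d[iu]


@dataclass
class Ordination:
    coordinates: np.ndarray  # (n_items, k)
    k: int
    stress: Optional[float] = None  # Kruskal stress-1 (MDS)
    explained_variance: Optional[np.ndarray] = None  # fractions (PCA)
    labels: Optional[list[str]] = None


def nei_distance(x: Sequence[float], y: Sequence[float]) -> float:
    """Nei's standard genetic distance -ln(Jxy / sqrt(Jx*Jy)).

    Returns ``inf`` (with a warning) when the two frequency rows share no
    haplogroups (Jxy = 0).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("frequency rows must cover the same haplogroups")
    for row in (x, y):
        if not np.isclose(row.sum(), 1.0, atol=1e-9):
            raise ValueError("frequency rows must sum to 1")
    jxy = float(np.dot(x, y))
    jx = float(np.dot(x, x))
    jy = float(np.dot(y, y))
    if jxy == 0.0:
        warnings.warn("no shared haplogroups; Nei distance is infinite")
        return math.inf
    return max(0.0, -math.log(jxy / math.sqrt(jx * jy)))


def nei_distance_matrix(ft: FrequencyTable) -> DistanceMatrix:
    n = len(ft.populations)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = nei_distance(ft.p[i], ft.p[j])
    dm = DistanceMatrix(labels=list(ft.populations), d=d, kind="nei_genetic")
    dm.validate()
    return dm


def haversine_km(lat1: float, lon1: float, lat2: float, lon2: float) -> float:
    phi1, phi2 = math.radians(lat1), math.radians(lat2)
    dphi = phi2 - phi1
    dlam = math.radians(lon2 - lon1)
    a = math.sin(dphi / 2) ** 2 + math.cos(phi1) * math.cos(phi2) * math.sin(dlam / 2) ** 2
    return 2 * EARTH_RADIUS_KM * math.asin(min(1.0, math.sqrt(a)))


def geographic_distance(meta: Sequence[PopulationMeta]) -> DistanceMatrix:
    """Great-circle distance matrix (km) between population coordinates."""
    for m in meta:
        if m.latitude is None or m.longitude is None:
            raise ValueError(f"missing coordinates for {m.population_code}")
    n = len(meta)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = haversine_km(
                meta[i].latitude, meta[i].longitude,
                meta[j].latitude, meta[j].longitude,
            )
    dm = DistanceMatrix(
        labels=[m.population_code for m in meta], d=d, kind="geographic_km"
    )
    dm.validate()
    return dm


def kruskal_stress(config: np.ndarray, target: np.ndarray) -> float:
    """Kruskal stress-1 between configuration distances and target distances."""
    from scipy.spatial.distance import pdist, squareform

    d = squareform(pdist(config))
    iu = np.triu_indices(target.shape[0], k=1)
    num = float(np.sum((d[iu] - target[iu]) ** 2))
    den = float(np.sum(target[iu] ** 2))
    if den == 0.0:
        return 0.0
    return math.sqrt(num / den)


def _classical_mds(d: np.ndarray, k: int) -> np.ndarray:
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    evals, evecs = np.linalg.eigh(b)
    order = np.argsort(evals)[::-1][:k]
    lam = np.clip(evals[order], 0.0, None)
    return evecs[:, order] * np.sqrt(lam)


def _smacof(
    d: np.ndarray, x0: np.ndarray, max_iter: int = 1000, tol: float = 1e-12
) -> np.ndarray:
    """Guttman-transform stress majorization; raw stress is non-increasing."""
    from scipy.spatial.distance import pdist, squareform

    n = d.shape[0]
    x = x0.copy()
    prev = None
    for _ in range(max_iter):
        dist = squareform(pdist(x))
        stress = float(np.sum((squareform(dist) - squareform(d)) ** 2))
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(dist > 0, d / dist, 0.0)
        b = -ratio
        np.fill_diagonal(b, 0.0)
        np.fill_diagonal(b, -b.sum(axis=1))
        x = (b @ x) / n
        if prev is not None and abs(prev - stress) <= tol * max(prev, 1e-30):
            break
        prev = stress
    return x - x.mean(axis=0)


def mds(dm: DistanceMatrix, k: int = 2, max_iter: int = 1000) -> Ordination:
    """Metric MDS: Torgerson start refined by SMACOF, stress-1 reported.

    Deterministic for fixed input; infinite entries are rejected.
    """
    dm.validate()
    n = len(dm.labels)
    if not np.all(np.isfinite(dm.d)):
        raise ValueError("distance matrix contains non-finite entries")
    if k >= n:
        raise ValueError(f"k={k} must be smaller than n={n}")
    x0 = _classical_mds(dm.d, k)
    x = _smacof(dm.d, x0, max_iter=max_iter)
    return Ordination(
        coordinates=x,
        k=k,
        stress=kruskal_stress(x, dm.d),
        labels=list(dm.labels),
    )


def pca(ft: FrequencyTable, k: int = 2) -> Ordination:
    """PCA of centered frequency rows via covariance eigendecomposition.

    Components are ordered by decreasing variance; each component's sign is
    fixed so its largest-magnitude loading is positive. ``explained_variance``
    holds fractions of total variance (all zero for a constant table).
    """
    n_pop, n_hg = ft.p.shape
    if n_pop < 2:
        raise ValueError("PCA requires at least two populations")
    if k > n_hg:
        raise ValueError(f"k={k} exceeds number of haplogroups {n_hg}")
    xc = ft.p - ft.p.mean(axis=0)
    cov = (xc.T @ xc) / (n_pop - 1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1][:k]
    lam = np.clip(evals[order], 0.0, None)
    v = evecs[:, order]
    for j in range(v.shape[1]):
        i_max = int(np.argmax(np.abs(v[:, j])))
        if v[i_max, j] < 0:
            v[:, j] = -v[:, j]
    total = float(np.clip(evals, 0.0, None).sum())
    frac = lam / total if total > 0 else np.zeros(k)
    return Ordination(
        coordinates=xc @ v,
        k=k,
        explained_variance=frac,
        labels=list(ft.populations),
    )
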