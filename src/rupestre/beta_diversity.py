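"""Floristic similarity: Bray–Curtis distances, Ward.D2 clustering, 2-D NMDS.

Species recorded at a single site (singletons) are excluded before the
distance computation, as they carry no information about compositional
overlap between sites.  On presence/absence data the Bray–Curtis
dissimilarity reduces to the Sørensen distance 1 − 2a/(2a + b + c), where a
is the number of shared species and b, c the numbers unique to each site.
Sites are grouped by Ward's method under the ward.D2 convention and ordered
by non-metric multidimensional scaling minimising Kruskal stress-1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import pdist, squareform
from sklearn.isotonic import IsotonicRegression

from .data_core import IncidenceMatrix

__all__ = [
    "DistanceMatrix",
    "Dendrogram",
    "Ordination",
    "drop_singletons",
    "bray_curtis",
    "ward_cluster",
    "nmds",
    "group_ellipses",
]


@dataclass
class DistanceMatrix:
    labels: list[str]
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("distance matrix shape mismatch")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("distance matrix not symmetric")
        if not np.allclose(np.diag(self.values), 0.0):
            raise ValueError("nonzero diagonal")
        if (self.values < 0).any():
            raise ValueError("negative distances")

    @property
    def n(self) -> int:
        return len(self.labels)

    def condensed(self) -> np.ndarray:
        return squareform(self.values, checks=False)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


@dataclass
class Dendrogram:
    """Agglomeration sequence: scipy-style linkage plus leaf labels."""

    linkage: np.ndarray  # (n−1) × 4
    labels: list[str]

    def heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    def to_newick(self) -> str:
        """Newick string with branch lengths derived from merge heights."""
        n = len(self.labels)
        height = {i: 0.0 for i in range(n)}
        rep = {i: self.labels[i] for i in range(n)}
        for step, (a, b, h, _) in enumerate(self.linkage):
            a, b = int(a), int(b)
            la = h - height[a]
            lb = h - height[b]
            rep[n + step] = f"({rep.pop(a)}:{la:.6g},{rep.pop(b)}:{lb:.6g})"
            height[n + step] = h
        return rep[n + len(self.linkage) - 1] + ";"


@dataclass
class Ordination:
    coordinates: np.ndarray  # n × 2, centered
    stress: float  # Kruskal stress-1
    labels: list[str]
    n_starts: int
    seed: int | None
    converged: bool

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.coordinates, index=self.labels, columns=["x", "y"]
        ).rename_axis("site_id")


def drop_singletons(matrix: IncidenceMatrix) -> IncidenceMatrix:
    """Remove species present at exactly one site; sites are untouched."""
    counts = matrix.values.sum(axis=0)
    keep = counts != 1
    if not keep.any():
        warnings.warn("all species are singletons; resulting matrix has no species")
    return IncidenceMatrix(
        list(matrix.sites),
        [s for s, k in zip(matrix.species, keep) if k],
        matrix.values[:, keep],
    )


def bray_curtis(matrix: IncidenceMatrix) -> DistanceMatrix:
    """Bray–Curtis (Sørensen, for presence/absence) distances between sites."""
    if matrix.n_sites < 2:
        raise ValueError("need at least 2 sites")
    empty = [s for s, r in zip(matrix.sites, matrix.values.sum(axis=1)) if r == 0]
    if empty:
        raise ValueError(f"sites with no species (distance undefined): {empty}")
    d = pdist(matrix.values.astype(float), metric="braycurtis")
    return DistanceMatrix(list(matrix.sites), squareform(d))


def ward_cluster(dist: DistanceMatrix) -> Dendrogram:
    """Agglomerative clustering under the Ward.D2 convention.

    Equivalent to the Lance–Williams update applied to squared input
    distances with heights reported on the original (square-root) scale —
    scipy's "ward" linkage on a precomputed distance matrix, matching R's
    hclust(method = "ward.D2").
    """
    if dist.n < 2:
        raise ValueError("need at least 2 points to cluster")
    Z = linkage(dist.condensed(), method="ward")
    return Dendrogram(linkage=Z, labels=list(dist.labels))


# ---------------------------------------------------------------------------
# NMDS


def _pcoa_init(D: np.ndarray, dims: int) -> np.ndarray:
    """Classical scaling (principal coordinates) of the dissimilarities."""
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    w, v = np.linalg.eigh(B)
    order = np.argsort(w)[::-1][:dims]
    w_pos = np.clip(w[order], 0.0, None)
    return v[:, order] * np.sqrt(w_pos)


def _stress_and_dhat(
    d_config: np.ndarray, order: np.ndarray, iso: IsotonicRegression
) -> tuple[float, np.ndarray]:
    """Kruskal stress-1 and the isotonic fit of configuration distances on
    dissimilarity ranks (primary approach to ties: the fit may break them)."""
    dhat = np.empty_like(d_config)
    dhat[order] = iso.fit_transform(np.arange(len(order)), d_config[order])
    denom = float((d_config**2).sum())
    if denom == 0:
        return 0.0, dhat
    stress = float(np.sqrt(((d_config - dhat) ** 2).sum() / denom))
    return stress, dhat


def _nmds_single(
    D_cond: np.ndarray, n: int, dims: int, init: np.ndarray, max_iter: int, tol: float
) -> tuple[np.ndarray, float, bool]:
    iu = np.triu_indices(n, 1)
    order = np.argsort(D_cond, kind="stable")
    iso = IsotonicRegression(increasing=True)
    X = init.copy()
    last = np.inf
    converged = False
    stress = np.inf
    for _ in range(max_iter):
        diff = X[:, None, :] - X[None, :, :]
        dfull = np.sqrt((diff**2).sum(-1))
        d_config = dfull[iu]
        stress, dhat = _stress_and_dhat(d_config, order, iso)
        if stress < 1e-12:
            converged = True
            break
        if last - stress < tol * max(stress, 1e-12):
            converged = True
            break
        last = stress
        # Guttman transform toward the isotonic targets
        W = np.zeros((n, n))
        W[iu] = np.divide(dhat, d_config, out=np.zeros_like(dhat), where=d_config > 0)
        W = W + W.T
        B = -W
        np.fill_diagonal(B, W.sum(axis=1))
        X = (B @ X) / n
        X -= X.mean(axis=0)
    return X - X.mean(axis=0), stress, converged


def nmds(
    dist: DistanceMatrix,
    dims: int = 2,
    n_starts: int = 20,
    seed: int | None = None,
    max_iter: int = 300,
    tol: float = 1e-7,
) -> Ordination:
    """Non-metric multidimensional scaling minimising Kruskal stress-1.

    The first start uses principal coordinates of the dissimilarities, the
    remaining starts are random (seeded); the best solution over all starts
    is returned.  Deterministic given the seed.
    """
    n = dist.n
    if n < dims + 1:
        raise ValueError(f"need at least {dims + 1} points for {dims}-D NMDS")
    rng = np.random.default_rng(seed)
    D_cond = dist.condensed()
    scale = D_cond.max() if D_cond.max() > 0 else 1.0

    best: tuple[np.ndarray, float, bool] | None = None
    for s in range(max(1, n_starts)):
        init = _pcoa_init(dist.values, dims) if s == 0 else rng.normal(size=(n, dims)) * scale
        X, stress, conv = _nmds_single(D_cond, n, dims, init, max_iter, tol)
        if best is None or stress < best[1]:
            best = (X, stress, conv)
    X, stress, conv = best
    if not conv:
        warnings.warn("NMDS did not converge in any start; returning best found")
    return Ordination(
        coordinates=X, stress=stress, labels=list(dist.labels),
        n_starts=max(1, n_starts), seed=seed, converged=conv,
    )


def group_ellipses(ord_: Ordination, groups: dict[str, str]) -> pd.DataFrame:
    """Per-group centroid and 2×2 covariance of ordination coordinates.

    The 95% confidence ellipse for a group is fully determined by these
    moments; drawing is left to the caller.
    """
    df = ord_.to_frame()
    df["group"] = [groups.get(l) for l in ord_.labels]
    rows = []
    for g, sub in df.dropna(subset=["group"]).groupby("group"):
        xy = sub[["x", "y"]].to_numpy()
        c = xy.mean(axis=0)
        cov = np.cov(xy.T) if len(xy) > 1 else np.zeros((2, 2))
        rows.append(
            {"group": g, "n": len(xy), "cx": c[0], "cy": c[1],
             "cov_xx": cov[0, 0], "cov_xy": cov[0, 1], "cov_yy": cov[1, 1]}
        )
    return pd.DataFrame(rows)
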