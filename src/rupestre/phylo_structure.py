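"""Per-site phylogenetic structure: MPD, MNTD, tip-shuffle nulls, NRI/NTI.

MPD is the mean patristic distance over all pairs of species co-occurring at
a site; MNTD is the mean distance from each species to its nearest
co-occurring relative.  The null model shuffles the tips of the dated tree
(equivalently, permutes the labels of the patristic distance matrix) and
recomputes each metric; the standardized effect size against 999 shuffles,
sign-flipped, gives the Net Relatedness Index (NRI = −SES of MPD) and the
Nearest Taxon Index (NTI = −SES of MNTD).  Positive values indicate
phylogenetic clustering, significant beyond ±1.96.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .data_core import IncidenceMatrix
from .megatree import DatedTree

logger = logging.getLogger(__name__)

__all__ = ["PatristicMatrix", "SesResult", "cophenetic", "mpd", "mntd", "ses", "ses_frame"]

SIGNIFICANCE_CUTOFF = 1.96


@dataclass
class PatristicMatrix:
    """Pairwise patristic (cophenetic) distances between tips, in My of path length."""

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
        self._index = {l: i for i, l in enumerate(self.labels)}

    def indices(self, community: Iterable[str]) -> np.ndarray:
        return np.array([self._index[s] for s in community], dtype=int)

    def submatrix(self, community: Iterable[str]) -> np.ndarray:
        idx = self.indices(community)
        return self.values[np.ix_(idx, idx)]


def cophenetic(tree: DatedTree) -> PatristicMatrix:
    """Patristic distance matrix of a dated tree.

    Distances are path lengths; on an ultrametric tree d(i, j) equals twice
    the age of the most recent common ancestor of i and j.
    """
    leaves = list(tree.tree.leaf_node_iter())
    if len(leaves) < 2:
        raise ValueError("cophenetic distances need at least 2 tips")
    from .megatree import _node_name

    labels = [_node_name(l) for l in leaves]
    index = {id(l): i for i, l in enumerate(leaves)}
    n = len(leaves)
    D = np.zeros((n, n))

    # depth of every node from the root
    depth: dict[int, float] = {id(tree.tree.seed_node): 0.0}
    tipsets: dict[int, np.ndarray] = {}
    for nd in tree.tree.preorder_node_iter():
        for ch in nd.child_nodes():
            depth[id(ch)] = depth[id(nd)] + (ch.edge.length or 0.0)
    # post-order: cross-join descendant tip sets of distinct children;
    # d(i, j) = depth_i + depth_j − 2 · depth of the MRCA
    for nd in tree.tree.postorder_node_iter():
        if nd.is_leaf():
            tipsets[id(nd)] = np.array([index[id(nd)]], dtype=int)
            continue
        sets = [tipsets.pop(id(ch)) for ch in nd.child_nodes()]
        for a in range(len(sets)):
            for b in range(a + 1, len(sets)):
                ia, ib = sets[a], sets[b]
                d_ia = np.array([depth[id(leaves[i])] for i in ia])
                d_ib = np.array([depth[id(leaves[i])] for i in ib])
                block = d_ia[:, None] + d_ib[None, :] - 2.0 * depth[id(nd)]
                D[np.ix_(ia, ib)] = block
                D[np.ix_(ib, ia)] = block.T
        tipsets[id(nd)] = np.concatenate(sets)
    return PatristicMatrix(labels=labels, values=D)


def mpd(community: Sequence[str], dist: PatristicMatrix) -> float:
    """Mean pairwise distance over all unordered distinct pairs."""
    sub = dist.submatrix(community)
    k = sub.shape[0]
    if k < 2:
        raise ValueError("MPD needs at least 2 taxa")
    iu = np.triu_indices(k, 1)
    return float(sub[iu].mean())


def mntd(community: Sequence[str], dist: PatristicMatrix) -> float:
    """Mean distance from each member to its nearest other member."""
    sub = dist.submatrix(community).astype(float)
    k = sub.shape[0]
    if k < 2:
        raise ValueError("MNTD needs at least 2 taxa")
    np.fill_diagonal(sub, np.inf)
    return float(sub.min(axis=1).mean())


@dataclass(frozen=True)
class SesResult:
    site_id: str
    metric: str  # "MPD" or "MNTD"
    n_taxa: int
    obs: float
    null_mean: float
    null_sd: float
    index: float  # NRI or NTI; NaN when undefined
    rank: int  # rank of obs among obs + nulls (1 = smallest)
    n_null: int
    significant: str  # clustered | overdispersed | ns | undefined

    @property
    def index_name(self) -> str:
        return "NRI" if self.metric == "MPD" else "NTI"


def _null_metrics(
    D: np.ndarray, k: int, n_null: int, rng: np.random.Generator, metric: str
) -> np.ndarray:
    """Null metric values under uniform tip shuffling.

    A uniform permutation of the distance-matrix labels restricted to a fixed
    community of size k is a uniform k-subset of the pool, so each null draw
    samples k pool indices without replacement.  Processed in blocks to bound
    memory on large communities.
    """
    N = D.shape[0]
    out = np.empty(n_null)
    block = max(1, int(2e7 / max(k * k, 1)))
    done = 0
    while done < n_null:
        b = min(block, n_null - done)
        # b × k index matrix of without-replacement draws
        idx = np.argsort(rng.random((b, N)), axis=1)[:, :k]
        sub = D[idx[:, :, None], idx[:, None, :]]  # b × k × k
        if metric == "MPD":
            out[done : done + b] = (sub.sum(axis=(1, 2))) / (k * (k - 1))
        else:
            sub[:, np.arange(k), np.arange(k)] = np.inf
            out[done : done + b] = sub.min(axis=2).mean(axis=1)
        done += b
    return out


def ses(
    matrix: IncidenceMatrix,
    dist: PatristicMatrix,
    metric: str = "MPD",
    n_null: int = 999,
    seed: int | None = None,
) -> list[SesResult]:
    """Standardized effect sizes per site against the tip-shuffle null.

    The pool is the full tip set of the dated tree; species in the matrix but
    absent from the tree are dropped globally with a warning.  Null SD uses
    the sample (n−1) estimator.  The sign flip makes positive indices mean
    clustering: NRI = −SES(MPD), NTI = −SES(MNTD).
    """
    if metric not in ("MPD", "MNTD"):
        raise ValueError(f"unknown metric {metric!r}")
    rng = np.random.default_rng(seed)
    in_tree = set(dist.labels)
    missing = [s for s in matrix.species if s not in in_tree]
    if missing:
        warnings.warn(
            f"{len(missing)} species absent from the tree dropped before SES: "
            f"{missing[:10]}"
        )
    keep = [s for s in matrix.species if s in in_tree]
    fn = mpd if metric == "MPD" else mntd

    results = []
    for i, site in enumerate(matrix.sites):
        community = [s for s, v in zip(matrix.species, matrix.values[i]) if v and s in in_tree]
        k = len(community)
        if k < 2:
            warnings.warn(f"site {site!r} has fewer than 2 tree species; skipped")
            continue
        obs = fn(community, dist)
        nulls = _null_metrics(dist.values, k, n_null, rng, metric)
        mu = float(nulls.mean())
        sd = float(nulls.std(ddof=1))
        rank = int((nulls < obs).sum()) + 1
        if sd > 0:
            index = -(obs - mu) / sd
            if index > SIGNIFICANCE_CUTOFF:
                sig = "clustered"
            elif index < -SIGNIFICANCE_CUTOFF:
                sig = "overdispersed"
            else:
                sig = "ns"
        else:
            index = float("nan")
            sig = "undefined"
            warnings.warn(f"site {site!r}: null SD is zero; index undefined")
        results.append(
            SesResult(site, metric, k, obs, mu, sd, index, rank, n_null, sig)
        )
    return results


def ses_frame(results: Sequence[SesResult]) -> pd.DataFrame:
    """Tabular view of SES results (one row per site × metric)."""
    return pd.DataFrame(
        {
            "site_id": [r.site_id for r in results],
            "metric": [r.metric for r in results],
            "n_taxa": [r.n_taxa for r in results],
            "obs": [r.obs for r in results],
            "null_mean": [r.null_mean for r in results],
            "null_sd": [r.null_sd for r in results],
            "index": [r.index for r in results],
            "index_name": [r.index_name for r in results],
            "significant": [r.significant for r in results],
        }
    )
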