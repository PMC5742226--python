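"""Per-clade over/under-representation (the nodesig test).

For a site with n species drawn from a pool of N tree tips, the null number
of site members descending from a node with K pool descendants is
Hypergeometric(N, K, n).  A node is called over-represented at a site when
the upper tail probability of its observed count is ≤ α/2 (default α=0.05),
under-represented on the lower tail.  Habitat-level summaries flag nodes
over- (or under-) represented in at least half of a habitat's sites, with
the clade's crown age attached from the dated tree.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data_core import SiteRecord
from .megatree import DatedTree, _node_name

__all__ = [
    "NodeRepresentation",
    "CladeSummary",
    "node_tip_counts",
    "nodesig_site",
    "nodesig_matrix",
    "tabulate_habitat",
    "annotated_newick",
]


@dataclass(frozen=True)
class NodeRepresentation:
    site_id: str
    node_id: str  # clade name, or leaf-set signature for unnamed nodes
    n_descendant_tips_in_pool: int  # K
    site_richness: int  # n
    pool_size: int  # N
    observed: int  # x
    p_over: float
    p_under: float
    status: str  # over | under | ns


@dataclass(frozen=True)
class CladeSummary:
    habitat: str
    clade_name: str
    crown_age: float
    n_sites_over: int
    n_sites_under: int
    n_sites_total: int
    flagged_over: bool
    flagged_under: bool


def _node_tables(tree: DatedTree):
    """Internal-node bookkeeping: ids, descendant-tip indicator matrix, ages.

    Unnamed nodes are identified by their nearest named ancestor plus the
    first/last descendant tips and descendant count — a stable, readable
    signature in lieu of the manual clade naming of published tables.
    """
    leaves = list(tree.tree.leaf_node_iter())
    tip_index = {id(l): i for i, l in enumerate(leaves)}
    N = len(leaves)
    nodes, names, ages, rows = [], [], [], []
    named_anc: dict[int, str] = {}
    for nd in tree.tree.preorder_node_iter():
        nm = _node_name(nd)
        parent_named = named_anc.get(id(nd.parent_node), "root") if nd.parent_node else "root"
        named_anc[id(nd)] = nm if nm is not None else parent_named
    tipsets: dict[int, list[int]] = {}
    for nd in tree.tree.postorder_node_iter():
        if nd.is_leaf():
            tipsets[id(nd)] = [tip_index[id(nd)]]
            continue
        ts = sorted(t for ch in nd.child_nodes() for t in tipsets[id(ch)])
        tipsets[id(nd)] = ts
        nm = _node_name(nd)
        if nm is None:
            first = _node_name(leaves[ts[0]])
            last = _node_name(leaves[ts[-1]])
            nm = f"[{named_anc[id(nd)]}:{first}..{last}:{len(ts)}]"
        nodes.append(nd)
        names.append(nm)
        ages.append(tree.age_of(nd))
        row = np.zeros(N, dtype=bool)
        row[ts] = True
        rows.append(row)
    A = np.array(rows)  # n_internal × N indicator
    labels = [_node_name(l) for l in leaves]
    return nodes, names, np.array(ages), A, labels


def node_tip_counts(tree: DatedTree, community: Iterable[str]) -> dict[str, int]:
    """Number of community members descending from each internal node."""
    _, names, _, A, labels = _node_tables(tree)
    idx = {l: i for i, l in enumerate(labels)}
    present = np.zeros(len(labels), dtype=bool)
    for s in community:
        if s not in idx:
            raise KeyError(f"species {s!r} is not a tip of the tree")
        present[idx[s]] = True
    counts = A.astype(np.int64) @ present.astype(np.int64)
    return dict(zip(names, counts.astype(int)))


def _analytic_tails(x: np.ndarray, N: int, K: np.ndarray, n: int):
    p_over = stats.hypergeom.sf(x - 1, N, K, n)
    p_under = stats.hypergeom.cdf(x, N, K, n)
    return p_over, p_under


def _montecarlo_tails(
    x: np.ndarray, A: np.ndarray, n: int, runs: int, rng: np.random.Generator
):
    """Tail probabilities from `runs` uniform draws of n tips, with the +1
    small-sample correction so no estimated p is exactly zero."""
    N = A.shape[1]
    over = np.zeros(len(x), dtype=np.int64)
    under = np.zeros(len(x), dtype=np.int64)
    block = max(1, int(5e7 / (A.shape[0] * max(n, 1))))
    done = 0
    while done < runs:
        b = min(block, runs - done)
        draws = np.argsort(rng.random((b, N)), axis=1)[:, :n]  # b × n tip indices
        S = np.zeros((b, N), dtype=bool)
        S[np.arange(b)[:, None], draws] = True
        counts = S.astype(np.int64) @ A.T.astype(np.int64)  # b × n_nodes
        over += (counts >= x[None, :]).sum(axis=0)
        under += (counts <= x[None, :]).sum(axis=0)
        done += b
    p_over = (over + 1) / (runs + 1)
    p_under = (under + 1) / (runs + 1)
    return p_over, p_under


def nodesig_site(
    tree: DatedTree,
    community: Sequence[str],
    site_id: str = "",
    mode: str = "analytic",
    runs: int = 1000,
    seed: int | None = None,
    alpha: float = 0.05,
    _tables=None,
) -> list[NodeRepresentation]:
    """Over/under-representation of every internal node at one site.

    ``mode="analytic"`` computes exact hypergeometric tails (the default:
    exact and fast); ``mode="montecarlo"`` estimates them from ``runs``
    uniform draws.  Two-tailed decision at per-tail threshold α/2.
    """
    if mode not in ("analytic", "montecarlo"):
        raise ValueError(f"unknown mode {mode!r}")
    nodes, names, ages, A, labels = _tables if _tables is not None else _node_tables(tree)
    idx = {l: i for i, l in enumerate(labels)}
    N = len(labels)
    n = len(set(community))
    if n > N:
        raise ValueError(f"community size {n} exceeds pool size {N}")
    if n < 1:
        raise ValueError("empty community")
    present = np.zeros(N, dtype=bool)
    for s in set(community):
        present[idx[s]] = True
    x = A.astype(np.int64) @ present.astype(np.int64)
    K = A.sum(axis=1).astype(int)
    if mode == "analytic":
        p_over, p_under = _analytic_tails(x, N, K, n)
    else:
        rng = np.random.default_rng(seed)
        p_over, p_under = _montecarlo_tails(x, A, n, runs, rng)
    cut = alpha / 2.0
    out = []
    for i in range(len(names)):
        status = "over" if p_over[i] <= cut else ("under" if p_under[i] <= cut else "ns")
        out.append(
            NodeRepresentation(
                site_id=site_id, node_id=names[i],
                n_descendant_tips_in_pool=int(K[i]), site_richness=n,
                pool_size=N, observed=int(x[i]),
                p_over=float(p_over[i]), p_under=float(p_under[i]), status=status,
            )
        )
    return out


def nodesig_matrix(
    tree: DatedTree,
    matrix,
    mode: str = "analytic",
    runs: int = 1000,
    seed: int | None = None,
    alpha: float = 0.05,
) -> dict[str, list[NodeRepresentation]]:
    """nodesig for every site of an incidence matrix (species absent from
    the tree are ignored per site)."""
    tables = _node_tables(tree)
    labels = set(tables[4])
    out = {}
    rng = np.random.default_rng(seed)
    for i, site in enumerate(matrix.sites):
        community = [s for s, v in zip(matrix.species, matrix.values[i]) if v and s in labels]
        if not community:
            warnings.warn(f"site {site!r} has no tree species; skipped")
            continue
        out[site] = nodesig_site(
            tree, community, site_id=site, mode=mode, runs=runs,
            seed=int(rng.integers(2**31)) if mode == "montecarlo" else None,
            alpha=alpha, _tables=tables,
        )
    return out


def tabulate_habitat(
    reps: Mapping[str, Sequence[NodeRepresentation]],
    meta: Sequence[SiteRecord],
    tree: DatedTree,
) -> list[CladeSummary]:
    """Habitat × node tabulation under the at-least-half-of-sites rule.

    A node is flagged for a habitat when it is over- (or under-) represented
    at ≥ ⌈sites/2⌉ of that habitat's sites.  Crown ages come from the dated
    tree; output is sorted by age ascending within habitat.  Sites without a
    derivable habitat are excluded with a warning.
    """
    by_id = {r.site_id: r for r in meta}
    _, names, ages, _, _ = _node_tables(tree)
    age_of = dict(zip(names, ages))
    per_hab: dict[str, list[str]] = {}
    for site in reps:
        rec = by_id.get(site)
        hab = rec.habitat if rec else None
        if hab is None:
            warnings.warn(f"site {site!r} lacks a habitat class; excluded")
            continue
        per_hab.setdefault(hab.value, []).append(site)

    out: list[CladeSummary] = []
    for hab, sites in sorted(per_hab.items()):
        total = len(sites)
        need = math.ceil(total / 2)
        over: dict[str, int] = {}
        under: dict[str, int] = {}
        for site in sites:
            for r in reps[site]:
                if r.status == "over":
                    over[r.node_id] = over.get(r.node_id, 0) + 1
                elif r.status == "under":
                    under[r.node_id] = under.get(r.node_id, 0) + 1
        for name in sorted(set(over) | set(under), key=lambda nm: age_of.get(nm, 0.0)):
            n_o, n_u = over.get(name, 0), under.get(name, 0)
            out.append(
                CladeSummary(
                    habitat=hab, clade_name=name,
                    crown_age=float(age_of.get(name, float("nan"))),
                    n_sites_over=n_o, n_sites_under=n_u, n_sites_total=total,
                    flagged_over=n_o >= need, flagged_under=n_u >= need,
                )
            )
    return out


def summary_frame(summaries: Sequence[CladeSummary]) -> pd.DataFrame:
    return pd.DataFrame([s.__dict__ for s in summaries])


def annotated_newick(tree: DatedTree, reps: Sequence[NodeRepresentation]) -> str:
    """Newick export with per-node status codes (the nodesigl-style listing),
    for external tree viewers."""
    status = {r.node_id: r.status for r in reps}
    clone = tree.tree.clone(depth=1)
    _, names, _, _, _ = _node_tables(tree)
    it_src = [nd for nd in tree.tree.postorder_internal_node_iter()]
    it_dst = [nd for nd in clone.postorder_internal_node_iter()]
    for src, dst, name in zip(it_src, it_dst, names):
        st = status.get(name, "ns")
        base = _node_name(src) or ""
        dst.label = f"{base}|{st.upper()}" if st != "ns" else base
    return clone.as_string(
        schema="newick", suppress_rooting=True, unquoted_underscores=True
    ).strip()
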