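"""Dated megatree construction.

A *megatree* is a backbone phylogeny whose internal nodes carry clade names
(families, genera, higher clades).  Species from a survey compilation are
grafted onto it — at their genus node when the backbone names it, otherwise
as a polytomy child of their family node — and node ages are then assigned
by even interpolation between calibrated nodes (the bladj algorithm),
yielding an ultrametric tree in millions of years from which patristic
distances and clade crown ages derive.
"""

from __future__ import annotations

import difflib
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy

from .data_core import TaxonName, sanitize_label

logger = logging.getLogger(__name__)

__all__ = [
    "AgeCalibration",
    "DatedTree",
    "GraftReport",
    "read_backbone",
    "read_ages",
    "graft_species",
    "bladj_date",
    "crown_age",
    "read_dated",
]


def _node_name(node: dendropy.Node) -> str | None:
    """Clade/tip name of a node, sanitized; None when unnamed."""
    raw = node.taxon.label if node.taxon is not None else node.label
    if raw is None or str(raw).strip() == "":
        return None
    return str(raw).strip().lower().replace(" ", "_").replace("-", ".")


def read_backbone(path: str | Path) -> dendropy.Tree:
    """Read a rooted newick backbone (internal node labels kept as clade names)."""
    tree = dendropy.Tree.get(
        path=str(path),
        schema="newick",
        suppress_internal_node_taxa=True,
        preserve_underscores=True,
    )
    tree.is_rooted = True
    names = [n for n in (_node_name(nd) for nd in tree) if n is not None]
    dupes = sorted({n for n in names if names.count(n) > 1})
    if dupes:
        raise ValueError(f"duplicate node names in backbone: {dupes}")
    return tree


@dataclass(frozen=True)
class AgeCalibration:
    """Clade-name → age (My) calibration set."""

    entries: Mapping[str, float]

    def __post_init__(self):
        object.__setattr__(
            self,
            "entries",
            {str(k).strip().lower(): float(v) for k, v in dict(self.entries).items()},
        )
        bad = {k: v for k, v in self.entries.items() if v <= 0}
        if bad:
            raise ValueError(f"non-positive calibration ages: {bad}")

    def __getitem__(self, name: str) -> float:
        return self.entries[name]

    def __contains__(self, name: str) -> bool:
        return name in self.entries


def read_ages(path: str | Path) -> AgeCalibration:
    """Read a two-column whitespace-delimited ages file (clade_name, age in My)."""
    entries: dict[str, float] = {}
    for ln, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 2:
            raise ValueError(f"{path}:{ln}: expected 'clade_name age', got {line!r}")
        entries[parts[0]] = float(parts[1])
    return AgeCalibration(entries)


@dataclass
class GraftReport:
    placed_at_genus: list[str] = field(default_factory=list)
    placed_at_family: list[str] = field(default_factory=list)
    unplaced: list[str] = field(default_factory=list)

    @property
    def n_placed(self) -> int:
        return len(self.placed_at_genus) + len(self.placed_at_family)


def graft_species(
    backbone: dendropy.Tree, taxa: Sequence[TaxonName]
) -> tuple[dendropy.Tree, GraftReport]:
    """Attach species tips to a named backbone and prune unused backbone tips.

    Each taxon becomes a new tip under its genus node if the backbone names
    it, else a polytomy child of its family node; species whose family is
    also absent are collected in the report, never fatal.  Backbone tips not
    grafted are pruned (named internal nodes are retained even when left with
    a single child, so they remain usable as calibration anchors).
    """
    tree = backbone.clone(depth=1)
    by_name: dict[str, dendropy.Node] = {}
    for nd in tree:
        name = _node_name(nd)
        if name is not None:
            by_name[name] = nd

    report = GraftReport()
    grafted: list[dendropy.Node] = []
    for t in taxa:
        anchor = by_name.get(t.genus.lower())
        if anchor is not None:
            report.placed_at_genus.append(t.label)
        else:
            anchor = by_name.get(t.family.lower()) if t.family else None
            if anchor is not None:
                report.placed_at_family.append(t.label)
            else:
                report.unplaced.append(t.label)
                continue
        # a named backbone tip becomes an internal node: move name to label
        if anchor.is_leaf() and anchor.taxon is not None:
            anchor.label = anchor.taxon.label
            anchor.taxon = None
        child = dendropy.Node()
        child.taxon = tree.taxon_namespace.new_taxon(label=t.label)
        anchor.add_child(child)
        grafted.append(child)

    placed = set(grafted)
    # prune leaves that are not grafted species, bottom-up
    changed = True
    while changed:
        changed = False
        for leaf in [nd for nd in tree.leaf_node_iter()]:
            if leaf not in placed and leaf.parent_node is not None:
                leaf.parent_node.remove_child(leaf)
                changed = True
    tree.update_taxon_namespace()
    if report.unplaced:
        logger.warning("%d species unplaced: %s", len(report.unplaced), report.unplaced[:10])
    return tree, report


@dataclass
class DatedTree:
    """Rooted ultrametric tree with node ages in My.

    Ages strictly decrease root → tip, tips sit at age 0, and every branch
    length equals the parent age minus the child age.
    """

    tree: dendropy.Tree
    ages: dict[int, float]  # id(node) -> age

    TOL = 1e-9

    def __post_init__(self):
        self._validate()

    def _validate(self):
        root_age = self.age_of(self.tree.seed_node)
        for nd in self.tree.preorder_node_iter():
            a = self.age_of(nd)
            if nd.is_leaf():
                if abs(a) > self.TOL:
                    raise ValueError(f"tip {_node_name(nd)} has nonzero age {a}")
            for ch in nd.child_nodes():
                ca = self.age_of(ch)
                if ca >= a + self.TOL * max(1.0, root_age):
                    raise ValueError(
                        f"age does not decrease: {_node_name(nd) or 'node'}={a} -> "
                        f"{_node_name(ch) or 'node'}={ca}"
                    )

    def age_of(self, node: dendropy.Node) -> float:
        return self.ages[id(node)]

    @property
    def root_age(self) -> float:
        return self.age_of(self.tree.seed_node)

    def tip_labels(self) -> list[str]:
        return [_node_name(l) for l in self.tree.leaf_node_iter()]

    def find_node(self, name: str) -> dendropy.Node:
        wanted = name.strip().lower().replace(" ", "_").replace("-", ".")
        all_names = []
        for nd in self.tree:
            nm = _node_name(nd)
            if nm == wanted:
                return nd
            if nm is not None:
                all_names.append(nm)
        near = difflib.get_close_matches(wanted, all_names, n=5)
        raise KeyError(f"no node named {name!r}; near matches: {near}")

    def write_newick(self, path: str | Path) -> None:
        self.tree.write(
            path=str(path), schema="newick", suppress_rooting=True,
            unquoted_underscores=True,
        )

    def as_newick(self) -> str:
        return self.tree.as_string(
            schema="newick", suppress_rooting=True, unquoted_underscores=True
        ).strip()


def _check_calibration_consistency(tree: dendropy.Tree, ages: AgeCalibration) -> None:
    """A calibrated node must be younger than its nearest calibrated ancestor."""
    def walk(node, anc_name, anc_age):
        name = _node_name(node)
        here_name, here_age = anc_name, anc_age
        if name is not None and name in ages and not node.is_leaf():
            a = ages[name]
            if anc_age is not None and a >= anc_age:
                raise ValueError(
                    f"calibrated node {name!r} (age {a}) is not younger than its "
                    f"calibrated ancestor {anc_name!r} (age {anc_age})"
                )
            here_name, here_age = name, a
        for ch in node.child_nodes():
            walk(ch, here_name, here_age)

    import sys
    old = sys.getrecursionlimit()
    sys.setrecursionlimit(max(old, 10000))
    try:
        walk(tree.seed_node, None, None)
    finally:
        sys.setrecursionlimit(old)


def bladj_date(tree: dendropy.Tree, ages: AgeCalibration) -> DatedTree:
    """Assign ages to undated nodes by even interpolation (bladj algorithm).

    Calibrated nodes receive exactly their file ages and tips are fixed at 0.
    Fixed nodes are processed oldest-first; on every descending path from a
    fixed node, the k-th of m intervening undated nodes gets
    ``a_top − (a_top − a_bot)·k/(m+1)`` where a_bot is the age of the nearest
    fixed descendant (or tip).  Ages assigned on one path become fixed for
    subsequent paths — the deterministic sweep of the original tool.
    """
    tree = tree.clone(depth=1)
    root_name = _node_name(tree.seed_node)
    if root_name is None or root_name not in ages:
        raise ValueError(f"root node ({root_name!r}) must be named and calibrated")
    _check_calibration_consistency(tree, ages)

    node_age: dict[int, float] = {}
    calibrated: list[dendropy.Node] = []
    for nd in tree.preorder_node_iter():
        if nd.is_leaf():
            node_age[id(nd)] = 0.0
        else:
            name = _node_name(nd)
            if name is not None and name in ages:
                node_age[id(nd)] = ages[name]
                calibrated.append(nd)

    def interpolate(chain: list[dendropy.Node], top_age: float, bot_age: float) -> None:
        """Assign unfixed tail of chain evenly between the deepest fixed
        prefix node (or top_age) and bot_age."""
        start = 0
        top = top_age
        for i, nd in enumerate(chain):
            if id(nd) in node_age:
                top = node_age[id(nd)]
                start = i + 1
        tail = chain[start:]
        if not tail:
            return
        if bot_age > top:
            raise ValueError(
                f"interpolation conflict: fixed descendant age {bot_age} exceeds "
                f"ancestor age {top}"
            )
        m = len(tail)
        for k, nd in enumerate(tail, 1):
            node_age[id(nd)] = top - (top - bot_age) * k / (m + 1)

    def sweep(node: dendropy.Node, top_age: float, chain: list[dendropy.Node]) -> None:
        # left-to-right DFS from a fixed top; a path terminates at any fixed
        # node (tip, calibrated, or previously assigned), where its chain of
        # undated nodes is interpolated
        for ch in node.child_nodes():
            if id(ch) in node_age:
                interpolate(chain, top_age, node_age[id(ch)])
            else:
                sweep(ch, top_age, chain + [ch])

    import sys
    old = sys.getrecursionlimit()
    sys.setrecursionlimit(max(old, 100000))
    try:
        # oldest-first over calibrated nodes
        for top in sorted(calibrated, key=lambda nd: -node_age[id(nd)]):
            sweep(top, node_age[id(top)], [])
    finally:
        sys.setrecursionlimit(old)
    return DatedTree(tree=_apply_ages(tree, node_age), ages=node_age)


def _apply_ages(tree: dendropy.Tree, node_age: dict[int, float]) -> dendropy.Tree:
    for nd in tree.preorder_node_iter():
        missing = [ch for ch in nd.child_nodes() if id(ch) not in node_age]
        if id(nd) not in node_age or missing:
            raise RuntimeError("bladj sweep left undated nodes")
        for ch in nd.child_nodes():
            ch.edge.length = node_age[id(nd)] - node_age[id(ch)]
    tree.seed_node.edge.length = None
    return tree


def read_dated(path_or_string: str | Path, *, is_string: bool = False) -> DatedTree:
    """Read an ultrametric newick with branch lengths in My as a DatedTree.

    Node ages are reconstructed from depths (root age = maximum tip depth);
    the DatedTree invariants then enforce ultrametricity.
    """
    kwargs = dict(
        schema="newick", suppress_internal_node_taxa=True, preserve_underscores=True
    )
    if is_string:
        tree = dendropy.Tree.get(data=str(path_or_string), **kwargs)
    else:
        tree = dendropy.Tree.get(path=str(path_or_string), **kwargs)
    tree.is_rooted = True
    depth = {id(tree.seed_node): 0.0}
    for nd in tree.preorder_node_iter():
        for ch in nd.child_nodes():
            depth[id(ch)] = depth[id(nd)] + (ch.edge.length or 0.0)
    root_age = max(depth[id(l)] for l in tree.leaf_node_iter())
    ages = {i: root_age - d for i, d in depth.items()}
    return DatedTree(tree=tree, ages=ages)


def crown_age(dated: DatedTree, clade_name: str) -> float:
    """Age (My) of the named node — the clade's crown age; tips return 0."""
    return dated.age_of(dated.find_node(clade_name))
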