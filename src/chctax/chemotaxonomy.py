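"""Chemotaxonomic trees from ordinal-coded CHC profiles.

The chemotaxonomic procedure converts each taxon's mean CHC profile
into ordinal presence/abundance codes, computes Bray-Curtis distances
between the coded rows, and clusters taxa by UPGMA into an ultrametric
dendrogram that can be compared with trees from independent markers
(e.g. mitochondrial COI) via the Robinson-Foulds distance.

Ordinal coding maps a mean relative percentage to {0..4}:
not detected -> 0; (0, 0.5) -> 1; [0.5, 1) -> 2; [1, 5] -> 3;
(5, inf) -> 4.  The published bin statement ("<0.5; 0.5-1; 1-5; >5")
leaves the boundaries 0.5, 1 and 5 ambiguous; the half-open convention
above keeps every rounded table mean unambiguous and can be overridden
through :class:`CodingScheme`.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .multivariate import DistanceMatrix, bray_curtis_from_values

__all__ = [
    "CodingScheme",
    "DEFAULT_CODING",
    "code_value",
    "code_profile",
    "build_coded_matrix",
    "coded_distances",
    "Clade",
    "Dendrogram",
    "upgma",
    "RFResult",
    "compare_trees",
]


# ---------------------------------------------------------------------------
# ordinal coding

@dataclass(frozen=True)
class CodingScheme:
    """Percentage-to-ordinal bins; edges are (upper bound, inclusive?)."""

    trace_upper: float = 0.5    # code 1: (0, trace_upper)
    minor_upper: float = 1.0    # code 2: [trace_upper, minor_upper)
    major_upper: float = 5.0    # code 3: [minor_upper, major_upper]

    def code(self, percentage: float, detected: bool = True) -> int:
        p = float(percentage)
        if p < 0:
            raise ValueError(f"negative percentage {p}")
        if not detected or p == 0:
            return 0
        if p < self.trace_upper:
            return 1
        if p < self.minor_upper:
            return 2
        if p <= self.major_upper:
            return 3
        return 4


DEFAULT_CODING = CodingScheme()


def code_value(percentage: float, detected: bool = True,
               scheme: CodingScheme = DEFAULT_CODING) -> int:
    """Ordinal code {0..4} for one mean percentage."""
    return scheme.code(percentage, detected)


def code_profile(mean_percentages: pd.Series,
                 detected: Optional[pd.Series] = None,
                 scheme: CodingScheme = DEFAULT_CODING) -> pd.Series:
    """Code one taxon's mean profile into ordinal values."""
    if detected is None:
        detected = mean_percentages > 0
    return pd.Series(
        [scheme.code(p, bool(d)) for p, d in zip(mean_percentages, detected)],
        index=mean_percentages.index, dtype=int,
    )


def build_coded_matrix(
    means: pd.DataFrame,
    detected: Optional[pd.DataFrame] = None,
    catalog=None,
    scheme: CodingScheme = DEFAULT_CODING,
) -> pd.DataFrame:
    """Taxa x components ordinal matrix from component x taxa means.

    ``means`` is indexed by component label with one column per taxon
    (the layout of the bundled population fixture).  Missing components
    relative to ``catalog`` are treated as nd; components not in the
    catalog raise.
    """
    if catalog is not None:
        known = set(catalog.labels)
        extra = [c for c in means.index if c not in known]
        if extra:
            raise KeyError(f"components not in catalog: {extra}")
        means = means.reindex(catalog.labels).fillna(0.0)
        if detected is not None:
            detected = detected.reindex(catalog.labels).fillna(False)
    codes = {}
    for taxon in means.columns:
        det = detected[taxon] if detected is not None else None
        row = code_profile(means[taxon], det, scheme)
        if (row == 0).all():
            warnings.warn(f"taxon {taxon!r} has an all-zero coded profile")
        codes[taxon] = row
    return pd.DataFrame(codes).T.astype(int)


def coded_distances(coded: pd.DataFrame) -> DistanceMatrix:
    """Bray-Curtis distances between ordinal-coded taxon rows."""
    return bray_curtis_from_values(coded.astype(float))


# ---------------------------------------------------------------------------
# ultrametric dendrograms

@dataclass(frozen=True)
class Clade:
    """Node of an ultrametric dendrogram; leaves have height 0."""

    height: float
    name: Optional[str] = None
    children: tuple["Clade", ...] = ()

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaf_names(self) -> tuple[str, ...]:
        if self.is_leaf:
            return (self.name,)
        out: list[str] = []
        for ch in self.children:
            out.extend(ch.leaf_names())
        return tuple(out)


@dataclass(frozen=True)
class Dendrogram:
    """Rooted ultrametric tree with merge heights, newick-serialisable."""

    root: Clade

    def __post_init__(self) -> None:
        def check(node: Clade) -> None:
            for ch in node.children:
                if ch.height > node.height + 1e-12:
                    raise ValueError("parent height below child height")
                check(ch)
        check(self.root)

    def leaf_names(self) -> tuple[str, ...]:
        return self.root.leaf_names()

    def cophenetic(self) -> DistanceMatrix:
        """Pairwise cophenetic distances (2x the merge height)."""
        leaves = sorted(self.leaf_names())
        pos = {n: i for i, n in enumerate(leaves)}
        n = len(leaves)
        d = np.zeros((n, n))

        def walk(node: Clade) -> list[str]:
            if node.is_leaf:
                return [node.name]
            groups = [walk(ch) for ch in node.children]
            for i, ga in enumerate(groups):
                for gb in groups[i + 1:]:
                    for a in ga:
                        for b in gb:
                            d[pos[a], pos[b]] = d[pos[b], pos[a]] = 2.0 * node.height
            return [x for g in groups for x in g]

        walk(self.root)
        return DistanceMatrix(d, tuple(leaves))

    def to_newick(self) -> str:
        """Canonical newick string (children ordered by smallest leaf name).

        Heights are quantised to 9 decimal places and branch lengths
        computed by exact decimal subtraction, so write -> read ->
        write is byte-stable.
        """
        from decimal import Decimal

        def dec(h: float) -> Decimal:
            return Decimal(f"{h:.9f}")

        def fmt(node: Clade, parent_height: Optional[float]) -> str:
            if node.is_leaf:
                body = node.name
            else:
                kids = sorted(node.children, key=lambda c: min(c.leaf_names()))
                body = "(" + ",".join(fmt(c, node.height) for c in kids) + ")"
            if parent_height is None:
                return body
            length = (dec(parent_height) - dec(node.height)).normalize()
            return f"{body}:{format(length, 'f')}"

        return fmt(self.root, None) + ";"

    @classmethod
    def from_newick(cls, newick: str, atol: float = 1e-6) -> "Dendrogram":
        """Parse an ultrametric newick string back into a dendrogram."""
        import skbio

        tree = skbio.TreeNode.read(io.StringIO(newick))
        depths: dict[int, float] = {}

        def depth(node, acc: float) -> None:
            depths[id(node)] = acc
            for ch in node.children:
                depth(ch, acc + (ch.length or 0.0))

        depth(tree, 0.0)
        leaf_depths = [depths[id(t)] for t in tree.tips()]
        if leaf_depths and max(leaf_depths) - min(leaf_depths) > atol:
            raise ValueError("newick tree is not ultrametric")

        # heights bottom-up from branch lengths (leaves exactly 0), so a
        # canonical write -> read -> write cycle is byte-stable
        def convert(node) -> Clade:
            if node.is_tip():
                return Clade(0.0, name=str(node.name))
            kids = tuple(convert(ch) for ch in node.children)
            h = max(k.height + (ch.length or 0.0)
                    for k, ch in zip(kids, node.children))
            return Clade(h, children=kids)

        return cls(convert(tree))


def upgma(d: DistanceMatrix) -> Dendrogram:
    """Classic UPGMA: merge the closest pair; new distances are
    size-weighted averages; node height is half the merge distance.

    Ties are broken by the lexicographically smallest pair of smallest
    member labels, making the tree deterministic.
    """
    n = len(d)
    if n < 2:
        raise ValueError("UPGMA needs at least two items")
    clusters: dict[int, Clade] = {i: Clade(0.0, name=str(d.ids[i])) for i in range(n)}
    sizes = {i: 1 for i in range(n)}
    minleaf = {i: str(d.ids[i]) for i in range(n)}
    dist = {
        (i, j): float(d.values[i, j]) for i in range(n) for j in range(i + 1, n)
    }
    next_id = n
    while len(clusters) > 1:
        best = min(
            dist.items(),
            key=lambda kv: (kv[1], tuple(sorted((minleaf[kv[0][0]], minleaf[kv[0][1]])))),
        )
        (a, b), dmin = best
        height = dmin / 2.0
        merged = Clade(height, children=(clusters[a], clusters[b]))
        na, nb = sizes[a], sizes[b]
        new_dist = {}
        for c in clusters:
            if c in (a, b):
                continue
            dac = dist[(min(a, c), max(a, c))]
            dbc = dist[(min(b, c), max(b, c))]
            new_dist[c] = (na * dac + nb * dbc) / (na + nb)
        for key in list(dist):
            if a in key or b in key:
                del dist[key]
        del clusters[a], clusters[b], sizes[a], sizes[b]
        clusters[next_id] = merged
        sizes[next_id] = na + nb
        minleaf[next_id] = min(min(ch.leaf_names()) for ch in merged.children)
        for c, v in new_dist.items():
            dist[(min(c, next_id), max(c, next_id))] = v
        next_id += 1
    (root,) = clusters.values()
    return Dendrogram(root)


# ---------------------------------------------------------------------------
# tree comparison

TreeLike = Union[Dendrogram, str]


def _as_skbio_tree(t: TreeLike):
    import skbio

    if isinstance(t, Dendrogram):
        return skbio.TreeNode.read(io.StringIO(t.to_newick()))
    if hasattr(t, "tips"):  # already a skbio TreeNode
        return t
    return skbio.TreeNode.read(io.StringIO(str(t)))


def _bipartitions(tree) -> set[frozenset[frozenset[str]]]:
    """Non-trivial unrooted bipartitions of the leaf set."""
    all_leaves = frozenset(str(t.name) for t in tree.tips())
    n = len(all_leaves)
    parts: set[frozenset[frozenset[str]]] = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(str(t.name) for t in node.tips())
        if 2 <= len(side) <= n - 2:
            parts.add(frozenset({side, all_leaves - side}))
    return parts


@dataclass(frozen=True)
class RFResult:
    rf: int
    normalized: float
    n_leaves: int
    shared: int


def compare_trees(t1: TreeLike, t2: TreeLike) -> RFResult:
    """Robinson-Foulds distance between two trees on the same leaf set.

    Counts non-trivial bipartitions present in exactly one tree;
    ``normalized`` divides by the total number of non-trivial
    bipartitions in both trees (0 for identical, 1 for disjoint).
    """
    a, b = _as_skbio_tree(t1), _as_skbio_tree(t2)
    leaves_a = {str(t.name) for t in a.tips()}
    leaves_b = {str(t.name) for t in b.tips()}
    if leaves_a != leaves_b:
        raise ValueError(
            "leaf sets differ: "
            f"only in first={sorted(leaves_a - leaves_b)}, "
            f"only in second={sorted(leaves_b - leaves_a)}"
        )
    pa, pb = _bipartitions(a), _bipartitions(b)
    rf = len(pa ^ pb)
    denom = len(pa) + len(pb)
    return RFResult(rf, rf / denom if denom else 0.0, len(leaves_a), len(pa & pb))
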