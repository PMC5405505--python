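"""Haplotype distances (Bruvo, Jaccard), neighbor-joining trees, locus bootstrap.

Bruvo's distance respects the stepwise mutation model of microsatellites: a
per-locus distance ``1 - 2**(-|x|)`` where ``x`` is the allele-size difference
in repeat units, averaged over the loci observed in both haplotypes.  Since
every haplotype here carries exactly one allele per locus, none of the
polyploid allele-matching machinery is needed.  Jaccard distance is computed
on binary (marker, allele-size) incidence.  Trees are built with the
Saitou-Nei neighbor-joining agglomeration and written as newick, with
bootstrap support from resampling the marker columns.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .germplasm import SSRMarker
from .m_haplotypes import MHaplotype

__all__ = [
    "DistanceMatrix",
    "bruvo_distance",
    "jaccard_distance",
    "distance_matrix",
    "Tree",
    "neighbor_joining",
    "tree_splits",
    "bootstrap_support",
    "NoSharedDataError",
]


class NoSharedDataError(ValueError):
    """Raised when two profiles share no observed loci/alleles."""


def _bruvo_locus(size_a: float, size_b: float, motif: int) -> float:
    x = abs(size_a - size_b) / motif
    x_int = round(x)
    if abs(x - x_int) > 1e-6:
        warnings.warn(
            f"size difference {abs(size_a - size_b)} bp is not an integer "
            f"multiple of the {motif} bp motif; using nearest repeat count "
            f"{x_int}",
            stacklevel=3,
        )
    return 1.0 - 2.0 ** (-x_int)


def bruvo_distance(
    a: MHaplotype, b: MHaplotype, panel: Sequence[SSRMarker]
) -> float:
    """Stepwise-mutation-aware distance in [0, 1] between two haplotypes.

    Missing loci are skipped; the multilocus value is the mean over loci
    observed in both.  No shared observed loci raises
    :class:`NoSharedDataError`.
    """
    if len(a.alleles) != len(panel) or len(b.alleles) != len(panel):
        raise ValueError("haplotypes and marker panel lengths disagree")
    terms = [
        _bruvo_locus(x, y, m.repeat_motif_length)
        for x, y, m in zip(a.alleles, b.alleles, panel)
        if x is not None and y is not None
    ]
    if not terms:
        raise NoSharedDataError(f"{a.label} vs {b.label}: no shared observed loci")
    return float(sum(terms) / len(terms))


def jaccard_distance(a: MHaplotype, b: MHaplotype, panel: Sequence[SSRMarker]) -> float:
    """1 - |A∩B|/|A∪B| on binary (marker, allele-size) incidence."""
    set_a = {
        (m.name, x) for m, x in zip(panel, a.alleles) if x is not None
    }
    set_b = {
        (m.name, x) for m, x in zip(panel, b.alleles) if x is not None
    }
    union = set_a | set_b
    if not union:
        raise NoSharedDataError(f"{a.label} vs {b.label}: both profiles empty")
    return 1.0 - len(set_a & set_b) / len(union)


@dataclass
class DistanceMatrix:
    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValueError("distance matrix shape does not match labels")
        if not np.allclose(v, v.T):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(v), 0.0):
            raise ValueError("distance matrix diagonal is not zero")
        self.values = v

    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(self.values, index=self.labels, columns=self.labels).to_csv(path)


def distance_matrix(
    haplotypes: Sequence[MHaplotype],
    panel: Sequence[SSRMarker],
    metric: str = "bruvo",
) -> DistanceMatrix:
    fn = {"bruvo": bruvo_distance, "jaccard": jaccard_distance}[metric]
    n = len(haplotypes)
    values = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        d = fn(haplotypes[i], haplotypes[j], panel)
        values[i, j] = values[j, i] = d
    return DistanceMatrix([h.label for h in haplotypes], values)


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------

@dataclass
class Tree:
    """An unrooted tree stored as a rooted binary scaffold with branch lengths."""

    label: str | None
    length: float = 0.0
    children: list["Tree"] = field(default_factory=list)
    support: float | None = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.label]
        out = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def to_newick(self, *, with_support: bool = False) -> str:
        return self._newick(with_support) + ";"

    def _newick(self, with_support: bool) -> str:
        if self.is_leaf:
            return f"{self.label}:{self.length:.6g}"
        inner = ",".join(c._newick(with_support) for c in self.children)
        name = ""
        if with_support and self.support is not None:
            name = f"{self.support:.2f}"
        return f"({inner}){name}:{self.length:.6g}"


def neighbor_joining(dm: DistanceMatrix) -> Tree:
    """Saitou-Nei neighbor joining with deterministic tie-breaking.

    Q-criterion agglomeration; ties resolved toward the lowest (i, j) label
    pair index.  Negative branch lengths are clamped to zero with the deficit
    transferred to the sibling branch, preserving path lengths through the
    joined pair.
    """
    n = len(dm.labels)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    if not np.all(np.isfinite(dm.values)):
        raise ValueError(
            "distance matrix has non-finite entries; filter loci with no "
            "shared data before tree building"
        )
    nodes: list[Tree] = [Tree(lbl) for lbl in dm.labels]
    D = dm.values.astype(float).copy()
    active = list(range(n))

    while len(active) > 2:
        m = len(active)
        # Q matrix over active nodes
        sums = {i: sum(D[i, k] for k in active if k != i) for i in active}
        best = None
        for ai in range(m):
            for aj in range(ai + 1, m):
                i, j = active[ai], active[aj]
                q = (m - 2) * D[i, j] - sums[i] - sums[j]
                key = (q, i, j)
                if best is None or key < best:
                    best = key
        _, i, j = best
        dij = D[i, j]
        li = 0.5 * dij + (sums[i] - sums[j]) / (2 * (m - 2))
        lj = dij - li
        # negative-branch adjustment: clamp and transfer to the sibling
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        node_i, node_j = nodes[i], nodes[j]
        node_i.length = li
        node_j.length = lj
        new = Tree(None, children=[node_i, node_j])
        # distances from the new node
        new_idx = D.shape[0]
        D = np.pad(D, ((0, 1), (0, 1)))
        for k in active:
            if k in (i, j):
                continue
            D[new_idx, k] = D[k, new_idx] = 0.5 * (D[i, k] + D[j, k] - dij)
        nodes.append(new)
        active = [k for k in active if k not in (i, j)] + [new_idx]

    i, j = active
    nodes[i].length = 0.0
    nodes[j].length = max(D[i, j], 0.0)
    root = Tree(None, children=[nodes[i], nodes[j]])
    return root


def tree_splits(tree: Tree) -> set[frozenset[str]]:
    """Non-trivial bipartitions of an unrooted tree, as leaf-label sets.

    Each split is canonicalised to the side not containing the first leaf so
    that identical topologies yield identical split sets.
    """
    all_leaves = frozenset(tree.leaves())
    anchor = min(all_leaves)
    splits: set[frozenset[str]] = set()

    def walk(node: Tree):
        if node.is_leaf:
            return frozenset([node.label])
        below = frozenset()
        for c in node.children:
            below |= walk(c)
        if 1 < len(below) < len(all_leaves) - 1:
            side = below if anchor not in below else all_leaves - below
            splits.add(side)
        return below

    walk(tree)
    return splits


def bootstrap_support(
    haplotypes: Sequence[MHaplotype],
    panel: Sequence[SSRMarker],
    *,
    metric: str = "bruvo",
    n_replicates: int = 100,
    seed: int = 0,
) -> tuple[Tree, dict[frozenset[str], float]]:
    """Locus-resampling bootstrap support for the NJ tree.

    Marker columns are resampled with replacement ``n_replicates`` times; the
    support of each split in the original tree is the fraction of replicate
    trees containing it.  Fully reproducible under a fixed seed.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    rng = np.random.default_rng(seed)
    base_dm = distance_matrix(haplotypes, panel, metric)
    base_tree = neighbor_joining(base_dm)
    base_splits = tree_splits(base_tree)
    counts = {s: 0 for s in base_splits}
    n_loci = len(panel)
    for _ in range(n_replicates):
        cols = rng.integers(0, n_loci, size=n_loci)
        resampled = [
            MHaplotype(h.label, tuple(h.alleles[c] for c in cols))
            for h in haplotypes
        ]
        rep_panel = [panel[c] for c in cols]
        rep_tree = neighbor_joining(distance_matrix(resampled, rep_panel, metric))
        rep_splits = tree_splits(rep_tree)
        for s in base_splits:
            if s in rep_splits:
                counts[s] += 1
    support = {s: c / n_replicates for s, c in counts.items()}
    _annotate_support(base_tree, support, frozenset(base_tree.leaves()))
    return base_tree, support


def _annotate_support(tree: Tree, support, all_leaves) -> None:
    anchor = min(all_leaves)

    def walk(node: Tree):
        if node.is_leaf:
            return frozenset([node.label])
        below = frozenset()
        for c in node.children:
            below |= walk(c)
        if 1 < len(below) < len(all_leaves) - 1:
            side = below if anchor not in below else all_leaves - below
            if side in support:
                node.support = support[side]
        return below

    walk(tree)
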