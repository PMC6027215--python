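"""Distance-based phylogenetics: p/JC69 distances with pairwise deletion,
neighbor-joining with the Saitou–Nei Q criterion, nonparametric bootstrap
support, and Newick round-tripping.

Trees are dendropy.Tree objects with an unrooted (trifurcating-root)
convention; bootstrap supports live on internal nodes as both a ``support``
attribute (float, percent) and the node label (so Newick carries them the
conventional way: ``((A,B)97:0.1,C,D);``).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import dendropy
import numpy as np

logger = logging.getLogger(__name__)

_VALID = frozenset(b"ACGT")


@dataclass(frozen=True)
class DistanceMatrix:
    """Labelled symmetric distance matrix with zero diagonal."""

    labels: tuple
    d: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.labels)
        if len(set(self.labels)) != n:
            raise ValueError("duplicate labels")
        if self.d.shape != (n, n):
            raise ValueError("matrix shape does not match label count")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("matrix not symmetric")
        if not np.allclose(np.diag(self.d), 0):
            raise ValueError("nonzero diagonal")
        if (self.d < -1e-12).any():
            raise ValueError("negative distances")

    @property
    def size(self) -> int:
        return len(self.labels)


def p_distance(a: str, b: str) -> float:
    """Proportion of differing sites under pairwise deletion: columns with a
    gap or N in either sequence are excluded."""
    if len(a) != len(b):
        raise ValueError("sequences differ in length")
    compared = diffs = 0
    for ca, cb in zip(a, b):
        if ca in "-N" or cb in "-N":
            continue
        compared += 1
        if ca != cb:
            diffs += 1
    if compared == 0:
        raise ValueError("zero comparable sites")
    return diffs / compared


def jc69(p: float) -> float:
    """Jukes–Cantor distance d = -(3/4) ln(1 - 4p/3); defined for p < 0.75."""
    if not 0 <= p < 0.75:
        raise ValueError(f"JC69 saturated: p={p} outside [0, 0.75)")
    return -0.75 * math.log1p(-4 * p / 3)


def msa_distance_matrix(
    labels: Sequence[str],
    seqs: Sequence[str],
    model: str = "jc69",
    saturation_fallback: bool = True,
) -> DistanceMatrix:
    """All pairwise distances from an aligned set of sequences.

    With ``model="jc69"``, any saturated pair (p >= 0.75) falls back to its
    p-distance and is logged, so bootstrap replicates never abort.
    """
    if model not in ("p", "jc69"):
        raise ValueError(f"unknown distance model {model!r}")
    n = len(labels)
    arr = np.frombuffer("".join(seqs).encode("ascii"), dtype=np.uint8).reshape(n, -1)
    valid = (
        (arr == ord("A")) | (arr == ord("C")) | (arr == ord("G")) | (arr == ord("T"))
    )
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = valid[i] & valid[j]
            compared = int(both.sum())
            if compared == 0:
                raise ValueError(
                    f"zero comparable sites between {labels[i]!r} and {labels[j]!r}"
                )
            p = float((arr[i][both] != arr[j][both]).sum()) / compared
            if model == "p":
                dist = p
            elif p < 0.75:
                dist = jc69(p)
            elif saturation_fallback:
                logger.warning(
                    "JC69 saturated for pair (%s, %s): p=%.3f, using p-distance",
                    labels[i], labels[j], p,
                )
                dist = p
            else:
                raise ValueError(f"saturated pair ({labels[i]}, {labels[j]})")
            d[i, j] = d[j, i] = dist
    return DistanceMatrix(labels=tuple(labels), d=d)


def _clamp_pair(bi: float, bj: float) -> tuple[float, float]:
    # negative branch clamped to 0, deficit shifted to the sibling branch so
    # the path length between the joined nodes is preserved
    if bi < 0:
        bj += bi
        bi = 0.0
    if bj < 0:
        bi += bj
        bj = 0.0
    return max(bi, 0.0), max(bj, 0.0)


def nj(dm: DistanceMatrix) -> dendropy.Tree:
    """Saitou–Nei neighbor joining.

    Joins the pair minimizing Q(i,j) = (n-2) d(i,j) - r_i - r_j (ties broken
    by smallest node-index pair), with the standard branch-length and
    distance-update formulas; ends in a trifurcating root so the result is
    unrooted. Exact on additive matrices.
    """
    if dm.size < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    tns = dendropy.TaxonNamespace()
    nodes: dict[int, dendropy.Node] = {}
    for i, lab in enumerate(dm.labels):
        nodes[i] = dendropy.Node(taxon=tns.new_taxon(label=str(lab)))
    D: dict[tuple[int, int], float] = {}
    for i in range(dm.size):
        for j in range(i + 1, dm.size):
            D[(i, j)] = float(dm.d[i, j])

    def dist(i: int, j: int) -> float:
        return 0.0 if i == j else D[(min(i, j), max(i, j))]

    active = list(range(dm.size))
    next_id = dm.size
    while len(active) > 3:
        m = len(active)
        r = {i: sum(dist(i, k) for k in active) for i in active}
        best: Optional[tuple[float, int, int]] = None
        for x in range(m):
            for y in range(x + 1, m):
                i, j = active[x], active[y]
                cand = ((m - 2) * dist(i, j) - r[i] - r[j], i, j)
                if best is None or cand < best:
                    best = cand
        _, i, j = best
        dij = dist(i, j)
        bi = dij / 2 + (r[i] - r[j]) / (2 * (m - 2))
        bj = dij - bi
        bi, bj = _clamp_pair(bi, bj)
        u = dendropy.Node()
        u.add_child(nodes[i])
        nodes[i].edge.length = bi
        u.add_child(nodes[j])
        nodes[j].edge.length = bj
        nodes[next_id] = u
        for k in active:
            if k in (i, j):
                continue
            D[(k, next_id)] = (dist(i, k) + dist(j, k) - dij) / 2
        active = [k for k in active if k not in (i, j)] + [next_id]
        next_id += 1

    i, j, k = active
    bi = (dist(i, j) + dist(i, k) - dist(j, k)) / 2
    bj = (dist(i, j) + dist(j, k) - dist(i, k)) / 2
    bk = (dist(i, k) + dist(j, k) - dist(i, j)) / 2
    root = dendropy.Node()
    for idx, b in ((i, bi), (j, bj), (k, bk)):
        root.add_child(nodes[idx])
        nodes[idx].edge.length = max(b, 0.0)
    tree = dendropy.Tree(taxon_namespace=tns, seed_node=root)
    tree.is_rooted = False
    return tree


def leaf_labels(tree: dendropy.Tree) -> frozenset:
    return frozenset(lf.taxon.label for lf in tree.leaf_node_iter())


def _canonical(side: frozenset, universe: frozenset) -> frozenset:
    other = universe - side
    return side if tuple(sorted(side)) < tuple(sorted(other)) else other


def bipartitions(tree: dendropy.Tree) -> dict:
    """Canonicalized nontrivial bipartitions of an unrooted tree, mapped to
    the internal node below the defining edge."""
    universe = leaf_labels(tree)
    out = {}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node or node.is_leaf():
            continue
        below = frozenset(lf.taxon.label for lf in node.leaf_iter())
        if 1 < len(below) < len(universe) - 1:
            out[_canonical(below, universe)] = node
    return out


def edge_lengths(tree: dendropy.Tree) -> dict:
    """Branch lengths keyed by what the edge separates: ``("leaf", label)``
    for terminal edges, ``("split", canonical bipartition)`` for internal
    ones. Stable under rerooting, so two unrooted trees compare directly."""
    universe = leaf_labels(tree)
    out: dict = {}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        if node.is_leaf():
            out[("leaf", node.taxon.label)] = node.edge.length or 0.0
        else:
            below = frozenset(lf.taxon.label for lf in node.leaf_iter())
            if 1 < len(below) < len(universe) - 1:
                out[("split", _canonical(below, universe))] = node.edge.length or 0.0
    return out


def is_monophyletic(tree: dendropy.Tree, group: Sequence[str]) -> bool:
    universe = leaf_labels(tree)
    target = _canonical(frozenset(group), universe)
    return target in bipartitions(tree)


def bootstrap_support(
    labels: Sequence[str],
    seqs: Sequence[str],
    n_reps: int = 100,
    seed: int = 0,
    model: str = "jc69",
) -> dendropy.Tree:
    """NJ tree on the full alignment with bootstrap supports.

    Each replicate r resamples alignment columns with replacement using its
    own generator seeded ``seed + r``, rebuilds distances and the NJ tree,
    and contributes its bipartitions; each internal edge of the full tree
    gets support = 100 * (replicates containing its bipartition) / n_reps.
    """
    if len(labels) < 4:
        raise ValueError("bootstrap support needs at least 4 sequences")
    width = len(seqs[0])
    tree = nj(msa_distance_matrix(labels, seqs, model=model))
    counts: dict[frozenset, int] = {}
    for r in range(n_reps):
        rng = np.random.default_rng(seed + r)
        cols = rng.integers(0, width, size=width)
        resampled = ["".join(s[c] for c in cols) for s in seqs]
        rep_tree = nj(msa_distance_matrix(labels, resampled, model=model))
        for bp in bipartitions(rep_tree):
            counts[bp] = counts.get(bp, 0) + 1
    for bp, node in bipartitions(tree).items():
        support = 100.0 * counts.get(bp, 0) / n_reps
        node.support = support
        node.label = f"{support:g}"
    return tree


def to_newick(tree: dendropy.Tree) -> str:
    """Newick with 6-decimal branch lengths and supports as internal-node
    labels, e.g. ``((A:0.1,B:0.1)97:0.2,C:0.1,D:0.1);``."""
    s = tree.as_string(
        schema="newick",
        suppress_rooting=True,
        real_value_format_specifier=".6f",
    )
    return s.strip()


def parse_newick(text: str) -> dendropy.Tree:
    """Parse Newick; numeric internal-node labels become supports."""
    try:
        tree = dendropy.Tree.get(
            data=text, schema="newick", suppress_internal_node_taxa=True
        )
    except Exception as e:  # dendropy raises schema-specific errors
        raise ValueError(f"malformed Newick: {e}") from e
    tree.is_rooted = False
    for node in tree.preorder_node_iter():
        if not node.is_leaf() and node.label:
            try:
                node.support = float(node.label)
            except ValueError:
                pass
    return tree


def total_length(tree: dendropy.Tree) -> float:
    return sum(e.length or 0.0 for e in tree.preorder_edge_iter())
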