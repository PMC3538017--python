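"""Band-sharing distances, neighbor-joining trees and cluster assignment.

Genotype calls at the informative markers (types I, II and IV) are rewritten
as a binary band-presence matrix: every distinct fragment size of a retained
marker is one band, a line scores 1 for each size it carries, and a null
allele scores 0 for all of that marker's bands.  Pairwise genetic distance is
1 minus Jaccard's similarity coefficient on band presence (shared absences
carry no information for dominant band data, so they are ignored).

The tree is built with the classical Saitou-Nei neighbor-joining
agglomeration, which is exact on additive distance matrices; negative branch
lengths are retained (clamping would break additivity) but can be listed or
clamped for display.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from skbio import DistanceMatrix, TreeNode

INFORMATIVE_TYPES = frozenset({"I", "II", "IV"})

from .genotype_typing import (GenotypeTable, MULTIBAND, NULL,
                              classify_marker_type)


@dataclass
class BandMatrix:
    """Lines x bands binary presence matrix; a band is a (marker, value) pair."""

    lines: list[str]
    bands: list[tuple]
    matrix: np.ndarray  # shape (n_lines, n_bands), dtype uint8

    def vector(self, line: str) -> np.ndarray:
        return self.matrix[self.lines.index(line)]


def binarize_bands(table: GenotypeTable,
                   types: Mapping[str, str] | None = None,
                   informative_types: frozenset = INFORMATIVE_TYPES) -> BandMatrix:
    """Score band presence/absence for the informative markers.

    ``types`` maps marker -> type; when omitted it is computed from the
    table.  Monomorphic (III) and excluded (na) markers carry no band
    information and are dropped.
    """
    if types is None:
        types = {m: classify_marker_type(table.column(m)) for m in table.markers}
    kept = [m for m in table.markers if types.get(m) in informative_types]
    bands: list[tuple] = []
    for marker in kept:
        values = {a for call in table.column(marker)
                  if call is not NULL and call is not MULTIBAND for a in call}
        bands.extend((marker, v) for v in
                     sorted(values, key=lambda v: (str(type(v)), v)))
    matrix = np.zeros((len(table.lines), len(bands)), dtype=np.uint8)
    index = {band: j for j, band in enumerate(bands)}
    for i, line in enumerate(table.lines):
        for marker in kept:
            call = table.call(line, marker)
            if call is NULL or call is MULTIBAND:
                continue
            for a in call:
                matrix[i, index[(marker, a)]] = 1
    return BandMatrix(lines=list(table.lines), bands=bands, matrix=matrix)


def jaccard_distance(a: Sequence[int], b: Sequence[int]) -> float:
    """1 - Jaccard similarity between two binary band vectors."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("band vectors differ in length")
    union = int(np.sum(a | b))
    if union == 0:
        raise ValueError("no bands to compare: both vectors are all-zero")
    return 1.0 - int(np.sum(a & b)) / union


def distance_matrix(band: BandMatrix) -> DistanceMatrix:
    """All-pairs 1 - Jaccard distances over a band matrix."""
    A = band.matrix.astype(np.float64)
    if A.shape[1] == 0:
        raise ValueError("no bands to compare: band matrix is empty")
    n11 = A @ A.T
    counts = A.sum(axis=1)
    union = counts[:, None] + counts[None, :] - n11
    off_diag = ~np.eye(len(A), dtype=bool)
    if np.any(union[off_diag] == 0):
        i, j = np.argwhere((union == 0) & off_diag)[0]
        raise ValueError("no bands to compare: lines "
                         f"{band.lines[i]!r} and {band.lines[j]!r} share no bands")
    with np.errstate(invalid="ignore", divide="ignore"):
        d = 1.0 - np.divide(n11, union, out=np.ones_like(n11), where=union > 0)
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0
    return DistanceMatrix(d, ids=band.lines)


# ---------------------------------------------------------------------------
# Neighbor joining

def neighbor_joining(dm: DistanceMatrix) -> TreeNode:
    """Saitou-Nei neighbor joining.

    At each step the pair minimising
    ``Q(i,j) = (m - 2) d(i,j) - sum_k d(i,k) - sum_k d(j,k)`` is joined, with
    ties broken by the smallest (i, j) index pair in the current node order;
    branch lengths follow the standard two-point formulas.  The result is an
    unrooted tree represented with a trifurcating root.  Negative branch
    lengths are retained; see :func:`negative_branches`.
    """
    n = dm.shape[0]
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 leaves")
    nodes: list[TreeNode] = [TreeNode(name=name) for name in dm.ids]
    D = dm.data.astype(np.float64).copy()
    active = list(range(n))

    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Q = (m - 2) * sub - r[:, None] - r[None, :]
        iu = np.triu_indices(m, k=1)
        flat = Q[iu]
        best = int(np.argmin(flat))  # row-major => smallest (i, j) on ties
        ai, aj = iu[0][best], iu[1][best]
        i, j = active[ai], active[aj]
        dij = D[i, j]
        li = 0.5 * dij + (r[ai] - r[aj]) / (2.0 * (m - 2))
        lj = dij - li
        nodes[i].length = li
        nodes[j].length = lj
        parent = TreeNode(children=[nodes[i], nodes[j]])
        # distances from the new node to the remaining active nodes
        new_row = np.zeros(D.shape[0] + 1)
        for ak in active:
            if ak in (i, j):
                continue
            new_row[ak] = 0.5 * (D[i, ak] + D[j, ak] - dij)
        D = np.pad(D, ((0, 1), (0, 1)))
        D[-1, :-1] = new_row[:-1]
        D[:-1, -1] = new_row[:-1]
        nodes.append(parent)
        active = [a for a in active if a not in (i, j)] + [len(nodes) - 1]

    i, j, k = active
    dij, dik, djk = D[i, j], D[i, k], D[j, k]
    nodes[i].length = 0.5 * (dij + dik - djk)
    nodes[j].length = 0.5 * (dij + djk - dik)
    nodes[k].length = 0.5 * (dik + djk - dij)
    return TreeNode(children=[nodes[i], nodes[j], nodes[k]])


def negative_branches(tree: TreeNode) -> list[tuple[str, float]]:
    """Report edges with negative length as (node description, length)."""
    report = []
    for node in tree.traverse(include_self=False):
        if node.length is not None and node.length < 0:
            label = node.name if node.name else \
                "internal({})".format(",".join(sorted(t.name for t in node.tips())))
            report.append((label, float(node.length)))
    return sorted(report)


def clamp_negative_branches(tree: TreeNode) -> TreeNode:
    """Copy of the tree with negative branch lengths set to 0 (display only)."""
    clamped = tree.copy()
    for node in clamped.traverse(include_self=False):
        if node.length is not None and node.length < 0:
            node.length = 0.0
    return clamped


# ---------------------------------------------------------------------------
# Cluster assignment

def _cut_blocks(tree: TreeNode, k: int) -> list[set[str]]:
    tips = list(tree.tips())
    if k > len(tips):
        raise ValueError(f"k={k} exceeds the number of leaves ({len(tips)})")
    internal = [node for node in tree.non_tips(include_self=False)]
    # longest internal branches first; deterministic tie-break by subtree tips
    internal.sort(key=lambda nd: (-(nd.length or 0.0),
                                  min(t.name for t in nd.tips())))
    cut = set(id(nd) for nd in internal[:k - 1])
    blocks: dict[object, set[str]] = {}
    for tip in tips:
        key = "root"
        node = tip.parent
        while node is not None:
            if id(node) in cut:
                key = id(node)
                break
            node = node.parent
        blocks.setdefault(key, set()).add(tip.name)
    return list(blocks.values())


def assign_clusters(tree: TreeNode, k: int | None = None,
                    reference: Mapping[str, str] | None = None,
                    min_size: int = 1) -> dict[str, str]:
    """Partition tree leaves into clusters.

    Two reproducible modes replace by-eye cluster delimitation:

    * fixed ``k``: remove the k-1 longest internal branches and take the
      resulting blocks;
    * with ``reference`` labels, each block is named after the majority
      a-priori label of its lines (ties broken lexicographically); without
      them blocks are named C1, C2, ... in decreasing size order.

    Blocks smaller than ``min_size`` are labelled "N" (not classifiable).
    """
    if k is None:
        raise ValueError("a cluster count k is required")
    blocks = _cut_blocks(tree, k)
    blocks.sort(key=lambda b: (-len(b), min(b)))
    assignment: dict[str, str] = {}
    for idx, block in enumerate(blocks, start=1):
        if len(block) < min_size:
            label = "N"
        elif reference is not None:
            votes: dict[str, int] = {}
            for line in block:
                ref = reference.get(line)
                if ref is not None:
                    votes[ref] = votes.get(ref, 0) + 1
            label = min((lbl for lbl, v in votes.items()
                         if v == max(votes.values())), default="N")
        else:
            label = f"C{idx}"
        for line in block:
            assignment[line] = label
    return assignment
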