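"""Pairwise p-distance with pairwise deletion, and neighbour-joining.

The distance between two aligned rows is the fraction of differing sites
over the columns where both rows carry unambiguous residues; ambiguous or
gapped columns are removed per pair, not globally.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["DistanceMatrix", "TreeNode", "p_distance", "p_distance_protein",
           "distance_matrix", "neighbor_joining", "write_newick",
           "UndefinedDistanceError"]

_DNA = frozenset("ACGT")
_AA = frozenset("ACDEFGHIKLMNPQRSTVWY")


class UndefinedDistanceError(ValueError):
    pass


def p_distance(row_a: str, row_b: str) -> tuple[float | None, int]:
    """(substitutions per compared site, compared sites); ``None`` distance
    when no column is comparable."""
    if len(row_a) != len(row_b):
        raise ValueError("rows differ in length")
    a, b = row_a.upper(), row_b.upper()
    diffs = sites = 0
    for x, y in zip(a, b):
        if x in _DNA and y in _DNA:
            sites += 1
            if x != y:
                diffs += 1
    return (diffs / sites if sites else None), sites


def p_distance_protein(row_a: str, row_b: str) -> tuple[float | None, int]:
    """Protein-mode equivalent: fraction of differing amino acids over
    pairwise-deleted columns."""
    if len(row_a) != len(row_b):
        raise ValueError("rows differ in length")
    diffs = sites = 0
    for x, y in zip(row_a.upper(), row_b.upper()):
        if x in _AA and y in _AA:
            sites += 1
            if x != y:
                diffs += 1
    return (diffs / sites if sites else None), sites


@dataclass
class DistanceMatrix:
    labels: list[str]
    values: np.ndarray              # symmetric, zero diagonal
    site_counts: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("matrix not symmetric")
        if np.any(np.diag(self.values) != 0):
            raise ValueError("nonzero diagonal")

    def to_phylip(self) -> str:
        rows = [str(len(self.labels))]
        for lbl, row in zip(self.labels, self.values):
            rows.append("\t".join([lbl] + [f"{v:.6f}" for v in row]))
        return "\n".join(rows) + "\n"


def distance_matrix(rows: dict[str, str], protein: bool = False) -> DistanceMatrix:
    """All-pairs p-distance over an aligned set of rows."""
    dist_fn = p_distance_protein if protein else p_distance
    labels = sorted(rows)
    n = len(labels)
    values = np.zeros((n, n))
    counts = np.zeros((n, n), dtype=int)
    for i in range(n):
        for j in range(i + 1, n):
            d, sites = dist_fn(rows[labels[i]], rows[labels[j]])
            if d is None:
                raise UndefinedDistanceError(
                    f"no comparable sites between {labels[i]!r} and {labels[j]!r}")
            values[i, j] = values[j, i] = d
            counts[i, j] = counts[j, i] = sites
    return DistanceMatrix(labels, values, counts)


@dataclass
class TreeNode:
    label: str | None = None
    children: list[tuple["TreeNode", float]] = field(default_factory=list)

    def is_leaf(self) -> bool:
        return not self.children

    def leaf_labels(self) -> list[str]:
        if self.is_leaf():
            return [self.label]
        out = []
        for child, _ in self.children:
            out.extend(child.leaf_labels())
        return out


def neighbor_joining(matrix: DistanceMatrix) -> TreeNode:
    """Saitou-Nei agglomeration on the Q criterion.

    Deterministic: Q ties resolve to the lexicographically smallest pair of
    cluster names (a cluster is named after its smallest leaf).  Negative
    inferred branch lengths are clamped to zero with the deficit moved to
    the sibling branch.  The returned tree is unrooted, represented with a
    trifurcation at the final join.
    """
    n = len(matrix.labels)
    if n < 3:
        raise ValueError("neighbour-joining needs at least 3 labels")
    if np.any(~np.isfinite(matrix.values)):
        bad = np.argwhere(~np.isfinite(matrix.values))[0]
        raise UndefinedDistanceError(
            f"undefined distance between {matrix.labels[bad[0]]!r} "
            f"and {matrix.labels[bad[1]]!r}")
    nodes: dict[str, TreeNode] = {
        lbl: TreeNode(lbl) for lbl in matrix.labels}
    dist: dict[frozenset, float] = {}
    for i, a in enumerate(matrix.labels):
        for j in range(i + 1, n):
            dist[frozenset([a, matrix.labels[j]])] = matrix.values[i, j]

    active = sorted(nodes)
    while len(active) > 3:
        r = len(active)
        totals = {a: sum(dist[frozenset([a, b])] for b in active if b != a)
                  for a in active}
        best = None
        for i, a in enumerate(active):
            for b in active[i + 1:]:
                q = (r - 2) * dist[frozenset([a, b])] - totals[a] - totals[b]
                key = (q, a, b)
                if best is None or key < best:
                    best = key
        _, a, b = best
        d_ab = dist[frozenset([a, b])]
        la = d_ab / 2 + (totals[a] - totals[b]) / (2 * (r - 2))
        lb = d_ab - la
        if la < 0:
            lb += la
            la = 0.0
        if lb < 0:
            la += lb
            lb = 0.0
        parent = TreeNode(children=[(nodes[a], la), (nodes[b], lb)])
        new_name = min(a, b)
        for c in active:
            if c in (a, b):
                continue
            d_new = (dist[frozenset([a, c])] + dist[frozenset([b, c])] - d_ab) / 2
            dist[frozenset([new_name, c])] = max(0.0, d_new)
        active = sorted(set(active) - {a, b} | {new_name})
        nodes[new_name] = parent

    a, b, c = active
    d_ab = dist[frozenset([a, b])]
    d_ac = dist[frozenset([a, c])]
    d_bc = dist[frozenset([b, c])]
    la = max(0.0, (d_ab + d_ac - d_bc) / 2)
    lb = max(0.0, (d_ab + d_bc - d_ac) / 2)
    lc = max(0.0, (d_ac + d_bc - d_ab) / 2)
    return TreeNode(children=[(nodes[a], la), (nodes[b], lb), (nodes[c], lc)])


def _quote(label: str) -> str:
    if any(ch in label for ch in " ()[]':;,"):
        return "'" + label.replace("'", "''") + "'"
    return label


def write_newick(tree: TreeNode) -> str:
    def fmt(node: TreeNode) -> str:
        if node.is_leaf():
            return _quote(node.label)
        inner = ",".join(f"{fmt(child)}:{length:.10g}"
                         for child, length in node.children)
        return f"({inner})"
    return fmt(tree) + ";"
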