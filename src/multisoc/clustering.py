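"""Agglomerative clustering of units on association similarity.

Clustering is run directly on the similarity (AI) scale: at each step the
two most-similar clusters merge and the merge height is recorded as that
similarity, so the field-standard clan cut (AI >= 0.05) applies directly to
merge heights. Average, complete and single linkage are computed on
similarities; Ward's method uses the standard Lance-Williams recurrence on
the equivalent distance d = 1 - ai (without checking Euclidean
embeddability, mirroring common practice) and its heights are mapped back to
the similarity scale as 1 - d, which may fall below 0 for late Ward merges.

Linkage choice follows the cophenetic correlation coefficient (CCC): the
Pearson correlation between observed dyadic AIs and the cophenetic
similarity implied by the tree (the height of the dyad's lowest common
merge). Merge-order ties break lexicographically for determinism.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import adjusted_rand_score

from .association import AssociationMatrix

LINKAGES = ("average", "ward", "complete", "single")

__all__ = [
    "ClusterTree",
    "ClanPartition",
    "build_tree",
    "cophenetic_matrix",
    "cophenetic_correlation",
    "select_linkage",
    "cut_clans",
    "compare_partitions",
    "LINKAGES",
]


@dataclass(frozen=True)
class Merge:
    left: int  # node id (leaf ids 0..n-1, internal ids n, n+1, ...)
    right: int
    height: float  # similarity (AI scale)
    size: int  # leaves under this merge


class ClusterTree:
    """Agglomerative merge tree over units with heights on the AI scale."""

    def __init__(self, leaves: list[str], merges: list[Merge], linkage: str):
        if len(merges) != len(leaves) - 1:
            raise ValueError("a tree over n leaves needs exactly n-1 merges")
        self.leaves = list(leaves)
        self.merges = list(merges)
        self.linkage = linkage

    def __repr__(self):
        return f"ClusterTree(n={len(self.leaves)}, linkage={self.linkage!r})"

    def leaf_sets(self) -> list[frozenset]:
        """Leaf set under every node id (leaves then internal merges)."""
        n = len(self.leaves)
        sets: list[frozenset] = [frozenset({i}) for i in range(n)]
        for m in self.merges:
            sets.append(sets[m.left] | sets[m.right])
        return sets

    def to_newick(self) -> str:
        """Newick string on the similarity scale: leaves sit at similarity 1,
        merges at their AI heights; a branch length is the similarity drop
        from child to parent (can be negative for non-monotone Ward trees)."""
        n = len(self.leaves)

        def node(i: int, parent_h: float) -> str:
            if i < n:
                return f"{self.leaves[i]}:{1.0 - parent_h:.6g}"
            m = self.merges[i - n]
            inner = f"{node(m.left, m.height)},{node(m.right, m.height)}"
            return f"({inner}):{m.height - parent_h:.6g}"

        root = self.merges[-1]
        return f"({node(root.left, root.height)},{node(root.right, root.height)}):0;"

    def to_merge_table(self):
        import pandas as pd

        return pd.DataFrame(
            [(m.left, m.right, m.height, m.size) for m in self.merges],
            columns=["left", "right", "height_ai", "size"],
        )


@dataclass(frozen=True)
class ClanPartition:
    """Unit -> clan label assignment from a threshold cut."""

    assignment: dict
    cutoff: float

    def labels(self, units: list[str]) -> list:
        return [self.assignment[u] for u in units]

    def clans(self) -> dict:
        out: dict = {}
        for unit, clan in self.assignment.items():
            out.setdefault(clan, set()).add(unit)
        return out


def _linkage_similarity(s_ab, s_a_c, s_b_c, na, nb, nc, d_ab, linkage):
    """Similarity between merged cluster (A u B) and C per linkage rule."""
    if linkage == "average":
        return (na * s_a_c + nb * s_b_c) / (na + nb)
    if linkage == "complete":  # least-similar cross pair
        return min(s_a_c, s_b_c)
    if linkage == "single":  # most-similar cross pair
        return max(s_a_c, s_b_c)
    if linkage == "ward":
        # Lance-Williams on d = 1 - s
        d_ac, d_bc = 1.0 - s_a_c, 1.0 - s_b_c
        n = na + nb + nc
        d = ((na + nc) * d_ac + (nb + nc) * d_bc - nc * d_ab) / n
        return 1.0 - d
    raise ValueError(f"unknown linkage {linkage!r}")


def build_tree(matrix: AssociationMatrix, linkage: str = "average") -> ClusterTree:
    """Agglomerate units on the AI similarity matrix.

    Undefined dyads enter as similarity 0. Ties in the merge criterion are
    broken by the lexicographically smallest pair of cluster name sets.
    """
    if linkage not in LINKAGES:
        raise ValueError(f"linkage must be one of {LINKAGES}")
    units = matrix.units
    n = len(units)
    if n < 2:
        raise ValueError("need at least 2 units to cluster")
    sim = matrix.filled(0.0).astype(float)

    # active clusters: id -> (node id, size, min unit name for tie-breaks)
    active = {i: (i, 1, units[i]) for i in range(n)}
    simmap = {(min(i, j), max(i, j)): sim[i, j] for i in range(n) for j in range(i + 1, n)}
    merges: list[Merge] = []
    next_id = n
    while len(active) > 1:
        best = None
        for (i, j), s in simmap.items():
            key = (-s, min(active[i][2], active[j][2]), max(active[i][2], active[j][2]))
            if best is None or key < best[0]:
                best = (key, i, j, s)
        _, i, j, s = best
        node_i, size_i, name_i = active[i]
        node_j, size_j, name_j = active[j]
        merges.append(Merge(node_i, node_j, float(s), size_i + size_j))
        # fold j into i
        for k in list(active):
            if k in (i, j):
                continue
            s_ic = simmap.pop((min(i, k), max(i, k)))
            s_jc = simmap.pop((min(j, k), max(j, k)))
            size_k = active[k][1]
            simmap[(min(i, k), max(i, k))] = _linkage_similarity(
                s, s_ic, s_jc, size_i, size_j, size_k, 1.0 - s, linkage
            )
        simmap.pop((min(i, j), max(i, j)))
        active[i] = (next_id, size_i + size_j, min(name_i, name_j))
        del active[j]
        next_id += 1
    return ClusterTree(list(units), merges, linkage)


def cophenetic_matrix(tree: ClusterTree) -> np.ndarray:
    """Cophenetic similarity: for each dyad, the height of the lowest merge
    joining the two leaves (diagonal NaN)."""
    n = len(tree.leaves)
    out = np.full((n, n), np.nan)
    sets = tree.leaf_sets()
    # each dyad is a cross pair of exactly one merge: its lowest common merge
    for m in tree.merges:
        for i in sets[m.left]:
            for j in sets[m.right]:
                out[i, j] = out[j, i] = m.height
    return out


def cophenetic_correlation(tree: ClusterTree, matrix: AssociationMatrix) -> float:
    """Pearson correlation between dyadic AI and cophenetic similarity over
    defined dyads; NaN flags a degenerate (zero-variance) input."""
    if list(tree.leaves) != list(matrix.units):
        raise ValueError("tree leaves must match matrix roster (same order)")
    coph = cophenetic_matrix(tree)
    iu = np.triu_indices(len(tree.leaves), k=1)
    ai = matrix.ai[iu]
    ch = coph[iu]
    ok = np.isfinite(ai)
    if ok.sum() < 3:
        raise ValueError("need at least 3 defined dyads for a CCC")
    ai, ch = ai[ok], ch[ok]
    if np.ptp(ai) == 0 or np.ptp(ch) == 0:
        return float("nan")
    return float(np.corrcoef(ai, ch)[0, 1])


def select_linkage(matrix: AssociationMatrix) -> tuple[str, dict]:
    """Fit all four linkages and pick the one with the highest CCC.

    Ties break in the fixed order average, ward, complete, single. Returns
    the chosen linkage and the full CCC table.
    """
    if len(matrix) < 3:
        raise ValueError("need at least 3 units to compare linkages")
    table: dict = {}
    for linkage in LINKAGES:
        tree = build_tree(matrix, linkage)
        table[linkage] = cophenetic_correlation(tree, matrix)
    best = max(
        LINKAGES,
        key=lambda lk: (np.nan_to_num(table[lk], nan=-np.inf), -LINKAGES.index(lk)),
    )
    return best, table


def cut_clans(tree: ClusterTree, cutoff: float = 0.05) -> ClanPartition:
    """Cut the tree at an AI threshold: units joined by merges at height >=
    cutoff share a clan; singletons allowed.

    Clans are labelled C1, C2, ... in order of their lexicographically
    smallest member.
    """
    if not 0 < cutoff < 1:
        raise ValueError("cutoff must lie in (0, 1)")
    n = len(tree.leaves)
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    sets = tree.leaf_sets()
    for m in tree.merges:
        if m.height >= cutoff:
            roots = {find(i) for i in sets[m.left] | sets[m.right]}
            first = min(roots)
            for r in roots:
                parent[r] = first
    groups: dict = {}
    for i, unit in enumerate(tree.leaves):
        groups.setdefault(find(i), []).append(unit)
    ordered = sorted(groups.values(), key=lambda g: min(g))
    assignment = {u: f"C{k + 1}" for k, group in enumerate(ordered) for u in group}
    return ClanPartition(assignment, cutoff)


def compare_partitions(
    p1: ClanPartition, p2: ClanPartition
) -> tuple[float, list[str]]:
    """Adjusted Rand index over shared units plus the units whose clan
    co-membership profile changed (e.g., a unit that switched clans)."""
    shared = sorted(set(p1.assignment) & set(p2.assignment))
    if not shared:
        raise ValueError("partitions share no units")
    ari = float(adjusted_rand_score(p1.labels(shared), p2.labels(shared)))

    # movers: greedily remove the unit with most pairwise co-membership
    # disagreements until the restricted partitions agree, so a single
    # switched unit is reported alone rather than dragging its clanmates in
    def disagreements(pool: list[str]) -> dict:
        counts = {u: 0 for u in pool}
        for a_i, a in enumerate(pool):
            for b in pool[a_i + 1 :]:
                same1 = p1.assignment[a] == p1.assignment[b]
                same2 = p2.assignment[a] == p2.assignment[b]
                if same1 != same2:
                    counts[a] += 1
                    counts[b] += 1
        return counts

    pool = list(shared)
    moved: list[str] = []
    while True:
        counts = disagreements(pool)
        worst = max(counts.values(), default=0)
        if worst == 0:
            break
        culprit = min(u for u, c in counts.items() if c == worst)
        moved.append(culprit)
        pool.remove(culprit)
    return ari, sorted(moved)
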