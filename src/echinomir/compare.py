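"""Cross-species comparison: set overlaps, expression clustering,
ortholog mutation categories.

Venn arithmetic over conserved-miRNA name sets; average-linkage
(UPGMA-style) hierarchical clustering of log2 relative-abundance rows
under Euclidean distance, with missing cells handled by
pairwise-complete rescaled distances; and classification of ortholog
triples (two echinoderms + an outgroup) into presence/identity
categories A, B, C, D1, D2, E, F, where a substitution at the last
base and short 3'-terminal length differences are not treated as
sequence changes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "VennResult",
    "overlap_sets",
    "Dendrogram",
    "upgma_cluster",
    "to_newick",
    "OrthologRecord",
    "classify_ortholog",
    "align_3prime_tolerant",
]


# ---------------------------------------------------------------------------
# Venn overlaps


@dataclass
class VennResult:
    regions: dict[str, set]
    union: set

    @property
    def region_counts(self) -> dict[str, int]:
        return {k: len(v) for k, v in self.regions.items()}

    @property
    def union_size(self) -> int:
        return len(self.union)


def overlap_sets(
    set_a: set, set_b: set, set_c: Optional[set] = None
) -> VennResult:
    """Exact Venn-region cardinalities and member lists for 2 or 3 sets."""
    a, b = set(set_a), set(set_b)
    if set_c is None:
        regions = {
            "a_only": a - b,
            "b_only": b - a,
            "ab": a & b,
        }
        return VennResult(regions, a | b)
    c = set(set_c)
    regions = {
        "a_only": a - b - c,
        "b_only": b - a - c,
        "c_only": c - a - b,
        "ab": (a & b) - c,
        "ac": (a & c) - b,
        "bc": (b & c) - a,
        "abc": a & b & c,
    }
    return VennResult(regions, a | b | c)


# ---------------------------------------------------------------------------
# Average-linkage clustering


@dataclass
class Dendrogram:
    """Binary merge tree over matrix rows.

    Nodes 0..n-1 are leaves; node n+k is created by ``merges[k]``.
    Heights are average-linkage distances and are non-decreasing.
    """

    n_leaves: int
    merges: list[tuple[int, int, float]] = field(default_factory=list)
    labels: list[str] = field(default_factory=list)

    def leaf_order(self) -> list[int]:
        """Depth-first left-to-right leaf ordering."""
        if not self.merges:
            return list(range(self.n_leaves))
        order: list[int] = []
        stack = [self.n_leaves + len(self.merges) - 1]
        while stack:
            node = stack.pop()
            if node < self.n_leaves:
                order.append(node)
            else:
                left, right, _ = self.merges[node - self.n_leaves]
                stack.append(right)
                stack.append(left)
        return order


def _pairwise_complete_distances(matrix: np.ndarray) -> np.ndarray:
    """Euclidean distances over shared (non-missing) dimensions.

    Squared distances over the d shared dimensions are rescaled by D/d
    (D = total dimensions) so rows with few shared samples are not
    artificially close. A pair with no shared dimension is an error.
    """
    n, total_dim = matrix.shape
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            mask = ~(np.isnan(matrix[i]) | np.isnan(matrix[j]))
            used = int(mask.sum())
            if used == 0:
                raise ValueError(
                    f"rows {i} and {j} share no observed samples; "
                    "distance undefined"
                )
            sq = float(np.sum((matrix[i, mask] - matrix[j, mask]) ** 2))
            dist[i, j] = dist[j, i] = math.sqrt(sq * total_dim / used)
    return dist


def upgma_cluster(
    matrix: pd.DataFrame | np.ndarray,
) -> tuple[Dendrogram, list[int]]:
    """Average-linkage hierarchical clustering of matrix rows.

    At every step the pair of clusters X, Y minimising
    d(X, Y) = (1 / (|X| |Y|)) * sum_{i in X} sum_{j in Y} d(x_i, x_j)
    is merged, with d the (pairwise-complete) Euclidean distance between
    row vectors. Ties are broken toward the pair whose smallest original
    row indices sort first. Returns the merge tree and the depth-first
    leaf order for heat-map row arrangement.
    """
    if isinstance(matrix, pd.DataFrame):
        labels = [str(x) for x in matrix.index]
        values = matrix.to_numpy(dtype=float)
    else:
        values = np.asarray(matrix, dtype=float)
        labels = [str(i) for i in range(values.shape[0])]
    n = values.shape[0]
    if n < 2:
        raise ValueError("clustering needs at least 2 rows")
    base = _pairwise_complete_distances(values)

    # Lance-Williams update for average linkage:
    # d(k, i+j) = (|i| d(k,i) + |j| d(k,j)) / (|i| + |j|)
    size: dict[int, int] = {i: 1 for i in range(n)}
    leader: dict[int, int] = {i: i for i in range(n)}  # smallest original row
    dist: dict[frozenset, float] = {
        frozenset((i, j)): base[i, j] for i in range(n) for j in range(i + 1, n)
    }
    dendro = Dendrogram(n_leaves=n, labels=labels)
    active = list(range(n))
    next_id = n
    while len(active) > 1:
        best_pair: tuple[int, int] | None = None
        best_dist = math.inf
        best_key: tuple[int, int] | None = None
        for ai in range(len(active)):
            for aj in range(ai + 1, len(active)):
                x, y = active[ai], active[aj]
                d = dist[frozenset((x, y))]
                key = tuple(sorted((leader[x], leader[y])))
                if d < best_dist - 1e-12 or (
                    abs(d - best_dist) <= 1e-12 and key < best_key
                ):
                    best_dist = d
                    best_pair = (x, y)
                    best_key = key
        x, y = best_pair
        # left child = the cluster containing the smaller original row
        if leader[x] > leader[y]:
            x, y = y, x
        dendro.merges.append((x, y, best_dist))
        active = [a for a in active if a not in (x, y)]
        for k in active:
            dist[frozenset((k, next_id))] = (
                size[x] * dist[frozenset((k, x))] + size[y] * dist[frozenset((k, y))]
            ) / (size[x] + size[y])
        size[next_id] = size[x] + size[y]
        leader[next_id] = min(leader[x], leader[y])
        active.append(next_id)
        next_id += 1
    return dendro, dendro.leaf_order()


def _node_height(dendro: Dendrogram, node: int) -> float:
    return 0.0 if node < dendro.n_leaves else dendro.merges[node - dendro.n_leaves][2]


def to_newick(dendro: Dendrogram) -> str:
    """Serialize a dendrogram as Newick; branch length of a child is the
    difference between its parent's and its own merge height."""

    def render(node: int, parent_height: float) -> str:
        height = _node_height(dendro, node)
        branch = max(parent_height - height, 0.0)
        if node < dendro.n_leaves:
            label = dendro.labels[node] if dendro.labels else str(node)
            return f"{label}:{branch:.6g}"
        left, right, _ = dendro.merges[node - dendro.n_leaves]
        return f"({render(left, height)},{render(right, height)}):{branch:.6g}"

    root = dendro.n_leaves + len(dendro.merges) - 1
    root_height = _node_height(dendro, root)
    left, right, _ = dendro.merges[root - dendro.n_leaves]
    return f"({render(left, root_height)},{render(right, root_height)});"


# ---------------------------------------------------------------------------
# Ortholog mutation categories


@dataclass
class OrthologRecord:
    gene: str
    seq_species1: Optional[str]
    seq_species2: Optional[str]
    seq_outgroup: Optional[str]
    category: str
    internal_substitutions: dict[str, int] = field(default_factory=dict)
    terminal_3prime_diff: dict[str, int] = field(default_factory=dict)


def align_3prime_tolerant(
    a: str, b: str, free_end: int = 3
) -> tuple[int, int, bool]:
    """Global ungapped-core alignment of two mature miRNAs.

    Needleman-Wunsch with match +1, mismatch -1, gap -2; gaps at the 3'
    terminus are free for up to ``free_end`` nt and reported separately
    as the terminal 3' length difference. Returns (internal
    substitutions excluding the final aligned base, terminal 3'
    difference, effectively identical). A substitution at the final
    aligned base is not treated as a change; internal gaps count as
    changes.
    """
    na, nb = len(a), len(b)
    GAP = -2.0
    F = np.full((na + 1, nb + 1), -math.inf)
    F[0, 0] = 0.0
    for i in range(1, na + 1):
        F[i, 0] = GAP * i  # 5' end gaps are penalised: miRNA 5' ends are fixed
    for j in range(1, nb + 1):
        F[0, j] = GAP * j
    for i in range(1, na + 1):
        for j in range(1, nb + 1):
            sub = F[i - 1, j - 1] + (1.0 if a[i - 1] == b[j - 1] else -1.0)
            F[i, j] = max(sub, F[i - 1, j] + GAP, F[i, j - 1] + GAP)

    # free trailing gaps up to free_end nt: the alignment may end on the
    # last row or column, the dangling tail costing nothing if short
    best = (-math.inf, na, nb)
    for i in range(na, -1, -1):
        tail = na - i
        cost = 0.0 if tail <= free_end else GAP * (tail - free_end)
        if F[i, nb] + cost > best[0]:
            best = (F[i, nb] + cost, i, nb)
    for j in range(nb, -1, -1):
        tail = nb - j
        cost = 0.0 if tail <= free_end else GAP * (tail - free_end)
        if F[na, j] + cost > best[0]:
            best = (F[na, j] + cost, na, j)
    _, ei, ej = best
    terminal_diff = (na - ei) + (nb - ej)

    # traceback of the aligned core
    i, j = ei, ej
    columns: list[tuple[Optional[str], Optional[str]]] = []
    while i > 0 or j > 0:
        if i > 0 and j > 0:
            sub = F[i - 1, j - 1] + (1.0 if a[i - 1] == b[j - 1] else -1.0)
            if math.isclose(F[i, j], sub):
                columns.append((a[i - 1], b[j - 1]))
                i, j = i - 1, j - 1
                continue
        if i > 0 and math.isclose(F[i, j], F[i - 1, j] + GAP):
            columns.append((a[i - 1], None))
            i -= 1
            continue
        columns.append((None, b[j - 1]))
        j -= 1
    columns.reverse()

    substitutions = 0
    internal_gaps = 0
    for idx, (ca, cb) in enumerate(columns):
        last = idx == len(columns) - 1 and terminal_diff == 0
        if ca is None or cb is None:
            internal_gaps += 1
        elif ca != cb and not last:
            substitutions += 1
    changes = substitutions + internal_gaps
    identical = changes == 0 and terminal_diff <= free_end
    return changes, terminal_diff, identical


def classify_ortholog(
    gene: str,
    seq_species1: Optional[str],
    seq_species2: Optional[str],
    seq_outgroup: Optional[str] = None,
    free_end: int = 3,
) -> OrthologRecord:
    """Assign an ortholog triple to a mutation category.

    A: present in all three, all effectively identical. B: present in
    all three, all pairwise different. C: present in all three with at
    least one mutated lineage. D1: present and identical in the two
    ingroup species only. D2: present and identical in one ingroup
    species and the outgroup only. E: present in exactly two species
    with sequence differences. F: present in one species.
    """
    seqs = {
        "species1": seq_species1,
        "species2": seq_species2,
        "outgroup": seq_outgroup,
    }
    norm = {
        k: (v.upper().replace("U", "T") if v else None) for k, v in seqs.items()
    }
    present = [k for k, v in norm.items() if v]
    if not present:
        raise ValueError(f"gene {gene!r}: no sequence present in any species")

    record = OrthologRecord(
        gene,
        norm["species1"],
        norm["species2"],
        norm["outgroup"],
        category="",
    )
    ident: dict[tuple[str, str], bool] = {}
    for i, ka in enumerate(present):
        for kb in present[i + 1 :]:
            changes, tdiff, same = align_3prime_tolerant(
                norm[ka], norm[kb], free_end
            )
            ident[(ka, kb)] = same
            record.internal_substitutions[f"{ka}/{kb}"] = changes
            record.terminal_3prime_diff[f"{ka}/{kb}"] = tdiff

    if len(present) == 3:
        same_flags = list(ident.values())
        if all(same_flags):
            record.category = "A"
        elif not any(same_flags):
            record.category = "B"
        else:
            record.category = "C"
    elif len(present) == 2:
        same = next(iter(ident.values()))
        if same:
            record.category = "D1" if "outgroup" not in present else "D2"
        else:
            record.category = "E"
    else:
        record.category = "F"
    return record
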