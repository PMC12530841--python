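"""Distance matrices, UPGMA dendrograms, PCoA, and synonym/homonym detection.

The default individual-level genetic distance is allele sharing:
GD(x, y) = 1 - mean over loci of (shared allele copies / 2), counting
multiplicity, so GD = 0 exactly when two accessions carry identical
multilocus genotypes -- the criterion used to flag synonymous (duplicate)
accessions.  Nei's (1972) standard distance is offered as an alternative,
treating each individual as a two-copy population; it is degenerate (infinite)
for pairs sharing no alleles and is intended for exploratory use only.

UPGMA merges the closest pair of clusters by average linkage; node height is
half the between-cluster average distance, so trees are ultrametric.  Ties
are broken deterministically by the lexicographically smallest pair of
minimum leaf labels.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .ssr import MISSING, GenotypeMatrix
from .traits import TraitTable
from .core_selection import standardize_traits

__all__ = [
    "DistanceMatrix",
    "Dendrogram",
    "TreeNode",
    "DuplicateReport",
    "HomonymReport",
    "genetic_distance_matrix",
    "trait_distance_matrix",
    "upgma",
    "write_newick",
    "cut_clusters",
    "find_duplicates",
    "find_homonyms",
    "genotype_pca",
]


@dataclass
class DistanceMatrix:
    ids: list[str]
    d: np.ndarray
    method: str

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.ids)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape must match ids")
        if not np.allclose(self.d, self.d.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.d), 0.0):
            raise ValueError("distance matrix diagonal must be zero")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.d, index=self.ids, columns=self.ids)

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path)

    def write_phylip(self, path) -> None:
        """Lower-triangle PHYLIP distance format."""
        with open(path, "w") as fh:
            fh.write(f"{len(self.ids)}\n")
            for i, name in enumerate(self.ids):
                row = " ".join(f"{self.d[i, j]:.6f}" for j in range(i))
                fh.write(f"{name}\t{row}\n".rstrip() + "\n")


@dataclass
class TreeNode:
    """Node of an ultrametric merge tree; leaves have height 0."""

    height: float = 0.0
    label: str | None = None
    children: tuple["TreeNode", ...] = ()

    def leaves(self) -> list[str]:
        if not self.children:
            return [self.label]
        out: list[str] = []
        for c in self.children:
            out.extend(c.leaves())
        return out


@dataclass
class Dendrogram:
    root: TreeNode

    def leaves(self) -> list[str]:
        return self.root.leaves()

    def internal_heights(self) -> list[float]:
        out: list[float] = []

        def walk(node: TreeNode) -> None:
            if node.children:
                out.append(node.height)
                for c in node.children:
                    walk(c)

        walk(self.root)
        return out


@dataclass
class DuplicateReport:
    groups: list[list[str]]       # duplicate groups of size >= 2
    n_total: int
    n_distinct: int
    n_redundant: int
    threshold: float


@dataclass
class HomonymReport:
    name_groups: dict[str, list[str]]
    flagged: dict[str, float] = field(default_factory=dict)  # name -> max pairwise GD


def _shared_copies(x1, x2, y1, y2) -> int:
    """Multiset intersection size of allele pairs {x1,x2} and {y1,y2} (pairs sorted)."""
    if x1 == y1 and x2 == y2:
        return 2
    if x1 == y1 or x1 == y2 or x2 == y1 or x2 == y2:
        return 1
    return 0


def genetic_distance_matrix(gm: GenotypeMatrix, method: str = "allele_share") -> DistanceMatrix:
    """Pairwise genetic distances between accessions over jointly typed loci."""
    n = gm.n
    if n < 2:
        raise ValueError("need >= 2 accessions")
    d = np.zeros((n, n))
    a1, a2 = gm.a1, gm.a2
    if method == "allele_share":
        for i in range(n):
            for j in range(i + 1, n):
                both = (a1[i] != MISSING) & (a1[j] != MISSING)
                L = int(both.sum())
                if L == 0:
                    raise ValueError(
                        f"no jointly typed loci for {gm.accessions[i]} and {gm.accessions[j]}")
                shared = sum(_shared_copies(a1[i, k], a2[i, k], a1[j, k], a2[j, k])
                             for k in np.flatnonzero(both))
                d[i, j] = d[j, i] = 1.0 - shared / (2.0 * L)
    elif method == "nei_individual":
        for i in range(n):
            for j in range(i + 1, n):
                both = (a1[i] != MISSING) & (a1[j] != MISSING)
                if not both.any():
                    raise ValueError(
                        f"no jointly typed loci for {gm.accessions[i]} and {gm.accessions[j]}")
                jxy = jx = jy = 0.0
                for k in np.flatnonzero(both):
                    x = {a1[i, k]: 0.5, a2[i, k]: 0.5} if a1[i, k] != a2[i, k] else {a1[i, k]: 1.0}
                    y = {a1[j, k]: 0.5, a2[j, k]: 0.5} if a1[j, k] != a2[j, k] else {a1[j, k]: 1.0}
                    jx += sum(v * v for v in x.values())
                    jy += sum(v * v for v in y.values())
                    jxy += sum(x[al] * y.get(al, 0.0) for al in x)
                d[i, j] = d[j, i] = (math.inf if jxy == 0.0
                                     else -math.log(jxy / math.sqrt(jx * jy)))
    else:
        raise ValueError(f"unknown method {method!r}")
    return DistanceMatrix(ids=list(gm.accessions), d=d, method=method)


def trait_distance_matrix(table: TraitTable) -> DistanceMatrix:
    """Euclidean distance on standardized graded codes (invariant traits dropped)."""
    z, _ = standardize_traits(table)
    d = squareform(pdist(z.to_numpy(), metric="euclidean"))
    return DistanceMatrix(ids=list(z.index), d=d, method="euclidean_standardized")


def upgma(dm: DistanceMatrix) -> Dendrogram:
    """Average-linkage agglomeration; merge height = half the average distance.

    Deterministic tie-break: among equally close pairs, merge the pair whose
    (min leaf label, other min leaf label) is lexicographically smallest.
    """
    if not np.all(np.isfinite(dm.d)):
        raise ValueError("distance matrix must be complete and finite")
    nodes = {i: TreeNode(label=name) for i, name in enumerate(dm.ids)}
    sizes = {i: 1 for i in nodes}
    minlab = {i: name for i, name in enumerate(dm.ids)}
    dist = {}
    n = len(dm.ids)
    for i in range(n):
        for j in range(i + 1, n):
            dist[(i, j)] = dm.d[i, j]
    next_id = n
    active = set(nodes)
    while len(active) > 1:
        best_key, best_pair = None, None
        for (i, j), dij in dist.items():
            lo, hi = sorted((minlab[i], minlab[j]))
            key = (dij, lo, hi)
            if best_key is None or key < best_key:
                best_key, best_pair = key, (i, j)
        i, j = best_pair
        dij = dist[(i, j)]
        if minlab[j] < minlab[i]:
            kids = (nodes[j], nodes[i])
        else:
            kids = (nodes[i], nodes[j])
        new = TreeNode(height=dij / 2.0, children=kids)
        nodes[next_id] = new
        sizes[next_id] = sizes[i] + sizes[j]
        minlab[next_id] = min(minlab[i], minlab[j])
        active -= {i, j}
        for k in active:
            dik = dist.pop((min(i, k), max(i, k)))
            djk = dist.pop((min(j, k), max(j, k)))
            dist[(min(next_id, k), max(next_id, k))] = (
                sizes[i] * dik + sizes[j] * djk) / (sizes[i] + sizes[j])
        del dist[(i, j)]
        active.add(next_id)
        next_id += 1
    return Dendrogram(root=nodes[active.pop()])


_NEWICK_META = set("(),:;'\" \t\n[]")


def _quote(label: str) -> str:
    if any(ch in _NEWICK_META for ch in label):
        return "'" + label.replace("'", "''") + "'"
    return label


def write_newick(tree: Dendrogram, path=None) -> str:
    """Serialize a dendrogram as Newick with branch lengths."""

    def render(node: TreeNode, parent_height: float | None) -> str:
        if not node.children:
            core = _quote(node.label)
        else:
            core = "(" + ",".join(render(c, node.height) for c in node.children) + ")"
        if parent_height is None:
            return core
        return f"{core}:{parent_height - node.height:.12g}"

    text = render(tree.root, None) + ";"
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text + "\n")
    return text


def cut_clusters(tree: Dendrogram, k: int) -> dict[str, int]:
    """Cut the dendrogram into exactly k clusters (when attainable).

    Clusters are numbered from 1 by decreasing size; ties broken by the
    lexicographically smallest member.  If tied merge heights make exactly k
    clusters unattainable, the nearest attainable count is returned with a
    warning.
    """
    leaves = tree.leaves()
    if not 1 <= k <= len(leaves):
        raise ValueError(f"k must be in [1, {len(leaves)}]")
    heights = sorted(tree.internal_heights(), reverse=True)
    if k == 1 or not heights:
        cut = float("inf")
    else:
        cut = heights[k - 2]  # remove the k-1 highest merges

    clusters: list[list[str]] = []

    def walk(node: TreeNode) -> None:
        if not node.children or node.height < cut:
            clusters.append(node.leaves())
        else:
            for c in node.children:
                walk(c)

    walk(tree.root)
    if len(clusters) != k:
        warnings.warn(f"tied merge heights: requested k={k}, attained {len(clusters)}")
    order = sorted(range(len(clusters)),
                   key=lambda c: (-len(clusters[c]), min(clusters[c])))
    assignment: dict[str, int] = {}
    for rank, ci in enumerate(order, start=1):
        for acc in clusters[ci]:
            assignment[acc] = rank
    return assignment


def find_duplicates(dm: DistanceMatrix, threshold: float = 0.0) -> DuplicateReport:
    """Connected components of the graph {(i, j): GD <= threshold}."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    n = len(dm.ids)
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n):
        for j in range(i + 1, n):
            if dm.d[i, j] <= threshold:
                parent[find(i)] = find(j)
    comps: dict[int, list[str]] = {}
    for i in range(n):
        comps.setdefault(find(i), []).append(dm.ids[i])
    groups = sorted((sorted(g) for g in comps.values() if len(g) > 1),
                    key=lambda g: (-len(g), g[0]))
    n_distinct = len(comps)
    return DuplicateReport(groups=groups, n_total=n, n_distinct=n_distinct,
                           n_redundant=n - n_distinct, threshold=threshold)


def find_homonyms(names: dict[str, str], dm: DistanceMatrix) -> HomonymReport:
    """Flag shared-name groups whose members are not genetically identical."""
    idx = {a: i for i, a in enumerate(dm.ids)}
    missing = [a for a in names if a not in idx]
    if missing:
        raise ValueError(f"accessions absent from the distance matrix: {missing}")
    name_groups: dict[str, list[str]] = {}
    for acc, name in names.items():
        name_groups.setdefault(name, []).append(acc)
    flagged: dict[str, float] = {}
    for name, members in name_groups.items():
        if len(members) < 2:
            continue
        gd_max = max(dm.d[idx[a], idx[b]]
                     for i, a in enumerate(members) for b in members[i + 1:])
        if gd_max > 0:
            flagged[name] = float(gd_max)
    return HomonymReport(name_groups=name_groups, flagged=flagged)


def genotype_pca(gm: GenotypeMatrix, method: str = "allele_share"):
    """Classical metric MDS (PCoA) of the genetic distance matrix.

    Gower double-centering of -D^2/2; negative eigenvalues (non-Euclidean GD)
    are clipped to 0 with a warning.  Returns (coordinates DataFrame,
    explained-variance fractions).
    """
    if gm.n < 3:
        raise ValueError("need >= 3 accessions")
    dm = genetic_distance_matrix(gm, method=method)
    return pcoa_from_distance(dm)


def pcoa_from_distance(dm: DistanceMatrix):
    n = len(dm.ids)
    d2 = dm.d ** 2
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ d2 @ J
    evals, evecs = np.linalg.eigh((B + B.T) / 2)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    if (evals < -1e-8 * max(1.0, abs(evals[0]))).any():
        warnings.warn("negative PCoA eigenvalues clipped to 0 (non-Euclidean distances)")
    evals = np.clip(evals, 0.0, None)
    coords = evecs * np.sqrt(evals)
    keep = evals > 1e-12
    total = evals.sum()
    explained = evals[keep] / total if total > 0 else evals[keep]
    cols = [f"Axis{j + 1}" for j in range(int(keep.sum()))]
    return (pd.DataFrame(coords[:, keep], index=dm.ids, columns=cols), explained)
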