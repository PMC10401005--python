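"""PAV-based clustering: binary distances, neighbor joining with a
gene-resampling bootstrap, PCA, Newick round-tripping and tree comparison.

The accession tree is built by neighbor joining on Hamming (simple
matching) or Jaccard distances computed from the binary PAV matrix, with
split supports from resampling gene columns with replacement. NJ is exact
on additive distances, which is the property the downstream clade-recovery
checks rely on.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .types import PavMatrix

__all__ = [
    "pav_distance",
    "neighbor_joining",
    "bootstrap_support",
    "pca",
    "PcaResult",
    "write_newick",
    "read_newick",
    "tree_splits",
    "robinson_foulds",
    "clade_recovery",
]


# ---------------------------------------------------------------------------
# Distances

def pav_distance(pav: PavMatrix, metric: str = "hamming") -> pd.DataFrame:
    """Symmetric accession-by-accession distance matrix from PAV states.

    ``hamming``: proportion of genes whose presence state differs (shared
    absence counts as agreement). ``jaccard``: 1 - |intersection|/|union|
    of the present-gene sets (shared absence ignored); a pair with an
    empty union gets distance 0 with a warning.
    """
    if metric not in ("hamming", "jaccard"):
        raise ValueError(f"unknown metric {metric!r}")
    X = pav.presence.to_numpy().astype(bool).T  # accessions x genes
    if metric == "jaccard" and (~X.any(axis=1)).any():
        warnings.warn(
            "accession(s) with empty gene set: jaccard distance to other "
            "empty accessions defined as 0",
            stacklevel=2,
        )
    D = squareform(pdist(X, metric=metric))
    return pd.DataFrame(D, index=pav.accession_ids, columns=pav.accession_ids)


# ---------------------------------------------------------------------------
# Neighbor joining

def neighbor_joining(distance_matrix: pd.DataFrame) -> dendropy.Tree:
    """Saitou-Nei neighbor joining; returns an unrooted dendropy tree.

    Q-criterion agglomeration with ties broken by the smallest (i, j)
    index pair in the current working order; negative branch lengths are
    clamped to zero with the deficit transferred to the sibling edge so
    the pair's summed length is preserved.
    """
    labels = [str(x) for x in distance_matrix.index]
    D = np.asarray(distance_matrix, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if D.shape[0] < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    if np.max(np.abs(D - D.T)) > 1e-9:
        raise ValueError("distance matrix is not symmetric (tolerance 1e-9)")
    if np.max(np.abs(np.diag(D))) > 1e-9:
        raise ValueError("distance matrix has a nonzero diagonal")

    taxon_namespace = dendropy.TaxonNamespace(labels)
    nodes: list[dendropy.Node] = []
    for label in labels:
        node = dendropy.Node()
        node.taxon = taxon_namespace.get_taxon(label)
        nodes.append(node)

    D = D.copy()
    active = list(range(len(labels)))

    def clamp(li: float, lj: float, d_ij: float) -> tuple[float, float]:
        if li < 0:
            return 0.0, d_ij
        if lj < 0:
            return d_ij, 0.0
        return li, lj

    while len(active) > 3:
        r = len(active)
        sub = D[np.ix_(active, active)]
        sums = sub.sum(axis=1)
        Q = (r - 2) * sub - sums[:, None] - sums[None, :]
        np.fill_diagonal(Q, np.inf)
        # argmin scans row-major: first minimum is the smallest (i, j) pair
        flat = int(np.argmin(Q))
        i_loc, j_loc = divmod(flat, r)
        if i_loc > j_loc:
            i_loc, j_loc = j_loc, i_loc
        i, j = active[i_loc], active[j_loc]
        d_ij = D[i, j]
        li = 0.5 * d_ij + (sums[i_loc] - sums[j_loc]) / (2.0 * (r - 2))
        lj = d_ij - li
        li, lj = clamp(li, lj, d_ij)

        parent = dendropy.Node()
        parent.add_child(nodes[i])
        nodes[i].edge.length = li
        parent.add_child(nodes[j])
        nodes[j].edge.length = lj

        # distances from the new node to the remaining taxa
        new_row = 0.5 * (D[i, :] + D[j, :] - d_ij)
        D[i, :] = new_row
        D[:, i] = new_row
        D[i, i] = 0.0
        nodes[i] = parent
        active.remove(j)

    # resolve the final three nodes around an unrooted central node
    i, j, k = active
    li = 0.5 * (D[i, j] + D[i, k] - D[j, k])
    lj = 0.5 * (D[i, j] + D[j, k] - D[i, k])
    lk = 0.5 * (D[i, k] + D[j, k] - D[i, j])
    center = dendropy.Node()
    for idx, length in ((i, li), (j, lj), (k, lk)):
        center.add_child(nodes[idx])
        nodes[idx].edge.length = max(0.0, length)

    tree = dendropy.Tree(taxon_namespace=taxon_namespace, seed_node=center)
    tree.is_rooted = False
    return tree


# ---------------------------------------------------------------------------
# Splits, RF distance, monophyly

def _leaf_labels(tree: dendropy.Tree) -> set[str]:
    return {leaf.taxon.label for leaf in tree.leaf_node_iter()}


def _canonical(side: frozenset, all_leaves: frozenset, anchor: str) -> frozenset:
    return side if anchor not in side else all_leaves - side


def tree_splits(tree: dendropy.Tree) -> set[frozenset]:
    """Non-trivial splits (bipartitions) of an unrooted tree, each encoded
    as the canonical side not containing the lexicographically smallest
    leaf label."""
    all_leaves = frozenset(_leaf_labels(tree))
    anchor = min(all_leaves)
    splits: set[frozenset] = set()
    for node in tree.preorder_node_iter():
        if node.parent_node is None or node.is_leaf():
            continue
        below = frozenset(leaf.taxon.label for leaf in node.leaf_iter())
        if 1 < len(below) < len(all_leaves) - 1:
            splits.add(_canonical(below, all_leaves, anchor))
    return splits


def robinson_foulds(tree_a: dendropy.Tree, tree_b: dendropy.Tree) -> int:
    """Unweighted Robinson-Foulds distance: the number of non-trivial
    splits present in exactly one of the two trees."""
    if _leaf_labels(tree_a) != _leaf_labels(tree_b):
        raise ValueError("trees have different leaf sets")
    return len(tree_splits(tree_a) ^ tree_splits(tree_b))


def clade_recovery(
    tree: dendropy.Tree,
    clade_map: Mapping[str, str],
    truth_tree: dendropy.Tree | None = None,
) -> tuple[dict[str, bool], int | None]:
    """Per-clade monophyly on the unrooted tree, plus the RF distance to a
    truth tree when one is supplied.

    A clade is monophyletic when its leaf set forms a split of the tree
    (or is trivial: a single leaf or all-but-one leaves).
    """
    leaves = frozenset(_leaf_labels(tree))
    assigned = set(clade_map)
    if not leaves <= assigned:
        raise ValueError(f"leaves without clade assignment: {sorted(leaves - assigned)}")
    anchor = min(leaves)
    splits = tree_splits(tree)
    mono: dict[str, bool] = {}
    for clade in sorted(set(clade_map[l] for l in leaves)):
        members = frozenset(l for l in leaves if clade_map[l] == clade)
        if len(members) <= 1 or len(members) >= len(leaves) - 1:
            mono[clade] = True  # trivially a split
        else:
            mono[clade] = _canonical(members, leaves, anchor) in splits
    rf = robinson_foulds(tree, truth_tree) if truth_tree is not None else None
    return mono, rf


# ---------------------------------------------------------------------------
# Bootstrap

def bootstrap_support(
    pav: PavMatrix,
    n_reps: int = 100,
    metric: str = "hamming",
    seed: int = 0,
) -> dendropy.Tree:
    """NJ tree with split supports from gene-resampling bootstrap.

    Gene columns are resampled with replacement ``n_reps`` times; the
    support of each internal split of the point-estimate tree is the
    percentage of replicate trees containing that split, stored as the
    internal node label (rounded to one decimal).
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    point_tree = neighbor_joining(pav_distance(pav, metric))
    all_leaves = frozenset(pav.accession_ids)
    anchor = min(all_leaves)
    counts: dict[frozenset, int] = {s: 0 for s in tree_splits(point_tree)}

    rng = np.random.default_rng(seed)
    n_genes = pav.n_genes
    presence = pav.presence
    for _ in range(n_reps):
        cols = rng.integers(0, n_genes, size=n_genes)
        resampled = PavMatrix(presence.iloc[cols].reset_index(drop=True))
        rep_tree = neighbor_joining(pav_distance(resampled, metric))
        for split in tree_splits(rep_tree):
            if split in counts:
                counts[split] += 1

    for node in point_tree.preorder_node_iter():
        if node.parent_node is None or node.is_leaf():
            continue
        below = frozenset(leaf.taxon.label for leaf in node.leaf_iter())
        if 1 < len(below) < len(all_leaves) - 1:
            support = 100.0 * counts[_canonical(below, all_leaves, anchor)] / n_reps
            node.label = f"{support:g}"
    return point_tree


# ---------------------------------------------------------------------------
# PCA

@dataclass
class PcaResult:
    """Accession scores on the leading principal components of the
    column-centred PAV matrix, with explained-variance fractions."""

    scores: pd.DataFrame                 # accessions x components
    explained_variance: np.ndarray       # per-component variance
    explained_variance_ratio: np.ndarray # fractions of total variance
    components: np.ndarray               # components x genes loadings


def pca(pav: PavMatrix, n_components: int = 2) -> PcaResult:
    """PCA of the PAV matrix (accessions as observations, genes as
    variables, columns centred).

    Computed by SVD of the centred matrix; component signs are fixed by
    making the largest-magnitude gene loading of each component positive.
    """
    X = pav.presence.to_numpy().astype(float).T  # accessions x genes
    n_acc, n_genes = X.shape
    if n_acc < 2:
        raise ValueError("PCA needs at least 2 accessions")
    max_components = min(n_acc, n_genes)
    if not (1 <= n_components <= max_components):
        raise ValueError(f"n_components must be in [1, {max_components}]")
    Xc = X - X.mean(axis=0, keepdims=True)
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    # sign convention: largest |loading| positive per component
    for k in range(Vt.shape[0]):
        j = int(np.argmax(np.abs(Vt[k])))
        if Vt[k, j] < 0:
            Vt[k] *= -1.0
            U[:, k] *= -1.0
    variances = S**2 / (n_acc - 1)
    total = variances.sum()
    ratios = variances / total if total > 0 else np.zeros_like(variances)
    scores = (U * S)[:, :n_components]
    return PcaResult(
        scores=pd.DataFrame(
            scores,
            index=pav.accession_ids,
            columns=[f"PC{k + 1}" for k in range(n_components)],
        ),
        explained_variance=variances[:n_components],
        explained_variance_ratio=ratios[:n_components],
        components=Vt[:n_components],
    )


# ---------------------------------------------------------------------------
# Newick I/O

def _canonical_order(tree: dendropy.Tree) -> None:
    for node in tree.postorder_node_iter():
        children = node.child_nodes()
        if children:
            node.set_child_nodes(
                sorted(children, key=lambda c: min(l.taxon.label for l in c.leaf_iter()))
            )


def write_newick(tree: dendropy.Tree, path: str | None = None) -> str:
    """Serialise a tree as Newick with canonical (smallest-leaf-first)
    child ordering; returns the string, writing to ``path`` if given."""
    _canonical_order(tree)
    text = tree.as_string(
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
    ).strip() + "\n"
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def read_newick(source: str) -> dendropy.Tree:
    """Parse a Newick string or file path; internal node labels are kept
    as split supports. Malformed input raises ValueError with the parser's
    position message."""
    import os

    kwargs = dict(
        schema="newick",
        preserve_underscores=True,
        suppress_internal_node_taxa=True,
    )
    try:
        if os.path.exists(source):
            tree = dendropy.Tree.get(path=source, **kwargs)
        else:
            tree = dendropy.Tree.get(data=source, **kwargs)
    except Exception as exc:
        raise ValueError(f"malformed Newick: {exc}") from exc
    tree.is_rooted = False
    return tree
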