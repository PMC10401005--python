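"""Pangenome-level statistics over a PAV matrix.

Core/shell/cloud classification, rarefaction curves, the shared-gene
matrix, clade presence/Venn set algebra, per-group core sets and group
summaries. A gene is core when present in more than 97% of accessions and
cloud when present in fewer than 3%; everything between is shell.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .types import PavMatrix

__all__ = [
    "classify_genes",
    "rarefaction",
    "RarefactionResult",
    "shared_gene_matrix",
    "clade_presence_sets",
    "CladeSets",
    "group_core_sets",
    "group_summaries",
]

CATEGORIES = ("core", "shell", "cloud")


def classify_genes(
    pav: PavMatrix,
    core_min: float = 0.97,
    cloud_max: float = 0.03,
) -> pd.DataFrame:
    """Classify every gene as core / shell / cloud by presence frequency.

    Returns a DataFrame indexed by gene_id with columns ``frequency`` and
    ``category``. Core requires frequency strictly above ``core_min``
    (present in more than 97% of accessions); cloud requires frequency
    strictly below ``cloud_max``.
    """
    if pav.n_accessions < 1 or pav.n_genes < 1:
        raise ValueError("PAV matrix must have at least one gene and one accession")
    freq = pav.frequencies()
    category = pd.Series("shell", index=freq.index, dtype=object)
    category[freq > core_min] = "core"
    category[freq < cloud_max] = "cloud"
    return pd.DataFrame({"frequency": freq, "category": category})


@dataclass
class RarefactionResult:
    """Pan/core set sizes as accessions accumulate in random orders.

    ``pan_curves`` and ``core_curves`` are (n_permutations x n_accessions)
    arrays; row p column k-1 is the pan (union) or core (intersection)
    gene count after the first k accessions of permutation p.
    """

    pan_curves: np.ndarray
    core_curves: np.ndarray
    n_permutations: int
    seed: int

    @property
    def k(self) -> np.ndarray:
        return np.arange(1, self.pan_curves.shape[1] + 1)

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "k": self.k,
                "pan_mean": self.pan_curves.mean(axis=0),
                "pan_min": self.pan_curves.min(axis=0),
                "pan_max": self.pan_curves.max(axis=0),
                "core_mean": self.core_curves.mean(axis=0),
                "core_min": self.core_curves.min(axis=0),
                "core_max": self.core_curves.max(axis=0),
            }
        ).set_index("k")

    def plateau_k(self, window: int = 10, rel_gain: float = 0.005) -> int | None:
        """Smallest K where the mean pan curve gains less than ``rel_gain``
        of pan(K) over the previous ``window`` accessions; None if never."""
        pan = self.pan_curves.mean(axis=0)
        for k in range(window, pan.size):
            if pan[k] - pan[k - window] < rel_gain * pan[k]:
                return k + 1
        return None


def rarefaction(pav: PavMatrix, n_permutations: int = 100, seed: int = 0) -> RarefactionResult:
    """Pan and core genome sizes over random accession orderings.

    For each of ``n_permutations`` random permutations of the accessions,
    pan(k) is the size of the union and core(k) the size of the
    intersection of the first k accessions' gene sets.
    """
    if pav.n_accessions < 2:
        raise ValueError("rarefaction needs at least 2 accessions")
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    rng = np.random.default_rng(seed)
    X = pav.presence.to_numpy().astype(bool).T  # accessions x genes
    n_acc = X.shape[0]
    pan_curves = np.empty((n_permutations, n_acc), dtype=np.int64)
    core_curves = np.empty((n_permutations, n_acc), dtype=np.int64)
    for p in range(n_permutations):
        order = rng.permutation(n_acc)
        pan_curves[p] = np.logical_or.accumulate(X[order], axis=0).sum(axis=1)
        core_curves[p] = np.logical_and.accumulate(X[order], axis=0).sum(axis=1)
    return RarefactionResult(pan_curves, core_curves, n_permutations, seed)


def shared_gene_matrix(pav: PavMatrix) -> pd.DataFrame:
    """Accession x accession counts of jointly present genes.

    Symmetric; the diagonal holds each accession's gene count.
    """
    X = pav.presence.to_numpy().astype(np.int64)
    shared = X.T @ X
    return pd.DataFrame(shared, index=pav.accession_ids, columns=pav.accession_ids)


@dataclass
class CladeSets:
    """Per-clade presence sets and their Venn partition.

    A gene is present in a clade if at least one member accession carries
    it. ``venn`` maps each non-empty clade combination (frozenset of clade
    labels) to the number of genes present in exactly those clades; the
    counts partition the union of all present genes.
    """

    present: dict[str, set[str]]
    unique: dict[str, set[str]]
    venn: dict[frozenset, int]


def clade_presence_sets(pav: PavMatrix, clade_map: Mapping[str, str] | None = None) -> CladeSets:
    """Union/unique gene sets per clade and all Venn partition counts."""
    if clade_map is None:
        clade_map = pav.clade_map()
    missing = [a for a in pav.accession_ids if a not in clade_map]
    if missing:
        raise ValueError(f"accessions without clade assignment: {missing}")
    clades = sorted(set(clade_map[a] for a in pav.accession_ids))
    present: dict[str, set[str]] = {}
    for clade in clades:
        members = [a for a in pav.accession_ids if clade_map[a] == clade]
        mask = pav.presence[members].to_numpy().any(axis=1)
        present[clade] = set(np.asarray(pav.gene_ids)[mask])
    unique = {
        c: present[c] - set().union(*(present[o] for o in clades if o != c))
        for c in clades
    }
    venn: dict[frozenset, int] = {}
    for r in range(1, len(clades) + 1):
        for combo in combinations(clades, r):
            inside = set.intersection(*(present[c] for c in combo))
            outside = set().union(*(present[c] for c in clades if c not in combo), set())
            venn[frozenset(combo)] = len(inside - outside)
    return CladeSets(present=present, unique=unique, venn=venn)


def group_core_sets(
    pav: PavMatrix,
    group_map: Mapping[str, str] | None = None,
    core_min: float = 0.97,
) -> tuple[dict[str, set[str]], dict[str, set[str]]]:
    """Core gene sets per group (within-group frequency > core_min) and the
    unique-core set of each group (its core minus every other group's core)."""
    if group_map is None:
        group_map = {a: g for a, g in pav.profiles["group"].items()}
    groups = sorted(set(group_map[a] for a in pav.accession_ids))
    core: dict[str, set[str]] = {}
    gene_ids = np.asarray(pav.gene_ids)
    for g in groups:
        members = [a for a in pav.accession_ids if group_map[a] == g]
        if not members:
            raise ValueError(f"group {g!r} has no accessions")
        freq = pav.presence[members].to_numpy().mean(axis=1)
        core[g] = set(gene_ids[freq > core_min])
    unique = {
        g: core[g] - set().union(*(core[o] for o in groups if o != g), set())
        for g in groups
    }
    return core, unique


def group_summaries(
    pav: PavMatrix,
    metadata: pd.DataFrame | None = None,
    annotation_counts: pd.DataFrame | None = None,
    by: str = "group",
) -> pd.DataFrame:
    """Per-group summaries of gene counts (and optional per-accession
    numeric columns such as TE counts): mean, depth-weighted mean, median
    and quartiles.

    ``by`` selects the stratifying metadata column (``group``, ``clade``,
    ``ploidy``...). Summarisation only: no re-classification is performed.
    """
    if metadata is None:
        metadata = pav.profiles
    missing = set(pav.accession_ids) - set(metadata.index)
    if missing:
        raise ValueError(f"metadata missing accessions: {sorted(missing)}")
    values = pd.DataFrame({"gene_count": pav.gene_counts()})
    if annotation_counts is not None:
        bad = annotation_counts.select_dtypes(exclude="number").columns
        if len(bad):
            raise ValueError(f"non-numeric annotation columns: {list(bad)}")
        values = values.join(annotation_counts, how="left")
    values[by] = metadata.loc[values.index, by]
    weights = metadata.loc[values.index, "mean_depth"] if "mean_depth" in metadata else None

    rows = []
    for key, sub in values.groupby(by, sort=True):
        numeric = sub.drop(columns=[by])
        for col in numeric.columns:
            x = numeric[col].to_numpy(dtype=float)
            row = {
                by: key,
                "variable": col,
                "n": x.size,
                "mean": float(np.mean(x)),
                "median": float(np.median(x)),
                "q1": float(np.percentile(x, 25)),
                "q3": float(np.percentile(x, 75)),
            }
            if weights is not None:
                w = weights.loc[sub.index].to_numpy(dtype=float)
                row["weighted_mean"] = float(np.average(x, weights=w)) if w.sum() > 0 else float(np.mean(x))
            rows.append(row)
    return pd.DataFrame(rows)
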