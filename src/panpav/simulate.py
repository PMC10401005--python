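"""Synthetic pangenome generator with known truth.

Emulates the study design the pipeline targets: a clade-structured panel
of wild, landrace and cultivar accessions (ploidy 2x-5x, optional in-vitro
flag), a PAV matrix produced by gene gain/loss on a guide tree with
ploidy-dependent gene-count inflation and planted selection genes, exon
coverage tracks consistent with the PAV truth plus spurious-mapping noise,
and contig/alignment-hit sets with planted novel, redundant and
contaminant sequence. Everything is seeded: the same configuration and
seed reproduce byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

from .calling import min_reads_threshold
from .types import (
    AccessionProfile,
    AlignmentHit,
    GeneModel,
    NonrefSegment,
    PavMatrix,
    TaxonHit,
    profiles_frame,
)

__all__ = [
    "SimulationConfig",
    "TruthSet",
    "simulate_guide_tree",
    "clade_map_from_tree",
    "simulate_pav",
    "make_gene_models",
    "simulate_coverage",
    "coverage_function",
    "simulate_contigs_and_hits",
    "ContigSim",
    "simulate_term_map",
]

_NUCS = np.array(list("ACGT"))

# independent random streams per product, derived from the master seed
_TREE_TAG, _PAV_TAG, _COV_TAG, _CONTIG_TAG, _TERM_TAG = 11, 23, 37, 53, 71


@dataclass
class SimulationConfig:
    """Parameters of the synthetic pangenome.

    Defaults describe the standard study panel used throughout the test
    suite: 3 clades x 20 accessions, 5,000 genes (2,500 core / 2,000
    shell / 500 cloud), mean depth 30x, and per-cell coverage-noise
    probabilities of 0.005. ``loss_rate``/``gain_rate`` are per-branch
    Bernoulli event probabilities for shell genes. ``ploidy_gene_bonus``
    is the expected number of extra present genes per ploidy step above
    diploid. ``selection_genes`` holds (gene_id, wild_frequency,
    domesticated_frequency) triples drawn independently per accession.
    """

    seed: int = 0
    n_clades: int = 3
    accessions_per_clade: int = 20
    n_core_genes: int = 2500
    n_shell_genes: int = 2000
    n_cloud_genes: int = 500
    loss_rate: float = 0.10
    gain_rate: float = 0.03
    ploidy_map: dict[str, int] | None = None
    ploidy_gene_bonus: float = 100.0
    selection_genes: list[tuple[str, float, float]] = field(default_factory=list)
    group_map: dict[str, str] | None = None
    depth_map: dict[str, float] | None = None
    default_depth: float = 30.0
    noise_fp: float = 0.005
    noise_fn: float = 0.005

    def __post_init__(self) -> None:
        for name in ("loss_rate", "gain_rate", "noise_fp", "noise_fn"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("n_core_genes", "n_shell_genes", "n_cloud_genes"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_clades < 2 or self.accessions_per_clade < 2:
            raise ValueError("need at least 2 clades with 2 accessions each")
        for gene_id, fw, fd in self.selection_genes:
            if not (0.0 <= fw <= 1.0 and 0.0 <= fd <= 1.0):
                raise ValueError(f"selection gene {gene_id}: frequencies must be in [0, 1]")
        if self.ploidy_gene_bonus < 0:
            raise ValueError("ploidy_gene_bonus must be >= 0")

    @classmethod
    def from_yaml(cls, path: str) -> "SimulationConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "selection_genes" in data:
            data["selection_genes"] = [tuple(x) for x in data["selection_genes"]]
        return cls(**data)


@dataclass
class TruthSet:
    """Ground truth attached to a simulated dataset."""

    true_pav: PavMatrix
    true_tree: dendropy.Tree
    true_categories: dict[str, str]
    true_favorable: set[str]
    clade_map: dict[str, str]
    contig_labels: dict[str, str] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Guide tree

def _random_join(nodes: list[dendropy.Node], rng: np.random.Generator,
                 scale: float) -> dendropy.Node:
    nodes = list(nodes)
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = dendropy.Node()
        for idx in (i, j):
            child = nodes[idx]
            parent.add_child(child)
            child.edge.length = float(rng.exponential(scale)) + 1e-3
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)]
        nodes.append(parent)
    return nodes[0]


def simulate_guide_tree(
    n_clades: int,
    accessions_per_clade: int,
    seed: int = 0,
) -> dendropy.Tree:
    """Random binary guide tree whose leaves are grouped into monophyletic
    clades. Leaf labels are ``C<clade>A<index>``; the clade of a leaf is
    recoverable via :func:`clade_map_from_tree`.
    """
    if n_clades < 2 or accessions_per_clade < 2:
        raise ValueError("need n_clades >= 2 and accessions_per_clade >= 2")
    rng = np.random.default_rng(np.random.SeedSequence((int(seed), _TREE_TAG)))
    labels = [
        f"C{c:02d}A{a:02d}"
        for c in range(1, n_clades + 1)
        for a in range(1, accessions_per_clade + 1)
    ]
    taxon_namespace = dendropy.TaxonNamespace(labels)
    clade_roots = []
    for c in range(1, n_clades + 1):
        leaves = []
        for a in range(1, accessions_per_clade + 1):
            node = dendropy.Node()
            node.taxon = taxon_namespace.get_taxon(f"C{c:02d}A{a:02d}")
            leaves.append(node)
        root = _random_join(leaves, rng, scale=0.05)
        clade_roots.append(root)
    seed_node = _random_join(clade_roots, rng, scale=0.15)
    tree = dendropy.Tree(taxon_namespace=taxon_namespace, seed_node=seed_node)
    tree.is_rooted = False
    return tree


def clade_map_from_tree(tree: dendropy.Tree) -> dict[str, str]:
    """Leaf label -> clade label (``clade<k>``) from the label convention."""
    out = {}
    for leaf in tree.leaf_node_iter():
        label = leaf.taxon.label
        if not (label.startswith("C") and "A" in label):
            raise ValueError(f"leaf {label!r} does not follow the C<k>A<i> convention")
        out[label] = f"clade{int(label[1:label.index('A')])}"
    return out


# ---------------------------------------------------------------------------
# PAV simulation

def _default_group_map(accessions: Sequence[str], clade_map: Mapping[str, str]) -> dict[str, str]:
    # domesticated material is confined to the last clade, split between
    # landraces and cultivars; all other clades are wild
    clades = sorted({clade_map[a] for a in accessions}, key=lambda c: int(c[5:]))
    last = clades[-1]
    group_map = {}
    members_last = [a for a in accessions if clade_map[a] == last]
    half = len(members_last) // 2
    for a in accessions:
        if clade_map[a] != last:
            group_map[a] = "wild"
        else:
            group_map[a] = "landrace" if members_last.index(a) < half else "cultivar"
    return group_map


def _default_ploidy_map(accessions: Sequence[str], group_map: Mapping[str, str]) -> dict[str, int]:
    # wilds diploid; landraces alternate 2x/4x; cultivars tetraploid
    ploidy = {}
    landrace_toggle = 0
    for a in accessions:
        g = group_map[a]
        if g == "wild":
            ploidy[a] = 2
        elif g == "landrace":
            ploidy[a] = 2 if landrace_toggle % 2 == 0 else 4
            landrace_toggle += 1
        else:
            ploidy[a] = 4
    return ploidy


def simulate_pav(
    tree: dendropy.Tree,
    config: SimulationConfig,
) -> tuple[PavMatrix, TruthSet]:
    """Simulate the binary PAV matrix on a guide tree.

    Core genes are present in every accession. Shell genes start present
    at the root and evolve by per-branch Bernoulli loss/gain events, which
    makes their pattern clade-structured. Cloud genes are placed in at
    most max(1, 3% of accessions). Polyploids then gain extra present
    genes (Poisson with mean ploidy_gene_bonus per ploidy step), and
    planted selection genes are drawn per accession at their stated
    group frequencies. Truth categories are the core/shell/cloud
    thresholds applied to the realized truth matrix.
    """
    leaves = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    clade_map = clade_map_from_tree(tree)
    n_acc = len(leaves)
    rng = np.random.default_rng(np.random.SeedSequence((int(config.seed), _PAV_TAG)))

    gene_ids: list[str] = []
    blocks: list[np.ndarray] = []

    # core: present everywhere
    if config.n_core_genes:
        gene_ids += [f"core_{i:05d}" for i in range(1, config.n_core_genes + 1)]
        blocks.append(np.ones((config.n_core_genes, n_acc), dtype=np.int8))

    # shell: gain/loss on branches
    if config.n_shell_genes:
        gene_ids += [f"shell_{i:05d}" for i in range(1, config.n_shell_genes + 1)]
        states: dict[int, np.ndarray] = {}
        leaf_states = np.zeros((config.n_shell_genes, n_acc), dtype=np.int8)
        leaf_index = {label: k for k, label in enumerate(leaves)}
        root_state = np.ones(config.n_shell_genes, dtype=np.int8)
        for node in tree.preorder_node_iter():
            if node.parent_node is None:
                states[id(node)] = root_state
            else:
                parent = states[id(node.parent_node)]
                u = rng.random(config.n_shell_genes)
                child = parent.copy()
                child[(parent == 1) & (u < config.loss_rate)] = 0
                child[(parent == 0) & (u < config.gain_rate)] = 1
                states[id(node)] = child
            if node.is_leaf():
                leaf_states[:, leaf_index[node.taxon.label]] = states[id(node)]
        blocks.append(leaf_states)

    # cloud: present in at most max(1, 3% of accessions)
    if config.n_cloud_genes:
        gene_ids += [f"cloud_{i:05d}" for i in range(1, config.n_cloud_genes + 1)]
        k_max = max(1, int(0.03 * n_acc))
        cloud = np.zeros((config.n_cloud_genes, n_acc), dtype=np.int8)
        for i in range(config.n_cloud_genes):
            k = int(rng.integers(1, k_max + 1))
            cloud[i, rng.choice(n_acc, size=k, replace=False)] = 1
        blocks.append(cloud)

    group_map = dict(config.group_map) if config.group_map else _default_group_map(leaves, clade_map)
    missing = set(leaves) - set(group_map)
    if missing:
        raise ValueError(f"group_map missing accessions: {sorted(missing)}")

    # planted selection genes: iid Bernoulli at the group's target frequency
    if config.selection_genes:
        sel = np.zeros((len(config.selection_genes), n_acc), dtype=np.int8)
        for i, (gene_id, fw, fd) in enumerate(config.selection_genes):
            gene_ids.append(gene_id)
            probs = np.array(
                [fw if group_map[a] == "wild" else fd for a in leaves]
            )
            sel[i] = (rng.random(n_acc) < probs).astype(np.int8)
        blocks.append(sel)

    presence = np.vstack(blocks) if blocks else np.zeros((0, n_acc), dtype=np.int8)

    # ploidy inflation: polyploids switch on extra absent genes
    ploidy_map = dict(config.ploidy_map) if config.ploidy_map else _default_ploidy_map(leaves, group_map)
    if config.ploidy_gene_bonus > 0:
        for k, acc in enumerate(leaves):
            steps = ploidy_map.get(acc, 2) - 2
            if steps <= 0:
                continue
            n_extra = int(rng.poisson(config.ploidy_gene_bonus * steps))
            absent = np.flatnonzero(presence[:, k] == 0)
            if absent.size and n_extra:
                chosen = rng.choice(absent, size=min(n_extra, absent.size), replace=False)
                presence[chosen, k] = 1

    depth_map = dict(config.depth_map) if config.depth_map else {a: config.default_depth for a in leaves}
    cultivars = [a for a in leaves if group_map[a] == "cultivar"]
    in_vitro = {a for i, a in enumerate(cultivars) if i % 2 == 0}
    profiles = profiles_frame(
        AccessionProfile(
            accession_id=a,
            mean_depth=float(depth_map.get(a, config.default_depth)),
            group=group_map[a],
            clade=clade_map[a],
            ploidy=int(ploidy_map.get(a, 2)),
            in_vitro=a in in_vitro,
        )
        for a in leaves
    )
    pav = PavMatrix(
        pd.DataFrame(presence, index=pd.Index(gene_ids, name="gene_id"), columns=leaves),
        profiles,
    )

    freq = pav.frequencies()
    categories = {
        g: ("core" if f > 0.97 else ("cloud" if f < 0.03 else "shell"))
        for g, f in freq.items()
    }
    favorable = {
        gene_id for gene_id, fw, fd in config.selection_genes if fd > fw
    }
    truth = TruthSet(
        true_pav=pav,
        true_tree=tree,
        true_categories=categories,
        true_favorable=favorable,
        clade_map=clade_map,
    )
    return pav, truth


# ---------------------------------------------------------------------------
# Gene models and coverage

def make_gene_models(
    gene_ids: Sequence[str],
    exons_per_gene: int = 2,
    exon_length: int = 100,
    intron_length: int = 50,
    intergenic: int = 50,
    genes_per_sequence: int = 500,
) -> list[GeneModel]:
    """Lay genes out head-to-tail on synthetic pangenome sequences."""
    models = []
    gene_span = exons_per_gene * exon_length + (exons_per_gene - 1) * intron_length
    for k, gene_id in enumerate(gene_ids):
        seq_idx = k // genes_per_sequence
        offset = (k % genes_per_sequence) * (gene_span + intergenic)
        exons = tuple(
            (offset + e * (exon_length + intron_length),
             offset + e * (exon_length + intron_length) + exon_length)
            for e in range(exons_per_gene)
        )
        models.append(GeneModel(gene_id, f"panseq{seq_idx + 1:03d}", exons))
    return models


def _sequence_lengths(gene_models: Sequence[GeneModel]) -> dict[str, int]:
    lengths: dict[str, int] = {}
    for gm in gene_models:
        lengths[gm.sequence_id] = max(lengths.get(gm.sequence_id, 0), gm.span[1])
    return lengths


def _simulate_track(
    pav: PavMatrix,
    gene_models: Sequence[GeneModel],
    config: SimulationConfig,
    accession: str,
    acc_index: int,
    seq_lengths: Mapping[str, int],
    positions: Mapping[str, np.ndarray],
) -> dict[str, np.ndarray]:
    rng = np.random.default_rng(
        np.random.SeedSequence((int(config.seed), _COV_TAG, acc_index))
    )
    mean_depth = float(pav.profiles.loc[accession, "mean_depth"])
    present = pav.presence[accession].to_numpy().astype(bool)
    u = rng.random(len(gene_models))

    track = {s: np.zeros(l, dtype=np.uint16) for s, l in seq_lengths.items()}
    normal_positions: dict[str, list[np.ndarray]] = {s: [] for s in seq_lengths}
    cap = np.iinfo(np.uint16).max

    for i, gm in enumerate(gene_models):
        pos = positions[gm.gene_id]
        if present[i]:
            if u[i] < config.noise_fn:
                # dropout: only a small random fraction of exonic bases covered
                f = rng.uniform(0.0, 0.15)
                chosen = pos[rng.random(pos.size) < f]
                if chosen.size:
                    track[gm.sequence_id][chosen] = np.minimum(
                        rng.poisson(mean_depth, chosen.size), cap
                    )
            else:
                normal_positions[gm.sequence_id].append(pos)
        else:
            if config.noise_fp <= 0:
                continue  # truly absent: zero exonic depth
            if u[i] < config.noise_fp:
                # spurious mapping strong enough to mimic presence
                f = rng.uniform(0.35, 0.6)
                chosen = pos[rng.random(pos.size) < f]
            else:
                # light spurious mapping, always below the 20% rule
                f = rng.uniform(0.0, 0.08)
                chosen = pos[rng.random(pos.size) < f]
            if chosen.size:
                track[gm.sequence_id][chosen] = np.minimum(
                    rng.poisson(mean_depth, chosen.size), cap
                )

    for seq_id, chunks in normal_positions.items():
        if chunks:
            pos = np.concatenate(chunks)
            track[seq_id][pos] = np.minimum(rng.poisson(mean_depth, pos.size), cap)
    return track


def _positions(gene_models: Sequence[GeneModel]) -> dict[str, np.ndarray]:
    return {
        gm.gene_id: np.concatenate([np.arange(s, e) for s, e in gm.exons])
        for gm in gene_models
    }


def coverage_function(
    pav: PavMatrix,
    gene_models: Sequence[GeneModel],
    config: SimulationConfig,
) -> Callable[[str], dict[str, np.ndarray]]:
    """Lazy per-accession coverage: returns a callable accession_id ->
    depth track, deterministic in (config.seed, accession). Suitable for
    feeding :func:`panpav.calling.build_pav_matrix` one accession at a
    time without holding all tracks in memory."""
    missing = [a for a in pav.accession_ids if a not in pav.profiles.index]
    if missing:
        raise ValueError(f"accessions missing from metadata/depth map: {missing}")
    model_genes = {gm.gene_id for gm in gene_models}
    unmodelled = [g for g in pav.gene_ids if g not in model_genes]
    if unmodelled:
        raise ValueError(f"genes without gene models: {unmodelled[:5]}...")
    ordered_models = {gm.gene_id: gm for gm in gene_models}
    models = [ordered_models[g] for g in pav.gene_ids]
    seq_lengths = _sequence_lengths(models)
    positions = _positions(models)
    index = {a: k for k, a in enumerate(pav.accession_ids)}

    def get(accession: str) -> dict[str, np.ndarray]:
        if accession not in index:
            raise ValueError(f"unknown accession {accession!r}")
        return _simulate_track(
            pav, models, config, accession, index[accession], seq_lengths, positions
        )

    return get


def simulate_coverage(
    pav: PavMatrix,
    gene_models: Sequence[GeneModel],
    config: SimulationConfig,
) -> dict[str, dict[str, np.ndarray]]:
    """Per-accession exon depth tracks consistent with the PAV truth.

    Present genes receive Poisson(mean_depth) per-base depth over their
    exons (with probability ``noise_fn`` a dropout leaves under 15% of
    exonic bases covered); absent genes stay at zero when ``noise_fp`` is
    0, otherwise they carry light spurious coverage, upgraded with
    probability ``noise_fp`` to a spurious signal strong enough to pass
    the 20% rule.
    """
    get = coverage_function(pav, gene_models, config)
    return {a: get(a) for a in pav.accession_ids}


# ---------------------------------------------------------------------------
# Contigs and hits

@dataclass
class ContigSim:
    """Planted contig/hit fixture for the non-reference extraction stages."""

    reference: dict[str, str]
    contigs: dict[str, str]
    hits: list[AlignmentHit]
    taxon_hits: list[TaxonHit]
    labels: dict[str, str]
    planted_inserts: dict[str, tuple[int, int]]
    redundant_pairs: list[tuple[str, str]]  # (kept, duplicate)


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(_NUCS[rng.integers(0, 4, size=length)])


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    arr = np.array(list(seq))
    mask = rng.random(arr.size) < rate
    if mask.any():
        arr[mask] = _NUCS[rng.integers(0, 4, size=int(mask.sum()))]
    return "".join(arr)


def simulate_contigs_and_hits(
    seed: int = 0,
    n_reference_like: int = 4,
    n_insert: int = 4,
    n_novel_pairs: int = 3,
    n_contaminant: int = 3,
    insert_length: int = 600,
    novel_length: int = 800,
    flank_length: int = 700,
    reference_length: int = 20000,
) -> ContigSim:
    """Contig/alignment-hit sets with planted truth for the extraction
    pipeline: fully aligned contigs, contigs with an internal novel insert,
    mutually redundant novel contigs, and non-green contaminants."""
    rng = np.random.default_rng(np.random.SeedSequence((int(seed), _CONTIG_TAG)))
    reference = {"ref1": _random_seq(rng, reference_length)}
    contigs: dict[str, str] = {}
    hits: list[AlignmentHit] = []
    taxon_hits: list[TaxonHit] = []
    labels: dict[str, str] = {}
    planted_inserts: dict[str, tuple[int, int]] = {}
    redundant_pairs: list[tuple[str, str]] = []

    for k in range(1, n_reference_like + 1):
        name = f"full_{k:03d}"
        start = int(rng.integers(0, reference_length - 1500))
        seq = reference["ref1"][start:start + 1500]
        contigs[name] = seq
        labels[name] = "reference-derived"
        hits.append(AlignmentHit(name, len(seq), 0, len(seq), "ref1", 98.5, len(seq)))
        taxon_hits.append(TaxonHit(name, 0, len(seq), "green_plant"))

    for k in range(1, n_insert + 1):
        name = f"insert_{k:03d}"
        start = int(rng.integers(0, reference_length - 2 * flank_length - 10))
        flank1 = reference["ref1"][start:start + flank_length]
        flank2 = reference["ref1"][start + flank_length:start + 2 * flank_length]
        insert = _random_seq(rng, insert_length)
        seq = flank1 + insert + flank2
        contigs[name] = seq
        labels[name] = "novel"
        L = len(seq)
        hits.append(AlignmentHit(name, L, 0, flank_length, "ref1", 97.0, flank_length))
        hits.append(
            AlignmentHit(name, L, flank_length + insert_length, L, "ref1", 97.0, flank_length)
        )
        planted_inserts[name] = (flank_length, flank_length + insert_length)
        taxon_hits.append(TaxonHit(name, 0, L, "green_plant"))

    for k in range(1, n_novel_pairs + 1):
        name = f"novel_{k:03d}"
        dup = f"novel_{k:03d}_dup"
        seq = _random_seq(rng, novel_length)
        contigs[name] = seq
        # slightly shorter, lightly mutated copy: clusters under the original
        contigs[dup] = _mutate(rng, seq[: int(novel_length * 0.97)], 0.01)
        labels[name] = "novel"
        labels[dup] = "redundant"
        redundant_pairs.append((name, dup))
        taxon_hits.append(TaxonHit(name, 0, novel_length, "green_plant"))
        taxon_hits.append(TaxonHit(dup, 0, len(contigs[dup]), "green_plant"))

    for k in range(1, n_contaminant + 1):
        name = f"contam_{k:03d}"
        seq = _random_seq(rng, 1000)
        contigs[name] = seq
        labels[name] = "contaminant"
        taxon_hits.append(TaxonHit(name, 0, 900, "other"))

    return ContigSim(
        reference=reference,
        contigs=contigs,
        hits=hits,
        taxon_hits=taxon_hits,
        labels=labels,
        planted_inserts=planted_inserts,
        redundant_pairs=redundant_pairs,
    )


# ---------------------------------------------------------------------------
# Term map

def simulate_term_map(
    genes: Sequence[str],
    n_terms: int = 50,
    enriched_pairs: Sequence[tuple[str, Sequence[str], float]] = (),
    seed: int = 0,
    mean_terms_per_gene: float = 2.0,
) -> dict[str, list[str]]:
    """Gene -> term map with uniform background assignment and optional
    planted enrichment.

    Every gene receives each term independently with probability
    ``mean_terms_per_gene / n_terms``. Each (term, gene_subset, factor)
    in ``enriched_pairs`` multiplies that probability by ``factor``
    (capped at 1) for the genes in the subset.
    """
    if n_terms < 1:
        raise ValueError("n_terms must be >= 1")
    gene_list = list(genes)
    gene_set = set(gene_list)
    for term, subset, factor in enriched_pairs:
        unknown = set(subset) - gene_set
        if unknown:
            raise ValueError(f"enriched pair {term!r} names unknown genes: {sorted(unknown)[:5]}")
    rng = np.random.default_rng(np.random.SeedSequence((int(seed), _TERM_TAG)))
    terms = [f"TERM:{t:04d}" for t in range(1, n_terms + 1)]
    p0 = min(1.0, mean_terms_per_gene / n_terms)
    draws = rng.random((len(gene_list), n_terms))
    thresholds = np.full((len(gene_list), n_terms), p0)
    term_index = {t: i for i, t in enumerate(terms)}
    gene_index = {g: i for i, g in enumerate(gene_list)}
    for term, subset, factor in enriched_pairs:
        if term not in term_index:
            raise ValueError(f"unknown term {term!r}")
        for g in subset:
            thresholds[gene_index[g], term_index[term]] = min(1.0, factor * p0)
    has_term = draws < thresholds
    return {
        g: [terms[t] for t in np.flatnonzero(has_term[i])]
        for i, g in enumerate(gene_list)
    }
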