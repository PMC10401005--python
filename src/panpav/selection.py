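"""Gene-frequency selection statistics.

Per-gene 2x2 Fisher's exact tests of presence frequency between accession
groups (e.g. wild vs. domesticated), Benjamini-Hochberg FDR, a fold-change
criterion, favorable/unfavorable classification, and a flat Fisher-based
term-enrichment analysis.

The headline rule: a gene is *favorable* when its FDR-corrected p-value is
below 0.001, its presence-frequency fold change exceeds 2, and the
domesticated groups carry it at higher frequency than the wild relatives;
*unfavorable* genes satisfy the same thresholds with the wild frequency
higher.
"""

from __future__ import annotations

import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .types import PavMatrix

__all__ = [
    "presence_frequency",
    "fisher_exact_2x2",
    "bh_fdr",
    "favorable_genes",
    "partition_favorable",
    "term_enrichment",
]


def presence_frequency(pav: PavMatrix, accession_subset: Sequence[str]) -> pd.Series:
    """Per-gene presence frequency within a subset of accessions."""
    subset = list(accession_subset)
    if not subset:
        raise ValueError("accession subset is empty")
    missing = set(subset) - set(pav.accession_ids)
    if missing:
        raise ValueError(f"unknown accessions: {sorted(missing)}")
    return pav.presence[subset].mean(axis=1)


def _log_hypergeom_pmf(k: np.ndarray, n: int, r1: int, c1: int) -> np.ndarray:
    # log P(X = k) for X ~ Hypergeom(n, r1, c1): tables with fixed margins.
    return (
        gammaln(r1 + 1) - gammaln(k + 1) - gammaln(r1 - k + 1)
        + gammaln(n - r1 + 1) - gammaln(c1 - k + 1) - gammaln(n - r1 - c1 + k + 1)
        - (gammaln(n + 1) - gammaln(c1 + 1) - gammaln(n - c1 + 1))
    )


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Two-sided Fisher's exact test for the table [[a, b], [c, d]].

    The two-sided p-value follows the minimum-likelihood convention: the
    sum of hypergeometric point probabilities (margins fixed) of every
    table whose probability does not exceed that of the observed table
    (within relative tolerance 1e-7, guarding against floating-point ties).
    The odds ratio is (a*d)/(b*c), infinite when b*c == 0 and a*d > 0.
    """
    for x in (a, b, c, d):
        if x < 0 or x != int(x):
            raise ValueError("table entries must be non-negative integers")
    a, b, c, d = int(a), int(b), int(c), int(d)
    n = a + b + c + d
    if n == 0:
        raise ValueError("all-zero contingency table")
    r1, c1 = a + b, a + c
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    support = np.arange(lo, hi + 1)
    logpmf = _log_hypergeom_pmf(support, n, r1, c1)
    pmf = np.exp(logpmf)
    p_obs = pmf[a - lo]
    p = float(pmf[pmf <= p_obs * (1 + 1e-7)].sum())
    p = min(p, 1.0)
    if b * c == 0:
        odds = math.inf if a * d > 0 else math.nan
    else:
        odds = (a * d) / (b * c)
    return p, odds


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    q_i = min over j >= i (in ascending p order) of p_j * m / j, clipped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m, dtype=float)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def _fold_change(freq_a: float, freq_b: float) -> float:
    hi, lo = max(freq_a, freq_b), min(freq_a, freq_b)
    if hi == lo:
        return 1.0
    if lo == 0.0:
        return math.inf
    return hi / lo


def favorable_genes(
    pav: PavMatrix,
    wild_set: Sequence[str],
    domesticated_set: Sequence[str],
    fdr_max: float = 0.001,
    fold_min: float = 2.0,
) -> pd.DataFrame:
    """Per-gene wild-vs-domesticated frequency tests with the favorable /
    unfavorable / none classification.

    Returns a DataFrame indexed by gene_id with the 2x2 counts
    (present/absent x domesticated/wild), frequencies, Fisher p, BH FDR
    across all genes tested, fold change (ratio of the larger to the
    smaller frequency, +inf when the smaller is 0), direction and category.
    """
    wild = list(wild_set)
    dom = list(domesticated_set)
    if not wild or not dom:
        raise ValueError("both accession sets must be non-empty")
    if set(wild) & set(dom):
        raise ValueError("wild and domesticated sets overlap")

    present_dom = pav.presence[dom].sum(axis=1).to_numpy()
    present_wild = pav.presence[wild].sum(axis=1).to_numpy()
    n_dom, n_wild = len(dom), len(wild)
    freq_dom = present_dom / n_dom
    freq_wild = present_wild / n_wild

    p_values = np.empty(pav.n_genes)
    for i in range(pav.n_genes):
        a = int(present_dom[i])            # present, domesticated
        b = n_dom - a                      # absent, domesticated
        c = int(present_wild[i])           # present, wild
        d = n_wild - c                     # absent, wild
        p_values[i], _ = fisher_exact_2x2(a, b, c, d)
    fdr = bh_fdr(p_values)

    fold = np.array([_fold_change(fw, fd) for fw, fd in zip(freq_wild, freq_dom)])
    direction = np.where(
        freq_dom > freq_wild, "domesticated_higher",
        np.where(freq_wild > freq_dom, "wild_higher", "equal"),
    )
    passes = (fdr < fdr_max) & (fold > fold_min)
    category = np.full(pav.n_genes, "none", dtype=object)
    category[passes & (freq_dom > freq_wild)] = "favorable"
    category[passes & (freq_wild > freq_dom)] = "unfavorable"

    return pd.DataFrame(
        {
            "present_dom": present_dom,
            "absent_dom": n_dom - present_dom,
            "present_wild": present_wild,
            "absent_wild": n_wild - present_wild,
            "freq_wild": freq_wild,
            "freq_dom": freq_dom,
            "p_value": p_values,
            "fdr": fdr,
            "fold_change": fold,
            "direction": direction,
            "category": category,
        },
        index=pd.Index(pav.gene_ids, name="gene_id"),
    )


def partition_favorable(
    favorable: pd.DataFrame | Sequence[str],
    pav: PavMatrix,
    landrace_set: Sequence[str],
    cultivar_set: Sequence[str],
) -> tuple[list[str], list[str], list[str]]:
    """Split favorable genes into landrace-favorable and cultivar-favorable.

    A favorable gene is landrace-favorable when its landrace presence
    frequency exceeds its cultivar frequency, cultivar-favorable in the
    opposite case; exact ties go to a separate tie bucket.
    """
    if isinstance(favorable, pd.DataFrame):
        gene_ids = list(favorable.index[favorable["category"] == "favorable"])
    else:
        gene_ids = list(favorable)
    if set(landrace_set) & set(cultivar_set):
        raise ValueError("landrace and cultivar sets overlap")
    f_land = presence_frequency(pav, landrace_set).loc[gene_ids]
    f_cult = presence_frequency(pav, cultivar_set).loc[gene_ids]
    landrace_fav = [g for g in gene_ids if f_land[g] > f_cult[g]]
    cultivar_fav = [g for g in gene_ids if f_cult[g] > f_land[g]]
    ties = [g for g in gene_ids if f_land[g] == f_cult[g]]
    return landrace_fav, cultivar_fav, ties


def term_enrichment(
    gene_set: Sequence[str],
    background_genes: Sequence[str],
    term_map: Mapping[str, Sequence[str]],
    fdr_max: float = 0.05,
) -> pd.DataFrame:
    """Flat Fisher term enrichment of a gene set against a background.

    For every term, a one-per-term 2x2 Fisher test of (in gene_set / not)
    x (annotated with term / not) over the background, BH-corrected across
    terms. Returns all terms sorted by FDR with a ``significant`` flag at
    ``fdr_max``. Term-to-term (DAG) relations are not modelled.
    """
    genes_in = set(gene_set)
    background = list(dict.fromkeys(background_genes))
    if not genes_in:
        raise ValueError("empty gene set")
    if not genes_in <= set(background):
        raise ValueError("gene_set must be a subset of the background")

    term_genes: dict[str, set[str]] = {}
    for gene in background:
        for term in term_map.get(gene, ()):
            term_genes.setdefault(term, set()).add(gene)

    N = len(background)
    n_in = len(genes_in)
    rows = []
    for term in sorted(term_genes):
        annotated = term_genes[term]
        k = len(annotated & genes_in)      # in set, with term
        K = len(annotated)                 # background with term
        p, _ = fisher_exact_2x2(k, n_in - k, K - k, N - n_in - (K - k))
        rows.append({"term": term, "set_with_term": k, "set_size": n_in,
                     "background_with_term": K, "background_size": N, "p_value": p})
    table = pd.DataFrame(rows)
    if len(table):
        table["fdr"] = bh_fdr(table["p_value"].to_numpy())
        table["significant"] = table["fdr"] < fdr_max
        table = table.sort_values(["fdr", "p_value", "term"]).reset_index(drop=True)
    return table
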