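"""Depth-adaptive gene absence calling from per-base coverage.

A gene is called absent in an accession when less than 20% of its exonic
bases are covered by at least *n* reads, where *n* steps with the
accession's mean sequencing depth: n = 2, 4, 6, 8 or 10 for mean depths
of 0-10, 11-20, 21-40, 41-80 and above 80, respectively. This re-creates
the map-to-pan PAV-calling rule from depth tracks, without read mapping.
"""

from __future__ import annotations

from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .types import AccessionProfile, GeneModel, PavMatrix, profiles_frame, profiles_from_frame

__all__ = [
    "min_reads_threshold",
    "covered_exon_fraction",
    "call_gene",
    "build_pav_matrix",
    "ABSENCE_FRACTION",
]

#: A gene is absent when fewer than this fraction of exonic bases is covered.
ABSENCE_FRACTION = 0.20

DepthTrack = Mapping[str, np.ndarray]


def min_reads_threshold(mean_depth: float) -> int:
    """Minimum read depth *n* for a base to count as covered.

    Piecewise-constant in mean depth: [0, 10] -> 2, (10, 20] -> 4,
    (20, 40] -> 6, (40, 80] -> 8, above 80 -> 10.
    """
    if mean_depth < 0:
        raise ValueError("mean depth must be non-negative")
    if mean_depth <= 10:
        return 2
    if mean_depth <= 20:
        return 4
    if mean_depth <= 40:
        return 6
    if mean_depth <= 80:
        return 8
    return 10


def covered_exon_fraction(gene_model: GeneModel, depth_track: DepthTrack, n: int) -> float:
    """Fraction of the gene's exonic bases with depth >= n (inclusive)."""
    if gene_model.sequence_id not in depth_track:
        raise ValueError(
            f"gene {gene_model.gene_id} lies on unknown sequence {gene_model.sequence_id!r}"
        )
    depth = depth_track[gene_model.sequence_id]
    covered = 0
    total = 0
    for s, e in gene_model.exons:
        covered += int(np.count_nonzero(depth[s:e] >= n))
        total += e - s
    return covered / total


def call_gene(
    gene_model: GeneModel,
    accession_profile: AccessionProfile,
    depth_track: DepthTrack,
) -> str:
    """``"absent"`` iff covered exon fraction < 0.20 at the depth-adaptive
    threshold, ``"present"`` otherwise (boundary 0.20 itself is present:
    the rule is strict "less than 20%")."""
    n = min_reads_threshold(accession_profile.mean_depth)
    fraction = covered_exon_fraction(gene_model, depth_track, n)
    return "absent" if fraction < ABSENCE_FRACTION else "present"


def build_pav_matrix(
    gene_models: Sequence[GeneModel],
    profiles: Sequence[AccessionProfile] | pd.DataFrame,
    depth_tracks: Mapping[str, DepthTrack] | Callable[[str], DepthTrack],
) -> PavMatrix:
    """Call every gene in every accession and assemble the binary matrix.

    ``depth_tracks`` maps accession id to a depth track, or is a callable
    returning one (so tracks can be generated or read lazily, one
    accession at a time). Rows are genes, columns accessions, 1 = present.
    """
    if isinstance(profiles, pd.DataFrame):
        profile_frame = profiles
        profile_list = profiles_from_frame(profiles)
    else:
        profile_list = list(profiles)
        profile_frame = profiles_frame(profile_list)

    get_track: Callable[[str], DepthTrack]
    if callable(depth_tracks):
        get_track = depth_tracks
    else:
        def get_track(acc: str) -> DepthTrack:
            if acc not in depth_tracks:
                raise ValueError(f"no depth track for accession {acc!r}")
            return depth_tracks[acc]

    gene_ids = [gm.gene_id for gm in gene_models]
    presence = np.zeros((len(gene_models), len(profile_list)), dtype=np.int8)
    # Exonic slices are precomputed once; the per-accession loop then only
    # thresholds and counts.
    for j, profile in enumerate(profile_list):
        track = get_track(profile.accession_id)
        n = min_reads_threshold(profile.mean_depth)
        for i, gm in enumerate(gene_models):
            if gm.sequence_id not in track:
                raise ValueError(
                    f"accession {profile.accession_id!r} track lacks sequence "
                    f"{gm.sequence_id!r} needed by gene {gm.gene_id}"
                )
            depth = track[gm.sequence_id]
            covered = 0
            total = 0
            for s, e in gm.exons:
                covered += int(np.count_nonzero(depth[s:e] >= n))
                total += e - s
            presence[i, j] = 1 if covered / total >= ABSENCE_FRACTION else 0

    matrix = pd.DataFrame(
        presence,
        index=pd.Index(gene_ids, name="gene_id"),
        columns=[p.accession_id for p in profile_list],
    )
    return PavMatrix(matrix, profile_frame)


def mean_depth_from_track(track: DepthTrack) -> float:
    """Average depth over the whole pangenome; the fallback estimator when
    metadata does not supply a mean depth."""
    total_depth = sum(float(np.sum(arr, dtype=np.float64)) for arr in track.values())
    total_len = sum(arr.size for arr in track.values())
    if total_len == 0:
        raise ValueError("empty depth track")
    return total_depth / total_len
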