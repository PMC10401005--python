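"""Map-to-pan non-reference sequence extraction.

The pipeline mirrors the construction of a superpangenome from de novo
contigs aligned against a reference: alignment hits are filtered (>=300 bp,
>=90% identity), continuous unaligned regions of at least 500 bp are
extracted, contigs dominated by non-green-plant database hits are removed
as contaminants, near-duplicate segments are collapsed (95% identity /
95% coverage, greedy longest-first), and the survivors are concatenated
with the reference to form the pangenome. All operations consume alignment
*records*; no aligner is invoked.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import Align

from .types import AlignmentHit, NonrefSegment, TaxonHit

__all__ = [
    "filter_hits",
    "covered_intervals",
    "extract_unaligned",
    "classify_contamination",
    "pairwise_identity",
    "remove_redundancy",
    "build_pangenome",
]


def filter_hits(
    hits: Iterable[AlignmentHit],
    min_len: int = 300,
    min_identity: float = 90.0,
) -> list[AlignmentHit]:
    """Keep hits with alignment_length >= min_len and identity >= min_identity.

    Both bounds are inclusive ("minimum of 300-bp alignment length and 90%
    identity"). Input order is preserved.
    """
    return [
        h for h in hits
        if h.alignment_length >= min_len and h.identity >= min_identity
    ]


def covered_intervals(
    hits_for_one_query: Iterable[AlignmentHit | tuple[int, int]],
) -> list[tuple[int, int]]:
    """Union of query intervals, sorted, with overlapping and adjacent
    intervals merged. Accepts AlignmentHit records or raw (start, end) pairs;
    all hits must share one query."""
    raw: list[tuple[int, int]] = []
    query_ids = set()
    for h in hits_for_one_query:
        if isinstance(h, AlignmentHit):
            query_ids.add(h.query_id)
            raw.append((h.query_start, h.query_end))
        else:
            raw.append((int(h[0]), int(h[1])))
    if len(query_ids) > 1:
        raise ValueError(f"hits span multiple queries: {sorted(query_ids)}")
    if not raw:
        return []
    raw.sort()
    merged = [raw[0]]
    for s, e in raw[1:]:
        ps, pe = merged[-1]
        if s <= pe:  # overlap or adjacency
            merged[-1] = (ps, max(pe, e))
        else:
            merged.append((s, e))
    return merged


def extract_unaligned(
    contig_id: str,
    contig_sequence: str,
    covered: Sequence[tuple[int, int]],
    min_unaligned: int = 500,
) -> list[NonrefSegment]:
    """Extract maximal uncovered runs of at least ``min_unaligned`` bases.

    A contig with no hits at all is returned whole iff it is long enough
    ("Sequences that did not align ... were kept as unaligned sequences");
    otherwise each continuous unaligned region >= min_unaligned is emitted
    ("containing a continuous unaligned region of at least 500 bp").
    """
    length = len(contig_sequence)
    for s, e in covered:
        if s < 0 or e > length or e <= s:
            raise ValueError(
                f"covered interval [{s}, {e}) out of bounds for {contig_id} (length {length})"
            )
    segments: list[NonrefSegment] = []
    pos = 0
    for s, e in sorted(covered) + [(length, length)]:
        if s - pos >= min_unaligned:
            segments.append(
                NonrefSegment(contig_id, pos, s, contig_sequence[pos:s])
            )
        pos = max(pos, e)
    return segments


def classify_contamination(
    contig_id: str,
    taxon_hits: Iterable[TaxonHit],
    green_fraction_min: float = 0.90,
) -> str:
    """Contamination decision for one contig: ``"keep"`` or ``"remove"``.

    Only green-plant hits -> keep; only other hits -> remove; both ->
    keep iff green-covered bases make up at least ``green_fraction_min``
    of the union of all hit-covered bases. Contigs with no hits are kept:
    the screen removes identified contaminants, not unclassified sequence.
    """
    hits = list(taxon_hits)
    for h in hits:
        if h.query_id != contig_id:
            raise ValueError(f"taxon hit for {h.query_id} passed with contig {contig_id}")
    if not hits:
        return "keep"
    classes = {h.taxon_class for h in hits}
    if classes == {"green_plant"}:
        return "keep"
    if classes == {"other"}:
        return "remove"
    all_cov = covered_intervals([(h.query_start, h.query_end) for h in hits])
    green_cov = covered_intervals(
        [(h.query_start, h.query_end) for h in hits if h.taxon_class == "green_plant"]
    )
    total = sum(e - s for s, e in all_cov)
    green = sum(e - s for s, e in green_cov)
    return "keep" if green / total >= green_fraction_min else "remove"


# ---------------------------------------------------------------------------
# Pairwise identity / redundancy removal

def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -2
    # free end gaps for the longer sequence's overhang only: the shorter
    # sequence is aligned globally (cd-hit's "identity with respect to the
    # shorter sequence" convention)
    try:
        aligner.end_insertion_score = 0
    except AttributeError:  # Biopython < 1.86 naming
        aligner.target_end_gap_score = 0
    return aligner


def pairwise_identity(seq_a: str, seq_b: str) -> tuple[float, float]:
    """Percent identity and percent coverage of the shorter sequence under
    an optimal global alignment of the shorter sequence against the longer
    (match +1, mismatch -1, gap -2; the longer sequence's terminal
    overhang is not penalised or counted).

    Identity is matches / alignment columns between the first and last
    aligned pair; coverage is the aligned span on the shorter sequence
    divided by its length. Intended for synthetic-scale sequences
    (<= ~50 kb); quadratic in length.
    """
    if not seq_a or not seq_b:
        raise ValueError("empty sequence")
    seq_a, seq_b = seq_a.upper(), seq_b.upper()
    shorter, longer = (seq_a, seq_b) if len(seq_a) <= len(seq_b) else (seq_b, seq_a)
    aligner = _make_aligner()
    aln = aligner.align(shorter, longer)[0]
    blocks_s, blocks_l = aln.aligned
    if len(blocks_s) == 0:
        return 0.0, 0.0
    matches = 0
    aligned_pairs = 0
    for (ss, se), (ls, le) in zip(blocks_s, blocks_l):
        sub_s, sub_l = shorter[ss:se], longer[ls:le]
        matches += sum(x == y for x, y in zip(sub_s, sub_l))
        aligned_pairs += se - ss
    span_s = blocks_s[-1][1] - blocks_s[0][0]
    span_l = blocks_l[-1][1] - blocks_l[0][0]
    columns = span_s + span_l - aligned_pairs  # aligned pairs + internal gaps
    identity = 100.0 * matches / columns
    coverage = 100.0 * span_s / len(shorter)
    return identity, coverage


def remove_redundancy(
    segments: Sequence[NonrefSegment],
    min_identity: float = 95.0,
    min_coverage: float = 95.0,
    identity_fn=pairwise_identity,
) -> tuple[list[NonrefSegment], dict[str, str]]:
    """Greedy longest-first clustering at 95% identity / 95% coverage.

    Segments are sorted by length descending (ties by input order); each
    segment joins the first existing representative it matches at both
    thresholds (coverage measured on the shorter sequence, cd-hit style),
    else founds a new cluster. Returns the representatives in rank order
    and a total map segment_id -> representative segment_id.
    """
    if not segments:
        raise ValueError("no segments to cluster")
    order = sorted(range(len(segments)), key=lambda i: (-len(segments[i]), i))
    representatives: list[NonrefSegment] = []
    cluster_map: dict[str, str] = {}
    for i in order:
        seg = segments[i]
        assigned = False
        for rep in representatives:
            identity, coverage = identity_fn(seg.sequence, rep.sequence)
            if identity >= min_identity and coverage >= min_coverage:
                cluster_map[seg.segment_id] = rep.segment_id
                assigned = True
                break
        if not assigned:
            representatives.append(seg)
            cluster_map[seg.segment_id] = seg.segment_id
    return representatives, cluster_map


def extract_nonref(
    contigs: Mapping[str, str],
    hits: Iterable[AlignmentHit],
    taxon_hits: Iterable[TaxonHit] = (),
    min_len: int = 300,
    min_identity: float = 90.0,
    min_unaligned: int = 500,
    redundancy_identity: float = 95.0,
    redundancy_coverage: float = 95.0,
) -> tuple[list[NonrefSegment], dict[str, str], list[str]]:
    """Run the full non-reference extraction cascade on a contig set.

    Hit filtering -> contamination screen (contig level, applied before
    extraction so contaminant contigs contribute no segments) -> unaligned
    region extraction -> redundancy removal. Returns the non-redundant
    representatives, the cluster map, and the list of contigs removed as
    contaminants.
    """
    kept_hits = filter_hits(hits, min_len=min_len, min_identity=min_identity)
    hits_by_query: dict[str, list[AlignmentHit]] = {}
    for h in kept_hits:
        hits_by_query.setdefault(h.query_id, []).append(h)
    tax_by_query: dict[str, list[TaxonHit]] = {}
    for t in taxon_hits:
        tax_by_query.setdefault(t.query_id, []).append(t)

    removed: list[str] = []
    segments: list[NonrefSegment] = []
    for contig_id, seq in contigs.items():
        verdict = classify_contamination(contig_id, tax_by_query.get(contig_id, []))
        if verdict == "remove":
            removed.append(contig_id)
            continue
        covered = covered_intervals(hits_by_query.get(contig_id, []))
        segments.extend(
            extract_unaligned(contig_id, seq, covered, min_unaligned=min_unaligned)
        )
    if not segments:
        return [], {}, removed
    representatives, cluster_map = remove_redundancy(
        segments, min_identity=redundancy_identity, min_coverage=redundancy_coverage
    )
    return representatives, cluster_map, removed


def build_pangenome(
    reference_sequences: Mapping[str, str],
    nonref_representatives: Sequence[NonrefSegment],
) -> tuple[dict[str, str], pd.DataFrame]:
    """Concatenate reference sequences with non-redundant segments.

    Reference sequences come first under their own ids; each segment is
    namespaced ``nonref_<k>`` with provenance kept in the manifest
    (pangenome_id, source, start, end, length, kind).
    """
    pangenome: dict[str, str] = {}
    rows = []
    for ref_id, seq in reference_sequences.items():
        if ref_id in pangenome:
            raise ValueError(f"duplicate sequence id {ref_id!r}")
        pangenome[ref_id] = seq
        rows.append(
            {"pangenome_id": ref_id, "source": ref_id, "start": 0,
             "end": len(seq), "length": len(seq), "kind": "reference"}
        )
    for k, seg in enumerate(nonref_representatives, start=1):
        pan_id = f"nonref_{k:05d}"
        if pan_id in pangenome:
            raise ValueError(f"duplicate sequence id {pan_id!r}")
        pangenome[pan_id] = seg.sequence
        rows.append(
            {"pangenome_id": pan_id, "source": seg.source_contig,
             "start": seg.start, "end": seg.end, "length": len(seg),
             "kind": "nonref"}
        )
    manifest = pd.DataFrame(
        rows, columns=["pangenome_id", "source", "start", "end", "length", "kind"]
    )
    return pangenome, manifest
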