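"""Readers and writers for the plain-text formats the pipeline consumes.

PAF and bedGraph are native 0-based half-open and are read as-is; GFF3 is
1-based closed and converted on read/write. FASTA goes through Biopython.
"""

from __future__ import annotations

import os
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .types import AccessionProfile, AlignmentHit, GeneModel, PavMatrix, TaxonHit, profiles_frame

__all__ = [
    "read_paf",
    "write_paf",
    "read_fasta",
    "write_fasta",
    "read_taxon_hits",
    "write_taxon_hits",
    "read_bedgraph",
    "write_bedgraph",
    "read_gff3",
    "write_gff3",
    "read_pav_tsv",
    "write_pav_tsv",
    "read_metadata_tsv",
    "write_metadata_tsv",
]


# ---------------------------------------------------------------------------
# PAF

def read_paf(path: str) -> list[AlignmentHit]:
    """Read the 12 mandatory PAF columns into AlignmentHit records.

    Identity is taken from a ``de:f`` divergence tag when present, else
    derived as 100 * matches / alignment-block-length (columns 10/11).
    """
    hits: list[AlignmentHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise ValueError(f"{path}:{lineno}: expected >= 12 PAF columns")
            try:
                qname, qlen, qstart, qend, strand, tname = fields[:6]
                nmatch, alnlen = int(fields[9]), int(fields[10])
                identity = None
                for tag in fields[12:]:
                    if tag.startswith("de:f:"):
                        identity = 100.0 * (1.0 - float(tag[5:]))
                if identity is None:
                    identity = 100.0 * nmatch / alnlen
                hit = AlignmentHit(
                    query_id=qname,
                    query_length=int(qlen),
                    query_start=int(qstart),
                    query_end=int(qend),
                    target_id=tname,
                    identity=identity,
                    alignment_length=alnlen,
                    strand=strand,
                )
            except (ValueError, IndexError) as exc:
                raise ValueError(f"{path}:{lineno}: malformed PAF record: {exc}") from exc
            hits.append(hit)
    return hits


def write_paf(hits: Iterable[AlignmentHit], path: str, target_length: int = 0) -> None:
    """Write hits as minimal 12-column PAF (target coordinates zeroed when
    unknown; matches back-computed from identity)."""
    with open(path, "w") as fh:
        for h in hits:
            nmatch = int(round(h.alignment_length * h.identity / 100.0))
            fields = [
                h.query_id, h.query_length, h.query_start, h.query_end,
                h.strand, h.target_id, target_length, 0, h.alignment_length,
                nmatch, h.alignment_length, 255,
            ]
            fh.write("\t".join(str(f) for f in fields) + "\n")


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")}


def write_fasta(sequences: Mapping[str, str], path: str) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()]
    SeqIO.write(records, path, "fasta")


# ---------------------------------------------------------------------------
# Taxon-hit TSV (query_id, start, end, taxon_class)

def read_taxon_hits(path: str) -> list[TaxonHit]:
    df = pd.read_csv(path, sep="\t")
    return [
        TaxonHit(str(r.query_id), int(r.query_start), int(r.query_end), str(r.taxon_class))
        for r in df.itertuples()
    ]


def write_taxon_hits(hits: Iterable[TaxonHit], path: str) -> None:
    rows = [
        {"query_id": h.query_id, "query_start": h.query_start,
         "query_end": h.query_end, "taxon_class": h.taxon_class}
        for h in hits
    ]
    pd.DataFrame(rows, columns=["query_id", "query_start", "query_end", "taxon_class"]).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# bedGraph depth tracks

def write_bedgraph(track: Mapping[str, np.ndarray], path: str) -> None:
    """Write a per-base depth track run-length-encoded as bedGraph."""
    with open(path, "w") as fh:
        for seq_id in track:
            depth = np.asarray(track[seq_id])
            if depth.size == 0:
                continue
            change = np.flatnonzero(np.diff(depth)) + 1
            starts = np.concatenate([[0], change])
            ends = np.concatenate([change, [depth.size]])
            for s, e in zip(starts, ends):
                v = depth[s]
                if v != 0:
                    fh.write(f"{seq_id}\t{s}\t{e}\t{int(v)}\n")


def read_bedgraph(path: str, sequence_lengths: Mapping[str, int]) -> dict[str, np.ndarray]:
    """Read bedGraph into dense per-base arrays (zero-filled between runs)."""
    track = {
        seq_id: np.zeros(length, dtype=np.int32)
        for seq_id, length in sequence_lengths.items()
    }
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("track", "#")):
                continue
            seq_id, start, end, value = line.split("\t")
            if seq_id not in track:
                raise ValueError(f"{path}:{lineno}: unknown sequence {seq_id!r}")
            track[seq_id][int(start):int(end)] = int(float(value))
    return track


# ---------------------------------------------------------------------------
# GFF3 gene models (1-based closed on disk, half-open in memory)

def write_gff3(gene_models: Iterable[GeneModel], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for gm in gene_models:
            g_start, g_end = gm.span
            fh.write(
                f"{gm.sequence_id}\tpanpav\tgene\t{g_start + 1}\t{g_end}\t.\t+\t.\t"
                f"ID={gm.gene_id}\n"
            )
            for i, (s, e) in enumerate(gm.exons, start=1):
                fh.write(
                    f"{gm.sequence_id}\tpanpav\texon\t{s + 1}\t{e}\t.\t+\t.\t"
                    f"ID={gm.gene_id}.exon{i};Parent={gm.gene_id}\n"
                )


def read_gff3(path: str) -> list[GeneModel]:
    """Read gene/exon features into GeneModel records via gffutils."""
    import gffutils

    db = gffutils.create_db(
        path, dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    models = []
    for gene in db.features_of_type("gene", order_by=("seqid", "start")):
        exons = [
            (exon.start - 1, exon.end)
            for exon in db.children(gene, featuretype="exon", order_by="start")
        ]
        if not exons:
            exons = [(gene.start - 1, gene.end)]
        models.append(GeneModel(gene_id=gene.id, sequence_id=gene.seqid, exons=tuple(exons)))
    return models


# ---------------------------------------------------------------------------
# PAV matrix and metadata TSV

def write_pav_tsv(pav: PavMatrix, path: str) -> None:
    out = pav.presence.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t")


def read_pav_tsv(path: str, metadata_path: str | None = None) -> PavMatrix:
    presence = pd.read_csv(path, sep="\t", index_col="gene_id")
    profiles = read_metadata_tsv(metadata_path) if metadata_path else None
    return PavMatrix(presence, profiles)


def write_metadata_tsv(profiles: pd.DataFrame | Iterable[AccessionProfile], path: str) -> None:
    if not isinstance(profiles, pd.DataFrame):
        profiles = profiles_frame(profiles)
    profiles.to_csv(path, sep="\t")


def read_metadata_tsv(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="accession_id")
    if "in_vitro" in df.columns:
        df["in_vitro"] = df["in_vitro"].astype(bool)
    return df
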