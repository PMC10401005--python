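"""Core domain containers shared across the pipeline.

Coordinates are 0-based half-open throughout. File formats with other
conventions (GFF3) are converted on read/write by :mod:`panpav.io`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AlignmentHit",
    "TaxonHit",
    "NonrefSegment",
    "GeneModel",
    "AccessionProfile",
    "PavMatrix",
]

GROUPS = ("wild", "landrace", "cultivar")


@dataclass(frozen=True)
class AlignmentHit:
    """One query-to-reference local alignment record (PAF-like).

    ``identity`` is a percentage in [0, 100]; ``alignment_length`` counts
    alignment columns and may exceed the query span because of gaps.
    """

    query_id: str
    query_length: int
    query_start: int
    query_end: int
    target_id: str
    identity: float
    alignment_length: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0 <= self.query_start < self.query_end <= self.query_length):
            raise ValueError(
                f"invalid query coordinates for {self.query_id}: "
                f"[{self.query_start}, {self.query_end}) on length {self.query_length}"
            )
        if self.alignment_length < 1:
            raise ValueError("alignment_length must be >= 1")
        if not (0.0 <= self.identity <= 100.0):
            raise ValueError("identity must be a percentage in [0, 100]")


@dataclass(frozen=True)
class TaxonHit:
    """A taxonomic database hit on a query interval.

    ``taxon_class`` is ``"green_plant"`` for Viridiplantae hits and
    ``"other"`` for everything else (including adaptor/organellar screens,
    which are expressed as a second non-green class).
    """

    query_id: str
    query_start: int
    query_end: int
    taxon_class: str

    def __post_init__(self) -> None:
        if not (0 <= self.query_start < self.query_end):
            raise ValueError("invalid taxon-hit interval")
        if self.taxon_class not in ("green_plant", "other"):
            raise ValueError(f"unknown taxon_class {self.taxon_class!r}")


@dataclass(frozen=True)
class NonrefSegment:
    """A non-reference sequence segment extracted from a source contig."""

    source_contig: str
    start: int
    end: int
    sequence: str = ""

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("empty segment interval")
        if self.sequence and len(self.sequence) != self.end - self.start:
            raise ValueError("sequence length does not match interval")

    @property
    def segment_id(self) -> str:
        return f"{self.source_contig}:{self.start}-{self.end}"

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class GeneModel:
    """A gene's exon intervals (0-based half-open) on a pangenome sequence."""

    gene_id: str
    sequence_id: str
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        exons = tuple(sorted((int(s), int(e)) for s, e in self.exons))
        object.__setattr__(self, "exons", exons)
        total = 0
        prev_end = -1
        for s, e in exons:
            if s < 0 or e <= s:
                raise ValueError(f"invalid exon [{s}, {e}) in {self.gene_id}")
            if s < prev_end:
                raise ValueError(f"overlapping exons in {self.gene_id}")
            prev_end = e
            total += e - s
        if total < 1:
            raise ValueError(f"gene {self.gene_id} has no exonic bases")

    @property
    def exonic_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]


@dataclass(frozen=True)
class AccessionProfile:
    """Per-accession metadata: sequencing depth, domestication group,
    clade, ploidy and in-vitro propagation flag."""

    accession_id: str
    mean_depth: float
    group: str
    clade: str
    ploidy: int = 2
    in_vitro: bool = False

    def __post_init__(self) -> None:
        if self.mean_depth < 0:
            raise ValueError("mean_depth must be non-negative")
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}, got {self.group!r}")
        if self.ploidy not in (2, 3, 4, 5):
            raise ValueError("ploidy must be in {2, 3, 4, 5}")


class PavMatrix:
    """Genes x accessions binary presence matrix plus accession metadata.

    The presence state is held as an int8 DataFrame (1 = present) indexed by
    gene id with one column per accession. ``profiles`` is a DataFrame
    indexed by accession id with columns ``mean_depth``, ``group``,
    ``clade``, ``ploidy``, ``in_vitro``; it may be empty when metadata is
    not needed.
    """

    def __init__(self, presence: pd.DataFrame, profiles: pd.DataFrame | None = None):
        values = presence.to_numpy()
        if values.size and not np.isin(np.unique(values), [0, 1]).all():
            raise ValueError("presence matrix entries must be 0/1")
        self.presence = presence.astype(np.int8)
        if profiles is None:
            profiles = pd.DataFrame(index=pd.Index(presence.columns, name="accession_id"))
        missing = set(presence.columns) - set(profiles.index)
        if missing and len(profiles.columns):
            raise ValueError(f"profiles missing accessions: {sorted(missing)}")
        self.profiles = profiles

    # -- basic accessors -------------------------------------------------

    @property
    def gene_ids(self) -> list[str]:
        return list(self.presence.index)

    @property
    def accession_ids(self) -> list[str]:
        return list(self.presence.columns)

    @property
    def n_genes(self) -> int:
        return self.presence.shape[0]

    @property
    def n_accessions(self) -> int:
        return self.presence.shape[1]

    def gene_counts(self) -> pd.Series:
        """Number of present genes per accession."""
        return self.presence.sum(axis=0)

    def frequencies(self) -> pd.Series:
        """Per-gene presence frequency across all accessions."""
        return self.presence.mean(axis=1)

    def accession_profiles(self) -> dict[str, AccessionProfile]:
        out = {}
        for acc, row in self.profiles.iterrows():
            out[acc] = AccessionProfile(
                accession_id=str(acc),
                mean_depth=float(row["mean_depth"]),
                group=str(row["group"]),
                clade=str(row["clade"]),
                ploidy=int(row.get("ploidy", 2)),
                in_vitro=bool(row.get("in_vitro", False)),
            )
        return out

    def subset_accessions(self, accessions: Sequence[str]) -> "PavMatrix":
        accessions = list(accessions)
        profiles = (
            self.profiles.loc[accessions] if len(self.profiles.columns) else None
        )
        return PavMatrix(self.presence[accessions], profiles)

    def group_accessions(self, group: str) -> list[str]:
        if "group" not in self.profiles.columns:
            raise ValueError("no group metadata attached")
        return list(self.profiles.index[self.profiles["group"] == group])

    def clade_map(self) -> dict[str, str]:
        if "clade" not in self.profiles.columns:
            raise ValueError("no clade metadata attached")
        return {str(a): str(c) for a, c in self.profiles["clade"].items()}

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PavMatrix):
            return NotImplemented
        return self.presence.equals(other.presence)

    def __repr__(self) -> str:
        return f"PavMatrix({self.n_genes} genes x {self.n_accessions} accessions)"


def profiles_from_frame(df: pd.DataFrame) -> list[AccessionProfile]:
    """Parse the metadata DataFrame layout back into AccessionProfile records."""
    return [
        AccessionProfile(
            accession_id=str(acc),
            mean_depth=float(row["mean_depth"]),
            group=str(row["group"]),
            clade=str(row["clade"]),
            ploidy=int(row.get("ploidy", 2)),
            in_vitro=bool(row.get("in_vitro", False)),
        )
        for acc, row in df.iterrows()
    ]


def profiles_frame(profiles: Iterable[AccessionProfile]) -> pd.DataFrame:
    """Assemble AccessionProfile records into the metadata DataFrame layout."""
    rows = [
        {
            "accession_id": p.accession_id,
            "mean_depth": p.mean_depth,
            "group": p.group,
            "clade": p.clade,
            "ploidy": p.ploidy,
            "in_vitro": p.in_vitro,
        }
        for p in profiles
    ]
    return pd.DataFrame(rows).set_index("accession_id")
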