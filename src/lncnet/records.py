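"""Core record types shared across the pipeline.

Coordinate convention
---------------------
All genomic intervals held in memory are **0-based, half-open** ``[start, end)``.
GTF input/output converts from/to the 1-based inclusive convention at the file
boundary (see :mod:`lncnet.io`), so that interval arithmetic everywhere else is
uniform.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import ConfigError

VALID_STRANDS = ("+", "-", ".")
CONDITIONS = ("control", "infected")
TIME_POINTS = (4, 12, 48)


@dataclass
class TranscriptModel:
    """A transcript: location, strand, exon chain and (optionally) sequence.

    ``exons`` are 0-based half-open intervals in genomic coordinates, sorted
    ascending and non-overlapping.  ``sequence`` is the spliced transcript
    sequence (5'->3' on the transcript strand for stranded input); when present
    its length must equal the summed exon length.
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    sequence: str | None = None

    def __post_init__(self) -> None:
        if not self.transcript_id:
            raise ValueError("transcript_id must be non-empty")
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"invalid strand {self.strand!r} for {self.transcript_id}")
        exons = tuple((int(s), int(e)) for s, e in self.exons)
        if not exons:
            raise ValueError(f"{self.transcript_id}: exon chain must be non-empty")
        for s, e in exons:
            if s < 0 or e <= s:
                raise ValueError(
                    f"{self.transcript_id}: invalid exon [{s}, {e}) (need 0 <= start < end)"
                )
        if any(exons[i][1] > exons[i + 1][0] for i in range(len(exons) - 1)):
            raise ValueError(f"{self.transcript_id}: exons must be sorted and non-overlapping")
        self.exons = exons
        if self.sequence is not None and len(self.sequence) != self.length:
            raise ValueError(
                f"{self.transcript_id}: sequence length {len(self.sequence)} != "
                f"summed exon length {self.length}"
            )

    @property
    def length(self) -> int:
        """Spliced transcript length in nucleotides."""
        return sum(e - s for s, e in self.exons)

    @property
    def span(self) -> tuple[int, int]:
        """Genomic span [start, end) covered by the exon chain."""
        return self.exons[0][0], self.exons[-1][1]

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        """Intron intervals between consecutive exons (may be empty)."""
        return tuple(
            (self.exons[i][1], self.exons[i + 1][0]) for i in range(len(self.exons) - 1)
        )

    def with_sequence(self, sequence: str) -> "TranscriptModel":
        return TranscriptModel(
            self.transcript_id, self.gene_id, self.chrom, self.strand, self.exons, sequence
        )


@dataclass(frozen=True)
class HomologyHit:
    """One row of a 12-column tabular homology search result."""

    query_id: str
    subject_id: str
    percent_identity: float
    align_length: int
    evalue: float
    bitscore: float

    def __post_init__(self) -> None:
        if not self.query_id:
            raise ValueError("query_id must be non-empty")
        if self.evalue < 0:
            raise ValueError(f"negative evalue {self.evalue} for {self.query_id}")


@dataclass(frozen=True)
class DomainHit:
    """A protein domain/motif hit for a transcript (query, accession, E-value)."""

    query_id: str
    domain_accession: str
    domain_evalue: float

    def __post_init__(self) -> None:
        if not self.query_id:
            raise ValueError("query_id must be non-empty")
        if self.domain_evalue < 0:
            raise ValueError("domain_evalue must be >= 0")


@dataclass(frozen=True)
class LibraryInfo:
    """One sequencing library of the condition x time x replicate design."""

    library_id: str
    condition: str
    time_h: int
    replicate: int

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(f"condition must be one of {CONDITIONS}, got {self.condition!r}")
        if self.time_h not in TIME_POINTS:
            raise ValueError(f"time_h must be one of {TIME_POINTS}, got {self.time_h!r}")
        if self.replicate < 1:
            raise ValueError("replicate must be a positive integer")


class CountMatrix:
    """Transcripts x libraries expression values with library metadata.

    Thin, validated wrapper around a :class:`pandas.DataFrame` whose index is
    the transcript ids and whose columns are the library ids (in the order of
    ``libraries``).
    """

    def __init__(self, counts: pd.DataFrame, libraries: Sequence[LibraryInfo]):
        libraries = list(libraries)
        lib_ids = [l.library_id for l in libraries]
        if len(set(lib_ids)) != len(lib_ids):
            raise ValueError("duplicate library ids")
        keys = {(l.condition, l.time_h, l.replicate) for l in libraries}
        if len(keys) != len(libraries):
            raise ValueError("(condition, time_h, replicate) must be unique across libraries")
        if list(counts.columns) != lib_ids:
            raise ValueError("count matrix columns must match library ids (same order)")
        if counts.index.has_duplicates:
            dup = counts.index[counts.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate transcript ids in count matrix: {dup[:5]}")
        values = counts.to_numpy(dtype=float)
        if np.any(values < 0) or not np.all(np.isfinite(values)):
            raise ValueError("counts must be finite and non-negative")
        self.counts = counts.astype(float)
        self.libraries = libraries

    @property
    def transcript_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def library_ids(self) -> list[str]:
        return [l.library_id for l in self.libraries]

    @property
    def n_libraries(self) -> int:
        return len(self.libraries)

    def libraries_where(self, condition: str | None = None, time_h: int | None = None) -> list[str]:
        """Library ids matching a condition and/or time point."""
        out = []
        for l in self.libraries:
            if condition is not None and l.condition != condition:
                continue
            if time_h is not None and l.time_h != time_h:
                continue
            out.append(l.library_id)
        return out

    def subset(self, transcript_ids: Iterable[str]) -> "CountMatrix":
        ids = list(transcript_ids)
        missing = sorted(set(ids) - set(self.counts.index))
        if missing:
            raise KeyError(f"unknown transcript ids: {missing[:5]}")
        return CountMatrix(self.counts.loc[ids], self.libraries)


@dataclass(frozen=True)
class DERecord:
    """A differential-expression result row for one transcript.

    ``direction`` is derived from the FDR threshold used upstream: "up" iff
    fdr <= threshold and log2fc > 0, "down" analogously, otherwise "ns".
    """

    transcript_id: str
    log2fc: float
    pvalue: float
    fdr: float
    direction: str

    def __post_init__(self) -> None:
        if not 0.0 <= self.pvalue <= 1.0:
            raise ValueError(f"{self.transcript_id}: pvalue outside [0, 1]")
        if not 0.0 <= self.fdr <= 1.0:
            raise ValueError(f"{self.transcript_id}: fdr outside [0, 1]")
        if self.direction not in ("up", "down", "ns"):
            raise ValueError(f"{self.transcript_id}: invalid direction {self.direction!r}")


def de_direction(log2fc: float, fdr: float, fdr_threshold: float = 0.05) -> str:
    """Direction label for a DE result at the given FDR threshold."""
    if fdr <= fdr_threshold and log2fc > 0:
        return "up"
    if fdr <= fdr_threshold and log2fc < 0:
        return "down"
    return "ns"


@dataclass(frozen=True)
class EnergyRecord:
    """Aggregated hybridization-energy magnitude for one lncRNA-mRNA pair."""

    lncrna_id: str
    mrna_id: str
    sum_energy: float

    def __post_init__(self) -> None:
        if self.sum_energy <= 0:
            raise ValueError(
                f"sum_energy must be > 0 after aggregation "
                f"({self.lncrna_id}-{self.mrna_id}: {self.sum_energy})"
            )


def make_library_layout(
    replicate_layout: Sequence[tuple[str, int, int]],
) -> list[LibraryInfo]:
    """Expand a (condition, time_h, n_reps) layout into LibraryInfo records.

    The default study layout is six statuses (control/infected x 4/12/48 h)
    with 3/3/2/2/3/3 replicates, i.e. 16 libraries in total.
    """
    libs: list[LibraryInfo] = []
    for condition, time_h, n_reps in replicate_layout:
        if n_reps < 1:
            raise ConfigError(f"replicate count must be >= 1 in layout entry {(condition, time_h, n_reps)}")
        for rep in range(1, n_reps + 1):
            libs.append(
                LibraryInfo(f"{condition}_{time_h:02d}h_rep{rep}", condition, time_h, rep)
            )
    keys = {(l.condition, l.time_h, l.replicate) for l in libs}
    if len(keys) != len(libs):
        raise ConfigError("replicate layout produces duplicate (condition, time, replicate) cells")
    return libs


DEFAULT_REPLICATE_LAYOUT: tuple[tuple[str, int, int], ...] = (
    ("control", 4, 3),
    ("infected", 4, 3),
    ("control", 12, 2),
    ("infected", 12, 2),
    ("control", 48, 3),
    ("infected", 48, 3),
)
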