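"""Readers and writers for the external file formats.

Every other module operates on the validated in-memory records defined in
:mod:`lncnet.records`; all file-format knowledge lives here.  GTF coordinates
are converted between the file convention (1-based inclusive) and the internal
convention (0-based half-open) at this boundary, and the conversion is an exact
bijection: reading a canonical record and writing it back reproduces the input
coordinates byte for byte.
"""

from __future__ import annotations

import warnings
from collections import OrderedDict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from gffutils.feature import feature_from_line

from .exceptions import ParseError
from .records import (
    CountMatrix,
    DERecord,
    DomainHit,
    HomologyHit,
    LibraryInfo,
    TranscriptModel,
    de_direction,
)

HIT_COLUMNS = (
    "qseqid sseqid pident length mismatch gapopen qstart qend sstart send evalue bitscore"
).split()


# ---------------------------------------------------------------------------
# GTF
# ---------------------------------------------------------------------------

def read_gtf(path: str | Path) -> list[TranscriptModel]:
    """Read exon features from a GTF file into :class:`TranscriptModel` records.

    Only ``exon`` features are considered; each must carry a ``transcript_id``
    attribute (``gene_id`` defaults to the transcript id when absent).  Exons
    are merged per transcript and sorted; 1-based inclusive file coordinates
    become 0-based half-open internal intervals.
    """
    path = Path(path)
    per_tx: "OrderedDict[str, dict]" = OrderedDict()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if len(line.split("\t")) < 9:
                raise ParseError(f"{path}:{lineno}: malformed GTF line (expected 9 fields)")
            try:
                feat = feature_from_line(line, dialect=None)
            except Exception as exc:  # malformed line
                raise ParseError(f"{path}:{lineno}: malformed GTF line ({exc})") from exc
            if feat.featuretype != "exon":
                continue
            attrs = feat.attributes
            if "transcript_id" not in attrs or not attrs["transcript_id"]:
                raise ParseError(f"{path}:{lineno}: exon feature without transcript_id")
            tid = attrs["transcript_id"][0]
            gid = attrs["gene_id"][0] if attrs.get("gene_id") else tid
            rec = per_tx.setdefault(
                tid, {"gene_id": gid, "chrom": feat.seqid, "strand": feat.strand or ".", "exons": []}
            )
            if rec["chrom"] != feat.seqid or rec["strand"] != (feat.strand or "."):
                raise ParseError(
                    f"{path}:{lineno}: transcript {tid} spans multiple chromosomes/strands"
                )
            # GTF is 1-based inclusive -> 0-based half-open
            rec["exons"].append((feat.start - 1, feat.end))
    models = []
    for tid, rec in per_tx.items():
        exons = tuple(sorted(rec["exons"]))
        models.append(
            TranscriptModel(tid, rec["gene_id"], rec["chrom"], rec["strand"], exons)
        )
    return models


def write_gtf(transcripts: Iterable[TranscriptModel], path: str | Path, source: str = "lncnet") -> None:
    """Write transcript models as GTF exon features (1-based inclusive)."""
    with open(path, "w") as fh:
        for t in transcripts:
            for start, end in t.exons:
                attrs = f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}";'
                fh.write(
                    f"{t.chrom}\t{source}\texon\t{start + 1}\t{end}\t.\t{t.strand}\t.\t{attrs}\n"
                )


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an id -> sequence map.

    Sequences are upper-cased and U is converted to T.  Duplicate ids raise;
    an empty sequence is retained with a warning.
    """
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise ParseError(f"{path}: duplicate FASTA id {rec.id!r}")
        seq = str(rec.seq).upper().replace("U", "T")
        if not seq:
            warnings.warn(f"{path}: empty sequence for {rec.id!r} (retained)")
        out[rec.id] = seq
    return out


def write_fasta(sequences: Mapping[str, str], path: str | Path, width: int = 60) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


# ---------------------------------------------------------------------------
# Tabular hit tables
# ---------------------------------------------------------------------------

def read_hits(path: str | Path, min_columns: int = 12) -> list[HomologyHit]:
    """Read a tab-separated 12-column homology hit table.

    Columns beyond ``min_columns`` are ignored; lines starting with ``#`` are
    skipped; no filtering is applied here.
    """
    hits: list[HomologyHit] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < min_columns:
                raise ParseError(
                    f"{path}:{lineno}: expected >= {min_columns} columns, got {len(fields)}"
                )
            try:
                hit = HomologyHit(
                    query_id=fields[0],
                    subject_id=fields[1],
                    percent_identity=float(fields[2]),
                    align_length=int(fields[3]),
                    evalue=float(fields[10]),
                    bitscore=float(fields[11]),
                )
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            hits.append(hit)
    return hits


def write_hits(hits: Iterable[HomologyHit], path: str | Path) -> None:
    """Write hits in the 12-column dialect (unused columns written as 0)."""
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                "\t".join(
                    [
                        h.query_id,
                        h.subject_id,
                        f"{h.percent_identity:.2f}",
                        str(h.align_length),
                        "0",
                        "0",
                        "1",
                        str(h.align_length),
                        "1",
                        str(h.align_length),
                        f"{h.evalue:.3g}",
                        f"{h.bitscore:.1f}",
                    ]
                )
                + "\n"
            )


def read_domain_hits(path: str | Path) -> list[DomainHit]:
    """Read a tab-separated domain hit table (query_id, accession, evalue)."""
    hits: list[DomainHit] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: expected 3 columns")
            try:
                hits.append(DomainHit(fields[0], fields[1], float(fields[2])))
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return hits


def write_domain_hits(hits: Iterable[DomainHit], path: str | Path) -> None:
    with open(path, "w") as fh:
        for h in hits:
            fh.write(f"{h.query_id}\t{h.domain_accession}\t{h.domain_evalue:.3g}\n")


# ---------------------------------------------------------------------------
# Counts, libraries, DE and energy tables
# ---------------------------------------------------------------------------

def read_libraries(path: str | Path) -> list[LibraryInfo]:
    df = pd.read_csv(path, sep="\t")
    required = {"library_id", "condition", "time_h", "replicate"}
    if not required.issubset(df.columns):
        raise ParseError(f"{path}: library table needs columns {sorted(required)}")
    return [
        LibraryInfo(str(r.library_id), str(r.condition), int(r.time_h), int(r.replicate))
        for r in df.itertuples()
    ]


def write_libraries(libraries: Sequence[LibraryInfo], path: str | Path) -> None:
    pd.DataFrame(
        {
            "library_id": [l.library_id for l in libraries],
            "condition": [l.condition for l in libraries],
            "time_h": [l.time_h for l in libraries],
            "replicate": [l.replicate for l in libraries],
        }
    ).to_csv(path, sep="\t", index=False)


def read_counts(counts_path: str | Path, libraries_path: str | Path) -> CountMatrix:
    """Read a counts TSV (header = library ids, first column = transcript id)
    together with its library metadata table."""
    libs = read_libraries(libraries_path)
    df = pd.read_csv(counts_path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    lib_ids = [l.library_id for l in libs]
    missing = [c for c in lib_ids if c not in df.columns]
    if missing:
        raise ParseError(f"{counts_path}: missing library columns {missing}")
    return CountMatrix(df[lib_ids], libs)


def write_counts(matrix: CountMatrix, path: str | Path) -> None:
    out = matrix.counts.copy()
    out.index.name = "transcript_id"
    out.to_csv(path, sep="\t", float_format="%.6g")


def read_de_table(path: str | Path, fdr_threshold: float = 0.05) -> list[DERecord]:
    """Read a DE result table (transcript_id, log2fc, pvalue, fdr[, direction]).

    When the file carries a direction column it is validated against the
    threshold rule; otherwise the direction is derived.
    """
    df = pd.read_csv(path, sep="\t")
    required = {"transcript_id", "log2fc", "pvalue", "fdr"}
    if not required.issubset(df.columns):
        raise ParseError(f"{path}: DE table needs columns {sorted(required)}")
    records = []
    for r in df.itertuples():
        direction = de_direction(float(r.log2fc), float(r.fdr), fdr_threshold)
        if "direction" in df.columns and str(r.direction) != direction:
            raise ParseError(
                f"{path}: direction {r.direction!r} for {r.transcript_id} inconsistent "
                f"with log2fc/fdr at threshold {fdr_threshold}"
            )
        records.append(
            DERecord(str(r.transcript_id), float(r.log2fc), float(r.pvalue), float(r.fdr), direction)
        )
    return records


def write_de_table(records: Iterable[DERecord], path: str | Path) -> None:
    pd.DataFrame(
        {
            "transcript_id": [r.transcript_id for r in records],
            "log2fc": [r.log2fc for r in records],
            "pvalue": [r.pvalue for r in records],
            "fdr": [r.fdr for r in records],
            "direction": [r.direction for r in records],
        }
    ).to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_energy_sites(path: str | Path) -> pd.DataFrame:
    """Read a per-site RNA-RNA interaction energy table.

    Returns a DataFrame with columns (lncrna_id, mrna_id, energy), one row per
    predicted interaction site; aggregation into per-pair sums is the network
    module's job.
    """
    try:
        df = pd.read_csv(path, sep="\t", comment="#")
    except Exception as exc:
        raise ParseError(f"{path}: cannot parse energy table ({exc})") from exc
    required = {"lncrna_id", "mrna_id", "energy"}
    if not required.issubset(df.columns):
        raise ParseError(f"{path}: energy table needs columns {sorted(required)}")
    if not pd.api.types.is_numeric_dtype(df["energy"]):
        raise ParseError(f"{path}: non-numeric energy values")
    return df[["lncrna_id", "mrna_id", "energy"]].astype({"lncrna_id": str, "mrna_id": str})


def write_energy_sites(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_annotation(path: str | Path) -> dict[str, set[str]]:
    """Read a term annotation TSV (term_id, member_id per row)."""
    df = pd.read_csv(path, sep="\t")
    if not {"term_id", "member_id"}.issubset(df.columns):
        raise ParseError(f"{path}: annotation table needs columns term_id, member_id")
    terms: dict[str, set[str]] = {}
    for r in df.itertuples():
        terms.setdefault(str(r.term_id), set()).add(str(r.member_id))
    return terms


def write_annotation(terms: Mapping[str, Iterable[str]], path: str | Path) -> None:
    rows = [
        {"term_id": term, "member_id": member}
        for term in sorted(terms)
        for member in sorted(terms[term])
    ]
    pd.DataFrame(rows, columns=["term_id", "member_id"]).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Network export (implemented over lncnet.network.InteractionNetwork)
# ---------------------------------------------------------------------------

def write_network(network, fmt: str, path: str | Path) -> None:
    """Write an interaction network as graphml, sif or tsv.

    graphml and the tsv edge table round-trip all node/edge attributes; sif
    preserves topology only (``lnc interacts mrna`` triples).
    """
    from .network import InteractionNetwork  # local import to avoid a cycle

    if not isinstance(network, InteractionNetwork):
        raise TypeError("write_network expects an InteractionNetwork")
    if fmt == "graphml":
        network.to_graphml(path)
    elif fmt == "sif":
        network.to_sif(path)
    elif fmt == "tsv":
        network.to_edge_table(path)
    else:
        raise ValueError(f"unknown network format {fmt!r} (expected graphml, sif or tsv)")


def read_network(fmt: str, path: str | Path):
    from .network import InteractionNetwork

    if fmt == "graphml":
        return InteractionNetwork.from_graphml(path)
    if fmt == "tsv":
        return InteractionNetwork.from_edge_table(path)
    raise ValueError(f"unsupported network read format {fmt!r}")
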