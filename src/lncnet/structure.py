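"""Transcript-structure analyses: splicing modes, status overlap, novelty.

Three independent comparisons of transcript models:

* classification of the five canonical alternative-splicing modes between
  isoform pairs of one locus — intron retention, exon skipping, alternative
  5'-donor, alternative 3'-acceptor, mutually exclusive exons;
* overlap of transcript sets observed in different experimental statuses,
  with a deterministic structural identity key;
* known/novel classification of transcripts against a reference-transcriptome
  homology hit table.

Loci are connected components of exonic overlap on the same strand, mirroring
how assemblers group transcripts without requiring gene annotation.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .exceptions import StructureError
from .records import HomologyHit, TranscriptModel

AS_MODES = (
    "intron_retention",
    "exon_skipping",
    "alt_3_acceptor",
    "alt_5_donor",
    "mutually_exclusive_exon",
)


@dataclass(frozen=True)
class ASEvent:
    """One alternative-splicing event between two isoforms of a locus.

    For intron retention, ``transcript_a`` is the isoform *retaining* the
    intron (its exon spans it); for exon skipping, ``transcript_a`` is the
    isoform *containing* the exon that the other skips.  For the remaining
    modes the pair is ordered by id.  ``coordinates`` are the defining
    interval(s) in internal (0-based half-open) genomic coordinates.
    """

    locus_id: str
    transcript_a: str
    transcript_b: str
    mode: str
    coordinates: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.transcript_a == self.transcript_b:
            raise ValueError("an AS event needs two distinct transcripts")
        if self.mode not in AS_MODES:
            raise ValueError(f"unknown AS mode {self.mode!r}")


def _overlaps(a: tuple[int, int], b: tuple[int, int]) -> bool:
    return a[0] < b[1] and b[0] < a[1]


def group_loci(transcripts: Sequence[TranscriptModel]) -> list[list[TranscriptModel]]:
    """Group transcripts into loci: connected components of exonic overlap on
    the same chromosome and strand."""
    loci: list[list[TranscriptModel]] = []
    by_group: dict[tuple[str, str], list[TranscriptModel]] = {}
    for t in transcripts:
        by_group.setdefault((t.chrom, t.strand), []).append(t)
    for _, members in sorted(by_group.items()):
        # sweep over exons; transcripts joined whenever their exons overlap
        exons = sorted(
            (s, e, i) for i, t in enumerate(members) for (s, e) in t.exons
        )
        parent = list(range(len(members)))

        def find(x: int) -> int:
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        def union(a: int, b: int) -> None:
            ra, rb = find(a), find(b)
            if ra != rb:
                parent[rb] = ra

        cur_end = -1
        cur_owner = -1
        for s, e, i in exons:
            if s < cur_end:
                union(cur_owner, i)
                cur_end = max(cur_end, e)
            else:
                cur_owner, cur_end = i, e
        clusters: dict[int, list[TranscriptModel]] = {}
        for i, t in enumerate(members):
            clusters.setdefault(find(i), []).append(t)
        for root in sorted(clusters, key=lambda r: clusters[r][0].span):
            loci.append(sorted(clusters[root], key=lambda t: t.transcript_id))
    return loci


def _pair_events(a: TranscriptModel, b: TranscriptModel, locus_id: str) -> list[ASEvent]:
    """All canonical events between one unordered isoform pair."""
    strand = "-" if a.strand == "-" else "+"
    events: list[ASEvent] = []

    # --- intron retention: an exon of one fully spans an intron of the other,
    # extending past both flanking exon edges.
    for retainer, spliced in ((a, b), (b, a)):
        for intron in spliced.introns:
            for exon in retainer.exons:
                if exon[0] < intron[0] and exon[1] > intron[1]:
                    events.append(
                        ASEvent(locus_id, retainer.transcript_id, spliced.transcript_id,
                                "intron_retention", (intron,))
                    )

    # --- exon skipping: an internal exon of one is absent from the other while
    # the flanking exon boundaries are intact (the other carries the fused intron).
    for container, skipper in ((a, b), (b, a)):
        skipper_introns = set(skipper.introns)
        for i in range(1, len(container.exons) - 1):
            exon = container.exons[i]
            outer = (container.exons[i - 1][1], container.exons[i + 1][0])
            if outer in skipper_introns and not any(
                _overlaps(exon, e) for e in skipper.exons
            ):
                events.append(
                    ASEvent(locus_id, container.transcript_id, skipper.transcript_id,
                            "exon_skipping", (exon,))
                )

    # --- alternative donor / acceptor: a shared intron differing at exactly one
    # end, where the differing region is exonic in the shorter-intron isoform.
    def _exon_covers(t: TranscriptModel, lo: int, hi: int) -> bool:
        return any(s <= lo and e >= hi for s, e in t.exons)

    for ia in a.introns:
        for ib in b.introns:
            if ia == ib or not _overlaps(ia, ib):
                continue
            if ia[1] == ib[1] and ia[0] != ib[0]:
                lo, hi = min(ia[0], ib[0]), max(ia[0], ib[0])
                shorter = a if ia[0] > ib[0] else b
                if _exon_covers(shorter, lo, hi):
                    mode = "alt_5_donor" if strand == "+" else "alt_3_acceptor"
                    events.append(
                        ASEvent(locus_id, *sorted((a.transcript_id, b.transcript_id)),
                                mode, ((lo, hi),))
                    )
            elif ia[0] == ib[0] and ia[1] != ib[1]:
                lo, hi = min(ia[1], ib[1]), max(ia[1], ib[1])
                shorter = a if ia[1] < ib[1] else b
                if _exon_covers(shorter, lo, hi):
                    mode = "alt_3_acceptor" if strand == "+" else "alt_5_donor"
                    events.append(
                        ASEvent(locus_id, *sorted((a.transcript_id, b.transcript_id)),
                                mode, ((lo, hi),))
                    )

    # --- mutually exclusive exons: one internal exon per isoform, mutually
    # non-overlapping, between shared flanking boundaries, each absent from the
    # other isoform.
    for i in range(1, len(a.exons) - 1):
        xa = a.exons[i]
        for j in range(1, len(b.exons) - 1):
            xb = b.exons[j]
            if _overlaps(xa, xb):
                continue
            if (
                a.exons[i - 1][1] == b.exons[j - 1][1]
                and a.exons[i + 1][0] == b.exons[j + 1][0]
                and not any(_overlaps(xa, e) for e in b.exons)
                and not any(_overlaps(xb, e) for e in a.exons)
            ):
                coords = tuple(sorted((xa, xb)))
                events.append(
                    ASEvent(locus_id, *sorted((a.transcript_id, b.transcript_id)),
                            "mutually_exclusive_exon", coords)
                )
    # deduplicate identical events emitted twice within the pair
    return sorted(set(events), key=lambda e: (e.mode, e.coordinates, e.transcript_a))


def classify_events(
    transcripts: Sequence[TranscriptModel], locus_id: str | None = None
) -> list[ASEvent]:
    """Classify all canonical AS events among isoforms of a single locus.

    Transcripts must share chromosome and strand ('.' is treated with the
    forward-strand labeling convention); mixed +/- strands raise.
    """
    if len(transcripts) < 2:
        return []
    chroms = {t.chrom for t in transcripts}
    if len(chroms) != 1:
        raise StructureError(f"locus spans multiple chromosomes: {sorted(chroms)}")
    strands = {t.strand for t in transcripts} - {"."}
    if len(strands) > 1:
        raise StructureError(f"mixed strands in one locus: {sorted(strands)}")
    lid = locus_id or f"{transcripts[0].chrom}:{min(t.span[0] for t in transcripts)}"
    events: list[ASEvent] = []
    ts = sorted(transcripts, key=lambda t: t.transcript_id)
    for i in range(len(ts)):
        for j in range(i + 1, len(ts)):
            events.extend(_pair_events(ts[i], ts[j], lid))
    return events


def classify_all(transcripts: Sequence[TranscriptModel]) -> list[ASEvent]:
    """Group transcripts into loci and classify events locus by locus."""
    events: list[ASEvent] = []
    for k, locus in enumerate(group_loci(transcripts)):
        lid = f"{locus[0].chrom}:L{k}"
        events.extend(classify_events(locus, locus_id=lid))
    return events


def event_mode_distribution(
    events: Iterable[ASEvent] | Mapping[str, Iterable[ASEvent]],
    deduplicate: bool = True,
) -> pd.DataFrame:
    """Per-mode event proportions, optionally per status.

    ``events`` may be a flat event list (one row labeled "all") or a mapping
    from status label to events.  With ``deduplicate`` (the default), events
    with identical (locus, mode, coordinates) count once per status, so the
    distribution counts event types rather than isoform pairs.  Statuses with
    zero events yield an empty (all-zero count, NaN-free) row omitted from the
    proportions table.
    """
    if isinstance(events, Mapping):
        groups = {str(k): list(v) for k, v in events.items()}
    else:
        groups = {"all": list(events)}
    rows = []
    for status in sorted(groups):
        evs = groups[status]
        if deduplicate:
            evs = list({(e.locus_id, e.mode, e.coordinates): e for e in evs}.values())
        counts = Counter(e.mode for e in evs)
        total = sum(counts.values())
        if total == 0:
            continue
        row = {"status": status, "n_events": total}
        for mode in AS_MODES:
            row[mode] = counts.get(mode, 0) / total
        rows.append(row)
    return pd.DataFrame(rows, columns=["status", "n_events", *AS_MODES])


# ---------------------------------------------------------------------------
# status overlap
# ---------------------------------------------------------------------------

def transcript_key(t: TranscriptModel) -> tuple:
    """Deterministic structural identity of a transcript across assemblies.

    Multi-exon transcripts are identified by (chrom, strand, intron chain);
    mono-exon transcripts by (chrom, strand, exact exon coordinates).
    """
    if len(t.exons) > 1:
        return (t.chrom, t.strand, t.introns)
    return (t.chrom, t.strand, t.exons)


@dataclass
class StatusSet:
    """The set of transcript structure keys observed in one status."""

    status_label: tuple[str, int]
    transcript_keys: frozenset

    @classmethod
    def from_transcripts(
        cls, status_label: tuple[str, int], transcripts: Iterable[TranscriptModel]
    ) -> "StatusSet":
        return cls(tuple(status_label), frozenset(transcript_key(t) for t in transcripts))


def status_overlap(status_sets: Sequence[StatusSet]) -> pd.DataFrame:
    """Full inclusion-exclusion cell counts for >= 2 status sets.

    Returns one row per non-empty membership pattern with a boolean column per
    status, the cell count, and a ``specific_to`` column naming the status
    when the pattern has exactly one member.  Cell counts sum to the size of
    the union of all sets.
    """
    if len(status_sets) < 2:
        raise ValueError("status_overlap needs at least two status sets")
    labels = [f"{c}_{t}h" for (c, t) in (s.status_label for s in status_sets)]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate status labels")
    universe = set().union(*(s.transcript_keys for s in status_sets))
    patterns: Counter = Counter()
    for key in universe:
        patterns[tuple(key in s.transcript_keys for s in status_sets)] += 1
    rows = []
    for pattern in sorted(patterns, reverse=True):
        members = [lab for lab, flag in zip(labels, pattern) if flag]
        rows.append(
            {
                **{lab: flag for lab, flag in zip(labels, pattern)},
                "count": patterns[pattern],
                "specific_to": members[0] if len(members) == 1 else "",
            }
        )
    return pd.DataFrame(rows, columns=[*labels, "count", "specific_to"])


def specific_counts(cells: pd.DataFrame) -> dict[str, int]:
    """Per-status counts of keys present in exactly one status."""
    out: dict[str, int] = {}
    for _, row in cells.iterrows():
        if row["specific_to"]:
            out[row["specific_to"]] = out.get(row["specific_to"], 0) + int(row["count"])
    return out


# ---------------------------------------------------------------------------
# novelty
# ---------------------------------------------------------------------------

def classify_novelty(
    query_ids: Iterable[str],
    reference_hits: Iterable[HomologyHit],
    evalue_max: float = 1e-5,
) -> dict[str, str]:
    """Label each query "known" iff it has >= 1 reference hit at
    ``evalue <= evalue_max``, else "novel"."""
    best: dict[str, float] = {}
    for h in reference_hits:
        if h.query_id not in best or h.evalue < best[h.query_id]:
            best[h.query_id] = h.evalue
    return {
        q: "known" if best.get(q, float("inf")) <= evalue_max else "novel"
        for q in query_ids
    }
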