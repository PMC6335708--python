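"""Stepwise lncRNA identification cascade and lncRNA/mRNA characterization.

The cascade removes putative protein-coding transcripts in a fixed stage
order — protein homology, minimum length, longest stop-to-stop ORF, external
coding-potential labels, protein-domain hits — and each transcript is assigned
the *first* stage at which it fails.  Whatever survives every stage is called
a lncRNA.  The per-stage bookkeeping makes both the candidate count after the
ORF stage and the final count reportable, mirroring how stepwise pipelines
report intermediate tallies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import ConfigError
from .orf import OrfResult, longest_orf
from .records import CountMatrix, DomainHit, HomologyHit, TranscriptModel

#: cascade stage order (fixed)
STAGES = ("homology", "length", "orf", "coding_potential", "domain")

#: terminal statuses a transcript can end in
STATUSES = tuple(f"removed:{s}" for s in STAGES) + ("lncRNA",)


@dataclass
class FilterConfig:
    """Thresholds of the stepwise lncRNA filter.

    Defaults reproduce the standard parameterization: homology exclusion at
    E <= 1e-3, minimum length 200 nt, and removal of any transcript whose
    longest stop-to-stop ORF reaches 100 aa ("less than 100 aa" is kept).
    """

    homology_evalue_max: float = 1e-3
    min_length_nt: int = 200
    max_orf_aa: int = 100
    require_coding_potential_labels: bool = False
    require_domain_table: bool = False

    def __post_init__(self) -> None:
        if self.homology_evalue_max <= 0:
            raise ConfigError("homology_evalue_max must be positive")
        if self.min_length_nt <= 0 or self.max_orf_aa <= 0:
            raise ConfigError("length/ORF thresholds must be positive")


@dataclass
class FilterReport:
    """Terminal status of every input transcript plus per-stage counts.

    ``table`` has one row per transcript: id, terminal status, length (nt),
    longest ORF (aa), homology hit count at the exclusion cutoff.
    ``stage_counts`` maps each removal stage (and "lncRNA") to its count;
    ``survivors_after`` gives the running candidate count after each stage.
    """

    table: pd.DataFrame
    stage_counts: dict[str, int]
    survivors_after: dict[str, int]
    lncrna_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        total = sum(self.stage_counts.values())
        if total != len(self.table):
            raise ValueError(
                f"stage counts sum to {total} but {len(self.table)} transcripts were filtered"
            )

    @property
    def n_input(self) -> int:
        return len(self.table)

    @property
    def n_lncrna(self) -> int:
        return self.stage_counts.get("lncRNA", 0)


def run_filter_cascade(
    transcripts: Sequence[TranscriptModel],
    homology_hits: Iterable[HomologyHit],
    domain_hits: Iterable[DomainHit] | None = None,
    coding_potential_labels: Mapping[str, str] | None = None,
    config: FilterConfig | None = None,
) -> FilterReport:
    """Run the stepwise filtering cascade and report per-transcript outcomes.

    Parameters
    ----------
    transcripts
        Transcript models with sequences attached.
    homology_hits
        Protein homology hits; any transcript with >= 1 hit at
        ``evalue <= config.homology_evalue_max`` is removed at the first stage.
    domain_hits
        Protein domain hits; transcripts present in the table are removed at
        the final stage.  ``None`` disables the stage unless
        ``config.require_domain_table`` is set.
    coding_potential_labels
        External classifier output mapping transcript id to ``"coding"`` or
        ``"noncoding"``; ids labeled coding are removed.  ``None`` disables
        the stage unless ``config.require_coding_potential_labels`` is set.
    """
    config = config or FilterConfig()
    if config.require_coding_potential_labels and coding_potential_labels is None:
        raise ConfigError("coding-potential labels required by config but not supplied")
    if config.require_domain_table and domain_hits is None:
        raise ConfigError("domain hit table required by config but not supplied")

    missing_seq = [t.transcript_id for t in transcripts if t.sequence is None]
    if missing_seq:
        raise ValueError(f"transcripts without sequences: {missing_seq[:5]}")

    hit_counts: dict[str, int] = {}
    for h in homology_hits:
        if h.evalue <= config.homology_evalue_max:
            hit_counts[h.query_id] = hit_counts.get(h.query_id, 0) + 1
    domain_ids = {h.query_id for h in domain_hits} if domain_hits is not None else set()
    labels = coding_potential_labels or {}

    rows = []
    stage_counts = {f"removed:{s}": 0 for s in STAGES}
    stage_counts["lncRNA"] = 0
    lncrna_ids: list[str] = []
    for t in transcripts:
        n_hits = hit_counts.get(t.transcript_id, 0)
        orf: OrfResult = longest_orf(t.sequence, t.transcript_id)
        if n_hits > 0:
            status = "removed:homology"
        elif t.length < config.min_length_nt:
            status = "removed:length"
        elif orf.longest_orf_aa >= config.max_orf_aa:
            status = "removed:orf"
        elif labels.get(t.transcript_id) == "coding":
            status = "removed:coding_potential"
        elif t.transcript_id in domain_ids:
            status = "removed:domain"
        else:
            status = "lncRNA"
            lncrna_ids.append(t.transcript_id)
        stage_counts[status] += 1
        rows.append(
            {
                "transcript_id": t.transcript_id,
                "status": status,
                "length_nt": t.length,
                "longest_orf_aa": orf.longest_orf_aa,
                "n_homology_hits": n_hits,
            }
        )

    table = pd.DataFrame(
        rows, columns=["transcript_id", "status", "length_nt", "longest_orf_aa", "n_homology_hits"]
    )
    survivors_after: dict[str, int] = {}
    remaining = len(rows)
    for s in STAGES:
        remaining -= stage_counts[f"removed:{s}"]
        survivors_after[s] = remaining
    return FilterReport(table, stage_counts, survivors_after, lncrna_ids)


def characterize(
    transcripts: Sequence[TranscriptModel],
    lncrna_ids: Iterable[str],
    counts: CountMatrix | None = None,
    normalized: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Feature table (length, longest ORF, exon count, expression) by class.

    Returns ``(per_transcript, summary)``: one row per transcript with its
    class ("lncRNA" for ids in ``lncrna_ids``, "mRNA" otherwise) and, when a
    count matrix or pre-normalized matrix is supplied, the per-library
    normalized expression columns; plus per-class median/quartile summaries of
    the structural features.
    """
    lnc = set(lncrna_ids)
    known = {t.transcript_id for t in transcripts}
    offenders = sorted(lnc - known)
    if offenders:
        raise KeyError(f"unknown lncRNA ids: {offenders[:10]}")

    rows = []
    for t in transcripts:
        if t.sequence is not None:
            orf_aa = longest_orf(t.sequence, t.transcript_id).longest_orf_aa
        else:
            orf_aa = np.nan
        rows.append(
            {
                "transcript_id": t.transcript_id,
                "class": "lncRNA" if t.transcript_id in lnc else "mRNA",
                "length_nt": t.length,
                "longest_orf_aa": orf_aa,
                "exon_count": len(t.exons),
            }
        )
    per_transcript = pd.DataFrame(
        rows, columns=["transcript_id", "class", "length_nt", "longest_orf_aa", "exon_count"]
    ).set_index("transcript_id")

    expr = None
    if normalized is not None:
        expr = normalized
    elif counts is not None:
        from .coexpression import normalize_counts

        _, expr = normalize_counts(counts)
    if expr is not None:
        common = [i for i in per_transcript.index if i in expr.index]
        per_transcript = per_transcript.join(expr.loc[common], how="left")

    metrics = ["length_nt", "longest_orf_aa", "exon_count"]
    if per_transcript.empty:
        summary = pd.DataFrame(columns=["class", "metric", "q25", "median", "q75"])
    else:
        recs = []
        for cls, grp in per_transcript.groupby("class", sort=True):
            for m in metrics:
                vals = grp[m].dropna()
                if vals.empty:
                    continue
                recs.append(
                    {
                        "class": cls,
                        "metric": m,
                        "q25": float(vals.quantile(0.25)),
                        "median": float(vals.median()),
                        "q75": float(vals.quantile(0.75)),
                    }
                )
        summary = pd.DataFrame(recs, columns=["class", "metric", "q25", "median", "q75"])
    return per_transcript, summary
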