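"""End-to-end orchestration: one config, deterministic seeding, a manifest.

Stages run in a fixed order — filter, structure, coexpress, network, enrich —
each writing its outputs before the next starts.  The manifest lists every
produced file with a SHA-256 checksum; identical config + seed always yields
identical checksums.  ``resume`` re-runs only from the first stage whose
outputs are missing or stale, recomputing everything downstream of it.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from . import io as lio
from .coexpression import (
    CoexpressionConfig,
    PermutationConfig,
    call_edges,
    edges_to_frame,
    log_expression,
    normalize_counts,
    permutation_validate,
)
from .enrichment import AnnotationTable, enrich
from .exceptions import ConfigError
from .filtering import FilterConfig, characterize, run_filter_cascade
from .network import (
    ENERGY_MODES,
    aggregate_energy,
    build_network,
    extract_subnetwork,
    lncrna_degree_table,
)
from .records import CountMatrix
from .structure import (
    StatusSet,
    classify_all,
    classify_novelty,
    event_mode_distribution,
    status_overlap,
    transcript_key,
)

logger = logging.getLogger(__name__)

STAGE_ORDER = ("filter", "structure", "coexpress", "network", "enrich")

STAGE_OUTPUTS = {
    "filter": ("filter_report.tsv", "lncrna_ids.txt", "lncrna.fasta", "characterization.tsv"),
    "structure": ("as_events.tsv", "as_mode_distribution.tsv", "status_overlap.tsv", "novelty.tsv"),
    "coexpress": ("size_factors.tsv", "edges.tsv", "permutation_summary.json"),
    "network": ("network.graphml", "network.sif", "network_edges.tsv",
                "subnetwork.graphml", "lncrna_degree.tsv"),
    "enrich": ("enrichment.tsv",),
}


@dataclass
class PipelineConfig:
    """All inputs, thresholds and the seed of one pipeline run.

    The threshold defaults pin the conventional parameterization — homology
    E <= 1e-3, length >= 200 nt, ORF < 100 aa, |r| >= 0.95 with p < 0.05 and
    a (100 lncRNAs x 1000 repetitions) permutation design.
    """

    fasta: str
    gtf: str
    homology_hits: str
    counts: str
    libraries: str
    de_table: str
    out_dir: str
    domain_hits: str | None = None
    cpc_labels: str | None = None
    reference_hits: str | None = None
    energy_sites: str | None = None
    annotation: str | None = None
    status_membership: str | None = None
    filter: FilterConfig = field(default_factory=FilterConfig)
    coexpression: CoexpressionConfig = field(default_factory=CoexpressionConfig)
    permutation: PermutationConfig = field(default_factory=PermutationConfig)
    energy_mode: str = "sum_abs"
    subnetwork_direction: str = "down"
    log_scale_expression: bool = True
    novelty_evalue_max: float = 1e-5
    enrichment_alpha: float = 0.05
    seed: int = 0

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        raw = dict(raw)
        for key, sub in (("filter", FilterConfig), ("coexpression", CoexpressionConfig),
                         ("permutation", PermutationConfig)):
            if key in raw and isinstance(raw[key], dict):
                raw[key] = sub(**raw[key])
        return cls(**raw)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: config must be a mapping")
        return cls.from_dict(raw)

    def to_dict(self) -> dict:
        return asdict(self)


def validate_config(config: PipelineConfig | str | Path) -> list[tuple[str, str]]:
    """Check paths, ranges and cross-field constraints.

    Returns a list of (severity, message) with severity "error" or "warning";
    an empty list means OK.
    """
    if not isinstance(config, PipelineConfig):
        config = PipelineConfig.from_yaml(config)
    problems: list[tuple[str, str]] = []
    required = ("fasta", "gtf", "homology_hits", "counts", "libraries", "de_table")
    optional = ("domain_hits", "cpc_labels", "reference_hits", "energy_sites",
                "annotation", "status_membership")
    for name in required:
        path = getattr(config, name)
        if not path or not Path(path).exists():
            problems.append(("error", f"required input {name} missing: {path!r}"))
    for name in optional:
        path = getattr(config, name)
        if path and not Path(path).exists():
            problems.append(("error", f"optional input {name} does not exist: {path!r}"))
    if config.energy_mode not in ENERGY_MODES:
        problems.append(("error", f"energy_mode must be one of {ENERGY_MODES}"))
    if config.subnetwork_direction not in ("up", "down"):
        problems.append(("error", "subnetwork_direction must be 'up' or 'down'"))
    if not 0 < config.novelty_evalue_max:
        problems.append(("error", "novelty_evalue_max must be positive"))
    if not 0 < config.enrichment_alpha <= 1:
        problems.append(("error", "enrichment_alpha must be in (0, 1]"))
    # dataclass __post_init__ already validates sub-config ranges on build;
    # cross-check the library table when available
    lib_path = getattr(config, "libraries")
    if lib_path and Path(lib_path).exists():
        try:
            libs = lio.read_libraries(lib_path)
            if len(libs) != 16:
                problems.append(
                    ("warning",
                     f"library table has {len(libs)} libraries; the reference design has 16")
                )
        except Exception as exc:
            problems.append(("error", f"cannot read library table: {exc}"))
    return problems


def _stage_seed(seed: int, stage: str) -> int:
    """Per-stage seed derived from the global one (stable, < 2**31)."""
    digest = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_all(config: PipelineConfig, resume: bool = False) -> dict:
    """Run every stage in order and write ``manifest.json``.

    With ``resume``, stages whose outputs all exist with checksums matching
    the previous manifest are skipped until the first stale stage; that stage
    and everything downstream are recomputed.  On a stage failure the partial
    manifest is written with the failed stage flagged, and the error re-raised.
    """
    problems = [p for p in validate_config(config) if p[0] == "error"]
    if problems:
        raise ConfigError("; ".join(msg for _, msg in problems))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    previous: dict = {}
    manifest_path = out / "manifest.json"
    if resume and manifest_path.exists():
        with open(manifest_path) as fh:
            previous = json.load(fh)

    manifest: dict = {
        "seed": config.seed,
        "config": _manifest_config(config),
        "stages": {},
        "files": {},
    }

    must_run = not resume
    runners = {
        "filter": _stage_filter,
        "structure": _stage_structure,
        "coexpress": _stage_coexpress,
        "network": _stage_network,
        "enrich": _stage_enrich,
    }
    state: dict = {"config": config, "out": out}
    for stage in STAGE_ORDER:
        outputs = STAGE_OUTPUTS[stage]
        fresh = (
            resume
            and not must_run
            and previous.get("config") == manifest["config"]
            and all(
                (out / f).exists()
                and previous.get("files", {}).get(f) == _sha256(out / f)
                for f in outputs
            )
        )
        if fresh:
            manifest["stages"][stage] = {"status": "skipped"}
        else:
            must_run = True  # everything downstream must be recomputed
            logger.info("running stage %s", stage)
            try:
                runners[stage](state)
            except Exception:
                manifest["stages"][stage] = {"status": "failed"}
                _write_manifest(manifest, out)
                raise
            manifest["stages"][stage] = {"status": "run"}
        for f in outputs:
            manifest["files"][f] = _sha256(out / f)
        _load_stage_state(stage, state)
    _write_manifest(manifest, out)
    return manifest


def _manifest_config(config: PipelineConfig) -> dict:
    d = config.to_dict()
    d.pop("out_dir", None)  # manifests compare equal across output locations
    return d


def _write_manifest(manifest: dict, out: Path) -> None:
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _load_inputs(state: dict) -> None:
    if "transcripts" in state:
        return
    config: PipelineConfig = state["config"]
    sequences = lio.read_fasta(config.fasta)
    transcripts = []
    for t in lio.read_gtf(config.gtf):
        if t.transcript_id not in sequences:
            raise ConfigError(f"transcript {t.transcript_id} in GTF but not in FASTA")
        transcripts.append(t.with_sequence(sequences[t.transcript_id]))
    state["transcripts"] = transcripts
    state["homology_hits"] = lio.read_hits(config.homology_hits)
    state["domain_hits"] = (
        lio.read_domain_hits(config.domain_hits) if config.domain_hits else None
    )
    state["cpc_labels"] = None
    if config.cpc_labels:
        df = pd.read_csv(config.cpc_labels, sep="\t")
        state["cpc_labels"] = dict(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(str)))
    state["count_matrix"] = lio.read_counts(config.counts, config.libraries)
    state["de_records"] = lio.read_de_table(config.de_table)


def _stage_filter(state: dict) -> None:
    config: PipelineConfig = state["config"]
    out: Path = state["out"]
    _load_inputs(state)
    report = run_filter_cascade(
        state["transcripts"],
        state["homology_hits"],
        domain_hits=state["domain_hits"],
        coding_potential_labels=state["cpc_labels"],
        config=config.filter,
    )
    report.table.to_csv(out / "filter_report.tsv", sep="\t", index=False)
    with open(out / "lncrna_ids.txt", "w") as fh:
        for tid in report.lncrna_ids:
            fh.write(tid + "\n")
    seqs = {t.transcript_id: t.sequence for t in state["transcripts"]
            if t.transcript_id in set(report.lncrna_ids)}
    lio.write_fasta(seqs, out / "lncrna.fasta")
    cm: CountMatrix = state["count_matrix"]
    in_counts = [t for t in state["transcripts"] if t.transcript_id in set(cm.transcript_ids)]
    per_tx, _ = characterize(in_counts, [i for i in report.lncrna_ids
                                         if i in set(cm.transcript_ids)], counts=cm)
    per_tx.to_csv(out / "characterization.tsv", sep="\t", float_format="%.6g")


def _load_filter_state(state: dict) -> None:
    out: Path = state["out"]
    with open(out / "lncrna_ids.txt") as fh:
        state["lncrna_ids"] = [line.strip() for line in fh if line.strip()]
    table = pd.read_csv(out / "filter_report.tsv", sep="\t")
    state["mrna_ids"] = list(
        table.loc[table["status"] == "removed:homology", "transcript_id"].astype(str)
    )


def _stage_structure(state: dict) -> None:
    config: PipelineConfig = state["config"]
    out: Path = state["out"]
    _load_inputs(state)
    events = classify_all(state["transcripts"])
    rows = [
        {
            "locus_id": e.locus_id,
            "transcript_a": e.transcript_a,
            "transcript_b": e.transcript_b,
            "mode": e.mode,
            "coordinates": ";".join(f"{s + 1}-{end}" for s, end in e.coordinates),
        }
        for e in events
    ]
    pd.DataFrame(rows, columns=["locus_id", "transcript_a", "transcript_b",
                                "mode", "coordinates"]).to_csv(
        out / "as_events.tsv", sep="\t", index=False
    )
    event_mode_distribution(events).to_csv(
        out / "as_mode_distribution.tsv", sep="\t", index=False, float_format="%.6g"
    )

    # status overlap from the membership table (empty output when absent)
    if config.status_membership:
        membership = pd.read_csv(config.status_membership, sep="\t")
        by_id = {t.transcript_id: t for t in state["transcripts"]}
        sets = []
        for (cond, time_h), grp in sorted(membership.groupby(["condition", "time_h"])):
            members = [by_id[t] for t in grp["transcript_id"].astype(str) if t in by_id]
            sets.append(StatusSet.from_transcripts((str(cond), int(time_h)), members))
        cells = status_overlap(sets) if len(sets) >= 2 else pd.DataFrame()
    else:
        cells = pd.DataFrame()
    cells.to_csv(out / "status_overlap.tsv", sep="\t", index=False)

    if config.reference_hits:
        ref_hits = lio.read_hits(config.reference_hits)
        labels = classify_novelty(
            [t.transcript_id for t in state["transcripts"]],
            ref_hits,
            evalue_max=config.novelty_evalue_max,
        )
        pd.DataFrame(
            sorted(labels.items()), columns=["transcript_id", "novelty"]
        ).to_csv(out / "novelty.tsv", sep="\t", index=False)
    else:
        pd.DataFrame(columns=["transcript_id", "novelty"]).to_csv(
            out / "novelty.tsv", sep="\t", index=False
        )


def _stage_coexpress(state: dict) -> None:
    config: PipelineConfig = state["config"]
    out: Path = state["out"]
    _load_inputs(state)
    _load_filter_state(state)
    cm: CountMatrix = state["count_matrix"]
    size_factors, normalized = normalize_counts(cm)
    size_factors.to_frame().to_csv(out / "size_factors.tsv", sep="\t", float_format="%.10g")
    expr = log_expression(normalized) if config.log_scale_expression else normalized
    lnc = [i for i in state["lncrna_ids"] if i in expr.index]
    mrna = [i for i in state["mrna_ids"] if i in expr.index]
    edges, qc = call_edges(expr.loc[lnc], expr.loc[mrna], config.coexpression)
    edges_to_frame(edges).to_csv(out / "edges.tsv", sep="\t", index=False,
                                 float_format="%.10g")
    perm_cfg = config.permutation
    n_avail = len(lnc)
    if n_avail < perm_cfg.n_lncrnas_sampled:
        logger.warning(
            "only %d lncRNAs available; clamping permutation panel from %d",
            n_avail, perm_cfg.n_lncrnas_sampled,
        )
    summary = permutation_validate(
        expr.loc[lnc],
        expr.loc[mrna],
        PermutationConfig(
            n_lncrnas_sampled=min(perm_cfg.n_lncrnas_sampled, n_avail),
            n_repetitions=perm_cfg.n_repetitions,
            threshold=perm_cfg.threshold,
            seed=_stage_seed(config.seed, "coexpress"),
            shared_permutation=perm_cfg.shared_permutation,
        ),
    )
    payload = summary.to_dict()
    payload["edge_qc"] = qc
    with open(out / "permutation_summary.json", "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
        fh.write("\n")


def _stage_network(state: dict) -> None:
    config: PipelineConfig = state["config"]
    out: Path = state["out"]
    _load_inputs(state)
    edges_df = pd.read_csv(out / "edges.tsv", sep="\t")
    from .coexpression import CoexpressionEdge

    edges = [
        CoexpressionEdge(str(r.lncrna_id), str(r.mrna_id), float(r.pcc), float(r.pvalue))
        for r in edges_df.itertuples()
    ]
    energies = None
    if config.energy_sites:
        sites = lio.read_energy_sites(config.energy_sites)
        energies = aggregate_energy(sites, mode=config.energy_mode)
    net = build_network(edges, energies=energies, de_records=state["de_records"])
    net.to_graphml(out / "network.graphml")
    net.to_sif(out / "network.sif")
    net.to_edge_table(out / "network_edges.tsv")
    sub = extract_subnetwork(net, direction=config.subnetwork_direction)
    sub.to_graphml(out / "subnetwork.graphml")
    lncrna_degree_table(net).to_csv(out / "lncrna_degree.tsv", sep="\t", index=False)
    state["network"] = net


def _stage_enrich(state: dict) -> None:
    config: PipelineConfig = state["config"]
    out: Path = state["out"]
    _load_inputs(state)
    empty = pd.DataFrame(columns=["term_id", "n_background", "n_term", "n_query",
                                  "k_overlap", "fold_enrichment", "fisher_p",
                                  "ease_p", "significant"])
    if not config.annotation:
        empty.to_csv(out / "enrichment.tsv", sep="\t", index=False)
        return
    terms = lio.read_annotation(config.annotation)
    if not terms:
        empty.to_csv(out / "enrichment.tsv", sep="\t", index=False)
        return
    background = set().union(*terms.values())
    table = AnnotationTable.from_memberships(terms, background)
    net = pd.read_csv(out / "network_edges.tsv", sep="\t")
    de_lnc = set(
        net.loc[net["lncrna_de"].isin(["up", "down"]), "lncrna_id"].astype(str)
    )
    if de_lnc:
        query = set(net.loc[net["lncrna_id"].isin(de_lnc), "mrna_id"].astype(str))
    else:  # fall back to every network target
        query = set(net["mrna_id"].astype(str))
    query &= table.background
    result = enrich(query, table, alpha=config.enrichment_alpha)
    result.to_csv(out / "enrichment.tsv", sep="\t", index=False, float_format="%.10g")


def _load_stage_state(stage: str, state: dict) -> None:
    """After a stage ran or was skipped, make its outputs available downstream."""
    if stage == "filter":
        _load_filter_state(state)
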