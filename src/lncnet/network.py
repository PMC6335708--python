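"""Bipartite lncRNA-mRNA interaction network assembly and queries.

Edges are called co-expression pairs; when per-site RNA-RNA hybridization
energies are available they are aggregated per pair into a SUMENERGY value
(sum of per-site energy magnitudes by default) and binned on a log10 scale
into thin / dotted / thick weight classes.  Nodes carry their molecular class
and differential-expression direction, which supports extraction of the
down-regulated sub-network and hub-lncRNA degree tables.
"""

from __future__ import annotations

import logging
import math
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

from .coexpression import CoexpressionEdge
from .exceptions import BipartiteError, ParseError
from .records import DERecord, EnergyRecord

logger = logging.getLogger(__name__)

ENERGY_MODES = ("sum_abs", "abs_sum", "min_site")
WEIGHT_CLASSES = ("thin", "dotted", "thick")


def aggregate_energy(sites: pd.DataFrame, mode: str = "sum_abs") -> list[EnergyRecord]:
    """Aggregate per-site hybridization energies into one value per pair.

    ``sites`` has columns (lncrna_id, mrna_id, energy) with one row per
    predicted interaction site (negative = favorable in the upstream
    predictor's convention).  Modes:

    * ``sum_abs`` (default): sum of magnitudes of the per-site energies,
    * ``abs_sum``: magnitude of the signed sum,
    * ``min_site``: magnitude of the single most favorable site.

    Pairs with no sites are simply absent from the output.
    """
    if mode not in ENERGY_MODES:
        raise ValueError(f"unknown energy mode {mode!r}")
    required = {"lncrna_id", "mrna_id", "energy"}
    if not required.issubset(sites.columns):
        raise ParseError(f"energy table needs columns {sorted(required)}")
    if not pd.api.types.is_numeric_dtype(sites["energy"]):
        raise ParseError("non-numeric energy values")
    grouped = sites.groupby(["lncrna_id", "mrna_id"], sort=True)["energy"]
    if mode == "sum_abs":
        agg = grouped.apply(lambda s: float(s.abs().sum()))
    elif mode == "abs_sum":
        agg = grouped.apply(lambda s: abs(float(s.sum())))
    else:
        agg = grouped.apply(lambda s: float(s.abs().max()))
    return [
        EnergyRecord(str(l), str(m), float(v))
        for (l, m), v in agg.items()
        if v > 0
    ]


def weight_class(sum_energy: float) -> str:
    """Map an aggregated energy to its line-weight bin.

    thin if log10(sum_energy) < 1; dotted if 1 <= log10 < 2; thick if
    log10 >= 2.  Bins are lower-inclusive / upper-exclusive.  A non-positive
    value falls back to "thin" with a logged warning rather than crashing a
    whole export on one degenerate record.
    """
    if sum_energy <= 0:
        logger.warning("non-positive SUMENERGY %r binned as 'thin'", sum_energy)
        return "thin"
    lg = math.log10(sum_energy)
    if lg < 1:
        return "thin"
    if lg < 2:
        return "dotted"
    return "thick"


class InteractionNetwork:
    """Strictly bipartite lncRNA-mRNA graph with DE and energy annotations.

    Wraps an undirected :class:`networkx.Graph`; node attributes are ``kind``
    ("lncRNA"/"mRNA") and ``de`` ("up"/"down"/"ns"), edge attributes ``pcc``,
    ``pvalue`` and, when energy is known, ``sum_energy`` and ``weight_class``.
    """

    def __init__(self, graph: nx.Graph | None = None):
        self.graph = graph if graph is not None else nx.Graph()
        self.validate()

    # -- construction -------------------------------------------------------

    def validate(self) -> None:
        for node, data in self.graph.nodes(data=True):
            if data.get("kind") not in ("lncRNA", "mRNA"):
                raise BipartiteError(f"node {node!r} lacks a valid kind attribute")
        for u, v in self.graph.edges():
            kinds = {self.graph.nodes[u]["kind"], self.graph.nodes[v]["kind"]}
            if kinds != {"lncRNA", "mRNA"}:
                raise BipartiteError(f"edge {u}-{v} does not join a lncRNA to an mRNA")
        for _, _, data in self.graph.edges(data=True):
            if ("weight_class" in data) != ("sum_energy" in data):
                raise ValueError("weight_class must be present iff sum_energy is")

    @property
    def lncrna_ids(self) -> list[str]:
        return sorted(n for n, d in self.graph.nodes(data=True) if d["kind"] == "lncRNA")

    @property
    def mrna_ids(self) -> list[str]:
        return sorted(n for n, d in self.graph.nodes(data=True) if d["kind"] == "mRNA")

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def __eq__(self, other) -> bool:
        if not isinstance(other, InteractionNetwork):
            return NotImplemented
        g, h = self.graph, other.graph
        if set(g.nodes) != set(h.nodes) or set(map(frozenset, g.edges)) != set(
            map(frozenset, h.edges)
        ):
            return False
        for n in g.nodes:
            if dict(g.nodes[n]) != dict(h.nodes[n]):
                return False
        for u, v in g.edges:
            a, b = dict(g.edges[u, v]), dict(h.edges[u, v])
            if set(a) != set(b):
                return False
            for key in a:
                va, vb = a[key], b[key]
                if isinstance(va, float):
                    if not math.isclose(va, float(vb), rel_tol=1e-9, abs_tol=1e-12):
                        return False
                elif va != vb:
                    return False
        return True

    # -- export / import ----------------------------------------------------

    def to_graphml(self, path: str | Path) -> None:
        nx.write_graphml(self.graph, str(path))

    @classmethod
    def from_graphml(cls, path: str | Path) -> "InteractionNetwork":
        return cls(nx.read_graphml(str(path)))

    def to_sif(self, path: str | Path) -> None:
        """Topology-only export: one 'lnc interacts mrna' triple per edge."""
        with open(path, "w") as fh:
            for u, v in sorted(self.graph.edges()):
                lnc, mrna = (u, v) if self.graph.nodes[u]["kind"] == "lncRNA" else (v, u)
                fh.write(f"{lnc}\tinteracts\t{mrna}\n")

    def to_edge_table(self, path: str | Path) -> None:
        rows = []
        for u, v, data in self.graph.edges(data=True):
            lnc, mrna = (u, v) if self.graph.nodes[u]["kind"] == "lncRNA" else (v, u)
            rows.append(
                {
                    "lncrna_id": lnc,
                    "mrna_id": mrna,
                    "lncrna_de": self.graph.nodes[lnc]["de"],
                    "mrna_de": self.graph.nodes[mrna]["de"],
                    "pcc": data.get("pcc"),
                    "pvalue": data.get("pvalue"),
                    "sum_energy": data.get("sum_energy", ""),
                    "weight_class": data.get("weight_class", ""),
                }
            )
        cols = ["lncrna_id", "mrna_id", "lncrna_de", "mrna_de", "pcc", "pvalue",
                "sum_energy", "weight_class"]
        pd.DataFrame(rows, columns=cols).sort_values(["lncrna_id", "mrna_id"]).to_csv(
            path, sep="\t", index=False, float_format="%.10g"
        )

    @classmethod
    def from_edge_table(cls, path: str | Path) -> "InteractionNetwork":
        df = pd.read_csv(path, sep="\t", keep_default_na=False, na_values=[])
        g = nx.Graph()
        for r in df.itertuples():
            g.add_node(str(r.lncrna_id), kind="lncRNA", de=str(r.lncrna_de))
            g.add_node(str(r.mrna_id), kind="mRNA", de=str(r.mrna_de))
            attrs = {"pcc": float(r.pcc), "pvalue": float(r.pvalue)}
            if str(r.sum_energy) != "":
                attrs["sum_energy"] = float(r.sum_energy)
                attrs["weight_class"] = str(r.weight_class)
            g.add_edge(str(r.lncrna_id), str(r.mrna_id), **attrs)
        return cls(g)

    def node_table(self) -> pd.DataFrame:
        rows = [
            {"node_id": n, "kind": d["kind"], "de": d["de"]}
            for n, d in sorted(self.graph.nodes(data=True))
        ]
        return pd.DataFrame(rows, columns=["node_id", "kind", "de"])


def build_network(
    edges: Sequence[CoexpressionEdge],
    energies: Iterable[EnergyRecord] | None = None,
    de_records: Iterable[DERecord] | None = None,
) -> InteractionNetwork:
    """Assemble the annotated bipartite network from called edges.

    DE directions are joined by id (missing ids become "ns"); the energy join
    is a left join — edges without an energy record carry no weight class.
    An id appearing as both a lncRNA and an mRNA endpoint raises.
    """
    lnc_ids = {e.lncrna_id for e in edges}
    mrna_ids = {e.mrna_id for e in edges}
    both = lnc_ids & mrna_ids
    if both:
        raise BipartiteError(f"ids on both sides of the bipartition: {sorted(both)[:5]}")
    de_map = {r.transcript_id: r.direction for r in de_records} if de_records else {}
    energy_map = (
        {(r.lncrna_id, r.mrna_id): r.sum_energy for r in energies} if energies else {}
    )
    g = nx.Graph()
    for e in edges:
        g.add_node(e.lncrna_id, kind="lncRNA", de=de_map.get(e.lncrna_id, "ns"))
        g.add_node(e.mrna_id, kind="mRNA", de=de_map.get(e.mrna_id, "ns"))
        attrs = {"pcc": e.pcc, "pvalue": e.pvalue}
        se = energy_map.get((e.lncrna_id, e.mrna_id))
        if se is not None:
            attrs["sum_energy"] = float(se)
            attrs["weight_class"] = weight_class(float(se))
        g.add_edge(e.lncrna_id, e.mrna_id, **attrs)
    return InteractionNetwork(g)


def extract_subnetwork(
    network: InteractionNetwork, direction: str = "down"
) -> InteractionNetwork:
    """Induced subgraph on nodes with the given DE direction, isolated nodes
    dropped; with the default "down" this is the down-regulated sub-network."""
    keep = [n for n, d in network.graph.nodes(data=True) if d.get("de") == direction]
    sub = network.graph.subgraph(keep).copy()
    sub.remove_nodes_from([n for n in list(sub.nodes) if sub.degree(n) == 0])
    return InteractionNetwork(sub)


def lncrna_degree_table(network: InteractionNetwork) -> pd.DataFrame:
    """Per-lncRNA target count, sorted descending (ties by id)."""
    rows = [
        {"lncrna_id": n, "n_targets": network.graph.degree(n),
         "de": network.graph.nodes[n]["de"]}
        for n, d in network.graph.nodes(data=True)
        if d["kind"] == "lncRNA"
    ]
    df = pd.DataFrame(rows, columns=["lncrna_id", "n_targets", "de"])
    return df.sort_values(
        ["n_targets", "lncrna_id"], ascending=[False, True]
    ).reset_index(drop=True)


def naive_duplex_sum_energy(
    lncrna_seq: str, mrna_seq: str, k: int = 8, energy_per_kmer: float = 1.5
) -> float:
    """Synthetic stand-in duplex scorer (test plumbing, not physical).

    Counts k-mers of the lncRNA whose reverse complement occurs in the mRNA
    and multiplies by a per-match constant.  This exercises the energy
    aggregation/binning path when no external RNA-RNA interaction predictor
    output is available; it models no thermodynamics whatsoever.
    """
    comp = str.maketrans("ACGT", "TGCA")
    rc = mrna_seq.upper().translate(comp)[::-1]
    lnc = lncrna_seq.upper()
    if len(lnc) < k or len(rc) < k:
        return 0.0
    mrna_kmers = {rc[i : i + k] for i in range(len(rc) - k + 1)}
    matches = sum(1 for i in range(len(lnc) - k + 1) if lnc[i : i + k] in mrna_kmers)
    return matches * energy_per_kmer
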