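"""Sign-stratified ceRNA triplet assembly and tripartite network handling.

A ceRNA triplet is a (lncRNA, miRNA, mRNA) triple in which the two
targets of one miRNA rise together while the miRNA falls (UP stratum:
up-lncRNA / down-miRNA / up-mRNA) or the mirror image (DOWN stratum),
supported by three kinds of evidence gathered upstream: predicted
binding of the miRNA on both transcripts, negative miRNA-target
coexpression for both, and strong positive lncRNA-mRNA coexpression.

Networks drawn from triplets are strictly tripartite with two edge
types, lncRNA-miRNA and miRNA-mRNA; the lncRNA-mRNA coexpression is
evidence but not a drawn edge.  Node ids are namespaced by RNA class
("lncRNA:X", "miRNA:X", "mRNA:X") so a name shared across classes can
never collide.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

from cernet.coexpression import CoexpressionEdge
from cernet.errors import ValidationError
from cernet.targets import TargetPair

logger = logging.getLogger(__name__)

STRATA = ("UP", "DOWN")
#: direction of each RNA class within a stratum
STRATUM_SIGNS = {
    "UP": {"lncRNA": "up", "miRNA": "down", "mRNA": "up"},
    "DOWN": {"lncRNA": "down", "miRNA": "up", "mRNA": "down"},
}
DEFAULT_HUB_DEGREE = 8


def node_key(rna_class: str, feature_id: str) -> str:
    return f"{rna_class}:{feature_id}"


@dataclass(frozen=True)
class CeRNATriplet:
    """One evidence-complete (lncRNA, miRNA, mRNA) competing triple."""

    lncrna_id: str
    mirna_id: str
    mrna_id: str
    stratum: str
    lnc_mrna_r: float
    mir_lnc_r: float
    mir_mrna_r: float
    lnc_pair: TargetPair | None = None
    mrna_pair: TargetPair | None = None

    def key(self) -> tuple[str, str, str]:
        return (self.lncrna_id, self.mirna_id, self.mrna_id)


@dataclass
class CeRNANetwork:
    """Tripartite graph over one stratum with triplet provenance."""

    stratum: str
    graph: nx.Graph = field(default_factory=nx.Graph)
    triplets: list[CeRNATriplet] = field(default_factory=list)

    def typed_edges(self) -> list[tuple[str, str, str]]:
        """Edges as (source, target, relation) with canonical direction
        lncRNA->miRNA and miRNA->mRNA."""
        out = []
        for u, v, attrs in self.graph.edges(data=True):
            rel = attrs["relation"]
            cu = self.graph.nodes[u]["rna_class"]
            if rel == "lncRNA_miRNA":
                src, dst = (u, v) if cu == "lncRNA" else (v, u)
            else:
                src, dst = (u, v) if cu == "miRNA" else (v, u)
            out.append((src, dst, rel))
        return sorted(out)

    def node_attributes(self) -> dict[str, dict]:
        return {n: dict(a) for n, a in self.graph.nodes(data=True)}

    def nodes_of_class(self, rna_class: str) -> set[str]:
        return {a["feature_id"] for _, a in self.graph.nodes(data=True)
                if a["rna_class"] == rna_class}

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def summary(self) -> dict:
        return {
            "stratum": self.stratum,
            "n_lncRNA": len(self.nodes_of_class("lncRNA")),
            "n_miRNA": len(self.nodes_of_class("miRNA")),
            "n_mRNA": len(self.nodes_of_class("mRNA")),
            "n_edges": self.n_edges,
            "n_triplets": len(self.triplets),
        }

    def validate(self) -> None:
        """Assert tripartiteness, sign consistency and provenance closure."""
        if self.stratum not in STRATA:
            raise ValidationError(f"unknown stratum '{self.stratum}'")
        signs = STRATUM_SIGNS[self.stratum]
        for n, attrs in self.graph.nodes(data=True):
            if attrs["rna_class"] not in signs:
                raise ValidationError(f"node {n}: unknown class {attrs['rna_class']}")
            if attrs["direction"] != signs[attrs["rna_class"]]:
                raise ValidationError(
                    f"node {n}: direction {attrs['direction']} inconsistent with stratum {self.stratum}")
        allowed = {frozenset(("lncRNA", "miRNA")): "lncRNA_miRNA",
                   frozenset(("miRNA", "mRNA")): "miRNA_mRNA"}
        covered: set[frozenset] = set()
        for t in self.triplets:
            covered.add(frozenset((node_key("lncRNA", t.lncrna_id), node_key("miRNA", t.mirna_id))))
            covered.add(frozenset((node_key("miRNA", t.mirna_id), node_key("mRNA", t.mrna_id))))
        for u, v, attrs in self.graph.edges(data=True):
            classes = frozenset((self.graph.nodes[u]["rna_class"], self.graph.nodes[v]["rna_class"]))
            if classes not in allowed:
                raise ValidationError(f"edge ({u}, {v}) violates tripartiteness")
            if attrs["relation"] != allowed[classes]:
                raise ValidationError(f"edge ({u}, {v}) mislabelled {attrs['relation']}")
            if frozenset((u, v)) not in covered:
                raise ValidationError(f"edge ({u}, {v}) has no provenance triplet")
        expected_nodes = set()
        for t in self.triplets:
            expected_nodes |= {node_key("lncRNA", t.lncrna_id), node_key("miRNA", t.mirna_id),
                               node_key("mRNA", t.mrna_id)}
        if expected_nodes != set(self.graph.nodes):
            raise ValidationError("node set differs from the union of provenance triplet members")


def assemble_triplets(
    strata: Mapping[str, Mapping[str, set[str]]],
    lnc_pairs: Sequence[tuple[TargetPair, CoexpressionEdge]],
    mrna_pairs: Sequence[tuple[TargetPair, CoexpressionEdge]],
    lnc_mrna: Sequence[CoexpressionEdge],
    stratum: str,
) -> list[CeRNATriplet]:
    """Enumerate evidence-complete triplets for one stratum.

    Parameters
    ----------
    strata:
        Per-class up/down id sets, e.g. ``{"lncRNA": {"up": {...}, "down":
        {...}}, ...}`` from :func:`cernet.diffexpr.stratify`.
    lnc_pairs, mrna_pairs:
        Anticorrelation-filtered (TargetPair, CoexpressionEdge) lists for
        miRNA->lncRNA and miRNA->mRNA predictions.
    lnc_mrna:
        Passing lncRNA-mRNA coexpression edges.

    Returns triplets sorted lexicographically by (lncRNA, miRNA, mRNA).
    """
    if stratum not in STRATA:
        raise ValidationError(f"unknown stratum '{stratum}'")
    signs = STRATUM_SIGNS[stratum]
    lnc_set = strata["lncRNA"][signs["lncRNA"]]
    mir_set = strata["miRNA"][signs["miRNA"]]
    mrna_set = strata["mRNA"][signs["mRNA"]]

    for edge in lnc_mrna:
        if (edge.a_class, edge.b_class) != ("lncRNA", "mRNA"):
            raise ValidationError(
                f"coexpression edge ({edge.a_id}, {edge.b_id}) has classes "
                f"({edge.a_class}, {edge.b_class}); expected (lncRNA, mRNA)")

    lnc_by_mir: dict[str, dict[str, tuple[TargetPair, CoexpressionEdge]]] = {}
    for pair, edge in lnc_pairs:
        if pair.target_class != "lncRNA":
            raise ValidationError(f"pair ({pair.mirna_id}, {pair.target_id}): expected lncRNA target")
        if pair.mirna_id in mir_set and pair.target_id in lnc_set:
            lnc_by_mir.setdefault(pair.mirna_id, {})[pair.target_id] = (pair, edge)
    mrna_by_mir: dict[str, dict[str, tuple[TargetPair, CoexpressionEdge]]] = {}
    for pair, edge in mrna_pairs:
        if pair.target_class != "mRNA":
            raise ValidationError(f"pair ({pair.mirna_id}, {pair.target_id}): expected mRNA target")
        if pair.mirna_id in mir_set and pair.target_id in mrna_set:
            mrna_by_mir.setdefault(pair.mirna_id, {})[pair.target_id] = (pair, edge)
    coexpr = {(e.a_id, e.b_id): e for e in lnc_mrna
              if e.a_id in lnc_set and e.b_id in mrna_set}

    triplets: list[CeRNATriplet] = []
    for mir in sorted(set(lnc_by_mir) & set(mrna_by_mir)):
        for lnc, (lpair, ledge) in sorted(lnc_by_mir[mir].items()):
            for mrna, (mpair, medge) in sorted(mrna_by_mir[mir].items()):
                ce = coexpr.get((lnc, mrna))
                if ce is None:
                    continue
                triplets.append(CeRNATriplet(
                    lncrna_id=lnc, mirna_id=mir, mrna_id=mrna, stratum=stratum,
                    lnc_mrna_r=ce.r, mir_lnc_r=ledge.r, mir_mrna_r=medge.r,
                    lnc_pair=lpair, mrna_pair=mpair,
                ))
    triplets.sort(key=CeRNATriplet.key)
    return triplets


def build_network(triplets: Sequence[CeRNATriplet], stratum: str | None = None) -> CeRNANetwork:
    """Union the triplets of one stratum into a validated tripartite network."""
    strata_present = {t.stratum for t in triplets}
    if len(strata_present) > 1:
        raise ValidationError(f"mixed strata {sorted(strata_present)} in one network")
    if stratum is None:
        stratum = next(iter(strata_present)) if strata_present else "UP"
    elif strata_present and strata_present != {stratum}:
        raise ValidationError(f"triplets of stratum {strata_present} passed to a {stratum} network")
    net = CeRNANetwork(stratum=stratum, triplets=sorted(triplets, key=CeRNATriplet.key))
    signs = STRATUM_SIGNS[stratum]
    for t in net.triplets:
        for cls, fid in (("lncRNA", t.lncrna_id), ("miRNA", t.mirna_id), ("mRNA", t.mrna_id)):
            net.graph.add_node(node_key(cls, fid), rna_class=cls, feature_id=fid,
                               direction=signs[cls])
        net.graph.add_edge(node_key("lncRNA", t.lncrna_id), node_key("miRNA", t.mirna_id),
                           relation="lncRNA_miRNA")
        net.graph.add_edge(node_key("miRNA", t.mirna_id), node_key("mRNA", t.mrna_id),
                           relation="miRNA_mRNA")
    net.validate()
    return net


def node_degrees(network: CeRNANetwork) -> pd.Series:
    """Degree of every node (number of incident typed edges)."""
    deg = {n: d for n, d in network.graph.degree()}
    return pd.Series(deg, dtype=int).sort_index()


def extract_hub_subnetwork(network: CeRNANetwork,
                           min_degree_exclusive: int = DEFAULT_HUB_DEGREE) -> CeRNANetwork:
    """Subnetwork induced by hub lncRNAs (degree strictly above threshold).

    A lncRNA with degree exactly at the threshold is not a hub.  The
    result is rebuilt from the provenance triplets that contain a hub
    lncRNA, so it keeps the miRNAs linked to hubs and the mRNAs those
    miRNAs reach within hub triplets.
    """
    deg = network.graph.degree()
    hubs = {a["feature_id"] for n, a in network.graph.nodes(data=True)
            if a["rna_class"] == "lncRNA" and deg[n] > min_degree_exclusive}
    kept = [t for t in network.triplets if t.lncrna_id in hubs]
    return build_network(kept, stratum=network.stratum)


def extract_geneset_subnetwork(network: CeRNANetwork, gene_ids: Iterable[str]) -> CeRNANetwork:
    """Subnetwork of triplets whose mRNA belongs to the given gene set."""
    genes = set(gene_ids)
    if not genes:
        raise ValidationError("extract_geneset_subnetwork requires a non-empty gene id set")
    kept = [t for t in network.triplets if t.mrna_id in genes]
    if not kept:
        logger.warning("gene set does not intersect the network; returning an empty network")
    return build_network(kept, stratum=network.stratum)


def triplet_table(triplets: Sequence[CeRNATriplet]) -> pd.DataFrame:
    """Tabulate triplets with their supporting statistics."""
    rows = []
    for t in triplets:
        rows.append(dict(
            lncrna_id=t.lncrna_id, mirna_id=t.mirna_id, mrna_id=t.mrna_id,
            stratum=t.stratum, lnc_mrna_r=t.lnc_mrna_r,
            mir_lnc_r=t.mir_lnc_r, mir_mrna_r=t.mir_mrna_r,
            lnc_site_score=t.lnc_pair.best_site.score if t.lnc_pair else float("nan"),
            lnc_site_energy=t.lnc_pair.best_site.energy if t.lnc_pair else float("nan"),
            mrna_site_score=t.mrna_pair.best_site.score if t.mrna_pair else float("nan"),
            mrna_site_energy=t.mrna_pair.best_site.energy if t.mrna_pair else float("nan"),
        ))
    return pd.DataFrame(rows, columns=[
        "lncrna_id", "mirna_id", "mrna_id", "stratum", "lnc_mrna_r",
        "mir_lnc_r", "mir_mrna_r", "lnc_site_score", "lnc_site_energy",
        "mrna_site_score", "mrna_site_energy"])
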