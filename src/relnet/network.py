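"""Relevance-network construction, comparison, locality annotation, export.

A relevance network links every pair of entities whose grouped correlation
meets a threshold t.  Edges between mature miRNAs can additionally be
annotated by genomic locality, in strict priority order: "stem-loop" (same
precursor hairpin anywhere in the genome), "transcript" (same transcribed
entity), "near" (within 10 kb), "cluster" (same connected component of the
transitive closure of the near relation, but not directly near), and
"non-local" otherwise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .correlation import CorrelationResult

logger = logging.getLogger(__name__)

__all__ = [
    "RelevanceNetwork",
    "build_network",
    "match_link_count",
    "difference_network",
    "annotate_locality",
    "export_network",
    "read_mirbase_gff3",
    "read_transcript_gtf",
]

LOCALITY_CATEGORIES = ("stem-loop", "transcript", "near", "cluster", "non-local")
NEAR_DISTANCE = 10_000


@dataclass
class RelevanceNetwork:
    """Thresholded co-expression network: edges (entity_i, entity_j, r)."""

    edges: pd.DataFrame
    threshold: float
    method: str = "bayesian"

    def __post_init__(self) -> None:
        cols = ["entity_i", "entity_j", "r"]
        self.edges = pd.DataFrame(self.edges, columns=cols).reset_index(drop=True)

    @property
    def nodes(self) -> list:
        """Entities incident to at least one edge (isolated ones excluded)."""
        return sorted(set(self.edges["entity_i"]) | set(self.edges["entity_j"]))

    @property
    def n_links(self) -> int:
        return len(self.edges)

    def edge_set(self) -> set:
        return {
            frozenset((i, j)) for i, j in zip(self.edges["entity_i"], self.edges["entity_j"])
        }

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        for row in self.edges.itertuples(index=False):
            g.add_edge(row.entity_i, row.entity_j, r=float(row.r))
        return g


def build_network(corr: CorrelationResult, t: float) -> RelevanceNetwork:
    """All defined pairs i < j with r >= t, deterministically ordered."""
    pairs = corr.pairs()
    edges = pairs[pairs["r"] >= t].copy()
    # canonical within-pair and between-edge lexicographic order
    flip = edges["entity_i"].astype(str) > edges["entity_j"].astype(str)
    edges.loc[flip, ["entity_i", "entity_j"]] = edges.loc[
        flip, ["entity_j", "entity_i"]
    ].to_numpy()
    edges = edges.sort_values(["entity_i", "entity_j"], kind="stable")
    return RelevanceNetwork(edges, float(t), corr.method)


def match_link_count(corr: CorrelationResult, target_links: int):
    """Largest threshold whose network has at least ``target_links`` edges.

    Returns ``(threshold, achieved_links)``; ties in the correlation values
    can make the achieved count exceed the target.
    """
    vals = np.sort(corr.defined_upper_values())[::-1]
    if not 1 <= target_links <= len(vals):
        raise ValueError(
            f"target_links must be in [1, {len(vals)}], got {target_links}"
        )
    t = float(vals[target_links - 1])
    achieved = int((vals >= t).sum())
    return t, achieved


def difference_network(netA: RelevanceNetwork, netB: RelevanceNetwork):
    """Union of two networks with edges labeled shared / A-only / B-only.

    Nodes are labeled shared when incident to at least one edge in each
    network.  Returns ``(edge_frame, node_labels)``.
    """
    ea, eb = netA.edge_set(), netB.edge_set()
    rows = []
    ra = {frozenset((r.entity_i, r.entity_j)): r.r for r in netA.edges.itertuples()}
    rb = {frozenset((r.entity_i, r.entity_j)): r.r for r in netB.edges.itertuples()}
    for pair in sorted(ea | eb, key=lambda p: sorted(map(str, p))):
        i, j = sorted(pair, key=str)
        label = "shared" if pair in ea and pair in eb else ("A-only" if pair in ea else "B-only")
        rows.append(
            {"entity_i": i, "entity_j": j, "label": label,
             "r_A": ra.get(pair, np.nan), "r_B": rb.get(pair, np.nan)}
        )
    edge_frame = pd.DataFrame(rows, columns=["entity_i", "entity_j", "label", "r_A", "r_B"])
    na, nb = set(netA.nodes), set(netB.nodes)
    node_labels = {}
    for v in sorted(na | nb):
        node_labels[v] = "shared" if v in na and v in nb else ("A-only" if v in na else "B-only")
    return edge_frame, node_labels


# genomic locality ----------------------------------------------------------


def _strip_occurrence_suffix(acc: str) -> str:
    """miRBase discriminates multiple genomic occurrences as MIMAT..._1,
    MIMAT..._2; the Alias field carries the bare accession."""
    base, _, suffix = acc.rpartition("_")
    if base and suffix.isdigit():
        return base
    return acc


def read_mirbase_gff3(path):
    """Parse a miRBase ``hsa.gff3``-style file.

    Returns ``(mature_intervals, stemloop_map)``:
    ``mature_intervals[accession] = [(chrom, start, end), ...]`` over all
    genomic occurrences, and ``stemloop_map[accession]`` the set of
    stem-loop precursor ids the mature miRNA derives from.
    """
    import gffutils

    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    mature_intervals: dict = {}
    stemloop_map: dict = {}
    stemloop_by_id = {}
    for f in db.features_of_type("miRNA_primary_transcript"):
        stemloop_by_id[f.attributes.get("ID", [f.id])[0]] = f
    for f in db.features_of_type("miRNA"):
        alias = f.attributes.get("Alias", f.attributes.get("ID", [f.id]))[0]
        acc = _strip_occurrence_suffix(alias)
        mature_intervals.setdefault(acc, []).append((f.seqid, f.start, f.end))
        for parent in f.attributes.get("Derives_from", []):
            stemloop_map.setdefault(acc, set()).add(parent)
    return mature_intervals, stemloop_map


def read_transcript_gtf(path):
    """Genomic intervals of transcript features from an ENSEMBL-style GTF.

    Returns a list of ``(chrom, start, end, transcript_id)``.
    """
    import gffutils

    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True, disable_infer_transcripts=True,
    )
    out = []
    for f in db.features_of_type("transcript"):
        tid = f.attributes.get("transcript_id", [f.id])[0]
        out.append((f.seqid, f.start, f.end, tid))
    return out


def _interval_distance(a, b) -> float:
    """Closest-endpoint gap between 1-based inclusive intervals on the same
    chromosome; 0 when they overlap, inf on different chromosomes."""
    if a[0] != b[0]:
        return float("inf")
    return max(0, max(a[1], b[1]) - min(a[2], b[2]))


def _near_components(mature_intervals, near_distance):
    """Entity-level connected components of the near relation, taken over
    all genomic occurrences of all mature miRNAs."""
    g = nx.Graph()
    accs = sorted(mature_intervals)
    g.add_nodes_from(accs)
    for idx, a in enumerate(accs):
        for b in accs[idx + 1:]:
            if any(
                _interval_distance(ia, ib) <= near_distance
                for ia in mature_intervals[a]
                for ib in mature_intervals[b]
            ):
                g.add_edge(a, b)
    component_of = {}
    for k, comp in enumerate(nx.connected_components(g)):
        for acc in comp:
            component_of[acc] = k
    return g, component_of


def annotate_locality(
    net: RelevanceNetwork,
    stemloop_map: dict,
    mature_intervals: dict,
    transcript_intervals=(),
    near_distance: int = NEAR_DISTANCE,
) -> pd.Series:
    """Mutually exclusive locality category per edge, priority order
    stem-loop > transcript > near > cluster > non-local.

    An edge qualifies for a category if ANY pair of genomic occurrences of
    its two endpoints qualifies.  Entities without a genomic record fall
    through to "non-local" with a warning.
    """
    transcripts_of: dict = {}
    for acc, ivs in mature_intervals.items():
        hits = set()
        for k, (chrom, start, end, _tid) in enumerate(transcript_intervals):
            for (c, s, e) in ivs:
                if c == chrom and start <= s and e <= end:
                    hits.add(k)
                    break
        transcripts_of[acc] = hits
    near_graph, component_of = _near_components(mature_intervals, near_distance)

    categories = []
    for row in net.edges.itertuples(index=False):
        i, j = row.entity_i, row.entity_j
        if i not in mature_intervals or j not in mature_intervals:
            logger.warning("no genomic record for edge (%s, %s)", i, j)
            categories.append("non-local")
            continue
        if stemloop_map.get(i, set()) & stemloop_map.get(j, set()):
            categories.append("stem-loop")
        elif transcripts_of.get(i, set()) & transcripts_of.get(j, set()):
            categories.append("transcript")
        elif near_graph.has_edge(i, j):
            categories.append("near")
        elif component_of.get(i) == component_of.get(j):
            categories.append("cluster")
        else:
            categories.append("non-local")
    return pd.Series(categories, index=net.edges.index, name="locality")


def export_network(net: RelevanceNetwork, path, format: str, annotation=None) -> None:
    """Write the network as SIF, GraphML or a long-format TSV.

    Edge order is deterministic (entity_i, then entity_j, lexicographic).
    ``annotation`` is an optional per-edge locality Series; in SIF it is
    used as the relation token, otherwise the method name is.
    """
    edges = net.edges
    if format == "sif":
        with open(path, "w") as fh:
            for k, row in enumerate(edges.itertuples(index=False)):
                rel = annotation.iloc[k] if annotation is not None else net.method
                fh.write(f"{row.entity_i}\t{rel}\t{row.entity_j}\n")
    elif format == "graphml":
        g = nx.Graph()
        g.add_nodes_from(net.nodes)
        for k, row in enumerate(edges.itertuples(index=False)):
            attrs = {"r": float(row.r)}
            if annotation is not None:
                attrs["locality"] = str(annotation.iloc[k])
            g.add_edge(row.entity_i, row.entity_j, **attrs)
        nx.write_graphml(g, path)
    elif format == "tsv":
        out = edges.copy()
        if annotation is not None:
            out["locality"] = annotation.to_numpy()
        out.to_csv(path, sep="\t", index=False)
    else:
        raise ValueError(f"unknown format {format!r}")
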