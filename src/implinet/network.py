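"""Gene clusters, the directed cluster graph, and path signatures.

Genes joined by "equivalent" implications are grouped into clusters of
shared expression architecture; clusters become nodes of a directed
graph whose edges carry the majority Boolean implication type between
the members of two clusters.  Simple directed paths through this graph
are candidate progression signatures: each cluster in a path gets a
signed integer weight (sign from its up/down direction relative to the
case class, magnitude from its position), and paths are ranked by the
training ROC-AUC of the resulting per-sample composite score.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .booleannet import CONVERSE, SYMMETRIC_RELATIONS
from .scoring import composite_score, normalize_matrix, roc_auc

logger = logging.getLogger(__name__)

__all__ = [
    "GeneCluster",
    "ClusterGraph",
    "SignaturePath",
    "build_clusters",
    "assign_directions",
    "build_cluster_graph",
    "select_signature",
    "refine_clusters",
]


@dataclass
class GeneCluster:
    """A group of genes with shared expression architecture.

    The seed gene (the member with the most equivalence partners at
    formation time) names the cluster, mirroring usage like the SPINK7
    or SLC44A4 clusters.  ``direction`` is "up"/"down" relative to the
    case class once labels have been supplied, else None.
    """

    cluster_id: str
    members: list[str]
    seed_gene: str
    direction: str | None = None

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class ClusterGraph:
    """Cluster nodes plus directed majority-implication edges."""

    clusters: list[GeneCluster]
    graph: nx.DiGraph

    def cluster(self, cluster_id: str) -> GeneCluster:
        for c in self.clusters:
            if c.cluster_id == cluster_id:
                return c
        raise KeyError(cluster_id)

    @property
    def members_by_id(self) -> dict[str, list[str]]:
        return {c.cluster_id: c.members for c in self.clusters}

    def edge_table(self) -> pd.DataFrame:
        rows = [
            {"from": u, "to": v, "relation": d["relation"], "support": d["support"]}
            for u, v, d in self.graph.edges(data=True)
        ]
        return pd.DataFrame(rows, columns=["from", "to", "relation", "support"])

    def node_table(self) -> pd.DataFrame:
        rows = [
            {
                "cluster_id": c.cluster_id,
                "seed_gene": c.seed_gene,
                "direction": c.direction or "",
                "n_genes": len(c.members),
                "members": ";".join(c.members),
            }
            for c in self.clusters
        ]
        return pd.DataFrame(
            rows, columns=["cluster_id", "seed_gene", "direction", "n_genes", "members"]
        )

    def to_dict(self) -> dict:
        return {
            "clusters": [
                {
                    "cluster_id": c.cluster_id,
                    "members": c.members,
                    "seed_gene": c.seed_gene,
                    "direction": c.direction,
                }
                for c in self.clusters
            ],
            "edges": [
                {"from": u, "to": v, "relation": d["relation"], "support": d["support"]}
                for u, v, d in self.graph.edges(data=True)
            ],
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "ClusterGraph":
        clusters = [GeneCluster(**c) for c in payload["clusters"]]
        g = nx.DiGraph()
        for c in clusters:
            g.add_node(c.cluster_id, seed_gene=c.seed_gene, n_genes=len(c.members))
        for e in payload["edges"]:
            g.add_edge(e["from"], e["to"], relation=e["relation"], support=e["support"])
        return cls(clusters=clusters, graph=g)

    def __eq__(self, other) -> bool:
        if not isinstance(other, ClusterGraph):
            return NotImplemented
        return self.to_dict() == other.to_dict()


@dataclass
class SignaturePath:
    """An ordered, signed cluster list with per-cluster integer weights.

    Weight magnitude is the 1-based position along the path; the sign is
    negative for clusters moving down in cases.  ``auc`` is the training
    ROC-AUC when the path has been scored.
    """

    cluster_ids: list[str]
    weights: list[int]
    auc: float | None = None

    def __post_init__(self):
        if len(self.cluster_ids) != len(self.weights):
            raise ValueError("cluster_ids and weights must align")
        if any(w == 0 for w in self.weights):
            raise ValueError("weights must be nonzero")

    def __str__(self) -> str:
        return ",".join(f"{c}:{w:+d}" for c, w in zip(self.cluster_ids, self.weights))


# ---------------------------------------------------------------------------
# Clustering


def _closed_neighborhoods(edges: pd.DataFrame, genes: list[str]) -> dict[str, frozenset]:
    nbrs: dict[str, set] = {g: {g} for g in genes}
    for a, b in edges[["gene_a", "gene_b"]].itertuples(index=False):
        nbrs.setdefault(a, {a}).add(b)
        nbrs.setdefault(b, {b}).add(a)
    return {g: frozenset(s) for g, s in nbrs.items()}


def _jaccard(a: frozenset, b: frozenset) -> float:
    return len(a & b) / len(a | b)


def build_clusters(
    implications: pd.DataFrame,
    min_share: float = 0.5,
    genes: list[str] | None = None,
) -> list[GeneCluster]:
    """Partition genes into equivalence clusters.

    The equivalence graph is built from rows with relation
    "equivalent".  Repeatedly, the unassigned gene with the most
    unassigned equivalence partners (ties: lexicographically smallest)
    seeds a cluster; its unassigned equivalent neighbors are admitted
    in degree order when their closed equivalence neighborhood shares a
    Jaccard fraction >= ``min_share`` with the seed and with every
    member already admitted.  Singletons are allowed; the result is a
    partition of the gene universe.

    Parameters
    ----------
    implications : DataFrame
        Output of :func:`implinet.booleannet.all_pairs`.
    min_share : float
        Minimum shared fraction of equivalences ("at least half" by
        default).
    genes : list, optional
        Gene universe; defaults to every gene in the table.
    """
    if genes is None:
        genes = sorted(set(implications["gene_a"]) | set(implications["gene_b"]))
    eq = implications[implications["relation"] == "equivalent"]
    closed = _closed_neighborhoods(eq, list(genes))

    unassigned = set(genes)
    clusters: list[GeneCluster] = []
    while unassigned:
        seed = min(
            unassigned,
            key=lambda g: (-len((closed[g] - {g}) & unassigned), g),
        )
        members = [seed]
        candidates = sorted(
            (closed[seed] - {seed}) & unassigned,
            key=lambda g: (-len(closed[g]), g),
        )
        for g in candidates:
            if all(_jaccard(closed[g], closed[m]) >= min_share for m in members):
                members.append(g)
        unassigned -= set(members)
        clusters.append(
            GeneCluster(
                cluster_id=f"C{len(clusters) + 1}",
                members=sorted(members),
                seed_gene=seed,
            )
        )
    return clusters


def assign_directions(
    clusters: list[GeneCluster],
    matrix: pd.DataFrame,
    fits: pd.DataFrame,
    labels: pd.Series,
    case_label: str,
    control_label: str | None = None,
    scale: float = 3.0,
) -> None:
    """Set each cluster's up/down direction from case-vs-control means.

    Direction is the sign of the difference of mean normalized member
    expression between case and control samples; assignment is in
    place.
    """
    z = normalize_matrix(matrix, fits, scale=scale)
    labels = labels.reindex(z.columns)
    case_cols = labels[labels == case_label].index
    if control_label is None:
        control_cols = labels[(labels != case_label) & labels.notna()].index
    else:
        control_cols = labels[labels == control_label].index
    if len(case_cols) == 0 or len(control_cols) == 0:
        raise ValueError("both case and control samples are required to assign directions")
    for c in clusters:
        members = [g for g in c.members if g in z.index]
        if not members:
            c.direction = None
            continue
        diff = z.loc[members, case_cols].mean(axis=None) - z.loc[
            members, control_cols
        ].mean(axis=None)
        c.direction = "up" if diff >= 0 else "down"


def refine_clusters(
    clusters: list[GeneCluster],
    second_implications: pd.DataFrame,
    min_share: float = 0.5,
) -> list[GeneCluster]:
    """Filter cluster members through a second (validation) cohort.

    A member is kept when, in the second cohort's implication table, it
    is equivalent to at least ``min_share`` of the other members of its
    cluster that appear in that table.  Clusters that lose all members
    are dropped; surviving clusters keep their ids and seed genes (a
    removed seed is replaced by the first surviving member).
    """
    eq = second_implications[second_implications["relation"] == "equivalent"]
    partners: dict[str, set] = {}
    for a, b in eq[["gene_a", "gene_b"]].itertuples(index=False):
        partners.setdefault(a, set()).add(b)
        partners.setdefault(b, set()).add(a)
    present = set(second_implications["gene_a"]) | set(second_implications["gene_b"])

    refined = []
    for c in clusters:
        others = {g: (set(c.members) - {g}) & present for g in c.members}
        kept = []
        for g in c.members:
            if g not in present or not others[g]:
                continue
            frac = len(partners.get(g, set()) & others[g]) / len(others[g])
            if frac >= min_share:
                kept.append(g)
        if kept:
            refined.append(
                GeneCluster(
                    cluster_id=c.cluster_id,
                    members=sorted(kept),
                    seed_gene=c.seed_gene if c.seed_gene in kept else sorted(kept)[0],
                    direction=c.direction,
                )
            )
    return refined


# ---------------------------------------------------------------------------
# Cluster graph


def build_cluster_graph(
    clusters: list[GeneCluster],
    implications: pd.DataFrame,
    min_edge_support: float = 0.5,
) -> ClusterGraph:
    """Assemble the directed cluster graph from pairwise implications.

    For each ordered cluster pair the support of a relation type is the
    fraction of cross-cluster gene pairs carrying that significant
    relation (orientation mapped through the contrapositive when the
    stored pair points the other way).  The maximal-support type is
    added as an edge when its support exceeds ``min_edge_support``;
    symmetric relations produce one edge in id order.  Conflicting
    types both above the cutoff are logged and the maximal kept.
    """
    sig = implications[implications["passes"]]
    gene_cluster = {g: c.cluster_id for c in clusters for g in c.members}
    sizes = {c.cluster_id: len(c.members) for c in clusters}

    # tallies[(ci, cj)][relation] with ci -> cj orientation
    tallies: dict[tuple[str, str], dict[str, int]] = {}
    for a, b, rel in sig[["gene_a", "gene_b", "relation"]].itertuples(index=False):
        ca, cb = gene_cluster.get(a), gene_cluster.get(b)
        if ca is None or cb is None or ca == cb:
            continue
        tallies.setdefault((ca, cb), {}).setdefault(rel, 0)
        tallies[(ca, cb)][rel] += 1
        tallies.setdefault((cb, ca), {}).setdefault(CONVERSE[rel], 0)
        tallies[(cb, ca)][CONVERSE[rel]] += 1

    order = {c.cluster_id: i for i, c in enumerate(clusters)}
    g = nx.DiGraph()
    for c in clusters:
        g.add_node(
            c.cluster_id,
            seed_gene=c.seed_gene,
            n_genes=len(c.members),
            direction=c.direction,
        )
    for (ci, cj), rel_counts in sorted(tallies.items(), key=lambda kv: (order[kv[0][0]], order[kv[0][1]])):
        total = sizes[ci] * sizes[cj]
        supports = sorted(
            ((count / total, rel) for rel, count in rel_counts.items()),
            key=lambda t: (-t[0], t[1]),
        )
        best_support, best_rel = supports[0]
        if best_support <= min_edge_support:
            continue
        runners = [r for s, r in supports[1:] if s > min_edge_support]
        if runners:
            logger.warning(
                "cluster pair (%s, %s): conflicting relation types above support "
                "threshold (%s kept over %s)",
                ci, cj, best_rel, runners,
            )
        if best_rel in SYMMETRIC_RELATIONS and order[ci] > order[cj]:
            continue  # stored once, from the lower-indexed cluster
        g.add_edge(ci, cj, relation=best_rel, support=float(best_support))
    return ClusterGraph(clusters=clusters, graph=g)


# ---------------------------------------------------------------------------
# Signature selection


def enumerate_paths(graph: nx.DiGraph, max_len: int) -> list[tuple[str, ...]]:
    """All simple directed paths with 1..max_len nodes, deterministic order."""
    nodes = sorted(graph.nodes)
    paths: list[tuple[str, ...]] = [(n,) for n in nodes]
    frontier = [(n,) for n in nodes]
    for _ in range(max_len - 1):
        nxt = []
        for path in frontier:
            for succ in sorted(graph.successors(path[-1])):
                if succ not in path:
                    nxt.append(path + (succ,))
        paths.extend(nxt)
        frontier = nxt
    return paths


def make_signature(path: tuple[str, ...], directions: dict[str, str | None]) -> SignaturePath:
    weights = []
    for pos, cid in enumerate(path, start=1):
        sign = -1 if directions.get(cid) == "down" else 1
        weights.append(sign * pos)
    return SignaturePath(cluster_ids=list(path), weights=weights)


def select_signature(
    cluster_graph: ClusterGraph,
    matrix: pd.DataFrame,
    fits: pd.DataFrame,
    labels: pd.Series,
    case_label: str,
    control_label: str | None = None,
    max_len: int = 3,
    scale: float = 3.0,
) -> list[SignaturePath]:
    """Rank candidate signature paths by training ROC-AUC.

    Simple directed paths of up to ``max_len`` clusters are enumerated
    exhaustively; each path's composite score over the training samples
    is scored by the ROC-AUC of case vs control.  The returned list is
    ranked by AUC (desc), then path length (asc), then lexical order.
    A warning is logged when no path separates the classes.
    """
    if any(c.direction is None for c in cluster_graph.clusters):
        assign_directions(
            cluster_graph.clusters, matrix, fits, labels, case_label, control_label, scale
        )
    directions = {c.cluster_id: c.direction for c in cluster_graph.clusters}
    members = cluster_graph.members_by_id

    labels = labels.reindex(matrix.columns)
    if control_label is None:
        mask = labels.notna()
    else:
        mask = labels.isin([case_label, control_label])
    y = (labels[mask] == case_label).astype(int)
    if y.nunique() < 2:
        raise ValueError("both classes must be present among labeled samples")

    ranked = []
    for path in enumerate_paths(cluster_graph.graph, max_len):
        sig = make_signature(path, directions)
        scores = composite_score(sig, matrix, fits, members, scale=scale)
        scores = scores[mask]
        ok = scores.notna()
        if y[ok].nunique() < 2:
            continue
        sig.auc = roc_auc(scores[ok].to_numpy(), y[ok].to_numpy())
        ranked.append(sig)
    ranked.sort(key=lambda s: (-s.auc, len(s.cluster_ids), tuple(s.cluster_ids)))
    if ranked and ranked[0].auc < 0.55:
        logger.warning(
            "no signature path separates %s from controls (best AUC %.3f)",
            case_label, ranked[0].auc,
        )
    return ranked
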