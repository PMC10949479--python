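"""Flux coupling analysis and coupled-reaction network topology.

Coupling between reaction pairs is classified from the geometry of the
steady-state flux cone {S v = 0, v_irr >= 0} (finite bound magnitudes do
not matter for coupling; blocked reactions are removed first using the
model's actual bounds).  Reversible reactions are split into nonnegative
forward/reverse halves; for each ordered half pair (i, j) the LP

    Rmin = min u_i,  Rmax = max u_i   s.t.  A u = 0, u >= 0, u_j = 1

classifies the pair: Rmin = Rmax != 0 means fully coupled with that ratio;
Rmin > 0 in both directions means partially coupled; Rmin > 0 in one
direction only means directional coupling; otherwise the pair is
uncoupled.  A net reaction pair takes the strongest relation among its
unblocked half pairs.

Coupled-reaction networks are anchored at the end-product exchanges
(lactate, acetate, succinate, formate, ethanol, 1,2-propanediol): the
connected components of the full/partial coupling graph that touch a seed
form the network; directional relations do not contribute edges.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.optimize import linprog

from .fluxcalc import ZERO_TOL, blocked_reactions, _equalities
from .netcore import MetabolicModel

__all__ = [
    "CouplingRelation",
    "CouplingMatrix",
    "RewiringScore",
    "fca",
    "build_coupled_network",
    "topology_metrics",
    "power_law_alpha",
    "dn_rewiring",
    "write_graphml",
]

_STRENGTH = {"fully": 4, "partially": 3, "directional": 2, "uncoupled": 1}


@dataclass(frozen=True)
class CouplingRelation:
    reaction_a: str
    reaction_b: str
    type: str            # fully | partially | directional | uncoupled
    direction: str = ""  # "a_to_b" or "b_to_a" for directional relations
    ratio: float | None = None  # v_b / v_a for fully coupled pairs

    def __post_init__(self):
        if self.type == "fully" and not (self.ratio and math.isfinite(self.ratio)):
            raise ValueError("fully coupled relation requires a finite "
                             "nonzero ratio")


@dataclass
class CouplingMatrix:
    """Pairwise coupling relations over the unblocked reactions."""

    relations: dict[frozenset, CouplingRelation]
    unblocked: list[str]
    blocked: set[str]

    def relation(self, a: str, b: str) -> CouplingRelation:
        return self.relations[frozenset((a, b))]

    def pairs(self, kinds=("fully", "partially")) -> list[CouplingRelation]:
        return [r for r in self.relations.values() if r.type in kinds]


@dataclass
class RewiringScore:
    node: str
    dn_score: float
    presence: tuple[bool, ...]


# --------------------------------------------------------------------------
# FCA core


def _cone_columns(model: MetabolicModel, keep: list[str]):
    """Split-halves cone matrix over the kept reactions.

    Returns (A, columns) where columns is a list of (reaction_id, sign).
    """
    A_full = _equalities(model)
    rxn_ids = model.reaction_ids()
    idx = {rid: j for j, rid in enumerate(rxn_ids)}
    cols, vecs = [], []
    for rid in keep:
        rxn = model.reaction(rid)
        j = idx[rid]
        if rxn.upper_bound > 0:
            cols.append((rid, +1))
            vecs.append(A_full[:, j])
        if rxn.lower_bound < 0:
            cols.append((rid, -1))
            vecs.append(-A_full[:, j])
    A = np.column_stack(vecs) if vecs else np.zeros((A_full.shape[0], 0))
    return A, cols


def _minmax(A, j_fix, j_obj):
    """min and max of u[j_obj] over {A u = 0, u >= 0, u[j_fix] = 1}.

    Returns (rmin, rmax) with rmax = inf when unbounded, or None when the
    normalization u[j_fix] = 1 is infeasible.
    """
    k = A.shape[1]
    bounds = [(0, None)] * k
    bounds[j_fix] = (1.0, 1.0)
    out = []
    for sign in (1.0, -1.0):
        c = np.zeros(k)
        c[j_obj] = sign
        res = linprog(c, A_eq=A, b_eq=np.zeros(A.shape[0]), bounds=bounds,
                      method="highs")
        if res.status == 2:       # infeasible normalization
            return None
        if res.status == 3:       # unbounded
            out.append(math.inf if sign < 0 else 0.0)
        elif res.status == 0:
            out.append(float(res.x[j_obj]))
        else:
            raise RuntimeError(f"FCA LP failed: {res.message}")
    rmin, rmax = out[0], out[1]
    return rmin, rmax


def fca(model: MetabolicModel, reactions: list[str] | None = None,
        tol: float = ZERO_TOL) -> CouplingMatrix:
    """Pairwise flux coupling classification over unblocked reactions."""
    blocked = blocked_reactions(model)
    keep = [rid for rid in (reactions or model.reaction_ids())
            if rid not in blocked]
    A, cols = _cone_columns(model, keep)
    k = len(cols)

    # drop halves that cannot be normalized to 1 within the cone
    feasible = []
    for j in range(k):
        bounds = [(0, None)] * k
        bounds[j] = (1.0, 1.0)
        res = linprog(np.zeros(k), A_eq=A, b_eq=np.zeros(A.shape[0]),
                      bounds=bounds, method="highs")
        if res.status == 0:
            feasible.append(j)
        elif res.status != 2:
            raise RuntimeError(f"FCA feasibility LP failed: {res.message}")
    halves_of: dict[str, list[int]] = {}
    for j in feasible:
        halves_of.setdefault(cols[j][0], []).append(j)

    # ordered-pair ranges; the reverse direction follows by homogeneity:
    # Rmin(j|i) = 1/Rmax(i|j), Rmax(j|i) = 1/Rmin(i|j)
    def classify_halves(i, j):
        mm = _minmax(A, j_fix=j, j_obj=i)
        if mm is None:
            return None
        rmin, rmax = mm
        j_to_i = rmin > tol
        i_to_j = math.isfinite(rmax)   # Rmin(j|i) = 1/Rmax(i|j) > 0
        if j_to_i and i_to_j and abs(rmax - rmin) <= 1e-6 * max(1.0, abs(rmax)):
            return "fully", rmin
        if j_to_i and i_to_j:
            return "partially", None
        if i_to_j:
            return "directional_i_to_j", None
        if j_to_i:
            return "directional_j_to_i", None
        return "uncoupled", None

    relations: dict[frozenset, CouplingRelation] = {}
    kept_ids = [rid for rid in keep if rid in halves_of]
    for a_pos in range(len(kept_ids)):
        for b_pos in range(a_pos + 1, len(kept_ids)):
            a, b = kept_ids[a_pos], kept_ids[b_pos]
            best = CouplingRelation(a, b, "uncoupled")
            for i in halves_of[a]:
                for j in halves_of[b]:
                    result = classify_halves(i, j)
                    if result is None:
                        continue
                    kind, ratio = result
                    if kind == "fully":
                        sign = cols[i][1] * cols[j][1]
                        # ratio is v_a per unit v_b on the halves; report
                        # v_b / v_a with net signs
                        rel = CouplingRelation(a, b, "fully",
                                               ratio=sign / ratio)
                    elif kind == "partially":
                        rel = CouplingRelation(a, b, "partially")
                    elif kind == "directional_i_to_j":
                        rel = CouplingRelation(a, b, "directional",
                                               direction="a_to_b")
                    elif kind == "directional_j_to_i":
                        rel = CouplingRelation(a, b, "directional",
                                               direction="b_to_a")
                    else:
                        rel = CouplingRelation(a, b, "uncoupled")
                    if _STRENGTH[rel.type] > _STRENGTH[best.type]:
                        best = rel
            relations[frozenset((a, b))] = best
    dropped = set(keep) - set(kept_ids)
    if dropped:
        warnings.warn(f"reactions unblocked by bounds but with no feasible "
                      f"cone half (treated as blocked): {sorted(dropped)}")
    return CouplingMatrix(relations=relations, unblocked=kept_ids,
                          blocked=blocked | dropped)


# --------------------------------------------------------------------------
# Network construction and topology


def build_coupled_network(coupling: CouplingMatrix,
                          seed_exchanges: list[str]) -> nx.Graph:
    """Coupling graph components anchored at the end-product exchanges.

    Nodes are the seeds plus every reaction in a full/partial coupling
    component containing a seed; edges carry a ``type`` attribute (full or
    partial).  Directional relations never form edges.  Blocked seeds are
    retained as isolated nodes with a warning.
    """
    graph = nx.Graph()
    graph.add_nodes_from(coupling.unblocked)
    for rel in coupling.pairs(("fully", "partially")):
        graph.add_edge(rel.reaction_a, rel.reaction_b,
                       type="full" if rel.type == "fully" else "partial",
                       ratio=rel.ratio if rel.ratio is not None else "")
    nodes: set[str] = set()
    for seed in seed_exchanges:
        if seed not in graph:
            warnings.warn(f"seed exchange {seed!r} is blocked; kept as an "
                          "isolated node")
            nodes.add(seed)
            continue
        nodes |= nx.node_connected_component(graph, seed)
    sub = nx.Graph(graph.subgraph(nodes & set(graph.nodes)))
    sub.add_nodes_from(nodes - set(sub.nodes))
    return sub


def topology_metrics(network: nx.Graph) -> dict:
    """Node/edge counts, mean clustering, degree sequence, edge betweenness.

    Clustering is the unweighted local coefficient averaged over all nodes,
    with degree < 2 nodes contributing zero (the mainstream graph-tool
    convention).
    """
    degrees = sorted((d for _, d in network.degree()), reverse=True)
    return {
        "n_nodes": network.number_of_nodes(),
        "n_edges": network.number_of_edges(),
        "clustering_coefficient": (nx.average_clustering(network)
                                   if network.number_of_nodes() else 0.0),
        "degree_sequence": degrees,
        "edge_betweenness": nx.edge_betweenness_centrality(network),
        "power_law_alpha": power_law_alpha(degrees),
    }


def power_law_alpha(degrees, dmin: int = 1) -> float | None:
    """Continuous MLE exponent of a power-law degree distribution.

    alpha = 1 + n / sum(ln(d / dmin)) over degrees >= dmin.  Reported as a
    descriptive fit statistic only; no goodness-of-fit decision is made.
    """
    ds = [d for d in degrees if d >= dmin]
    if len(ds) < 2:
        return None
    total = sum(math.log(d / dmin) for d in ds)
    if total <= 0:
        return None
    return 1.0 + len(ds) / total


# --------------------------------------------------------------------------
# Rewiring (Dn) and consensus


def dn_rewiring(networks: list[nx.Graph],
                labels: list[str] | None = None
                ) -> tuple[list[RewiringScore], nx.Graph]:
    """Per-node rewiring scores across condition networks plus a consensus.

    For each node, each network containing it contributes a binary
    incidence vector over the union of the node's neighbors across all
    networks; the Dn score is the mean Euclidean distance of these vectors
    to their centroid, normalized by the node's mean degree (nodes with no
    neighbors anywhere normalize by 1).  Dn = 0 iff the neighbor set is
    identical in every network containing the node.  The consensus graph is
    the union of nodes and edges, each edge annotated with the number of
    networks containing it.
    """
    if len(networks) < 2:
        raise ValueError("need at least two networks")
    labels = labels or [f"network_{i}" for i in range(len(networks))]
    all_nodes = set().union(*(set(g.nodes) for g in networks))
    scores = []
    for node in sorted(all_nodes):
        containing = [g for g in networks if node in g]
        presence = tuple(node in g for g in networks)
        union_neighbors = sorted(set().union(
            *(set(g.neighbors(node)) for g in containing)))
        if not union_neighbors:
            scores.append(RewiringScore(node, 0.0, presence))
            continue
        vectors = np.array([
            [1.0 if g.has_edge(node, nb) else 0.0 for nb in union_neighbors]
            for g in containing
        ])
        centroid = vectors.mean(axis=0)
        dist = np.linalg.norm(vectors - centroid, axis=1).mean()
        mean_degree = vectors.sum(axis=1).mean()
        scores.append(RewiringScore(node, float(dist / max(mean_degree, 1.0)),
                                    presence))
    consensus = nx.Graph()
    consensus.add_nodes_from(sorted(all_nodes))
    for g, label in zip(networks, labels):
        for u, v, data in g.edges(data=True):
            if consensus.has_edge(u, v):
                consensus[u][v]["multiplicity"] += 1
                consensus[u][v]["networks"] += f";{label}"
            else:
                consensus.add_edge(u, v, multiplicity=1, networks=label,
                                   type=data.get("type", ""))
    for score in scores:
        consensus.nodes[score.node]["dn_score"] = score.dn_score
        consensus.nodes[score.node]["n_networks"] = sum(score.presence)
    return scores, consensus


def write_graphml(network: nx.Graph, path,
                  model: MetabolicModel | None = None) -> None:
    """GraphML export with subsystem node attributes when a model is given."""
    out = nx.Graph()
    out.add_nodes_from(network.nodes(data=True))
    out.add_edges_from(network.edges(data=True))
    if model is not None:
        for node in out.nodes:
            if model.has_reaction(node):
                out.nodes[node]["subsystem"] = model.reaction(node).subsystem
    for _, _, data in out.edges(data=True):
        if data.get("ratio") is None:
            data["ratio"] = ""
    nx.write_graphml(out, str(path))
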