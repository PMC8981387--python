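"""Metabolite-metabolite interaction (MMI) subnetworks and hub ranking.

DMs are projected onto a chemical-chemical association edge list (STITCH
convention: integer confidence scores on a 0-1000 scale); only
high-confidence edges (score >= 700 by default) are kept.  Hubs are the
nodes with the highest shortest-path betweenness centrality, computed
exactly on the unweighted graph — DM subnetworks are small enough that
no sampling is needed.  Ties are broken by degree (descending) then id.
"""

from __future__ import annotations

import dataclasses

import networkx as nx
import pandas as pd

from .io import StudyValidationError

HIGH_CONFIDENCE = 700
TOP_K = 4


@dataclasses.dataclass(frozen=True)
class InteractionGraph:
    """Induced DM subnetwork plus the DMs that ended up isolated."""

    graph: nx.Graph
    isolated_dms: tuple

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


def build_subnetwork(dm_ids, edges: pd.DataFrame, min_score: int = HIGH_CONFIDENCE) -> InteractionGraph:
    """Induced subgraph of the edge list on the DM set, confidence-filtered.

    Duplicate rows for the same unordered pair are deduplicated keeping
    the maximum score; self-loops are discarded.  DMs with no surviving
    edge are excluded from the graph but reported in ``isolated_dms``.
    """
    dm_set = set(dm_ids)
    if not dm_set:
        raise StudyValidationError("dm_ids is empty")
    g = nx.Graph()
    for a, b, score in edges[["chemical_a", "chemical_b", "combined_score"]].itertuples(index=False):
        if a == b:
            continue
        if a not in dm_set or b not in dm_set:
            continue
        if score < min_score:
            continue
        prev = g.get_edge_data(a, b)
        if prev is None or prev["score"] < score:
            g.add_edge(a, b, score=int(score))
    isolated = tuple(sorted(dm_set - set(g.nodes)))
    return InteractionGraph(graph=g, isolated_dms=isolated)


def rank_hubs(interaction: InteractionGraph | nx.Graph, top_k: int = TOP_K) -> pd.DataFrame:
    """Rank nodes by exact normalized betweenness centrality.

    Returns a table indexed by metabolite id with columns betweenness,
    degree, rank (1-based) and is_top.  Ranking order: betweenness
    descending, degree descending, id ascending.  An empty graph yields
    an empty ranking.
    """
    g = interaction.graph if isinstance(interaction, InteractionGraph) else interaction
    if g.number_of_nodes() == 0:
        return pd.DataFrame(
            columns=["betweenness", "degree", "rank", "is_top"],
            index=pd.Index([], name="metabolite_id"),
        )
    bc = nx.betweenness_centrality(g, normalized=True)
    out = pd.DataFrame(
        {
            "betweenness": pd.Series(bc),
            "degree": pd.Series(dict(g.degree())),
        }
    )
    out.index.name = "metabolite_id"
    out = out.loc[
        sorted(out.index, key=lambda i: (-out.at[i, "betweenness"], -out.at[i, "degree"], str(i)))
    ]
    out["rank"] = range(1, len(out) + 1)
    out["is_top"] = out["rank"] <= top_k
    return out


def annotate_hub_directions(ranking: pd.DataFrame, results: pd.DataFrame) -> pd.DataFrame:
    """Attach each ranked node's direction and log2 fold change.

    ``results`` is the per-metabolite differential table; every ranked
    node must have a record.
    """
    missing = [mid for mid in ranking.index if mid not in results.index]
    if missing:
        raise StudyValidationError(f"ranked nodes without differential records: {missing}")
    out = ranking.copy()
    out["direction"] = results.loc[ranking.index, "direction"].to_numpy()
    out["log2_fold_change"] = results.loc[ranking.index, "log2_fold_change"].to_numpy()
    return out


def export_graph(interaction: InteractionGraph, edge_path, node_path, node_attrs: pd.DataFrame | None = None) -> None:
    """Write the subnetwork as edge + node attribute TSVs for graph viewers."""
    edges = pd.DataFrame(
        [
            {"chemical_a": min(a, b), "chemical_b": max(a, b), "combined_score": d["score"]}
            for a, b, d in interaction.graph.edges(data=True)
        ]
    ).sort_values(["chemical_a", "chemical_b"]) if interaction.n_edges else pd.DataFrame(
        columns=["chemical_a", "chemical_b", "combined_score"]
    )
    edges.to_csv(edge_path, sep="\t", index=False)
    nodes = pd.DataFrame(index=pd.Index(sorted(interaction.graph.nodes), name="metabolite_id"))
    nodes["isolated"] = False
    iso = pd.DataFrame(index=pd.Index(interaction.isolated_dms, name="metabolite_id"))
    iso["isolated"] = True
    nodes = pd.concat([nodes, iso])
    if node_attrs is not None:
        nodes = nodes.join(node_attrs, how="left")
    nodes.to_csv(node_path, sep="\t", na_rep="NA")
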