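"""Shared oracles and simulation-replicate helpers for the test suite."""

from __future__ import annotations

from collections import deque

import numpy as np

from metabosig import differential, enrichment, preprocess, synthetic

PLANTED_UP = "Leucine, Isoleucine and Valine Metabolism"
PLANTED_DOWN = "Benzoate Metabolism"


def brute_force_betweenness(nodes, edges) -> dict:
    """Betweenness by explicit shortest-path counting (BFS per source).

    Independent of networkx: counts, for every unordered pair (s, t),
    the fraction of shortest s-t paths through each other node, then
    normalizes by (n-1)(n-2)/2 as the undirected convention does.
    """
    nodes = list(nodes)
    adj = {v: set() for v in nodes}
    for a, b in edges:
        adj[a].add(b)
        adj[b].add(a)

    def bfs(s):
        dist = {s: 0}
        sigma = {s: 1}
        q = deque([s])
        while q:
            u = q.popleft()
            for w in adj[u]:
                if w not in dist:
                    dist[w] = dist[u] + 1
                    sigma[w] = 0
                    q.append(w)
                if dist[w] == dist[u] + 1:
                    sigma[w] += sigma[u]
        return dist, sigma

    info = {s: bfs(s) for s in nodes}
    bc = {v: 0.0 for v in nodes}
    for i, s in enumerate(nodes):
        dist_s, sigma_s = info[s]
        for t in nodes[i + 1:]:
            if t == s or t not in dist_s:
                continue
            dist_t, sigma_t = info[t]
            d_st = dist_s[t]
            for v in nodes:
                if v in (s, t) or v not in dist_s or v not in dist_t:
                    continue
                if dist_s[v] + dist_t[v] == d_st:
                    bc[v] += sigma_s[v] * sigma_t[v] / sigma_s[t]
    n = len(nodes)
    norm = (n - 1) * (n - 2) / 2.0
    if norm <= 0:
        return {v: 0.0 for v in nodes}
    return {v: bc[v] / norm for v in nodes}


def null_rep_pvalues(seed: int, n_metabolites: int = 100) -> np.ndarray:
    """p-values from one no-effect, no-dropout replicate."""
    cfg = synthetic.SimulationConfig(
        seed=seed, n_metabolites=n_metabolites, planted_dm_sets=(), dropout_quantile=0.0
    )
    study, _, _ = synthetic.simulate_study(cfg)
    results = differential.run_differential(preprocess.normalize(study))
    return results["p_value"].to_numpy()


def recovery_rep(seed: int, n_metabolites: int = 200):
    """One planted-effect replicate: (sensitivity, FDP, signature flag).

    Uses the generator defaults (fold-3 planted sets, 5 samples/group,
    10% dropout) at a compact metabolite panel.
    """
    cfg = synthetic.SimulationConfig(seed=seed, n_metabolites=n_metabolites)
    study, annotations, truth = synthetic.simulate_study(cfg)
    results = differential.run_differential(preprocess.normalize(study))
    called = set(results.index[results["is_dm"]])
    true_dms = set(truth.dm_ids())
    sensitivity = len(called & true_dms) / len(true_dms)
    fdp = len(called - true_dms) / max(len(called), 1)
    pathways = enrichment.score_all_pathways(results, annotations)
    signature = bool(
        PLANTED_UP in pathways.index and pathways.at[PLANTED_UP, "is_signature"]
    )
    return sensitivity, fdp, signature
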