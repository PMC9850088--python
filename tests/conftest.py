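"""Shared fixtures and independent oracles used across the suite.

The oracles here deliberately avoid the library code paths they check:
centralities are recomputed from all-pairs BFS distance/path-count tables,
hypergeometric tails from exact rational arithmetic, and interval windows
from quadratic brute-force scans.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from ucsig.types import DETable


# ---------------------------------------------------------------------------
# brute-force centrality oracle (all-pairs BFS, pair-dependency counting)


def bfs_all(g: nx.Graph, source):
    """Distances and shortest-path counts from one source by plain BFS."""
    dist = {source: 0}
    sigma = {source: 1}
    queue = [source]
    while queue:
        nxt = []
        for u in queue:
            for v in g.neighbors(u):
                if v not in dist:
                    dist[v] = dist[u] + 1
                    sigma[v] = 0
                    nxt.append(v)
                if dist[v] == dist[u] + 1:
                    sigma[v] += sigma[u]
        queue = nxt
    return dist, sigma


def brute_force_centralities(g: nx.Graph) -> pd.DataFrame:
    """Degree, harmonic closeness and betweenness from first principles.

    Betweenness uses the pair-dependency identity
    sigma_sv * sigma_vt / sigma_st summed over unordered pairs (s, t) with
    d(s,v) + d(v,t) = d(s,t) — a different computation from Brandes's
    accumulation.  All measures normalized as the library documents.
    """
    nodes = sorted(g.nodes, key=str)
    n = len(nodes)
    dist = {}
    sigma = {}
    for s in nodes:
        dist[s], sigma[s] = bfs_all(g, s)
    degree = {v: g.degree(v) for v in nodes}
    closeness = {}
    for v in nodes:
        inv = sum(1.0 / d for u, d in dist[v].items() if u != v)
        closeness[v] = inv / (n - 1) if n > 1 else 0.0
    bet = {v: 0.0 for v in nodes}
    for i, s in enumerate(nodes):
        for t in nodes[i + 1 :]:
            if t not in dist[s]:
                continue
            dst = dist[s][t]
            for v in nodes:
                if v in (s, t) or v not in dist[s] or v not in dist[t]:
                    continue
                if dist[s][v] + dist[t][v] == dst:
                    bet[v] += sigma[s][v] * sigma[t][v] / sigma[s][t]
    scale = 2.0 / ((n - 1) * (n - 2)) if n > 2 else 0.0
    return pd.DataFrame(
        {
            "node": nodes,
            "degree": [float(degree[v]) for v in nodes],
            "closeness": [closeness[v] for v in nodes],
            "betweenness": [bet[v] * scale for v in nodes],
        }
    )


# ---------------------------------------------------------------------------
# exact hypergeometric tail


def exact_hypergeom_tail(k: int, N: int, K: int, n: int) -> Fraction:
    """Upper-tail P(X >= k) as an exact rational."""
    total = comb(N, n)
    return sum(
        (Fraction(comb(K, j) * comb(N - K, n - j), total) for j in range(k, min(K, n) + 1)),
        Fraction(0),
    )


# ---------------------------------------------------------------------------
# small hand-built inputs


def make_de_table(rows, dataset_id="d1", species="mouse", tissue="colon", assay="total_rna"):
    """rows: (gene_id, biotype, log2fc, padj) tuples; pvalue = padj/2."""
    df = pd.DataFrame(rows, columns=["gene_id", "biotype", "log2fc", "padj"])
    df["base_mean"] = 100.0
    df["pvalue"] = df["padj"] / 2
    return DETable(
        dataset_id=dataset_id,
        species=species,
        tissue=tissue,
        assay=assay,
        records=df[["gene_id", "biotype", "base_mean", "log2fc", "pvalue", "padj"]],
    )


@pytest.fixture
def small_mouse_table():
    return make_de_table(
        [
            ("g_up", "pcg", 2.0, 0.01),
            ("g_down", "pcg", -1.5, 0.02),
            ("g_weak_fc", "pcg", 0.5, 0.01),
            ("g_not_sig", "pcg", 3.0, 0.5),
            ("g_lnc_up", "lncrna", 1.8, 0.03),
            ("g_na", "pcg", 2.5, np.nan),
        ]
    )


@pytest.fixture
def star_graph():
    g = nx.Graph()
    for leaf in "BCDE":
        g.add_edge("A", leaf, confidence=0.9)
    return g
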