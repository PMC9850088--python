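"""Combined centrality ranking on a confidence-scored interaction network.

Three complementary measures are computed per node — degree, harmonic
closeness and shortest-path betweenness — then min-max normalized and
averaged (configurable weights) into one combined importance score used to
rank candidate genes.  Harmonic closeness is used instead of the classic
form because interaction subnetworks are frequently disconnected and the
harmonic mean of inverse distances stays well-defined across components.

By default paths are hop-count based; optionally edge confidences enter as
lengths (1 - confidence + eps) and degree becomes the confidence sum.
"""

from __future__ import annotations

import numpy as np
import networkx as nx
import pandas as pd

from .types import CentralityResult

#: small positive floor so a confidence-1.0 edge still has positive length
_EPS = 1e-3

RAW_COLUMNS = ["node", "degree", "closeness", "betweenness"]


def centralities(net: nx.Graph, use_confidence_weights: bool = False) -> pd.DataFrame:
    """Raw per-node degree, harmonic closeness and betweenness.

    * degree: edge count, or summed edge confidence when weighted;
    * harmonic closeness: sum of 1/d over reachable nodes, divided by N-1;
    * betweenness: Brandes, pair-normalized (2/((N-1)(N-2)) for undirected).

    Isolated nodes score 0 on all three.  An empty graph yields an empty
    frame.  Rows are sorted by node id.
    """
    nodes = sorted(net.nodes, key=str)
    if not nodes:
        return pd.DataFrame(columns=RAW_COLUMNS)
    n = len(nodes)
    if use_confidence_weights:
        for a, b, data in net.edges(data=True):
            data["length"] = 1.0 - data.get("confidence", 1.0) + _EPS
        degree = {v: sum(d.get("confidence", 1.0) for _, _, d in net.edges(v, data=True)) for v in nodes}
        dist_arg = {"distance": "length"}
        bw_arg = {"weight": "length"}
    else:
        degree = dict(net.degree())
        dist_arg = {}
        bw_arg = {"weight": None}
    harmonic = nx.harmonic_centrality(net, **dist_arg)
    scale = 1.0 / (n - 1) if n > 1 else 0.0
    betweenness = nx.betweenness_centrality(net, normalized=True, **bw_arg)
    return pd.DataFrame(
        {
            "node": nodes,
            "degree": [float(degree[v]) for v in nodes],
            "closeness": [harmonic[v] * scale for v in nodes],
            "betweenness": [betweenness[v] for v in nodes],
        }
    )


def _minmax(x: np.ndarray) -> np.ndarray:
    lo, hi = x.min(), x.max()
    if hi == lo:
        # constant measure carries no ranking information
        return np.full_like(x, 0.5)
    return (x - lo) / (hi - lo)


def combined_rank(
    raw: pd.DataFrame,
    weights: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3),
    normalization: str = "minmax",
) -> CentralityResult:
    """Combine raw centralities into a single score and dense rank.

    Each measure is min-max scaled to [0,1] over the node set (a constant
    measure maps to 0.5 everywhere), then combined as a weighted mean with
    weights normalized to sum 1.  Rank 1 is the highest combined score;
    ties share the smaller rank (dense ranking) and output order breaks
    ties lexicographically by node id.
    """
    if normalization != "minmax":
        raise ValueError(f"unknown normalization {normalization!r}")
    w = np.asarray(weights, dtype=float)
    if w.sum() <= 0:
        raise ValueError("weights must have positive sum")
    w = w / w.sum()
    df = raw.copy()
    if not len(df):
        df["combined"] = []
        df["rank"] = []
        return CentralityResult(table=df, weights=tuple(w))
    scaled = np.column_stack(
        [_minmax(df[c].to_numpy(dtype=float)) for c in ("degree", "closeness", "betweenness")]
    )
    df["combined"] = scaled @ w
    df = df.sort_values(["combined", "node"], ascending=[False, True], kind="stable")
    df["rank"] = (
        df["combined"].rank(method="dense", ascending=False).astype(int)
    )
    return CentralityResult(
        table=df.reset_index(drop=True), normalization=normalization, weights=tuple(w)
    )


def rank_genes(
    net: nx.Graph,
    candidates=None,
    weights: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3),
    use_confidence_weights: bool = False,
) -> CentralityResult:
    """Centrality-rank candidate genes on the full network.

    Centralities are computed on the whole graph (context nodes still route
    paths); when ``candidates`` is given the result is filtered to them and
    re-ranked among themselves.
    """
    raw = centralities(net, use_confidence_weights=use_confidence_weights)
    result = combined_rank(raw, weights=weights)
    if candidates is None:
        return result
    keep = result.table[result.table["node"].isin(set(candidates))].copy()
    keep = keep.sort_values(["combined", "node"], ascending=[False, True], kind="stable")
    keep["rank"] = keep["combined"].rank(method="dense", ascending=False).astype(int)
    return CentralityResult(
        table=keep.reset_index(drop=True),
        normalization=result.normalization,
        weights=result.weights,
    )
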