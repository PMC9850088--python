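"""Over-representation analysis of a gene set against a term collection.

For each term with members K inside the universe N, a query of size n with
k hits gets the one-sided hypergeometric tail p = P(X >= k); p-values are
corrected across all tested terms with Benjamini-Hochberg step-up.  The
gene ratio k / K (hits over expressed genes in the term) is the dot-plot
x-axis statistic.

Only over-representation is tested; depletion is out of scope.  The
universe should be the expressed genes of the relevant experiment; query
genes outside the universe are trimmed with a warning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from ._errors import UsageError
from .types import GeneSetCollection

logger = logging.getLogger(__name__)

ENRICHMENT_COLUMNS = [
    "term_id",
    "term_name",
    "k",
    "K",
    "n",
    "N",
    "p_value",
    "fdr",
    "gene_ratio",
    "hits",
]


@dataclass
class EnrichmentResult:
    """Ranked enrichment rows (sorted by fdr, then p, then term_id)."""

    table: pd.DataFrame

    def significant(self, fdr_max: float = 0.05) -> pd.DataFrame:
        return self.table[self.table["fdr"] <= fdr_max]

    def __len__(self) -> int:
        return len(self.table)


def hypergeom_tail(k: int, N: int, K: int, n: int) -> float:
    """Upper-tail hypergeometric probability P(X >= k | N, K, n)."""
    if k <= 0:
        return 1.0
    return float(hypergeom.sf(k - 1, N, K, n))


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR values, order-preserving."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def enrich(
    query,
    universe,
    collection: GeneSetCollection,
    min_term_size: int = 3,
) -> EnrichmentResult:
    """Test every term in the collection for over-representation of the query.

    Terms are restricted to the universe before sizing; terms smaller than
    ``min_term_size`` within the universe (including terms entirely outside
    it) are skipped.  Terms with zero hits are reported with p = 1.
    """
    universe = set(universe)
    if not universe:
        raise UsageError("empty universe")
    query = set(query)
    outside = query - universe
    if outside:
        logger.warning("%d query gene(s) outside universe trimmed", len(outside))
        query &= universe
    N, n = len(universe), len(query)
    rows = []
    for term_id in sorted(collection.sets):
        term_name, members = collection.sets[term_id]
        members_in = members & universe
        K = len(members_in)
        if K < min_term_size:
            logger.debug("term %s skipped (size %d in universe)", term_id, K)
            continue
        hit_genes = sorted(query & members_in)
        k = len(hit_genes)
        rows.append(
            (
                term_id,
                term_name,
                k,
                K,
                n,
                N,
                hypergeom_tail(k, N, K, n),
                np.nan,
                k / K,
                ",".join(hit_genes),
            )
        )
    table = pd.DataFrame(rows, columns=ENRICHMENT_COLUMNS)
    if len(table):
        table["fdr"] = bh_adjust(table["p_value"].to_numpy())
        table = table.sort_values(
            ["fdr", "p_value", "term_id"], kind="stable"
        ).reset_index(drop=True)
    return EnrichmentResult(table=table)


def dot_plot(result: EnrichmentResult, ax=None, top: int = 15, fdr_max: float | None = None):
    """Gene-ratio dot plot (size = hit count, color = FDR) for the top terms.

    Terms with zero hits are excluded by default.  Returns the axes.
    """
    import matplotlib.pyplot as plt

    df = result.table
    df = df[df["k"] > 0]
    if fdr_max is not None:
        df = df[df["fdr"] <= fdr_max]
    df = df.head(top).iloc[::-1]
    if ax is None:
        _, ax = plt.subplots(figsize=(6, max(2, 0.4 * len(df))))
    sc = ax.scatter(
        df["gene_ratio"],
        df["term_name"],
        s=20 + 12 * df["k"],
        c=df["fdr"],
        cmap="viridis_r",
    )
    ax.set_xlabel("gene ratio (k / K)")
    if len(df):
        ax.figure.colorbar(sc, ax=ax, label="FDR")
    return ax
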