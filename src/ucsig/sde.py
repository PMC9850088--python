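"""Single-dataset significant-differential-expression (SDE) calling.

A gene is SDE when its adjusted p-value passes the cutoff (inclusive,
padj <= 0.05 by default) and its fold change passes the biotype-appropriate
floor (strict): |log2FC| > 1 for total-RNA genes (PCGs, lncRNAs, others),
|FC| > 1.5 for miRNAs measured by small-RNA assays.  Missing padj means the
upstream DE tool filtered the gene and is treated as not significant.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd

from ._errors import ConfigError, UsageError
from .types import BIOTYPES, DETable, SDESet

logger = logging.getLogger(__name__)


def call_sde(
    table: DETable,
    padj_max: float = 0.05,
    lfc_min_total: float = 1.0,
    fc_min_mirna: float = 1.5,
) -> SDESet:
    """Call SDE genes in one dataset.

    Parameters
    ----------
    table:
        Validated DE results for one dataset.
    padj_max:
        Inclusive adjusted-p cutoff.
    lfc_min_total:
        Strict |log2FC| floor for total-RNA assays.  Note FC > 2 is the
        same call as |log2FC| > 1, so the enrichment-input gene set needs
        no separate code path.
    fc_min_mirna:
        Strict linear |FC| floor for small-RNA assays (applied in either
        direction, as down-regulated miRNAs are also called).

    A gene with log2fc exactly 0 cannot be direction-labelled and is
    excluded (logged) even if significant.
    """
    if padj_max <= 0 or lfc_min_total < 0 or fc_min_mirna < 1.0:
        raise ConfigError("thresholds out of range")
    df = table.records
    padj = df["padj"].to_numpy(dtype=float)
    lfc = df["log2fc"].to_numpy(dtype=float)
    sig = ~np.isnan(padj) & (padj <= padj_max)
    if table.assay == "small_rna":
        passes_fc = np.abs(lfc) > math.log2(fc_min_mirna)
    else:
        passes_fc = np.abs(lfc) > lfc_min_total
    keep = sig & passes_fc & (lfc != 0)
    n_zero = int((sig & passes_fc & (lfc == 0)).sum())
    if n_zero:
        logger.warning(
            "%s: %d significant gene(s) with log2fc == 0 excluded (no direction)",
            table.dataset_id,
            n_zero,
        )
    entries = {
        g: ("up" if f > 0 else "down")
        for g, f in zip(df.loc[keep, "gene_id"], lfc[keep])
    }
    return SDESet(
        species=table.species,
        tissue=table.tissue,
        source=table.dataset_id,
        entries=entries,
        thresholds={
            "padj_max": padj_max,
            "lfc_min_total": lfc_min_total,
            "fc_min_mirna": fc_min_mirna,
        },
    )


def tally_by_biotype(sde: SDESet, table: DETable) -> pd.DataFrame:
    """Count up/down SDE genes per biotype.

    Returns a frame indexed by biotype with columns ``n_up, n_down, total``;
    the grand total equals the number of SDE entries (counts are conserved).
    """
    lookup = dict(zip(table.records["gene_id"], table.records["biotype"]))
    missing = [g for g in sde.entries if g not in lookup]
    if missing:
        raise UsageError(f"SDE gene(s) absent from table: {missing[:3]}")
    counts = {bt: [0, 0] for bt in BIOTYPES}
    for gene, direction in sde.entries.items():
        counts[lookup[gene]][0 if direction == "up" else 1] += 1
    out = pd.DataFrame(
        [(bt, up, down, up + down) for bt, (up, down) in counts.items()],
        columns=["biotype", "n_up", "n_down", "total"],
    ).set_index("biotype")
    return out
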