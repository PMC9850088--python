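"""Multi-dataset evidence combination within one species and tissue.

Human evidence is combined by vote, not by p-value pooling: a gene enters
the combined set when it is significant (padj <= cutoff; fold change is not
thresholded here) in at least ``min_support`` datasets with agreeing
fold-change signs; genes meeting the support rule with conflicting signs
go to the ``inconsistent`` partition and are excluded from all downstream
cross-species comparison.  Direction consistency is judged only over the
datasets where the gene is significant: a non-significant opposite-sign
fold change elsewhere is noise and does not veto.

miRNAs follow a laxer rule (significant in at least one of exactly two
datasets), reflecting the much smaller number of available small-RNA
studies.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ._errors import UsageError
from .types import DETable, SDESet


def _check_same_context(tables: list[DETable]) -> tuple[str, str]:
    species = {t.species for t in tables}
    tissue = {t.tissue for t in tables}
    if len(species) != 1 or len(tissue) != 1:
        raise UsageError(
            f"datasets must share species and tissue, got {species} / {tissue}"
        )
    return species.pop(), tissue.pop()


def _evidence_frame(tables, padj_max, strict):
    """Long frame of (gene_id, dataset_id, sig, sign) over all datasets."""
    parts = []
    for t in tables:
        df = t.records
        padj = df["padj"].to_numpy(dtype=float)
        sig = ~np.isnan(padj) & ((padj < padj_max) if strict else (padj <= padj_max))
        parts.append(
            pd.DataFrame(
                {
                    "gene_id": df["gene_id"],
                    "dataset_id": t.dataset_id,
                    "sig": sig,
                    "sign": np.sign(df["log2fc"].to_numpy(dtype=float)),
                }
            )
        )
    return pd.concat(parts, ignore_index=True)


def combine_datasets(
    tables: list[DETable],
    padj_max: float = 0.05,
    min_support: int = 2,
    strict_padj: bool = False,
) -> SDESet:
    """Combine several same-tissue datasets of one species by vote.

    For each gene let D be the datasets where it is significant.  With
    |D| >= ``min_support`` and all fold-change signs over D agreeing, the
    gene enters with that direction; with signs disagreeing it goes to the
    inconsistent partition; with |D| < ``min_support`` it is absent.  A gene
    missing from a dataset's universe counts as not significant there.
    """
    if len(tables) < min_support:
        raise UsageError(f"need >= {min_support} datasets, got {len(tables)}")
    species, tissue = _check_same_context(tables)
    ev = _evidence_frame(tables, padj_max, strict_padj)
    # zero fold change carries no direction and cannot count as evidence
    sig = ev[ev["sig"] & (ev["sign"] != 0)]
    entries: dict[str, str] = {}
    inconsistent: set[str] = set()
    evidence_rows = []
    for gene, grp in sig.groupby("gene_id", sort=True):
        support = len(grp)
        if support < min_support:
            continue
        signs = set(grp["sign"])
        dirvec = ";".join(
            f"{d}:{'+' if s > 0 else '-' if s < 0 else '0'}"
            for d, s in zip(grp["dataset_id"], grp["sign"])
        )
        if signs == {1.0}:
            entries[gene] = "up"
            label = "up"
        elif signs == {-1.0}:
            entries[gene] = "down"
            label = "down"
        else:
            inconsistent.add(gene)
            label = "inconsistent"
        evidence_rows.append((gene, label, support, dirvec))
    evidence = pd.DataFrame(
        evidence_rows, columns=["gene_id", "call", "support", "directions"]
    )
    return SDESet(
        species=species,
        tissue=tissue,
        source="combined",
        entries=entries,
        inconsistent=inconsistent,
        thresholds={"padj_max": padj_max, "min_support": min_support},
        evidence=evidence,
    )


def combine_mirna(
    tables: list[DETable],
    padj_max: float = 0.05,
    strict_padj: bool = False,
) -> SDESet:
    """Combine exactly two small-RNA datasets, requiring significance in >= 1.

    Direction comes from the significant dataset(s); a miRNA significant in
    both with opposite signs is inconsistent.  The evidence frame records
    ``both_support`` so the count significant in both datasets is reported.
    """
    if len(tables) != 2:
        raise UsageError(f"miRNA combination uses exactly 2 datasets, got {len(tables)}")
    species, tissue = _check_same_context(tables)
    ev = _evidence_frame(tables, padj_max, strict_padj)
    sig = ev[ev["sig"] & (ev["sign"] != 0)]
    entries: dict[str, str] = {}
    inconsistent: set[str] = set()
    rows = []
    for gene, grp in sig.groupby("gene_id", sort=True):
        signs = set(grp["sign"])
        both = len(grp) == 2
        if signs <= {1.0}:
            entries[gene] = "up"
            label = "up"
        elif signs <= {-1.0}:
            entries[gene] = "down"
            label = "down"
        else:
            inconsistent.add(gene)
            label = "inconsistent"
        rows.append((gene, label, len(grp), both))
    evidence = pd.DataFrame(rows, columns=["gene_id", "call", "support", "both_support"])
    return SDESet(
        species=species,
        tissue=tissue,
        source="combined",
        entries=entries,
        inconsistent=inconsistent,
        thresholds={"padj_max": padj_max, "min_support": 1},
        evidence=evidence,
    )
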