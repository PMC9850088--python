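"""Ortholog-mediated intersection of mouse and human SDE sets.

Each matched orthology pair gets a direction class: up in both species
(concordant_up), down in both (concordant_down), or opposite directions
(contra).  Gene-level tallies count distinct mouse genes: a one-to-many
mouse gene matched by several human orthologs counts once, concordant if
any matched pair is concordant and contra only when every matched pair is
contra.  Genes flagged inconsistent by the multi-dataset combination are
excluded on both sides before the overlap.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ._errors import UsageError
from .types import (
    ConcordanceTable,
    CoreSet,
    DETable,
    OrthologyMap,
    SDESet,
    concordance_class,
)

PAIR_COLUMNS = [
    "mouse_gene_id",
    "human_gene_id",
    "relation",
    "mouse_dir",
    "human_dir",
    "pair_class",
]


def overlap_species(
    mouse_sde: SDESet, human_sde: SDESet, orth: OrthologyMap
) -> ConcordanceTable:
    """Intersect mouse and human SDE sets through an orthology map.

    Produces one row per orthology pair whose mouse member is in the mouse
    entries and whose human member is in the human entries, plus per-mouse-
    gene class labels and the sizes of each species' SDE set restricted to
    genes having an ortholog.
    """
    if mouse_sde.tissue != human_sde.tissue:
        raise UsageError(
            f"tissue mismatch: {mouse_sde.tissue} vs {human_sde.tissue}"
        )
    if mouse_sde.species != "mouse" or human_sde.species != "human":
        raise UsageError("expected (mouse SDE, human SDE) in that order")
    m_entries = {g: d for g, d in mouse_sde.entries.items() if g not in mouse_sde.inconsistent}
    h_entries = {g: d for g, d in human_sde.entries.items() if g not in human_sde.inconsistent}

    pairs = orth.pairs
    rows = []
    for m, h, rel in zip(
        pairs["mouse_gene_id"], pairs["human_gene_id"], pairs["relation"]
    ):
        if m in m_entries and h in h_entries:
            md, hd = m_entries[m], h_entries[h]
            rows.append((m, h, rel, md, hd, concordance_class(md, hd)))
    row_df = pd.DataFrame(rows, columns=PAIR_COLUMNS)

    # membership-oriented gene-level classes: one label per distinct mouse gene
    gene_rows = []
    if len(row_df):
        for m, grp in row_df.groupby("mouse_gene_id", sort=True):
            classes = set(grp["pair_class"])
            if "concordant_up" in classes or "concordant_down" in classes:
                # concordant wins; direction from the mouse side is unambiguous
                label = (
                    "concordant_up"
                    if grp["mouse_dir"].iloc[0] == "up"
                    else "concordant_down"
                )
            else:
                label = "contra"
            gene_rows.append((m, grp["human_gene_id"].iloc[0], label, grp["mouse_dir"].iloc[0]))
    gene_df = pd.DataFrame(
        gene_rows, columns=["mouse_gene_id", "human_gene_id", "gene_class", "mouse_dir"]
    )

    mouse_mapped = set(pairs["mouse_gene_id"])
    human_mapped = set(pairs["human_gene_id"])
    return ConcordanceTable(
        tissue=mouse_sde.tissue,
        rows=row_df,
        gene_classes=gene_df,
        n_mouse_sde_with_human_ortholog=len(set(m_entries) & mouse_mapped),
        n_human_sde_with_mouse_ortholog=len(set(h_entries) & human_mapped),
    )


def tally_concordance(ct: ConcordanceTable) -> dict[str, int]:
    """Gene-level tallies: total common, per class, and same-direction.

    Identities: ``n_total_common = n_up_up + n_down_down + n_contra`` and
    ``n_same_direction = n_up_up + n_down_down`` hold on every input.
    """
    counts = ct.gene_classes["gene_class"].value_counts() if len(ct.gene_classes) else {}
    n_uu = int(counts.get("concordant_up", 0))
    n_dd = int(counts.get("concordant_down", 0))
    n_x = int(counts.get("contra", 0))
    return {
        "n_total_common": n_uu + n_dd + n_x,
        "n_up_up": n_uu,
        "n_down_down": n_dd,
        "n_contra": n_x,
        "n_same_direction": n_uu + n_dd,
    }


def tally_from_counts(n_up_up: int, n_down_down: int, n_contra: int) -> dict[str, int]:
    """Tally identities from pre-counted concordance classes (table arithmetic)."""
    return {
        "n_total_common": n_up_up + n_down_down + n_contra,
        "n_up_up": n_up_up,
        "n_down_down": n_down_down,
        "n_contra": n_contra,
        "n_same_direction": n_up_up + n_down_down,
    }


def tally_concordance_by_biotype(
    ct: ConcordanceTable, biotypes: dict[str, str]
) -> pd.DataFrame:
    """Per-biotype class tallies over distinct mouse genes.

    ``biotypes`` maps mouse gene ids onto the closed biotype vocabulary;
    unmapped genes count as 'other'.
    """
    df = ct.gene_classes.copy()
    if not len(df):
        return pd.DataFrame(columns=["biotype", "concordant_up", "concordant_down", "contra"])
    df["biotype"] = df["mouse_gene_id"].map(lambda g: biotypes.get(g, "other"))
    out = (
        df.pivot_table(
            index="biotype",
            columns="gene_class",
            values="mouse_gene_id",
            aggfunc="count",
            fill_value=0,
        )
        .reindex(columns=["concordant_up", "concordant_down", "contra"], fill_value=0)
        .reset_index()
    )
    out.columns.name = None
    return out


def core_set(colon: ConcordanceTable, blood: ConcordanceTable) -> CoreSet:
    """Genes concordant within colon AND within blood.

    Cross-tissue direction agreement is recorded as an annotation, not a
    filter: a gene up in one tissue and down in the other (both concordant
    within their tissue) is a member with ``agreement=False``.  Contra genes
    in either tissue never enter.
    """
    def concordant_only(ct: ConcordanceTable) -> pd.DataFrame:
        df = ct.gene_classes
        return df[df["gene_class"] != "contra"]

    c = concordant_only(colon).set_index("mouse_gene_id")
    b = concordant_only(blood).set_index("mouse_gene_id")
    common = sorted(set(c.index) & set(b.index))
    members = pd.DataFrame(
        {
            "mouse_gene_id": common,
            "human_gene_id": [c.loc[g, "human_gene_id"] for g in common],
            "colon_class": [c.loc[g, "gene_class"] for g in common],
            "blood_class": [b.loc[g, "gene_class"] for g in common],
        }
    )
    members["agreement"] = members["colon_class"] == members["blood_class"]
    return CoreSet(members=members)


def relaxed_mirna_overlap(
    mouse_table: DETable,
    human_tables: list[DETable],
    orth: OrthologyMap,
    padj_max: float = 0.1,
) -> ConcordanceTable:
    """Cross-species miRNA overlap at a relaxed, strict-inequality cutoff.

    Builds significance-only direction sets with padj < ``padj_max`` on both
    species (mouse: its single dataset; human: significant in >= 1 of the two
    datasets) and runs the standard overlap.  The default 0.1 cutoff widens
    the common-miRNA set relative to the primary 0.05 analysis; the 0.05
    result is always a subset of the 0.1 result.
    """
    from .combine import combine_mirna

    df = mouse_table.records
    padj = df["padj"].to_numpy(dtype=float)
    lfc = df["log2fc"].to_numpy(dtype=float)
    keep = ~np.isnan(padj) & (padj < padj_max) & (lfc != 0)
    mouse_sde = SDESet(
        species=mouse_table.species,
        tissue=mouse_table.tissue,
        source=mouse_table.dataset_id,
        entries={
            g: ("up" if f > 0 else "down")
            for g, f in zip(df.loc[keep, "gene_id"], lfc[keep])
        },
        thresholds={"padj_max": padj_max, "strict": True},
    )
    human_sde = combine_mirna(human_tables, padj_max=padj_max, strict_padj=True)
    return overlap_species(mouse_sde, human_sde, orth)
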