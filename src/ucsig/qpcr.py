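"""Relative quantification of qPCR data by the Livak 2^-ddCt method.

Per sample, technical replicate Cts are averaged and the sample's reference
level is the arithmetic mean of its reference-gene Cts (equivalent to the
geometric mean of reference expression).  dCt = target Ct - reference Ct;
ddCt is the difference of group means of dCt between cases and controls
(unpaired subjects), and the fold change is 2^-ddCt.  No amplification-
efficiency correction is applied.

A sample missing every reference gene is invalid and is dropped from all
targets; a target missing from one group fails for that gene only.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from ._errors import UsageError
from .types import CtTable, FoldChangeResult

logger = logging.getLogger(__name__)

RESULT_COLUMNS = [
    "gene_id",
    "fold_change",
    "log2_fold_change",
    "delta_ct_case",
    "delta_ct_control",
    "n_case",
    "n_control",
    "error",
]


def ddct_fold_change(
    ct: CtTable,
    target_genes,
    reference_genes,
    control_group: str = "control",
    case_group: str = "case",
) -> FoldChangeResult:
    """Fold change per target gene relative to the control group.

    Returns one row per requested target; a per-gene problem (absent in a
    group) is recorded in the ``error`` column without affecting other
    genes.  Shifting every Ct of one sample by a constant leaves the fold
    changes unchanged, and swapping case and control inverts them.
    """
    reference_genes = list(reference_genes)
    if not reference_genes:
        raise UsageError("at least one reference gene required")
    rows = ct.rows
    # replicate means per (sample, gene)
    means = (
        rows.groupby(["sample_id", "group", "gene_id"], sort=False)["ct"]
        .mean()
        .reset_index()
    )
    wide = means.pivot_table(index=["sample_id", "group"], columns="gene_id", values="ct")
    present_refs = [g for g in reference_genes if g in wide.columns]
    if not present_refs:
        raise UsageError(f"no reference gene found among {reference_genes}")
    ref_ct = wide[present_refs].mean(axis=1, skipna=True)
    valid = ref_ct.notna()
    n_invalid = int((~valid).sum())
    if n_invalid:
        logger.warning("%d sample(s) lack all reference genes; dropped", n_invalid)
    wide = wide[valid]
    ref_ct = ref_ct[valid]
    groups = wide.index.get_level_values("group")

    out = []
    for gene in target_genes:
        if gene not in wide.columns:
            out.append((gene, np.nan, np.nan, np.nan, np.nan, 0, 0, "target absent"))
            continue
        dct = wide[gene] - ref_ct
        dcase = dct[(groups == case_group) & dct.notna()]
        dctrl = dct[(groups == control_group) & dct.notna()]
        if not len(dcase) or not len(dctrl):
            missing = case_group if not len(dcase) else control_group
            out.append(
                (gene, np.nan, np.nan, np.nan, np.nan, len(dcase), len(dctrl),
                 f"no measurements in group {missing!r}")
            )
            continue
        ddct = dcase.mean() - dctrl.mean()
        fc = 2.0 ** (-ddct)
        out.append(
            (gene, fc, -ddct, dcase.mean(), dctrl.mean(), len(dcase), len(dctrl), "")
        )
    table = pd.DataFrame(out, columns=RESULT_COLUMNS)
    return FoldChangeResult(table=table, reference_genes=tuple(reference_genes))
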