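"""Genomic-context annotation for non-coding genes.

Three annotations, all on 1-based inclusive coordinates:

* neighbors of lncRNAs — expressed protein-coding genes whose body overlaps
  a symmetric window (default 100 kb) around the lncRNA gene body,
* proximity of genes to disease-risk loci within the same window,
* miRNA target sets restricted to the expressed gene universe.

Window logic is strand-agnostic and anchored on the gene body by default
(configurable to the TSS).  The distance between non-overlapping intervals
is the gap in bp (later.start - earlier.end), compared inclusively with the
window size, so a gene starting exactly window_bp past the anchor end still
qualifies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._errors import UsageError
from .types import GeneLocus, loci_frame


@dataclass
class NeighborResult:
    """Per-lncRNA sets of expressed protein-coding neighbors."""

    neighbors: dict[str, set[str]]
    window_bp: int


@dataclass
class TargetSet:
    """Per-miRNA target sets within the expressed universe, with coverage."""

    targets: dict[str, set[str]]
    n_mirnas_with_targets: int
    n_input: int


def _anchor_interval(locus: GeneLocus, anchor: str) -> tuple[int, int]:
    if anchor == "tss":
        tss = locus.end if locus.strand == "-" else locus.start
        return tss, tss
    return locus.start, locus.end


def interval_gap(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    """Gap in bp between two 1-based inclusive intervals; 0 when overlapping."""
    if a_end < b_start:
        return b_start - a_end
    if b_end < a_start:
        return a_start - b_end
    return 0


def lncrna_neighbors(
    lnc_ids,
    loci: list[GeneLocus],
    window_bp: int = 100_000,
    expressed_only: bool = True,
    anchor: str = "body",
) -> NeighborResult:
    """Find protein-coding genes within ``window_bp`` of each lncRNA.

    A PCG is a neighbor when its gene body intersects
    ``[lnc.start - window, lnc.end + window]`` on the same chromosome
    (any-bp overlap, boundary inclusive).  The lncRNA is never its own
    neighbor.  With ``expressed_only`` (the default) only PCGs flagged
    expressed qualify.
    """
    by_id = {l.gene_id: l for l in loci}
    missing = [g for g in lnc_ids if g not in by_id]
    if missing:
        raise UsageError(f"lncRNA id(s) absent from loci: {missing}")
    frame = loci_frame(loci)
    pcg = frame[frame["biotype"] == "pcg"]
    if expressed_only:
        pcg = pcg[pcg["expressed"]]
    out: dict[str, set[str]] = {}
    for lnc in lnc_ids:
        locus = by_id[lnc]
        a_start, a_end = _anchor_interval(locus, anchor)
        lo, hi = a_start - window_bp, a_end + window_bp
        hit = pcg[
            (pcg["chrom"] == locus.chrom)
            & (pcg["start"] <= hi)
            & (pcg["end"] >= lo)
            & (pcg["gene_id"] != lnc)
        ]
        out[lnc] = set(hit["gene_id"])
    return NeighborResult(neighbors=out, window_bp=window_bp)


def risk_locus_proximity(
    gene_ids,
    loci: list[GeneLocus],
    risk_loci: list[GeneLocus],
    window_bp: int = 100_000,
) -> set[str]:
    """Flag genes within ``window_bp`` of any risk locus on the same chromosome.

    Overlap counts as distance 0; point loci are single-base intervals.
    """
    by_id = {l.gene_id: l for l in loci}
    missing = [g for g in gene_ids if g not in by_id]
    if missing:
        raise UsageError(f"gene id(s) absent from loci: {missing}")
    if not risk_loci:
        return set()
    risk = loci_frame(risk_loci)
    flagged = set()
    for g in gene_ids:
        locus = by_id[g]
        same = risk[risk["chrom"] == locus.chrom]
        if not len(same):
            continue
        starts = same["start"].to_numpy()
        ends = same["end"].to_numpy()
        gaps = np.maximum(starts - locus.end, 0) + np.maximum(locus.start - ends, 0)
        if (gaps <= window_bp).any():
            flagged.add(g)
    return flagged


def build_target_sets(mirna_ids, target_map: dict, expressed_universe) -> TargetSet:
    """Restrict mapped miRNA targets to the expressed gene universe.

    miRNAs absent from the map, or whose targets are all unexpressed, get an
    empty set and count as uncovered in the coverage statistics.
    """
    universe = set(expressed_universe)
    targets = {m: set(target_map.get(m, set())) & universe for m in mirna_ids}
    covered = sum(1 for s in targets.values() if s)
    return TargetSet(
        targets=targets,
        n_mirnas_with_targets=covered,
        n_input=len(list(mirna_ids)),
    )
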