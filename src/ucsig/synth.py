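"""Synthetic pipeline inputs with known planted ground truth.

Every generator is deterministic given its seed and returns, next to the
data, the truth needed to verify downstream recovery: which ortholog pairs
were planted as concordant-up, concordant-down, contra-regulated,
dataset-inconsistent, species-specific or null; which network nodes are
hubs; which fold changes the Ct tables encode; which protein-coding genes
sit within the neighbor window of each lncRNA (computed here by brute
force, independently of the annotation module).

Adjusted p-values are generated directly rather than derived from simulated
counts: the analysis consumes DE-tool output tables, so emulating the output
distribution suffices and keeps the generator analytic.  Signal genes draw
padj ~ U[0, 0.05] in the datasets where they fire and log2FC around a
class-signed effect mu; null genes draw padj ~ U(0.05, 1] and log2FC around
zero.  One shared gene universe per species is used across that species'
datasets, with per-dataset missingness available as a dropout fraction.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from ._errors import ConfigError
from .types import (
    CtTable,
    DETable,
    GeneLocus,
    GeneSetCollection,
    OrthologyMap,
    validate_network,
)

GENE_CLASSES = (
    "concordant_up",
    "concordant_down",
    "contra",
    "inconsistent",
    "species_specific",
    "single_support",
    "null",
)


# ---------------------------------------------------------------------------
# differential-expression tables


@dataclass
class SynthDEConfig:
    """Class sizes and noise model for one tissue's DE tables.

    Defaults plant 50 concordant-up, 30 concordant-down, 20 contra,
    15 inconsistent, 25 species-specific and 500 null ortholog pairs with a
    strong effect (mu = 3 log2 units) and small spread (sigma = 0.1), one
    mouse dataset and four human datasets — a size at which every class is
    exactly recoverable and the run stays fast.
    """

    n_concordant_up: int = 50
    n_concordant_down: int = 30
    n_contra: int = 20
    n_inconsistent: int = 15
    n_species_specific: int = 25
    n_single_support: int = 0
    n_null: int = 500
    mu: float = 3.0
    sigma: float = 0.1
    fire_prob: float = 1.0
    n_human_datasets: int = 4
    tissue: str = "colon"
    biotype_props: dict = field(
        default_factory=lambda: {"pcg": 0.7, "lncrna": 0.15, "other": 0.15}
    )
    one2many_frac: float = 0.05
    unmapped_frac: float = 0.05
    dropout: float = 0.0

    def class_sizes(self) -> dict[str, int]:
        return {
            "concordant_up": self.n_concordant_up,
            "concordant_down": self.n_concordant_down,
            "contra": self.n_contra,
            "inconsistent": self.n_inconsistent,
            "species_specific": self.n_species_specific,
            "single_support": self.n_single_support,
            "null": self.n_null,
        }


@dataclass
class PlantedTruth:
    """Ground truth for one tissue's synthetic DE tables."""

    tissue: str
    classes: dict[str, list[tuple[str, str]]]  # class -> [(mouse_id, human_id)]
    mouse_direction: dict[str, str]  # mouse genes SDE in the mouse dataset
    human_direction: dict[str, str]  # expected combined-set human calls
    human_inconsistent: set[str]
    orthology: OrthologyMap
    biotypes: dict[str, str]  # per mouse/human gene id
    mu: float
    sigma: float

    def expected_tallies(self) -> dict[str, int]:
        n_uu = len(self.classes["concordant_up"])
        n_dd = len(self.classes["concordant_down"])
        n_x = len(self.classes["contra"])
        return {
            "n_total_common": n_uu + n_dd + n_x,
            "n_up_up": n_uu,
            "n_down_down": n_dd,
            "n_contra": n_x,
            "n_same_direction": n_uu + n_dd,
        }


def _firing_sets(rng, n_genes, n_datasets, fire_prob, min_fire):
    """Per-gene boolean firing matrix with at least ``min_fire`` per row."""
    fires = rng.random((n_genes, n_datasets)) < fire_prob
    for i in range(n_genes):
        deficit = min_fire - fires[i].sum()
        if deficit > 0:
            off = np.flatnonzero(~fires[i])
            fires[i, rng.choice(off, size=deficit, replace=False)] = True
    return fires


def _signal_stats(rng, sign, mu, sigma):
    lfc = rng.normal(sign * mu, sigma)
    padj = rng.uniform(0.0, 0.05)
    return lfc, padj


def _null_stats(rng, sigma):
    lfc = rng.normal(0.0, sigma)
    padj = 0.05 + rng.uniform(0.0, 1.0) * 0.95  # U(0.05, 1]
    return lfc, padj


def _assign_classes(rng, n_pairs, sizes, forced=None) -> np.ndarray:
    """Class label per pair index; ``forced`` pins chosen indices to a class."""
    pair_class = np.empty(n_pairs, dtype=object)
    taken: set[int] = set()
    forced = forced or {}
    for cls, idxs in forced.items():
        if cls not in sizes:
            raise ConfigError(f"unknown class {cls!r}")
        if len(idxs) > sizes[cls]:
            raise ConfigError(f"forced {cls} indices exceed class size {sizes[cls]}")
        for i in idxs:
            if i in taken or not (0 <= i < n_pairs):
                raise ConfigError(f"bad forced index {i}")
            pair_class[i] = cls
            taken.add(i)
    free = np.array([i for i in range(n_pairs) if i not in taken])
    perm = rng.permutation(free)
    cursor = 0
    for cls in GENE_CLASSES:
        remaining = sizes[cls] - sum(1 for i in forced.get(cls, []))
        idx = perm[cursor : cursor + remaining]
        cursor += remaining
        pair_class[idx] = cls
    return pair_class


def synth_de(
    config: SynthDEConfig,
    seed: int,
    mouse_ids: list[str] | None = None,
    human_ids: list[str] | None = None,
    forced_classes: dict[str, list[int]] | None = None,
    make_orthology: bool = True,
) -> tuple[list[DETable], PlantedTruth]:
    """Generate one mouse + N human total-RNA DE tables for one tissue.

    Returns the tables (mouse first) and the planted truth.  Signal classes
    are planted on one-to-one ortholog pairs; one-to-many and unmapped
    relations are introduced among null genes only, so recovery checks stay
    exact.  Explicit ``mouse_ids``/``human_ids`` let several tissues share
    one genome-wide universe, and ``forced_classes`` pins selected pair
    indices to a class (used to plant a cross-tissue core).
    """
    sizes = config.class_sizes()
    if any(v < 0 for v in sizes.values()):
        raise ConfigError("class sizes must be >= 0")
    if config.sigma < 0:
        raise ConfigError("sigma must be >= 0")
    n_pairs = sum(sizes.values())
    rng = np.random.default_rng(seed)

    if mouse_ids is None:
        mouse_ids = [f"mmu_g{i:05d}" for i in range(n_pairs)]
    if human_ids is None:
        human_ids = [f"hsa_g{i:05d}" for i in range(n_pairs)]
    if len(mouse_ids) != n_pairs or len(human_ids) != n_pairs:
        raise ConfigError("id lists must match the total pair count")

    pair_class = _assign_classes(rng, n_pairs, sizes, forced_classes)
    classes: dict[str, list[tuple[str, str]]] = {
        cls: [
            (mouse_ids[i], human_ids[i])
            for i in sorted(np.flatnonzero(pair_class == cls))
        ]
        for cls in GENE_CLASSES
    }

    # biotypes, shared within an ortholog pair
    props = config.biotype_props
    bts = list(props)
    bt_draw = rng.choice(bts, size=n_pairs, p=[props[b] for b in bts])
    biotypes = {}
    for i in range(n_pairs):
        biotypes[mouse_ids[i]] = bt_draw[i]
        biotypes[human_ids[i]] = bt_draw[i]

    # per-class signs (mouse side); contra flips across species
    mouse_sign = np.zeros(n_pairs)
    for i in range(n_pairs):
        cls = pair_class[i]
        if cls == "concordant_up":
            mouse_sign[i] = 1
        elif cls == "concordant_down":
            mouse_sign[i] = -1
        elif cls in ("contra", "species_specific", "single_support"):
            mouse_sign[i] = rng.choice([-1.0, 1.0])

    # species-specific pairs split: even index -> mouse-only, odd -> human-only
    ss_idx = sorted(np.flatnonzero(pair_class == "species_specific"))
    mouse_only = set(ss_idx[0::2])
    human_only = set(ss_idx[1::2])

    n_h = config.n_human_datasets
    fires = _firing_sets(rng, n_pairs, n_h, config.fire_prob, min_fire=2)
    single_ds = rng.integers(0, n_h, size=n_pairs)  # dataset for single_support

    # ---- mouse dataset -------------------------------------------------
    mouse_rows = []
    mouse_direction = {}
    for i in range(n_pairs):
        cls = pair_class[i]
        fires_mouse = cls in ("concordant_up", "concordant_down", "contra", "single_support") or (
            cls == "species_specific" and i in mouse_only
        )
        if fires_mouse:
            lfc, padj = _signal_stats(rng, mouse_sign[i], config.mu, config.sigma)
            mouse_direction[mouse_ids[i]] = "up" if mouse_sign[i] > 0 else "down"
        else:
            lfc, padj = _null_stats(rng, config.sigma)
        mouse_rows.append(
            (mouse_ids[i], bt_draw[i], float(rng.lognormal(5, 1.5)), lfc, padj * rng.uniform(0.5, 1.0), padj)
        )
    tables = [
        DETable(
            dataset_id=f"mouse_{config.tissue}",
            species="mouse",
            tissue=config.tissue,
            assay="total_rna",
            records=pd.DataFrame(
                mouse_rows,
                columns=["gene_id", "biotype", "base_mean", "log2fc", "pvalue", "padj"],
            ),
        )
    ]

    # ---- human datasets ------------------------------------------------
    human_direction = {}
    human_inconsistent = set()
    # inconsistent genes: pre-assign alternating signs over their firing sets
    incon_signs = {}
    for i in np.flatnonzero(pair_class == "inconsistent"):
        ds = np.flatnonzero(fires[i])
        signs = np.where(np.arange(len(ds)) % 2 == 0, 1.0, -1.0)
        incon_signs[i] = dict(zip(ds, signs))
        human_inconsistent.add(human_ids[i])

    for j in range(n_h):
        rows = []
        for i in range(n_pairs):
            cls = pair_class[i]
            sign = 0.0
            firing = False
            if cls in ("concordant_up", "concordant_down"):
                firing = fires[i, j]
                sign = mouse_sign[i]
            elif cls == "contra":
                firing = fires[i, j]
                sign = -mouse_sign[i]
            elif cls == "inconsistent":
                firing = j in incon_signs[i]
                sign = incon_signs[i].get(j, 0.0)
            elif cls == "species_specific" and i in human_only:
                firing = fires[i, j]
                sign = mouse_sign[i]
            elif cls == "single_support":
                firing = j == single_ds[i]
                sign = mouse_sign[i]
            if firing:
                lfc, padj = _signal_stats(rng, sign, config.mu, config.sigma)
            else:
                lfc, padj = _null_stats(rng, config.sigma)
            if config.dropout and cls == "null" and rng.random() < config.dropout:
                continue
            rows.append(
                (human_ids[i], bt_draw[i], float(rng.lognormal(5, 1.5)), lfc, padj * rng.uniform(0.5, 1.0), padj)
            )
        tables.append(
            DETable(
                dataset_id=f"human_{config.tissue}_{j + 1}",
                species="human",
                tissue=config.tissue,
                assay="total_rna",
                records=pd.DataFrame(
                    rows,
                    columns=["gene_id", "biotype", "base_mean", "log2fc", "pvalue", "padj"],
                ),
            )
        )

    for i in range(n_pairs):
        cls = pair_class[i]
        if cls in ("concordant_up", "concordant_down", "contra") or (
            cls == "species_specific" and i in human_only
        ):
            s = mouse_sign[i] if cls != "contra" else -mouse_sign[i]
            human_direction[human_ids[i]] = "up" if s > 0 else "down"

    # ---- orthology: signal pairs one2one; variation among nulls --------
    null_idx = sorted(np.flatnonzero(pair_class == "null"))
    n_null = len(null_idx)
    n_unmapped = int(round(config.unmapped_frac * n_null)) if make_orthology else 0
    n_o2m = int(round(config.one2many_frac * n_null)) if make_orthology else 0
    shuffled = list(rng.permutation(null_idx))
    unmapped = set(shuffled[:n_unmapped])
    one2many = set(shuffled[n_unmapped : n_unmapped + n_o2m])
    pair_rows = []
    extra_id = 0
    for i in range(n_pairs):
        if i in unmapped:
            continue
        if i in one2many:
            extra = f"hsa_{config.tissue[:1]}x{extra_id:04d}"
            extra_id += 1
            biotypes[extra] = bt_draw[i]
            pair_rows.append((mouse_ids[i], human_ids[i], "one2many"))
            pair_rows.append((mouse_ids[i], extra, "one2many"))
        else:
            pair_rows.append((mouse_ids[i], human_ids[i], "one2one"))
    orth = OrthologyMap(
        pairs=pd.DataFrame(
            pair_rows, columns=["mouse_gene_id", "human_gene_id", "relation"]
        )
    )
    truth = PlantedTruth(
        tissue=config.tissue,
        classes=classes,
        mouse_direction=mouse_direction,
        human_direction=human_direction,
        human_inconsistent=human_inconsistent,
        orthology=orth,
        biotypes=biotypes,
        mu=config.mu,
        sigma=config.sigma,
    )
    return tables, truth


# ---------------------------------------------------------------------------
# miRNA (small-RNA) tables


@dataclass
class SynthMirnaConfig:
    """Small-RNA class sizes: one mouse dataset, exactly two human datasets.

    Human miRNAs need significance in only one of the two datasets, so the
    human firing count per signal miRNA is 1 or 2 at random.  ``n_borderline``
    miRNAs are planted just past the primary cutoff (padj in (0.05, 0.1) in
    both species) and surface only under the relaxed threshold.
    """

    n_concordant_up: int = 9
    n_concordant_down: int = 12
    n_contra: int = 4
    n_borderline: int = 3
    n_null: int = 50
    mu: float = 2.0
    sigma: float = 0.1
    tissue: str = "colon"


def synth_mirna_de(config: SynthMirnaConfig, seed: int) -> tuple[list[DETable], PlantedTruth]:
    """Generate one mouse + two human small-RNA DE tables for one tissue."""
    rng = np.random.default_rng(seed)
    sizes = {
        "concordant_up": config.n_concordant_up,
        "concordant_down": config.n_concordant_down,
        "contra": config.n_contra,
        "borderline": config.n_borderline,
        "null": config.n_null,
    }
    n = sum(sizes.values())
    mouse_ids = [f"mmu-mir-{i:04d}" for i in range(n)]
    human_ids = [f"hsa-mir-{i:04d}" for i in range(n)]
    perm = rng.permutation(n)
    cls_of = np.empty(n, dtype=object)
    classes: dict[str, list[tuple[str, str]]] = {}
    cursor = 0
    for cls, size in sizes.items():
        idx = perm[cursor : cursor + size]
        cursor += size
        cls_of[idx] = cls
        classes[cls] = [(mouse_ids[i], human_ids[i]) for i in sorted(idx)]

    sign = np.zeros(n)
    for i in range(n):
        if cls_of[i] == "concordant_up":
            sign[i] = 1
        elif cls_of[i] in ("concordant_down", "borderline"):
            sign[i] = -1
        elif cls_of[i] == "contra":
            sign[i] = rng.choice([-1.0, 1.0])

    def borderline_stats(s):
        return rng.normal(s * config.mu, config.sigma), rng.uniform(0.055, 0.095)

    mouse_rows = []
    mouse_direction = {}
    for i in range(n):
        cls = cls_of[i]
        if cls in ("concordant_up", "concordant_down", "contra"):
            lfc, padj = _signal_stats(rng, sign[i], config.mu, config.sigma)
            mouse_direction[mouse_ids[i]] = "up" if sign[i] > 0 else "down"
        elif cls == "borderline":
            lfc, padj = borderline_stats(sign[i])
        else:
            lfc, padj = _null_stats(rng, config.sigma)
        mouse_rows.append((mouse_ids[i], "mirna", float(rng.lognormal(4, 1)), lfc, padj * rng.uniform(0.5, 1.0), padj))
    tables = [
        DETable(
            dataset_id=f"mouse_{config.tissue}_mirna",
            species="mouse",
            tissue=config.tissue,
            assay="small_rna",
            records=pd.DataFrame(
                mouse_rows, columns=["gene_id", "biotype", "base_mean", "log2fc", "pvalue", "padj"]
            ),
        )
    ]

    human_direction = {}
    fire_count = rng.integers(1, 3, size=n)  # 1 or 2 of the two datasets
    fire_first = rng.integers(0, 2, size=n)
    for j in range(2):
        rows = []
        for i in range(n):
            cls = cls_of[i]
            h_sign = -sign[i] if cls == "contra" else sign[i]
            firing = cls in ("concordant_up", "concordant_down", "contra") and (
                fire_count[i] == 2 or fire_first[i] == j
            )
            if firing:
                lfc, padj = _signal_stats(rng, h_sign, config.mu, config.sigma)
            elif cls == "borderline" and fire_first[i] == j:
                lfc, padj = borderline_stats(h_sign)
            else:
                lfc, padj = _null_stats(rng, config.sigma)
            rows.append((human_ids[i], "mirna", float(rng.lognormal(4, 1)), lfc, padj * rng.uniform(0.5, 1.0), padj))
        tables.append(
            DETable(
                dataset_id=f"human_{config.tissue}_mirna_{j + 1}",
                species="human",
                tissue=config.tissue,
                assay="small_rna",
                records=pd.DataFrame(
                    rows, columns=["gene_id", "biotype", "base_mean", "log2fc", "pvalue", "padj"]
                ),
            )
        )
        for i in range(n):
            cls = cls_of[i]
            if cls in ("concordant_up", "concordant_down", "contra"):
                h_sign = -sign[i] if cls == "contra" else sign[i]
                human_direction[human_ids[i]] = "up" if h_sign > 0 else "down"

    orth = OrthologyMap(
        pairs=pd.DataFrame(
            [(m, h, "one2one") for m, h in zip(mouse_ids, human_ids)],
            columns=["mouse_gene_id", "human_gene_id", "relation"],
        )
    )
    truth = PlantedTruth(
        tissue=config.tissue,
        classes=classes,
        mouse_direction=mouse_direction,
        human_direction=human_direction,
        human_inconsistent=set(),
        orthology=orth,
        biotypes={g: "mirna" for g in mouse_ids + human_ids},
        mu=config.mu,
        sigma=config.sigma,
    )
    return tables, truth


# ---------------------------------------------------------------------------
# gene loci


def synth_loci(
    n_genes: int,
    chrom_length: int = 10_000_000,
    seed: int = 0,
    n_chroms: int = 3,
    window_bp: int = 100_000,
    biotype_props: dict | None = None,
    expressed_prob: float = 0.8,
) -> tuple[list[GeneLocus], dict[str, set[str]]]:
    """Place genes uniformly on synthetic chromosomes.

    lncRNAs are interleaved with PCGs, and each lncRNA's true set of
    expressed PCG neighbors within ``window_bp`` is computed here by a
    brute-force double loop, independent of the annotation module, so the
    two can be checked against each other.
    """
    props = biotype_props or {"pcg": 0.6, "lncrna": 0.25, "other": 0.15}
    rng = np.random.default_rng(seed)
    loci = []
    for i in range(n_genes):
        length = int(rng.integers(500, 20_000))
        start = int(rng.integers(1, max(2, chrom_length - length)))
        loci.append(
            GeneLocus(
                gene_id=f"g{i:05d}",
                chrom=f"chr{int(rng.integers(1, n_chroms + 1))}",
                start=start,
                end=start + length - 1,
                strand=str(rng.choice(["+", "-"])),
                biotype=str(rng.choice(list(props), p=[props[b] for b in props])),
                expressed=bool(rng.random() < expressed_prob),
            )
        )
    truth: dict[str, set[str]] = {}
    for l in loci:
        if l.biotype != "lncrna":
            continue
        hits = set()
        for p in loci:
            if p.biotype != "pcg" or not p.expressed or p.gene_id == l.gene_id:
                continue
            if p.chrom != l.chrom:
                continue
            if p.start <= l.end + window_bp and p.end >= l.start - window_bp:
                hits.add(p.gene_id)
        truth[l.gene_id] = hits
    return loci, truth


def synth_risk_loci(n_loci: int, chrom_length: int = 10_000_000, seed: int = 0, n_chroms: int = 3) -> list[GeneLocus]:
    """Point risk loci (single-base intervals) scattered uniformly."""
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n_loci):
        pos = int(rng.integers(1, chrom_length))
        out.append(
            GeneLocus(
                gene_id=f"risk_{i:03d}",
                chrom=f"chr{int(rng.integers(1, n_chroms + 1))}",
                start=pos,
                end=pos,
            )
        )
    return out


# ---------------------------------------------------------------------------
# interaction network


def synth_network(
    core_genes,
    n_noise_nodes: int = 30,
    hub_ids=("HUB1",),
    seed: int = 0,
    hub_coverage: float = 0.9,
    noise_edge_prob: float = 0.05,
) -> nx.Graph:
    """Star-plus-noise topology with planted hubs.

    Each hub connects to ``hub_coverage`` of the core genes at confidence
    0.9; noise nodes and core genes are additionally wired Erdos-Renyi at
    confidence U(0.41, 0.6), so hubs dominate every centrality measure.
    """
    core = list(core_genes)
    hubs = list(hub_ids)
    rng = np.random.default_rng(seed)
    g = nx.Graph()
    g.add_nodes_from(hubs + core + [f"noise_{i:03d}" for i in range(n_noise_nodes)])
    n_connect = max(1, math.ceil(hub_coverage * len(core))) if core else 0
    for h in hubs:
        targets = rng.choice(core, size=n_connect, replace=False) if core else []
        for t in targets:
            g.add_edge(h, str(t), confidence=0.9)
    non_hubs = [v for v in g.nodes if v not in hubs]
    for i, a in enumerate(non_hubs):
        for b in non_hubs[i + 1 :]:
            if rng.random() < noise_edge_prob:
                g.add_edge(a, b, confidence=float(rng.uniform(0.41, 0.6)))
    return validate_network(g)


# ---------------------------------------------------------------------------
# qPCR Ct tables


def synth_ct(
    planted_fc: dict[str, float],
    reference_genes=("GUSB", "B2M", "ACTB", "TBP"),
    n_case: int = 5,
    n_control: int = 5,
    replicates: int = 3,
    noise_sd: float = 0.0,
    seed: int = 0,
    tissue: str = "colon",
    sample_offset_sd: float = 0.0,
) -> CtTable:
    """Ct table encoding known fold changes.

    Case samples measure the target at ``Ct(control) - log2(fc)``; reference
    genes sit at a fixed level in both groups.  Gaussian noise with
    ``noise_sd`` is added per replicate measurement, and an optional
    per-sample offset (shared by all genes of that sample) exercises the
    reference normalization, which must cancel it exactly.
    """
    rng = np.random.default_rng(seed)
    base_target = 26.0
    base_ref = 20.0
    rows = []
    samples = [("case", f"case_{i + 1}") for i in range(n_case)] + [
        ("control", f"control_{i + 1}") for i in range(n_control)
    ]
    for group, sample in samples:
        offset = rng.normal(0.0, sample_offset_sd) if sample_offset_sd > 0 else 0.0
        for gene, fc in planted_fc.items():
            if fc <= 0:
                raise ConfigError(f"planted fold change for {gene!r} must be > 0")
            level = base_target - (math.log2(fc) if group == "case" else 0.0)
            for _ in range(replicates):
                noise = rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0
                rows.append((sample, group, tissue, gene, level + offset + noise))
        for ref in reference_genes:
            for _ in range(replicates):
                noise = rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0
                rows.append((sample, group, tissue, ref, base_ref + offset + noise))
    return CtTable(
        rows=pd.DataFrame(
            rows, columns=["sample_id", "group", "tissue", "gene_id", "ct"]
        )
    )


# ---------------------------------------------------------------------------
# orthology, target maps, gene sets


def synth_orthology(
    n_pairs: int,
    one2many_frac: float = 0.1,
    unmapped_frac: float = 0.1,
    seed: int = 0,
) -> OrthologyMap:
    """Standalone orthology map with controlled relation fractions."""
    rng = np.random.default_rng(seed)
    rows = []
    perm = rng.permutation(n_pairs)
    n_un = int(round(unmapped_frac * n_pairs))
    n_o2m = int(round(one2many_frac * n_pairs))
    o2m = set(perm[n_un : n_un + n_o2m])
    unmapped = set(perm[:n_un])
    extra = 0
    for i in range(n_pairs):
        if i in unmapped:
            continue
        if i in o2m:
            rows.append((f"mmu_{i:05d}", f"hsa_{i:05d}", "one2many"))
            rows.append((f"mmu_{i:05d}", f"hsa_x{extra:04d}", "one2many"))
            extra += 1
        else:
            rows.append((f"mmu_{i:05d}", f"hsa_{i:05d}", "one2one"))
    return OrthologyMap(
        pairs=pd.DataFrame(rows, columns=["mouse_gene_id", "human_gene_id", "relation"])
    )


def synth_target_map(
    mirna_ids,
    universe,
    targets_per_mirna: int = 20,
    uncovered_frac: float = 0.2,
    seed: int = 0,
) -> tuple[dict[str, set[str]], set[str]]:
    """miRNA->target map over a gene universe; a fraction stay uncovered.

    Returns the map and the set of covered miRNA ids (the truth for the
    "m out of n with targets" coverage statistic).
    """
    rng = np.random.default_rng(seed)
    mirnas = list(mirna_ids)
    uni = np.asarray(sorted(set(universe)))
    n_uncovered = int(round(uncovered_frac * len(mirnas)))
    uncovered = set(rng.choice(mirnas, size=n_uncovered, replace=False)) if n_uncovered else set()
    out = {}
    for m in mirnas:
        if m in uncovered:
            continue
        k = min(targets_per_mirna, len(uni))
        out[m] = set(rng.choice(uni, size=k, replace=False))
    return out, set(mirnas) - uncovered


def synth_genesets(
    universe,
    enriched_genes,
    n_terms: int = 20,
    term_size: int = 30,
    seed: int = 0,
    enriched_term_id: str = "TERM_PLANTED",
) -> GeneSetCollection:
    """Random term collection plus one term enriched for ``enriched_genes``.

    The planted term contains every enriched gene plus random padding to
    ``term_size``; the other terms are uniform draws from the universe.
    """
    rng = np.random.default_rng(seed)
    uni = np.asarray(sorted(set(universe)))
    enriched = sorted(set(enriched_genes))
    sets = {}
    for t in range(n_terms):
        members = set(rng.choice(uni, size=min(term_size, len(uni)), replace=False))
        sets[f"TERM_{t:03d}"] = (f"random term {t}", members)
    pad = [g for g in uni if g not in set(enriched)]
    n_pad = max(0, term_size - len(enriched))
    planted = set(enriched) | set(rng.choice(pad, size=min(n_pad, len(pad)), replace=False))
    sets[enriched_term_id] = ("planted enriched term", planted)
    return GeneSetCollection(sets=sets)


# ---------------------------------------------------------------------------
# full input bundle


@dataclass
class BundleConfig:
    """Study-shaped defaults for a complete synthetic input bundle.

    One mouse dataset per tissue; four human colon and three human blood
    total-RNA datasets; two human colon small-RNA datasets; four reference
    genes for qPCR.
    """

    colon: SynthDEConfig = field(default_factory=lambda: SynthDEConfig(tissue="colon", n_human_datasets=4))
    blood: SynthDEConfig = field(
        default_factory=lambda: SynthDEConfig(
            tissue="blood",
            n_human_datasets=3,
            n_concordant_up=20,
            n_concordant_down=10,
            n_contra=5,
            n_inconsistent=5,
            n_species_specific=10,
            n_null=300,
        )
    )
    mirna: SynthMirnaConfig = field(default_factory=SynthMirnaConfig)
    n_core_planted: int = 10
    n_risk_loci: int = 10
    n_noise_nodes: int = 30
    n_hubs: int = 2
    qpcr_noise_sd: float = 0.0
    qpcr_replicates: int = 3


@dataclass
class SynthBundle:
    """Every pipeline input plus the planted truth, in memory."""

    colon_tables: list[DETable]
    blood_tables: list[DETable]
    mirna_tables: list[DETable]
    colon_truth: PlantedTruth
    blood_truth: PlantedTruth
    mirna_truth: PlantedTruth
    orthology: OrthologyMap
    loci: list[GeneLocus]
    neighbor_truth: dict[str, set[str]]
    risk_loci: list[GeneLocus]
    target_map: dict[str, set[str]]
    covered_mirnas: set[str]
    genesets: GeneSetCollection
    network: nx.Graph
    hub_ids: list[str]
    ct_table: CtTable
    planted_fc: dict[str, float]

    def expected_core(self) -> set[str]:
        """Mouse genes planted concordant in both tissues (the core truth).

        Colon and blood share one genome-wide universe; the bundle forces
        ``n_core_planted`` colon-concordant genes into the blood concordant
        class, and chance overlaps of the remaining assignments add to the
        set.  Both are captured here, directly from the planted classes.
        """
        colon = {m for c in ("concordant_up", "concordant_down") for m, _ in self.colon_truth.classes[c]}
        blood = {m for c in ("concordant_up", "concordant_down") for m, _ in self.blood_truth.classes[c]}
        return colon & blood


def synth_bundle(config: BundleConfig | None = None, seed: int = 0) -> SynthBundle:
    """Generate a complete, internally consistent input bundle.

    Sub-generators get independent child seeds from one SeedSequence, so
    the bundle is deterministic in ``seed`` and any one part can be
    regenerated in isolation.
    """
    config = config or BundleConfig()
    ss = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(10)]

    # one genome-wide universe per species, shared by both tissues (blood
    # measures a prefix subset of it)
    n_colon = sum(config.colon.class_sizes().values())
    n_blood = sum(config.blood.class_sizes().values())
    if n_blood > n_colon:
        raise ConfigError("blood universe may not exceed the colon universe")
    mouse_ids = [f"mmu_g{i:05d}" for i in range(n_colon)]
    human_ids = [f"hsa_g{i:05d}" for i in range(n_colon)]

    colon_tables, colon_truth = synth_de(
        config.colon, seeds[0], mouse_ids=mouse_ids, human_ids=human_ids
    )
    # plant the cross-tissue core: force colon-concordant genes measured in
    # blood into blood's concordant classes (direction preserved)
    idx_of = {m: i for i, m in enumerate(mouse_ids)}
    forced: dict[str, list[int]] = {"concordant_up": [], "concordant_down": []}
    for cls in ("concordant_up", "concordant_down"):
        for m, _ in colon_truth.classes[cls]:
            i = idx_of[m]
            if i < n_blood and len(forced[cls]) < max(
                1, config.n_core_planted // 2
            ) and len(forced[cls]) < config.blood.class_sizes()[cls]:
                forced[cls].append(i)
    blood_tables, blood_truth = synth_de(
        config.blood,
        seeds[1],
        mouse_ids=mouse_ids[:n_blood],
        human_ids=human_ids[:n_blood],
        forced_classes=forced,
        make_orthology=False,
    )
    mirna_tables, mirna_truth = synth_mirna_de(config.mirna, seeds[2])
    # one orthology map for the whole universe: genes carrying signal in
    # EITHER tissue stay one2one so recovery is exact; one2many/unmapped
    # variation is confined to genes that are null in both tissues
    signal_mouse = {
        m
        for truth in (colon_truth, blood_truth)
        for cls, pairs in truth.classes.items()
        if cls != "null"
        for m, _ in pairs
    }
    orng = np.random.default_rng(seeds[9])
    null_ids = [m for m in mouse_ids if m not in signal_mouse]
    n_un = int(round(config.colon.unmapped_frac * len(null_ids)))
    n_o2m = int(round(config.colon.one2many_frac * len(null_ids)))
    shuffled = list(orng.permutation(null_ids))
    unmapped = set(shuffled[:n_un])
    o2m = set(shuffled[n_un : n_un + n_o2m])
    rows = []
    extra = 0
    for m, h in zip(mouse_ids, human_ids):
        if m in unmapped:
            continue
        if m in o2m:
            rows.append((m, h, "one2many"))
            rows.append((m, f"hsa_gx{extra:04d}", "one2many"))
            extra += 1
        else:
            rows.append((m, h, "one2one"))
    orthology = OrthologyMap(
        pairs=pd.concat(
            [
                pd.DataFrame(rows, columns=["mouse_gene_id", "human_gene_id", "relation"]),
                mirna_truth.orthology.pairs,
            ],
            ignore_index=True,
        )
    )

    mouse_colon = colon_tables[0]
    expressed = list(mouse_colon.records["gene_id"])
    n_loci = len(expressed)
    loci_raw, _ = synth_loci(n_loci, seed=seeds[3])
    # reuse the mouse colon universe as locus ids so annotations line up
    biotype_of = dict(zip(mouse_colon.records["gene_id"], mouse_colon.records["biotype"]))
    loci = [
        GeneLocus(
            gene_id=g,
            chrom=l.chrom,
            start=l.start,
            end=l.end,
            strand=l.strand,
            biotype=biotype_of.get(g, "other"),
            expressed=True,
        )
        for g, l in zip(expressed, loci_raw)
    ]
    neighbor_truth = {}
    for l in loci:
        if l.biotype != "lncrna":
            continue
        hits = set()
        for p in loci:
            if p.biotype != "pcg" or p.gene_id == l.gene_id or p.chrom != l.chrom:
                continue
            if p.start <= l.end + 100_000 and p.end >= l.start - 100_000:
                hits.add(p.gene_id)
        neighbor_truth[l.gene_id] = hits
    risk_loci = synth_risk_loci(config.n_risk_loci, seed=seeds[4])

    mirna_mouse = [m for m, _ in sum(mirna_truth.classes.values(), [])]
    target_map, covered = synth_target_map(mirna_mouse, expressed, seed=seeds[5])

    core_mouse = sorted(
        m for c in ("concordant_up", "concordant_down") for m, _ in colon_truth.classes[c]
    )
    hub_ids = [f"HUB{i + 1}" for i in range(config.n_hubs)]
    network = synth_network(core_mouse, config.n_noise_nodes, hub_ids, seed=seeds[6])
    genesets = synth_genesets(expressed, core_mouse[:20], seed=seeds[8])

    up_pairs = colon_truth.classes["concordant_up"]
    planted_fc = {m: 4.0 for m, _ in up_pairs[:4]}
    planted_fc.update({m: 0.25 for m, _ in colon_truth.classes["concordant_down"][:2]})
    ct_table = synth_ct(
        planted_fc,
        noise_sd=config.qpcr_noise_sd,
        replicates=config.qpcr_replicates,
        seed=seeds[7],
    )
    return SynthBundle(
        colon_tables=colon_tables,
        blood_tables=blood_tables,
        mirna_tables=mirna_tables,
        colon_truth=colon_truth,
        blood_truth=blood_truth,
        mirna_truth=mirna_truth,
        orthology=orthology,
        loci=loci,
        neighbor_truth=neighbor_truth,
        risk_loci=risk_loci,
        target_map=target_map,
        covered_mirnas=covered,
        genesets=genesets,
        network=network,
        hub_ids=hub_ids,
        ct_table=ct_table,
        planted_fc=planted_fc,
    )


def write_bundle(bundle: SynthBundle, outdir, config: BundleConfig | None = None) -> None:
    """Write a bundle to disk as the pipeline's input file formats."""
    from . import io as uio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for t in bundle.colon_tables + bundle.blood_tables + bundle.mirna_tables:
        uio.write_de_table(t, outdir / f"de_{t.dataset_id}.tsv")
    uio.write_orthology(bundle.orthology, outdir / "orthology.tsv")
    uio.write_gtf_loci(bundle.loci, outdir / "loci.gtf")
    with open(outdir / "risk_loci.bed", "w", encoding="utf-8") as fh:
        for l in bundle.risk_loci:
            fh.write(f"{l.chrom}\t{l.start - 1}\t{l.end}\t{l.gene_id}\n")
    uio.write_target_map(bundle.target_map, outdir / "targets.tsv")
    uio.write_gmt(bundle.genesets, outdir / "genesets.gmt")
    uio.write_string_edges(bundle.network, outdir / "string_edges.tsv")
    uio.write_ct_csv(bundle.ct_table, outdir / "ct.csv")
    truth = {
        "colon_classes": {c: v for c, v in bundle.colon_truth.classes.items()},
        "blood_classes": {c: v for c, v in bundle.blood_truth.classes.items()},
        "mirna_classes": {c: v for c, v in bundle.mirna_truth.classes.items()},
        "hub_ids": bundle.hub_ids,
        "planted_fc": bundle.planted_fc,
        "covered_mirnas": sorted(bundle.covered_mirnas),
        "neighbor_truth": {k: sorted(v) for k, v in bundle.neighbor_truth.items()},
    }
    with open(outdir / "truth.json", "w", encoding="utf-8") as fh:
        json.dump(truth, fh, indent=1)
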