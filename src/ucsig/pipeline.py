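"""End-to-end orchestration: inputs -> SDE -> combine -> cross-species ->
context -> enrichment -> centrality ranking -> qPCR -> report.

The run is configured by a single :class:`RunConfig` (loadable from YAML),
is deterministic given config + seed, writes every intermediate table to
the output directory, and produces a summary report whose tallies satisfy
the arithmetic identities of the study's table shapes (per-tissue
total common = up-up + down-down + contra; same-direction = up-up +
down-down; per-biotype counts sum to the grand total).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import io as uio
from ._errors import ConfigError, UcsigError
from .combine import combine_datasets, combine_mirna
from .context import build_target_sets, lncrna_neighbors, risk_locus_proximity
from .cross_species import (
    core_set,
    overlap_species,
    relaxed_mirna_overlap,
    tally_concordance,
)
from .enrichment import enrich
from .network_rank import rank_genes
from .qpcr import ddct_fold_change
from .sde import call_sde, tally_by_biotype
from .synth import BundleConfig, SynthBundle, synth_bundle, write_bundle
from .types import DETable, SDESet

logger = logging.getLogger(__name__)

_THRESHOLD_RANGES = {
    "padj_max": (0.0, 1.0),
    "lfc_min_total": (0.0, 20.0),
    "fc_min_mirna": (1.0, 100.0),
    "min_support": (1, 100),
    "relaxed_padj": (0.0, 1.0),
    "window_bp": (0, 10**9),
    "string_min_confidence": (0.0, 1.0),
}


@dataclass
class RunConfig:
    """Validated settings for a full pipeline run.

    ``input_dir`` may point at a bundle directory written by the synthetic
    generator (or files in the same layout); when None, a bundle is
    generated in memory from ``seed``.  Unknown keys in a YAML config are
    rejected rather than silently ignored.
    """

    seed: int = 0
    input_dir: str | None = None
    output_dir: str = "ucsig_run"
    padj_max: float = 0.05
    lfc_min_total: float = 1.0
    fc_min_mirna: float = 1.5
    min_support: int = 2
    relaxed_padj: float = 0.1
    window_bp: int = 100_000
    string_min_confidence: float = 0.4
    centrality_weights: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)
    reference_genes: tuple[str, ...] = ("GUSB", "B2M", "ACTB", "TBP")

    def __post_init__(self) -> None:
        for key, (lo, hi) in _THRESHOLD_RANGES.items():
            v = getattr(self, key)
            if not (lo <= v <= hi):
                raise ConfigError(f"{key}={v} outside [{lo}, {hi}]")
        if len(self.centrality_weights) != 3 or sum(self.centrality_weights) <= 0:
            raise ConfigError("centrality_weights must be 3 values with positive sum")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        for tup_key in ("centrality_weights", "reference_genes"):
            if tup_key in raw and isinstance(raw[tup_key], list):
                raw[tup_key] = tuple(raw[tup_key])
        return cls(**raw)

    def digest(self) -> str:
        # where the outputs land does not change what is computed
        payload = {k: v for k, v in asdict(self).items() if k != "output_dir"}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


@dataclass
class RunReport:
    """Structured results of one pipeline run."""

    config_hash: str
    seed: int
    mouse_tallies: dict  # tissue -> biotype tally frame (as dict)
    human_combined: dict  # tissue -> {n_up, n_down, n_inconsistent}
    concordance: dict  # tissue -> tally dict
    core_n: int
    core_members: list
    mirna_common: dict
    neighbors_n: dict
    risk_flagged: dict
    target_coverage: dict
    top_enriched: list
    top_ranked: list
    qpcr: dict

    def summary_text(self) -> str:
        lines = [
            "ucsig run report",
            f"config {self.config_hash}  seed {self.seed}",
            "",
            "[mouse SDE by biotype]",
        ]
        for tissue, tal in sorted(self.mouse_tallies.items()):
            for bt, row in tal.items():
                lines.append(
                    f"  {tissue:6s} {bt:7s} total {row['total']:5d} "
                    f"(up {row['n_up']}, down {row['n_down']})"
                )
        lines.append("")
        lines.append("[human combined sets]")
        for tissue, d in sorted(self.human_combined.items()):
            lines.append(
                f"  {tissue:6s} up {d['n_up']} down {d['n_down']} "
                f"inconsistent {d['n_inconsistent']}"
            )
        lines.append("")
        lines.append("[cross-species concordance]")
        for tissue, t in sorted(self.concordance.items()):
            lines.append(
                f"  {tissue:6s} common {t['n_total_common']} "
                f"(up-up {t['n_up_up']}, down-down {t['n_down_down']}, "
                f"contra {t['n_contra']}); same-direction {t['n_same_direction']}"
            )
        lines.append("")
        lines.append(f"[core set] {self.core_n} genes concordant in both tissues")
        lines.append(
            f"[miRNA] common {self.mirna_common.get('n_total_common', 0)} "
            f"(relaxed {self.mirna_common.get('n_relaxed', 0)})"
        )
        lines.append(
            "[context] lncRNA neighbor sets: "
            + ", ".join(f"{k}={v}" for k, v in sorted(self.neighbors_n.items()))
        )
        lines.append(
            "[risk loci] flagged: "
            + ", ".join(f"{k}={v}" for k, v in sorted(self.risk_flagged.items()))
        )
        lines.append(
            f"[targets] {self.target_coverage.get('covered', 0)} of "
            f"{self.target_coverage.get('n_input', 0)} miRNAs with expressed targets"
        )
        lines.append("[enrichment] top terms: " + ", ".join(self.top_enriched[:5]))
        lines.append("[ranking] top nodes: " + ", ".join(self.top_ranked[:5]))
        lines.append("[qPCR] " + ", ".join(f"{g}={fc:.3g}" for g, fc in sorted(self.qpcr.items())))
        return "\n".join(lines) + "\n"


def _read_bundle_dir(path: Path) -> SynthBundle:
    """Load a bundle directory written by :func:`ucsig.synth.write_bundle`."""
    from .types import GeneLocus

    def meta_of(tsv: Path) -> dict:
        with open(tsv, encoding="utf-8") as fh:
            header = fh.readline()
        if not header.startswith("#"):
            raise UcsigError(f"{tsv}: missing metadata header line")
        return dict(kv.split("=", 1) for kv in header[1:].split())

    colon, blood, mirna = [], [], []
    for tsv in sorted(path.glob("de_*.tsv")):
        meta = meta_of(tsv)
        table = uio.read_de_table(tsv, meta)
        if table.assay == "small_rna":
            mirna.append(table)
        elif table.tissue == "colon":
            colon.append(table)
        else:
            blood.append(table)
    loci = uio.read_gtf_loci(path / "loci.gtf", expressed_ids=None)
    loci = [
        GeneLocus(**{**l.__dict__, "expressed": True}) for l in loci
    ]
    target_map = uio.read_target_map(path / "targets.tsv")
    with open(path / "truth.json", encoding="utf-8") as fh:
        truth = json.load(fh)
    return SynthBundle(
        colon_tables=colon,
        blood_tables=blood,
        mirna_tables=mirna,
        colon_truth=None,
        blood_truth=None,
        mirna_truth=None,
        orthology=uio.read_orthology(path / "orthology.tsv"),
        loci=loci,
        neighbor_truth={k: set(v) for k, v in truth.get("neighbor_truth", {}).items()},
        risk_loci=uio.read_bed_loci(path / "risk_loci.bed"),
        target_map=target_map,
        covered_mirnas=set(truth.get("covered_mirnas", [])),
        genesets=uio.read_gmt(path / "genesets.gmt"),
        network=uio.read_string_edges(path / "string_edges.tsv", min_confidence=0.0),
        hub_ids=list(truth.get("hub_ids", [])),
        ct_table=uio.read_ct_csv(path / "ct.csv"),
        planted_fc={k: float(v) for k, v in truth.get("planted_fc", {}).items()},
    )


def _significance_only_set(table: DETable, padj_max: float) -> SDESet:
    """Direction-labelled set by significance alone (no fold-change floor)."""
    return call_sde(table, padj_max=padj_max, lfc_min_total=0.0, fc_min_mirna=1.0)


def run_pipeline(
    config: RunConfig,
    bundle: SynthBundle | None = None,
    bundle_config: BundleConfig | None = None,
) -> RunReport:
    """Execute the full analysis and write intermediates + report.

    A stage failure aborts with the stage name in the error message and a
    ``FAILED`` marker file left next to whatever partial outputs exist.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    stage = "inputs"
    try:
        if bundle is None:
            if config.input_dir:
                bundle = _read_bundle_dir(Path(config.input_dir))
            else:
                bundle = synth_bundle(bundle_config, seed=config.seed)

        # ---- per-dataset SDE calling + biotype tallies -------------------
        stage = "sde"
        mouse_tallies = {}
        mouse_sig_sets = {}
        for tissue, tables in (("colon", bundle.colon_tables), ("blood", bundle.blood_tables)):
            mouse_table = next(t for t in tables if t.species == "mouse")
            sde = call_sde(
                mouse_table,
                padj_max=config.padj_max,
                lfc_min_total=config.lfc_min_total,
                fc_min_mirna=config.fc_min_mirna,
            )
            tal = tally_by_biotype(sde, mouse_table)
            mouse_tallies[tissue] = tal.to_dict(orient="index")
            uio.write_tsv(tal.reset_index(), outdir / f"mouse_sde_tally_{tissue}.tsv",
                          {"padj_max": config.padj_max, "lfc_min_total": config.lfc_min_total})
            mouse_sig_sets[tissue] = _significance_only_set(mouse_table, config.padj_max)
            logger.info("stage sde %s: %d mouse SDE genes", tissue, len(sde))

        # ---- human multi-dataset combination -----------------------------
        stage = "combine"
        human_combined = {}
        combined_sets = {}
        for tissue, tables in (("colon", bundle.colon_tables), ("blood", bundle.blood_tables)):
            humans = [t for t in tables if t.species == "human"]
            if len(humans) >= config.min_support:
                comb = combine_datasets(
                    humans, padj_max=config.padj_max, min_support=config.min_support
                )
            else:
                # support demanded exceeds the datasets available: nothing
                # can qualify, so the combined set is empty by definition
                comb = SDESet(
                    species="human", tissue=tissue, source="combined", entries={},
                    thresholds={"padj_max": config.padj_max, "min_support": config.min_support},
                    evidence=pd.DataFrame(columns=["gene_id", "call", "support", "directions"]),
                )
            combined_sets[tissue] = comb
            human_combined[tissue] = {
                "n_up": len(comb.up),
                "n_down": len(comb.down),
                "n_inconsistent": len(comb.inconsistent),
            }
            if comb.evidence is not None:
                uio.write_tsv(comb.evidence, outdir / f"human_combined_{tissue}.tsv",
                              {"padj_max": config.padj_max, "min_support": config.min_support})
            logger.info("stage combine %s: %d entries, %d inconsistent",
                        tissue, len(comb), len(comb.inconsistent))

        # ---- cross-species ortholog overlap ------------------------------
        stage = "overlap"
        concordance = {}
        ctables = {}
        for tissue in ("colon", "blood"):
            ct = overlap_species(mouse_sig_sets[tissue], combined_sets[tissue], bundle.orthology)
            ctables[tissue] = ct
            concordance[tissue] = tally_concordance(ct)
            uio.write_tsv(ct.rows, outdir / f"concordance_pairs_{tissue}.tsv")
            uio.write_tsv(ct.gene_classes, outdir / f"concordance_genes_{tissue}.tsv")

        stage = "core_set"
        core = core_set(ctables["colon"], ctables["blood"])
        uio.write_tsv(core.members, outdir / "core_set.tsv")

        # ---- miRNA cross-species ----------------------------------------
        stage = "mirna"
        mirna_common = {}
        if bundle.mirna_tables:
            m_mouse = next(t for t in bundle.mirna_tables if t.species == "mouse")
            m_humans = [t for t in bundle.mirna_tables if t.species == "human"]
            mouse_mirna_sde = _significance_only_set(m_mouse, config.padj_max)
            human_mirna = combine_mirna(m_humans, padj_max=config.padj_max)
            ct_mirna = overlap_species(mouse_mirna_sde, human_mirna, bundle.orthology)
            mirna_common = tally_concordance(ct_mirna)
            relaxed = relaxed_mirna_overlap(m_mouse, m_humans, bundle.orthology,
                                            padj_max=config.relaxed_padj)
            mirna_common["n_relaxed"] = tally_concordance(relaxed)["n_total_common"]
            uio.write_tsv(ct_mirna.rows, outdir / "mirna_concordance.tsv")

        # ---- genomic context ---------------------------------------------
        stage = "context"
        colon_mouse = next(t for t in bundle.colon_tables if t.species == "mouse")
        sde_colon = call_sde(colon_mouse, padj_max=config.padj_max,
                             lfc_min_total=config.lfc_min_total)
        bt = dict(zip(colon_mouse.records["gene_id"], colon_mouse.records["biotype"]))
        locus_ids = {l.gene_id for l in bundle.loci}
        sde_lnc = sorted(g for g in sde_colon.entries if bt.get(g) == "lncrna" and g in locus_ids)
        nb = lncrna_neighbors(sde_lnc, bundle.loci, window_bp=config.window_bp)
        neighbors_n = {k: len(v) for k, v in nb.neighbors.items()}
        sde_in_loci = sorted(set(sde_colon.entries) & locus_ids)
        flagged = risk_locus_proximity(sde_in_loci, bundle.loci, bundle.risk_loci,
                                       window_bp=config.window_bp)
        risk_flagged = {"colon": len(flagged)}
        mirna_sde_ids = sorted(bundle.target_map)
        expressed = sorted(locus_ids)
        ts = build_target_sets(mirna_sde_ids, bundle.target_map, expressed)
        target_coverage = {"covered": ts.n_mirnas_with_targets, "n_input": ts.n_input}

        # ---- enrichment ----------------------------------------------------
        stage = "enrichment"
        common_mouse = sorted(ctables["colon"].gene_classes["mouse_gene_id"]) if len(
            ctables["colon"].gene_classes
        ) else []
        universe = sorted(colon_mouse.records["gene_id"])
        enr = enrich(common_mouse, universe, bundle.genesets)
        uio.write_tsv(enr.table.drop(columns=["hits"]), outdir / "enrichment.tsv")
        top_enriched = list(enr.table.head(10)["term_id"])

        # ---- network ranking ----------------------------------------------
        stage = "network_rank"
        ranked = rank_genes(bundle.network, weights=config.centrality_weights)
        uio.write_tsv(ranked.table, outdir / "centrality_rank.tsv")
        top_ranked = list(ranked.table.head(10)["node"])

        # ---- qPCR ----------------------------------------------------------
        stage = "qpcr"
        fc = ddct_fold_change(bundle.ct_table, sorted(bundle.planted_fc),
                              config.reference_genes)
        uio.write_tsv(fc.table, outdir / "qpcr_fold_changes.tsv")
        qpcr = dict(zip(fc.table["gene_id"], fc.table["fold_change"]))

    except Exception as exc:
        (outdir / "FAILED").write_text(f"stage={stage}: {exc}\n", encoding="utf-8")
        raise UcsigError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    report = RunReport(
        config_hash=config.digest(),
        seed=config.seed,
        mouse_tallies=mouse_tallies,
        human_combined=human_combined,
        concordance=concordance,
        core_n=len(core),
        core_members=list(core.members["mouse_gene_id"]),
        mirna_common=mirna_common,
        neighbors_n=neighbors_n,
        risk_flagged=risk_flagged,
        target_coverage=target_coverage,
        top_enriched=top_enriched,
        top_ranked=top_ranked,
        qpcr=qpcr,
    )
    (outdir / "report.txt").write_text(report.summary_text(), encoding="utf-8")
    with open(outdir / "report.json", "w", encoding="utf-8") as fh:
        json.dump(asdict(report), fh, indent=1, default=str)
    return report
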