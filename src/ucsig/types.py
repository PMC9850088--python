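"""In-memory containers shared by every analysis stage.

Tabular payloads are pandas DataFrames wrapped in light dataclasses that
carry the metadata the analysis needs (species, tissue, assay, thresholds)
and enforce the domain invariants on construction.  Genomic coordinates
are 1-based inclusive throughout (GTF convention); BED inputs are converted
at the reading boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from ._errors import ValidationError

logger = logging.getLogger(__name__)

SPECIES = ("mouse", "human")
TISSUES = ("colon", "blood")
ASSAYS = ("total_rna", "small_rna")
BIOTYPES = ("pcg", "lncrna", "mirna", "other")
DIRECTIONS = ("up", "down")

#: column order of the DE record payload, also the on-disk TSV order
DE_COLUMNS = ["gene_id", "biotype", "base_mean", "log2fc", "pvalue", "padj"]


def normalize_biotype(value: str) -> str:
    """Map a free-text biotype onto the closed vocabulary.

    Common annotation spellings (``protein_coding``, ``miRNA`` ...) are
    recognized; anything else becomes ``other`` with a logged warning, the
    same bucket that pseudogenes, TEC, snoRNA and miscRNA fall into.
    """
    v = str(value).strip().lower()
    aliases = {
        "pcg": "pcg",
        "protein_coding": "pcg",
        "lncrna": "lncrna",
        "lincrna": "lncrna",
        "long_noncoding": "lncrna",
        "mirna": "mirna",
        "other": "other",
    }
    if v in aliases:
        return aliases[v]
    logger.warning("unknown biotype %r mapped to 'other'", value)
    return "other"


@dataclass
class DETable:
    """Differential-expression results for one dataset.

    ``records`` has columns ``gene_id, biotype, base_mean, log2fc, pvalue,
    padj``; ``padj`` may be NaN (genes filtered by the upstream DE tool),
    which downstream stages treat as "not significant".
    """

    dataset_id: str
    species: str
    tissue: str
    assay: str
    records: pd.DataFrame

    def __post_init__(self) -> None:
        if self.species not in SPECIES:
            raise ValidationError(f"unknown species {self.species!r}")
        if self.tissue not in TISSUES:
            raise ValidationError(f"unknown tissue {self.tissue!r}")
        if self.assay not in ASSAYS:
            raise ValidationError(f"unknown assay {self.assay!r}")
        df = self.records
        missing = [c for c in DE_COLUMNS if c not in df.columns]
        if missing:
            raise ValidationError(f"DETable missing columns: {missing}")
        dup = df["gene_id"][df["gene_id"].duplicated()]
        if len(dup):
            raise ValidationError(
                f"duplicate gene_id in dataset {self.dataset_id!r}: {dup.iloc[0]!r}"
            )
        if not np.isfinite(df["log2fc"].to_numpy(dtype=float)).all():
            raise ValidationError(f"non-finite log2fc in dataset {self.dataset_id!r}")
        if (df["base_mean"].to_numpy(dtype=float) < 0).any():
            raise ValidationError(f"negative base_mean in dataset {self.dataset_id!r}")
        for col in ("pvalue", "padj"):
            vals = df[col].to_numpy(dtype=float)
            ok = np.isnan(vals) | ((vals >= 0) & (vals <= 1))
            if not ok.all():
                raise ValidationError(
                    f"{col} outside [0,1] in dataset {self.dataset_id!r}"
                )
        bad_bt = set(df["biotype"]) - set(BIOTYPES)
        if bad_bt:
            raise ValidationError(f"unknown biotypes {sorted(bad_bt)}; normalize first")
        self.records = df.reset_index(drop=True)

    @property
    def gene_ids(self) -> set[str]:
        return set(self.records["gene_id"])

    def __len__(self) -> int:
        return len(self.records)


@dataclass(frozen=True)
class GeneLocus:
    """One gene's genomic span, 1-based inclusive."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str = "."
    biotype: str = "other"
    expressed: bool = False

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < 1:
            raise ValidationError(f"{self.gene_id}: coordinates must be positive")
        if self.start > self.end:
            raise ValidationError(f"{self.gene_id}: start > end")
        if self.strand not in ("+", "-", "."):
            raise ValidationError(f"{self.gene_id}: bad strand {self.strand!r}")


def loci_frame(loci: list[GeneLocus]) -> pd.DataFrame:
    """Tabular view of a locus list (vectorized interval arithmetic)."""
    return pd.DataFrame(
        {
            "gene_id": [l.gene_id for l in loci],
            "chrom": [l.chrom for l in loci],
            "start": [l.start for l in loci],
            "end": [l.end for l in loci],
            "strand": [l.strand for l in loci],
            "biotype": [l.biotype for l in loci],
            "expressed": [l.expressed for l in loci],
        }
    )


RELATIONS = ("one2one", "one2many")


@dataclass
class OrthologyMap:
    """Mouse-to-human gene pairs with relationship class.

    ``pairs`` columns: ``mouse_gene_id, human_gene_id, relation``.
    A ``one2one`` gene appears in exactly one pair on both sides.
    """

    pairs: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.pairs
        need = ["mouse_gene_id", "human_gene_id", "relation"]
        missing = [c for c in need if c not in df.columns]
        if missing:
            raise ValidationError(f"OrthologyMap missing columns: {missing}")
        bad = set(df["relation"]) - set(RELATIONS)
        if bad:
            raise ValidationError(f"unknown orthology relation labels: {sorted(bad)}")
        if df.duplicated(["mouse_gene_id", "human_gene_id"]).any():
            raise ValidationError("duplicate orthology pairs")
        one = df[df["relation"] == "one2one"]
        for col in ("mouse_gene_id", "human_gene_id"):
            counts = df[col].value_counts()
            multi = set(one[col]) & set(counts[counts > 1].index)
            if multi:
                raise ValidationError(
                    f"one2one gene appears in multiple pairs: {sorted(multi)[:3]}"
                )
        self.pairs = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.pairs)


def validate_network(g: nx.Graph) -> nx.Graph:
    """Check the invariants of a confidence-scored interaction network."""
    for a, b, data in g.edges(data=True):
        if a == b:
            raise ValidationError(f"self-loop on node {a!r}")
        c = data.get("confidence")
        if c is None or not (0.0 <= c <= 1.0):
            raise ValidationError(f"edge ({a},{b}) confidence {c!r} outside [0,1]")
    return g


@dataclass
class GeneSetCollection:
    """Named gene sets (GMT-style): term_id -> (term_name, member ids)."""

    sets: dict[str, tuple[str, set[str]]]

    def __post_init__(self) -> None:
        for term_id, (_, members) in self.sets.items():
            if not members:
                raise ValidationError(f"term {term_id!r} has no members")

    def __len__(self) -> int:
        return len(self.sets)


@dataclass
class CtTable:
    """qPCR cycle-threshold measurements, one row per replicate.

    Columns: ``sample_id, group, tissue, gene_id, ct``.
    """

    rows: pd.DataFrame

    def __post_init__(self) -> None:
        need = ["sample_id", "group", "tissue", "gene_id", "ct"]
        missing = [c for c in need if c not in self.rows.columns]
        if missing:
            raise ValidationError(f"CtTable missing columns: {missing}")
        ct = self.rows["ct"].to_numpy(dtype=float)
        if not np.isfinite(ct).all() or (ct <= 0).any():
            raise ValidationError("Ct values must be finite and > 0")
        bad = set(self.rows["group"]) - {"case", "control"}
        if bad:
            raise ValidationError(f"unknown groups: {sorted(bad)}")
        self.rows = self.rows.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.rows)


@dataclass
class SDESet:
    """Direction-labelled significant genes for one (species, tissue).

    ``entries`` maps gene_id -> ``up``/``down``; ``inconsistent`` holds genes
    significant in enough datasets but with conflicting fold-change signs
    (only populated by multi-dataset combination).  ``evidence`` optionally
    records per-gene support counts and per-dataset direction vectors.
    """

    species: str
    tissue: str
    source: str
    entries: dict[str, str]
    inconsistent: set[str] = field(default_factory=set)
    thresholds: dict = field(default_factory=dict)
    evidence: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        overlap = set(self.entries) & self.inconsistent
        if overlap:
            raise ValidationError(
                f"genes both direction-labelled and inconsistent: {sorted(overlap)[:3]}"
            )
        bad = set(self.entries.values()) - set(DIRECTIONS)
        if bad:
            raise ValidationError(f"bad directions: {sorted(bad)}")

    @property
    def up(self) -> set[str]:
        return {g for g, d in self.entries.items() if d == "up"}

    @property
    def down(self) -> set[str]:
        return {g for g, d in self.entries.items() if d == "down"}

    def __len__(self) -> int:
        return len(self.entries)


CONCORDANCE_CLASSES = ("concordant_up", "concordant_down", "contra")


def concordance_class(mouse_dir: str, human_dir: str) -> str:
    """Direction-pair classification: up/up, down/down, else contra."""
    if mouse_dir == "up" and human_dir == "up":
        return "concordant_up"
    if mouse_dir == "down" and human_dir == "down":
        return "concordant_down"
    return "contra"


@dataclass
class ConcordanceTable:
    """Ortholog-pair level cross-species comparison for one tissue.

    ``rows`` has one line per matched orthology pair; ``gene_classes`` has
    one line per distinct mouse gene (a one-to-many mouse gene matched by
    several human orthologs counts once: concordant if any matched pair is
    concordant, contra only if all matched pairs are contra).
    """

    tissue: str
    rows: pd.DataFrame
    gene_classes: pd.DataFrame
    n_mouse_sde_with_human_ortholog: int = 0
    n_human_sde_with_mouse_ortholog: int = 0

    def __post_init__(self) -> None:
        if len(self.rows):
            bad = set(self.rows["pair_class"]) - set(CONCORDANCE_CLASSES)
            if bad:
                raise ValidationError(f"bad concordance classes: {sorted(bad)}")


@dataclass
class CoreSet:
    """Genes concordant between species in both colon and blood.

    ``members`` columns: ``mouse_gene_id, human_gene_id, colon_class,
    blood_class, agreement`` where agreement is False when the colon and
    blood directions differ (both still concordant within their tissue).
    """

    members: pd.DataFrame

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class CentralityResult:
    """Per-node centralities, combined score and dense rank.

    ``table`` columns: ``node, degree, closeness, betweenness, combined,
    rank``; sorted by rank, ties broken lexicographically by node id.
    """

    table: pd.DataFrame
    normalization: str = "minmax"
    weights: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)


@dataclass
class FoldChangeResult:
    """Relative expression per target gene from the Livak 2^-ddCt method."""

    table: pd.DataFrame  # gene_id, fold_change, delta_ct_case, delta_ct_control, n_case, n_control
    reference_genes: tuple[str, ...] = ()
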