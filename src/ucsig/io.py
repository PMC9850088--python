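"""Readers and writers for every external format the pipeline touches.

All writers emit UTF-8, tab-separated files with ``#``-prefixed metadata
header lines recording the parameters that produced them; all readers
validate strictly and raise errors that name the file, line and column.

Coordinate conventions: GTF is 1-based inclusive and is stored unchanged;
BED (0-based half-open) is converted to 1-based inclusive at this boundary
so all interval arithmetic downstream uses a single convention.
"""

from __future__ import annotations

import logging
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from ._errors import FormatError, ValidationError
from .types import (
    DE_COLUMNS,
    CtTable,
    DETable,
    GeneLocus,
    GeneSetCollection,
    OrthologyMap,
    normalize_biotype,
    validate_network,
)

logger = logging.getLogger(__name__)


def _read_tsv(path, required, sep="\t", fmt="TSV"):
    path = Path(path)
    try:
        df = pd.read_csv(path, sep=sep, comment="#", dtype=str)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise FormatError(f"{path}: cannot parse as {fmt}: {exc}") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    return df


def _to_float(df, col, path, allow_nan=False):
    out = pd.to_numeric(df[col], errors="coerce")
    bad = out.isna() & df[col].notna() if allow_nan else out.isna()
    if bad.any():
        i = int(np.flatnonzero(bad.to_numpy())[0])
        raise FormatError(
            f"{path}: non-numeric value {df[col].iloc[i]!r} in column "
            f"{col!r} at data row {i + 1}"
        )
    return out.astype(float)


# ---------------------------------------------------------------------------
# differential-expression tables


def read_de_table(path, dataset_meta: dict) -> DETable:
    """Read a DESeq2-style result TSV into a validated :class:`DETable`.

    ``dataset_meta`` must supply ``dataset_id``, ``species``, ``tissue`` and
    ``assay``.  Rows with missing ``padj`` are retained (flagged NaN); they
    are treated as non-significant downstream, never imputed.
    """
    path = Path(path)
    df = _read_tsv(path, DE_COLUMNS)
    rec = pd.DataFrame({"gene_id": df["gene_id"].astype(str)})
    rec["biotype"] = df["biotype"].map(normalize_biotype)
    rec["base_mean"] = _to_float(df, "base_mean", path)
    rec["log2fc"] = _to_float(df, "log2fc", path)
    rec["pvalue"] = _to_float(df, "pvalue", path, allow_nan=True)
    rec["padj"] = _to_float(df, "padj", path, allow_nan=True)
    n_na = int(rec["padj"].isna().sum())
    if n_na:
        logger.info("%s: %d rows with missing padj retained as non-significant", path, n_na)
    try:
        return DETable(records=rec, **dataset_meta)
    except ValidationError as exc:
        raise ValidationError(f"{path}: {exc}") from exc


def write_de_table(table: DETable, path) -> None:
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(
            f"# dataset_id={table.dataset_id} species={table.species} "
            f"tissue={table.tissue} assay={table.assay}\n"
        )
        table.records[DE_COLUMNS].to_csv(fh, sep="\t", index=False)


# ---------------------------------------------------------------------------
# gene loci: GTF and BED


def read_gtf_loci(path, expressed_ids=None) -> list[GeneLocus]:
    """Extract gene-level loci from a GTF file.

    Only ``gene`` features are used; coordinates stay 1-based inclusive as
    in the file.  ``expressed`` is set from membership in ``expressed_ids``.
    A file with no gene features yields an empty list with a warning.
    """
    path = Path(path)
    expressed = set(expressed_ids) if expressed_ids is not None else set()
    loci: list[GeneLocus] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 9:
                raise FormatError(f"{path}:{lineno}: expected 9 GTF columns")
            chrom, _src, feature, start, end, _score, strand, _frame, attrs = parts[:9]
            if feature != "gene":
                continue
            attr = _parse_gtf_attributes(attrs)
            gene_id = attr.get("gene_id")
            if not gene_id:
                raise FormatError(f"{path}:{lineno}: gene feature missing gene_id attribute")
            biotype = normalize_biotype(attr.get("gene_biotype", "other"))
            try:
                loci.append(
                    GeneLocus(
                        gene_id=gene_id,
                        chrom=chrom,
                        start=int(start),
                        end=int(end),
                        strand=strand if strand in "+-." else ".",
                        biotype=biotype,
                        expressed=gene_id in expressed,
                    )
                )
            except (ValueError, ValidationError) as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    if not loci:
        logger.warning("%s: no gene features found", path)
    return loci


def _parse_gtf_attributes(text: str) -> dict[str, str]:
    out = {}
    for chunk in text.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        key, _, value = chunk.partition(" ")
        out[key] = value.strip().strip('"')
    return out


def write_gtf_loci(loci: list[GeneLocus], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for l in loci:
            bt = {"pcg": "protein_coding", "lncrna": "lncRNA", "mirna": "miRNA"}.get(
                l.biotype, l.biotype
            )
            fh.write(
                f"{l.chrom}\tucsig\tgene\t{l.start}\t{l.end}\t.\t{l.strand}\t.\t"
                f'gene_id "{l.gene_id}"; gene_biotype "{bt}";\n'
            )


def read_bed_loci(path, name_prefix="locus") -> list[GeneLocus]:
    """Read BED intervals (risk loci) converting to 1-based inclusive.

    BED is 0-based half-open: start+1..end inclusive internally.  A point
    locus may be encoded as a zero-length interval (start == end); it is
    widened to the single base it marks.
    """
    path = Path(path)
    loci = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: expected >=3 BED columns")
            chrom, start, end = parts[0], parts[1], parts[2]
            name = parts[3] if len(parts) > 3 else f"{name_prefix}_{lineno}"
            try:
                s0, e0 = int(start), int(end)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinate") from exc
            if e0 < s0:
                raise FormatError(f"{path}:{lineno}: end < start")
            s1 = s0 + 1
            e1 = max(e0, s1)  # zero-length point -> single base
            loci.append(GeneLocus(gene_id=name, chrom=chrom, start=s1, end=e1))
    return loci


# ---------------------------------------------------------------------------
# STRING-dialect edge lists


def read_string_edges(path, min_confidence: float = 0.4) -> nx.Graph:
    """Read a STRING-dialect edge TSV into an undirected weighted graph.

    Scores on the 0-1000 STRING scale are divided by 1000; edges below
    ``min_confidence`` are dropped; symmetric duplicates collapse keeping
    the maximum confidence.  Output is invariant to row order and to
    swapping the two protein columns.
    """
    path = Path(path)
    df = _read_tsv(path, ["protein1", "protein2", "combined_score"])
    score = _to_float(df, "combined_score", path)
    if ((score < 0) | (score > 1000)).any():
        i = int(np.flatnonzero(((score < 0) | (score > 1000)).to_numpy())[0])
        raise ValidationError(
            f"{path}: combined_score {score.iloc[i]} outside [0,1000] at data row {i + 1}"
        )
    g = nx.Graph()
    for a, b, s in zip(df["protein1"], df["protein2"], score):
        conf = s / 1000.0
        if conf < min_confidence or a == b:
            continue
        if g.has_edge(a, b):
            g[a][b]["confidence"] = max(g[a][b]["confidence"], conf)
        else:
            g.add_edge(a, b, confidence=conf)
    return validate_network(g)


def write_string_edges(g: nx.Graph, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("protein1\tprotein2\tcombined_score\n")
        for a, b, data in sorted(g.edges(data=True), key=lambda e: (str(e[0]), str(e[1]))):
            a, b = sorted((str(a), str(b)))
            fh.write(f"{a}\t{b}\t{int(round(data['confidence'] * 1000))}\n")


# ---------------------------------------------------------------------------
# orthology


def read_orthology(path) -> OrthologyMap:
    """Read an orthology TSV (mouse_gene_id, human_gene_id, relation)."""
    path = Path(path)
    df = _read_tsv(path, ["mouse_gene_id", "human_gene_id", "relation"])
    try:
        return OrthologyMap(pairs=df)
    except ValidationError as exc:
        raise ValidationError(f"{path}: {exc}") from exc


def write_orthology(orth: OrthologyMap, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# orthology pairs (mouse -> human)\n")
        orth.pairs.to_csv(fh, sep="\t", index=False)


# ---------------------------------------------------------------------------
# gene sets (GMT)


def read_gmt(path) -> GeneSetCollection:
    """Read a GMT file: term_id <tab> term_name <tab> member genes..."""
    path = Path(path)
    sets: dict[str, tuple[str, set[str]]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line needs term_id, term_name and >=1 member"
                )
            term_id, term_name, members = parts[0], parts[1], parts[2:]
            if term_id in sets:
                raise ValidationError(f"{path}:{lineno}: duplicate term_id {term_id!r}")
            sets[term_id] = (term_name, {m for m in members if m})
    return GeneSetCollection(sets=sets)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for term_id in sorted(collection.sets):
            name, members = collection.sets[term_id]
            fh.write("\t".join([term_id, name, *sorted(members)]) + "\n")


# ---------------------------------------------------------------------------
# qPCR Ct tables


def read_ct_csv(path) -> CtTable:
    """Read a Ct CSV with columns sample_id, group, tissue, gene_id, ct."""
    path = Path(path)
    df = _read_tsv(path, ["sample_id", "group", "tissue", "gene_id", "ct"], sep=",", fmt="CSV")
    df["ct"] = _to_float(df, "ct", path)
    try:
        return CtTable(rows=df)
    except ValidationError as exc:
        raise ValidationError(f"{path}: {exc}") from exc


def write_ct_csv(ct: CtTable, path) -> None:
    ct.rows.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# miRNA target maps


def read_target_map(path) -> dict[str, set[str]]:
    """Read a miRNA->target TSV (mirna_id, target_gene_id) into a dict."""
    path = Path(path)
    df = _read_tsv(path, ["mirna_id", "target_gene_id"])
    out: dict[str, set[str]] = {}
    for m, t in zip(df["mirna_id"], df["target_gene_id"]):
        out.setdefault(str(m), set()).add(str(t))
    return out


def write_target_map(target_map: dict[str, set[str]], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("mirna_id\ttarget_gene_id\n")
        for m in sorted(target_map):
            for t in sorted(target_map[m]):
                fh.write(f"{m}\t{t}\n")


# ---------------------------------------------------------------------------
# generic annotated-TSV writer used by the pipeline report


def write_tsv(df: pd.DataFrame, path, params: dict | None = None) -> None:
    """Write a DataFrame as TSV with '#'-prefixed parameter header lines."""
    with open(path, "w", encoding="utf-8") as fh:
        for k, v in (params or {}).items():
            fh.write(f"# {k}={v}\n")
        df.to_csv(fh, sep="\t", index=False)
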