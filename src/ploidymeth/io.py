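"""Readers and writers for the on-disk formats.

Formats
-------
Cytosine table
    Tab-separated, ``#``-prefixed header, columns
    ``chrom pos strand context n_meth n_total``. Positions may be
    0-based (default) or 1-based (``one_based_input=True``); in memory
    they are always 0-based. Rows with ``n_total == 0`` (uncovered
    cytosines) are legal and retained.
GFF3
    1-based inclusive on disk, converted to 0-based half-open. Feature
    types ``gene`` map to PCG; ``lnc_RNA``/``lncRNA`` map to lncRNA
    (attribute ``lincRNA=1`` marks the intergenic subclass).
BED
    0-based half-open, passed through. Used for TE input (name column
    ``class:order``) and DMR output.
TE TSV
    Tab-separated with 0-based half-open coordinates and explicit
    class/order columns (mirrors a RepeatMasker-derived TE table).
Expression TSV
    Long format: one row per (feature, cytotype, replicate) with an
    FPKM value.
"""

from __future__ import annotations

import os
from typing import Iterable

import numpy as np
import pandas as pd

from ploidymeth.constants import (
    CONTEXTS,
    CYTOSINE_COLUMNS,
    FEATURE_COLUMNS,
    TE_CLASSES,
    TE_ORDERS,
)


class ParseError(ValueError):
    """Malformed input; carries the offending file and line number."""

    def __init__(self, path, line: int, message: str):
        self.path = path
        self.line = line
        super().__init__(f"{path}:{line}: {message}")


def _data_lines(path) -> tuple[list[str], list[int]]:
    """Return non-comment, non-blank lines and their 1-based numbers."""
    lines, numbers = [], []
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            lines.append(line)
            numbers.append(lineno)
    return lines, numbers


# ---------------------------------------------------------------------------
# cytosine tables


def read_cytosine_table(path, one_based_input: bool = False) -> pd.DataFrame:
    """Read a per-cytosine bisulfite count table.

    Parameters
    ----------
    path
        TSV with columns chrom, pos, strand, context, n_meth, n_total.
    one_based_input
        If True, positions on disk are 1-based and are shifted to
        0-based on read.

    Returns
    -------
    DataFrame with columns ``chrom pos strand context n_meth n_total``,
    positions 0-based, row order preserved. Uncovered rows
    (``n_total == 0``) are retained.
    """
    lines, numbers = _data_lines(path)
    if not lines:
        return _empty_cytosine_frame()

    chroms, poss, strands, contexts, n_meths, n_totals = [], [], [], [], [], []
    for line, lineno in zip(lines, numbers):
        fields = line.split("\t")
        if len(fields) != 6:
            raise ParseError(
                path, lineno, f"expected 6 tab-separated columns, found {len(fields)}"
            )
        chrom, pos_s, strand, context, m_s, t_s = fields
        if strand not in ("+", "-"):
            raise ParseError(path, lineno, f"strand must be + or -, got {strand!r}")
        if context not in CONTEXTS:
            raise ParseError(
                path,
                lineno,
                f"unknown context {context!r}; expected one of {', '.join(CONTEXTS)}",
            )
        try:
            pos = int(pos_s)
            n_meth = int(m_s)
            n_total = int(t_s)
        except ValueError as exc:
            raise ParseError(path, lineno, f"non-integer numeric field: {exc}")
        if one_based_input:
            pos -= 1
        if pos < 0:
            raise ParseError(path, lineno, f"negative position {pos}")
        if n_meth < 0 or n_total < 0:
            raise ParseError(path, lineno, "negative read count")
        if n_meth > n_total:
            raise ParseError(
                path, lineno, f"n_meth ({n_meth}) exceeds n_total ({n_total})"
            )
        chroms.append(chrom)
        poss.append(pos)
        strands.append(strand)
        contexts.append(context)
        n_meths.append(n_meth)
        n_totals.append(n_total)

    return pd.DataFrame(
        {
            "chrom": chroms,
            "pos": np.asarray(poss, dtype=np.int64),
            "strand": strands,
            "context": contexts,
            "n_meth": np.asarray(n_meths, dtype=np.int64),
            "n_total": np.asarray(n_totals, dtype=np.int64),
        }
    )


def _empty_cytosine_frame() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": pd.Series(dtype=object),
            "pos": pd.Series(dtype=np.int64),
            "strand": pd.Series(dtype=object),
            "context": pd.Series(dtype=object),
            "n_meth": pd.Series(dtype=np.int64),
            "n_total": pd.Series(dtype=np.int64),
        }
    )


def write_cytosine_table(records: pd.DataFrame, path) -> None:
    """Write a cytosine table (0-based positions) with a ``#`` header."""
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("#" + "\t".join(CYTOSINE_COLUMNS) + "\n")
        records.to_csv(fh, sep="\t", header=False, index=False, columns=list(CYTOSINE_COLUMNS))


# ---------------------------------------------------------------------------
# features


def _validate_features(df: pd.DataFrame, path) -> pd.DataFrame:
    dup = df["id"].duplicated()
    if dup.any():
        first = df.loc[dup, "id"].iloc[0]
        raise ParseError(path, 0, f"duplicate feature id {first!r}")
    bad = df["end"] <= df["start"]
    if bad.any():
        row = df[bad].iloc[0]
        raise ParseError(
            path, 0, f"feature {row['id']!r}: end ({row['end']}) <= start ({row['start']})"
        )
    return df.reset_index(drop=True)


def _te_fields(te_class: str, te_order: str, path, lineno: int) -> tuple[str, str]:
    if te_class not in TE_CLASSES:
        raise ParseError(
            path, lineno,
            f"unknown TE class {te_class!r}; allowed: {', '.join(TE_CLASSES)}",
        )
    if te_order not in TE_ORDERS:
        raise ParseError(
            path, lineno,
            f"unknown TE order {te_order!r}; allowed: {', '.join(TE_ORDERS)}",
        )
    return te_class, te_order


def read_features(path, format: str = "gff3") -> pd.DataFrame:
    """Read a feature annotation into the normalized feature table.

    Parameters
    ----------
    path
        Annotation file.
    format
        ``"gff3"`` (1-based inclusive; genes and lncRNAs),
        ``"bed"`` (0-based half-open; name column may be
        ``class:order`` for TEs, otherwise features are TEs of class I
        order "other"), or ``"te-tsv"`` (0-based half-open with
        explicit id/class/order columns).

    Returns
    -------
    DataFrame with columns ``id chrom start end strand kind subkind
    te_class te_order``; all coordinates 0-based half-open.
    """
    fmt = format.lower()
    if fmt == "gff3":
        return _read_gff3(path)
    if fmt == "bed":
        return _read_bed_tes(path)
    if fmt in ("te-tsv", "te_tsv", "tetsv"):
        return _read_te_tsv(path)
    raise ValueError(f"unknown feature format {format!r}")


def _parse_gff3_attributes(text: str) -> dict:
    out = {}
    for item in text.strip().split(";"):
        if not item:
            continue
        key, _, value = item.partition("=")
        out[key.strip()] = value.strip()
    return out


def _read_gff3(path) -> pd.DataFrame:
    lines, numbers = _data_lines(path)
    rows = []
    for line, lineno in zip(lines, numbers):
        fields = line.split("\t")
        if len(fields) != 9:
            raise ParseError(path, lineno, f"expected 9 GFF3 columns, found {len(fields)}")
        chrom, _source, ftype, start_s, end_s, _score, strand, _phase, attrs_s = fields
        try:
            start1 = int(start_s)
            end1 = int(end_s)
        except ValueError:
            raise ParseError(path, lineno, "non-integer start/end")
        start, end = start1 - 1, end1  # 1-based inclusive -> 0-based half-open
        attrs = _parse_gff3_attributes(attrs_s)
        fid = attrs.get("ID")
        if fid is None:
            raise ParseError(path, lineno, "missing ID attribute")
        if strand not in ("+", "-", "."):
            raise ParseError(path, lineno, f"bad strand {strand!r}")
        if ftype == "gene":
            kind, subkind, te_class, te_order = "PCG", "", "", ""
        elif ftype in ("lnc_RNA", "lncRNA"):
            kind = "lncRNA"
            subkind = "lincRNA" if attrs.get("lincRNA") in ("1", "true", "True") else "other"
            te_class, te_order = "", ""
        elif ftype in ("transposable_element", "TE"):
            kind, subkind = "TE", ""
            te_class, te_order = _te_fields(
                attrs.get("te_class", ""), attrs.get("te_order", ""), path, lineno
            )
        else:
            # unrelated record types (mRNA, exon, ...) are skipped
            continue
        if end <= start:
            raise ParseError(path, lineno, f"end ({end1}) <= start ({start1}) after conversion")
        rows.append((fid, chrom, start, end, strand, kind, subkind, te_class, te_order))
    return _validate_features(_feature_frame(rows), path)


def _read_bed_tes(path) -> pd.DataFrame:
    lines, numbers = _data_lines(path)
    rows = []
    for i, (line, lineno) in enumerate(zip(lines, numbers)):
        fields = line.split("\t")
        if len(fields) < 3:
            raise ParseError(path, lineno, "BED line needs at least 3 columns")
        chrom, start_s, end_s = fields[:3]
        try:
            start, end = int(start_s), int(end_s)
        except ValueError:
            raise ParseError(path, lineno, "non-integer start/end")
        if end <= start:
            raise ParseError(path, lineno, f"end ({end}) <= start ({start})")
        name = fields[3] if len(fields) > 3 and fields[3] != "." else f"TE{i + 1:06d}"
        strand = fields[5] if len(fields) > 5 else "."
        if ":" in name:
            fid_or_class, _, order = name.partition(":")
            te_class, te_order = _te_fields(fid_or_class, order, path, lineno)
            fid = f"TE{i + 1:06d}"
        else:
            fid, te_class, te_order = name, "I", "other"
        rows.append((fid, chrom, start, end, strand, "TE", "", te_class, te_order))
    return _validate_features(_feature_frame(rows), path)


def _read_te_tsv(path) -> pd.DataFrame:
    """TE table: columns ``chrom start end class order`` (0-based,
    half-open), optionally preceded by an ``id`` column."""
    lines, numbers = _data_lines(path)
    rows = []
    for i, (line, lineno) in enumerate(zip(lines, numbers)):
        fields = line.split("\t")
        if len(fields) == 5:
            fid = f"TE{i + 1:06d}"
            chrom, start_s, end_s, te_class, te_order = fields
        elif len(fields) == 6:
            fid, chrom, start_s, end_s, te_class, te_order = fields
        else:
            raise ParseError(path, lineno, f"expected 5 or 6 columns, found {len(fields)}")
        try:
            start, end = int(start_s), int(end_s)
        except ValueError:
            raise ParseError(path, lineno, "non-integer start/end")
        if end <= start:
            raise ParseError(path, lineno, f"end ({end}) <= start ({start})")
        te_class, te_order = _te_fields(te_class, te_order, path, lineno)
        rows.append((fid, chrom, start, end, ".", "TE", "", te_class, te_order))
    return _validate_features(_feature_frame(rows), path)


def _feature_frame(rows: Iterable[tuple]) -> pd.DataFrame:
    df = pd.DataFrame(list(rows), columns=list(FEATURE_COLUMNS))
    if df.empty:
        df = pd.DataFrame(
            {c: pd.Series(dtype=np.int64 if c in ("start", "end") else object)
             for c in FEATURE_COLUMNS}
        )
    else:
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
    return df


def write_features_gff3(features: pd.DataFrame, path) -> None:
    """Write PCG/lncRNA/TE features as GFF3 (1-based inclusive)."""
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("##gff-version 3\n")
        for row in features.itertuples(index=False):
            if row.kind == "PCG":
                ftype, attrs = "gene", f"ID={row.id}"
            elif row.kind == "lncRNA":
                ftype = "lnc_RNA"
                attrs = f"ID={row.id}"
                if row.subkind == "lincRNA":
                    attrs += ";lincRNA=1"
            else:
                ftype = "transposable_element"
                attrs = f"ID={row.id};te_class={row.te_class};te_order={row.te_order}"
            fh.write(
                f"{row.chrom}\tploidymeth\t{ftype}\t{row.start + 1}\t{row.end}\t.\t"
                f"{row.strand}\t.\t{attrs}\n"
            )


def write_te_table(tes: pd.DataFrame, path) -> None:
    """Write the TE table dialect (id, 0-based half-open, class, order)."""
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("#id\tchrom\tstart\tend\tclass\torder\n")
        for row in tes.itertuples(index=False):
            fh.write(
                f"{row.id}\t{row.chrom}\t{row.start}\t{row.end}\t"
                f"{row.te_class}\t{row.te_order}\n"
            )


# ---------------------------------------------------------------------------
# expression tables


def read_expression_table(path) -> pd.DataFrame:
    """Read a long-format expression table.

    Columns: ``feature_id cytotype replicate fpkm``; cytotype in
    {2x, 4x}; FPKM non-negative.
    """
    lines, numbers = _data_lines(path)
    rows = []
    for line, lineno in zip(lines, numbers):
        fields = line.split("\t")
        if len(fields) != 4:
            raise ParseError(path, lineno, f"expected 4 columns, found {len(fields)}")
        fid, cytotype, rep_s, fpkm_s = fields
        if cytotype not in ("2x", "4x"):
            raise ParseError(path, lineno, f"cytotype must be 2x or 4x, got {cytotype!r}")
        try:
            rep = int(rep_s)
            fpkm = float(fpkm_s)
        except ValueError:
            raise ParseError(path, lineno, "non-numeric replicate or FPKM")
        if fpkm < 0:
            raise ParseError(path, lineno, f"negative FPKM {fpkm}")
        rows.append((fid, cytotype, rep, fpkm))
    return pd.DataFrame(rows, columns=["feature_id", "cytotype", "replicate", "fpkm"])


def write_expression_table(expr: pd.DataFrame, path) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("#feature_id\tcytotype\treplicate\tfpkm\n")
        expr.to_csv(fh, sep="\t", header=False, index=False,
                    columns=["feature_id", "cytotype", "replicate", "fpkm"],
                    float_format="%.6g")


# ---------------------------------------------------------------------------
# DMR output


def write_dmr_output(dmrs: pd.DataFrame, bed_path, tsv_path) -> None:
    """Write called DMRs as BED6 and annotated TSV.

    BED name is ``context:direction``; BED score is
    ``round(1000 * |delta|)``. Both outputs sorted by (chrom, start).
    """
    cols = ["chrom", "start", "end", "context", "ratio_2x", "ratio_4x",
            "delta", "q", "direction", "annotation"]
    if dmrs.empty:
        ordered = pd.DataFrame(columns=cols)
    else:
        d = dmrs.copy()
        if "annotation" not in d.columns:
            d["annotation"] = ""
        ordered = d.sort_values(["chrom", "start"], kind="mergesort")[cols]
    with open(bed_path, "wt", encoding="utf-8") as fh:
        for row in ordered.itertuples(index=False):
            score = int(round(1000 * abs(row.delta)))
            fh.write(
                f"{row.chrom}\t{row.start}\t{row.end}\t"
                f"{row.context}:{row.direction}\t{score}\t.\n"
            )
    with open(tsv_path, "wt", encoding="utf-8") as fh:
        fh.write("#" + "\t".join(cols) + "\n")
        for row in ordered.itertuples(index=False):
            fh.write(
                f"{row.chrom}\t{row.start}\t{row.end}\t{row.context}\t"
                f"{row.ratio_2x:.6g}\t{row.ratio_4x:.6g}\t{row.delta:.6g}\t"
                f"{row.q:.6g}\t{row.direction}\t{row.annotation}\n"
            )


# ---------------------------------------------------------------------------
# FASTA


def write_fasta(genome: dict[str, str], path, width: int = 70) -> None:
    """Write a chromosome-name -> sequence mapping as FASTA."""
    with open(path, "wt", encoding="utf-8") as fh:
        for name, seq in genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def read_fasta(path) -> dict[str, str]:
    """Read a FASTA into a chromosome-name -> uppercase sequence dict."""
    from pyfaidx import Fasta

    fa = Fasta(str(path), rebuild=True, build_index=not os.path.exists(str(path) + ".fai"))
    return {name: str(fa[name][:]).upper() for name in fa.keys()}
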