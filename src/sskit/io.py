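"""Readers and writers for the plain-text formats the pipeline consumes.

BED3/BED5 for intervals and element calls, BEDPE for contacts and
translocation partners, and headered TSV for element signal tables,
variants, genes/expression, LD pairs, CpG methylation and
activity/TFBS matrices.  All readers accept gzip-compressed files and
emit errors that name the offending line.  Output formatting is
canonical (tab-separated, ``%.6g`` floats) so write-then-read
round-trips are byte-stable.
"""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import Iterable, List, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .core import (
    ActivityMatrix,
    ContactRecord,
    GeneRecord,
    GenomicInterval,
    RegulatoryElement,
    SILENCER,
    TADSet,
    TFBSMatrix,
    VariantRecord,
)

PathLike = Union[str, Path]


def _open(path: PathLike, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def _fmt(value: float) -> str:
    return format(float(value), ".6g")


def _norm_chrom(chrom: str, add_chr: bool) -> str:
    if add_chr and not chrom.startswith("chr"):
        return "chr" + chrom
    return chrom


def _parse_coords(fields, lineno, path, one_based):
    try:
        start, end = int(fields[1]), int(fields[2])
    except ValueError as exc:
        raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
    if one_based:
        start -= 1
    if start >= end:
        raise ValueError(f"{path}:{lineno}: start >= end ({start} >= {end})")
    if start < 0:
        raise ValueError(f"{path}:{lineno}: negative start {start}")
    return start, end


# ---------------------------------------------------------------------------
# BED / BEDPE
# ---------------------------------------------------------------------------

def read_bed(
    path: PathLike,
    with_score: bool = False,
    mark: str = "H3K27me3",
    element_class: str = SILENCER,
    cell_type: str = "",
    add_chr: bool = False,
    one_based: bool = False,
):
    """Read a BED file.

    With ``with_score`` false the result is a list of
    :class:`GenomicInterval`; otherwise column 4 is taken as the
    element name and column 5 as the signal for ``mark``, yielding
    :class:`RegulatoryElement` records.
    """
    out = []
    with _open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected >=3 tab-separated columns")
            chrom = _norm_chrom(fields[0], add_chr)
            start, end = _parse_coords(fields, lineno, path, one_based)
            iv = GenomicInterval(chrom, start, end)
            if not with_score:
                out.append(iv)
                continue
            name = fields[3] if len(fields) > 3 and fields[3] not in (".", "") else (
                f"{chrom}:{start}-{end}"
            )
            try:
                score = float(fields[4]) if len(fields) > 4 else 0.0
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric score") from exc
            out.append(
                RegulatoryElement(
                    id=name,
                    interval=iv,
                    element_class=element_class,
                    signal={mark: score},
                    cell_type=cell_type,
                )
            )
    return out


def write_bed(path: PathLike, items: Iterable, mark: Optional[str] = None) -> None:
    """Write intervals (BED3), elements or super regions (BED5)."""
    with _open(path, "wt") as fh:
        for item in items:
            if isinstance(item, GenomicInterval):
                fh.write(f"{item.chrom}\t{item.start}\t{item.end}\n")
            elif isinstance(item, RegulatoryElement):
                iv = item.interval
                score = item.signal.get(mark, 0.0) if mark else next(
                    iter(item.signal.values()), 0.0
                )
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{item.id}\t{_fmt(score)}\n")
            else:  # SuperRegion
                iv = item.interval
                status = "super" if item.is_super else "typical"
                name = f"{status}_rank{item.rank}" if item.rank else status
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{_fmt(item.total_signal)}\n"
                )


def read_bedpe(path: PathLike, cell_type: str = "", add_chr: bool = False) -> List[ContactRecord]:
    out = []
    with _open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ValueError(f"{path}:{lineno}: expected >=6 BEDPE columns")
            try:
                a = GenomicInterval(_norm_chrom(fields[0], add_chr), int(fields[1]), int(fields[2]))
                b = GenomicInterval(_norm_chrom(fields[3], add_chr), int(fields[4]), int(fields[5]))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
            out.append(ContactRecord(anchor1=a, anchor2=b, cell_type=cell_type))
    return out


def write_bedpe(path: PathLike, contacts: Iterable[ContactRecord]) -> None:
    with _open(path, "wt") as fh:
        for c in contacts:
            a, b = c.anchor1, c.anchor2
            fh.write(f"{a.chrom}\t{a.start}\t{a.end}\t{b.chrom}\t{b.start}\t{b.end}\n")


def read_tads(path: PathLike, add_chr: bool = False) -> TADSet:
    return TADSet(read_bed(path, add_chr=add_chr))


# ---------------------------------------------------------------------------
# Element signal tables
# ---------------------------------------------------------------------------

ELEMENT_FIXED_COLS = ["id", "chrom", "start", "end", "element_class", "cell_type"]


def read_elements_tsv(path: PathLike) -> List[RegulatoryElement]:
    """Read an element table: fixed columns plus one column per mark."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "id": str})
    missing = [c for c in ELEMENT_FIXED_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    marks = [c for c in df.columns if c not in ELEMENT_FIXED_COLS]
    out = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        out.append(
            RegulatoryElement(
                id=str(d["id"]),
                interval=GenomicInterval(d["chrom"], int(d["start"]), int(d["end"])),
                element_class=d["element_class"],
                signal={m: float(d[m]) for m in marks},
                cell_type=str(d["cell_type"]) if not pd.isna(d["cell_type"]) else "",
            )
        )
    return out


def write_elements_tsv(path: PathLike, elements: Sequence[RegulatoryElement]) -> None:
    marks = sorted({m for e in elements for m in e.signal})
    with _open(path, "wt") as fh:
        fh.write("\t".join(ELEMENT_FIXED_COLS + marks) + "\n")
        for e in elements:
            iv = e.interval
            row = [e.id, iv.chrom, str(iv.start), str(iv.end), e.element_class, e.cell_type]
            row += [_fmt(e.signal.get(m, 0.0)) for m in marks]
            fh.write("\t".join(row) + "\n")


# ---------------------------------------------------------------------------
# Variants
# ---------------------------------------------------------------------------

def _split_tags(text) -> frozenset:
    if text is None or (isinstance(text, float) and np.isnan(text)) or text == "":
        return frozenset()
    return frozenset(str(text).split(";"))


def read_variants_tsv(path: PathLike) -> List[VariantRecord]:
    """Variant table: chrom, pos (0-based), vtype, categories, samples,
    studies and optional partner_chrom/partner_pos for breakpoints.
    Set-valued columns are ``;``-separated."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    out = []
    has_partner = "partner_chrom" in df.columns
    has_id = "id" in df.columns
    for i, row in enumerate(df.itertuples(index=False)):
        d = row._asdict()
        pos = int(d["pos"])
        partner = None
        if has_partner and not pd.isna(d["partner_chrom"]):
            ppos = int(d["partner_pos"])
            partner = GenomicInterval(str(d["partner_chrom"]), ppos, ppos + 1)
        out.append(
            VariantRecord(
                position=GenomicInterval(d["chrom"], pos, pos + 1),
                vtype=str(d["vtype"]),
                categories=_split_tags(d.get("categories")),
                sample_ids=_split_tags(d.get("samples")),
                study_ids=_split_tags(d.get("studies")),
                partner=partner,
                id=str(d["id"]) if has_id else f"v{i}",
            )
        )
    return out


def write_variants_tsv(path: PathLike, variants: Sequence[VariantRecord]) -> None:
    with _open(path, "wt") as fh:
        fh.write("id\tchrom\tpos\tvtype\tcategories\tsamples\tstudies\tpartner_chrom\tpartner_pos\n")
        for v in variants:
            pc = v.partner.chrom if v.partner else ""
            pp = str(v.partner.start) if v.partner else ""
            fh.write(
                "\t".join(
                    [
                        v.id,
                        v.position.chrom,
                        str(v.position.start),
                        v.vtype,
                        ";".join(sorted(v.categories)),
                        ";".join(sorted(v.sample_ids)),
                        ";".join(sorted(v.study_ids)),
                        pc,
                        pp,
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Genes, LD pairs, methylation, matrices
# ---------------------------------------------------------------------------

def read_genes_tsv(path: PathLike) -> List[GeneRecord]:
    """Gene table: gene_id, chrom, tss, strand plus ``expr_<cell>`` columns."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "gene_id": str})
    expr_cols = [c for c in df.columns if c.startswith("expr_")]
    out = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        expr = {
            c[len("expr_"):]: float(d[c]) for c in expr_cols if not pd.isna(d[c])
        }
        out.append(
            GeneRecord(
                gene_id=str(d["gene_id"]),
                chrom=d["chrom"],
                tss=int(d["tss"]),
                strand=str(d.get("strand", "+")),
                expression=expr,
            )
        )
    return out


def write_genes_tsv(path: PathLike, genes: Sequence[GeneRecord]) -> None:
    cell_types = sorted({c for g in genes for c in g.expression})
    with _open(path, "wt") as fh:
        fh.write("gene_id\tchrom\ttss\tstrand\t" + "\t".join(f"expr_{c}" for c in cell_types) + "\n")
        for g in genes:
            row = [g.gene_id, g.chrom, str(g.tss), g.strand]
            row += [_fmt(g.expression[c]) if c in g.expression else "" for c in cell_types]
            fh.write("\t".join(row) + "\n")


def read_ld_tsv(path: PathLike) -> List[tuple]:
    """LD pair table with columns snp_a, snp_b, r2."""
    df = pd.read_csv(path, sep="\t", dtype={"snp_a": str, "snp_b": str})
    bad = df[(df["r2"] < 0) | (df["r2"] > 1)]
    if len(bad):
        raise ValueError(f"{path}: r2 outside [0,1]")
    return list(df[["snp_a", "snp_b", "r2"]].itertuples(index=False, name=None))


def write_ld_tsv(path: PathLike, pairs: Iterable[tuple]) -> None:
    with _open(path, "wt") as fh:
        fh.write("snp_a\tsnp_b\tr2\n")
        for a, b, r2 in pairs:
            fh.write(f"{a}\t{b}\t{_fmt(r2)}\n")


def read_methylation_tsv(path: PathLike) -> pd.DataFrame:
    """Per-CpG-site beta values: chrom, pos, beta; beta validated in [0,1]."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    if ((df["beta"] < 0) | (df["beta"] > 1)).any():
        raise ValueError(f"{path}: beta outside [0,1]")
    return df


def write_methylation_tsv(path: PathLike, df: pd.DataFrame) -> None:
    with _open(path, "wt") as fh:
        fh.write("chrom\tpos\tbeta\n")
        for row in df.itertuples(index=False):
            fh.write(f"{row.chrom}\t{int(row.pos)}\t{_fmt(row.beta)}\n")


def read_matrix_tsv(path: PathLike, kind: str = "activity"):
    """Read an element-by-column matrix (row index = element ids)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    cls = ActivityMatrix if kind == "activity" else TFBSMatrix
    return cls(df.to_numpy(), [str(i) for i in df.index], [str(c) for c in df.columns])


def write_matrix_tsv(path: PathLike, matrix) -> None:
    with _open(path, "wt") as fh:
        fh.write("element_id\t" + "\t".join(matrix.col_ids) + "\n")
        for rid, row in zip(matrix.row_ids, matrix.values):
            fh.write(rid + "\t" + "\t".join(str(int(v)) for v in row) + "\n")
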