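"""Element annotation: CGI status, TAD geometry, gene linkage,
expression specificity and methylation summaries.

Thresholds follow the conventions used for B-cell regulatory element
analysis: an element is "CGI" when it overlaps a CpG island by more
than 200 bp (strict); TAD sections are measured from the element
midpoint to the nearest TAD boundary, with the boundary band at
<= 20 kb, the shore at (20 kb, 50 kb] and everything farther labeled
center.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Set

import numpy as np
import pandas as pd

from .core import (
    ContactRecord,
    GeneRecord,
    GenomicInterval,
    IntervalIndex,
    SskitError,
    TADSet,
)

logger = logging.getLogger(__name__)

CGI = "CGI"
NON_CGI = "non_CGI"
CGI_MIN_OVERLAP_BP = 200

BOUNDARY = "boundary"
SHORE = "shore"
CENTER = "center"
BOUNDARY_BAND_BP = 20_000
SHORE_BAND_BP = 50_000

DEFAULT_PROMOTER_WINDOW_BP = 2_000


@dataclass(frozen=True)
class TADSectionLabel:
    label: str  # boundary | shore | center
    distance_bp: int
    side: str  # left | right of the nearest boundary


def cgi_class(element: GenomicInterval, cgis: IntervalIndex) -> str:
    """CGI iff the best single CpG-island overlap exceeds 200 bp."""
    return CGI if cgis.max_overlap(element) > CGI_MIN_OVERLAP_BP else NON_CGI


def tad_section(element: GenomicInterval, tads: TADSet) -> Optional[TADSectionLabel]:
    """Classify an element by midpoint distance to the nearest TAD boundary."""
    boundaries = tads.boundaries.get(element.chrom)
    if boundaries is None or len(boundaries) == 0:
        logger.warning("no TADs on %s; element left unassigned", element.chrom)
        return None
    mid = element.midpoint
    i = int(np.searchsorted(boundaries, mid))
    cands = boundaries[max(0, i - 1): i + 1]
    nearest = int(cands[np.argmin(np.abs(cands - mid))])
    d = abs(mid - nearest)
    if d <= BOUNDARY_BAND_BP:
        label = BOUNDARY
    elif d <= SHORE_BAND_BP:
        label = SHORE
    else:
        label = CENTER
    side = "left" if mid < nearest else "right"
    return TADSectionLabel(label=label, distance_bp=int(d), side=side)


def counterpart_shore(
    chrom: str, boundary_pos: int, query_side: str
) -> GenomicInterval:
    """The 20-50 kb shore band on the side opposite to ``query_side``.

    Bands running past the chromosome start are truncated at 0.
    """
    if query_side not in ("left", "right"):
        raise ValueError("query_side must be 'left' or 'right'")
    if query_side == "right":
        start, end = boundary_pos - SHORE_BAND_BP, boundary_pos - BOUNDARY_BAND_BP
        if start < 0:
            logger.warning("counterpart shore truncated at chromosome start")
            start = 0
        if end <= start:
            end = start + 1  # fully truncated band degenerates to 1 bp
    else:
        start, end = boundary_pos + BOUNDARY_BAND_BP, boundary_pos + SHORE_BAND_BP
    return GenomicInterval(chrom, start, end)


def nearest_gene(element: GenomicInterval, genes: Sequence[GeneRecord]) -> Optional[str]:
    """Gene with TSS closest to the element midpoint; ties go to the
    lexicographically smaller gene id (logged)."""
    on_chrom = [g for g in genes if g.chrom == element.chrom]
    if not on_chrom:
        return None
    mid = element.midpoint
    dists = np.asarray([abs(g.tss - mid) for g in on_chrom])
    best = dists.min()
    winners = sorted(g.gene_id for g, d in zip(on_chrom, dists) if d == best)
    if len(winners) > 1:
        logger.info("nearest-gene tie at %s:%d -> %s", element.chrom, int(mid), winners[0])
    return winners[0]


class GeneIndex:
    """Sorted TSS arrays per chromosome for fast nearest-gene lookup."""

    def __init__(self, genes: Sequence[GeneRecord]):
        self._per_chrom: Dict[str, tuple] = {}
        by_chrom: Dict[str, List[GeneRecord]] = {}
        for g in genes:
            by_chrom.setdefault(g.chrom, []).append(g)
        for chrom, gs in by_chrom.items():
            gs.sort(key=lambda g: (g.tss, g.gene_id))
            # genes sharing a TSS are equidistant from everything: keep the
            # lexicographically smallest id, which always wins the tie rule
            dedup: List[GeneRecord] = []
            for g in gs:
                if dedup and dedup[-1].tss == g.tss:
                    continue
                dedup.append(g)
            self._per_chrom[chrom] = (
                np.asarray([g.tss for g in dedup], dtype=np.int64),
                [g.gene_id for g in dedup],
            )

    def nearest(self, element: GenomicInterval) -> Optional[str]:
        entry = self._per_chrom.get(element.chrom)
        if entry is None:
            return None
        tss, ids = entry
        mid = element.midpoint
        i = int(np.searchsorted(tss, mid))
        cands = [k for k in (i - 1, i, i + 1) if 0 <= k < len(tss)]
        best = min(cands, key=lambda k: (abs(tss[k] - mid), ids[k]))
        return ids[best]


def contact_genes(
    element: GenomicInterval,
    contacts: Sequence[ContactRecord],
    genes: Sequence[GeneRecord],
    promoter_window: int = DEFAULT_PROMOTER_WINDOW_BP,
) -> Set[str]:
    """Genes whose promoter sits on the far anchor of a contact whose
    near anchor overlaps the element (>= 1 bp each)."""
    from .core import overlap_bp

    out: Set[str] = set()
    for c in contacts:
        for near, far in ((c.anchor1, c.anchor2), (c.anchor2, c.anchor1)):
            if overlap_bp(near, element) < 1:
                continue
            for g in genes:
                if overlap_bp(g.promoter(promoter_window), far) >= 1:
                    out.add(g.gene_id)
    return out


class ContactGeneLinker:
    """Precomputed contact-to-promoter linkage for batch annotation."""

    def __init__(
        self,
        contacts: Sequence[ContactRecord],
        genes: Sequence[GeneRecord],
        promoter_window: int = DEFAULT_PROMOTER_WINDOW_BP,
    ):
        # anchor -> gene ids whose promoter overlaps it
        prom_by_chrom: Dict[str, List[tuple]] = {}
        for g in genes:
            p = g.promoter(promoter_window)
            prom_by_chrom.setdefault(g.chrom, []).append((p.start, p.end, g.gene_id))
        self._edges: List[tuple] = []  # (anchor_interval, gene_ids_on_far_anchor)
        for c in contacts:
            for near, far in ((c.anchor1, c.anchor2), (c.anchor2, c.anchor1)):
                gids = [
                    gid
                    for (ps, pe, gid) in prom_by_chrom.get(far.chrom, [])
                    if min(pe, far.end) - max(ps, far.start) >= 1
                ]
                if gids:
                    self._edges.append((near, gids))
        self._edge_index = IntervalIndex([e[0] for e in self._edges])
        # group edges per chromosome sorted by start for scanning
        self._by_chrom: Dict[str, List[tuple]] = {}
        for near, gids in self._edges:
            self._by_chrom.setdefault(near.chrom, []).append((near.start, near.end, gids))
        for edges in self._by_chrom.values():
            edges.sort()

    def genes_for(self, element: GenomicInterval) -> Set[str]:
        out: Set[str] = set()
        for start, end, gids in self._by_chrom.get(element.chrom, []):
            if start >= element.end:
                break
            if min(end, element.end) - max(start, element.start) >= 1:
                out.update(gids)
        return out


def tau(expr: Sequence[float]) -> float:
    """Tissue-specificity index in [0, 1]: 0 uniform, 1 single-tissue.

    tau = sum_i (1 - x_i / max(x)) / (N - 1) for non-negative x.
    """
    x = np.asarray(expr, dtype=float)
    if len(x) < 2:
        raise ValueError("tau needs >= 2 tissues")
    if (x < 0).any():
        raise ValueError("tau requires non-negative expression")
    m = x.max()
    if m == 0:
        raise SskitError("tau undefined for an all-zero expression vector")
    return float((1.0 - x / m).sum() / (len(x) - 1))


def mean_methylation(element: GenomicInterval, cpg_meth: pd.DataFrame) -> float:
    """Mean beta of CpG sites inside the element; NaN when no site falls in."""
    sub = cpg_meth[
        (cpg_meth["chrom"] == element.chrom)
        & (cpg_meth["pos"] >= element.start)
        & (cpg_meth["pos"] < element.end)
    ]
    if len(sub) == 0:
        return float("nan")
    return float(sub["beta"].mean())


def annotate_elements(
    elements: Sequence,
    cgis: Optional[Iterable[GenomicInterval]] = None,
    tads: Optional[TADSet] = None,
    contacts: Optional[Sequence[ContactRecord]] = None,
    genes: Optional[Sequence[GeneRecord]] = None,
    cpg_meth: Optional[pd.DataFrame] = None,
    promoter_window: int = DEFAULT_PROMOTER_WINDOW_BP,
) -> pd.DataFrame:
    """One annotation row per element; absent inputs leave NaN columns."""
    cgi_index = IntervalIndex(cgis) if cgis is not None else None
    gene_index = GeneIndex(genes) if genes else None
    linker = (
        ContactGeneLinker(contacts, genes, promoter_window)
        if contacts is not None and genes
        else None
    )
    rows = []
    for e in elements:
        iv = e.interval if hasattr(e, "interval") else e
        eid = getattr(e, "id", f"{iv.chrom}:{iv.start}-{iv.end}")
        row = {"id": eid, "chrom": iv.chrom, "start": iv.start, "end": iv.end}
        if cgi_index is not None:
            row["cgi_class"] = cgi_class(iv, cgi_index)
        if tads is not None:
            sec = tad_section(iv, tads)
            row["tad_section"] = sec.label if sec else ""
            row["tad_boundary_distance_bp"] = sec.distance_bp if sec else np.nan
        if gene_index is not None:
            row["nearest_gene"] = gene_index.nearest(iv)
        if linker is not None:
            row["contact_genes"] = ";".join(sorted(linker.genes_for(iv)))
        if cpg_meth is not None:
            row["mean_methylation"] = mean_methylation(iv, cpg_meth)
        rows.append(row)
    return pd.DataFrame(rows)


def gene_tau_table(genes: Sequence[GeneRecord]) -> pd.DataFrame:
    """Per-gene tau over the cell types with expression values."""
    rows = []
    for g in genes:
        if len(g.expression) < 2:
            continue
        vals = np.asarray(list(g.expression.values()), dtype=float)
        vals = np.clip(vals, 0, None)
        if vals.max() == 0:
            continue
        rows.append({"gene_id": g.gene_id, "tau": tau(vals)})
    return pd.DataFrame(rows)
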