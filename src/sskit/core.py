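"""Domain types and genomic-interval algebra.

Every analysis in this package operates on a small set of containers:
regulatory elements (silencers/enhancers with per-mark ChIP signal),
stitched super regions, ternary activity and binary TF-occupancy
matrices, variant records, TAD sets, chromatin contacts and gene
models.  Coordinates are 0-based half-open throughout, matching BED.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

SILENCER = "silencer"
ENHANCER = "enhancer"


class SskitError(Exception):
    """Base class for errors raised by this package."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open genomic interval [start, end) on a named chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"require 0 <= start < end, got [{self.start}, {self.end})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2.0


@dataclass(frozen=True)
class RegulatoryElement:
    """A silencer or enhancer call with per-mark signal levels."""

    id: str
    interval: GenomicInterval
    element_class: str
    signal: Mapping[str, float] = field(default_factory=dict)
    cell_type: str = ""

    def __post_init__(self) -> None:
        if self.element_class not in (SILENCER, ENHANCER):
            raise ValueError(f"unknown element_class {self.element_class!r}")
        for mark, value in self.signal.items():
            if value < 0:
                raise ValueError(f"negative signal {value} for mark {mark!r} on {self.id}")


@dataclass
class SuperRegion:
    """A stitched cluster of elements with aggregate signal and rank.

    ``rank`` is 1-based ascending by total signal; ``is_super`` is None
    until a cutoff has been applied.
    """

    interval: GenomicInterval
    constituent_ids: Tuple[str, ...]
    total_signal: float = 0.0
    rank: Optional[int] = None
    is_super: Optional[bool] = None

    @property
    def n_constituents(self) -> int:
        return len(self.constituent_ids)


@dataclass(frozen=True)
class VariantRecord:
    """A point variant (SNV/SNP) or translocation breakpoint (TLBP)."""

    position: GenomicInterval
    vtype: str  # SNV | SNP | TLBP
    categories: FrozenSet[str] = frozenset()
    sample_ids: FrozenSet[str] = frozenset()
    study_ids: FrozenSet[str] = frozenset()
    partner: Optional[GenomicInterval] = None
    id: str = ""

    def __post_init__(self) -> None:
        if self.vtype not in ("SNV", "SNP", "TLBP"):
            raise ValueError(f"unknown vtype {self.vtype!r}")


@dataclass(frozen=True)
class ContactRecord:
    """A chromatin contact between two equal-width bins on one chromosome."""

    anchor1: GenomicInterval
    anchor2: GenomicInterval
    cell_type: str = ""

    def __post_init__(self) -> None:
        if self.anchor1.chrom != self.anchor2.chrom:
            raise ValueError("contact anchors must share a chromosome")


@dataclass(frozen=True)
class GeneRecord:
    """A gene model reduced to its TSS, strand and per-cell-type expression."""

    gene_id: str
    chrom: str
    tss: int
    strand: str = "+"
    expression: Mapping[str, float] = field(default_factory=dict)

    def promoter(self, window: int = 2000) -> GenomicInterval:
        """Window of +/- ``window`` bp around the TSS, clipped at 0."""
        return GenomicInterval(self.chrom, max(0, self.tss - window), self.tss + window)


class TADSet:
    """Non-overlapping TADs per chromosome with derived boundary positions."""

    def __init__(self, tads: Iterable[GenomicInterval]):
        self.tads: List[GenomicInterval] = sorted(tads)
        by_chrom: Dict[str, List[GenomicInterval]] = {}
        for t in self.tads:
            by_chrom.setdefault(t.chrom, []).append(t)
        self.boundaries: Dict[str, np.ndarray] = {}
        for chrom, ts in by_chrom.items():
            prev_end = -1
            for t in ts:
                if t.start < prev_end:
                    raise ValueError(f"overlapping TADs on {chrom} near {t.start}")
                prev_end = t.end
            pos = sorted({p for t in ts for p in (t.start, t.end)})
            self.boundaries[chrom] = np.asarray(pos, dtype=np.int64)

    def __len__(self) -> int:
        return len(self.tads)


class _TernaryOrBinaryMatrix:
    def __init__(self, values, row_ids: Sequence[str], col_ids: Sequence[str], allowed):
        arr = np.asarray(values)
        if arr.shape != (len(row_ids), len(col_ids)):
            raise ValueError("matrix dimensions inconsistent with labels")
        if not np.isin(arr, allowed).all():
            raise ValueError(f"matrix entries must be in {sorted(allowed)}")
        self.values = arr.astype(np.int8)
        self.row_ids = list(row_ids)
        self.col_ids = list(col_ids)
        self._row_index = {r: i for i, r in enumerate(self.row_ids)}

    def row(self, element_id: str) -> np.ndarray:
        return self.values[self._row_index[element_id]]

    def __contains__(self, element_id: str) -> bool:
        return element_id in self._row_index

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.row_ids, columns=self.col_ids)


class ActivityMatrix(_TernaryOrBinaryMatrix):
    """Element x cell-type ternary activity: 1 active, -1 repressed, 0 uncertain."""

    def __init__(self, values, element_ids, cell_types):
        super().__init__(values, element_ids, cell_types, (-1, 0, 1))

    @property
    def element_ids(self):
        return self.row_ids

    @property
    def cell_types(self):
        return self.col_ids


class TFBSMatrix(_TernaryOrBinaryMatrix):
    """Element x TF binary occupancy from ChIP-seq peak overlap."""

    def __init__(self, values, element_ids, tf_names):
        super().__init__(values, element_ids, tf_names, (0, 1))

    @property
    def element_ids(self):
        return self.row_ids

    @property
    def tf_names(self):
        return self.col_ids


# ---------------------------------------------------------------------------
# Interval algebra
# ---------------------------------------------------------------------------

def overlap_bp(a: GenomicInterval, b: GenomicInterval) -> int:
    """Number of shared bases between two intervals (0 across chromosomes)."""
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def merge_intervals(intervals: Iterable[GenomicInterval]) -> List[GenomicInterval]:
    """Union of intervals as a sorted list of disjoint intervals."""
    out: List[GenomicInterval] = []
    for iv in sorted(intervals):
        if out and iv.chrom == out[-1].chrom and iv.start <= out[-1].end:
            if iv.end > out[-1].end:
                out[-1] = GenomicInterval(iv.chrom, out[-1].start, iv.end)
        else:
            out.append(iv)
    return out


def total_bp(intervals: Iterable[GenomicInterval]) -> int:
    """Total base-pair footprint of the union of ``intervals``."""
    return sum(iv.length for iv in merge_intervals(intervals))


class IntervalIndex:
    """Sorted per-chromosome index supporting fast max-overlap queries.

    Built once from a target interval set; queries are O(log n + k)
    using a running-maximum on interval ends to bound the candidate
    slice.
    """

    def __init__(self, intervals: Iterable[GenomicInterval]):
        self._per_chrom: Dict[str, Tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        by_chrom: Dict[str, List[GenomicInterval]] = {}
        self.n = 0
        for iv in intervals:
            by_chrom.setdefault(iv.chrom, []).append(iv)
            self.n += 1
        for chrom, ivs in by_chrom.items():
            ivs.sort(key=lambda v: (v.start, v.end))
            starts = np.asarray([v.start for v in ivs], dtype=np.int64)
            ends = np.asarray([v.end for v in ivs], dtype=np.int64)
            self._per_chrom[chrom] = (starts, ends, np.maximum.accumulate(ends))

    def max_overlap(self, iv: GenomicInterval) -> int:
        """Largest single-interval overlap (bp) between ``iv`` and the index."""
        entry = self._per_chrom.get(iv.chrom)
        if entry is None:
            return 0
        starts, ends, max_ends = entry
        hi = int(np.searchsorted(starts, iv.end, side="left"))
        lo = int(np.searchsorted(max_ends[:hi], iv.start, side="right"))
        if lo >= hi:
            return 0
        ov = np.minimum(ends[lo:hi], iv.end) - np.maximum(starts[lo:hi], iv.start)
        best = int(ov.max())
        return max(best, 0)

    def overlaps(self, iv: GenomicInterval, min_bp: int = 1) -> bool:
        return self.max_overlap(iv) >= min_bp

    def contains_point(self, chrom: str, pos: int) -> bool:
        return self.max_overlap(GenomicInterval(chrom, pos, pos + 1)) >= 1


def fraction_overlapping(
    set_a: Sequence,
    set_b: Iterable[GenomicInterval],
    min_bp: int = 1,
) -> float:
    """Fraction of ``set_a`` whose best single-interval overlap with
    ``set_b`` reaches ``min_bp``.

    ``set_a`` may hold intervals or objects carrying an ``interval``
    attribute (e.g. :class:`RegulatoryElement`).
    """
    if min_bp < 1:
        raise ValueError("min_bp must be >= 1")
    items = list(set_a)
    if not items:
        raise SskitError("fraction_overlapping undefined for empty set_a")
    index = IntervalIndex(set_b)
    hits = sum(
        1 for item in items if index.max_overlap(_as_interval(item)) >= min_bp
    )
    return hits / len(items)


def _as_interval(item) -> GenomicInterval:
    if isinstance(item, GenomicInterval):
        return item
    return item.interval


def elements_by_id(elements: Iterable[RegulatoryElement]) -> Dict[str, RegulatoryElement]:
    out: Dict[str, RegulatoryElement] = {}
    for e in elements:
        if e.id in out:
            raise ValueError(f"duplicate element id {e.id!r}")
        out[e.id] = e
    return out
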