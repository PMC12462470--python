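"""Super-silencer / super-enhancer calling.

Elements on each chromosome are stitched into regions whenever the
end-to-start gap is at most ``gap_bp`` (default 12,500 bp, the
classical rank-ordering convention for super-enhancer detection).
Region totals (the sum of constituent signal for the chosen histone
mark, H3K27me3 for silencers or H3K27ac for enhancers) are rank
ordered ascending, both axes are scaled to the unit square, and the
cutoff rank is the point farthest below the diagonal — the discrete
analogue of the slope-1 tangent.  Regions whose total is strictly
greater than the total at the cutoff rank are "super"; their
constituents become components, everything else stays typical.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .core import (
    GenomicInterval,
    RegulatoryElement,
    SskitError,
    SuperRegion,
    elements_by_id,
)

DEFAULT_GAP_BP = 12_500

NO_SUPERS = -1  # sentinel returned by find_cutoff for degenerate curves


@dataclass
class RankCurve:
    """Ascending region totals with unit-square scaled coordinates."""

    sorted_totals: np.ndarray
    x_scaled: np.ndarray
    y_scaled: np.ndarray

    @classmethod
    def from_totals(cls, totals: Sequence[float]) -> "RankCurve":
        t = np.sort(np.asarray(totals, dtype=float))
        n = len(t)
        if n < 2:
            x = np.zeros(n)
            y = np.zeros(n)
        else:
            x = np.arange(n, dtype=float) / (n - 1)
            span = t[-1] - t[0]
            y = (t - t[0]) / span if span > 0 else np.zeros(n)
        return cls(sorted_totals=t, x_scaled=x, y_scaled=y)

    def __len__(self) -> int:
        return len(self.sorted_totals)


def stitch(elements: Sequence[RegulatoryElement], gap_bp: int = DEFAULT_GAP_BP) -> List[SuperRegion]:
    """Merge same-chromosome elements within ``gap_bp`` into regions.

    The input must come from a single chromosome; regions span the
    min start to max end of their constituents, and every element
    lands in exactly one region.
    """
    if gap_bp < 0:
        raise ValueError("gap_bp must be >= 0")
    if not elements:
        return []
    chroms = {e.interval.chrom for e in elements}
    if len(chroms) > 1:
        raise SskitError(f"stitch requires one chromosome, got {sorted(chroms)}")
    ordered = sorted(elements, key=lambda e: (e.interval.start, e.interval.end))
    regions: List[SuperRegion] = []
    cur_ids = [ordered[0].id]
    cur_start, cur_end = ordered[0].interval.start, ordered[0].interval.end
    chrom = ordered[0].interval.chrom
    for e in ordered[1:]:
        if e.interval.start - cur_end <= gap_bp:
            cur_ids.append(e.id)
            cur_end = max(cur_end, e.interval.end)
        else:
            regions.append(
                SuperRegion(GenomicInterval(chrom, cur_start, cur_end), tuple(cur_ids))
            )
            cur_ids = [e.id]
            cur_start, cur_end = e.interval.start, e.interval.end
    regions.append(SuperRegion(GenomicInterval(chrom, cur_start, cur_end), tuple(cur_ids)))
    return regions


def aggregate_signal(
    region: SuperRegion,
    elements: Dict[str, RegulatoryElement],
    mark: str,
    background_mark: Optional[str] = None,
) -> float:
    """Sum of constituent signal for ``mark``.

    When ``background_mark`` is given, each constituent contributes
    max(0, signal - background) instead.
    """
    total = 0.0
    for eid in region.constituent_ids:
        e = elements[eid]
        if mark not in e.signal:
            raise SskitError(f"element {eid!r} lacks mark {mark!r}")
        value = e.signal[mark]
        if background_mark is not None:
            value = max(0.0, value - e.signal.get(background_mark, 0.0))
        total += value
    return total


def find_cutoff(curve: RankCurve) -> int:
    """Index (0-based, ascending order) of the rank farthest below the
    unit-square diagonal, i.e. argmax of (x_scaled - y_scaled).

    Ties break toward the higher rank (fewer supers).  Returns
    :data:`NO_SUPERS` when the curve is degenerate (all totals equal
    or fewer than 3 regions).
    """
    n = len(curve)
    if n < 3 or curve.sorted_totals[-1] <= curve.sorted_totals[0]:
        return NO_SUPERS
    gap = curve.x_scaled - curve.y_scaled
    best = float(gap.max())
    # highest rank among the ties
    return int(np.nonzero(gap == best)[0][-1])


def call_super_elements(
    elements: Sequence[RegulatoryElement],
    mark: str = "H3K27me3",
    gap_bp: int = DEFAULT_GAP_BP,
    background_mark: Optional[str] = None,
) -> Tuple[List[SuperRegion], List[RegulatoryElement], List[RegulatoryElement]]:
    """Full calling pass: stitch, aggregate, rank, cut.

    Returns ``(regions, components, typicals)`` where components are
    the constituents of super regions and typicals everything else;
    the two lists partition the input.
    """
    if not elements:
        raise SskitError("no elements to call on")
    by_id = elements_by_id(elements)
    by_chrom: Dict[str, List[RegulatoryElement]] = {}
    for e in elements:
        by_chrom.setdefault(e.interval.chrom, []).append(e)
    regions: List[SuperRegion] = []
    for chrom in sorted(by_chrom):
        regions.extend(stitch(by_chrom[chrom], gap_bp))
    for r in regions:
        r.total_signal = aggregate_signal(r, by_id, mark, background_mark)

    order = np.argsort([r.total_signal for r in regions], kind="stable")
    for rank0, idx in enumerate(order):
        regions[idx].rank = rank0 + 1

    curve = RankCurve.from_totals([r.total_signal for r in regions])
    cut = find_cutoff(curve)
    if cut == NO_SUPERS:
        threshold = np.inf
    else:
        threshold = curve.sorted_totals[cut]
    for r in regions:
        r.is_super = r.total_signal > threshold

    component_ids = {eid for r in regions if r.is_super for eid in r.constituent_ids}
    components = [e for e in elements if e.id in component_ids]
    typicals = [e for e in elements if e.id not in component_ids]
    return regions, components, typicals
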