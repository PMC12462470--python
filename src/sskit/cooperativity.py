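"""Cooperativity among components of the same super region.

Two complementary similarity measures are used.  Activity
cooperativity is the cosine similarity of ternary activity vectors
across a panel of cell types, where an element is coded 1 when it
overlaps an H3K27ac peak only, -1 with an H3K27me3 peak only, and 0
when it overlaps both (uncertain) or neither (no evidence):

    coop(i, j) = sum_k a_ik a_jk / (||a_i|| ||a_j||)

TF-binding similarity is the Jaccard index of the binary occupancy
vectors over the TF panel.  Within-region pairs are compared against
two backgrounds: typical elements paired at matching midpoint
distances, and typical elements paired at random.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .core import (
    GenomicInterval,
    IntervalIndex,
    RegulatoryElement,
    SskitError,
    SuperRegion,
    TFBSMatrix,
)

logger = logging.getLogger(__name__)

WITHIN_REGION = "within_region"
MATCHED_BACKGROUND = "matched_background"
RANDOM_BACKGROUND = "random_background"

DEFAULT_BIN_WIDTH_BP = 10_000


@dataclass(frozen=True)
class PairSample:
    """An element pair with its midpoint distance and sampling group."""

    pair: Tuple[str, str]
    distance_bp: int
    group: str

    def __post_init__(self) -> None:
        if self.pair[0] == self.pair[1]:
            raise ValueError("pair members must differ")


def ternary_activity(
    element: GenomicInterval,
    ac_peaks: IntervalIndex,
    me3_peaks: IntervalIndex,
) -> int:
    """Ternary activity of an element in one cell type.

    1 = H3K27ac only, -1 = H3K27me3 only, 0 = both marks (uncertain)
    or neither (no evidence).  Overlap criterion is >= 1 bp.
    """
    has_ac = ac_peaks.overlaps(element)
    has_me3 = me3_peaks.overlaps(element)
    if has_ac and not has_me3:
        return 1
    if has_me3 and not has_ac:
        return -1
    return 0


def cooperativity_score(a_i: Sequence[int], a_j: Sequence[int]) -> float:
    """Cosine similarity of two ternary activity vectors in [-1, 1]."""
    x = np.asarray(a_i, dtype=float)
    y = np.asarray(a_j, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 1:
        raise ValueError("vectors must be 1-D and of equal length >= 1")
    nx = np.sqrt((x * x).sum())
    ny = np.sqrt((y * y).sum())
    if nx == 0 or ny == 0:
        raise SskitError("cooperativity undefined for an all-zero activity vector")
    return float((x * y).sum() / (nx * ny))


def tfbs_similarity(t_i: Sequence[int], t_j: Sequence[int]) -> float:
    """Jaccard similarity of two binary TF-occupancy vectors in [0, 1].

    Two empty profiles share no binding and score 0.
    """
    x = np.asarray(t_i, dtype=bool)
    y = np.asarray(t_j, dtype=bool)
    if x.shape != y.shape:
        raise ValueError("vectors must be of equal length")
    union = int((x | y).sum())
    if union == 0:
        return 0.0
    return float((x & y).sum() / union)


def within_region_pairs(regions: Sequence[SuperRegion], elements: Dict[str, RegulatoryElement]) -> List[PairSample]:
    """All component pairs sharing a super region, with midpoint distances."""
    out: List[PairSample] = []
    for r in regions:
        if r.is_super is False:
            continue
        ids = list(r.constituent_ids)
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                d = abs(
                    elements[ids[i]].interval.midpoint
                    - elements[ids[j]].interval.midpoint
                )
                out.append(PairSample((ids[i], ids[j]), int(d), WITHIN_REGION))
    return out


def _candidate_pairs(pool: Sequence[RegulatoryElement], max_distance: float):
    """Same-chromosome pool pairs with midpoint distance <= max_distance."""
    by_chrom: Dict[str, List[RegulatoryElement]] = {}
    for e in pool:
        by_chrom.setdefault(e.interval.chrom, []).append(e)
    pairs = []
    dists = []
    for es in by_chrom.values():
        es.sort(key=lambda e: e.interval.midpoint)
        mids = np.asarray([e.interval.midpoint for e in es])
        for i in range(len(es)):
            hi = int(np.searchsorted(mids, mids[i] + max_distance, side="right"))
            for j in range(i + 1, hi):
                pairs.append((es[i].id, es[j].id))
                dists.append(mids[j] - mids[i])
    return pairs, np.asarray(dists, dtype=float)


def matched_background_pairs(
    target_distances: Sequence[int],
    pool: Sequence[RegulatoryElement],
    n_pairs: int,
    bin_width_bp: int = DEFAULT_BIN_WIDTH_BP,
    seed: int = 0,
) -> List[PairSample]:
    """Sample pool pairs whose distance histogram matches the target.

    Target distances are binned at ``bin_width_bp``; the per-bin demand
    is proportional to the target histogram and filled by sampling
    candidate pool pairs without replacement within each bin.  Demand
    that cannot be met in a bin is redistributed to the remaining
    occupied bins with a warning.  Deterministic for a given seed.
    """
    if not pool:
        raise SskitError("empty background pool")
    target = np.asarray(target_distances, dtype=float)
    if len(target) == 0:
        raise SskitError("no target distances")
    rng = np.random.default_rng(seed)
    max_d = float(target.max()) + bin_width_bp
    pairs, dists = _candidate_pairs(pool, max_d)
    if not pairs:
        raise SskitError("background pool yields no candidate pairs in range")

    t_bins = (target // bin_width_bp).astype(int)
    c_bins = (dists // bin_width_bp).astype(int)
    bin_ids, bin_counts = np.unique(t_bins, return_counts=True)
    # largest-remainder allocation of n_pairs across occupied bins
    quota = bin_counts / bin_counts.sum() * n_pairs
    demand = np.floor(quota).astype(int)
    remainder_order = np.argsort(-(quota - demand), kind="stable")
    for k in remainder_order[: n_pairs - demand.sum()]:
        demand[k] += 1

    candidates_by_bin = {b: np.nonzero(c_bins == b)[0] for b in bin_ids}
    chosen: List[int] = []
    shortfall = 0
    for b, want in zip(bin_ids, demand):
        avail = candidates_by_bin.get(b, np.empty(0, dtype=int))
        take = min(want, len(avail))
        if take < want:
            shortfall += want - take
        if take:
            chosen.extend(rng.choice(avail, size=take, replace=False).tolist())
    if shortfall:
        warnings.warn(
            f"{shortfall} pair(s) redistributed: some distance bins lacked candidates",
            stacklevel=2,
        )
        used = set(chosen)
        leftovers = [i for b in bin_ids for i in candidates_by_bin.get(b, []) if i not in used]
        extra = min(shortfall, len(leftovers))
        if extra:
            chosen.extend(
                rng.choice(np.asarray(leftovers), size=extra, replace=False).tolist()
            )
    return [
        PairSample(pairs[i], int(dists[i]), MATCHED_BACKGROUND) for i in sorted(chosen)
    ]


def random_background_pairs(
    pool: Sequence[RegulatoryElement],
    n_pairs: int,
    seed: int = 0,
    max_distance_bp: int = 10_000_000,
) -> List[PairSample]:
    """Uniformly random same-chromosome pool pairs (no distance matching)."""
    if not pool:
        raise SskitError("empty background pool")
    rng = np.random.default_rng(seed)
    pairs, dists = _candidate_pairs(pool, max_distance_bp)
    if not pairs:
        raise SskitError("background pool yields no candidate pairs")
    take = min(n_pairs, len(pairs))
    idx = rng.choice(len(pairs), size=take, replace=False)
    return [PairSample(pairs[i], int(dists[i]), RANDOM_BACKGROUND) for i in sorted(idx)]


def score_pairs(
    pairs: Iterable[PairSample],
    activity=None,
    tfbs: Optional[TFBSMatrix] = None,
) -> "pd.DataFrame":
    """Per-pair activity cooperativity and TFBS similarity table.

    Pairs whose activity vector is all-zero are excluded from the
    cosine score (logged), mirroring the undefined-similarity rule.
    """
    import pandas as pd

    rows = []
    n_excluded = 0
    for p in pairs:
        i, j = p.pair
        coop = np.nan
        if activity is not None and i in activity and j in activity:
            try:
                coop = cooperativity_score(activity.row(i), activity.row(j))
            except SskitError:
                n_excluded += 1
        sim = np.nan
        if tfbs is not None and i in tfbs and j in tfbs:
            sim = tfbs_similarity(tfbs.row(i), tfbs.row(j))
        rows.append(
            {
                "id_a": i,
                "id_b": j,
                "group": p.group,
                "distance_bp": p.distance_bp,
                "cooperativity": coop,
                "tfbs_similarity": sim,
            }
        )
    if n_excluded:
        logger.info("excluded %d pair(s) with all-zero activity vectors", n_excluded)
    return pd.DataFrame(rows)


def shared_tf_fraction(region: SuperRegion, tfbs: TFBSMatrix) -> float:
    """Fraction of the TF panel bound in at least two constituents."""
    ids = [i for i in region.constituent_ids if i in tfbs]
    if len(ids) < 2:
        raise SskitError("shared_tf_fraction needs >= 2 constituents with TFBS rows")
    sub = np.stack([tfbs.row(i) for i in ids])
    return float((sub.sum(axis=0) >= 2).sum() / sub.shape[1])


def group_comparison(scores: "pd.DataFrame", value: str = "cooperativity"):
    """Median by group plus one-sided Wilcoxon rank-sum p-values of
    within-region vs each background (greater alternative)."""
    import pandas as pd

    out = []
    within = scores.loc[scores["group"] == WITHIN_REGION, value].dropna()
    for group, sub in scores.groupby("group"):
        vals = sub[value].dropna()
        p = np.nan
        if group != WITHIN_REGION and len(vals) and len(within):
            p = stats.mannwhitneyu(within, vals, alternative="greater").pvalue
        out.append(
            {"group": group, "metric": value, "n": len(vals), "median": vals.median(), "p_vs_within": p}
        )
    return pd.DataFrame(out)
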