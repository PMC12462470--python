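"""Functional conversion of normal-cell elements into cancer
super-elements across patient samples.

An element "converts" (e.g. SS-to-SE) when it overlaps a cancer SE
region in at least one patient sample; a conversion is "recurrent
over half" when it hits strictly more than half of the sample
universe.  Contact retention measures how many chromatin contacts
anchored at an element set persist, bin-for-bin, between two
conditions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import FrozenSet, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .core import (
    ContactRecord,
    GenomicInterval,
    IntervalIndex,
    SskitError,
    _as_interval,
)

DEFAULT_BIN_BP = 10_000


@dataclass(frozen=True)
class ConversionRecord:
    element_id: str
    direction: str  # SS_to_SE | SE_to_SS | TS_to_SE | TE_to_SS
    samples_hit: FrozenSet[str]
    n_samples_total: int

    @property
    def recurrent_over_half(self) -> bool:
        return len(self.samples_hit) > self.n_samples_total / 2


def detect_conversions(
    elements: Sequence,
    cancer_regions_by_sample: Mapping[str, Sequence[GenomicInterval]],
    min_bp: int = 1,
    direction: str = "SS_to_SE",
    contained: bool = False,
) -> List[ConversionRecord]:
    """Elements overlapping a cancer region by >= min_bp in >= 1 sample.

    With ``contained`` true the element must lie fully inside a cancer
    region instead of merely overlapping it.
    """
    if not cancer_regions_by_sample:
        raise SskitError("empty cancer sample map")
    if min_bp < 1:
        raise ValueError("min_bp must be >= 1")
    indexes = {
        sample: IntervalIndex(regions)
        for sample, regions in sorted(cancer_regions_by_sample.items())
    }
    n_total = len(indexes)
    out: List[ConversionRecord] = []
    for e in elements:
        iv = _as_interval(e)
        eid = getattr(e, "id", f"{iv.chrom}:{iv.start}-{iv.end}")
        need = iv.length if contained else min_bp
        hits = frozenset(
            sample for sample, idx in indexes.items() if idx.max_overlap(iv) >= need
        )
        if hits:
            out.append(ConversionRecord(eid, direction, hits, n_total))
    return out


def recurrence_summary(
    records: Sequence[ConversionRecord], universe_size: int
) -> Tuple[float, Optional[float]]:
    """(converted_fraction, recurrent_over_half_fraction among converted).

    The recurrence fraction is None when nothing converted.
    """
    if universe_size <= 0:
        raise SskitError("universe_size must be positive")
    if len(records) > universe_size:
        raise ValueError("more conversion records than elements in the universe")
    converted_fraction = len(records) / universe_size
    if not records:
        return converted_fraction, None
    recurrent = sum(1 for r in records if r.recurrent_over_half)
    return converted_fraction, recurrent / len(records)


def _bin_pair(c: ContactRecord, bin_bp: int) -> Tuple[str, int, int]:
    b1 = (c.anchor1.start // bin_bp) * bin_bp
    b2 = (c.anchor2.start // bin_bp) * bin_bp
    if b2 < b1:
        b1, b2 = b2, b1
    return (c.anchor1.chrom, b1, b2)


def contact_retention(
    contacts_a: Sequence[ContactRecord],
    contacts_b: Sequence[ContactRecord],
    elements: Sequence,
    bin_bp: int = DEFAULT_BIN_BP,
) -> float:
    """Fraction of element-anchored contacts in A with an identical
    bin pair present in B.

    Both sets are re-binned at ``bin_bp``; identity requires the same
    chromosome and both anchor bin starts to match (anchor order
    ignored).
    """
    index = IntervalIndex(_as_interval(e) for e in elements)
    qualifying = [
        c
        for c in contacts_a
        if index.max_overlap(c.anchor1) >= 1 or index.max_overlap(c.anchor2) >= 1
    ]
    if not qualifying:
        raise SskitError("no contacts in A anchored at the element set")
    b_keys = {_bin_pair(c, bin_bp) for c in contacts_b}
    kept = sum(1 for c in qualifying if _bin_pair(c, bin_bp) in b_keys)
    return kept / len(qualifying)


def retention_null(
    contacts_a: Sequence[ContactRecord],
    contacts_b: Sequence[ContactRecord],
    elements: Sequence,
    pool: Sequence,
    n_permutations: int = 1000,
    bin_bp: int = DEFAULT_BIN_BP,
    seed: int = 0,
) -> np.ndarray:
    """Null distribution of retention from label shuffling.

    Each permutation draws |elements| intervals from ``pool`` (the
    matched candidate set, e.g. all elements of the same class) and
    recomputes retention; returns the vector of null retentions,
    skipping permutations with no qualifying contacts.
    """
    rng = np.random.default_rng(seed)
    pool_ivs = [_as_interval(e) for e in pool]
    k = min(len(elements), len(pool_ivs))
    if k == 0:
        raise SskitError("empty pool or element set")
    out = []
    for _ in range(n_permutations):
        idx = rng.choice(len(pool_ivs), size=k, replace=False)
        sample = [pool_ivs[i] for i in idx]
        try:
            out.append(contact_retention(contacts_a, contacts_b, sample, bin_bp))
        except SskitError:
            continue
    return np.asarray(out)
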