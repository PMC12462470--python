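"""Variant enrichment statistics over regulatory element sets.

Covers SNV/SNP density per kb on merged element footprints,
category-fraction enrichment (e.g. the fraction of B-cell-cancer SNVs
among all cancer SNVs inside a set, compared against a reference
fraction with a two-sided binomial test), GWAS LD expansion at
r^2 > 0.8, replicated-SNP and recurrent-SNV fractions, translocation
partner classification, and cross-cell-type element-set Jaccard
indices.  No multiple-testing adjustment is applied anywhere.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
from scipy import stats

from .core import (
    GenomicInterval,
    IntervalIndex,
    SskitError,
    VariantRecord,
    merge_intervals,
    total_bp,
    _as_interval,
)

DEFAULT_LD_THRESHOLD = 0.8
DEFAULT_FLANK_BP = 50_000


@dataclass
class EnrichmentResult:
    set_name: str
    count: int
    density_per_kb: float
    category_fraction: float
    fold_vs_reference: float
    p_value: float


def variants_in_set(
    variants: Sequence[VariantRecord], elements: Iterable[GenomicInterval]
) -> List[VariantRecord]:
    """Variants whose breakpoint/position lies in the merged element set."""
    index = IntervalIndex(merge_intervals(_as_interval(e) for e in elements))
    return [v for v in variants if index.contains_point(v.position.chrom, v.position.start)]


def density_per_kb(
    variants: Sequence[VariantRecord], elements: Sequence
) -> float:
    """Variant positions per kb of the merged element footprint."""
    merged = merge_intervals(_as_interval(e) for e in elements)
    length = sum(iv.length for iv in merged)
    if length == 0:
        raise SskitError("zero total element length")
    hits = len(variants_in_set(variants, merged))
    return hits / (length / 1000.0)


def category_fraction(variants_in: Sequence[VariantRecord], category: str) -> float:
    """Fraction of the given variants carrying the category tag."""
    if not variants_in:
        raise SskitError("category_fraction undefined on an empty variant list")
    k = sum(1 for v in variants_in if category in v.categories)
    return k / len(variants_in)


def enrichment_fold(
    set_fraction: float, reference_fraction: float, n_in_set: int
) -> Tuple[float, float]:
    """Fold over a reference fraction and a two-sided binomial p-value.

    The test treats k = round(set_fraction * n_in_set) tagged variants
    among n_in_set as binomial draws at the reference probability.
    """
    if not (0.0 < reference_fraction < 1.0):
        raise ValueError("reference_fraction must be in (0, 1)")
    if n_in_set < 1:
        raise ValueError("n_in_set must be >= 1")
    fold = set_fraction / reference_fraction
    k = int(round(set_fraction * n_in_set))
    p = stats.binomtest(k, n_in_set, reference_fraction, alternative="two-sided").pvalue
    return fold, float(p)


def density_fold(
    variants: Sequence[VariantRecord],
    set_a: Sequence,
    set_b: Sequence,
    alpha: float = 0.05,
) -> Tuple[float, float, float]:
    """Density ratio of set_a over set_b with a (1 - alpha) CI.

    Conditional on the total count, hits in A are binomial with
    p = L_a·f / (L_a·f + L_b); a Clopper-Pearson interval on p maps to
    an exact interval on the fold f = (p / (1-p)) · (L_b / L_a).
    """
    ivs_a = merge_intervals(_as_interval(e) for e in set_a)
    ivs_b = merge_intervals(_as_interval(e) for e in set_b)
    la, lb = total_bp(ivs_a), total_bp(ivs_b)
    if la == 0 or lb == 0:
        raise SskitError("zero-length element set")
    k = len(variants_in_set(variants, ivs_a))
    m = len(variants_in_set(variants, ivs_b))
    n = k + m
    if n == 0 or m == 0:
        raise SskitError("no variants in either set, or none in the reference")
    fold = (k / la) / (m / lb)
    p_lo = stats.beta.ppf(alpha / 2, k, n - k + 1) if k > 0 else 0.0
    p_hi = stats.beta.ppf(1 - alpha / 2, k + 1, n - k) if k < n else 1.0
    ratio = lb / la
    lo = (p_lo / (1 - p_lo)) * ratio if p_lo < 1 else np.inf
    hi = (p_hi / (1 - p_hi)) * ratio if p_hi < 1 else np.inf
    return float(fold), float(lo), float(hi)


def flanks(
    elements: Sequence, flank_bp: int = DEFAULT_FLANK_BP
) -> List[GenomicInterval]:
    """±flank_bp proximity regions, excluding the element footprint itself."""
    ivs = [_as_interval(e) for e in elements]
    widened = merge_intervals(
        GenomicInterval(iv.chrom, max(0, iv.start - flank_bp), iv.end + flank_bp)
        for iv in ivs
    )
    footprint = merge_intervals(ivs)
    out: List[GenomicInterval] = []
    by_chrom: Dict[str, List[GenomicInterval]] = {}
    for iv in footprint:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    for w in widened:
        cursor = w.start
        for f in by_chrom.get(w.chrom, []):
            if f.end <= w.start or f.start >= w.end:
                continue
            if f.start > cursor:
                out.append(GenomicInterval(w.chrom, cursor, f.start))
            cursor = max(cursor, f.end)
        if cursor < w.end:
            out.append(GenomicInterval(w.chrom, cursor, w.end))
    return out


def ld_expand(
    seed_snps: Set[str],
    ld_pairs: Iterable[Tuple[str, str, float]],
    threshold: float = DEFAULT_LD_THRESHOLD,
) -> Set[str]:
    """Single-pass LD expansion: seeds plus partners of any pair with
    one end in the seed set and r^2 strictly above the threshold."""
    if not (0.0 < threshold < 1.0):
        raise ValueError("threshold must be in (0, 1)")
    out = set(seed_snps)
    for a, b, r2 in ld_pairs:
        if r2 > threshold:
            if a in seed_snps:
                out.add(b)
            if b in seed_snps:
                out.add(a)
    return out


def replicated_fraction(
    snp_to_studies: Mapping[str, Set[str]], trait_filter: Optional[str] = None
) -> float:
    """Fraction of SNPs reported by >= 2 distinct studies.

    When ``trait_filter`` is given the mapping is expected to already
    be restricted to that trait class; it is accepted for symmetry
    with variant tables carrying per-trait study sets.
    """
    if not snp_to_studies:
        raise SskitError("replicated_fraction undefined on an empty map")
    k = sum(1 for studies in snp_to_studies.values() if len(studies) >= 2)
    return k / len(snp_to_studies)


def recurrent_fraction(snv_to_samples: Mapping[str, Set[str]]) -> float:
    """Fraction of SNVs detected in >= 2 distinct cancer samples."""
    if not snv_to_samples:
        raise SskitError("recurrent_fraction undefined on an empty map")
    k = sum(1 for samples in snv_to_samples.values() if len(samples) >= 2)
    return k / len(snv_to_samples)


def elementset_jaccard(
    set_a: Sequence, set_b: Sequence, min_bp: int = 1
) -> float:
    """Jaccard index of two element sets under overlap matching.

    An element of one set is matched when it overlaps any element of
    the other by >= min_bp; each element counts once.  The index is
    |matched(a)| / (|a| + |b| - |matched(a)|).
    """
    if not set_a and not set_b:
        raise SskitError("elementset_jaccard undefined for two empty sets")
    if not set_a or not set_b:
        return 0.0
    index_b = IntervalIndex(_as_interval(e) for e in set_b)
    matched = sum(1 for e in set_a if index_b.max_overlap(_as_interval(e)) >= min_bp)
    return matched / (len(set_a) + len(set_b) - matched)


PARTNER_PRECEDENCE = ("SS", "SE", "TS", "TE")


def classify_partner(
    breakpoint: GenomicInterval,
    element_groups: Mapping[str, Sequence],
    flank_bp: int = DEFAULT_FLANK_BP,
) -> str:
    """Assign a translocation partner breakpoint to an element group.

    ``element_groups`` maps group names (subset of SS/SE/TS/TE) to
    element sequences; the breakpoint is assigned to the first group,
    in super-before-typical and silencer-before-enhancer precedence,
    whose footprint widened by ±flank_bp contains it; otherwise
    "none".
    """
    for group in PARTNER_PRECEDENCE:
        elements = element_groups.get(group)
        if not elements:
            continue
        widened = [
            GenomicInterval(
                iv.chrom, max(0, iv.start - flank_bp), iv.end + flank_bp
            )
            for iv in (_as_interval(e) for e in elements)
        ]
        if IntervalIndex(widened).contains_point(breakpoint.chrom, breakpoint.start):
            return group
    return "none"


def enrichment_table(
    variants: Sequence[VariantRecord],
    element_sets: Mapping[str, Sequence],
    category: str,
    reference_fraction: Optional[float] = None,
) -> "pd.DataFrame":
    """One EnrichmentResult row per element set for one category.

    The reference fraction defaults to the category fraction over all
    supplied variants (the "whole collection" baseline).
    """
    import pandas as pd

    if reference_fraction is None:
        reference_fraction = category_fraction(list(variants), category)
    rows = []
    for name, elements in element_sets.items():
        inside = variants_in_set(variants, [_as_interval(e) for e in elements])
        n = len(inside)
        dens = density_per_kb(variants, elements)
        if n == 0:
            rows.append(
                EnrichmentResult(name, 0, dens, float("nan"), float("nan"), float("nan"))
            )
            continue
        frac = category_fraction(inside, category)
        fold, p = enrichment_fold(frac, reference_fraction, n)
        rows.append(EnrichmentResult(name, n, dens, frac, fold, p))
    return pd.DataFrame([r.__dict__ for r in rows])
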