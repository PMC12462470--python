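"""End-to-end orchestration and paper-style summary report.

``run_pipeline`` executes every analysis stage on an in-memory
dataset (from the synthetic generator or loaded from disk) and
returns a flat dictionary of summary quantities; ``run_all`` wraps it
with file loading, per-stage logging and TSV/JSON report output.
``plant_report`` compares recovered values against a ground-truth
manifest at configured tolerances.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Dict, Optional

import numpy as np
import pandas as pd
from scipy import stats

from . import annotate as ann
from . import cooperativity as coop
from . import conversion as conv
from . import enrichment as enr
from .caller import call_super_elements
from .core import IntervalIndex, SskitError
from .synthetic import SyntheticBundle, load_manifest

logger = logging.getLogger(__name__)


def run_pipeline(bundle: SyntheticBundle, seed: int = 0, gap_bp: Optional[int] = None) -> Dict[str, float]:
    """Run calling, cooperativity, annotation, enrichment and conversion
    on a dataset and return the summary quantities."""
    gap = gap_bp if gap_bp is not None else bundle.config.stitch_gap_bp
    out: Dict[str, float] = {}

    # --- super-silencer / super-enhancer calling -------------------------
    ss_regions, ss_comp, ts = call_super_elements(bundle.silencers, "H3K27me3", gap)
    se_regions, se_comp, te = call_super_elements(bundle.enhancers, "H3K27ac", gap)
    n_super = sum(1 for r in ss_regions if r.is_super)
    out["n_regions"] = len(ss_regions)
    out["n_super_silencer_regions"] = n_super
    out["called_super_fraction"] = n_super / len(ss_regions)
    out["n_ss_components"] = len(ss_comp)
    out["n_typical_silencers"] = len(ts)
    out["n_super_enhancer_regions"] = sum(1 for r in se_regions if r.is_super)
    out["n_se_components"] = len(se_comp)
    logger.info("called %d SS regions (%d components)", n_super, len(ss_comp))

    # --- cooperativity ----------------------------------------------------
    by_id = {e.id: e for e in bundle.silencers}
    within = coop.within_region_pairs([r for r in ss_regions if r.is_super], by_id)
    if within:
        target_d = [p.distance_bp for p in within]
        matched = coop.matched_background_pairs(target_d, ts, len(within), seed=seed)
        randoms = coop.random_background_pairs(ts, len(within), seed=seed + 1)
        scores = coop.score_pairs(within + matched + randoms, bundle.activity, bundle.tfbs)
        med = scores.groupby("group")["cooperativity"].median()
        out["coop_within_median"] = float(med.get(coop.WITHIN_REGION, np.nan))
        out["coop_matched_median"] = float(med.get(coop.MATCHED_BACKGROUND, np.nan))
        out["coop_random_median"] = float(med.get(coop.RANDOM_BACKGROUND, np.nan))
        w = scores.loc[scores.group == coop.WITHIN_REGION, "cooperativity"].dropna()
        m = scores.loc[scores.group == coop.MATCHED_BACKGROUND, "cooperativity"].dropna()
        if len(w) and len(m):
            out["coop_wilcoxon_p"] = float(
                stats.mannwhitneyu(w, m, alternative="greater").pvalue
            )
        shared = []
        for r in ss_regions if bundle.tfbs is not None else []:
            if r.is_super and r.n_constituents >= 2:
                try:
                    shared.append(coop.shared_tf_fraction(r, bundle.tfbs))
                except SskitError:
                    pass
        if shared:
            out["shared_tf_fraction_mean"] = float(np.mean(shared))

    # --- annotation -------------------------------------------------------
    if bundle.cgis:
        cgi_index = IntervalIndex(bundle.cgis)
        for name, elements in (("components", ss_comp), ("typicals", ts)):
            if elements:
                frac = np.mean(
                    [ann.cgi_class(e.interval, cgi_index) == ann.CGI for e in elements]
                )
                out[f"cgi_fraction_{name}"] = float(frac)
    labels = []
    if bundle.tads is not None and len(bundle.tads):
        sections = [ann.tad_section(e.interval, bundle.tads) for e in ss_comp]
        labels = [s.label for s in sections if s is not None]
    if labels:
        for lab in (ann.BOUNDARY, ann.SHORE, ann.CENTER):
            out[f"tad_{lab}_fraction_components"] = labels.count(lab) / len(labels)

    gene_index = ann.GeneIndex(bundle.genes or [])
    tau_by_gene = {
        g.gene_id: ann.tau(np.clip(list(g.expression.values()), 0, None))
        for g in bundle.genes
        if len(g.expression) >= 2 and max(g.expression.values()) > 0
    }
    comp_genes = {gene_index.nearest(e.interval) for e in ss_comp} - {None}
    if comp_genes:
        taus = [tau_by_gene[g] for g in comp_genes if g in tau_by_gene]
        out["tau_ss_proximal_median"] = float(np.median(taus)) if taus else np.nan
        out["tau_all_median"] = float(np.median(list(tau_by_gene.values())))
        expr_by_gene = {g.gene_id: g.expression for g in bundle.genes}
        diff_expr = [
            expr_by_gene[g]["differentiated"]
            for g in comp_genes
            if g in expr_by_gene and "differentiated" in expr_by_gene[g]
        ]
        if diff_expr:
            out["expr_differentiated_ss_proximal_mean"] = float(np.mean(diff_expr))

    meth_comp = []
    if bundle.methylation is not None and len(bundle.methylation):
        meth_comp = [ann.mean_methylation(e.interval, bundle.methylation) for e in ss_comp]
        meth_comp = [m for m in meth_comp if not np.isnan(m)]
    if meth_comp:
        out["methylation_components_mean"] = float(np.mean(meth_comp))

    # --- variant enrichment ----------------------------------------------
    bcc = [v for v in bundle.variants if v.vtype == "SNV" and "b_cell_cancer" in v.categories]
    snv = [v for v in bundle.variants if v.vtype == "SNV"]
    if bcc and ss_comp and ts:
        d_comp = enr.density_per_kb(bcc, ss_comp)
        d_typ = enr.density_per_kb(bcc, ts)
        out["bcc_snv_density_components"] = d_comp
        out["bcc_snv_density_typicals"] = d_typ
        out["bcc_snv_fold_components_vs_typicals"] = d_comp / d_typ if d_typ > 0 else np.nan
        try:
            _, lo, hi = enr.density_fold(bcc, ss_comp, ts)
            out["bcc_snv_fold_ci_low"] = lo
            out["bcc_snv_fold_ci_high"] = hi
        except SskitError:
            pass
        in_comp = enr.variants_in_set(snv, ss_comp)
        in_typ = enr.variants_in_set(snv, ts)
        if in_comp and in_typ:
            frac_comp = enr.category_fraction(in_comp, "b_cell_cancer")
            ref = enr.category_fraction(in_typ, "b_cell_cancer")
            fold, p = enr.enrichment_fold(frac_comp, ref, len(in_comp))
            out["bcc_fraction_components"] = frac_comp
            out["bcc_fraction_fold"] = fold
            out["bcc_fraction_p"] = p
        rec_map = {
            v.id: set(v.sample_ids)
            for v in enr.variants_in_set(bcc, ss_comp)
        }
        if rec_map:
            out["recurrent_bcc_fraction_components"] = enr.recurrent_fraction(rec_map)

    snps = [v for v in bundle.variants if v.vtype == "SNP"]
    immune_in_comp = [
        v for v in enr.variants_in_set(snps, ss_comp) if "immune" in v.categories
    ]
    if immune_in_comp:
        out["replicated_immune_snp_fraction_components"] = enr.replicated_fraction(
            {v.id: set(v.study_ids) for v in immune_in_comp}
        )

    # --- conversions ------------------------------------------------------
    if ss_comp and bundle.cancer_se_by_sample:
        records = conv.detect_conversions(ss_comp, bundle.cancer_se_by_sample)
        converted_fraction, recurrence = conv.recurrence_summary(records, len(ss_comp))
        out["converted_fraction"] = converted_fraction
        out["recurrent_over_half_fraction"] = recurrence if recurrence is not None else np.nan

    # --- contact retention ------------------------------------------------
    if bundle.contacts_normal and ss_comp:
        try:
            out["contact_retention_components"] = conv.contact_retention(
                bundle.contacts_normal, bundle.contacts_cancer, ss_comp
            )
        except SskitError:
            pass

    return out


# ---------------------------------------------------------------------------
# recovery report
# ---------------------------------------------------------------------------

DEFAULT_TOLERANCES = {
    "super_fraction_rel": 0.5,       # +/- 50% relative on called super fraction
    "fold_rel": 0.2,                 # +/- 20% relative on the variant fold
    "conversion_abs": 0.02,          # +/- 2 points on converted fraction
    "recurrence_abs": 0.05,          # +/- 5 points on recurrence
    "coop_p_max": 0.01,              # within vs matched separation
}


def plant_report(
    manifest: dict, recovered: Dict[str, float], tolerances: Optional[dict] = None,
    seed: Optional[int] = None,
) -> pd.DataFrame:
    """Planted-vs-recovered table with pass/fail at the tolerances."""
    tol = dict(DEFAULT_TOLERANCES)
    if tolerances:
        tol.update(tolerances)
    if seed is not None and manifest.get("seed") != seed:
        raise SskitError(
            f"manifest seed {manifest.get('seed')} does not match run seed {seed}"
        )
    rows = []

    def add(name, planted, got, ok):
        rows.append({"quantity": name, "planted": planted, "recovered": got, "pass": bool(ok)})

    planted_sf = manifest["planted_super_fraction"]
    got_sf = recovered.get("called_super_fraction", np.nan)
    add("super_fraction", planted_sf, got_sf,
        np.isfinite(got_sf) and abs(got_sf - planted_sf) <= tol["super_fraction_rel"] * planted_sf)

    planted_fold = manifest["bcc_component_fold"]
    got_fold = recovered.get("bcc_snv_fold_components_vs_typicals", np.nan)
    add("bcc_snv_fold", planted_fold, got_fold,
        np.isfinite(got_fold) and abs(got_fold - planted_fold) <= tol["fold_rel"] * planted_fold)

    planted_cf = manifest["conversion_fraction_components"]
    got_cf = recovered.get("converted_fraction", np.nan)
    add("conversion_fraction", planted_cf, got_cf,
        np.isfinite(got_cf) and abs(got_cf - planted_cf) <= tol["conversion_abs"])

    planted_rec = manifest["conversion_recurrence"]
    got_rec = recovered.get("recurrent_over_half_fraction", np.nan)
    add("conversion_recurrence", planted_rec, got_rec,
        np.isfinite(got_rec) and abs(got_rec - planted_rec) <= tol["recurrence_abs"])

    got_p = recovered.get("coop_wilcoxon_p", np.nan)
    add("cooperativity_separation_p", 0.0, got_p,
        np.isfinite(got_p) and got_p < tol["coop_p_max"])
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# disk-based run
# ---------------------------------------------------------------------------

def load_bundle_dir(data_dir) -> SyntheticBundle:
    """Reload a serialized bundle directory into memory."""
    from . import io as sio
    from .synthetic import SimConfig, SyntheticBundle

    d = Path(data_dir)
    manifest = load_manifest(d / "manifest.json") if (d / "manifest.json").exists() else {}
    cfg = SimConfig.from_dict(manifest["config"]) if "config" in manifest else SimConfig()
    peaks = {}
    peaks_dir = d / "peaks"
    if peaks_dir.exists():
        for ac_path in sorted(peaks_dir.glob("*.H3K27ac.bed")):
            ct = ac_path.name.split(".")[0]
            peaks[ct] = (
                sio.read_bed(ac_path),
                sio.read_bed(peaks_dir / f"{ct}.H3K27me3.bed"),
            )
    se_by_sample = {}
    se_dir = d / "cancer_se"
    if se_dir.exists():
        for p in sorted(se_dir.glob("*.bed")):
            se_by_sample[p.stem] = sio.read_bed(p)
    def optional(path, reader, default):
        if not path.exists():
            logger.warning("%s missing; the dependent report sections are omitted", path.name)
            return default
        return reader(path)

    return SyntheticBundle(
        config=cfg,
        seed=manifest.get("seed", 0),
        silencers=sio.read_elements_tsv(d / "silencers.tsv"),
        enhancers=sio.read_elements_tsv(d / "enhancers.tsv"),
        background_peaks=optional(d / "background_peaks.bed", sio.read_bed, []),
        activity=optional(d / "activity.tsv", lambda p: sio.read_matrix_tsv(p, "activity"), None),
        peaks_by_cell_type=peaks,
        tfbs=optional(d / "tfbs.tsv", lambda p: sio.read_matrix_tsv(p, "tfbs"), None),
        cgis=optional(d / "cgi.bed", sio.read_bed, []),
        tads=optional(d / "tads.bed", sio.read_tads, None),
        genes=optional(d / "genes.tsv", sio.read_genes_tsv, []),
        methylation=optional(d / "methylation.tsv", sio.read_methylation_tsv, None),
        contacts_normal=optional(d / "contacts_normal.bedpe", lambda p: sio.read_bedpe(p, "normal"), []),
        contacts_cancer=optional(d / "contacts_cancer.bedpe", lambda p: sio.read_bedpe(p, "cancer"), []),
        variants=optional(d / "variants.tsv", sio.read_variants_tsv, []),
        ld_pairs=optional(d / "ld_pairs.tsv", sio.read_ld_tsv, []),
        cancer_se_by_sample=se_by_sample,
        manifest=manifest,
    )


def run_all(data_dir, out_dir, seed: int = 0) -> Dict[str, float]:
    """Load a bundle directory, run every stage, write the report bundle.

    Writes ``summary.json`` (all recovered quantities), ``recovery.tsv``
    (planted vs recovered when a manifest is present) and a plain-text
    summary.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle = load_bundle_dir(data_dir)
    logger.info("loaded %d silencers, %d enhancers, %d variants",
                len(bundle.silencers), len(bundle.enhancers), len(bundle.variants))
    recovered = run_pipeline(bundle, seed=seed)
    with open(out / "summary.json", "w") as fh:
        json.dump({"seed": seed, "quantities": recovered}, fh, indent=2, sort_keys=True)
        fh.write("\n")
    if bundle.manifest:
        report = plant_report(bundle.manifest, recovered)
        report.to_csv(out / "recovery.tsv", sep="\t", index=False)
    with open(out / "summary.txt", "w") as fh:
        for key in sorted(recovered):
            fh.write(f"{key}\t{recovered[key]:.6g}\n")
    return recovered
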