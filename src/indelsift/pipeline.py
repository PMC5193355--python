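"""File-to-file pipeline stages and end-to-end orchestration.

Stages communicate through files only, so each is independently runnable and
restartable; every stage records its parameter values and counts in a JSON
manifest.  The end-to-end driver reproduces the analysis funnel:

    per-sample calls -> confidence filter -> nonredundant union
    -> concordant differential filter -> functional annotation + novelty
    -> QTL/GWAS/pathway evidence integration -> candidate tiers
    -> gene-set enrichment -> descriptive summaries (-> recovery vs truth)
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Optional

import pandas as pd

from . import annotation as ann
from . import contrast, evidence, summaries
from .config import PipelineConfig
from .errors import ValidationError
from .simulate import SyntheticTruth, evaluate_recovery
from .variants import (
    FamilyDesign,
    GenotypeMatrix,
    apply_call_filters,
    merge_nonredundant,
    normalize_indel,
    read_indel_calls,
)

__all__ = [
    "filter_sample_vcf",
    "merge_sample_vcfs",
    "run_differential",
    "run_annotation",
    "run_integration",
    "run_end_to_end",
]


def filter_sample_vcf(vcf_path, sample_id=None, config: Optional[PipelineConfig] = None):
    """Read one sample's indel calls, filter them, normalize survivors.

    Returns ``(kept_records, filter_counts)`` with each kept record's variant
    replaced by its normalized form.
    """
    config = config or PipelineConfig()
    records = read_indel_calls(vcf_path, sample_id, strand_field=config.strand_field)
    kept, counts = apply_call_filters(records, config.thresholds)
    for rec in kept:
        rec.variant = normalize_indel(rec.variant)
    return kept, counts


def merge_sample_vcfs(vcf_paths: dict, config: Optional[PipelineConfig] = None):
    """Filter + normalize each sample VCF, then union into a GenotypeMatrix.

    ``vcf_paths`` maps sample id -> VCF path.  Returns
    ``(matrix, per_sample_counts)``.
    """
    config = config or PipelineConfig()
    per_sample, counts = {}, {}
    for sample, path in vcf_paths.items():
        kept, c = filter_sample_vcf(path, sample, config)
        per_sample[sample] = kept
        counts[sample] = c.as_dict()
    return merge_nonredundant(per_sample), counts


def run_differential(matrix: GenotypeMatrix, design: FamilyDesign):
    """Concordant sib-pair filter; returns (results, n_excluded_missing)."""
    return contrast.concordant_differential_filter(matrix, design)


def run_annotation(
    variants,
    model: ann.GeneModel,
    known: Optional[ann.KnownVariantSet] = None,
    config: Optional[PipelineConfig] = None,
):
    """Categorical annotation (+ novelty when a known set is given).

    Returns ``(records, summary_frame, novel_pct)``; ``novel_pct`` is None
    without a known set.
    """
    config = config or PipelineConfig()
    records = ann.annotate_all(
        variants,
        model,
        upstream_window=config.upstream_window,
        downstream_window=config.downstream_window,
        splice_window=config.splice_window,
    )
    novel_pct = None
    if known is not None:
        flags, novel_pct = ann.novelty_assessment([r.variant for r in records], known)
        for rec, flag in zip(records, flags):
            rec.novel = flag
    return records, ann.annotation_summary(records), novel_pct


def run_integration(
    records,
    model: ann.GeneModel,
    qtls,
    gwas_hits,
    pathways,
    gmap,
    config: Optional[PipelineConfig] = None,
):
    """Evidence profiles + tiers for genes carrying differential indels."""
    config = config or PipelineConfig()
    return evidence.prioritize(
        records,
        qtls,
        gwas_hits,
        pathways,
        gmap,
        model,
        trait_labels=config.trait_labels,
        peak_radius_cM=config.peak_radius_cM,
        gwas_radius_bp=config.gwas_radius_bp,
    )


def annotation_records_table(records) -> pd.DataFrame:
    rows = []
    for r in records:
        v = r.variant
        rows.append(
            {
                "chrom": v.chrom,
                "pos": v.pos,
                "ref": v.ref,
                "alt": v.alt,
                "svtype": v.svtype,
                "length": v.length,
                "category": r.category,
                "gene_ids": ";".join(r.gene_ids) or None,
                "exonic_effect": r.exonic_effect,
                "novel": r.novel,
            }
        )
    return pd.DataFrame(rows)


def run_end_to_end(
    input_dir,
    out_dir,
    config: Optional[PipelineConfig] = None,
) -> dict:
    """Run the whole pipeline on a directory laid out like ``simulate`` output.

    Expects ``design.tsv``, ``vcf/<sample>.vcf``, ``genome.gff3``,
    ``map.tsv``, ``chrom_lengths.tsv``, ``qtl.tsv``, ``gwas.tsv``,
    ``pathways.gmt`` and optionally ``known.vcf`` and ``truth.json`` under
    ``input_dir``.  Writes all stage outputs plus ``manifest.json`` under
    ``out_dir`` and returns the manifest dict.
    """
    config = config or PipelineConfig()
    indir, outdir = Path(input_dir), Path(out_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    for required in ("design.tsv", "genome.gff3"):
        if not (indir / required).exists():
            raise ValidationError(f"missing required input {indir / required}")

    design = FamilyDesign.from_tsv(indir / "design.tsv")
    vcf_paths = {s: indir / "vcf" / f"{s}.vcf" for s in design.all_samples}
    matrix, filter_counts = merge_sample_vcfs(vcf_paths, config)
    matrix.to_tsv(outdir / "matrix.tsv")
    matrix.to_vcf(outdir / "merged.vcf")

    results, n_missing = run_differential(matrix, design)
    diff_table = contrast.differential_table(results, design)
    diff_table.to_csv(outdir / "differential.tsv", sep="\t", index=False)
    diff_variants = [r.variant for r in results]

    model = ann.GeneModel.from_gff3(indir / "genome.gff3")
    known = None
    if (indir / "known.vcf").exists():
        known = ann.KnownVariantSet.from_vcf(indir / "known.vcf", source="synthetic")
    records, summary, novel_pct = run_annotation(diff_variants, model, known, config)
    annotation_records_table(records).to_csv(
        outdir / "annotation.tsv", sep="\t", index=False
    )
    summary.to_csv(outdir / "annotation_summary.tsv", sep="\t", index=False)

    gmap = evidence.GeneticMap.from_tsv(indir / "map.tsv")
    qtls = evidence.load_qtl_tsv(indir / "qtl.tsv")
    hits = evidence.load_gwas_tsv(indir / "gwas.tsv")
    pathways = ann_pathways = evidence.PathwayGeneSets.from_gmt(indir / "pathways.gmt")
    report = run_integration(records, model, qtls, hits, pathways, gmap, config)
    report.to_csv(outdir / "candidates.tsv", sep="\t", index=False)
    report.to_json(outdir / "candidates.json", orient="records", indent=1)

    retained = report[report["retained"]] if len(report) else report
    if len(retained):
        enrich = evidence.fisher_enrichment(
            retained["gene_id"].tolist(),
            list(model.genes),
            ann_pathways,
            alpha=config.enrichment_alpha,
        )
        evidence.enrichment_table(enrich).to_csv(
            outdir / "enrichment.tsv", sep="\t", index=False
        )

    chrom_lengths = None
    if (indir / "chrom_lengths.tsv").exists():
        cl = pd.read_csv(indir / "chrom_lengths.tsv", sep="\t", dtype={"chrom": str})
        chrom_lengths = dict(zip(cl["chrom"], cl["length_bp"]))
    if diff_variants:
        dist = summaries.length_distribution(diff_variants)
        dist["counts"].to_csv(outdir / "length_distribution.tsv", sep="\t")
        if chrom_lengths:
            summaries.chromosome_distribution(diff_variants, chrom_lengths).to_csv(
                outdir / "chromosome_distribution.tsv", sep="\t", index=False
            )

    genic = sum(1 for r in records if r.category != "intergenic")
    manifest = {
        "inputs": {"input_dir": str(indir)},
        "parameters": config.to_dict(),
        "per_sample_filter_counts": filter_counts,
        "funnel": {
            "merged_nonredundant": matrix.n_variants,
            "excluded_missing_genotype": n_missing,
            "common_differential": len(results),
            "genic_or_flanking": genic,
            "genes_with_indel": len(
                {g for r in records for g in r.gene_ids if r.category != "intergenic"}
            ),
            "retained_genes": int(report["retained"].sum()) if len(report) else 0,
            "tier_counts": report["tier"].value_counts().to_dict()
            if len(report)
            else {},
        },
        "novel_pct": novel_pct,
    }

    if (indir / "truth.json").exists():
        truth = SyntheticTruth.from_json(indir / "truth.json")
        recovery = evaluate_recovery(results, truth, candidate_report=report)
        (outdir / "recovery.json").write_text(
            json.dumps(recovery.to_dict(), indent=1)
        )
        manifest["recovery"] = recovery.to_dict()

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
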