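"""Shared fixtures: small synthetic bundles and toy gene models."""

from pathlib import Path

import numpy as np
import pytest

from indelsift.annotation import Gene, GeneModel, Transcript
from indelsift.simulate import (
    SimulationConfig,
    generate_cohort,
    generate_evidence_resources,
    generate_genome,
)


def small_config(seed=11, **overrides) -> SimulationConfig:
    """Desk-scale cohort for fast unit tests."""
    kwargs = dict(
        seed=seed,
        n_background_loci=2_000,
        n_planted_differential=60,
        filter_fail_per_criterion=20,
    )
    kwargs.update(overrides)
    return SimulationConfig(**kwargs)


def build_bundle(config: SimulationConfig, outdir: Path) -> Path:
    """Write a full simulate-style input directory for a config."""
    rng = np.random.default_rng(config.seed)
    genome = generate_genome(config, rng)
    cohort = generate_cohort(config, genome, rng)
    resources = generate_evidence_resources(config, genome, cohort.truth, rng)
    outdir.mkdir(parents=True, exist_ok=True)
    genome.write_gff3(outdir / "genome.gff3")
    genome.gmap.to_tsv(outdir / "map.tsv")
    genome.write_chrom_lengths(outdir / "chrom_lengths.tsv")
    cohort.write_design(outdir / "design.tsv")
    cohort.write_vcfs(outdir / "vcf")
    resources.write_qtl_tsv(outdir / "qtl.tsv")
    resources.write_gwas_tsv(outdir / "gwas.tsv")
    resources.write_gmt(outdir / "pathways.gmt")
    resources.write_known_vcf(outdir / "known.vcf", cohort.chrom_lengths)
    cohort.truth.to_json(outdir / "truth.json")
    return outdir


@pytest.fixture(scope="session")
def small_sim():
    """In-memory small cohort: (config, genome, cohort, resources)."""
    config = small_config()
    rng = np.random.default_rng(config.seed)
    genome = generate_genome(config, rng)
    cohort = generate_cohort(config, genome, rng)
    resources = generate_evidence_resources(config, genome, cohort.truth, rng)
    return config, genome, cohort, resources


@pytest.fixture(scope="session")
def small_bundle(tmp_path_factory):
    """Small cohort written to disk as a simulate-style directory."""
    return build_bundle(small_config(), tmp_path_factory.mktemp("bundle"))


def toy_gene(gene_id="G1", chrom="chr1", strand="+", coding=True):
    """Three-exon gene on [1000, 1999]: exons 1000-1199 / 1400-1599 /
    1800-1999; CDS trims 50 bp UTR off each terminal exon."""
    exons = [(1000, 1199), (1400, 1599), (1800, 1999)]
    cds = [(1050, 1199), (1400, 1599), (1800, 1949)] if coding else []
    t = Transcript(f"{gene_id}.t1", exons, cds, strand, coding)
    return Gene(gene_id, chrom, strand, 1000, 1999, [t])


@pytest.fixture
def toy_model():
    """Two-gene model: coding G1 (+, 1000-1999) and noncoding N1 (-, 5000-5599)."""
    n1 = Gene(
        "N1",
        "chr1",
        "-",
        5000,
        5599,
        [Transcript("N1.t1", [(5000, 5199), (5400, 5599)], [], "-", False)],
    )
    return GeneModel([toy_gene(), n1])
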