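"""Synthetic-data generator: determinism, file round-trips, planted truth,
chance pass rate and recovery scoring."""

import itertools
import json

import numpy as np
import pytest

from indelsift.annotation import GeneModel, KnownVariantSet
from indelsift.contrast import concordant_differential_filter
from indelsift.errors import ConfigError
from indelsift.evidence import GeneticMap, PathwayGeneSets
from indelsift.simulate import (
    SimulationConfig,
    SyntheticTruth,
    evaluate_recovery,
    generate_cohort,
    generate_genome,
)
from indelsift.variants import apply_call_filters, read_indel_calls

from conftest import build_bundle, small_config


# --------------------------------------------------------------------------
# config validation
# --------------------------------------------------------------------------


def test_config_rejects_unreachable_frequency_targets():
    with pytest.raises(ConfigError):
        SimulationConfig(planted_frequency_targets=[(0.3, 0.1)])  # not /8
    with pytest.raises(ConfigError):
        SimulationConfig(planted_frequency_targets=[(0.5, 0.5)])  # no contrast


def test_config_rejects_overfull_planting():
    with pytest.raises(ConfigError):
        SimulationConfig(n_background_loci=10, n_planted_differential=20)


# --------------------------------------------------------------------------
# determinism and round-trips
# --------------------------------------------------------------------------


def test_same_seed_identical_truth_and_files(tmp_path):
    cfg = small_config(seed=5)
    d1 = build_bundle(cfg, tmp_path / "a")
    d2 = build_bundle(small_config(seed=5), tmp_path / "b")
    for name in ("truth.json", "genome.gff3", "map.tsv", "qtl.tsv",
                 "pathways.gmt", "known.vcf", "vcf/S5.vcf"):
        assert (d1 / name).read_bytes() == (d2 / name).read_bytes(), name


def test_emitted_files_roundtrip(small_bundle):
    """Every emitted resource reloads losslessly through the package readers."""
    model = GeneModel.from_gff3(small_bundle / "genome.gff3")
    cfg = small_config()
    n_expected_genes = len(cfg.candidate_tiers)
    assert len(model) >= n_expected_genes
    assert all(g.transcripts for g in model.genes.values())

    gmap = GeneticMap.from_tsv(small_bundle / "map.tsv")
    for chrom, (bp, cm) in gmap.anchors.items():
        assert np.all(np.diff(bp) > 0) and np.all(np.diff(cm) >= 0)

    pathways = PathwayGeneSets.from_gmt(small_bundle / "pathways.gmt")
    assert len(pathways.core_pathways) == 8

    known = KnownVariantSet.from_vcf(small_bundle / "known.vcf")
    truth = SyntheticTruth.from_json(small_bundle / "truth.json")
    planted_known = {tuple(k.split(":")) for k in truth.known_overlap}
    assert len(known.keys) >= len(planted_known)

    records = read_indel_calls(small_bundle / "vcf" / "S1.vcf", "S1")
    assert records and all(r.quality is not None for r in records)


def test_vcf_fields_pass_filters_except_bait(small_bundle):
    """All ordinary records pass the call filter; the bait records reproduce
    the planted per-criterion rejection counts."""
    truth = SyntheticTruth.from_json(small_bundle / "truth.json")
    totals = {"quality": 0, "depth": 0, "strand_support": 0, "length": 0}
    for i in range(1, 9):
        recs = read_indel_calls(small_bundle / "vcf" / f"S{i}.vcf", f"S{i}")
        _, counts = apply_call_filters(recs)
        for crit in totals:
            totals[crit] += getattr(counts, crit)
    assert totals == truth.filter_fail_counts


# --------------------------------------------------------------------------
# planted truth
# --------------------------------------------------------------------------


def test_planted_loci_recovered_exactly(small_sim):
    _, _, cohort, _ = small_sim
    matrix = cohort.genotype_matrix()
    results, _ = concordant_differential_filter(matrix, cohort.design)
    rep = evaluate_recovery(results, cohort.truth)
    assert rep.sensitivity == 1.0 and rep.fdp == 0.0
    assert rep.direction_accuracy == 1.0


def test_planted_frequencies_match_genotypes(small_sim):
    _, _, cohort, _ = small_sim
    matrix = cohort.genotype_matrix()
    results, _ = concordant_differential_filter(matrix, cohort.design)
    truth = cohort.truth.differential
    for r in results:
        t = truth[SyntheticTruth.key_of(r.variant)]
        assert (r.freq_high, r.freq_low) == (t["freq_high"], t["freq_low"])
        assert r.freq_high * 8 == round(r.freq_high * 8)


def test_frequency_targets_are_honored(tmp_path):
    cfg = small_config(
        seed=9,
        n_planted_differential=8,
        planted_frequency_targets=[(1.0, 0.0), (0.25, 0.75)],
    )
    rng = np.random.default_rng(cfg.seed)
    genome = generate_genome(cfg, rng)
    cohort = generate_cohort(cfg, genome, rng)
    freqs = {
        (d["freq_high"], d["freq_low"], d["direction"])
        for d in cohort.truth.differential.values()
    }
    assert freqs == {(1.0, 0.0, 1), (0.25, 0.75, -1)}


def test_infeasible_sign_consistent_target_errors():
    """A frequency pair on the 1/8 grid can still be unreachable when all
    four families must be polymorphic with one shared sign."""
    cfg = small_config(seed=9, n_planted_differential=4,
                       planted_frequency_targets=[(0.625, 0.25)])
    rng = np.random.default_rng(cfg.seed)
    genome = generate_genome(cfg, rng)
    with pytest.raises(ConfigError):
        generate_cohort(cfg, genome, rng)


def test_label_swap_antisymmetry(small_sim):
    """Swapping high/low keeps locus recovery but flips every direction."""
    _, _, cohort, _ = small_sim
    matrix = cohort.genotype_matrix()
    results, _ = concordant_differential_filter(matrix, cohort.design.swapped())
    rep = evaluate_recovery(results, cohort.truth)
    assert rep.sensitivity == 1.0 and rep.direction_accuracy == 0.0


def test_discordant_noise_breaks_some_families():
    cfg = small_config(seed=13, discordant_call_rate=0.3,
                       filter_fail_per_criterion=0)
    rng = np.random.default_rng(cfg.seed)
    genome = generate_genome(cfg, rng)
    cohort = generate_cohort(cfg, genome, rng)
    matrix = cohort.genotype_matrix()
    results, _ = concordant_differential_filter(matrix, cohort.design)
    rep = evaluate_recovery(results, cohort.truth)
    assert rep.sensitivity < 1.0


def test_missing_rate_excludes_expected_loci():
    cfg = small_config(seed=17, missing_call_rate=0.05,
                       filter_fail_per_criterion=0)
    rng = np.random.default_rng(cfg.seed)
    genome = generate_genome(cfg, rng)
    cohort = generate_cohort(cfg, genome, rng)
    matrix = cohort.genotype_matrix()
    _, n_missing = concordant_differential_filter(matrix, cohort.design)
    assert n_missing == cohort.truth.n_missing_excluded
    assert n_missing > 0


def test_known_overlap_gives_planted_novelty(small_sim):
    _, _, cohort, resources = small_sim
    truth = cohort.truth
    known = {tuple(k.split(":")) for k in resources.known_keys}
    planted = set(truth.differential)
    overlap = {k for k in planted if tuple(k.split(":")) in known}
    assert len(overlap) == round(0.2333 * len(planted))


# --------------------------------------------------------------------------
# chance pass rate of the contrast filter
# --------------------------------------------------------------------------


def locus_pass_probability(p):
    """Enumerate all 3^8 dosage patterns under Binomial(2, p) genotypes."""
    g = np.array([(1 - p) ** 2, 2 * p * (1 - p), p ** 2])
    prob = 0.0
    for pat in itertools.product(range(3), repeat=8):
        d = [pat[i] - pat[i + 4] for i in range(4)]
        if all(x > 0 for x in d) or all(x < 0 for x in d):
            prob += float(np.prod(g[list(pat)]))
    return prob


def test_chance_pass_rate_matches_enumeration():
    """With the chance-veto off, the number of background loci passing the
    filter matches the 3^8 enumeration expectation within 3 sigma."""
    cfg = small_config(
        seed=23,
        n_background_loci=2_000,
        n_planted_differential=0,
        filter_fail_per_criterion=0,
        exclude_chance_differential=False,
    )
    rng = np.random.default_rng(cfg.seed)
    genome = generate_genome(cfg, rng)
    cohort = generate_cohort(cfg, genome, rng)
    matrix = cohort.genotype_matrix()
    results, _ = concordant_differential_filter(matrix, cohort.design)
    observed = len(results)

    # expectation from the genotype law, using a coarse quadrature over the
    # pass probability (smooth in p) at the planted per-locus frequencies
    grid = np.linspace(0.05, 0.95, 46)
    probs = np.array([locus_pass_probability(p) for p in grid])
    per_locus = np.interp(cohort.background_freqs, grid, probs)
    mean, sd = per_locus.sum(), np.sqrt((per_locus * (1 - per_locus)).sum())
    assert abs(observed - mean) <= 3 * sd


def test_chance_veto_empties_background(small_sim):
    """With the default veto, only planted loci pass (FDP would otherwise be
    nonzero at this cohort size)."""
    _, _, cohort, _ = small_sim
    matrix = cohort.genotype_matrix()
    results, _ = concordant_differential_filter(matrix, cohort.design)
    assert len(results) == len(cohort.truth.differential)


# --------------------------------------------------------------------------
# length law and placement
# --------------------------------------------------------------------------


def test_length_law_matches_configured_shares(small_sim):
    """Observed 1-bp and <10-bp shares sit within 3 sigma binomial bounds of
    the configured law."""
    cfg, _, cohort, _ = small_sim
    lengths = np.array(
        [r.variant.length for r in cohort.records["S1"]]
    )
    lengths = lengths[lengths <= cfg.max_length]  # drop filter-bait records
    n = len(lengths)
    for share, p in ((np.mean(lengths == 1), cfg.p_1bp),
                     (np.mean(lengths < 10), cfg.p_lt10)):
        sd = np.sqrt(p * (1 - p) / n)
        assert abs(share - p) <= 3 * sd

    svtypes = np.array([r.variant.svtype for r in cohort.records["S1"]])
    ins_share = np.mean(svtypes == "INS")
    sd = np.sqrt(cfg.ins_fraction * (1 - cfg.ins_fraction) / len(svtypes))
    assert abs(ins_share - cfg.ins_fraction) <= 4 * sd


def test_x_density_multiplier_recovered():
    cfg = small_config(seed=29, n_background_loci=6_000,
                       n_planted_differential=0, filter_fail_per_criterion=0,
                       x_density_multiplier=0.6)
    rng = np.random.default_rng(cfg.seed)
    genome = generate_genome(cfg, rng)
    cohort = generate_cohort(cfg, genome, rng)
    variants = {r.variant.key: r.variant for s in cohort.samples
                for r in cohort.records[s]}
    counts = {c: 0 for c in cfg.chromosomes}
    for v in variants.values():
        counts[v.chrom] += 1
    auto_density = np.mean(
        [counts[c] / l for c, l in cfg.chromosomes.items() if c != "chrX"]
    )
    x_density = counts["chrX"] / cfg.chromosomes["chrX"]
    ratio = x_density / auto_density
    assert ratio == pytest.approx(0.6, abs=0.15)


def test_autosome_counts_length_proportional():
    cfg = small_config(seed=31, n_background_loci=6_000,
                       n_planted_differential=0, filter_fail_per_criterion=0)
    rng = np.random.default_rng(cfg.seed)
    genome = generate_genome(cfg, rng)
    cohort = generate_cohort(cfg, genome, rng)
    variants = {r.variant.key: r.variant for s in cohort.samples
                for r in cohort.records[s]}
    autosomes = {c: l for c, l in cfg.chromosomes.items() if c != "chrX"}
    n_auto = sum(1 for v in variants.values() if v.chrom in autosomes)
    total_len = sum(autosomes.values())
    for chrom, length in autosomes.items():
        p = length / total_len
        observed = sum(1 for v in variants.values() if v.chrom == chrom)
        sd = np.sqrt(n_auto * p * (1 - p))
        assert abs(observed - n_auto * p) <= 3.5 * sd
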