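"""Self-contained synthetic cohorts with known truth for every pipeline stage.

The generator emulates the study conditions the pipeline was designed for:
eight diploid samples in four high/low sib pairs, an indel landscape with a
1-bp modal length (44.47% single-bp, 97.96% under 10 bp, max 49 bp), a
slight insertion excess (ins fraction 1842/3625), chromosome-length-
proportional placement with reduced density on X, a planted set of common
differential loci that satisfy the concordant sib-pair filter by
construction, planted candidate genes wired to attain target evidence tiers
A–E, and a known-variant set containing a configured fraction (default
23.33%) of the differential loci so that the novelty fraction is planted.

Genotypes are drawn per sample from per-locus allele frequencies; sib-pair
relatedness is not simulated, because the contrast filter never uses it.
Background loci that would pass the concordant filter by chance are redrawn
by default (``exclude_chance_differential``) so that noise-free recovery is
exact; disable it to study the filter's chance pass rate.

Default scale (~1.5×10⁴ loci, ~10⁴ variant calls per sample) keeps a full
synthetic run in seconds; ``SimulationConfig.paper_scale()`` returns a
profile near the real cohort's per-sample counts.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
from scipy.optimize import brentq

from .annotation import Gene, GeneModel, Transcript
from .contrast import DifferentialResult
from .errors import ConfigError
from .evidence import (
    DEFAULT_CORE_PATHWAYS,
    GeneticMap,
    GwasHit,
    PathwayGeneSets,
    QTLRecord,
)
from .variants import CallRecord, FamilyDesign, IndelVariant

__all__ = [
    "SimulationConfig",
    "SyntheticTruth",
    "SyntheticGenome",
    "Cohort",
    "EvidenceResources",
    "generate_genome",
    "generate_cohort",
    "generate_evidence_resources",
    "evaluate_recovery",
    "RecoveryReport",
]

_DEFAULT_CHROMS = {
    "chr1": 45_000_000,
    "chr2": 40_000_000,
    "chr3": 35_000_000,
    "chr4": 30_000_000,
    "chr5": 25_000_000,
    "chr6": 20_000_000,
    "chrX": 15_000_000,
}

# fixed fractional placements of candidate genes; pairwise genetic distance
# stays large enough that planted QTL/peak evidence cannot leak between them
_CANDIDATE_SLOTS = [
    ("chr1", 0.15), ("chr1", 0.50), ("chr1", 0.85),
    ("chr2", 0.25), ("chr2", 0.75),
    ("chr3", 0.25), ("chr3", 0.75),
    ("chr4", 0.30), ("chr4", 0.80),
    ("chr5", 0.50),
    ("chr6", 0.50),
]


@dataclass
class SimulationConfig:
    """Knobs of the synthetic cohort; defaults ARE the emulated study conditions."""

    seed: int = 0
    chromosomes: dict = field(default_factory=lambda: dict(_DEFAULT_CHROMS))
    n_genes: int = 60               # coding genes
    n_noncoding_genes: int = 6
    n_background_loci: int = 15_000
    n_planted_differential: int = 300
    candidate_tiers: str = "AAAABBCCDDE"  # 11 genes across the five tiers
    p_1bp: float = 0.4447           # share of 1-bp indels
    p_lt10: float = 0.9796          # share under 10 bp
    max_length: int = 49
    ins_fraction: float = 1842 / 3625
    x_density_multiplier: float = 0.6
    known_overlap_fraction: float = 0.2333
    missing_call_rate: float = 0.0
    discordant_call_rate: float = 0.0
    filter_fail_per_criterion: int = 50
    exclude_chance_differential: bool = True
    background_freq_range: tuple = (0.1, 0.9)
    planted_frequency_targets: Optional[list] = None  # (freq_high, freq_low) pairs

    def __post_init__(self):
        for name in ("p_1bp", "p_lt10", "ins_fraction", "known_overlap_fraction",
                     "missing_call_rate", "discordant_call_rate",
                     "x_density_multiplier"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ConfigError(f"{name}={v} outside [0, 1]")
        if self.p_lt10 < self.p_1bp:
            raise ConfigError("p_lt10 must be >= p_1bp")
        if self.n_planted_differential > self.n_background_loci:
            raise ConfigError("planted count exceeds background size")
        if len(self.candidate_tiers) > len(_CANDIDATE_SLOTS):
            raise ConfigError(
                f"at most {len(_CANDIDATE_SLOTS)} candidate genes supported"
            )
        if any(t not in "ABCDE" for t in self.candidate_tiers):
            raise ConfigError("candidate tiers must be in A-E")
        if self.planted_frequency_targets is not None:
            for fh, fl in self.planted_frequency_targets:
                for f in (fh, fl):
                    if not (0 <= f <= 1) or round(f * 8) != f * 8:
                        raise ConfigError(
                            f"frequency {f} not a multiple of 0.125 in [0,1]"
                        )
                if fh == fl:
                    raise ConfigError("planted freq_high must differ from freq_low")

    @classmethod
    def paper_scale(cls, seed: int = 0) -> "SimulationConfig":
        """Profile near the real cohort's per-sample variant counts."""
        return cls(
            seed=seed,
            n_background_loci=550_000,
            n_planted_differential=3_625,
        )


# --------------------------------------------------------------------------
# genome
# --------------------------------------------------------------------------


@dataclass
class SyntheticGenome:
    model: GeneModel
    gmap: GeneticMap
    chrom_lengths: dict
    candidate_gene_ids: list  # aligned with config.candidate_tiers

    def write_gff3(self, path) -> None:
        lines = ["##gff-version 3"]
        for chrom, length in self.chrom_lengths.items():
            lines.append(f"##sequence-region {chrom} 1 {length}")
        for g in self.genes_sorted():
            gtype = "gene" if g.coding else "ncRNA_gene"
            lines.append(
                f"{g.chrom}\tindelsift\t{gtype}\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={g.id};Name={g.id}"
            )
            for t in g.transcripts:
                ttype = "mRNA" if t.coding else "ncRNA"
                lines.append(
                    f"{g.chrom}\tindelsift\t{ttype}\t{t.span[0]}\t{t.span[1]}\t.\t"
                    f"{t.strand}\t.\tID={t.id};Parent={g.id}"
                )
                for i, (lo, hi) in enumerate(t.exons, 1):
                    lines.append(
                        f"{g.chrom}\tindelsift\texon\t{lo}\t{hi}\t.\t{t.strand}\t.\t"
                        f"ID={t.id}.exon{i};Parent={t.id}"
                    )
                for i, (lo, hi) in enumerate(t.cds, 1):
                    lines.append(
                        f"{g.chrom}\tindelsift\tCDS\t{lo}\t{hi}\t.\t{t.strand}\t0\t"
                        f"ID={t.id}.cds{i};Parent={t.id}"
                    )
        Path(path).write_text("\n".join(lines) + "\n")

    def write_chrom_lengths(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("chrom\tlength_bp\n")
            for chrom, length in self.chrom_lengths.items():
                fh.write(f"{chrom}\t{length}\n")

    def genes_sorted(self):
        return sorted(
            self.model.genes.values(), key=lambda g: (g.chrom, g.start)
        )


def _make_gene(gene_id, chrom, start, length, rng, coding=True) -> Gene:
    """One multi-exon gene; CDS trims UTR margins off the terminal exons."""
    n_exons = int(rng.integers(3, 9))
    exon_lens = rng.integers(120, 400, size=n_exons)
    gap_total = length - int(exon_lens.sum())
    if gap_total < 200 * (n_exons - 1):
        n_exons = max(2, gap_total // 400)
        exon_lens = rng.integers(120, 400, size=n_exons)
        gap_total = length - int(exon_lens.sum())
    gaps = rng.multinomial(gap_total - 200 * (n_exons - 1), [1 / (n_exons - 1)] * (n_exons - 1))
    gaps = gaps + 200
    exons, pos = [], start
    for i, el in enumerate(exon_lens):
        exons.append((pos, pos + int(el) - 1))
        pos = exons[-1][1] + 1 + (int(gaps[i]) if i < n_exons - 1 else 0)
    end = exons[-1][1]
    strand = "+" if rng.random() < 0.5 else "-"
    cds = []
    if coding:
        utr5 = int(rng.integers(30, exon_lens[0] - 30))
        utr3 = int(rng.integers(30, exon_lens[-1] - 30))
        cds = [list(iv) for iv in exons]
        cds[0][0] += utr5
        cds[-1][1] -= utr3
        cds = [tuple(iv) for iv in cds]
    t = Transcript(
        id=f"{gene_id}.t1", exons=exons, cds=cds, strand=strand, coding=coding
    )
    return Gene(id=gene_id, chrom=chrom, strand=strand, start=start, end=end,
                transcripts=[t])


def generate_genome(config: SimulationConfig, rng=None) -> SyntheticGenome:
    """Gene model + genetic map + chromosome table with planted candidate genes.

    Candidate genes sit at fixed chromosome fractions so their planted QTL
    and GWAS evidence cannot interfere with one another; the remaining genes
    fill evenly spaced slots with random jitter.  The genetic map has anchors
    every ~2 Mb with local rates of 0.8–1.2 cM/Mb.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    chroms = config.chromosomes
    genes: list[Gene] = []
    occupied: dict[str, list] = {c: [] for c in chroms}

    def place(gene_id, chrom, start, length, coding):
        start = max(1000, min(start, chroms[chrom] - length - 1000))
        for lo, hi in occupied[chrom]:
            if start <= hi + 1000 and start + length >= lo - 1000:
                start = hi + 1001  # nudge past the conflict
        g = _make_gene(gene_id, chrom, start, length, rng, coding)
        occupied[chrom].append((g.start, g.end))
        genes.append(g)
        return g

    n_cand = len(config.candidate_tiers)
    candidate_ids = []
    for i in range(n_cand):
        chrom, frac = _CANDIDATE_SLOTS[i]
        if chrom not in chroms:
            raise ConfigError(f"candidate slot chromosome {chrom} not configured")
        length = int(rng.integers(8_000, 30_000))
        g = place(f"CAND{i + 1:02d}", chrom, int(frac * chroms[chrom]), length, True)
        candidate_ids.append(g.id)

    total_len = sum(chroms.values())
    n_rest = config.n_genes - n_cand + config.n_noncoding_genes
    if n_rest < 0:
        raise ConfigError("n_genes smaller than the number of candidate genes")
    # distribute remaining genes across chromosomes proportional to length
    alloc = {c: max(1, round(n_rest * l / total_len)) for c, l in chroms.items()}
    gi = 0
    n_noncoding_left = config.n_noncoding_genes
    for chrom, n_c in alloc.items():
        slot = chroms[chrom] / (n_c + 1)
        for j in range(n_c):
            gi += 1
            coding = n_noncoding_left <= 0 or rng.random() > 0.5
            if not coding:
                n_noncoding_left -= 1
            length = int(rng.integers(5_000, 25_000))
            center = (j + 1) * slot * (1 + rng.uniform(-0.08, 0.08))
            prefix = "GENE" if coding else "NCG"
            place(f"{prefix}{gi:03d}", chrom, int(center), length, coding)

    anchors = {}
    for chrom, length in chroms.items():
        bps = list(range(1, length, 2_000_000)) + [length]
        rates = rng.uniform(0.8, 1.2, size=len(bps) - 1)
        cms = np.concatenate([[0.0], np.cumsum(np.diff(bps) / 1e6 * rates)])
        anchors[chrom] = (np.array(bps, dtype=float), cms)
    gmap = GeneticMap(anchors)
    return SyntheticGenome(
        model=GeneModel(genes),
        gmap=gmap,
        chrom_lengths=dict(chroms),
        candidate_gene_ids=candidate_ids,
    )


# --------------------------------------------------------------------------
# cohort
# --------------------------------------------------------------------------


@dataclass
class SyntheticTruth:
    """Planted ground truth for recovery scoring."""

    differential: dict  # key-string -> {direction, freq_high, freq_low, gene}
    candidate_genes: dict  # gene_id -> tier
    union_count: int
    known_overlap: list  # key-strings planted into the known-variant set
    filter_fail_counts: dict
    n_missing_excluded: int

    @staticmethod
    def key_of(variant: IndelVariant) -> str:
        return f"{variant.chrom}:{variant.pos}:{variant.ref}:{variant.alt}"

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=1))

    @classmethod
    def from_json(cls, path) -> "SyntheticTruth":
        return cls(**json.loads(Path(path).read_text()))


_BASES = np.array(list("ACGT"))

_POS_PAIRS = [(1, 0), (2, 0), (2, 1)]  # (high, low) dosages with high > low


class _LengthLaw:
    """Point mass at 1 bp + truncated geometric on 2..max, matching the
    configured single-bp and <10 bp shares."""

    def __init__(self, p_1bp: float, p_lt10: float, max_length: int):
        self.p_1bp = p_1bp
        self.max_length = max_length
        t = (p_lt10 - p_1bp) / (1 - p_1bp)  # P(L < 10 | L >= 2)

        def gap(r):
            ks = np.arange(2, max_length + 1)
            w = r ** (ks - 2)
            return w[ks < 10].sum() / w.sum() - t

        r = brentq(gap, 1e-6, 1 - 1e-9)
        ks = np.arange(2, max_length + 1)
        w = r ** (ks - 2.0)
        self.tail_lengths = ks
        self.tail_probs = w / w.sum()

    def sample(self, n: int, rng) -> np.ndarray:
        one = rng.random(n) < self.p_1bp
        tail = rng.choice(self.tail_lengths, size=n, p=self.tail_probs)
        return np.where(one, 1, tail)


def _random_variant(chrom, pos, length, is_ins, rng) -> IndelVariant:
    anchor = str(rng.choice(_BASES))
    seq = "".join(rng.choice(_BASES, size=length))
    if is_ins:
        return IndelVariant(chrom, pos, anchor, anchor + seq)
    return IndelVariant(chrom, pos, anchor + seq, anchor)


def _planted_pattern(
    direction, rng, target=None
) -> tuple[np.ndarray, np.ndarray, int]:
    """Per-family (high, low) dosage pairs sharing one sign.

    Without a ``target``, pairs are sampled uniformly from the
    sign-consistent set for the requested ``direction``.  With a ``target``
    (freq_high, freq_low) the direction is implied by the target and the four
    pairs are searched exhaustively to realize the exact group dosage sums.
    Returns ``(high, low, direction)``.
    """
    if target is None:
        idx = rng.integers(0, len(_POS_PAIRS), size=4)
        pairs = np.array([_POS_PAIRS[i] for i in idx])
        high, low = pairs[:, 0].copy(), pairs[:, 1].copy()
        if direction < 0:
            high, low = low, high
        return high, low, int(direction)

    fh, fl = target
    direction = 1 if fh > fl else -1
    # search in the "greater side" frame: pairs always have first > second
    want_big, want_small = round(max(fh, fl) * 8), round(min(fh, fl) * 8)
    from itertools import product

    options = [
        combo
        for combo in product(_POS_PAIRS, repeat=4)
        if sum(p[0] for p in combo) == want_big
        and sum(p[1] for p in combo) == want_small
    ]
    if not options:
        raise ConfigError(
            f"frequency target ({fh}, {fl}) unreachable with 4 sib pairs"
        )
    pairs = np.array(options[rng.integers(0, len(options))])
    big, small = pairs[:, 0].copy(), pairs[:, 1].copy()
    return (big, small, 1) if direction > 0 else (small, big, -1)


def _concordant_pass(high: np.ndarray, low: np.ndarray) -> np.ndarray:
    """Vectorized concordant-filter decision for (n_loci, 4) dosage arrays."""
    d = high - low
    return ((d > 0).all(axis=1)) | ((d < 0).all(axis=1))


@dataclass
class Cohort:
    design: FamilyDesign
    samples: list
    records: dict  # sample -> list[CallRecord]
    truth: SyntheticTruth
    chrom_lengths: dict
    background_freqs: np.ndarray  # per-background-locus allele frequency

    def write_design(self, path) -> None:
        self.design.to_tsv(path)

    def genotype_matrix(self):
        """In-memory nonredundant union of the raw records (no call filter).

        Convenience for tests that study the contrast filter directly;
        the file pipeline applies the confidence filter first.
        """
        from .variants import merge_nonredundant

        return merge_nonredundant(self.records)

    def write_vcfs(self, outdir) -> dict:
        """One plain-text VCF 4.2 per sample; returns sample -> path."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {}
        for sample in self.samples:
            lines = [
                "##fileformat=VCFv4.2",
                '##INFO=<ID=DP,Number=1,Type=Integer,Description="Raw depth">',
                '##INFO=<ID=DP4,Number=4,Type=Integer,Description='
                '"Ref-fwd, ref-rev, alt-fwd, alt-rev read counts">',
                '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
                '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
            ]
            for chrom, length in self.chrom_lengths.items():
                lines.append(f"##contig=<ID={chrom},length={length}>")
            lines.append(
                f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample}"
            )
            gt = {0: "0/0", 1: "0/1", 2: "1/1", None: "./."}
            recs = sorted(
                self.records[sample],
                key=lambda r: (r.variant.chrom, r.variant.pos, r.variant.alt),
            )
            for r in recs:
                v = r.variant
                info = f"DP={r.depth};DP4={r.depth - (r.fwd_alt_support or 0) - (r.rev_alt_support or 0)},0,{r.fwd_alt_support or 0},{r.rev_alt_support or 0}"
                lines.append(
                    f"{v.chrom}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t{r.quality:.1f}\t.\t"
                    f"{info}\tGT:DP\t{gt[r.dosage]}:{r.depth}"
                )
            path = outdir / f"{sample}.vcf"
            path.write_text("\n".join(lines) + "\n")
            paths[sample] = path
        return paths


def generate_cohort(
    config: SimulationConfig, genome: SyntheticGenome, rng=None
) -> Cohort:
    """Eight-sample cohort with planted differential loci and filter bait.

    Planted loci satisfy the concordant filter by construction (every family
    polymorphic, one shared sign); one planted locus is embedded in each
    candidate gene.  Background loci receive genotypes from per-locus allele
    frequencies; chance concordant patterns are redrawn unless
    ``exclude_chance_differential`` is off.  A configured number of extra
    records is built to fail each call filter exactly once, for
    rejection-count bookkeeping tests.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    chroms = config.chromosomes
    samples = [f"S{i}" for i in range(1, 9)]
    design = FamilyDesign(
        [(f"F{i}", f"S{2 * i - 1}", f"S{2 * i}") for i in range(1, 5)]
    )
    high_idx = [0, 2, 4, 6]  # S1,S3,S5,S7
    low_idx = [1, 3, 5, 7]

    law = _LengthLaw(config.p_1bp, config.p_lt10, config.max_length)
    names = list(chroms)
    weights = np.array(
        [
            chroms[c] * (config.x_density_multiplier if c in ("chrX", "X") else 1.0)
            for c in names
        ],
        dtype=float,
    )
    weights /= weights.sum()

    used_pos: set = set()

    def fresh_position(chrom=None) -> tuple[str, int]:
        while True:
            c = chrom or names[rng.choice(len(names), p=weights)]
            p = int(rng.integers(1_000, chroms[c] - 1_000))
            if (c, p) not in used_pos:
                used_pos.add((c, p))
                return c, p

    def new_variant(chrom=None, pos=None) -> IndelVariant:
        if pos is None:
            chrom, pos = fresh_position(chrom)
        else:
            used_pos.add((chrom, pos))
        length = int(law.sample(1, rng)[0])
        is_ins = rng.random() < config.ins_fraction
        return _random_variant(chrom, pos, length, is_ins, rng)

    # ---- planted differential loci -------------------------------------
    n_planted = config.n_planted_differential
    cand_ids = genome.candidate_gene_ids
    planted: list[tuple[IndelVariant, np.ndarray, int, Optional[str]]] = []
    directions = rng.permutation(
        np.array([1] * (n_planted // 2) + [-1] * (n_planted - n_planted // 2))
    )
    targets = config.planted_frequency_targets
    for i in range(n_planted):
        gene_id = None
        if i < len(cand_ids):
            gene_id = cand_ids[i]
            g = genome.model.genes[gene_id]
            # middle of the gene body: genic by construction
            pos = (g.start + g.end) // 2
            while (g.chrom, pos) in used_pos:
                pos += 1
            v = new_variant(g.chrom, pos)
        else:
            v = new_variant()
        target = targets[i % len(targets)] if targets else None
        high, low, d = _planted_pattern(int(directions[i]), rng, target)
        dosages = np.empty(8, dtype=int)
        dosages[high_idx] = high
        dosages[low_idx] = low
        planted.append((v, dosages, d, gene_id))

    # ---- background loci ------------------------------------------------
    nb = config.n_background_loci - n_planted
    bg_variants = [new_variant() for _ in range(nb)]
    lo_f, hi_f = config.background_freq_range
    freqs = rng.uniform(lo_f, hi_f, size=nb)
    bg_dosages = rng.binomial(2, freqs[:, None], size=(nb, 8))
    if config.exclude_chance_differential:
        while True:
            passing = _concordant_pass(
                bg_dosages[:, high_idx], bg_dosages[:, low_idx]
            )
            if not passing.any():
                break
            idx = np.flatnonzero(passing)
            bg_dosages[idx] = rng.binomial(2, freqs[idx, None], size=(len(idx), 8))

    # ---- assemble per-sample records ------------------------------------
    all_loci = [(v, d) for v, d, _, _ in planted] + list(zip(bg_variants, bg_dosages))
    n_loci = len(all_loci)
    quals = np.round(rng.uniform(50, 200, size=n_loci), 1)
    depths = np.clip(rng.poisson(8, size=(n_loci, 8)), 2, 99)
    missing = rng.random((n_loci, 8)) < config.missing_call_rate

    dosage_mat = np.stack([d for _, d in all_loci])
    if config.discordant_call_rate > 0:
        flip = rng.random((n_loci, 8)) < config.discordant_call_rate
        dosage_mat = np.where(flip, rng.integers(0, 3, size=(n_loci, 8)), dosage_mat)

    records: dict[str, list[CallRecord]] = {s: [] for s in samples}
    for i, (v, _) in enumerate(all_loci):
        for j, s in enumerate(samples):
            if missing[i, j]:
                continue
            dose = int(dosage_mat[i, j])
            if dose > 0:
                fwd = int(rng.integers(4, 16))
                rev = int(rng.integers(0, 8))
            else:
                fwd = rev = 0
            records[s].append(
                CallRecord(
                    variant=v,
                    dosage=dose,
                    quality=float(quals[i]),
                    depth=int(depths[i, j]),
                    fwd_alt_support=fwd,
                    rev_alt_support=rev,
                )
            )

    # ---- records engineered to fail exactly one filter criterion --------
    m = config.filter_fail_per_criterion
    fail_counts = {"quality": m, "depth": m, "strand_support": m, "length": m}
    for criterion in fail_counts:
        for _ in range(m):
            v = new_variant()
            kw = dict(
                dosage=1,
                quality=float(np.round(rng.uniform(50, 200), 1)),
                depth=int(rng.integers(5, 60)),
                fwd_alt_support=int(rng.integers(4, 16)),
                rev_alt_support=int(rng.integers(0, 3)),
            )
            if criterion == "quality":
                kw["quality"] = float(np.round(rng.uniform(0, 19.4), 1))
            elif criterion == "depth":
                kw["depth"] = int(rng.integers(100, 200))
            elif criterion == "strand_support":
                kw["fwd_alt_support"] = int(rng.integers(0, 4))
                kw["rev_alt_support"] = int(rng.integers(0, 4))
            elif criterion == "length":
                v = _random_variant(
                    v.chrom, v.pos, int(rng.integers(50, 90)),
                    rng.random() < 0.5, rng,
                )
            sample = samples[int(rng.integers(0, 8))]
            records[sample].append(CallRecord(variant=v, **kw))

    # ---- truth -----------------------------------------------------------
    n_overlap = round(config.known_overlap_fraction * n_planted)
    overlap_idx = rng.choice(n_planted, size=n_overlap, replace=False)
    overlap_keys = [SyntheticTruth.key_of(planted[i][0]) for i in sorted(overlap_idx)]

    differential = {}
    for v, dosages, d, gene_id in planted:
        differential[SyntheticTruth.key_of(v)] = {
            "direction": d,
            "freq_high": float(dosages[high_idx].sum() / 8),
            "freq_low": float(dosages[low_idx].sum() / 8),
            "gene": gene_id,
        }
    truth = SyntheticTruth(
        differential=differential,
        candidate_genes=dict(zip(cand_ids, config.candidate_tiers)),
        union_count=n_loci,
        known_overlap=overlap_keys,
        filter_fail_counts=fail_counts,
        n_missing_excluded=int((missing.any(axis=1)).sum()),
    )
    return Cohort(
        design=design,
        samples=samples,
        records=records,
        truth=truth,
        chrom_lengths=dict(chroms),
        background_freqs=freqs,
    )


# --------------------------------------------------------------------------
# evidence resources
# --------------------------------------------------------------------------


@dataclass
class EvidenceResources:
    qtls: list
    gwas_hits: list
    pathways: PathwayGeneSets
    known_keys: list  # key strings in the known-variant set

    def write_qtl_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("trait\tchrom\tci_lo_cM\tci_hi_cM\tpeak_cM\n")
            for q in self.qtls:
                peak = "" if q.peak is None else f"{q.peak:.4f}"
                fh.write(
                    f"{q.trait}\t{q.chrom}\t{q.ci_lo:.4f}\t{q.ci_hi:.4f}\t{peak}\n"
                )

    def write_gwas_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("trait\tchrom\tpos_bp\n")
            for h in self.gwas_hits:
                fh.write(f"{h.trait}\t{h.chrom}\t{h.pos}\n")

    def write_gmt(self, path) -> None:
        with open(path, "w") as fh:
            for name, members in self.pathways.sets.items():
                fh.write("\t".join([name, "synthetic"] + sorted(members)) + "\n")

    def write_known_vcf(self, path, chrom_lengths) -> None:
        lines = ["##fileformat=VCFv4.2"]
        for chrom, length in chrom_lengths.items():
            lines.append(f"##contig=<ID={chrom},length={length}>")
        lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")
        entries = []
        for i, key in enumerate(self.known_keys, 1):
            chrom, pos, ref, alt = key.split(":")
            entries.append((chrom, int(pos), ref, alt, f"rs{900000 + i}"))
        for chrom, pos, ref, alt, vid in sorted(entries):
            lines.append(f"{chrom}\t{pos}\t{vid}\t{ref}\t{alt}\t.\t.\t.")
        Path(path).write_text("\n".join(lines) + "\n")


_TRAITS = ("protein percentage", "fat percentage")


def generate_evidence_resources(
    config: SimulationConfig,
    genome: SyntheticGenome,
    truth: SyntheticTruth,
    rng=None,
) -> EvidenceResources:
    """QTL/GWAS/pathway/known-variant resources wired to the planted tiers.

    For each candidate gene the QTL, GWAS hit and pathway membership needed
    for its target tier are placed; decoy records with unmatched trait labels
    and decoy pathways exercise the trait filter and enrichment machinery.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 2)
    model, gmap = genome.model, genome.gmap
    qtls: list[QTLRecord] = []
    hits: list[GwasHit] = []
    core_membership: dict[str, set] = {p: set() for p in DEFAULT_CORE_PATHWAYS}
    cand_set = set(truth.candidate_genes)

    for i, (gene_id, tier) in enumerate(truth.candidate_genes.items()):
        g = model.genes[gene_id]
        trait = _TRAITS[i % 2]
        cm_lo = gmap.interpolate(g.chrom, g.start)
        cm_hi = gmap.interpolate(g.chrom, g.end)
        mid = 0.5 * (cm_lo + cm_hi)
        # every tier requires a nearby GWAS SNP (< 5 Mb, strict)
        offset = int(rng.integers(300_000, 2_000_000))
        pos = g.end + offset
        if pos >= genome.chrom_lengths[g.chrom]:
            pos = max(1, g.start - offset)
        hits.append(GwasHit(trait=trait, chrom=g.chrom, pos=pos))
        if tier == "A":
            qtls.append(QTLRecord(trait, g.chrom, mid - 3.0, mid + 3.0, peak=mid))
            core_membership[DEFAULT_CORE_PATHWAYS[i % 8]].add(gene_id)
        elif tier == "B":
            qtls.append(QTLRecord(trait, g.chrom, cm_lo - 2.0, cm_hi + 2.0, peak=None))
        elif tier == "C":
            qtls.append(
                QTLRecord(trait, g.chrom, cm_hi + 1.0, cm_hi + 6.0, peak=cm_hi + 2.0)
            )
        elif tier == "D":
            core_membership[DEFAULT_CORE_PATHWAYS[i % 8]].add(gene_id)
        # tier E: the GWAS hit alone

    # decoys: unmatched traits must be ignored by the trait filter
    first_chrom = next(iter(genome.chrom_lengths))
    qtls.append(QTLRecord("somatic cell score", first_chrom, 0.0, 500.0, peak=10.0))
    hits.append(GwasHit("somatic cell score", first_chrom, 1_000_000))

    other_genes = sorted(set(model.genes) - cand_set)
    sets = {}
    for name in DEFAULT_CORE_PATHWAYS:
        fill = rng.choice(other_genes, size=int(rng.integers(5, 12)), replace=False)
        sets[name] = core_membership[name] | set(map(str, fill))
    for name in ("Ribosome", "Spliceosome", "Cell cycle"):
        fill = rng.choice(other_genes, size=int(rng.integers(5, 15)), replace=False)
        sets[name] = set(map(str, fill))
    pathways = PathwayGeneSets(
        sets=sets, core_pathways=frozenset(DEFAULT_CORE_PATHWAYS)
    )

    # known set = planted overlap + decoy entries never seen in the cohort
    known = list(truth.known_overlap)
    for i in range(200):
        chrom = first_chrom
        pos = 5_000_000 + 17 * i  # deterministic, collision-free with cohort? no:
        # cohort positions are random; collide with negligible probability, and a
        # collision only matters if the allele strings also matched
        known.append(f"{chrom}:{pos}:CAT:C")
    return EvidenceResources(
        qtls=qtls, gwas_hits=hits, pathways=pathways, known_keys=known
    )


# --------------------------------------------------------------------------
# recovery scoring
# --------------------------------------------------------------------------


@dataclass
class RecoveryReport:
    n_planted: int
    n_detected: int
    sensitivity: float
    fdp: float
    direction_accuracy: float
    tier_expected: dict
    tier_observed: dict
    tier_accuracy: float

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def evaluate_recovery(
    results: list[DifferentialResult],
    truth: SyntheticTruth,
    candidate_report=None,
) -> RecoveryReport:
    """Score detected differential loci (and optionally tiers) against truth.

    Sensitivity = detected planted / planted; FDP = non-planted detected /
    detected; direction accuracy over true positives.  When a candidate
    report (from :func:`indelsift.evidence.prioritize`) is supplied, each
    planted candidate gene's observed tier is compared with its target.
    """
    planted = truth.differential
    detected = {SyntheticTruth.key_of(r.variant): r for r in results}
    tp = [k for k in detected if k in planted]
    sens = len(tp) / len(planted) if planted else 1.0
    fdp = (len(detected) - len(tp)) / len(detected) if detected else 0.0
    dir_ok = sum(
        1 for k in tp if detected[k].direction == planted[k]["direction"]
    )
    dir_acc = dir_ok / len(tp) if tp else 0.0

    expected = dict(truth.candidate_genes)
    observed: dict[str, str] = {}
    tier_acc = float("nan")
    if candidate_report is not None and len(expected):
        by_gene = (
            candidate_report.set_index("gene_id")["tier"].to_dict()
            if len(candidate_report)
            else {}
        )
        observed = {g: by_gene.get(g, "absent") for g in expected}
        tier_acc = sum(
            1 for g in expected if observed[g] == expected[g]
        ) / len(expected)
    return RecoveryReport(
        n_planted=len(planted),
        n_detected=len(detected),
        sensitivity=sens,
        fdp=fdp,
        direction_accuracy=dir_acc,
        tier_expected=expected,
        tier_observed=observed,
        tier_accuracy=tier_acc,
    )
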