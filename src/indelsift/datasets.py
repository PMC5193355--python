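"""Published candidate-indel genotype and summary tables as in-code fixtures.

These are the printed tables from the eight-bull Holstein resequencing study
this package operationalizes: the sib-family design (four high/low pairs),
the per-sample sequencing statistics, the category counts of the 3,625
common differential indels, and the genotypes of the 25 indels inside the 11
candidate genes.  Genomic coordinates for the candidate indels are synthetic
(the study reports genotypes and indel sequences, not positions); anchors use
base 'A' and each gene is placed on its own pseudo-chromosome, so the rows
are usable as a GenotypeMatrix fixture anywhere a coordinate is required.
"""

from __future__ import annotations

import pandas as pd

from .summaries import SampleStats
from .variants import FamilyDesign, GenotypeMatrix, IndelVariant

__all__ = [
    "family_design",
    "sequencing_stats",
    "annotation_category_counts",
    "exonic_effect_counts",
    "candidate_indel_rows",
    "candidate_genotype_matrix",
    "VALIDATION_ASSAYED",
    "VALIDATION_CONFIRMED",
]

#: indels assayed by PCR + Sanger follow-up, and how many were confirmed
VALIDATION_ASSAYED = 20
VALIDATION_CONFIRMED = 14

#: samples 1,3,5,7 are the high-EBV sibs; 2,4,6,8 their low-EBV pair members
_FAMILIES = [
    ("Full-sib1", "1", "2"),
    ("Full-sib2", "3", "4"),
    ("Half-sib1", "5", "6"),
    ("Half-sib2", "7", "8"),
]


def family_design() -> FamilyDesign:
    """Four high/low sib pairs (two full-sib, two half-sib families)."""
    return FamilyDesign(list(_FAMILIES))


# per-sample: raw reads, mapped reads, uniquely mapped %, coverage %, depth, indels
_SEQ_STATS = [
    ("1", 289_952_310, 261_783_075, 83.75, 98.58, 8, 363_757),
    ("2", 286_870_238, 252_201_294, 81.15, 98.55, 8, 346_453),
    ("3", 292_878_886, 257_840_281, 81.69, 98.59, 8, 366_402),
    ("4", 272_948_496, 241_748_531, 82.97, 98.52, 8, 360_827),
    ("5", 251_953_446, 218_677_291, 82.90, 98.34, 7, 323_490),
    ("6", 337_815_303, 314_651_325, 80.88, 98.40, 10, 411_070),
    ("7", 288_003_254, 253_311_627, 82.45, 98.61, 8, 368_232),
    ("8", 283_359_516, 255_124_411, 85.16, 98.57, 8, 381_119),
]


def sequencing_stats() -> list[SampleStats]:
    return [SampleStats(*row) for row in _SEQ_STATS]


def annotation_category_counts() -> dict[str, int]:
    """Category counts of the 3,625 common differential indels."""
    return {
        "intergenic": 2488,
        "upstream": 30,
        "downstream": 24,
        "upstream;downstream": 1,
        "UTR3": 10,
        "splicing": 1,
        "ncRNA_exonic": 1,
        "intronic": 1065,
        "exonic": 5,
    }


def exonic_effect_counts() -> dict[str, int]:
    return {
        "nonframeshift_deletion": 1,
        "nonframeshift_insertion": 2,
        "frameshift_deletion": 1,
        "frameshift_insertion": 1,
    }


# (gene, kind, location, sequence, genotypes for samples 1,3,5,7 then 2,4,6,8)
_CANDIDATE_ROWS = [
    ("FCGR2B", "ins", "exon", "G",
     ["ins/del", "del/del", "ins/del", "del/del",
      "ins/ins", "ins/del", "ins/ins", "ins/del"]),
    ("CENPE", "ins", "exon", "AGA",
     ["del/del", "del/del", "del/del", "del/del",
      "ins/del", "ins/del", "ins/ins", "ins/ins"]),
    ("CENPE", "del", "exon", "TAG",
     ["ins/ins", "ins/ins", "del/ins", "ins/ins",
      "del/ins", "del/ins", "del/del", "del/del"]),
    ("CENPE", "ins", "intron", "GTT",
     ["del/del", "del/del", "del/del", "ins/del",
      "ins/del", "ins/del", "ins/ins", "ins/ins"]),
    ("CENPE", "ins", "intron", "T",
     ["del/del", "del/del", "ins/del", "ins/del",
      "ins/del", "ins/del", "ins/ins", "ins/ins"]),
    ("CENPE", "del", "intron", "A",
     ["ins/ins", "ins/ins", "ins/ins", "del/ins",
      "del/del", "del/ins", "del/del", "del/del"]),
    ("CENPE", "ins", "intron", "ACTTAAGTATATAACCTTAAC",
     ["del/del", "del/del", "del/del", "del/del",
      "ins/del", "ins/del", "ins/ins", "ins/ins"]),
    ("CENPE", "del", "intron", "CC",
     ["ins/ins", "ins/ins", "del/ins", "del/ins",
      "del/ins", "del/ins", "del/del", "del/del"]),
    ("CENPE", "del", "intron", "C",
     ["ins/ins", "ins/ins", "ins/ins", "del/ins",
      "del/ins", "del/ins", "del/del", "del/del"]),
    ("CENPE", "ins", "intron", "ACAC",
     ["ins/del", "ins/ins", "ins/ins", "ins/ins",
      "del/del", "ins/del", "del/del", "del/del"]),
    ("RETSAT", "del", "3'UTR", "AA",
     ["del/del", "del/ins", "del/del", "del/ins",
      "ins/ins", "ins/ins", "del/ins", "ins/ins"]),
    ("RETSAT", "ins", "intron", "ATTCTGGGG",
     ["ins/ins", "ins/del", "ins/ins", "ins/del",
      "del/del", "del/del", "del/del", "del/del"]),
    ("ACSBG2", "ins", "upstream", "GGC",
     ["ins/ins", "ins/ins", "ins/ins", "ins/ins",
      "del/del", "del/del", "ins/del", "ins/del"]),
    ("ACSBG2", "ins", "intron", "C",
     ["ins/ins", "ins/ins", "ins/ins", "ins/ins",
      "del/del", "del/del", "ins/del", "ins/del"]),
    ("NFKB2", "ins", "upstream", "GG",
     ["ins/ins", "ins/ins", "ins/ins", "ins/ins",
      "del/del", "del/del", "del/del", "del/del"]),
    ("TBC1D1", "del", "intron", "T",
     ["ins/ins", "ins/ins", "ins/ins", "ins/ins",
      "del/ins", "del/ins", "del/ins", "del/ins"]),
    ("NLK", "ins", "intron", "T",
     ["ins/ins", "ins/del", "ins/ins", "ins/ins",
      "del/del", "del/del", "ins/del", "ins/del"]),
    ("NLK", "del", "intron", "AT",
     ["del/ins", "del/ins", "del/del", "del/del",
      "ins/ins", "ins/ins", "del/ins", "del/ins"]),
    ("NLK", "del", "intron", "A",
     ["del/ins", "del/ins", "del/del", "del/del",
      "ins/ins", "ins/ins", "del/ins", "del/ins"]),
    ("NLK", "del", "intron", "AAAA",
     ["ins/ins", "del/ins", "ins/ins", "ins/ins",
      "del/ins", "del/del", "del/ins", "del/del"]),
    ("MAP3K1", "del", "intron", "CATTT",
     ["ins/ins", "ins/ins", "ins/ins", "del/ins",
      "del/del", "del/del", "del/ins", "del/del"]),
    ("SLC30A2", "del", "intron", "TTTTTG",
     ["del/ins", "del/ins", "del/ins", "del/ins",
      "ins/ins", "ins/ins", "ins/ins", "ins/ins"]),
    ("ANGPT1", "ins", "intron", "AT",
     ["del/del", "del/del", "del/del", "del/del",
      "ins/ins", "ins/ins", "ins/ins", "ins/del"]),
    ("UGDH", "ins", "intron", "T",
     ["del/del", "del/del", "del/del", "del/del",
      "ins/ins", "ins/del", "ins/ins", "ins/del"]),
    ("UGDH", "ins", "intron", "G",
     ["del/del", "del/del", "del/del", "del/del",
      "ins/ins", "ins/del", "ins/ins", "ins/del"]),
]

#: column order of the published genotype table: high sibs first
_GT_SAMPLE_ORDER = ["1", "3", "5", "7", "2", "4", "6", "8"]


def candidate_indel_rows() -> pd.DataFrame:
    """The 25 candidate-gene indel rows with genotypes as printed."""
    rows = []
    for gene, kind, location, seq, gts in _CANDIDATE_ROWS:
        row = {"gene": gene, "kind": kind, "location": location, "sequence": seq}
        row.update(dict(zip(_GT_SAMPLE_ORDER, gts)))
        rows.append(row)
    return pd.DataFrame(rows)


def _dosage(genotype: str, alt_label: str) -> int:
    return genotype.split("/").count(alt_label)


def candidate_genotype_matrix() -> tuple[GenotypeMatrix, FamilyDesign]:
    """The 25 rows as an alt-allele dosage matrix with the sib-pair design.

    For an insertion row the alternate allele is the inserted form
    (``ins/ins`` → dosage 2); for a deletion row it is the deleted form.
    Coordinates are synthetic: one pseudo-chromosome per gene, rows spaced
    10 kb apart.
    """
    gene_chrom: dict[str, str] = {}
    variants, dosage_rows = [], []
    pos_in_gene: dict[str, int] = {}
    for gene, kind, _loc, seq, gts in _CANDIDATE_ROWS:
        chrom = gene_chrom.setdefault(gene, f"chr{len(gene_chrom) + 1}")
        pos_in_gene[gene] = pos_in_gene.get(gene, 0) + 1
        pos = 10_000 * pos_in_gene[gene]
        if kind == "ins":
            ref, alt = "A", "A" + seq
        else:
            ref, alt = "A" + seq, "A"
        variants.append(IndelVariant(chrom, pos, ref, alt))
        dosage_rows.append([_dosage(g, kind) for g in gts])

    samples = list("12345678")
    data = {
        s: pd.array(
            [dosage_rows[i][_GT_SAMPLE_ORDER.index(s)] for i in range(len(variants))],
            dtype="Int8",
        )
        for s in samples
    }
    matrix = GenotypeMatrix(
        variants=variants, samples=samples, dosages=pd.DataFrame(data, columns=samples)
    )
    return matrix, family_design()
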