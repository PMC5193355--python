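"""Candidate-gene evidence tiers from QTL, GWAS and pathway resources.

Profiles genes carrying differential indels against QTL confidence
intervals, QTL peak proximity (< 5 cM), GWAS SNP proximity (< 5 Mb) and
membership in the eight core protein/fat-metabolism pathways, then assigns
rule-based tiers A-E.
"""

from indelsift.annotation import AnnotationRecord, Gene, GeneModel, Transcript
from indelsift.evidence import (
    GeneticMap,
    GwasHit,
    PathwayGeneSets,
    QTLRecord,
    prioritize,
)
from indelsift.variants import IndelVariant


def gene(gid, start):
    end = start + 20_000
    return Gene(gid, "chr1", "+", start, end, [
        Transcript(f"{gid}.t", [(start, end)], [(start + 100, end - 100)],
                   "+", True)
    ])


model = GeneModel([gene("ACSL_like", 1_000_000), gene("KINASE_like", 12_000_000),
                   gene("TRANSPORTER_like", 24_000_000)])
# ~1 cM per Mb map
gmap = GeneticMap({"chr1": ([1, 30_000_000], [0.0, 30.0])})

qtls = [
    QTLRecord("protein percentage", "chr1", 0.0, 3.0, peak=1.2),    # covers gene 1
    QTLRecord("fat percentage", "chr1", 10.0, 14.0, peak=None),     # covers gene 2
]
hits = [
    GwasHit("protein percentage", "chr1", 1_300_000),
    GwasHit("fat percentage", "chr1", 13_500_000),
    GwasHit("protein percentage", "chr1", 24_800_000),
]
pathways = PathwayGeneSets(
    sets={"PPAR signaling pathway": {"ACSL_like"}},
    core_pathways=frozenset({"PPAR signaling pathway"}),
)

records = [
    AnnotationRecord(IndelVariant("chr1", 1_010_000, "A", "AT"), "intronic",
                     ("ACSL_like",)),
    AnnotationRecord(IndelVariant("chr1", 12_005_000, "AC", "A"), "intronic",
                     ("KINASE_like",)),
    AnnotationRecord(IndelVariant("chr1", 24_010_000, "A", "AGG"), "intronic",
                     ("TRANSPORTER_like",)),
]
report = prioritize(records, qtls, hits, pathways, gmap, model)
print(report[["gene_id", "qtl_ci_overlap", "qtl_peak_within", "gwas_within",
              "core_pathway", "tier", "gwas_distance_bp"]].to_string(index=False))
print("\nTier A = QTL peak + GWAS SNP + core pathway; B = QTL interval + "
      "SNP; E = SNP only. Distances use strict '< 5 cM' / '< 5 Mb' rules.")
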