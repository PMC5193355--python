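"""Gene-model annotation of indels, frameshift classification and novelty.

Each variant receives exactly one primary category, assigned by precedence

    exonic > splicing > ncRNA_exonic > UTR5 > UTR3 > intronic >
    upstream / downstream / upstream;downstream > intergenic

mirroring the conventional gene-based annotator hierarchy.  A variant inside
a CDS is additionally classified as frameshift (length not divisible by 3)
or nonframeshift ("3n") insertion/deletion.  Novelty is exact-key membership
against a known-variant set normalized by the same rule as the queries.

Overlap convention (VCF anchor coordinates): an insertion occupies its anchor
base ``pos``; a deletion occupies the deleted span ``[pos+1, pos+length]``
(anchor excluded).
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Optional

import pandas as pd
from intervaltree import IntervalTree

from ._util import round_half_away
from .errors import ModelValidationError, ValidationError
from .variants import IndelVariant, normalize_indel

__all__ = [
    "Transcript",
    "Gene",
    "GeneModel",
    "AnnotationRecord",
    "KnownVariantSet",
    "CATEGORIES",
    "annotate_variant",
    "classify_exonic_effect",
    "annotation_summary",
    "summarize_counts",
    "novelty_assessment",
]

CATEGORIES = (
    "exonic",
    "splicing",
    "ncRNA_exonic",
    "UTR5",
    "UTR3",
    "intronic",
    "upstream",
    "downstream",
    "upstream;downstream",
    "intergenic",
)
_PRECEDENCE = {c: i for i, c in enumerate(CATEGORIES)}

EXONIC_EFFECTS = (
    "frameshift_insertion",
    "frameshift_deletion",
    "nonframeshift_insertion",
    "nonframeshift_deletion",
)


@dataclass
class Transcript:
    id: str
    exons: list[tuple[int, int]]  # 1-based inclusive, sorted
    cds: list[tuple[int, int]]
    strand: str
    coding: bool

    def validate(self):
        for lo, hi in self.exons + self.cds:
            if lo > hi:
                raise ModelValidationError(f"inverted interval in {self.id}: {lo}>{hi}")
        for i in range(1, len(self.exons)):
            if self.exons[i][0] <= self.exons[i - 1][1]:
                raise ModelValidationError(f"overlapping exons in {self.id}")
        for lo, hi in self.cds:
            if not any(elo <= lo and hi <= ehi for elo, ehi in self.exons):
                raise ModelValidationError(f"CDS outside exons in {self.id}")

    @property
    def span(self) -> tuple[int, int]:
        return (self.exons[0][0], self.exons[-1][1])

    @property
    def cds_span(self) -> Optional[tuple[int, int]]:
        if not self.cds:
            return None
        return (self.cds[0][0], self.cds[-1][1])


@dataclass
class Gene:
    id: str
    chrom: str
    strand: str
    start: int
    end: int
    transcripts: list[Transcript] = field(default_factory=list)

    @property
    def coding(self) -> bool:
        return any(t.coding for t in self.transcripts)


class GeneModel:
    """Indexed gene set supporting fast interval queries per chromosome."""

    def __init__(self, genes: list[Gene]):
        self.genes: dict[str, Gene] = {}
        self._trees: dict[str, IntervalTree] = {}
        for g in genes:
            if g.start > g.end:
                raise ModelValidationError(f"inverted gene span for {g.id}")
            for t in g.transcripts:
                t.validate()
            self.genes[g.id] = g
            # half-open tree coordinates; data = gene id
            self._trees.setdefault(g.chrom, IntervalTree())[g.start : g.end + 1] = g.id

    @property
    def chromosomes(self) -> list[str]:
        return list(self._trees)

    def __len__(self) -> int:
        return len(self.genes)

    def overlapping(self, chrom: str, lo: int, hi: int, pad: int = 0) -> list[Gene]:
        """Genes whose span (padded by ``pad`` bp) intersects [lo, hi]."""
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        hits = tree.overlap(lo - pad, hi + 1 + pad)
        return [self.genes[iv.data] for iv in hits]

    @classmethod
    def from_gff3(cls, path) -> "GeneModel":
        """Load from GFF3 (gffutils, in-memory db).

        Coding status is inferred from the presence of CDS features; genes of
        type ``ncRNA_gene`` (or transcripts without CDS) are noncoding.
        """
        import gffutils

        db = gffutils.create_db(
            str(path),
            dbfn=":memory:",
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
        )
        genes = []
        for gf in db.features_of_type(("gene", "ncRNA_gene")):
            transcripts = []
            for tf in db.children(gf, level=1):
                exons = sorted(
                    (f.start, f.end) for f in db.children(tf, featuretype="exon")
                )
                cds = sorted(
                    (f.start, f.end) for f in db.children(tf, featuretype="CDS")
                )
                if not exons:
                    continue
                transcripts.append(
                    Transcript(
                        id=tf.id,
                        exons=exons,
                        cds=cds,
                        strand=tf.strand,
                        coding=bool(cds),
                    )
                )
            genes.append(
                Gene(
                    id=gf.id,
                    chrom=gf.seqid,
                    strand=gf.strand,
                    start=gf.start,
                    end=gf.end,
                    transcripts=transcripts,
                )
            )
        return cls(genes)


@dataclass
class AnnotationRecord:
    """One variant's primary category, associated genes and exonic effect."""

    variant: IndelVariant
    category: str
    gene_ids: tuple[str, ...] = ()
    exonic_effect: Optional[str] = None
    novel: Optional[bool] = None

    def __post_init__(self):
        if self.category not in CATEGORIES:
            raise ValidationError(f"unknown category {self.category!r}")
        if (self.exonic_effect is not None) != (self.category == "exonic"):
            raise ValidationError("exonic_effect present iff category == exonic")


def variant_span(variant: IndelVariant) -> tuple[int, int]:
    """Genomic footprint: anchor base for INS, deleted span for DEL."""
    if variant.is_insertion:
        return (variant.pos, variant.pos)
    return (variant.pos + 1, variant.pos + variant.length)


def classify_exonic_effect(variant: IndelVariant) -> str:
    """Frameshift iff length is not divisible by 3; suffix by variant type."""
    if variant.length == 0:
        raise ValidationError("zero-length variant has no exonic effect")
    frame = "frameshift" if variant.length % 3 != 0 else "nonframeshift"
    kind = "insertion" if variant.is_insertion else "deletion"
    return f"{frame}_{kind}"


def _overlaps(lo: int, hi: int, ivs) -> bool:
    return any(lo <= b and a <= hi for a, b in ivs)


def _transcript_category(lo: int, hi: int, t: Transcript, splice_window: int) -> Optional[str]:
    """Category of span [lo, hi] relative to one transcript, or None if outside."""
    tlo, thi = t.span
    if hi < tlo or lo > thi:
        return None
    if t.coding and _overlaps(lo, hi, t.cds):
        return "exonic"
    # splice windows: first/last bases of each intron
    for i in range(1, len(t.exons)):
        intron_lo = t.exons[i - 1][1] + 1
        intron_hi = t.exons[i][0] - 1
        if intron_lo > intron_hi:
            continue
        w = min(splice_window, intron_hi - intron_lo + 1)
        if _overlaps(lo, hi, [(intron_lo, intron_lo + w - 1), (intron_hi - w + 1, intron_hi)]):
            return "splicing"
    if _overlaps(lo, hi, t.exons):
        if not t.coding:
            return "ncRNA_exonic"
        clo, chi = t.cds_span
        # exonic but outside the CDS span: a UTR; side determined by strand
        if hi < clo:
            return "UTR5" if t.strand == "+" else "UTR3"
        if lo > chi:
            return "UTR3" if t.strand == "+" else "UTR5"
        # inside CDS span but not in CDS intervals on a coding transcript:
        # intron-within-CDS, fall through
    return "intronic"


def annotate_variant(
    variant: IndelVariant,
    model: GeneModel,
    upstream_window: int = 1000,
    downstream_window: Optional[int] = None,
    splice_window: int = 2,
) -> AnnotationRecord:
    """Assign the primary functional category of one normalized variant.

    All genes the variant overlaps are recorded in ``gene_ids``; for flanking
    categories the flanking gene(s) are recorded.  A variant upstream of one
    gene and downstream of another (and in no gene body) is categorized
    ``upstream;downstream``.  A chromosome absent from the model yields
    ``intergenic`` with a warning.
    """
    if downstream_window is None:
        downstream_window = upstream_window
    lo, hi = variant_span(variant)
    if variant.chrom not in model._trees:
        warnings.warn(
            f"chromosome {variant.chrom} absent from gene model; "
            f"{variant} annotated intergenic",
            stacklevel=2,
        )
        return AnnotationRecord(variant, "intergenic")

    pad = max(upstream_window, downstream_window)
    nearby = model.overlapping(variant.chrom, lo, hi, pad=pad)
    best: Optional[str] = None
    genic_ids: list[str] = []
    upstream_ids: list[str] = []
    downstream_ids: list[str] = []
    for gene in nearby:
        if hi >= gene.start and lo <= gene.end:
            cats = [
                _transcript_category(lo, hi, t, splice_window)
                for t in gene.transcripts
            ]
            cats = [c for c in cats if c is not None]
            cat = min(cats, key=_PRECEDENCE.get, default="intronic")
            genic_ids.append(gene.id)
        else:
            before = hi < gene.start  # variant 5' of gene in genome coordinates
            if gene.strand == "+":
                cat = "upstream" if before else "downstream"
            else:
                cat = "downstream" if before else "upstream"
            window = upstream_window if cat == "upstream" else downstream_window
            dist = gene.start - hi if before else lo - gene.end
            if dist > window:
                continue
            (upstream_ids if cat == "upstream" else downstream_ids).append(gene.id)
        if best is None or _PRECEDENCE[cat] < _PRECEDENCE[best]:
            best = cat

    if genic_ids:
        effect = classify_exonic_effect(variant) if best == "exonic" else None
        return AnnotationRecord(variant, best, tuple(sorted(genic_ids)), effect)
    if upstream_ids and downstream_ids:
        return AnnotationRecord(
            variant,
            "upstream;downstream",
            tuple(sorted(set(upstream_ids + downstream_ids))),
        )
    if upstream_ids or downstream_ids:
        ids = upstream_ids or downstream_ids
        return AnnotationRecord(variant, best, tuple(sorted(set(ids))))
    return AnnotationRecord(variant, "intergenic")


def annotate_all(
    variants,
    model: GeneModel,
    upstream_window: int = 1000,
    downstream_window: Optional[int] = None,
    splice_window: int = 2,
) -> list[AnnotationRecord]:
    return [
        annotate_variant(v, model, upstream_window, downstream_window, splice_window)
        for v in variants
    ]


def summarize_counts(
    category_counts: dict[str, int],
    exonic_effect_counts: Optional[dict[str, int]] = None,
    gene_counts: Optional[dict[str, int]] = None,
) -> pd.DataFrame:
    """Category count/percentage table from raw counts.

    Percentages are ``100·count/total`` rounded half-away-from-zero to three
    decimals (the printed convention).  The table carries two derived rows:
    ``All`` (the total) and ``Genic`` (all non-intergenic categories), plus
    one row per exonic effect when provided.
    """
    unknown = set(category_counts) - set(CATEGORIES)
    if unknown:
        raise ValidationError(f"unknown categories {sorted(unknown)}")
    total = sum(category_counts.values())
    if total == 0:
        raise ValidationError("no annotation records to summarize")
    rows = [{"category": "All", "kind": "total", "count": total, "pct": 100.0}]
    for cat in CATEGORIES:
        n = category_counts.get(cat, 0)
        if n == 0 and cat not in category_counts:
            continue
        rows.append(
            {"category": cat, "kind": "category", "count": n,
             "pct": round_half_away(100 * n / total, 3)}
        )
    genic = total - category_counts.get("intergenic", 0)
    rows.append(
        {"category": "Genic", "kind": "derived", "count": genic,
         "pct": round_half_away(100 * genic / total, 3)}
    )
    if exonic_effect_counts:
        for eff in EXONIC_EFFECTS:
            if eff in exonic_effect_counts:
                rows.append(
                    {"category": eff, "kind": "exonic_effect",
                     "count": exonic_effect_counts[eff], "pct": None}
                )
    df = pd.DataFrame(rows)
    if gene_counts:
        df.attrs.update(gene_counts)
    return df


def annotation_summary(records: list[AnnotationRecord]) -> pd.DataFrame:
    """Summary table for a list of annotation records.

    Beyond category counts/percentages, records the number of distinct genes
    associated with non-intergenic variants under two conventions in
    ``DataFrame.attrs``: ``genes_any_overlap`` (every listed gene id) and
    ``genes_primary`` (counting a gene only through variants whose primary
    category is genic, which here coincides because intergenic records carry
    no gene ids).
    """
    if not records:
        raise ValidationError("no annotation records to summarize")
    cats = Counter(r.category for r in records)
    effects = Counter(
        r.exonic_effect for r in records if r.exonic_effect is not None
    )
    genes_any = {g for r in records for g in r.gene_ids}
    genes_primary = {
        g for r in records if r.category != "intergenic" for g in r.gene_ids
    }
    return summarize_counts(
        dict(cats),
        dict(effects),
        {"genes_any_overlap": len(genes_any), "genes_primary": len(genes_primary)},
    )


@dataclass
class KnownVariantSet:
    """Normalized (chrom, pos, ref, alt) keys of a known-variant resource."""

    keys: set[tuple]
    source: str = "unknown"
    version: str = ""

    @classmethod
    def from_vcf(cls, path, source: str = "", version: str = "") -> "KnownVariantSet":
        import pysam

        keys = set()
        with pysam.VariantFile(str(path)) as vf:
            for rec in vf:
                if rec.alts is None:
                    continue
                for alt in rec.alts:
                    if alt is None or alt.startswith("<") or alt in ("*", "."):
                        continue
                    if len(alt) == len(rec.ref):
                        continue
                    v = IndelVariant(rec.chrom, rec.pos, rec.ref.upper(), alt.upper())
                    keys.add(normalize_indel(v).key)
        return cls(keys=keys, source=source or str(path), version=version)

    def __contains__(self, variant: IndelVariant) -> bool:
        return variant.key in self.keys


def novelty_assessment(
    variants: list[IndelVariant], known: KnownVariantSet
) -> tuple[list[bool], float]:
    """Flag variants absent from the known set; return flags and novel %.

    The fraction is reported as a percentage rounded to two decimals.
    Matching is exact on normalized keys — no positional fuzz.
    """
    flags = [v.key not in known.keys for v in variants]
    if not variants:
        return flags, 0.0
    pct = round_half_away(100 * sum(flags) / len(variants), 2)
    return flags, pct
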