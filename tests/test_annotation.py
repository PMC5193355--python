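"""Gene-model annotation: category precedence, frameshift rule, UTR/strand
semantics, fuzz oracle, summaries and novelty."""

import warnings

import numpy as np
import pytest

from indelsift.annotation import (
    CATEGORIES,
    AnnotationRecord,
    Gene,
    GeneModel,
    KnownVariantSet,
    Transcript,
    annotate_variant,
    annotation_summary,
    classify_exonic_effect,
    novelty_assessment,
    summarize_counts,
    variant_span,
)
from indelsift.errors import ValidationError
from indelsift.variants import IndelVariant

from conftest import toy_gene


def ins(pos, seq="T", chrom="chr1"):
    return IndelVariant(chrom, pos, "A", "A" + seq)


def dele(pos, n=1, chrom="chr1"):
    return IndelVariant(chrom, pos, "A" + "C" * n, "A")


# --------------------------------------------------------------------------
# categories on the toy model
# --------------------------------------------------------------------------
# toy G1 (+): exons 1000-1199 / 1400-1599 / 1800-1999; CDS 1050-1949 across
# exons; N1 (-): noncoding, exons 5000-5199 / 5400-5599.


@pytest.mark.parametrize(
    "variant,category",
    [
        (ins(1100), "exonic"),            # inside CDS of exon 1
        (dele(1099, 3), "exonic"),        # deleted span 1100-1102 in CDS
        (ins(1020), "UTR5"),              # exon 1 before CDS start (+ strand)
        (ins(1970), "UTR3"),              # exon 3 after CDS end (+ strand)
        (ins(1200), "splicing"),          # first base of intron 1
        (ins(1399), "splicing"),          # last base of intron 1
        (ins(1300), "intronic"),          # mid-intron
        (ins(500), "upstream"),           # 500 bp 5' of a + strand gene
        (ins(2500), "downstream"),        # 3' of a + strand gene
        (ins(5100), "ncRNA_exonic"),      # noncoding exon
        (ins(5300), "intronic"),          # noncoding intron
        (ins(4500), "downstream"),        # 5' in genome = 3' of the - strand N1
        (ins(3500), "intergenic"),        # beyond both windows
    ],
)
def test_category_assignment(toy_model, variant, category):
    rec = annotate_variant(variant, toy_model)
    assert rec.category == category
    assert (rec.category == "intergenic") == (rec.gene_ids == ())


def test_upstream_downstream_both(toy_model):
    """A variant upstream of one gene and downstream of another, in neither
    gene body, gets the combined category with both gene ids."""
    # G1 (+) ends at 1999 -> downstream side; N1 (-) starts at 5000 and is on
    # the minus strand, so the region 5' of its start is its downstream side.
    # Build a plus-strand gene to the right instead so the site is upstream of it.
    g2 = toy_gene("G2")
    g2 = Gene("G2", "chr1", "+", 2600, 3599, [
        Transcript("G2.t1", [(2600, 3599)], [(2700, 3499)], "+", True)
    ])
    model = GeneModel([toy_gene(), g2])
    rec = annotate_variant(ins(2400), model)
    assert rec.category == "upstream;downstream"
    assert set(rec.gene_ids) == {"G1", "G2"}


def test_deletion_span_excludes_anchor(toy_model):
    """A deletion anchored on the last intron base whose deleted bases lie in
    the following exon is exonic: overlap uses [pos+1, pos+len]."""
    assert variant_span(dele(1399, 2)) == (1400, 1401)
    rec = annotate_variant(dele(1399, 2), toy_model)
    assert rec.category == "exonic"


def test_exonic_precedence_over_flanking(toy_model):
    """A CDS variant near another gene's window still reports exonic."""
    g2 = Gene("G2", "chr1", "+", 2300, 2999, [
        Transcript("G2.t1", [(2300, 2999)], [(2400, 2899)], "+", True)
    ])
    model = GeneModel([toy_gene(), g2])
    rec = annotate_variant(ins(1900), model)  # CDS of G1, 400bp upstream of G2
    assert rec.category == "exonic"
    assert rec.gene_ids == ("G1",)


def test_missing_chromosome_warns_intergenic(toy_model):
    with warnings.catch_warnings(record=True) as w:
        warnings.simplefilter("always")
        rec = annotate_variant(ins(100, chrom="chr9"), toy_model)
    assert rec.category == "intergenic" and len(w) == 1


def _mirror_model(model, L, flip_strand):
    genes = []
    for g in model.genes.values():
        ts = []
        for t in g.transcripts:
            m = lambda iv: (L + 1 - iv[1], L + 1 - iv[0])
            strand = ("-" if t.strand == "+" else "+") if flip_strand else t.strand
            ts.append(
                Transcript(t.id, sorted(m(e) for e in t.exons),
                           sorted(m(c) for c in t.cds), strand, t.coding)
            )
        strand = ("-" if g.strand == "+" else "+") if flip_strand else g.strand
        genes.append(Gene(g.id, g.chrom, strand, L + 1 - g.end, L + 1 - g.start, ts))
    return GeneModel(genes)


@pytest.mark.parametrize("flip_strand", [True, False])
def test_strand_mirror_symmetry(toy_model, flip_strand):
    """Reverse-complementing (coordinate mirror + strand flip) preserves every
    category; a bare coordinate mirror with strands kept swaps the
    strand-polarized categories (upstream/downstream, UTR5/UTR3)."""
    L = 10_000
    mirrored = _mirror_model(toy_model, L, flip_strand)
    swap = (
        {}
        if flip_strand
        else {"upstream": "downstream", "downstream": "upstream",
              "UTR5": "UTR3", "UTR3": "UTR5"}
    )
    for pos in (500, 1100, 1300, 2500, 5100, 3500, 1020, 1970, 4500):
        a = annotate_variant(ins(pos), toy_model).category
        b = annotate_variant(ins(L + 1 - pos), mirrored).category
        assert b == swap.get(a, a), f"pos {pos}: {a} vs {b}"


# --------------------------------------------------------------------------
# exonic effect
# --------------------------------------------------------------------------


def test_classify_exonic_effect_exhaustive():
    for length in range(1, 50):
        i = IndelVariant("chr1", 10, "A", "A" + "G" * length)
        d = IndelVariant("chr1", 10, "A" + "G" * length, "A")
        frame = "frameshift" if length % 3 else "nonframeshift"
        assert classify_exonic_effect(i) == f"{frame}_insertion"
        assert classify_exonic_effect(d) == f"{frame}_deletion"


# --------------------------------------------------------------------------
# fuzz against a naive membership oracle
# --------------------------------------------------------------------------


def oracle_category(pos, genes, window=1000, splice=2):
    """Naive re-derivation of the category of a 1-bp insertion at ``pos``."""
    per_gene = []
    flank = []
    for g in genes:
        t = g.transcripts[0]
        if g.start <= pos <= g.end:
            if any(lo <= pos <= hi for lo, hi in t.cds):
                per_gene.append("exonic")
                continue
            in_splice = False
            for i in range(1, len(t.exons)):
                ilo, ihi = t.exons[i - 1][1] + 1, t.exons[i][0] - 1
                if ilo <= pos <= ihi and (pos - ilo < splice or ihi - pos < splice):
                    in_splice = True
            if in_splice:
                per_gene.append("splicing")
            elif any(lo <= pos <= hi for lo, hi in t.exons):
                if not t.coding:
                    per_gene.append("ncRNA_exonic")
                else:
                    clo, chi = t.cds[0][0], t.cds[-1][1]
                    if pos < clo:
                        per_gene.append("UTR5" if t.strand == "+" else "UTR3")
                    elif pos > chi:
                        per_gene.append("UTR3" if t.strand == "+" else "UTR5")
                    else:
                        per_gene.append("intronic")
            else:
                per_gene.append("intronic")
        elif 0 < g.start - pos <= window:
            flank.append("upstream" if g.strand == "+" else "downstream")
        elif 0 < pos - g.end <= window:
            flank.append("downstream" if g.strand == "+" else "upstream")
    if per_gene:
        return min(per_gene, key=CATEGORIES.index)
    if "upstream" in flank and "downstream" in flank:
        return "upstream;downstream"
    if flank:
        return flank[0]
    return "intergenic"


def random_toy_model(rng):
    genes = []
    start = 2000
    for gi in range(2):
        n_exons = int(rng.integers(2, 5))
        exons, pos = [], start
        for _ in range(n_exons):
            e = pos + int(rng.integers(50, 300))
            exons.append((pos, e))
            pos = e + 1 + int(rng.integers(20, 400))
        coding = bool(rng.random() < 0.8)
        cds = []
        if coding:
            cds = [list(iv) for iv in exons]
            cds[0][0] += int(rng.integers(0, exons[0][1] - exons[0][0]))
            cds[-1][1] -= int(rng.integers(0, exons[-1][1] - exons[-1][0]))
            cds = [tuple(iv) for iv in cds]
        strand = "+" if rng.random() < 0.5 else "-"
        g = Gene(f"g{gi}", "chr1", strand, exons[0][0], exons[-1][1],
                 [Transcript(f"g{gi}.t", exons, cds, strand, coding)])
        genes.append(g)
        start = exons[-1][1] + int(rng.integers(1500, 6000))
    return genes


def test_annotation_matches_interval_oracle():
    rng = np.random.default_rng(42)
    for trial in range(40):
        genes = random_toy_model(rng)
        model = GeneModel(genes)
        span_hi = genes[-1].end + 2000
        for pos in rng.integers(1, span_hi, size=25):
            got = annotate_variant(ins(int(pos)), model).category
            want = oracle_category(int(pos), genes)
            assert got == want, f"trial {trial} pos {pos}: {got} != {want}"


# --------------------------------------------------------------------------
# summary + novelty
# --------------------------------------------------------------------------


def test_summary_partition_and_percentages(toy_model):
    variants = [ins(1100), ins(1300), ins(500), ins(3500), dele(1099, 3)]
    records = [annotate_variant(v, toy_model) for v in variants]
    df = annotation_summary(records)
    body = df[df["kind"] == "category"]
    assert body["count"].sum() == len(variants)
    pct = body["pct"].dropna().sum()
    assert abs(pct - 100.0) <= 0.005 * len(body)
    genic = df.loc[df["category"] == "Genic", "count"].iloc[0]
    assert genic == sum(1 for r in records if r.category != "intergenic")


def test_single_intergenic_summary():
    rec = AnnotationRecord(IndelVariant("chr1", 5, "A", "AT"), "intergenic")
    df = annotation_summary([rec])
    assert df.loc[df["category"] == "intergenic", "pct"].iloc[0] == 100.0


def test_summarize_counts_empty_errors():
    with pytest.raises(ValidationError):
        summarize_counts({})


def test_exonic_effect_field_consistency():
    with pytest.raises(ValidationError):
        AnnotationRecord(IndelVariant("chr1", 5, "A", "AT"), "intronic",
                         ("G1",), "frameshift_insertion")


def test_novelty_trivial_cases():
    variants = [ins(10), ins(20), dele(30, 2)]
    empty = KnownVariantSet(keys=set())
    flags, pct = novelty_assessment(variants, empty)
    assert all(flags) and pct == 100.0
    full = KnownVariantSet(keys={v.key for v in variants})
    flags, pct = novelty_assessment(variants, full)
    assert not any(flags) and pct == 0.0


def test_novelty_planted_fraction():
    """A known set holding 7 of 30 queries leaves 76.67% novel."""
    variants = [ins(10 * i) for i in range(1, 31)]
    known = KnownVariantSet(keys={v.key for v in variants[:7]})
    _, pct = novelty_assessment(variants, known)
    assert pct == 76.67
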