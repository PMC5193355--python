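"""Multi-evidence candidate-gene prioritization.

Genes carrying at least one differential indel in a genic or flanking region
are scored against four sources of evidence:

* **QTL confidence-interval overlap** — the gene's genetic-map (cM) interval
  intersects the CI of a trait-matched QTL;
* **QTL peak proximity** — the gene's cM interval lies strictly within 5 cM
  of a QTL peak;
* **GWAS-SNP proximity** — the gene's physical interval lies strictly within
  5 Mb of a trait-associated SNP;
* **core pathway membership** — the gene belongs to one of the eight
  protein/fat metabolism signaling pathways (mTOR, insulin, AMPK, PPAR,
  Jak-STAT, PI3K-Akt, MAPK, TGF-β).

The four flags collapse into a deterministic evidence tier A–E (see
:func:`assign_tier`); gene-set over-representation is tested with a
one-sided Fisher's exact test at P < 0.05 without multiple-testing
correction (a Benjamini–Hochberg column is emitted for reference only).

Physical positions are converted to genetic positions by piecewise-linear
interpolation on a marker map, clamping beyond the terminal anchors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .errors import MapCoverageError, ValidationError

__all__ = [
    "GeneticMap",
    "QTLRecord",
    "GwasHit",
    "PathwayGeneSets",
    "EvidenceProfile",
    "EnrichmentResult",
    "DEFAULT_CORE_PATHWAYS",
    "DEFAULT_TRAIT_LABELS",
    "interpolate_cM",
    "qtl_evidence",
    "gwas_evidence",
    "fisher_enrichment",
    "assign_tier",
    "prioritize",
]

DEFAULT_CORE_PATHWAYS = (
    "mTOR signaling pathway",
    "Insulin signaling pathway",
    "AMPK signaling pathway",
    "PPAR signaling pathway",
    "Jak-STAT signaling pathway",
    "PI3K-Akt signaling pathway",
    "MAPK signaling pathway",
    "TGF-beta signaling pathway",
)

#: QTL/GWAS records are matched to the analysis through their trait label;
#: records with any other trait are ignored.
DEFAULT_TRAIT_LABELS = frozenset(
    {
        "protein percentage",
        "fat percentage",
        "milk protein percentage",
        "milk fat percentage",
        "pp",
        "fp",
    }
)

TIER_ORDER = {"A": 0, "B": 1, "C": 2, "D": 3, "E": 4, "none": 5}


class GeneticMap:
    """Per-chromosome sorted (bp, cM) anchors with linear interpolation."""

    def __init__(self, anchors: dict[str, tuple[np.ndarray, np.ndarray]]):
        self.anchors = {}
        for chrom, (bp, cm) in anchors.items():
            bp = np.asarray(bp, dtype=float)
            cm = np.asarray(cm, dtype=float)
            if bp.size < 2:
                raise ValidationError(f"map for {chrom} needs >= 2 anchors")
            if not np.all(np.diff(bp) > 0):
                raise ValidationError(f"map bp must be strictly increasing on {chrom}")
            if not np.all(np.diff(cm) >= 0):
                raise ValidationError(f"map cM must be nondecreasing on {chrom}")
            self.anchors[chrom] = (bp, cm)

    @classmethod
    def from_tsv(cls, path) -> "GeneticMap":
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
        need = {"chrom", "bp", "cM"}
        if not need.issubset(df.columns):
            raise ValidationError(f"map TSV {path} must have columns {sorted(need)}")
        anchors = {
            chrom: (grp["bp"].to_numpy(), grp["cM"].to_numpy())
            for chrom, grp in df.sort_values("bp").groupby("chrom")
        }
        return cls(anchors)

    def to_tsv(self, path) -> None:
        rows = []
        for chrom, (bp, cm) in self.anchors.items():
            for b, c in zip(bp, cm):
                rows.append({"chrom": chrom, "bp": int(b), "cM": c})
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)

    def interpolate(self, chrom: str, bp) -> float:
        if chrom not in self.anchors:
            raise MapCoverageError(f"chromosome {chrom} absent from genetic map")
        xs, ys = self.anchors[chrom]
        return float(np.interp(bp, xs, ys))  # np.interp clamps outside the range


def interpolate_cM(gmap: GeneticMap, chrom: str, bp) -> float:
    """Genetic position of a physical coordinate (clamped linear interpolation)."""
    return gmap.interpolate(chrom, bp)


@dataclass(frozen=True)
class QTLRecord:
    trait: str
    chrom: str
    ci_lo: float
    ci_hi: float
    peak: Optional[float] = None

    def __post_init__(self):
        if self.ci_lo > self.ci_hi:
            raise ValidationError(f"QTL CI inverted: {self.ci_lo} > {self.ci_hi}")


@dataclass(frozen=True)
class GwasHit:
    trait: str
    chrom: str
    pos: int

    def __post_init__(self):
        if self.pos < 1:
            raise ValidationError("GWAS hit position must be >= 1")


def load_qtl_tsv(path) -> list[QTLRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    return [
        QTLRecord(
            trait=r.trait,
            chrom=r.chrom,
            ci_lo=float(r.ci_lo_cM),
            ci_hi=float(r.ci_hi_cM),
            peak=None if pd.isna(r.peak_cM) else float(r.peak_cM),
        )
        for r in df.itertuples(index=False)
    ]


def load_gwas_tsv(path) -> list[GwasHit]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    return [
        GwasHit(trait=r.trait, chrom=r.chrom, pos=int(r.pos_bp))
        for r in df.itertuples(index=False)
    ]


@dataclass
class PathwayGeneSets:
    """Named gene sets (GMT) with a flagged core protein/fat-metabolism subset."""

    sets: dict[str, set[str]]
    core_pathways: frozenset[str] = frozenset()

    def __post_init__(self):
        extra = set(self.core_pathways) - set(self.sets)
        if extra:
            raise ValidationError(f"core pathways absent from sets: {sorted(extra)}")

    @classmethod
    def from_gmt(cls, path, core_pathways=None) -> "PathwayGeneSets":
        """Read a GMT file (name <tab> description <tab> gene...).

        ``core_pathways`` defaults to whichever of the eight canonical
        protein/fat metabolism pathway names appear in the file.
        """
        sets: dict[str, set[str]] = {}
        with open(path) as fh:
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                if len(parts) < 3 or not parts[0]:
                    continue
                sets[parts[0]] = {g for g in parts[2:] if g}
        if core_pathways is None:
            core_pathways = [p for p in DEFAULT_CORE_PATHWAYS if p in sets]
        return cls(sets=sets, core_pathways=frozenset(core_pathways))

    def core_genes(self) -> set[str]:
        out: set[str] = set()
        for name in self.core_pathways:
            out |= self.sets[name]
        return out


def _interval_distance(lo: float, hi: float, point: float) -> float:
    if lo <= point <= hi:
        return 0.0
    return min(abs(lo - point), abs(hi - point))


def qtl_evidence(
    gene_cm: tuple[float, float],
    chrom: str,
    qtls: list[QTLRecord],
    peak_radius: float = 5.0,
) -> tuple[bool, list[QTLRecord], bool, list[QTLRecord]]:
    """CI-overlap and peak-proximity evidence for one gene.

    ``gene_cm`` is the gene's genetic interval.  CI overlap is closed-interval
    intersection; peak proximity is strict: the minimum distance from the
    gene interval to the peak must be ``< peak_radius`` cM.  Only
    same-chromosome QTL are compared.  Returns
    ``(ci_overlap, ci_matches, peak_within, peak_matches)``.
    """
    lo, hi = min(gene_cm), max(gene_cm)
    ci_matches, peak_matches = [], []
    for q in qtls:
        if q.chrom != chrom:
            continue
        if lo <= q.ci_hi and q.ci_lo <= hi:
            ci_matches.append(q)
        if q.peak is not None and _interval_distance(lo, hi, q.peak) < peak_radius:
            peak_matches.append(q)
    return (bool(ci_matches), ci_matches, bool(peak_matches), peak_matches)


def gwas_evidence(
    gene_bp: tuple[int, int],
    chrom: str,
    hits: list[GwasHit],
    radius: int = 5_000_000,
) -> tuple[bool, Optional[float], Optional[GwasHit]]:
    """Proximity of the nearest trait-associated SNP (strict ``< radius`` bp).

    Distance 0 when a hit lies inside the gene body.  Returns
    ``(flag, min_distance, nearest_hit)``; distance and hit are ``None`` when
    no same-chromosome hit exists.
    """
    lo, hi = min(gene_bp), max(gene_bp)
    best: Optional[float] = None
    nearest: Optional[GwasHit] = None
    for h in hits:
        if h.chrom != chrom:
            continue
        d = _interval_distance(lo, hi, h.pos)
        if best is None or d < best:
            best, nearest = d, h
    return (best is not None and best < radius, best, nearest)


@dataclass
class EnrichmentResult:
    term: str
    k: int  # list ∩ term
    K: int  # term size (in background)
    n: int  # list size
    N: int  # background size
    p_value: float
    significant: bool = False
    p_bh: Optional[float] = None


def fisher_enrichment(
    gene_list,
    background,
    sets: PathwayGeneSets,
    alpha: float = 0.05,
) -> list[EnrichmentResult]:
    """One-sided (over-representation) Fisher's exact test per gene set.

    Sets are intersected with the background before testing; the p-value is
    the hypergeometric upper tail P(X ≥ k) of the 2×2 table
    ``(k, n−k, K−k, N−K−n+k)``.  Significance is uncorrected ``p < alpha``,
    matching the stated criterion; a Benjamini–Hochberg adjusted column is
    attached for reference but does not drive the flag.
    """
    background = set(background)
    if not background:
        raise ValidationError("enrichment background must be nonempty")
    genes = set(gene_list)
    if not genes <= background:
        raise ValidationError("gene_list must be a subset of background")
    N, n = len(background), len(genes)
    results = []
    for term, members in sets.sets.items():
        K = len(members & background)
        k = len(members & genes)
        # hypergeometric survival function: P(X >= k)
        p = float(hypergeom.sf(k - 1, N, K, n))
        p = min(1.0, max(0.0, p))
        results.append(EnrichmentResult(term, k, K, n, N, p, significant=p < alpha))
    if results:
        from statsmodels.stats.multitest import multipletests

        _, p_bh, _, _ = multipletests([r.p_value for r in results], method="fdr_bh")
        for r, adj in zip(results, p_bh):
            r.p_bh = float(adj)
    return results


def enrichment_table(results: list[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "term": r.term,
                "k": r.k,
                "K": r.K,
                "n": r.n,
                "N": r.N,
                "p_value": r.p_value,
                "p_bh": r.p_bh,
                "significant": r.significant,
            }
            for r in sorted(results, key=lambda r: r.p_value)
        ]
    )


def assign_tier(
    ci_overlap: bool, peak_within: bool, gwas_within: bool, core_pathway: bool
) -> str:
    """Deterministic evidence tier from the four flags.

    A: near a QTL peak and a GWAS SNP and in a core pathway;
    B: in a QTL confidence interval and near a GWAS SNP;
    C: near a QTL peak and a GWAS SNP;
    D: near a GWAS SNP and in a core pathway;
    E: near a GWAS SNP only;
    none: otherwise.  Rules are evaluated in that order.
    """
    if peak_within and gwas_within and core_pathway:
        return "A"
    if ci_overlap and gwas_within:
        return "B"
    if peak_within and gwas_within:
        return "C"
    if gwas_within and core_pathway:
        return "D"
    if gwas_within:
        return "E"
    return "none"


@dataclass
class EvidenceProfile:
    """Per-gene evidence flags, tier, and supporting records."""

    gene_id: str
    qtl_ci_overlap: bool
    qtl_peak_within: bool
    gwas_within: bool
    core_pathway: bool
    tier: str = field(init=False)
    n_indels: int = 0
    gwas_distance: Optional[float] = None
    ci_qtls: list[QTLRecord] = field(default_factory=list)
    peak_qtls: list[QTLRecord] = field(default_factory=list)
    nearest_hit: Optional[GwasHit] = None

    def __post_init__(self):
        self.tier = assign_tier(
            self.qtl_ci_overlap,
            self.qtl_peak_within,
            self.gwas_within,
            self.core_pathway,
        )

    @property
    def qtl_evidenced(self) -> bool:
        return self.qtl_ci_overlap or self.qtl_peak_within


def prioritize(
    annotations,
    qtls: list[QTLRecord],
    gwas_hits: list[GwasHit],
    pathways: PathwayGeneSets,
    gmap: GeneticMap,
    model,
    trait_labels=DEFAULT_TRAIT_LABELS,
    peak_radius_cM: float = 5.0,
    gwas_radius_bp: int = 5_000_000,
) -> pd.DataFrame:
    """Rule-based candidate-gene report.

    Profiles every gene carrying ≥ 1 differential indel whose primary
    category is genic or flanking (i.e. not intergenic); the *retained* set is
    the union of QTL-evidenced and GWAS-evidenced genes.  Rows are sorted by
    tier then gene id; non-retained profiled genes appear with
    ``retained=False`` for transparency.
    """
    labels = {t.lower() for t in trait_labels} if trait_labels else None
    if labels is not None:
        qtls = [q for q in qtls if q.trait.lower() in labels]
        gwas_hits = [h for h in gwas_hits if h.trait.lower() in labels]

    indels_per_gene: dict[str, int] = {}
    for rec in annotations:
        if rec.category == "intergenic":
            continue
        for g in rec.gene_ids:
            indels_per_gene[g] = indels_per_gene.get(g, 0) + 1

    core = pathways.core_genes()
    rows = []
    for gene_id, n_indels in indels_per_gene.items():
        gene = model.genes.get(gene_id)
        if gene is None:
            continue
        try:
            cm_lo = gmap.interpolate(gene.chrom, gene.start)
            cm_hi = gmap.interpolate(gene.chrom, gene.end)
            ci, ci_q, peak, peak_q = qtl_evidence(
                (cm_lo, cm_hi), gene.chrom, qtls, peak_radius_cM
            )
        except MapCoverageError:
            ci = peak = False
            ci_q = peak_q = []
        gw, dist, hit = gwas_evidence(
            (gene.start, gene.end), gene.chrom, gwas_hits, gwas_radius_bp
        )
        prof = EvidenceProfile(
            gene_id=gene_id,
            qtl_ci_overlap=ci,
            qtl_peak_within=peak,
            gwas_within=gw,
            core_pathway=gene_id in core,
            n_indels=n_indels,
            gwas_distance=dist,
            ci_qtls=ci_q,
            peak_qtls=peak_q,
            nearest_hit=hit,
        )
        rows.append(
            {
                "gene_id": gene_id,
                "chrom": gene.chrom,
                "start": gene.start,
                "end": gene.end,
                "n_indels": n_indels,
                "qtl_ci_overlap": prof.qtl_ci_overlap,
                "qtl_peak_within": prof.qtl_peak_within,
                "gwas_within": prof.gwas_within,
                "core_pathway": prof.core_pathway,
                "tier": prof.tier,
                "retained": prof.qtl_evidenced or prof.gwas_within,
                "gwas_distance_bp": dist,
                "nearest_hit": f"{hit.chrom}:{hit.pos}" if hit else None,
                "supporting_qtl": ";".join(
                    f"{q.trait}@{q.chrom}:{q.ci_lo}-{q.ci_hi}" for q in (ci_q or peak_q)
                )
                or None,
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "gene_id", "chrom", "start", "end", "n_indels",
            "qtl_ci_overlap", "qtl_peak_within", "gwas_within", "core_pathway",
            "tier", "retained", "gwas_distance_bp", "nearest_hit", "supporting_qtl",
        ],
    )
    if not df.empty:
        df = df.sort_values(
            ["tier", "gene_id"], key=lambda s: s.map(TIER_ORDER) if s.name == "tier" else s
        ).reset_index(drop=True)
    return df
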