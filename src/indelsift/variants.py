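"""Indel data model: reading, normalization, quality filtering and merging.

The unit of analysis is a short (1–49 bp) insertion or deletion in VCF
anchor-base convention: the reference allele carries the anchor base plus any
deleted bases; the alternate allele carries the anchor base plus any inserted
bases.  After :func:`normalize_indel` exactly one of the two alleles has
length 1, so variants can be keyed and deduplicated on
``(chrom, pos, ref, alt)``.

Per-sample call sets pass through three stages:

1. :func:`read_indel_calls` — pull biallelic indel records (with quality,
   depth and strand-resolved alt support) out of a VCF;
2. :func:`apply_call_filters` — the call-confidence filter: site quality
   ``>= 20``, per-individual depth ``< 100``, more than 3 alt-supporting
   reads on the forward *or* reverse strand, length within 1–49 bp;
3. :func:`merge_nonredundant` — union the per-sample call sets into one
   nonredundant :class:`GenotypeMatrix` of alt-allele dosages.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from ._util import chrom_sort_key
from .errors import (
    ConsistencyError,
    DegenerateVariantError,
    SampleLookupError,
    ValidationError,
    VcfParseError,
)

__all__ = [
    "IndelVariant",
    "CallRecord",
    "CallQualityThresholds",
    "FilterCounts",
    "GenotypeMatrix",
    "FamilyDesign",
    "read_indel_calls",
    "normalize_indel",
    "apply_call_filters",
    "merge_nonredundant",
]


@dataclass(frozen=True)
class IndelVariant:
    """One insertion or deletion in VCF anchor convention.

    ``svtype`` and ``length`` are derived from the alleles; ``known_id`` is
    carried along (e.g. an rs id) but excluded from equality so that identity
    is purely positional/allelic.
    """

    chrom: str
    pos: int  # 1-based anchor position
    ref: str
    alt: str
    known_id: Optional[str] = field(default=None, compare=False)

    @property
    def svtype(self) -> str:
        return "INS" if len(self.alt) > len(self.ref) else "DEL"

    @property
    def length(self) -> int:
        return abs(len(self.alt) - len(self.ref))

    @property
    def key(self) -> tuple:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def is_insertion(self) -> bool:
        return self.svtype == "INS"

    def validate(self) -> None:
        """Raise :class:`ValidationError` on any violated invariant."""
        if self.pos < 1:
            raise ValidationError(f"pos must be >= 1, got {self.pos}")
        if not self.ref or not self.alt:
            raise ValidationError("ref and alt must be nonempty")
        if len(self.ref) == len(self.alt):
            raise ValidationError(f"not an indel: ref={self.ref} alt={self.alt}")
        if self.length < 1:
            raise ValidationError("indel length must be >= 1")

    def sort_key(self) -> tuple:
        return (chrom_sort_key(self.chrom), self.pos, self.ref, self.alt)

    def __str__(self) -> str:  # compact "chr1:100 A>AG" form for logs
        return f"{self.chrom}:{self.pos} {self.ref}>{self.alt}"


@dataclass
class CallRecord:
    """One per-sample indel call with the fields the confidence filter uses.

    ``dosage`` is the count of alternate alleles (0/1/2) or ``None`` when the
    genotype is missing.  Quality/depth/strand-support fields are ``None``
    when the source VCF does not provide them; a missing field passes the
    corresponding filter criterion.
    """

    variant: IndelVariant
    dosage: Optional[int] = None
    quality: Optional[float] = None
    depth: Optional[int] = None
    fwd_alt_support: Optional[int] = None
    rev_alt_support: Optional[int] = None

    def __post_init__(self):
        for name in ("depth", "fwd_alt_support", "rev_alt_support"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValidationError(f"{name} must be nonnegative, got {v}")
        if self.dosage is not None and self.dosage not in (0, 1, 2):
            raise ValidationError(f"dosage must be in {{0,1,2}}, got {self.dosage}")


@dataclass(frozen=True)
class CallQualityThresholds:
    """Call-confidence thresholds.

    Defaults mirror the SAMtools-era filter: phred site quality at least 20,
    per-individual read depth strictly below 100, strictly more than 3
    alt-supporting reads on at least one strand, and indel length 1–49 bp.
    ``max_depth`` and ``min_strand_alt_support`` are exclusive bounds.
    """

    min_quality: float = 20.0
    max_depth: int = 100
    min_strand_alt_support: int = 3
    min_length: int = 1
    max_length: int = 49

    def __post_init__(self):
        if min(self.min_quality, self.max_depth, self.min_strand_alt_support) < 0:
            raise ValidationError("thresholds must be nonnegative")
        if self.min_length > self.max_length:
            raise ValidationError("min_length must be <= max_length")


@dataclass
class FilterCounts:
    """Per-criterion rejection bookkeeping from :func:`apply_call_filters`."""

    n_input: int = 0
    n_kept: int = 0
    quality: int = 0
    depth: int = 0
    strand_support: int = 0
    length: int = 0

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


def normalize_indel(variant: IndelVariant) -> IndelVariant:
    """Reduce ref/alt to their minimal anchored representation.

    Trims the shared allele suffix, then the shared prefix, always leaving at
    least one base in each allele (the anchor); the position advances by one
    for each trimmed prefix base.  Idempotent.  Left-alignment against a
    reference sequence is deliberately not attempted — no reference is
    required to run — so two calls of one event are identical only if the
    caller emitted them at the same anchor.

    Raises
    ------
    DegenerateVariantError
        If ref == alt (no variant remains after trimming).
    """
    ref, alt, pos = variant.ref, variant.alt, variant.pos
    if not ref or not alt:
        raise ValidationError("ref and alt must be nonempty")
    if ref == alt:
        raise DegenerateVariantError(f"ref == alt at {variant.chrom}:{pos}")
    # shared suffix first (keeps the left anchor), then shared prefix
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    if ref == alt:
        raise DegenerateVariantError(f"ref == alt at {variant.chrom}:{pos}")
    return IndelVariant(variant.chrom, pos, ref, alt, known_id=variant.known_id)


def _gt_dosage(sample_call, alt_index: int) -> Optional[int]:
    alleles = sample_call.get("GT")
    if alleles is None or any(a is None for a in alleles):
        return None
    return sum(1 for a in alleles if a == alt_index)


def read_indel_calls(
    vcf_source,
    sample_id: Optional[str] = None,
    strand_field: str = "DP4",
) -> list[CallRecord]:
    """Read biallelic indel calls for one sample from a VCF.

    Multiallelic records are split into one biallelic record per alternate
    allele; SNVs, MNVs, symbolic and spanning-deletion alleles are skipped.
    ``strand_field`` names a DP4-style INFO field laid out as
    (ref-fwd, ref-rev, alt-fwd, alt-rev); when absent the strand criterion is
    treated as passing.  Depth is taken from the sample FORMAT ``DP`` when
    present, else from INFO ``DP``.

    Parameters
    ----------
    vcf_source
        Path to a VCF (plain or bgzipped).
    sample_id
        Sample to extract.  May be omitted only for single-sample files.
    """
    import pysam

    try:
        vf = pysam.VariantFile(str(vcf_source))
    except (OSError, ValueError) as exc:
        raise VcfParseError(f"cannot parse VCF {vcf_source}: {exc}") from exc
    with vf:
        samples = list(vf.header.samples)
        if sample_id is None:
            if len(samples) != 1:
                raise SampleLookupError(
                    f"{vcf_source} has {len(samples)} samples; sample_id is required"
                )
            sample_id = samples[0]
        if sample_id not in samples:
            raise SampleLookupError(
                f"sample {sample_id!r} not in {vcf_source} (has {samples})"
            )
        out: list[CallRecord] = []
        for rec in vf:
            if rec.alts is None:
                continue
            call = rec.samples[sample_id]
            dp = call.get("DP")
            if dp is None:
                dp = rec.info.get("DP")
            dp4 = rec.info.get(strand_field)
            fwd = rev = None
            if dp4 is not None and len(dp4) == 4:
                fwd, rev = int(dp4[2]), int(dp4[3])
            for ai, alt in enumerate(rec.alts, start=1):
                if alt is None or alt in ("*", ".") or alt.startswith("<"):
                    continue
                if any(c not in "ACGTNacgtn" for c in alt):
                    continue
                if len(alt) == len(rec.ref):
                    continue  # SNV or MNV
                variant = IndelVariant(
                    rec.chrom,
                    rec.pos,
                    rec.ref.upper(),
                    alt.upper(),
                    known_id=rec.id if rec.id not in (None, ".") else None,
                )
                out.append(
                    CallRecord(
                        variant=variant,
                        dosage=_gt_dosage(call, ai),
                        quality=rec.qual,
                        depth=None if dp is None else int(dp),
                        fwd_alt_support=fwd,
                        rev_alt_support=rev,
                    )
                )
        return out


def apply_call_filters(
    records: Iterable[CallRecord],
    thresholds: CallQualityThresholds = CallQualityThresholds(),
) -> tuple[list[CallRecord], FilterCounts]:
    """Apply the call-confidence filter; return kept records + rejection counts.

    A record is kept iff every criterion passes:

    * ``quality >= min_quality``;
    * ``depth < max_depth`` (exclusive);
    * ``fwd_alt_support > min_strand_alt_support`` OR
      ``rev_alt_support > min_strand_alt_support`` (exclusive, either strand);
    * ``min_length <= variant.length <= max_length``.

    A criterion whose fields are absent (``None``) passes.  The strand
    criterion applies only to records carrying the alternate allele
    (dosage ≥ 1): a backfilled homozygous-reference record has no
    alt-supporting reads by definition and is not penalized for it.
    Each rejected record increments the counter of every criterion it fails.
    """
    kept: list[CallRecord] = []
    counts = FilterCounts()
    for rec in records:
        counts.n_input += 1
        ok = True
        if rec.quality is not None and rec.quality < thresholds.min_quality:
            counts.quality += 1
            ok = False
        if rec.depth is not None and rec.depth >= thresholds.max_depth:
            counts.depth += 1
            ok = False
        carries_alt = rec.dosage is None or rec.dosage > 0
        if carries_alt and not (
            (rec.fwd_alt_support is None and rec.rev_alt_support is None)
            or (rec.fwd_alt_support or 0) > thresholds.min_strand_alt_support
            or (rec.rev_alt_support or 0) > thresholds.min_strand_alt_support
        ):
            counts.strand_support += 1
            ok = False
        if not (thresholds.min_length <= rec.variant.length <= thresholds.max_length):
            counts.length += 1
            ok = False
        if ok:
            counts.n_kept += 1
            kept.append(rec)
    return kept, counts


@dataclass
class GenotypeMatrix:
    """Nonredundant variant set × samples table of alt-allele dosages.

    ``dosages`` is a pandas DataFrame (nullable Int8) whose rows align with
    ``variants`` and whose columns are ``samples``; NA marks a missing call.
    """

    variants: list[IndelVariant]
    samples: list[str]
    dosages: pd.DataFrame

    def __post_init__(self):
        if len(set(self.samples)) != len(self.samples):
            raise ValidationError("sample ids must be unique")
        if self.dosages.shape != (len(self.variants), len(self.samples)):
            raise ValidationError(
                f"dosage table shape {self.dosages.shape} does not match "
                f"{len(self.variants)} variants x {len(self.samples)} samples"
            )

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def dosage_array(self) -> np.ndarray:
        """Float array with NaN for missing calls (n_variants × n_samples)."""
        return self.dosages.to_numpy(dtype=float, na_value=np.nan)

    # ---------------------------------------------------------------- I/O --
    TSV_FIXED_COLS = ["chrom", "pos", "ref", "alt", "svtype", "length"]

    def to_frame(self) -> pd.DataFrame:
        meta = pd.DataFrame(
            {
                "chrom": [v.chrom for v in self.variants],
                "pos": [v.pos for v in self.variants],
                "ref": [v.ref for v in self.variants],
                "alt": [v.alt for v in self.variants],
                "svtype": [v.svtype for v in self.variants],
                "length": [v.length for v in self.variants],
            }
        )
        dos = self.dosages.reset_index(drop=True)
        return pd.concat([meta, dos], axis=1)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, na_rep=".")

    @classmethod
    def from_tsv(cls, path) -> "GenotypeMatrix":
        df = pd.read_csv(path, sep="\t", na_values=["."], dtype={"chrom": str})
        missing = [c for c in ("chrom", "pos", "ref", "alt") if c not in df.columns]
        if missing:
            raise ValidationError(f"matrix TSV {path} lacks columns {missing}")
        samples = [c for c in df.columns if c not in cls.TSV_FIXED_COLS]
        variants = [
            IndelVariant(r.chrom, int(r.pos), r.ref, r.alt)
            for r in df.itertuples(index=False)
        ]
        dosages = df[samples].astype("Int8")
        return cls(variants=variants, samples=samples, dosages=dosages)

    def to_vcf(self, path) -> None:
        """Write the merged matrix as a sorted multi-sample VCF 4.2."""
        lines = [
            "##fileformat=VCFv4.2",
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        ]
        for chrom in sorted({v.chrom for v in self.variants}, key=chrom_sort_key):
            lines.append(f"##contig=<ID={chrom}>")
        lines.append(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(self.samples)
        )
        gt_map = {0: "0/0", 1: "0/1", 2: "1/1"}
        order = sorted(range(self.n_variants), key=lambda i: self.variants[i].sort_key())
        arr = self.dosages.to_numpy(dtype=object)
        for i in order:
            v = self.variants[i]
            gts = "\t".join(
                gt_map[int(d)] if d is not pd.NA and not pd.isna(d) else "./."
                for d in arr[i]
            )
            vid = v.known_id or "."
            lines.append(
                f"{v.chrom}\t{v.pos}\t{vid}\t{v.ref}\t{v.alt}\t.\tPASS\t.\tGT\t{gts}"
            )
        Path(path).write_text("\n".join(lines) + "\n")

    def subset(self, mask) -> "GenotypeMatrix":
        idx = np.flatnonzero(np.asarray(mask))
        return GenotypeMatrix(
            variants=[self.variants[i] for i in idx],
            samples=list(self.samples),
            dosages=self.dosages.iloc[idx].reset_index(drop=True),
        )


def merge_nonredundant(
    per_sample_calls: Mapping[str, Sequence[CallRecord]],
) -> GenotypeMatrix:
    """Union per-sample filtered call lists into one nonredundant matrix.

    Variants are keyed on ``(chrom, pos, ref, alt)`` (calls must already be
    normalized).  Each sample's dosage is taken from its record at the locus;
    0 marks an explicit homozygous-reference call, NA marks the absence of any
    call.  The result is sorted by genome coordinate and is invariant under
    permutation of the input samples.

    Raises
    ------
    ConsistencyError
        If two samples claim contradictory reference sequence at one
        position.  Different deletion lengths at one anchor (refs that are
        prefixes of one another) are legitimate distinct variants; refs that
        disagree on an overlapping base are irreconcilable.
    """
    samples = list(per_sample_calls)
    variant_by_key: dict[tuple, IndelVariant] = {}
    site_ref: dict[tuple, str] = {}
    dosage_maps: dict[str, dict[tuple, Optional[int]]] = {}
    for sample, calls in per_sample_calls.items():
        dmap: dict[tuple, Optional[int]] = {}
        for rec in calls:
            v = rec.variant
            site = (v.chrom, v.pos)
            prev = site_ref.setdefault(site, v.ref)
            if not (prev.startswith(v.ref) or v.ref.startswith(prev)):
                raise ConsistencyError(
                    f"contradictory REF at {v.chrom}:{v.pos}: "
                    f"{prev!r} vs {v.ref!r}"
                )
            if len(v.ref) > len(prev):
                site_ref[site] = v.ref
            variant_by_key.setdefault(v.key, v)
            dmap[v.key] = rec.dosage
        dosage_maps[sample] = dmap

    variants = sorted(variant_by_key.values(), key=IndelVariant.sort_key)
    data = {
        sample: pd.array(
            [dosage_maps[sample].get(v.key) for v in variants], dtype="Int8"
        )
        for sample in samples
    }
    dosages = pd.DataFrame(data, columns=samples)
    return GenotypeMatrix(variants=variants, samples=samples, dosages=dosages)


@dataclass
class FamilyDesign:
    """High/low sib-pair structure: one high and one low sample per family."""

    families: list[tuple[str, str, str]]  # (family_id, high_sample, low_sample)

    def __post_init__(self):
        if not self.families:
            raise ValidationError("design needs at least one family")
        seen: set[str] = set()
        for fam, hi, lo in self.families:
            for s in (hi, lo):
                if s in seen:
                    raise ValidationError(f"sample {s} appears in more than one slot")
                seen.add(s)

    @property
    def high_samples(self) -> list[str]:
        return [hi for _, hi, _ in self.families]

    @property
    def low_samples(self) -> list[str]:
        return [lo for _, _, lo in self.families]

    @property
    def all_samples(self) -> list[str]:
        return self.high_samples + self.low_samples

    def swapped(self) -> "FamilyDesign":
        """Design with high/low labels exchanged (for antisymmetry checks)."""
        return FamilyDesign([(f, lo, hi) for f, hi, lo in self.families])

    def to_tsv(self, path) -> None:
        rows = []
        for fam, hi, lo in self.families:
            rows.append({"sample_id": hi, "family_id": fam, "group": "high"})
            rows.append({"sample_id": lo, "family_id": fam, "group": "low"})
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "FamilyDesign":
        df = pd.read_csv(path, sep="\t", dtype=str)
        need = {"sample_id", "family_id", "group"}
        if not need.issubset(df.columns):
            raise ValidationError(f"design TSV {path} must have columns {sorted(need)}")
        families = []
        for fam, grp in df.groupby("family_id", sort=False):
            hi = grp.loc[grp["group"].str.lower() == "high", "sample_id"].tolist()
            lo = grp.loc[grp["group"].str.lower() == "low", "sample_id"].tolist()
            if len(hi) != 1 or len(lo) != 1:
                raise ValidationError(
                    f"family {fam} must have exactly one high and one low sample"
                )
            families.append((str(fam), hi[0], lo[0]))
        return cls(families)
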