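"""Common-differential indel detection across high/low sib pairs.

A cohort of families each contributes one high-trait and one low-trait
individual.  A locus is a *common differential indel* when

1. within **every** family the two sibs carry different genotypes
   (alt-allele dosages differ), and
2. the per-family dosage differences ``dosage_high − dosage_low`` share one
   sign across all families (a consistent allelic direction).

No statistical test is attached; the filter is purely combinatorial, which is
what makes an exhaustive 3^(2·n_families) enumeration oracle possible for
small designs.

Direction is defined on alternate-allele dosage uniformly for insertions and
deletions: a retained set computed on "insertion-allele" labels is identical,
only the sign convention differs for deletion loci.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .errors import MissingGenotypeError, SampleLookupError, ValidationError
from .variants import FamilyDesign, GenotypeMatrix, IndelVariant

__all__ = [
    "DifferentialResult",
    "family_polymorphic",
    "concordant_differential_filter",
    "group_allele_frequency",
    "frequency_profile",
]


@dataclass
class DifferentialResult:
    """One retained locus: per-family deltas, shared direction, group frequencies."""

    variant: IndelVariant
    family_deltas: dict[str, int]
    direction: int  # +1 or -1
    freq_high: float
    freq_low: float

    @property
    def insertion_freq_high(self) -> float:
        """Frequency of the *insertion* allele in the high group.

        For INS variants the insertion allele is the alternate allele; for
        DEL variants it is the reference allele, so the complement is taken.
        """
        return self.freq_high if self.variant.is_insertion else 1.0 - self.freq_high

    @property
    def insertion_freq_low(self) -> float:
        return self.freq_low if self.variant.is_insertion else 1.0 - self.freq_low


def family_polymorphic(
    dosage_high: Optional[int], dosage_low: Optional[int]
) -> tuple[bool, int]:
    """Within-family contrast: is the sib pair polymorphic, and in which direction?

    Returns ``(is_polymorphic, delta)`` with ``delta = dosage_high −
    dosage_low`` in [-2, 2].  A het-vs-hom difference counts as polymorphic:
    the criterion is genotype inequality, not mere allele sharing.
    """
    if dosage_high is None or dosage_low is None:
        raise MissingGenotypeError("both dosages must be present")
    delta = int(dosage_high) - int(dosage_low)
    return (delta != 0, delta)


def group_allele_frequency(dosages, group: list[str]) -> float:
    """Alternate-allele frequency of one group at one locus.

    ``dosages`` maps sample id → dosage (a dict or pandas Series row).
    With *n* diploid samples the result is a multiple of ``1/(2n)``.
    """
    if not group:
        raise ValidationError("group must be nonempty")
    total = 0
    for s in group:
        d = dosages[s]
        if d is None or (d is pd.NA) or pd.isna(d):
            raise MissingGenotypeError(f"missing dosage for sample {s}")
        total += int(d)
    return total / (2 * len(group))


def concordant_differential_filter(
    matrix: GenotypeMatrix, design: FamilyDesign
) -> tuple[list[DifferentialResult], int]:
    """Retain loci polymorphic within every family with one shared direction.

    Loci with any missing dosage among the design samples are excluded from
    consideration; the second return value counts those exclusions.

    Returns ``(results, n_excluded_missing)``.
    """
    missing = [s for s in design.all_samples if s not in matrix.samples]
    if missing:
        raise SampleLookupError(f"design samples absent from matrix: {missing}")

    high_ids = design.high_samples
    low_ids = design.low_samples
    arr = matrix.dosage_array()
    col = {s: i for i, s in enumerate(matrix.samples)}
    H = arr[:, [col[s] for s in high_ids]]
    L = arr[:, [col[s] for s in low_ids]]

    any_missing = np.isnan(H).any(axis=1) | np.isnan(L).any(axis=1)
    deltas = H - L
    with np.errstate(invalid="ignore"):
        all_poly = (deltas != 0).all(axis=1)
        same_sign = (deltas > 0).all(axis=1) | (deltas < 0).all(axis=1)
    retained = ~any_missing & all_poly & same_sign

    n_high, n_low = len(high_ids), len(low_ids)
    results: list[DifferentialResult] = []
    for i in np.flatnonzero(retained):
        fam_deltas = {
            fam: int(deltas[i, j]) for j, (fam, _, _) in enumerate(design.families)
        }
        results.append(
            DifferentialResult(
                variant=matrix.variants[i],
                family_deltas=fam_deltas,
                direction=1 if deltas[i, 0] > 0 else -1,
                freq_high=float(H[i].sum() / (2 * n_high)),
                freq_low=float(L[i].sum() / (2 * n_low)),
            )
        )
    return results, int(any_missing.sum())


def frequency_profile(results: list[DifferentialResult]) -> pd.DataFrame:
    """Per-locus paired frequency table (one row per retained locus).

    Reports both the alt-allele frequencies used internally and the
    insertion-allele frequencies (reference-allele complement for deletion
    loci), which is the scale on which allele-frequency distributions of
    differential indels are conventionally plotted.
    """
    if not results:
        raise ValidationError("no differential results to profile")
    rows = []
    for r in results:
        v = r.variant
        rows.append(
            {
                "chrom": v.chrom,
                "pos": v.pos,
                "ref": v.ref,
                "alt": v.alt,
                "svtype": v.svtype,
                "length": v.length,
                "direction": r.direction,
                "freq_high": r.freq_high,
                "freq_low": r.freq_low,
                "insertion_freq_high": r.insertion_freq_high,
                "insertion_freq_low": r.insertion_freq_low,
            }
        )
    return pd.DataFrame(rows)


def differential_table(
    results: list[DifferentialResult], design: FamilyDesign
) -> pd.DataFrame:
    """Exportable table: variant key, per-family deltas, direction, frequencies."""
    prof = frequency_profile(results)
    for fam, _, _ in design.families:
        prof[f"delta_{fam}"] = [r.family_deltas[fam] for r in results]
    return prof
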