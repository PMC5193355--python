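"""Cohort- and variant-set-level descriptive statistics.

Rounding matches the printed precision of sequencing summary tables:
integers to the nearest integer, percentage columns to 2 decimals, depth to
1 decimal, all half-away-from-zero (so printed per-sample values reproduce
printed means exactly).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from ._util import exact_mean, round_half_away
from .errors import ValidationError
from .variants import IndelVariant

__all__ = [
    "SampleStats",
    "cohort_averages",
    "length_distribution",
    "chromosome_distribution",
    "validation_rate",
]


def validation_rate(confirmed: int, assayed: int) -> float:
    """Share of assayed variants confirmed by follow-up, as a 2-decimal %."""
    if assayed <= 0 or confirmed < 0 or confirmed > assayed:
        raise ValidationError(f"invalid validation counts {confirmed}/{assayed}")
    return round_half_away(100 * confirmed / assayed, 2)


@dataclass
class SampleStats:
    """Per-sample sequencing/mapping statistics plus the sample's indel count."""

    sample: str
    raw_reads: int
    mapped_reads: int
    uniquely_mapped_pct: float
    coverage_pct: float
    depth: float
    indel_count: int

    def __post_init__(self):
        if self.mapped_reads > self.raw_reads:
            raise ValidationError(
                f"{self.sample}: mapped_reads > raw_reads"
            )
        for name in ("uniquely_mapped_pct", "coverage_pct"):
            v = getattr(self, name)
            if not 0 <= v <= 100:
                raise ValidationError(f"{self.sample}: {name}={v} outside [0, 100]")


#: (attribute, decimals) at printed precision; 0 decimals -> integer column
_AVG_PRECISION = [
    ("raw_reads", 0),
    ("mapped_reads", 0),
    ("uniquely_mapped_pct", 2),
    ("coverage_pct", 2),
    ("depth", 1),
    ("indel_count", 0),
]


def cohort_averages(stats: list[SampleStats]) -> SampleStats:
    """Column-wise arithmetic means rounded at each column's printed precision.

    Means are computed in exact rational arithmetic so the rounding step sees
    the true mean, not a float approximation.
    """
    if not stats:
        raise ValidationError("cohort_averages needs >= 1 sample")
    values = {}
    for attr, ndigits in _AVG_PRECISION:
        mean = exact_mean([getattr(s, attr) for s in stats])
        values[attr] = round_half_away(mean, ndigits)
    return SampleStats(sample="Average", **values)


def stats_table(stats: list[SampleStats], with_average: bool = True) -> pd.DataFrame:
    rows = list(stats) + ([cohort_averages(stats)] if with_average else [])
    return pd.DataFrame([vars(s) for s in rows])


def length_distribution(
    variants: list[IndelVariant], max_length: int = 49
) -> dict:
    """Length histogram and derived shares of a normalized indel set.

    Returns a dict with ``counts`` (pandas Series indexed 1..max_length),
    ``share_1bp_pct`` and ``share_lt10bp_pct`` (2-decimal percentages),
    insertion/deletion totals and cumulative indel length in bp.
    """
    if not variants:
        raise ValidationError("length_distribution needs >= 1 variant")
    lengths = np.array([v.length for v in variants])
    counts = pd.Series(
        np.bincount(lengths, minlength=max_length + 1)[1 : max_length + 1],
        index=pd.RangeIndex(1, max_length + 1, name="length"),
        name="count",
    )
    n = len(variants)
    n_ins = sum(1 for v in variants if v.is_insertion)
    return {
        "counts": counts,
        "n_total": n,
        "n_insertions": n_ins,
        "n_deletions": n - n_ins,
        "share_1bp_pct": round_half_away(100 * int((lengths == 1).sum()) / n, 2),
        "share_lt10bp_pct": round_half_away(100 * int((lengths < 10).sum()) / n, 2),
        "max_length": int(lengths.max()),
        "cumulative_bp": int(lengths.sum()),
    }


def chromosome_distribution(
    variants: list[IndelVariant],
    chrom_lengths: dict[str, int],
    x_chrom: Optional[str] = None,
) -> pd.DataFrame:
    """Per-chromosome indel counts and densities per Mb.

    When ``x_chrom`` is given (or a chromosome named X/chrX is present), the
    table's ``attrs['x_autosome_density_ratio']`` holds the X density divided
    by the mean autosomal density — the statistic behind "fewer indels on X".
    """
    counts: dict[str, int] = {c: 0 for c in chrom_lengths}
    for v in variants:
        if v.chrom not in chrom_lengths:
            raise ValidationError(f"variant on undeclared chromosome {v.chrom}")
        counts[v.chrom] += 1
    df = pd.DataFrame(
        {
            "chrom": list(chrom_lengths),
            "length_bp": [chrom_lengths[c] for c in chrom_lengths],
            "count": [counts[c] for c in chrom_lengths],
        }
    )
    df["density_per_Mb"] = df["count"] / (df["length_bp"] / 1e6)
    if x_chrom is None:
        for cand in ("chrX", "X"):
            if cand in chrom_lengths:
                x_chrom = cand
                break
    if x_chrom is not None and x_chrom in chrom_lengths:
        auto = df.loc[df["chrom"] != x_chrom, "density_per_Mb"]
        x_dens = float(df.loc[df["chrom"] == x_chrom, "density_per_Mb"].iloc[0])
        if len(auto) and auto.mean() > 0:
            df.attrs["x_autosome_density_ratio"] = x_dens / float(auto.mean())
    return df


def plot_length_distribution(dist: dict, path) -> None:
    """Bar plot of the indel length histogram (lazy matplotlib import)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    counts = dist["counts"]
    fig, ax = plt.subplots(figsize=(8, 4))
    ax.bar(counts.index, counts.to_numpy(), color="steelblue")
    ax.set_xlabel("indel length (bp)")
    ax.set_ylabel("count")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_chromosome_counts(df: pd.DataFrame, path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 4))
    ax.bar(df["chrom"], df["count"], color="darkseagreen")
    ax.set_xlabel("chromosome")
    ax.set_ylabel("indel count")
    ax.tick_params(axis="x", rotation=60)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
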