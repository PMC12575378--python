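"""Per-position mean profiles and distribution summaries of adjusted reads.

These are the descriptive readouts used to compare transcription of a coding
sequence between the wild type and the Mfd-deficient mutant: a position-wise
mean coverage profile per strain, and a five-number-style summary (median,
quartiles, min/max/range) of the pooled per-base values.  Spread comparison
is deliberately descriptive — IQR and range ratios, no test statistic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .coverage import CoverageBundle
from .errors import ValidationError


@dataclass(frozen=True)
class DistributionSummary:
    gene_id: str
    strain: str
    n_replicates: int
    median: float
    q1: float
    q3: float
    min: float
    max: float

    def __post_init__(self):
        if not (self.min <= self.q1 <= self.median <= self.q3 <= self.max):
            raise ValidationError(
                f"{self.gene_id} {self.strain}: quartile ordering violated"
            )

    @property
    def range(self) -> float:
        return self.max - self.min

    @property
    def iqr(self) -> float:
        return self.q3 - self.q1


def _strain_profiles(bundle: CoverageBundle, strain: str, n_replicates: int | None):
    profiles = bundle.strain_profiles(strain)
    if not profiles:
        raise ValidationError(f"{bundle.gene_id}: no {strain} replicates")
    if len({p.adjusted for p in profiles}) != 1:
        raise ValidationError(
            f"{bundle.gene_id}: mixed adjusted/unadjusted {strain} profiles"
        )
    if n_replicates is not None:
        if n_replicates < 1:
            raise ValidationError("n_replicates must be >= 1")
        if n_replicates > len(profiles):
            raise ValidationError(
                f"{bundle.gene_id}: requested {n_replicates} {strain} replicates, "
                f"only {len(profiles)} available"
            )
        profiles = profiles[:n_replicates]
    return profiles


def mean_profile(
    bundle: CoverageBundle, strain: str, n_replicates: int | None = None
) -> np.ndarray:
    """Position-wise mean coverage across a strain's replicates."""
    profiles = _strain_profiles(bundle, strain, n_replicates)
    return np.mean([p.counts for p in profiles], axis=0)


def summarize_distribution(
    bundle: CoverageBundle, strain: str, n_replicates: int | None = None
) -> DistributionSummary:
    """Summary of the pooled per-base values of the chosen replicates.

    Quartiles use linear interpolation between order statistics.  The
    replicate subset is explicit (default: all available), taken in replicate
    order.
    """
    profiles = _strain_profiles(bundle, strain, n_replicates)
    pooled = np.concatenate([p.counts for p in profiles])
    q1, med, q3 = np.percentile(pooled, [25, 50, 75])
    return DistributionSummary(
        gene_id=bundle.gene_id,
        strain=strain,
        n_replicates=len(profiles),
        median=float(med),
        q1=float(q1),
        q3=float(q3),
        min=float(pooled.min()),
        max=float(pooled.max()),
    )


def compare_spread(wt: DistributionSummary, mut: DistributionSummary) -> dict:
    """Descriptive WT/MUT spread comparison: IQR ratio and range ratio."""
    if wt.gene_id != mut.gene_id:
        raise ValidationError(
            f"cannot compare different genes ({wt.gene_id} vs {mut.gene_id})"
        )
    mut_iqr_zero = mut.iqr == 0
    mut_range_zero = mut.range == 0
    return {
        "gene_id": wt.gene_id,
        "wt_iqr": wt.iqr,
        "mut_iqr": mut.iqr,
        "iqr_ratio": math.inf if mut_iqr_zero else wt.iqr / mut.iqr,
        "wt_range": wt.range,
        "mut_range": mut.range,
        "range_ratio": math.inf if mut_range_zero else wt.range / mut.range,
        "mut_iqr_zero": mut_iqr_zero,
        "mut_range_zero": mut_range_zero,
    }


def distribution_tables(
    bundles: dict[str, CoverageBundle],
    genes: list[str],
    n_replicates: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Plot-ready mean-profile and summary tables for the chosen genes."""
    prof_rows, summ_rows = [], []
    for gene in genes:
        if gene not in bundles:
            raise ValidationError(f"no coverage bundle for gene {gene}")
        bundle = bundles[gene]
        for strain in ("WT", "MUT"):
            means = mean_profile(bundle, strain, n_replicates)
            prof_rows.append(
                pd.DataFrame(
                    {
                        "gene_id": gene,
                        "strain": strain,
                        "position": np.arange(1, len(means) + 1),
                        "mean": means,
                    }
                )
            )
            s = summarize_distribution(bundle, strain, n_replicates)
            summ_rows.append(
                {
                    "gene_id": gene,
                    "strain": strain,
                    "n_replicates": s.n_replicates,
                    "median": s.median,
                    "q1": s.q1,
                    "q3": s.q3,
                    "min": s.min,
                    "max": s.max,
                    "range": s.range,
                }
            )
    profiles = pd.concat(prof_rows, ignore_index=True)
    summaries = pd.DataFrame(summ_rows)
    return profiles, summaries
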