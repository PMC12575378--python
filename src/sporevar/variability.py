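"""Coverage-variability statistics and five-way strain-exclusivity classification.

For each gene and each of the six samples, two statistics are computed over
the per-base coverage within the gene body:

* CV — sample standard deviation (n-1 denominator) divided by the mean, a
  dimensionless measure of how "punctuated" transcription of the coding
  sequence is;
* range — max minus min per-base coverage, in reads.

A replicate *meets* the variability thresholds when CV >= cv_min OR
range >= range_min (both comparisons inclusive; defaults 0.11 and 2,000
reads).  A gene is then classified from its six meets flags:

==================  =======================================================
category            definition (fullWT = all 3 WT meet; fullMUT likewise)
==================  =======================================================
common              fullWT and fullMUT
wt_only             fullWT and not fullMUT
mutant_only         fullMUT and not fullWT
below_threshold     no replicate in either strain meets
partial             anything else (>=1 meets, neither strain fully)
==================  =======================================================

Classification runs on unadjusted counts.  The default mode computes CV and
range per replicate across positions (one dot per replicate in the scatter
export); an alternative ``across-replicates`` mode pools a strain's three
replicates into one vector per strain before computing the statistics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .coverage import CoverageBundle, CoverageProfile, STRAINS
from .errors import ValidationError
from .gene_sets import GeneSet

CATEGORIES = ("below_threshold", "partial", "common", "wt_only", "mutant_only")

#: Fig.-3-style scatter colors, one per category.
CATEGORY_COLORS = {
    "below_threshold": "gray",
    "partial": "black",
    "common": "green",
    "wt_only": "blue",
    "mutant_only": "red",
}


@dataclass(frozen=True)
class ThresholdConfig:
    """Dual variability thresholds; a replicate meets if either arm does."""

    cv_min: float = 0.11
    range_min: float = 2000.0

    def __post_init__(self):
        if self.cv_min < 0 or self.range_min < 0:
            raise ValidationError("thresholds must be non-negative")

    def meets(self, cv: float, rng: float) -> bool:
        return bool(cv >= self.cv_min or rng >= self.range_min)


@dataclass(frozen=True)
class VariabilityRecord:
    gene_id: str
    strain: str
    replicate: int
    cv: float
    range: float
    meets: bool


def compute_cv(counts: np.ndarray | CoverageProfile) -> float:
    """CV = sample sd (ddof=1) / mean over positions; 0 for an all-zero profile."""
    if isinstance(counts, CoverageProfile):
        counts = counts.counts
    counts = np.asarray(counts, dtype=float)
    if counts.size < 2:
        raise ValidationError("CV requires a profile of length >= 2")
    mean = counts.mean()
    if mean == 0.0:
        if np.any(counts != 0):
            raise ValidationError("zero mean with non-zero counts")
        return 0.0
    return float(counts.std(ddof=1) / mean)


def compute_range(counts: np.ndarray | CoverageProfile) -> float:
    """max(counts) - min(counts)."""
    if isinstance(counts, CoverageProfile):
        counts = counts.counts
    counts = np.asarray(counts, dtype=float)
    if counts.size < 1:
        raise ValidationError("range requires a non-empty profile")
    return float(counts.max() - counts.min())


def evaluate_replicate(
    profile: CoverageProfile,
    thresholds: ThresholdConfig = ThresholdConfig(),
    strict: bool = True,
) -> VariabilityRecord:
    """Score one replicate against the thresholds (unadjusted counts).

    Classification is defined on raw coverage; passing an adjusted profile is
    an error under ``strict`` and a warning otherwise (CV is unaffected by the
    scaling but the range threshold is calibrated in raw reads).
    """
    if profile.adjusted:
        msg = (
            f"{profile.gene_id} {profile.sample}: classification expects "
            "unadjusted counts"
        )
        if strict:
            raise ValidationError(msg)
        warnings.warn(msg, stacklevel=2)
    cv = compute_cv(profile)
    rng = compute_range(profile)
    return VariabilityRecord(
        gene_id=profile.gene_id,
        strain=profile.strain,
        replicate=profile.replicate,
        cv=cv,
        range=rng,
        meets=thresholds.meets(cv, rng),
    )


def classify_gene(records: Iterable[VariabilityRecord]) -> str:
    """Five-way category from the six per-replicate meets flags."""
    records = list(records)
    genes = {r.gene_id for r in records}
    if len(genes) != 1:
        raise ValidationError(f"records span multiple genes: {sorted(genes)}")
    by_strain = {s: [r for r in records if r.strain == s] for s in STRAINS}
    for s in STRAINS:
        if len(by_strain[s]) != 3 or len({r.replicate for r in by_strain[s]}) != 3:
            raise ValidationError(
                f"{genes.pop()}: need exactly 3 {s} replicates, got {len(by_strain[s])}"
            )
    full_wt = all(r.meets for r in by_strain["WT"])
    full_mut = all(r.meets for r in by_strain["MUT"])
    any_meets = any(r.meets for r in records)
    if full_wt and full_mut:
        return "common"
    if full_wt:
        return "wt_only"
    if full_mut:
        return "mutant_only"
    if not any_meets:
        return "below_threshold"
    return "partial"


@dataclass(frozen=True)
class ClassificationResult:
    """Per-replicate records, per-gene categories and summary counts."""

    records: pd.DataFrame
    categories: pd.DataFrame
    summary: dict

    def scatter_table(self) -> pd.DataFrame:
        """Fig.-3-style dot table: x=cv, y=range, one row per replicate dot.

        All six dots of a gene carry the gene's single category color.
        """
        cat = dict(zip(self.categories["gene_id"], self.categories["category"]))
        df = self.records.copy()
        df["category"] = df["gene_id"].map(cat)
        df["color"] = df["category"].map(CATEGORY_COLORS)
        return df[["gene_id", "strain", "replicate", "cv", "range", "category", "color"]]


def classify_universe(
    bundles: Mapping[str, CoverageBundle],
    universe: GeneSet,
    thresholds: ThresholdConfig = ThresholdConfig(),
    mode: str = "per-replicate",
) -> ClassificationResult:
    """Classify every gene in the universe; error on genes without coverage."""
    if mode not in ("per-replicate", "across-replicates"):
        raise ValidationError(f"unknown mode {mode!r}")
    missing = [g for g in universe if g not in bundles]
    if missing:
        raise ValidationError(f"no coverage bundle for gene(s): {missing}")
    rec_rows: list[VariabilityRecord] = []
    cat_rows = []
    for gene in universe:
        bundle = bundles[gene]
        if mode == "per-replicate":
            recs = [evaluate_replicate(p, thresholds) for p in bundle.profiles]
            category = classify_gene(recs)
            rec_rows.extend(recs)
        else:
            # one pooled vector per strain; category from the two strain flags
            strain_meets = {}
            for strain in STRAINS:
                pooled = np.concatenate(
                    [p.counts for p in bundle.strain_profiles(strain)]
                )
                cv, rng = compute_cv(pooled), compute_range(pooled)
                strain_meets[strain] = thresholds.meets(cv, rng)
                rec_rows.append(
                    VariabilityRecord(gene, strain, 0, cv, rng, strain_meets[strain])
                )
            if strain_meets["WT"] and strain_meets["MUT"]:
                category = "common"
            elif strain_meets["WT"]:
                category = "wt_only"
            elif strain_meets["MUT"]:
                category = "mutant_only"
            else:
                category = "below_threshold"
        cat_rows.append({"gene_id": gene, "category": category})

    records = pd.DataFrame(
        [vars(r) for r in rec_rows],
        columns=["gene_id", "strain", "replicate", "cv", "range", "meets"],
    )
    categories = pd.DataFrame(cat_rows, columns=["gene_id", "category"])
    counts = {c: int((categories["category"] == c).sum()) for c in CATEGORIES}
    summary = {
        "n_genes": len(universe),
        "mode": mode,
        "thresholds": {"cv_min": thresholds.cv_min, "range_min": thresholds.range_min},
        "category_counts": counts,
        "exclusive_total": counts["wt_only"] + counts["mutant_only"],
    }
    return ClassificationResult(records=records, categories=categories, summary=summary)


# ---------------------------------------------------------------------------
# Range-threshold derivation

def median_gene_reads(
    bundles: Mapping[str, CoverageBundle], universe: GeneSet | None = None
) -> float:
    """Median over genes of the per-gene mean per-base coverage.

    The per-gene value pools all six samples (mean over positions and
    samples); the median is then taken across genes.
    """
    genes = list(universe) if universe is not None else sorted(bundles)
    if not genes:
        raise ValidationError("cannot take a median over zero genes")
    means = [
        float(np.mean([p.counts.mean() for p in bundles[g].profiles])) for g in genes
    ]
    return float(np.median(means))


def implied_fraction(median_reads: float, range_threshold: float) -> float:
    """Fraction of the median coverage that a range threshold represents."""
    if median_reads <= 0:
        raise ValidationError("median reads must be positive")
    return range_threshold / median_reads


def derive_range_threshold(
    bundles: Mapping[str, CoverageBundle],
    universe: GeneSet | None = None,
    fraction: float = 0.39,
) -> dict:
    """Derive a range threshold as ``fraction x median gene reads``.

    Returns the median, the derived threshold, and a formatter-friendly
    implied-fraction report so the choice can be audited in both directions
    (fraction -> threshold and threshold -> fraction of the median).
    """
    if not 0 < fraction <= 1:
        raise ValidationError("fraction must be in (0, 1]")
    median = median_gene_reads(bundles, universe)
    threshold = fraction * median
    return {
        "median_reads": median,
        "fraction": fraction,
        "range_threshold": threshold,
        "implied_fraction_pct": round(100 * implied_fraction(median, threshold)),
    }
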