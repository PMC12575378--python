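"""Sporulation-phenotype statistics: efficiency, germination, morphometry.

Three readouts compare the wild type with the Mfd-deficient strain:

* sporulation efficiency — the percentage of viable CFU surviving a wet-heat
  pulse (80 degC, 20 min), i.e. heat-resistant spores / total CFU x 100;
  strains compared by one-way ANOVA with Tukey post-hoc (alpha 0.05);
* germination — OD600 time series normalised to the initial reading
  (OD_t / OD_0); descriptive curve export only, no kinetic fit;
* spore morphometry — per-strain medians of spore radius, cortex thickness
  and their ratio from TEM measurements, compared metric-by-metric with a
  two-sample t-test (Welch by default) and significance flagged at
  alpha 0.01.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import anova_tukey
from .errors import FormatError, ValidationError

CFU_COLUMNS = ["strain", "bio_rep", "cfu_total", "cfu_heat"]
MORPH_COLUMNS = ["spore_id", "strain", "radius_nm", "cortex_nm"]


def sporulation_efficiency(cfu: pd.DataFrame, alpha: float = 0.05) -> dict:
    """Per-replicate and per-strain heat-resistant percentages + group test.

    cfu_heat > cfu_total (counting noise) is flagged but retained — plating
    counts can legitimately cross when efficiency is near 100%.
    """
    missing = set(CFU_COLUMNS) - set(cfu.columns)
    if missing:
        raise FormatError(f"CFU table missing column(s) {sorted(missing)}")
    cfu = cfu[CFU_COLUMNS].copy()
    if (cfu["cfu_total"] <= 0).any():
        raise ValidationError("cfu_total must be positive for every record")
    if (cfu["cfu_heat"] < 0).any():
        raise ValidationError("cfu_heat must be non-negative")
    cfu["efficiency_pct"] = 100.0 * cfu["cfu_heat"] / cfu["cfu_total"]
    cfu["heat_exceeds_total"] = cfu["cfu_heat"] > cfu["cfu_total"]
    per_strain = (
        cfu.groupby("strain")["efficiency_pct"]
        .agg(["mean", "std", "count"])
        .rename(columns={"count": "n"})
        .reset_index()
    )
    groups = {
        s: sub["efficiency_pct"].to_numpy() for s, sub in cfu.groupby("strain")
    }
    test = anova_tukey(groups, alpha=alpha) if len(groups) >= 2 else None
    return {"per_replicate": cfu, "per_strain": per_strain, "test": test}


def normalize_germination(times: np.ndarray, od: np.ndarray) -> np.ndarray:
    """OD ratios relative to the initial reading; ratio at t=0 is exactly 1."""
    times = np.asarray(times, dtype=float)
    od = np.asarray(od, dtype=float)
    if times.shape != od.shape or times.ndim != 1 or times.size == 0:
        raise ValidationError("times and od must be equal-length 1-D vectors")
    if times[0] != 0:
        raise ValidationError("first time point must be 0")
    if np.any(np.diff(times) <= 0):
        raise ValidationError("times must be strictly ascending")
    if od[0] <= 0:
        raise ValidationError(f"initial OD must be positive, got {od[0]}")
    return od / od[0]


def germination_table(curves: pd.DataFrame) -> pd.DataFrame:
    """Normalise long-format germination data (strain, bio_rep, time_min, od)."""
    required = {"strain", "bio_rep", "time_min", "od"}
    missing = required - set(curves.columns)
    if missing:
        raise FormatError(f"germination table missing column(s) {sorted(missing)}")
    out = []
    for (strain, rep), grp in curves.groupby(["strain", "bio_rep"]):
        grp = grp.sort_values("time_min")
        ratios = normalize_germination(
            grp["time_min"].to_numpy(), grp["od"].to_numpy()
        )
        grp = grp.copy()
        grp["od_ratio"] = ratios
        out.append(grp)
    return pd.concat(out, ignore_index=True)


def _morph_with_ratio(morphometry: pd.DataFrame) -> pd.DataFrame:
    missing = set(MORPH_COLUMNS) - set(morphometry.columns)
    if missing:
        raise FormatError(f"morphometry table missing column(s) {sorted(missing)}")
    df = morphometry[MORPH_COLUMNS].copy()
    if (df["radius_nm"] <= 0).any() or (df["cortex_nm"] <= 0).any():
        raise ValidationError("radius and cortex must be positive")
    bad = df["cortex_nm"] >= 2 * df["radius_nm"]
    if bad.any():
        sid = df.loc[bad.idxmax(), "spore_id"]
        raise ValidationError(
            f"spore {sid}: cortex thickness must be < 2 x radius"
        )
    # ratio is always recomputed, never read from the input
    df["ratio"] = df["radius_nm"] / df["cortex_nm"]
    return df


def morphometry_compare(
    morphometry: pd.DataFrame,
    alpha: float = 0.01,
    equal_var: bool = False,
) -> pd.DataFrame:
    """Per-strain medians and two-sample t-tests for radius, cortex, ratio.

    Welch's unequal-variance test by default (``equal_var=True`` for the
    pooled-variance variant).  Exactly two strains are required; each needs
    at least two spores.
    """
    df = _morph_with_ratio(morphometry)
    strains = sorted(df["strain"].unique())
    if len(strains) != 2:
        raise ValidationError(f"expected exactly 2 strains, got {strains}")
    a, b = strains
    rows = []
    for metric in ("radius_nm", "cortex_nm", "ratio"):
        xa = df.loc[df["strain"] == a, metric].to_numpy()
        xb = df.loc[df["strain"] == b, metric].to_numpy()
        if len(xa) < 2 or len(xb) < 2:
            raise ValidationError("each strain needs >= 2 spores")
        t, p = stats.ttest_ind(xa, xb, equal_var=equal_var)
        rows.append(
            {
                "metric": metric,
                f"median_{a}": float(np.median(xa)),
                f"median_{b}": float(np.median(xb)),
                "t": float(t),
                "p": float(p),
                "significant": bool(p <= alpha),
                "alpha": alpha,
                f"n_{a}": len(xa),
                f"n_{b}": len(xb),
            }
        )
    return pd.DataFrame(rows)
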