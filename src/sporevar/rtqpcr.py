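"""Relative transcript quantification by the 2^-ddCt method.

Transcript abundance is probed at a 5'-proximal amplicon (A1) and a
3'-proximal amplicon (A2) of each target gene; comparing the two
distinguishes incomplete from complete transcripts.  Ct values are
normalised to the RNase P RNA gene *rnpB* (region ``REF``), which is
unaffected by Mfd status:

    dCt  = Ct_target - Ct_rnpB              (per biological replicate)
    ddCt = dCt - mean dCt of the reference strain (same target/region)
    fold = 2^-ddCt

Technical replicates are averaged first; the reference strain's mean fold is
1 by construction.  Primer-pair amplification efficiency comes from a
standard dilution curve: efficiency = 10^(-1/slope) - 1, where the slope is
the OLS regression of Ct on log10 dilution (slope -3.3219 <=> 100%).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import anova_tukey
from .errors import FormatError, ValidationError

CT_COLUMNS = ["target", "region", "strain", "bio_rep", "tech_rep", "ct"]
REGIONS = ("A1", "A2", "REF")
STRAINS = ("WT", "MUT", "RESTORED")
REFERENCE_GENE = "rnpB"

#: Amplicon coordinates in +bp from the translation start (+1 = first base of
#: the start codon), closed intervals.
DEFAULT_AMPLICONS: dict[tuple[str, str], tuple[int, int]] = {
    ("asnO", "A1"): (163, 332),
    ("asnO", "A2"): (1069, 1209),
    ("cotT", "A1"): (41, 103),
    ("cotT", "A2"): (176, 247),
}


def validate_ct_table(df: pd.DataFrame) -> pd.DataFrame:
    missing = set(CT_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"Ct table missing column(s) {sorted(missing)}")
    df = df[CT_COLUMNS].copy()
    if (df["ct"] <= 0).any():
        raise ValidationError("Ct values must be positive cycles")
    bad_region = ~df["region"].isin(REGIONS)
    if bad_region.any():
        raise ValidationError(
            f"unknown region {df.loc[bad_region.idxmax(), 'region']!r}"
        )
    ref = df[df["region"] == "REF"]
    if (ref["target"] != REFERENCE_GENE).any():
        raise ValidationError(f"REF rows must carry target {REFERENCE_GENE!r}")
    return df


def read_ct_csv(path) -> pd.DataFrame:
    return validate_ct_table(pd.read_csv(path))


def collapse_technical(ct: pd.DataFrame) -> pd.DataFrame:
    """Average technical replicates: one row per (target, region, strain, bio_rep)."""
    ct = validate_ct_table(ct)
    out = (
        ct.groupby(["target", "region", "strain", "bio_rep"], as_index=False)["ct"]
        .mean()
    )
    return out


def ddct(
    ct: pd.DataFrame,
    reference_strain: str = "WT",
    reference_gene: str = REFERENCE_GENE,
) -> pd.DataFrame:
    """Per-biological-replicate dCt, ddCt and fold = 2^-ddCt.

    ``ct`` may contain technical replicates (collapsed here).  Each target
    measurement is paired with the *rnpB* Ct of the same (strain, bio_rep)
    sample; ddCt is relative to the mean dCt of ``reference_strain`` for the
    same target/region, so that strain's mean ddCt is 0 and its mean fold is
    1 by construction.  Adding a constant to every Ct (a plate offset)
    leaves the result unchanged.
    """
    collapsed = collapse_technical(ct)
    ref_rows = collapsed[
        (collapsed["region"] == "REF") & (collapsed["target"] == reference_gene)
    ]
    ref_ct = {
        (r.strain, r.bio_rep): r.ct for r in ref_rows.itertuples()
    }
    targets = collapsed[collapsed["region"] != "REF"].copy()
    if targets.empty:
        raise ValidationError("no target (non-REF) rows in Ct table")

    def _ref(row):
        key = (row["strain"], row["bio_rep"])
        if key not in ref_ct:
            raise ValidationError(
                f"no {reference_gene} row for strain={key[0]} bio_rep={key[1]} "
                f"(needed by {row['target']}/{row['region']})"
            )
        return ref_ct[key]

    targets["delta_ct"] = targets["ct"] - targets.apply(_ref, axis=1)
    out_groups = []
    for (target, region), grp in targets.groupby(["target", "region"]):
        ref_grp = grp[grp["strain"] == reference_strain]
        if ref_grp.empty:
            raise ValidationError(
                f"reference strain {reference_strain!r} absent for "
                f"{target}/{region}"
            )
        ref_mean = ref_grp["delta_ct"].mean()
        grp = grp.copy()
        grp["delta_delta_ct"] = grp["delta_ct"] - ref_mean
        grp["fold"] = 2.0 ** (-grp["delta_delta_ct"])
        out_groups.append(grp)
    out = pd.concat(out_groups, ignore_index=True)
    return out[
        ["target", "region", "strain", "bio_rep", "ct", "delta_ct",
         "delta_delta_ct", "fold"]
    ]


@dataclass(frozen=True)
class PrimerEfficiency:
    primer_pair: str
    slope: float
    intercept: float
    efficiency: float
    r_squared: float
    valid: bool


def primer_efficiency(
    dilution_curve: np.ndarray | pd.DataFrame, primer_pair: str = ""
) -> PrimerEfficiency:
    """Standard-curve efficiency from >= 3 (log10 dilution, Ct) points.

    efficiency = 10^(-1/slope) - 1; a non-negative slope is flagged invalid
    (Ct must rise as template is diluted).
    """
    if isinstance(dilution_curve, pd.DataFrame):
        arr = dilution_curve[["log10_dilution", "ct"]].to_numpy(dtype=float)
    else:
        arr = np.asarray(dilution_curve, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 3:
        raise ValidationError("dilution curve needs >= 3 (log10_dilution, ct) points")
    res = stats.linregress(arr[:, 0], arr[:, 1])
    valid = res.slope < 0
    eff = float(10.0 ** (-1.0 / res.slope) - 1.0) if valid else float("nan")
    return PrimerEfficiency(
        primer_pair=primer_pair,
        slope=float(res.slope),
        intercept=float(res.intercept),
        efficiency=eff,
        r_squared=float(res.rvalue ** 2),
        valid=bool(valid),
    )


def efficiencies_comparable(
    target: PrimerEfficiency, reference: PrimerEfficiency, tol: float = 0.10
) -> bool:
    """Operational check that two primer pairs amplify with similar efficiency."""
    if not (target.valid and reference.valid):
        return False
    return abs(target.efficiency - reference.efficiency) <= tol


def compare_groups(
    expression: pd.DataFrame,
    value: str = "fold",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """One-way ANOVA + Tukey HSD across strains for each (target, region).

    ``value`` selects the analysed scale: ``fold`` (the plotted quantity) or
    ``delta_delta_ct``.  Returns a long table with one row per strain pair
    per (target, region), carrying the group F/p and adjusted pairwise p.
    """
    if value not in ("fold", "delta_delta_ct"):
        raise ValidationError(f"value must be 'fold' or 'delta_delta_ct', got {value!r}")
    rows = []
    for (target, region), grp in expression.groupby(["target", "region"]):
        groups = {
            strain: sub[value].to_numpy()
            for strain, sub in grp.groupby("strain")
        }
        report = anova_tukey(groups, alpha=alpha)
        for pair in report["pairwise"]:
            rows.append(
                {
                    "target": target,
                    "region": region,
                    "value": value,
                    "f": report["f"],
                    "p": report["p"],
                    "degenerate": report["degenerate"],
                    **pair,
                }
            )
    return pd.DataFrame(rows)
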