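"""Stability filtering of externally predicted structure-forming motifs.

Candidate non-B DNA / RNA motifs (G-quadruplexes, inverted repeats, ...) are
discovered and folded by external tools; this module consumes their tabular
export (gene, motif type, +bp interval, minimum free energy in kcal/mol) and
keeps motifs stable enough to plausibly stall an elongating RNA polymerase:
MFE <= -5.0 kcal/mol, boundary inclusive.  A helper intersects the surviving
motifs with qPCR amplicon intervals (closed-interval overlap, shared +bp
frame from the gene start).
"""

from __future__ import annotations

import pandas as pd

from .errors import FormatError, ValidationError

MOTIF_COLUMNS = ["gene_id", "motif_type", "start", "end", "mfe"]
STABILITY_CUTOFF = -5.0  # kcal/mol


def validate_motifs(motifs: pd.DataFrame) -> pd.DataFrame:
    missing = set(MOTIF_COLUMNS) - set(motifs.columns)
    if missing:
        raise FormatError(f"motif table missing column(s) {sorted(missing)}")
    df = motifs[MOTIF_COLUMNS].copy()
    if df["mfe"].isna().any():
        row = int(df.index[df["mfe"].isna()][0])
        raise ValidationError(f"missing MFE at row {row}")
    if (df["start"] >= df["end"]).any():
        raise ValidationError("motif start must be < end")
    return df


def filter_stable_motifs(
    motifs: pd.DataFrame, cutoff: float = STABILITY_CUTOFF
) -> pd.DataFrame:
    """Keep motifs with MFE <= cutoff; the kept rows carry stable=True.

    Monotone (lowering the cutoff never adds rows) and idempotent.
    """
    df = validate_motifs(motifs)
    kept = df[df["mfe"] <= cutoff].copy()
    kept["stable"] = True
    return kept.reset_index(drop=True)


def motif_counts(motifs: pd.DataFrame) -> pd.DataFrame:
    """Per-gene motif counts for a (typically filtered) motif table."""
    df = validate_motifs(motifs)
    return (
        df.groupby("gene_id")
        .size()
        .rename("n_motifs")
        .reset_index()
        .sort_values("gene_id")
        .reset_index(drop=True)
    )


def annotate_amplicons(
    motifs: pd.DataFrame,
    amplicon_map: dict[tuple[str, str], tuple[int, int]],
) -> pd.DataFrame:
    """Motifs overlapping each (gene, region) amplicon, closed intervals."""
    df = validate_motifs(motifs)
    rows = []
    for (gene, region), (a_start, a_end) in sorted(amplicon_map.items()):
        if a_start >= a_end:
            raise ValidationError(
                f"amplicon {gene}/{region}: start must be < end"
            )
        sub = df[
            (df["gene_id"] == gene)
            & (df["start"] <= a_end)
            & (df["end"] >= a_start)
        ]
        for rec in sub.itertuples():
            rows.append(
                {
                    "gene_id": gene,
                    "region": region,
                    "amplicon_start": a_start,
                    "amplicon_end": a_end,
                    "motif_type": rec.motif_type,
                    "motif_start": rec.start,
                    "motif_end": rec.end,
                    "mfe": rec.mfe,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "gene_id", "region", "amplicon_start", "amplicon_end",
            "motif_type", "motif_start", "motif_end", "mfe",
        ],
    )
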