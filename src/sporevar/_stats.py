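"""Shared group-comparison helper: one-way ANOVA with Tukey HSD post-hoc."""

from __future__ import annotations

import numpy as np
from scipy import stats

from .errors import ValidationError


def anova_tukey(groups: dict[str, np.ndarray], alpha: float = 0.05) -> dict:
    """One-way ANOVA F/p plus pairwise Tukey HSD adjusted p-values.

    ``groups`` maps group label -> 1-D sample.  A fully degenerate input
    (zero within-group variance in every group) is flagged rather than
    raised: identical groups then yield F = 0 and no significant pairs.
    """
    if len(groups) < 2:
        raise ValidationError("ANOVA requires at least 2 groups")
    labels = list(groups)
    samples = [np.asarray(groups[k], dtype=float) for k in labels]
    for lbl, s in zip(labels, samples):
        if s.size < 2:
            raise ValidationError(f"group {lbl!r} needs >= 2 observations")
    degenerate = all(np.ptp(s) == 0 for s in samples)
    if degenerate:
        # zero within-group variance everywhere: F is 0/0 (identical groups)
        # or infinite (distinct constants); define both outcomes explicitly
        identical = len({float(s[0]) for s in samples}) == 1
        pairs = [
            {
                "group1": a,
                "group2": b,
                "p_adj": 1.0 if float(groups[a][0]) == float(groups[b][0]) else 0.0,
                "significant": float(groups[a][0]) != float(groups[b][0]),
            }
            for i, a in enumerate(labels)
            for b in labels[i + 1:]
        ]
        return {
            "f": 0.0 if identical else float("inf"),
            "p": 1.0 if identical else 0.0,
            "significant": not identical,
            "degenerate": True,
            "alpha": alpha,
            "pairwise": pairs,
        }
    f, p = stats.f_oneway(*samples)
    tukey = stats.tukey_hsd(*samples)
    pairs = []
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            p_adj = float(tukey.pvalue[i, j])
            pairs.append(
                {
                    "group1": labels[i],
                    "group2": labels[j],
                    "p_adj": p_adj,
                    "significant": bool(p_adj <= alpha),
                }
            )
    return {
        "f": float(f),
        "p": float(p),
        "significant": bool(p <= alpha),
        "degenerate": bool(degenerate),
        "alpha": alpha,
        "pairwise": pairs,
    }
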