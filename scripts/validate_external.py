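#!/usr/bin/env python
"""Optional benchmark validation against the authors' deposited data.

Given a directory containing the deposited per-gene coverage CSVs plus the
regulon and DEG lists laid out as::

    <input-dir>/regulons.tsv      gene_id<TAB>regulon
    <input-dir>/deg.txt           one gene id per line
    <input-dir>/coverage/<gene>.csv

this script runs universe selection and the default per-replicate CV/range
classification and prints the headline counts (universe size, wt-only,
mutant-only and strain-exclusive totals) as JSON.  It is a thin wrapper so
the published counts can be checked whenever the deposit is available
locally; nothing is downloaded.

Usage:
    python scripts/validate_external.py --input-dir DIR [--cv-min 0.11]
        [--range-min 2000]
"""

import argparse
import json
import sys
from pathlib import Path

from sporevar.coverage import read_coverage_dir
from sporevar.gene_sets import load_gene_set, load_regulon_table, select_gene_universe
from sporevar.variability import ThresholdConfig, classify_universe


def main(argv=None) -> int:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--input-dir", required=True, type=Path)
    ap.add_argument("--cv-min", type=float, default=0.11)
    ap.add_argument("--range-min", type=float, default=2000.0)
    args = ap.parse_args(argv)

    d = args.input_dir
    universe = select_gene_universe(
        load_regulon_table(d / "regulons.tsv"), load_gene_set(d / "deg.txt")
    )
    bundles = read_coverage_dir(d / "coverage", universe)
    res = classify_universe(
        bundles, universe, ThresholdConfig(args.cv_min, args.range_min)
    )
    counts = res.summary["category_counts"]
    print(json.dumps(
        {
            "universe": len(universe),
            "wt_only": counts["wt_only"],
            "mutant_only": counts["mutant_only"],
            "exclusive": res.summary["exclusive_total"],
            "category_counts": counts,
        },
        indent=2, sort_keys=True,
    ))
    return 0


if __name__ == "__main__":
    sys.exit(main())
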