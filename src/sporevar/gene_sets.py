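"""Build the analysis gene universe.

The universe is the intersection of sporulation regulon membership (genes
controlled by Spo0A or the sporulation sigma factors sigma-H/E/F/K/G) with a
list of genes differentially expressed upon loss of the transcription-repair
coupling factor Mfd.  Gene identifiers are matched by exact, case-insensitive
equality after whitespace stripping; synonym resolution is out of scope.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .errors import FormatError, ValidationError

logger = logging.getLogger(__name__)

#: The six sporulation regulators whose regulons define the candidate pool.
ALLOWED_REGULONS = frozenset({"Spo0A", "SigH", "SigE", "SigF", "SigK", "SigG"})


def _norm(gene_id: str) -> str:
    return str(gene_id).strip().casefold()


@dataclass(frozen=True)
class GeneSet:
    """An ordered, duplicate-free set of gene identifiers.

    Genes are stored sorted by their case-folded form so that output order is
    deterministic regardless of input order.
    """

    genes: tuple[str, ...]
    provenance: str = ""

    @classmethod
    def from_iterable(cls, genes, provenance: str = "") -> "GeneSet":
        seen: dict[str, str] = {}
        for g in genes:
            g = str(g).strip()
            if not g:
                raise ValidationError("empty gene identifier in gene set")
            seen.setdefault(_norm(g), g)
        ordered = tuple(seen[k] for k in sorted(seen))
        return cls(genes=ordered, provenance=provenance)

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes)

    def __contains__(self, gene_id: str) -> bool:
        return _norm(gene_id) in {_norm(g) for g in self.genes}

    @property
    def normalized(self) -> frozenset[str]:
        return frozenset(_norm(g) for g in self.genes)


def load_regulon_table(path: str | Path, sep: str = "\t") -> pd.DataFrame:
    """Read a regulon membership table (columns ``gene_id``, ``regulon``).

    Duplicate (gene, regulon) pairs are collapsed; a regulon label outside the
    six sporulation regulators is rejected with the offending row named.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=sep, dtype=str)
    missing = {"gene_id", "regulon"} - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing column(s) {sorted(missing)}")
    df = df[["gene_id", "regulon"]].copy()
    df["gene_id"] = df["gene_id"].astype(str).str.strip()
    df["regulon"] = df["regulon"].astype(str).str.strip()
    if (df["gene_id"] == "").any():
        row = int(df.index[df["gene_id"] == ""][0])
        raise ValidationError(f"{path}: empty gene_id at row {row}")
    bad = ~df["regulon"].isin(ALLOWED_REGULONS)
    if bad.any():
        row = df.index[bad][0]
        raise ValidationError(
            f"{path}: unknown regulon {df.loc[row, 'regulon']!r} at row {int(row)} "
            f"(allowed: {sorted(ALLOWED_REGULONS)})"
        )
    df["_key"] = df["gene_id"].map(_norm)
    df = df.drop_duplicates(subset=["_key", "regulon"]).drop(columns="_key")
    return df.reset_index(drop=True)


def load_gene_set(path: str | Path, provenance: str | None = None) -> GeneSet:
    """Read a plain-text gene list, one identifier per line."""
    path = Path(path)
    lines = [ln.strip() for ln in path.read_text().splitlines()]
    return GeneSet.from_iterable(
        (ln for ln in lines if ln), provenance=provenance or str(path)
    )


def write_gene_set(genes: GeneSet, path: str | Path) -> None:
    Path(path).write_text("\n".join(genes.genes) + ("\n" if len(genes) else ""))


def select_gene_universe(regulons: pd.DataFrame, deg_list: GeneSet) -> GeneSet:
    """Intersect regulon members with the Mfd-affected DEG list.

    Returns genes present in at least one sporulation regulon AND in
    ``deg_list``.  An empty intersection is returned (with a warning), not
    raised: a disjoint pair of inputs is a legitimate, if unproductive, query.
    """
    if len(regulons) == 0 or len(deg_list) == 0:
        raise ValidationError("both regulon table and DEG list must be non-empty")
    regulon_genes = {}
    for g in regulons["gene_id"]:
        regulon_genes.setdefault(_norm(g), g)
    deg_keys = deg_list.normalized
    hit_keys = sorted(set(regulon_genes) & deg_keys)
    provenance = (
        f"intersection of regulon members (n={len(regulon_genes)}) "
        f"with DEG list '{deg_list.provenance}' (n={len(deg_list)}): "
        f"{len(hit_keys)} genes"
    )
    if not hit_keys:
        logger.warning("gene universe is empty: regulon and DEG inputs are disjoint")
    return GeneSet(
        genes=tuple(regulon_genes[k] for k in hit_keys), provenance=provenance
    )
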