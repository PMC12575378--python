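"""Per-gene per-base read-coverage profiles.

The on-disk layout is one CSV per gene: a ``position`` column (1-based,
contiguous along the coding sequence in the direction of transcription) plus
six sample columns named ``<strain>_r<replicate>`` with strain in {WT, MUT}
and replicate in 1..3 — three biological replicates of the wild-type strain
and three of the Mfd-deficient mutant.

"Unadjusted" counts are the values as parsed; "adjusted" counts are
library-size scaled (counts x scale / library_size), the minimal per-million
style normalisation.  Variability classification operates on unadjusted
counts; distribution summaries operate on adjusted counts.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

STRAINS = ("WT", "MUT")
REPLICATES = (1, 2, 3)
SAMPLE_COLUMNS = tuple(f"{s}_r{r}" for s in STRAINS for r in REPLICATES)


def sample_name(strain: str, replicate: int) -> str:
    return f"{strain}_r{replicate}"


@dataclass(frozen=True)
class CoverageProfile:
    """Read coverage of one gene in one sample (strain x replicate).

    ``counts[i]`` is the coverage at 1-based position ``i + 1`` within the
    gene body.  Counts may be integer reads or already-normalised reals; both
    are accepted, but they must be non-negative.
    """

    gene_id: str
    strain: str
    replicate: int
    counts: np.ndarray
    adjusted: bool = False

    def __post_init__(self):
        if self.strain not in STRAINS:
            raise ValidationError(
                f"{self.gene_id}: strain must be one of {STRAINS}, got {self.strain!r}"
            )
        if self.replicate not in REPLICATES:
            raise ValidationError(
                f"{self.gene_id}: replicate must be in {REPLICATES}, "
                f"got {self.replicate!r}"
            )
        counts = np.asarray(self.counts, dtype=float)
        if counts.ndim != 1 or counts.size < 1:
            raise ValidationError(f"{self.gene_id}: counts must be a non-empty vector")
        if not np.all(np.isfinite(counts)):
            raise ValidationError(f"{self.gene_id}: non-finite count")
        if np.any(counts < 0):
            pos = int(np.argmax(counts < 0)) + 1
            raise ValidationError(
                f"{self.gene_id} {self.sample}: negative count at position {pos}"
            )
        object.__setattr__(self, "counts", counts)

    @property
    def sample(self) -> str:
        return sample_name(self.strain, self.replicate)

    def __len__(self) -> int:
        return self.counts.size


@dataclass(frozen=True)
class CoverageBundle:
    """The six profiles of one gene (3 WT + 3 MUT replicates, equal length)."""

    gene_id: str
    profiles: tuple[CoverageProfile, ...]

    def __post_init__(self):
        samples = [p.sample for p in self.profiles]
        missing = [s for s in SAMPLE_COLUMNS if s not in samples]
        if missing or len(self.profiles) != 6:
            raise ValidationError(
                f"{self.gene_id}: expected exactly one profile per sample "
                f"{SAMPLE_COLUMNS}; missing {missing or 'none'}, "
                f"got {len(self.profiles)}"
            )
        lengths = {len(p) for p in self.profiles}
        if len(lengths) != 1:
            raise ValidationError(
                f"{self.gene_id}: profiles have unequal lengths {sorted(lengths)}"
            )
        for p in self.profiles:
            if p.gene_id != self.gene_id:
                raise ValidationError(
                    f"bundle {self.gene_id} contains profile for {p.gene_id}"
                )
        # canonical sample order
        ordered = tuple(sorted(self.profiles, key=lambda p: SAMPLE_COLUMNS.index(p.sample)))
        object.__setattr__(self, "profiles", ordered)

    @property
    def length(self) -> int:
        return len(self.profiles[0])

    @property
    def adjusted(self) -> bool:
        flags = {p.adjusted for p in self.profiles}
        if len(flags) != 1:
            raise ValidationError(f"{self.gene_id}: mixed adjusted/unadjusted profiles")
        return flags.pop()

    def profile(self, strain: str, replicate: int) -> CoverageProfile:
        for p in self.profiles:
            if p.strain == strain and p.replicate == replicate:
                return p
        raise KeyError((strain, replicate))

    def strain_profiles(self, strain: str) -> list[CoverageProfile]:
        return [p for p in self.profiles if p.strain == strain]


def read_gene_csv(path: str | Path, adjusted: bool = False) -> CoverageBundle:
    """Parse one per-gene coverage CSV into a validated bundle.

    The gene id is taken from the file stem.  Positions must run contiguously
    from 1 to the gene length; any gap, missing sample column or negative
    count raises a :class:`ValidationError` naming the gene and defect.
    """
    path = Path(path)
    gene_id = path.stem
    df = pd.read_csv(path)
    if "position" not in df.columns:
        raise FormatError(f"{gene_id}: missing 'position' column in {path}")
    missing = [c for c in SAMPLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{gene_id}: missing sample column(s) {missing}")
    if df[list(SAMPLE_COLUMNS)].isna().any().any():
        raise ValidationError(f"{gene_id}: ragged table (missing values)")
    pos = df["position"].to_numpy()
    expected = np.arange(1, len(df) + 1)
    if len(pos) == 0 or not np.array_equal(pos, expected):
        bad = int(np.argmax(pos != expected[: len(pos)])) if len(pos) else 0
        raise ValidationError(
            f"{gene_id}: positions must be contiguous 1..{len(df)} "
            f"(first defect near row {bad})"
        )
    profiles = []
    for strain in STRAINS:
        for rep in REPLICATES:
            profiles.append(
                CoverageProfile(
                    gene_id=gene_id,
                    strain=strain,
                    replicate=rep,
                    counts=df[sample_name(strain, rep)].to_numpy(dtype=float),
                    adjusted=adjusted,
                )
            )
    return CoverageBundle(gene_id=gene_id, profiles=tuple(profiles))


def write_gene_csv(bundle: CoverageBundle, path: str | Path) -> None:
    """Write a bundle in the one-CSV-per-gene layout (inverse of read)."""
    data = {"position": np.arange(1, bundle.length + 1)}
    for p in bundle.profiles:
        data[p.sample] = p.counts
    pd.DataFrame(data).to_csv(Path(path), index=False)


def read_coverage_dir(directory: str | Path, genes: Iterable[str] | None = None) -> dict[str, CoverageBundle]:
    """Load every ``<gene>.csv`` in a directory (or only the named genes)."""
    directory = Path(directory)
    if genes is None:
        paths = sorted(directory.glob("*.csv"))
    else:
        paths = [directory / f"{g}.csv" for g in genes]
    missing = [p.stem for p in paths if not p.exists()]
    if missing:
        raise ValidationError(f"missing coverage file(s) for gene(s): {missing}")
    return {p.stem: read_gene_csv(p) for p in paths}


def read_library_sizes(path: str | Path) -> dict[str, float]:
    """Read a two-column ``sample,total_reads`` CSV into a mapping."""
    df = pd.read_csv(path)
    missing = {"sample", "total_reads"} - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing column(s) {sorted(missing)}")
    return dict(zip(df["sample"].astype(str), df["total_reads"].astype(float)))


def adjust_counts(
    bundle: CoverageBundle,
    library_sizes: Mapping[str, float],
    scale: float = 1e6,
) -> CoverageBundle:
    """Library-size scale a bundle: counts x scale / library_size(sample).

    CV is unchanged by this linear scaling; per-profile range is multiplied by
    the same factor as the counts.
    """
    if scale <= 0:
        raise ValidationError(f"scale must be positive, got {scale}")
    new_profiles = []
    for p in bundle.profiles:
        if p.sample not in library_sizes:
            raise ValidationError(
                f"{bundle.gene_id}: no library size for sample {p.sample}"
            )
        size = float(library_sizes[p.sample])
        if size <= 0:
            raise ValidationError(
                f"{bundle.gene_id}: library size for {p.sample} must be > 0, got {size}"
            )
        new_profiles.append(
            replace(p, counts=p.counts * (scale / size), adjusted=True)
        )
    return CoverageBundle(gene_id=bundle.gene_id, profiles=tuple(new_profiles))


# ---------------------------------------------------------------------------
# bedGraph support: a thin bridge from genome-frame interval coverage to the
# internal 1-based gene-relative frame.

def read_bedgraph(path: str | Path) -> pd.DataFrame:
    """Read a bedGraph (chrom, start, end, value; 0-based half-open)."""
    df = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        header=None,
        names=["chrom", "start", "end", "value"],
    )
    if len(df) and (df["end"] <= df["start"]).any():
        raise ValidationError(f"{path}: bedGraph interval with end <= start")
    return df


def read_bed(path: str | Path) -> pd.DataFrame:
    """Read a 6-column BED annotation (chrom, start, end, name, score, strand)."""
    df = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        header=None,
        names=["chrom", "start", "end", "name", "score", "strand"],
    )
    if not df["strand"].isin(["+", "-"]).all():
        raise ValidationError(f"{path}: strand must be '+' or '-'")
    return df


def profile_from_bedgraph(
    bedgraph: pd.DataFrame,
    chrom: str,
    start: int,
    end: int,
    strand: str = "+",
) -> np.ndarray:
    """Slice per-base coverage for one gene from bedGraph intervals.

    ``start``/``end`` follow BED convention (0-based half-open, genome frame).
    The returned vector is in the 1-based gene-relative frame: index 0 is the
    first transcribed base, so a minus-strand gene is reversed.  Bases not
    covered by any interval get 0.
    """
    if end <= start:
        raise ValidationError(f"gene interval end ({end}) must exceed start ({start})")
    out = np.zeros(end - start, dtype=float)
    sub = bedgraph[(bedgraph["chrom"] == chrom)
                   & (bedgraph["end"] > start)
                   & (bedgraph["start"] < end)]
    for _, row in sub.iterrows():
        lo = max(int(row["start"]), start) - start
        hi = min(int(row["end"]), end) - start
        out[lo:hi] = float(row["value"])
    if strand == "-":
        out = out[::-1].copy()
    return out
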