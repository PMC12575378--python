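"""Synthetic inputs with the statistical structure the analysis assumes.

The generator emulates the features of the real data that the pipeline keys
on, so every stage is testable without any download:

* per-base coverage drawn from a negative binomial (dispersion exposed; a
  Poisson limit is available via ``dispersion=inf``) around a mean function
  with localized pause peaks — rectangular bumps of elevated mean at
  sequence-fixed positions, producing the high-CV / high-range "punctuated"
  signature of pause-and-reactivation transcription;
* strain-dependent 3' attenuation — a step (or geometric) drop in mean
  coverage after a breakpoint, modelling decreased formation of transcripts
  containing the 3' end in the Mfd-deficient mutant;
* Gaussian Ct noise around configured true fold changes, with an
  Mfd-independent *rnpB* reference;
* near-normal morphometry and binomially thinned heat-resistance counts.

Every gene uses its own RNG substream seeded by (seed, gene index), so the
profile of gene *i* is identical no matter how many genes are generated,
and identical seeds give byte-identical output files.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .coverage import (
    REPLICATES,
    STRAINS,
    CoverageBundle,
    CoverageProfile,
    sample_name,
    write_gene_csv,
)
from .errors import ValidationError
from .gene_sets import ALLOWED_REGULONS

TRUTH_CATEGORIES = ("below_threshold", "partial", "common", "wt_only", "mutant_only")


@dataclass(frozen=True)
class PauseModel:
    """Localized elongation-pause peaks: ``n_pauses`` rectangular bumps of
    ``width`` bp where the mean is multiplied by ``amplitude``."""

    n_pauses: int = 2
    amplitude: float = 8.0
    width: int = 50

    def __post_init__(self):
        if self.n_pauses < 0 or self.width < 1 or self.amplitude < 1:
            raise ValidationError("invalid pause model")


@dataclass(frozen=True)
class Attenuation:
    """3' coverage attenuation: retention fraction applied after a
    breakpoint at ``breakpoint_fraction`` of the gene length."""

    breakpoint_fraction: float = 0.6
    retention: float = 0.4
    mode: str = "step"  # or "geometric": decays to `retention` at the 3' end

    def __post_init__(self):
        if not 0 < self.breakpoint_fraction < 1:
            raise ValidationError("breakpoint_fraction must be in (0, 1)")
        if not 0 < self.retention <= 1:
            raise ValidationError("retention must be in (0, 1]")
        if self.mode not in ("step", "geometric"):
            raise ValidationError(f"unknown attenuation mode {self.mode!r}")

    def factor(self, length: int) -> np.ndarray:
        x = np.arange(length, dtype=float)
        b = self.breakpoint_fraction * length
        f = np.ones(length)
        tail = x >= b
        if self.mode == "step":
            f[tail] = self.retention
        else:
            span = max(length - b, 1.0)
            f[tail] = np.exp(np.log(self.retention) * (x[tail] - b) / span)
        return f


@dataclass(frozen=True)
class SyntheticConfig:
    """All generator knobs; defaults define the standard study conditions."""

    seed: int = 0
    n_genes: int = 200
    gene_length_range: tuple[int, int] = (800, 2000)
    baseline_mean: float = 1000.0  # reads/base in the wild type
    dispersion: float = 200.0  # NB size parameter; inf = Poisson
    pause: PauseModel = field(default_factory=PauseModel)
    attenuation: Attenuation = field(default_factory=Attenuation)
    mut_multiplier: float = 0.6  # mutant expression relative to WT
    category_weights: dict = field(
        default_factory=lambda: {
            "below_threshold": 0.3,
            "partial": 0.1,
            "common": 0.2,
            "wt_only": 0.2,
            "mutant_only": 0.2,
        }
    )
    regulon_probs: dict = field(
        default_factory=lambda: {r: 1 / 6 for r in sorted(ALLOWED_REGULONS)}
    )
    deg_fraction: float = 0.9

    def __post_init__(self):
        lo, hi = self.gene_length_range
        if not (1 <= lo <= hi):
            raise ValidationError("invalid gene_length_range")
        if self.n_genes < 0 or self.baseline_mean <= 0 or self.dispersion <= 0:
            raise ValidationError("n_genes, baseline_mean, dispersion must be positive")
        if not 0 < self.mut_multiplier:
            raise ValidationError("mut_multiplier must be positive")
        if set(self.category_weights) - set(TRUTH_CATEGORIES):
            raise ValidationError("unknown truth category in category_weights")
        if any(w < 0 for w in self.category_weights.values()) or sum(
            self.category_weights.values()
        ) <= 0:
            raise ValidationError("category weights must be non-negative, sum > 0")
        if sum(self.regulon_probs.values()) > 1 + 1e-9:
            raise ValidationError("regulon probabilities must sum to <= 1")
        if not 0 <= self.deg_fraction <= 1:
            raise ValidationError("deg_fraction must be in [0, 1]")


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative-binomial counts with position-varying mean and fixed size k.

    var = mean + mean^2 / k; ``dispersion=inf`` gives the Poisson limit.
    """
    mean = np.asarray(mean, dtype=float)
    if math.isinf(dispersion):
        return rng.poisson(mean).astype(float)
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p).astype(float)


def _pause_positions(rng: np.random.Generator, length: int, pause: PauseModel) -> np.ndarray:
    """Sequence-fixed pause centers, kept off the gene ends."""
    margin = pause.width
    lo, hi = margin, max(length - margin, margin + 1)
    return np.sort(rng.integers(lo, hi, size=pause.n_pauses))


def _mean_function(
    length: int,
    base_mean: float,
    pause: PauseModel | None,
    pause_centers: np.ndarray | None,
    attenuation: Attenuation | None,
) -> np.ndarray:
    mean = np.full(length, base_mean)
    if pause is not None and pause_centers is not None and pause.n_pauses:
        half = pause.width // 2
        for c in pause_centers:
            lo = max(int(c) - half, 0)
            hi = min(int(c) + half + 1, length)
            mean[lo:hi] = base_mean * pause.amplitude
    if attenuation is not None:
        mean = mean * attenuation.factor(length)
    return mean


def simulate_bundle(
    gene_id: str,
    length: int,
    rng: np.random.Generator,
    config: SyntheticConfig,
    pause_strains: dict[str, list[int]] | None = None,
    attenuate_strains: tuple[str, ...] = (),
) -> CoverageBundle:
    """Draw one gene's six profiles.

    ``pause_strains`` maps strain -> replicate numbers carrying the pause
    signature (pause centers are drawn once per gene: the pause is a property
    of the sequence, not of the replicate).  ``attenuate_strains`` lists
    strains with 3' attenuation.
    """
    pause_strains = pause_strains or {}
    centers = _pause_positions(rng, length, config.pause)
    profiles = []
    for strain in STRAINS:
        base = config.baseline_mean * (
            1.0 if strain == "WT" else config.mut_multiplier
        )
        att = config.attenuation if strain in attenuate_strains else None
        for rep in REPLICATES:
            has_pause = rep in pause_strains.get(strain, [])
            mean = _mean_function(
                length,
                base,
                config.pause if has_pause else None,
                centers if has_pause else None,
                att,
            )
            profiles.append(
                CoverageProfile(
                    gene_id=gene_id,
                    strain=strain,
                    replicate=rep,
                    counts=_nb_draw(rng, mean, config.dispersion),
                )
            )
    return CoverageBundle(gene_id=gene_id, profiles=tuple(profiles))


def _category_pauses(category: str, rng: np.random.Generator) -> dict[str, list[int]]:
    all_reps = list(REPLICATES)
    if category == "below_threshold":
        return {}
    if category == "wt_only":
        return {"WT": all_reps}
    if category == "mutant_only":
        return {"MUT": all_reps}
    if category == "common":
        return {"WT": all_reps, "MUT": all_reps}
    # partial: the pause fires in exactly one replicate of one strain
    strain = str(rng.choice(STRAINS))
    rep = int(rng.choice(all_reps))
    return {strain: [rep]}


def simulate_coverage(
    config: SyntheticConfig,
) -> tuple[dict[str, CoverageBundle], pd.DataFrame]:
    """Truth-stratified coverage simulation.

    Each gene is assigned an intended five-way category; pause placement per
    strain/replicate realises it.  Attenuation is not applied to these
    category genes (a step drop is itself whole-gene variance and would
    change the intended class); use :func:`simulate_attenuation_scenario`
    for 3'-attenuated gene pairs.  Returns bundles plus a truth table.
    """
    cats = sorted(config.category_weights)
    probs = np.array([config.category_weights[c] for c in cats], dtype=float)
    probs = probs / probs.sum()
    bundles: dict[str, CoverageBundle] = {}
    truth_rows = []
    lo, hi = config.gene_length_range
    for i in range(config.n_genes):
        rng = np.random.default_rng([config.seed, i])
        gene_id = f"gene{i:04d}"
        length = int(rng.integers(lo, hi + 1))
        category = str(rng.choice(cats, p=probs))
        pauses = _category_pauses(category, rng)
        bundles[gene_id] = simulate_bundle(gene_id, length, rng, config, pauses)
        regulon = str(
            rng.choice(
                sorted(config.regulon_probs),
                p=np.array([config.regulon_probs[r] for r in sorted(config.regulon_probs)])
                / sum(config.regulon_probs.values()),
            )
        )
        in_deg = bool(rng.random() < config.deg_fraction)
        truth_rows.append(
            {
                "gene_id": gene_id,
                "category": category,
                "length": length,
                "regulon": regulon,
                "in_deg": in_deg,
            }
        )
    truth = pd.DataFrame(
        truth_rows, columns=["gene_id", "category", "length", "regulon", "in_deg"]
    )
    return bundles, truth


def simulate_attenuation_scenario(
    config: SyntheticConfig, n_genes: int = 20, name_prefix: str = "att"
) -> dict[str, CoverageBundle]:
    """Fig.-4-style genes: WT carries pauses, the mutant is generated from
    WT parameters with reduced expression and 3' attenuation, no pauses."""
    bundles = {}
    for i in range(n_genes):
        rng = np.random.default_rng([config.seed, 1_000_000 + i])
        gene_id = f"{name_prefix}{i:03d}"
        lo, hi = config.gene_length_range
        length = int(rng.integers(lo, hi + 1))
        bundles[gene_id] = simulate_bundle(
            gene_id,
            length,
            rng,
            config,
            pause_strains={"WT": list(REPLICATES)},
            attenuate_strains=("MUT",),
        )
    return bundles


# ---------------------------------------------------------------------------
# RT-qPCR

def default_ct_truth() -> dict[tuple[str, str, str], float]:
    """True fold changes emulating the transcript-completion experiment:
    5' amplicons unaffected, the mutant's 3' amplicon reduced four-fold in
    the Mfd-affected genes, restored by complementation; the control gene
    *ctc* is unaffected everywhere."""
    folds = {}
    for gene in ("ctc", "asnO", "cotT"):
        for strain in ("WT", "MUT", "RESTORED"):
            for region in ("A1", "A2"):
                folds[(gene, region, strain)] = 1.0
    folds[("asnO", "A2", "MUT")] = 0.25
    folds[("cotT", "A2", "MUT")] = 0.25
    return folds


def simulate_ct(
    true_folds: dict[tuple[str, str, str], float],
    noise_sd: float = 0.15,
    n_bio: int = 3,
    n_tech: int = 3,
    seed: int = 0,
    target_base_ct: float = 22.0,
    ref_base_ct: float = 16.0,
) -> pd.DataFrame:
    """Ct table with Ct = base - log2(expression) + N(0, noise_sd) per
    technical measurement; *rnpB* reference rows are strain-independent.

    With ``noise_sd=0`` the ddCt pipeline returns the true folds exactly.
    """
    if noise_sd < 0 or n_bio < 1 or n_tech < 1:
        raise ValidationError("invalid Ct simulation parameters")
    rng = np.random.default_rng([seed, 2_000_000])
    strains = sorted({k[2] for k in true_folds})
    rows = []
    for strain in strains:
        for bio in range(1, n_bio + 1):
            for tech in range(1, n_tech + 1):
                rows.append(
                    {
                        "target": "rnpB",
                        "region": "REF",
                        "strain": strain,
                        "bio_rep": bio,
                        "tech_rep": tech,
                        "ct": ref_base_ct + rng.normal(0.0, noise_sd),
                    }
                )
    for (gene, region, strain), fold in sorted(true_folds.items()):
        if fold <= 0:
            raise ValidationError(f"fold must be positive for {(gene, region, strain)}")
        for bio in range(1, n_bio + 1):
            for tech in range(1, n_tech + 1):
                rows.append(
                    {
                        "target": gene,
                        "region": region,
                        "strain": strain,
                        "bio_rep": bio,
                        "tech_rep": tech,
                        "ct": target_base_ct
                        - math.log2(fold)
                        + rng.normal(0.0, noise_sd),
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Phenotype inputs

DEFAULT_MORPH_PARAMS: dict[str, dict[str, tuple[float, float]]] = {
    # (mean nm, sd nm); means follow the reported strain medians, spreads
    # reflect large spore-size vs tight cortex-thickness variability
    "WT": {"radius": (310.0, 40.0), "cortex": (91.0, 10.0)},
    "MUT": {"radius": (301.0, 40.0), "cortex": (61.0, 10.0)},
}


def simulate_morphometry(
    params: dict | None = None, n: int = 30, seed: int = 0
) -> pd.DataFrame:
    """Near-normal radius/cortex draws per strain, truncated to positive
    values and to cortex < 2 x radius (redrawn on violation)."""
    params = params if params is not None else DEFAULT_MORPH_PARAMS
    rng = np.random.default_rng([seed, 3_000_000])
    rows = []
    for strain in sorted(params):
        r_mean, r_sd = params[strain]["radius"]
        c_mean, c_sd = params[strain]["cortex"]
        for i in range(n):
            for _ in range(1000):
                radius = rng.normal(r_mean, r_sd)
                cortex = rng.normal(c_mean, c_sd)
                if radius > 0 and 0 < cortex < 2 * radius:
                    break
            else:  # pragma: no cover - parameters would have to be absurd
                raise ValidationError("could not draw a valid spore")
            rows.append(
                {
                    "spore_id": f"{strain}_{i + 1:03d}",
                    "strain": strain,
                    "radius_nm": radius,
                    "cortex_nm": cortex,
                }
            )
    return pd.DataFrame(rows, columns=["spore_id", "strain", "radius_nm", "cortex_nm"])


def simulate_cfu(
    efficiency: dict[str, float] | None = None,
    total_cfu: float = 1e8,
    n_reps: int = 6,
    rep_sd: float = 0.1,
    seed: int = 0,
) -> pd.DataFrame:
    """Heat-resistance counts: binomial thinning of total CFU.

    ``rep_sd`` adds log-normal between-replicate variation to the thinning
    probability (dilution/plating noise); 0 gives pure binomial sampling.
    """
    efficiency = efficiency or {"WT": 0.45, "MUT": 0.30, "RESTORED": 0.43}
    rng = np.random.default_rng([seed, 4_000_000])
    rows = []
    for strain in sorted(efficiency):
        eff = efficiency[strain]
        if not 0 <= eff <= 1:
            raise ValidationError(f"efficiency for {strain} must be in [0, 1]")
        for rep in range(1, n_reps + 1):
            total = int(rng.poisson(total_cfu))
            p = eff * float(rng.lognormal(0.0, rep_sd)) if rep_sd > 0 else eff
            heat = int(rng.binomial(total, min(p, 1.0))) if total > 0 else 0
            rows.append(
                {
                    "strain": strain,
                    "bio_rep": rep,
                    "cfu_total": total,
                    "cfu_heat": heat,
                }
            )
    return pd.DataFrame(rows, columns=["strain", "bio_rep", "cfu_total", "cfu_heat"])


def simulate_germination(
    strains: tuple[str, ...] = ("WT", "MUT"),
    n_reps: int = 3,
    t_end_min: int = 210,
    step_min: int = 15,
    noise_sd: float = 0.01,
    seed: int = 0,
) -> pd.DataFrame:
    """OD600 time series: initial drop (spore darkening on germination) to
    ~60% of the starting OD by ~60 min, then rise during outgrowth.  Both
    strains share the same kinetics — germination is Mfd-independent."""
    rng = np.random.default_rng([seed, 5_000_000])
    times = np.arange(0, t_end_min + 1, step_min, dtype=float)
    # smooth drop-then-rise template on the OD-ratio scale
    drop = 1.0 - 0.4 * (1.0 - np.exp(-times / 25.0))
    rise = 0.6 * np.clip((times - 75.0) / 135.0, 0.0, None) ** 1.5
    template = drop + rise
    rows = []
    for strain in strains:
        for rep in range(1, n_reps + 1):
            od0 = 0.5 * float(rng.lognormal(0.0, 0.05))
            od = od0 * template * np.exp(rng.normal(0.0, noise_sd, size=times.size))
            od[0] = od0
            for t, v in zip(times, od):
                rows.append(
                    {"strain": strain, "bio_rep": rep, "time_min": t, "od": v}
                )
    return pd.DataFrame(rows, columns=["strain", "bio_rep", "time_min", "od"])


def simulate_motifs(
    genes: tuple[str, ...] = ("asnO", "cotT", "ctc"),
    n_per_gene: int = 4,
    seed: int = 0,
) -> pd.DataFrame:
    """Motif candidates with MFE spread around the stability cutoff."""
    rng = np.random.default_rng([seed, 6_000_000])
    rows = []
    for gene in genes:
        for i in range(n_per_gene):
            start = int(rng.integers(1, 1200))
            rows.append(
                {
                    "gene_id": gene,
                    "motif_type": str(rng.choice(["G4", "inverted_repeat"])),
                    "start": start,
                    "end": start + int(rng.integers(15, 60)),
                    "mfe": float(np.round(rng.uniform(-12.0, -1.0), 2)),
                }
            )
    return pd.DataFrame(rows, columns=["gene_id", "motif_type", "start", "end", "mfe"])


# ---------------------------------------------------------------------------
# Full input-directory layout

def write_simulation(config: SyntheticConfig, outdir: str | Path) -> dict:
    """Emit every input the pipeline consumes, plus the truth table.

    Layout: ``coverage/<gene>.csv``, ``truth.csv``, ``regulons.tsv``,
    ``deg.txt``, ``library_sizes.csv``, ``ct.csv``, ``cfu.csv``,
    ``germination.csv``, ``morphometry.csv``, ``motifs.csv``.
    """
    outdir = Path(outdir)
    (outdir / "coverage").mkdir(parents=True, exist_ok=True)
    bundles, truth = simulate_coverage(config)
    for gene_id, bundle in sorted(bundles.items()):
        write_gene_csv(bundle, outdir / "coverage" / f"{gene_id}.csv")
    truth.to_csv(outdir / "truth.csv", index=False)
    truth[["gene_id", "regulon"]].to_csv(
        outdir / "regulons.tsv", sep="\t", index=False
    )
    deg = truth.loc[truth["in_deg"], "gene_id"].tolist()
    (outdir / "deg.txt").write_text("\n".join(deg) + ("\n" if deg else ""))
    lib_rng = np.random.default_rng([config.seed, 7_000_000])
    lib = pd.DataFrame(
        {
            "sample": [sample_name(s, r) for s in STRAINS for r in REPLICATES],
            "total_reads": np.round(lib_rng.uniform(1.5e7, 2.5e7, size=6)),
        }
    )
    lib.to_csv(outdir / "library_sizes.csv", index=False)
    simulate_ct(default_ct_truth(), seed=config.seed).to_csv(
        outdir / "ct.csv", index=False
    )
    simulate_cfu(seed=config.seed).to_csv(outdir / "cfu.csv", index=False)
    simulate_germination(seed=config.seed).to_csv(
        outdir / "germination.csv", index=False
    )
    simulate_morphometry(seed=config.seed).to_csv(
        outdir / "morphometry.csv", index=False
    )
    simulate_motifs(seed=config.seed).to_csv(outdir / "motifs.csv", index=False)
    return {
        "n_genes": config.n_genes,
        "truth_counts": truth["category"].value_counts().to_dict(),
        "outdir": str(outdir),
    }
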