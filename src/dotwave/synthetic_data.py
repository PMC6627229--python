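"""Seeded simulator of a toy yeast-like genome with planted Rpd3 biology.

The generator lays out non-overlapping genes on a handful of chromosomes and
assigns each gene a wild-type Dot1 dose (lambda, drawn log-normally so the
population spans the me1 and me3 waves), a transcription rate and an H2Bub
level coupled to it.  Two planted gene classes carry the effects the analysis
must recover:

* Rpd3 targets — repressed genes with sub-median wild-type dose whose
  transcription, H2Bub and Dot1 dose all rise (default 4-fold) in the
  rpd3-deletion genotype, so H3K79me3 rises at their 5' ends.
* Subtelomeric genes — placed within 30 kb of a chromosome end; their dose
  falls in the mutant (default to 0.25x), mimicking the loss of subtelomeric
  H3K79 methylation.

Tracks for H3K79me1, H3K79me3, H3, H2Bub and H2B are produced by Poisson
sampling per-base read starts against the expected measured signal and
extending reads to the configured length — the same transform the real
pipeline applies to aligned reads.  The measurement model mirrors real
ChIP-seq in two ways, both configurable:

* a nonspecific pulldown background proportional to the mark's genome-mean
  specific signal (``nonspecific_background``; 1.4 means ~40% of reads are
  informative, a realistic IP efficiency), which floors coverage the way
  real antibody background does;
* library-size equalization (``equalize_depth``): every track is sampled to
  the same genome-mean coverage, as sequencing a fixed read budget would,
  rather than in proportion to the mark's absolute abundance.

With ``nonspecific_background=0, equalize_depth=False`` the expected
coverage of each methylation mark is exactly proportional to occupancy times
its state fraction, so window me3/me1 ratios converge to the model's
activity ratio.  A low uniform background dose outside genes makes me1, but
essentially no me3, appear in intergenic space.

Everything is deterministic for a fixed config seed; replicates share
expectations and differ only in their noise streams.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .coverage_ops import CoverageTrack, GeneAnnotation, coverage_from_start_counts
from .methylation_model import state_fractions

__all__ = [
    "GeneTruth",
    "SimulationConfig",
    "MARKS",
    "GENOTYPES",
    "simulate_genome",
    "simulate_tracks",
    "simulate_bulk_fractions",
    "expected_coverage",
]

MARKS = ("H3K79me1", "H3K79me3", "H3", "H2Bub", "H2B")
GENOTYPES = ("WT", "rpd3")
_GENOTYPE_ALIASES = {
    "WT": "WT",
    "wt": "WT",
    "rpd3": "rpd3",
    "rpd3Δ": "rpd3",  # rpd3Δ
    "rpd3D": "rpd3",
}


def canonical_genotype(genotype: str) -> str:
    try:
        return _GENOTYPE_ALIASES[genotype]
    except KeyError:
        raise ValueError(
            f"unknown genotype {genotype!r}; expected one of {sorted(set(_GENOTYPE_ALIASES))}"
        ) from None


@dataclass(frozen=True)
class GeneTruth(GeneAnnotation):
    """Ground-truth gene record: annotation plus latent simulation parameters."""

    tx_rate_wt: float = 1.0
    tx_rate_mut: float = 1.0
    h2bub_wt: float = 1.0
    h2bub_mut: float = 1.0
    lambda_wt: float = 1.0
    lambda_mut: float = 1.0
    is_rpd3_target: bool = False
    is_subtelomeric: bool = False

    def __post_init__(self) -> None:
        super().__post_init__()
        for name in ("tx_rate_wt", "tx_rate_mut", "h2bub_wt", "h2bub_mut", "lambda_wt", "lambda_mut"):
            if getattr(self, name) < 0:
                raise ValueError(f"{self.gene_id}: {name} must be nonnegative")
        if self.is_rpd3_target and not (
            self.lambda_mut > self.lambda_wt
            and self.tx_rate_mut > self.tx_rate_wt
            and self.h2bub_mut > self.h2bub_wt
        ):
            raise ValueError(f"{self.gene_id}: Rpd3 target must gain dose/tx/H2Bub in the mutant")
        if self.is_subtelomeric and not self.lambda_mut < self.lambda_wt:
            raise ValueError(f"{self.gene_id}: subtelomeric gene must lose dose in the mutant")

    def dose(self, genotype: str) -> float:
        return self.lambda_wt if canonical_genotype(genotype) == "WT" else self.lambda_mut

    def h2bub(self, genotype: str) -> float:
        return self.h2bub_wt if canonical_genotype(genotype) == "WT" else self.h2bub_mut


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic genome.

    Defaults give a 200-gene genome on 4 chromosomes with 10% planted Rpd3
    targets (4-fold dose/transcription/H2Bub gain in the mutant) and 10%
    planted subtelomeric genes (dose falling to 0.25x), sampled at ~30x
    genome-mean coverage with 150-bp read extension and two replicates per
    condition.  Planted genes draw their wild-type dose from restricted
    (log-uniform) ranges: targets are repressed, sub-saturation genes
    (lambda 0.5-1.5) so a 4-fold gain is visible before me3 saturates;
    subtelomeric genes carry a moderate dose (lambda 1-3) so the loss is
    measurable above the assay background.
    """

    n_genes: int = 200
    n_chromosomes: int = 4
    chrom_length: int = 520_000
    fraction_targets: float = 0.10
    fraction_subtelomeric: float = 0.10
    target_dose_fold: float = 4.0
    subtel_dose_fold: float = 0.25
    target_tx_fold: float = 4.0
    mean_window_depth: float = 30.0
    read_length: int = 150
    n_replicates: int = 2
    seed: int = 0
    gene_length: int = 1500
    gene_spacing: int = 10_000
    subtel_spacing: int = 3000
    background_dose: float = 0.3
    background_h2bub: float = 0.05
    subtelomere_margin: int = 30_000
    lambda_log_mean: float = math.log(2.0)
    lambda_log_sigma: float = 0.7
    lambda_clip: tuple[float, float] = (0.4, 8.0)
    target_lambda_range: tuple[float, float] = (0.5, 1.5)
    subtel_lambda_range: tuple[float, float] = (1.0, 3.0)
    nonspecific_background: float = 1.4
    equalize_depth: bool = True

    def __post_init__(self) -> None:
        if self.n_genes < 0 or self.n_chromosomes < 1 or self.chrom_length < 1:
            raise ValueError("counts and lengths must be positive")
        if not (0 <= self.fraction_targets <= 1 and 0 <= self.fraction_subtelomeric <= 1):
            raise ValueError("fractions must lie in [0, 1]")
        if self.fraction_targets + self.fraction_subtelomeric > 1:
            raise ValueError("fraction_targets + fraction_subtelomeric must be <= 1")
        if self.n_replicates < 1 or self.read_length < 1:
            raise ValueError("n_replicates and read_length must be >= 1")
        if self.gene_length + 500 > min(self.gene_spacing, self.subtel_spacing):
            # keep each gene's upstream-500 window out of its neighbour
            raise ValueError("gene spacing must exceed gene_length + 500")
        if self.nonspecific_background < 0:
            raise ValueError("nonspecific_background must be >= 0")


def _chrom_names(config: SimulationConfig) -> list[str]:
    return [f"chr{i + 1}" for i in range(config.n_chromosomes)]


def _log_uniform(rng: np.random.Generator, lo: float, hi: float, size: int) -> np.ndarray:
    return np.exp(rng.uniform(math.log(lo), math.log(hi), size=size))


def simulate_genome(config: SimulationConfig) -> tuple[list[GeneTruth], dict[str, int]]:
    """Place genes and draw their latent parameters; deterministic per seed.

    Planted subtelomeric genes occupy slots within ``subtelomere_margin`` of a
    chromosome end; all other genes sit in the interior, so the positional
    subtelomere annotation and the planted flag coincide by construction.
    """
    chrom_sizes = {c: config.chrom_length for c in _chrom_names(config)}
    if config.n_genes == 0:
        return [], chrom_sizes
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0]))

    n = config.n_genes
    n_subtel = int(round(config.fraction_subtelomeric * n))
    n_targets = int(round(config.fraction_targets * n))

    chroms = _chrom_names(config)
    per_chrom = [n // len(chroms) + (1 if i < n % len(chroms) else 0) for i in range(len(chroms))]
    subtel_per_chrom = [
        n_subtel // len(chroms) + (1 if i < n_subtel % len(chroms) else 0)
        for i in range(len(chroms))
    ]

    glen, margin = config.gene_length, config.subtelomere_margin
    placements: list[tuple[str, int, int, bool]] = []  # chrom, start, end, subtel
    for chrom, k_total, k_sub in zip(chroms, per_chrom, subtel_per_chrom):
        size = chrom_sizes[chrom]
        # subtelomeric slots alternate between the two chromosome ends
        left = (k_sub + 1) // 2
        right = k_sub - left
        for j in range(left):
            start = 2000 + j * config.subtel_spacing
            if start + glen > margin:
                raise ValueError("config error: subtelomeric genes do not fit within the margin")
            placements.append((chrom, start, start + glen, True))
        for j in range(right):
            end = size - 2000 - j * config.subtel_spacing
            if end - glen < size - margin:
                raise ValueError("config error: subtelomeric genes do not fit within the margin")
            placements.append((chrom, end - glen, end, True))
        k_interior = k_total - k_sub
        first = margin + 1000
        last_end = first + (k_interior - 1) * config.gene_spacing + glen if k_interior else first
        if last_end > size - margin:
            raise ValueError(
                "config error: interior genes cannot be placed without entering the "
                "subtelomeric margin; increase chrom_length or reduce n_genes"
            )
        for j in range(k_interior):
            start = first + j * config.gene_spacing
            placements.append((chrom, start, start + glen, False))

    interior_idx = [i for i, p in enumerate(placements) if not p[3]]
    target_idx = set(rng.choice(interior_idx, size=n_targets, replace=False).tolist())

    lam_wt = np.clip(
        rng.lognormal(config.lambda_log_mean, config.lambda_log_sigma, size=len(placements)),
        *config.lambda_clip,
    )
    # planted classes draw from their detectable-dose ranges
    lam_target = _log_uniform(rng, *config.target_lambda_range, size=len(placements))
    lam_subtel = _log_uniform(rng, *config.subtel_lambda_range, size=len(placements))
    strands = rng.choice(["+", "-"], size=len(placements))

    genes: list[GeneTruth] = []
    for i, (chrom, start, end, is_sub) in enumerate(placements):
        is_target = i in target_idx
        if is_target:
            lw = float(lam_target[i])
            fold_l, fold_t = config.target_dose_fold, config.target_tx_fold
        elif is_sub:
            lw = float(lam_subtel[i])
            fold_l = fold_t = config.subtel_dose_fold
        else:
            lw = float(lam_wt[i])
            fold_l = fold_t = 1.0
        tx = lw  # transcription in arbitrary units, coupled to dose
        genes.append(
            GeneTruth(
                gene_id=f"g{i:04d}",
                chrom=chrom,
                start=start,
                end=end,
                strand=str(strands[i]),
                tx_rate_wt=tx,
                tx_rate_mut=tx * fold_t,
                h2bub_wt=tx,
                h2bub_mut=tx * fold_t,
                lambda_wt=lw,
                lambda_mut=lw * fold_l,
                is_rpd3_target=is_target,
                is_subtelomeric=is_sub,
            )
        )
    genes.sort(key=lambda g: (g.chrom, g.start))
    return genes, chrom_sizes


def _specific_signals(
    genes: list[GeneTruth], chrom_sizes: dict[str, int], genotype: str, config: SimulationConfig
) -> dict[str, dict[str, np.ndarray]]:
    """Per-base specific (pre-background) signal for every mark; occupancy 1."""
    genotype = canonical_genotype(genotype)
    lam = {c: np.full(size, config.background_dose) for c, size in chrom_sizes.items()}
    h2bub = {c: np.full(size, config.background_h2bub) for c, size in chrom_sizes.items()}
    for g in genes:
        lam[g.chrom][g.start : g.end] = g.dose(genotype)
        h2bub[g.chrom][g.start : g.end] = g.h2bub(genotype)
    signals: dict[str, dict[str, np.ndarray]] = {m: {} for m in MARKS}
    for c in chrom_sizes:
        frac = state_fractions(lam[c])
        signals["H3K79me1"][c] = frac[:, 1]
        signals["H3K79me3"][c] = frac[:, 3]
        signals["H3"][c] = np.ones(chrom_sizes[c])
        signals["H2B"][c] = np.ones(chrom_sizes[c])
        signals["H2Bub"][c] = h2bub[c]
    return signals


def _measured_signals(
    genes: list[GeneTruth], chrom_sizes: dict[str, int], genotype: str, config: SimulationConfig
) -> dict[str, dict[str, np.ndarray]]:
    """Apply antibody background and optional library-size equalization.

    measured = specific + beta * genome_mean(specific); with equalize_depth
    the result is rescaled so its genome mean is 1 (every track sequenced to
    the same budget).
    """
    specific = _specific_signals(genes, chrom_sizes, genotype, config)
    genome = sum(chrom_sizes.values())
    out: dict[str, dict[str, np.ndarray]] = {}
    for mark, per_chrom in specific.items():
        mean_s = sum(float(v.sum()) for v in per_chrom.values()) / genome
        meas = {c: v + config.nonspecific_background * mean_s for c, v in per_chrom.items()}
        if config.equalize_depth:
            mean_m = sum(float(v.sum()) for v in meas.values()) / genome
            if mean_m > 0:
                meas = {c: v / mean_m for c, v in meas.items()}
        out[mark] = meas
    return out


def expected_coverage(
    genes: list[GeneTruth],
    chrom_sizes: dict[str, int],
    genotype: str,
    config: SimulationConfig,
    mark: str,
) -> dict[str, np.ndarray]:
    """Noise-free expected coverage (measured signal x mean_window_depth)."""
    if mark not in MARKS:
        raise ValueError(f"unknown mark {mark!r}")
    sig = _measured_signals(genes, chrom_sizes, genotype, config)[mark]
    return {c: v * config.mean_window_depth for c, v in sig.items()}


def simulate_tracks(
    genes: list[GeneTruth],
    genotype: str,
    config: SimulationConfig,
    chrom_sizes: dict[str, int] | None = None,
    marks: tuple[str, ...] = MARKS,
) -> dict[tuple[str, int], CoverageTrack]:
    """Poisson-sample raw coverage tracks for every mark and replicate.

    Read starts are drawn per base with rate signal * depth / read_length,
    split evenly between strands, then extended ``read_length`` bp — so a
    region of unit measured signal has expected coverage
    ``mean_window_depth``.  Returns ``{(mark, replicate_index):
    CoverageTrack}`` with raw units and the sampled read totals.
    """
    genotype = canonical_genotype(genotype)
    if chrom_sizes is None:
        chrom_sizes = {c: config.chrom_length for c in _chrom_names(config)}
    unknown = set(marks) - set(MARKS)
    if unknown:
        raise ValueError(f"unknown marks: {sorted(unknown)}")
    signals = _measured_signals(genes, chrom_sizes, genotype, config)
    tracks: dict[tuple[str, int], CoverageTrack] = {}
    geno_idx = GENOTYPES.index(genotype)
    for mark in marks:
        mark_idx = MARKS.index(mark)
        for rep in range(config.n_replicates):
            rng = np.random.default_rng(
                np.random.SeedSequence([config.seed, 1, geno_idx, mark_idx, rep])
            )
            data: dict[str, np.ndarray] = {}
            total = 0
            for c in sorted(chrom_sizes):
                rate = signals[mark][c] * (config.mean_window_depth / config.read_length)
                starts_plus = rng.poisson(rate / 2.0)
                starts_minus = rng.poisson(rate / 2.0)
                total += int(starts_plus.sum() + starts_minus.sum())
                data[c] = coverage_from_start_counts(
                    starts_plus, starts_minus, config.read_length
                )
            tracks[(mark, rep)] = CoverageTrack(
                data=data,
                total_reads=total,
                read_length=config.read_length,
                units="raw",
                mark=mark,
                genotype=genotype,
                replicate_id=f"rep{rep + 1}",
            )
    return tracks


def simulate_bulk_fractions(genes: list[GeneTruth], genotype: str) -> np.ndarray:
    """Genome-averaged me0..me3 fractions — what a bulk mass-spec readout sees.

    Occupancy-weighted mean of the per-gene state distributions; with flat
    occupancy the weights reduce to gene lengths.
    """
    if not genes:
        raise ValueError("simulate_bulk_fractions needs a nonempty gene list")
    genotype = canonical_genotype(genotype)
    lengths = np.array([g.end - g.start for g in genes], dtype=float)
    fracs = state_fractions([g.dose(genotype) for g in genes])
    out = (lengths[:, None] * fracs).sum(axis=0) / lengths.sum()
    return out
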