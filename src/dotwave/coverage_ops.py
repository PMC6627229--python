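"""Coverage-track operations for TSS-anchored ChIP-seq quantification.

The pipeline consumes stranded read 5'-positions (alignment itself is out of
scope), extends each read to a fixed fragment length, and works on per-base
coverage vectors per chromosome.  From there: depth normalization (reads per
million, or RPGC — reads per genomic content, where a uniformly 1x-covered
genome scores 1.0), fixed-width binning, replicate similarity/merging, and
strand-oriented gene-window matrices around the TSS with their metagene
averages.

Coordinates are 0-based half-open throughout.  The TSS of a plus-strand gene
is its start coordinate; of a minus-strand gene, its end coordinate minus 1.
Window positions falling off a chromosome end are marked NaN and excluded
from means (zero-filling would bias genes near chromosome ends).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "GeneAnnotation",
    "CoverageTrack",
    "TssMatrix",
    "MergeReport",
    "extend_reads",
    "coverage_from_start_counts",
    "normalize_rpgc",
    "normalize_rpm",
    "bin_array",
    "bin_coverage",
    "merge_replicates",
    "tss_matrix",
    "metagene",
    "DEFAULT_READ_LENGTH",
    "DEFAULT_WINDOW",
]

DEFAULT_READ_LENGTH = 150  # bp, single-end read extension length
DEFAULT_WINDOW = (-500, 1000)  # bp relative to TSS
DEFAULT_BIN = 10  # bp, heatmap/merge binning
REPLICATE_R_THRESHOLD = 0.8  # Pearson r below which replicates are not merged

VALID_UNITS = ("raw", "rpm", "rpgc")


@dataclass(frozen=True)
class GeneAnnotation:
    """Strand-aware gene interval (0-based half-open)."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"{self.gene_id}: invalid interval [{self.start}, {self.end})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be + or -, got {self.strand!r}")

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1


@dataclass
class CoverageTrack:
    """Per-base coverage for one mark/genotype/replicate.

    ``data`` maps chromosome name to a float vector whose length equals the
    chromosome length (divided by ``bin_size`` once binned).  ``units`` tracks
    which normalization has been applied so transforms cannot be stacked
    inconsistently.
    """

    data: dict[str, np.ndarray]
    total_reads: int
    read_length: int = DEFAULT_READ_LENGTH
    units: str = "raw"
    mark: str = ""
    genotype: str = ""
    replicate_id: str = ""
    bin_size: int = 1
    skipped_reads: int = 0

    def __post_init__(self) -> None:
        if self.units not in VALID_UNITS:
            raise ValueError(f"unknown units {self.units!r}; expected one of {VALID_UNITS}")
        for chrom, vec in self.data.items():
            v = np.asarray(vec, dtype=float)
            if v.ndim != 1:
                raise ValueError(f"{chrom}: coverage must be 1-D")
            if np.any(v < 0) or not np.all(np.isfinite(v)):
                raise ValueError(f"{chrom}: coverage must be finite and nonnegative")
            self.data[chrom] = v

    @property
    def genome_size(self) -> int:
        return sum(len(v) for v in self.data.values()) * self.bin_size

    def concatenated(self) -> np.ndarray:
        """Genome-wide vector in sorted-chromosome order (for correlations)."""
        return np.concatenate([self.data[c] for c in sorted(self.data)])


def extend_reads(
    read_positions: Mapping[str, tuple[Sequence[int], Sequence[str]]],
    chrom_sizes: Mapping[str, int],
    read_length: int = DEFAULT_READ_LENGTH,
    **track_meta,
) -> CoverageTrack:
    """Build raw coverage by extending stranded 5' read positions.

    ``read_positions`` maps chromosome -> (positions, strands).  A plus-strand
    read at position p covers [p, p + L); a minus-strand read is anchored at
    its 5' end so that a read recorded with (exclusive) end position p covers
    [p - L, p).  Extension is clipped at chromosome bounds.  Reads anchored
    outside their chromosome are skipped and counted (``skipped_reads``), not
    fatal.
    """
    if read_length < 1:
        raise ValueError("read_length must be >= 1")
    data: dict[str, np.ndarray] = {}
    n_reads = 0
    n_skipped = 0
    for chrom, size in chrom_sizes.items():
        diff = np.zeros(size + 1)
        if chrom in read_positions:
            pos, strands = read_positions[chrom]
            pos = np.asarray(pos, dtype=np.int64)
            strands = np.asarray(strands)
            plus = strands == "+"
            ok_p = plus & (pos >= 0) & (pos < size)
            ok_m = ~plus & (pos > 0) & (pos <= size)
            n_skipped += int(pos.size - ok_p.sum() - ok_m.sum())
            starts = np.concatenate(
                [pos[ok_p], np.maximum(pos[ok_m] - read_length, 0)]
            )
            ends = np.concatenate(
                [np.minimum(pos[ok_p] + read_length, size), pos[ok_m]]
            )
            np.add.at(diff, starts, 1.0)
            np.add.at(diff, ends, -1.0)
            n_reads += int(ok_p.sum() + ok_m.sum())
        data[chrom] = np.cumsum(diff[:-1])
    if n_skipped:
        logger.warning("extend_reads: skipped %d out-of-bounds reads", n_skipped)
    return CoverageTrack(
        data=data,
        total_reads=n_reads,
        read_length=read_length,
        units="raw",
        skipped_reads=n_skipped,
        **track_meta,
    )


def coverage_from_start_counts(
    counts_plus: np.ndarray, counts_minus: np.ndarray, read_length: int
) -> np.ndarray:
    """Coverage from per-base read-start counts (fast path for simulation).

    ``counts_plus[x]`` holds plus-strand 5' starts at x (reads cover
    [x, x+L)); ``counts_minus[x]`` holds minus-strand reads whose exclusive
    end is x+1 (covering [x+1-L, x+1)).  Equivalent to materializing positions
    and calling :func:`extend_reads`.
    """
    size = len(counts_plus)
    diff = np.zeros(size + 1)
    diff[:size] += counts_plus
    ends_p = np.minimum(np.arange(size) + read_length, size)
    np.add.at(diff, ends_p, -counts_plus)
    ends_m = np.arange(1, size + 1)
    starts_m = np.maximum(ends_m - read_length, 0)
    np.add.at(diff, starts_m, counts_minus)
    np.add.at(diff, np.minimum(ends_m, size), -counts_minus)
    return np.cumsum(diff[:-1])


def _require_units(track: CoverageTrack, units: str, op: str) -> None:
    if track.units != units:
        raise ValueError(f"{op} expects a {units!r} track, got units={track.units!r}")


def normalize_rpgc(track: CoverageTrack, genome_size: int | None = None) -> CoverageTrack:
    """Scale raw coverage to reads per genomic content (1x genome -> 1.0).

    Every base is multiplied by genome_size / (total_reads * read_length), so
    a genome uniformly covered at physical depth 1 maps to RPGC 1.0.
    """
    _require_units(track, "raw", "normalize_rpgc")
    if track.total_reads <= 0:
        raise ValueError("cannot RPGC-normalize a track with zero reads")
    g = track.genome_size if genome_size is None else int(genome_size)
    scale = g / (track.total_reads * track.read_length)
    return replace(track, data={c: v * scale for c, v in track.data.items()}, units="rpgc")


def normalize_rpm(track: CoverageTrack) -> CoverageTrack:
    """Scale raw coverage to reads per million mapped reads."""
    _require_units(track, "raw", "normalize_rpm")
    if track.total_reads <= 0:
        raise ValueError("cannot depth-normalize a track with zero reads")
    scale = 1e6 / track.total_reads
    return replace(track, data={c: v * scale for c, v in track.data.items()}, units="rpm")


def bin_array(values: np.ndarray, bin_size: int) -> np.ndarray:
    """Mean of consecutive ``bin_size`` entries; a trailing partial bin is
    averaged over its actual width."""
    if bin_size < 1:
        raise ValueError("bin_size must be >= 1")
    v = np.asarray(values, dtype=float)
    if bin_size == 1:
        return v.copy()
    n_full = len(v) // bin_size
    out = np.empty(int(np.ceil(len(v) / bin_size)))
    if n_full:
        out[:n_full] = v[: n_full * bin_size].reshape(n_full, bin_size).mean(axis=1)
    if len(v) % bin_size:
        out[n_full] = v[n_full * bin_size :].mean()
    return out


def bin_coverage(track: CoverageTrack, bin_size: int = DEFAULT_BIN) -> CoverageTrack:
    """Bin every chromosome of a per-base track into ``bin_size``-bp means."""
    if track.bin_size != 1:
        raise ValueError("track is already binned")
    return replace(
        track,
        data={c: bin_array(v, bin_size) for c, v in track.data.items()},
        bin_size=bin_size,
    )


@dataclass(frozen=True)
class MergeReport:
    """Outcome of a replicate-similarity check."""

    pearson_r: float
    merged: bool
    threshold: float
    n_tracks: int


def merge_replicates(
    tracks: Sequence[CoverageTrack],
    r_threshold: float = REPLICATE_R_THRESHOLD,
    bin_size: int = DEFAULT_BIN,
) -> tuple[CoverageTrack | list[CoverageTrack], MergeReport]:
    """Merge same-condition replicates when they are similar enough.

    Similarity is the (minimum pairwise) Pearson correlation of genome-wide
    ``bin_size``-bp binned coverage.  When it clears ``r_threshold`` the
    merged track is the read-count-weighted mean of the replicates; otherwise
    the tracks are returned unmerged with a warning (not an exception), so the
    caller can inspect the discordant pair.
    """
    if len(tracks) < 2:
        raise ValueError("need at least two tracks to merge")
    first = tracks[0]
    for t in tracks[1:]:
        if (t.mark, t.genotype, t.units, t.bin_size) != (
            first.mark,
            first.genotype,
            first.units,
            first.bin_size,
        ):
            raise ValueError("replicates must share mark, genotype, units and binning")
        if sorted(t.data) != sorted(first.data) or any(
            len(t.data[c]) != len(first.data[c]) for c in first.data
        ):
            raise ValueError("replicates must cover identical chromosomes")
    binned = [np.concatenate([bin_array(t.data[c], bin_size) for c in sorted(t.data)]) for t in tracks]
    r = min(
        float(np.corrcoef(binned[i], binned[j])[0, 1])
        for i in range(len(tracks))
        for j in range(i + 1, len(tracks))
    )
    if r < r_threshold:
        logger.warning(
            "replicates %s not merged: min pairwise r=%.3f < %.3f",
            [t.replicate_id for t in tracks],
            r,
            r_threshold,
        )
        return list(tracks), MergeReport(r, False, r_threshold, len(tracks))
    weights = np.array([t.total_reads for t in tracks], dtype=float)
    if weights.sum() <= 0:
        weights = np.ones(len(tracks))
    weights /= weights.sum()
    merged_data = {
        c: sum(w * t.data[c] for w, t in zip(weights, tracks)) for c in first.data
    }
    # coverage is a weighted mean, so the equivalent depth is the weighted
    # mean of the replicate read totals (not their sum)
    merged = replace(
        first,
        data=merged_data,
        total_reads=int(round(sum(w * t.total_reads for w, t in zip(weights, tracks)))),
        replicate_id="merged",
    )
    return merged, MergeReport(r, True, r_threshold, len(tracks))


@dataclass
class TssMatrix:
    """Genes x offsets matrix of coverage around the TSS, strand-oriented.

    Column 0 is always ``window[0]`` bp upstream of the TSS along the gene's
    own 5'->3' direction; minus-strand genes are read right-to-left.  Entries
    falling outside the chromosome are NaN.
    """

    gene_ids: list[str]
    values: np.ndarray
    window: tuple[int, int] = DEFAULT_WINDOW
    bin_size: int = 1
    units: str = "raw"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), self.n_cols):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {self.n_cols} bins"
            )

    @property
    def n_cols(self) -> int:
        span = self.window[1] - self.window[0]
        return int(np.ceil(span / self.bin_size))

    @property
    def offsets(self) -> np.ndarray:
        """Start offset (bp, TSS-relative) of each column's bin."""
        return self.window[0] + self.bin_size * np.arange(self.n_cols)


def tss_matrix(
    track: CoverageTrack,
    genes: Iterable[GeneAnnotation],
    window: tuple[int, int] = DEFAULT_WINDOW,
    bin_size: int = 1,
) -> TssMatrix:
    """Per-gene coverage in a strand-oriented window around the TSS.

    Genes on unknown chromosomes are skipped with a warning.  Positions off
    the chromosome ends are NaN (excluded from downstream means rather than
    zero-filled).
    """
    if track.bin_size != 1:
        raise ValueError("tss_matrix requires a per-base (unbinned) track")
    lo, hi = window
    if lo >= hi:
        raise ValueError(f"invalid window {window}")
    span = hi - lo
    gene_ids: list[str] = []
    rows: list[np.ndarray] = []
    n_skipped = 0
    for g in genes:
        vec = track.data.get(g.chrom)
        if vec is None:
            n_skipped += 1
            continue
        size = len(vec)
        row = np.full(span, np.nan)
        if g.strand == "+":
            a, b = g.tss + lo, g.tss + hi
            src_lo, src_hi = max(a, 0), min(b, size)
            if src_lo < src_hi:
                row[src_lo - a : src_hi - a] = vec[src_lo:src_hi]
        else:
            # offsets run 5'->3' along the gene: genomic position tss - offset
            a, b = g.tss - hi + 1, g.tss - lo + 1
            src_lo, src_hi = max(a, 0), min(b, size)
            if src_lo < src_hi:
                rev = vec[src_lo:src_hi][::-1]
                dst_lo = (g.tss - lo) - (src_hi - 1)
                row[dst_lo : dst_lo + len(rev)] = rev
        gene_ids.append(g.gene_id)
        rows.append(row)
    if n_skipped:
        logger.warning("tss_matrix: skipped %d genes on unknown chromosomes", n_skipped)
    values = np.vstack(rows) if rows else np.empty((0, span))
    if bin_size > 1:
        n_bins = int(np.ceil(span / bin_size))
        binned = np.full((values.shape[0], n_bins), np.nan)
        with np.errstate(invalid="ignore"):
            for b_idx in range(n_bins):
                seg = values[:, b_idx * bin_size : (b_idx + 1) * bin_size]
                binned[:, b_idx] = np.nanmean(seg, axis=1)
        values = binned
    return TssMatrix(gene_ids, values, window=window, bin_size=bin_size, units=track.units)


def metagene(matrix: TssMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Columnwise mean profile over genes, plus per-column gene counts.

    Counts fall below the number of genes wherever chromosome-end clipping
    produced NaNs.
    """
    if matrix.values.shape[0] == 0:
        raise ValueError("metagene of an empty matrix")
    counts = np.sum(~np.isnan(matrix.values), axis=0)
    with np.errstate(invalid="ignore"):
        profile = np.nanmean(matrix.values, axis=0)
    return profile, counts
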