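"""Per-gene window statistics: filters, ratio statistics, Epi-ID scores.

Quantification follows the TSS-window scheme: per-gene means over the full
-500..+1000 bp window and over the first 500 bp of the ORF.  Genes with no
coverage anywhere in the window, or an average first-500-bp coverage below a
threshold (default 0.5), are filtered out of any required mark/genotype
matrix.  Activity and change statistics are pseudocounted ratios:

* ``wt_me3_me1_ratio`` — me3/me1 in the first 500 bp of WT, the per-gene
  Dot1-activity readout used for sorting heatmaps;
* ``log2_change`` — log2 of the H3-normalized me3 statistic in mutant over
  wild type, the ranking key for the group partition and enrichment.

The Epi-ID score is the barcode-reporter analogue: log2 of the mutant/WT
me3-me1 ratio, optionally growth-corrected by taking residuals of a linear
regression on a growth covariate across the mutant collection.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .coverage_ops import TssMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "window_mean",
    "filter_genes",
    "ratio_stat",
    "log2_change",
    "epiid_score",
    "build_gene_metrics",
    "DEFAULT_PSEUDOCOUNT",
    "DEFAULT_FILTER_THRESHOLD",
    "FIRST_500",
]

DEFAULT_PSEUDOCOUNT = 0.1  # RPGC units, added to both ratio terms
DEFAULT_FILTER_THRESHOLD = 0.5  # minimum first-500-bp mean coverage
FIRST_500 = (0, 500)  # bp relative to TSS


def window_mean(matrix: TssMatrix, span: tuple[int, int] | None = None) -> pd.Series:
    """Per-gene mean coverage over an offset interval of a TSS matrix.

    ``span`` is a half-open TSS-relative interval; bins whose start offset
    falls inside it are averaged (NaN positions from chromosome-end clipping
    are excluded).  ``None`` means the full window.
    """
    if span is None:
        span = matrix.window
    lo, hi = span
    if lo < matrix.window[0] or hi > matrix.window[1]:
        raise ValueError(f"span {span} outside matrix window {matrix.window}")
    sel = (matrix.offsets >= lo) & (matrix.offsets < hi)
    if not sel.any():
        raise ValueError(f"span {span} selects no bins at bin_size {matrix.bin_size}")
    with np.errstate(invalid="ignore"):
        means = np.nanmean(matrix.values[:, sel], axis=1)
    return pd.Series(means, index=pd.Index(matrix.gene_ids, name="gene_id"))


def filter_genes(
    matrices: dict[str, TssMatrix],
    threshold: float = DEFAULT_FILTER_THRESHOLD,
    first_span: tuple[int, int] = FIRST_500,
    strict_per_base: bool = False,
) -> tuple[pd.Series, dict[str, int]]:
    """Coverage filter over all required mark/genotype matrices.

    A gene fails if, in *any* supplied matrix, its full-window mean coverage
    is exactly 0 or its first-500-bp mean is below ``threshold``.  With
    ``strict_per_base`` the zero-coverage clause instead fails a gene whose
    window contains any zero base.  Returns the boolean pass flags plus
    ``{"total": ..., "retained": ...}`` counts.
    """
    if not matrices:
        raise ValueError("filter_genes needs at least one matrix")
    items = list(matrices.items())
    universe = items[0][1].gene_ids
    for name, m in items[1:]:
        if m.gene_ids != universe:
            raise ValueError(f"matrix {name!r} has a mismatched gene universe")
    passing = pd.Series(True, index=pd.Index(universe, name="gene_id"))
    for name, m in items:
        full = window_mean(m)
        first = window_mean(m, first_span)
        if strict_per_base:
            has_zero = pd.Series(
                np.nanmin(m.values, axis=1) <= 0, index=passing.index
            )
        else:
            has_zero = full == 0
        passing &= ~has_zero & (first >= threshold)
    counts = {"total": len(universe), "retained": int(passing.sum())}
    logger.info("gene filter: retained %d of %d genes", counts["retained"], counts["total"])
    return passing, counts


def ratio_stat(numerator_mean, denominator_mean, pseudocount: float = DEFAULT_PSEUDOCOUNT):
    """Pseudocounted ratio (num + eps) / (den + eps); scalar or vectorized."""
    num = np.asarray(numerator_mean, dtype=float)
    den = np.asarray(denominator_mean, dtype=float)
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    if np.any(num < 0) or np.any(den < 0):
        raise ValueError("window means must be nonnegative")
    out = (num + pseudocount) / (den + pseudocount)
    return float(out) if out.ndim == 0 else out


def log2_change(stat_mut, stat_wt):
    """log2(mutant / wild-type) of a per-gene statistic; 0 means unchanged."""
    mut = np.asarray(stat_mut, dtype=float)
    wt = np.asarray(stat_wt, dtype=float)
    if np.any(mut <= 0) or np.any(wt <= 0):
        raise ValueError("statistics must be > 0 (use a pseudocount upstream)")
    out = np.log2(mut / wt)
    return float(out) if out.ndim == 0 else out


def epiid_score(
    me3_me1_mut,
    me3_me1_wt,
    growth_covariate=None,
    mode: str = "regression",
) -> pd.DataFrame:
    """Epi-ID style methylation score across a mutant collection.

    raw_score = log2((me3/me1)_mutant / (me3/me1)_WT), so 0 is the wild-type
    level.  In regression mode the corrected score is the residual of an
    ordinary least-squares fit of raw_score on the growth covariate (with
    intercept) across mutants, removing the systematic effect of growth rate
    on methylation; with fewer than 3 mutants (or no covariate) it falls back
    to the raw score with a warning.
    """
    mut = np.atleast_1d(np.asarray(me3_me1_mut, dtype=float))
    wt = np.broadcast_to(np.asarray(me3_me1_wt, dtype=float), mut.shape)
    if np.any(mut <= 0) or np.any(wt <= 0):
        raise ValueError("me3/me1 ratios must be > 0")
    raw = np.log2(mut / wt)
    if mode not in ("regression", "none"):
        raise ValueError(f"unknown mode {mode!r}")
    growth = None if growth_covariate is None else np.asarray(growth_covariate, dtype=float)
    if mode == "regression" and (growth is None or mut.size < 3):
        logger.warning("epiid_score: <3 mutants or no covariate; falling back to mode='none'")
        mode = "none"
    if mode == "regression":
        X = sm.add_constant(growth)
        corrected = sm.OLS(raw, X).fit().resid
    else:
        growth = np.full(mut.shape, np.nan) if growth is None else growth
        corrected = raw.copy()
    return pd.DataFrame(
        {"raw_score": raw, "growth_covariate": growth, "corrected_score": corrected}
    )


def build_gene_metrics(
    matrices: dict[tuple[str, str], TssMatrix],
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    filter_threshold: float = DEFAULT_FILTER_THRESHOLD,
    filter_marks: tuple[str, ...] = ("H3K79me1", "H3K79me3", "H3"),
) -> pd.DataFrame:
    """Assemble the per-gene metrics table from (mark, genotype) TSS matrices.

    Requires matrices for H3K79me1, H3K79me3 and H3 in both WT and rpd3
    genotypes (same gene universe, same units).  Emits a sensitivity warning
    when the pseudocount choice is influential (>5% of genes change sign of
    their log2 change when the pseudocount is doubled).
    """
    required = [(m, g) for m in ("H3K79me1", "H3K79me3", "H3") for g in ("WT", "rpd3")]
    missing = [k for k in required if k not in matrices]
    if missing:
        raise ValueError(f"missing matrices for {missing}")
    filt_keys = [(m, g) for (m, g) in matrices if m in filter_marks]
    passing, counts = filter_genes(
        {f"{m}:{g}": matrices[(m, g)] for m, g in filt_keys}, threshold=filter_threshold
    )
    first = {k: window_mean(matrices[k], FIRST_500) for k in required}
    df = pd.DataFrame(index=passing.index)
    df["filter_pass"] = passing
    for (mark, geno), s in first.items():
        df[f"{mark.lower()}_{geno.lower()}_mean"] = s
    df["wt_me3_me1_ratio"] = ratio_stat(
        first[("H3K79me3", "WT")], first[("H3K79me1", "WT")], pseudocount
    )
    me3_h3_wt = ratio_stat(first[("H3K79me3", "WT")], first[("H3", "WT")], pseudocount)
    me3_h3_mut = ratio_stat(first[("H3K79me3", "rpd3")], first[("H3", "rpd3")], pseudocount)
    df["me3_h3_wt"] = me3_h3_wt
    df["me3_h3_mut"] = me3_h3_mut
    df["log2_change"] = log2_change(me3_h3_mut, me3_h3_wt)
    alt = log2_change(
        ratio_stat(first[("H3K79me3", "rpd3")], first[("H3", "rpd3")], 2 * pseudocount),
        ratio_stat(first[("H3K79me3", "WT")], first[("H3", "WT")], 2 * pseudocount),
    )
    flipped = np.mean(np.sign(alt) != np.sign(df["log2_change"]))
    if flipped > 0.05:
        logger.warning(
            "pseudocount sensitivity: %.1f%% of genes change log2-change sign "
            "when the pseudocount is doubled",
            100 * flipped,
        )
    df.attrs["filter_counts"] = counts
    return df
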