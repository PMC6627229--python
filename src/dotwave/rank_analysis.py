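"""Ranking, group partition, LOESS rank smoothing, and rank-set enrichment.

Filter-passing genes are ranked (descending) on the log2 change of the
H3-normalized H3K79me3 statistic in the mutant, then partitioned into four
groups by log2 cutpoints — group I holds the genes whose methylation drops
most in the mutant (in practice subtelomeric genes), group IV those where it
rises most (Rpd3 targets).  Per-gene covariates are smoothed along the rank
axis by locally weighted regression (tricube-weighted local linear fits) with
a seeded-bootstrap confidence band.

Enrichment of an annotated gene set at either extreme of the ranking is the
barcode-plot statistic made inferential: the rank-sum of the set, with an
exact null (every equally-sized subset of ranks equally likely) when the
universe is small enough to enumerate, and a normal (Mann-Whitney style)
approximation with continuity correction otherwise.  Over-representation of
an annotation among a candidate set uses the hypergeometric upper tail.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.nonparametric.smoothers_lowess import lowess

from .coverage_ops import GeneAnnotation

__all__ = [
    "EnrichmentResult",
    "SmoothedRankCurve",
    "rank_genes",
    "assign_groups",
    "loess_rank_smooth",
    "barcode_enrichment",
    "annotate_subtelomeric",
    "overrepresentation",
    "GROUP_CUTPOINTS",
    "SUBTELOMERE_BP",
]

GROUP_CUTPOINTS = (-0.5, 0.5, 1.5)  # log2 units separating groups I|II|III|IV
SUBTELOMERE_BP = 30_000  # bp from a chromosome end
EXACT_ENUMERATION_LIMIT = 100_000  # max C(n, k) for the exact rank-sum null


def rank_genes(table: pd.DataFrame, key: str = "log2_change") -> pd.DataFrame:
    """Rank filter-passing genes descending by ``key``; ties broken by gene id.

    Returns a copy restricted to passing genes, sorted, with a 1-based
    ``rank`` column (rank 1 = largest key value).
    """
    if key not in table.columns:
        raise ValueError(f"missing ranking key column {key!r}")
    df = table[table["filter_pass"]].copy() if "filter_pass" in table.columns else table.copy()
    if "gene_id" in df.columns:
        df = df.sort_values([key, "gene_id"], ascending=[False, True], kind="mergesort")
    else:  # gene ids live in the index; stable sort keeps id order within ties
        df = df.sort_index(kind="mergesort").sort_values(key, ascending=False, kind="mergesort")
    df["rank"] = np.arange(1, len(df) + 1)
    return df


def assign_groups(
    ranked: pd.DataFrame,
    cutpoints: tuple[float, float, float] = GROUP_CUTPOINTS,
    key: str = "log2_change",
) -> pd.DataFrame:
    """Partition genes into groups I-IV by log2-change cutpoints.

    I: change <= c1 (strong decrease); II: c1 < change < c2 (unchanged);
    III: c2 <= change < c3; IV: change >= c3 (strong increase).
    """
    c1, c2, c3 = cutpoints
    if not (c1 < c2 < c3):
        raise ValueError(f"cutpoints must be strictly increasing, got {cutpoints}")
    x = ranked[key].to_numpy()
    group = np.select(
        [x <= c1, x < c2, x < c3], ["I", "II", "III"], default="IV"
    )
    out = ranked.copy()
    out["group"] = group
    return out


@dataclass
class SmoothedRankCurve:
    """LOESS fit of a per-gene value along the rank axis with a 95% band."""

    rank_grid: np.ndarray
    fitted: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    span: float
    n_boot: int

    def __post_init__(self) -> None:
        if np.any(self.lower > self.fitted) or np.any(self.fitted > self.upper):
            raise ValueError("band must bracket the fitted curve pointwise")


def loess_rank_smooth(
    values: Sequence[float],
    ranks: Sequence[float] | None = None,
    span: float = 0.3,
    ci: float = 0.95,
    n_boot: int = 200,
    seed: int = 0,
) -> SmoothedRankCurve:
    """Locally weighted regression of a covariate over gene rank.

    Local linear fits with tricube weights over a moving window covering a
    ``span`` fraction of the genes; the confidence band comes from ``n_boot``
    seeded bootstrap resamples of genes (percentile interval, clipped so it
    brackets the point fit).
    """
    y = np.asarray(values, dtype=float)
    if y.size < 10:
        raise ValueError("need at least 10 points to smooth")
    x = np.arange(1, y.size + 1, dtype=float) if ranks is None else np.asarray(ranks, dtype=float)
    if x.shape != y.shape:
        raise ValueError("ranks and values must align")
    if not (0 < span <= 1) or span * y.size < 4:
        raise ValueError(f"span {span} too small for {y.size} points")
    fitted = lowess(y, x, frac=span, return_sorted=False)
    rng = np.random.default_rng(seed)
    boots = np.empty((n_boot, y.size))
    for b in range(n_boot):
        idx = rng.integers(0, y.size, size=y.size)
        boots[b] = lowess(y[idx], x[idx], frac=span, xvals=x)
    alpha = 1.0 - ci
    lower = np.nanquantile(boots, alpha / 2, axis=0)
    upper = np.nanquantile(boots, 1 - alpha / 2, axis=0)
    return SmoothedRankCurve(
        rank_grid=x,
        fitted=fitted,
        lower=np.minimum(lower, fitted),
        upper=np.maximum(upper, fitted),
        span=span,
        n_boot=n_boot,
    )


@dataclass(frozen=True)
class EnrichmentResult:
    """Rank-set enrichment outcome (barcode-plot statistic with a p-value)."""

    set_name: str
    set_size: int
    universe_size: int
    rank_positions: tuple[int, ...]
    statistic: float
    p_value: float
    direction: str
    method: str

    def __post_init__(self) -> None:
        if not (0 < self.p_value <= 1):
            raise ValueError(f"p-value out of range: {self.p_value}")
        pos = self.rank_positions
        if len(set(pos)) != len(pos) or any(p < 1 or p > self.universe_size for p in pos):
            raise ValueError("rank positions must be distinct ranks in 1..universe_size")


def _exact_ranksum_cdf_counts(n: int, k: int, s_max: int) -> float:
    """Number of k-subsets of {1..n} with rank-sum <= s_max (exact DP count)."""
    # ways[j][s]: subsets of size j with sum s, built by scanning ranks 1..n
    max_sum = s_max
    ways = np.zeros((k + 1, max_sum + 1))
    ways[0, 0] = 1.0
    for r in range(1, n + 1):
        hi = min(k, r)
        for j in range(hi, 0, -1):
            if r <= max_sum:
                ways[j, r:] += ways[j - 1, : max_sum + 1 - r]
    return float(ways[k].sum())


def _ranksum_pvalue(n: int, k: int, stat: int, direction: str) -> tuple[float, str]:
    total = math.comb(n, k)
    s_min = k * (k + 1) // 2
    s_max = k * (2 * n - k + 1) // 2
    if total <= EXACT_ENUMERATION_LIMIT:
        method = "exact"

        def p_le(s: int) -> float:
            if s < s_min:
                return 0.0
            return _exact_ranksum_cdf_counts(n, k, s) / total

        p_top = p_le(stat)
        p_bottom = 1.0 - p_le(stat - 1)
    else:
        method = "normal"
        mean = k * (n + 1) / 2.0
        var = k * (n - k) * (n + 1) / 12.0
        sd = math.sqrt(var)
        from scipy.stats import norm

        p_top = float(norm.cdf((stat + 0.5 - mean) / sd))
        p_bottom = float(norm.sf((stat - 0.5 - mean) / sd))
    if direction == "top":
        p = p_top
    elif direction == "bottom":
        p = p_bottom
    elif direction == "two-sided":
        p = min(1.0, 2.0 * min(p_top, p_bottom))
    else:
        raise ValueError(f"direction must be top, bottom or two-sided, got {direction!r}")
    return max(p, np.finfo(float).tiny), method


def barcode_enrichment(
    ranked: pd.DataFrame,
    gene_set: Iterable[str],
    direction: str = "top",
    set_name: str = "gene_set",
) -> EnrichmentResult:
    """Test whether a gene set concentrates at one extreme of the ranking.

    Statistic: the rank-sum of the set's members.  Null: every size-k subset
    of the n ranks is equally likely.  direction="top" asks whether the set
    sits at small ranks (strong increase), "bottom" at large ranks.  The null
    tail is computed exactly (dynamic-programming enumeration over subsets)
    when C(n, k) <= 1e5, otherwise by a Mann-Whitney normal approximation
    with continuity correction.
    """
    if "rank" not in ranked.columns:
        raise ValueError("table must carry a 'rank' column (see rank_genes)")
    ids = ranked["gene_id"] if "gene_id" in ranked.columns else ranked.index.to_series()
    rank_by_id = pd.Series(ranked["rank"].to_numpy(), index=ids.to_numpy())
    members = [g for g in set(gene_set) if g in rank_by_id.index]
    if not members:
        raise ValueError(f"gene set {set_name!r} has empty intersection with the universe")
    positions = tuple(sorted(int(rank_by_id[g]) for g in members))
    stat = int(sum(positions))
    n = len(ranked)
    p, method = _ranksum_pvalue(n, len(positions), stat, direction)
    return EnrichmentResult(
        set_name=set_name,
        set_size=len(positions),
        universe_size=n,
        rank_positions=positions,
        statistic=float(stat),
        p_value=p,
        direction=direction,
        method=method,
    )


def annotate_subtelomeric(
    genes: Iterable[GeneAnnotation],
    chrom_sizes: dict[str, int],
    threshold: int = SUBTELOMERE_BP,
) -> pd.DataFrame:
    """Distance of each gene to the nearer chromosome end, with a < threshold flag.

    The distance is the minimum over the gene's two ends of the distance to
    the closer telomere of its chromosome.
    """
    rows = []
    for g in genes:
        size = chrom_sizes.get(g.chrom)
        if size is None:
            raise ValueError(f"{g.gene_id}: unknown chromosome {g.chrom}")
        if g.end > size:
            raise ValueError(f"{g.gene_id}: gene extends past chromosome end")
        dist = min(g.start, size - g.end)
        rows.append((g.gene_id, dist, dist < threshold))
    return pd.DataFrame(
        rows, columns=["gene_id", "telomere_distance", "is_subtelomeric"]
    ).set_index("gene_id")


def overrepresentation(
    candidates: Iterable[str], annotation: Iterable[str], universe: Iterable[str]
) -> tuple[float, float]:
    """Fold over-representation of an annotation among candidates, with a
    hypergeometric upper-tail p-value P(X >= k)."""
    uni = set(universe)
    cand = set(candidates)
    annot = set(annotation)
    if not cand <= uni or not annot <= uni:
        raise ValueError("candidates and annotation must be subsets of the universe")
    if not cand or not annot:
        raise ValueError("candidates and annotation must be nonempty")
    N, K, n = len(uni), len(annot), len(cand)
    k = len(cand & annot)
    fold = (k / n) / (K / N)
    p = float(hypergeom.sf(k - 1, N, K, n))
    return fold, min(max(p, np.finfo(float).tiny), 1.0)
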