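"""Distributive Dot1 kinetics: methylation dose -> H3K79 state distribution.

Dot1 is a distributive (non-processive) methyltransferase: each enzyme
encounter adds at most one methyl group, so a nucleosome's H3K79 state after
exposure to a methylation "dose" lambda (the expected number of productive
methylation events per H3K79 site) is the count of a Poisson process truncated
at the terminal state me3::

    f_k = exp(-lambda) * lambda**k / k!   for k in {0, 1, 2}
    f_3 = 1 - f_0 - f_1 - f_2

As lambda rises the state abundances sweep through successive "waves": me1
peaks at lambda = 1, me2 at lambda = 2, and me3 accumulates monotonically
while me0 decays.  The me3/me1 ratio is strictly increasing in lambda and is
therefore usable as a scalar readout of Dot1 activity.

This module owns the forward model, its inverse (dose estimation from observed
state fractions), the activity-ratio statistic, and bookkeeping for bulk
(mass-spec style) state-fraction tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

__all__ = [
    "MethylationStateDistribution",
    "state_distribution",
    "fit_dose",
    "activity_ratio",
    "wave_profile",
    "bulk_fraction_table",
    "simulate_sequential_methylation",
    "read_fraction_table",
    "write_fraction_table",
]

N_STATES = 4
SIMPLEX_TOL = 1e-3  # tolerance on sum(fractions) == 1 for user-supplied input


@dataclass(frozen=True)
class MethylationStateDistribution:
    """H3K79 me0..me3 state fractions at a given methylation dose.

    Attributes
    ----------
    lambda_dose
        Expected number of methylation events per H3K79 site (dimensionless).
        ``nan`` when the distribution was built from data rather than a dose.
    fractions
        Length-4 array ``(f0, f1, f2, f3)``; nonnegative, sums to 1.
    """

    lambda_dose: float
    fractions: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        f = np.asarray(self.fractions, dtype=float)
        if f.shape != (N_STATES,):
            raise ValueError(f"fractions must be a 4-vector, got shape {f.shape}")
        if np.any(f < -SIMPLEX_TOL) or not np.all(np.isfinite(f)):
            raise ValueError(f"fractions must be finite and nonnegative: {f}")
        if abs(f.sum() - 1.0) > SIMPLEX_TOL:
            raise ValueError(f"fractions must sum to 1, got {f.sum():.6g}")
        object.__setattr__(self, "fractions", np.clip(f, 0.0, None))

    @property
    def f0(self) -> float:
        return float(self.fractions[0])

    @property
    def f1(self) -> float:
        return float(self.fractions[1])

    @property
    def f2(self) -> float:
        return float(self.fractions[2])

    @property
    def f3(self) -> float:
        return float(self.fractions[3])


def _check_dose(lambda_dose: float) -> float:
    lam = float(lambda_dose)
    if not math.isfinite(lam) or lam < 0:
        raise ValueError(f"methylation dose must be finite and >= 0, got {lambda_dose!r}")
    return lam


def state_fractions(lambda_dose) -> np.ndarray:
    """Vectorized truncated-Poisson state fractions.

    Accepts a scalar or array of doses; returns an array with a trailing axis
    of length 4 holding ``(f0, f1, f2, f3)``.
    """
    lam = np.asarray(lambda_dose, dtype=float)
    if np.any(~np.isfinite(lam)) or np.any(lam < 0):
        raise ValueError("methylation dose must be finite and >= 0")
    e = np.exp(-lam)
    f0 = e
    f1 = e * lam
    f2 = e * lam**2 / 2.0
    f3 = 1.0 - f0 - f1 - f2
    return np.stack([f0, f1, f2, np.clip(f3, 0.0, None)], axis=-1)


def state_distribution(lambda_dose: float) -> MethylationStateDistribution:
    """Forward model: dose -> me0..me3 distribution (Poisson truncated at me3)."""
    lam = _check_dose(lambda_dose)
    return MethylationStateDistribution(lam, state_fractions(lam))


def _validate_simplex(fractions) -> np.ndarray:
    f = np.asarray(fractions, dtype=float)
    if f.shape != (N_STATES,):
        raise ValueError(f"expected a 4-vector of fractions, got shape {f.shape}")
    if np.any(f < 0) or not np.all(np.isfinite(f)):
        raise ValueError(f"fractions must be finite and nonnegative: {f}")
    if abs(f.sum() - 1.0) > SIMPLEX_TOL:
        raise ValueError(f"fractions must sum to 1 (tolerance {SIMPLEX_TOL}), got {f.sum():.6g}")
    return f


class DoseAboveIdentifiableRange(ValueError):
    """Raised when f0 = 0: every dose above the saturation point fits equally well."""


def fit_dose(fractions, method: str = "f0") -> float:
    """Invert the state model: observed fractions -> dose estimate.

    method="f0" uses the exact inversion ``lambda = -ln(f0)`` (f0 is untouched
    by the me3 truncation, so this is exact under the model).  method="lsq"
    minimizes the squared distance between observed and model fractions over a
    bounded dose range, which is more robust when the input is noisy.
    """
    f = _validate_simplex(fractions)
    if method == "f0":
        if f[0] <= 0:
            raise DoseAboveIdentifiableRange(
                "f0 = 0: dose above identifiable range for f0 inversion"
            )
        return float(-math.log(f[0]))
    if method == "lsq":
        res = minimize_scalar(
            lambda lam: float(np.sum((state_fractions(lam) - f) ** 2)),
            bounds=(0.0, 20.0),
            method="bounded",
            options={"xatol": 1e-12},
        )
        return float(res.x)
    raise ValueError(f"unknown fit method: {method!r}")


def activity_ratio(fractions) -> float:
    """me3/me1 ratio, the scalar readout of Dot1 activity.

    Returns ``inf`` when f1 = 0 with f3 > 0 (fully saturated) and ``nan``
    when f1 = f3 = 0 (unmethylated: the ratio is undefined and the caller
    decides how to treat it).
    """
    f = _validate_simplex(fractions)
    if f[1] == 0:
        return math.inf if f[3] > 0 else math.nan
    return float(f[3] / f[1])


def wave_profile(lambda_grid) -> np.ndarray:
    """State fractions along a dose grid: one row of (f0..f3) per grid point.

    The grid must be sorted ascending; over a grid spanning [0, 5] the f1 wave
    peaks at lambda ~ 1 and the f2 wave at lambda ~ 2, while f3 only rises.
    """
    grid = np.asarray(lambda_grid, dtype=float)
    if grid.ndim != 1 or grid.size == 0:
        raise ValueError("lambda grid must be a nonempty 1-D array")
    if np.any(np.diff(grid) < 0):
        raise ValueError("lambda grid must be sorted ascending")
    return state_fractions(grid)


def bulk_fraction_table(raw_abundances) -> np.ndarray:
    """Rescale per-sample raw state abundances to percentages summing to 100.

    Mimics the bookkeeping applied to bulk mass-spec measurements of H3K79
    methylation, where only relative state abundances are meaningful.
    Accepts a single row or a 2-D (samples x 4 states) array.
    """
    raw = np.atleast_2d(np.asarray(raw_abundances, dtype=float))
    if raw.shape[1] != N_STATES:
        raise ValueError(f"expected {N_STATES} state columns, got {raw.shape[1]}")
    if np.any(raw < 0) or not np.all(np.isfinite(raw)):
        raise ValueError("abundances must be finite and nonnegative")
    totals = raw.sum(axis=1)
    if np.any(totals <= 0):
        bad = np.flatnonzero(totals <= 0)
        raise ValueError(f"all-zero abundance row(s) at index {bad.tolist()}")
    out = 100.0 * raw / totals[:, None]
    return out if np.asarray(raw_abundances).ndim == 2 else out[0]


def simulate_sequential_methylation(
    lambda_dose: float, n_sites: int, rng: np.random.Generator
) -> np.ndarray:
    """Monte-Carlo oracle: simulate distributive methylation event-by-event.

    Each of ``n_sites`` H3K79 sites receives a Poisson(lambda) number of
    enzyme encounters; each encounter advances the site one state, capped at
    me3.  Returns observed fractions ``(f0..f3)``.  Kept deliberately naive —
    it is the independent check on the closed form, not a fast path.
    """
    lam = _check_dose(lambda_dose)
    events = rng.poisson(lam, size=int(n_sites))
    states = np.minimum(events, N_STATES - 1)
    counts = np.bincount(states, minlength=N_STATES)
    return counts / counts.sum()


# ---------------------------------------------------------------------------
# Fraction-table TSV interface
# ---------------------------------------------------------------------------

_FRACTION_COLUMNS = ["sample_id", "me0", "me1", "me2", "me3"]


def read_fraction_table(path) -> pd.DataFrame:
    """Read a per-sample state-fraction TSV (columns sample_id, me0..me3).

    Rows summing near 100 are taken as percents and rescaled to proportions;
    rows summing near 1 are taken as proportions already.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in _FRACTION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"fraction table missing columns: {missing}")
    vals = df[["me0", "me1", "me2", "me3"]].to_numpy(dtype=float)
    sums = vals.sum(axis=1)
    percent = np.abs(sums - 100.0) < np.abs(sums - 1.0)
    vals[percent] /= 100.0
    out = df[["sample_id"]].copy()
    out[["me0", "me1", "me2", "me3"]] = vals
    return out


def write_fraction_table(df: pd.DataFrame, path, percent: bool = False) -> None:
    """Write a per-sample state-fraction table as TSV (proportions by default)."""
    out = df[_FRACTION_COLUMNS].copy()
    if percent:
        out[["me0", "me1", "me2", "me3"]] *= 100.0
    out.to_csv(path, sep="\t", index=False)
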