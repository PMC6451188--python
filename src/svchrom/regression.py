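"""Bin-level regression of NAHR breakpoint density and the closed-form
estimator of the meiotic fraction of NAHR deletions.

The regression relates the fraction of NAHR breakpoints per compartment
bin (Y) to the fractions of simulated homologous breakpoints (X1),
spontaneous DSB peaks (X2) and meiotic DSB peaks (X3), singly and jointly,
by ordinary least squares.

The estimator models the aggregated meiotic-DSB signal at NAHR breakpoints
as a two-component mixture: a fraction x of NAHR deletions sits at meiotic
DSBs and contributes full signal (attenuated by the meiotic capture
fraction f_m), while the remaining 1 - x contribute only background b
(attenuated by the spontaneous capture fraction f_s):

    f_m * x + b * (1 - x) * f_s = S_obs
    x = (S_obs - b * f_s) / (f_m - b * f_s)
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import statsmodels.api as sm

from .aggregation import AggregationProfile
from .core import SegmentationTrack

__all__ = [
    "bin_fractions",
    "RegressionFit",
    "fit_linear",
    "discordant_bins",
    "MeioticFractionEstimate",
    "meiotic_fraction",
    "meiotic_fraction_range",
    "estimate_from_profiles",
]

DEFAULT_S_OBS = 0.08
DEFAULT_BACKGROUND = 0.04


def bin_fractions(
    points: Sequence[tuple[str, int]], bins: SegmentationTrack
) -> np.ndarray:
    """Fraction of a point set residing in each bin (track segment order).

    Points outside every bin are excluded from numerators but count in the
    denominator, so the vector sums to at most 1.
    """
    if len(points) == 0:
        raise ValueError("no points supplied")
    index: dict[tuple[str, int], int] = {}
    for k, (iv, _) in enumerate(bins.segments):
        index[(iv.chrom, iv.start)] = k
    counts = np.zeros(len(bins.segments))
    for chrom, pos in points:
        entry = bins._by_chrom.get(chrom)
        if entry is None:
            continue
        starts, ends, _ = entry
        i = int(np.searchsorted(starts, pos, side="right")) - 1
        if i >= 0 and pos < ends[i]:
            counts[index[(chrom, int(starts[i]))]] += 1
    return counts / len(points)


@dataclass
class RegressionFit:
    """OLS fit of bin fractions: coefficients, R^2, residual diagnostics."""

    intercept: float
    coefficients: dict[str, float]
    r_squared: float
    adj_r_squared: float
    residuals: np.ndarray
    residual_sd: float
    predicted: np.ndarray

    def summary(self) -> str:
        lines = [f"intercept\t{self.intercept:.6g}"]
        lines += [f"{k}\t{v:.6g}" for k, v in self.coefficients.items()]
        lines.append(f"R2\t{self.r_squared:.4f}")
        lines.append(f"adj_R2\t{self.adj_r_squared:.4f}")
        return "\n".join(lines)


def fit_linear(
    y: np.ndarray, x: np.ndarray | Mapping[str, np.ndarray]
) -> RegressionFit:
    """Ordinary least squares of Y on one or more predictors (with intercept)."""
    if isinstance(x, Mapping):
        names = list(x)
        X = np.column_stack([np.asarray(x[n], dtype=float) for n in names])
    else:
        X = np.asarray(x, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        names = [f"x{i + 1}" for i in range(X.shape[1])]
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if n <= p + 1:
        raise ValueError(f"need more observations ({n}) than parameters ({p + 1})")
    design = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(design) < design.shape[1]:
        # name the offending predictors for the caller
        bad = []
        for i in range(p):
            others = np.delete(design, i + 1, axis=1)
            if np.linalg.matrix_rank(others) == np.linalg.matrix_rank(design):
                bad.append(names[i])
        raise ValueError(f"collinear predictors: {bad or names}")
    res = sm.OLS(y, design).fit()
    resid = np.asarray(res.resid)
    return RegressionFit(
        intercept=float(res.params[0]),
        coefficients={n_: float(b) for n_, b in zip(names, res.params[1:])},
        r_squared=float(res.rsquared),
        adj_r_squared=float(res.rsquared_adj),
        residuals=resid,
        residual_sd=float(resid.std(ddof=1)),
        predicted=np.asarray(res.fittedvalues),
    )


def discordant_bins(fit: RegressionFit, k: float = 3.0) -> list[tuple[int, float]]:
    """Bins whose residual lies more than k standard deviations from the mean.

    Returns (bin index, observed - predicted); positive values are bins the
    model under-predicts.
    """
    r = fit.residuals
    if fit.residual_sd == 0:
        return [] if k > 0 else [(i, float(v)) for i, v in enumerate(r)]
    dev = np.abs(r - r.mean())
    idx = np.flatnonzero(dev > k * fit.residual_sd)
    return [(int(i), float(r[i])) for i in idx]


@dataclass
class MeioticFractionEstimate:
    """Closed-form estimate of the meiotic fraction of NAHR deletions."""

    s_obs: float
    background: float
    f_m: float
    f_s: float
    x: float
    x_range: tuple[float, float] | None = None
    warning: str | None = None


def meiotic_fraction(
    f_m: float,
    f_s: float,
    s_obs: float = DEFAULT_S_OBS,
    b: float = DEFAULT_BACKGROUND,
) -> float:
    """Evaluate x = (S_obs - b*f_s) / (f_m - b*f_s).

    ``f_m`` and ``f_s`` are the experimental capture fractions of meiotic
    and spontaneous DSB sites, each in (0, 1].  Raises when the denominator
    is non-positive; warns (without clamping) when x falls outside [0, 1].
    """
    if not (0 < f_m <= 1 and 0 < f_s <= 1):
        raise ValueError("capture fractions must lie in (0, 1]")
    denom = f_m - b * f_s
    if denom <= 0:
        raise ValueError(f"denominator f_m - b*f_s = {denom:g} is not positive")
    x = (s_obs - b * f_s) / denom
    if not 0 <= x <= 1:
        warnings.warn(f"estimated fraction x = {x:.4g} outside [0, 1]: model violated")
    return x


def meiotic_fraction_range(
    s_obs: float = DEFAULT_S_OBS,
    b: float = DEFAULT_BACKGROUND,
    f_m_bounds: tuple[float, float] = (0.5, 1.0),
    f_s_bounds: tuple[float, float] = (0.5, 1.0),
    grid: int = 101,
) -> tuple[float, float]:
    """Extrema of the estimate over a dense grid on the capture-fraction box."""
    fm = np.linspace(f_m_bounds[0], f_m_bounds[1], grid)
    fs = np.linspace(f_s_bounds[0], f_s_bounds[1], grid)
    FM, FS = np.meshgrid(fm, fs)
    denom = FM - b * FS
    if np.any(denom <= 0):
        raise ValueError("denominator non-positive somewhere on the box")
    X = (s_obs - b * FS) / denom
    return float(X.min()), float(X.max())


def estimate_from_profiles(
    nahr_profile: AggregationProfile,
    control_profiles: Sequence[AggregationProfile],
    f_m: float,
    f_s: float,
    f_bounds: tuple[float, float] | None = None,
) -> MeioticFractionEstimate:
    """Estimate x from measured aggregation profiles.

    S_obs is the NAHR profile's value at the breakpoint (mean of the two
    bins flanking offset 0); the background b is the mean breakpoint value
    of the control profiles (NHEJ, NHrepl).
    """
    s_obs = nahr_profile.value_at_zero()
    if not control_profiles:
        raise ValueError("need at least one control profile for the background")
    bvals = [p.value_at_zero() for p in control_profiles]
    b = float(np.mean(bvals))
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        x = meiotic_fraction(f_m, f_s, s_obs=s_obs, b=b)
    rng = None
    if f_bounds is not None:
        rng = meiotic_fraction_range(
            s_obs=s_obs, b=b, f_m_bounds=f_bounds, f_s_bounds=f_bounds
        )
    return MeioticFractionEstimate(
        s_obs=s_obs,
        background=b,
        f_m=f_m,
        f_s=f_s,
        x=x,
        x_range=rng,
        warning=str(caught[0].message) if caught else None,
    )
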