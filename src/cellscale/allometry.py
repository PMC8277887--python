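"""Standardized major axis (SMA) regression for allometric scaling.

Allometries are power laws ``Y = Y0 * M**b`` that become straight lines on
log10-log10 axes.  Because both traits carry sampling error and neither is
a natural predictor, the line is fitted by standardized major axis
regression (also called reduced major axis): the slope is
``sign(r) * sd(y) / sd(x)`` and the line passes through the centroid.  The
95% confidence interval of the slope and the one-sample slope test follow
the standard SMA constructions (Warton et al. 2006, Biol. Rev.):

* CI: ``b * (sqrt(B + 1) +/- sqrt(B))`` with
  ``B = F(0.95; 1, n-2) * (1 - r**2) / (n - 2)``;
* test of ``b = b0``: the correlation between ``y - b0*x`` (residual axis)
  and ``y + b0*x`` (fitted axis) is zero under the null, tested with the
  usual t statistic on n - 2 degrees of freedom.

The p-value attached to a fit is the test of the *correlation* against
zero, not of the slope against any reference value; the two are exposed as
distinct operations because conflating them is a classic reporting error.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SMAFit",
    "sma_fit",
    "sma_slope_test",
    "pearson_test",
    "residual_correlations",
    "sma_table",
]


@dataclass(frozen=True)
class SMAFit:
    """One SMA fit of log10(y) against log10(x)."""

    slope: float
    intercept: float
    ci_lo: float
    ci_hi: float
    r2: float
    p_corr: float  #: p-value of the Pearson correlation against 0
    residuals: np.ndarray = field(repr=False)  #: y - (intercept + slope*x)
    n: int
    x: np.ndarray = field(repr=False)
    y: np.ndarray = field(repr=False)
    species: np.ndarray | None = field(default=None, repr=False)


def _as_clean_1d(name: str, v) -> np.ndarray:
    arr = np.asarray(v, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be 1-D")
    if np.any(~np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")
    return arr


def sma_fit(x, y, species=None, ci_level: float = 0.95) -> SMAFit:
    """Fit a standardized major axis line to (x, y), both already log10.

    Requires n >= 3 and non-degenerate variance on both axes.  The slope's
    sign is the sign of the sample correlation, its magnitude the ratio of
    standard deviations, which also makes the fit symmetric:
    ``slope(y~x) = 1/slope(x~y)``.
    """
    x = _as_clean_1d("x", x)
    y = _as_clean_1d("y", y)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 points for an SMA fit")
    sx = x.std(ddof=1)
    sy = y.std(ddof=1)
    if sx == 0 or sy == 0:
        raise ValueError("zero variance on one axis; SMA slope undefined")
    r, p_corr = stats.pearsonr(x, y)
    sign = 1.0 if r >= 0 else -1.0
    slope = sign * sy / sx
    intercept = y.mean() - slope * x.mean()
    F = stats.f.ppf(ci_level, 1, n - 2)
    B = F * (1.0 - r**2) / (n - 2)
    bounds = sorted((slope * (np.sqrt(B + 1.0) + np.sqrt(B)),
                     slope * (np.sqrt(B + 1.0) - np.sqrt(B))))
    residuals = y - (intercept + slope * x)
    return SMAFit(
        slope=float(slope),
        intercept=float(intercept),
        ci_lo=float(bounds[0]),
        ci_hi=float(bounds[1]),
        r2=float(r**2),
        p_corr=float(p_corr),
        residuals=residuals,
        n=n,
        x=x,
        y=y,
        species=None if species is None else np.asarray(species),
    )


def sma_slope_test(fit: SMAFit, b0: float) -> float:
    """Two-sided p-value of the test that the SMA slope equals ``b0``.

    Under the null the residual axis ``y - b0*x`` and the fitted axis
    ``y + b0*x`` are uncorrelated; their sample correlation is tested with
    a t statistic on n - 2 degrees of freedom.  ``b0 = 0`` is rejected as
    input (a zero SMA slope is undefined).
    """
    if b0 == 0:
        raise ValueError("slope test against b0 = 0 is undefined for SMA")
    u = fit.y - b0 * fit.x
    v = fit.y + b0 * fit.x
    su = u.std(ddof=1)
    sv = v.std(ddof=1)
    if su == 0 or sv == 0:
        # degenerate only when the data are perfectly on the line y = +/-b0 x
        return 1.0
    r = float(np.corrcoef(u, v)[0, 1])
    r = np.clip(r, -1.0, 1.0)
    df = fit.n - 2
    if abs(r) == 1.0:
        return 0.0
    t = r * np.sqrt(df / (1.0 - r**2))
    return float(2.0 * stats.t.sf(abs(t), df))


def pearson_test(u, v) -> tuple[float, float]:
    """Pearson correlation of two trait vectors with its two-sided p-value."""
    u = _as_clean_1d("u", u)
    v = _as_clean_1d("v", v)
    if u.size != v.size or u.size < 3:
        raise ValueError("need two equal-length vectors with n >= 3")
    if u.std() == 0 or v.std() == 0:
        raise ValueError("zero variance; correlation undefined")
    r, p = stats.pearsonr(u, v)
    return float(r), float(p)


def residual_correlations(
    table: pd.DataFrame, fit: SMAFit, traits: list[str]
) -> pd.DataFrame:
    """Correlate SMA residuals with named traits of the same species set.

    ``table`` must contain a ``species`` column matching the species the
    fit was computed on (same set, any order).  Returns a frame with
    columns ``trait, r, p``.  No multiple-testing adjustment is applied —
    a deliberate reporting choice, flagged in the documentation.
    """
    if fit.species is None:
        raise ValueError("fit carries no species labels; cannot align traits")
    if "species" not in table.columns:
        raise ValueError("trait table needs a 'species' column")
    if set(table["species"]) != set(fit.species):
        raise ValueError("species in trait table and SMA fit do not match")
    indexed = table.set_index("species").loc[list(fit.species)]
    rows = []
    for trait in traits:
        r, p = pearson_test(fit.residuals, indexed[trait].to_numpy(float))
        rows.append(dict(trait=trait, r=r, p=p))
    return pd.DataFrame(rows)


def sma_table(
    traits: pd.DataFrame,
    pairs: list[tuple[str, str]],
) -> tuple[pd.DataFrame, dict[tuple[str, str], SMAFit]]:
    """SMA fits for a list of (response, predictor) trait pairs.

    Traits are log10-transformed here; the input table holds raw positive
    values.  Returns the report frame (one row per pair, Table-style
    columns) and the underlying fits keyed by pair.
    """
    rows = []
    fits: dict[tuple[str, str], SMAFit] = {}
    for response, predictor in pairs:
        sub = traits[["species", response, predictor]].dropna()
        x = np.log10(sub[predictor].to_numpy(float))
        y = np.log10(sub[response].to_numpy(float))
        fit = sma_fit(x, y, species=sub["species"].to_numpy())
        fits[(response, predictor)] = fit
        rows.append(
            dict(
                response=response,
                predictor=predictor,
                slope=fit.slope,
                ci_lo=fit.ci_lo,
                ci_hi=fit.ci_hi,
                intercept=fit.intercept,
                r2=fit.r2,
                p=fit.p_corr,
                n=fit.n,
            )
        )
    return pd.DataFrame(rows), fits
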