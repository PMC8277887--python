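"""Synthetic cells, growth curves and trait tables with known ground truth.

The study organisms (large flattened, lobed desmid cells) deposit no
machine-readable raw data, so every pipeline input can be generated here
with an analytic or quadrature oracle attached:

* shape families — spheres, ellipsoids and lobed flattened discs with
  outline ``rho(theta) = r0 * (1 + eps*cos(m*theta))`` and an elliptic
  thickness profile — carrying exact volumes and closed-form or converged
  quadrature surface areas;
* logistic growth trajectories with optional serial-dilution events and
  multiplicative lognormal counting noise;
* log10-log10 trait pairs with a known SMA slope, with independent normal
  noise on the two axes whose standard deviations are in the ratio |slope|
  (the condition under which the SMA estimator is consistent).

All stochastic generators are deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd
from scipy.integrate import simpson

from .geometry import CellViews
from .growth import GrowthSeries
from .images import BinaryMask

__all__ = [
    "SyntheticCell",
    "make_sphere_cell",
    "make_ellipsoid_cell",
    "make_lobed_cell",
    "simulate_growth_series",
    "simulate_allometric_traits",
    "ellipse_perimeter",
    "spheroid_surface",
    "ellipsoid_surface",
]


@dataclass(frozen=True)
class SyntheticCell:
    """A generated cell: measured views plus ground-truth V and S."""

    descriptor: str
    views: CellViews
    oracle_V: float  #: exact volume (µm³)
    oracle_S: float  #: reference surface area (µm²)
    oracle_method: str  #: "closed form" or "quadrature"
    #: radial outline rho(theta) of the frontal view, for mask rasterization
    outline: Callable[[np.ndarray], np.ndarray] | None = None


def ellipse_perimeter(a: float, b: float) -> float:
    """Perimeter of an ellipse by Ramanujan's second approximation.

    Relative error below 1e-9 for aspect ratios up to about 5, far inside
    every tolerance used here.
    """
    h = ((a - b) / (a + b)) ** 2
    return float(np.pi * (a + b) * (1.0 + 3.0 * h / (10.0 + np.sqrt(4.0 - 3.0 * h))))


def spheroid_surface(a: float, c: float) -> float:
    """Closed-form surface of a spheroid with equatorial semi-axis ``a`` (x2)
    and polar semi-axis ``c``."""
    if a == c:
        return float(4.0 * np.pi * a**2)
    if c < a:  # oblate
        e = np.sqrt(1.0 - (c / a) ** 2)
        return float(2.0 * np.pi * a**2 * (1.0 + ((1.0 - e**2) / e) * np.arctanh(e)))
    e = np.sqrt(1.0 - (a / c) ** 2)  # prolate
    return float(2.0 * np.pi * a**2 * (1.0 + (c / (a * e)) * np.arcsin(e)))


def _surface_quadrature(
    rho: Callable[[np.ndarray], np.ndarray],
    drho: Callable[[np.ndarray], np.ndarray],
    half_T: float,
    n_theta: int,
    n_phi: int,
) -> float:
    """Surface of the solid with cross-sections ``rho(theta) * cos(phi)``
    at height ``half_T * sin(phi)`` (elliptic thickness profile)."""
    th = np.linspace(0.0, 2.0 * np.pi, n_theta)
    ph = np.linspace(-np.pi / 2.0, np.pi / 2.0, n_phi)
    TH, PH = np.meshgrid(th, ph, indexing="ij")
    R = rho(TH)
    dR = drho(TH)
    g = np.cos(PH)
    a1 = g * (dR * np.cos(TH) - R * np.sin(TH))
    a2 = g * (dR * np.sin(TH) + R * np.cos(TH))
    b1 = -np.sin(PH) * R * np.cos(TH)
    b2 = -np.sin(PH) * R * np.sin(TH)
    b3 = half_T * np.cos(PH)
    cross = np.sqrt((a2 * b3) ** 2 + (a1 * b3) ** 2 + (a1 * b2 - a2 * b1) ** 2)
    return float(simpson(simpson(cross, x=ph, axis=1), x=th))


def _converged_surface(rho, drho, half_T, rtol: float = 1e-4) -> float:
    """Doubling-resolution quadrature with a convergence check."""
    n_theta, n_phi = 361, 181
    prev = _surface_quadrature(rho, drho, half_T, n_theta, n_phi)
    for _ in range(4):
        n_theta = 2 * (n_theta - 1) + 1
        n_phi = 2 * (n_phi - 1) + 1
        cur = _surface_quadrature(rho, drho, half_T, n_theta, n_phi)
        if abs(cur - prev) <= rtol * abs(cur):
            return cur
        prev = cur
    raise RuntimeError("surface quadrature did not converge")


def ellipsoid_surface(a: float, b: float, c: float) -> float:
    """Surface of a general ellipsoid: closed form for spheroids, converged
    quadrature otherwise (semi-axes ``a >= b >= c``)."""
    if a == b:
        return spheroid_surface(a, c)
    if b == c:
        return spheroid_surface(b, a)
    th = np.linspace(0.0, np.pi, 1441)
    ph = np.linspace(0.0, 2.0 * np.pi, 1441)
    TH, PH = np.meshgrid(th, ph, indexing="ij")
    st, ct = np.sin(TH), np.cos(TH)
    sp, cp = np.sin(PH), np.cos(PH)
    integrand = st * np.sqrt(
        (b * c * st * cp) ** 2 + (a * c * st * sp) ** 2 + (a * b * ct) ** 2
    )
    return float(simpson(simpson(integrand, x=ph, axis=1), x=th))


def _elliptic_widths(W: float, n: int) -> np.ndarray:
    """Width profile of an elliptic thickness section at n+1 stations."""
    u = np.linspace(-1.0, 1.0, n + 1)
    return W * np.sqrt(np.clip(1.0 - u**2, 0.0, None))


def make_sphere_cell(r: float, n: int = 1000) -> SyntheticCell:
    """A spherical cell of radius ``r`` with exact closed-form oracles."""
    if r <= 0:
        raise ValueError("radius must be positive")
    if n < 2:
        raise ValueError("need at least 2 slabs")
    views = CellViews(
        A_f=np.pi * r**2,
        P_f=2.0 * np.pi * r,
        L=2.0 * r,
        W=2.0 * r,
        T=2.0 * r,
        widths=_elliptic_widths(2.0 * r, n),
    )
    return SyntheticCell(
        descriptor=f"sphere(r={r})",
        views=views,
        oracle_V=4.0 * np.pi * r**3 / 3.0,
        oracle_S=4.0 * np.pi * r**2,
        oracle_method="closed form",
        outline=lambda theta, r=r: np.full_like(np.asarray(theta, float), r),
    )


def make_ellipsoid_cell(a: float, b: float, c: float, n: int = 1000) -> SyntheticCell:
    """An ellipsoidal cell with semi-axes ``a >= b >= c``.

    The frontal view is the (a, b) ellipse; the width profile across the
    thickness ``2c`` is elliptic.  Volume is exact; the surface oracle is
    the closed spheroid form when two axes coincide, otherwise converged
    quadrature over the parametrized ellipsoid.
    """
    if not (a >= b >= c > 0):
        raise ValueError("semi-axes must satisfy a >= b >= c > 0")
    if a == b == c:
        return make_sphere_cell(a, n)
    views = CellViews(
        A_f=np.pi * a * b,
        P_f=ellipse_perimeter(a, b),
        L=2.0 * a,
        W=2.0 * b,
        T=2.0 * c,
        widths=_elliptic_widths(2.0 * b, n),
    )
    method = "closed form" if (a == b or b == c) else "quadrature"
    return SyntheticCell(
        descriptor=f"ellipsoid(a={a},b={b},c={c})",
        views=views,
        oracle_V=4.0 * np.pi * a * b * c / 3.0,
        oracle_S=ellipsoid_surface(a, b, c),
        oracle_method=method,
        outline=lambda theta, a=a, b=b: a * b
        / np.sqrt((b * np.cos(theta)) ** 2 + (a * np.sin(theta)) ** 2),
    )


def make_lobed_cell(
    r0: float, m: int, eps: float, flat: float, n: int = 1000
) -> SyntheticCell:
    """A lobed flattened cell, the synthetic stand-in for desmid morphology.

    The frontal outline is ``rho(theta) = r0 * (1 + eps*cos(m*theta))``
    (``m`` even lobes, depth ``eps < 0.5`` to avoid self-intersection) and
    the thickness profile is an ellipse with thickness-to-width ratio
    ``flat``.  Frontal area has the closed form ``pi*r0**2*(1+eps**2/2)``;
    the perimeter is a converged line integral; volume is exactly
    ``(2/3)*A_f*T``; the surface oracle is converged 2-D quadrature.
    """
    if r0 <= 0:
        raise ValueError("r0 must be positive")
    if not (0.0 <= eps < 0.5):
        raise ValueError("lobe depth eps must lie in [0, 0.5)")
    if m < 2 or m % 2:
        raise ValueError("lobe count m must be an even integer >= 2")
    if not (0.0 < flat <= 1.0):
        raise ValueError("thickness ratio flat must lie in (0, 1]")
    if eps == 0.0:
        if flat == 1.0:
            return make_sphere_cell(r0, n)
        cell = make_ellipsoid_cell(r0, r0, flat * r0, n)
        return SyntheticCell(
            descriptor=f"lobed(r0={r0},m={m},eps=0,flat={flat})",
            views=cell.views,
            oracle_V=cell.oracle_V,
            oracle_S=cell.oracle_S,
            oracle_method=cell.oracle_method,
            outline=cell.outline,
        )

    def rho(theta):
        return r0 * (1.0 + eps * np.cos(m * np.asarray(theta, float)))

    def drho(theta):
        return -r0 * eps * m * np.sin(m * np.asarray(theta, float))

    th = np.linspace(0.0, 2.0 * np.pi, 8 * 2048 + 1)
    A_f = np.pi * r0**2 * (1.0 + eps**2 / 2.0)
    P_f = float(simpson(np.sqrt(rho(th) ** 2 + drho(th) ** 2), x=th))
    W = 2.0 * r0 * (1.0 + eps)  # even m puts lobes on both ends of each axis
    T = flat * W
    views = CellViews(
        A_f=A_f, P_f=P_f, L=W, W=W, T=T, widths=_elliptic_widths(W, n)
    )
    S = _converged_surface(rho, drho, T / 2.0)
    return SyntheticCell(
        descriptor=f"lobed(r0={r0},m={m},eps={eps},flat={flat})",
        views=views,
        oracle_V=(2.0 / 3.0) * A_f * T,
        oracle_S=S,
        oracle_method="quadrature",
        outline=rho,
    )


def rasterize_outline(
    outline: Callable[[np.ndarray], np.ndarray],
    max_radius: float,
    pixel_size: float,
    squash: float = 1.0,
) -> BinaryMask:
    """Rasterize a radial outline ``rho(theta)`` into a binary mask.

    ``squash`` compresses the second image axis (used to draw apical views
    of flattened cells from the same outline).  Pixel centers inside the
    outline are foreground.
    """
    half = int(np.ceil(max_radius / pixel_size)) + 2
    coords = (np.arange(2 * half + 1) - half) * pixel_size
    X, Y = np.meshgrid(coords, coords, indexing="ij")
    Yc = Y / squash
    radius = np.hypot(X, Yc)
    theta = np.arctan2(Yc, X)
    grid = radius <= outline(theta)
    return BinaryMask(grid=grid, pixel_size=pixel_size)


def simulate_growth_series(
    mu: float,
    K: float,
    N0: float,
    days: np.ndarray,
    noise_sigma: float = 0.0,
    sample_fraction: float = 0.0,
    seed: int | None = None,
    species: str = "synthetic",
    replicate: str = "r1",
    event_interval: float = 4.0,
) -> GrowthSeries:
    """Simulate logistic growth sampled on a day schedule.

    The trajectory follows ``N(t) = K / (1 + (K/N0 - 1) * exp(-mu*t))``
    piecewise; at each sampling event (every ``event_interval`` days,
    matching a serial 10 %-medium-replacement protocol) the concentration is
    multiplied by ``1 - sample_fraction`` after the observation.
    Observations carry multiplicative lognormal noise of log-SD
    ``noise_sigma``.  Deterministic for a fixed ``seed``.
    """
    if mu <= 0:
        raise ValueError("mu must be positive")
    if not K > N0 > 0:
        raise ValueError("need K > N0 > 0")
    if not 0.0 <= sample_fraction < 1.0:
        raise ValueError("sample_fraction must be in [0, 1)")
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be non-negative")
    days = np.asarray(days, dtype=float)
    if days.ndim != 1 or days.size < 4 or np.any(np.diff(days) <= 0):
        raise ValueError("days must be a strictly increasing schedule of >= 4 days")
    events = np.arange(days[0] + event_interval, days[-1] + 1e-9, event_interval)
    # piecewise logistic between dilution events
    breakpoints = np.concatenate([[days[0]], events]) if sample_fraction > 0 else np.array([days[0]])
    N_true = np.empty_like(days)
    N_start, t_start = N0, days[0]
    bp_iter = list(breakpoints[1:]) + [np.inf]
    bp_idx = 0
    for i, t in enumerate(days):
        while t > bp_iter[bp_idx] + 1e-12:
            t_bp = bp_iter[bp_idx]
            N_start = _logistic(N_start, K, mu, t_bp - t_start) * (1.0 - sample_fraction)
            t_start = t_bp
            bp_idx += 1
        N_true[i] = _logistic(N_start, K, mu, t - t_start)
    rng = np.random.default_rng(seed)
    noise = np.exp(noise_sigma * rng.standard_normal(days.size)) if noise_sigma else 1.0
    return GrowthSeries(
        species=species,
        replicate=replicate,
        times=days,
        abundances=N_true * noise,
    )


def _logistic(N0: float, K: float, mu: float, dt: float) -> float:
    return K / (1.0 + (K / N0 - 1.0) * np.exp(-mu * dt))


def simulate_allometric_traits(
    n_species: int,
    slope: float,
    intercept: float,
    x_range: tuple[float, float],
    scatter_sd: float,
    seed: int | None = None,
) -> pd.DataFrame:
    """Simulate a log10-log10 trait pair with known SMA slope.

    ``x`` is uniform over ``x_range`` (log10 units); noise is added
    independently on both axes with SDs ``scatter_sd`` on y and
    ``scatter_sd/|slope|`` on x.  The SD ratio equal to |slope| is exactly
    the error structure under which the SMA estimator is consistent, making
    parameter-recovery checks well-posed.  Returns a frame with columns
    ``species, x, y``.
    """
    if n_species < 3:
        raise ValueError("need at least 3 species")
    if scatter_sd < 0:
        raise ValueError("scatter_sd must be non-negative")
    if slope == 0:
        raise ValueError("slope must be nonzero")
    lo, hi = x_range
    if not hi > lo:
        raise ValueError("degenerate x_range")
    rng = np.random.default_rng(seed)
    x0 = rng.uniform(lo, hi, n_species)
    ex = rng.normal(0.0, scatter_sd / abs(slope), n_species) if scatter_sd else 0.0
    ey = rng.normal(0.0, scatter_sd, n_species) if scatter_sd else 0.0
    return pd.DataFrame(
        dict(
            species=[f"sp{i + 1:02d}" for i in range(n_species)],
            x=x0 + ex,
            y=intercept + slope * x0 + ey,
        )
    )
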