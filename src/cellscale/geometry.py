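"""Frustum-stack reconstruction of cell volume and surface area.

A flattened cell (the motivating organisms are large desmid green algae with
deeply lobed, plate-like cells) is modelled as a stack of thin slabs cut
parallel to the frontal plane.  The frontal view supplies the outline of the
widest cross-section (area ``A_f``, perimeter ``P_f``); the apical view
supplies the cell thickness ``T`` and a profile of slice widths across it.
Every cross-section is treated as a scaled copy of the frontal outline: at a
boundary where the apical width is ``W_j``, the linear scale factor is
``f_j = W_j / W``, so the section area is ``A_f f_j**2`` and its perimeter
``P_f f_j``.  Consecutive sections bound a frustum; summing frustum volumes
and lateral areas, plus the two flat end caps, yields the cell volume ``V``
and surface area ``S``.

The model is exact in the limit of many slabs for solids of revolution about
the thickness axis (spheres, oblate spheroids, lobed discs with an elliptic
thickness profile).  For strongly elongated frontal outlines the single
width-based slant is an approximation; see the package methods note.

Four dimensionless indices summarise shape:

* ``alpha = 4*pi*A_f / P_f**2`` — circularity of the frontal outline
  (1 for a circle, -> 0 with elongation or lobulation);
* ``beta = S / S_ellipsoid`` — degree of fractalization, the surface gained
  by lobulation relative to the equal-volume ellipsoid with the same axis
  proportions;
* ``gamma = S_ellipsoid / S_sphere`` — degree of flattening, the surface
  gained by departing from a sphere while staying smooth;
* ``delta = beta * gamma = S / S_sphere`` — overall surface gain over the
  equal-volume sphere.

The ellipsoid surface uses the Knud Thomsen approximation
``4*pi*((a^p b^p + a^p c^p + b^p c^p)/3)^(1/p)`` with ``p = 1.6075``
(worst-case error about 1.1 % over moderate axis ratios).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "THOMSEN_P",
    "DEFAULT_N_SLABS",
    "CellViews",
    "CellGeometry",
    "ShapeIndices",
    "frustum_slab",
    "stack_cell",
    "circularity",
    "thomsen_surface",
    "equal_volume_ellipsoid",
    "sphere_surface_equal_volume",
    "shape_indices",
    "cell_shape_indices",
]

#: Exponent of the Knud Thomsen ellipsoid surface approximation.
THOMSEN_P = 1.6075

#: Default number of frustum slabs used when reconstructing a cell.
DEFAULT_N_SLABS = 1000

#: Relative slack allowed before a width exceeding the maximum width W is an
#: error (frontal and apical views are measured on different cells, so small
#: inconsistencies are expected).
WIDTH_TOLERANCE = 0.01


def _require_positive(**values: float) -> None:
    for name, v in values.items():
        if not np.isfinite(v) or v <= 0:
            raise ValueError(f"{name} must be positive and finite, got {v!r}")


@dataclass(frozen=True)
class CellViews:
    """Raw geometric measurements of one cell from its two orthogonal views.

    Lengths are in µm, areas in µm².  ``widths`` holds the n+1 boundary
    widths sampled at equally spaced stations across the full thickness
    ``[0, T]``; station j sits at ``z_j = j * T / n``.
    """

    A_f: float  #: frontal area (µm²)
    P_f: float  #: frontal perimeter (µm)
    L: float  #: maximum cell length (µm)
    W: float  #: maximum cell width (µm)
    T: float  #: cell thickness (µm)
    widths: np.ndarray = field(repr=False)  #: boundary widths W_0..W_n (µm)

    def __post_init__(self) -> None:
        _require_positive(A_f=self.A_f, P_f=self.P_f, L=self.L, W=self.W, T=self.T)
        w = np.asarray(self.widths, dtype=float)
        object.__setattr__(self, "widths", w)
        if w.ndim != 1 or w.size < 3:
            raise ValueError("widths must hold at least 3 boundary values (n >= 2 slabs)")
        if np.any(~np.isfinite(w)) or np.any(w < 0):
            raise ValueError("widths must be finite and non-negative")
        if np.any(w > self.W * (1.0 + WIDTH_TOLERANCE)):
            raise ValueError(
                "a boundary width exceeds the maximum cell width W by more than "
                f"{WIDTH_TOLERANCE:.0%}"
            )
        # isoperimetric inequality: a closed outline of area A_f needs
        # perimeter >= that of the circle of equal area
        if self.P_f**2 < 4.0 * np.pi * self.A_f * (1.0 - 1e-9):
            raise ValueError("P_f**2 < 4*pi*A_f violates the isoperimetric inequality")
        if w.max() < self.W * 0.9:
            warnings.warn(
                "max(widths) is more than 10% below W; the width profile may not "
                "cover the widest section",
                stacklevel=2,
            )

    @property
    def n_slabs(self) -> int:
        """Number of frusta in the stack (one less than boundary count)."""
        return self.widths.size - 1


@dataclass(frozen=True)
class CellGeometry:
    """Reconstructed cell volume and surface with per-slab diagnostics."""

    V: float  #: total volume (µm³)
    S: float  #: total surface area (µm²)
    slab_volumes: np.ndarray = field(repr=False)  #: per-slab V_i (µm³)
    slab_laterals: np.ndarray = field(repr=False)  #: per-slab lateral area S_i (µm²)
    cap_area: float  #: flat area added at the two outermost boundaries (µm²)


@dataclass(frozen=True)
class ShapeIndices:
    """Dimensionless shape summary of one cell.

    ``alpha`` is NaN when frontal outline measurements were not supplied.
    """

    alpha: float
    beta: float
    gamma: float
    delta: float
    S_ellipsoid: float
    S_sphere: float
    k: float


def frustum_slab(
    A_lo: float,
    A_hi: float,
    P_lo: float,
    P_hi: float,
    W_lo: float,
    W_hi: float,
    t: float,
) -> tuple[float, float]:
    """Volume and lateral area of one frustum slab.

    The slab is bounded by two parallel similar cross-sections with areas
    ``A_lo``/``A_hi``, perimeters ``P_lo``/``P_hi`` and widths
    ``W_lo``/``W_hi``, a slab thickness ``t`` apart.

    Returns ``(V_i, S_i)`` with the prismatoid frustum volume
    ``V_i = t/3 * (A_lo + A_hi + sqrt(A_lo * A_hi))`` and the lateral area
    ``S_i = s_i/2 * (P_lo + P_hi)`` where the slant height is
    ``s_i = sqrt(t**2 + ((W_lo - W_hi)/2)**2)``.

    Reduces exactly to the prism (equal faces) and the cone (one face of
    zero area) closed forms.
    """
    for name, v in dict(A_lo=A_lo, A_hi=A_hi, P_lo=P_lo, P_hi=P_hi,
                        W_lo=W_lo, W_hi=W_hi).items():
        if not np.isfinite(v) or v < 0:
            raise ValueError(f"{name} must be non-negative and finite, got {v!r}")
    if not np.isfinite(t) or t <= 0:
        raise ValueError(f"slab thickness t must be positive, got {t!r}")
    V_i = (t / 3.0) * (A_lo + A_hi + np.sqrt(A_lo * A_hi))
    s_i = np.hypot(t, 0.5 * (W_lo - W_hi))
    S_i = 0.5 * s_i * (P_lo + P_hi)
    return float(V_i), float(S_i)


def stack_cell(views: CellViews) -> CellGeometry:
    """Reconstruct cell volume and surface from measured views.

    Each boundary j carries the scale factor ``f_j = W_j / W``; sections are
    similar copies of the frontal outline (``A_j = A_f f_j**2``,
    ``P_j = P_f f_j``).  The surface is the sum of the frustum lateral areas
    plus the flat areas of the two outermost boundaries (zero whenever the
    profile tapers to a point, as for spheres; equal to twice the smallest
    slice area for symmetric profiles).
    """
    f = views.widths / views.W
    if np.any(f > 1.0 + WIDTH_TOLERANCE):
        raise ValueError("width profile scale factor exceeds 1 beyond tolerance")
    f = np.minimum(f, 1.0)
    t = views.T / views.n_slabs
    A = views.A_f * f**2
    P = views.P_f * f
    W = views.W * f
    V_i = (t / 3.0) * (A[:-1] + A[1:] + np.sqrt(A[:-1] * A[1:]))
    s_i = np.hypot(t, 0.5 * np.diff(W))
    S_i = 0.5 * s_i * (P[:-1] + P[1:])
    cap = float(A[0] + A[-1])
    return CellGeometry(
        V=float(V_i.sum()),
        S=float(S_i.sum() + cap),
        slab_volumes=V_i,
        slab_laterals=S_i,
        cap_area=cap,
    )


def circularity(A_f: float, P_f: float) -> float:
    """Circularity ``alpha = 4*pi*A_f / P_f**2`` of the frontal outline.

    Equals 1 for a perfect circle and tends to 0 for infinitely elongated or
    lobed outlines.  A value above 1 is geometrically impossible; it is
    returned unclamped with a warning because it signals inconsistent area
    and perimeter measurements.
    """
    _require_positive(A_f=A_f, P_f=P_f)
    alpha = 4.0 * np.pi * A_f / P_f**2
    if alpha > 1.0 + 1e-9:
        warnings.warn(
            f"circularity {alpha:.4f} exceeds 1: area and perimeter are "
            "mutually inconsistent",
            stacklevel=2,
        )
    return float(alpha)


def thomsen_surface(a: float, b: float, c: float, p: float = THOMSEN_P) -> float:
    """Knud Thomsen approximation to the surface of an ellipsoid.

    ``a, b, c`` are the semi-axes.  Exact for spheres; documented worst-case
    error about 1.1 % for general ellipsoids.
    """
    _require_positive(a=a, b=b, c=c)
    return float(4.0 * np.pi * ((a**p * b**p + a**p * c**p + b**p * c**p) / 3.0) ** (1.0 / p))


def equal_volume_ellipsoid(V: float, L: float, W: float, T: float) -> tuple[float, float]:
    """Shrink coefficient and surface of the equal-volume, same-proportion ellipsoid.

    Finds ``k`` such that an ellipsoid with semi-axes ``(k*L, k*W, k*T)``
    has volume ``V`` (i.e. ``V = 4/3 pi (kL)(kW)(kT)`` up to the convention
    that L, W, T are full axis lengths scaled by a common factor), then
    evaluates its Thomsen surface.  Returns ``(k, S_ellipsoid)``.
    """
    _require_positive(V=V, L=L, W=W, T=T)
    k = (3.0 * V / (4.0 * np.pi * L * W * T)) ** (1.0 / 3.0)
    return float(k), thomsen_surface(k * L, k * W, k * T)


def sphere_surface_equal_volume(V: float) -> float:
    """Surface area ``(36*pi)**(1/3) * V**(2/3)`` of the sphere of volume ``V``."""
    _require_positive(V=V)
    return float((36.0 * np.pi) ** (1.0 / 3.0) * V ** (2.0 / 3.0))


def shape_indices(
    S: float,
    V: float,
    L: float,
    W: float,
    T: float,
    A_f: float | None = None,
    P_f: float | None = None,
) -> ShapeIndices:
    """Compute the shape indices beta, gamma, delta (and alpha when possible).

    ``beta = S/S_ellipsoid`` (fractalization), ``gamma =
    S_ellipsoid/S_sphere`` (flattening) and ``delta = beta*gamma =
    S/S_sphere`` (overall surface gain); the product identity holds to
    machine precision by construction.  ``alpha`` is filled in when the
    frontal area and perimeter are given, else NaN.
    """
    _require_positive(S=S, V=V)
    k, S_ell = equal_volume_ellipsoid(V, L, W, T)
    S_sph = sphere_surface_equal_volume(V)
    beta = S / S_ell
    gamma = S_ell / S_sph
    alpha = circularity(A_f, P_f) if A_f is not None and P_f is not None else float("nan")
    return ShapeIndices(
        alpha=alpha,
        beta=float(beta),
        gamma=float(gamma),
        delta=float(beta * gamma),
        S_ellipsoid=S_ell,
        S_sphere=S_sph,
        k=k,
    )


def cell_shape_indices(views: CellViews, geometry: CellGeometry | None = None) -> ShapeIndices:
    """Shape indices of a measured cell; reconstructs geometry when not given."""
    if geometry is None:
        geometry = stack_cell(views)
    return shape_indices(
        geometry.S, geometry.V, views.L, views.W, views.T, A_f=views.A_f, P_f=views.P_f
    )
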