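"""Real solid spherical harmonics and the gradient basis for source-free fields.

A static magnetic field in a source-free region is curl- and divergence-free,
so it is the gradient of a scalar potential that satisfies Laplace's equation.
Expanding that potential in regular solid harmonics ``r^l S_lm`` (``S_lm`` the
real, orthonormal spherical harmonics) gives a basis of vector fields
``∇(r^l S_lm)`` that spans every physical background field inside the region
of interest.  The ``l = 0`` term has zero gradient and is excluded; the three
``l = 1`` fields are the spatially uniform fields along x, y and z, and higher
degrees add gradients and curvature.

Because ``r^l S_lm`` is a homogeneous polynomial in the Cartesian coordinates,
its gradient is evaluated here as an exact polynomial (built symbolically once
per ``(l, m)`` and cached), which avoids the polar-axis singularity that
spherical-coordinate differentiation would introduce.

Conventions
-----------
* ``S_lm`` are orthonormal on the unit sphere (``∫ S_lm S_l'm' dΩ = δ δ``).
* Condon–Shortley-free associated Legendre functions ``P_l^m``.
* ``m < 0`` pairs with ``sin(|m| φ)``, ``m > 0`` with ``cos(m φ)``.
* Flattened coefficient ordering: ``l`` ascending, ``m`` from ``−l`` to ``+l``.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Callable, Iterator

import numpy as np
from scipy.special import lpmv

__all__ = [
    "MAX_DEGREE",
    "HarmonicIndex",
    "BasisField",
    "harmonic_indices",
    "n_harmonic_coefficients",
    "associated_legendre",
    "real_spherical_harmonic",
    "solid_harmonic_gradient",
    "basis_block",
]

#: Largest supported expansion degree.  Low-order models (l ≤ 2) already
#: describe the central volume of a well-degaussed shielded room; degrees
#: beyond 6 add hundreds of ill-constrained parameters for head-sized motion.
MAX_DEGREE = 6


@dataclass(frozen=True)
class HarmonicIndex:
    """Degree/order pair ``(l, m)`` of one basis field, with ``l ≥ 1``."""

    l: int
    m: int

    def __post_init__(self) -> None:
        if self.l < 1:
            raise ValueError(f"degree l must be >= 1 (l=0 has zero gradient), got l={self.l}")
        if abs(self.m) > self.l:
            raise ValueError(f"order m must satisfy |m| <= l, got (l={self.l}, m={self.m})")


def harmonic_indices(l_max: int) -> Iterator[HarmonicIndex]:
    """Yield indices in the flattened model ordering (l ascending, m = −l..+l)."""
    if not 1 <= l_max <= MAX_DEGREE:
        raise ValueError(f"l_max must be in 1..{MAX_DEGREE}, got {l_max}")
    for l in range(1, l_max + 1):
        for m in range(-l, l + 1):
            yield HarmonicIndex(l, m)


def n_harmonic_coefficients(l_max: int) -> int:
    """Number of basis fields for degrees 1..l_max: ``l_max (l_max + 2)``."""
    if not 1 <= l_max <= MAX_DEGREE:
        raise ValueError(f"l_max must be in 1..{MAX_DEGREE}, got {l_max}")
    return l_max * (l_max + 2)


# ---------------------------------------------------------------------------
# Scalar harmonics
# ---------------------------------------------------------------------------

def associated_legendre(l: int, m: int, x):
    """Associated Legendre function ``P_l^m(x)`` without the Condon–Shortley phase.

    ``P_l^m(x) = (1−x²)^{m/2} d^m/dx^m P_l(x)`` for ``0 ≤ m ≤ l``; e.g.
    ``P_1^1(x) = √(1−x²)`` (positive).
    """
    if not 0 <= m <= l:
        raise ValueError(f"require 0 <= m <= l, got (l={l}, m={m})")
    x = np.asarray(x, dtype=float)
    if np.any(np.abs(x) > 1.0):
        raise ValueError("argument of P_l^m must lie in [-1, 1]")
    # scipy's lpmv includes the Condon–Shortley (−1)^m; strip it.
    out = (-1.0) ** m * lpmv(m, l, x)
    return out if out.ndim else float(out)


def _real_harmonic_norm(l: int, m: int) -> float:
    """Normalisation giving ⟨S_lm, S_l'm'⟩ = δ_ll' δ_mm' on the sphere."""
    am = abs(m)
    from math import factorial, pi, sqrt

    if m == 0:
        return sqrt((2 * l + 1) / (4.0 * pi))
    return sqrt((2 * l + 1) / (2.0 * pi) * factorial(l - am) / factorial(l + am))


def real_spherical_harmonic(l: int, m: int, theta, phi):
    """Real orthonormal spherical harmonic ``S_lm(θ, φ)``.

    ``S_l0 ∝ P_l(cos θ)``; for ``m ≠ 0`` the azimuthal factor is
    ``cos(mφ)`` (m > 0) or ``sin(|m|φ)`` (m < 0).  ``l = 0`` is allowed here
    (the constant ``(4π)^{−1/2}``) even though it carries no field.
    """
    if l < 0 or abs(m) > l:
        raise ValueError(f"invalid harmonic index (l={l}, m={m})")
    theta = np.asarray(theta, dtype=float)
    phi = np.asarray(phi, dtype=float)
    am = abs(m)
    radial = associated_legendre(l, am, np.cos(theta))
    norm = _real_harmonic_norm(l, m)
    if m == 0:
        out = norm * np.asarray(radial)
    elif m > 0:
        out = norm * radial * np.cos(am * phi)
    else:
        out = norm * radial * np.sin(am * phi)
    out = np.asarray(out)
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# Gradient basis fields (exact Cartesian polynomials)
# ---------------------------------------------------------------------------

@lru_cache(maxsize=None)
def _gradient_evaluator(l: int, m: int) -> Callable[[np.ndarray], np.ndarray]:
    """Build (once) a vectorised evaluator for ∇(r^l S_lm) at N×3 points.

    ``r^l S_lm`` is assembled as an explicit polynomial:
    ``(r sinθ)^{|m|} {cos,sin}(|m|φ)`` is Re/Im of ``(x + iy)^{|m|}`` and
    ``r^{l−|m|} P_l^{(|m|)}(z/r)`` expands in powers of ``z`` and ``x²+y²+z²``.
    """
    import sympy as sp

    x, y, z = sp.symbols("x y z", real=True)
    am = abs(m)
    t = sp.Symbol("t")
    pder = sp.Poly(sp.diff(sp.legendre(l, t), t, am), t)
    r2 = x * x + y * y + z * z
    radial = sp.S.Zero
    for (k,), c in pder.terms():
        radial += c * z**k * r2 ** sp.Rational(l - am - k, 2)  # l−|m|−k is even
    if m == 0:
        ang = sp.S.One
        norm = sp.sqrt(sp.Rational(2 * l + 1, 4) / sp.pi)
    else:
        re, im = sp.expand((x + sp.I * y) ** am).as_real_imag()
        ang = re if m > 0 else im
        norm = sp.sqrt(
            sp.Rational(2 * l + 1, 2) / sp.pi * sp.Rational(sp.factorial(l - am), sp.factorial(l + am))
        )
    solid = sp.expand(norm * radial * ang)
    grads = [sp.lambdify((x, y, z), sp.diff(solid, v), modules="numpy") for v in (x, y, z)]

    def evaluate(points: np.ndarray) -> np.ndarray:
        px, py, pz = points[..., 0], points[..., 1], points[..., 2]
        out = np.empty(points.shape, dtype=float)
        for i, g in enumerate(grads):
            out[..., i] = np.broadcast_to(g(px, py, pz), px.shape)
        return out

    return evaluate


def solid_harmonic_gradient(index: HarmonicIndex | tuple[int, int], position) -> np.ndarray:
    """Evaluate the basis field ``∇(r^l S_lm)`` at one or many positions.

    Parameters
    ----------
    index
        ``HarmonicIndex`` or plain ``(l, m)`` with ``1 ≤ l ≤ 6``.
    position
        3-vector or ``(..., 3)`` array of Cartesian positions in metres.

    Returns
    -------
    Array of the same shape as ``position``: the field direction, scaling as
    length^(l−1).  For ``l = 1`` the field is position-independent, with
    ``(1, 1) ∝ x̂``, ``(1, −1) ∝ ŷ`` and ``(1, 0) ∝ ẑ``.
    """
    if not isinstance(index, HarmonicIndex):
        index = HarmonicIndex(*index)
    if index.l > MAX_DEGREE:
        raise ValueError(f"degree l={index.l} exceeds supported maximum {MAX_DEGREE}")
    pts = np.asarray(position, dtype=float)
    if pts.shape[-1] != 3:
        raise ValueError("position must have trailing dimension 3")
    if not np.all(np.isfinite(pts)):
        raise ValueError("position must be finite")
    single = pts.ndim == 1
    out = _gradient_evaluator(index.l, index.m)(np.atleast_2d(pts))
    return out[0] if single else out


@dataclass(frozen=True)
class BasisField:
    """One gradient basis field, bundling its index with an evaluator."""

    index: HarmonicIndex

    def evaluate(self, position) -> np.ndarray:
        return solid_harmonic_gradient(self.index, position)


def basis_block(positions: np.ndarray, orientations: np.ndarray, l_max: int) -> np.ndarray:
    """Project every basis field onto sensor axes at a set of sample points.

    Parameters
    ----------
    positions, orientations
        ``(T, 3)`` arrays: where each sample was taken (m, room frame) and the
        unit vector of the sensitive axis at that sample.
    l_max
        Expansion degree, 1..6.

    Returns
    -------
    ``(T, l_max (l_max + 2))`` matrix whose column ``j`` is
    ``∇(r^l S_lm)(position_t) · orientation_t`` for the j-th index in the
    flattened ordering.
    """
    positions = np.asarray(positions, dtype=float)
    orientations = np.asarray(orientations, dtype=float)
    if positions.shape != orientations.shape or positions.ndim != 2 or positions.shape[1] != 3:
        raise ValueError("positions and orientations must both be (T, 3)")
    norms = np.linalg.norm(orientations, axis=1)
    if np.any(np.abs(norms - 1.0) > 1e-6):
        raise ValueError("orientations must be unit vectors (tolerance 1e-6)")
    cols = [
        np.einsum("ij,ij->i", solid_harmonic_gradient(idx, positions), orientations)
        for idx in harmonic_indices(l_max)
    ]
    return np.column_stack(cols)
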