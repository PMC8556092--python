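"""The Dutreix effective-point integral for a cylindrical cavity.

A cylindrical air cavity of inner radius ``r`` in a parallel, uniform,
forward-directed charged-particle fluence reads high upstream of its axis:
a particle entering the circular cross-section at polar angle ``theta``
(measured from the beam axis) crosses a chord of length ``2y`` centred a
distance ``y = r cos(theta)`` upstream of the axis.  Weighting the
displacement ``y`` by the number of particles entering through the surface
element (``ds = r dtheta``, projected by ``cos(theta)``) and by the chord
length gives the fluence-weighted mean displacement

    y_eff = [2 r^3 \\int_0^{pi/2} cos^3(theta) dtheta]
            / [2 r^2 \\int_0^{pi/2} cos^2(theta) dtheta]
          = (4/3 r^3) / (2 r^2 pi/4)  =  r * 8 / (3 pi)  ~  0.85 r.

A constant fluence weight cancels in the ratio, so the shift is a pure
geometry factor times ``r``.
"""

from __future__ import annotations

import math

import numpy as np

__all__ = ["DUTREIX_RATIO", "shift_ratio", "shift_quadrature", "gauss_legendre_nodes"]

#: Closed-form effective-point shift as a fraction of the cavity radius.
DUTREIX_RATIO: float = 8.0 / (3.0 * math.pi)


def gauss_legendre_nodes(n_nodes: int, a: float = 0.0, b: float = math.pi / 2):
    """Gauss-Legendre nodes/weights mapped from [-1, 1] to [a, b]."""
    if n_nodes < 1:
        raise ValueError("n_nodes must be >= 1")
    x, w = np.polynomial.legendre.leggauss(n_nodes)
    half = 0.5 * (b - a)
    return a + half * (x + 1.0), half * w


def shift_ratio() -> float:
    """Effective-point shift ratio ``y_eff / r`` = 8/(3*pi) ~ 0.84883.

    Independent of the cavity radius and of any constant fluence weight.
    """
    return DUTREIX_RATIO


def shift_quadrature(r: float, n_nodes: int = 128) -> float:
    """Effective-point shift ``y_eff`` in mm by Gauss-Legendre quadrature.

    Evaluates the chord-weighted displacement integral numerator
    ``2 r^3 \\int cos^3`` over denominator ``2 r^2 \\int cos^2`` on
    ``theta`` in [0, pi/2].  Converges spectrally to ``r * 8/(3 pi)``.

    Parameters
    ----------
    r:
        Cavity inner radius, mm (> 0).
    n_nodes:
        Quadrature node count (>= 16).
    """
    if r <= 0:
        raise ValueError(f"cavity radius must be > 0, got {r}")
    if n_nodes < 16:
        raise ValueError("n_nodes must be >= 16")
    theta, w = gauss_legendre_nodes(n_nodes)
    c = np.cos(theta)
    numerator = 2.0 * r**3 * float(np.sum(w * c**3))
    denominator = 2.0 * r**2 * float(np.sum(w * c**2))
    return numerator / denominator
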