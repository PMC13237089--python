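"""Porous channel wall collapsed into a single permeability coefficient.

A cylindrical channel of inner radius ``R_c`` carries medium; its porous wall
of thickness ``t_w`` separates the lumen from the tissue at the outer radius
``R_w = R_c + t_w``.  Radial steady diffusion through the wall annulus has the
exact solution ``c_w(r) = A + B·ln r``, so the whole wall acts as a single
series resistance and can be replaced by a Robin (flux) coefficient

    Π_w = D_w / (R_w · ln(R_w/R_c)),

the wall permeability, with ``R_w·ln(R_w/R_c)`` the logarithmic wall
thickness.  Channels made by sacrificial templating have no wall at all;
this limit is represented by Dirichlet coupling (``Π_w = ∞``), never by a
large finite coefficient.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ChannelSpec",
    "WallGeometryError",
    "effective_wall_diffusivity",
    "log_wall_thickness",
    "wall_permeability",
    "wall_flux",
    "radial_wall_profile",
]

#: mm s⁻¹ × mol m⁻³  →  mol m⁻² s⁻¹
_MM_TO_M = 1.0e-3


class WallGeometryError(ValueError):
    """Degenerate channel/wall geometry."""


@dataclass(frozen=True)
class ChannelSpec:
    """Channel cross-section geometry.

    R_c : inner (lumen) radius, mm
    t_w : wall thickness, mm (0 in ``no_wall`` mode)
    f_p : wall porosity, fraction of the wall cross-section that is pore
    wall_mode : "walled" or "no_wall" (sacrificial templating, no wall)
    """

    R_c: float
    t_w: float = 0.0
    f_p: float = 0.0
    wall_mode: str = "walled"

    def __post_init__(self):
        if self.wall_mode not in ("walled", "no_wall"):
            raise WallGeometryError(f"unknown wall_mode {self.wall_mode!r}")
        if self.R_c <= 0:
            raise WallGeometryError(f"R_c must be positive, got {self.R_c!r}")
        if self.t_w < 0:
            raise WallGeometryError(f"t_w must be non-negative, got {self.t_w!r}")
        if not 0.0 <= self.f_p <= 1.0:
            raise WallGeometryError(f"f_p must lie in [0, 1], got {self.f_p!r}")
        if self.wall_mode == "no_wall" and self.t_w != 0.0:
            raise WallGeometryError("no_wall mode requires t_w = 0")

    @property
    def R_w(self) -> float:
        """Outer radius R_c + t_w, mm."""
        return self.R_c + self.t_w


def effective_wall_diffusivity(f_p: float, D_c: float, D_ws: float) -> float:
    """Linear-superposition effective diffusivity of a porous wall.

    D_w = f_p·D_c + (1−f_p)·D_ws, valid for parallel disconnected pores.
    Tortuosity or pore-size corrections are deliberately out of scope.
    """
    if not 0.0 <= f_p <= 1.0:
        raise WallGeometryError(f"porosity f_p must lie in [0, 1], got {f_p!r}")
    return f_p * D_c + (1.0 - f_p) * D_ws


def log_wall_thickness(spec: ChannelSpec) -> float:
    """Logarithmic wall thickness t̃_w = R_w·ln(R_w/R_c), mm."""
    if spec.R_w <= spec.R_c:
        raise WallGeometryError("log wall thickness needs R_w > R_c")
    return spec.R_w * math.log(spec.R_w / spec.R_c)


def wall_permeability(spec: ChannelSpec, D_w: float) -> float:
    """Wall permeability Π_w = D_w / (R_w·ln(R_w/R_c)), mm s⁻¹.

    Returns ``math.inf`` for ``no_wall`` specs; callers must then use
    Dirichlet coupling rather than a Robin flux.
    """
    if spec.wall_mode == "no_wall":
        return math.inf
    if spec.t_w == 0.0:
        raise WallGeometryError(
            "walled mode with t_w = 0; use wall_mode='no_wall' for bare channels"
        )
    return D_w / log_wall_thickness(spec)


def wall_flux(c_inner: float, c_outer: float, pi_w: float) -> float:
    """Species flux through the wall, J_w = (c_inner − c_outer)·Π_w.

    Inputs in mol m⁻³ and mm s⁻¹; the returned flux is in SI mol m⁻² s⁻¹.
    ``pi_w = inf`` signals the Dirichlet limit: the caller must impose
    ``c_outer = c_inner / K`` instead of a flux, and this function raises.
    """
    if math.isinf(pi_w):
        raise WallGeometryError(
            "infinite permeability: impose Dirichlet coupling, not a flux"
        )
    if not pi_w > 0:
        raise WallGeometryError(f"Π_w must be positive, got {pi_w!r}")
    return (c_inner - c_outer) * pi_w * _MM_TO_M


def radial_wall_profile(c_inner: float, c_outer: float, spec: ChannelSpec,
                        n: int = 101):
    """Analytic radial concentration profile c_w(r) = A + B·ln r in the wall.

    Returns ``(r, c)`` arrays on [R_c, R_w] with the boundary values matched.
    The diffusive flux of this profile evaluated at R_w equals
    ``wall_flux(c_inner, c_outer, Π_w)`` exactly; this is the derivation of
    the permeability formula and is asserted in the tests.
    """
    if spec.wall_mode == "no_wall" or spec.R_w <= spec.R_c:
        raise WallGeometryError("radial wall profile needs a walled spec with t_w > 0")
    r = np.linspace(spec.R_c, spec.R_w, n)
    B = (c_outer - c_inner) / math.log(spec.R_w / spec.R_c)
    A = c_inner - B * math.log(spec.R_c)
    return r, A + B * np.log(r)
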