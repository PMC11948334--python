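"""Domain types and the dimensionless parameterization of the two-sphere problem.

Unit conventions (reduced Gaussian-style units, used throughout the library):

* lengths in nanometres,
* charges in units of the elementary charge ``e``,
* energies in units of ``e**2 / (4*pi*eps0*nm)`` (~1.44 eV),
* forces in units of ``e**2 / (4*pi*eps0*nm**2)``.

In these units the Coulomb energy of two charges ``q1, q2`` a distance ``r``
apart in a medium of relative permittivity ``eps_out`` is simply
``q1*q2 / (eps_out*r)``; the vacuum permittivity never appears explicitly.

Geometry convention: both sphere centers lie on the z axis, sphere 1 at the
origin and sphere 2 at ``z = R``; every image charge or dipole produced by the
solvers is a 1D coordinate on this axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "SphereSpec",
    "MediumSpec",
    "TwoSphereSystem",
    "DimensionlessParams",
    "dielectric_contrast",
    "screening_exponent",
    "to_dimensionless",
    "OverlapError",
]


class OverlapError(ValueError):
    """Raised when a configuration violates the nonoverlap constraint R >= a1 + a2."""


def _require_positive(name: str, value: float) -> None:
    if not value > 0.0:
        raise ValueError(f"{name} must be positive, got {value!r}")


@dataclass(frozen=True)
class SphereSpec:
    """One polarizable sphere: radius ``a`` (nm), relative permittivity
    ``eps_in`` and central point charge ``Q`` (in units of e)."""

    a: float
    eps_in: float
    Q: float = 0.0

    def __post_init__(self) -> None:
        _require_positive("radius a", self.a)
        _require_positive("eps_in", self.eps_in)


@dataclass(frozen=True)
class MediumSpec:
    """Homogeneous background medium of relative permittivity ``eps_out``."""

    eps_out: float = 1.0

    def __post_init__(self) -> None:
        _require_positive("eps_out", self.eps_out)


@dataclass(frozen=True)
class TwoSphereSystem:
    """Two polarizable spheres at center-to-center separation ``R`` (nm).

    Sphere 1 sits at the origin and sphere 2 at ``z = R``.  The surface gap is
    ``d = R - a1 - a2 >= 0``.
    """

    sphere1: SphereSpec
    sphere2: SphereSpec
    medium: MediumSpec
    R: float

    def __post_init__(self) -> None:
        _require_positive("separation R", self.R)
        if self.R < self.sphere1.a + self.sphere2.a:
            raise OverlapError(
                f"R = {self.R} violates nonoverlap: requires "
                f"R >= a1 + a2 = {self.sphere1.a + self.sphere2.a}"
            )

    @property
    def gap(self) -> float:
        """Surface-to-surface separation d = R - a1 - a2 (nm)."""
        return self.R - self.sphere1.a - self.sphere2.a

    def at_separation(self, R: float) -> "TwoSphereSystem":
        """Same spheres and medium at a different center distance."""
        return TwoSphereSystem(self.sphere1, self.sphere2, self.medium, R)


def dielectric_contrast(eps_in: float, eps_out: float) -> float:
    """Dielectric contrast k = (eps_in - eps_out) / (eps_in + eps_out).

    ``k -> 1`` is the perfect-conductor limit (eps_in -> inf), ``k = 0`` is
    index matching, and ``k < 0`` means the medium is the more polarizable
    phase (no like-charge attraction is possible there).
    """
    _require_positive("eps_in", eps_in)
    _require_positive("eps_out", eps_out)
    return (eps_in - eps_out) / (eps_in + eps_out)


def screening_exponent(eps_in: float, eps_out: float) -> float:
    """Exponent g = eps_out / (eps_in + eps_out) of the line-image density.

    Satisfies the identity ``k + 2*g = 1`` with the dielectric contrast, and
    ``g -> 0`` in the conductor limit.  The Neumann line-image density decays
    from the Kelvin point toward the center as ``r**(g-1)``.
    """
    _require_positive("eps_in", eps_in)
    _require_positive("eps_out", eps_out)
    return eps_out / (eps_in + eps_out)


@dataclass(frozen=True)
class DimensionlessParams:
    """Dimensionless view of a two-sphere configuration.

    ``t_i = a_i / R`` are the contact parameters (contact at ``t = 1/2`` for
    equal spheres, ``t1 + t2 = 1`` in general), ``k_i`` and ``g_i`` the
    per-sphere dielectric contrast and line-image exponent, and
    ``charge_ratio = Q2/Q1``.  ``chi`` is the combined charge/dielectric
    asymmetry ``k1*(Q2/Q1) + k2*(Q1/Q2)`` that controls like-charge
    attraction of equal-sized spheres; it is only defined when both charges
    are nonzero.
    """

    t1: float
    t2: float
    k1: float
    k2: float
    g1: float
    g2: float
    charge_ratio: float | None = None
    chi: float | None = field(default=None)


def to_dimensionless(system: TwoSphereSystem) -> DimensionlessParams:
    """Reduce a system to the dimensionless parameters (t_i, k_i, g_i, ratios).

    All physics downstream (critical conditions, phase diagrams) depends on
    the geometry only through these scale-invariant combinations.
    """
    s1, s2, eo = system.sphere1, system.sphere2, system.medium.eps_out
    t1 = s1.a / system.R
    t2 = s2.a / system.R
    k1 = dielectric_contrast(s1.eps_in, eo)
    k2 = dielectric_contrast(s2.eps_in, eo)
    g1 = screening_exponent(s1.eps_in, eo)
    g2 = screening_exponent(s2.eps_in, eo)
    ratio = chi = None
    if s1.Q != 0.0 and s2.Q != 0.0:
        ratio = s2.Q / s1.Q
        chi = k1 * ratio + k2 / ratio
    return DimensionlessParams(
        t1=t1, t2=t2, k1=k1, k2=k2, g1=g1, g2=g2, charge_ratio=ratio, chi=chi
    )
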