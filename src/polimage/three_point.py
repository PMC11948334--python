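"""The three-point image formula for a single polarizable sphere.

Resumming the Neumann line image with the incomplete beta function shows
that the polarization energy of a point charge ``Q`` at distance ``R`` from
the sphere center can be written as the interaction of ``Q`` with exactly
three images held at fixed, source-independent positions:

* a charge ``-Q*k/2`` at ``+a`` on the axis (source side of the sphere),
* a charge ``+Q*k/2`` at ``-a`` (far side), and
* a point dipole ``p`` at the center, oriented toward the source, with

      p(t) = Q*k*a*g * sum_{n>=0} t**(2n) / (n + g),      t = a/R,

whose leading term is the conductor-like ``p ~ Q*k*a``.  The pair is
neutral, so total charge neutrality is preserved, and with the exact series
for ``p`` the energy

      E_pol = Q/(2*eps_out) * [ q_near/(R-a) + q_far/(R+a) + p/R**2 ]

equals the Neumann line-image energy identically.

The three-point set matches the true polarization *field* at the location
of the inducing source (which is all the energy needs); away from that
point it is a compressed surrogate of the line image, a fact that matters
when the formula is iterated between two spheres (see
:mod:`polimage.two_sphere`).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

from .model import MediumSpec, SphereSpec, dielectric_contrast, screening_exponent
from .single_sphere import lerch_series, polarization_series

__all__ = [
    "ImageSet",
    "dipole_strength",
    "dipole_response_dipole",
    "three_point_images",
    "three_point_energy",
]

Mode = Literal["exact", "leading"]


@dataclass(frozen=True)
class ImageSet:
    """Three-point image strengths for one sphere's response to one charge.

    ``q_near`` sits at axial position ``+a`` from the sphere center (toward
    the source), ``q_far`` at ``-a``, and ``p_center`` is the central dipole
    moment (e*nm), positive when oriented from the center toward the source.
    """

    q_near: float
    q_far: float
    p_center: float
    source_distance: float
    a: float


def dipole_strength(
    Q: float,
    sphere: SphereSpec,
    medium: MediumSpec,
    t: float,
    mode: Mode = "exact",
) -> float:
    """Central image-dipole moment ``p`` for a source charge at ``t = a/R``.

    ``mode="exact"`` evaluates the full series
    ``p = Q*k*a*g*sum t**(2n)/(n+g)``; ``mode="leading"`` keeps only the
    leading term ``Q*k*a`` (exact in the conductor limit g -> 0, and dominant
    whenever ``1/g >> t**2/(1+g)``, i.e. for strongly polarizable spheres).
    """
    if not 0.0 < t < 1.0:
        raise ValueError(f"dipole_strength requires 0 < t < 1, got t = {t}")
    a = sphere.a
    k = dielectric_contrast(sphere.eps_in, medium.eps_out)
    if mode == "leading":
        return Q * k * a
    g = screening_exponent(sphere.eps_in, medium.eps_out)
    if k == 0.0:
        return 0.0
    return Q * k * a * g * lerch_series(t * t, g)


def dipole_response_dipole(
    sphere: SphereSpec,
    medium: MediumSpec,
    t: float,
    mode: Mode = "exact",
) -> float:
    """Central dipole induced by a unit axial *dipole* source at ``t = a/r``.

    The sphere's exact response to an axial point dipole is the source-
    position derivative of its response to a point charge (two displaced
    charges in the limit of vanishing separation).  Matching the resulting
    field at the source location, as the three-point formula does for charge
    sources, gives the transfer coefficient

        P(t) = k * sum_{n>=1} n*(n+1)/(n+g) * t**(2n+1)

    (dimensionless; induced moment is parallel to the source moment).  Its
    leading term ``2*k*t**3/(1+g)`` is the familiar mutual-dipole image
    scaling ``2*k*a**3/((1+g)*r**3)``.
    """
    if not 0.0 < t < 1.0:
        raise ValueError(f"dipole response requires 0 < t < 1, got t = {t}")
    k = dielectric_contrast(sphere.eps_in, medium.eps_out)
    if k == 0.0:
        return 0.0
    g = screening_exponent(sphere.eps_in, medium.eps_out)
    t2 = t * t
    if mode == "leading":
        return 2.0 * k * t * t2 / (1.0 + g)
    # sum n(n+1)/(n+g) t^{2n} = sum (n+1) t^{2n} - g * sum (n+1)/(n+g) t^{2n}
    #   sum_{n>=1} (n+1) x^n = 1/(1-x)^2 - 1
    #   sum_{n>=1} (n+1)/(n+g) x^n = sum (n+g+1-g)/(n+g) x^n
    #                              = x/(1-x) + (1-g)*(lerch(x,g) - 1/g)
    x = t2
    s_np1 = 1.0 / (1.0 - x) ** 2 - 1.0
    s_frac = x / (1.0 - x) + (1.0 - g) * (lerch_series(x, g) - 1.0 / g)
    return k * t * (s_np1 - g * s_frac)


def three_point_images(
    Q: float,
    R: float,
    sphere: SphereSpec,
    medium: MediumSpec,
    mode: Mode = "exact",
) -> ImageSet:
    """Three-point image set of charge ``Q`` at distance ``R`` from the center.

    Image positions are always ``{+a, -a, 0}`` regardless of ``R``; only the
    central dipole strength depends on the source distance.  The near-side
    charge has the opposite sign to ``Q`` for ``k > 0`` (verified against the
    Neumann line-image construction, which places the negative Kelvin image
    on the source side).
    """
    a = sphere.a
    if R <= a:
        raise ValueError(f"source must lie outside the sphere: R = {R} <= a = {a}")
    k = dielectric_contrast(sphere.eps_in, medium.eps_out)
    p = dipole_strength(Q, sphere, medium, a / R, mode=mode) if k != 0.0 else 0.0
    return ImageSet(
        q_near=-0.5 * Q * k,
        q_far=+0.5 * Q * k,
        p_center=p,
        source_distance=R,
        a=a,
    )


def three_point_energy(
    Q: float,
    R: float,
    sphere: SphereSpec,
    medium: MediumSpec,
    mode: Mode = "exact",
) -> float:
    """Single-sphere polarization energy from the three-point image set.

    ``mode="exact"`` reproduces the Neumann quadrature energy to near machine
    precision (the resummation is exact); ``mode="leading"`` gives the
    closed-form approximation used by the critical-condition theory,

        E_pol ~ -k*Q**2*a**3 / (2*eps_out*R**2*(R**2 - a**2)),

    which is also the exact neutral-conductor image energy when k = 1.
    """
    img = three_point_images(Q, R, sphere, medium, mode=mode)
    a = img.a
    if mode == "leading":
        phi = img.q_near / (R - a) + img.q_far / (R + a) + img.p_center / (R * R)
        return Q * phi / (2.0 * medium.eps_out)
    # exact mode: the +-Qk/2 pair sums to -Q*k*a/(R^2-a^2); combining it with
    # the dipole term and expanding in t = a/R removes the near-complete
    # cancellation between pair and dipole potentials at large R
    k = dielectric_contrast(sphere.eps_in, medium.eps_out)
    if k == 0.0:
        return 0.0
    g = screening_exponent(sphere.eps_in, medium.eps_out)
    t2 = (a / R) ** 2
    return -(k * Q * Q / (2.0 * medium.eps_out * a)) * t2 * polarization_series(t2, g)
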