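"""Critical conditions for like-charge attraction (LCA).

Keeping one reflection level with the leading-order image dipole
``p = Q*k*a`` gives a closed-form interaction energy for two like-charged
polarizable spheres,

    E_ele = 1/eps_out * [ Q1*Q2/R
                          - k1*Q2**2*a1**3 / (2*R**2*(R**2 - a1**2))
                          - k2*Q1**2*a2**3 / (2*R**2*(R**2 - a2**2)) ]

and force ``F = -dE_ele/dR`` (> 0 repulsive).  Because the per-level force
contributions alternate in sign and decay, the first-level force being
repulsive everywhere is a *sufficient* condition for the converged force to
be repulsive everywhere (alternating-series remainder theorem) — so a root
of the first-level force is a necessary-and-quantitative predictor of LCA.

Setting F = 0 and factoring out the Coulomb force yields the dimensionless
critical condition

    k1*(Q2/Q1)*h(t1) + k2*(Q1/Q2)*h(t2) = 1,
    h(t) = t**3*(2 - t**2) / (1 - t**2)**2,   t_i = a_i/R,

(equivalently ``1 + sum_i k_i*q_ji*H(t_i) = 0`` with ``H = -h < 0`` on the
physical domain).  ``h`` is strictly increasing, so at fixed parameters the
condition has at most one root ``R_c``; attraction occurs for every
``R < R_c``.  Specializations:

* equal sizes: ``chi * h(t) = 1`` with the asymmetry parameter
  ``chi = k1*(Q2/Q1) + k2*(Q1/Q2)``.  At contact (t = 1/2) ``h = 7/18``, so
  LCA requires ``chi > 18/7``; symmetric charges give ``chi = k1 + k2 <= 2``,
  hence equal-sized, equally charged spheres never attract.
* equal charges and permittivities: ``k*(h(t1) + h(t2)) = 1``; attraction is
  driven by size asymmetry, maximal for conductors (k = 1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy.optimize import brentq

from .model import (
    DimensionlessParams,
    TwoSphereSystem,
    to_dimensionless,
)

__all__ = [
    "CriticalResult",
    "PhaseDiagram",
    "h_factor",
    "H_factor",
    "first_level_energy",
    "first_level_force",
    "critical_condition_general",
    "contact_threshold_equal_size",
    "solve_rc",
    "solve_rc_numeric",
    "phase_diagram",
    "CHI_CONTACT_THRESHOLD",
]

logger = logging.getLogger(__name__)

#: equal-size contact threshold 18/7 for the asymmetry parameter chi
CHI_CONTACT_THRESHOLD = 18.0 / 7.0

_RMAX_FACTOR = 1e3
_SCAN_POINTS = 512


def h_factor(t):
    """Geometric factor h(t) = t**3*(2 - t**2)/(1 - t**2)**2 of the critical
    condition; strictly increasing from 0 to infinity on (0, 1)."""
    t = np.asarray(t, dtype=float)
    t2 = t * t
    out = t * t2 * (2.0 - t2) / (1.0 - t2) ** 2
    return out if out.ndim else float(out)


def H_factor(t):
    """The negative-definite form ``H(t) = -h(t)`` (< 0 on 0 < t < 1)."""
    out = -np.asarray(h_factor(t))
    return out if out.ndim else float(out)


def _h_inverse(y: float) -> float:
    """Inverse of h on (0, 1); h is strictly increasing and unbounded."""
    if y <= 0.0:
        raise ValueError("h(t) is positive on (0, 1)")
    lo, hi = 1e-12, 1.0 - 1e-14
    if y <= h_factor(lo):
        # h ~ 2 t^3 for small t
        return float((y / 2.0) ** (1.0 / 3.0))
    if y >= h_factor(hi):
        raise ValueError(f"h(t) = {y} unreachable below t = 1")
    return float(brentq(lambda t: h_factor(t) - y, lo, hi, xtol=1e-15, rtol=1e-15))


def first_level_energy(system: TwoSphereSystem) -> float:
    """Closed-form total energy with one reflection level and p = Q*k*a."""
    p = to_dimensionless(system)
    s1, s2 = system.sphere1, system.sphere2
    R, eps_out = system.R, system.medium.eps_out
    a1, a2 = s1.a, s2.a
    e = s1.Q * s2.Q / R
    e -= p.k1 * s2.Q**2 * a1**3 / (2.0 * R**2 * (R**2 - a1**2))
    e -= p.k2 * s1.Q**2 * a2**3 / (2.0 * R**2 * (R**2 - a2**2))
    return e / eps_out


def first_level_force(system: TwoSphereSystem) -> float:
    """Analytic derivative F = -dE/dR of :func:`first_level_energy`."""
    p = to_dimensionless(system)
    s1, s2 = system.sphere1, system.sphere2
    R, eps_out = system.R, system.medium.eps_out
    a1, a2 = s1.a, s2.a
    f = s1.Q * s2.Q / R**2
    f -= p.k1 * s2.Q**2 * a1**3 * (2.0 * R**2 - a1**2) / (R**3 * (R**2 - a1**2) ** 2)
    f -= p.k2 * s1.Q**2 * a2**3 * (2.0 * R**2 - a2**2) / (R**3 * (R**2 - a2**2) ** 2)
    return f / eps_out


def critical_condition_general(params: DimensionlessParams) -> float:
    """Residual of the dimensionless critical condition.

    Returns ``1 - k1*(Q2/Q1)*h(t1) - k2*(Q1/Q2)*h(t2)``; zero exactly where
    the first-level force vanishes, positive where it is repulsive.  Requires
    both charges nonzero (the condition divides out the Coulomb force).
    """
    if params.charge_ratio is None:
        raise ValueError("critical condition requires two nonzero charges")
    if not (0.0 < params.t1 < 1.0 and 0.0 < params.t2 < 1.0):
        raise ValueError("t1, t2 must lie in (0, 1)")
    if params.t1 + params.t2 > 1.0 + 1e-12:
        raise ValueError("nonphysical geometry: t1 + t2 > 1 (overlap)")
    q21 = params.charge_ratio
    return float(
        1.0
        + params.k1 * q21 * H_factor(params.t1)
        + params.k2 / q21 * H_factor(params.t2)
    )


def contact_threshold_equal_size() -> float:
    """Critical asymmetry parameter chi at contact for equal-sized spheres.

    Solves ``chi * h(1/2) = 1``; since ``h(1/2) = 7/18`` exactly, the
    threshold is 18/7.  Below it, LCA occurs at no separation; symmetric
    charges give ``chi = k1 + k2 < 2 < 18/7``, hence never attract.
    """
    return float(1.0 / h_factor(0.5))


@dataclass(frozen=True)
class CriticalResult:
    """Outcome of a critical-separation solve.

    ``lca_occurs`` is False when the first-level force is repulsive at all
    admissible separations; otherwise ``R_c`` is the unique zero crossing
    (repulsive beyond, attractive within) and ``t_c = (t1, t2)`` its
    dimensionless image.  ``residual`` is the critical-condition residual at
    the reported root.
    """

    lca_occurs: bool
    R_c: float | None = None
    t_c: tuple[float, float] | None = None
    residual: float | None = None
    method: str = "eq_general"
    crossings: tuple[float, ...] = ()


def solve_rc(system: TwoSphereSystem, method: str = "numeric") -> CriticalResult:
    """Solve the first-level critical condition for ``R_c >= a1 + a2``.

    The residual is scanned on a uniform grid in the contact parameter (the
    condition is best behaved near contact), every sign change is bisected to
    ~1e-12, and the *largest* ``R_c`` — the outermost onset of attraction —
    is reported.  No sign change up to ``R = 1000*(a1+a2)`` is a valid
    "no LCA" outcome, not an error.  Since ``h`` is monotone the root is in
    fact unique; multiple crossings would indicate a numerical problem and
    are all recorded.
    """
    a1, a2 = system.sphere1.a, system.sphere2.a
    contact = a1 + a2
    base = system if system.R >= contact else system.at_separation(contact)

    def residual_at_r(r: float) -> float:
        return critical_condition_general(to_dimensionless(base.at_separation(r)))

    # scan in u = contact/R in (0, 1]: u = 1 is contact, u -> 0 long range
    u_grid = np.linspace(1.0, 1.0 / _RMAX_FACTOR, _SCAN_POINTS)
    res = np.array([residual_at_r(contact / u) for u in u_grid])
    sign_changes = np.nonzero(np.diff(np.signbit(res)))[0]
    crossings = []
    for i in sign_changes:
        u_root = brentq(
            lambda u: residual_at_r(contact / u),
            u_grid[i],
            u_grid[i + 1],
            xtol=1e-15,
            rtol=1e-14,
        )
        crossings.append(contact / u_root)
    if res[0] == 0.0:  # touching exactly at contact
        crossings.append(contact)
    if not crossings:
        return CriticalResult(lca_occurs=False, method="eq_general")
    if len(crossings) > 1:
        logger.warning("multiple critical-condition roots found: %s", crossings)
    r_c = max(crossings)
    t_c = (a1 / r_c, a2 / r_c)
    return CriticalResult(
        lca_occurs=True,
        R_c=r_c,
        t_c=t_c,
        residual=residual_at_r(r_c),
        method="eq_general",
        crossings=tuple(sorted(crossings)),
    )


def solve_rc_numeric(
    system: TwoSphereSystem,
    method: str = "neumann",
    rc_guess: float | None = None,
    tol: float = 1e-12,
    xtol_rel: float = 1e-9,
    **solver_kwargs,
) -> CriticalResult:
    """Critical separation from the sign change of a *converged* solver force.

    Brackets the zero crossing of the converged reflection force (Neumann
    oracle by default) around ``rc_guess`` (defaults to the first-level
    theory root) and refines it with Brent's method.  Used to validate the
    closed-form theory; the two roots agree to ~1% for strongly polarizable
    spheres.  Returns ``lca_occurs=False`` if the force is repulsive down to
    just outside contact.
    """
    from .two_sphere import force as _force  # local import: avoid cycle

    a1, a2 = system.sphere1.a, system.sphere2.a
    contact = a1 + a2

    def f(r: float) -> float:
        return _force(system.at_separation(r), method=method, tol=tol, **solver_kwargs)

    if rc_guess is None:
        theory = solve_rc(system)
        rc_guess = theory.R_c if theory.lca_occurs else 1.5 * contact

    lo = max(rc_guess * 0.9, contact * 1.003)
    hi = max(rc_guess * 1.05, lo * 1.01)
    f_lo, f_hi = f(lo), f(hi)
    while f_lo > 0.0 and lo > contact * 1.0035:
        lo = max(0.97 * lo, contact * 1.003)
        f_lo = f(lo)
    n_expand = 0
    while f_hi < 0.0:
        hi *= 1.05
        f_hi = f(hi)
        n_expand += 1
        if n_expand > 200:
            raise RuntimeError("force does not turn repulsive at large R")
    if f_lo > 0.0:
        return CriticalResult(lca_occurs=False, method=f"numeric_{method}")
    r_c = float(brentq(f, lo, hi, xtol=xtol_rel * rc_guess))
    return CriticalResult(
        lca_occurs=True,
        R_c=r_c,
        t_c=(a1 / r_c, a2 / r_c),
        residual=f(r_c),
        method=f"numeric_{method}",
        crossings=(r_c,),
    )


@dataclass
class PhaseDiagram:
    """Critical curves in dimensionless parameter space.

    ``mode="equal_size"``: abscissa is the asymmetry parameter chi, ordinate
    the critical contact parameter ``t_c`` (curve exists only for
    chi >= 18/7; attraction for t > t_c at given chi).

    ``mode="equal_charge"``: one critical curve ``t2(t1)`` per dielectric
    contrast k; the region between the curve and the contact line
    ``t1 + t2 = 1`` is the attraction region, growing with k.
    """

    mode: Literal["equal_size", "equal_charge"]
    curves: dict = field(default_factory=dict)


def phase_diagram(
    mode: Literal["equal_size", "equal_charge"],
    grid: Sequence[float] | None = None,
    k_values: Sequence[float] | None = None,
) -> PhaseDiagram:
    """Trace the zero set of the critical condition.

    ``equal_size``: for each chi in ``grid`` (default 18/7..12) solve
    ``chi*h(t) = 1`` for ``t in (0, 1/2]``; chi below 18/7 yields no point.

    ``equal_charge``: for each k in ``k_values`` (default Fig.-style
    0.01..1) and each ``t1`` in ``grid`` solve ``k*(h(t1) + h(t2)) = 1``;
    points with ``t1 + t2 > 1`` are masked (NaN) as nonphysical.
    """
    diagram = PhaseDiagram(mode=mode)
    if mode == "equal_size":
        chis = np.asarray(
            grid if grid is not None else np.linspace(CHI_CONTACT_THRESHOLD, 12.0, 200)
        )
        t_c = np.full_like(chis, np.nan, dtype=float)
        for i, chi in enumerate(chis):
            if chi < CHI_CONTACT_THRESHOLD:
                continue
            t = _h_inverse(1.0 / chi)
            if t <= 0.5 + 1e-12:
                t_c[i] = min(t, 0.5)
        diagram.curves["chi"] = chis
        diagram.curves["t_c"] = t_c
        return diagram
    if mode == "equal_charge":
        ks = list(k_values if k_values is not None else (0.01, 0.1, 0.25, 0.5, 0.75, 1.0))
        t1s = np.asarray(grid if grid is not None else np.linspace(0.005, 0.995, 200))
        diagram.curves["t1"] = t1s
        per_k = {}
        for k in ks:
            if not 0.0 < k <= 1.0:
                raise ValueError(f"equal_charge mode requires 0 < k <= 1, got {k}")
            t2 = np.full_like(t1s, np.nan, dtype=float)
            for i, t1 in enumerate(t1s):
                rhs = 1.0 / k - h_factor(t1)
                if rhs <= 0.0:
                    # already supercritical from sphere 1 alone at any t2 -> the
                    # critical curve has passed below the axis
                    continue
                try:
                    cand = _h_inverse(rhs)
                except ValueError:
                    continue
                if t1 + cand <= 1.0:
                    t2[i] = cand
            per_k[k] = t2
        diagram.curves["t2_by_k"] = per_k
        return diagram
    raise ValueError(f"unknown phase-diagram mode {mode!r}")
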