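"""Core mass-action equilibrium of the cooperative ternary complex.

A ternary complex CLT forms when a ligand L simultaneously engages a
"chaperone" protein C (the presenter: FKBP12, CRBN, VHL, 14-3-3, ...) and a
target protein T.  Formation proceeds through either binary intermediate::

    C + L <-> CL        (K_C1 = [C][L]/[CL])
    T + L <-> TL        (K_T1 = [T][L]/[TL])
    CL + T <-> CLT      (K_T2 = K_T1 / alpha)
    TL + C <-> CLT      (K_C2 = K_C1 / alpha)

The intrinsic cooperativity ``alpha`` is the fold-change in the ligand's
affinity for one protein when the ligand is pre-bound to the other; it is
identical along both pathways (path independence), which makes the combined
mass-action condition

    [CLT] * K_C1 * K_T1 = alpha * [C] * [L] * [T]

hold at every equilibrium point.  Substituting the protein conservation
relations ``[C_tot] = [C] + [CL] + [CLT]`` and ``[T_tot] = [T] + [TL] + [CLT]``
reduces the system, at a known *free* ligand concentration, to a single
quadratic in [CLT] with exactly one physical root.  The total ligand implied
by a free-ligand value is then ``[L_tot] = [L] + [CL] + [TL] + [CLT]``, a
strictly increasing map whose numerical inverse converts a dosed (total)
ligand concentration into the free concentration that actually drives
binding.

All concentrations and dissociation constants throughout this package are in
nanomolar (nM); there is no unit-conversion layer.  The direct association
pathway through a pre-formed C-T protein dimer is not modelled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from scipy.optimize import brentq, minimize_scalar

from .errors import SolverError, ValidationError

__all__ = [
    "TernarySystem",
    "EquilibriumState",
    "validate_system",
    "clt_given_free_ligand",
    "state_from_free_ligand",
    "total_ligand_of_free",
    "free_ligand_of_total",
    "state_from_total_ligand",
    "free_ligand_at_max_clt",
    "ltot_at_max_clt",
]

#: relative discriminant clamp: b^2 - 4ac below this (relative to b^2) is
#: treated as an exact double root rather than a numerical error
_DISC_CLAMP = 1e-10

#: minimum relative tolerance accepted by scipy's brentq (4 * machine eps)
_BRENT_RTOL = 4 * math.ulp(1.0)


@dataclass(frozen=True)
class TernarySystem:
    """The five parameters that fully specify a closed ternary equilibrium.

    Parameters
    ----------
    k_c1 : float
        Dissociation constant of free ligand to free chaperone, nM.
    k_t1 : float
        Dissociation constant of free ligand to free target, nM.
    alpha : float
        Intrinsic cooperativity (dimensionless).  ``alpha > 1`` means the
        ligand binds each protein more tightly once pre-bound to the other;
        values below 1 (negative cooperativity) are allowed, zero is not.
    c_tot : float
        Total chaperone concentration, nM.
    t_tot : float
        Total target concentration, nM.
    """

    k_c1: float
    k_t1: float
    alpha: float
    c_tot: float
    t_tot: float

    def __post_init__(self) -> None:
        for name in ("k_c1", "k_t1", "alpha"):
            v = getattr(self, name)
            if not (v > 0) or not math.isfinite(v):
                raise ValidationError(f"{name} must be a positive finite number, got {v!r}")
        for name in ("c_tot", "t_tot"):
            v = getattr(self, name)
            if v < 0 or not math.isfinite(v):
                raise ValidationError(f"{name} must be a finite non-negative number, got {v!r}")

    @property
    def k_c2(self) -> float:
        """Dissociation constant of ligand to chaperone when pre-bound as TL (nM)."""
        return self.k_c1 / self.alpha

    @property
    def k_t2(self) -> float:
        """Dissociation constant of ligand to target when pre-bound as CL (nM)."""
        return self.k_t1 / self.alpha

    @property
    def k_clt(self) -> float:
        """Ternary potency constant K_C1 * K_T2 = K_C1 * K_T1 / alpha (nM^2)."""
        return self.k_c1 * self.k_t1 / self.alpha

    def replace(self, **changes) -> "TernarySystem":
        """Return a copy with the given fields replaced (re-validated)."""
        params = dict(k_c1=self.k_c1, k_t1=self.k_t1, alpha=self.alpha,
                      c_tot=self.c_tot, t_tot=self.t_tot)
        params.update(changes)
        return TernarySystem(**params)


@dataclass(frozen=True)
class EquilibriumState:
    """All six species concentrations (nM) at one equilibrium point."""

    l_free: float
    c_free: float
    t_free: float
    cl: float
    tl: float
    clt: float
    #: total ligand implied by this state: l_free + cl + tl + clt
    l_tot_implied: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.l_tot_implied is None:
            object.__setattr__(
                self, "l_tot_implied", self.l_free + self.cl + self.tl + self.clt
            )


def validate_system(
    k_c1: float, k_t1: float, alpha: float, c_tot: float, t_tot: float
) -> TernarySystem:
    """Validate raw parameters and return a :class:`TernarySystem`.

    Raises :class:`~ternaq.errors.ValidationError` naming the offending field
    when a dissociation constant or the cooperativity is non-positive, or a
    total concentration is negative.
    """
    return TernarySystem(float(k_c1), float(k_t1), float(alpha), float(c_tot), float(t_tot))


def clt_given_free_ligand(system: TernarySystem, l_free: float) -> float:
    """Ternary complex concentration (nM) at a known free ligand concentration.

    Solves the quadratic ``a*x^2 - b*x + c = 0`` obtained by substituting the
    protein conservation relations into the mass-action condition, with

    * ``a = alpha * l``
    * ``b = alpha * l * (c_tot + t_tot) + k_c1 * k_t1 * (1 + l/k_c1) * (1 + l/k_t1)``
    * ``c = alpha * l * c_tot * t_tot``

    and returns the smaller root, the only one not exceeding
    ``min(c_tot, t_tot)``.  The evaluation uses the cancellation-safe form
    ``x = 2c / (b + sqrt(b^2 - 4ac))`` because ``b`` dominates ``a*c`` by many
    orders of magnitude in weak-binding regimes.  Degenerate inputs
    (``l_free = 0`` or an absent protein) return exactly 0.
    """
    if l_free < 0:
        raise ValidationError(f"l_free must be non-negative, got {l_free}")
    if l_free == 0.0 or system.c_tot == 0.0 or system.t_tot == 0.0:
        return 0.0
    l = l_free
    a = system.alpha * l
    b = a * (system.c_tot + system.t_tot) + system.k_c1 * system.k_t1 * (
        1.0 + l / system.k_c1
    ) * (1.0 + l / system.k_t1)
    c = a * system.c_tot * system.t_tot
    disc = b * b - 4.0 * a * c
    if disc < 0.0:
        if disc > -_DISC_CLAMP * b * b:
            disc = 0.0
        else:  # pragma: no cover - mathematically unreachable (real coefficients, real root)
            raise SolverError(f"negative discriminant {disc} for ternary quadratic")
    # b > 0 always, so the smaller root 2c/(b + sqrt(disc)) is cancellation-free
    return 2.0 * c / (b + math.sqrt(disc))


def state_from_free_ligand(system: TernarySystem, l_free: float) -> EquilibriumState:
    """Full species state at a known free ligand concentration.

    The free proteins follow from conservation,
    ``[C] = ([C_tot] - [CLT]) / (1 + [L]/K_C1)`` (and symmetrically for T),
    the binaries from the binary isotherms ``[CL] = [C][L]/K_C1``,
    ``[TL] = [T][L]/K_T1``.

    Near protein saturation ``[C_tot] - [CLT]`` cancels catastrophically, so
    the remainders are instead recovered from the factored quadratic: at the
    root, ``([C_tot]-x)([T_tot]-x) = x*k_c1*k_t1*(1+l/k_c1)(1+l/k_t1)/(alpha*l)``
    exactly, and together with the known difference ``[T_tot]-[C_tot]`` the
    two remainders follow from a well-conditioned quadratic of their own.
    """
    clt = clt_given_free_ligand(system, l_free)
    dc = 1.0 + l_free / system.k_c1
    dt = 1.0 + l_free / system.k_t1
    if clt > 0.0:
        prod = clt * system.k_c1 * system.k_t1 * dc * dt / (system.alpha * l_free)
        diff = system.t_tot - system.c_tot
        s = math.sqrt(diff * diff + 4.0 * prod)
        # remainders c_tot - clt and t_tot - clt; the smaller one uses the
        # conjugate form so neither suffers cancellation
        if diff >= 0.0:
            t_rem = 0.5 * (s + diff)
            c_rem = 2.0 * prod / (s + diff) if s + diff > 0 else 0.0
        else:
            c_rem = 0.5 * (s - diff)
            t_rem = 2.0 * prod / (s - diff)
    else:
        c_rem = system.c_tot
        t_rem = system.t_tot
    c_free = c_rem / dc
    t_free = t_rem / dt
    cl = c_free * l_free / system.k_c1
    tl = t_free * l_free / system.k_t1
    return EquilibriumState(
        l_free=l_free, c_free=c_free, t_free=t_free, cl=cl, tl=tl, clt=clt
    )


def total_ligand_of_free(system: TernarySystem, l_free: float) -> float:
    """Total ligand (nM) implied by a free ligand concentration.

    ``[L_tot] = [L] + [CL] + [TL] + [CLT]``; strictly increasing in ``[L]``,
    which is what makes the inverse transform well defined.
    """
    return state_from_free_ligand(system, l_free).l_tot_implied


def free_ligand_of_total(system: TernarySystem, l_tot: float) -> float:
    """Invert the total-ligand map: the free ligand concentration at a dosed total.

    Since bound ligand is non-negative, the root of
    ``total_ligand_of_free(l) - l_tot`` is bracketed by ``[0, l_tot]``;
    Brent's method on that bracket is guaranteed to converge.
    """
    if l_tot < 0:
        raise ValidationError(f"l_tot must be non-negative, got {l_tot}")
    if l_tot == 0.0:
        return 0.0
    if system.c_tot == 0.0 and system.t_tot == 0.0:
        return l_tot

    def f(l: float) -> float:
        return total_ligand_of_free(system, l) - l_tot

    try:
        root, res = brentq(
            f, 0.0, l_tot, rtol=_BRENT_RTOL, maxiter=200, full_output=True
        )
    except RuntimeError as exc:  # pragma: no cover - monotone map, should not happen
        raise SolverError(
            f"free-ligand inversion failed on bracket [0, {l_tot}] nM: {exc}"
        ) from exc
    if not res.converged:  # pragma: no cover
        raise SolverError(
            f"free-ligand inversion did not converge on [0, {l_tot}] nM "
            f"after {res.iterations} iterations (last iterate {res.root})"
        )
    return root


def state_from_total_ligand(system: TernarySystem, l_tot: float) -> EquilibriumState:
    """Full species state at a dosed *total* ligand concentration (closed system)."""
    return state_from_free_ligand(system, free_ligand_of_total(system, l_tot))


def free_ligand_at_max_clt(system: TernarySystem) -> float:
    """Free ligand concentration (nM) that maximizes the ternary complex.

    The quadratic's coefficients depend on ``l`` only through
    ``alpha*l / (k_c1*k_t1*(1 + l/k_c1)*(1 + l/k_t1))``, which is invariant
    under ``l -> k_c1*k_t1/l``; the CLT(l) curve is therefore geometrically
    symmetric about ``sqrt(k_c1*k_t1)``, the position of its single maximum
    (the "hook").  The argmax is located by bounded scalar maximization on a
    log axis and cross-checked against the closed form; the closed form is
    returned.
    """
    if system.c_tot <= 0 or system.t_tot <= 0:
        raise ValidationError("free_ligand_at_max_clt requires c_tot > 0 and t_tot > 0")
    center = math.sqrt(system.k_c1 * system.k_t1)
    log_c = math.log10(center)
    res = minimize_scalar(
        lambda u: -clt_given_free_ligand(system, 10.0 ** u),
        bounds=(log_c - 6.0, log_c + 6.0),
        method="bounded",
        options={"xatol": 1e-10},
    )
    numeric = 10.0 ** res.x
    if abs(numeric - center) > 1e-6 * center:  # pragma: no cover - symmetry guarantee
        raise SolverError(
            f"numerical CLT argmax {numeric} nM disagrees with the symmetry "
            f"point sqrt(k_c1*k_t1) = {center} nM"
        )
    return center


def ltot_at_max_clt(system: TernarySystem) -> float:
    """Total ligand concentration (nM) at which the ternary complex peaks.

    Equal to ``total_ligand_of_free`` evaluated at the free-ligand argmax;
    always at least the free-ligand argmax because the bound species add to
    the total.  Unlike the free-ligand hook, the CLT curve against *total*
    ligand is generally asymmetric.
    """
    return total_ligand_of_free(system, free_ligand_at_max_clt(system))
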