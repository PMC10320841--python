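"""Binding-curve simulation and model-based EC50 extraction.

Experiments monitor a *bound fraction* of one protein — %C_bound =
([CL]+[CLT])/[C_tot] or %T_bound = ([TL]+[CLT])/[T_tot] — against the dosed
ligand concentration.  Because the monitored signal is the sum of binary and
ternary binding events, its half-maximal concentration (EC50) moves left of
the monitored protein's binary K_d when the counter protein and positive
cooperativity are present; that shift is the experimental fingerprint of
cooperativity.

Grids here are presentation artifacts: every quantitative output (EC50,
curve maxima) is computed on the continuous model by root finding, never by
interpolating a sampled table.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .equilibrium import (
    EquilibriumState,
    TernarySystem,
    state_from_free_ligand,
    state_from_total_ligand,
)
from .errors import Ec50NotIdentifiableError, ValidationError

__all__ = [
    "Axis",
    "Monitor",
    "GridSpec",
    "BindingCurve",
    "Ec50Result",
    "bound_fraction",
    "simulate_curve",
    "ec50",
]

Axis = Literal["total_ligand", "free_ligand"]
Monitor = Literal["c_bound", "t_bound"]

#: saturation requirement: bound fraction at the bracket top must reach this
#: share of the bound fraction at 100x the bracket top
_SATURATION = 0.99
#: automatic bracket extension factor and retry count when not saturated
_EXTEND_FACTOR = 10.0
_EXTEND_RETRIES = 3

_CSV_COLUMNS = [
    "l_axis_nM",
    "l_free_nM",
    "c_free_nM",
    "t_free_nM",
    "cl_nM",
    "tl_nM",
    "clt_nM",
    "pct_c_bound",
    "pct_t_bound",
    "pct_clt_of_target",
    "pct_clt_of_chaperone",
]


@dataclass(frozen=True)
class GridSpec:
    """A log-spaced ligand grid: `points` concentrations from `min` to `max` nM."""

    min: float
    max: float
    points: int = 200
    axis: Axis = "total_ligand"

    def __post_init__(self) -> None:
        if not (self.min > 0):
            raise ValidationError(f"grid min must be positive, got {self.min}")
        if not (self.max > self.min):
            raise ValidationError(f"grid max must exceed min, got [{self.min}, {self.max}]")
        if self.points < 2:
            raise ValidationError(f"grid needs at least 2 points, got {self.points}")
        if self.axis not in ("total_ligand", "free_ligand"):
            raise ValidationError(f"unknown axis {self.axis!r}")

    def values(self) -> np.ndarray:
        return np.geomspace(self.min, self.max, self.points)


def _state_at(system: TernarySystem, x: float, axis: Axis) -> EquilibriumState:
    if axis == "total_ligand":
        return state_from_total_ligand(system, x)
    return state_from_free_ligand(system, x)


def bound_fraction(
    system: TernarySystem, x: float, monitor: Monitor, axis: Axis = "total_ligand"
) -> float:
    """Monitored bound fraction (0..1) at one applied ligand concentration."""
    s = _state_at(system, x, axis)
    if monitor == "c_bound":
        if system.c_tot == 0:
            raise ValidationError("c_bound fraction undefined: c_tot = 0")
        return (s.cl + s.clt) / system.c_tot
    if monitor == "t_bound":
        if system.t_tot == 0:
            raise ValidationError("t_bound fraction undefined: t_tot = 0")
        return (s.tl + s.clt) / system.t_tot
    raise ValidationError(f"unknown monitor {monitor!r}")


@dataclass(frozen=True)
class BindingCurve:
    """Equilibrium states tabulated over a ligand grid, with monitored columns.

    Percentage columns whose reference total is zero (e.g. ``pct_t_bound``
    for a system without target) are NaN — undefined, not 0.
    """

    system: TernarySystem
    axis: Axis
    table: pd.DataFrame

    @property
    def grid(self) -> np.ndarray:
        return self.table["l_axis_nM"].to_numpy()

    def to_csv(self, path_or_buf) -> None:
        """Write the curve as CSV with a '#' metadata header recording the system."""
        s = self.system
        header = (
            f"# ternaq binding curve; axis={self.axis}\n"
            f"# k_c1_nM={s.k_c1} k_t1_nM={s.k_t1} alpha={s.alpha} "
            f"c_tot_nM={s.c_tot} t_tot_nM={s.t_tot}\n"
        )
        body = self.table.to_csv(index=False)
        if hasattr(path_or_buf, "write"):
            path_or_buf.write(header + body)
        else:
            with open(path_or_buf, "w") as fh:
                fh.write(header + body)

    @staticmethod
    def read_csv(path_or_buf) -> pd.DataFrame:
        """Read back a curve CSV (metadata comment lines are skipped)."""
        if isinstance(path_or_buf, str) and "\n" in path_or_buf:
            path_or_buf = io.StringIO(path_or_buf)
        return pd.read_csv(path_or_buf, comment="#")


def simulate_curve(system: TernarySystem, grid_spec: GridSpec) -> BindingCurve:
    """Simulate the equilibrium over a log-spaced ligand grid.

    Each grid point is solved independently: on the ``total_ligand`` axis the
    free ligand is first recovered by the monotone inversion, on the
    ``free_ligand`` axis the species equations are evaluated directly.
    """
    rows = []
    for x in grid_spec.values():
        s = _state_at(system, x, grid_spec.axis)
        rows.append(
            (
                x,
                s.l_free,
                s.c_free,
                s.t_free,
                s.cl,
                s.tl,
                s.clt,
                (s.cl + s.clt) / system.c_tot * 100.0 if system.c_tot > 0 else np.nan,
                (s.tl + s.clt) / system.t_tot * 100.0 if system.t_tot > 0 else np.nan,
                s.clt / system.t_tot * 100.0 if system.t_tot > 0 else np.nan,
                s.clt / system.c_tot * 100.0 if system.c_tot > 0 else np.nan,
            )
        )
    table = pd.DataFrame(rows, columns=_CSV_COLUMNS)
    return BindingCurve(system=system, axis=grid_spec.axis, table=table)


@dataclass(frozen=True)
class Ec50Result:
    """Half-maximal concentration of a monitored bound fraction.

    ``plateau`` is the asymptotic bound fraction (0..1] used as the 100%
    reference; the EC50 is where the curve crosses half of *that* plateau,
    which keeps the definition meaningful for systems that never reach 100%.
    In this mass-action model excess ligand always drives the monitored
    protein fully into its binary complex, so the asymptote is exactly 1;
    the bracket saturation check verifies the search interval actually
    reaches it.
    """

    ec50: float
    axis: Axis
    monitor: Monitor
    plateau: float
    bracket: tuple[float, float]


def _default_bracket(system: TernarySystem, monitor: Monitor) -> tuple[float, float]:
    """A bracket wide enough for any cooperativity-shifted transition.

    Cooperativity can shift the EC50 below the monitored binary K_d by at
    most ~alpha-fold, and depletion can push it above by the protein totals.
    """
    k_mon = system.k_c1 if monitor == "c_bound" else system.k_t1
    lo = 1e-4 * k_mon / max(system.alpha, 1.0)
    lo = min(lo, 1e-3)
    hi = 1e3 * k_mon + 10.0 * (system.c_tot + system.t_tot + 1.0)
    return lo, hi


def ec50(
    system: TernarySystem,
    monitor: Monitor,
    axis: Axis = "total_ligand",
    bracket: tuple[float, float] | None = None,
) -> Ec50Result:
    """EC50 of the monitored bound fraction by continuous-model root finding.

    The bracket top must have saturated — its bound fraction must reach 99%
    of the value at 100x that concentration — otherwise the bracket is
    extended 10-fold up to three times before failing.  Once saturation is
    established the plateau is the model's exact asymptote (1: excess ligand
    always saturates the monitored protein in its binary complex), which
    keeps the analytic limits exact — e.g. the target-free EC50 on the
    free-ligand axis equals K_C1 to machine precision.  The EC50 is the
    bracketed root of ``bound_fraction(x) - plateau/2``.
    """
    if monitor == "c_bound" and system.c_tot == 0:
        raise ValidationError("EC50 of c_bound undefined: c_tot = 0")
    if monitor == "t_bound" and system.t_tot == 0:
        raise ValidationError("EC50 of t_bound undefined: t_tot = 0")
    lo, hi = bracket if bracket is not None else _default_bracket(system, monitor)
    if not (0 < lo < hi):
        raise ValidationError(f"invalid EC50 bracket [{lo}, {hi}]")

    f = lambda x: bound_fraction(system, x, monitor, axis)

    f_hi = f(hi)
    for _ in range(_EXTEND_RETRIES):
        if f_hi >= _SATURATION * f(100.0 * hi):
            break
        hi *= _EXTEND_FACTOR
        f_hi = f(hi)
    else:
        if f_hi < _SATURATION * f(100.0 * hi):
            raise Ec50NotIdentifiableError(
                f"EC50 not identifiable in bracket [{lo}, {hi}] nM: the "
                f"{monitor} curve has not saturated (fraction {f_hi:.4g} at "
                f"{hi:.4g} nM keeps rising)"
            )
    plateau = 1.0  # exact asymptote of every monitored bound fraction
    half = 0.5 * plateau
    if not (f(lo) < half < f_hi):
        raise Ec50NotIdentifiableError(
            f"EC50 not identifiable in bracket [{lo}, {hi}] nM: half-plateau "
            f"crossing not inside the bracket (fractions {f(lo):.4g} .. {f_hi:.4g})"
        )
    root = brentq(lambda x: f(x) - half, lo, hi, rtol=4 * math.ulp(1.0), maxiter=200)
    return Ec50Result(ec50=root, axis=axis, monitor=monitor, plateau=plateau, bracket=(lo, hi))
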