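"""Biochemical-well (closed) vs cellular (open) target occupancy.

A biochemical assay is a closed system: the dosed ligand is shared between
free ligand and all bound species, so the free concentration that drives
binding can fall far below the dose.  A cellular assay with a large medium
reservoir (well volume ~1000x the total cell volume) behaves as an open
system at steady state: the reservoir pins the free intracellular ligand at
the applied well concentration, [L_well_tot] ~ [L_well_unbound] ~
[L_cell_unbound,ss], and no depletion correction applies.  The same dose can
therefore produce very different occupancies in the two regimes, which is
why ranking compounds on closed-system potency alone can mislead.

Occupancy is reported as %CLT_bound = [CLT]/[T_tot] * 100, the share of
target engaged in the ternary complex.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import pandas as pd

from .curves import GridSpec
from .equilibrium import (
    TernarySystem,
    state_from_free_ligand,
    state_from_total_ligand,
    total_ligand_of_free,
)
from .errors import ValidationError

__all__ = ["Mode", "AssayContext", "occupancy", "ltot_for_target_free", "occupancy_curve"]

Mode = Literal["closed", "open"]


@dataclass(frozen=True)
class AssayContext:
    """A system plus the assay regime and the applied ligand concentration.

    In ``closed`` mode `applied` is the total ligand in the well; in ``open``
    mode it is the well concentration, taken as the free intracellular
    concentration at steady state.
    """

    mode: Mode
    system: TernarySystem
    applied: float

    def __post_init__(self) -> None:
        if self.mode not in ("closed", "open"):
            raise ValidationError(f"unknown assay mode {self.mode!r}")
        if self.applied < 0:
            raise ValidationError(f"applied ligand must be non-negative, got {self.applied}")


def occupancy(context: AssayContext) -> float:
    """Percent of total target bound in the ternary complex.

    Closed mode resolves the free ligand from the dosed total first; open
    mode evaluates the species equations directly at the applied (= free)
    concentration.
    """
    system = context.system
    if system.t_tot <= 0:
        raise ValidationError("occupancy undefined: t_tot = 0")
    if context.mode == "closed":
        state = state_from_total_ligand(system, context.applied)
    else:
        state = state_from_free_ligand(system, context.applied)
    return state.clt / system.t_tot * 100.0


def ltot_for_target_free(system: TernarySystem, l_free_target: float) -> float:
    """Closed-system dose (total ligand, nM) that realizes a desired free level.

    This is the forward total-of-free map; it quantifies how much more
    compound a biochemical well needs than an open cellular system to expose
    the proteins to the same free ligand concentration.
    """
    if l_free_target < 0:
        raise ValidationError(f"l_free_target must be non-negative, got {l_free_target}")
    return total_ligand_of_free(system, l_free_target)


def occupancy_curve(system: TernarySystem, mode: Mode, grid_spec: GridSpec) -> pd.DataFrame:
    """Occupancy over a grid of applied concentrations.

    Returns a DataFrame with columns ``applied_nM`` and ``occupancy_pct``.
    At equal applied concentration up to the hook maximum sqrt(K_C1*K_T1)
    the open-system occupancy is never below the closed-system one, because
    the closed system loses ligand to binding and CLT increases with free
    ligand there.  Past the hook the inequality can reverse: the closed
    system's depleted free ligand sits closer to the CLT peak.
    """
    rows = [
        (x, occupancy(AssayContext(mode=mode, system=system, applied=float(x))))
        for x in grid_spec.values()
    ]
    return pd.DataFrame(rows, columns=["applied_nM", "occupancy_pct"])
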