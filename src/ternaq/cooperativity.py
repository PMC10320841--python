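"""Apparent vs intrinsic cooperativity, alpha retrieval, compound taxonomy.

The EC50 shift of a monitored bound-fraction curve caused by adding the
counter protein is the *apparent* cooperativity.  It depends on protein
concentrations and on which protein is monitored — for one and the same
system the shift seen through the weak binder can exceed the shift seen
through the strong binder by orders of magnitude — whereas the *intrinsic*
cooperativity alpha is a compound constant.  Given both binary dissociation
constants and the protein totals, alpha is the single remaining unknown and
can be recovered from one measured EC50 (or fitted to whole curves); with
only one binary K_d known, the shift is not attributable to cooperativity
alone and the problem is not identifiable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq, minimize_scalar

from .curves import Monitor, bound_fraction, ec50
from .equilibrium import TernarySystem, validate_system
from .errors import AlphaRangeError, IdentifiabilityError, ValidationError

__all__ = [
    "AlphaFit",
    "UNMEASURABLE",
    "resolve_kd",
    "apparent_cooperativity",
    "apparent_cooperativity_from_ec50s",
    "fit_alpha_from_ec50",
    "fit_alpha_from_curve",
    "classify_compound",
    "read_observed_curve",
]

#: sentinel for a binary K_d too weak to measure (> 250 uM); mapped to
#: `kd_ceiling` (default 1e6 nM = 1 mM) wherever a number is required
UNMEASURABLE = "unmeasurable"

_LOG_ALPHA_BRACKET = (-6.0, 9.0)

#: taxonomy thresholds: "significant" binary binding, and the minimum
#: cooperativity for each glue-like class
SIGNIFICANT_KD_NM = 1000.0
COOPERATIVE_ALPHA = 10.0
GLUE1_ALPHA = 100.0
GLUE2_ALPHA = 1000.0


def resolve_kd(kd: float | str, kd_ceiling: float = 1e6) -> tuple[float, bool]:
    """Map a K_d input to a number; the sentinel ``UNMEASURABLE`` (or any
    string) becomes `kd_ceiling`.  Returns (value_nM, was_sentinel)."""
    if isinstance(kd, str):
        if kd.strip().lower() in (UNMEASURABLE, ">250um", ">250 um"):
            return float(kd_ceiling), True
        raise ValidationError(f"unrecognized K_d value {kd!r}")
    return float(kd), False


@dataclass(frozen=True)
class AlphaFit:
    """Result of an intrinsic-cooperativity estimation."""

    alpha_hat: float
    monitor: Monitor
    bracket: tuple[float, float]
    converged: bool
    iterations: int
    target_ec50: float | None = None
    achieved_ec50: float | None = None
    residual_norm: float | None = None
    kd_ceiling_applied: bool = False

    def to_dict(self) -> dict:
        return {
            "alpha_hat": self.alpha_hat,
            "monitor": self.monitor,
            "bracket": list(self.bracket),
            "converged": self.converged,
            "iterations": self.iterations,
            "target_ec50_nM": self.target_ec50,
            "achieved_ec50_nM": self.achieved_ec50,
            "residual_norm": self.residual_norm,
            "kd_ceiling_applied": self.kd_ceiling_applied,
        }


def apparent_cooperativity(system: TernarySystem, monitor: Monitor) -> float:
    """EC50 ratio of the monitored curve without vs with the counter protein.

    Both EC50s are computed on the total-ligand axis; the reference curve
    sets the counter protein's total to zero (clean binary control).  Values
    above 1 indicate positive apparent cooperativity (left shift).  Note this
    is the exact model ratio: the binary reference EC50 includes the small
    depletion offset from the monitored protein itself (+c_tot/2 for a
    binary Langmuir system), so the ratio can differ at the percent level
    from one formed with the binary K_d in the numerator.
    """
    counter_field = "t_tot" if monitor == "c_bound" else "c_tot"
    reference = system.replace(**{counter_field: 0.0})
    e_ref = ec50(reference, monitor, axis="total_ligand").ec50
    e_obs = ec50(system, monitor, axis="total_ligand").ec50
    return e_ref / e_obs


def apparent_cooperativity_from_ec50s(ec50_without: float, ec50_with: float) -> float:
    """Apparent cooperativity from two measured EC50s (counter absent / present)."""
    if ec50_without <= 0 or ec50_with <= 0:
        raise ValidationError("EC50 values must be positive")
    return ec50_without / ec50_with


def _model_ec50(
    k_c1: float, k_t1: float, c_tot: float, t_tot: float, alpha: float, monitor: Monitor
) -> float:
    system = validate_system(k_c1, k_t1, alpha, c_tot, t_tot)
    return ec50(system, monitor, axis="total_ligand").ec50


def fit_alpha_from_ec50(
    k_c1: float | str,
    k_t1: float | str,
    c_tot: float,
    t_tot: float,
    observed_ec50: float,
    monitor: Monitor = "c_bound",
    ec50_rtol: float = 1e-6,
    kd_ceiling: float = 1e6,
) -> AlphaFit:
    """Retrieve intrinsic alpha from one measured EC50 on the total-ligand axis.

    The model EC50 decreases monotonically in alpha (more cooperativity,
    larger left shift), so the unique alpha matching `observed_ec50` is found
    by bracketed root finding on log10(alpha) over [1e-6, 1e9].  Monotonicity
    is asserted at the bracket ends; an observed EC50 outside the attainable
    range [EC50(alpha→inf), EC50(alpha→0)] raises
    :class:`~ternaq.errors.AlphaRangeError` — the shift cannot be explained
    by cooperativity alone.

    Both binary dissociation constants must be known (possibly as the
    ``UNMEASURABLE`` sentinel, mapped to `kd_ceiling`); with only one known
    the problem is not identifiable and no fit is attempted here.
    """
    if observed_ec50 <= 0:
        raise ValidationError(f"observed_ec50 must be positive, got {observed_ec50}")
    k_c1, s1 = resolve_kd(k_c1, kd_ceiling)
    k_t1, s2 = resolve_kd(k_t1, kd_ceiling)
    ceiling_applied = s1 or s2

    lo_la, hi_la = _LOG_ALPHA_BRACKET
    e_lo = _model_ec50(k_c1, k_t1, c_tot, t_tot, 10.0 ** lo_la, monitor)  # alpha -> 0
    e_hi = _model_ec50(k_c1, k_t1, c_tot, t_tot, 10.0 ** hi_la, monitor)  # alpha -> inf
    if not (e_lo > e_hi):
        raise IdentifiabilityError(
            f"model EC50 is not decreasing in alpha on this system "
            f"(EC50 {e_lo} nM at alpha=1e{lo_la:.0f} vs {e_hi} nM at alpha=1e{hi_la:.0f})"
        )
    if not (e_hi <= observed_ec50 <= e_lo):
        raise AlphaRangeError(
            f"observed EC50 {observed_ec50} nM is outside the range attainable "
            f"by varying cooperativity alone: [{e_hi:.6g}, {e_lo:.6g}] nM",
            attainable_range=(e_hi, e_lo),
        )

    iterations = 0

    def g(la: float) -> float:
        nonlocal iterations
        iterations += 1
        return math.log(_model_ec50(k_c1, k_t1, c_tot, t_tot, 10.0 ** la, monitor)) - math.log(
            observed_ec50
        )

    la_hat = brentq(g, lo_la, hi_la, xtol=1e-12, maxiter=200)
    alpha_hat = 10.0 ** la_hat
    achieved = _model_ec50(k_c1, k_t1, c_tot, t_tot, alpha_hat, monitor)
    converged = abs(achieved - observed_ec50) <= ec50_rtol * observed_ec50
    return AlphaFit(
        alpha_hat=alpha_hat,
        monitor=monitor,
        bracket=(10.0 ** lo_la, 10.0 ** hi_la),
        converged=converged,
        iterations=iterations,
        target_ec50=observed_ec50,
        achieved_ec50=achieved,
        kd_ceiling_applied=ceiling_applied,
    )


def _as_curve_array(curve) -> np.ndarray:
    if isinstance(curve, pd.DataFrame):
        cols = [c for c in ("l_tot_nM", "bound_fraction") if c in curve.columns]
        arr = curve[cols].to_numpy() if len(cols) == 2 else curve.to_numpy()
    else:
        arr = np.asarray(curve, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 3:
        raise ValidationError(
            "an observed curve needs >= 3 (l_tot, bound_fraction) points"
        )
    return arr


def fit_alpha_from_curve(
    k_c1: float | str,
    k_t1: float | str,
    c_tot: float | Sequence[float],
    t_tot: float | Sequence[float],
    curve,
    monitor: Monitor = "c_bound",
    kd_ceiling: float = 1e6,
) -> AlphaFit:
    """Least-squares fit of intrinsic alpha to observed binding-curve points.

    `curve` holds (l_tot_nM, bound_fraction) pairs — an (n, 2) array or a
    DataFrame with those columns.  Several curves measured at different
    protein concentrations are fitted jointly by passing sequences of equal
    length for `c_tot`, `t_tot` and `curve`.  The squared residual between
    observed and model bound fractions (uniform weights) is minimized over
    log10(alpha) on [1e-6, 1e9].
    """
    k_c1, s1 = resolve_kd(k_c1, kd_ceiling)
    k_t1, s2 = resolve_kd(k_t1, kd_ceiling)

    if np.ndim(c_tot) == 0:
        datasets = [(float(c_tot), float(t_tot), _as_curve_array(curve))]
    else:
        if not (len(c_tot) == len(t_tot) == len(curve)):
            raise ValidationError("c_tot, t_tot and curve sequences must align")
        datasets = [
            (float(c), float(t), _as_curve_array(cv))
            for c, t, cv in zip(c_tot, t_tot, curve)
        ]

    spread = max(float(arr[:, 1].max() - arr[:, 1].min()) for _, _, arr in datasets)
    if spread < 0.1:
        raise IdentifiabilityError(
            f"observed curve spans only {spread:.3f} bound-fraction units; all "
            "points sit on a plateau, so the transition (and alpha) is not constrained"
        )

    evaluations = 0

    def ssr(la: float) -> float:
        nonlocal evaluations
        evaluations += 1
        total = 0.0
        for c, t, arr in datasets:
            system = validate_system(k_c1, k_t1, 10.0 ** la, c, t)
            for l_tot, obs in arr:
                total += (bound_fraction(system, l_tot, monitor) - obs) ** 2
        return total

    lo_la, hi_la = _LOG_ALPHA_BRACKET
    res = minimize_scalar(
        ssr, bounds=(lo_la, hi_la), method="bounded", options={"xatol": 1e-10}
    )
    alpha_hat = 10.0 ** res.x
    return AlphaFit(
        alpha_hat=alpha_hat,
        monitor=monitor,
        bracket=(10.0 ** lo_la, 10.0 ** hi_la),
        converged=bool(res.success),
        iterations=evaluations,
        residual_norm=math.sqrt(res.fun),
        kd_ceiling_applied=s1 or s2,
    )


def classify_compound(
    k_c1: float | str,
    k_t1: float | str,
    alpha: float,
    kd_ceiling: float = 1e6,
) -> str:
    """Assign a ternary-complex compound to the bifunctional/glue taxonomy.

    "Significant" binary binding means K_d < 1 uM.  Both arms significant
    gives a bifunctional (cooperative bifunctional when alpha > 10); only the
    chaperone arm significant with alpha > 100 gives a type-I molecular glue;
    neither arm significant with alpha > 1000 a type-II molecular glue.
    Everything else — including target-only binders — is 'unclassified/hybrid',
    reflecting that real compounds often sit between the idealized classes.
    The classification is total: every valid (k_c1, k_t1, alpha) receives
    exactly one label.
    """
    k_c1, _ = resolve_kd(k_c1, kd_ceiling)
    k_t1, _ = resolve_kd(k_t1, kd_ceiling)
    if k_c1 <= 0 or k_t1 <= 0:
        raise ValidationError("dissociation constants must be positive")
    if alpha <= 0:
        raise ValidationError("alpha must be positive")
    c_sig = k_c1 < SIGNIFICANT_KD_NM
    t_sig = k_t1 < SIGNIFICANT_KD_NM
    if c_sig and t_sig:
        return "cooperative bifunctional" if alpha > COOPERATIVE_ALPHA else "bifunctional"
    if c_sig and not t_sig and alpha > GLUE1_ALPHA:
        return "molecular glue I"
    if not c_sig and not t_sig and alpha > GLUE2_ALPHA:
        return "molecular glue II"
    return "unclassified/hybrid"


def read_observed_curve(path_or_buf) -> pd.DataFrame:
    """Read an observed curve CSV with columns l_tot_nM, bound_fraction."""
    df = pd.read_csv(path_or_buf, comment="#")
    missing = {"l_tot_nM", "bound_fraction"} - set(df.columns)
    if missing:
        raise ValidationError(f"observed curve CSV lacks columns: {sorted(missing)}")
    return df[["l_tot_nM", "bound_fraction"]]
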