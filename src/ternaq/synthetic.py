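"""Synthetic noisy binding curves for demos and parameter-recovery studies.

The generator evaluates the deterministic equilibrium model on a ligand grid
and adds independent Gaussian noise to the monitored bound fraction,
truncated to [0, 1] — the simplest defensible stand-in for a measured
%C_bound/%T_bound dilution series.  All randomness is seeded; the model
itself is fully deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .curves import GridSpec, Monitor, bound_fraction
from .equilibrium import TernarySystem
from .errors import ValidationError

__all__ = ["NoisySyntheticCurve", "generate_noisy_curve"]


@dataclass(frozen=True)
class NoisySyntheticCurve:
    """A seeded noisy realization of a monitored binding curve."""

    system: TernarySystem
    monitor: Monitor
    grid: np.ndarray
    true_fraction: np.ndarray
    observed_fraction: np.ndarray
    sigma: float
    seed: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "l_tot_nM": self.grid,
                "bound_fraction": self.observed_fraction,
                "true_fraction": self.true_fraction,
            }
        )

    def observed(self) -> np.ndarray:
        """(n, 2) array of (l_tot, bound_fraction) pairs for the fitting API."""
        return np.column_stack([self.grid, self.observed_fraction])

    def to_csv(self, path_or_buf) -> None:
        s = self.system
        header = (
            f"# ternaq synthetic noisy curve; monitor={self.monitor} "
            f"sigma={self.sigma} seed={self.seed}\n"
            f"# k_c1_nM={s.k_c1} k_t1_nM={s.k_t1} alpha={s.alpha} "
            f"c_tot_nM={s.c_tot} t_tot_nM={s.t_tot}\n"
        )
        body = self.to_frame().to_csv(index=False)
        if hasattr(path_or_buf, "write"):
            path_or_buf.write(header + body)
        else:
            with open(path_or_buf, "w") as fh:
                fh.write(header + body)


def generate_noisy_curve(
    system: TernarySystem,
    grid_spec: GridSpec,
    sigma: float,
    seed: int,
    monitor: Monitor = "c_bound",
) -> NoisySyntheticCurve:
    """Simulate a monitored curve and add truncated Gaussian noise.

    Bit-for-bit reproducible for a fixed (system, grid, sigma, seed);
    ``sigma = 0`` returns the model values exactly.
    """
    if sigma < 0:
        raise ValidationError(f"sigma must be non-negative, got {sigma}")
    grid = grid_spec.values()
    truth = np.array(
        [bound_fraction(system, float(x), monitor, grid_spec.axis) for x in grid]
    )
    if sigma == 0:
        observed = truth.copy()
    else:
        rng = np.random.default_rng(seed)
        observed = np.clip(truth + rng.normal(0.0, sigma, size=truth.shape), 0.0, 1.0)
    return NoisySyntheticCurve(
        system=system,
        monitor=monitor,
        grid=grid,
        true_fraction=truth,
        observed_fraction=observed,
        sigma=float(sigma),
        seed=int(seed),
    )
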