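"""Shared fixtures: the worked-example systems and an independent equilibrium oracle."""

import numpy as np
import pytest
from hypothesis import HealthCheck, settings
from scipy.optimize import brentq

from ternaq import TernarySystem

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=60,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def biochemical_system() -> TernarySystem:
    """Strong chaperone binder, weak target binder, chaperone in excess:
    the canonical biochemical-assay parameterization."""
    return TernarySystem(k_c1=100, k_t1=1e5, alpha=100, c_tot=1000, t_tot=5)


@pytest.fixture
def chaperone_monitored_system() -> TernarySystem:
    """Dilute chaperone monitored against a large target excess (alpha=200)."""
    return TernarySystem(k_c1=100, k_t1=1e5, alpha=200, c_tot=5, t_tot=1000)


@pytest.fixture
def target_monitored_system() -> TernarySystem:
    """Same affinities/cooperativity, monitored through the weak-binding target."""
    return TernarySystem(k_c1=100, k_t1=1e5, alpha=200, c_tot=1000, t_tot=5)


@pytest.fixture
def noncooperative_system() -> TernarySystem:
    """Equal affinities, alpha=1: substantial CLT forms but no EC50 shift."""
    return TernarySystem(k_c1=100, k_t1=100, alpha=1, c_tot=5, t_tot=1000)


@pytest.fixture
def binary_system() -> TernarySystem:
    """No target present: pure chaperone-ligand Langmuir binding."""
    return TernarySystem(k_c1=100, k_t1=1e5, alpha=200, c_tot=5, t_tot=0)


@pytest.fixture
def hook_demo_system() -> TernarySystem:
    """Cooperative bifunctional at biophysical-assay protein excess; shows a
    strongly distorted total-ligand hook."""
    return TernarySystem(k_c1=100, k_t1=1e4, alpha=16, c_tot=25000, t_tot=10000)


def clt_oracle(system: TernarySystem, l_free: float) -> float:
    """Independent ternary-complex solve: Eqs for the coupled equilibrium are
    solved jointly by bracketed root finding on the unreduced mass-action
    residual g(x) = alpha*l*C(x)*T(x)/(K_C1*K_T1) - x on [0, min(totals)],
    then Newton-polished to near machine precision.  Never uses the
    production quadratic.
    """
    if l_free <= 0 or system.c_tot <= 0 or system.t_tot <= 0:
        return 0.0
    kc1, kt1, a = system.k_c1, system.k_t1, system.alpha
    ct, tt = system.c_tot, system.t_tot
    dc = 1.0 + l_free / kc1
    dt = 1.0 + l_free / kt1
    scale = a * l_free / (kc1 * kt1)

    def g(x: float) -> float:
        return scale * (ct - x) / dc * (tt - x) / dt - x

    m = min(ct, tt)
    x = brentq(g, 0.0, m, rtol=4 * np.finfo(float).eps, maxiter=300)
    for _ in range(8):  # Newton polish; g' < 0 everywhere on the bracket
        gp = scale * (-(tt - x) - (ct - x)) / (dc * dt) - 1.0
        step = g(x) / gp
        x_new = min(max(x - step, 0.0), m)
        if x_new == x:
            break
        x = x_new
    return x


def random_systems(n: int, seed: int):
    """Log-uniform random systems + free-ligand values spanning the domain."""
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        system = TernarySystem(
            k_c1=10 ** rng.uniform(0, 6),
            k_t1=10 ** rng.uniform(0, 6),
            alpha=10 ** rng.uniform(-2, 4),
            c_tot=10 ** rng.uniform(-1, 5),
            t_tot=10 ** rng.uniform(-1, 5),
        )
        l_free = 10 ** rng.uniform(-3, 7)
        out.append((system, l_free))
    return out
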