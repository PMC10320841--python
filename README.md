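# ternaq

Equilibrium modelling of cooperative **ternary complexes** — the
chaperone–ligand–target (C·L·T) assemblies formed by PROTACs, molecular
glues and other proximity-inducing compounds.

`ternaq` is for discovery scientists and modellers who need to connect what
a binding assay *measures* (EC50s of bound-fraction curves, dose–response
tables) to what the compound *is* (binary affinities and intrinsic
cooperativity) and to what it will *do* in a cell (target occupancy).

## The model

Two binary pathways lead to the ternary complex:

    C + L ⇌ CL   (K_C,1)        CL + T ⇌ CLT   (K_T,2 = K_T,1/α)
    T + L ⇌ TL   (K_T,1)        TL + C ⇌ CLT   (K_C,2 = K_C,1/α)

The intrinsic cooperativity **α = K_C,1/K_C,2 = K_T,1/K_T,2** is a
compound constant, identical along both pathways, so at equilibrium

    [CLT]·K_C,1·K_T,1 = α·[C]·[L]·[T].

Substituting the conservation relations [C_tot] = [C]+[CL]+[CLT] and
[T_tot] = [T]+[TL]+[CLT] turns this into a quadratic in [CLT] at known
*free* ligand [L], with exactly one physical root.  A closed (biochemical)
system doses *total* ligand instead; `ternaq` recovers [L] by inverting the
strictly increasing map [L_tot] = [L]+[CL]+[TL]+[CLT] with bracketed root
finding.  On top of this core the package provides:

- **Hook effect** — [CLT] versus [L] is bell-shaped and geometrically
  symmetric about √(K_C,1·K_T,1); against [L_tot] it is distorted by
  depletion.
- **EC50s and apparent cooperativity** — half-plateau points of %C_bound =
  ([CL]+[CLT])/[C_tot] or %T_bound curves, and the EC50 ratio without/with
  the counter protein.
- **Intrinsic α retrieval** — invert one measured EC50 (or least-squares
  fit whole curves, singly or jointly) for α, given both binary K_d's.
- **Biochemical → cellular translation** — closed-well occupancy versus
  open-system occupancy, where a large medium reservoir pins the free
  intracellular ligand at the applied well concentration.
- **Compound taxonomy** — bifunctional / cooperative bifunctional /
  molecular glue I & II by binary-arm significance (K_d < 1 µM) and α.

**All concentrations and dissociation constants are in nM.**

## A worked example

A characteristic biochemical assay: K_C,1 = 100 nM, K_T,1 = 100 000 nM,
α = 100, [C_tot] = 1000 nM, [T_tot] = 5 nM.

```python
from ternaq import (AssayContext, TernarySystem, free_ligand_of_total, occupancy)

system = TernarySystem(k_c1=100, k_t1=1e5, alpha=100, c_tot=1000, t_tot=5)

free_ligand_of_total(system, 1000.0)                 # 269.82 nM
free_ligand_of_total(system, 100.0)                  # 9.86 nM
occupancy(AssayContext("closed", system, 100.0))     # 8.23 (% target in CLT)
occupancy(AssayContext("open",   system, 100.0))     # 33.27 (%)
```

Dosing 1000 nM into the well leaves only ~270 nM free — the chaperone
excess soaks up the rest.  At a 100 nM dose the closed well engages 8.2% of
the target, while a cell exposed to the same 100 nM well concentration
(open system, no depletion) engages 33.3%: ranking compounds on biochemical
numbers alone misestimates cellular engagement severalfold.

EC50 shifts from the same affinities with α = 200:

```python
from ternaq import apparent_cooperativity, ec50, fit_alpha_from_ec50

c_mon = TernarySystem(100, 1e5, 200, c_tot=5, t_tot=1000)   # monitor chaperone
ec50(c_mon, "c_bound").ec50                  # 36.21 nM (binary baseline ~100)
apparent_cooperativity(c_mon, "c_bound")     # 2.83

t_mon = TernarySystem(100, 1e5, 200, c_tot=1000, t_tot=5)   # monitor target
ec50(t_mon, "t_bound").ec50                  # 602.3 nM (baseline ~100 000)
apparent_cooperativity(t_mon, "t_bound")     # 166.0

fit_alpha_from_ec50(100, 1e5, 5, 1000, observed_ec50=36.21).alpha_hat  # 200.0
```

Same compound, same α — but the apparent (EC50-shift) cooperativity is 2.8
through the strong binder and 166 through the weak one.  Given both binary
K_d's, one measured EC50 recovers the intrinsic α.

The `examples/` directory holds one short script per capability
(`free_ligand_inversion.py`, `hook_effect.py`, `ec50_shift_and_alpha.py`,
`occupancy_translation.py`, `fit_alpha_from_noisy_curve.py`,
`classify_compounds.py`); each prints the numbers above with a line on what
they mean.  A thin CLI mirrors the library:

```bash
ternaq free-ligand --kc1 100 --kt1 100000 --alpha 100 --ctot 1000 --ttot 5 --ltot 1000
# 269.823
ternaq classify --kc1 100 --kt1 1000000 --alpha 500
# molecular glue I
```

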