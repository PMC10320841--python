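# Methods

## Model and assumptions

`ternaq` treats ternary complex formation as a closed mass-action
equilibrium of six species — free ligand L, free chaperone C, free target
T, the binary complexes CL and TL, and the ternary complex CLT — linked by
four binding reactions (two per pathway).  The assumptions are:

- **Equilibrium only.** No kinetics, no synthesis/degradation, no
  downstream events (e.g. ubiquitination in a degrader context).  The model
  describes the instantaneous equilibrium at fixed totals.
- **Path independence.** The cooperativity α is the same along both
  assembly routes (C-first and T-first), which is a thermodynamic identity
  for a closed cycle.  This collapses the four dissociation constants to
  three parameters: K_C,1, K_T,1, α.
- **No direct C–T association.** The pathway through a pre-formed
  chaperone–target dimer subsequently stabilized by the ligand is outside
  the model's scope, as are tracer/probe competition equilibria.
- **Monomeric species.** Protein totals are monomer concentrations;
  oligomerization of C or T is not corrected for.

### Parameters (all concentrations in nM)

| parameter | meaning | typical range |
|---|---|---|
| `k_c1` | K_d of L to free C | 1–10⁵ nM |
| `k_t1` | K_d of L to free T | 1–10⁶ nM (weak arms can be unmeasurable) |
| `alpha` | intrinsic cooperativity K_x,1/K_x,2 | 10⁻²–10⁴; >1 positive, <1 negative |
| `c_tot`, `t_tot` | total protein | assay- or cell-dependent |

Derived constants: K_C,2 = K_C,1/α, K_T,2 = K_T,1/α, and the ternary
potency constant K_CLT = K_C,1·K_T,2 = K_C,1·K_T,1/α.  α is accepted on
(0, ∞); only α ≤ 0 is rejected, since negative cooperativity is physically
meaningful.

## Core computation

At known free ligand l, substituting the conservation relations into the
mass-action condition [CLT]·K_C,1·K_T,1 = α·[C]·[L]·[T] yields

    a·x² − b·x + c = 0,  x = [CLT],
    a = α·l
    b = α·l·(C_tot + T_tot) + K_C,1·K_T,1·(1 + l/K_C,1)(1 + l/K_T,1)
    c = α·l·C_tot·T_tot

whose smaller root is the unique physical solution (the larger always
exceeds min(C_tot, T_tot)).  Numerical choices:

- The root is evaluated as `2c/(b + √(b²−4ac))`, which is free of the
  catastrophic cancellation the textbook formula suffers when `b² ≫ 4ac`
  (weak binding, dilute systems).  Discriminants negative by less than
  10⁻¹⁰·b² are clamped to zero.
- The protein remainders C_tot − [CLT] and T_tot − [CLT] are recovered from
  the factored quadratic (product + difference of the remainders), using
  the conjugate form for the smaller one, so free-protein concentrations
  keep full relative precision even at >99.9999% saturation.  This is what
  lets the mass-balance and pathway-consistency invariants hold to 10⁻⁹
  relative across the whole tested parameter domain.
- Degenerate inputs (l = 0, C_tot = 0 or T_tot = 0) return exact zeros via
  explicit branches, never through the quadratic.

**Total ↔ free ligand.** [L_tot](l) = l + [CL] + [TL] + [CLT] is strictly
increasing, so the inverse is computed with Brent's method on the bracket
[0, L_tot] (the bound ligand is non-negative), at 4-ulp relative tolerance,
200-iteration cap.  Round trips close to 10⁻⁹ relative.

**Hook maximum.** The quadratic's l-dependence is invariant under
l → K_C,1·K_T,1/l, so [CLT](l) is geometrically symmetric about
√(K_C,1·K_T,1) — its single maximum.  `free_ligand_at_max_clt` locates the
maximum by bounded scalar minimization on a log axis (±6 decades around the
symmetry point), asserts agreement with the closed form to 10⁻⁶ relative,
and returns the closed form.  The total-ligand position of the maximum is
the forward map of the free-ligand argmax; the maximum can be extremely
flat on the total axis (for the dilute-chaperone EC50-shift system the CLT
share changes by <1% over a several-fold dose range around it), so dose
optima read from such curves carry little precision.

## EC50s and apparent cooperativity

The monitored signal is a bound fraction, %C_bound = ([CL]+[CLT])/C_tot or
%T_bound = ([TL]+[CLT])/T_tot.  The EC50 is the half-plateau crossing of
the *continuous* model (bracketed root finding), never a grid
interpolation; grids exist only for tables and plots.  In this model excess
ligand always drives the monitored protein fully into its binary complex,
so the plateau is exactly 100%; the saturation check (bound fraction at the
bracket top must reach 99% of its value at 100× that concentration, with
three automatic 10× bracket extensions) only verifies that the search
bracket actually covers the transition.  Using the exact asymptote keeps
the analytic limits sharp: with no target and on the free-ligand axis the
EC50 equals K_C,1 to machine precision; on the total-ligand axis it is
K_C,1 + C_tot/2 (the classic depletion offset).

Apparent cooperativity is the EC50 ratio *without* versus *with* the
counter protein, both on the total-ligand axis, the reference obtained by
setting the counter-protein total to zero.  Because the reference EC50
carries the +C_tot/2 depletion offset, the exact ratio can differ at the
percent level from a ratio formed with the binary K_d as numerator; an
overload accepts two measured EC50s directly.  Apparent cooperativity is
concentration- and monitor-dependent: it approaches the intrinsic α only
for a dilute monitored protein under saturating counter-protein excess
(verified numerically in the tests), and monitoring through the weaker
binary arm always shows the larger shift.

## Retrieving intrinsic α

`fit_alpha_from_ec50` exploits that the model EC50 decreases monotonically
in α: a bracketed root find on log₁₀α over [10⁻⁶, 10⁹] matches the observed
EC50 to 10⁻⁶ relative.  Monotonicity is asserted at the bracket endpoints;
an observed EC50 outside the attainable range [α→∞ floor, α→0 ceiling]
raises an error reporting that range — the shift cannot be explained by
cooperativity alone.  Both binary K_d's are required inputs: with only one
known, an EC50 shift is ambiguous between cooperativity and direct binding,
and the package deliberately refuses to fit the two jointly.  Unmeasurably
weak arms may be passed as the sentinel `"unmeasurable"`, mapped to a
configurable 10⁶ nM ceiling and flagged in the result.

`fit_alpha_from_curve` minimizes the uniform-weight sum of squared
residuals between observed and model bound fractions over log₁₀α (bounded
scalar minimization, 10⁻¹⁰ log-units tolerance), optionally across several
curves at different protein concentrations jointly.  Curves whose observed
fractions span less than 0.1 are rejected as plateau-only (no transition,
no information on α).

## Synthetic data

`generate_noisy_curve` evaluates the deterministic model on a log-spaced
dilution series and adds i.i.d. Gaussian noise to the bound fraction,
truncated to [0, 1].  Defaults used in the recovery studies: the
dilute-chaperone EC50-shift system (K_C,1 = 100 nM, K_T,1 = 10⁵ nM,
α = 200, C_tot = 5 nM, T_tot = 1000 nM), a 12-point series from 1 nM to
100 µM, σ = 0.02 — a 2% fraction error typical of a well-behaved plate
assay.  The generator is seeded and bit-for-bit reproducible.  It emulates
only measurement noise: real curves additionally carry pipetting-correlated
errors, baseline/plateau miscalibration and protein-activity uncertainty,
so passing recovery tests here demonstrates identifiability under the
stated noise model, not robustness to systematic error.  Under these
conditions the median α recovery error across 50 seeded replicates is
within 15% of truth.

## Closed vs open systems

The closed mode conserves total ligand (biochemical well).  The open mode
implements the steady-state infinite-reservoir approximation exactly: free
intracellular ligand equals the applied well concentration (valid when the
well volume exceeds the cellular volume by ~10³ and uptake has reached
steady state without metabolic loss); no uptake/efflux parameters are
modelled.  Cellular protein totals must be supplied as per-cell
aqueous-volume concentrations; converting copies/cell is the caller's
responsibility.  Below the hook maximum the open system's occupancy always
dominates the closed system's at equal applied concentration; past the
maximum the inequality can reverse, because the closed system's depleted
free ligand lies closer to the CLT peak — both behaviours are asserted in
the tests.  Matching doses through the free-ligand map
(`ltot_for_target_free`) makes the two regimes agree identically.

## Known limitations

- No C–T pre-association pathway; compounds whose complexes assemble
  through a protein–protein interface first are outside scope.
- Equilibrium only: time-to-steady-state, uptake kinetics and metabolic
  stability are validity conditions, not model terms.
- EC50-based α retrieval assumes the measured curve is an equilibrium
  bound fraction of a single monitored protein; mixed or kinetic readouts
  need the curve-fitting route with appropriate caution.
- Printed three-significant-figure values quoted in the README are
  roundings of the exact model outputs; derived ratios of rounded values
  (e.g. an apparent cooperativity quoted as 100/37 ≈ 2.7) can differ by a
  few percent from the exact model ratio (2.83).
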