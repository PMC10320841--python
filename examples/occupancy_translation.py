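"""Translating biochemical potency into cellular target occupancy.

A biochemical well is a closed system (the dose is depleted by binding); a
cell bathed in a large medium reservoir is open (free intracellular ligand
is pinned at the well concentration at steady state).  The same nominal dose
can therefore engage very different amounts of target.
"""

from ternaq import AssayContext, TernarySystem, occupancy

system = TernarySystem(k_c1=100, k_t1=1e5, alpha=100, c_tot=1000, t_tot=5)
applied = 100.0  # nM

closed = occupancy(AssayContext("closed", system, applied))
open_ = occupancy(AssayContext("open", system, applied))

print(f"applied ligand: {applied:.0f} nM")
print(f"  closed system (biochemical well): {closed:5.1f}% of target in CLT")
print(f"  open system   (cellular, steady state): {open_:5.1f}%")
print(
    "\nThe well's chaperone excess leaves only ~10 nM free ligand, while the\n"
    "cell sees the full 100 nM: the cellular assay engages ~4x more target\n"
    "at the same dose. Ranking compounds on closed-system numbers alone\n"
    "can therefore mislead."
)
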