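"""The bifunctional / molecular-glue taxonomy.

Compounds that induce ternary complexes are classified by whether each
binary arm binds significantly (K_d < 1 uM) and how much of the complex's
stability comes from cooperativity.
"""

from ternaq import UNMEASURABLE, classify_compound

cases = [
    ("classic PROTAC-like bifunctional", 100, 500, 1),
    ("cooperative bifunctional", 100, 500, 50),
    ("glue with chaperone-arm anchor", 100, 3e5, 500),
    ("pure glue, neither arm measurable", UNMEASURABLE, UNMEASURABLE, 5000),
    ("weak target arm, modest alpha", 100, 3e5, 5),
]

for name, k_c1, k_t1, alpha in cases:
    label = classify_compound(k_c1, k_t1, alpha)
    print(f"{name:38s} K_C1={k_c1!s:>12} K_T1={k_t1!s:>12} alpha={alpha:<6g} -> {label}")

print(
    "\n'unmeasurable' arms are mapped to a 1 mM ceiling; anything between the\n"
    "idealized classes reports as unclassified/hybrid."
)
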