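"""Build a binding-specificity model (PWM) from per-mutant K_D measurements.

Measuring the consensus plus all 3N single-base variants determines the PWM
without motif alignment: column probabilities are proportional to 1/K_D.
"""

import numpy as np

from hipfa.specificity import (
    KdTable,
    enumerate_point_mutants,
    information_content,
    pwm_from_kds,
)

consensus = "TAATCC"
rng = np.random.default_rng(5)
variants = {
    (pos, base): float(round(10 ** rng.uniform(0.5, 2.2), 1))
    for pos, base, _ in enumerate_point_mutants(consensus)
}
table = KdTable(consensus=consensus, consensus_kd=2.0, variants=variants)

pwm = pwm_from_kds(table)
print(f"consensus {consensus}: K_D = {table.consensus_kd} nM, "
      f"{len(variants)} single-base variants measured")
print("\npos    A      C      G      T")
for i, row in enumerate(pwm.matrix):
    print(f"{i:>3}  " + "  ".join(f"{p:.3f}" for p in row))
print(f"\ninformation content: {information_content(pwm):.2f} bits")
print(
    "\nEach column is the affinity-weighted base preference at one position;\n"
    "the information content summarizes how sharply the factor discriminates\n"
    "against mutations (2 bits per position would be absolute specificity)."
)
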