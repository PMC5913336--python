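"""Measure a picomolar affinity with the conventional 12-point dilution series.

Below ~0.5 nM the in-gel gradient cannot resolve K_D, so very strong binders
are titrated conventionally: the printed 12-concentration design is simulated
and fitted with the same competition model.
"""

from hipfa.binding import FitOptions, fit_titration
from hipfa.simulate import simulate_dilution_series

curve, truth = simulate_dilution_series(
    0.05, kd1_nM=1.0, rt_nM=20.0, lst_nM=1.0, noise_rel_sd=0.001, seed=3
)
result = fit_titration(curve, kd1=1.0, cfg=FitOptions(nominal_rt_nM=20.0))

print("concentration series (nM):", [p[0] for p in curve.points])
print(f"true K_D   : {truth['kd2_nM'] * 1000:.1f} pM")
print(f"fitted K_D : {result.kd2 * 1000:.1f} pM  (active TF {result.rt:.1f} nM)")
print(
    "\nA 50 pM dissociation constant -- the strongest affinity reported for\n"
    "the Cad consensus -- is recovered from twelve equilibrium points."
)
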