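"""Predict TF occupancy along a sequence and score it against known peaks.

A PWM is scanned over a synthetic region with planted binding sites, site
strengths are weighted by chromatin accessibility, smoothed with a gamma
kernel mimicking ChIP fragment lengths, and the per-base profile is scored
with a precision-recall sweep against the true site neighborhoods.
"""

import numpy as np

from hipfa.occupancy import GammaKernel, evaluate_regions
from hipfa.specificity import KdTable, enumerate_point_mutants, pwm_from_kds

consensus = "TAATCC"
rng = np.random.default_rng(6)
variants = {
    (pos, base): float(10 ** rng.uniform(1.2, 2.5))
    for pos, base, _ in enumerate_point_mutants(consensus)
}
pwm = pwm_from_kds(KdTable(consensus=consensus, consensus_kd=2.0, variants=variants))

sequence = "".join(rng.choice(list("ACGT"), size=4000))
sites = [500, 1800, 3300]
for s in sites:
    sequence = sequence[:s] + consensus + sequence[s + len(consensus):]
truth = np.zeros(len(sequence), dtype=bool)
for s in sites:
    truth[s - 75 : s + 81] = True

accessibility = np.ones(len(sequence))
accessibility[3200:3500] = 0.0  # the third site sits in closed chromatin

kernel = GammaKernel(shape=2.0, scale_bp=25.0, truncation_bp=100)
curve = evaluate_regions(pwm, [("region", sequence, accessibility, truth)],
                         kernel=kernel, score_threshold=5.0)

f1 = 2 * curve.precision * curve.recall / np.maximum(curve.precision + curve.recall, 1e-12)
best = int(np.argmax(f1))
print(f"planted sites: {sites} (the last one inaccessible)")
print(f"positive-base prevalence (random-guess precision): {truth.mean():.3f}")
print(f"PR AUC: {curve.auc:.3f}")
print(f"best-F1 operating point: precision {curve.precision[best]:.2f}, "
      f"recall {curve.recall[best]:.2f}")
print(
    "\nThe two accessible sites are recovered far above the random-guess\n"
    "baseline; the closed-chromatin site is removed by the accessibility\n"
    "weighting, which caps recall near 2/3 -- exactly what the filter is\n"
    "meant to do."
)
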