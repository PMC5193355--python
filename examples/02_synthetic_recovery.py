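"""Generate a small synthetic cohort and verify the filter recovers the truth.

The generator plants differential loci that satisfy the sib-pair contrast by
construction; the filter should recover them all with no false discoveries
(background loci that would pass by chance are redrawn by default).
"""

import numpy as np

from indelsift.contrast import concordant_differential_filter
from indelsift.simulate import (
    SimulationConfig,
    evaluate_recovery,
    generate_cohort,
    generate_genome,
)

config = SimulationConfig(seed=0, n_background_loci=4000,
                          n_planted_differential=120)
rng = np.random.default_rng(config.seed)
genome = generate_genome(config, rng)
cohort = generate_cohort(config, genome, rng)

matrix = cohort.genotype_matrix()
results, _ = concordant_differential_filter(matrix, cohort.design)
report = evaluate_recovery(results, cohort.truth)

print(f"cohort: {matrix.n_variants} nonredundant loci across 8 samples")
print(f"planted differential loci: {report.n_planted}, "
      f"detected: {report.n_detected}")
print(f"sensitivity: {report.sensitivity:.3f}  "
      f"false-discovery proportion: {report.fdp:.3f}  "
      f"direction accuracy: {report.direction_accuracy:.3f}")
print("\nSensitivity 1 / FDP 0 means the combinatorial filter is exact on a "
      "noise-free cohort; add missing_call_rate or discordant_call_rate to "
      "the config to study its degradation.")
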