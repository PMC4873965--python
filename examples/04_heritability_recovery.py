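"""Parameter recovery of the realized-heritability estimator.

Simulates replicate experiments at several generating heritabilities and
summarizes how well the full pipeline (control-reference residuals ->
response R -> cumulative effective differential S_c -> 2x regression
slope) recovers the truth.  Uses 25 replicates per value here for speed;
the test suite runs 200.
"""

from allomsel.simulate import SimConfig, recovery_study

table = recovery_study(SimConfig(seed=2), [0.0, 0.1, 0.3, 0.5], n_reps=25)
print(table.round(4).to_string(index=False))
print("\nmean_h2 tracks true_h2_d with a small downward bias at high "
      "heritability (selection erodes additive variance); at h2_d = 0 the "
      "estimator is centred on zero, so the pipeline does not manufacture "
      "spurious heritability.")
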