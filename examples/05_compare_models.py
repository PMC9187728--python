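"""Six-model comparison: RBF and GRNN, plain and optimizer-tuned.

Trains RBF, GA-RBF, QGA-RBF, GRNN, GA-GRNN and QGA-GRNN on the identical
split (a reduced design keeps this quick) and prints one row of verification
errors per model.  Spread-optimized variants should match or beat their
fixed-spread counterparts; RBF variants interpolate and typically beat the
kernel-averaging GRNN.
"""

import qgarbf as q

design = q.ExperimentDesign(
    temperatures=(18.0, 21.0, 24.0, 27.0, 30.0),
    ppfd_levels=(1600.0, 1000.0, 600.0, 200.0, 50.0, 10.0, 0.0),
    blue_ratios=(0.1, 0.3, 0.5, 0.7, 0.9),
)
records = q.generate_dataset(design, q.GroundTruthParams(seed=11))
ds = q.split(q.clean(records).groups, 0.8, seed=11)

table = q.compare_models(
    ds,
    qga_config=q.QGAConfig(max_generations=25, stall_generations=8),
    ga_config=q.GAConfig(max_generations=25, stall_generations=8),
    seed=11,
)
cols = ["model", "spread", "mse", "max_abs_error", "mean_abs_error", "r_squared"]
print(table.to_frame()[cols].to_string(index=False, float_format=lambda v: f"{v:.4f}"))
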