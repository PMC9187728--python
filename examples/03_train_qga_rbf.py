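"""Train the QGA-RBF model end to end and evaluate it.

The quantum genetic algorithm searches the spread on [0.1, 10]; each
candidate trains an RBF network (one hidden unit per training sample) and is
scored by verification mean squared error on the normalized scale.  The
report shows agreement between predicted and measured Pn: a slope near 1,
intercept near 0 and R-squared near 1 mean a well-calibrated model.
"""

import qgarbf as q

records = q.generate_dataset(q.ExperimentDesign(), q.GroundTruthParams(seed=1))
ds = q.split(q.clean(records).groups, 0.8, seed=1)

result = q.optimize_spread(ds, "rbf", "qga", opt_config=q.QGAConfig(seed=1))
rep = q.metrics(ds.y_verify, q.predict(result.model, ds.X_verify))

print(f"selected spread : {result.spread:.4f}")
print(f"search MSE (normalized): {result.fitness:.3e} "
      f"after {result.trace.generations} generations")
print(f"verification R2 : {rep.r_squared:.4f}")
print(f"slope/intercept : {rep.slope:.4f} / {rep.intercept:.4f}")
print(f"MAE / MaxAE     : {rep.mean_abs_error:.3f} / {rep.max_abs_error:.3f} umol m-2 s-1")

# predict at an unmeasured condition: 25 C, 700 umol m-2 s-1, 35% blue
pn = q.predict(result.model, [[0.35, 700.0, 25.0]])[0]
print(f"predicted Pn at (35% blue, 700 PPFD, 25 C): {pn:.2f} umol m-2 s-1")
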