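"""Generate a synthetic gas-exchange dataset with the factorial design.

Builds the default campaign (5 temperatures x 15 light levels x 9 blue-light
ratios x 3 replicates) and prints one light-response curve.  The Pn values
are in umol m-2 s-1; at zero light the leaf respires (negative rate), and the
rate saturates as light increases.
"""

import qgarbf as q

design = q.ExperimentDesign()
params = q.GroundTruthParams(seed=42)
records = q.generate_dataset(design, params)

print(f"{len(records)} observations over {design.n_groups} condition groups")
print("\nLight response at 24 C, 30% blue light (replicate 1):")
print(f"{'PPFD':>6}  {'Pn':>7}")
for r in records:
    if r.temperature == 24.0 and r.blue_ratio == 0.3 and r.replicate == 1:
        print(f"{r.par:6.0f}  {r.pn:7.3f}")
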