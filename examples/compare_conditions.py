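"""Detect a differentiation shift between two simulated conditions.

Emulates the control-vs-knockdown comparison: five fields per condition,
generated at ground-truth MDI 0.3 (control-like) and 0.6 (accelerated
differentiation), quantified blind, then compared with a two-sided
unpaired Student t test on the per-image MDI values.
"""

from myoquant import (
    PipelineParams,
    SimulationConfig,
    compare_groups,
    generate_image,
    quantify_micrograph,
)

params = PipelineParams()
conditions = {"control (MDI 0.3)": (0.3, 100), "perturbed (MDI 0.6)": (0.6, 200)}
measured = {}
for name, (target, base_seed) in conditions.items():
    values = []
    for k in range(5):
        image, _ = generate_image(SimulationConfig(seed=base_seed + k, target_mdi=target))
        *_, result = quantify_micrograph(image, params)
        values.append(result.mdi)
    measured[name] = values
    print(f"{name}: per-image MDI = {[round(v, 3) for v in values]}")

a, b = measured.values()
res = compare_groups(b, a)
print(f"\nmean difference = {res.mean_difference:.3f} "
      f"(simulated effect size: 0.30)")
print(f"t = {res.t_statistic:.2f}, p = {res.p_value:.2e} (two-sided unpaired t test)")
print("\nA small p with a mean difference near the simulated 0.30 shows the")
print("pipeline resolves a biologically plausible differentiation shift.")
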