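"""Compare V-gene usage between allogeneic and syngeneic recipients.

Simulates a small experiment with V26-biased alloreactive clones and runs
the template-weighted usage comparison with Šidák correction.
"""

from clonetrace import SimConfig, simulate_experiment
from clonetrace.gene_usage import compare_usage, comparisons_to_frame, usage_matrix

config = SimConfig(
    n_clones=5000,
    depth_lymphoid=5000,
    depth_parenchymal=2500,
    donor_sample_depth=4000,
    allo_fraction=0.01,
    activated_per_recipient=20,
    seed=3,
)
exp = simulate_experiment(config)
allo = exp.repertoires.subset(group="allogeneic")
syn = exp.repertoires.subset(group="syngeneic")

comparisons = compare_usage(
    usage_matrix(allo, segment="V"),
    usage_matrix(syn, segment="V"),
    method="anova_sidak",
)
frame = comparisons_to_frame(comparisons)
frame = frame.rename(columns={"mean_a": "mean_allo", "mean_b": "mean_syn"})
print(frame[["segment", "mean_allo", "mean_syn", "adjusted_pvalue", "significant"]]
      .to_string(index=False, float_format=lambda v: f"{v:.4f}"))

v26 = next(c for c in comparisons if c.segment == "V26")
print(f"\nV26: allo {v26.mean_a:.3f} vs syn {v26.mean_b:.3f}, "
      f"adjusted p = {v26.adjusted_pvalue:.2e} ({v26.direction})")

# The expanded alloreactive clones drag the V26 family up with them, so the
# allogeneic group shows significantly higher template-weighted V26 usage -
# the recoverable ground-truth signal planted by the simulator.
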