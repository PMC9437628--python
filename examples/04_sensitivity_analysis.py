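"""Local sensitivity of the outcome accumulators to every rate constant.

Integrates the forward sensitivity equations alongside the state and
aggregates |∂species/∂kf| over the 100-RTU horizon.  The ranking answers:
which interactions does neuronal death (or survival) depend on most?
"""

from sphingosim import build_flagship_model
from sphingosim.sensitivity import rank_influences, sensitivity_to_parameters

model = build_flagship_model()
matrix = sensitivity_to_parameters(model)

names = {str(r.index): r.name for r in model.reactions}
for outcome in ("CellDeath", "CellSurvival"):
    print(f"top-5 rate-constant sensitivities for {outcome}:")
    for idx, value in rank_influences(matrix, outcome, 5):
        print(f"  reaction {idx:>2s} ({names[idx]}): {value:.3g}")
    print()
print("Large values flag reactions whose kinetics the outcome depends on "
      "most; these are the candidate intervention points.")
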