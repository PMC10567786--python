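"""Define a custom restricted model in files and fit it.

A perfectly fair lineup can be encoded by fixing b = 0; restrictions are
declared per (parameter, condition) cell, either as a shared free-parameter
name or a fixed value.  Specs and counts round-trip through plain-text files.
"""

import tempfile
from pathlib import Path

import lineup2ht as l2

cond = l2.LineupCondition("fair3", "simultaneous", 3, n_participants=300)
spec = l2.ModelSpec(
    conditions=(cond,),
    restrictions={
        ("dP", "fair3"): "dP",
        ("dA", "fair3"): "dA",
        ("g", "fair3"): "g",
        ("b", "fair3"): 0.0,  # fairness assumption: no biased selection
    },
    free_parameter_names=("dP", "dA", "g"),
)
print("model df:", l2.degrees_of_freedom(spec))
print("information rank at an interior point:",
      l2.information_rank(spec, [0.4, 0.15, 0.35]), "of", spec.n_free)

with tempfile.TemporaryDirectory() as tmp:
    spec_path = Path(tmp) / "fair.yaml"
    l2.write_model_spec(spec, spec_path)
    spec_back = l2.read_model_spec(spec_path)
    assert spec_back == spec

truth = {"fair3": l2.ConditionParameters(dP=0.4, dA=0.15, b=0.0, g=0.35)}
data = l2.simulate_counts(l2.SimulationDesign((cond,), truth, seed=7))
result = l2.fit(spec_back, data)
for name in spec.free_parameter_names:
    print(f"{name}: estimate {result.estimates[name]:.3f} "
          f"(SE {result.standard_errors[name]:.3f})")
print(
    "\nA full-rank information matrix confirms the three free parameters are\n"
    "locally identifiable, and the estimates recover the generating values\n"
    "within sampling error."
)
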