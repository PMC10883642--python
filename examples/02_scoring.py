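"""Desirability scoring of one molecule against several objectives.

Scores aspirin against a lipophilicity window, drug-likeness, synthetic
accessibility, similarity to a reference and an ester motif.  Each raw
property value is rescaled to a desirability S in [0, 1] (1 inside the
optimal range, 0 outside the recommended range, linear in between); the
final score F is the weight-normalized mean of the S values.
"""

from latentmol import (
    Objective, compute_builtin, score_molecule, similarity_objective,
    substructure_objective,
)

aspirin = "CC(=O)Oc1ccccc1C(=O)O"

objectives = [
    Objective("SlogP", lambda m: compute_builtin(m, "SlogP"),
              optimal_range=(1.0, 3.0), recommended_range=(-0.4, 5.6),
              weight=1.0),
    Objective("QED", lambda m: compute_builtin(m, "QED"),
              optimal_range=(0.67, float("inf")),
              recommended_range=(0.3, float("inf")), weight=2.0),
    Objective("SA", lambda m: compute_builtin(m, "SA"),
              optimal_range=(1.0, 3.5), recommended_range=(1.0, 6.0),
              weight=1.0),
    similarity_objective("CC(=O)Oc1ccccc1", threshold=0.3, weight=1.0),
    substructure_objective("C(=O)O", hard=True, weight=1.0),
]

report = score_molecule(aspirin, objectives)
for name, raw, s, w in zip(report.names, report.raw_values,
                           report.scaled_scores, report.weights):
    print(f"{name:14s} raw={raw:7.3f}  desirability={s:.3f}  weight={w}")
print(f"final score F = {report.F:.3f}  "
      "(weighted mean of the desirabilities; 1 would mean every property "
      "sits in its optimal range)")
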