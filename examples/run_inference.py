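"""Classify individual leaf spots from their crisp features.

Builds the default fuzzy engine (shipped linguistic ranges and six rules)
and runs it on a few (intensity difference, area) feature pairs, printing
the full audit trail: memberships, rule activations, the crisp spot-state
score z and the final label.
"""

from plantwatch import default_engine

engine = default_engine()

examples = [
    (0.30, 1000),   # moderate contrast, smallish spot
    (0.90, 4000),   # strong contrast, large spot
    (0.10, 2500),   # faint large smudge: no rule covers it
    (0.72, 3400),   # typical pest-damage spot
]

for intensity_diff, area in examples:
    res = engine.infer({"Intensity": intensity_diff, "Area": float(area)})
    print(f"\nintensity_diff={intensity_diff}  area={area} px")
    for set_name, mv in res.memberships.items():
        degrees = ", ".join(f"{k}={v:.3f}" for k, v in mv.as_dict().items() if v)
        print(f"  {set_name}: {degrees or 'all zero'}")
    for act in res.activations:
        if act.fired:
            print(f"  fired: {act.rule.describe()}  (activation {act.activation:.3f})")
    if res.no_rule_fired:
        print("  no rule fired -> conservative label:", res.label)
    else:
        print(f"  z = {res.z:.2f} -> {res.label}")

# z is the spot-state score on a 0-100 universe; scores at or above 50 (the
# midpoint of the Noise/Defect overlap) are treated as real pest damage.
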