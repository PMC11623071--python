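"""Frame-level agreement on the bundled twenty-trial benchmark table.

Each trial pairs a manual pest assessment with the pipeline's binary call;
the metric is the percentage of trials where they agree.
"""

from plantwatch import evaluate_trials
from plantwatch.reference import benchmark_trials

trials = benchmark_trials()
print("trial  real  detected  agree")
for t in trials:
    print(f"{t.trial:5d}  {t.real_pest:4d}  {t.detected_pest:8d}  {'yes' if t.real_pest == t.detected_pest else 'NO'}")

print(f"\nagreement: {evaluate_trials(trials):.1f}%  ({len(trials)} trials)")
# 15 of the 20 trials agree -> 75.0 %
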