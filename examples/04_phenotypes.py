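"""Classify simulated subjects into time-preference phenotypes.

Simulates the 25-agent cohort matching the published phenotype mix
(7 zero / 4 positive / 12 negative / 2 reversing), pools each agent's two
frames, and classifies the binned choice curve with exact binomial and
Fisher tests.  Prints the confusion between generating and recovered labels.
"""

from collections import Counter

import dreadchoice as dc

cohort = dc.phenotype_mix_cohort()
bundle = dc.simulate_study(cohort, seed=42)

confusion = Counter()
for sid, frames in sorted(bundle.datasets.items()):
    truth = bundle.manifest["agents"][sid]["phenotype"]
    curve = dc.pooled_choice_curve(list(frames.values()), experiment=1)
    label = dc.classify_time_preference(curve).label
    confusion[(truth, label)] += 1

print(f"{'generated':>12} {'classified':>12} {'n':>4}")
for (truth, label), n in sorted(confusion.items()):
    print(f"{truth:>12} {label:>12} {n:>4}")
agree = sum(n for (t, l), n in confusion.items() if t == l)
print(f"\nagreement: {agree}/25")
print("Zero-preference agents hug the 0.5 bound; negative ones fall below")
print("it; reversing ones dip then climb back above it at long delays.")
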