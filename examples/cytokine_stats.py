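"""Cytokine-response statistics: proportion transform and one-tailed test.

Simulates six independent IL-8 ELISA experiments in which a flagellin
preparation triples secretion relative to the untreated control, with a
log-normal day-to-day scale shared within each experiment.  Raw
concentrations are converted to within-experiment proportions (which cancels
the day effect) and compared with a one-tailed Mann-Whitney U test; with
n = 6 untied pairs the p-value is exact by enumeration.  A null run (effect
1.0) is shown for contrast.
"""

import flagmet as fm

for effect, label in [(3.0, "3-fold flagellin effect"), (1.0, "null effect")]:
    raw = fm.simulate_cytokine_experiment(
        6, ["control", "flagellin"], {"control": 1.0, "flagellin": effect},
        seed=42)
    props = fm.to_proportions(raw)
    x = props[props.treatment == "flagellin"].proportion
    y = props[props.treatment == "control"].proportion
    res = fm.mann_whitney_one_tailed(x, y, alternative="greater")
    print(f"{label}: treated median proportion {x.median():.3f} vs control "
          f"{y.median():.3f}; U={res.U:.0f}, one-tailed p={res.p:.4g} ({res.mode})")

print()
print("Spearman association of species abundance with a biomarker, with")
print("Bonferroni adjustment across species (one truly associated species):")
import numpy as np

rng = np.random.default_rng(0)
biomarker = rng.normal(size=24)
abundance = {f"species_{i}": list(rng.normal(size=24)) for i in range(4)}
abundance["associated"] = list(-biomarker + rng.normal(0, 0.6, size=24))
table = fm.spearman_with_adjustment(abundance, biomarker, method="bonferroni")
print(table.round(4).to_string(index=False))
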