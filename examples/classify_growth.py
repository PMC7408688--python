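"""Classify cell lines by in vivo growth from bioluminescence series.

Simulates per-mouse radiance measured every 7 days (RG lines double every
3.5 days, MSG lines every 14 days, 20% multiplicative noise), normalizes
each mouse to its day-0 radiance, summarizes lines by the log10 mean
day-28 ratio, and splits at the largest gap.
"""

from brainsig import (
    SyntheticGrowthSpec,
    classify_growth,
    growth_ratio,
    simulate_bioluminescence,
    summarize_growth,
)

series, truth = simulate_bioluminescence(SyntheticGrowthSpec(seed=0))
ratios = [growth_ratio(s) for s in series]
summary = summarize_growth(ratios, day=28).sort_values(ascending=False)
cls = classify_growth(summary, method="max_gap")

print("cell line          log10(mean day-28 ratio)   label   true doubling (d)")
for line, v in summary.items():
    print(f"{line:<18} {v:>24.3f}   {cls.labels[line]:<5}   {truth[line]:.1f}")
print(f"\nmax-gap threshold: {cls.threshold_used:.3f} (log10 ratio units)")
# Lines above the threshold grew ~2.4 orders of magnitude in 28 days and
# form the rapid-growth group; the rest grew ~0.6 orders and form the MSG.
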