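"""Egested / retained / lysed partition report from vial-level counts.

Builds the published microbial-fate measurements (five vials of 45-50
flies over three replicate days), partitions each vial's ingested cells,
and prints the hierarchical treatment summary: vials are averaged within a
replicate day first, then mean ± SEM is taken across day means. The
headline line averages the two treatments and rounds to the nearest 5%.
"""

from gutflow import FateSample, headline_fractions, hierarchical_summary
from gutflow.fate import partition_table, round_half_up

vials = [
    FateSample(1, "axenic", 50, ingested=100, egested=11, retained_cfu=9),
    FateSample(1, "axenic", 49, ingested=100, egested=10, retained_cfu=3),
    FateSample(3, "axenic", 50, ingested=100, egested=26, retained_cfu=9),
    FateSample(2, "gnotobiotic", 45, ingested=100, egested=64, retained_cfu=10),
    FateSample(3, "gnotobiotic", 49, ingested=100, egested=42, retained_cfu=16),
]

parts = partition_table(vials)
summary = hierarchical_summary(parts)
for _, row in summary.iterrows():
    print(f"{row['fly_treatment']:12s} {row['fraction']:9s} "
          f"{round_half_up(row['mean']):.2f} +/- {round_half_up(row['sem']):.2f} "
          f"({row['n_days']} replicate days)")

headline = headline_fractions(summary)
print(f"headline: ~{headline['egested']}% egested, ~{headline['retained']}% "
      f"retained, ~{headline['lysed']}% lysed")
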