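"""Reproduce the percentage conventions of the published agreement table.

Applies the evaluate module's column-percentage and pooled-accuracy
arithmetic to the bundled genomic-vs-histological agreement counts from
five public breast-cancer cohorts.
"""

from rankgrade import overall_accuracy_g1g3, published_cohort_tables, round_percentage

for name, table in published_cohort_tables().items():
    print(f"== {name} (n = {int(table.counts.to_numpy().sum())}) ==")
    print(table.to_text())
    acc = round_percentage(overall_accuracy_g1g3(table))
    print(f"pooled G1/G3 accuracy: {acc:g}%\n")

print(
    "Percentages are within each histological-grade column; the pooled "
    "accuracy counts histological G1 tumours called G1 and histological G3 "
    "tumours called G3, ignoring the ambiguous G2 column."
)
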