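"""Pairwise annotation-method statistics from hit counts.

Feeds the published 12-bacterial-genome comparison counts (hits of each
method intersected with the reference annotation) through the evaluate
module. Sensitivity is the fraction of reference hits recovered, precision
the fraction of the method's hits confirmed by the reference, and F1 their
harmonic mean.
"""

from hotpep import ComparisonCounts, combined_f1, comparison_table

bacterial = {
    "hotpep": ComparisonCounts(1546, 296, 220),
    "dbcan_web": ComparisonCounts(1701, 599, 67),
    "dbcan_download": ComparisonCounts(1571, 178, 197),
}
table = comparison_table(bacterial, reference_total=1768)
print(table.to_string())

fungal_hotpep = ComparisonCounts(3084, 450, 901)
combined = combined_f1([bacterial["hotpep"], fungal_hotpep])
print(f"\ncombined bacterial+fungal F1 (mean of per-dataset F1): {combined['mean']:.2f}")
print(f"combined bacterial+fungal F1 (pooled counts):           {combined['pooled']:.2f}")
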