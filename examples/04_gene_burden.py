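"""Gene-based rare-variant burden tests on a simulated five-gene panel.

Simulates the default cohort (285 cases / 445 controls; one target gene at
carrier odds ratio 2.5 and four null comparator genes), applies QC, and
prints the gene report: carrier counts, percent frequencies and the CMC,
Madsen-Browning and SKAT-O p-values against the Bonferroni threshold 0.01.
"""

from famrare.burden import gene_burden_report
from famrare.simulate import CohortSimConfig, default_gene_models, simulate_case_control

cohort = simulate_case_control(
    CohortSimConfig(genes=default_gene_models(target_or=2.5), seed=5)
)
_, table = gene_burden_report(
    cohort.variants,
    cohort.genotypes,
    cohort.design,
    mb_permutations=9_999,
    seed=5,
)
cols = [
    "gene",
    "n_variants_tested",
    "case_count",
    "control_count",
    "case_freq_pct",
    "control_freq_pct",
    "p_cmc",
    "p_mb",
    "p_skato",
    "significant",
]
print(table[cols].to_string(index=False, float_format=lambda x: f"{x:.4g}"))

# The enriched gene shows a higher case carrier frequency and the smallest
# p-values in all three tests; the comparator genes stay near-uniform.
# Each row mirrors how gene-based screens of candidate genes are reported.
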