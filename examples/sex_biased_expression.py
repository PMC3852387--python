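"""Call sex-biased genes from a male/female FPKM table.

Simulates an expression table with 9% male- and 1% female-biased genes,
applies the two-clause rule (>=2-fold difference, higher sex >2 FPKM) and
summarizes, then demonstrates cross-species bias-switch detection.
"""

from spotwing import (bias_summary, bias_switch, call_sex_bias,
                      records_from_frame, simulate_expression)

table, truth = simulate_expression(n_genes=2000, frac_male=0.09,
                                   frac_female=0.01, seed=12)
calls = call_sex_bias(records_from_frame(table))

summary = bias_summary(calls, n_annotated=2000, n_expressed=2000)
print(f"male-biased: {summary['n_male']}, female-biased: "
      f"{summary['n_female']}, unbiased: {summary['n_none']}")
print(f"biased fraction of annotated genes: {summary['pct_of_annotated']}%")
match = sum(c.label == truth.sexbias_labels[c.gene_id] for c in calls)
print(f"calls matching planted truth: {match}/{len(calls)}")

# a second species; cross-map a few orthologs so male-biased genes in A
# correspond to female-biased genes in B (an expression-direction switch)
table_b, truth_b = simulate_expression(n_genes=2000, frac_male=0.09,
                                       frac_female=0.01, seed=13)
calls_b = call_sex_bias(records_from_frame(table_b))
males_a = [c.gene_id for c in calls if c.label == "male"]
females_b = [c.gene_id for c in calls_b if c.label == "female"]
orthologs = {c.gene_id: c.gene_id for c in calls}
for ga, gb in zip(males_a[:3], females_b[:3]):
    orthologs[ga], orthologs[gb] = gb, ga
switches = bias_switch(calls, calls_b, orthologs)
print(f"bias switches between species: {switches['n_switches']} "
      f"(male->female {len(switches['male_to_female'])}, "
      f"female->male {len(switches['female_to_male'])})")
# A switch requires bias in both species; genes unbiased in either are not
# counted.
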