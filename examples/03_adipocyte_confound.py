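"""Identify genes confounded by adipocyte (fat-cell) content.

Fresh-frozen breast tissue prepared at the surgeon's table retains fat
cells that formalin-fixed, microdissected sections do not.  Comparing a
breast reference panel against pure fat samples yields the adipocyte-
signature (ASG) exclusion set; overlap statistics summarize how it relates
to other confound sets.
"""

import normref as nr

counts, meta, truth = nr.generate_cohort(nr.CohortConfig(seed=7))
cpm = nr.compute_cpm(counts)
frame = nr.metadata_frame(meta)

panel = nr.build_reference_panel(cpm, meta, "FFPE", "targeted")
fat_cols = list(frame.index[frame.tissue == "fat"])
asg = nr.asg_gene_set(panel, cpm.cpm[fat_cols])

# evaluable truth: strong planted effects on genes the targeted kit captures
planted = {
    g for g, eff in truth.fat_signature.items()
    if abs(eff) >= 3.0 and g not in truth.masked_genes
}
recall = len(asg & planted) / len(planted)
print(f"ASG exclusion set: {len(asg)} genes "
      f"(|log2FC| > 2 vs fat, breast CV < 0.3)")
print(f"recall of planted strong fat-signature genes: {recall:.2f}")

stats = nr.overlap_stats(asg, planted)
print(f"overlap: {stats.n_intersection} of {stats.n_a} ASG genes "
      f"({stats.percent_of_a}%) are planted fat-signature genes")

odds, p = nr.geneset_enrichment(asg, planted, universe_size=len(panel.table))
print(f"enrichment of the planted signature in the ASG set: OR {odds:.1f}, "
      f"hypergeometric p {p:.2e}")
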