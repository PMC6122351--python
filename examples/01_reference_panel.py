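"""Build a low-variability reference panel from a synthetic normal cohort.

Generates a cohort mirroring the study design (19 FFPE + 9 FF total-RNA
normals, left/right pairs, tumors and fat samples), normalizes to CPM,
derives the left/right pair-variability (TLV) exclusion set, and builds
the FFPE/total reference panel.
"""

import normref as nr

counts, meta, truth = nr.generate_cohort(nr.CohortConfig(seed=7))
cpm = nr.compute_cpm(counts)
frame = nr.metadata_frame(meta)

# left/right pairs of the FFPE/total normal group
grp = frame[(frame.tissue == "breast_normal") & (frame.asservation == "FFPE") & (frame.kit == "total")]
pairs = []
for pair_id, members in grp[grp.pair_id.notna()].groupby("pair_id"):
    left = members.index[members.side == "L"][0]
    right = members.index[members.side == "R"][0]
    pairs.append((cpm.cpm[left], cpm.cpm[right]))

tlv = nr.tlv_gene_set(pairs)
panel = nr.build_reference_panel(cpm, meta, "FFPE", "total", tlv_set=tlv)

n_low = len(panel.low_variability_genes)
print(f"FFPE/total group: {panel.n_samples} samples, {len(panel.table)} genes")
print(f"TLV (left/right discordant) genes excluded: {len(tlv)}")
print(f"low-variability reference genes: {n_low} ({100 * n_low / len(panel.table):.0f}%)")
print(panel.table.head(8).round(3))
# A gene is 'low_variability' iff its CV across the 19 normals is < 0.30
# and it carries neither the TLV nor the ASG exclusion flag; only such
# genes are trustworthy references for tumor overexpression calls.
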