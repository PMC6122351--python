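"""Call overexpressed tumor genes without a matched normal and match them
to inhibitors.

Ten synthetic tumors are compared against the 19-sample FFPE/total normal
reference; called genes are annotated with their reliability in normals
(CV / ASG / TLV -> variability) and matched against a local drug-gene
interaction snapshot filtered to expert-curated, clinically actionable,
antineoplastic inhibitor-type records.
"""

import pandas as pd

import normref as nr

counts, meta, truth = nr.generate_cohort(nr.CohortConfig(seed=7))
cpm = nr.compute_cpm(counts)
frame = nr.metadata_frame(meta)

tumors = list(frame.index[frame.tissue == "breast_tumor"])
normals = list(
    frame.index[(frame.tissue == "breast_normal")
                & (frame.asservation == "FFPE") & (frame.kit == "total")]
)
panel = nr.build_reference_panel(cpm, meta, "FFPE", "total")
de = nr.group_tumor_de(cpm.cpm[tumors], cpm.cpm[normals])
called = de[de.called]
print(f"{len(called)} genes called overexpressed "
      f"(q <= 0.05 and log2FC > 1.5) out of {len(de)}")

# interaction snapshot: planted qualifying + disqualified records
interactions, _ = nr.generate_interaction_table(
    nr.InteractionTableConfig(seed=7, n_extra_qualifying=40, n_disqualified=30)
)
# pretend a few called genes have known inhibitors
fc = pd.Series(called["log2fc"])
renamed = {g: f"SYN{i:03d}" for i, g in enumerate(fc.index[:10])}
panel.table.rename(index=renamed, inplace=True)
fc = fc.rename(index=renamed)

rows = nr.match_drugs(fc, panel, interactions)
print(nr.report_frame(rows).head(10).to_string(index=False))
# Each row: an overexpressed gene, its fold change over the normal panel,
# its CV and exclusion flags in normals (variability 'low' marks a
# trustworthy biomarker), and the matched inhibitors.
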