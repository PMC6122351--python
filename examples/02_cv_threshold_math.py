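"""The correspondence between a CV threshold and a maximal fold change.

For normally distributed expression with coefficient of variation c, the
central 95% interval is [mu(1 - 1.96 c), mu(1 + 1.96 c)]; its upper/lower
ratio determines the largest fold change expected among healthy samples.
"""

import normref as nr

for cv in (0.10, 0.20, 0.30):
    fc = nr.cv_to_max_log2fc(cv, z=1.96)
    print(f"CV {cv:.2f}  ->  maximal log2 fold change {fc:.3f}  ({2**fc:.2f}-fold)")

c_star = nr.max_log2fc_to_cv(2.0, z=1.96)
print(f"\nCV at which the 95% interval spans exactly 4-fold: {c_star:.4f} (= 3/9.8)")
print("A working threshold of 0.30 therefore keeps the expected spread of a")
print("reference gene within a 4-fold (log2FC 2) envelope, conservatively.")
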