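"""End-to-end malignant B-cell identification.

A B subcluster is malignant when it shows a dominant BCR clonotype, a
consistent IGK/IGL light-chain ratio and high CCND1, with the
expression-inferred CNV score confirming the call.
"""

import mcltools as m

cfg = m.default_config(seed=0)
adata, truth = m.generate_expression(cfg)
bcr = m.generate_bcr(cfg)

res = m.identify_malignant(adata, bcr, seed=0)

print("per-cluster evidence:")
print(res.evidence[["n_cells", "clonotype_fraction", "ratio_mean",
                    "ratio_sd", "ccnd1_lfc", "cnv_score_median"]].round(3))
print("calls:", res.b_cluster_calls.to_dict())
print("label counts:", res.labels.value_counts().to_dict())

pred = res.labels == "malignant"
tru = truth.cells.loc[res.labels.index, "cell_type"] == "malignantB"
tp = int((pred & tru).sum())
prec = tp / max(int(pred.sum()), 1)
rec = tp / max(int(tru.sum()), 1)
print(f"precision {prec:.3f}, recall {rec:.3f} against planted truth")
print("The light-chain ratio IGKC/(IGKC+max IGLC) near 1 with small spread")
print("marks kappa restriction; the CNV score counts genes outside the")
print("0.95-1.05 band of the smoothed expression ratio.")
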