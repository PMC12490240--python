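"""Ligand-receptor testing between malignant B cells and T cells.

The statistic averages the ligand's mean in the sender and the receptor's
mean in the receiver; a label-permutation null (1000 shuffles) gives the
p-value, and reported pairs need p < 0.05, > 10% expressing cells on both
sides and membership in a curated list.
"""

import mcltools as m

cfg = m.default_config(seed=0, n_cells=1000)
adata, truth = m.generate_expression(cfg)
norm = m.normalize_log(m.apply_qc(adata))
types = truth.cells.loc[norm.obs_names, "cell_type"]

curated = ["CD70_CD27", "CD40LG_CD40"]
pairs = [
    m.LrPair("CD70_CD27", ["CD70"], ["CD27"], "costimulation"),
    m.LrPair("CD40LG_CD40", ["CD40LG"], ["CD40"], "costimulation"),
    m.LrPair("GNLY_CST3", ["GNLY"], ["CST3"], "other"),  # no planted axis
]
results = []
for pair, sender, receiver in [
    (pairs[0], "malignantB", "T"),
    (pairs[1], "T", "malignantB"),
    (pairs[2], "NK", "myeloid"),
]:
    r = m.permutation_test(norm, types, pair, sender, receiver,
                           n_perm=1000, seed=0)
    results.append(r)
    print(f"{r.pair:12s} {sender:10s}->{receiver:10s} stat={r.statistic:.2f} "
          f"p={r.p_value:.4f} fracs=({r.ligand_fraction:.2f},"
          f"{r.receptor_fraction:.2f})")

kept = m.filter_interactions(results, curated)
print(f"reported after filtering: {list(kept['pair'])}")
print("The planted CD70 (tumor) - CD27 (T cell) axis reaches the minimal")
print("possible p of 1/1001. Any type-specific marker pair looks")
print("'significant' under label permutation (GNLY-CST3 here), which is")
print("why the curated immune-related list is part of the reporting rule.")
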