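"""Generate a small synthetic MCL cohort and write it to disk.

The generator plants everything the downstream stages look for: clonal
BCRs, kappa restriction, CCND1 overexpression, copy-number segments,
a clone tree with per-sample CCFs, and multi-caller variant tables.
"""

import os

import mcltools as m
from mcltools.io import write_10x_dir, write_tsv

cfg = m.default_config(seed=0, n_cells=500)
adata, truth = m.generate_expression(cfg)
bcr = m.generate_bcr(cfg)
vt = m.generate_variant_tables(cfg)

out = "scratch/example_cohort"
os.makedirs(out, exist_ok=True)
for sample in cfg.sample_ids:
    write_10x_dir(adata[adata.obs["sample"] == sample].copy(),
                  os.path.join(out, sample))
write_tsv(bcr, os.path.join(out, "bcr_rearrangements.tsv"))
write_tsv(vt["calls"], os.path.join(out, "caller_calls.tsv"))
write_tsv(vt["panel"], os.path.join(out, "germline_panel.tsv"))
truth.to_json(os.path.join(out, "truth.json"))

print(f"cells x genes: {adata.shape[0]} x {adata.shape[1]}")
print(truth.cells["cell_type"].value_counts().to_string())
print(f"BCR rows: {len(bcr)}, caller calls: {len(vt['calls'])}")
print("Counts, BCR and variant tables written to", out)
print("Each malignant cell carries one of the two planted clonotypes; the")
print("clone tree and CNV segments drive the variant and expression layers.")
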