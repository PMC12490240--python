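"""Consensus-NMF expression programs with cophenetic K selection.

NMF is restarted with random initializations; the cophenetic coefficient
of the restart-consensus matrix measures stability per K, and K is the
first value where the coefficient starts decreasing.
"""

import anndata as ad
import scipy.sparse as sp

import mcltools as m
from mcltools.programs import run_consensus_nmf, select_k

counts, W_true, H_true = m.generate_program_data(n_programs=3, seed=0)
A = ad.AnnData(X=sp.csr_matrix(counts))
A.obs_names = [f"c{i}" for i in range(counts.shape[0])]
A.var_names = [f"g{i}" for i in range(counts.shape[1])]
X, genes = m.prepare_nmf_input(m.normalize_log(A))

res = run_consensus_nmf(X, genes, k_range=range(2, 7), n_restarts=10, seed=0)
coph = {k: r.cophenetic for k, r in res.items()}
k_star = select_k(coph)
print("cophenetic by K:", {k: round(v, 3) for k, v in coph.items()})
print(f"selected K* = {k_star} (3 programs were planted)")

programs = res[k_star].programs
metas = m.build_meta_programs(programs + programs)  # two identical "samples"
print(f"top genes of program 0: {programs[0].top_genes[:8]} ...")
print(f"{len(metas)} meta-programs from duplicated samples "
      "(identical programs merge)")
print("Each program's 30 top-scoring genes summarize a transcriptional")
print("state; sharing >= 3 of them groups programs into meta-programs.")
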