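"""Similarity index between paired tumors of one patient.

SI = sum over joint subclusters of min(fraction in A, fraction in B);
below 0.35 is low, above 0.67 high.
"""

import pandas as pd

import mcltools as m

# hand-built composition vectors over a joint clustering
a = pd.Series({0: 0.5, 1: 0.5, 2: 0.0})
b = pd.Series({0: 0.25, 1: 0.75, 2: 0.0})
si = m.similarity_index(a, b)
print(f"SI(a, b) = {si:.2f} -> {m.classify_si(si)}")

for value in (0.052, 0.49, 0.80):
    print(f"SI {value:.3f} -> {m.classify_si(value)}")

print("A low SI means the two tumors barely share transcriptional")
print("subclusters (strong drift at progression); a high SI means the")
print("relapse kept the primary's composition.")
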