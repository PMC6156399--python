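"""Sparse-neighbourhood similarity learned from interaction profiles.

Uses the fixed 5x5 toy association network: each miRNA's profile (its
column of the association matrix) is reconstructed as a sparse
combination of the other miRNAs' profiles; the surviving coefficients
form a learned miRNA-miRNA similarity.
"""

import numpy as np

from snmda import figure2_fixture, interaction_profiles, reconstruct_similarity

A = figure2_fixture()
print("association matrix (rows = diseases, cols = miRNAs):")
print(A.values)

profiles = interaction_profiles(A, side="mirna")
print("\nprofile of M1 (its association column):", profiles.vectors[:, 0].astype(int))

result = reconstruct_similarity(profiles)
print("\nreconstruction coefficients W (row i reconstructs miRNA i):")
print(np.round(result.weights, 3))
print("\nsymmetrized reconstructed similarity:")
print(np.round(result.similarity.values, 3))

print(
    "\nA positive entry (i, j) means miRNA j's disease profile helps "
    "express miRNA i's profile - they are associated with overlapping "
    "disease sets. Zero rows would mean a profile orthogonal to all "
    "others; the diagonal is zero because an entity never reconstructs "
    "itself."
)
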