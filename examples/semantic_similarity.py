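"""Disease semantic similarity from a small classification DAG.

Builds a five-node DAG (a root, two subtypes, and two leaf diseases),
then prints each disease's semantic value and the pairwise similarity
matrix. Diseases sharing more (and closer) ancestors score higher.
"""

from snmda import DiseaseDAG, EntityIndex, build_dss, contributions, semantic_value

dag = DiseaseDAG({
    "neoplasms": set(),
    "lung_neoplasms": {"neoplasms"},
    "breast_neoplasms": {"neoplasms"},
    "nsclc": {"lung_neoplasms"},
    "sclc": {"lung_neoplasms"},
})

for d in sorted(dag.nodes):
    dv = semantic_value(contributions(dag, d))
    print(f"DV({d}) = {dv:.4f}")

diseases = EntityIndex.sorted(dag.nodes)
S = build_dss(dag, diseases)
print("\nsemantic similarity matrix (rows/cols:", ", ".join(diseases), ")")
for row in S.values:
    print("  ".join(f"{v:.3f}" for v in row))

print(
    "\nSibling lung-cancer subtypes (nsclc, sclc) share the whole lung "
    "lineage and score highest; breast vs lung share only the root and "
    "score low; unrelated pairs would score 0."
)
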