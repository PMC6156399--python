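# snmda

Sparse-neighbourhood similarity learning and label propagation for
predicting miRNA–disease associations.

## The problem

Experimentally confirmed miRNA–disease associations are sparse: most
miRNAs and most diseases have only a handful of known links, while many
true associations remain undiscovered. Given

* a binary disease × miRNA association matrix **A** (A(i, j) = 1 if
  disease *i* is known to be associated with miRNA *j*),
* a precomputed miRNA functional similarity matrix **MFS**, and
* a disease semantic similarity matrix **DSS** (supplied directly or
  computed here from a MeSH-style disease DAG),

the method scores every unconfirmed (miRNA, disease) pair so that likely
true associations rank near the top. It is aimed at computational
biologists prioritising candidate miRNAs for follow-up.

## The method

1. **Sparse-neighbourhood reconstruction.** Each miRNA's *interaction
   profile* is its column of A (each disease's is its row). Profile
   x<sub>i</sub> is expressed through the other profiles by the lasso
   relaxation of basis pursuit,

   min<sub>w</sub> ‖D<sub>i</sub>w − x<sub>i</sub>‖₂² + λ‖w‖₁,

   with the dictionary D<sub>i</sub> holding all *other* profiles. The
   coefficients above a threshold ε (the *sparse neighbourhood*,
   negatives clipped) form a learned similarity matrix — **RMS** for
   miRNAs, **RDS** for diseases — that encodes the association
   structure itself.

2. **Fusion.** Learned and prior similarities are merged entrywise:
   where the prior is exactly 0 the reconstructed value is used,
   otherwise their mean:
   FMS = (RMS + MFS)/2, FDS = (RDS + DSS)/2 (elementwise, with the
   zero-prior fallback).

3. **Label propagation.** With the symmetric normalization
   MS = Dg<sup>−1/2</sup> FMS Dg<sup>−1/2</sup> (Dg = diagonal of row
   sums), known labels Y = Aᵀ diffuse as
   F(t+1) = α·MS·F(t) + (1−α)·Y, converging to
   F = (1−α)(I − α·MS)<sup>−1</sup>Y. The disease network propagates
   A the same way, and the final score is
   **F = β·F_M + (1−β)·F_Dᵀ** (β = 0.5 by default).

The package also ships the full evaluation harness (global LOOCV, local
LOOCV, repeated k-fold CV with tie-aware Mann–Whitney AUC) and seeded
synthetic generators (planted-block networks, power-law bipartite
networks, toy disease DAGs) so everything runs offline.

## Worked example

```sh
python examples/cross_validation.py
```

```
network: 60 x 80, 509 known associations
global LOOCV AUC : 0.8560   (each masked edge vs all unknown pairs)
local  LOOCV AUC : 0.8375   (masked edge vs its disease's unknown pairs)
5-fold CV AUC    : 0.7580   (mean of 5 repetitions)
chance baseline  : 0.5001
```

Every known edge of a synthetic planted-block network is masked in turn
and re-scored; AUC near 1 means masked edges outrank never-known pairs,
0.5 is chance. The local protocol — ranking only against the same
disease's candidates — is the harder task, hence its lower AUC. The
other scripts in `examples/` walk through semantic similarity, sparse
reconstruction, and candidate ranking; the `snmda` command line exposes
the same pipeline (`snmda predict --help`).

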