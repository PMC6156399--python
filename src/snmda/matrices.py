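"""Core matrix containers: associations, similarities and prediction scores.

Orientation convention (used everywhere, all transposes are explicit):

* ``AssociationMatrix`` ``A`` is disease x miRNA — ``A[i, j] = 1`` means
  disease ``i`` is known to be associated with miRNA ``j``.
* ``ScoreMatrix`` ``F`` is miRNA x disease — the miRNA-side propagation
  works on labels ``Y = A.T`` (miRNA x disease) and the disease-side
  result is transposed before combination, so the natural orientation of
  the final score matrix is miRNA x disease.

Matrices are dense: the networks this package targets have at most a few
hundred entities per side, and sparsity is exploited algorithmically (L1
reconstruction), not in storage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .indexing import EntityIndex

#: tolerance below which a similarity matrix is accepted as symmetric
SYMMETRY_TOL = 1e-10


@dataclass(frozen=True)
class AssociationMatrix:
    """Binary disease x miRNA adjacency matrix with name indices."""

    values: np.ndarray
    disease_index: EntityIndex
    mirna_index: EntityIndex

    def __post_init__(self) -> None:
        v = np.asarray(self.values)
        if v.ndim != 2:
            raise ValueError(f"association matrix must be 2-D, got {v.ndim}-D")
        if v.shape != (len(self.disease_index), len(self.mirna_index)):
            raise ValueError(
                f"shape {v.shape} does not match indices "
                f"({len(self.disease_index)} diseases, {len(self.mirna_index)} miRNAs)"
            )
        if not np.isin(v, (0, 1)).all():
            raise ValueError("association matrix entries must be 0 or 1")
        object.__setattr__(self, "values", v.astype(np.int8, copy=False))

    @property
    def n_diseases(self) -> int:
        return len(self.disease_index)

    @property
    def n_mirnas(self) -> int:
        return len(self.mirna_index)

    @property
    def n_associations(self) -> int:
        return int(self.values.sum())

    def known_pairs(self) -> np.ndarray:
        """(k, 2) array of (disease_pos, mirna_pos) for every known association."""
        return np.argwhere(self.values == 1)

    def with_masked(self, pairs: np.ndarray) -> "AssociationMatrix":
        """Copy with the given (disease_pos, mirna_pos) entries set to 0."""
        v = self.values.copy()
        pairs = np.atleast_2d(np.asarray(pairs, dtype=int))
        v[pairs[:, 0], pairs[:, 1]] = 0
        return AssociationMatrix(v, self.disease_index, self.mirna_index)


@dataclass(frozen=True)
class SimilarityMatrix:
    """Square nonnegative similarity matrix over a single entity set.

    ``kind`` tags provenance: ``precomputed`` (functional/semantic priors),
    ``reconstructed`` (sparse-neighbourhood output), ``fused`` (average of
    the two) or ``normalized`` (symmetric degree normalization applied).
    """

    values: np.ndarray
    index: EntityIndex
    kind: str = "precomputed"

    _KINDS = ("precomputed", "reconstructed", "fused", "normalized")

    def __post_init__(self) -> None:
        if self.kind not in self._KINDS:
            raise ValueError(f"unknown similarity kind {self.kind!r}")
        v = np.asarray(self.values, dtype=float)
        n = len(self.index)
        if v.shape != (n, n):
            raise ValueError(f"similarity matrix shape {v.shape} != ({n}, {n})")
        if not np.isfinite(v).all():
            raise ValueError("similarity matrix contains non-finite entries")
        if (v < 0).any():
            raise ValueError("similarity matrix contains negative entries")
        # Raw reconstructed coefficient matrices may be asymmetric (the
        # symmetrized similarity is the default downstream object);
        # normalized matrices are symmetric by construction and not re-checked.
        if self.kind in ("precomputed", "fused"):
            asym = float(np.abs(v - v.T).max()) if n else 0.0
            if asym > SYMMETRY_TOL:
                raise ValueError(f"similarity matrix asymmetric (max |S-S.T| = {asym:.3g})")
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return len(self.index)


@dataclass(frozen=True)
class ScoreMatrix:
    """Final (or intermediate) relevance scores, miRNA x disease."""

    values: np.ndarray
    mirna_index: EntityIndex
    disease_index: EntityIndex

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.mirna_index), len(self.disease_index)):
            raise ValueError(
                f"score matrix shape {v.shape} does not match indices "
                f"({len(self.mirna_index)} miRNAs, {len(self.disease_index)} diseases)"
            )
        if not np.isfinite(v).all():
            raise ValueError("score matrix contains non-finite entries")
        object.__setattr__(self, "values", v)

    def score(self, disease: str, mirna: str) -> float:
        return float(
            self.values[self.mirna_index.index(mirna), self.disease_index.index(disease)]
        )
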