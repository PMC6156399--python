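"""Sparse-neighbourhood similarity reconstruction from interaction profiles.

The association matrix is sparse, so each entity's binary interaction
profile (its row or column of ``A``) can typically be expressed as a
sparse combination of the other entities' profiles. Solving, for each
entity ``i`` with profile ``x_i`` and dictionary ``D_i`` (all other
profiles as columns),

    min_w  || D_i w - x_i ||_2^2  +  lam * || w ||_1

yields coefficients whose large entries identify the entity's *sparse
neighbourhood* — the set ``{ j : w_j > eps }``. Keeping only those
coefficients (negatives clipped to zero) and stacking the rows produces a
learned similarity matrix that reflects the association structure itself,
complementing precomputed functional/semantic similarities.

The penalized (lasso) form above is the practical relaxation of the
equality-constrained basis-pursuit program ``min ||w||_1 s.t. x = D w``,
which is infeasible whenever ``x`` is outside the dictionary's span.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .matrices import AssociationMatrix, SimilarityMatrix
from .indexing import EntityIndex

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ProfileSet:
    """Per-entity binary feature vectors, one per column."""

    vectors: np.ndarray  # (len of opposite side) x (n entities)
    index: EntityIndex
    side: str  # 'mirna' or 'disease'

    def __post_init__(self) -> None:
        if self.side not in ("mirna", "disease"):
            raise ValueError(f"side must be 'mirna' or 'disease', got {self.side!r}")
        v = np.asarray(self.vectors)
        if v.ndim != 2 or v.shape[1] != len(self.index):
            raise ValueError("profile matrix shape does not match index")
        if not np.isin(v, (0, 1)).all():
            raise ValueError("profiles must be binary")
        object.__setattr__(self, "vectors", v.astype(float))


@dataclass(frozen=True)
class SparseConfig:
    """Settings of the L1 reconstruction.

    ``lam=None`` scales the penalty per sample as ``0.01 * max|D.T x|``,
    which keeps the effective shrinkage comparable across profile
    densities; a float is used as an absolute penalty for every sample.
    ``eps`` is the sparse-neighbourhood threshold: coefficients at or
    below it are discarded.
    """

    lam: float | None = None
    lam_rel: float = 0.01
    eps: float = 1e-4
    nonneg: bool = False
    symmetrize: bool = True
    tol: float = 1e-10
    max_iter: int = 10000

    def __post_init__(self) -> None:
        if self.lam is not None and not self.lam > 0:
            raise ValueError("lam must be positive")
        if not self.lam_rel > 0:
            raise ValueError("lam_rel must be positive")
        if self.eps < 0:
            raise ValueError("eps must be nonnegative")


@dataclass(frozen=True)
class ReconstructionResult:
    """Coefficient matrix W (row i = reconstruction of entity i) and the
    post-processed similarity built from it."""

    weights: np.ndarray
    similarity: SimilarityMatrix
    config: SparseConfig


def interaction_profiles(A: AssociationMatrix, side: str) -> ProfileSet:
    """Binary feature vectors: miRNA profiles are columns of A, disease
    profiles are rows of A."""
    if side == "mirna":
        return ProfileSet(A.values.astype(float), A.mirna_index, side)
    if side == "disease":
        return ProfileSet(A.values.T.astype(float), A.disease_index, side)
    raise ValueError(f"side must be 'mirna' or 'disease', got {side!r}")


def _fista(
    G: np.ndarray,
    C: np.ndarray,
    lam: np.ndarray,
    nonneg: bool,
    tol: float,
    max_iter: int,
    zero_diag: bool = False,
) -> np.ndarray:
    """Accelerated proximal gradient (FISTA) for the columnwise lasso.

    Minimises, independently for every column ``j``,

        w_j' G w_j - 2 C[:, j]' w_j + lam[j] * ||w_j||_1

    which is ``||D w_j - x_j||^2 + lam[j] ||w_j||_1`` up to a constant
    when ``G = D'D`` and ``C[:, j] = D' x_j``. ``zero_diag`` constrains
    ``W[j, j] = 0`` (entity never reconstructs itself), which is exactly
    the per-sample program with the self column removed from the
    dictionary. Deterministic: fixed start W = 0 and step size.
    """
    n_atoms, n_rhs = C.shape
    W = np.zeros((n_atoms, n_rhs))
    lipschitz = 2.0 * float(np.linalg.eigvalsh(G)[-1]) if n_atoms else 0.0
    if lipschitz <= 0.0:
        return W
    step = lam / lipschitz  # per-column threshold, broadcast over rows
    Z = W.copy()
    t = 1.0
    for _ in range(max_iter):
        V = Z - (2.0 / lipschitz) * (G @ Z - C)
        if nonneg:
            W_new = np.maximum(0.0, V - step)
        else:
            W_new = np.sign(V) * np.maximum(0.0, np.abs(V) - step)
        if zero_diag:
            np.fill_diagonal(W_new, 0.0)
        t_new = (1.0 + np.sqrt(1.0 + 4.0 * t * t)) / 2.0
        Z = W_new + ((t - 1.0) / t_new) * (W_new - W)
        done = float(np.abs(W_new - W).max()) < tol
        W, t = W_new, t_new
        if done:
            break
    return W


def solve_l1(
    x: np.ndarray,
    D: np.ndarray,
    lam: float,
    nonneg: bool = False,
    tol: float = 1e-10,
    max_iter: int = 20000,
) -> np.ndarray:
    """Minimise ``||D w - x||_2^2 + lam * ||w||_1`` (optionally with w >= 0).

    Solved by FISTA on the Gram form; deterministic for fixed inputs.
    """
    x = np.asarray(x, dtype=float).ravel()
    D = np.asarray(D, dtype=float)
    if D.ndim != 2 or D.shape[0] != x.size:
        raise ValueError(f"dictionary shape {D.shape} incompatible with x of size {x.size}")
    if not lam > 0:
        raise ValueError("lam must be positive")
    G = D.T @ D
    c = D.T @ x
    return _fista(G, c[:, None], np.array([lam]), nonneg, tol, max_iter)[:, 0]


def sparse_neighbourhood(w: np.ndarray, eps: float) -> set[int]:
    """Indices of dictionary samples with coefficient strictly above eps."""
    if eps < 0:
        raise ValueError("eps must be nonnegative")
    return set(np.flatnonzero(np.asarray(w) > eps).tolist())


def reconstruct_similarity(
    profiles: ProfileSet, config: SparseConfig | None = None
) -> ReconstructionResult:
    """Learn a similarity matrix by sparsely reconstructing every profile
    from all the others.

    For each entity, the dictionary excludes its own profile (an entity is
    never its own neighbour, so the diagonal of W is exactly 0). Negative
    coefficients are clipped to zero and coefficients outside the sparse
    neighbourhood are zeroed. The final similarity is symmetrized as
    ``(W + W.T) / 2`` by default.
    """
    config = config or SparseConfig()
    X = profiles.vectors
    n = X.shape[1]
    if n < 2:
        raise ValueError("need at least 2 entities to reconstruct similarities")
    for i in np.flatnonzero(~X.any(axis=0)):
        log.warning("entity %r has an all-zero profile; similarity row left zero",
                    profiles.index[int(i)])
    # All entities solved at once on the Gram form; the W[j, j] = 0
    # constraint is exactly the per-sample program with the self column
    # removed from the dictionary (see solve_l1).
    G = X.T @ X
    off_diag_max = np.abs(G - np.diag(np.diag(G))).max(axis=0)
    if config.lam is not None:
        lam = np.full(n, float(config.lam))
    else:
        lam = config.lam_rel * off_diag_max
        # entities orthogonal to every other get w = 0 regardless of lam
        lam[lam == 0.0] = 1.0
    W_cols = _fista(G, G, lam, config.nonneg, config.tol, config.max_iter, zero_diag=True)
    W = W_cols.T  # row i = reconstruction of entity i
    W = np.clip(W, 0.0, None)  # a similarity cannot be negative
    W[W <= config.eps] = 0.0  # keep the sparse neighbourhood only
    values = (W + W.T) / 2.0 if config.symmetrize else W
    sim = SimilarityMatrix(values, profiles.index, kind="reconstructed")
    return ReconstructionResult(weights=W, similarity=sim, config=config)
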