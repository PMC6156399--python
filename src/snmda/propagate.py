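"""Label propagation on the miRNA and disease similarity networks.

Known associations are diffused over each similarity graph. With the
symmetrically normalized similarity ``MS = Dg^{-1/2} S Dg^{-1/2}`` (``Dg``
diagonal of row sums) the iteration

    F(t+1) = alpha * MS * F(t) + (1 - alpha) * Y,      F(0) = Y

contracts geometrically (spectral radius of ``alpha * MS`` is at most
``alpha`` < 1) to the closed form

    F = (1 - alpha) * (I - alpha * MS)^{-1} * Y.

The miRNA-side propagation uses labels ``Y = A.T`` (miRNA x disease), the
disease side uses ``Y' = A``, and the final score combines both:

    F = beta * F_M + (1 - beta) * F_D.T         (miRNA x disease)

``alpha`` is the rate at which a node keeps absorbing information from
its neighbours; ``1 - alpha`` anchors it to its initial labels. ``beta``
weighs the two networks; 0.5 treats them equally.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .matrices import AssociationMatrix, ScoreMatrix, SimilarityMatrix

#: slack allowed on the spectral-radius <= 1 check
_RADIUS_TOL = 1e-8


class ConvergenceError(RuntimeError):
    """Iterative propagation failed to reach tolerance; carries the residual."""

    def __init__(self, residual: float, max_iter: int) -> None:
        super().__init__(
            f"propagation did not converge in {max_iter} iterations "
            f"(residual {residual:.3g})"
        )
        self.residual = residual


@dataclass(frozen=True)
class PropagationConfig:
    alpha: float = 0.5
    beta: float = 0.5
    tol: float = 1e-6
    max_iter: int = 1000
    mode: str = "closed_form"

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie strictly between 0 and 1")
        if not 0.0 <= self.beta <= 1.0:
            raise ValueError("beta must lie in [0, 1]")
        if not self.tol > 0:
            raise ValueError("tol must be positive")
        if self.max_iter < 1:
            raise ValueError("max_iter must be positive")
        if self.mode not in ("iterative", "closed_form"):
            raise ValueError(f"unknown propagation mode {self.mode!r}")


def normalize_similarity(S: SimilarityMatrix) -> SimilarityMatrix:
    """Symmetric degree normalization ``Dg^{-1/2} S Dg^{-1/2}``.

    Rows/columns with zero sum are left all-zero (no division); the result
    has spectral radius at most 1, which guarantees convergence of the
    propagation for any alpha < 1.
    """
    v = S.values
    if (v < 0).any():
        raise ValueError("cannot normalize a similarity with negative entries")
    row_sums = v.sum(axis=1)
    inv_sqrt = np.zeros_like(row_sums)
    nz = row_sums > 0
    inv_sqrt[nz] = 1.0 / np.sqrt(row_sums[nz])
    ms = inv_sqrt[:, None] * v * inv_sqrt[None, :]
    return SimilarityMatrix(ms, S.index, kind="normalized")


def _check_normalized(ms: np.ndarray) -> None:
    if ms.size == 0:
        return
    radius = float(np.abs(np.linalg.eigvalsh(ms)).max())
    if radius > 1.0 + _RADIUS_TOL:
        raise ValueError(
            f"similarity is not normalized (spectral radius {radius:.6g} > 1); "
            "apply normalize_similarity first"
        )


def propagate(
    MS: SimilarityMatrix, Y: np.ndarray, cfg: PropagationConfig | None = None
) -> np.ndarray:
    """Diffuse label matrix Y over the normalized similarity MS."""
    cfg = cfg or PropagationConfig()
    ms = MS.values
    Y = np.asarray(Y, dtype=float)
    if Y.shape[0] != ms.shape[0]:
        raise ValueError(f"label matrix has {Y.shape[0]} rows, network has {ms.shape[0]} nodes")
    _check_normalized(ms)
    alpha = cfg.alpha
    if cfg.mode == "closed_form":
        lhs = np.eye(ms.shape[0]) - alpha * ms
        return (1.0 - alpha) * np.linalg.solve(lhs, Y)
    F = Y.copy()
    anchor = (1.0 - alpha) * Y
    for _ in range(cfg.max_iter):
        F_next = alpha * (ms @ F) + anchor
        residual = float(np.abs(F_next - F).max())
        F = F_next
        if residual < cfg.tol:
            return F
    raise ConvergenceError(residual, cfg.max_iter)


def propagation_kernel(MS: SimilarityMatrix, alpha: float) -> np.ndarray:
    """Closed-form propagation operator ``(1-alpha)(I - alpha MS)^{-1}``.

    ``propagate(MS, Y)`` in closed form equals ``kernel @ Y``; precomputing
    the kernel lets many label matrices (cross-validation folds) be scored
    against one fixed network cheaply.
    """
    _check_normalized(MS.values)
    n = MS.values.shape[0]
    return (1.0 - alpha) * np.linalg.inv(np.eye(n) - alpha * MS.values)


def predict(
    A: AssociationMatrix,
    FMS: SimilarityMatrix,
    FDS: SimilarityMatrix,
    cfg: PropagationConfig | None = None,
) -> ScoreMatrix:
    """Full propagation step: both networks, combined miRNA x disease scores."""
    cfg = cfg or PropagationConfig()
    if FMS.index != A.mirna_index:
        raise ValueError("miRNA similarity index does not match association matrix")
    if FDS.index != A.disease_index:
        raise ValueError("disease similarity index does not match association matrix")
    MS = normalize_similarity(FMS)
    DS = normalize_similarity(FDS)
    F_M = propagate(MS, A.values.T.astype(float), cfg)   # miRNA x disease
    F_D = propagate(DS, A.values.astype(float), cfg)     # disease x miRNA
    F = cfg.beta * F_M + (1.0 - cfg.beta) * F_D.T
    return ScoreMatrix(F, A.mirna_index, A.disease_index)
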