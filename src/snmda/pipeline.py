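"""End-to-end scoring: reconstruction -> fusion -> propagation."""

from __future__ import annotations

from .integrate import build_network, fuse
from .matrices import AssociationMatrix, ScoreMatrix, SimilarityMatrix
from .propagate import PropagationConfig, predict
from .sparse import SparseConfig, interaction_profiles, reconstruct_similarity


def fused_similarities(
    A: AssociationMatrix,
    mfs: SimilarityMatrix,
    dss: SimilarityMatrix,
    sparse_cfg: SparseConfig | None = None,
) -> tuple[SimilarityMatrix, SimilarityMatrix]:
    """Reconstruct both sides from A and fuse with the priors -> (FMS, FDS)."""
    sparse_cfg = sparse_cfg or SparseConfig()
    rms = reconstruct_similarity(interaction_profiles(A, "mirna"), sparse_cfg).similarity
    rds = reconstruct_similarity(interaction_profiles(A, "disease"), sparse_cfg).similarity
    fms = build_network(fuse(rms, mfs))
    fds = build_network(fuse(rds, dss))
    return fms, fds


def run_pipeline(
    A: AssociationMatrix,
    mfs: SimilarityMatrix,
    dss: SimilarityMatrix,
    sparse_cfg: SparseConfig | None = None,
    prop_cfg: PropagationConfig | None = None,
) -> ScoreMatrix:
    """Score every (miRNA, disease) pair from the known associations and priors."""
    fms, fds = fused_similarities(A, mfs, dss, sparse_cfg)
    return predict(A, fms, fds, prop_cfg or PropagationConfig())
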