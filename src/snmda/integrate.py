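"""Fusion of reconstructed similarities with precomputed priors.

Where a prior similarity (miRNA functional similarity or disease semantic
similarity) is exactly zero, the reconstructed value fills the gap; where
both are available they are averaged with equal weight:

    fused(x, y) = reconstructed(x, y)                      if prior(x, y) = 0
                = (reconstructed(x, y) + prior(x, y)) / 2  otherwise

The zero test is literal (no epsilon): a prior of exactly 0.0 means "no
information", anything else is evidence to be averaged in.
"""

from __future__ import annotations

import logging

import numpy as np

from .matrices import SimilarityMatrix

log = logging.getLogger(__name__)


def fuse(reconstructed: SimilarityMatrix, precomputed: SimilarityMatrix) -> SimilarityMatrix:
    """Elementwise fusion of a reconstructed and a prior similarity matrix."""
    if reconstructed.index != precomputed.index:
        raise ValueError("reconstructed and precomputed similarities have mismatched indices")
    r, p = reconstructed.values, precomputed.values
    fused = np.where(p == 0.0, r, (r + p) / 2.0)
    return SimilarityMatrix(fused, reconstructed.index, kind="fused")


def build_network(S: SimilarityMatrix) -> SimilarityMatrix:
    """Validate a fused similarity as a weighted network and log its size.

    The network *is* the matrix (nodes = entities, edge weights = similarity);
    this is a checked pass-through. Asymmetry or negative entries are
    rejected by the ``SimilarityMatrix`` invariants re-checked here.
    """
    v = S.values
    if (v < 0).any():
        raise ValueError("similarity network has negative edge weights")
    if np.abs(v - v.T).max() > 1e-10:
        raise ValueError("similarity network is asymmetric")
    off = v.copy()
    np.fill_diagonal(off, 0.0)
    n_edges = int(np.count_nonzero(off) // 2)
    log.info("similarity network: %d nodes, %d edges", len(S), n_edges)
    return S
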