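"""Synthetic fixtures and generators.

The real inputs of this method (curated association catalogues plus
functional/semantic similarity matrices) are download-only; these
generators emulate their structure so every stage of the pipeline is
exercisable offline:

* :func:`figure2_fixture` — a tiny fixed 5x5 association network whose
  first miRNA column and first disease row are the canonical worked
  example of an interaction profile.
* :func:`planted_network` — a bipartite block model with matching block
  structure in the prior similarities; masked within-block edges are
  recoverable, giving an end-to-end signal-recovery testbed.
* :func:`powerlaw_bipartite` — a configuration-model network with
  heavy-tailed degrees, emulating the sparsity regime of real
  association catalogues (most entities have very few known links).
* :func:`toy_dag` — small disease classification DAGs for the semantic
  similarity computation.

All generators are pure functions of their parameters and seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .indexing import EntityIndex
from .matrices import AssociationMatrix, SimilarityMatrix
from .semantic import DiseaseDAG

log = logging.getLogger(__name__)


def figure2_fixture() -> AssociationMatrix:
    """Fixed 5 miRNA x 5 disease toy network.

    Column M1 is (1, 1, 0, 1, 0) and row D1 is (1, 0, 1, 0, 0); the
    remaining cells are arbitrary frozen constants.
    """
    values = np.array(
        [
            [1, 0, 1, 0, 0],
            [1, 1, 0, 0, 1],
            [0, 0, 1, 1, 0],
            [1, 0, 1, 0, 1],
            [0, 1, 0, 0, 1],
        ],
        dtype=np.int8,
    )
    diseases = EntityIndex([f"D{i}" for i in range(1, 6)])
    mirnas = EntityIndex([f"M{i}" for i in range(1, 6)])
    return AssociationMatrix(values, diseases, mirnas)


@dataclass(frozen=True)
class PlantedNetworkSpec:
    """Bipartite block model with block-structured similarity priors.

    ``p_within``/``p_noise`` are the edge probabilities inside/outside
    matched blocks; ``prior_strength`` interpolates the similarity priors
    between the exact block indicator (1) and uniform noise (0).
    """

    n_diseases: int = 60
    n_mirnas: int = 80
    n_blocks: int = 4
    p_within: float = 0.35
    p_noise: float = 0.02
    prior_strength: float = 0.7
    seed: int = 7

    def __post_init__(self) -> None:
        if min(self.n_diseases, self.n_mirnas, self.n_blocks) < 1:
            raise ValueError("sizes and block count must be positive")
        if self.n_blocks > min(self.n_diseases, self.n_mirnas):
            raise ValueError("more blocks than entities: empty blocks")
        if not (0.0 < self.p_within <= 1.0 and 0.0 <= self.p_noise < 1.0):
            raise ValueError("p_within must be in (0,1], p_noise in [0,1)")
        if not self.p_within > self.p_noise:
            raise ValueError("p_within must exceed p_noise")
        if not 0.0 <= self.prior_strength <= 1.0:
            raise ValueError("prior_strength must lie in [0, 1]")


def _block_labels(n: int, n_blocks: int) -> np.ndarray:
    labels = np.empty(n, dtype=int)
    for b, chunk in enumerate(np.array_split(np.arange(n), n_blocks)):
        labels[chunk] = b
    return labels


def _block_prior(labels: np.ndarray, strength: float, rng: np.random.Generator) -> np.ndarray:
    indicator = (labels[:, None] == labels[None, :]).astype(float)
    noise = rng.random((len(labels), len(labels)))
    noise = (noise + noise.T) / 2.0
    prior = strength * indicator + (1.0 - strength) * noise
    np.fill_diagonal(prior, 1.0)
    return np.clip(prior, 0.0, 1.0)


def planted_network(
    spec: PlantedNetworkSpec | None = None,
) -> tuple[AssociationMatrix, SimilarityMatrix, SimilarityMatrix]:
    """Generate (associations, miRNA prior, disease prior) with planted blocks."""
    spec = spec or PlantedNetworkSpec()
    rng = np.random.default_rng(spec.seed)
    d_labels = _block_labels(spec.n_diseases, spec.n_blocks)
    m_labels = _block_labels(spec.n_mirnas, spec.n_blocks)
    same_block = d_labels[:, None] == m_labels[None, :]
    probs = np.where(same_block, spec.p_within, spec.p_noise)
    values = (rng.random((spec.n_diseases, spec.n_mirnas)) < probs).astype(np.int8)
    d_idx = EntityIndex([f"disease_{i:03d}" for i in range(spec.n_diseases)])
    m_idx = EntityIndex([f"mirna_{j:03d}" for j in range(spec.n_mirnas)])
    A = AssociationMatrix(values, d_idx, m_idx)
    mfs = SimilarityMatrix(_block_prior(m_labels, spec.prior_strength, rng), m_idx)
    dss = SimilarityMatrix(_block_prior(d_labels, spec.prior_strength, rng), d_idx)
    return A, mfs, dss


def _truncated_zeta(n: int, exponent: float, k_max: int, rng: np.random.Generator) -> np.ndarray:
    ks = np.arange(1, k_max + 1)
    pmf = ks.astype(float) ** (-exponent)
    pmf /= pmf.sum()
    return rng.choice(ks, size=n, p=pmf)


def powerlaw_bipartite(
    n_diseases: int, n_mirnas: int, exponent: float = 3.0, seed: int = 0
) -> AssociationMatrix:
    """Heavy-tailed bipartite network via a configuration-model pairing.

    Degrees are drawn from a zeta law truncated at the opposite side's
    size; stub totals are balanced by incrementing degrees on the
    deficient side; multi-edges are collapsed, so realized degrees can be
    slightly below the drawn ones.
    """
    if exponent <= 1.0:
        raise ValueError("exponent must exceed 1")
    rng = np.random.default_rng(seed)
    for attempt in range(10):
        d_deg = _truncated_zeta(n_diseases, exponent, n_mirnas, rng)
        m_deg = _truncated_zeta(n_mirnas, exponent, n_diseases, rng)
        if d_deg.sum() > 0 and m_deg.sum() > 0:
            break
        log.warning("degree sequence infeasible (attempt %d); resampling", attempt + 1)
    # balance stub totals so every stub can be paired
    while d_deg.sum() != m_deg.sum():
        if d_deg.sum() < m_deg.sum():
            grow, cap = d_deg, n_mirnas
        else:
            grow, cap = m_deg, n_diseases
        candidates = np.flatnonzero(grow < cap)
        grow[rng.choice(candidates)] += 1
    d_stubs = np.repeat(np.arange(n_diseases), d_deg)
    m_stubs = np.repeat(np.arange(n_mirnas), m_deg)
    rng.shuffle(m_stubs)
    values = np.zeros((n_diseases, n_mirnas), dtype=np.int8)
    values[d_stubs, m_stubs] = 1  # duplicate pairings collapse to one edge
    d_idx = EntityIndex([f"disease_{i:03d}" for i in range(n_diseases)])
    m_idx = EntityIndex([f"mirna_{j:03d}" for j in range(n_mirnas)])
    return AssociationMatrix(values, d_idx, m_idx)


def toy_dag(
    depth: int, branching: int, seed: int = 0, cross_parent_frac: float = 0.0
) -> DiseaseDAG:
    """Rooted tree DAG with ``depth`` levels plus optional extra cross-parents.

    ``depth=3, branching=1`` gives the 3-node chain; cross-parents are
    drawn from strictly shallower levels, so the graph stays acyclic.
    """
    if depth < 1:
        raise ValueError("depth must be at least 1")
    if branching < 1:
        raise ValueError("branching must be at least 1")
    rng = np.random.default_rng(seed)
    parents: dict[str, set[str]] = {}
    levels: list[list[str]] = []
    counter = 0
    for level in range(depth):
        nodes: list[str] = []
        if level == 0:
            name = f"t{counter}"
            counter += 1
            parents[name] = set()
            nodes.append(name)
        else:
            for parent in levels[level - 1]:
                for _ in range(branching):
                    name = f"t{counter}"
                    counter += 1
                    parents[name] = {parent}
                    nodes.append(name)
        levels.append(nodes)
    if cross_parent_frac > 0.0:
        for level, nodes in enumerate(levels[1:], start=1):
            shallower = [n for lvl in levels[:level] for n in lvl]
            for name in nodes:
                if rng.random() < cross_parent_frac:
                    extra = shallower[rng.integers(len(shallower))]
                    parents[name].add(extra)
    return DiseaseDAG(parents)
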