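"""Readers and writers for the plain-text formats the pipeline touches.

Formats
-------
* association edge list: 2-column TSV ``disease<TAB>mirna``, ``#`` comments
* association matrix: TSV, header row = miRNA names, first column = disease
  names, cells 0/1
* similarity matrix: TSV, header row and first column both carry entity
  names, cells decimal floats
* predictions: 4-column TSV ``disease  mirna  score  rank``

All writers stamp a ``# snmda <version>`` comment line; all readers skip
``#`` lines, so round-trips are clean.
"""

from __future__ import annotations

import io as _stdio
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .indexing import EntityIndex
from .matrices import AssociationMatrix, ScoreMatrix, SimilarityMatrix

#: asymmetry up to this value is silently symmetrized on read; beyond it, error
READ_SYMMETRY_TOL = 1e-8


def _stamp(handle) -> None:
    handle.write(f"# snmda {__version__}\n")


def read_associations(path: str | Path, format: str = "edge_list") -> AssociationMatrix:
    """Read a binary disease x miRNA association matrix.

    ``format='edge_list'``: one ``disease<TAB>mirna`` pair per line;
    duplicated edges collapse to one; indices are sorted lexicographically
    so any permutation of input rows yields the identical matrix.
    ``format='matrix'``: labeled 0/1 table as written by
    :func:`write_associations`.
    """
    path = Path(path)
    if format == "edge_list":
        return _read_edge_list(path)
    if format == "matrix":
        df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
        if df.empty:
            raise ValueError(f"{path}: empty association matrix")
        d_idx = EntityIndex(str(n) for n in df.index)
        m_idx = EntityIndex(str(n) for n in df.columns)
        values = df.to_numpy()
        return AssociationMatrix(values, d_idx, m_idx)
    raise ValueError(f"unknown association format {format!r}")


def _read_edge_list(path: Path) -> AssociationMatrix:
    # Parsed line by line (rather than via pandas) so malformed rows can be
    # reported with their line number.
    edges: set[tuple[str, str]] = set()
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2 or not parts[0].strip() or not parts[1].strip():
                raise ValueError(
                    f"{path}:{lineno}: expected 'disease<TAB>mirna', got {line!r}"
                )
            edges.add((parts[0].strip(), parts[1].strip()))
    if not edges:
        raise ValueError(f"{path}: no associations found")
    d_idx = EntityIndex.sorted(d for d, _ in edges)
    m_idx = EntityIndex.sorted(m for _, m in edges)
    values = np.zeros((len(d_idx), len(m_idx)), dtype=np.int8)
    for d, m in edges:
        values[d_idx.index(d), m_idx.index(m)] = 1
    return AssociationMatrix(values, d_idx, m_idx)


def write_associations(A: AssociationMatrix, path: str | Path, format: str = "matrix") -> None:
    """Write an association matrix (labeled 0/1 table or edge list)."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        _stamp(fh)
        if format == "matrix":
            df = pd.DataFrame(
                A.values, index=list(A.disease_index), columns=list(A.mirna_index)
            )
            df.to_csv(fh, sep="\t", lineterminator="\n")
        elif format == "edge_list":
            for i, j in A.known_pairs():
                fh.write(f"{A.disease_index[i]}\t{A.mirna_index[j]}\n")
        else:
            raise ValueError(f"unknown association format {format!r}")


def read_similarity(
    path: str | Path, expected_index: EntityIndex | None = None, kind: str = "precomputed"
) -> SimilarityMatrix:
    """Read a labeled square similarity table.

    If ``expected_index`` is given the table's labels must cover it and the
    matrix is reordered to match. Asymmetry up to 1e-8 is silently fixed as
    ``(S + S.T) / 2``; anything larger is an error.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    if df.shape[0] != df.shape[1]:
        raise ValueError(f"{path}: similarity table is not square {df.shape}")
    rows = [str(n) for n in df.index]
    cols = [str(n) for n in df.columns]
    if set(rows) != set(cols):
        raise ValueError(f"{path}: row and column labels differ")
    df.index = rows
    df.columns = cols
    df = df.loc[rows, rows]  # align columns to row order
    if expected_index is not None:
        missing = [n for n in expected_index if n not in set(rows)]
        if missing:
            raise ValueError(f"{path}: missing labels {missing[:5]}")
        order = list(expected_index)
        df = df.loc[order, order]
        index = expected_index
    else:
        index = EntityIndex(rows)
    values = df.to_numpy(dtype=float)
    if not np.isfinite(values).all():
        raise ValueError(f"{path}: non-numeric or non-finite cells")
    asym = float(np.abs(values - values.T).max()) if len(values) else 0.0
    if asym > READ_SYMMETRY_TOL:
        raise ValueError(f"{path}: asymmetric similarity (max |S-S.T| = {asym:.3g})")
    if asym > 0:
        values = (values + values.T) / 2.0
    return SimilarityMatrix(values, index, kind=kind)


def write_similarity(S: SimilarityMatrix, path: str | Path) -> None:
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        _stamp(fh)
        df = pd.DataFrame(S.values, index=list(S.index), columns=list(S.index))
        df.to_csv(fh, sep="\t", lineterminator="\n")


def prediction_table(
    F: ScoreMatrix, known: AssociationMatrix, top_k: int | None = None
) -> pd.DataFrame:
    """Ranked candidate table: one row per (disease, candidate miRNA) pair.

    Known pairs (``A = 1``) are excluded — candidates are the unconfirmed
    pairs only. Rank is per disease, descending score, average rank for
    ties; with ``top_k`` at most that many rows are kept per disease.
    """
    if F.disease_index != known.disease_index or F.mirna_index != known.mirna_index:
        raise ValueError("score and association matrices have mismatched indices")
    records = []
    for d_pos, disease in enumerate(known.disease_index):
        unknown = np.flatnonzero(known.values[d_pos] == 0)
        if unknown.size == 0:
            continue
        scores = F.values[unknown, d_pos]
        ranks = pd.Series(scores).rank(ascending=False, method="average").to_numpy()
        order = np.lexsort((np.asarray([known.mirna_index[m] for m in unknown]), -scores))
        if top_k is not None:
            order = order[:top_k]
        for pos in order:
            records.append(
                (disease, known.mirna_index[unknown[pos]], float(scores[pos]), float(ranks[pos]))
            )
    return pd.DataFrame(records, columns=["disease", "mirna", "score", "rank"])


def write_predictions(
    F: ScoreMatrix,
    known: AssociationMatrix,
    path: str | Path,
    top_k: int | None = None,
) -> None:
    """Write the ranked candidate list as a 4-column TSV."""
    df = prediction_table(F, known, top_k=top_k)
    buf = _stdio.StringIO()
    _stamp(buf)
    df.to_csv(buf, sep="\t", index=False, lineterminator="\n")
    Path(path).write_text(buf.getvalue(), encoding="utf-8")
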