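"""Pedigree handling: numerator relationship matrix A, inbreeding, and inverses.

Identifiers are opaque strings; ``0`` (or empty) marks an unknown parent.
Records are kept in topological order (parents before offspring) and mapped
to dense 0-based indices in that order, which is the row/column order of
every matrix built here.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

UNKNOWN = "0"

__all__ = [
    "Pedigree",
    "RelationshipMatrices",
    "read_pedigree",
    "compute_inbreeding",
    "build_A",
    "build_A_inverse",
    "extract_A22",
]


@dataclass
class Pedigree:
    """Topologically ordered pedigree with optional inbreeding coefficients.

    Attributes
    ----------
    records : list of (animal, sire, dam) string triples, parents first.
    F : per-animal inbreeding coefficients aligned with ``records``
        (``None`` until :func:`compute_inbreeding` runs).
    """

    records: list[tuple[str, str, str]]
    F: np.ndarray | None = None
    _index: dict[str, int] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if not self._index:
            self._index = {a: i for i, (a, _, _) in enumerate(self.records)}

    def __len__(self) -> int:
        return len(self.records)

    @property
    def ids(self) -> list[str]:
        return [a for a, _, _ in self.records]

    def index_of(self, ids) -> np.ndarray:
        """Dense row indices for the given animal ids (error on unknowns)."""
        missing = [i for i in ids if i not in self._index]
        if missing:
            raise KeyError(f"animals absent from pedigree: {missing[:10]}")
        return np.asarray([self._index[i] for i in ids], dtype=np.intp)

    def parent_indices(self) -> np.ndarray:
        """n x 2 array of sire/dam dense indices, -1 for unknown."""
        out = np.full((len(self.records), 2), -1, dtype=np.intp)
        for i, (_, s, d) in enumerate(self.records):
            if s != UNKNOWN:
                out[i, 0] = self._index[s]
            if d != UNKNOWN:
                out[i, 1] = self._index[d]
        return out


@dataclass
class RelationshipMatrices:
    """A, its inverse, and the genotyped block A22 with its inverse."""

    A: np.ndarray
    A_inv: np.ndarray
    A22: np.ndarray
    A22_inv: np.ndarray
    genotyped_index: dict[str, int]


def read_pedigree(path: str | Path) -> Pedigree:
    """Read a 3-column (animal, sire, dam) pedigree file.

    Whitespace- or comma-separated; a non-numeric first row is treated as a
    header. Parents that never appear in the animal column are inserted as
    founder records; the result is topologically sorted.
    """
    df = pd.read_csv(path, sep=r"[,\s]+", engine="python", header=None, dtype=str)
    if df.shape[1] < 3:
        raise ValueError(f"pedigree file needs 3 columns, found {df.shape[1]}")
    first = df.iloc[0].astype(str)
    if not all(v.replace("-", "").replace(".", "").isdigit() for v in first):
        df = df.iloc[1:]
    triples = [
        (str(a), str(s), str(d))
        for a, s, d in zip(df.iloc[:, 0], df.iloc[:, 1], df.iloc[:, 2])
    ]
    return _order_pedigree(triples)


def _order_pedigree(triples: list[tuple[str, str, str]]) -> Pedigree:
    seen: set[str] = set()
    for a, _, _ in triples:
        if a in seen:
            raise ValueError(f"duplicate animal id in pedigree: {a!r}")
        seen.add(a)
    parents = {p for _, s, d in triples for p in (s, d) if p != UNKNOWN}
    phantoms = sorted(parents - seen)
    triples = [(p, UNKNOWN, UNKNOWN) for p in phantoms] + triples

    # deterministic Kahn ordering: among ready animals, file order wins
    rec = {a: (s, d) for a, s, d in triples}
    pos = {a: i for i, (a, _, _) in enumerate(triples)}
    children: dict[str, list[str]] = {a: [] for a in rec}
    indeg = {a: 0 for a in rec}
    for a, (s, d) in rec.items():
        for p in {p for p in (s, d) if p != UNKNOWN}:
            children[p].append(a)
            indeg[a] += 1
    ready = [(pos[a], a) for a in rec if indeg[a] == 0]
    heapq.heapify(ready)
    order: list[str] = []
    while ready:
        _, a = heapq.heappop(ready)
        order.append(a)
        for c in children[a]:
            indeg[c] -= 1
            if indeg[c] == 0:
                heapq.heappush(ready, (pos[c], c))
    if len(order) < len(rec):
        stuck = min((a for a in rec if indeg[a] > 0), key=pos.get)
        raise ValueError(f"pedigree contains a cycle involving animal {stuck!r}")
    return Pedigree([(a, rec[a][0], rec[a][1]) for a in order])


def build_A(ped: Pedigree) -> np.ndarray:
    """Numerator relationship matrix by the recursive tabular method.

    a_ii = 1 + F_i with F_i = 0.5 * a(sire_i, dam_i);
    a_ij = 0.5 * (a_{j,sire_i} + a_{j,dam_i}) for j < i, unknown parents
    contributing 0.
    """
    n = len(ped)
    par = ped.parent_indices()
    A = np.zeros((n, n))
    for i in range(n):
        s, d = par[i]
        rs = A[s, :i] if s >= 0 else 0.0
        rd = A[d, :i] if d >= 0 else 0.0
        row = 0.5 * (rs + rd) if (s >= 0 or d >= 0) else np.zeros(i)
        A[i, :i] = row
        A[:i, i] = row
        A[i, i] = 1.0 + (0.5 * A[s, d] if (s >= 0 and d >= 0) else 0.0)
    return A


def compute_inbreeding(ped: Pedigree) -> np.ndarray:
    """Inbreeding coefficients F_i = 0.5 * a(sire_i, dam_i) (tabular A)."""
    A = build_A(ped)
    F = np.diag(A) - 1.0
    ped.F = F
    return F


def build_A_inverse(ped: Pedigree, F: np.ndarray | None = None) -> np.ndarray:
    """Henderson's rules for A^-1 accounting for inbreeding.

    The Mendelian-sampling variance for animal i is
    d_i = 0.5 - 0.25 (F_s + F_d) with both parents known,
    d_i = 0.75 - 0.25 F_p with one parent known, and 1 for founders.
    """
    if F is None:
        F = ped.F if ped.F is not None else compute_inbreeding(ped)
    n = len(ped)
    par = ped.parent_indices()
    Ainv = np.zeros((n, n))
    for i in range(n):
        s, d = par[i]
        if s >= 0 and d >= 0:
            di = 0.5 - 0.25 * (F[s] + F[d])
        elif s >= 0 or d >= 0:
            p = s if s >= 0 else d
            di = 0.75 - 0.25 * F[p]
        else:
            di = 1.0
        if di <= 0:
            raise ValueError(f"non-positive Mendelian sampling variance for {ped.records[i][0]!r}")
        w = 1.0 / di
        known = [p for p in (s, d) if p >= 0]
        Ainv[i, i] += w
        for p in known:
            Ainv[i, p] -= 0.5 * w
            Ainv[p, i] -= 0.5 * w
        for p in known:
            for q in known:
                Ainv[p, q] += 0.25 * w
    return Ainv


def extract_A22(
    A: np.ndarray, ped: Pedigree, genotyped_ids: list[str]
) -> tuple[np.ndarray, np.ndarray]:
    """Genotyped block of A and its inverse by dense Cholesky of the block.

    A22^-1 is the inverse of the extracted sub-matrix, never the genotyped
    sub-block of A^-1 (those differ whenever non-genotyped relatives exist).
    """
    idx = ped.index_of(genotyped_ids)
    A22 = A[np.ix_(idx, idx)]
    from scipy.linalg import cho_factor, cho_solve

    c = cho_factor(A22)
    A22_inv = cho_solve(c, np.eye(A22.shape[0]))
    A22_inv = 0.5 * (A22_inv + A22_inv.T)
    return A22, A22_inv


def relationship_matrices(ped: Pedigree, genotyped_ids: list[str]) -> RelationshipMatrices:
    """Convenience bundle: A, A^-1, A22 and A22^-1 for one pedigree."""
    A = build_A(ped)
    F = np.diag(A) - 1.0
    ped.F = F
    A_inv = build_A_inverse(ped, F)
    A22, A22_inv = extract_A22(A, ped, genotyped_ids)
    gidx = {g: i for i, g in enumerate(genotyped_ids)}
    return RelationshipMatrices(A, A_inv, A22, A22_inv, gidx)
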