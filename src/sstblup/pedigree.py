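"""Pedigree-based numerator relationship structures.

Builds the numerator relationship matrix A by the tabular method, its sparse
inverse by Henderson's rules (with inbreeding), and the partition of A inverse
into blocks aligned with the genotyped / non-genotyped split.  The Schur
complement A22 - A21 (A11)^-1 A12 of that partition equals the inverse of the
genotyped diagonal block of A itself (A_{2,2}^-1) and is exposed as a
matrix-vector routine so that A_{2,2} never has to be formed or inverted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import splu

logger = logging.getLogger("sstblup")

UNKNOWN = ""  # canonical unknown-parent marker after normalisation

_UNKNOWN_TOKENS = {"", "0", ".", "na", "nan", "none"}


def _norm_parent(tok) -> str:
    """Normalise a parent field: '0', empty, NA-like -> unknown."""
    if tok is None:
        return UNKNOWN
    s = str(tok).strip()
    if s.lower() in _UNKNOWN_TOKENS:
        return UNKNOWN
    return s


class PedigreeError(ValueError):
    """Raised for structurally invalid pedigrees (cycles, duplicates, ...)."""


@dataclass
class Pedigree:
    """Topologically ordered pedigree of (animal, sire, dam) trios.

    ``records`` holds original ids; ``sire_idx``/``dam_idx`` hold internal
    0-based positions (-1 = unknown parent).  Parents always precede their
    offspring in internal order; input order is preserved where possible and
    re-sorted otherwise.
    """

    records: list[tuple[str, str, str]]
    index: dict[str, int] = field(init=False)
    sire_idx: np.ndarray = field(init=False)
    dam_idx: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        normed = []
        seen: dict[str, tuple[str, str]] = {}
        for animal, sire, dam in self.records:
            a = str(animal).strip()
            s, d = _norm_parent(sire), _norm_parent(dam)
            if not a or a.lower() in _UNKNOWN_TOKENS:
                raise PedigreeError(f"invalid animal id {animal!r}")
            if a in seen:
                if seen[a] != (s, d):
                    raise PedigreeError(
                        f"animal {a!r} listed with more than one pair of parents; "
                        "only a single sire/dam per animal is supported"
                    )
                raise PedigreeError(f"duplicate animal id {a!r}")
            if a in (s, d):
                raise PedigreeError(f"animal {a!r} is its own parent")
            seen[a] = (s, d)
            normed.append((a, s, d))
        self.records = self._toposort(normed)
        self.index = {a: i for i, (a, _, _) in enumerate(self.records)}
        n = len(self.records)
        self.sire_idx = np.full(n, -1, dtype=np.int64)
        self.dam_idx = np.full(n, -1, dtype=np.int64)
        for i, (_, s, d) in enumerate(self.records):
            if s != UNKNOWN:
                self.sire_idx[i] = self.index[s]
            if d != UNKNOWN:
                self.dam_idx[i] = self.index[d]

    @staticmethod
    def _toposort(records: list[tuple[str, str, str]]) -> list[tuple[str, str, str]]:
        pos = {a: i for i, (a, _, _) in enumerate(records)}
        # fast path: already ordered
        ok = True
        for i, (_, s, d) in enumerate(records):
            for p in (s, d):
                if p != UNKNOWN and (p not in pos or pos[p] >= i):
                    ok = False
                    break
            if not ok:
                break
        if ok:
            return records
        for _, s, d in records:
            for p in (s, d):
                if p != UNKNOWN and p not in pos:
                    raise PedigreeError(f"parent {p!r} has no pedigree record")
        return [records[i] for i in _stable_topo(records, pos)]

    def __len__(self) -> int:
        return len(self.records)

    @property
    def ids(self) -> list[str]:
        return [a for a, _, _ in self.records]


def _stable_topo(records, pos) -> list[int]:
    """Topological order of record indices, preferring original order."""
    import heapq

    n = len(records)
    n_parents = np.zeros(n, dtype=np.int64)
    children: list[list[int]] = [[] for _ in range(n)]
    for i, (_, s, d) in enumerate(records):
        for p in (s, d):
            if p != UNKNOWN:
                n_parents[i] += 1
                children[pos[p]].append(i)
    heap = [i for i in range(n) if n_parents[i] == 0]
    heapq.heapify(heap)
    order = []
    while heap:
        i = heapq.heappop(heap)
        order.append(i)
        for c in children[i]:
            n_parents[c] -= 1
            if n_parents[c] == 0:
                heapq.heappush(heap, c)
    if len(order) < n:
        raise PedigreeError("pedigree contains a cycle (an animal is its own ancestor)")
    return order


@dataclass
class GenotypePartition:
    """Split of pedigree positions into non-genotyped (1) and genotyped (2) sets.

    ``genotyped_idx`` order defines the row order of the marker matrix.
    """

    nongenotyped_idx: np.ndarray
    genotyped_idx: np.ndarray

    def __post_init__(self) -> None:
        self.nongenotyped_idx = np.asarray(self.nongenotyped_idx, dtype=np.int64)
        self.genotyped_idx = np.asarray(self.genotyped_idx, dtype=np.int64)
        both = np.concatenate([self.nongenotyped_idx, self.genotyped_idx])
        if len(np.unique(both)) != len(both):
            raise ValueError("genotype partition sets overlap")

    @property
    def m_n(self) -> int:
        return len(self.nongenotyped_idx)

    @property
    def m_g(self) -> int:
        return len(self.genotyped_idx)

    def validate_for(self, n: int) -> None:
        if self.m_n + self.m_g != n:
            raise ValueError(
                f"partition covers {self.m_n + self.m_g} of {n} pedigree positions"
            )
        if len(np.union1d(self.nongenotyped_idx, self.genotyped_idx)) != n:
            raise ValueError("partition does not cover all pedigree positions")

    @classmethod
    def from_ids(cls, ped: Pedigree, genotyped_ids) -> "GenotypePartition":
        gset = []
        for a in genotyped_ids:
            a = str(a).strip()
            if a not in ped.index:
                raise ValueError(f"genotyped animal {a!r} not in pedigree")
            gset.append(ped.index[a])
        g = np.asarray(gset, dtype=np.int64)
        mask = np.ones(len(ped), dtype=bool)
        mask[g] = False
        return cls(np.flatnonzero(mask), g)


# ---------------------------------------------------------------------------
# A and its inverse
# ---------------------------------------------------------------------------

def build_A(ped: Pedigree) -> np.ndarray:
    """Numerator relationship matrix by the tabular method.

    A_jj = 1 + 0.5 * A_{sire(j),dam(j)}; A_ij = 0.5 * (A_{i,sire(j)} +
    A_{i,dam(j)}) for i < j; an unknown parent contributes zero.
    """
    n = len(ped)
    A = np.zeros((n, n))
    s, d = ped.sire_idx, ped.dam_idx
    for j in range(n):
        row = np.zeros(j)
        if s[j] >= 0:
            row += 0.5 * A[s[j], :j]
        if d[j] >= 0:
            row += 0.5 * A[d[j], :j]
        A[j, :j] = row
        A[:j, j] = row
        A[j, j] = 1.0 + (0.5 * A[s[j], d[j]] if s[j] >= 0 and d[j] >= 0 else 0.0)
    return A


def inbreeding(ped: Pedigree) -> np.ndarray:
    """Inbreeding coefficients F_i = A_ii - 1 (tabular method, desk scale)."""
    return np.diag(build_A(ped)) - 1.0


def build_A_inverse(ped: Pedigree, F: np.ndarray | None = None) -> sp.csc_matrix:
    """Sparse A^-1 by Henderson's rules with inbreeding.

    For each animal the Mendelian sampling variance is
    d_i = 0.5 - 0.25 (F_s + F_d) with both parents known,
    d_i = 0.75 - 0.25 F_p with one parent known, d_i = 1 otherwise;
    the rule adds 1/d_i to (i,i), -1/(2 d_i) to (i,parent) and 1/(4 d_i)
    to each (parent,parent) pair.
    """
    if F is None:
        F = inbreeding(ped)
    n = len(ped)
    rows, cols, vals = [], [], []

    def add(i, j, v):
        rows.append(i)
        cols.append(j)
        vals.append(v)

    for i in range(n):
        s, d = ped.sire_idx[i], ped.dam_idx[i]
        parents = [p for p in (s, d) if p >= 0]
        if len(parents) == 2:
            di = 0.5 - 0.25 * (F[s] + F[d])
        elif len(parents) == 1:
            di = 0.75 - 0.25 * F[parents[0]]
        else:
            di = 1.0
        if di <= 0:
            raise PedigreeError(f"non-positive Mendelian sampling variance at row {i}")
        a = 1.0 / di
        add(i, i, a)
        for p in parents:
            add(i, p, -0.5 * a)
            add(p, i, -0.5 * a)
        for p in parents:
            for q in parents:
                add(p, q, 0.25 * a)
    Ainv = sp.csc_matrix((vals, (rows, cols)), shape=(n, n))
    Ainv.sum_duplicates()
    return Ainv


# ---------------------------------------------------------------------------
# Partitioned inverse and the Schur complement machinery
# ---------------------------------------------------------------------------

@dataclass
class AInverseBlocks:
    """Blocks of A^-1 aligned with a genotype partition.

    A11 covers the non-genotyped rows/columns of A^-1, A22 the genotyped ones,
    A12 the off-diagonal block.  ``solve_A11`` applies (A11)^-1 through a
    sparse factorisation computed once; the Schur complement
    A22 - A21 (A11)^-1 A12 acts as A_{2,2}^-1 without ever forming A_{2,2}.
    """

    A11: sp.csc_matrix
    A12: sp.csc_matrix
    A22: sp.csc_matrix
    partition: GenotypePartition
    _lu: object = field(init=False, default=None, repr=False)

    def __post_init__(self) -> None:
        if self.partition.m_n > 0:
            self._lu = splu(self.A11.tocsc())

    def solve_A11(self, f: np.ndarray) -> np.ndarray:
        """Solve (A11) f* = f for one vector or a stack of column vectors."""
        if self.partition.m_n == 0:
            return np.zeros_like(f)
        return self._lu.solve(np.asarray(f, dtype=float))


def partition_A_inverse(Ainv: sp.spmatrix, part: GenotypePartition) -> AInverseBlocks:
    """Extract the partition blocks of A^-1 and factorise A11 once."""
    n = Ainv.shape[0]
    part.validate_for(n)
    Ainv = Ainv.tocsr()
    ng, g = part.nongenotyped_idx, part.genotyped_idx
    A11 = Ainv[np.ix_(ng, ng)].tocsc()
    A12 = Ainv[np.ix_(ng, g)].tocsc()
    A22 = Ainv[np.ix_(g, g)].tocsc()
    return AInverseBlocks(A11=A11, A12=A12, A22=A22, partition=part)


def schur_matvec(blocks: AInverseBlocks, z: np.ndarray) -> np.ndarray:
    """(A22 - A21 (A11)^-1 A12) z, i.e. A_{2,2}^-1 z, computed matrix-free.

    Evaluated as A22 z - A21 * solve(A11, f) with f = A12 z; one sparse solve
    per application.  Accepts a vector or a column-stacked matrix.
    """
    z = np.asarray(z, dtype=float)
    if z.shape[0] != blocks.partition.m_g:
        raise ValueError(f"vector length {z.shape[0]} != m_g {blocks.partition.m_g}")
    out = blocks.A22 @ z
    if blocks.partition.m_n > 0:
        f = blocks.A12 @ z
        out -= blocks.A12.T @ blocks.solve_A11(f)
    return out


def schur_diagonal(blocks: AInverseBlocks, block_size: int = 128) -> np.ndarray:
    """Exact diag(A_{2,2}^-1) column-block by column-block.

    Never allocates an m_g x m_g array; the largest intermediate is
    m_g x block_size.  A stochastic alternative is ``sample_diag_A22inv``.
    """
    m_g = blocks.partition.m_g
    out = np.empty(m_g)
    for lo in range(0, m_g, block_size):
        hi = min(lo + block_size, m_g)
        E = np.zeros((m_g, hi - lo))
        E[np.arange(lo, hi), np.arange(hi - lo)] = 1.0
        S = schur_matvec(blocks, E)
        out[lo:hi] = S[np.arange(lo, hi), np.arange(hi - lo)]
    return out


def sample_diag_A22inv(
    blocks: AInverseBlocks, n_samples: int, seed: int
) -> np.ndarray:
    """Stochastic estimate of diag(A_{2,2}^-1) with Rademacher probes.

    Averages r * (S r) over ``n_samples`` probe vectors r with entries +-1,
    where S is the Schur complement; unbiased for the true diagonal and exact
    when S is diagonal.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    m_g = blocks.partition.m_g
    rng = np.random.default_rng(seed)
    est = np.zeros(m_g)
    batch = 256
    done = 0
    while done < n_samples:
        k = min(batch, n_samples - done)
        R = rng.choice([-1.0, 1.0], size=(m_g, k))
        est += np.sum(R * schur_matvec(blocks, R), axis=1)
        done += k
    return est / n_samples
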