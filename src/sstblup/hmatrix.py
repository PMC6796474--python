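"""Three equivalent formulations of the inverse of the single-step H matrix.

The combined pedigree-genomic relationship matrix H replaces the genotyped
diagonal block of A by G_w and propagates the change through the pedigree.
Its inverse is A^-1 plus a genomic correction confined to the genotyped
block, and that correction can be organised three ways:

* explicit        : G_w^-1 - A_{2,2}^-1, both inverted up front ("SS-H-BLUP");
* Schur-implicit  : G_w^-1 minus the Schur complement
                    A^{22} - A^{21}(A^{11})^-1 A^{12} of the partitioned A^-1,
                    so A_{2,2} is never inverted ("SS-H~-BLUP");
* Woodbury/T      : with C = A_{2,2}, the Woodbury identity turns the
                    correction into (lam^-1 - 1) A_{2,2}^-1 - M* M*', where
                    M* is a precomputed m_g x m_m matrix — neither G_w nor
                    A_{2,2} nor their inverses are ever built ("SS-T-BLUP").

All three agree to machine precision; they differ only in what is prepared
before solving and what one operator application costs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Literal

import numpy as np
import scipy.linalg as sla
import scipy.sparse as sp

from .genomic import CenteredScaledMarkers, GwSpec, woodbury_inner
from .pedigree import AInverseBlocks, GenotypePartition, schur_diagonal, schur_matvec

Formulation = Literal["H", "Htilde", "Psi"]


@dataclass
class HInvOperator:
    """Matrix-free symmetric operator applying one H^-1 formulation.

    ``apply`` accepts a length-n vector (or an n x k stack) over all pedigree
    positions and returns A^-1 z plus the genomic correction scattered to the
    genotyped positions.  ``diag`` returns the exact diagonal, used for
    block preconditioning.
    """

    formulation: Formulation
    n: int
    partition: GenotypePartition
    _ainv: sp.spmatrix = field(repr=False)
    _correction: Callable[[np.ndarray], np.ndarray] = field(repr=False)
    _corr_diag: np.ndarray = field(repr=False)

    def apply(self, z: np.ndarray) -> np.ndarray:
        z = np.asarray(z, dtype=float)
        if z.shape[0] != self.n:
            raise ValueError(f"vector length {z.shape[0]} != n {self.n}")
        out = self._ainv @ z
        g = self.partition.genotyped_idx
        if len(g):
            out[g] += self._correction(z[g])
        return out

    def diag(self) -> np.ndarray:
        d = np.asarray(self._ainv.diagonal()).ravel().copy()
        d[self.partition.genotyped_idx] += self._corr_diag
        return d

    def materialise(self) -> np.ndarray:
        """Dense H^-1 by applying to identity columns (test oracle only)."""
        return self.apply(np.eye(self.n))


def _dense_A22_inverse(blocks: AInverseBlocks) -> np.ndarray:
    """A_{2,2}^-1 materialised densely via the Schur complement of A^-1.

    Algebraically identical to inverting the genotyped block of A; used by
    the explicit formulation at desk scale.
    """
    m_g = blocks.partition.m_g
    S = schur_matvec(blocks, np.eye(m_g))
    return 0.5 * (S + S.T)


def _chol_inverse(B: np.ndarray, what: str) -> np.ndarray:
    try:
        c = sla.cho_factor(0.5 * (B + B.T))
    except np.linalg.LinAlgError as e:
        raise np.linalg.LinAlgError(
            f"{what} is singular or indefinite and cannot be inverted; "
            "with lambda = 0 and more genotyped animals than markers the "
            "genomic relationship matrix is rank deficient by construction"
        ) from e
    return sla.cho_solve(c, np.eye(B.shape[0]))


def make_Hinv_explicit(
    Ainv: sp.spmatrix,
    blocks: AInverseBlocks,
    Gw: np.ndarray,
    part: GenotypePartition | None = None,
) -> HInvOperator:
    """SS-H-BLUP operator: correction G_w^-1 - A_{2,2}^-1, both dense.

    Requires factorising both G_w and A_{2,2} (m_g x m_g); fails with a
    rank-deficiency message when G_w is singular (lambda = 0, m_g > m_m).
    """
    part = part or blocks.partition
    Gw_inv = _chol_inverse(np.asarray(Gw, dtype=float), "G_w")
    A22_inv = _dense_A22_inverse(blocks)
    delta = Gw_inv - A22_inv  # Delta H_{2,2}^-1
    return HInvOperator(
        formulation="H",
        n=Ainv.shape[0],
        partition=part,
        _ainv=Ainv.tocsr(),
        _correction=lambda z2: delta @ z2,
        _corr_diag=np.diag(delta).copy(),
    )


def make_Hinv_tilde(
    Ainv: sp.spmatrix,
    blocks: AInverseBlocks,
    Gw: np.ndarray,
    part: GenotypePartition | None = None,
) -> HInvOperator:
    """SS-H~-BLUP operator: G_w^-1 z minus one Schur matvec per application.

    G_w is still factorised up front, but A_{2,2} is never formed or
    inverted; its inverse acts through the sparse factorisation of A^{11}.
    """
    part = part or blocks.partition
    Gw = np.asarray(Gw, dtype=float)
    try:
        c = sla.cho_factor(0.5 * (Gw + Gw.T))
    except np.linalg.LinAlgError as e:
        raise np.linalg.LinAlgError(
            "G_w is singular or indefinite; with lambda = 0 and more "
            "genotyped animals than markers it is rank deficient by construction"
        ) from e

    def correction(z2: np.ndarray) -> np.ndarray:
        return sla.cho_solve(c, z2) - schur_matvec(blocks, z2)

    m_g = part.m_g
    Gw_inv_diag = np.diag(sla.cho_solve(c, np.eye(m_g))).copy() if m_g else np.zeros(0)
    corr_diag = Gw_inv_diag - schur_diagonal(blocks)
    return HInvOperator(
        formulation="Htilde",
        n=Ainv.shape[0],
        partition=part,
        _ainv=Ainv.tocsr(),
        _correction=correction,
        _corr_diag=corr_diag,
    )


# ---------------------------------------------------------------------------
# The T-BLUP (Psi) pieces
# ---------------------------------------------------------------------------

@dataclass
class TOperator:
    """Precomputed matrices realising the Woodbury correction.

    Mdagger = lam^-1 A_{2,2}^-1 M (applied via the Schur complement),
    Ku the upper Cholesky factor of gamma^-1 D^-1 + M' Mdagger, and
    Mstar = Mdagger Ku^-1, so that the genomic correction becomes
    (lam^-1 - 1) A_{2,2}^-1 - Mstar Mstar'.
    """

    Mdagger: np.ndarray   # m_g x m_m
    Ku: np.ndarray        # m_m x m_m upper triangular
    Mstar: np.ndarray     # m_g x m_m
    lam: float

    @property
    def m_g(self) -> int:
        return self.Mstar.shape[0]

    @property
    def m_m(self) -> int:
        return self.Mstar.shape[1]


def build_T_operator(
    M: CenteredScaledMarkers, blocks: AInverseBlocks, spec: GwSpec
) -> TOperator:
    """Prepare Mdagger, Ku and Mstar; only an m_m x m_m dense factorisation.

    Assumes C = A_{2,2} (spec.C_kind == 'A22'); C itself is never built —
    its inverse acts columnwise through the Schur complement of A^-1.
    """
    if spec.C_kind != "A22":
        raise ValueError("the T-BLUP operator assumes C = A_{2,2}")
    if M.m_g != blocks.partition.m_g:
        raise ValueError("marker rows do not match the genotyped partition")
    Mdagger = schur_matvec(blocks, M.M) / spec.lam
    inner = spec.D_inv(M.m_m) / spec.gamma + M.M.T @ Mdagger
    inner = 0.5 * (inner + inner.T)
    try:
        Ku = sla.cholesky(inner, lower=False)
    except np.linalg.LinAlgError as e:
        raise np.linalg.LinAlgError(
            f"inner matrix gamma^-1 D^-1 + M'Mdagger is not SPD "
            f"(gamma={spec.gamma}, lambda={spec.lam}); check D conditioning"
        ) from e
    # Mstar Ku = Mdagger  <=>  Ku' Mstar' = Mdagger'
    Mstar = sla.solve_triangular(Ku, Mdagger.T, trans="T", lower=False).T
    return TOperator(Mdagger=Mdagger, Ku=Ku, Mstar=Mstar, lam=spec.lam)


def make_Hinv_psi(
    T: TOperator,
    Ainv: sp.spmatrix,
    blocks: AInverseBlocks,
    part: GenotypePartition | None = None,
) -> HInvOperator:
    """SS-T-BLUP operator: (lam^-1 - 1) Schur matvec minus Mstar (Mstar' z).

    Two dense m_g x m_m products and one sparse solve per application; no
    m_g x m_g dense array is ever allocated.
    """
    part = part or blocks.partition
    if T.m_g != part.m_g:
        raise ValueError("T operator dimension does not match the partition")
    lam_term = 1.0 / T.lam - 1.0
    Mstar = T.Mstar

    def correction(z2: np.ndarray) -> np.ndarray:
        return lam_term * schur_matvec(blocks, z2) - Mstar @ (Mstar.T @ z2)

    # exact diagonal (lam^-1 - 1) diag(A_{2,2}^-1) - rowsums(Mstar^2),
    # computed in column blocks so no m_g x m_g array is ever allocated;
    # Hutchinson sampling (sample_diag_A22inv) is the large-scale alternative
    corr_diag = lam_term * schur_diagonal(blocks) - np.einsum("ij,ij->i", Mstar, Mstar)
    return HInvOperator(
        formulation="Psi",
        n=Ainv.shape[0],
        partition=part,
        _ainv=Ainv.tocsr(),
        _correction=correction,
        _corr_diag=corr_diag,
    )


def make_Ainv_operator(Ainv: sp.spmatrix) -> HInvOperator:
    """Pedigree-only operator: A^-1 with no genomic correction.

    Plugs plain pedigree BLUP into the same solver, e.g. as the baseline
    against which single-step accuracy is compared.
    """
    n = Ainv.shape[0]
    part = GenotypePartition(np.arange(n), np.zeros(0, dtype=np.int64))
    return HInvOperator(
        formulation="H",
        n=n,
        partition=part,
        _ainv=Ainv.tocsr(),
        _correction=lambda z2: z2,
        _corr_diag=np.zeros(0),
    )


# ---------------------------------------------------------------------------
# Dense H oracle and FLOP accounting
# ---------------------------------------------------------------------------

def build_H(
    A: np.ndarray, Gw: np.ndarray, part: GenotypePartition
) -> np.ndarray:
    """Dense H assembled blockwise (small-n test oracle).

    Upper-left A11 - A12 A22^-1 A21 + A12 A22^-1 G_w (A12 A22^-1)',
    off-diagonal (A12 A22^-1) G_w, lower-right G_w, where the subscripted
    blocks here are blocks of A itself.
    """
    A = np.asarray(A, dtype=float)
    ng, g = part.nongenotyped_idx, part.genotyped_idx
    part.validate_for(A.shape[0])
    A11 = A[np.ix_(ng, ng)]
    A12 = A[np.ix_(ng, g)]
    A22 = A[np.ix_(g, g)]
    try:
        c = sla.cho_factor(A22)
    except np.linalg.LinAlgError as e:
        raise np.linalg.LinAlgError("A_{2,2} is singular") from e
    P = sla.cho_solve(c, A12.T).T          # A12 A22^-1
    H = np.empty_like(A)
    H[np.ix_(ng, ng)] = A11 - P @ A12.T + P @ Gw @ P.T
    H[np.ix_(ng, g)] = P @ Gw
    H[np.ix_(g, ng)] = (P @ Gw).T
    H[np.ix_(g, g)] = Gw
    return 0.5 * (H + H.T)


def flop_count(formulation: Formulation, m_g: int, m_m: int | None = None) -> int:
    """Per-iteration dense-FLOP count of the genomic correction.

    One multiply-add per matrix entry: the explicit and Schur-implicit
    formulations multiply z by a dense m_g x m_g matrix (m_g^2 MACs); the
    Woodbury formulation performs two m_g x m_m products (2 m_g m_m MACs).
    The sparse-solve cost shared by the implicit formulations is not part of
    this dense count.
    """
    if m_g <= 0:
        raise ValueError("m_g must be positive")
    if formulation in ("H", "Htilde"):
        return m_g * m_g
    if formulation == "Psi":
        if m_m is None or m_m <= 0:
            raise ValueError("Psi FLOP count needs a positive m_m")
        return 2 * m_g * m_m
    raise ValueError(f"unknown formulation {formulation!r}")
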