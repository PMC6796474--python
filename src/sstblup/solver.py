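"""Multi-trait animal-model mixed model equations and their PCG solution.

The model is y = Xb + Zu + e with one fixed factor per trait, additive
genetic effects u with var(u) = H (x) G0 (traits nested within animal) and
residuals with var(e) built from R0 restricted to each animal's observed
trait pattern.  The coefficient matrix is never materialised: the inverse of
H enters only through a pluggable HInvOperator, so the same solver serves
the explicit, Schur-implicit and Woodbury formulations (and plain
pedigree-BLUP when handed an A^-1 operator).

Solving uses preconditioned conjugate gradients with a block-diagonal
preconditioner (one t x t block per animal) for the genetic equations and a
diagonal preconditioner for the fixed-effect equations; convergence is
declared when ||y - Xb|| / ||y|| drops below the tolerance (default
2.68e-9).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg as sla
import scipy.sparse as sp

from .hmatrix import HInvOperator
from .pedigree import GenotypePartition, Pedigree

logger = logging.getLogger("sstblup")

DEFAULT_TOL = 2.68e-9


def _check_spd(mat: np.ndarray, name: str) -> np.ndarray:
    mat = np.asarray(mat, dtype=float)
    if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
        raise ValueError(f"{name} must be square")
    if not np.allclose(mat, mat.T, atol=1e-10):
        raise ValueError(f"{name} must be symmetric")
    try:
        sla.cholesky(mat)
    except np.linalg.LinAlgError as e:
        raise ValueError(f"{name} must be positive definite") from e
    return mat


@dataclass
class ModelSpec:
    """Trait count, per-trait fixed factor levels, and (co)variances.

    G0 and R0 are t x t SPD genetic and residual covariance matrices; they
    are treated as known inputs throughout (no variance estimation).
    """

    n_traits: int
    G0: np.ndarray
    R0: np.ndarray

    def __post_init__(self) -> None:
        self.G0 = _check_spd(self.G0, "G0")
        self.R0 = _check_spd(self.R0, "R0")
        if self.G0.shape != (self.n_traits, self.n_traits):
            raise ValueError("G0 dimension does not match n_traits")
        if self.R0.shape != (self.n_traits, self.n_traits):
            raise ValueError("R0 dimension does not match n_traits")


@dataclass
class EquationMap:
    """Bidirectional map between equations and (effect, level/animal, trait).

    Fixed equations come first, grouped by trait then level (the first level
    of each trait's factor is dropped for full rank); genetic equations
    follow, traits nested within animal in pedigree order.
    """

    n_traits: int
    fixed_levels: list[list]           # per trait, levels kept (first dropped)
    fixed_offsets: np.ndarray          # per trait, first equation index
    n_fixed: int
    animal_ids: list[str]
    u_offset: int

    def u_index(self, animal_pos: int, trait: int) -> int:
        return self.u_offset + animal_pos * self.n_traits + trait

    def fixed_index(self, trait: int, level) -> int | None:
        """Equation index of a fixed level, or None if it is the dropped one."""
        levels = self.fixed_levels[trait]
        try:
            k = levels.index(level)
        except ValueError:
            return None
        return int(self.fixed_offsets[trait]) + k

    @property
    def n_equations(self) -> int:
        return self.u_offset + len(self.animal_ids) * self.n_traits


@dataclass
class MMESystem:
    """Matrix-free mixed model equations Xb = y with preconditioner."""

    eqmap: EquationMap
    rhs: np.ndarray
    hinv: HInvOperator
    _data_apply: object = field(repr=False)
    _precond_apply: object = field(repr=False)
    G0_inv: np.ndarray = field(repr=False, default=None)

    @property
    def n_equations(self) -> int:
        return self.eqmap.n_equations

    def coeff_apply(self, b: np.ndarray) -> np.ndarray:
        """X b: data part (W'R^-1 W b) plus H^-1 (x) G0^-1 on the u block."""
        b = np.asarray(b, dtype=float)
        out = self._data_apply(b)
        em = self.eqmap
        t = em.n_traits
        U = b[em.u_offset:].reshape(-1, t)
        HU = self.hinv.apply(U)
        out[em.u_offset:] += (HU @ self.G0_inv).ravel()
        return out

    def precond_apply(self, r: np.ndarray) -> np.ndarray:
        return self._precond_apply(r)


def _group_records(phenos: pd.DataFrame, ped: Pedigree, t: int):
    """Group one-trait-per-row records into per-animal observation patterns."""
    required = {"animal", "trait", "value", "fixed_level"}
    missing = required - set(phenos.columns)
    if missing:
        raise ValueError(f"phenotype table missing columns {sorted(missing)}")
    phenos = phenos.copy()
    phenos["animal"] = phenos["animal"].astype(str).str.strip()
    unknown = set(phenos["animal"]) - set(ped.index)
    if unknown:
        raise ValueError(f"phenotyped animal(s) not in pedigree: {sorted(unknown)[:5]}")
    tr = phenos["trait"].to_numpy()
    if not np.isin(tr, np.arange(t)).all():
        raise ValueError(f"trait codes must be integers in [0, {t})")
    dup = phenos.duplicated(subset=["animal", "trait"])
    if dup.any():
        raise ValueError("more than one record per (animal, trait)")
    return phenos


def build_mme(
    phenos: pd.DataFrame,
    model: ModelSpec,
    hinv: HInvOperator,
    ped: Pedigree,
    part: GenotypePartition | None = None,
) -> MMESystem:
    """Assemble the matrix-free MME for a phenotype table.

    ``phenos`` has one row per (animal, trait) record with columns
    animal, trait (0-based integer), value, fixed_level.  Residual
    covariance across an animal's observed traits comes from the matching
    R0 sub-matrix; H^-1 itself enters only through ``hinv.apply``.
    """
    t = model.n_traits
    if hinv.n != len(ped):
        raise ValueError("H^-1 operator dimension does not match pedigree size")
    phenos = _group_records(phenos, ped, t)

    # fixed-effect layout: per trait, sorted levels with the first dropped
    fixed_levels: list[list] = []
    fixed_offsets = np.zeros(t, dtype=np.int64)
    off = 0
    for k in range(t):
        levels = sorted(phenos.loc[phenos["trait"] == k, "fixed_level"].unique())
        kept = levels[1:]  # drop first level for full rank
        fixed_levels.append(kept)
        fixed_offsets[k] = off
        off += len(kept)
    eqmap = EquationMap(
        n_traits=t,
        fixed_levels=fixed_levels,
        fixed_offsets=fixed_offsets,
        n_fixed=off,
        animal_ids=ped.ids,
        u_offset=off,
    )
    n_eq = eqmap.n_equations

    # per-animal observation patterns, grouped by pattern for vectorisation
    groups = []  # (pattern tuple, animal positions, W index matrix, y values)
    by_animal: dict[int, list[tuple[int, float, object]]] = {}
    for row in phenos.itertuples(index=False):
        pos = ped.index[row.animal]
        by_animal.setdefault(pos, []).append((int(row.trait), float(row.value), row.fixed_level))
    pattern_buckets: dict[tuple, list] = {}
    for pos, recs in by_animal.items():
        recs.sort(key=lambda r: r[0])
        pattern = tuple(r[0] for r in recs)
        pattern_buckets.setdefault(pattern, []).append((pos, recs))
    for pattern, members in sorted(pattern_buckets.items()):
        S = list(pattern)
        Rinv = np.linalg.inv(model.R0[np.ix_(S, S)])
        positions = np.array([pos for pos, _ in members], dtype=np.int64)
        yvals = np.array([[v for _, v, _ in recs] for _, recs in members])
        # equation indices: u always present; fixed may be -1 (dropped level)
        u_idx = np.array(
            [[eqmap.u_index(pos, k) for k in S] for pos, _ in members], dtype=np.int64
        )
        f_idx = np.full((len(members), len(S)), -1, dtype=np.int64)
        for i, (_, recs) in enumerate(members):
            for j, (k, _, lev) in enumerate(recs):
                fi = eqmap.fixed_index(k, lev)
                f_idx[i, j] = -1 if fi is None else fi
        groups.append((S, Rinv, positions, yvals, u_idx, f_idx))

    def data_apply(b: np.ndarray) -> np.ndarray:
        out = np.zeros(n_eq)
        for S, Rinv, positions, yvals, u_idx, f_idx in groups:
            V = b[u_idx]
            fmask = f_idx >= 0
            Vf = np.where(fmask, b[np.where(fmask, f_idx, 0)], 0.0)
            T = (V + Vf) @ Rinv
            np.add.at(out, u_idx, T)
            np.add.at(out, f_idx[fmask], T[fmask])
        return out

    # right-hand side W' R^-1 y
    rhs = np.zeros(n_eq)
    for S, Rinv, positions, yvals, u_idx, f_idx in groups:
        T = yvals @ Rinv
        np.add.at(rhs, u_idx, T)
        fmask = f_idx >= 0
        np.add.at(rhs, f_idx[fmask], T[fmask])

    # preconditioner: exact diagonal for fixed equations, exact t x t blocks
    # (data contribution + diag(H^-1)_ii * G0^-1) for each animal
    G0_inv = np.linalg.inv(model.G0)
    fixed_diag = np.zeros(eqmap.n_fixed)
    animal_blocks = np.zeros((len(ped), t, t))
    for S, Rinv, positions, yvals, u_idx, f_idx in groups:
        for j, k in enumerate(S):
            fmask = f_idx[:, j] >= 0
            np.add.at(fixed_diag, f_idx[fmask, j], Rinv[j, j])
        block = np.zeros((t, t))
        block[np.ix_(S, S)] = Rinv
        animal_blocks[positions] += block
    hdiag = hinv.diag()
    animal_blocks += hdiag[:, None, None] * G0_inv[None, :, :]
    block_inv = np.linalg.inv(animal_blocks)
    fixed_diag_inv = np.where(fixed_diag > 0, 1.0 / np.maximum(fixed_diag, 1e-300), 1.0)

    def precond_apply(r: np.ndarray) -> np.ndarray:
        out = np.empty_like(r)
        out[: eqmap.n_fixed] = fixed_diag_inv * r[: eqmap.n_fixed]
        U = r[eqmap.u_offset:].reshape(len(ped), t)
        out[eqmap.u_offset:] = np.einsum("nij,nj->ni", block_inv, U).ravel()
        return out

    return MMESystem(
        eqmap=eqmap,
        rhs=rhs,
        hinv=hinv,
        _data_apply=data_apply,
        _precond_apply=precond_apply,
        G0_inv=G0_inv,
    )


@dataclass
class PCGResult:
    solution: np.ndarray
    trace: list[float]
    n_iter: int
    converged: bool


def pcg_solve(
    system: MMESystem,
    tol: float = DEFAULT_TOL,
    max_iter: int | None = None,
    start: np.ndarray | None = None,
) -> PCGResult:
    """Preconditioned conjugate gradients on the MME.

    The convergence criterion is ||y - Xb|| / ||y|| (L2), recorded every
    round; iteration stops when it reaches ``tol`` or at ``max_iter``
    (default 10 x n_equations), in which case ``converged`` is False.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    n = system.n_equations
    if max_iter is None:
        max_iter = 10 * n
    y = system.rhs
    y_norm = np.linalg.norm(y)
    b = np.zeros(n) if start is None else np.asarray(start, dtype=float).copy()
    if y_norm == 0.0:
        return PCGResult(solution=np.zeros(n), trace=[0.0], n_iter=0, converged=True)
    r = y - system.coeff_apply(b)
    crit = np.linalg.norm(r) / y_norm
    trace = [float(crit)]
    if crit <= tol:
        return PCGResult(solution=b, trace=trace, n_iter=0, converged=True)
    z = system.precond_apply(r)
    p = z.copy()
    rz = float(r @ z)
    converged = False
    k = 0
    for k in range(1, max_iter + 1):
        q = system.coeff_apply(p)
        alpha = rz / float(p @ q)
        b += alpha * p
        r -= alpha * q
        crit = np.linalg.norm(r) / y_norm
        trace.append(float(crit))
        if crit <= tol:
            converged = True
            break
        z = system.precond_apply(r)
        rz_new = float(r @ z)
        p = z + (rz_new / rz) * p
        rz = rz_new
    if not converged:
        logger.warning("PCG stopped at max_iter=%d with criterion %.3e", max_iter, crit)
    return PCGResult(solution=b, trace=trace, n_iter=k, converged=converged)


def extract_ebv(result: PCGResult, eqmap: EquationMap) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Map solutions back to (animal, trait, ebv) plus fixed-effect table.

    Returns (ebv_table, fixed_table); an unconverged result attaches a
    warning but still reports the last iterate.
    """
    if not result.converged:
        logger.warning("extracting EBVs from an unconverged PCG result")
    t = eqmap.n_traits
    b = result.solution
    U = b[eqmap.u_offset:].reshape(len(eqmap.animal_ids), t)
    ebv = pd.DataFrame(
        {
            "animal": np.repeat(eqmap.animal_ids, t),
            "trait": np.tile(np.arange(t), len(eqmap.animal_ids)),
            "ebv": U.ravel(),
        }
    )
    rows = []
    for k in range(t):
        for j, lev in enumerate(eqmap.fixed_levels[k]):
            rows.append((k, lev, b[int(eqmap.fixed_offsets[k]) + j]))
    fixed = pd.DataFrame(rows, columns=["trait", "level", "estimate"])
    ebv.attrs["converged"] = result.converged
    fixed.attrs["converged"] = result.converged
    return ebv, fixed
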