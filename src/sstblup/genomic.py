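"""Marker centering/scaling and the weighted genomic relationship G_w.

G_w = gamma * M D M' + lambda * C, where M is the centred and scaled marker
matrix (m_g x m_m), D an SPD marker-weight matrix (identity by default) and C
an SPD add-on matrix — either the genotyped block A_{2,2} of the pedigree
relationship matrix with lambda read as the residual polygenic proportion, or
a diagonal matrix of random noise.  When m_g > m_m the marker part M D M' is
rank deficient, but G_w remains SPD for any lambda > 0; its inverse is applied
through the Woodbury identity so that only an m_m x m_m matrix is factorised.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Literal

import numpy as np
import scipy.linalg as sla

logger = logging.getLogger("sstblup")


@dataclass
class MarkerMatrix:
    """Raw allele counts in {0,1,2}, one row per genotyped animal.

    ``allele_freq`` defaults to column mean / 2; missing entries (NaN) are
    mean-imputed unless ``strict`` is set at centering time.
    """

    counts: np.ndarray
    ids: list[str] | None = None
    allele_freq: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2:
            raise ValueError("marker counts must be a 2-D matrix")
        valid = np.isnan(self.counts) | np.isin(self.counts, (0.0, 1.0, 2.0))
        if not valid.all():
            raise ValueError("marker counts must be 0, 1 or 2 (NaN = missing)")


@dataclass
class CenteredScaledMarkers:
    M: np.ndarray            # m_g x m_m, centred (and scaled) real matrix
    center: np.ndarray       # 2 p_j per kept column
    scale: np.ndarray        # s_j per kept column
    kept_columns: np.ndarray  # indices into the raw matrix

    @property
    def m_g(self) -> int:
        return self.M.shape[0]

    @property
    def m_m(self) -> int:
        return self.M.shape[1]


def center_scale(
    raw: MarkerMatrix,
    scaling: Literal["per_marker", "global", "none"] = "per_marker",
    strict: bool = False,
) -> CenteredScaledMarkers:
    """Centre allele counts by 2 p_j and scale.

    ``per_marker`` divides column j by s_j = sqrt(2 p_j (1 - p_j)) (the usual
    convention making E[diag(MM')/m_m] = 1 under Hardy-Weinberg); ``global``
    centres only and divides all columns by sqrt(sum_j 2 p_j (1-p_j) / m_m);
    ``none`` centres without scaling.  Monomorphic columns are dropped with a
    warning.  Missing entries are imputed to 2 p_j (strict=True errors).
    """
    counts = raw.counts.copy()
    n_missing = int(np.isnan(counts).sum())
    if n_missing:
        if strict:
            raise ValueError(f"{n_missing} missing genotype entries (strict mode)")
        col_mean = np.nanmean(counts, axis=0)
        idx = np.where(np.isnan(counts))
        counts[idx] = col_mean[idx[1]]
        logger.warning("mean-imputed %d missing genotype entries", n_missing)
    if raw.allele_freq is not None:
        p = np.asarray(raw.allele_freq, dtype=float)
        if p.shape[0] != counts.shape[1]:
            raise ValueError("allele_freq length does not match marker count")
    else:
        p = counts.mean(axis=0) / 2.0
    poly = (p > 0.0) & (p < 1.0)
    n_dropped = int((~poly).sum())
    if n_dropped:
        logger.warning("dropped %d monomorphic marker column(s)", n_dropped)
    if not poly.any():
        raise ValueError("all markers are monomorphic; nothing to centre")
    kept = np.flatnonzero(poly)
    counts = counts[:, kept]
    p = p[kept]
    center = 2.0 * p
    het = 2.0 * p * (1.0 - p)
    if scaling == "per_marker":
        scale = np.sqrt(het)
    elif scaling == "global":
        scale = np.full(len(p), np.sqrt(het.mean()))
    elif scaling == "none":
        scale = np.ones(len(p))
    else:
        raise ValueError(f"unknown scaling {scaling!r}")
    M = (counts - center) / scale
    return CenteredScaledMarkers(M=M, center=center, scale=scale, kept_columns=kept)


@dataclass
class GwSpec:
    """Weights and add-on matrix defining G_w = gamma M D M' + lambda C.

    With ``C_kind='A22'`` (the default single-step setting) lambda is the
    proportion of additive genetic variance not explained by markers and
    gamma defaults to 1 - lambda.  ``C`` holds the dense add-on matrix where
    one is needed explicitly; ``C_inv_apply`` applies C^-1 (for C = A_{2,2}
    this is the Schur-complement matvec, so C is never built).
    """

    gamma: float = 0.95
    lam: float = 0.05
    D: np.ndarray | None = None            # None = identity
    C_kind: Literal["A22", "diagonal_noise"] = "A22"
    C: np.ndarray | None = None
    C_inv_apply: Callable[[np.ndarray], np.ndarray] | None = field(
        default=None, repr=False
    )

    def __post_init__(self) -> None:
        if not 0.0 < self.lam <= 1.0:
            raise ValueError(f"lambda must be in (0, 1], got {self.lam}")
        if self.gamma <= 0.0:
            raise ValueError(f"gamma must be positive, got {self.gamma}")

    def D_inv(self, m_m: int) -> np.ndarray:
        if self.D is None:
            return np.eye(m_m)
        D = np.asarray(self.D, dtype=float)
        if D.shape != (m_m, m_m):
            raise ValueError(f"D has shape {D.shape}, expected ({m_m}, {m_m})")
        try:
            c = sla.cho_factor(0.5 * (D + D.T))
        except np.linalg.LinAlgError as e:
            raise ValueError("marker-weight matrix D is not SPD") from e
        return sla.cho_solve(c, np.eye(m_m))

    def apply_C_inv(self, z: np.ndarray) -> np.ndarray:
        if self.C_inv_apply is not None:
            return self.C_inv_apply(z)
        if self.C is None:
            raise ValueError("GwSpec has neither C nor C_inv_apply")
        C = 0.5 * (self.C + self.C.T)
        try:
            c = sla.cho_factor(C)
        except np.linalg.LinAlgError as e:
            raise ValueError("add-on matrix C is not SPD") from e
        return sla.cho_solve(c, np.asarray(z, dtype=float))


def diagonal_noise_C(m_g: int, eps: float, seed: int) -> np.ndarray:
    """Diagonal add-on of random noise, entries U(0.5, 1.5) * eps."""
    rng = np.random.default_rng(seed)
    return np.diag(rng.uniform(0.5, 1.5, size=m_g) * eps)


def build_Gw(M: CenteredScaledMarkers, spec: GwSpec) -> np.ndarray:
    """Dense G_w = gamma M D M' + lambda C (desk scale / oracle use).

    SPD whenever lambda > 0 and C is SPD, even when m_g > m_m and the marker
    part alone is singular.
    """
    if spec.C is None:
        raise ValueError("build_Gw needs an explicit dense C")
    if spec.C.shape != (M.m_g, M.m_g):
        raise ValueError(f"C has shape {spec.C.shape}, expected ({M.m_g}, {M.m_g})")
    if spec.D is None:
        G = M.M @ M.M.T
    else:
        G = M.M @ np.asarray(spec.D, dtype=float) @ M.M.T
    Gw = spec.gamma * G + spec.lam * np.asarray(spec.C, dtype=float)
    return 0.5 * (Gw + Gw.T)


def woodbury_inner(M: CenteredScaledMarkers, spec: GwSpec) -> tuple[np.ndarray, np.ndarray]:
    """The Woodbury kernel pieces: (lam^-1 C^-1 M, inner matrix).

    inner = gamma^-1 D^-1 + M' (lam^-1 C^-1) M is m_m x m_m and SPD; it is the
    only matrix that needs a dense factorisation when applying G_w^-1.
    """
    CinvM = spec.apply_C_inv(M.M) / spec.lam
    inner = spec.D_inv(M.m_m) / spec.gamma + M.M.T @ CinvM
    return CinvM, 0.5 * (inner + inner.T)


def woodbury_inverse_apply(
    M: CenteredScaledMarkers, spec: GwSpec, z: np.ndarray
) -> np.ndarray:
    """(gamma M D M' + lambda C)^-1 z via the Woodbury identity.

    lam^-1 C^-1 z - lam^-1 C^-1 M (gamma^-1 D^-1 + M' lam^-1 C^-1 M)^-1
    M' C^-1 lam^-1 z; only the m_m x m_m inner matrix is factorised.
    """
    z = np.asarray(z, dtype=float)
    if z.shape[0] != M.m_g:
        raise ValueError(f"vector length {z.shape[0]} != m_g {M.m_g}")
    CinvM, inner = woodbury_inner(M, spec)
    try:
        c = sla.cho_factor(inner)
    except np.linalg.LinAlgError as e:
        raise ValueError(
            "Woodbury inner matrix is not SPD; check gamma, lambda and D"
        ) from e
    u = spec.apply_C_inv(z) / spec.lam
    return u - CinvM @ sla.cho_solve(c, M.M.T @ u)
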