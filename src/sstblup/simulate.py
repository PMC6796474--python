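"""Synthetic pedigrees, genotypes, phenotypes and dummy genotypes.

Everything the solver consumes can be generated here: a discrete-generation
random-mating pedigree, gene-dropped biallelic genotypes (founders in
Hardy-Weinberg proportions, no linkage), multi-trait phenotypes with known
variance components, and the regression-sampling dummy-genotype scheme that
projects real marker counts onto non-genotyped relatives through
A_{*,2} A_{2,2}^-1 and redraws integer genotypes binomially.

All randomness flows from a single master seed through independent named
streams, so any single product can be regenerated without replaying the
others.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg as sla

from .pedigree import (
    AInverseBlocks,
    GenotypePartition,
    Pedigree,
    schur_matvec,
)

logger = logging.getLogger("sstblup")

_STREAMS = ("pedigree", "genotypes", "phenotypes", "dummy", "probes")


def stream_rng(seed: int, stream: str) -> np.random.Generator:
    """Independent generator for a named stream of the master seed."""
    if stream not in _STREAMS:
        raise ValueError(f"unknown stream {stream!r}; one of {_STREAMS}")
    root = np.random.SeedSequence(seed)
    children = root.spawn(len(_STREAMS))
    return np.random.default_rng(children[_STREAMS.index(stream)])


@dataclass
class SimConfig:
    """Study conditions for one simulated dataset.

    Defaults give a moderate livestock-like pedigree whose genotyped cohort
    can be pushed to either side of the m_g vs m_m boundary by adjusting
    ``genotyping_fraction`` and ``m_markers``.
    """

    n_founders: int = 40
    n_generations: int = 3
    offspring_per_mating: int = 2
    matings_per_generation: int | None = None  # default: n_founders // 2
    m_markers: int = 100
    founder_freq_range: tuple[float, float] = (0.05, 0.95)
    genotyping_fraction: float = 0.4
    n_traits: int = 2
    G0: np.ndarray = field(default_factory=lambda: np.array([[1.0, 0.3], [0.3, 1.0]]))
    R0: np.ndarray = field(default_factory=lambda: np.array([[2.0, 0.5], [0.5, 2.0]]))
    n_fixed_levels: int = 3
    fixed_effect_scale: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_founders < 2:
            raise ValueError("need at least 2 founders to form matings")
        for name in ("n_generations", "offspring_per_mating", "m_markers", "n_traits"):
            if getattr(self, name) < 0 or (name != "n_generations" and getattr(self, name) < 1):
                raise ValueError(f"{name} must be positive")
        lo, hi = self.founder_freq_range
        if not (0.0 < lo < hi < 1.0):
            raise ValueError("founder_freq_range must satisfy 0 < lo < hi < 1")
        if not 0.0 <= self.genotyping_fraction <= 1.0:
            raise ValueError("genotyping_fraction must lie in [0, 1]")
        self.G0 = np.asarray(self.G0, dtype=float)
        self.R0 = np.asarray(self.R0, dtype=float)

    @property
    def n_matings(self) -> int:
        return self.matings_per_generation or self.n_founders // 2


def simulate_pedigree(cfg: SimConfig) -> Pedigree:
    """Discrete generations with random mating among the previous one.

    Size is exactly n_founders + n_generations * n_matings * offspring_per_
    mating; topologically ordered by construction.
    """
    rng = stream_rng(cfg.seed, "pedigree")
    records: list[tuple[str, str, str]] = [
        (f"F{i:04d}", "", "") for i in range(cfg.n_founders)
    ]
    previous = [a for a, _, _ in records]
    counter = 0
    for gen in range(1, cfg.n_generations + 1):
        current = []
        for _ in range(cfg.n_matings):
            sire, dam = rng.choice(previous, size=2, replace=False)
            for _ in range(cfg.offspring_per_mating):
                animal = f"G{gen}_{counter:05d}"
                counter += 1
                records.append((animal, sire, dam))
                current.append(animal)
        previous = current
    return Pedigree(records)


@dataclass
class GenotypeSim:
    """Gene-dropping output: full counts plus the genotyped subset."""

    all_counts: np.ndarray          # n x m_m allele counts for every animal
    allele_freq: np.ndarray         # founder frequencies p_j
    partition: GenotypePartition    # genotyped subset, row order = counts rows


def simulate_genotypes(ped: Pedigree, cfg: SimConfig) -> GenotypeSim:
    """Founders Bernoulli(p_j) per allele; descendants by gene dropping.

    Each child receives one uniformly chosen allele from each parent per
    marker, markers independent (no linkage).  The genotyped subset is a
    uniform random sample of size round(genotyping_fraction * n).
    """
    rng = stream_rng(cfg.seed, "genotypes")
    n, m = len(ped), cfg.m_markers
    p = rng.uniform(*cfg.founder_freq_range, size=m)
    # two haplotypes per animal; children draw one allele per parent
    hap = np.zeros((2, n, m), dtype=np.int8)
    for i in range(n):
        s, d = ped.sire_idx[i], ped.dam_idx[i]
        for h, parent in enumerate((s, d)):
            if parent < 0:
                hap[h, i] = rng.random(m) < p
            else:
                pick = rng.integers(0, 2, size=m)
                hap[h, i] = hap[pick, parent, np.arange(m)]
    counts = hap.sum(axis=0).astype(float)
    n_geno = int(round(cfg.genotyping_fraction * n))
    g_idx = np.sort(rng.choice(n, size=n_geno, replace=False))
    mask = np.ones(n, dtype=bool)
    mask[g_idx] = False
    part = GenotypePartition(np.flatnonzero(mask), g_idx)
    return GenotypeSim(all_counts=counts, allele_freq=p, partition=part)


def simulate_phenotypes(
    ped: Pedigree,
    A: np.ndarray,
    cfg: SimConfig,
    marker_counts: np.ndarray | None = None,
    marker_h2: float = 0.9,
) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """Phenotypes y = fixed + u + e with known truth.

    In the default pedigree mode u ~ N(0, A (x) G0) via Cholesky of A and
    G0.  When ``marker_counts`` (n x m, every animal) is given, a fraction
    ``marker_h2`` of the genetic variance is driven by additive marker
    effects and the remainder stays polygenic on the pedigree — the
    configuration under which genomic information genuinely adds accuracy.

    Returns (phenotype table, true breeding values n x t, fixed effects
    t x n_levels).
    """
    rng = stream_rng(cfg.seed, "phenotypes")
    n, t = len(ped), cfg.n_traits
    L_G0 = sla.cholesky(cfg.G0, lower=True)
    # A is PSD (can be singular with inbred duplicates): shift-free Cholesky
    # with tiny jitter fallback
    try:
        L_A = sla.cholesky(A, lower=True)
    except np.linalg.LinAlgError:
        L_A = sla.cholesky(A + 1e-10 * np.eye(n), lower=True)
    U_poly = L_A @ rng.standard_normal((n, t)) @ L_G0.T
    if marker_counts is None:
        U = U_poly
    else:
        if not 0.0 <= marker_h2 <= 1.0:
            raise ValueError("marker_h2 must lie in [0, 1]")
        counts = np.asarray(marker_counts, dtype=float)
        p = counts.mean(axis=0) / 2.0
        keep = (p > 0) & (p < 1)
        W = (counts[:, keep] - 2 * p[keep]) / np.sqrt(2 * p[keep] * (1 - p[keep]))
        alpha = rng.standard_normal((W.shape[1], t)) @ L_G0.T / np.sqrt(W.shape[1])
        U = np.sqrt(marker_h2) * (W @ alpha) + np.sqrt(1.0 - marker_h2) * U_poly
    beta = rng.standard_normal((t, cfg.n_fixed_levels)) * cfg.fixed_effect_scale
    levels = rng.integers(0, cfg.n_fixed_levels, size=(n, t))
    L_R0 = sla.cholesky(cfg.R0, lower=True)
    E = rng.standard_normal((n, t)) @ L_R0.T
    rows = []
    for i, animal in enumerate(ped.ids):
        for k in range(t):
            rows.append(
                (animal, k, beta[k, levels[i, k]] + U[i, k] + E[i, k], int(levels[i, k]))
            )
    phenos = pd.DataFrame(rows, columns=["animal", "trait", "value", "fixed_level"])
    return phenos, U, beta


# ---------------------------------------------------------------------------
# Regression-sampled dummy genotypes
# ---------------------------------------------------------------------------

@dataclass
class DummyGenotypeJob:
    """Inputs for projecting real genotypes onto non-genotyped relatives.

    ``source_centered`` is the centred real marker-count matrix M_c
    (m_g x m_m) with its column means (mean allele counts) supplied
    separately; ``A_star2`` is the relationship block between the target
    individuals and the genotyped set.  Truncation bounds are fixed at
    [0, 2].
    """

    source_centered: np.ndarray      # M_c, centred counts
    column_means: np.ndarray         # mean allele count per marker (2 p_j)
    target_idx: np.ndarray           # pedigree positions of the targets
    A_star2: np.ndarray              # n_targets x m_g block of A
    seed: int = 0

    def __post_init__(self) -> None:
        self.source_centered = np.asarray(self.source_centered, dtype=float)
        self.column_means = np.asarray(self.column_means, dtype=float)
        self.A_star2 = np.asarray(self.A_star2, dtype=float)
        if self.A_star2.shape != (len(self.target_idx), self.source_centered.shape[0]):
            raise ValueError("A_star2 shape must be (n_targets, m_g)")
        if self.column_means.shape[0] != self.source_centered.shape[1]:
            raise ValueError("column_means length must equal the marker count")


def expected_dummy_counts(
    job: DummyGenotypeJob, blocks: AInverseBlocks, add_means: bool = True
) -> np.ndarray:
    """Truncated expected counts Mtilde = A_{*,2} A_{2,2}^-1 M_c.

    A_{2,2}^-1 acts columnwise through the Schur complement; with
    ``add_means`` (default) the column mean allele count is restored before
    truncating to [0, 2], which puts Mtilde back on the count scale.  The
    strict as-written alternative (add_means=False) truncates the centred
    regression directly.
    """
    targets = set(int(i) for i in np.asarray(job.target_idx))
    genotyped = set(int(i) for i in blocks.partition.genotyped_idx)
    if targets & genotyped:
        raise ValueError("dummy targets overlap the genotyped set")
    proj = job.A_star2 @ schur_matvec(blocks, job.source_centered)
    if add_means:
        proj = proj + job.column_means[None, :]
    n_out = int(((proj < 0) | (proj > 2)).sum())
    frac = n_out / proj.size if proj.size else 0.0
    logger.info("dummy-genotype regression: %.3f%% entries truncated to [0, 2]", 100 * frac)
    return np.clip(proj, 0.0, 2.0)


def generate_dummy_genotypes(
    job: DummyGenotypeJob, blocks: AInverseBlocks, add_means: bool = True
) -> np.ndarray:
    """Integer dummy genotypes drawn from the truncated expected counts.

    Each expected count m is converted to a genotype as the sum of two
    Bernoulli(m / 2) draws — i.e. Binomial(2, m / 2) — so the sampled
    genotypes lie in {0, 1, 2} with mean equal to the truncated expectation.
    They need not be Mendelian-consistent with the pedigree.
    """
    mtilde = expected_dummy_counts(job, blocks, add_means=add_means)
    rng = stream_rng(job.seed, "dummy")
    return rng.binomial(2, mtilde / 2.0).astype(float)
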