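"""Shared fixtures: hand-built pedigrees and simulated desk-scale datasets."""

from dataclasses import dataclass

import numpy as np
import pytest

import sstblup as st


@pytest.fixture
def trio_ped() -> st.Pedigree:
    """Unrelated sire and dam with one offspring."""
    return st.Pedigree([("S", "", ""), ("D", "", ""), ("O", "S", "D")])


@pytest.fixture
def inbred_ped() -> st.Pedigree:
    """Full sibs X, Y mated to produce the inbred Z (F_Z = 0.25)."""
    return st.Pedigree(
        [
            ("S", "", ""),
            ("D", "", ""),
            ("X", "S", "D"),
            ("Y", "S", "D"),
            ("Z", "X", "Y"),
        ]
    )


@dataclass
class Dataset:
    """One simulated instance with every derived structure the tests need."""

    cfg: st.SimConfig
    ped: st.Pedigree
    geno: st.GenotypeSim
    part: st.GenotypePartition
    A: np.ndarray
    Ainv: object
    blocks: st.AInverseBlocks
    M: st.CenteredScaledMarkers
    A22: np.ndarray
    spec: st.GwSpec
    Gw: np.ndarray


def make_dataset(
    seed: int,
    n_founders: int = 30,
    n_generations: int = 3,
    m_markers: int = 20,
    genotyping_fraction: float = 0.4,
    lam: float = 0.05,
    **cfg_kwargs,
) -> Dataset:
    cfg = st.SimConfig(
        n_founders=n_founders,
        n_generations=n_generations,
        m_markers=m_markers,
        genotyping_fraction=genotyping_fraction,
        seed=seed,
        **cfg_kwargs,
    )
    ped = st.simulate_pedigree(cfg)
    geno = st.simulate_genotypes(ped, cfg)
    part = geno.partition
    A = st.build_A(ped)
    Ainv = st.build_A_inverse(ped)
    blocks = st.partition_A_inverse(Ainv, part)
    M = st.center_scale(st.MarkerMatrix(geno.all_counts[part.genotyped_idx]))
    A22 = A[np.ix_(part.genotyped_idx, part.genotyped_idx)]
    spec = st.GwSpec(gamma=1.0 - lam, lam=lam, C=A22)
    Gw = st.build_Gw(M, spec)
    return Dataset(
        cfg=cfg, ped=ped, geno=geno, part=part, A=A, Ainv=Ainv,
        blocks=blocks, M=M, A22=A22, spec=spec, Gw=Gw,
    )


@pytest.fixture
def small_ds() -> Dataset:
    """~50-animal instance with m_g > m_m (the rank-deficient regime)."""
    return make_dataset(seed=7, n_founders=20, n_generations=2, m_markers=8,
                        genotyping_fraction=0.6)


@pytest.fixture
def tall_ds() -> Dataset:
    """Instance with m_g < m_m (classic more-markers-than-animals regime)."""
    return make_dataset(seed=8, n_founders=20, n_generations=2, m_markers=60,
                        genotyping_fraction=0.3)
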