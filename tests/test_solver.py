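"""Mixed model equations, PCG, and EBV extraction."""

import numpy as np
import pandas as pd
import pytest

import sstblup as st
from conftest import make_dataset


def solved_dataset(seed=30, **kwargs):
    ds = make_dataset(seed=seed, **kwargs)
    phenos, truth, beta = st.simulate_phenotypes(
        ds.ped, ds.A, ds.cfg, marker_counts=ds.geno.all_counts
    )
    model = st.ModelSpec(n_traits=ds.cfg.n_traits, G0=ds.cfg.G0, R0=ds.cfg.R0)
    return ds, phenos, truth, model


def dense_coefficient_matrix(system):
    n = system.n_equations
    return np.column_stack([system.coeff_apply(e) for e in np.eye(n)])


class TestBuildMME:
    def test_single_trait_textbook_u_block(self):
        # single trait: u-block must equal Z'Z / sigma_e^2 + H^-1 / sigma_u^2
        ds = make_dataset(seed=31, n_founders=10, n_generations=1, m_markers=6,
                          n_traits=1, G0=np.array([[0.5]]), R0=np.array([[2.0]]))
        phenos, _, _ = st.simulate_phenotypes(ds.ped, ds.A, ds.cfg)
        op = st.make_Hinv_explicit(ds.Ainv, ds.blocks, ds.Gw)
        model = st.ModelSpec(n_traits=1, G0=np.array([[0.5]]), R0=np.array([[2.0]]))
        system = st.build_mme(phenos, model, op, ds.ped)
        X = dense_coefficient_matrix(system)
        n = len(ds.ped)
        u_block = X[system.eqmap.u_offset:, system.eqmap.u_offset:]
        expected = np.eye(n) / 2.0 + op.materialise() / 0.5
        assert np.abs(u_block - expected).max() < 1e-10

    def test_coeff_apply_symmetry(self):
        ds, phenos, _, model = solved_dataset(seed=32, n_founders=12,
                                              n_generations=2, m_markers=8)
        op = st.make_Hinv_tilde(ds.Ainv, ds.blocks, ds.Gw)
        system = st.build_mme(phenos, model, op, ds.ped)
        rng = np.random.default_rng(0)
        for _ in range(20):
            b, w = rng.standard_normal((2, system.n_equations))
            lhs, rhs = b @ system.coeff_apply(w), w @ system.coeff_apply(b)
            assert lhs == pytest.approx(rhs, rel=1e-10)

    def test_matches_directly_assembled_dense_mme(self):
        # n = 80, t = 2: materialised operator vs explicit Kronecker assembly
        ds, phenos, _, model = solved_dataset(seed=33, n_founders=20,
                                              n_generations=3, m_markers=10)
        assert len(ds.ped) == 80
        op = st.make_Hinv_explicit(ds.Ainv, ds.blocks, ds.Gw)
        system = st.build_mme(phenos, model, op, ds.ped)
        X = dense_coefficient_matrix(system)
        assert np.allclose(X, X.T)
        em = system.eqmap
        t, n = em.n_traits, len(ds.ped)
        # direct dense assembly: W'R^-1W + [0, 0; 0, H^-1 (x) G0^-1]
        n_eq = em.n_equations
        Rfull_inv = np.linalg.inv(model.R0)
        direct = np.zeros((n_eq, n_eq))
        for pos in range(n):
            idx = []
            for k in range(t):
                row = np.zeros(n_eq)
                row[em.u_index(pos, k)] = 1.0
                rec = phenos[(phenos.animal == ds.ped.ids[pos]) & (phenos.trait == k)]
                fi = em.fixed_index(k, rec.fixed_level.iloc[0])
                if fi is not None:
                    row[fi] = 1.0
                idx.append(row)
            Wi = np.array(idx)
            direct += Wi.T @ Rfull_inv @ Wi
        Hinv = op.materialise()
        G0inv = np.linalg.inv(model.G0)
        direct[em.u_offset:, em.u_offset:] += np.kron(Hinv, G0inv)
        assert np.abs(X - direct).max() < 1e-9 * max(1.0, np.abs(direct).max())

    def test_unknown_animal_rejected(self, small_ds):
        phenos = pd.DataFrame(
            {"animal": ["ghost"], "trait": [0], "value": [1.0], "fixed_level": [0]}
        )
        model = st.ModelSpec(n_traits=2, G0=small_ds.cfg.G0, R0=small_ds.cfg.R0)
        op = st.make_Hinv_tilde(small_ds.Ainv, small_ds.blocks, small_ds.Gw)
        with pytest.raises(ValueError, match="not in pedigree"):
            st.build_mme(phenos, model, op, small_ds.ped)

    def test_non_spd_covariance_rejected(self):
        with pytest.raises(ValueError, match="positive definite"):
            st.ModelSpec(n_traits=2, G0=np.array([[1.0, 2.0], [2.0, 1.0]]),
                         R0=np.eye(2))


class TestPCG:
    def test_exact_start_converges_immediately(self):
        ds, phenos, _, model = solved_dataset(seed=34, n_founders=12,
                                              n_generations=1, m_markers=6)
        op = st.make_Hinv_explicit(ds.Ainv, ds.blocks, ds.Gw)
        system = st.build_mme(phenos, model, op, ds.ped)
        X = dense_coefficient_matrix(system)
        exact = np.linalg.solve(X, system.rhs)
        res = st.pcg_solve(system, start=exact)
        assert res.converged and res.n_iter == 0

    def test_matches_dense_solve(self):
        ds, phenos, _, model = solved_dataset(seed=35, n_founders=14,
                                              n_generations=2, m_markers=8)
        op = st.make_Hinv_tilde(ds.Ainv, ds.blocks, ds.Gw)
        system = st.build_mme(phenos, model, op, ds.ped)
        X = dense_coefficient_matrix(system)
        exact = np.linalg.solve(X, system.rhs)
        res = st.pcg_solve(system)
        assert res.converged
        assert res.trace[-1] <= st.DEFAULT_TOL
        rel = np.linalg.norm(res.solution - exact) / np.linalg.norm(exact)
        assert rel < 1e-8

    def test_three_formulations_same_solutions_and_rounds(self):
        ds, phenos, _, model = solved_dataset(seed=36, n_founders=20,
                                              n_generations=3, m_markers=12)
        T = st.build_T_operator(ds.M, ds.blocks, ds.spec)
        ops = [
            st.make_Hinv_explicit(ds.Ainv, ds.blocks, ds.Gw),
            st.make_Hinv_tilde(ds.Ainv, ds.blocks, ds.Gw),
            st.make_Hinv_psi(T, ds.Ainv, ds.blocks),
        ]
        results = [st.pcg_solve(st.build_mme(phenos, model, op, ds.ped)) for op in ops]
        assert all(r.converged for r in results)
        assert len({r.n_iter for r in results}) == 1  # equal numbers of rounds
        sol_scale = np.abs(results[0].solution).max()
        for r in results[1:]:
            assert np.abs(r.solution - results[0].solution).max() < 1e-6 * sol_scale

    def test_max_iter_reached_reports_not_converged(self):
        ds, phenos, _, model = solved_dataset(seed=37, n_founders=12,
                                              n_generations=2, m_markers=6)
        op = st.make_Hinv_explicit(ds.Ainv, ds.blocks, ds.Gw)
        system = st.build_mme(phenos, model, op, ds.ped)
        res = st.pcg_solve(system, max_iter=2)
        assert not res.converged
        assert res.n_iter == 2
        assert len(res.trace) == 3

    def test_zero_rhs_gives_zero_solution(self):
        ds, phenos, _, model = solved_dataset(seed=38, n_founders=10,
                                              n_generations=1, m_markers=6)
        phenos = phenos.assign(value=0.0)
        op = st.make_Hinv_explicit(ds.Ainv, ds.blocks, ds.Gw)
        system = st.build_mme(phenos, model, op, ds.ped)
        res = st.pcg_solve(system)
        assert res.converged
        assert np.abs(res.solution).max() == 0.0


class TestExtractEBV:
    def test_round_trip_every_animal_trait_once(self):
        ds, phenos, _, model = solved_dataset(seed=39, n_founders=10,
                                              n_generations=1, m_markers=6)
        op = st.make_Hinv_explicit(ds.Ainv, ds.blocks, ds.Gw)
        system = st.build_mme(phenos, model, op, ds.ped)
        res = st.pcg_solve(system)
        ebv, fixed = st.extract_ebv(res, system.eqmap)
        assert len(ebv) == len(ds.ped) * model.n_traits
        assert not ebv.duplicated(subset=["animal", "trait"]).any()
        assert set(ebv.animal) == set(ds.ped.ids)

    def test_permuting_pedigree_input_order_leaves_ebv_unchanged(self):
        ds, phenos, _, model = solved_dataset(seed=40, n_founders=12,
                                              n_generations=2, m_markers=8)

        def run(ped):
            A = st.build_A(ped)
            Ainv = st.build_A_inverse(ped)
            g_ids = [ds.ped.ids[i] for i in ds.part.genotyped_idx]
            part = st.GenotypePartition.from_ids(ped, g_ids)
            blocks = st.partition_A_inverse(Ainv, part)
            A22 = A[np.ix_(part.genotyped_idx, part.genotyped_idx)]
            spec = st.GwSpec(C=A22, gamma=ds.spec.gamma, lam=ds.spec.lam)
            Gw = st.build_Gw(ds.M, spec)
            op = st.make_Hinv_explicit(Ainv, blocks, Gw)
            system = st.build_mme(phenos, model, op, ped)
            ebv, _ = st.extract_ebv(st.pcg_solve(system), system.eqmap)
            return ebv.sort_values(["animal", "trait"]).reset_index(drop=True)

        rng = np.random.default_rng(0)
        shuffled = list(ds.ped.records)
        rng.shuffle(shuffled)
        base = run(ds.ped)
        perm = run(st.Pedigree(shuffled))
        # genotyped row order is preserved (marker rows pinned to ids)
        assert list(base.animal) == list(perm.animal)
        assert np.abs(base.ebv.to_numpy() - perm.ebv.to_numpy()).max() < 1e-8
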