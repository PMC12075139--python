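"""GRM construction, blending, core selection, and the factored APY inverse."""

import numpy as np
import pytest

from apygwas import (
    CenteredGenotypes,
    Grm,
    MISSING,
    allele_frequencies,
    apy_matvec,
    assemble_apy_inverse,
    blend_grm,
    build_apy_inverse,
    build_grm,
    center_genotypes,
    select_core_animals,
    select_core_size,
)
from conftest import blended_grm_from_sim, make_panel


class TestCenterGenotypes:
    def test_centering_kills_constant_column(self):
        panel = make_panel([[1, 1], [1, 1]])
        zc = center_genotypes(panel, np.array([0.5, 0.5]))
        np.testing.assert_allclose(zc.Z, 0.0)

    def test_hand_case(self):
        panel = make_panel([[0, 2], [2, 0]])
        zc = center_genotypes(panel, np.array([0.5, 0.5]))
        np.testing.assert_allclose(zc.Z, [[-1, 1], [1, -1]])
        assert zc.scale_k == pytest.approx(1.0)

    def test_missing_becomes_zero(self):
        panel = make_panel([[MISSING, 0], [2, 1]])
        zc = center_genotypes(panel, np.array([0.3, 0.25]))
        assert zc.Z[0, 0] == 0.0
        assert zc.Z[1, 0] == pytest.approx(2 - 0.6)

    def test_rejects_out_of_range_p(self):
        panel = make_panel([[0, 1]])
        with pytest.raises(ValueError):
            center_genotypes(panel, np.array([1.2, 0.5]))

    def test_column_means_vanish_with_observed_p(self, sim_panel, sim_zc):
        np.testing.assert_allclose(sim_zc.Z.mean(axis=0), 0.0, atol=1e-10)


class TestBuildGrm:
    def test_hand_matrix_product(self):
        zc = CenteredGenotypes(
            Z=np.array([[-1.0, 1.0], [1.0, -1.0]]), p=np.array([0.5, 0.5]), scale_k=1.0
        )
        g = build_grm(zc)
        np.testing.assert_allclose(g.G, [[2, -2], [-2, 2]])

    def test_identical_animals_identical_rows(self):
        panel = make_panel([[0, 2, 1], [0, 2, 1], [2, 0, 1]])
        zc = center_genotypes(panel, allele_frequencies(panel))
        g = build_grm(zc).G
        np.testing.assert_allclose(g[0], g[1])
        np.testing.assert_allclose(g[:, 0], g[:, 1])

    def test_vanraden_diagonal_expectation(self):
        """mean diag(G) ≈ 1 when p comes from the data itself."""
        _, zc, _ = blended_grm_from_sim(200, 2000, seed=21, beta=0.0)
        g = build_grm(zc)
        assert 0.9 <= np.mean(np.diag(g.G)) <= 1.1

    def test_all_fixed_loci_raise(self):
        zc = CenteredGenotypes(Z=np.zeros((3, 2)), p=np.array([0.0, 1.0]), scale_k=0.0)
        with pytest.raises(ValueError, match="fixed"):
            build_grm(zc)


class TestBlendGrm:
    def test_beta_zero_is_identity_operation(self, sim_grm_blended):
        g = Grm(G=sim_grm_blended.G.copy())
        np.testing.assert_array_equal(blend_grm(g, 0.0).G, g.G)

    def test_beta_one_gives_target(self):
        g = Grm(G=np.array([[2.0, -2.0], [-2.0, 2.0]]))
        np.testing.assert_allclose(blend_grm(g, 1.0).G, np.eye(2))

    def test_hand_blend(self):
        g = Grm(G=np.array([[2.0, -2.0], [-2.0, 2.0]]))
        gb = blend_grm(g, 0.05)
        np.testing.assert_allclose(gb.G, [[1.95, -1.9], [-1.9, 1.95]])
        assert gb.is_blended

    def test_supplied_target_and_dimension_check(self):
        g = Grm(G=np.eye(3))
        t = np.full((3, 3), 0.5)
        np.testing.assert_allclose(
            blend_grm(g, 0.2, t).G, 0.8 * np.eye(3) + 0.1
        )
        with pytest.raises(ValueError):
            blend_grm(g, 0.2, np.eye(2))


class TestSelectCoreSize:
    def test_rank_one_needs_single_core(self):
        z = np.tile([1.0, -2.0, 0.5, 1.5], (3, 1))  # 3 identical animals
        zc = CenteredGenotypes(Z=z, p=np.full(4, 0.5), scale_k=1.0)
        assert select_core_size(zc, 0.5) == 1
        assert select_core_size(zc, 0.999) == 1

    def test_flat_spectrum_ceiling(self):
        # 50 orthogonal rows of equal norm: each eigenvalue carries 2%
        zc = CenteredGenotypes(Z=np.eye(50), p=np.full(50, 0.5), scale_k=1.0)
        assert select_core_size(zc, 0.98) == 49
        assert select_core_size(zc, 0.981) == 50

    def test_matches_grm_eigen_oracle(self):
        """Same k as applying the cumulative rule to eigenvalues of G itself."""
        rng = np.random.default_rng(3)
        z = rng.standard_normal((100, 500))
        zc = CenteredGenotypes(Z=z, p=np.full(500, 0.5), scale_k=250.0)
        ev = np.linalg.eigvalsh(z @ z.T / zc.scale_k)[::-1]
        cum = np.cumsum(ev) / ev.sum()
        for thr in (0.5, 0.9, 0.98, 0.99):
            expected = int(np.argmax(cum >= thr - 1e-12)) + 1
            assert select_core_size(zc, thr) == expected

    def test_threshold_one_recovers_rank(self):
        rng = np.random.default_rng(4)
        z = rng.standard_normal((30, 7)) @ rng.standard_normal((7, 60))  # rank 7
        zc = CenteredGenotypes(Z=z, p=np.full(60, 0.5), scale_k=30.0)
        assert select_core_size(zc, 1.0) == np.linalg.matrix_rank(z)

    def test_zero_matrix_raises(self):
        zc = CenteredGenotypes(Z=np.zeros((4, 4)), p=np.full(4, 0.5), scale_k=1.0)
        with pytest.raises(ValueError):
            select_core_size(zc, 0.98)


class TestSelectCoreAnimals:
    def test_all_core_is_full_index_set(self):
        np.testing.assert_array_equal(select_core_animals(7, 7, seed=0), np.arange(7))

    def test_deterministic_and_sorted(self):
        a = select_core_animals(100, 20, seed=5)
        b = select_core_animals(100, 20, seed=5)
        np.testing.assert_array_equal(a, b)
        assert np.all(np.diff(a) > 0)

    def test_oversized_core_raises(self):
        with pytest.raises(ValueError):
            select_core_animals(5, 6, seed=0)

    def test_uniform_inclusion_frequency(self):
        """Each of 10 animals appears in a 3-animal core with frequency 0.3."""
        hits = np.zeros(10)
        n_draws = 10_000
        for seed in range(n_draws):
            hits[select_core_animals(10, 3, seed=seed)] += 1
        np.testing.assert_allclose(hits / n_draws, 0.3, atol=0.02)


class TestApyInverse:
    def test_all_core_degenerates_to_dense_inverse(self, sim_grm_blended):
        apy = build_apy_inverse(sim_grm_blended, np.arange(sim_grm_blended.n))
        dense = np.linalg.inv(sim_grm_blended.G)
        assert apy.noncore_indices.size == 0
        np.testing.assert_allclose(assemble_apy_inverse(apy), dense, atol=1e-8)

    def test_hand_recursion_diagonal(self):
        gb = Grm(G=np.array([[1.0, 0.2], [0.2, 1.0]]), is_blended=True)
        apy = build_apy_inverse(gb, np.array([0]))
        assert apy.Mnn_diag[0] == pytest.approx(1 - 0.2 * 1.0 * 0.2)

    def test_block_assembly_matches_term_by_term_oracle(self):
        """Assembled G_APY⁻¹ equals the block formula evaluated from scratch."""
        _, _, gb = blended_grm_from_sim(30, 300, seed=31)
        core = select_core_animals(30, 10, seed=1)
        apy = build_apy_inverse(gb, core)

        noncore = np.setdiff1d(np.arange(30), core)
        g = gb.G
        gcc_inv = np.linalg.inv(g[np.ix_(core, core)])
        gcn = g[np.ix_(core, noncore)]
        mnn = np.array(
            [
                g[j, j] - g[j, core] @ gcc_inv @ g[core, j]
                for j in noncore
            ]
        )
        perm = np.concatenate([core, noncore])
        nc, nn = len(core), len(noncore)
        top = np.zeros((30, 30))
        top[:nc, :nc] = gcc_inv
        wings = np.vstack([-gcc_inv @ gcn, np.eye(nn)])
        oracle_perm = top + wings @ np.diag(1.0 / mnn) @ wings.T
        oracle = np.empty((30, 30))
        oracle[np.ix_(perm, perm)] = oracle_perm
        np.testing.assert_allclose(assemble_apy_inverse(apy), oracle, atol=1e-10)

    def test_matvec_matches_dense_assembly(self):
        _, _, gb = blended_grm_from_sim(40, 400, seed=32)
        apy = build_apy_inverse(gb, select_core_animals(40, 15, seed=2))
        dense = assemble_apy_inverse(apy)
        rng = np.random.default_rng(6)
        for _ in range(20):
            v = rng.standard_normal(40)
            np.testing.assert_allclose(apy_matvec(apy, v), dense @ v, atol=1e-8)

    def test_matvec_trivial_contracts(self, sim_grm_blended):
        apy = build_apy_inverse(sim_grm_blended, np.arange(sim_grm_blended.n))
        n = sim_grm_blended.n
        np.testing.assert_allclose(apy_matvec(apy, np.zeros(n)), 0.0)
        rng = np.random.default_rng(7)
        v = rng.standard_normal(n)
        np.testing.assert_allclose(
            apy_matvec(apy, v), np.linalg.solve(sim_grm_blended.G, v), atol=1e-8
        )
        with pytest.raises(ValueError):
            apy_matvec(apy, np.zeros(n + 1))

    def test_larger_cores_reduce_inverse_error(self):
        """mean |(G_APY⁻¹ − G_b⁻¹)v| is non-increasing in core size."""
        sizes = (10, 30, 60, 100)
        err = np.zeros(len(sizes))
        for seed in range(5):
            _, _, gb = blended_grm_from_sim(100, 500, seed=40 + seed)
            dense = np.linalg.inv(gb.G)
            rng = np.random.default_rng(50 + seed)
            vs = rng.standard_normal((10, 100))
            for k, n_core in enumerate(sizes):
                apy = build_apy_inverse(
                    gb, select_core_animals(100, n_core, seed=60 + seed)
                )
                err[k] += np.mean(
                    [np.abs(apy_matvec(apy, v) - dense @ v).mean() for v in vs]
                )
        err /= 5
        assert np.all(np.diff(err) <= 1e-9)
        assert err[-1] < 1e-8

    def test_core_row_deviation_shrinks_with_core(self):
        """Deviation of G_APY⁻¹·G_b from I decreases as the core grows and
        vanishes at all-core; with a blended G it is not exactly zero for a
        partial core even beyond the unblended rank."""
        _, _, gb = blended_grm_from_sim(60, 40, seed=41)
        devs = []
        for n_core in (20, 40, 60):
            apy = build_apy_inverse(gb, select_core_animals(60, n_core, seed=3))
            prod = assemble_apy_inverse(apy) @ gb.G
            devs.append(np.abs(prod - np.eye(60)).max())
        assert devs[0] >= devs[1] >= devs[2]
        assert devs[-1] < 1e-8

    def test_non_positive_diagonal_names_animal(self):
        g = np.ones((3, 3))  # rank 1, unblended: noncore fully dependent
        with pytest.raises(np.linalg.LinAlgError, match="noncore animal"):
            build_apy_inverse(Grm(G=g + 1e-13 * np.eye(3)), np.array([0]))

    def test_round_trip_npz(self, tmp_path, sim_grm_blended):
        from apygwas import ApyInverse

        apy = build_apy_inverse(
            sim_grm_blended, select_core_animals(sim_grm_blended.n, 30, seed=4)
        )
        apy.save(tmp_path / "apy.npz")
        back = ApyInverse.load(tmp_path / "apy.npz")
        rng = np.random.default_rng(8)
        v = rng.standard_normal(apy.n_total)
        np.testing.assert_array_equal(apy_matvec(apy, v), apy_matvec(back, v))
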