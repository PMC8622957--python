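"""Sparse coding (OMP) and dictionary learning (k-SVD) unit tests."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from scdsparse.errors import (
    DimensionMismatchError,
    InvalidArgumentError,
    RankDeficiencyError,
)
from scdsparse.experiments import brute_force_sparse_fit
from scdsparse.sparse_core import (
    CodingConfig,
    Dictionary,
    init_dictionary,
    ksvd_train,
    load_dictionary,
    omp_code,
    reconstruct,
    save_dictionary,
)


class TestInitDictionary:
    def test_columns_unit_norm(self):
        D = init_dictionary(4, 8, seed=1)
        assert D.atoms.shape == (4, 8)
        assert np.allclose(np.linalg.norm(D.atoms, axis=0), 1.0, atol=1e-9)

    def test_seed_determinism(self):
        a = init_dictionary(4, 8, seed=1)
        b = init_dictionary(4, 8, seed=1)
        assert np.array_equal(a.atoms, b.atoms)
        c = init_dictionary(4, 8, seed=2)
        assert not np.array_equal(a.atoms, c.atoms)

    def test_overcomplete_flag(self):
        assert init_dictionary(128, 256, seed=7).overcomplete
        assert not init_dictionary(8, 8, seed=7).overcomplete

    @pytest.mark.parametrize("n,m", [(1, 5), (0, 5), (4, 0), (-2, 3)])
    def test_invalid_sizes(self, n, m):
        with pytest.raises(InvalidArgumentError):
            init_dictionary(n, m, seed=0)

    def test_rejects_zero_or_unnormalized_atoms(self):
        with pytest.raises(InvalidArgumentError):
            Dictionary(atoms=np.zeros((4, 2)))
        with pytest.raises(InvalidArgumentError):
            Dictionary(atoms=2.0 * init_dictionary(4, 2, seed=0).atoms)


class TestCodingConfig:
    @pytest.mark.parametrize("eps", [0.0, -0.1, 1.5])
    def test_epsilon_range(self, eps):
        with pytest.raises(InvalidArgumentError):
            CodingConfig(epsilon=eps)

    def test_max_atoms_positive(self):
        with pytest.raises(InvalidArgumentError):
            CodingConfig(max_atoms=0)
        assert CodingConfig(max_atoms=200).resolved_max_atoms(16) == 16


class TestOMP:
    def test_exact_atom_match(self, small_dictionary):
        code = omp_code(small_dictionary, small_dictionary.atoms[:, 3],
                        CodingConfig(epsilon=0.05))
        assert code.support == [3]
        assert code.alpha[3] == pytest.approx(1.0, abs=1e-9)
        assert code.rel_error < 1e-15

    def test_epsilon_one_yields_empty_code(self, small_dictionary):
        x = small_dictionary.atoms[:, 0] + 0.3 * small_dictionary.atoms[:, 4]
        code = omp_code(small_dictionary, x, CodingConfig(epsilon=1.0))
        assert code.support == []
        assert np.all(code.alpha == 0.0)
        assert code.rel_error == 1.0

    def test_two_atom_combination_matches_brute_force(self):
        D = init_dictionary(4, 8, seed=4)
        x = 0.8 * D.atoms[:, 2] - 0.5 * D.atoms[:, 5]
        code = omp_code(D, x, CodingConfig(epsilon=1e-10))
        support, coef, res2 = brute_force_sparse_fit(D, x, 2)
        assert sorted(code.support) == sorted(support) == [2, 5]
        assert code.alpha[2] == pytest.approx(0.8, abs=1e-6)
        assert code.alpha[5] == pytest.approx(-0.5, abs=1e-6)
        assert res2 < 1e-20

    def test_zero_signal_rejected(self, small_dictionary):
        with pytest.raises(InvalidArgumentError):
            omp_code(small_dictionary, np.zeros(4))

    def test_dimension_mismatch(self, small_dictionary):
        with pytest.raises(DimensionMismatchError):
            omp_code(small_dictionary, np.ones(5))

    def test_duplicate_atoms_never_degenerate_the_support(self):
        """A dictionary holding numerically identical atoms: greedy pursuit
        must stop (residual orthogonal to the span) instead of looping or
        selecting a dependent atom."""
        rng = np.random.default_rng(0)
        a = rng.standard_normal(6)
        a /= np.linalg.norm(a)
        b = a + 1e-13 * np.eye(6)[0]
        b /= np.linalg.norm(b)
        D = Dictionary(atoms=np.column_stack([a, b]))
        x = a + 0.5 * rng.standard_normal(6)
        code = omp_code(D, x, CodingConfig(epsilon=1e-12))
        assert len(code.support) == 1  # the twin cannot enlarge the span
        assert abs(float(D.atoms[:, code.support[0]] @ code.residual)) < 1e-8

    def test_rank_deficiency_error_carries_support(self):
        err = RankDeficiencyError([3, 1, 4])
        assert err.support == [3, 1, 4]
        assert "3" in str(err)

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(seed=st.integers(0, 10**6))
    def test_contract_and_orthogonality(self, seed):
        """Stopping rule, residual orthogonality, duplicate-free support and
        rel_error consistency on random instances."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(6, 24))
        m = int(rng.integers(n, 2 * n))
        D = init_dictionary(n, m, seed=seed)
        x = rng.standard_normal(n)
        eps = float(rng.uniform(0.01, 0.9))
        cfg = CodingConfig(epsilon=eps, max_atoms=int(rng.integers(1, n + 1)))
        code = omp_code(D, x, cfg)
        assert code.rel_error < eps or len(code.support) == cfg.resolved_max_atoms(n)
        assert len(set(code.support)) == len(code.support)
        if code.support:
            ortho = np.abs(D.atoms[:, code.support].T @ code.residual)
            assert np.max(ortho) < 1e-8
        assert np.all(code.alpha[[i for i in range(m) if i not in code.support]] == 0.0)
        recomputed = float(code.residual @ code.residual) / float(x @ x)
        assert code.rel_error == pytest.approx(recomputed, abs=1e-9)

    def test_achieved_residual_never_beats_exhaustive_search(self):
        rng = np.random.default_rng(3)
        for seed in range(12):
            D = init_dictionary(6, 9, seed=seed)
            x = rng.standard_normal(6)
            code = omp_code(D, x, CodingConfig(epsilon=1e-12, max_atoms=2))
            _, _, best = brute_force_sparse_fit(D, x, 2)
            assert float(code.residual @ code.residual) >= best - 1e-9


class TestReconstruct:
    def test_zero_alpha_gives_zero(self, small_dictionary):
        from scdsparse.sparse_core import SparseCode

        code = SparseCode(alpha=np.zeros(8), support=[], residual=np.zeros(4), rel_error=1.0)
        assert np.array_equal(reconstruct(small_dictionary, code), np.zeros(4))

    def test_single_atom_synthesis(self, small_dictionary):
        alpha = np.zeros(8)
        alpha[6] = -2.5
        out = reconstruct(small_dictionary, alpha)
        assert np.allclose(out, -2.5 * small_dictionary.atoms[:, 6], atol=1e-12)

    def test_residual_consistency_at_epsilon(self, small_dictionary):
        rng = np.random.default_rng(5)
        x = rng.standard_normal(4)
        code = omp_code(small_dictionary, x, CodingConfig(epsilon=0.05))
        approx = reconstruct(small_dictionary, code)
        assert np.linalg.norm(x - approx) == pytest.approx(
            np.linalg.norm(code.residual), abs=1e-9
        )
        assert float(np.sum((x - approx) ** 2) / np.sum(x**2)) <= 0.05 + 1e-12

    def test_dimension_mismatch(self, small_dictionary):
        with pytest.raises(DimensionMismatchError):
            reconstruct(small_dictionary, np.zeros(9))


class TestKSVD:
    def test_rank_one_training_set_learns_the_signal(self):
        rng = np.random.default_rng(8)
        s = rng.standard_normal(10)
        s /= np.linalg.norm(s)
        X = np.tile(s[:, None], (1, 12))
        D0 = init_dictionary(10, 6, seed=0)
        # rank-1 data is coded one atom per signal, so the atom update sees
        # the whole signal and must converge onto it
        cfg = CodingConfig(epsilon=1e-6, max_atoms=1)
        D = ksvd_train(X, D0, K=2, cfg=cfg)
        sims = np.abs(D.atoms.T @ s)
        assert sims.max() > 1 - 1e-6
        assert omp_code(D, s, cfg).rel_error < 1e-6

    def test_atoms_stay_unit_norm_and_residual_decreases(self):
        from scdsparse.synthetic import make_planted_sparse_set

        ps = make_planted_sparse_set(n=12, m=20, M=240, s=2, noise_sigma=0.0, seed=4)
        D0 = init_dictionary(12, 20, seed=99)
        cfg = CodingConfig(epsilon=1e-6, max_atoms=2)
        D = ksvd_train(ps.signals, D0, K=6, cfg=cfg)
        assert np.allclose(np.linalg.norm(D.atoms, axis=0), 1.0, atol=1e-9)
        assert D.history[-1] < D.history[1]
        assert D.history[-1] <= D.history[0] * 1.05
        assert D.iterations == 6

    def test_training_is_deterministic(self):
        from scdsparse.synthetic import make_planted_sparse_set

        ps = make_planted_sparse_set(n=10, m=16, M=120, s=2, noise_sigma=0.0, seed=6)
        D0 = init_dictionary(10, 16, seed=7)
        cfg = CodingConfig(epsilon=1e-6, max_atoms=2)
        a = ksvd_train(ps.signals, D0, K=3, cfg=cfg)
        b = ksvd_train(ps.signals, D0, K=3, cfg=cfg)
        assert np.array_equal(a.atoms, b.atoms)

    def test_invalid_arguments(self):
        D0 = init_dictionary(4, 6, seed=0)
        X = np.random.default_rng(0).standard_normal((4, 5))
        with pytest.raises(InvalidArgumentError):
            ksvd_train(X, D0, K=0)
        with pytest.raises(InvalidArgumentError):
            ksvd_train(np.empty((4, 0)), D0, K=1)
        with pytest.raises(DimensionMismatchError):
            ksvd_train(np.ones((5, 3)), D0, K=1)


class TestSerialization:
    @pytest.mark.parametrize("suffix", [".txt", ".npz"])
    def test_lossless_round_trip(self, tmp_path, suffix):
        D = init_dictionary(6, 9, seed=11)
        D.class_label = "NSR"
        D.iterations = 20
        path = tmp_path / f"dict{suffix}"
        save_dictionary(D, path, epsilon=0.05)
        back = load_dictionary(path)
        assert np.array_equal(back.atoms, D.atoms)
        assert back.seed == 11
        assert back.iterations == 20
        assert back.class_label == "NSR"

    def test_rejects_foreign_file(self, tmp_path):
        from scdsparse.errors import FormatError

        p = tmp_path / "junk.txt"
        p.write_text("not a dictionary\n1\t2\n")
        with pytest.raises(FormatError):
            load_dictionary(p)
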