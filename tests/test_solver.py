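import numpy as np
import pytest

from episcan import (
    EffectMap,
    SolverConfig,
    average_over_sketches,
    make_sketch,
    omp_refit,
    permutation_threshold,
    sample_architecture,
    sample_genotypes,
    simulate_phenotype,
    sketch_gram,
    solve_block,
    solve_compressed_ridge,
    top_n_support,
)
from episcan.interactions import TermKey, n_pairs
from episcan.solver import default_sketch_dim, term_design


def all_terms(p):
    keys = [TermKey.single(i) for i in range(p)]
    keys += [TermKey.pair(i, j) for i in range(p) for j in range(i + 1, p)]
    return keys


class TestSketch:
    def test_identity_mode(self):
        A = make_sketch(4, 4, kind="identity", seed=0)
        assert np.array_equal(A.values, np.eye(4))
        with pytest.raises(ValueError):
            make_sketch(3, 4, kind="identity")

    def test_same_seed_identical(self):
        a = make_sketch(16, 100, seed=5)
        b = make_sketch(16, 100, seed=5)
        assert np.array_equal(a.values, b.values)

    def test_m_larger_than_d_rejected(self):
        with pytest.raises(ValueError):
            make_sketch(11, 10)

    @pytest.mark.parametrize("kind", ["gaussian", "rademacher"])
    def test_row_norm_concentration(self, kind):
        # rows have expected squared norm d/m; chi^2-type relative spread
        # sqrt(2/d) ~ 4.5% at d=1000, so 15% is a >3-sigma band
        A = make_sketch(64, 1000, kind=kind, seed=6)
        norms = np.square(A.values).sum(axis=1)
        assert np.allclose(norms, 1000 / 64, rtol=0.15)

    def test_default_dim_rule(self):
        assert default_sketch_dim(10) == 10  # capped at d
        d = 50_000
        assert default_sketch_dim(d) == int(np.ceil(8 * 50 * np.log(d)))


class TestSketchGram:
    def test_identity_gives_exact_gram(self):
        rng = np.random.default_rng(0)
        M = rng.standard_normal((20, 6))
        A = make_sketch(6, 6, kind="identity")
        assert np.allclose(sketch_gram(A, M), M.T @ M)

    def test_matches_naive_order_of_operations(self):
        rng = np.random.default_rng(1)
        M = rng.standard_normal((12, 8))
        A = make_sketch(5, 8, seed=2)
        naive = A.values @ (M.T @ M) @ A.values.T
        assert np.allclose(sketch_gram(A, M), naive, atol=1e-10)

    def test_symmetric_psd(self):
        rng = np.random.default_rng(2)
        M = rng.standard_normal((30, 15))
        G = sketch_gram(make_sketch(7, 15, seed=3), M)
        assert np.allclose(G, G.T)
        assert np.linalg.eigvalsh(G).min() > -1e-10

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            sketch_gram(make_sketch(3, 5, seed=1), np.zeros((4, 6)))


class TestCompressedRidge:
    def test_identity_zero_lambda_is_ols(self):
        M = np.array([[1.0, 0.0], [0.0, 1.0], [1.0, 1.0]])
        Y = np.array([1.0, 2.0, 3.0])
        theta = solve_compressed_ridge(M, Y, None, lam=0.0)
        assert np.allclose(theta, [1.0, 2.0], atol=1e-12)

    def test_huge_lambda_shrinks_to_zero(self):
        rng = np.random.default_rng(3)
        M = rng.standard_normal((50, 10))
        theta = solve_compressed_ridge(M, rng.standard_normal(50), None, lam=1e12)
        assert np.abs(theta).max() < 1e-6

    def test_planted_signal_survives_compression(self):
        # 2 strong planted coordinates among 50; m=25 gaussian sketch
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            M = rng.standard_normal((400, 50))
            theta_true = np.zeros(50)
            theta_true[[7, 31]] = [3.0, -3.0]
            Y = M @ theta_true + rng.standard_normal(400)
            cfg = SolverConfig(n_sketches=8, ridge_mult=1.0)
            est = np.zeros(50)
            for s in range(8):
                A = make_sketch(25, 50, seed=1000 * seed + s)
                est += solve_compressed_ridge(M, Y, A, config=cfg)
            top2 = set(np.argsort(-np.abs(est))[:2])
            hits += top2 == {7, 31}
        assert hits >= 18  # >= 90% of replicates

    def test_decompression_consistency(self):
        # theta = A' c exactly: re-sketching theta recovers c up to A A' distortion
        rng = np.random.default_rng(4)
        M = rng.standard_normal((60, 40))
        Y = rng.standard_normal(60)
        Y -= Y.mean()  # the solver contract expects a centered response
        A = make_sketch(20, 40, seed=5)
        theta = solve_compressed_ridge(M, Y, A, lam=1.0)
        B = M @ A.values.T
        c = np.linalg.solve(B.T @ B + 1.0 * np.eye(20), B.T @ Y)
        assert np.allclose(theta, A.values.T @ c, atol=1e-8)


class TestAveraging:
    def test_single_sketch_equals_one_solve(self):
        rng = np.random.default_rng(5)
        M = rng.standard_normal((80, 30))
        Y = rng.standard_normal(80)
        cfg = SolverConfig(n_sketches=1, sketch_dim=12, seed=9, ridge=2.0)
        avg = average_over_sketches(M, Y, cfg)
        from episcan.solver import seed_for

        A = make_sketch(12, 30, "gaussian", seed_for(9, "sketch", 0))
        single = solve_compressed_ridge(M, Y, A, lam=2.0, config=cfg)
        assert np.allclose(avg, single)

    def test_identity_path_ignores_sketch_count(self):
        rng = np.random.default_rng(6)
        M = rng.standard_normal((40, 10))
        Y = rng.standard_normal(40)
        one = average_over_sketches(M, Y, SolverConfig(n_sketches=1, ridge=1.0))
        many = average_over_sketches(M, Y, SolverConfig(n_sketches=5, ridge=1.0))
        assert np.array_equal(one, many)

    def test_variance_shrinks_with_averaging(self):
        rng = np.random.default_rng(7)
        M = rng.standard_normal((100, 60))
        Y = rng.standard_normal(100)

        def spread(S):
            ests = [
                average_over_sketches(
                    M, Y, SolverConfig(n_sketches=S, sketch_dim=20, ridge=5.0), seed=s
                )
                for s in range(20)
            ]
            return np.mean(np.var(ests, axis=0))

        assert spread(4) < 0.5 * spread(1)  # ~1/S scaling


class TestSolveBlock:
    def test_planted_pair_ranks_first(self):
        wins = 0
        for seed in range(10):
            X = sample_genotypes(2000, 100, seed=300 + seed)
            arch = sample_architecture(
                100, 0, 1, effect_range=(1.5, 1.5), target_h2=0.4, seed=400 + seed
            )
            Y = simulate_phenotype(X, arch, seed=500 + seed)
            em = solve_block(
                X, all_terms(100), Y.values,
                SolverConfig(dtype="float32", seed=seed),
            )
            i, j, _, _ = arch.pair_effects[0]
            wins += em.pairs_only().top(1)[0] == TermKey.pair(i, j)
        assert wins >= 9

    def test_permuted_phenotype_breaks_ranking(self):
        X = sample_genotypes(2000, 100, seed=310)
        arch = sample_architecture(
            100, 0, 1, effect_range=(1.5, 1.5), target_h2=0.4, seed=410
        )
        Y = simulate_phenotype(X, arch, seed=510)
        i, j, _, _ = arch.pair_effects[0]
        hits = 0
        for s in range(5):
            yp = np.random.default_rng(s).permutation(Y.values)
            em = solve_block(X, all_terms(100), yp, SolverConfig(dtype="float32", seed=s))
            hits += em.pairs_only().top(1)[0] == TermKey.pair(i, j)
        assert hits <= 1  # top-1 under the null is essentially uniform over 4950

    def test_duplicate_columns_split_but_sum_to_ols(self, tiny):
        # two SNPs with identical columns: ridge splits the effect evenly;
        # the sum matches the single-column OLS slope
        rng = np.random.default_rng(8)
        col = rng.binomial(1, 0.5, 200).astype(np.int8)
        X = tiny(np.column_stack([col, col]))
        y = 2.0 * col + 0.1 * rng.standard_normal(200)
        keys = [TermKey.single(0), TermKey.single(1)]
        em = solve_block(X, keys, y, SolverConfig(ridge=1e-6))
        yc = y - y.mean()
        colc = (col - col.mean()) / col.std()
        ols = float(colc @ yc / (colc @ colc))
        total = em.theta_std[keys[0]] + em.theta_std[keys[1]]
        assert total == pytest.approx(ols, rel=1e-4)
        assert em.theta_std[keys[0]] == pytest.approx(em.theta_std[keys[1]], rel=1e-6)

    def test_constant_column_reported_as_zero(self, tiny):
        X = tiny([[1, 0], [1, 1], [1, 0], [1, 1]])
        y = np.array([0.0, 1.0, 0.1, 1.1])
        em = solve_block(X, [TermKey.single(0), TermKey.single(1)], y, SolverConfig())
        assert em.theta_std[TermKey.single(0)] == 0.0
        assert em.theta[TermKey.single(0)] == 0.0
        assert em.theta_std[TermKey.single(1)] != 0.0

    def test_row_order_invariance(self):
        X = sample_genotypes(300, 20, seed=12)
        rng = np.random.default_rng(13)
        y = rng.standard_normal(300)
        cfg = SolverConfig(sketch_dim=64, seed=14)
        em1 = solve_block(X, all_terms(20), y, cfg)
        perm = rng.permutation(300)
        from episcan import GenotypeMatrix

        Xp = GenotypeMatrix(
            X.values[perm], X.markers, [X.individuals[i] for i in perm], X.ploidy
        )
        em2 = solve_block(Xp, all_terms(20), y[perm], cfg)
        a = np.array([em1.theta_std[k] for k in all_terms(20)])
        b = np.array([em2.theta_std[k] for k in all_terms(20)])
        assert np.allclose(a, b, atol=1e-8)

    def test_bit_reproducible(self):
        X = sample_genotypes(200, 15, seed=15)
        y = np.random.default_rng(16).standard_normal(200)
        cfg = SolverConfig(sketch_dim=32, seed=17)
        em1 = solve_block(X, all_terms(15), y, cfg)
        em2 = solve_block(X, all_terms(15), y, cfg)
        assert em1.theta_std == em2.theta_std

    def test_memory_guard(self):
        X = sample_genotypes(100, 50, seed=18)
        cfg = SolverConfig(memory_limit_bytes=1000)
        with pytest.raises(MemoryError, match="block_size"):
            solve_block(X, all_terms(50), np.random.default_rng(0).standard_normal(100), cfg)


class TestTopNSupport:
    def test_largest_magnitudes_kept(self):
        em = EffectMap(p=5)
        em.set(TermKey.single(0), 3.0, 3.0)
        em.set(TermKey.single(1), -5.0, -5.0)
        em.set(TermKey.single(2), 1.0, 1.0)
        top = top_n_support(em, 2)
        assert set(top.keys()) == {TermKey.single(1), TermKey.single(0)}
        assert top.support_score[TermKey.single(1)] == 5.0

    def test_oversized_n_star_warns_and_returns_all(self):
        em = EffectMap(p=3)
        em.set(TermKey.single(0), 1.0, 1.0)
        with pytest.warns(UserWarning, match="exceeds"):
            top = top_n_support(em, 50)
        assert len(top) == 1

    def test_exact_ties_break_lexicographically(self):
        em = EffectMap(p=4)
        for key in [TermKey.pair(0, 3), TermKey.pair(0, 1), TermKey.single(2)]:
            em.set(key, 2.0, 2.0)
        assert top_n_support(em, 2).top(2) == [TermKey.pair(0, 1), TermKey.pair(0, 3)]


class TestEffectMapIO:
    def _map(self):
        em = EffectMap(p=6)
        em.set(TermKey.single(2), 1.5, 3.0)
        em.set(TermKey.pair(0, 4), -2.25, -4.5)
        em.support_score[TermKey.pair(0, 4)] = 2.25
        return em

    def test_tsv_round_trip(self, tmp_path):
        em = self._map()
        em.to_tsv(tmp_path / "e.tsv")
        em2 = EffectMap.from_tsv(tmp_path / "e.tsv", p=6)
        assert em2.theta == em.theta
        assert em2.theta_std == em.theta_std
        assert em2.support_score == em.support_score

    def test_hdf5_round_trip(self, tmp_path):
        em = self._map()
        em.to_hdf5(tmp_path / "e.h5")
        em2 = EffectMap.from_hdf5(tmp_path / "e.h5")
        assert em2.theta == em.theta and em2.p == 6


class TestOmpRefit:
    def test_recovers_planted_support_and_drops_relatives(self):
        X = sample_genotypes(1500, 40, seed=19)
        arch = sample_architecture(40, 1, 1, target_h2=0.6, seed=20)
        Y = simulate_phenotype(X, arch, seed=21)
        s = arch.simple_effects[0][0]
        i, j, _, _ = arch.pair_effects[0]
        truth = [TermKey.single(s), TermKey.pair(i, j)]
        # candidate pool includes the truth plus correlated relatives
        relatives = [TermKey.pair(*sorted((s, t))) for t in range(5) if t != s]
        pool = truth + relatives + [TermKey.single(t) for t in range(5)]
        pool = list(dict.fromkeys(pool))
        keys, t_std, _ = omp_refit(X, Y.values, pool, n_select=2)
        assert set(keys) == set(truth)

    def test_refit_matches_ols_on_selected(self):
        X = sample_genotypes(600, 10, seed=22)
        y = np.random.default_rng(23).standard_normal(600)
        keys, t_std, t_raw = omp_refit(X, y, [TermKey.single(i) for i in range(10)], 3)
        M, _, sd = term_design(X, keys, standardize=True)
        coef, *_ = np.linalg.lstsq(M, y - y.mean(), rcond=None)
        assert np.allclose([t_std[k] for k in keys], coef)


class TestCvRidgeSelection:
    def test_strong_dense_signal_prefers_weak_penalty(self):
        X = sample_genotypes(400, 10, seed=27)
        rng = np.random.default_rng(28)
        beta = rng.standard_normal(10)
        y = X.values.astype(float) @ beta + 0.3 * rng.standard_normal(400)
        from episcan import select_ridge_cv

        keys = [TermKey.single(i) for i in range(10)]
        lam = select_ridge_cv(X, keys, y, seed=29)
        assert lam == pytest.approx(0.1 * 400)  # smallest grid multiplier

    def test_high_dimensional_noise_prefers_strong_penalty(self):
        # near-square noise design: CV must avoid the overfitting weak end
        X = sample_genotypes(200, 150, seed=30)
        y = np.random.default_rng(31).standard_normal(200)
        from episcan import select_ridge_cv

        keys = [TermKey.single(i) for i in range(150)]
        lam = select_ridge_cv(X, keys, y, seed=32)
        assert lam >= 10 * 200  # one of the strong-shrinkage entries


class TestPermutationThreshold:
    def test_quantile_one_is_max(self, small_inbred):
        y = np.random.default_rng(24).standard_normal(small_inbred.n)
        keys = [TermKey.single(i) for i in range(small_inbred.p)]
        cfg = SolverConfig(seed=25)
        thr = permutation_threshold(small_inbred, keys, y, cfg, n_perm=20, quantile=1.0)
        maxima = []
        from episcan.solver import seed_for

        for b in range(20):
            rng = np.random.default_rng(seed_for(25, "perm", b))
            em = solve_block(
                small_inbred, keys, rng.permutation(y), cfg,
                seed=seed_for(25, "permsolve", b),
            )
            maxima.append(max(abs(v) for v in em.theta_std.values()))
        assert thr == pytest.approx(max(maxima))

    def test_planted_signal_exceeds_threshold(self):
        exceed = 0
        keys = None
        for s in range(5):
            X = sample_genotypes(2000, 40, seed=600 + s)
            arch = sample_architecture(40, 0, 1, target_h2=0.3, seed=700 + s)
            Y = simulate_phenotype(X, arch, seed=800 + s)
            keys = all_terms(40)
            cfg = SolverConfig(dtype="float32", seed=s)
            em = solve_block(X, keys, Y.values, cfg)
            obs = max(abs(v) for v in em.theta_std.values())
            thr = permutation_threshold(X, keys, Y.values, cfg, n_perm=20)
            exceed += obs > thr
        assert exceed >= 4

    def test_too_few_permutations_rejected(self, small_inbred):
        y = np.random.default_rng(26).standard_normal(small_inbred.n)
        with pytest.raises(ValueError):
            permutation_threshold(
                small_inbred, [TermKey.single(0)], y, SolverConfig(), n_perm=5
            )
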