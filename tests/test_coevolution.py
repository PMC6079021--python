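"""Frequency models, covariance, precision estimation, PSICOV scores,
APC, thresholding and the shuffle null."""

import numpy as np
import pytest
from scipy import stats

from coevoring import (
    Msa,
    apc_correct,
    build_covariance,
    column_shuffle_null,
    compute_coevolution,
    normalize_and_threshold,
    pair_frequencies,
    psicov_score_matrix,
    sparse_precision,
    sequence_weights,
)
from coevoring.errors import CoevoringError, ParameterError
from coevoring.msa import N_STATES


def _msa(rows, ids=None):
    ids = ids or [f"s{k}" for k in range(len(rows))]
    return Msa(ids=ids, rows=rows, reference_id=ids[0])


class TestPairFrequencies:
    def test_pure_column(self):
        fm = pair_frequencies(_msa(["AC", "AC", "AC"]), lam=0.0)
        assert fm.f1[0, 0] == pytest.approx(1.0)  # index 0 = 'A'
        assert fm.f1[0, 1:].sum() == pytest.approx(0.0)

    def test_perfectly_correlated_pair(self):
        fm = pair_frequencies(_msa(["AA", "AA", "CC", "CC"]), lam=0.0)
        block = fm.f2[0, 1]
        assert block[0, 0] == pytest.approx(0.5)  # (A, A)
        assert block[1, 1] == pytest.approx(0.5)  # (C, C)
        assert block.sum() == pytest.approx(1.0)

    def test_large_lambda_limit_is_uniform(self):
        fm = pair_frequencies(_msa(["AC", "AC"]), lam=1e12)
        assert np.allclose(fm.f1, 1.0 / N_STATES, atol=1e-9)

    def test_f2_marginals_match_f1_without_gaps(self):
        rng = np.random.default_rng(0)
        rows = ["".join(rng.choice(list("ACDE"), 4)) for _ in range(30)]
        fm = pair_frequencies(_msa(rows), lam=1.0)
        for i, j in [(0, 1), (1, 3)]:
            assert np.allclose(fm.f2[i, j].sum(axis=1), fm.f1[i], atol=1e-9)
            assert np.allclose(fm.f2[i, j].sum(axis=0), fm.f1[j], atol=1e-9)

    def test_all_gap_column_errors(self):
        with pytest.raises(CoevoringError, match="column 2"):
            pair_frequencies(_msa(["A-", "A-"]))


class TestCovariance:
    def test_constant_column_blocks_vanish(self):
        fm = pair_frequencies(_msa(["AC", "AD", "AC", "AE"]), lam=0.0)
        cov = build_covariance(fm)
        assert np.allclose(cov[:N_STATES, N_STATES:], 0.0, atol=1e-12)

    def test_diagonal_block_multinomial_form(self):
        fm = pair_frequencies(_msa(["AC", "CC", "AC", "DC"]), lam=0.0)
        cov = build_covariance(fm)
        f = fm.f1[0]
        expected = np.diag(f) - np.outer(f, f)
        assert np.allclose(cov[:N_STATES, :N_STATES], expected, atol=1e-12)

    def test_independent_columns_small_offdiagonal(self):
        rng = np.random.default_rng(3)
        n = 4000
        rows = ["".join(r) for r in rng.choice(list("ACDEFG"), size=(n, 2))]
        fm = pair_frequencies(_msa(rows), lam=0.0)
        cov = build_covariance(fm)
        off = cov[:N_STATES, N_STATES:]
        assert np.abs(off).max() < 3.0 / np.sqrt(n)


class TestSparsePrecision:
    def test_identity_maps_to_identity(self):
        eye = np.eye(6)
        assert np.allclose(sparse_precision(eye, rho=0.0), eye, atol=1e-10)

    @pytest.mark.parametrize("dim", [8, 17, 40])
    def test_rho_zero_matches_direct_inverse(self, dim):
        rng = np.random.default_rng(dim)
        A = rng.normal(size=(dim, dim))
        spd = A @ A.T + dim * np.eye(dim)
        prec = sparse_precision(spd, rho=0.0)
        direct = np.linalg.inv(spd)
        rel = np.abs(prec - direct).max() / np.abs(direct).max()
        assert rel < 1e-6

    def test_large_penalty_kills_offdiagonal(self):
        rng = np.random.default_rng(0)
        A = rng.normal(size=(6, 6))
        spd = A @ A.T + 6 * np.eye(6)
        prec = sparse_precision(spd, rho=50.0)
        off = prec - np.diag(np.diag(prec))
        assert np.abs(off).max() < 1e-6

    def test_negative_penalty_rejected(self):
        with pytest.raises(ParameterError):
            sparse_precision(np.eye(3), rho=-1.0)


class TestPsicovScore:
    def test_block_diagonal_gives_zero(self):
        L = 3
        prec = np.eye(L * N_STATES)
        raw = psicov_score_matrix(prec, L)
        assert np.allclose(raw, 0.0)

    def test_single_entry(self):
        L = 2
        prec = np.zeros((L * N_STATES, L * N_STATES))
        prec[3, N_STATES + 7] = 0.5
        raw = psicov_score_matrix(prec, L)
        # symmetrised over the two half-blocks: (0.5 + 0) / 2
        assert raw[0, 1] == pytest.approx(0.25)
        prec[N_STATES + 7, 3] = 0.5
        assert psicov_score_matrix(prec, L)[0, 1] == pytest.approx(0.5)

    def test_sum_of_absolute_values(self):
        L = 2
        prec = np.zeros((L * N_STATES, L * N_STATES))
        prec[0, N_STATES] = 0.1
        prec[N_STATES, 0] = 0.1
        prec[1, N_STATES + 1] = -0.2
        prec[N_STATES + 1, 1] = -0.2
        raw = psicov_score_matrix(prec, L)
        assert raw[0, 1] == pytest.approx(0.3)

    def test_dimension_mismatch(self):
        with pytest.raises(ParameterError):
            psicov_score_matrix(np.eye(10), 3)


class TestApc:
    def test_constant_matrix_cancels_exactly(self):
        L = 5
        raw = np.full((L, L), 2.0)
        np.fill_diagonal(raw, 0.0)
        assert np.allclose(apc_correct(raw), 0.0, atol=1e-12)

    def test_hand_computed_three_by_three(self):
        raw = np.array([[0.0, 1.0, 2.0], [1.0, 0.0, 3.0], [2.0, 3.0, 0.0]])
        apc = apc_correct(raw)
        # row means (1.5, 2, 2.5), overall mean 2
        assert apc[0, 1] == pytest.approx(-0.5, abs=1e-12)
        assert apc[0, 2] == pytest.approx(0.125, abs=1e-12)
        assert apc[1, 2] == pytest.approx(0.5, abs=1e-12)

    def test_matches_bruteforce_recompute(self):
        rng = np.random.default_rng(7)
        L = 12
        raw = np.abs(rng.normal(size=(L, L)))
        raw = (raw + raw.T) / 2
        np.fill_diagonal(raw, 0.0)
        apc = apc_correct(raw)
        mean_all = np.mean([raw[i, j] for i in range(L) for j in range(i + 1, L)])
        for i, j in [(0, 5), (3, 9), (10, 11)]:
            mi = raw[i].sum() / (L - 1)
            mj = raw[j].sum() / (L - 1)
            assert apc[i, j] == pytest.approx(raw[i, j] - mi * mj / mean_all, abs=1e-12)

    def test_zero_mean_returns_input(self):
        raw = np.zeros((4, 4))
        assert np.allclose(apc_correct(raw), raw)


class TestNormalizeAndThreshold:
    def test_degenerate_distribution_errors(self):
        apc = np.ones((8, 8))
        np.fill_diagonal(apc, 0.0)
        with pytest.raises(CoevoringError, match="degenerate"):
            normalize_and_threshold(apc, min_separation=1, min_eligible=2)

    def test_hand_z_score_of_lone_outlier(self):
        # one score 10 among n-1 zeros has z = sqrt(n - 1): for the spec's
        # 4-pair case 1.732; here 6 eligible pairs -> sqrt(5)
        vals = np.array([0.0, 0.0, 0.0, 10.0])
        assert (vals.max() - vals.mean()) / vals.std() == pytest.approx(np.sqrt(3), rel=1e-9)
        apc = np.zeros((4, 4))
        apc[0, 3] = apc[3, 0] = 10.0
        z, couplings, frac = normalize_and_threshold(
            apc, sigma_cut=1.5, min_separation=1, min_eligible=4
        )
        assert len(couplings) == 1
        assert couplings[0].z == pytest.approx(np.sqrt(5), rel=1e-6)
        assert (couplings[0].i, couplings[0].j) == (1, 4)
        assert frac == pytest.approx(1 / 6)

    def test_minus_infinity_returns_all_sorted(self):
        rng = np.random.default_rng(1)
        apc = np.abs(rng.normal(size=(7, 7)))
        apc = (apc + apc.T) / 2
        np.fill_diagonal(apc, 0.0)
        z, couplings, frac = normalize_and_threshold(
            apc, sigma_cut=-np.inf, min_separation=1, min_eligible=2
        )
        assert len(couplings) == 21
        zs = [c.z for c in couplings]
        assert zs == sorted(zs, reverse=True)
        assert frac == pytest.approx(1.0)

    def test_z_standardisation_invariant(self):
        rng = np.random.default_rng(2)
        apc = np.abs(rng.normal(size=(12, 12)))
        apc = (apc + apc.T) / 2
        np.fill_diagonal(apc, 0.0)
        z, _, _ = normalize_and_threshold(apc, min_separation=2, min_eligible=2)
        iu = np.triu_indices(12, 2)
        assert z[iu].mean() == pytest.approx(0.0, abs=1e-9)
        assert z[iu].std() == pytest.approx(1.0, abs=1e-9)


class TestShuffleNull:
    def test_column_composition_preserved(self, tiny_msa):
        out = column_shuffle_null(tiny_msa, seed=5)
        for c in range(tiny_msa.L):
            before = sorted(r[c] for r in tiny_msa.rows)
            after = sorted(r[c] for r in out.rows)
            assert before == after

    def test_deterministic_per_seed(self, tiny_msa):
        a = column_shuffle_null(tiny_msa, seed=9)
        b = column_shuffle_null(tiny_msa, seed=9)
        assert a.rows == b.rows
        c = column_shuffle_null(tiny_msa, seed=10)
        assert a.rows != c.rows or tiny_msa.N < 2


class TestPipelineProperties:
    def test_column_permutation_equivariance(self):
        rng = np.random.default_rng(4)
        rows = ["".join(r) for r in rng.choice(list("ACDEFGHIKL"), size=(80, 8))]
        msa = _msa(rows)
        res = compute_coevolution(msa, rho=0.0, min_separation=1)
        perm = rng.permutation(8)
        msa_p = _msa(["".join(row[p] for p in perm) for row in rows])
        res_p = compute_coevolution(msa_p, rho=0.0, min_separation=1)
        assert np.allclose(res_p.raw, res.raw[np.ix_(perm, perm)], atol=1e-8)

    def test_duplicating_rows_leaves_raw_invariant(self):
        rng = np.random.default_rng(5)
        rows = ["".join(r) for r in rng.choice(list("ACDEFG"), size=(40, 6))]
        msa = _msa(rows)
        doubled = _msa(rows + rows, ids=[f"s{k}" for k in range(80)])
        w1 = sequence_weights(msa)
        w2 = sequence_weights(doubled)
        assert w2.n_eff == pytest.approx(w1.n_eff)
        r1 = compute_coevolution(msa, weights=w1, rho=0.0, min_separation=1)
        r2 = compute_coevolution(doubled, weights=w2, rho=0.0, min_separation=1)
        assert np.allclose(r1.raw, r2.raw, atol=1e-8)

    def test_shuffle_symmetrises_score_distribution(self, planted_small):
        msa, truth, result = planted_small
        shuffled = column_shuffle_null(msa, seed=77)
        res_null = compute_coevolution(shuffled, sigma_cut=2.5, seed=77)
        iu = np.triu_indices(msa.L, 5)
        skew_before = abs(stats.skew(result.z[iu]))
        skew_after = abs(stats.skew(res_null.z[iu]))
        assert skew_after < skew_before

    def test_planted_pairs_score_highest(self, planted_small):
        msa, truth, result = planted_small
        top = {(c.i, c.j) for c in result.couplings[: len(truth.planted_pairs)]}
        assert top == set(truth.planted_pairs)
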