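"""Decomposition core: log transform, imputation, SVD, significance,
membership, activity, reconstruction."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.linalg import subspace_angles

import secretoscope as sc
from conftest import brute_force_svd


def _df(arr, prefix=("r", "c")):
    arr = np.asarray(arr, dtype=float)
    return pd.DataFrame(
        arr,
        index=[f"{prefix[0]}{i}" for i in range(arr.shape[0])],
        columns=[f"{prefix[1]}{j}" for j in range(arr.shape[1])],
    )


class TestLogTransform:
    def test_known_values(self):
        sec = sc.SecretomeMatrix(
            _df([[1.0, 0.0, np.e]]), detection_floor=0.1
        )
        ln = sc.log_transform(sec)
        np.testing.assert_allclose(
            ln.to_numpy()[0], [0.0, np.log(0.1), 1.0], atol=1e-6
        )

    def test_missing_stays_missing(self, small_secretome):
        ln = sc.log_transform(small_secretome)
        assert ln.isna().equals(small_secretome.values.isna())


class TestImputation:
    def test_no_missing_is_identity(self):
        x = _df(np.arange(12.0).reshape(3, 4) + 1)
        out = sc.impute_missing_svd(x, rank=2)
        assert out.values.equals(x)
        assert out.n_iter == 0 and out.converged

    def test_rank1_closed_form(self):
        """Masked entry of outer((1,2),(1,3)) completes to 2·3 = 6."""
        x = _df(np.outer([1.0, 2.0], [1.0, 3.0]))
        x.iloc[1, 1] = np.nan
        out = sc.impute_missing_svd(x, rank=1)
        assert abs(out.values.iloc[1, 1] - 6.0) < 1e-6

    def test_exact_low_rank_completion(self):
        """5%-masked rank-2 20×20 matrices complete to < 1e-6 error."""
        rng = np.random.default_rng(5)
        truth = rng.standard_normal((20, 2)) @ rng.standard_normal((2, 20))
        masked = truth.copy()
        idx = rng.choice(400, size=20, replace=False)
        masked.flat[idx] = np.nan
        out = sc.impute_missing_svd(_df(masked), rank=2)
        assert np.abs(out.values.to_numpy() - truth).max() < 1e-6

    def test_observed_entries_never_altered(self):
        rng = np.random.default_rng(1)
        truth = rng.standard_normal((10, 3)) @ rng.standard_normal((3, 10))
        x = _df(truth)
        x.iloc[0, 0] = np.nan
        out = sc.impute_missing_svd(x, rank=3)
        obs = ~x.isna().to_numpy()
        np.testing.assert_array_equal(
            out.values.to_numpy()[obs], x.to_numpy()[obs])

    def test_all_missing_row_raises(self):
        x = _df([[1.0, 2.0], [np.nan, np.nan]])
        with pytest.raises(ValueError, match="r1"):
            sc.impute_missing_svd(x, rank=1)

    def test_non_convergence_warns_not_raises(self):
        x = _df(np.outer([1.0, 2.0], [1.0, 3.0]))
        x.iloc[1, 1] = np.nan
        with pytest.warns(RuntimeWarning, match="converge"):
            out = sc.impute_missing_svd(x, rank=1, max_iter=2)
        assert not out.converged


class TestDecompose:
    def test_matches_gram_eigendecomposition_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            shape = rng.integers(2, 11, size=2)
            x = rng.standard_normal(shape)
            res = sc.decompose(_df(x))
            s_oracle, u_oracle, _ = brute_force_svd(x)
            np.testing.assert_allclose(res.singular_values, s_oracle, atol=1e-8)
            for j in range(len(s_oracle)):
                if s_oracle[j] < 1e-9:
                    continue
                dot = abs(res.G.iloc[:, j].to_numpy() @ u_oracle[:, j])
                assert dot == pytest.approx(1.0, abs=1e-8)

    def test_identical_columns_have_no_process_amplitudes(self):
        x = _df(np.tile([[1.0], [2.0], [5.0]], (1, 6)))
        res = sc.decompose(x)
        assert np.abs(res.lam.to_numpy()[1:]).max() < 1e-8

    def test_full_reconstruction(self, paper_like):
        sec, _ = paper_like
        ln = sc.log_transform(sec)
        res = sc.decompose(ln)
        recon = res.G.to_numpy() @ res.lam.to_numpy()
        np.testing.assert_allclose(recon, ln.to_numpy(), atol=1e-8)

    def test_orthogonality_invariants(self, paper_like):
        sec, _ = paper_like
        res = sc.decompose(sc.log_transform(sec))
        g = res.G.to_numpy()
        np.testing.assert_allclose(g.T @ g, np.eye(g.shape[1]), atol=1e-10)
        llt = res.lam.to_numpy() @ res.lam.to_numpy().T
        np.testing.assert_allclose(llt - np.diag(np.diag(llt)), 0, atol=1e-8)
        assert (np.diff(res.singular_values) <= 1e-12).all()

    def test_single_process_amplitude_recovered(self):
        truth = sc.make_truth(k_true=1, noise_sd=0.0, seed=13)
        sec, _ = sc.gen_secretome(truth)
        res = sc.decompose(sc.log_transform(sec))
        lam = res.lam.iloc[1].to_numpy()
        r = np.corrcoef(lam, truth.planted_lambda[0])[0, 1]
        assert abs(abs(r) - 1.0) < 1e-8

    def test_sign_convention(self, paper_like):
        sec, _ = paper_like
        res = sc.decompose(sc.log_transform(sec))
        for alpha in range(res.n_components):
            col = res.G.iloc[:, alpha].to_numpy()
            assert col[np.argmax(np.abs(col))] > 0

    def test_scale_covariance(self, paper_like):
        """Multiplying concentrations by c only shifts the steady state:
        ln(cX) = ln c + ln X, and the added uniform term shares the steady
        state's sample direction.  Exact in the noiseless model; with
        noise, the extra term couples to noise components, so only
        noise-order deviations are tolerated."""
        truth = sc.make_truth(noise_sd=0.0, seed=2)
        clean, _ = sc.gen_secretome(truth)
        r1 = sc.decompose(sc.log_transform(clean))
        scaled = sc.SecretomeMatrix(clean.values * 37.0, clean.detection_floor)
        r2 = sc.decompose(sc.log_transform(scaled))
        np.testing.assert_allclose(r1.lam.to_numpy()[1:5],
                                   r2.lam.to_numpy()[1:5], atol=1e-8)

        sec, _ = paper_like
        res1 = sc.decompose(sc.log_transform(sec))
        res2 = sc.decompose(sc.log_transform(
            sc.SecretomeMatrix(sec.values * 37.0, sec.detection_floor)))
        np.testing.assert_allclose(
            res1.lam.to_numpy()[1:5], res2.lam.to_numpy()[1:5], atol=0.01
        )

    def test_rejects_missing_and_single_sample(self):
        with pytest.raises(ValueError, match="missing"):
            sc.decompose(_df([[1.0, np.nan], [2.0, 3.0]]))
        with pytest.raises(ValueError, match="2 samples"):
            sc.decompose(_df([[1.0], [2.0]]))


class TestSignificance:
    def test_noiseless_count_is_exact(self):
        truth = sc.make_truth(k_true=2, noise_sd=0.0, seed=3)
        sec, _ = sc.gen_secretome(truth)
        res = sc.decompose(sc.log_transform(sec))
        assert sc.count_significant_processes(res, noise_sd=0.0, seed=0) == 2

    def test_paper_like_recovery_rate(self):
        """K = K_true in >= 90% of seeds at signal-to-noise 10."""
        hits = 0
        n_seeds = 25
        for seed in range(n_seeds):
            truth = sc.make_truth(seed=seed)
            sec, _ = sc.gen_secretome(truth)
            res = sc.decompose(sc.log_transform(sec))
            hits += sc.count_significant_processes(
                res, noise_sd=0.1, n_boot=50, seed=seed) == 4
        assert hits >= 0.9 * n_seeds

    def test_pure_noise_yields_zero(self):
        hits = 0
        n_seeds = 25
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed + 500)
            noise = _df(rng.normal(0, 0.1, (30, 48)))
            res = sc.decompose(noise)
            hits += sc.count_significant_processes(
                res, noise_sd=0.1, n_boot=50, seed=seed) == 0
        assert hits >= 0.9 * n_seeds

    def test_spectral_noise_estimate_close(self, paper_like):
        sec, truth = paper_like
        res = sc.decompose(sc.log_transform(sec))
        sc.count_significant_processes(res, noise_sd="estimate", seed=0)
        assert res.noise_sd_est == pytest.approx(truth.noise_sd, rel=0.3)

    def test_replicate_noise_estimator(self):
        sec, _, meta, truth = sc.simulate_study(
            seed=21, replicates=4, treatment_shifts={}
        )
        est = sc.estimate_noise_sd_replicates(sec, meta)
        assert est == pytest.approx(truth.noise_sd, rel=0.15)

    def test_small_n_boot_rejected(self, paper_like):
        sec, _ = paper_like
        res = sc.decompose(sc.log_transform(sec))
        with pytest.raises(ValueError, match="n_boot"):
            sc.count_significant_processes(res, n_boot=5)


def _result_with_g(g_col):
    """DecompositionResult with a given process-1 weight vector."""
    n = len(g_col)
    g0 = np.ones(n) / np.sqrt(n)
    G = pd.DataFrame({"0": g0, "1": np.asarray(g_col, dtype=float)},
                     index=[f"c{i + 1}" for i in range(n)])
    lam = pd.DataFrame(np.ones((2, 3)), index=["0", "1"],
                       columns=["s1", "s2", "s3"])
    return sc.DecompositionResult(G=G, lam=lam,
                                  singular_values=np.array([2.0, 1.0]))


class TestMembership:
    def test_worked_example(self):
        """|G| vector with two tiny trailing weights: baseline = mean of the
        two smallest, 20× cutoff keeps exactly cytokines 1–3."""
        g = [0.50, 0.24, 0.30, 0.013, 0.02, 0.015, 0.012, 0.011, 0.009, 0.010]
        proc = sc.process_membership(_result_with_g(g), 1,
                                     fold=20, quantile=0.20)
        assert proc.member_ids == ["c1", "c2", "c3"]

    def test_signed_weights_and_exclusion(self):
        """Opposite-sign members move in opposite directions; near-zero
        weights are excluded by any reasonable baseline."""
        proc = sc.process_membership(_result_with_g([-0.50, 0.24, 0.02]), 1,
                                     fold=10, quantile=0.34)
        assert proc.member_ids == ["c1", "c2"]
        assert proc.member_weights["c1"] < 0 < proc.member_weights["c2"]

    def test_all_equal_weights(self):
        res = _result_with_g([0.3, 0.3, 0.3, 0.3])
        assert len(sc.process_membership(res, 1, fold=1.0).member_ids) == 4
        assert len(sc.process_membership(res, 1, fold=1.01).member_ids) == 0

    def test_steady_state_has_no_membership(self):
        with pytest.raises(ValueError, match="steady state"):
            sc.process_membership(_result_with_g([0.1, 0.2]), 0)

    @given(
        g=st.lists(st.floats(-1, 1, allow_nan=False, width=32),
                   min_size=3, max_size=20),
        fold_lo=st.floats(1, 30),
        fold_hi=st.floats(0, 30),
    )
    @settings(max_examples=50, deadline=None)
    def test_membership_monotone_in_fold(self, g, fold_lo, fold_hi):
        """Raising the fold cutoff never adds members."""
        res = _result_with_g(g)
        lo = sc.process_membership(res, 1, fold=fold_lo)
        hi = sc.process_membership(res, 1, fold=fold_lo + fold_hi)
        assert set(hi.member_ids) <= set(lo.member_ids)


class TestActivity:
    def test_worked_example(self):
        """λ = (3.1, 0.02, 2.5) at threshold 1: samples 1 and 3 active in
        the same direction, sample 2 inactive."""
        res = _result_with_g([0.5, 0.5])
        res.lam = pd.DataFrame([[1.0, 1.0, 1.0], [3.1, 0.02, 2.5]],
                               index=["0", "1"], columns=["s1", "s2", "s3"])
        proc = sc.process_activity(res, 1, threshold=1.0)
        assert list(proc.activity_calls) == [
            "active_positive", "inactive", "active_positive"
        ]

    def test_zero_amplitudes_all_inactive(self):
        res = _result_with_g([0.5, 0.5])
        res.lam.iloc[1] = 0.0
        proc = sc.process_activity(res, 1, threshold=1.0)
        assert (proc.activity_calls == "inactive").all()

    def test_sign_symmetry(self):
        res = _result_with_g([0.5, 0.5])
        res.lam = pd.DataFrame([[1.0, 1.0], [-2.0, 2.0]],
                               index=["0", "1"], columns=["s1", "s2"])
        proc = sc.process_activity(res, 1, threshold=1.0)
        assert list(proc.activity_calls) == ["active_negative", "active_positive"]

    def test_bad_threshold_rejected(self):
        res = _result_with_g([0.5, 0.5])
        with pytest.raises(ValueError, match="threshold"):
            sc.process_activity(res, 1, threshold=-1.0)
        with pytest.raises(ValueError, match="count_significant"):
            sc.process_activity(res, 1, threshold="auto")

    def test_auto_uses_null_threshold(self, paper_like):
        sec, _ = paper_like
        res = sc.decompose(sc.log_transform(sec))
        sc.count_significant_processes(res, noise_sd=0.1, seed=0)
        proc = sc.process_activity(res, 1, threshold="auto")
        assert proc.activity_threshold == pytest.approx(res.null_threshold)
        lam = res.lam.iloc[1]
        for s in lam.index:
            expected = ("active_positive" if lam[s] > proc.activity_threshold
                        else "active_negative" if lam[s] < -proc.activity_threshold
                        else "inactive")
            assert proc.activity_calls[s] == expected


class TestReconstruct:
    def test_steady_state_only_is_rank_one(self, paper_like):
        sec, _ = paper_like
        res = sc.decompose(sc.log_transform(sec))
        rec = sc.reconstruct(res, 0)
        assert np.linalg.matrix_rank(rec.to_numpy(), tol=1e-8) <= 1

    def test_all_processes_reproduce_input(self, paper_like):
        sec, _ = paper_like
        ln = sc.log_transform(sec)
        res = sc.decompose(ln)
        rec = sc.reconstruct(res, res.n_components - 1)
        np.testing.assert_allclose(rec.to_numpy(), ln.to_numpy(), atol=1e-8)

    def test_truncation_at_k_true_leaves_noise_floor(self, paper_like):
        sec, truth = paper_like
        ln = sc.log_transform(sec)
        res = sc.decompose(ln)
        resid = ln.to_numpy() - sc.reconstruct(res, truth.K_true).to_numpy()
        assert resid.std() <= 1.1 * truth.noise_sd


def test_subspace_recovery_across_k(paper_like):
    """Signal-to-noise 5 suffices for < 5° principal angles at 30×48."""
    for k_true, seed in [(1, 0), (3, 1), (5, 2)]:
        truth = sc.make_truth(k_true=k_true, amplitude_sd=0.5, seed=seed)
        sec, _ = sc.gen_secretome(truth)
        res = sc.decompose(sc.log_transform(sec))
        ang = subspace_angles(res.G.iloc[:, 1:k_true + 1].to_numpy(),
                              truth.planted_G)
        assert np.degrees(ang).max() < 5.0
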