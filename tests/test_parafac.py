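import numpy as np
import pytest

from serumeem import (
    EEMStack,
    ParafacConfig,
    SerumSimConfig,
    component_peaks,
    corcondia,
    default_fluorophores,
    fit_parafac,
    make_grid,
    remove_scatter,
    score_reference_correlation,
    select_n_components,
    simulate_dataset,
)
from serumeem.parafac import ParafacModel, congruence_matrix, greedy_match
from conftest import random_rank_f, rank1_tensor

FAST = ParafacConfig(n_starts=3, max_iter=1500, rel_tol=1e-10, seed=0)


def oracle_als(T, F, n_starts=5, n_iter=400, seed=123):
    """Independent reference: plain unconstrained ALS via per-mode lstsq.

    Deliberately naive (no HALS, no nonnegativity, explicit Khatri-Rao and
    pseudoinverse) so it shares no code path with the implementation under
    test.  Returns the best reconstruction SSE over random restarts.
    """
    I, J, K = T.shape
    rng = np.random.default_rng(seed)
    best = np.inf
    for _ in range(n_starts):
        A = rng.normal(size=(I, F))
        B = rng.normal(size=(J, F))
        C = rng.normal(size=(K, F))
        for _ in range(n_iter):
            kr = np.stack([np.kron(B[:, f], C[:, f]) for f in range(F)], 1)
            A = T.reshape(I, -1) @ kr @ np.linalg.pinv(kr.T @ kr)
            kr = np.stack([np.kron(A[:, f], C[:, f]) for f in range(F)], 1)
            B = (T.transpose(1, 0, 2).reshape(J, -1) @ kr
                 @ np.linalg.pinv(kr.T @ kr))
            kr = np.stack([np.kron(A[:, f], B[:, f]) for f in range(F)], 1)
            C = (T.transpose(2, 0, 1).reshape(K, -1) @ kr
                 @ np.linalg.pinv(kr.T @ kr))
        recon = np.einsum("if,jf,kf->ijk", A, B, C)
        best = min(best, float(np.sum((T - recon) ** 2)))
    return best


def matched_congruences(model, truth_ex, truth_em):
    cg_ex = congruence_matrix(truth_ex, model.ex_loadings)
    cg_em = congruence_matrix(truth_em, model.em_loadings)
    pairs = greedy_match(cg_ex * cg_em)
    return ([cg_ex[t, f] for t, f in pairs],
            [cg_em[t, f] for t, f in pairs], pairs)


class TestFitParafac:
    def test_rank1_recovery(self):
        T, (a, b, c) = rank1_tensor(seed=5)
        model = fit_parafac(T, 1, FAST)
        assert abs(congruence_matrix(a[:, None], model.ex_loadings)[0, 0]) \
            > 0.999
        assert abs(congruence_matrix(b[:, None], model.em_loadings)[0, 0]) \
            > 0.999
        assert model.explained_pct > 99.99

    def test_noiseless_four_fluorophore_recovery(self):
        cfg = SerumSimConfig(n_samples=24, noise_sd=0.0,
                             replicate_jitter=0.0, scatter=False,
                             ex_grid=(250, 450, 10), em_grid=(250, 600, 5),
                             seed=11)
        ds = simulate_dataset(cfg, default_fluorophores(include_secondary=False))
        model = fit_parafac(ds.stack, 4, FAST)
        ex_c, em_c, _ = matched_congruences(model, ds.truth.ex_profiles,
                                            ds.truth.em_profiles)
        assert min(ex_c) > 0.99 and min(em_c) > 0.99

    def test_all_zero_tensor_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            fit_parafac(np.zeros((4, 5, 6)), 1, FAST)

    def test_f_exceeding_mode_rejected(self):
        T, _ = rank1_tensor(shape=(3, 8, 8))
        with pytest.raises(ValueError, match="exceeds"):
            fit_parafac(T, 4, FAST)

    def test_all_missing_rejected(self):
        with pytest.raises(ValueError):
            fit_parafac(np.full((4, 5, 6), np.nan), 1, FAST)

    def test_sse_monotone_nonincreasing(self):
        T, _ = random_rank_f((10, 14, 12), 3, seed=2)
        T += np.random.default_rng(3).normal(0, 0.02 * T.mean(), T.shape)
        model = fit_parafac(T, 3, ParafacConfig(n_starts=2, seed=1))
        h = model.sse_history
        assert np.all(np.diff(h) <= 1e-10 * np.maximum(h[:-1], 1e-12))

    def test_masked_fit_recovers_missing_cells(self):
        T, _ = random_rank_f((8, 10, 9), 2, seed=4)
        Tm = T.copy()
        Tm[1, 2, :] = np.nan
        Tm[4, 7, 3] = np.nan
        model = fit_parafac(Tm, 2, FAST)
        recon = model.reconstruct()
        np.testing.assert_allclose(recon[1, 2, :], T[1, 2, :], rtol=1e-3)

    def test_reordering_leaves_reconstruction_identical(self):
        T, _ = random_rank_f((8, 10, 9), 3, seed=6)
        model = fit_parafac(T, 3, FAST)
        perm = [2, 0, 1]
        permuted = ParafacModel(
            n_components=3,
            sample_scores=model.sample_scores[:, perm],
            em_loadings=model.em_loadings[:, perm],
            ex_loadings=model.ex_loadings[:, perm],
            sse=model.sse, explained_pct=model.explained_pct,
            corcondia=model.corcondia, converged=model.converged,
            n_iter=model.n_iter,
        )
        np.testing.assert_allclose(permuted.reconstruct(),
                                   model.reconstruct(), atol=1e-12)

    def test_spectral_loadings_unit_norm_nonnegative(self):
        T, _ = random_rank_f((8, 10, 9), 3, seed=7)
        model = fit_parafac(T, 3, FAST)
        np.testing.assert_allclose(
            np.linalg.norm(model.ex_loadings, axis=0), 1.0, atol=1e-9)
        np.testing.assert_allclose(
            np.linalg.norm(model.em_loadings, axis=0), 1.0, atol=1e-9)
        assert (model.ex_loadings >= 0).all()
        assert (model.em_loadings >= 0).all()

    def test_matches_independent_als_oracle(self):
        # noisy small dense tensor: same reconstruction SSE as a naive
        # unconstrained-ALS reference, within 1e-6 relative
        T, _ = random_rank_f((7, 9, 8), 2, seed=8)
        T += np.random.default_rng(9).normal(0, 0.05 * T.mean(), T.shape)
        T = np.abs(T)
        model = fit_parafac(T, 2, ParafacConfig(n_starts=5, seed=2))
        ref_sse = oracle_als(T, 2)
        assert model.sse == pytest.approx(ref_sse, rel=1e-6)


class TestCorcondia:
    def test_exact_rank_is_100(self):
        for F in (1, 2, 3):
            T, _ = random_rank_f((8, 10, 9), F, seed=F)
            model = fit_parafac(T, F, FAST)
            assert model.corcondia == pytest.approx(100.0, abs=1e-6)
            assert corcondia(model, T) == pytest.approx(100.0, abs=1e-6)

    def test_overfactored_rank2_drops(self):
        T, _ = random_rank_f((10, 12, 11), 2, seed=20)
        model = fit_parafac(T, 3, ParafacConfig(n_starts=5, seed=3))
        assert model.corcondia < 90.0


class TestSelectNComponents:
    def test_rank1_noiseless(self):
        T, _ = rank1_tensor(seed=30)
        assert select_n_components(T, range(1, 4), config=FAST) == 1

    def test_no_qualifying_f_warns_and_returns_minimum(self):
        # every candidate F overfactors a noisy rank-2 tensor, so CORCONDIA
        # collapses for all of them and the fallback contract applies
        rng = np.random.default_rng(20)
        A = rng.uniform(0.1, 1, (10, 2))
        B = rng.uniform(0.1, 1, (12, 2))
        C = rng.uniform(0.1, 1, (11, 2))
        T = np.einsum("if,jf,kf->ijk", A, B, C)
        T = np.abs(T + rng.normal(0, 0.02 * T.mean(), T.shape))
        with pytest.warns(UserWarning, match="falling back"):
            chosen = select_n_components(T, range(4, 7), config=ParafacConfig(
                n_starts=3, max_iter=500, seed=4))
        assert chosen == 4

    def test_synthetic_four_component_selection(self):
        # reduced-size analog of the serum stack: four spectrally distinct
        # fluorophores at low noise select exactly four components
        cfg = SerumSimConfig(n_samples=24, noise_sd=0.005,
                             ex_grid=(250, 450, 10), em_grid=(250, 600, 5),
                             seed=13)
        ds = simulate_dataset(cfg, default_fluorophores(include_secondary=False))
        stack = EEMStack([remove_scatter(e) for e in ds.stack.eems])
        chosen = select_n_components(
            stack, range(2, 7),
            config=ParafacConfig(n_starts=2, max_iter=400, rel_tol=1e-8,
                                 seed=5))
        assert chosen == 4


class TestPeaksAndCorrelation:
    def test_single_gaussian_band_peak(self):
        ex, em = make_grid(250, 450, 5), make_grid(250, 600, 1)
        ex_band = np.exp(-((ex.values - 325) ** 2) / (2 * 18.0 ** 2))
        em_band = np.exp(-((em.values - 447) ** 2) / (2 * 28.0 ** 2))
        model = ParafacModel(
            n_components=1,
            sample_scores=np.ones((5, 1)),
            em_loadings=em_band[:, None] / np.linalg.norm(em_band),
            ex_loadings=ex_band[:, None] / np.linalg.norm(ex_band),
            sse=0.0, explained_pct=100.0, corcondia=100.0,
            converged=True, n_iter=1,
        )
        assert component_peaks(model, ex, em) == [(325.0, 447.0)]

    def test_flat_loading_ties_to_lowest_wavelength(self):
        ex, em = make_grid(250, 450, 5), make_grid(250, 600, 1)
        flat_ex = np.ones((len(ex), 1)) / np.sqrt(len(ex))
        flat_em = np.ones((len(em), 1)) / np.sqrt(len(em))
        model = ParafacModel(1, np.ones((3, 1)), flat_em, flat_ex,
                             0.0, 100.0, 100.0, True, 1)
        assert component_peaks(model, ex, em) == [(250.0, 250.0)]

    @pytest.mark.parametrize("sign,expected", [(1.0, 1.0), (-1.0, -1.0)])
    def test_perfect_correlation(self, sign, expected):
        ref = np.array([10.0, 20.0, 30.0, 40.0])
        model = ParafacModel(1, sign * ref[:, None], np.ones((5, 1)),
                             np.ones((4, 1)), 0.0, 100.0, 100.0, True, 1)
        r, p, n = score_reference_correlation(model, 0, ref)
        assert r == pytest.approx(expected)
        assert n == 4

    def test_too_few_scans_rejected(self):
        model = ParafacModel(1, np.ones((2, 1)), np.ones((5, 1)),
                             np.ones((4, 1)), 0.0, 100.0, 100.0, True, 1)
        with pytest.raises(ValueError):
            score_reference_correlation(model, 0, np.array([1.0, 2.0]))


class TestRecoveryOnSyntheticSerum:
    """Recovery from the reduced-size serum simulation (coarse sample count,
    instrument grids, default noise)."""

    @pytest.fixture(scope="class")
    def default_noise_fit(self):
        ds = simulate_dataset(SerumSimConfig(n_samples=60, seed=1))
        stack = EEMStack([remove_scatter(e) for e in ds.stack.eems],
                         reference=ds.stack.reference)
        model = fit_parafac(stack, 5, ParafacConfig(
            n_starts=2, max_iter=800, rel_tol=1e-9, seed=0))
        return ds, stack, model

    def test_congruence_above_095_at_default_noise(self, default_noise_fit):
        ds, _, model = default_noise_fit
        ex_c, em_c, _ = matched_congruences(model, ds.truth.ex_profiles,
                                            ds.truth.em_profiles)
        assert min(ex_c) > 0.95 and min(em_c) > 0.95

    def test_retinol_score_tracks_concentration(self, default_noise_fit):
        ds, stack, model = default_noise_fit
        *_, pairs = matched_congruences(model, ds.truth.ex_profiles,
                                        ds.truth.em_profiles)
        retinol_idx = ds.truth.names.index("retinol_free")
        fitted_idx = dict(pairs)[retinol_idx]
        r, p, n = score_reference_correlation(
            model, fitted_idx, stack.reference_vector())
        assert r > 0.9
        assert p < 0.001
        assert n == len(stack)
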