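import numpy as np
import pandas as pd
import pytest

import haplomix as hx
from haplomix.engine import (
    DEFAULT_W_GRID,
    call_states,
    em_fit,
    forward_backward,
    grid_init_w,
    overrepresented_posterior,
)
from haplomix.states import (
    AberrationTPMSpec,
    build_tpm,
    enumerate_states,
    reduced_state_space,
    stationary_distribution,
)

from conftest import brute_force_joint, random_table


@pytest.fixture(scope="module")
def toy_setup(tiny_model):
    space = enumerate_states(2)
    spec = AberrationTPMSpec(3.0, 0.3)
    tpm = build_tpm(spec, space)
    pi = stationary_distribution(spec, space)
    table = random_table(tiny_model, seed=0)
    params = hx.TumorParams(w=0.2, sigma_b=0.05, sigma_r=0.2)
    return tiny_model, space, spec, tpm, pi, table, params


class TestForwardBackward:
    def test_matches_exhaustive_enumeration(self, toy_setup):
        model, space, spec, tpm, pi, table, params = toy_setup
        jp = forward_backward(table, model, params, spec, space=space)
        marg, ll = brute_force_joint(table, model, params, space, tpm, pi)
        assert jp.loglik == pytest.approx(ll, abs=1e-9)
        np.testing.assert_allclose(jp.cat_probs, space.collapse(marg), atol=1e-9)

    def test_matches_enumeration_without_lrr(self, toy_setup):
        model, space, spec, tpm, pi, table, params = toy_setup
        jp = forward_backward(table, model, params, spec, space=space,
                              use_lrr=False)
        marg, ll = brute_force_joint(table, model, params, space, tpm, pi,
                                     use_lrr=False)
        assert jp.loglik == pytest.approx(ll, abs=1e-9)
        np.testing.assert_allclose(jp.cat_probs, space.collapse(marg), atol=1e-9)

    def test_factorized_equals_dense_product_chain(self, small_model):
        """Factorized transitions match a dense joint-matrix HMM (K=3)."""
        model = small_model.subset(np.arange(12))
        space = enumerate_states(2)  # 6 states keeps the dense chain small
        spec = AberrationTPMSpec(4.0, 0.25)
        tpm = build_tpm(spec, space)
        pi = stationary_distribution(spec, space)
        table = random_table(model, seed=4)
        params = hx.TumorParams(w=0.15, sigma_b=0.06, sigma_r=0.25)
        jp = forward_backward(table, model, params, spec, space=space)
        # dense reference: states (l, k1, k2) flattened
        from haplomix.emission import marker_emission

        K, L, M = model.K, len(space), 12
        S = L * K * K
        g, b, r = table.genotype, table.baf, table.lrr
        E = np.empty((M, S))
        for m in range(M):
            for l, st in enumerate(space.states):
                for k1 in range(K):
                    for k2 in range(K):
                        s = (l * K + k1) * K + k2
                        E[m, s] = hx.genotype_prob(model, m, (k1, k2), int(g[m])) * \
                            marker_emission(b[m], r[m], int(g[m]), st, (k1, k2),
                                            model, params, m)
        init = np.einsum("l,i,j->lij", pi, model.alpha[0], model.alpha[0]).ravel()
        f = init * E[0]
        ll = 0.0
        post = np.empty((M, S))
        fs = [None] * M
        c = f.sum()
        f /= c
        ll += np.log(c)
        fs[0] = f
        for m in range(1, M):
            rho = model.rho[m - 1]
            Tz = (1 - rho) * np.eye(K) + rho * np.tile(model.alpha[m], (K, 1))
            T = np.kron(tpm, np.kron(Tz, Tz))
            f = (fs[m - 1] @ T) * E[m]
            c = f.sum()
            f /= c
            ll += np.log(c)
            fs[m] = f
        beta = np.ones(S)
        post[M - 1] = fs[M - 1] * beta
        for m in range(M - 2, -1, -1):
            rho = model.rho[m]
            Tz = (1 - rho) * np.eye(K) + rho * np.tile(model.alpha[m + 1], (K, 1))
            T = np.kron(tpm, np.kron(Tz, Tz))
            beta = T @ (E[m + 1] * beta)
            beta /= beta.max()
            post[m] = fs[m] * beta
        post /= post.sum(axis=1, keepdims=True)
        gamma_l = post.reshape(M, L, K * K).sum(axis=2)
        assert jp.loglik == pytest.approx(ll, abs=1e-8)
        np.testing.assert_allclose(jp.cat_probs, space.collapse(gamma_l),
                                   atol=1e-10)

    def test_w_zero_gives_stationary_posteriors(self, toy_setup):
        model, space, spec, tpm, pi, table, _ = toy_setup
        jp = forward_backward(table, model, hx.TumorParams(w=0.0, sigma_b=0.05),
                              spec, space=space)
        np.testing.assert_allclose(
            jp.cat_probs, np.tile(space.collapse(pi), (len(table), 1)),
            atol=1e-10,
        )

    def test_mirror_invariance_under_haplotype_relabeling(self, toy_setup):
        """Collapsed posteriors are unchanged when haplotype labels swap.

        The two haplotype chains share all parameters and the TPM is
        mirror-symmetric, so globally swapping the haplotype labels (which
        mirrors every ordered state and reverses every cluster pair) leaves
        every collapsed and allele-level posterior identical.  Reordering
        the state list to its mirror image is that relabeling.
        """
        model, space, spec, tpm, pi, table, params = toy_setup
        jp = forward_backward(table, model, params, spec, space=space)
        mirrored = hx.StateSpace([s.mirror() for s in space.states])
        jp_m = forward_backward(table, model, params, spec, space=mirrored)
        np.testing.assert_allclose(jp.cat_probs, jp_m.cat_probs, atol=1e-9)
        np.testing.assert_allclose(jp.p_b_over, jp_m.p_b_over, atol=1e-9)
        np.testing.assert_allclose(jp.p_a_over, jp_m.p_a_over, atol=1e-9)

    def test_k1_equals_independent_mixture_likelihood(self, small_model):
        """K=1 reduces to an equal-weight two-normal mixture HMM over l."""
        from scipy.stats import norm

        model = small_model
        M = model.n_markers
        k1 = hx.ClusterModel(
            K=1, theta=model.theta[:, :1].clip(1e-4, 1 - 1e-4),
            alpha=np.ones((M, 1)), rho=model.rho.copy(),
            marker_map=model.marker_map.copy(),
        )
        space = enumerate_states(2)
        spec = AberrationTPMSpec(5.0, 0.2)
        tpm = build_tpm(spec, space)
        pi = stationary_distribution(spec, space)
        table = random_table(k1, seed=8)
        params = hx.TumorParams(w=0.25, sigma_b=0.05, sigma_r=0.2)
        jp = forward_backward(table, k1, params, spec, space=space)
        # independent reference: forward over l only, emission = P(g) x
        # 0.5 N(mu1) + 0.5 N(mu2) at het sites, x N(lrr)
        g, b, r = table.genotype, table.baf, table.lrr
        chrom = table.chrom
        ll_ref = 0.0
        from haplomix.emission import baf_mean, lrr_mean
        from haplomix.panel import chrom_bounds

        for start, stop in chrom_bounds(chrom):
            f = pi.copy()
            for m in range(start, stop):
                e = np.empty(len(space))
                th = k1.theta[m, 0]
                pg = {0: (1 - th) ** 2, 1: 2 * th * (1 - th), 2: th * th}[int(g[m])]
                for i, st_ in enumerate(space.states):
                    v = pg * norm.pdf(r[m], lrr_mean(st_, params), params.sigma_r)
                    if g[m] == 1:
                        v *= 0.5 * norm.pdf(b[m], baf_mean(st_, True, params.w),
                                            params.sigma_b) + \
                             0.5 * norm.pdf(b[m], baf_mean(st_, False, params.w),
                                            params.sigma_b)
                    e[i] = v
                f = (f if m == start else f @ tpm) * e
                c = f.sum()
                f /= c
                ll_ref += np.log(c)
        assert jp.loglik == pytest.approx(ll_ref, abs=1e-9)

    def test_misaligned_inputs_rejected(self, small_model):
        df = small_model.marker_map.iloc[:10].copy()
        df["baf"] = 0.5
        df["lrr"] = 0.0
        with pytest.raises(ValueError):
            forward_backward(hx.MarkerTable(df), small_model,
                             hx.TumorParams(w=0.1))


class TestReducedMode:
    def test_reduced_space_without_lrr(self, toy_setup):
        model, *_ = toy_setup
        table = random_table(model, seed=1)
        spec = AberrationTPMSpec(3.0, 0.3)
        jp = forward_backward(table, model, hx.TumorParams(w=0.2, sigma_b=0.05),
                              spec, reduced_states=True, use_lrr=False)
        assert jp.space.categories == ["1-0", "1-1", "2-0"]
        # LRR must not influence the result
        df = table.df.copy()
        df["lrr"] = df["lrr"].to_numpy() + 100.0
        jp2 = forward_backward(hx.MarkerTable(df), model,
                               hx.TumorParams(w=0.2, sigma_b=0.05),
                               spec, reduced_states=True, use_lrr=False)
        np.testing.assert_allclose(jp.cat_probs, jp2.cat_probs, atol=1e-12)


class TestGridInit:
    def test_default_grid_is_six_to_thirty_percent(self):
        np.testing.assert_allclose(DEFAULT_W_GRID,
                                   [0.06, 0.08, 0.10, 0.12, 0.14, 0.16, 0.18,
                                    0.20, 0.22, 0.24, 0.26, 0.28, 0.30])

    def test_grid_recovers_simulated_purity(self, grid_sample):
        table, model, _ = grid_sample
        w0 = grid_init_w(table, model, AberrationTPMSpec(600, 0.1))
        assert w0 in (0.18, 0.20, 0.22)

    def test_tie_broken_to_smaller_w(self, toy_setup):
        model, space, spec, tpm, pi, table, _ = toy_setup
        # w has no effect on the likelihood when all BAF/LRR are missing
        df = table.df.copy()
        df["baf"] = np.nan
        df["lrr"] = np.nan
        df["genotype"] = -1
        t = hx.MarkerTable(df)
        w0 = grid_init_w(t, model, spec, grid=[0.1, 0.2, 0.3], space=space)
        assert w0 == 0.1


@pytest.fixture(scope="module")
def grid_sample():
    """A 20k-marker sample at 20% purity with a fitted K=3 model."""
    NCH, MPC = 2, 10000
    panel, gen = hx.simulate_panel(60, NCH * MPC, 3, seed=31, n_chromosomes=NCH)
    model = hx.fit_cluster_model(panel, K=3, n_starts=1, max_iter=25, seed=31)[0]
    spec = hx.SimulationSpec(purity=0.20, n_chromosomes=NCH, markers_per_chrom=MPC,
                             seed=31)
    table, truth, _ = hx.simulate_sample(spec, gen, seed=31)
    return hx.call_genotypes(table), model, truth


class TestEmFit:
    def test_purity_recovery_and_monotone_loglik(self, grid_sample):
        table, model, _ = grid_sample
        jp = em_fit(table, model, AberrationTPMSpec(600, 0.1), init="grid",
                    seed=0)
        assert jp.params.w == pytest.approx(0.20, abs=0.02)
        ll = np.array(jp.run_loglik_traces[0])
        assert np.all(np.diff(ll) >= -1e-6 * np.abs(ll[:-1]))

    def test_averaging_over_runs_is_arithmetic_mean(self, grid_sample):
        table, model, _ = grid_sample
        m2 = hx.ClusterModel(
            K=model.K, theta=model.theta[:, ::-1].copy(),
            alpha=model.alpha[:, ::-1].copy(), rho=model.rho.copy(),
            marker_map=model.marker_map.copy(),
        )
        jp = em_fit(table, [model, m2], AberrationTPMSpec(600, 0.1),
                    init=0.2, max_iter=2, seed=0)
        mean = (jp.run_cat_probs[0] + jp.run_cat_probs[1]) / 2
        np.testing.assert_allclose(jp.cat_probs, mean, atol=1e-12)

    def test_update_tpm_tracks_event_geometry(self, grid_sample):
        table, model, truth = grid_sample
        jp = em_fit(table, model, AberrationTPMSpec(600, 0.1), init=0.2,
                    max_iter=6, seed=0, update_tpm=True)
        # posteriors should still be valid and the run recorded
        np.testing.assert_allclose(jp.cat_probs.sum(axis=1), 1.0, atol=1e-8)


class TestCalling:
    def _mk_posterior(self, probs, space=None):
        space = space or reduced_state_space()
        M = probs.shape[0]
        return hx.JointPosterior(
            marker_ids=np.array([f"m{i}" for i in range(M)], dtype=object),
            chrom=np.array(["chr1"] * M, dtype=object),
            pos=np.arange(M) + 1,
            genotype=np.ones(M, dtype=np.int8),
            space=space,
            cat_probs=probs,
            p_b_over=np.zeros(M),
            p_a_over=np.zeros(M),
            cluster_amp=np.zeros((M, 1)),
            loglik=0.0,
            params=hx.TumorParams(w=0.1),
        )

    def test_uniform_posterior_ties_to_normal(self):
        jp = self._mk_posterior(np.full((4, 3), 1 / 3))
        assert list(jp.modal_category()) == ["1-1"] * 4

    def test_segment_merging(self):
        probs = np.full((30, 3), 0.05)
        probs[:, 1] = 0.9
        probs[10:21, 1] = 0.05
        probs[10:21, 2] = 0.9  # markers 10..20 are cn-LOH
        jp = self._mk_posterior(probs)
        calls, segs = call_states(jp)
        assert (calls["category"].to_numpy()[10:21] == "2-0").all()
        seg = segs[segs["category"] == "2-0"]
        assert len(seg) == 1
        assert int(seg["n_markers"].iloc[0]) == 11
        assert seg["mean_posterior"].iloc[0] == pytest.approx(0.9)

    def test_min_markers_relabels_short_segments(self):
        probs = np.full((10, 3), 0.05)
        probs[:, 1] = 0.9
        probs[4, 1] = 0.05
        probs[4, 0] = 0.9  # single-marker deletion call
        jp = self._mk_posterior(probs)
        calls1, segs1 = call_states(jp, min_markers=1)
        assert (calls1["category"] == "1-0").sum() == 1
        calls2, segs2 = call_states(jp, min_markers=3)
        assert (calls2["category"] == "1-0").sum() == 0
        assert len(segs2) == 1

    def test_alternating_categories_one_segment_per_marker(self):
        probs = np.full((6, 3), 0.05)
        probs[::2, 0] = 0.9
        probs[1::2, 2] = 0.9
        jp = self._mk_posterior(probs)
        _, segs = call_states(jp)
        assert len(segs) == 6


class TestOverrepresented:
    def test_all_mass_on_normal_is_balanced(self, toy_setup):
        model, space, spec, tpm, pi, table, _ = toy_setup
        jp = forward_backward(table, model, hx.TumorParams(w=0.0, sigma_b=0.05),
                              spec, space=space)
        # w=0: no state is informative, but P(A)+P(B)+P(balanced)=1 holds
        np.testing.assert_allclose(
            jp.p_a_over + jp.p_b_over + jp.p_balanced, 1.0, atol=1e-9
        )

    def test_homozygous_markers_report_balanced_one(self, toy_setup):
        model, space, spec, tpm, pi, table, params = toy_setup
        jp = forward_backward(table, model, params, spec, space=space)
        hom = table.genotype != 1
        if hom.any():
            np.testing.assert_allclose(jp.p_balanced[hom], 1.0, atol=1e-12)

    def test_forced_overrepresentation(self, toy_setup):
        """Posterior mass on (2,0) with config B-on-hap1 gives P(B over)=1."""
        model, space, spec, tpm, pi, table, params = toy_setup
        # build a het marker strongly favouring state (2,0), B on hap 1
        df = model.marker_map.copy()
        df["baf"] = 0.5
        df["lrr"] = 0.0
        m = model.n_markers // 2
        df.loc[m, "baf"] = 0.62  # way above 0.5 at w=0.2: c_B > c_other
        t = hx.call_genotypes(hx.MarkerTable(df))
        jp = forward_backward(t, model, hx.TumorParams(w=0.2, sigma_b=0.02),
                              spec, space=space, use_lrr=False)
        assert jp.p_b_over[m] > jp.p_a_over[m]
        frame = overrepresented_posterior(jp)
        assert {"p_a_over", "p_b_over", "p_balanced"} <= set(frame.columns)
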