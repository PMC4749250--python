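"""Two-layer cluster model: weighted theta update, forward-backward E-step,
EM fit, label alignment."""

import numpy as np
import pytest

from admixsel.model import (ModelConfig, ModelInputError, TwoLayerParams,
                            align_labels, e_step, e_step_diploid, fit,
                            split_clusters, switch_probs, update_theta)
from admixsel.panel import HaplotypePanel, make_markers
from admixsel.simulate import generate_source_panels

from oracles import enumerate_diploid, enumerate_haploid, theta_unweighted


def _random_posteriors(rng, n, m, c):
    q = rng.dirichlet(np.ones(c), size=(n, m))
    return q


class TestUpdateTheta:
    def test_equal_weights_reduce_to_unweighted_bitwise(self, rng):
        q = _random_posteriors(rng, 8, 5, 4)
        h = rng.integers(0, 2, size=(8, 5))
        w = np.full(8, 1.0)
        got = update_theta(q, h, w, floor=0.0)
        want = theta_unweighted(q, h)
        assert np.array_equal(got, want)  # bit-identical, not approx
        # any common weight cancels exactly
        got2 = update_theta(q, h, np.full(8, 3.7), floor=0.0)
        assert np.array_equal(got2, want)

    def test_cohort_only_invariant_to_weight_value(self, rng):
        q = _random_posteriors(rng, 10, 4, 3)
        h = rng.integers(0, 2, size=(10, 4))
        a = update_theta(q, h, np.full(10, 0.31), floor=0.0)
        b = update_theta(q, h, np.full(10, 7.0), floor=0.0)
        assert np.array_equal(a, b)

    def test_hand_evaluated_weighted_updates(self):
        # cluster j receives all posterior mass; training carries allele 1,
        # cohort allele 0, w_t=10, w_c=1
        def one_marker(n_train, n_coh):
            n = n_train + n_coh
            q = np.ones((n, 1, 1))
            h = np.array([[1]] * n_train + [[0]] * n_coh)
            w = np.array([10.0] * n_train + [1.0] * n_coh)
            return update_theta(q, h, w, floor=0.0)[0, 0]

        assert one_marker(1, 2) == pytest.approx(10 / 12)
        assert one_marker(2, 2) == pytest.approx(20 / 22)

    def test_unoccupied_cluster_keeps_previous_theta(self, rng, caplog):
        q = np.zeros((4, 2, 3))
        q[:, :, 0] = 1.0  # clusters 1 and 2 unoccupied
        h = rng.integers(0, 2, size=(4, 2))
        prev = np.full((2, 3), 0.42)
        with caplog.at_level("WARNING"):
            t = update_theta(q, h, np.ones(4), prev_theta=prev, floor=1e-4)
        assert "unoccupied" in caplog.text
        np.testing.assert_allclose(t[:, 1:], 0.42)

    def test_result_clamped_to_floor(self):
        q = np.ones((3, 1, 1))
        h = np.array([[1], [1], [1]])
        t = update_theta(q, h, np.ones(3), floor=1e-4)
        assert t[0, 0] == pytest.approx(1 - 1e-4)

    def test_rejects_bad_weights(self, rng):
        q = _random_posteriors(rng, 3, 2, 2)
        h = rng.integers(0, 2, size=(3, 2))
        with pytest.raises(ModelInputError):
            update_theta(q, h, np.zeros(3))
        with pytest.raises(ModelInputError):
            update_theta(q, h, np.array([-1.0, 1.0, 1.0]))


def _tiny_params(rng, S=2, C=4, M=4, n_rows=2):
    anc = split_clusters(C, S)
    theta = rng.uniform(0.05, 0.95, (M, C))
    cm = np.linspace(0, 0.5, M)
    u = switch_probs(cm, 20.0)
    v = switch_probs(cm, 300.0)
    pi = rng.dirichlet(np.ones(S), n_rows)
    return TwoLayerParams(theta, anc, u, v, pi)


class TestEStep:
    @pytest.mark.parametrize("S,C,M", [(2, 4, 3), (2, 4, 4), (3, 6, 3)])
    def test_matches_exhaustive_enumeration(self, rng, S, C, M):
        params = _tiny_params(rng, S, C, M, n_rows=3)
        H = rng.integers(0, 2, (3, M))
        H[0, 1] = -1  # one missing site
        post = e_step(params, H)
        for i in range(3):
            marg, ll = enumerate_haploid(params.theta, params.cluster_ancestry,
                                         S, params.upper_switch,
                                         params.lower_switch,
                                         params.admix_prop[i], H[i])
            assert abs(ll - post.loglik[i]) < 1e-10
            assert np.abs(marg - post.q[i]).max() < 1e-10

    @pytest.mark.parametrize("S,C,M", [(2, 4, 3), (3, 6, 2)])
    def test_diploid_matches_exhaustive_enumeration(self, rng, S, C, M):
        params = _tiny_params(rng, S, C, M, n_rows=2)
        g = rng.integers(0, 3, (2, M)).astype(float)
        g[1, 0] = np.nan  # missing genotype
        post = e_step_diploid(params, g)
        for i in range(2):
            marg, ll = enumerate_diploid(params.theta, params.cluster_ancestry,
                                         S, params.upper_switch,
                                         params.lower_switch,
                                         params.admix_prop[i], g[i])
            assert abs(ll - post.loglik[i]) < 1e-10
            assert np.abs(marg - post.q[i]).max() < 1e-10

    def test_uninformative_emissions_return_chain_prior(self, rng):
        params = _tiny_params(rng)
        params.theta[:] = 0.5
        H = rng.integers(0, 2, (2, 4))
        post = e_step(params, H)
        wvec = params.cluster_prior_weights()
        for i in range(2):
            pstar = params.admix_prop[i][params.cluster_ancestry] * wvec
            np.testing.assert_allclose(
                post.q[i], np.tile(pstar, (post.q.shape[1], 1)), atol=1e-12)

    def test_perfectly_informative_single_marker(self):
        anc = np.array([0, 0, 1, 1])
        theta = np.array([[1.0, 0.0, 1.0, 0.0]])
        pi = np.array([[0.25, 0.75]])
        params = TwoLayerParams(theta, anc, np.empty(0), np.empty(0), pi)
        post = e_step(params, np.array([[1]]))
        # mass only on the theta=1 clusters, proportional to the state prior
        np.testing.assert_allclose(post.q[0, 0], [0.25, 0.0, 0.75, 0.0])

    def test_posteriors_normalized_and_ancestry_sums(self, rng):
        params = _tiny_params(rng, 3, 6, 5, n_rows=4)
        H = rng.integers(0, 2, (4, 5))
        post = e_step(params, H)
        np.testing.assert_allclose(post.q.sum(axis=2), 1.0, atol=1e-12)
        np.testing.assert_allclose(post.ancestry.sum(axis=2), 1.0, atol=1e-12)

    def test_marker_mismatch_rejected(self, rng):
        params = _tiny_params(rng)
        with pytest.raises(ModelInputError):
            e_step(params, rng.integers(0, 2, (2, 7)))


def _training_cohort(rng, n_markers=120, n_train=40, n_cohort_haps=60,
                     diff=(0.3, 0.3, 0.3)):
    sp = generate_source_panels(n_markers, n_train + n_cohort_haps, diff,
                                seed=rng, region_length=n_markers * 5000)
    training, cohort_rows = [], []
    props = (0.5, 0.45, 0.05)
    take = rng.multinomial(n_cohort_haps, props)
    for k, p in enumerate(sp.panels):
        training.append(HaplotypePanel(p.alleles[:n_train], p.markers,
                                       population=p.population))
        cohort_rows.append(p.alleles[n_train:n_train + take[k]])
    cohort = HaplotypePanel(np.concatenate(cohort_rows), sp.markers)
    return training, cohort


class TestFit:
    def test_weighted_loglik_monotone_over_em(self, rng):
        training, cohort = _training_cohort(rng)
        cfg = ModelConfig(em_runs=2, em_steps=8, seed=3)
        res = fit(training, cohort, cfg)
        for trace in res.loglik_traces:
            diffs = np.diff(trace)
            assert (diffs >= -1e-8 * np.abs(trace[:-1])).all(), trace

    def test_dosages_sum_to_ploidy(self, small_fit):
        np.testing.assert_allclose(small_fit.dosage.values.sum(axis=2), 2.0,
                                   atol=1e-6)

    def test_supervised_recovers_truth(self, small_study, small_fit):
        truth = small_study.cohort.truth_dosage_field()
        err = np.abs(small_fit.dosage.values.mean(0) - truth.mean(0))
        assert err[:, 2].max() < 0.05    # African track within 0.05 everywhere

    def test_diploid_cohort_close_to_haploid_cohort(self, small_study):
        cfg = ModelConfig(em_runs=2, em_steps=8, seed=13)
        hap_res = fit(small_study.training, small_study.cohort.panel(), cfg)
        geno = small_study.cohort.panel().to_genotypes()
        dip_res = fit(small_study.training, geno, cfg)
        d = np.abs(hap_res.dosage.values.mean(0) - dip_res.dosage.values.mean(0))
        assert d.mean() < 0.05

    def test_partial_mode_matches_supervised_african_track(self, small_study,
                                                           small_fit):
        """Withholding the Amerindian panel leaves the African average-dosage
        track essentially unchanged, and two partial-mode fits with different
        seeds agree closely with each other."""
        cfg = ModelConfig(em_runs=3, em_steps=12, seed=5)
        partial = fit([None, small_study.training[1], small_study.training[2]],
                      small_study.cohort.panel(), cfg)
        sup_track = small_fit.dosage.values[:, :, 2].mean(axis=0)
        par_track = partial.dosage.values[:, :, 2].mean(axis=0)
        assert np.abs(sup_track - par_track).mean() < 0.03
        cfg2 = ModelConfig(em_runs=3, em_steps=12, seed=77)
        partial2 = fit([None, small_study.training[1], small_study.training[2]],
                       small_study.cohort.panel(), cfg2)
        par2_track = partial2.dosage.values[:, :, 2].mean(axis=0)
        assert np.abs(par_track - par2_track).mean() < 0.02

    def test_structure_mode_separates_two_populations(self, rng):
        sp = generate_source_panels(200, 80, (0.35, 0.35, 0.35), seed=7,
                                    region_length=10**6)
        merged = HaplotypePanel(
            np.concatenate([sp.panels[0].alleles, sp.panels[1].alleles]),
            sp.markers)
        cfg = ModelConfig(n_upper=2, n_lower=6, em_runs=3, em_steps=10, seed=1)
        res = fit([], merged, cfg, pair_haplotypes=False)
        comp = res.dosage.values[:, :, 0].mean(axis=1)  # one admixture component
        gap = abs(comp[:80].mean() - comp[80:].mean())
        assert gap > 0.5

    def test_empty_cohort_rejected(self, small_study):
        empty = HaplotypePanel(small_study.cohort.haplotypes[:0],
                               small_study.cohort.markers)
        with pytest.raises(ModelInputError):
            fit(small_study.training, empty, ModelConfig())

    def test_grid_mismatch_rejected(self, small_study, rng):
        bad = HaplotypePanel(rng.integers(0, 2, (10, 50)),
                             make_markers(50, 50000), population="EUR")
        with pytest.raises(Exception):
            fit([None, bad, None], small_study.cohort.panel(), ModelConfig())


class TestAlignLabels:
    def test_consistent_runs_identity(self, rng):
        d = rng.uniform(0, 2, size=(5, 20, 3))
        perms = align_labels([d, d + rng.normal(0, 0.01, d.shape)], anchors=())
        for p in perms:
            np.testing.assert_array_equal(p, np.arange(3))

    def test_swapped_run_is_unswapped(self, rng):
        d = rng.uniform(0, 2, size=(5, 20, 3))
        swapped = d[:, :, [1, 0, 2]]
        perms = align_labels([d, swapped], anchors=(2,))
        np.testing.assert_array_equal(perms[1], [1, 0, 2])
        aligned = swapped[..., perms[1]]
        ref = d[..., 0].ravel()
        before = np.corrcoef(ref, swapped[..., 0].ravel())[0, 1]
        after = np.corrcoef(ref, aligned[..., 0].ravel())[0, 1]
        assert after > before

    def test_fully_anchored_runs_identity(self, rng):
        d1 = rng.uniform(0, 2, size=(4, 10, 3))
        d2 = d1[:, :, [2, 1, 0]]
        perms = align_labels([d1, d2], anchors=(0, 1, 2))
        np.testing.assert_array_equal(perms[1], np.arange(3))

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ModelInputError):
            align_labels([rng.uniform(size=(2, 3, 3)),
                          rng.uniform(size=(2, 4, 3))])


def test_model_config_validation():
    with pytest.raises(ModelInputError):
        ModelConfig(n_upper=1)
    with pytest.raises(ModelInputError):
        ModelConfig(n_lower=2, n_upper=3)
    with pytest.raises(ModelInputError):
        ModelConfig(weight_training=0.0, weight_cohort=0.0)
    with pytest.raises(ModelInputError):
        ModelConfig(mode="label-free")


def test_split_clusters_even_partition():
    np.testing.assert_array_equal(split_clusters(15, 3),
                                  [0] * 5 + [1] * 5 + [2] * 5)
    counts = np.bincount(split_clusters(7, 3))
    assert sorted(counts) == [2, 2, 3]
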