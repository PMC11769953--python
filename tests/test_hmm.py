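"""VB-HMM core: exact-inference oracles, free energy, recovery, matching."""

import itertools

import numpy as np
import pytest
from scipy.special import logsumexp, multigammaln

from dynstates.hmm import (
    HMMPrior,
    compute_free_energy,
    forward_backward,
    match_states,
    select_model_order,
    vb_fit,
    viterbi_decode,
)
from dynstates.synthetic import GeneratorConfig, generate_cohort


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def enumerate_posteriors(log_b, pi, A):
    """Exact smoothing by brute-force summation over all K^T paths."""
    T, K = log_b.shape
    paths = np.array(list(itertools.product(range(K), repeat=T)))
    lp = np.log(pi)[paths[:, 0]] + log_b[np.arange(T), paths].sum(axis=1)
    for t in range(1, T):
        lp += np.log(A)[paths[:, t - 1], paths[:, t]]
    log_evidence = logsumexp(lp)
    w = np.exp(lp - log_evidence)
    gamma = np.zeros((T, K))
    for t in range(T):
        for k in range(K):
            gamma[t, k] = w[paths[:, t] == k].sum()
    return gamma, log_evidence, paths, lp


def nw_log_evidence(X, beta0, m0, w0_inv, nu0):
    """Closed-form marginal likelihood of the conjugate Normal-Wishart model."""
    T, N = X.shape
    xbar = X.mean(axis=0)
    S = (X - xbar).T @ (X - xbar)
    beta_t, nu_t = beta0 + T, nu0 + T
    d = xbar - m0
    wt_inv = w0_inv + S + beta0 * T / (beta0 + T) * np.outer(d, d)
    _, ld0 = np.linalg.slogdet(w0_inv)
    _, ldt = np.linalg.slogdet(wt_inv)
    return (
        -T * N / 2 * np.log(np.pi)
        + N / 2 * np.log(beta0 / beta_t)
        + nu0 / 2 * ld0 - nu_t / 2 * ldt
        + multigammaln(nu_t / 2, N) - multigammaln(nu0 / 2, N)
    )


def random_instance(rng, k_max=3, t_max=8):
    K = int(rng.integers(2, k_max + 1))
    T = int(rng.integers(2, t_max + 1))
    log_b = rng.normal(0, 2, (T, K))
    pi = rng.dirichlet(np.ones(K))
    A = rng.dirichlet(np.ones(K), K)
    return log_b, pi, A


# ---------------------------------------------------------------------------
# forward-backward / Viterbi
# ---------------------------------------------------------------------------

class TestForwardBackward:
    def test_single_state_is_certain(self):
        log_b = np.random.default_rng(0).normal(size=(9, 1))
        gamma, xi, log_z = forward_backward(log_b, np.array([1.0]), np.array([[1.0]]))
        assert np.allclose(gamma, 1.0)
        assert log_z == pytest.approx(log_b.sum())

    def test_symmetric_instance_gives_half(self):
        log_b = np.zeros((7, 2))
        gamma, _, _ = forward_backward(
            log_b, np.array([0.5, 0.5]), np.full((2, 2), 0.5)
        )
        assert np.allclose(gamma, 0.5)

    def test_matches_enumeration(self):
        rng = np.random.default_rng(42)
        for _ in range(25):
            log_b, pi, A = random_instance(rng)
            gamma, xi, log_z = forward_backward(log_b, pi, A)
            gamma_o, log_z_o, paths, lp = enumerate_posteriors(log_b, pi, A)
            assert abs(log_z - log_z_o) < 1e-10
            assert np.max(np.abs(gamma - gamma_o)) < 1e-10

    def test_xi_marginalises_to_gamma(self):
        rng = np.random.default_rng(1)
        log_b, pi, A = random_instance(rng, t_max=8)
        gamma, xi, _ = forward_backward(log_b, pi, A)
        assert np.allclose(xi.sum(axis=(1, 2)), 1.0, atol=1e-9)
        assert np.allclose(xi.sum(axis=1), gamma[1:], atol=1e-8)
        assert np.allclose(xi.sum(axis=2), gamma[:-1], atol=1e-8)

    def test_long_sequence_stable(self):
        rng = np.random.default_rng(2)
        log_b = rng.normal(-50, 10, size=(10_000, 3))
        pi = np.full(3, 1 / 3)
        A = np.full((3, 3), 0.1) + np.eye(3) * 0.7
        gamma, _, log_z = forward_backward(log_b, pi, A)
        assert np.isfinite(log_z)
        assert np.allclose(gamma.sum(axis=1), 1.0)

    def test_nonfinite_likelihood_rejected(self):
        log_b = np.zeros((4, 2))
        log_b[2, 1] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            forward_backward(log_b, np.array([0.5, 0.5]), np.full((2, 2), 0.5))


class TestViterbi:
    def test_single_state(self):
        path = viterbi_decode(np.zeros((6, 1)), np.array([1.0]), np.array([[1.0]]))
        assert np.all(path == 0)

    def test_dominant_likelihood_gives_argmax(self):
        rng = np.random.default_rng(3)
        best = rng.integers(0, 3, size=12)
        log_b = np.full((12, 3), -1e6)
        log_b[np.arange(12), best] = 0.0
        pi = np.full(3, 1 / 3)
        A = np.full((3, 3), 1 / 3)
        assert np.array_equal(viterbi_decode(log_b, pi, A), best)

    def test_matches_enumeration(self):
        rng = np.random.default_rng(7)
        for _ in range(25):
            log_b, pi, A = random_instance(rng, t_max=7)
            path = viterbi_decode(log_b, pi, A)
            _, _, paths, lp = enumerate_posteriors(log_b, pi, A)
            assert lp[(paths == path).all(axis=1)][0] == pytest.approx(lp.max())


# ---------------------------------------------------------------------------
# VB fitting and free energy
# ---------------------------------------------------------------------------

class TestVBFit:
    def test_k1_matches_closed_form_evidence(self):
        rng = np.random.default_rng(11)
        X = rng.normal(0.3, 1.2, size=(180, 4))
        model, _ = vb_fit([X], 1, n_init=1, seed=0, max_iter=50)
        prior = HMMPrior().materialize(1, 4)
        log_ev = nw_log_evidence(X, prior.beta0, prior.m0, prior.w0_inv, prior.nu0)
        assert model.free_energy == pytest.approx(-log_ev, abs=1e-6)
        # K = 1 point estimates: global mean / covariance scale
        assert np.allclose(model.state_means[0], X.mean(axis=0), atol=1e-2)

    def test_free_energy_trace_non_increasing(self, small_cohort):
        _, subjects, _, _ = small_cohort
        model, _ = vb_fit(subjects[:6], 3, n_init=2, seed=1, max_iter=60)
        trace = np.array(model.free_energy_trace)
        assert np.all(np.diff(trace) <= 1e-7 * np.maximum(1.0, np.abs(trace[:-1])))

    def test_seeded_fit_is_bit_identical(self, small_cohort):
        _, subjects, _, _ = small_cohort
        m1, p1 = vb_fit(subjects[:4], 3, n_init=2, seed=5, max_iter=25)
        m2, p2 = vb_fit(subjects[:4], 3, n_init=2, seed=5, max_iter=25)
        assert np.array_equal(m1.transition_matrix, m2.transition_matrix)
        assert np.array_equal(m1.state_means, m2.state_means)
        assert m1.free_energy_trace == m2.free_energy_trace
        assert all(np.array_equal(a, b) for a, b in zip(p1.gamma, p2.gamma))

    def test_subject_order_does_not_matter(self, small_cohort):
        """Permuting subjects leaves every estimated parameter unchanged."""
        _, subjects, _, _ = small_cohort
        subset = subjects[:6]
        m1, _ = vb_fit(subset, 3, n_init=1, seed=2, max_iter=40)
        m2, _ = vb_fit(subset[::-1], 3, n_init=1, seed=2, max_iter=40)
        assert np.allclose(m1.transition_matrix, m2.transition_matrix, atol=1e-8)
        assert np.allclose(m1.state_means, m2.state_means, atol=1e-8)
        assert m1.free_energy == pytest.approx(m2.free_energy, abs=1e-6)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            vb_fit([np.ones((50, 3))], 2, n_init=1, seed=0)
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError, match="exceeds"):
            vb_fit([rng.normal(size=(4, 2))], 9, n_init=1, seed=0)

    def test_posterior_invariants(self, small_cohort):
        _, subjects, _, _ = small_cohort
        model, post = vb_fit(subjects[:5], 4, n_init=1, seed=3, max_iter=30)
        assert np.allclose(model.transition_matrix.sum(axis=1), 1.0, atol=1e-10)
        assert model.initial_distribution.sum() == pytest.approx(1.0, abs=1e-10)
        for gamma, xi in zip(post.gamma, post.xi):
            assert np.allclose(gamma.sum(axis=1), 1.0, atol=1e-9)
            assert np.allclose(xi.sum(axis=(1, 2)), 1.0, atol=1e-9)
            assert np.allclose(xi.sum(axis=2), gamma[:-1], atol=1e-8)
        for cov in model.state_covariances:
            assert np.linalg.eigvalsh(cov).min() > 0

    def test_extra_state_never_cheaper(self):
        """A 2-state fit on single-state data pays a complexity penalty."""
        rng = np.random.default_rng(19)
        X = [rng.normal(0, 1, size=(150, 3)) for _ in range(2)]
        m1, _ = vb_fit(X, 1, n_init=1, seed=0, max_iter=80)
        m2, _ = vb_fit(X, 2, n_init=3, seed=0, max_iter=80)
        assert m2.free_energy >= m1.free_energy - 1e-6

    def test_two_state_parameter_recovery(self):
        """Well-separated two-state data: transitions and means recovered."""
        cfg = GeneratorConfig(
            n_states=2, n_regions=5, n_subjects_per_group=(6, 6),
            group_effect=None, mean_separation=4.0, seed=23,
        )
        subjects, _, truth = generate_cohort(cfg)
        model, _ = vb_fit(subjects, 2, n_init=2, seed=1)
        perm = match_states(model.state_means, truth.true_state_means)
        order = np.empty(2, dtype=int)
        order[perm] = np.arange(2)
        a_est = model.transition_matrix[np.ix_(order, order)]
        assert np.max(np.abs(a_est - truth.true_transition_matrices["control"])) < 0.05
        for k in range(2):
            mu_e = model.state_means[order][k]
            mu_t = truth.true_state_means[k]
            cos = mu_e @ mu_t / np.linalg.norm(mu_e) / np.linalg.norm(mu_t)
            assert cos > 0.99

    def test_agrees_with_em_reference(self):
        """Cross-check against hmmlearn's maximum-likelihood Gaussian HMM."""
        hmmlearn = pytest.importorskip("hmmlearn.hmm")
        cfg = GeneratorConfig(
            n_states=2, n_regions=4, n_subjects_per_group=(8, 8),
            group_effect=None, mean_separation=4.0, seed=31,
        )
        subjects, _, truth = generate_cohort(cfg)
        X = np.concatenate([s.data for s in subjects])
        lengths = [s.n_timepoints for s in subjects]
        ref = hmmlearn.GaussianHMM(
            n_components=2, covariance_type="full", n_iter=100, random_state=0
        )
        ref.fit(X, lengths)
        model, _ = vb_fit(subjects, 2, n_init=2, seed=4)
        perm = match_states(model.state_means, ref.means_)
        order = np.empty(2, dtype=int)
        order[perm] = np.arange(2)
        assert np.max(np.abs(model.state_means[order] - ref.means_)) < 0.1
        assert np.max(np.abs(model.transition_matrix[order][:, order] - ref.transmat_)) < 0.05

    def test_compute_free_energy_matches_trace(self, small_cohort):
        _, subjects, _, _ = small_cohort
        model, _ = vb_fit(subjects[:5], 3, n_init=1, seed=6, max_iter=40)
        f = compute_free_energy(model, subjects[:5])
        assert f == pytest.approx(model.free_energy, rel=1e-6)


class TestModelOrderSelection:
    def test_singleton_range(self, small_cohort):
        _, subjects, _, _ = small_cohort
        k, table = select_model_order(
            subjects[:4], k_range=[3], n_init=1, seed=0, max_iter=25
        )
        assert k == 3
        assert len(table) == 1

    def test_two_state_generator_recovered(self):
        hits = 0
        for seed in range(5):
            cfg = GeneratorConfig(
                n_states=2, n_regions=5, n_subjects_per_group=(5, 5),
                group_effect=None, mean_separation=4.0, seed=50 + seed,
            )
            subjects, _, _ = generate_cohort(cfg)
            k, _ = select_model_order(
                subjects, k_range=range(2, 5), n_init=2, seed=seed, max_iter=100
            )
            hits += k == 2
        assert hits >= 4

    def test_empty_range_rejected(self, small_cohort):
        _, subjects, _, _ = small_cohort
        with pytest.raises(ValueError):
            select_model_order(subjects[:3], k_range=[])


class TestMatchStates:
    def test_identity(self):
        rng = np.random.default_rng(0)
        means = rng.normal(size=(5, 8))
        assert np.array_equal(match_states(means, means), np.arange(5))

    def test_row_swap_recovered(self):
        rng = np.random.default_rng(1)
        means = rng.normal(size=(4, 6))
        perm = np.array([2, 0, 3, 1])
        assert np.array_equal(match_states(means[perm], means), perm)

    def test_matches_bruteforce_assignment(self):
        rng = np.random.default_rng(2)
        est = rng.normal(size=(4, 7))
        ref = rng.normal(size=(4, 7))

        def corr(a, b):
            a = a - a.mean()
            b = b - b.mean()
            return a @ b / np.linalg.norm(a) / np.linalg.norm(b)

        best, best_total = None, -np.inf
        for perm in itertools.permutations(range(4)):
            total = sum(corr(est[i], ref[perm[i]]) for i in range(4))
            if total > best_total:
                best, best_total = perm, total
        assert np.array_equal(match_states(est, ref), np.array(best))

    def test_unequal_k_rejected(self):
        with pytest.raises(ValueError):
            match_states(np.zeros((2, 3)), np.zeros((3, 3)))
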