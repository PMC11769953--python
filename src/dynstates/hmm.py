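"""Variational-Bayes inference for Gaussian-observation hidden Markov models.

The model: a K-state hidden Markov chain with initial distribution pi and
row-stochastic transition matrix A generates, at each timepoint, an
N-dimensional observation from a state-specific full-covariance Gaussian
N(mu_k, Sigma_k).  Subjects share one set of states and dynamics; the chain
restarts from pi at each subject's first row, so state sequences are never
bridged across subjects.

Inference is conjugate variational Bayes:

* Dirichlet priors on pi and each row of A (with a "sticky" extra
  concentration on the diagonal that discourages degenerate fast switching);
* Normal-Wishart priors on (mu_k, Lambda_k = Sigma_k^{-1}).

The E-step runs scaled forward-backward under the usual sub-normalised
quantities exp(E[log pi]), exp(E[log A]), exp(E[log p(x|k)]); the M-step is
the standard conjugate update.  The variational free energy

    F = -(sum over subjects of log-normaliser of the E-step)
        + KL(q(pi) || p(pi)) + sum_i KL(q(A_i.) || p(A_i.))
        + sum_k KL(q(mu_k, Lambda_k) || p(mu_k, Lambda_k))

is the negative evidence lower bound; it is non-increasing over iterations
and is the model-selection criterion (smaller is better).  The number of
states is chosen as the arg-min of F over a range of K.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import linear_sum_assignment
from scipy.special import digamma, gammaln, multigammaln
from sklearn.cluster import KMeans

logger = logging.getLogger(__name__)

_LOG_2PI = float(np.log(2.0 * np.pi))
#: Ridge added to posterior scale matrices before inversion.
COV_RIDGE = 1e-6


# --------------------------------------------------------------------------
# priors and posterior containers
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class HMMPrior:
    """Conjugate prior hyper-parameters.

    dirichlet_transition
        Base concentration for every entry of each transition-matrix row.
    dirichlet_sticky
        Extra concentration added to the diagonal entry of each row; favours
        state persistence a priori.
    dirichlet_initial
        Concentration for the initial-state Dirichlet.
    gaussian_mean_scale
        beta0, the prior precision scale on state means (relative to Lambda).
    wishart_dof
        nu0; defaults to N + 2 when ``None``.
    wishart_scale
        W0 (N x N SPD); defaults to the identity when ``None``.
    """

    dirichlet_transition: float = 1.0
    dirichlet_sticky: float = 10.0
    dirichlet_initial: float = 1.0
    gaussian_mean_scale: float = 0.01
    wishart_dof: float | None = None
    wishart_scale: np.ndarray | None = None

    def materialize(self, n_states: int, n_regions: int) -> "_MaterializedPrior":
        if min(self.dirichlet_transition, self.dirichlet_initial) <= 0:
            raise ValueError("Dirichlet concentrations must be positive")
        if self.dirichlet_sticky < 0:
            raise ValueError("sticky bonus must be non-negative")
        nu0 = float(self.wishart_dof) if self.wishart_dof is not None else n_regions + 2.0
        if nu0 < n_regions:
            raise ValueError(f"wishart_dof must be >= N = {n_regions}")
        if self.wishart_scale is None:
            w0 = np.eye(n_regions)
        else:
            w0 = np.asarray(self.wishart_scale, dtype=float)
            if w0.shape != (n_regions, n_regions) or not np.allclose(w0, w0.T):
                raise ValueError("wishart_scale must be a symmetric N x N matrix")
        alpha_trans = np.full((n_states, n_states), self.dirichlet_transition)
        alpha_trans[np.diag_indices(n_states)] += self.dirichlet_sticky
        return _MaterializedPrior(
            alpha_init=np.full(n_states, self.dirichlet_initial),
            alpha_trans=alpha_trans,
            beta0=float(self.gaussian_mean_scale),
            m0=np.zeros(n_regions),
            w0_inv=np.linalg.inv(w0),
            logdet_w0_inv=float(np.linalg.slogdet(np.linalg.inv(w0))[1]),
            nu0=nu0,
        )


@dataclass
class _MaterializedPrior:
    alpha_init: np.ndarray          # (K,)
    alpha_trans: np.ndarray         # (K, K)
    beta0: float
    m0: np.ndarray                  # (N,)
    w0_inv: np.ndarray              # (N, N)
    logdet_w0_inv: float
    nu0: float


@dataclass
class _Posterior:
    """Variational posterior parameters for all factors."""

    alpha_init: np.ndarray          # (K,)
    alpha_trans: np.ndarray         # (K, K)
    beta: np.ndarray                # (K,)
    m: np.ndarray                   # (K, N)
    w_inv: np.ndarray               # (K, N, N) posterior Wishart scale inverses
    nu: np.ndarray                  # (K,)

    @property
    def n_states(self) -> int:
        return self.m.shape[0]

    @property
    def n_regions(self) -> int:
        return self.m.shape[1]


@dataclass
class HMMModel:
    """A fitted K-state Gaussian HMM (posterior-mean point estimates + posterior)."""

    n_states: int
    initial_distribution: np.ndarray        # (K,) posterior-mean simplex
    transition_matrix: np.ndarray           # (K, K) posterior-mean, row-stochastic
    state_means: np.ndarray                 # (K, N)
    state_covariances: np.ndarray           # (K, N, N) posterior-mean covariances
    free_energy_trace: list[float]
    seed: int
    init_index: int
    n_iter: int
    converged: bool
    prior: HMMPrior = field(default_factory=HMMPrior, repr=False)
    posterior: _Posterior | None = field(default=None, repr=False)

    @property
    def free_energy(self) -> float:
        return self.free_energy_trace[-1]

    def to_dict(self) -> dict:
        return {
            "n_states": self.n_states,
            "initial_distribution": self.initial_distribution.tolist(),
            "transition_matrix": self.transition_matrix.tolist(),
            "state_means": self.state_means.tolist(),
            "state_covariances": self.state_covariances.tolist(),
            "free_energy_trace": list(map(float, self.free_energy_trace)),
            "seed": self.seed,
            "init_index": self.init_index,
            "n_iter": self.n_iter,
            "converged": self.converged,
        }


@dataclass
class StatePosterior:
    """Per-subject state responsibilities, joint responsibilities and hard paths."""

    gamma: list[np.ndarray]          # each (T, K)
    xi: list[np.ndarray]             # each (T-1, K, K)
    viterbi_path: list[np.ndarray]   # each (T,)
    log_evidence: np.ndarray         # (S,) per-subject E-step log-normalisers


# --------------------------------------------------------------------------
# Dirichlet / Normal-Wishart expectations and KL divergences
# --------------------------------------------------------------------------

def dirichlet_expected_log(alpha: np.ndarray, axis: int = -1) -> np.ndarray:
    """E[log x] under Dirichlet(alpha), elementwise."""
    alpha = np.asarray(alpha, dtype=float)
    return digamma(alpha) - digamma(alpha.sum(axis=axis, keepdims=True))


def dirichlet_kl(alpha_q: np.ndarray, alpha_p: np.ndarray) -> float:
    """KL( Dirichlet(alpha_q) || Dirichlet(alpha_p) ) for one concentration vector."""
    aq = np.asarray(alpha_q, dtype=float)
    ap = np.asarray(alpha_p, dtype=float)
    aq0, ap0 = aq.sum(), ap.sum()
    return float(
        gammaln(aq0) - gammaln(aq).sum() - gammaln(ap0) + gammaln(ap).sum()
        + ((aq - ap) * (digamma(aq) - digamma(aq0))).sum()
    )


def _expected_logdet_lambda(nu: float, w_inv: np.ndarray) -> float:
    """E[log |Lambda|] under Wishart(W, nu) with W = w_inv^{-1}."""
    n = w_inv.shape[0]
    sign, logdet_winv = np.linalg.slogdet(w_inv)
    if sign <= 0:
        raise np.linalg.LinAlgError("posterior scale matrix is not positive definite")
    return float(
        digamma(0.5 * (nu - np.arange(n))).sum() + n * np.log(2.0) - logdet_winv
    )


def normal_wishart_kl(
    m_q: np.ndarray, beta_q: float, w_inv_q: np.ndarray, nu_q: float,
    m_p: np.ndarray, beta_p: float, w_inv_p: np.ndarray, nu_p: float,
) -> float:
    """KL between Normal-Wishart distributions q and p over (mu, Lambda)."""
    n = m_q.shape[0]
    e_logdet = _expected_logdet_lambda(nu_q, w_inv_q)
    cf = cho_factor(w_inv_q)
    w_q = cho_solve(cf, np.eye(n))
    e_lambda = nu_q * w_q
    dm = m_q - m_p
    # E_Lambda[ KL( N(m_q,(beta_q Lambda)^-1) || N(m_p,(beta_p Lambda)^-1) ) ]
    kl_gauss = 0.5 * (
        n * beta_p / beta_q - n + n * np.log(beta_q / beta_p)
        + beta_p * float(dm @ e_lambda @ dm)
    )
    # KL( Wishart(W_q,nu_q) || Wishart(W_p,nu_p) )
    sign_q, logdet_winv_q = np.linalg.slogdet(w_inv_q)
    sign_p, logdet_winv_p = np.linalg.slogdet(w_inv_p)
    # log B(W_q, nu_q) - log B(W_p, nu_p) contributes the last four terms,
    # with B the Wishart normaliser and |W| = -log|W^{-1}|.
    kl_wish = (
        0.5 * (nu_q - nu_p) * e_logdet
        + 0.5 * nu_q * (float(np.trace(w_inv_p @ w_q)) - n)
        + 0.5 * nu_q * logdet_winv_q
        - 0.5 * nu_p * logdet_winv_p
        + 0.5 * n * (nu_p - nu_q) * np.log(2.0)
        + multigammaln(0.5 * nu_p, n) - multigammaln(0.5 * nu_q, n)
    )
    return float(kl_gauss + kl_wish)


# --------------------------------------------------------------------------
# forward-backward / Viterbi
# --------------------------------------------------------------------------

def _fb_batch(
    log_b: np.ndarray, log_pi: np.ndarray, log_a: np.ndarray, want_xi: bool = False
):
    """Scaled forward-backward on a batch of equal-length sequences.

    Parameters
    ----------
    log_b : (S, T, K)
        Per-sequence log observation weights; need not be normalised (VB uses
        expected log-likelihoods, which are sub-normalised densities).
    log_pi, log_a
        Log initial weights (K,) and log transition weights (K, K); again not
        required to normalise, which is exactly what makes the summed
        log-normaliser the free-energy data term.

    Returns
    -------
    gamma : (S, T, K), trans_counts : (K, K) summed over sequences and time,
    init_counts : (K,), log_z : (S,), and xi (S, T-1, K, K) if requested.
    """
    s_n, t_n, k_n = log_b.shape
    shift = log_b.max(axis=2)
    b = np.exp(log_b - shift[:, :, None])
    a = np.exp(log_a)
    pi = np.exp(log_pi)

    ahat = np.empty_like(b)
    c = np.empty((s_n, t_n))
    fwd = pi[None, :] * b[:, 0]
    c[:, 0] = fwd.sum(axis=1)
    ahat[:, 0] = fwd / c[:, 0, None]
    for t in range(1, t_n):
        fwd = (ahat[:, t - 1] @ a) * b[:, t]
        c[:, t] = fwd.sum(axis=1)
        ahat[:, t] = fwd / c[:, t, None]

    bhat = np.empty_like(b)
    bhat[:, -1] = 1.0
    for t in range(t_n - 2, -1, -1):
        bhat[:, t] = ((b[:, t + 1] * bhat[:, t + 1]) @ a.T) / c[:, t + 1, None]

    gamma = ahat * bhat
    gamma /= gamma.sum(axis=2, keepdims=True)
    log_z = np.log(c).sum(axis=1) + shift.sum(axis=1)

    w = (b[:, 1:] * bhat[:, 1:]) / c[:, 1:, None]
    trans_counts = np.einsum("sti,stj->ij", ahat[:, :-1], w) * a
    init_counts = gamma[:, 0].sum(axis=0)
    xi = None
    if want_xi:
        xi = ahat[:, :-1, :, None] * a[None, None] * w[:, :, None, :]
    return gamma, trans_counts, init_counts, log_z, xi


def forward_backward(
    log_obs_likelihood: np.ndarray, pi: np.ndarray, A: np.ndarray
):
    """Exact smoothing posteriors for a single sequence under known parameters.

    Returns ``(gamma, xi, log_evidence)`` where ``gamma`` is T x K state
    responsibilities, ``xi`` the (T-1) x K x K joint responsibilities and
    ``log_evidence`` the log marginal likelihood of the sequence.  Stable in
    scaled space for long sequences.
    """
    log_b = np.asarray(log_obs_likelihood, dtype=float)
    if log_b.ndim != 2:
        raise ValueError("log_obs_likelihood must be T x K")
    if not np.all(np.isfinite(log_b)):
        raise ValueError("log_obs_likelihood contains non-finite entries")
    pi = np.asarray(pi, dtype=float)
    A = np.asarray(A, dtype=float)
    k = log_b.shape[1]
    if pi.shape != (k,) or not np.isclose(pi.sum(), 1.0, atol=1e-8):
        raise ValueError("pi must be a length-K simplex vector")
    if A.shape != (k, k) or not np.allclose(A.sum(axis=1), 1.0, atol=1e-8):
        raise ValueError("A must be K x K row-stochastic")
    with np.errstate(divide="ignore"):
        gamma, _, _, log_z, xi = _fb_batch(
            log_b[None], np.log(pi), np.log(A), want_xi=True
        )
    xi_out = xi[0]
    if xi_out.size:
        xi_out = xi_out / xi_out.sum(axis=(1, 2), keepdims=True)
    return gamma[0], xi_out, float(log_z[0])


def viterbi_decode(
    log_obs_likelihood: np.ndarray, pi: np.ndarray, A: np.ndarray
) -> np.ndarray:
    """Maximum-a-posteriori hard state path for a single sequence (log-space DP)."""
    log_b = np.asarray(log_obs_likelihood, dtype=float)
    if not np.all(np.isfinite(log_b)):
        raise ValueError("log_obs_likelihood contains non-finite entries")
    with np.errstate(divide="ignore"):
        log_pi = np.log(np.asarray(pi, dtype=float))
        log_a = np.log(np.asarray(A, dtype=float))
    return _viterbi_core(log_b, log_pi, log_a)


def _viterbi_core(log_b: np.ndarray, log_pi: np.ndarray, log_a: np.ndarray) -> np.ndarray:
    t_n, k_n = log_b.shape
    delta = log_pi + log_b[0]
    back = np.zeros((t_n, k_n), dtype=int)
    for t in range(1, t_n):
        cand = delta[:, None] + log_a
        back[t] = np.argmax(cand, axis=0)
        delta = cand[back[t], np.arange(k_n)] + log_b[t]
    path = np.empty(t_n, dtype=int)
    path[-1] = int(np.argmax(delta))
    for t in range(t_n - 2, -1, -1):
        path[t] = back[t + 1][path[t + 1]]
    return path


# --------------------------------------------------------------------------
# VB fitting
# --------------------------------------------------------------------------

def _as_data_blocks(data) -> list[np.ndarray]:
    """Normalise input to a list of per-subject (T, N) float arrays."""
    blocks = []
    for item in data:
        arr = item.data if hasattr(item, "data") else np.asarray(item, dtype=float)
        arr = np.asarray(arr, dtype=float)
        if arr.ndim != 2:
            raise ValueError("each subject block must be a 2-D (T x N) matrix")
        blocks.append(arr)
    if not blocks:
        raise ValueError("no subjects supplied")
    n_set = {b.shape[1] for b in blocks}
    if len(n_set) != 1:
        raise ValueError(f"subjects disagree on the number of regions: {sorted(n_set)}")
    return blocks


def _expected_log_obs(x: np.ndarray, post: _Posterior) -> np.ndarray:
    """E_q[log N(x_t | mu_k, Lambda_k^{-1})] for all t, k.  Shape (T, K)."""
    t_n, n = x.shape
    k_n = post.n_states
    out = np.empty((t_n, k_n))
    for k in range(k_n):
        w_inv = post.w_inv[k] + COV_RIDGE * np.eye(n)
        cf = cho_factor(w_inv)
        w_k = cho_solve(cf, np.eye(n))
        e_logdet = _expected_logdet_lambda(post.nu[k], w_inv)
        y = x - post.m[k]
        quad = post.nu[k] * ((y @ w_k) * y).sum(axis=1)
        out[:, k] = 0.5 * (e_logdet - n * _LOG_2PI - n / post.beta[k] - quad)
    return out


def _m_step(
    x: np.ndarray,
    gamma: np.ndarray,
    trans_counts: np.ndarray,
    init_counts: np.ndarray,
    prior: _MaterializedPrior,
) -> _Posterior:
    """Conjugate parameter updates from responsibilities and pair counts."""
    n = x.shape[1]
    nk = gamma.sum(axis=0)                      # (K,)
    nk_safe = np.maximum(nk, 1e-12)
    xbar = (gamma.T @ x) / nk_safe[:, None]     # (K, N)
    beta = prior.beta0 + nk
    nu = prior.nu0 + nk
    m = (prior.beta0 * prior.m0[None, :] + nk[:, None] * xbar) / beta[:, None]
    k_n = gamma.shape[1]
    w_inv = np.empty((k_n, n, n))
    for k in range(k_n):
        y = x - xbar[k]
        s_k = (gamma[:, k][:, None] * y).T @ y
        d = xbar[k] - prior.m0
        w_inv[k] = (
            prior.w0_inv
            + s_k
            + (prior.beta0 * nk[k] / (prior.beta0 + nk[k])) * np.outer(d, d)
        )
        w_inv[k] = 0.5 * (w_inv[k] + w_inv[k].T)
    return _Posterior(
        alpha_init=prior.alpha_init + init_counts,
        alpha_trans=prior.alpha_trans + trans_counts,
        beta=beta,
        m=m,
        w_inv=w_inv,
        nu=nu,
    )


def _kl_total(post: _Posterior, prior: _MaterializedPrior) -> float:
    kl = dirichlet_kl(post.alpha_init, prior.alpha_init)
    for i in range(post.n_states):
        kl += dirichlet_kl(post.alpha_trans[i], prior.alpha_trans[i])
    for k in range(post.n_states):
        kl += normal_wishart_kl(
            post.m[k], float(post.beta[k]), post.w_inv[k], float(post.nu[k]),
            prior.m0, prior.beta0, prior.w0_inv, prior.nu0,
        )
    return kl


def _init_responsibilities(
    x_sorted: np.ndarray, order: np.ndarray, k_n: int, seed: int
) -> np.ndarray:
    """K-means-style initial responsibilities, invariant to subject order.

    K-means is run on a lexicographically sorted copy of the rows so the
    resulting centres (and hence the initialisation) do not depend on how
    subjects are ordered on input.
    """
    km = KMeans(n_clusters=k_n, n_init=1, random_state=int(seed), init="k-means++")
    labels_sorted = km.fit_predict(x_sorted)
    labels = np.empty(x_sorted.shape[0], dtype=int)
    labels[order] = labels_sorted
    gamma = np.full((x_sorted.shape[0], k_n), 0.1 / k_n)
    gamma[np.arange(labels.size), labels] += 0.9
    return gamma


def _estep(
    blocks_by_len: dict[int, tuple[np.ndarray, np.ndarray]],
    log_b_all: np.ndarray,
    log_pi: np.ndarray,
    log_a: np.ndarray,
):
    """Run batched forward-backward per length group; return pooled statistics."""
    t_total, k_n = log_b_all.shape
    gamma_all = np.empty((t_total, k_n))
    trans_counts = np.zeros((k_n, k_n))
    init_counts = np.zeros(k_n)
    log_z_total = 0.0
    for t_len, (idx_rows, subj_idx) in blocks_by_len.items():
        log_b = log_b_all[idx_rows].reshape(len(subj_idx), t_len, k_n)
        gamma, tc, ic, log_z, _ = _fb_batch(log_b, log_pi, log_a)
        gamma_all[idx_rows] = gamma.reshape(-1, k_n)
        trans_counts += tc
        init_counts += ic
        log_z_total += float(log_z.sum())
    return gamma_all, trans_counts, init_counts, log_z_total


def _vb_run(
    x: np.ndarray,
    blocks_by_len: dict,
    post: _Posterior,
    mat_prior: _MaterializedPrior,
    max_iter: int,
    tol: float,
    n_states: int,
    trace: list[float] | None = None,
):
    """Iterate E-step / free energy / M-step from a given posterior.

    Returns ``(trace, post, gamma, converged)`` with ``post`` and ``gamma``
    mutually consistent (the posterior whose E-step produced ``gamma``).
    """
    trace = list(trace) if trace else []
    gamma = None
    converged = False
    for it in range(max_iter):
        log_b = _expected_log_obs(x, post)
        log_pi = dirichlet_expected_log(post.alpha_init)
        log_a = dirichlet_expected_log(post.alpha_trans, axis=1)
        gamma, tc, ic, log_z = _estep(blocks_by_len, log_b, log_pi, log_a)
        f = -log_z + _kl_total(post, mat_prior)
        if trace and f > trace[-1] + 1e-7 * max(1.0, abs(trace[-1])):
            logger.warning(
                "free energy increased by %.3g at iteration %d (K=%d)",
                f - trace[-1], it, n_states,
            )
        done = bool(trace) and abs(trace[-1] - f) <= tol * abs(f)
        trace.append(float(f))
        if done:
            converged = True
            break
        post = _m_step(x, gamma, tc, ic, mat_prior)
    return trace, post, gamma, converged


def vb_fit(
    data,
    n_states: int,
    prior: HMMPrior | None = None,
    n_init: int = 5,
    seed: int = 0,
    max_iter: int = 500,
    tol: float = 1e-5,
    burn_iter: int = 30,
) -> tuple[HMMModel, StatePosterior]:
    """Fit a K-state VB Gaussian HMM to group-concatenated subject series.

    Parameters
    ----------
    data
        Iterable of :class:`~dynstates.parcellation.SubjectTimeSeries` or
        (T, N) arrays; the chain restarts at each subject's first row.
    n_states
        K >= 1.
    n_init
        Number of seeded k-means-style initialisations.  Each is run for
        ``burn_iter`` iterations; the one with the lowest free energy is then
        continued to convergence (the usual short-run strategy).
    tol
        Relative free-energy change |dF| / |F| declaring convergence.

    Returns the winning :class:`HMMModel` and its :class:`StatePosterior`.
    """
    blocks = _as_data_blocks(data)
    if n_states < 1:
        raise ValueError("n_states must be >= 1")
    prior = prior or HMMPrior()
    x = np.concatenate(blocks, axis=0)
    t_total, n = x.shape
    if n_states > t_total:
        raise ValueError(f"K = {n_states} exceeds the total number of timepoints {t_total}")
    if np.allclose(x.std(axis=0), 0.0):
        raise ValueError("all-constant data: observation covariance is degenerate")
    mat_prior = prior.materialize(n_states, n)

    # group subjects by length for batched forward-backward
    lengths = [b.shape[0] for b in blocks]
    offsets = np.concatenate([[0], np.cumsum(lengths)])
    blocks_by_len: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    for t_len in sorted(set(lengths)):
        subj_idx = np.array([i for i, L in enumerate(lengths) if L == t_len])
        idx_rows = np.concatenate(
            [np.arange(offsets[i], offsets[i + 1]) for i in subj_idx]
        )
        blocks_by_len[t_len] = (idx_rows, subj_idx)

    order = np.lexsort(x.T[::-1])
    x_sorted = x[order]
    init_seeds = [
        int(s.generate_state(1)[0] % (2**31 - 1))
        for s in np.random.SeedSequence(seed).spawn(n_init)
    ]

    runs = []
    for init_index, init_seed in enumerate(init_seeds):
        gamma = _init_responsibilities(x_sorted, order, n_states, init_seed)
        # crude pair counts from independent products, only to seed the M-step
        tc0 = np.zeros((n_states, n_states))
        ic0 = np.zeros(n_states)
        for i, L in enumerate(lengths):
            g = gamma[offsets[i]:offsets[i + 1]]
            tc0 += g[:-1].T @ g[1:]
            ic0 += g[0]
        post = _m_step(x, gamma, tc0, ic0, mat_prior)
        trace, post, gamma, converged = _vb_run(
            x, blocks_by_len, post, mat_prior, min(burn_iter, max_iter), tol, n_states
        )
        runs.append((trace[-1], init_index, trace, post, converged))

    best_f, init_index, trace, post, converged = min(runs, key=lambda r: (r[0], r[1]))
    if not converged and len(trace) < max_iter:
        trace, post, gamma, converged = _vb_run(
            x, blocks_by_len, post, mat_prior, max_iter - len(trace), tol,
            n_states, trace=trace,
        )

    pi_hat = post.alpha_init / post.alpha_init.sum()
    a_hat = post.alpha_trans / post.alpha_trans.sum(axis=1, keepdims=True)
    covs = np.empty_like(post.w_inv)
    for k in range(n_states):
        denom = post.nu[k] - n - 1.0
        covs[k] = post.w_inv[k] / (denom if denom > 0 else post.nu[k])
    model = HMMModel(
        n_states=n_states,
        initial_distribution=pi_hat,
        transition_matrix=a_hat,
        state_means=post.m.copy(),
        state_covariances=covs,
        free_energy_trace=trace,
        seed=seed,
        init_index=init_index,
        n_iter=len(trace),
        converged=converged,
        prior=prior,
        posterior=post,
    )
    posterior = decode(model, blocks)
    return model, posterior


def decode(model: HMMModel, data) -> StatePosterior:
    """Per-subject smoothing posteriors and Viterbi paths under a fitted model.

    Uses the same expected-log parameters as the E-step, so the soft
    responsibilities are exactly the final variational posteriors.
    """
    blocks = _as_data_blocks(data)
    post = model.posterior
    if post is None:
        raise ValueError("model carries no variational posterior; refit with vb_fit")
    log_pi = dirichlet_expected_log(post.alpha_init)
    log_a = dirichlet_expected_log(post.alpha_trans, axis=1)
    gammas, xis, paths, log_z_list = [], [], [], []
    for b in blocks:
        log_b = _expected_log_obs(b, post)
        gamma, _, _, log_z, xi = _fb_batch(log_b[None], log_pi, log_a, want_xi=True)
        xi0 = xi[0]
        if xi0.size:
            xi0 = xi0 / xi0.sum(axis=(1, 2), keepdims=True)
        gammas.append(gamma[0])
        xis.append(xi0)
        paths.append(_viterbi_core(log_b, log_pi, log_a))
        log_z_list.append(float(log_z[0]))
    return StatePosterior(
        gamma=gammas, xi=xis, viterbi_path=paths, log_evidence=np.array(log_z_list)
    )


def compute_free_energy(model: HMMModel, data, prior: HMMPrior | None = None) -> float:
    """Recompute the variational free energy of a fitted model on ``data``."""
    blocks = _as_data_blocks(data)
    post = model.posterior
    if post is None:
        raise ValueError("model carries no variational posterior")
    prior = prior or model.prior
    mat_prior = prior.materialize(post.n_states, post.n_regions)
    log_pi = dirichlet_expected_log(post.alpha_init)
    log_a = dirichlet_expected_log(post.alpha_trans, axis=1)
    log_z = 0.0
    for b in blocks:
        log_b = _expected_log_obs(b, post)
        _, _, _, lz, _ = _fb_batch(log_b[None], log_pi, log_a)
        log_z += float(lz[0])
    return -log_z + _kl_total(post, mat_prior)


def select_model_order(
    data,
    prior: HMMPrior | None = None,
    k_range: Iterable[int] = range(2, 16),
    n_init: int = 5,
    seed: int = 0,
    max_iter: int = 500,
    tol: float = 1e-5,
) -> tuple[int, "pd.DataFrame"]:
    """Free-energy model-order selection over a range of K.

    Fits every K in ``k_range`` and returns the K attaining the minimum final
    free energy (ties broken toward smaller K) together with the full per-K
    table for reporting.  A K whose fit fails is recorded as missing and
    excluded from the arg-min.
    """
    import pandas as pd

    ks = sorted(set(int(k) for k in k_range))
    if not ks:
        raise ValueError("k_range is empty")
    blocks = _as_data_blocks(data)
    seeds = {
        k: int(s.generate_state(1)[0] % (2**31 - 1))
        for k, s in zip(ks, np.random.SeedSequence(seed).spawn(len(ks)))
    }
    rows = []
    for k in ks:
        try:
            model, _ = vb_fit(
                blocks, k, prior=prior, n_init=n_init, seed=seeds[k],
                max_iter=max_iter, tol=tol,
            )
            rows.append(
                {"n_states": k, "free_energy": model.free_energy,
                 "n_iter": model.n_iter, "converged": model.converged}
            )
        except Exception as exc:
            warnings.warn(f"VB fit failed for K={k}: {exc}")
            logger.warning("VB fit failed for K=%d: %s", k, exc)
            rows.append(
                {"n_states": k, "free_energy": np.nan, "n_iter": 0, "converged": False}
            )
    table = pd.DataFrame(rows)
    valid = table.dropna(subset=["free_energy"])
    if valid.empty:
        raise RuntimeError("every candidate K failed to fit")
    # ties toward smaller K: stable idxmin on a sorted table
    selected = int(valid.loc[valid["free_energy"].idxmin(), "n_states"])
    return selected, table


def match_states(estimated_means: np.ndarray, reference_means: np.ndarray) -> np.ndarray:
    """Optimal state relabelling between two fits (label switching).

    Returns the permutation ``perm`` maximising the total Pearson correlation
    between matched state-mean vectors, solved exactly by the assignment
    problem: estimated state ``i`` corresponds to reference state ``perm[i]``.
    """
    est = np.atleast_2d(np.asarray(estimated_means, dtype=float))
    ref = np.atleast_2d(np.asarray(reference_means, dtype=float))
    if est.shape != ref.shape:
        raise ValueError(f"shape mismatch: estimated {est.shape} vs reference {ref.shape}")
    k_n = est.shape[0]
    ec = est - est.mean(axis=1, keepdims=True)
    rc = ref - ref.mean(axis=1, keepdims=True)
    es = np.linalg.norm(ec, axis=1)
    rs = np.linalg.norm(rc, axis=1)
    corr = np.zeros((k_n, k_n))
    ok = np.outer(es > 1e-12, rs > 1e-12)
    denom = np.outer(np.where(es > 1e-12, es, 1.0), np.where(rs > 1e-12, rs, 1.0))
    corr = np.where(ok, (ec @ rc.T) / denom, 0.0)
    row, col = linear_sum_assignment(-corr)
    perm = np.empty(k_n, dtype=int)
    perm[row] = col
    return perm
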