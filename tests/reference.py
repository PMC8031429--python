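"""Independent oracle implementations used only by the tests.

Everything here is written straight from the mathematical definitions, with
plain Python loops and from-scratch recomputation, deliberately sharing no
code path with the package's vectorized/incremental implementations.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp
from scipy.optimize import minimize
from scipy.special import gammaln

from typedlda.corpus import CorpusMode, TypedCorpus


# ---------------------------------------------------------------------------
# straight-line transcription of the collapsed variational update
# ---------------------------------------------------------------------------

def cvb0_sweep_transcription(doc_idx, type_idx, word_idx, counts, gamma0,
                             alpha, beta, vocab_sizes):
    """One sequential sweep, recomputing every statistic from scratch.

    Token groups are visited in the given order.  Before each group's update
    all sufficient statistics are rebuilt by explicit summation over every
    group's count-weighted responsibility; the exclusion counts then subtract
    one instance's responsibility (the group's current row).  The update is

        gamma_k ∝ (alpha_k + n_jk^-) (beta_t + n_wk^-) / (W_t beta_t + n_.k^-)

    normalized over k.  Returns the post-sweep responsibilities.
    """
    G = len(counts)
    K = len(alpha)
    gamma = [np.array(gamma0[g], dtype=float) for g in range(G)]
    for g in range(G):
        j, t, w = doc_idx[g], type_idx[g], word_idx[g]
        n_jk = np.zeros(K)
        n_wk = np.zeros(K)
        n_tk = np.zeros(K)
        for h in range(G):
            contrib = counts[h] * gamma[h]
            if doc_idx[h] == j:
                n_jk += contrib
            if type_idx[h] == t:
                n_tk += contrib
                if word_idx[h] == w:
                    n_wk += contrib
        ex_d = np.maximum(n_jk - gamma[g], 0.0)
        ex_w = np.maximum(n_wk - gamma[g], 0.0)
        ex_t = np.maximum(n_tk - gamma[g], 0.0)
        val = (alpha + ex_d) * (beta[t] + ex_w) / (vocab_sizes[t] * beta[t] + ex_t)
        gamma[g] = val / val.sum()
    return np.array(gamma)


# ---------------------------------------------------------------------------
# independently written plain single-type CVB0 LDA
# ---------------------------------------------------------------------------

class PlainLdaCvb0:
    """Minimal single-vocabulary CVB0 LDA, dense and loop-based.

    Token groups are unique (document, word) pairs with their counts, visited
    in (document, word) order; responsibilities update sequentially with
    single-instance exclusion; statistics are re-aggregated from scratch
    after each sweep.
    """

    def __init__(self, counts: sp.spmatrix, n_topics: int,
                 alpha: np.ndarray, beta: float, gamma0: np.ndarray):
        coo = sp.coo_matrix(counts)
        order = np.lexsort((coo.col, coo.row))
        self.docs = coo.row[order]
        self.words = coo.col[order]
        self.cnts = coo.data[order].astype(float)
        self.D, self.W = counts.shape
        self.K = n_topics
        self.alpha = np.asarray(alpha, float)
        self.beta = float(beta)
        self.gamma = np.array(gamma0, dtype=float, copy=True)
        self._aggregate()

    def _aggregate(self):
        self.N_jk = np.zeros((self.D, self.K))
        self.N_wk = np.zeros((self.W, self.K))
        self.N_k = np.zeros(self.K)
        for g in range(len(self.cnts)):
            contrib = self.cnts[g] * self.gamma[g]
            self.N_jk[self.docs[g]] += contrib
            self.N_wk[self.words[g]] += contrib
            self.N_k += contrib

    def sweep(self):
        for g in range(len(self.cnts)):
            j, w, c = self.docs[g], self.words[g], self.cnts[g]
            old = self.gamma[g]
            ex_d = np.maximum(self.N_jk[j] - old, 0.0)
            ex_w = np.maximum(self.N_wk[w] - old, 0.0)
            ex_k = np.maximum(self.N_k - old, 0.0)
            val = (self.alpha + ex_d) * (self.beta + ex_w) \
                / (self.W * self.beta + ex_k)
            new = val / val.sum()
            delta = c * (new - old)
            self.N_jk[j] += delta
            self.N_wk[w] += delta
            self.N_k += delta
            self.gamma[g] = new
        self._aggregate()

    def run(self, n_sweeps: int):
        for _ in range(n_sweeps):
            self.sweep()
        theta = self.alpha + self.N_jk
        theta /= theta.sum(axis=1, keepdims=True)
        phi = (self.beta + self.N_wk) / (self.W * self.beta + self.N_k)
        return theta, phi


# ---------------------------------------------------------------------------
# Dirichlet-multinomial marginal likelihoods and numerical maximizers
# ---------------------------------------------------------------------------

def dm_loglik_alpha(alpha: np.ndarray, n_jk: np.ndarray) -> float:
    """Dirichlet-multinomial marginal log-likelihood of doc-topic counts."""
    alpha = np.asarray(alpha, float)
    n = np.asarray(n_jk, float)
    a0 = alpha.sum()
    totals = n.sum(axis=1)
    return float(
        (gammaln(a0) - gammaln(totals + a0)).sum()
        + (gammaln(n + alpha) - gammaln(alpha)).sum()
    )


def maximize_alpha(n_jk: np.ndarray, k: int) -> np.ndarray:
    """Numerically maximize the marginal likelihood over asymmetric alpha."""
    def neg(log_a):
        return -dm_loglik_alpha(np.exp(log_a), n_jk)

    best = None
    for start in (np.zeros(k), np.full(k, -2.0), np.full(k, 1.0)):
        res = minimize(neg, start, method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-12,
                                "maxiter": 20000, "maxfev": 20000})
        if best is None or res.fun < best.fun:
            best = res
    return np.exp(best.x)


def penalized_loglik_beta(beta: float, n_wk: np.ndarray,
                          a: float = 1.0, b: float = 100.0) -> float:
    """Symmetric Dirichlet-multinomial marginal log-likelihood of the
    word-topic counts of one type, plus the Gamma(a, b) log-prior on beta."""
    n = np.asarray(n_wk, float)
    W, K = n.shape
    n_k = n.sum(axis=0)
    ll = (
        K * gammaln(W * beta)
        - gammaln(W * beta + n_k).sum()
        + (gammaln(beta + n) - gammaln(beta)).sum()
    )
    return float(ll + (a - 1.0) * np.log(beta) - b * beta)


def maximize_beta(n_wk: np.ndarray, a: float = 1.0, b: float = 100.0) -> float:
    def neg(log_b):
        return -penalized_loglik_beta(float(np.exp(log_b[0])), n_wk, a, b)

    best = None
    for start in (-3.0, -1.0, 0.0):
        res = minimize(neg, [start], method="Nelder-Mead",
                       options={"xatol": 1e-12, "fatol": 1e-13,
                                "maxiter": 20000})
        if best is None or res.fun < best.fun:
            best = res
    return float(np.exp(best.x[0]))


# ---------------------------------------------------------------------------
# small random instances and topic matching
# ---------------------------------------------------------------------------

def make_small_instance(seed: int) -> TypedCorpus:
    """A random tiny typed corpus: D<=3, T<=2, small vocabularies, <=30 tokens."""
    rng = np.random.default_rng(seed)
    D = int(rng.integers(1, 4))
    T = int(rng.integers(1, 3))
    labels = ["physician", "nursing"][:T]
    sizes = [int(rng.integers(3, 5)) for _ in range(T)]
    budget = 30
    dense = [np.zeros((D, w), dtype=np.int64) for w in sizes]
    # scatter tokens (counts up to 3) until the budget runs out
    while budget > 0:
        t = int(rng.integers(T))
        j = int(rng.integers(D))
        w = int(rng.integers(sizes[t]))
        c = int(min(rng.integers(1, 4), budget))
        dense[t][j, w] += c
        budget -= c
    # every document needs at least one token
    for j in range(D):
        if all(d[j].sum() == 0 for d in dense):
            dense[0][j, 0] += 1
    width = max(3, len(str(max(sizes))))
    return TypedCorpus(
        type_labels=labels,
        vocabs=[[f"w{i:0{width}d}" for i in range(w)] for w in sizes],
        counts=[sp.csr_matrix(d) for d in dense],
        doc_ids=[f"d{j}" for j in range(D)],
        mode=CorpusMode.MULTI_TYPE,
    )


def match_topics(phi_est: np.ndarray, phi_true: np.ndarray):
    """Hungarian matching of estimated to true topics by column cosine.

    Returns (perm, cosines): ``perm[k]`` is the estimated topic matched to
    true topic k, and ``cosines[k]`` their cosine similarity.
    """
    from scipy.optimize import linear_sum_assignment

    a = phi_est / np.linalg.norm(phi_est, axis=0, keepdims=True)
    b = phi_true / np.linalg.norm(phi_true, axis=0, keepdims=True)
    sim = a.T @ b  # (K_est, K_true)
    rows, cols = linear_sum_assignment(-sim)
    perm = np.empty(len(cols), dtype=int)
    perm[cols] = rows
    return perm, sim[rows, cols][np.argsort(cols)]
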