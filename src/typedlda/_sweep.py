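"""Sequential CVB0 sweep kernels.

The collapsed variational update visits token groups (one group per unique
(document, type, word) triple) in a fixed order and updates each group's
responsibility vector in place, removing the group's previous contribution
from the running sufficient statistics and adding the new one immediately —
the classic sequential CVB0 sweep, here over count-weighted groups.

The kernels are jitted with numba when available; the pure-Python bodies are
the reference semantics and are used unchanged as a fallback.  Exclusion
counts that go slightly negative from floating-point drift are clamped at
zero inside the kernel.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - import side
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        if len(args) == 1 and callable(args[0]):
            return args[0]

        def wrap(fn):
            return fn

        return wrap


@njit(cache=False)
def cvb0_sweep(doc_idx, type_idx, word_idx, counts, gamma,
               n_jk, n_wk, n_tk, alpha, beta, w_beta):
    """One in-place CVB0 E-step sweep over all token groups.

    gamma : (G, K) responsibilities, one row per group, updated in place.
    n_jk  : (D, K) expected document-topic counts, updated in place.
    n_wk  : (W_total, K) expected word-topic counts over the concatenated
            per-type vocabularies, updated in place.
    n_tk  : (T, K) per-type topic totals (column sums of the type's block of
            n_wk), updated in place.
    w_beta: (T,) precomputed W_t * beta_t.

    The exclusion statistics subtract one token instance's responsibility
    (the group's current gamma row), per the collapsed update.
    """
    G, K = gamma.shape
    tmp = np.empty(K)
    for g in range(G):
        j = doc_idx[g]
        t = type_idx[g]
        w = word_idx[g]
        c = counts[g]
        s = 0.0
        for k in range(K):
            ed = n_jk[j, k] - gamma[g, k]
            if ed < 0.0:
                ed = 0.0
            ew = n_wk[w, k] - gamma[g, k]
            if ew < 0.0:
                ew = 0.0
            et = n_tk[t, k] - gamma[g, k]
            if et < 0.0:
                et = 0.0
            v = (alpha[k] + ed) * (beta[t] + ew) / (w_beta[t] + et)
            tmp[k] = v
            s += v
        for k in range(K):
            nv = tmp[k] / s
            d = c * (nv - gamma[g, k])
            n_jk[j, k] += d
            n_wk[w, k] += d
            n_tk[t, k] += d
            gamma[g, k] = nv


@njit(cache=False)
def foldin_sweep(doc_idx, type_idx, word_idx, counts, gamma,
                 n_jk, n_wk, n_tk, alpha, beta, w_beta):
    """One fold-in sweep: trained topic-word statistics held fixed.

    Identical to :func:`cvb0_sweep` on the document side (own-token exclusion
    on n_jk) but the word-topic factors use the frozen trained statistics
    n_wk / n_tk, which the new tokens neither belong to nor modify.
    """
    G, K = gamma.shape
    tmp = np.empty(K)
    for g in range(G):
        j = doc_idx[g]
        t = type_idx[g]
        w = word_idx[g]
        c = counts[g]
        s = 0.0
        for k in range(K):
            ed = n_jk[j, k] - gamma[g, k]
            if ed < 0.0:
                ed = 0.0
            v = (alpha[k] + ed) * (beta[t] + n_wk[w, k]) / (w_beta[t] + n_tk[t, k])
            tmp[k] = v
            s += v
        for k in range(K):
            nv = tmp[k] / s
            d = c * (nv - gamma[g, k])
            n_jk[j, k] += d
            gamma[g, k] = nv
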