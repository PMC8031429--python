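"""Collapsed variational Bayes EM for the multi-type topic model.

All Dirichlet parameters are integrated out; the variational distribution
factorises over token groups, each carrying a responsibility vector gamma
over the K topics.  The E-step is the zeroth-order collapsed update

    gamma_ijk^(t)  ∝  (alpha_k + n_jk^-)
                      * (beta_t + n_wk^(t),-) / (W_t beta_t + n_.k^(t),-)

where the superscript ``-`` marks expected counts with the current token's
own responsibility removed.  Responsibilities are kept per unique
(document, type, word) triple weighted by its count — identical to per-token
updates under CVB0, since all instances of a word in a document share gamma;
the exclusion subtracts a single instance's gamma.  The M-step re-aggregates
the sufficient statistics

    n_jk      = sum_t sum_i c * gamma        (document-topic)
    n_wk^(t)  = sum_j sum_i [x = w] c * gamma  (word-topic, per type)

and the Dirichlet concentrations are optionally re-estimated each iteration
by Gamma-penalized Minka fixed points (empirical Bayes).  Posterior means

    theta_jk = (alpha_k + n_jk) / (sum_k' alpha_k' + n_jk')
    phi_wk^(t) = (beta_t + n_wk^(t)) / (W_t beta_t + n_.k^(t))

are returned on convergence of the monitored objective, the per-token
pseudo log-likelihood  sum log sum_k theta_jk phi_{x,k}^(t) / N.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Callable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.special import psi

from ._sweep import cvb0_sweep, foldin_sweep
from .corpus import CorpusMode, TypedCorpus, build_corpus_variant

logger = logging.getLogger(__name__)

__all__ = [
    "ModelConfig",
    "VariationalState",
    "FittedModel",
    "init_state",
    "e_step",
    "m_step",
    "update_alpha",
    "update_beta",
    "fit",
    "infer_heldout_theta",
]

_PSI_FLOOR = 1e-12   # digamma evaluated only at arguments >= this
_HYPER_FLOOR = 1e-10  # concentrations clamped to stay strictly positive


def _psi(x):
    return psi(np.maximum(x, _PSI_FLOOR))


@dataclass
class ModelConfig:
    """Fit settings.

    Parameters
    ----------
    n_topics
        Number of latent topics K (default 50, the operating point after
        perplexity-based model selection).
    mode
        Corpus representation to fit on; the corpus is re-represented with
        :func:`typedlda.corpus.build_corpus_variant` before fitting.
    max_iter, min_iter, tol
        EM iteration cap, minimum iterations before convergence may be
        declared (the near-uniform start plateaus before symmetry breaks, so
        an early relative-change test would stop prematurely), and relative
        convergence tolerance on the monitored per-token pseudo
        log-likelihood.
    hyper_update
        ``"off"``, ``"alpha_only"`` or ``"alpha_and_beta"``: which Dirichlet
        concentrations get empirical-Bayes fixed-point updates.
    hyper_start_iter
        First EM iteration (1-based) at which hyperparameter updates run;
        earlier iterations let the statistics stabilise.
    alpha_init, beta_init
        Initial concentrations; defaults 1/K per topic and 0.1 per type.
    gamma_prior
        Fixed Gamma prior parameters (a_alpha, b_alpha, a_beta, b_beta) of
        the empirical-Bayes updates; default (1, 0, 1, 100).
    init_noise
        Relative amplitude of the positive perturbation applied to the
        uniform responsibility initialisation (symmetry breaking).
    randomize_sweep
        Visit token groups in seeded random order instead of (document,
        type, word) order.
    """

    n_topics: int = 50
    mode: CorpusMode = CorpusMode.MULTI_TYPE
    max_iter: int = 500
    min_iter: int = 20
    tol: float = 1e-5
    seed: int = 0
    hyper_update: str = "alpha_and_beta"
    hyper_start_iter: int = 10
    alpha_init: Optional[Sequence[float]] = None
    beta_init: Optional[Sequence[float]] = None
    gamma_prior: Tuple[float, float, float, float] = (1.0, 0.0, 1.0, 100.0)
    init_noise: float = 0.01
    randomize_sweep: bool = False

    def __post_init__(self):
        self.mode = CorpusMode(self.mode)
        if self.n_topics < 1:
            raise ValueError("n_topics must be >= 1")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.tol <= 0:
            raise ValueError("tol must be > 0")
        if self.hyper_update not in ("off", "alpha_only", "alpha_and_beta"):
            raise ValueError("hyper_update must be off|alpha_only|alpha_and_beta")
        if self.alpha_init is not None and np.any(np.asarray(self.alpha_init) <= 0):
            raise ValueError("alpha_init must be strictly positive")
        if self.beta_init is not None and np.any(np.asarray(self.beta_init) <= 0):
            raise ValueError("beta_init must be strictly positive")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["mode"] = self.mode.value
        for key in ("alpha_init", "beta_init"):
            if d[key] is not None:
                d[key] = list(map(float, d[key]))
        d["gamma_prior"] = list(self.gamma_prior)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        d["gamma_prior"] = tuple(d.get("gamma_prior", (1.0, 0.0, 1.0, 100.0)))
        return cls(**d)


class VariationalState:
    """Responsibilities and aggregated sufficient statistics for one corpus.

    Token groups (unique (document, type, word) triples with their counts)
    are stored flat, sorted by (document, type, word) — the deterministic
    sweep order.  Word indices are global offsets into the concatenation of
    the per-type vocabularies; ``type_offsets`` delimits each type's block.
    """

    def __init__(self, corpus: TypedCorpus, n_topics: int):
        self.n_topics = int(n_topics)
        self.n_docs = corpus.num_docs
        self.n_types = corpus.num_types
        self.type_offsets = np.concatenate(
            [[0], np.cumsum(corpus.vocab_sizes)]
        ).astype(np.int64)
        self.vocab_sizes = np.asarray(corpus.vocab_sizes, dtype=np.int64)

        docs, types, words, cnts = [], [], [], []
        for t, m in enumerate(corpus.counts):
            coo = m.tocoo()
            docs.append(coo.row.astype(np.int64))
            types.append(np.full(coo.nnz, t, dtype=np.int64))
            words.append(coo.col.astype(np.int64) + self.type_offsets[t])
            cnts.append(coo.data.astype(np.float64))
        self.doc_idx = np.concatenate(docs) if docs else np.zeros(0, np.int64)
        self.type_idx = np.concatenate(types) if types else np.zeros(0, np.int64)
        self.word_idx = np.concatenate(words) if words else np.zeros(0, np.int64)
        self.counts = np.concatenate(cnts) if cnts else np.zeros(0)
        order = np.lexsort((self.word_idx, self.type_idx, self.doc_idx))
        self.doc_idx = self.doc_idx[order]
        self.type_idx = self.type_idx[order]
        self.word_idx = self.word_idx[order]
        self.counts = self.counts[order]

        K = self.n_topics
        self.gamma = np.full((len(self.counts), K), 1.0 / K)
        self.n_jk = np.zeros((self.n_docs, K))
        self.n_wk = np.zeros((int(self.type_offsets[-1]), K))
        self.n_tk = np.zeros((self.n_types, K))
        self.objective_trace: List[float] = []

    @property
    def n_groups(self) -> int:
        return len(self.counts)

    @property
    def total_tokens(self) -> float:
        return float(self.counts.sum())

    def n_wk_for_type(self, t: int) -> np.ndarray:
        return self.n_wk[self.type_offsets[t]: self.type_offsets[t + 1]]

    def word_row_types(self) -> np.ndarray:
        """Type index of every row of the stacked n_wk matrix."""
        return np.repeat(np.arange(self.n_types), self.vocab_sizes)


def init_state(corpus: TypedCorpus, config: ModelConfig) -> VariationalState:
    """Initial responsibilities: uniform 1/K plus small positive seeded noise.

    Statistics are then aggregated from the responsibilities, so the state is
    internally consistent from the start.  Deterministic given the seed.
    """
    if corpus.num_docs == 0:
        raise ValueError("corpus is empty")
    state = VariationalState(corpus, config.n_topics)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 101]))
    K = config.n_topics
    noise = rng.random((state.n_groups, K))
    g = 1.0 + config.init_noise * noise
    state.gamma = g / g.sum(axis=1, keepdims=True)
    m_step(state)
    return state


def e_step(state: VariationalState, alpha: np.ndarray, beta: np.ndarray,
           rng: Optional[np.random.Generator] = None) -> VariationalState:
    """One sequential CVB0 sweep over all token groups, in place.

    Visits groups in (document, type, word) order (or a seeded random
    permutation when the config asked for randomised sweeps, in which case
    ``rng`` supplies the permutation), maintaining the statistics
    incrementally: each group's old contribution is removed before, and its
    new one added after, its responsibility update.
    """
    w_beta = state.vocab_sizes.astype(float) * np.asarray(beta, dtype=float)
    if rng is None:
        cvb0_sweep(state.doc_idx, state.type_idx, state.word_idx, state.counts,
                   state.gamma, state.n_jk, state.n_wk, state.n_tk,
                   np.asarray(alpha, float), np.asarray(beta, float), w_beta)
    else:
        perm = rng.permutation(state.n_groups)
        g = state.gamma[perm]  # fancy indexing copies; write back afterwards
        cvb0_sweep(state.doc_idx[perm], state.type_idx[perm],
                   state.word_idx[perm], state.counts[perm],
                   g, state.n_jk, state.n_wk, state.n_tk,
                   np.asarray(alpha, float), np.asarray(beta, float), w_beta)
        state.gamma[perm] = g
    return state


def m_step(state: VariationalState) -> VariationalState:
    """Full (non-incremental) recomputation of the sufficient statistics."""
    contrib = state.counts[:, None] * state.gamma
    state.n_jk.fill(0.0)
    state.n_wk.fill(0.0)
    state.n_tk.fill(0.0)
    np.add.at(state.n_jk, state.doc_idx, contrib)
    np.add.at(state.n_wk, state.word_idx, contrib)
    np.add.at(state.n_tk, state.type_idx, contrib)
    return state


def update_alpha(alpha: np.ndarray, n_jk: np.ndarray,
                 m_jk: Optional[np.ndarray] = None,
                 gamma_prior: Tuple[float, float, float, float] = (1.0, 0.0, 1.0, 100.0),
                 ) -> np.ndarray:
    """Gamma-penalized Minka fixed-point step for the asymmetric alpha.

        alpha_k* = [a-1 + alpha_k sum_j (psi(alpha_k + n_jk + m_jk) - psi(alpha_k))]
                   / [b + sum_j (psi(N_j + sum_k alpha_k) - psi(sum_k alpha_k))]

    ``m_jk`` is an optional auxiliary count array added to the document-topic
    statistics (zero by default).  With the default Gamma(1, 0) this is the
    plain fixed point of the Dirichlet-multinomial marginal likelihood.  A
    non-positive denominator skips the update; the result is clamped to a
    small positive floor.
    """
    alpha = np.asarray(alpha, dtype=float)
    a, b = gamma_prior[0], gamma_prior[1]
    n = np.asarray(n_jk, dtype=float)
    if m_jk is not None:
        n = n + np.asarray(m_jk, dtype=float)
    totals = n.sum(axis=1)
    alpha_sum = alpha.sum()
    num = (a - 1.0) + alpha * (_psi(alpha + n) - _psi(alpha)).sum(axis=0)
    den = b + (_psi(totals + alpha_sum) - _psi(alpha_sum)).sum()
    if den <= 0.0:
        logger.warning("alpha update skipped: non-positive denominator %g", den)
        return alpha.copy()
    return np.maximum(num / den, _HYPER_FLOOR)


def update_beta(beta: np.ndarray, n_wk_t: Sequence[np.ndarray],
                gamma_prior: Tuple[float, float, float, float] = (1.0, 0.0, 1.0, 100.0),
                ) -> np.ndarray:
    """Gamma-penalized symmetric Minka fixed-point step, one scalar per type.

        beta_t* = [a-1 + beta_t sum_k sum_w (psi(beta_t + n_wk) - psi(beta_t))]
                  / [b + W_t sum_k (psi(W_t beta_t + n_.k) - psi(W_t beta_t))]

    The W_t factor in the denominator makes the fixed point a stationary
    point of the symmetric Dirichlet-multinomial marginal likelihood plus the
    Gamma(a_beta, b_beta) log-prior.  Per-type; clamped positive; a
    non-positive denominator skips that type's update.
    """
    beta = np.asarray(beta, dtype=float)
    a, b = gamma_prior[2], gamma_prior[3]
    out = beta.copy()
    for t, n in enumerate(n_wk_t):
        n = np.asarray(n, dtype=float)
        W, K = n.shape
        bt = beta[t]
        num = (a - 1.0) + bt * (_psi(bt + n) - _psi(bt)).sum()
        n_k = n.sum(axis=0)
        den = b + W * (_psi(W * bt + n_k) - _psi(W * bt)).sum()
        if den <= 0.0:
            logger.warning("beta update skipped for type %d: denominator %g", t, den)
            continue
        out[t] = max(num / den, _HYPER_FLOOR)
    return out


def _theta_hat(alpha: np.ndarray, n_jk: np.ndarray) -> np.ndarray:
    num = alpha[None, :] + n_jk
    return num / num.sum(axis=1, keepdims=True)


def _phi_hat(beta_t: float, n_wk: np.ndarray) -> np.ndarray:
    W = n_wk.shape[0]
    num = beta_t + n_wk
    return num / (W * beta_t + n_wk.sum(axis=0))[None, :]


def _pseudo_loglik(state: VariationalState, alpha: np.ndarray,
                   beta: np.ndarray) -> float:
    """Per-token mean log-likelihood under the current posterior means."""
    theta = _theta_hat(np.asarray(alpha, float), state.n_jk)
    row_types = state.word_row_types()
    w_beta = state.vocab_sizes.astype(float) * np.asarray(beta, float)
    denom = (w_beta[:, None] + state.n_tk)[row_types]          # (W_total, K)
    phi = (np.asarray(beta, float)[row_types][:, None] + state.n_wk) / denom
    p = np.einsum("gk,gk->g", theta[state.doc_idx], phi[state.word_idx])
    return float((state.counts * np.log(p)).sum() / state.total_tokens)


@dataclass
class FittedModel:
    """A converged (or iteration-capped) fit.

    ``phi_hat[t]`` is the ``W_t x K`` posterior-mean word distribution of
    type ``type_labels[t]`` (columns on the simplex); ``theta_hat`` the
    ``D x K`` posterior-mean document mixtures (rows on the simplex).  The
    final expected-count statistics are retained so held-out documents can be
    folded in.
    """

    config: ModelConfig
    type_labels: List[str]
    vocabs: List[List[str]]
    doc_ids: List[str]
    alpha: np.ndarray
    beta: np.ndarray
    theta_hat: np.ndarray
    phi_hat: List[np.ndarray]
    n_jk: np.ndarray
    n_wk: np.ndarray              # stacked over types
    n_tk: np.ndarray
    n_iter: int
    converged: bool
    objective_trace: List[float] = field(default_factory=list)

    @property
    def n_topics(self) -> int:
        return self.config.n_topics

    @property
    def type_offsets(self) -> np.ndarray:
        return np.concatenate([[0], np.cumsum([len(v) for v in self.vocabs])]).astype(np.int64)

    def n_wk_for_type(self, t: int) -> np.ndarray:
        off = self.type_offsets
        return self.n_wk[off[t]: off[t + 1]]

    def training_perplexity(self) -> float:
        return float(np.exp(-self.objective_trace[-1]))

    # -- serialization -----------------------------------------------------
    def save(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        fmt = dict(sep="\t", index=False, float_format="%.17g")
        pd.DataFrame({"alpha": self.alpha}).to_csv(out / "alpha.tsv", **fmt)
        pd.DataFrame({"beta": self.beta}).to_csv(out / "beta.tsv", **fmt)
        pd.DataFrame(self.theta_hat).to_csv(out / "theta.tsv", **fmt)
        pd.DataFrame(self.n_jk).to_csv(out / "n_jk.tsv", **fmt)
        pd.DataFrame(self.n_wk).to_csv(out / "n_wk.tsv", **fmt)
        for label, p in zip(self.type_labels, self.phi_hat):
            pd.DataFrame(p).to_csv(out / f"phi_{label}.tsv", **fmt)
        meta = {
            "config": self.config.to_dict(),
            "type_labels": self.type_labels,
            "vocabs": self.vocabs,
            "doc_ids": self.doc_ids,
            "n_iter": self.n_iter,
            "converged": self.converged,
            "objective_trace": self.objective_trace,
        }
        (out / "model.json").write_text(json.dumps(meta, indent=2, sort_keys=True))

    @classmethod
    def load(cls, in_dir: str | Path) -> "FittedModel":
        src = Path(in_dir)
        meta = json.loads((src / "model.json").read_text())
        config = ModelConfig.from_dict(meta["config"])
        alpha = pd.read_csv(src / "alpha.tsv", sep="\t", float_precision="round_trip")["alpha"].to_numpy()
        beta = pd.read_csv(src / "beta.tsv", sep="\t", float_precision="round_trip")["beta"].to_numpy()
        theta = pd.read_csv(src / "theta.tsv", sep="\t", float_precision="round_trip").to_numpy()
        n_jk = pd.read_csv(src / "n_jk.tsv", sep="\t", float_precision="round_trip").to_numpy()
        n_wk = pd.read_csv(src / "n_wk.tsv", sep="\t", float_precision="round_trip").to_numpy()
        phi = [
            pd.read_csv(src / f"phi_{label}.tsv", sep="\t", float_precision="round_trip").to_numpy()
            for label in meta["type_labels"]
        ]
        sizes = [len(v) for v in meta["vocabs"]]
        offsets = np.concatenate([[0], np.cumsum(sizes)]).astype(int)
        n_tk = np.stack(
            [n_wk[offsets[t]: offsets[t + 1]].sum(axis=0) for t in range(len(sizes))]
        )
        return cls(config, meta["type_labels"], meta["vocabs"], meta["doc_ids"],
                   alpha, beta, theta, phi, n_jk, n_wk, n_tk,
                   meta["n_iter"], meta["converged"], meta["objective_trace"])


def fit(corpus: TypedCorpus, config: ModelConfig,
        m_jk: Optional[np.ndarray] = None,
        iteration_callback: Optional[Callable] = None) -> FittedModel:
    """Fit the model by collapsed variational EM.

    The corpus is first re-represented per ``config.mode``.  Each iteration
    runs one E-step sweep, recomputes the statistics (M-step), optionally
    applies the empirical-Bayes concentration updates, and monitors the
    per-token pseudo log-likelihood; the loop stops when its relative change
    drops below ``config.tol`` or at ``config.max_iter`` (flagged, not an
    error).  Deterministic given ``config.seed``.

    ``m_jk`` is an optional auxiliary document-topic count array forwarded to
    the alpha update.  ``iteration_callback(iteration, state, alpha, beta)``
    is invoked after every iteration (diagnostics / invariant checks).
    """
    variant = build_corpus_variant(corpus, config.mode)
    variant.validate()
    K = config.n_topics
    alpha = (np.full(K, 1.0 / K) if config.alpha_init is None
             else np.asarray(config.alpha_init, dtype=float).copy())
    beta = (np.full(variant.num_types, 0.1) if config.beta_init is None
            else np.asarray(config.beta_init, dtype=float).copy())
    if alpha.shape != (K,):
        raise ValueError("alpha_init must have length n_topics")
    if beta.shape != (variant.num_types,):
        raise ValueError("beta_init must have one entry per note type")

    state = init_state(variant, config)
    sweep_rng = (np.random.default_rng(np.random.SeedSequence([config.seed, 202]))
                 if config.randomize_sweep else None)

    converged = False
    n_iter = 0
    for it in range(1, config.max_iter + 1):
        n_iter = it
        e_step(state, alpha, beta, rng=sweep_rng)
        m_step(state)
        if config.hyper_update != "off" and it >= config.hyper_start_iter:
            alpha = update_alpha(alpha, state.n_jk, m_jk, config.gamma_prior)
            if config.hyper_update == "alpha_and_beta":
                beta = update_beta(
                    beta,
                    [state.n_wk_for_type(t) for t in range(state.n_types)],
                    config.gamma_prior,
                )
        obj = _pseudo_loglik(state, alpha, beta)
        state.objective_trace.append(obj)
        if iteration_callback is not None:
            iteration_callback(it, state, alpha, beta)
        if len(state.objective_trace) > 1:
            prev = state.objective_trace[-2]
            delta = abs(obj - prev) / max(abs(prev), 1e-12)
            logger.debug("iter %d obj=%.8f delta=%.3e alpha_mean=%.4g beta=%s",
                         it, obj, delta, alpha.mean(), np.array_str(beta, precision=4))
            if it >= config.min_iter and delta < config.tol:
                converged = True
                break

    theta = _theta_hat(alpha, state.n_jk)
    phi = [_phi_hat(beta[t], state.n_wk_for_type(t)) for t in range(state.n_types)]
    return FittedModel(
        config=config,
        type_labels=list(variant.type_labels),
        vocabs=[list(v) for v in variant.vocabs],
        doc_ids=list(variant.doc_ids),
        alpha=alpha,
        beta=beta,
        theta_hat=theta,
        phi_hat=phi,
        n_jk=state.n_jk,
        n_wk=state.n_wk,
        n_tk=state.n_tk,
        n_iter=n_iter,
        converged=converged,
        objective_trace=list(state.objective_trace),
    )


def _align_new_corpus(model: FittedModel, new_corpus: TypedCorpus):
    """Map a new corpus onto the trained vocabularies.

    Returns flat (doc, type, global-word, count) arrays in sweep order.
    Out-of-vocabulary words are dropped with a warning; note types unknown to
    the model raise.
    """
    variant = build_corpus_variant(new_corpus, model.config.mode)
    offsets = model.type_offsets
    docs, types, words, cnts = [], [], [], []
    n_oov = 0
    for label, vocab, m in zip(variant.type_labels, variant.vocabs, variant.counts):
        if label not in model.type_labels:
            raise ValueError(f"note type {label!r} was not seen in training")
        t = model.type_labels.index(label)
        index = {w: i for i, w in enumerate(model.vocabs[t])}
        col_map = np.array([index.get(w, -1) for w in vocab], dtype=np.int64)
        coo = m.tocoo()
        keep = col_map[coo.col] >= 0
        n_oov += int(coo.data[~keep].sum())
        docs.append(coo.row[keep].astype(np.int64))
        types.append(np.full(int(keep.sum()), t, dtype=np.int64))
        words.append(col_map[coo.col[keep]] + offsets[t])
        cnts.append(coo.data[keep].astype(np.float64))
    if n_oov:
        warnings.warn(f"dropping {n_oov} out-of-vocabulary tokens during fold-in")
    doc_idx = np.concatenate(docs) if docs else np.zeros(0, np.int64)
    type_idx = np.concatenate(types) if types else np.zeros(0, np.int64)
    word_idx = np.concatenate(words) if words else np.zeros(0, np.int64)
    counts = np.concatenate(cnts) if cnts else np.zeros(0)
    order = np.lexsort((word_idx, type_idx, doc_idx))
    return (doc_idx[order], type_idx[order], word_idx[order], counts[order],
            variant.num_docs)


def infer_heldout_theta(model: FittedModel, new_corpus: TypedCorpus,
                        max_sweeps: Optional[int] = None,
                        tol: Optional[float] = None) -> np.ndarray:
    """Fold new documents into a trained model (topic-word statistics fixed).

    Runs CVB0 sweeps over the new documents' tokens only: the document-topic
    statistics of the new documents are updated (with own-token exclusion)
    while the trained word-topic statistics stay frozen — new tokens do not
    alter them.  Convergence is monitored on the new documents' per-token
    pseudo log-likelihood with the training tolerance.  A document with zero
    in-vocabulary tokens gets the prior mean alpha / sum(alpha), with a
    warning.
    """
    max_sweeps = model.config.max_iter if max_sweeps is None else max_sweeps
    tol = model.config.tol if tol is None else tol
    doc_idx, type_idx, word_idx, counts, n_new = _align_new_corpus(model, new_corpus)
    K = model.n_topics
    alpha, beta = model.alpha, model.beta
    sizes = np.diff(model.type_offsets).astype(float)
    w_beta = sizes * beta

    if len(counts) == 0:
        warnings.warn("all held-out documents are empty; returning prior means")
        return np.tile(alpha / alpha.sum(), (n_new, 1))

    gamma = np.full((len(counts), K), 1.0 / K)
    n_jk = np.zeros((n_new, K))
    np.add.at(n_jk, doc_idx, counts[:, None] * gamma)

    phi_stack = np.concatenate(model.phi_hat, axis=0)
    prev = None
    for _ in range(max_sweeps):
        foldin_sweep(doc_idx, type_idx, word_idx, counts, gamma,
                     n_jk, model.n_wk, model.n_tk, alpha, beta, w_beta)
        theta = _theta_hat(alpha, n_jk)
        p = np.einsum("gk,gk->g", theta[doc_idx], phi_stack[word_idx])
        obj = float((counts * np.log(p)).sum() / counts.sum())
        if prev is not None and abs(obj - prev) / max(abs(prev), 1e-12) < tol:
            break
        prev = obj

    theta = _theta_hat(alpha, n_jk)
    empty = ~np.isin(np.arange(n_new), doc_idx)
    if empty.any():
        warnings.warn(f"{int(empty.sum())} held-out documents have no "
                      "in-vocabulary tokens; using the prior mean")
        theta[empty] = alpha / alpha.sum()
    return theta
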