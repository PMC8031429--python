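"""Model evaluation: held-out perplexity, outcome prediction, correlations.

Three protocols sit on top of a fitted model:

* **Perplexity / model selection** — fold held-out documents in, score their
  tokens under the posterior-mean parameters, and report
  ``exp(-mean per-token log-likelihood)``.  Full-document fold-in (the same
  tokens infer theta and are scored) is the default single-model report;
  the K-selection sweep uses document completion (infer on one half of each
  document, score the other half), which removes fold-in's optimistic bias
  in K.
* **Outcome prediction** — stratified cross-validated L2 logistic regression
  using the document topic mixtures as features, reporting AUROC and AUPRC
  (average precision, step-wise — no optimistic interpolation) with the
  mean ± 1.96 std / sqrt(n_runs) confidence construction.
* **Topic-outcome correlation** — column-wise Pearson (optionally Spearman /
  Kendall) between each topic's mixture weight and a continuous outcome,
  reporting the most positively and negatively correlated topics.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import average_precision_score, roc_auc_score
from sklearn.model_selection import RepeatedStratifiedKFold

from .corpus import TypedCorpus
from .inference import FittedModel, ModelConfig, fit, infer_heldout_theta

__all__ = [
    "heldout_perplexity",
    "perplexity_sweep",
    "DEFAULT_K_SWEEP",
    "topic_outcome_correlation",
    "CorrelationReport",
    "predict_outcome_cv",
    "CVMetrics",
    "top_words",
    "EvalReport",
]

DEFAULT_K_SWEEP: Tuple[int, ...] = (10, 30, 50, 100)


def _score_tokens(model: FittedModel, theta: np.ndarray, doc_idx, word_idx,
                  counts) -> Tuple[float, float]:
    phi_stack = np.concatenate(model.phi_hat, axis=0)
    p = np.einsum("gk,gk->g", theta[doc_idx], phi_stack[word_idx])
    return float((counts * np.log(p)).sum()), float(counts.sum())


def _split_counts(doc_idx, type_idx, word_idx, counts, seed: int):
    """Split token multiplicities of each group ~Binomial(c, 1/2) into halves."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 77]))
    first = rng.binomial(counts.astype(np.int64), 0.5).astype(float)
    second = counts - first
    return first, second


def heldout_perplexity(model: FittedModel, heldout: TypedCorpus,
                       method: str = "fold_in", seed: int = 0) -> float:
    """Held-out perplexity of a fitted model.

    ``method="fold_in"`` infers each held-out document's mixture from all of
    its tokens and scores those same tokens.  ``method="completion"`` infers
    from a random half of each document's tokens and scores the other half
    (unbiased; ``seed`` drives the split).  Raises on a corpus with zero
    held-out tokens.
    """
    from .inference import _align_new_corpus, _theta_hat
    from ._sweep import foldin_sweep

    if heldout.total_tokens == 0:
        raise ValueError("held-out corpus has no tokens")
    if method == "fold_in":
        theta = infer_heldout_theta(model, heldout)
        doc_idx, type_idx, word_idx, counts, _ = _align_new_corpus(model, heldout)
        ll, n = _score_tokens(model, theta, doc_idx, word_idx, counts)
        return float(np.exp(-ll / n))
    if method != "completion":
        raise ValueError("method must be 'fold_in' or 'completion'")

    doc_idx, type_idx, word_idx, counts, n_new = _align_new_corpus(model, heldout)
    obs, score = _split_counts(doc_idx, type_idx, word_idx, counts, seed)
    keep = obs > 0
    K = model.n_topics
    alpha, beta = model.alpha, model.beta
    w_beta = np.diff(model.type_offsets).astype(float) * beta
    gamma = np.full((int(keep.sum()), K), 1.0 / K)
    n_jk = np.zeros((n_new, K))
    np.add.at(n_jk, doc_idx[keep], obs[keep][:, None] * gamma)
    prev = None
    for _ in range(model.config.max_iter):
        foldin_sweep(doc_idx[keep], type_idx[keep], word_idx[keep], obs[keep],
                     gamma, n_jk, model.n_wk, model.n_tk, alpha, beta, w_beta)
        theta = _theta_hat(alpha, n_jk)
        ll, n = _score_tokens(model, theta, doc_idx[keep], word_idx[keep], obs[keep])
        obj = ll / n
        if prev is not None and abs(obj - prev) / max(abs(prev), 1e-12) < model.config.tol:
            break
        prev = obj
    theta = _theta_hat(alpha, n_jk)
    hold = score > 0
    if not hold.any():
        raise ValueError("completion split left no tokens to score")
    ll, n = _score_tokens(model, theta, doc_idx[hold], word_idx[hold], score[hold])
    return float(np.exp(-ll / n))


def perplexity_sweep(train: TypedCorpus, heldout: TypedCorpus,
                     k_values: Sequence[int] = DEFAULT_K_SWEEP,
                     config: Optional[ModelConfig] = None,
                     method: str = "completion",
                     seed: int = 0) -> Dict[int, float]:
    """Fit one model per candidate K and report its held-out perplexity.

    The default grid is {10, 30, 50, 100}; the default scoring is document
    completion (see :func:`heldout_perplexity`).  Returns ``{K: perplexity}``;
    the argmin is the selected model order.
    """
    base = (config or ModelConfig()).to_dict()
    out: Dict[int, float] = {}
    for k in k_values:
        cfg = ModelConfig.from_dict({**base, "n_topics": int(k)})
        model = fit(train, cfg)
        out[int(k)] = heldout_perplexity(model, heldout, method=method, seed=seed)
    return out


@dataclass
class CorrelationReport:
    """Per-topic correlation with a continuous outcome."""

    r: np.ndarray                      # (K,)
    method: str
    top_positive: List[int]            # topic indices, most positive first
    top_negative: List[int]            # topic indices, most negative first
    degenerate: List[int] = field(default_factory=list)  # zero-variance topics

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"topic": np.arange(len(self.r)), "r": self.r})


def topic_outcome_correlation(theta: np.ndarray, outcome: np.ndarray,
                              method: str = "pearson",
                              top_m: int = 3) -> CorrelationReport:
    """Correlate every topic's mixture weight with a continuous outcome.

    Pearson by default ("a normalized metric in the range -1 to 1");
    Spearman and Kendall available behind ``method``.  A zero-variance
    outcome or topic column yields r = 0 for that entry, flagged in
    ``degenerate`` rather than NaN.  Reports the ``top_m`` most positively
    and most negatively correlated topics (the figure convention is 3 each).
    """
    theta = np.asarray(theta, dtype=float)
    outcome = np.asarray(outcome, dtype=float)
    if theta.ndim != 2:
        raise ValueError("theta must be D x K")
    D, K = theta.shape
    if outcome.shape != (D,):
        raise ValueError("outcome length must match number of documents")
    if D < 3:
        raise ValueError("need at least 3 documents")
    if np.any(np.isnan(outcome)):
        raise ValueError("outcome contains missing values")
    funcs = {"pearson": stats.pearsonr, "spearman": stats.spearmanr,
             "kendall": stats.kendalltau}
    if method not in funcs:
        raise ValueError(f"unknown method {method!r}")

    r = np.zeros(K)
    degenerate: List[int] = []
    out_const = np.ptp(outcome) == 0
    for k in range(K):
        if out_const or np.ptp(theta[:, k]) == 0:
            degenerate.append(k)
            continue
        r[k] = funcs[method](theta[:, k], outcome)[0]
    order = np.argsort(r, kind="stable")
    m = min(top_m, K)
    return CorrelationReport(
        r=r,
        method=method,
        top_positive=[int(i) for i in order[::-1][:m]],
        top_negative=[int(i) for i in order[:m]],
        degenerate=degenerate,
    )


@dataclass
class CVMetrics:
    """Cross-validated classification metrics from topic-mixture features."""

    auroc: List[float]
    auprc: List[float]
    n_folds: int
    n_repeats: int

    @property
    def n_runs(self) -> int:
        return len(self.auroc)

    def summary(self) -> Dict[str, float]:
        out = {}
        for name, vals in (("auroc", self.auroc), ("auprc", self.auprc)):
            vals = np.asarray(vals)
            mean, std = float(vals.mean()), float(vals.std(ddof=1))
            half = 1.96 * std / np.sqrt(len(vals))
            out[f"{name}_mean"] = mean
            out[f"{name}_std"] = std
            out[f"{name}_ci95"] = (mean - half, mean + half)
        return out


def predict_outcome_cv(theta: np.ndarray, labels: np.ndarray,
                       n_folds: int = 5, n_repeats: int = 1,
                       seed: int = 0, C: float = 1.0) -> CVMetrics:
    """Stratified K-fold logistic regression on topic mixtures.

    Within each training fold an L2-regularized logistic regression
    (fixed C, intercept included) is fit on the mixture features as-is; AUROC
    and AUPRC (average precision) are computed on the held-out fold.  Both
    classes must have at least ``n_folds`` members so every fold is
    two-class.
    """
    theta = np.asarray(theta, dtype=float)
    y = np.asarray(labels).astype(int)
    if theta.shape[0] != y.shape[0]:
        raise ValueError("theta and labels must have the same length")
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise ValueError("labels must contain exactly two classes")
    if counts.min() < n_folds:
        raise ValueError(
            f"minority class has {counts.min()} members; need >= n_folds={n_folds}"
        )
    splitter = RepeatedStratifiedKFold(n_splits=n_folds, n_repeats=n_repeats,
                                       random_state=seed)
    aurocs, auprcs = [], []
    for tr, te in splitter.split(theta, y):
        clf = LogisticRegression(C=C, max_iter=1000)  # L2 penalty (default)
        clf.fit(theta[tr], y[tr])
        scores = clf.decision_function(theta[te])
        aurocs.append(float(roc_auc_score(y[te], scores)))
        auprcs.append(float(average_precision_score(y[te], scores)))
    return CVMetrics(aurocs, auprcs, n_folds, n_repeats)


def top_words(model: FittedModel, topic: int, note_type: int | str = 0,
              n: int = 100) -> List[Tuple[str, float]]:
    """The ``n`` highest-probability words of one topic under one note type.

    Sorted by descending posterior-mean word probability, ties broken by
    vocabulary order; the default n=100 matches the word-cloud convention.
    """
    t = (model.type_labels.index(note_type) if isinstance(note_type, str)
         else int(note_type))
    if not (0 <= topic < model.n_topics):
        raise ValueError(f"topic must be in [0, {model.n_topics})")
    probs = model.phi_hat[t][:, topic]
    if n > len(probs):
        raise ValueError("n exceeds the vocabulary size")
    order = np.lexsort((np.arange(len(probs)), -probs))
    vocab = model.vocabs[t]
    return [(vocab[i], float(probs[i])) for i in order[:n]]


@dataclass
class EvalReport:
    """Bundle of evaluation outputs, writable as JSON + TSV tables."""

    perplexity_by_k: Dict[int, float] = field(default_factory=dict)
    cv_metrics: Optional[CVMetrics] = None
    correlations: Optional[CorrelationReport] = None
    top_words: Dict[str, List[Tuple[str, float]]] = field(default_factory=dict)

    def save(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        payload: dict = {}
        if self.perplexity_by_k:
            payload["perplexity_by_k"] = {
                str(k): float(v) for k, v in sorted(self.perplexity_by_k.items())
            }
            pd.DataFrame(
                sorted(self.perplexity_by_k.items()), columns=["K", "perplexity"]
            ).to_csv(out / "perplexity_sweep.tsv", sep="\t", index=False,
                     float_format="%.6f")
        if self.cv_metrics is not None:
            s = self.cv_metrics.summary()
            payload["cv_metrics"] = {
                k: (list(v) if isinstance(v, tuple) else v) for k, v in s.items()
            }
            pd.DataFrame({
                "fold": range(self.cv_metrics.n_runs),
                "auroc": self.cv_metrics.auroc,
                "auprc": self.cv_metrics.auprc,
            }).to_csv(out / "cv_metrics.tsv", sep="\t", index=False,
                      float_format="%.6f")
        if self.correlations is not None:
            payload["correlations"] = {
                "method": self.correlations.method,
                "top_positive": [int(i) for i in self.correlations.top_positive],
                "top_negative": [int(i) for i in self.correlations.top_negative],
            }
            self.correlations.to_frame().to_csv(
                out / "correlations.tsv", sep="\t", index=False,
                float_format="%.6f")
        for key, words in self.top_words.items():
            pd.DataFrame(words, columns=["word", "probability"]).to_csv(
                out / f"top_words_{key}.tsv", sep="\t", index=False,
                float_format="%.8f")
        (out / "report.json").write_text(json.dumps(payload, indent=2,
                                                    sort_keys=True))
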