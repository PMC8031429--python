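"""Simulate typed corpora from the model's generative process.

The generative story: every topic k has one word distribution per note type,
phi_k^(t) ~ Dir(beta_t) over that type's vocabulary; every document j draws a
single topic mixture theta_j ~ Dir(alpha) that is *shared by all its note
types*; each token first draws a topic z ~ Cat(theta_j), then a word
w ~ Cat(phi_z^(t)).  The simulator keeps all latent variables so that
inference can be scored against the truth (after resolving topic-label
permutation).

Defaults emulate a two-type clinical-note corpus: types "physician" and
"nursing" sharing word strings, 300 tokens per note type per document,
moderately sparse mixtures (alpha = 0.3) and sparse topics (beta = 0.05).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .corpus import CorpusMode, TypedCorpus

__all__ = ["GroundTruth", "simulate_corpus", "DEFAULT_TYPE_SIZES"]

DEFAULT_TYPE_SIZES: Dict[str, int] = {"physician": 100, "nursing": 100}


@dataclass
class GroundTruth:
    """Latent variables of a simulated corpus.

    ``z[j][t]`` and ``words[j][t]`` are the per-token topic assignments and
    word indices of document j under note type t, in sampling order.
    """

    alpha: np.ndarray            # (K,)
    beta: np.ndarray             # (T,) symmetric per-type concentration
    theta: np.ndarray            # (D, K), rows on the simplex
    phi: List[np.ndarray]        # per type: (W_t, K), columns on the simplex
    z: List[List[np.ndarray]]    # [doc][type] -> int topic per token
    words: List[List[np.ndarray]]
    seed: int

    @property
    def n_topics(self) -> int:
        return self.alpha.shape[0]

    def doc_topic_counts(self, t: Optional[int] = None) -> np.ndarray:
        """Empirical per-document topic usage counts from z (optionally one type)."""
        D, K = self.theta.shape
        out = np.zeros((D, K))
        types = range(len(self.beta)) if t is None else [t]
        for j in range(D):
            for tt in types:
                out[j] += np.bincount(self.z[j][tt], minlength=K)
        return out

    def validate(self) -> None:
        if np.any(self.alpha <= 0) or np.any(self.beta <= 0):
            raise ValueError("hyperparameters must be strictly positive")
        if not np.allclose(self.theta.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("theta rows must sum to 1")
        for p in self.phi:
            if not np.allclose(p.sum(axis=0), 1.0, atol=1e-9):
                raise ValueError("phi columns must sum to 1")

    def save(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        fmt = dict(sep="\t", index=False, float_format="%.17g")
        pd.DataFrame(self.theta).to_csv(out / "theta.tsv", **fmt)
        pd.DataFrame({"alpha": self.alpha}).to_csv(out / "alpha.tsv", **fmt)
        pd.DataFrame({"beta": self.beta}).to_csv(out / "beta.tsv", **fmt)
        for t, p in enumerate(self.phi):
            pd.DataFrame(p).to_csv(out / f"phi_{t}.tsv", **fmt)
        rows = []
        for j, per_type in enumerate(self.z):
            for t, zz in enumerate(per_type):
                for i, (k, w) in enumerate(zip(zz, self.words[j][t])):
                    rows.append((j, t, i, int(k), int(w)))
        pd.DataFrame(rows, columns=["doc", "type", "token", "topic", "word"]).to_csv(
            out / "assignments.tsv", sep="\t", index=False
        )
        (out / "meta.json").write_text(
            json.dumps({"seed": self.seed, "n_types": len(self.beta)}, indent=2)
        )

    @classmethod
    def load(cls, in_dir: str | Path) -> "GroundTruth":
        src = Path(in_dir)
        meta = json.loads((src / "meta.json").read_text())
        theta = pd.read_csv(src / "theta.tsv", sep="\t", float_precision="round_trip").to_numpy()
        alpha = pd.read_csv(src / "alpha.tsv", sep="\t", float_precision="round_trip")["alpha"].to_numpy()
        beta = pd.read_csv(src / "beta.tsv", sep="\t", float_precision="round_trip")["beta"].to_numpy()
        phi = [
            pd.read_csv(src / f"phi_{t}.tsv", sep="\t", float_precision="round_trip").to_numpy()
            for t in range(meta["n_types"])
        ]
        asg = pd.read_csv(src / "assignments.tsv", sep="\t", float_precision="round_trip")
        D, T = theta.shape[0], meta["n_types"]
        z = [[np.zeros(0, dtype=np.int64) for _ in range(T)] for _ in range(D)]
        words = [[np.zeros(0, dtype=np.int64) for _ in range(T)] for _ in range(D)]
        for (j, t), grp in asg.groupby(["doc", "type"], sort=True):
            grp = grp.sort_values("token")
            z[j][t] = grp["topic"].to_numpy(dtype=np.int64)
            words[j][t] = grp["word"].to_numpy(dtype=np.int64)
        return cls(alpha, beta, theta, phi, z, words, meta["seed"])


def _doc_rng(seed: int, j: int) -> np.random.Generator:
    # per-document sub-stream: document j's draws do not depend on D
    return np.random.default_rng(np.random.SeedSequence([seed, 1, j]))


def simulate_corpus(
    n_topics: int = 5,
    type_sizes: Mapping[str, int] | None = None,
    n_docs: int = 200,
    doc_length: int | Mapping[str, int] = 300,
    doc_length_law: str = "fixed",
    alpha: float | Sequence[float] = 0.3,
    beta: float | Sequence[float] = 0.05,
    seed: int = 0,
) -> Tuple[TypedCorpus, GroundTruth]:
    """Draw a typed corpus and its latent truth from the generative process.

    Parameters
    ----------
    n_topics, n_docs
        Number of topics K and documents D.
    type_sizes
        Ordered map of note-type label -> vocabulary size W_t.  Words are
        named ``w000, w001, ...`` in every type, so types of equal size share
        word strings (needed for the same-word flattening to merge anything).
    doc_length
        Tokens per document per type (scalar or per-type map).
    doc_length_law
        ``"fixed"`` (every document exactly ``doc_length`` tokens per type)
        or ``"poisson"`` (Poisson with that mean; empty draws are redrawn as
        length 1 so no document is entirely empty).
    alpha, beta
        True Dirichlet concentrations: alpha scalar (symmetric) or length-K;
        beta scalar or per-type.
    seed
        Single global seed; each document uses a deterministic sub-stream, so
        growing ``n_docs`` leaves earlier documents unchanged.

    Returns
    -------
    (TypedCorpus, GroundTruth) — deterministic given ``seed``.
    """
    if n_topics < 1 or n_docs < 1:
        raise ValueError("n_topics and n_docs must be >= 1")
    type_sizes = dict(DEFAULT_TYPE_SIZES if type_sizes is None else type_sizes)
    labels = list(type_sizes)
    sizes = [int(type_sizes[t]) for t in labels]
    if any(w < 2 for w in sizes):
        raise ValueError("every vocabulary must have at least 2 words")
    T = len(labels)

    alpha_vec = np.broadcast_to(np.asarray(alpha, dtype=float), (n_topics,)).copy() \
        if np.ndim(alpha) == 0 else np.asarray(alpha, dtype=float).copy()
    beta_vec = np.broadcast_to(np.asarray(beta, dtype=float), (T,)).copy() \
        if np.ndim(beta) == 0 else np.asarray(beta, dtype=float).copy()
    if alpha_vec.shape != (n_topics,) or beta_vec.shape != (T,):
        raise ValueError("alpha must have length K and beta length T")
    if np.any(alpha_vec <= 0) or np.any(beta_vec <= 0):
        raise ValueError("hyperparameters must be strictly positive")
    if doc_length_law not in ("fixed", "poisson"):
        raise ValueError("doc_length_law must be 'fixed' or 'poisson'")
    if np.ndim(doc_length) == 0:
        lengths = {t: int(doc_length) for t in labels}
    else:
        lengths = {t: int(doc_length[t]) for t in labels}

    # global variables: one word distribution per (type, topic)
    phi: List[np.ndarray] = []
    for t, (label, W) in enumerate(zip(labels, sizes)):
        rng = np.random.default_rng(np.random.SeedSequence([seed, 0, t]))
        phi.append(rng.dirichlet(np.full(W, beta_vec[t]), size=n_topics).T)  # (W, K)

    theta = np.zeros((n_docs, n_topics))
    z_all: List[List[np.ndarray]] = []
    w_all: List[List[np.ndarray]] = []
    dense = [np.zeros((n_docs, W), dtype=np.int64) for W in sizes]
    for j in range(n_docs):
        rng = _doc_rng(seed, j)
        theta[j] = rng.dirichlet(alpha_vec)
        z_doc, w_doc = [], []
        for t, (label, W) in enumerate(zip(labels, sizes)):
            n = lengths[label]
            if doc_length_law == "poisson":
                n = max(1, int(rng.poisson(n)))
            zz = rng.choice(n_topics, size=n, p=theta[j])
            ww = np.zeros(n, dtype=np.int64)
            for k in np.unique(zz):
                mask = zz == k
                ww[mask] = rng.choice(W, size=int(mask.sum()), p=phi[t][:, k])
            np.add.at(dense[t][j], ww, 1)
            z_doc.append(zz.astype(np.int64))
            w_doc.append(ww)
        z_all.append(z_doc)
        w_all.append(w_doc)

    width = max(3, len(str(max(sizes) - 1)))
    vocabs = [[f"w{i:0{width}d}" for i in range(W)] for W in sizes]
    corpus = TypedCorpus(
        type_labels=labels,
        vocabs=vocabs,
        counts=[sp.csr_matrix(d) for d in dense],
        doc_ids=[f"doc{j:05d}" for j in range(n_docs)],
        mode=CorpusMode.MULTI_TYPE,
    )
    truth = GroundTruth(alpha_vec, beta_vec, theta, phi, z_all, w_all, seed)
    return corpus, truth
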