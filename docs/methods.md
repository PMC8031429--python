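# Methods

## Model

`typedlda` fits a multi-type latent Dirichlet topic model to document
collections whose tokens carry a *note type* t ∈ {1, …, T} (the motivating
case: physician vs nursing notes of one hospital admission). With K topics,
D documents and per-type vocabularies of size W⁽ᵗ⁾, the generative process
is

  φₖ⁽ᵗ⁾ ~ Dir(βₜ·1)                 one word distribution per (topic, type),
  θⱼ ~ Dir(α)                       one mixture per document, shared by all
                                    of its note types,
  zᵢⱼ⁽ᵗ⁾ ~ Cat(θⱼ),  xᵢⱼ⁽ᵗ⁾ ~ Cat(φ_{z}⁽ᵗ⁾)   per token.

The shared mixture is the point of the model: the types "borrow" information
from each other when learning their separate word distributions, while a
standard LDA either merges the types' counts (losing the distinction) or
is run with a doubled vocabulary (splitting its probability mass). Both
flattenings are implemented as corpus representations
(`single_same_word`, `single_diff_word`) so the three model classes can be
compared on identical token sets.

α is asymmetric (length K); β is one symmetric scalar per type. This
matches the per-type scalar form of the empirical-Bayes update below.

## Inference: collapsed variational Bayes (CVB0)

The Dirichlet parameters are integrated out and the variational posterior
factorises over tokens. Each token group — a unique (document, type, word)
triple with count c — carries one responsibility vector γ over topics, which
is exact under CVB0 because all instances of a word within a document share
the same update. One E-step sweep visits groups in (document, type, word)
order and applies, in place,

  γₖ ∝ (αₖ + ñⱼₖ⁻) · (βₜ + ñ_wₖ⁽ᵗ⁾⁻) / (W⁽ᵗ⁾βₜ + ñ_·ₖ⁽ᵗ⁾⁻),

where ñ⁻ are the running expected counts with *one instance's* γ (the
group's current row) subtracted — the collapsed "exclude yourself" rule.
Statistics are maintained incrementally (old contribution removed before,
new added after each update) and fully re-aggregated once per iteration
(the M-step), which removes any accumulated floating-point drift. Only the
zeroth-order expansion is used; no second-order variance corrections.

The sweep kernel is compiled with numba when available; an identical
pure-Python body is the fallback. Exclusion counts that drift slightly
negative are clamped at zero inside the kernel.

### Monitored objective and convergence

No closed-form ELBO is monitored; instead the per-token pseudo
log-likelihood Σ c·log Σₖ θ̂ⱼₖ φ̂ₓₖ⁽ᵗ⁾ / N of the training corpus under the
current posterior means is tracked. EM stops when its relative change falls
below `tol` (default 1e-5) or at `max_iter` (default 500; hitting the cap
flags the fit, it is not an error). Because the near-uniform initialisation
sits on a symmetry plateau where the objective barely moves for a few
sweeps, convergence may not be declared before `min_iter` (default 20)
iterations. CVB0 is not guaranteed monotone, but a sustained decrease of
the objective (5 consecutive iterations dropping by more than 1e-6) fails
the test suite.

### Initialisation and determinism

γ starts at 1/K with a small positive seeded perturbation (`init_noise`,
default 0.01 relative) to break topic symmetry; α starts at 1/K per topic,
β at 0.1 per type. All randomness flows from one integer seed through
`numpy.random.SeedSequence` sub-streams, so identical configuration and
seed reproduce a fit bit-for-bit. Sweep order is deterministic; a seeded
random sweep order is available behind `randomize_sweep`.

### Empirical-Bayes hyperparameter updates

From iteration `hyper_start_iter` (default 10) onward, one fixed-point step
per EM iteration re-estimates the concentrations, maximising the
Dirichlet-multinomial marginal likelihood of the expected counts under a
fixed Gamma prior (a_α, b_α, a_β, b_β) = (1, 0, 1, 100):

  αₖ* = [a_α − 1 + αₖ Σⱼ(Ψ(αₖ + ñⱼₖ + m̃ⱼₖ) − Ψ(αₖ))]
        / [b_α + Σⱼ(Ψ(Nⱼ + Σₖαₖ) − Ψ(Σₖαₖ))]

  βₜ* = [a_β − 1 + βₜ ΣₖΣ_w(Ψ(βₜ + ñ_wₖ⁽ᵗ⁾) − Ψ(βₜ))]
        / [b_β + W⁽ᵗ⁾ Σₖ(Ψ(W⁽ᵗ⁾βₜ + ñ_·ₖ⁽ᵗ⁾) − Ψ(W⁽ᵗ⁾βₜ))]

With the default flat Gamma on α this is the classic Minka fixed point. The
W⁽ᵗ⁾ factor in the β denominator is required for the fixed point to be a
stationary point of the symmetric Dirichlet-multinomial likelihood plus the
Gamma log-prior; the test suite verifies both fixed points against direct
numerical maximisation of those objectives. `m̃ⱼₖ` is an auxiliary
document-topic count array (for models with additional non-text data
channels); it defaults to zero and is exposed as an injection point on
`fit`. A non-positive denominator skips that update with a warning; results
are clamped to a 1e-10 positivity floor. The digamma function is only
evaluated at arguments ≥ 1e-12.

### Posterior means

On termination, θ̂ⱼₖ = (αₖ + ñⱼₖ)/(Σₖ'αₖ' + ñⱼₖ') and
φ̂_wₖ⁽ᵗ⁾ = (βₜ + ñ_wₖ⁽ᵗ⁾)/(W⁽ᵗ⁾βₜ + ñ_·ₖ⁽ᵗ⁾). Both are recomputable from
the stored final statistics, which the serialised model retains so held-out
documents can be folded in after reloading.

## Fold-in and perplexity

New documents are folded in by running the same sweep with the trained
word-topic statistics frozen (new tokens do not alter them); only the new
documents' doc-topic counts update, with own-token exclusion on the
document side. A document with no in-vocabulary tokens receives the prior
mean α/Σα. Folding the training documents back in reproduces the training
θ̂ only up to O(1/ñ_·ₖ): training E-steps exclude each token's own γ from
the word-topic factor, which fold-in by construction cannot, so tests check
this self-consistency at the tolerance the perturbation analysis supports
(max |Δθ̂| < 0.02, per-document correlation > 0.999 on the test corpus)
rather than at machine precision.

Held-out perplexity is exp(−Σ log Σₖ θ̂ⱼₖ φ̂ₓₖ⁽ᵗ⁾ / N) over held-out
tokens. Two estimators are provided:

* **full fold-in** (default for reporting a single model): θ̂ inferred from
  all of a document's tokens, the same tokens scored. Simple, but
  optimistically biased in K because extra topics help fit the scored
  tokens themselves.
* **document completion** (default for the model-selection sweep): each
  held-out document's token multiplicities are split Binomial(c, ½) by a
  seeded draw; θ̂ is inferred from one half and the other half is scored.
  Unbiased across K, hence used when *comparing* model orders.

A uniform single-topic model scores exactly the vocabulary size W, which
anchors the scale: any non-degenerate fit must land below the
token-weighted geometric mean of the vocabulary sizes.

## Preprocessing

Raw notes are lowercased, split on non-alphanumeric runs, and tokens
shorter than 2 characters or in the stopword list (bundled standard English
list, injectable) are dropped. The vocabulary filter keeps a word iff its
note-level document frequency — counted over individual notes *before*
grouping into admissions — is ≥ `min_doc_count` (default 5) and ≤
`max_doc_fraction` × number of notes (default 0.15). The frequency universe
pools all note types by default; `per_type_df=True` counts within each
type. All notes sharing a group id are then summed into one document, one
count slice per type; documents emptied by the filter are dropped with a
warning. No stemming, lemmatisation or n-grams — the pipeline is a minimal
deterministic realisation of generic bag-of-words preprocessing.

The diff-word flattening names composites `<type>-<word>`, doubling any
literal hyphen in the word (`x-ray` → `physician-x--ray`) so composites
stay unambiguous.

## Synthetic-data generator

`simulate_corpus` draws exactly from the generative process above and
retains every latent variable (θ, φ, z, per-token words) for recovery
scoring. Defaults define the study conditions used throughout the tests:
two types labelled `physician`/`nursing` with 100-word vocabularies sharing
word strings (so the same-word merge actually merges), 300 tokens per
document per type (a realistic clinical-note length scale), true α = 0.3
symmetric (documents use a few topics each) and true β = 0.05 (sparse,
well-separated topics, as assumed by the recovery analyses). Document
lengths are fixed by default; Poisson lengths are available. Each document
draws from its own deterministic sub-stream of the global seed, so
enlarging the corpus never reshuffles earlier documents.

What the simulator deliberately does *not* emulate: word burstiness,
Zipfian marginals, type-specific document lengths, missing note types,
label noise in outcomes, or any clinical vocabulary structure. Passing
recovery and model-comparison tests therefore demonstrates correctness of
the inference machinery under the model's own assumptions, not performance
on real clinical text.

## Evaluation protocols

* **Model selection**: fit each K on a training split, score held-out
  documents by completion perplexity, pick the argmin. The default grid is
  {10, 30, 50, 100}; the default operating point of `ModelConfig` is
  K = 50.
* **Outcome prediction**: stratified K-fold (default 5 folds × 1 repeat,
  seeded; repeats available) L2 logistic regression (fixed C = 1.0,
  intercept, simplex features used as-is) on θ̂; AUROC and AUPRC per fold,
  AUPRC as step-wise average precision (no trapezoidal interpolation, which
  is optimistic). Summary reports mean ± std and mean ± 1.96·std/√n_runs as
  the 95% interval.
* **Topic-outcome correlation**: column-wise Pearson r (Spearman/Kendall
  behind a flag) between θ̂_·ₖ and a continuous outcome; zero-variance
  columns yield r = 0 with a degeneracy flag instead of NaN; the report
  lists the 3 most positive and 3 most negative topics.
* **Top words**: the n = 100 highest-φ̂ words per (topic, type), ties broken
  by vocabulary order.

## Problem sizes used by the test suite and acceptance script

Recovery and model-comparison experiments run at D = 200 training
documents (+50 held out), T = 2, K = 5, W⁽ᵗ⁾ = 100, 300 tokens per document
per type, 10 seeds; the model-order sweep uses D = 150 (+50), W⁽ᵗ⁾ = 80,
200 tokens, K ∈ {2, 5, 20}. These sizes give stable verdicts (recovery
cosines ≈ 1, the multi-type model's perplexity advantage appears in
essentially every seed) while keeping a full run in minutes on one core.

## Known limitations

* CVB0 keeps only expected counts; no second-order correction, no Gibbs
  sampler, no stochastic/online variant.
* The monitored objective is a surrogate, not the ELBO; convergence is
  declared on its relative change.
* Fold-in cannot self-exclude (see above), so full fold-in perplexity is
  mildly optimistic; use completion for comparisons.
* The empirical-Bayes β estimate is biased upward relative to the
  simulating truth at moderate corpus sizes (it maximises the marginal
  likelihood of *expected* counts, which are smoother than real draws);
  recovery of θ and φ is unaffected in practice.
* Topics are identified only up to permutation; all truth comparisons go
  through Hungarian matching on topic-word cosine similarity.
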