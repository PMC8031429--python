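# typedlda

Multi-type latent Dirichlet topic modeling for typed document collections —
built for clinical notes, where an admission accumulates notes from authors
with different expertise (physicians, nurses) whose vocabularies and
emphases differ, but whose notes describe the same patient.

Standard LDA forces one topic-word distribution on all notes. `typedlda`
gives every topic one word distribution **per note type** while all notes of
an admission share a single topic mixture:

```
φ_k^(t) ~ Dir(β_t)        topic k's word distribution under note type t
θ_j     ~ Dir(α)          admission j's topic mixture (shared across types)
z_ij^(t) ~ Cat(θ_j)       topic of token i
x_ij^(t) ~ Cat(φ_z^(t))   the observed word
```

The shared mixture lets the types borrow statistical strength from each
other while keeping their vocabularies distinct. Inference is collapsed
variational Bayes (CVB0) with empirical-Bayes (Minka fixed-point) updates of
α and the per-type β under a fixed Gamma prior. The package also implements
the two flattened baselines the model is compared against — merging
identical words across types ("same word") and splitting every (type, word)
pair into its own vocabulary entry ("diff word") — plus the evaluation
protocols: held-out perplexity model selection, cross-validated outcome
prediction from topic mixtures, topic-outcome correlation, and top-word
export. A simulator draws corpora exactly from the generative process with
full latent truth retained, so inference can be validated end to end.

Intended users: researchers mining multi-modality text (EHR notes, but
nothing is clinical-specific) who want a typed topic model with a testable,
reproducible inference stack.

## Worked example

`examples/simulate_fit_recover.py` simulates a two-type corpus (200
admissions, 300 physician + 300 nursing tokens each, 5 topics) and fits the
model at the true K:

```
corpus: 200 documents, types ['physician', 'nursing'], 120000 tokens
EM converged after 28 iterations; training perplexity 19.86
estimated alpha: [0.327 0.324 0.294 0.355 0.346] (truth: symmetric 0.3)
estimated beta:  [0.135 0.126] (truth: 0.05 per type)
matched topic-word cosines: [1.    1.    1.    1.    0.999]
mean per-document mixture Pearson r: 0.998
```

Topics are identified only up to permutation, so estimates are matched to
the truth by Hungarian assignment on cosine similarity before scoring:
cosines ≈ 1 mean every estimated per-type word distribution recovers a true
topic; r ≈ 1 means the admission mixtures are recovered. Training
perplexity 19.9 against a 100-word vocabulary (a uniform model scores 100)
shows the fit explains most token-level structure.

`examples/model_comparison.py` fits the three representations of one corpus
and scores 50 held-out admissions:

```
            multi_type: held-out perplexity   18.53
      single_same_word: held-out perplexity   32.81
      single_diff_word: held-out perplexity   37.06
```

The multi-type model wins because it scores each token within its own
type's word distribution; the diff-word baseline additionally pays for
splitting its probability mass over a doubled vocabulary.

The other examples cover model selection by held-out perplexity
(`model_selection.py`, which picks the true K = 5 from {2, 5, 20}),
outcome prediction and topic-outcome correlation (`outcome_analysis.py`),
and the raw-note preprocessing pipeline (`preprocess_notes.py`).

## Command line

The same pipeline is scriptable via subcommands, each writing a re-runnable
manifest:

```bash
typedlda --seed 7 simulate out/sim --num-topics 5
typedlda --seed 7 fit out/sim/corpus out/model --num-topics 5
typedlda --seed 7 eval out/sim/corpus out/sim/corpus out/eval --sweep 2,5,20
typedlda --seed 7 predict out/model labels.tsv out/pred
typedlda top-words out/model out/words --n 100
```

`typedlda preprocess notes.jsonl out/corpus` turns raw JSONL notes
(`group_id`, `note_type`, `text`) into a corpus directory (Matrix Market
counts + TSV vocabularies + JSONL manifest), applying the default
document-frequency filter: words kept only if they appear in at least 5
notes and at most 15% of notes.

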