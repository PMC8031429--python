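"""Choose the number of topics by held-out perplexity.

Fits models over a grid of candidate K on a training split and scores each
on held-out documents by document completion (the mixture is inferred from
half of each document's tokens and the other half is scored), then selects
the K with the lowest perplexity.  The simulation uses 5 true topics, so the
sweep should select 5.
"""

from typedlda import ModelConfig, fit, heldout_perplexity, simulate_corpus

corpus, _ = simulate_corpus(n_topics=5,
                            type_sizes={"physician": 80, "nursing": 80},
                            n_docs=200, doc_length=200, seed=3)
train, held = corpus.subset(range(150)), corpus.subset(range(150, 200))

perplexity = {}
for k in (2, 5, 20):
    model = fit(train, ModelConfig(n_topics=k, seed=3))
    perplexity[k] = heldout_perplexity(model, held, method="completion", seed=3)
    print(f"K={k:>2}: held-out perplexity {perplexity[k]:7.2f}")

best = min(perplexity, key=perplexity.get)
print(f"selected K={best} (truth: 5) — too few topics underfit, "
      "too many waste mass on noise topics")
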