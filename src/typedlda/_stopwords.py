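"""Bundled English stopword list.

The default stopword set used by :func:`typedlda.corpus.tokenize_and_filter`.
The content matches the standard English list shipped with common NLP
toolkits; callers may inject any other word set instead.  Single-letter
fragments left by contraction splitting ("don't" -> "don", "t") are included
so they vanish regardless of the tokenizer's minimum-length rule.
"""

ENGLISH_STOPWORDS = frozenset("""
i me my myself we our ours ourselves you your yours yourself yourselves
he him his himself she her hers herself it its itself they them their
theirs themselves what which who whom this that these those am is are was
were be been being have has had having do does did doing a an the and but
if or because as until while of at by for with about against between into
through during before after above below to from up down in out on off over
under again further then once here there when where why how all any both
each few more most other some such no nor not only own same so than too
very s t can will just don should now d ll m o re ve y ain aren couldn
didn doesn hadn hasn haven isn ma mightn mustn needn shan shouldn wasn
weren won wouldn
""".split())
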