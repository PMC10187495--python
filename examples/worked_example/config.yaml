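# Worked-example analysis configuration: twelve hand-written tweets,
# default phase scheme, bundled fixture lexicon, default keyword list.
# Paths are relative to the repository root.
corpus: examples/worked_example/tweets.jsonl
incidence: examples/worked_example/incidence.csv
language: de
top_k: 5
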