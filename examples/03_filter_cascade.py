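"""The full candidate-selection cascade with per-stage accounting.

Samples peptides from a quickly fine-tuned generative model and pushes them
through deduplication, novelty screening against a reference database,
classifier consensus, toxicity-verdict intersection, and Butina/Levenshtein
clustering with centroid selection.
"""

import aopgen as ag
from aopgen import synthetic_data as sd

aop = sd.make_aop_corpus(sd.default_aop_spec(n=600, seed=1))
tr, va = ag.split_train_val(aop, 0.9, seed=1)
model, _ = ag.train(ag.build_model(ag.GenConfig(embed_dim=32, recurrent_units=64,
                                                seed=0)), tr, va, epochs=25)
generated = ag.sample(model, n=1000, max_len=8, seed=5)

ensemble = ag.train_cv(aop, ag.ClfConfig(embed_dim=16, conv_filters=32,
                                         epochs=15, seed=0))
unique, _ = ag.dedupe(generated)
reference = sd.make_reference_db(unique, overlap_fraction=0.1, extra_n=100, seed=6)
verdicts = sd.make_verdict_tables(generated, nontoxic_prob=0.8, seed=7)

final, report = ag.run_cascade(generated, reference, verdicts, ensemble,
                               consensus_threshold=0.99, cluster_threshold=2.0)
print(report)
print("\nfinal centroid peptides:")
for rec in final:
    print(" ", rec.sequence)
# Each stage only removes sequences; the report chains counts so the whole
# funnel, from raw samples to cluster centroids, is auditable.
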