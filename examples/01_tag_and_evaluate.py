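"""Train a baseline tagger on synthetic abstracts and score held-out docs.

Builds a 150-document corpus of chemical-like mentions, trains the
second-order BIO CRF on 120 documents with the baseline feature set, tags
the remaining 30, and prints exact-match mention-level (CEM) and
document-indexing (CDI) precision/recall/F1 percentages.
"""

from chemner.evaluation import cdi_evaluate, cem_evaluate, report
from chemner.pipeline import TaggerConfig, tag_corpus, train_tagger
from chemner.synthetic import gen_labeled_corpus, split_corpus

corpus = gen_labeled_corpus(seed=1, n_docs=150)
train_c, test_c = split_corpus(corpus, 120, 30)

tagger = train_tagger(train_c, TaggerConfig(max_iter=60))
predicted = tag_corpus(tagger, test_c.documents)

print(f"{len(predicted)} predicted mentions on {len(test_c.documents)} held-out docs")
print("CEM (exact offsets):")
report(cem_evaluate(predicted, test_c.mentions))
print("CDI (unique strings per document):")
report(cdi_evaluate(predicted, test_c.mentions))
# The three numbers per line are precision / recall / F1 in percent;
# an exact prediction must match the gold offsets (CEM) or string (CDI).
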