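"""Train word vectors, derive word-vector classes, check class recovery.

Trains skip-gram vectors with negative sampling on a 3-class bigram
corpus, clusters them with K-means into 3 word-vector classes, and prints
the contingency between generating classes and learned classes.
"""

import numpy as np

from chemner.synthetic import gen_class_lm_corpus
from chemner.wordrep import WVConfig, kmeans, train_wv, wvc_feature

lines, word_to_class = gen_class_lm_corpus(
    seed=41, n_classes=3, words_per_class=4, n_tokens=12000, switch_noise=0.02
)
wv = train_wv(lines, WVConfig(dimension=16, epochs=4, seed=5, min_count=1,
                              mode="skipgram"))
wvc = kmeans(wv, C=3, seed=2)

table = np.zeros((3, 3), dtype=int)
for word, cid in wvc.assignment.items():
    table[word_to_class[word], cid] += 1
print("generator class (rows) x learned class (columns):")
print(table)
print("example feature key:", wvc_feature(wvc, sorted(wv.vectors)[0], "WVC3"))
# A permutation matrix means the K-means classes recover the latent
# classes exactly; the feature key is what the CRF consumes.
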