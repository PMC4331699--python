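# chemner

Chemical and biomedical named-entity recognition with semi-supervised
word-representation features.

## The problem and the approach

Chemical NER — locating mentions such as `2-aminoethanol` or
`sodium methoxide` in titles and abstracts — is hard for purely supervised
taggers because nomenclature is productive: held-out text is full of
well-formed names never seen in training, and of chemical-*looking* words
that are not chemicals. `chemner` implements the classic semi-supervised
answer: keep a discriminative sequence model, but let unlabeled domain
text supply the generalization.

The core model is a **second-order linear-chain CRF** over BIO labels:

    P(y | x) ∝ exp Σ_t  w · f(x, t, y_{t−2}, y_{t−1}, y_t)

trained by penalized maximum likelihood (Gaussian prior, exact gradients
via forward–backward on a pair-state lattice, L-BFGS) and decoded by
Viterbi with BIO-illegal transitions structurally forbidden. Features per
token are a **baseline set** — word, lemma, full-match orthographic
patterns, 2/3/4-character prefixes/suffixes, boundary-marked character
n-grams, word n-grams, all replicated over a ±2 window — plus two kinds of
**word-representation features** induced from unlabeled text:

* **Brown clusters** — hierarchical word clustering maximizing the
  mutual information of adjacent-cluster bigrams,
  `I = Σ P(c,c') log₂ P(c,c')/(P(c)P(c'))`; each word's root-to-leaf
  bit string yields prefix features at lengths 4/6/10/20.
* **Word-vector classes (WVC)** — K-means cluster ids over word vectors
  trained with negative-sampling CBOW/skip-gram (a log-linear model, no
  hidden layer).

Mentions are post-processed with two corpus-independent rules (drop
mentions with unbalanced brackets/quotes; propagate tags across
`long form (SF)` abbreviation definitions) and scored by exact matching:
mention-level offsets (CEM) and per-document unique strings (CDI), with
`p = TP/(TP+FP)`, `r = TP/(TP+FN)`, `F1 = 2pr/(p+r)`.

No lexicon or dictionary is used anywhere. A synthetic-data module
generates labeled corpora with exact gold offsets and unlabeled corpora
with recoverable latent word classes, so the entire pipeline is testable
without external downloads.

## Worked example

```python
from chemner.evaluation import cem_evaluate, report
from chemner.pipeline import TaggerConfig, tag_corpus, train_tagger
from chemner.synthetic import gen_labeled_corpus, split_corpus

corpus = gen_labeled_corpus(seed=1, n_docs=150)
train_c, test_c = split_corpus(corpus, 120, 30)
tagger = train_tagger(train_c, TaggerConfig(max_iter=60))
predicted = tag_corpus(tagger, test_c.documents)
report(cem_evaluate(predicted, test_c.mentions))
```

prints

```
P / R / F1 (%): 96.92 / 100.00 / 98.44
TP=126	FP=4	FN=0	P=0.969231	R=1.000000	F1=0.984375
```

— all 126 gold mentions in the 30 held-out documents were found at their
exact offsets, with 4 false alarms on chemical-shaped distractor words,
giving 98.44% F1. Adding representation features induced from
unlabeled text removes most such false alarms (see
`examples/04_semi_supervised_gain.py`; the `examples/` scripts each
demonstrate one capability and print what the numbers mean).

## Command line

The same pipeline is scriptable via the `chemner` command:

```bash
chemner synth --seed 7 --n-docs 200 --out corpus/
chemner preprocess --input corpus/unlabeled.txt --out tok.txt
chemner induce-brown --input tok.txt --k 24 --out clusters.tsv
chemner train-wv --input tok.txt --dim 25 --out vectors.txt
chemner induce-wvc --vectors vectors.txt --c 12 --out wvc.tsv
chemner train --abstracts corpus/abstracts.tsv --annotations corpus/annotations.tsv \
              --brown clusters.tsv --wvc wvc.tsv --out model.tsv
chemner tag --model model.tsv --abstracts corpus/abstracts.tsv \
            --brown clusters.tsv --wvc wvc.tsv --task cem --out pred.tsv
chemner evaluate --task cem --abstracts corpus/abstracts.tsv \
                 --gold corpus/annotations.tsv --pred pred.tsv
```

Every subcommand accepts `--config file` with flat `key=value` settings
(flags override) and logs the config hash, seed and library versions to
stderr. Exit codes: 0 success, 1 data error, 2 usage error.

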