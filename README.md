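# biolemma

An inflectional-morphology lemmatizer for biomedical text, with the
evaluation machinery needed to compare lemmatization tools.

Biomedical literature is dense with Latinate technical terms whose
inflected forms general-English lemmatizers miss (*spermatogonia* →
*spermatogonium*, *lactobacilli* → *lactobacillus*), and those terms
are frequently mis-tagged — plural nouns tagged `NN`, past participles
tagged `VBD` — which defeats any tool that requires an exact
(word, POS) lexicon match. `biolemma` addresses both problems:

- **Hierarchical POS-relaxed lexicon search.** A three-layer tag
  hierarchy relates the fine-grained NUPOS tagset, the 36 primary Penn
  Treebank tags and a small set of major word classes. A lookup that
  misses at the exact (word, POS) key is retried under the tag's
  inflection-family *siblings* (NN↔NNS, NNP↔NNPS, VBD↔VBN, VBZ↔VBP, …)
  and then *across tagsets* (a Penn-tagged query is retried under the
  corresponding NUPOS tags and their siblings). The first non-empty
  stage wins, so `(anlagen, NN)` — a plural mis-tagged as singular —
  still finds the lemma *anlage* recorded under `NNS`.
- **Ordered, lexicon-validated suffix-detachment rules.** Words the
  lexicon misses fall through to per-word-class rule chains of literal
  suffix swaps (noun: `mata→ma`, `ae→a`, `i→us`, `xes→xis`, …).
  A rule may carry a *lexicon-validation constraint*: its candidate
  must be a known form, otherwise the next matching rule is tried —
  *appendixes* first yields the invalid *appendixis* (rejected), then
  the correct *appendix* via the `es`-strip rule.
- **Unicode key normalization.** Diacritics are stripped and ligatures
  split on the lookup key only (*tænia* matches the lexicon entry
  *taenia*; the surface form is preserved in the output).
- **Evaluation tools.** Multi-output-aware precision/recall/F scoring
  (a record is correct if *any* predicted lemma is in the gold set;
  precision divides by total emitted lemmas), silver-standard consensus
  construction across systems, and POS-error QA that flags nouns whose
  lemma contradicts their tag.

Every token yields at least one lemma: tokens whose POS mandates no
inflection (punctuation, symbols, foreign words, singular nouns after
a lexicon miss) and tokens no rule accepts return their surface form.
Without a POS, lemmas for *all* recorded parts of speech are returned
and disambiguation is left to the caller.

The package ships no third-party lexicons. A fixture module generates
a compact, fully declared lexicon/rule/hierarchy set (every irregular
form and worked example the method is known for, plus programmatic
regular inflection families for a few hundred biomedical stems) and
seeded synthetic evaluation corpora, so everything runs self-contained.

## Worked example

```sh
biolemma make-fixtures --outdir resources   # optional: inspect the TSVs
printf 'anlagen\tNN\nspermatogonia\tNN\nretinas\tNNS\nappendixes\tNNS\nMost\tJJS\nmight\tMD\nsigmaG\tNN\ntænia\tNN\n' > demo.tsv
biolemma lemmatize demo.tsv
```

prints (token, POS, lemma, provenance):

```
anlagen	NN	anlage	SIBLING
spermatogonia	NN	spermatogonium	SIBLING
retinas	NNS	retina	EXACT
appendixes	NNS	appendix	RULE
Most	JJS	many	EXACT
might	MD	may	EXACT
sigmaG	NN	sigmaG	SURFACE
tænia	NN	taenia	EXACT
8 tokens processed (EXACT=4, RULE=1, SIBLING=2, SURFACE=1)
```

The provenance column records how each lemma was found: `SIBLING`
means the mis-tagged plurals were recovered through the relaxed
search; `RULE` means the detachment chain (with the *appendixis*
rejection visible under `--output-format jsonl`); `SURFACE` means the
gene-product name *sigmaG* was correctly left untouched.

The same pipeline is available as a library:

```python
from biolemma import Lemmatizer, fixtures

lem = Lemmatizer(*fixtures.default_resources())
lem.lemmatize("anlagen", "NN").lemma        # 'anlage'
lem.lemmatize("axes").lemma_strings         # ('axe', 'axis')  — no-POS mode
```

Other subcommands: `eval` (P/R/F against gold lemmas, with optional
British/American variant maps), `consensus` (agreement partition
across system outputs), `qa-pos` (flag suspect noun tags),
`make-fixtures` (write the resource TSVs and seeded corpora).

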