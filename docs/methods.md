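# Methods

## The lemmatization model

`biolemma` performs inflectional lemmatization: it maps a surface
token plus its part-of-speech usage to the dictionary form — singular
for nouns, infinitive for verbs, positive for adjectives and adverbs.
Derivational morphology is out of scope except for the adverb →
adjective relation, which is realized as lexicon data (see below).
The design assumption throughout is that *lexicon lookup is more
reliable than heuristic rules*: curated (surface, POS) → lemma entries
are consulted first and exhaustively, and the suffix-rule engine runs
only when every lexicon stage has missed. Once any lexicon stage
yields a lemma, the process stops.

The pipeline for one token is:

1. **Key normalization.** The lookup key is the token with combining
   diacritical marks removed (canonical decomposition, then removal of
   the `Mn` category) and declared ligatures expanded (æ→ae, œ→oe,
   ﬁ→fi, …). Marks are stripped *before* ligature expansion so that a
   decomposed ligature (ǣ = æ + macron) still expands. This makes
   normalization idempotent, which the property tests check over
   arbitrary Unicode. Normalization affects keys only; output records
   keep the original surface. Greek letters, fullwidth forms and other
   compatibility foldings are deliberately not touched.
2. **Hierarchical lexicon search** (POS given): EXACT → SIBLING →
   CROSS_TAGSET, first non-empty stage wins; details below. With no
   POS, the entire lexicon is searched and lemmas for all recorded
   parts of speech are returned (ANY_POS).
3. **Compound fallback.** If the full token missed and contains a
   hyphen or slash, each part is lemmatized independently with the
   token's POS and the parts are rejoined with the original
   separators (*T-cells*/NNS → *T-cell*). Where to split a compound is
   a genuinely open choice; hyphen/slash with non-empty parts is this
   package's definition of "a logical point".
4. **Bypass.** Tokens whose word class is punctuation, symbol or
   foreign, purely numeric tokens, and singular-noun tags (NN/NNP)
   after a lexicon miss return the surface form: a singular tag
   asserts the token already is a lemma, and unknown names (*sigmaG*,
   *ykvD*) must pass through untouched.
5. **Rule engine.** Otherwise the word class's detachment chain runs
   (all-class union in no-POS mode). If no rule accepts, the surface
   form is the lemma — the pipeline is total.

## The POS hierarchy

Three layers: NUPOS (fine-grained; 241 tags in the full published
inventory), Penn Treebank (36 primary tags), major word classes
(closed set of 13). NUPOS→Penn is many-to-many (`pc-acp` maps to both
`RP` and `TO`); Penn→class is exactly one-to-one, and at load time
every NUPOS tag's Penn images must agree on a single word class —
which is why `RP` is housed with `TO` under `preposition`. Sibling
sets are *declared*, not inferred: NN↔NNS, NNP↔NNPS, {VBD,VBN},
{VBZ,VBP}, {JJ,JJR,JJS}, {RB,RBR,RBS}, and their NUPOS counterparts.
Declaration keeps the relaxation auditable; the families encode the
attested tagging-error patterns (singular/plural confusion, past
tense vs past participle).

Search relaxation order, given input tag *t*:

- EXACT: the key under *t* itself.
- SIBLING: the key under each declared sibling of *t* (same tagset);
  hits from all siblings at this stage are merged. The matched
  (sibling) tag, not the input tag, is reported with the candidate, so
  provenance is visible downstream.
- CROSS_TAGSET: for Penn input, the key under each NUPOS image of
  *t*; if all images miss, under the images' siblings. The reverse
  (NUPOS→Penn) direction exists behind `cross_both=True` but is off by
  default, matching the practical deployment where taggers emit Penn
  tags and only one traversal direction is exercised.

Case policy at every probe: the verbatim key is tried before the
case-folded key, and lemmas are returned as stored — this is what maps
sentence-initial *Most*/JJS to *many* without corrupting
case-sensitive entries like *Laboratory*.

The staged search is verified against an independent brute-force
oracle that rescans the whole lexicon under the same relaxation order
for every fixture surface and a panel of probe tags.

## The rule engine

Rules are literal suffix swaps grouped by word class and applied in
declared priority order; regular-expression patterns are intentionally
not supported, keeping priority semantics auditable. A suffix must be
a *proper* suffix (the stem is never empty), matching is case-folded
but the stem preserves case (*Retinas* → *Retina*). A validated rule's
candidate must be a known form — membership is checked against both
surface and lemma sides of the lexicon, case-folded — otherwise the
candidate is recorded as a rejection and the chain continues. Every
`RuleApplication` records the matched rule, the rejections that
preceded acceptance, and the surface-fallback outcome, so error
analyses can be replayed.

Default chains (priority order; `(v)` = validated):

- noun: `mata→ma`, `ae→a`, `i→us`, `xes→xis (v)`, `ices→ex (v)`,
  `es→∅`, `s→∅`
- verb: `ies→y`, `ed→∅ (v)`, `ed→e (v)`, `d→∅ (v)`, `es→∅ (v)`,
  `es→e (v)`, `s→∅`, `ing→∅ (v)`, `ing→e (v)`
- adjective: `ier→y`, `iest→y`, `er→∅ (v)`, `est→∅ (v)`
- adverb: `ily→y (v)`, `ly→∅ (v)`

The verb chain ships with the d-strip family validated: historically
an unvalidated d-strip produced invalid lemmas (*immunolabeled* →
*immunolabele*), and the corrected chain instead accepts
*immunolabel*, which is a lexicon entry. The pre-fix behavior remains
reproducible — `fixtures.legacy_verb_ruleset()` plus
`enforce_validation=False` — because the regression tests assert the
error mode itself.

Abbreviation/symbol expansion (`&` → *and*, `St.` → *saint*) is OFF by
default: expanding general-English abbreviations inside biomedical
text produces errors more often than it helps, so surface preservation
is the default and the expansion table sits behind a config flag.

Adverb→adjective mappings (*evolutionarily* → *evolutionary*, and the
corrected *strikingly* → *striking*) are lexicon entries rather than
rules, so mistakes of this class are fixable by data alone.

## Fixture resources and what they do (not) show

All resources are generated from a single in-module manifest, so the
worked examples, the lexicon and the rules cannot drift apart;
regeneration is byte-identical. The lexicon (~700 entries) contains
every irregular entry the worked examples need plus programmatically
generated regular inflection families (~120 noun stems, ~60 verb
stems, ~20 adjective stems with orthographic plural/conjugation/
comparison rules — only genuinely regular stems are included). Closure
holds by construction: every lemma is a known form, so validated rules
can fire.

`generate_eval_corpus(out, seed, n, pos_corruption)` samples lexicon
entries (uniformly, with replacement, seeded) into (token, POS, gold
lemma) triples and swaps the tags of a `pos_corruption` fraction of
eligible tokens to their family sibling (NN↔NNS, NNP↔NNPS, VBD↔VBN) —
the two documented tagging-error patterns. Default corruption is 0;
the test suite exercises 0 and 0.2. Because corrupted tokens always
retain a true entry under the sibling tag, 100% recovery is the
*designed* outcome; these corpora validate internal consistency and
the relaxation machinery, not real-corpus accuracy. Real biomedical
text has out-of-lexicon vocabulary, genuinely ambiguous forms and
tagging errors outside the declared families, so passing these tests
bounds nothing about corpus-scale performance.

## Evaluation semantics

- `score`: recall = correct/gold-inputs, precision = correct/emitted-
  lemmas, F = 2PR/(P+R) (0 when P+R=0). A record is correct if *any*
  predicted lemma is in the (variant-expanded, case-folded) gold set;
  an empty prediction set contributes zero to the output count. Tools
  emitting exactly one lemma per input therefore get P = R.
- Spelling-variant expansion is a user-supplied `form<TAB>variant`
  map applied to gold sets in both directions; no built-in dictionary.
- `build_consensus`: inputs on which every system's case-folded lemma
  set is identical form the consensus ("silver standard") partition;
  systems must cover identical key sets, and a key-set mismatch is an
  error that names the offenders.
- `detect_pos_errors`: criterion 1 flags token == lemma under a plural
  tag (NNS/NNPS); criterion 2 flags token ≠ lemma under a singular tag
  (NN/NNP). Only noun tags are ever flagged, and flags are candidates
  for human review — invariant nouns (*species*, *series*) fire
  criterion 1 legitimately.

## Numerical and degenerate-input choices

- Candidate ordering is lexicographic by (lemma, tag label, tagset);
  ties in no-POS display are de-duplicated on (case-folded lemma,
  Penn-mapped tag).
- Empty token → error; unknown POS tag → `UnknownTagError`, distinct
  from a lexicon miss (lenient mode converts per-token errors into
  surface-form results instead of aborting a stream).
- Duplicate lexicon records collapse on (surface, tag, tagset, lemma);
  identical surface+tag under different tagsets coexist.
- Duplicate rule priorities within a word class are a load error.
- Scoring of an empty record list is an error, not a 0% report.

## Problem sizes

The test suite and the acceptance script run entirely on the fixture
resources: ~700 lexicon entries, 22 rules, synthetic corpora of a few
hundred tokens, and scoring/consensus instances of 579 and 6,441
records matching the published arithmetic they reproduce. The whole
suite completes in a few seconds on one CPU.

## Known limitations

- The shipped hierarchy is a faithful but partial stand-in: it covers
  the full primary Penn layer but only a representative NUPOS slice;
  the full published 241-tag mapping would drop in as configuration.
- Sentence punctuation tags (`.`, `,`, `:`) are outside the 36-tag
  Penn layer; strict mode rejects them, lenient mode passes tokens
  through as surface forms.
- Rule chains are suffix-only; prefix/infix morphology and
  frequency-based POS selection in no-POS mode are not implemented.
- Compound lemmatization is per-part with the whole token's POS, which
  can over-apply verb rules to non-head parts of rare compounds.
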