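# Methods

This note documents the models, rules and design choices behind
`hepanlp`, in the package's own terms: what is computed, which knobs
matter, what the synthetic corpus does and does not emulate, and the
numerical conventions the implementation relies on.

## Task and annotation scheme

The unit of input is the Findings-section text of one contrast-enhanced
abdominal CT report, treated as a sequence of Unicode characters; digits,
Latin letters and punctuation inside CT-value expressions are characters
like any other, so gold tags always align 1:1 with the text.  Mentions of
the two hepatocellular-carcinoma hallmarks — arterial-phase
hyperenhancement (APHE) and portal/delayed-phase washout (PDPH) — are
annotated as character spans under a five-tag BIO scheme: B-APHE, I-APHE,
B-PDPH, I-PDPH, O.  Legality means an I-X follows B-X or I-X of the same
type.  Offsets are 0-based and half-open throughout; all files are UTF-8
without BOM and text is NFC-normalized on read so that substring tests on
快进/快出 behave identically across input sources.

The two report-level flags are *not* mutually exclusive: one report can,
and in cancer cases often does, carry both hallmarks.

## Linear-chain CRF

Both labelers share one inference core.  A tag sequence scores
`Σ_t e_t[y_t] + Σ_t A[y_{t-1}, y_t]`, with per-position emission scores
`e_t` and a 5×5 transition matrix `A`.  The log-partition is computed by
the forward recursion in log space (log-sum-exp with max subtraction);
decoding uses Viterbi with ties broken toward the lowest tag index at
every backtrack step, which makes decoding fully deterministic.
Sequence beginnings/ends are carried by sentinel *features* rather than
explicit start/stop transition vectors — with emissions free to absorb
boundary information the two parameterizations are equally expressive,
and it keeps the inference core symmetric for the neural path.

The feature-based tagger uses a fixed window template per position:
current character, characters at offsets ±1/±2, the two adjacent
bigrams, and a coarse character class (digit/Latin/punctuation/other),
padded with sentinels — exactly 8 features per position.  Training
maximizes the L2-regularized conditional log-likelihood
(`l2_strength` default 0.1) by L-BFGS (at most 200 iterations, tolerance
1e-6); the gradient is observed-minus-expected feature counts with
expectations from forward–backward marginals.  Everything is
deterministic given the data and settings; the objective trace is
recorded and is non-increasing across accepted steps.

No hard transition constraints enforce BIO legality.  Predicted
sequences are repaired by coercing an orphan I-X to B-X, which preserves
the predicted extent of the evidence instead of deleting it; downstream
report-level filtering is designed to tolerate noisy fragments anyway.

## BiLSTM-CRF

The neural labeler encodes each character with a bidirectional LSTM —
100 hidden units **per direction** (the spec-level phrase "100 hidden
units" is ambiguous; this reading gives a 200-dimensional concatenated
state and is stated explicitly) — followed by a linear projection to the
5 emission scores and the shared CRF output layer.  Character vectors
come from one of three providers behind a common contract (constant
dimension; one vector per character):

- a trainable lookup table, dimension 100, learned jointly (the default);
- pretrained static vectors read from the standard whitespace text
  format, dimension 100 by convention; unknown characters map to the
  zero vector plus one learned unknown-offset vector;
- a deterministic hash-based contextual encoder that mixes a character
  with its ±2 neighbor window (maximum input length 256), so identical
  characters in different contexts receive different vectors.  It stands
  in for a transformer sentence encoder as a frozen provider, letting the
  contextual adapter path run and be tested entirely offline.

Training minimizes the negative CRF log-likelihood with Adam
(learning rate 1e-3), dropout 0.5 on the concatenated encoder output,
batch size 64 (120 is the documented alternative for the static-vector
path), and 30 epochs by default; epoch count, learning rate and dropout
are implementation defaults, always logged with the run.  Sequences
longer than 256 characters are truncated together with their tags (or
rejected when truncation is disabled); predictions pad the truncated tail
with O so evaluation stays aligned.  The encoder, its manual
backpropagation and Adam run in NumPy in float32; batches are
length-bucketed and batch order is reshuffled per epoch from the model
seed, so a fixed seed reproduces the loss trajectory and final weights
exactly on a given BLAS build.  Single-threaded execution is the test
default; reproducibility claims do not extend to other BLAS/thread
configurations.

## Report-level evidence criteria

Per entity type, independently and in this order:

1. the two-character abbreviation (快进 for APHE, 快出 for PDPH) occurs
   literally in the text — character-based only, predictions not
   consulted;
2. otherwise, some maximal run of consecutive characters carrying that
   predicted entity (B and I tags alike) is longer than 3 characters.

"More than 3" is read as run length ≥ 4 and is the single most
consequential threshold in the pipeline, so it is configurable
(`min_run`, default 4).  Runs are computed over entity type: two adjacent
same-type spans (B-X followed by B-X) merge into one run, because the
criterion is phrased over continuous characters, not spans; a run breaks
on any change of entity type.  Single-character predictions are treated
as noise and never set a flag.  Provenance (which criterion fired, with
offsets) is recorded for every raised flag.

## Rule-based feature extraction

Four successive stages per sentence, driven by a lexicon mapping terms to
five entity types (Location, Morphology, Density, Enhancement, Modifier)
plus a synonym → canonical map:

1. **Segmentation** — forward maximum matching, longest term first;
   uncovered characters become single-character untyped tokens; tokens
   tile the sentence exactly.
2. **Entity annotation** — tokens whose (canonicalized) surface is a
   lexicon entry receive its type.
3. **Canonicalization** — synonym variants are replaced by canonical
   terms; idempotent by construction.
4. **Relation extraction** — attributes (Density, Enhancement,
   Morphology) attach to the nearest preceding Location until the next
   Location; a Modifier immediately following an attached Density or
   Enhancement upgrades that feature in place to the three-term pattern.
   Five patterns are emitted: Location+Density, Location+Enhancement,
   Location+Enhancement+Modifier, Location+Density+Modifier,
   Location+Morphology.  Morphology takes no modifier (no such pattern
   exists), and duplicates collapse within a report.

The attachment rule is the simplest one consistent with the canonical
worked examples (肝脏+低密度影, 肝脏+增强扫描未见强化); nothing richer
(true anaphora, cross-sentence linking) is attempted.  Sentences split on
。；！？; and newline only — clause commas do not split, because feature
descriptions routinely span clauses.

Counting is report-level presence: a feature mentioned twice in one
report counts once, matching the 0-1 vectors used downstream.  Features
kept for the vocabulary must occur "more than twice", i.e. in ≥ 3
reports (`min_count = 3`); the boundary is inclusive at 3 and exclusive
at 2 by design.

## Diagnosis model

Each report is a 0-1 vector: APHE and PDPH flags first (taken from the
report-level aggregation of the neural labeler's predictions — the
pipeline feeds the classifier what the extraction stage actually
produces, not gold annotations), then one column per retained feature.
The classifier is a 500-tree random forest with Gini splits, √p features
per split, unlimited depth and a logged seed.  One stratified 8:2
train/test split, governed by a single corpus-level seed, serves every
model in a run (no cross-validation); the retained-feature vocabulary is
counted on the training split only, so the test split never shapes the
feature space.  Performance is accuracy/precision/recall/F1 with liver
cancer as the positive class.  Feature importances are normalized
mean-impurity-decrease scores; the ranking is restricted to features with
corpus-wide frequency > 10 (`min_frequency = 11`), sorted by importance
with lexicographic tie-break, top 10 reported.

## Evaluation conventions

Character-level scoring is per-entity **binary membership**: a character
is APHE-positive if its tag carries the APHE entity, B and I alike, and
precision/recall/F1 pool counts over all characters of the corpus.  The
per-entity rows of a character-level score table admit a second reading —
exact BIO label required — which is implemented behind
`mode="strict"`; neither mode claims to reproduce any externally
reported table.  Report-level scoring is ordinary binary classification
over the flag tables.  Zero-denominator precision/recall/F1 are defined
as 0.  All metrics are percentages.

The train/test split takes ⌈0.8 n⌉ reports for training, allocated
across diagnosis strata by largest remainder, shuffled within strata by
the split seed.

## Synthetic corpus

Defaults emulate the corpus structure this pipeline targets: 480 cancer
and 609 non-cancer reports; APHE in 442/480 cancer and 160/609
non-cancer reports (so ≈ 602 of 1,089 overall), PDPH in 330/480 cancer
reports and never in non-cancer ones; APHE and PDPH are drawn
independently given the diagnosis (their within-report joint distribution
is unknown beyond the marginals).  Mentions are rendered as full phrases
(the five canonical expressions), abbreviations (probability 0.3) or
CT-value style wordings (probability 0.15), embedded after lesion-context
clauses inside a single sentence, so shuffling sentence order never
strands a washout mention without context.  Six feature-sentence
families with class-conditional prevalences realize all five extraction
patterns (including 肝脏+低密度影 and 肝脏+肝裂增宽, the
hepatic-fissure-broadening finding typical of cirrhotic livers);
hard-negative distractors (动脉期未见强化, 动脉期强化不明显,
门脉期呈相对等密度, enhancement vocabulary outside the arterial/portal
context) appear at rate 0.3 with all-O tags so that labeling is not a
pure lookup.  Reports are 3–10 sentences, order shuffled per report; a
fixed seed reproduces the corpus byte-for-byte.

What the generator does **not** emulate: real hospital prose (free
word-order paraphrase, typos, section headers), annotator disagreement,
CT-value mentions whose polarity requires comparing numbers across
phases, and lexicon coverage at realistic scale (the bundled lexicon has
~60 terms, not hundreds).  Consequently, near-ceiling labeler scores on
synthetic text demonstrate that the machinery is correct and the
orderings are achievable — report-level scores dominating
character-level ones, the neural labeler matching or beating the feature
CRF, combined features beating either feature family alone — but say
nothing about absolute performance on clinical text.

## Numerical and procedural choices

- Log-sum-exp with max subtraction everywhere; float64 for CRF
  training/inference, float32 for the neural encoder.
- Viterbi ties break to the lowest tag index; retained features sort by
  descending count then key; importance ties break lexicographically —
  every ordering in the package is total and deterministic.
- Empty texts are legal inputs (empty tag sequence, zero flags); empty
  training sets and single-class training labels are errors.
- One pipeline seed derives per-stage seeds by fixed offsets
  (generation, split, CRF, neural, forest), so any stage can be rerun in
  isolation; all derived seeds stay below 2^31.
- Problem sizes: the default corpus is 1,089 reports; the acceptance
  run trains both labelers on the 872-report training split and
  evaluates on 217 held-out reports; the repeat-run determinism check
  uses a 200-report corpus with 6 training epochs, the seed-plumbing
  property being size-independent; the planted-signal simulation uses
  400 reports × 11 features × 20 seeds.

## Known limitations

- No negation or uncertainty handling at report level beyond what the
  labelers learn; CT-value comparison logic is out of scope.
- The rule pipeline's synonym canonicalization is table lookup, not
  anaphora resolution; Modifier+Morphology combinations are deliberately
  not a pattern.
- The feature CRF's window is ±2 characters; cues farther away are
  invisible to it by construction (the BiLSTM path exists for exactly
  that reason).
- Reported scores on synthetic data sit near the ceiling; they validate
  mechanics and orderings, not clinical accuracy.
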