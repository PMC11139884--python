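# Methods

This note documents the models, conventions and numerical choices behind
`ptsdlang`, what the synthetic-data generator does and does not emulate,
and therefore what the test suite does and does not demonstrate.

## Transcripts and tokenization

Transcription marks are data. The tokenizer is a deterministic
whitespace/punctuation splitter in which the ellipsis character "…" is
always its own token (a silent break), and a word glued to "…" is flagged
`truncated=True` when the following word strictly extends it
(case-insensitive proper prefix): "par… partir" is a truncated restart
(false start), while "Je… je" is an immediate repetition across a silent
break. Word counts used as normalisation denominators exclude punctuation,
silent-break marks and truncated fragments — a fragment is a disfluency
event, not a lexical word. Character spans are 0-based half-open into the
raw text, and the surface form always equals the raw-text slice, so
feature extraction is reversible to the transcript.

Annotation comes from a rule-based French tagger: closed-class lists
(pronouns with person/number, determiners, prepositions, conjunctions,
common adverbs, filler interjections), full paradigms for the auxiliaries
"être"/"avoir", and verb-ending heuristics driven by syntactic context (a
token reached from a subject pronoun through clitics/negation is treated
as a finite verb; participle endings after an auxiliary mark past
participles). The conditional is recognised by the r-stem endings
(-erais/-irais/-rrais…), which separates it from the imperfect
(courais vs courrais). Any learned tagger can be plugged in through the
same interface; the rule tagger is the always-available default and is
what the tests exercise.

## The feature registry

81 features in 8 groups with pinned sizes: textual 2,
sentiment/emotion 27, lexical 4, morphosyntactic 18, passive 4,
disfluency 9, readability 5, graph 12. The sentiment family is composed
of 4 LIWC-style category rates, 10 EMA-style and 6 FEEL-style emotion
rates, a valence-weighted happiness score (weighted mean over matched
tokens), polarity/subjectivity from a pluggable scorer (default: a
lexicon-difference scorer), and 4 EMPATH-style categories. The
collinearity reduction used for modelling keeps the 6 valence-based
sentiment scores (polarity, subjectivity, positive-emotion rate,
happiness, positive/negative emotion) and collapses the passive family to
the normalised passive count, leaving 57 features.

Conventions worth stating:

* All category rates are matched-token weight divided by the word count;
  tense proportions are normalised by the finite-verb count, "on"-value
  proportions by the number of "on" occurrences.
* Zero denominators (empty or verb-less documents) yield the 0 sentinel,
  never NaN.
* The perception field merges perception verbs and perception words into
  one feature so the lexical family has exactly 4 members.
* Present-tense values (generic / historical / enunciative) and "on"
  values (we / someone / generic) are disambiguated by deterministic
  contextual rules — genericity cues ("toujours", "jamais", …), past-time
  anchors (temporal adverbs, clock times, a past finite verb in the
  sentence), and object clitics between "on" and its verb ("On m'a …" →
  someone). A learned tagger emitting those categories overrides the
  rules.
* Passive detection: a form of "être" (finite, infinitive, or "été" in a
  compound tense) followed within ≤3 interveners (adverbs, clitics,
  negation) by a past participle not on the intransitive motion/state
  list ("Elle est partie" is a compound past, not a passive); a "par"/"de"
  phrase directly after the participle marks the passive as agented.
* The composite disfluency score is the sum of the eight component rates.

## Speech graphs

The narrative is a directed multigraph over word types (lemmas by
default, whole-document scope, punctuation excluded), one edge per
consecutive pair. On the simple directed projection (self-loops removed
from the adjacency): L1 = self-loop instances, L2 = node pairs linked in
both directions, L3 = distinct directed 3-cycles (trace(A³)/3),
PE = Σ C(m, 2) over ordered-pair multiplicities m. Degree statistics use
multigraph degrees (mean degree 2E/N). Clustering, transitivity and the
average shortest path are computed on the undirected simple projection of
the largest connected component (scipy sparse/csgraph; the values equal
networkx's on the same subgraph, which the tests assert). Single-node
components yield the 0 sentinel. The whole loop/parallel-edge vector is
property-tested against exhaustive enumeration (including Floyd–Warshall
paths) on hundreds of random multigraphs with ≤8 nodes.

## Univariate screen

Two-group comparisons use the Mann–Whitney U test: full permutation
enumeration of all C(n1+n2, n1) assignments when n1+n2 ≤ 12 (two-sided
p = 2·min(P(U≤u), P(U≥u)), capped at 1), otherwise the normal
approximation with tie correction. Effect size is pooled-SD Cohen's d with
the group1 − group2 sign convention and the symptomatic group second, so
an elevated marker in the symptomatic group is negative. Three-group
comparisons use one-way ANOVA with eta². Categorical covariates use the
chi-square contingency test with Yates continuity correction on 2×2
tables (this convention reproduces p ≈ 0.227 on the cohort
sex-by-exposure table reconstructed from the published percentages) and a
Cramér's-V-style effect size.

Power is estimated post hoc by seeded Monte-Carlo simulation at the
observed effect size and sample sizes (default B = 2000): normal samples
shifted by |d| for the rank test, group means with pooled SD for the
ANOVA, multinomial resampling of the observed table for chi-square. A
closed form is awkward for rank tests; simulation keeps one definition
across the three tests. Constant features return p = 1 and d = 0. Raw
p-values are reported by default (no multiplicity correction);
Benjamini–Hochberg is available by flag.

## Classification protocol

Each run draws a stratified 80/20 document split (per-stratum rounding
half-up, repaired to the global 20% count; 148 documents → 118/30).
Stratification is exposure × diagnosis; a coarsening helper backs off to
exposure-only (then a single stratum) when the cross yields singleton
strata. Standardization and SMOTE are fitted on the training fold only —
SMOTE interpolates each synthetic sample on the segment between a
minority point and one of its k = 5 nearest minority neighbours, in the
standardized space — and the test fold is untouched until scoring, which
the suite verifies by perturbing test rows and asserting an unchanged
fitted model. Runs with a single-class test fold are reseeded, not
skipped, so the run count stays exact. Importances are |coefficients| for
the logistic family (standardized features), impurity importances for the
forest, and term importances for the EBM; the EBM family is optional at
runtime and skipped with a warning when no implementation is importable.
Error analysis ranks documents by misclassification frequency over their
test-fold appearances (ties broken by doc_id), takes the worst 20, and
reuses the screen (chi-square / Mann–Whitney) against metadata
covariates.

## CNN branch

A compact deterministic text CNN implemented in NumPy with manual
backpropagation: per-channel embedding (dimension 128, PAD id 0 pinned to
the zero vector, UNK id 1) → channel concatenation → spatial dropout
(whole embedding dimensions, p = 0.1) → one valid 1-D convolution
(32 filters, kernel 9) → ReLU → global max pooling → dense sigmoid. This
single-block topology is the minimal architecture consistent with
CAM/deconvolution interpretability and is an assumption of this package.
Training uses focal loss (−α_t(1−p_t)^γ log p_t with α = 0.7, γ = 2; at
γ = 0 it equals α-weighted cross-entropy to machine precision, which is
asserted), Adam (lr 3e-3), L2 penalty 1e-4, batch 32, a 50-epoch cap and
early stopping on validation focal loss (patience 8, best weights
restored). The backward pass is verified against finite differences to
~1e-11. Class imbalance is handled by the focal loss alone — no
oversampling in this branch.

Sequences are cut after the document-level split (train / validation
carved per class / test), so no document feeds more than one fold; the
vocabulary is the training fold's top (vocab_size − 2) forms plus
PAD/UNK. K sequences per document are sampled at random start offsets
(with replacement when the document is short; right-padding below one
window), with K = ceil(Q75/seq_len) by default, Q75 being the length at
the threshold of the 25% longest documents. Inference uses exhaustive
non-overlapping windows and averages their probabilities — order- and
duplication-invariant by construction.

Saliency decomposes each active convolution unit's pre-activation into
its exact additive token contributions W[k,d,h]·x[t,d], weights them by
the unit's classifier weight, and sums them back onto token positions
(a transposed convolution of the class-weighted feature maps). The
combination across channels is a parameter (per-channel or summed).
Patterns are maximal spans exceeding the sequence mean + 1 SD, with pads
masked out of the normalisation; the "most representative sequence" of a
class is the probability argmax.

## Synthetic cohorts

The generator emulates the cohort's statistical structure: 148 documents
(110 A1 / 38 A2 exposure; 70 full / 42 partial / 36 no PTSD; partial PTSD
always carries criteria B and G), log-normal document lengths
(moment-matched to mean 5553, SD 3628, truncated to [200, 20000] tokens),
and age/sex marginals per exposure stratum. Text is token-stream
realistic, not grammatical prose: French function-word skeletons with
content slots, built so that every feature family has non-degenerate
variation — category words from the generator's own stand-in lexicons,
inserted fillers/breaks/truncations/repetitions, passive templates, a
bigram-recycling knob that raises PE and L2, proper names, all tenses and
all three "on" values. Stand-in lexicons (≥20 terms per category,
surface-matched, plus a weighted happiness lexicon) replace the licensed
resources, whose term lists are not redistributable.

Group effects are planted as per-document target rates drawn from a Gamma
distribution with mean p0 + shift and SD σ = 0.02 (Gamma avoids the
zero-clipping bias of a truncated normal); category draws use cumulative
intervals so one category's shift never distorts another's probability.
An effect requested as Cohen's d is converted to a rate shift against the
*realised* between-document SD — σ combined with the binomial sampling
noise implied by the drawn document lengths and the measured content-slot
fraction (0.26) of the sentence templates — so the extracted feature
realises approximately the requested d. Class-exclusive marker tokens
(insertion rate configurable; 0.2 in the separability fixtures, ≈4
markers per 128-token window) provide a cleanly learnable signal for the
CNN tests. Per-stratum label noise flips the recorded diagnosis while the
text keeps the true class, which lets the error analysis be validated
against a planted error concentration.

What passing tests show — and what they do not: the pipeline recovers
effects of the planted kind (rate shifts, repetition structure, marker
vocabulary) at the configured sample sizes, and is calibrated under the
null. They do not show that real trauma narratives carry such effects,
that the rule tagger reaches the accuracy of a learned French pipeline on
natural speech, or that the published cohort's statistics would be
reproduced — the original interviews are not public, and the published
headline AUCs are properties of that private corpus.

## Problem sizes

Tests and the acceptance script run the full 148-document cohort with
shortened documents (length means 400–600 tokens, bounded ≤ 2000) and
sequence length 128 for the CNN; these sizes keep a complete run in the
low minutes on one CPU while leaving every statistical property
(calibration, planted-effect recovery, separability) intact. The
generator's defaults remain the full-scale study conditions.

## Known limitations

* The rule tagger's tense and POS heuristics are tuned for interview-style
  French and the generator's vocabulary; rare verb forms default to NOUN.
* The 18 morphosyntactic feature names and the exact composition that
  makes the published total "80 built / 55 kept" are not reconstructible
  from the main text; this registry pins the printed group sizes (total
  81, 57 retained) and documents the discrepancy.
* Polarity/subjectivity default to a lexicon-difference scorer, not a
  trained sentiment engine.
* The EBM family requires an external implementation at runtime.
* Document-level CNN inference assumes the discourse signal is roughly
  uniform across windows; a localised signal dilutes under probability
  averaging.
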