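# Methods

## The prediction procedure

`protofunc` annotates an unannotated protein `p_u` in three stages.

1. **Specification rules.** Known protein characteristics are written as
   premises of a propositional fragment of predicate logic over a fixed
   vocabulary of eight predicates (structure `ST`, folding `FD`,
   function `F`, amino-acid sequence `AAS`, covalent protein–ligand bond
   `CBND`, protein–protein interaction `PPI`, non-covalent bond `NCBND`,
   complex of functions `PCF`). The bundled base has 13 premises; the
   rule DSL makes the set extensible without code changes. Rule
   variables are implicitly universally quantified.

2. **Explicit extraction.** Dictionary terms related to `p_u` in its
   sentences are extracted. Category terms annotate `p_u` directly
   (*explicit* predictions); predicate-template terms become ground
   atoms ("given premises"), bound to the nearest named protein/ligand.

3. **Implicit inference.** The rule base is grounded over the extracted
   constants and forward-chained with the ten standard inference rules.
   Every newly derived function atom `F(Px)` transfers all of `Px`'s
   known annotations to `p_u` (*implicit* predictions), citing a proof.

## Logic engine

**Syntax and equality.** Connectives are binary and ordered as written;
formula equality is structural (no associativity/commutativity
normalisation), because the inference-rule patterns are directional.
The single exception is *specification-rule instance matching* in the
proof checker, which matches modulo commutativity of `&`/`|`: premises
are universally quantified schemata, so a conjunction cited in either
order names the same premise. This is needed to replay printed
derivations that instantiate a two-variable premise with its variables
swapped.

**Grounding.** Substitutions are sort-respecting (protein variables to
protein constants, ligand to ligand) and injective by default — distinct
variables take distinct constants — which prevents degenerate
self-instantiations of the two-protein premises (e.g. a structural
classification of a protein with itself). Injectivity is configurable
off. Grounding order is deterministic: rule-file order, then
lexicographic constant order.

**Termination.** Forward chaining only admits a conclusion that lies in
the subformula closure of the input (given atoms plus grounded rules,
plus the `False` constant). This bounds the two generative rules
(Conjunction, Disjunctive Amplification) and forces a fixpoint in at
most `|universe|` iterations. A consequence worth knowing: conjunctions
that appear in a printed derivation but not as a subformula of any rule
(e.g. `FD(Px) & ST(Px)`) are not built by the live chainer, which
reaches the same function atoms through Modus Ponens routes instead;
the proof *checker* accepts both styles.

**Proofs.** Derivations are recorded as 1-based, consecutively numbered
lines, each justified as a given premise, a named specification-rule
instance, or a named inference rule applied to earlier lines. The first
derivation of a formula wins (determinism; minimality is not claimed).
The checker treats two-premise antecedent citations as unordered, since
that is how printed derivations cite them. An independent truth-table
oracle (`entails_bruteforce`, vectorised over all `2^n` assignments,
capped at 16 atoms) is used in the test suite to confirm soundness of
everything the chainer derives; it shares no code with the chainer.

## Extraction layer

**Units and tokenization.** The co-occurrence unit is the sentence: the
linguistic rules are sentence-level, so no windowing across sentence
boundaries is used. Sentences are split by a small deterministic rule
(a run of `.!?` ends a sentence unless the preceding word is a
configured abbreviation); tokens are lowercased words with punctuation
stripped, spans 0-based half-open. The package does not attempt
parsing, coreference, or named-entity recognition beyond dictionary
lookup — constants and their sorts are always declared in the lexicon.

**Relatedness rules.** Two mentions in a sentence are *unrelated* if a
disconnector (*whereas*, *but*, *while*) lies strictly between them,
else *related* if a pronoun connector (*that*, *who*, *which*) does,
else undetermined. A sentence labelled unrelated is discarded as
evidence for that pair but does not veto other sentences.

**Z-score.** The collocation statistic is
`z = (k − N·p)/sqrt(N·p·(1−p))` with `p = (n_a/N)(n_b/N)`, where `k` is
the pair's co-occurrence sentence count, `n_a`, `n_b` the marginal
sentence counts and `N` the corpus size; under independent placement it
is approximately standard normal (slightly conservative, because the
marginals are estimated). The default acceptance threshold is
`z > −1.96`, configurable; note that this literal one-sided reading
accepts nearly all observed pairs, and `+1.96` is the meaningful
one-sided test — the threshold is exposed precisely so users can choose.

**Training index.** A pair enters the training index when at least one
training sentence relates it and its corpus-wide Z-score clears the
threshold. At query time a term must also form an index pair with the
query protein, which presumes the training corpus contains that
protein's texts (the intended protocol: the database holds the
literature of the studied proteins).

**Template binding.** A template mention fills each role slot with the
nearest non-overlapping constant mention of the required sort (token
distance, ties broken leftward, slots take distinct mentions). This is
deliberately simple and deterministic.

## Pipeline and scoring

Derived `F(Px)` transfers *all* categories annotated to `Px`; no subset
selection is attempted. Support — the number of independent evidence
items (sentences for explicit records, source proteins for implicit
ones) — is the only ranking key; no pseudo-probability is invented.
Records below `min_support` (default 1) are dropped; ordering is
explicit-first, support descending, category id. Disabling inference
(`inference_enabled=False` / `--no-inference`) yields exactly the
explicit records, which is the explicit-only ablation arm.

Scoring is per protein: recall `C_p/N_p`, precision `C_p/M_p`,
F-value `2PR/(P+R)` (0 when both are 0), macro-averaged because the
metrics are defined per protein. Correctness is exact category-id match
(no ontology-ancestor credit). A protein with `N_p = 0` or `M_p = 0`
has undefined metrics and is skipped with a logged warning — how such
proteins should enter the averages is genuinely open, and skipping is
the choice that adds no invented signal. Cross-validation is a seeded
shuffle plus round-robin deal, so folds differ in size by at most one.

## Synthetic corpora

The generator emulates only the features the extraction rules are
sensitive to: dictionary terms, declared constant names, pronoun
connectors and disconnectors, at the sentence level. Planted pairs fire
independently per sentence at a configured rate (at most one renders a
given sentence) through fixed templates, e.g.
`"the folding of PA , which involves PU ."`; background terms occur
independently at their rates; everything is a deterministic function of
the seed. Real biomedical language — syntactic variety, entity
ambiguity, nested clauses, negation — is *not* simulated, so passing
tests demonstrate the correctness of the implemented rules, not
extraction quality on PubMed text.

Default study conditions used by the checks: calibration corpora of
20,000 sentences (2,500 documents × 8 sentences) with 50 independent
terms at occurrence rate 0.05 — large enough that pair counts are in
the normal regime for the Z-score while keeping the suite fast;
planted-signal scenarios of 200 documents (4–8 sentences each) with
pronoun-pair rates 0.3 (premise terms) and 0.2 (category terms), rates
at which every planted pair is observed many times; soundness sweeps of
500 random instances over ≤3 constants (≤16 ground atoms, within the
truth-table cap). The default seed everywhere is 17.

## Known limitations

- Only the two shipped linguistic rules (pronoun connector,
  disconnector) are implemented; other computational-linguistic
  techniques a production system might add are out of scope.
- The rule base ships with the 13 sample premises; real deployments
  would extend the `.plr` file.
- Forward chaining is propositional after grounding; quantifiers,
  function symbols and equality are out of scope, as are proof
  minimisation and SAT/resolution methods.
- GO-hierarchy propagation of predictions and protein-centric maximum
  F-measure are out of scope.
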