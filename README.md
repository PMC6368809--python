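# protofunc

Protein function prediction from biomedical text via predicate-logic
forward chaining.

Most of what is known about a protein is written down in sentences, not
databases. When a functional-category term co-occurs with a protein in
text and is *semantically related* to it, the protein can be annotated
with that function directly. But many functions are never stated
outright: the text mentions the protein's folding, its structure, its
amino-acid sequence, or its binding partners — facts that *entail* a
function without naming one. `protofunc` targets exactly those implicit
annotations: it extracts explicitly related biological-molecule terms
from sentences, turns them into ground logical premises, and
forward-chains a rule base of protein specifications to derive function
atoms with complete, replayable natural-deduction proofs.

It is aimed at researchers in biomedical text mining and automated
protein function annotation who want an auditable, rule-based
complement to statistical annotation transfer.

## The model

**Specification rules.** Known protein characteristics are encoded as
premises over a fixed predicate vocabulary — `ST(Px)` structure,
`FD(Px)` folding, `F(Px)` function, `AAS(Px)` amino-acid sequence,
`CBND(Px, Ly)` covalent protein–ligand bond, `PPI`/`NCBND`/`PCF`
protein–protein interaction, non-covalent bond and complex of
functions. The bundled rule base (`src/protofunc/data/protein_rules.plr`)
holds 13 premises, e.g.

```
R1:  FD(Px) -> (ST(Px) -> F(Px))     # folding then structure determine function
R10: (AAS(Px) & AAS(Py)) -> (ST(Px) -> F(Py))   # sequence-classification transfer
R12: NCBND(Px, Py) -> PPI(Px, Py)    # non-covalent bonds drive interactions
```

Rule variables are implicitly universally quantified and are grounded
(injectively, by default) over the protein/ligand constants extracted
from text.

**Extraction.** A term mention and a protein mention in one sentence are
related if a pronoun connector (*that*, *who*, *which*) links them and no
disconnector (*whereas*, *but*, *while*) lies between them; the pair must
additionally clear a collocation Z-score

z = (k − N·p) / √(N·p·(1−p)),  p = (n_a/N)(n_b/N),

over sentence counts, and — when a training index is supplied — have
been validated as related on the training corpus.

**Inference.** The ten standard propositional inference rules (Modus
Ponens, Modus Tollens, Simplification, Conjunction, Disjunctive
Syllogism, Disjunctive Amplification, Contradiction, Conditional Proof,
Proof by Cases, Law of Syllogism) are applied to the given premises and
grounded rules until a fixpoint, restricted to the subformula-closure
universe of the input so chaining always terminates. Each derived
function atom `F(Px)` transfers all categories annotated to `Px` onto
the query protein as *implicit* predictions, each citing a proof the
checker can replay line by line.

**Evaluation.** Per protein: recall = C_p/N_p, precision = C_p/M_p,
F-value = 2PR/(P+R), macro-averaged, with a seeded k-fold
cross-validation harness.

## Worked example

Given premises stating that some protein `Px` folds and has a structure:

```bash
$ printf 'FD(Px)\nST(Px)\n' > given.txt
$ protofunc prove --given given.txt
AAS(Px)
AAS(Px) -> F(Px)
AAS(Px) -> ST(Px)
F(Px)
FD(Px)
FD(Px) -> (ST(Px) -> F(Px))
FD(Px) | ST(Px)
FD(Px) | ST(Px) -> F(Px)
ST(Px)
ST(Px) -> AAS(Px)
ST(Px) -> F(Px)
# 11 formulas in 3 iteration(s)
```

The engine saturates in 3 iterations; the key line is `F(Px)` — the
protein's function is entailed even though no sentence stated it. The
other lines are the grounded premises it used and the intermediate
formulas (e.g. `ST(Px) -> F(Px)` from Modus Ponens on `R1`, `AAS(Px)`
from the structure–sequence premise `R13`).

End-to-end on a synthetic corpus with planted sentence structure
("the folding of PA , which involves PU ."):

```bash
$ protofunc synth --spec spec.json --lexicon lex.tsv -o corpus.jsonl
$ protofunc annotate --protein PU --corpus corpus.jsonl --lexicon lex.tsv \
      --annotations ann.tsv -o pred.tsv
$ cat pred.tsv
protein  category    evidence  support  provenance
PU       GO:0042981  explicit  39       doc00000:s2;...
PU       GO:0001     implicit  1        F(PA)[proof:5 lines]
PU       GO:0002     implicit  1        F(PA)[proof:5 lines]
```

`GO:0042981` was extracted explicitly (39 supporting sentences); the two
implicit records come from deriving `F(PA)` out of `FD(PA)`/`ST(PA)` and
transferring PA's known annotations, with a 5-line proof attached.
`protofunc annotate --no-inference` reproduces the explicit-only
ablation. `protofunc eval --predictions pred.tsv --gold ann.tsv` prints
per-protein counts and macro recall/precision/F.

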