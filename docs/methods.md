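# Methods

This note documents the models, conventions and design choices behind
`rulefinder`, in the spirit of a statistical-software methods appendix. It
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Rule model and matrix semantics

A rule is an ordered list of clauses `(predicate, direction)` with an
optional *scope* predicate. Predicates are SMARTS leaves composed with
`and` / `or` / `not` / `count_ge(pattern, k)` (k counted over deduplicated
substructure matches). Evaluation of a rule on a molecule:

* scope present and not matched → `0`;
* otherwise the **first** clause (authored order) whose predicate matches
  decides the output (`+1` predicts high activity, `−1` low);
* no clause matches → `0`.

First-match precedence mirrors the if/elif structure of generated
rule-to-matrix code and makes conflicting clauses well-defined; permuting
clauses whose match sets do not overlap cannot change any output, and this
is property-tested.

**"Para" definition.** A para-scoped clause requires 1,4-disubstitution on
a six-membered aromatic carbocycle, expressed directly in SMARTS by ring
walking (`[!#1]c1ccc(cc1)C(=O)[OX2H1,OX1-]`); ortho or meta placement of
the same group does not satisfy it. Because implicit hydrogens are not
atoms, `[!#1]` at the para position enforces a heavy-atom substituent.

**Nitro-group conventions.** RDKit sanitization rewrites hypervalent nitro
`N(=O)=O` into the charge-separated `[N+](=O)[O-]`, so SMARTS written
against the hypervalent depiction (the convention of several other
toolkits, and common in generated code) would never match an RDKit
molecule. The matcher therefore also tests a hypervalent-nitro variant of
the molecule (charges zeroed, the N–O single bond promoted); a pattern
matches if either view matches. This makes both depictions equivalent at
matching time without mutating the stored molecule.

Molecules are handled as neutral, explicit-H-free graphs; no tautomer or
protonation-state enumeration is attempted. Model-generated *executable*
code is out of scope by design: rules are exchanged as declarative JSON and
interpreted, which keeps matrix generation reproducible and safe.

## Association metrics

With `A = {i : column[i] ≠ 0}`, `n` samples, and
`correct(i) = (column[i]=+1 ∧ label=high) ∨ (column[i]=−1 ∧ label=low)`:

* `support = |A| / n`
* `confidence = |{i ∈ A : correct}| / |A|`
* `baseline = mean over i ∈ A of the full-dataset marginal rate of the
  class predicted for i` (0.5 on balanced labels)
* `lift = confidence / baseline`
* `leverage = ½ Σ_{c ∈ {high, low}} [P(pred=c ∧ actual=c) − P(pred=c)·P(actual=c)]`

These are the standard association-rule definitions adapted to *signed*
predictions; the adaptation is the central modelling decision of the
metrics module, since the four quantities are otherwise only defined for
one-directional rules. Leverage is the **mean** of the two directional
leverages: this keeps it in the classical `[−0.25, 0.25]` range and gives
the canonical value 0.25 for a perfect full-coverage rule on balanced
labels (the sum of the directional leverages would reach 0.5 there).
"Support" counts *applied* samples, not applied-and-correct ones;
correctness is the job of confidence. The baseline uses the full dataset's
class rates, not the applied subset's. Rules that never apply get explicit
`undefined` flags rather than NaNs so downstream commentary stages can
reason about them. Under label permutation, lift centres at 1 and leverage
at 0; both nulls are simulation-tested (1000 permutations, 3-SE bands).

## Labeling

Labels are `high` iff yield is **strictly** above the median (middle /
mean-of-middle-two order statistic); ties go to `low`. Strictness makes the
rule deterministic; with continuous yields it leaves class sizes within one
of each other. Downstream encoding is high→1, low→0, and `high` is the
positive class in every classification metric.

## Cross-validation protocol

* **5-fold CV**: stratified, shuffled, seed-controlled, extra-trees
  classifier (100 trees, unlimited depth by default; hyperparameters are
  recorded in every report).
* **LOO**: n single-sample splits per seed; the headline accuracy is the
  mean across seeds of per-seed accuracies, with spreads reported both
  across seeds and across splits (a "± sd" is ambiguous between the two,
  so both are exposed). Nine seeds is the default.
* **Balanced leave-P-out** (P=4): test sets of exactly 2 high + 2 low,
  drawn uniformly *without replacement* from the full combinatorial pool
  (enumerated exactly; e.g. 9+9 labels give C(9,2)² = 1296 candidate test
  sets), 50 by default.
* **Forward selection**: greedy, scored by LOO accuracy on the training
  set; ties break by column order; stops at no strict improvement or a cap
  of 5 features (the cap is a termination guard, not a tuning knob).
* **RFECV**: elimination step 1, 5-fold stratified CV, accuracy scoring.
* **Attribution**: seeded permutation importance by default; tree-Shapley
  values (on the positive-class probability, mean |value| per feature) are
  used only when the optional `shap` package is importable. The backend is
  recorded in the report. Note that permutation importance splits
  attribution between duplicated features rather than assigning each the
  full share — the duplication test asserts exactly that behaviour.

Prediction ties in ensemble votes resolve to class 0 (low), sklearn's
argmax convention.

## Fragment-pooled descriptors

The descriptor baseline pools five additive atomic properties — Gasteiger
(PEOE) partial charge, Crippen LogP and MR contributions, Labute ASA, TPSA
contributions — over three nested shells of heavy atoms within 2, 4 and 6
bonds of the carboxyl carbon (the surface-attachment anchor). "Fragment
level" has no unique operational definition; topological bond-radius
shells were chosen because they are deterministic, nested by construction,
and converge to whole-molecule means as the radius grows (both properties
are tested, including recovery of molecular TPSA in the whole-molecule
limit). The radii are configurable. Molecules with several carboxyl groups
use the first match in canonical atom order with a warning. Redundancy
pruning replaces a manual step with a deterministic greedy screen: scan
column pairs in order, drop the later column of any pair with |Pearson r|
above 0.95. Quantum-chemistry and 3D/conformer descriptors are out of
scope.

## Refinement loop

One round: rule generation/revision → commenter review → advisor guidance
→ matrix compilation (code mode) → matrix checking and guideline
diagnostics (rule count within 5–15, per-rule coverage ≥ 2) → association
metrics → k-fold CV → ML commentary → manager decision. The generator and
commenter see only the current round; the advisor and manager may use full
history. Structured payloads are exchanged as exactly one JSON object per
response, tolerant of surrounding prose; a parse failure triggers one
retry with the error echoed back, after which the round fails loudly and
the state rolls back (no partially-advanced rounds).

Stopping: (a) manager acceptance, (b) any rule revised more than 3 times
with accuracy improvement below ε = 0.01 in the last round, (c) an
iteration cap (10). The ε-based formalization of "limited improvement" is
this package's choice; it is configurable.

The scripted backend replays transcripts verbatim and makes the loop fully
deterministic and offline; the bundled replay walks the benzoate rule
through its four recorded wordings to manager acceptance. The live
HTTP backend (chat-completion style, stdlib urllib) exists for real runs
and is deliberately outside the test surface.

## Synthetic data generator

The generator emulates the study conditions: n = 36 modifiers drawn from
five scaffold families (para/meta/ortho benzoates, a propanoate chain, an
α-amino acetate) × nine substituents spanning EWG / EDG / coordinating /
neutral classes. Allocation across scaffolds is proportional (remainders
by seeded draw), which guarantees every family — and hence the planted
para-benzoate rule — has coverage well above the two-sample minimum.

Yields follow `latent = β_fe·fe_loading + Σ_r β_r·indicator_r + ε` with
`fe_loading ~ U(0.5, 2.0)` (arbitrary units; only ordering matters for
tree models), `ε ~ N(0, 0.5)`, `β_fe = 1.0` and a planted-rule coefficient
of 3.0 — a dominant substructure effect, the regime the recovery
experiments are specified in. The latent maps to (0, 100) by a scaled
logistic centred at the latent midpoint, so median binarization is
well-defined and monotone in the latent. Modifier/SBU and Fe/Hf are
nuisance uniforms.

What the generator does **not** emulate: real measured yields, assay
noise structure, correlated experimental features, or any mechanistic
chemistry (charge transfer, coordination equilibria). Passing recovery
tests therefore demonstrates that the pipeline's statistics and protocol
recover a planted signal at study scale — not that the original
laboratory numbers are reproduced. The published accuracies of the
original study depend on its deposited experimental dataset and on
language-model outputs, and are intentionally not asserted anywhere in
this package.

## Numerical and degenerate-input conventions

* All stochastic operations take explicit seeds; repeated runs are
  bit-identical (floating-point CV accuracies included, since sklearn is
  deterministic given seeds).
* Empty rule sets compile to n×0 matrices; empty datasets raise.
* Undefined metrics (no applied samples, zero baseline) are flagged, not
  NaN.
* Matrix agreement requires identical row/column ids and is the plain
  fraction of equal cells.
* Zero-variance feature columns are dropped by the pruner with a
  diagnostic, and score zero under permutation importance.

## Problem sizes in tests and the acceptance script

Simulation-based checks use study-scale data (n = 36) with 20 seeds for
recovery/comparison experiments, 200 seeds for cheap metric nulls, and
1000 label permutations for the association-metric nulls; tree counts are
reduced to 25 in tests where only a protocol property (not model quality)
is under test. These sizes are the package's own reproducibility choices
and are stated in the relevant docstrings.
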