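# Methods

## The evaluation model

`funcbench` scores ontology-structured predictions in the time-delayed
setting: predictions are frozen at a deadline *ts*, ground truth is the set
of experimental annotations accumulated by a later benchmark time *tB*. The
working assumptions are the standard ones for this kind of assessment:

* **True-path rule.** An annotation or prediction of a term implies all of
  its ancestors. Both truth and predictions are therefore compared after
  ancestral closure ("propagation"). Propagation follows `is_a` and
  `part_of` edges within an aspect; regulates-type relations do not imply
  the parent and are ignored (an `is_a`-only mode is available via the
  `relations` argument of `parse_obo`).
* **Aspect roots carry no information.** The three roots are true for every
  annotated protein and have zero information accretion, so they are removed
  from every propagated set and from predictions. A flag
  (`propagate(..., include_roots=True)`) retains them for diagnostic use.
* **Open-world truth.** Absence of an annotation is not evidence of absence.
  The prior-subtraction logic below, and the NK/LK/PK split itself, exist
  because truth at *ts* is incomplete.
* **Experimental ground truth.** Records are filtered to the 13 evidence
  codes EXP, IDA, IPI, IMP, IGI, IEP, TAS, IC, HTP, HDA, HMP, HGI, HEP.
  TAS and IC are curator/author statements in GO's own classification but
  are kept in the experimental set used for ground truth here. Negated
  (NOT-qualified) records, duplicates, and the MF "protein binding" term
  GO:0005515 are dropped; the GO:0005515 exclusion is applied *before*
  propagation so its ancestors still enter through other terms.

Benchmark membership is decided on propagated, filtered sets: a protein
whose only deadline-time annotations are electronic is treated as
unannotated. Gained truth is the *propagated* tB set minus the *propagated*
ts set (propagate-then-subtract): a new leaf under an already-annotated
branch contributes only its genuinely novel ancestors, and a protein whose
new records imply nothing new is excluded. Deadline snapshots are nominally
subsets of benchmark-time snapshots, but curated databases retract records;
violations are reported (`annotations.superset_violations`) and tolerated
rather than enforced.

## Metrics and numerical conventions

The threshold sweep visits every distinct submitted score plus 1.0, so the
reported Fmax/Smin are exact optima rather than grid approximations; the
historical 101-point grid (0.00–1.00) can be requested through the
`thresholds` argument for comparability with older assessments.

Per-protein counters are updated incrementally as the threshold descends,
but each reported ratio is recomputed from integer counters at each
threshold, so exact cases stay exact: an ideal method (scoring exactly the
gained truth at 1.0) yields Fmax = 1.0 and Smin = 0.0 as float literals, not
within rounding. Conventions for degenerate points:

* precision with no predicting proteins, and F with pr + rc = 0, are 0;
* `m(τ)` counts proteins whose *effective* set `P_i(τ) \ T_i^ts` is
  non-empty, so macro precision never averages 0/0 terms; for NK/LK this
  coincides with "proteins with at least one prediction";
* per-protein recall denominators cannot vanish (benchmark proteins have
  non-empty gained truth by construction; asserted, not patched);
* the standalone coverage operation counts proteins with ≥ 1 stored score.
  For a PK protein predicted *only* on its prior terms this can exceed
  m(0)/n computed from the curve; the two agree in NK/LK and whenever a
  method predicts anything novel;
* Smin is the minimum over thresholds of the Euclidean norm of (ru, mi).
  Some descriptions typeset this with a max and no radical; the established
  definition — closest approach of the information-weighted curve to the
  origin — is what is implemented;
* Fmax/Smin tie-breaks report the smallest optimal threshold;
* in the incomplete mode with an empty submission, n_e = 0 and recall, ru
  and mi are reported as 0 rather than raising.

Macro precision scores correctness against the full tB truth (a PK method
re-discovering a prior term's sibling under the same parent is correct even
though the parent was known); a `strict_novelty` toggle restricts the
numerator to gained terms only for sensitivity analyses.

**Information accretion.** `ia(f) = −log₂(n_{f,P} / n_P)` where `n_P` counts
reference proteins carrying all (non-root) parents of `f` and `n_{f,P}`
those also carrying `f`, a maximum-likelihood estimate of the conditional
probability. Zero-count terms (no protein carries the parents, or none
carries `f` given the parents) have an undefined or infinite estimate; they
are assigned the maximum finite ia observed in their aspect and logged —
rare terms stay maximally informative without infinities leaking into Smin.
The pipeline and acceptance runs estimate ia from the benchmark-time
snapshot, mirroring the use of a current reference release by assessors;
any propagated snapshot can be supplied instead.

**Cross-version comparisons.** `common_term_restriction` intersects the term
sets of several ontology releases and rebuilds edges as the transitive
reduction of the newest release's ancestor relation over surviving terms, so
terms whose intermediate parents disappeared are reconnected to their
nearest retained ancestors and propagation semantics follow the newest
graph. Cross-aspect edges, which never carry propagation, are not
reconstructed.

**Bootstrap.** The resampling unit is the benchmark protein, matching the
per-protein evaluation; thresholds are re-swept on every resample.
Percentiles (2.5/97.5) use linear interpolation between order statistics.
Each (method, aspect, setting) derives its own stream from the master seed
via a CRC mix, so adding methods never perturbs existing intervals.
Team-best selection is fixed before bootstrapping (the interval describes
the chosen method, not the selection process); ranking ties break by higher
coverage, then team name, making leaderboards byte-deterministic.

**Other conventions.** Duplicate predicted pairs collapse to the maximum
score (deterministic and order-independent, unlike last-wins); score
propagation is max-over-descendants, which preserves (0,1] and ancestor
consistency; obsolete terms resolve through `replaced_by` only (`consider`
suggestions are ambiguous and never auto-applied); the ID mapping must be
injective so distinct proteins cannot silently merge. Arbitrary score
precision is accepted; the historical two-decimal convention is not
enforced. The sequence-similarity baseline consumes a precomputed hit table
(target, reference protein, percent identity in (0,100]) and transfers each
reference protein's propagated terms at identity/100, max over hits; running
the alignment itself is out of scope.

## The synthetic study

The generator (`funcbench.synthetic`) emulates the *structure* of the real
inputs so every parser and operation is exercised end to end with planted
truth:

* `random_ontology`: one rooted DAG per aspect; each non-root term gets 1–2
  parents among earlier terms (second parent with probability 0.3, `part_of`
  with probability 0.15), so acyclicity and root reachability hold by
  construction. Default 30 terms per aspect.
* `simulate_snapshots`: 200 proteins by default, planted as 25% NK, 25% LK,
  40% PK and the rest inert, relative to one evaluation aspect (MF by
  default). Gains draw `max(1, Poisson(2))` source terms which are then
  propagated; PK priors are closures of 1–2 random terms, and gained sources
  are re-drawn until they imply something outside the prior, so every PK
  protein strictly grows. These sizes keep a full study in the tens of
  milliseconds while leaving ~100-protein benchmarks, large enough for
  stable rank orderings.
* `simulate_predictor`: with base u ~ U(0.001, 1), true terms score
  `u^(1/(1+4q))` and false terms `u^(1+4q)` (rounded to 3 decimals, floored
  at 0.001), giving exchangeable scores at q = 0, overlapping but shifting
  distributions for intermediate q, and exact separation (1.0 vs 0.001) at
  q = 1, where Fmax = 1 is attainable by construction. False-term counts per
  protein follow `Poisson(|gained|)`. A `coverage` argument drops whole
  proteins to emulate partial submissions.

What the generator does **not** emulate: GO's scale and topology (tens of
thousands of terms, heavy-tailed depth and fan-out), annotation biases
toward well-studied proteins and shallow terms, inter-protein correlation
(families sharing function), retracted annotations, and score calibration
quirks of real methods. Passing tests therefore certify the *evaluation
machinery* — formulas, set semantics, determinism, ordering properties —
not any claim about how real predictors rank on real data.

## Design choices on genuinely open points

* Propagation relations (`is_a` + `part_of`) follow established practice for
  this assessment family; the choice is configurable because it is a
  convention, not a theorem.
* "Annotated at the deadline" is judged after the experimental-evidence
  filter, so electronic-only proteins are no-knowledge targets — consistent
  with the challenge's notion of ground truth.
* The reference corpus for ia is not pinned to a particular release; the
  estimator takes any propagated snapshot.
* Duplicate-pair handling in submissions (max) and the treatment of the
  incomplete mode's empty-submission corner are not fixed by any published
  convention; the choices above favor determinism and order-independence.

## Known limitations

* The per-event sweep is O(events + thresholds × proteins) per method; it is
  sized for challenge-scale benchmarks (10³–10⁴ proteins), not proteome-wide
  scans with millions of scored pairs.
* `common_term_restriction` requires each aspect root to survive the
  intersection and emits the transitive reduction, so decorative redundant
  edges of the input are not preserved.
* Obsolete terms without `replaced_by` are dropped; predictions on them are
  lost (counted and logged) rather than remapped through `consider`.
* The ia zero-count fallback (aspect maximum) is a pragmatic cap; other
  conventions (e.g. +1 smoothing) would shift Smin by a bounded amount and
  are not currently implemented.
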