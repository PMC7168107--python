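# Methods

## Diagnosis model

The anatomy is a typed DAG: nerve roots (sources) feed nerves, which feed
muscles and dermatomes (sinks); nerve→nerve edges are permitted. The
behavioural theory is a weak fault model over test outcomes: a healthy
component with proper inputs yields proper outputs, and proper outputs make
its test pass. Two consequences drive everything:

* **transitivity** — a failed test of `c` implicates `c` or a transitive
  ancestor of `c`;
* **passes are uninformative** — a passed test never entails health.

Dermatomes are assumed healthy (skin pathology is outside the clinical
scope), so they are excluded from conflicts, diagnoses and every metric
population, while still acting as test surfaces for their ancestors.

Conflicts are computed directly as the faultable ancestor closures of failed
tests rather than through a truth-maintenance system: on a DAG under this
fault model, these closures are exactly the minimal conflicts (a set of
components is jointly un-healthy-assumable precisely when it contains some
failed test's closure). The test suite checks this equivalence by brute
force on small models. Minimal diagnoses are the subset-minimal hitting sets
of the conflicts, built incrementally with minimality pruning; conflict sets
here are short root–nerve–sink chains, so no compilation machinery is
warranted.

### Probabilities

Components fail independently with a shared prior `p` (default 0.1,
configurable), so `P(Δ) ∝ p^|Δ|`, normalized over the returned minimal set
only. Any `p < 0.5` orders diagnoses by cardinality first; the default
simply makes single-fault explanations 10× likelier per component than
double faults, which matches the minimality preference. Renormalization
after every probing filter is assumed throughout — entropy needs a
distribution — and "after" metrics are computed from the renormalized final
set.

## Probing loop

Candidates are the union of all diagnosis members not yet tested (a
dermatome can therefore never be probed in this loop: it is never a
diagnosis member). Expected gain of probing `c`:

    IG(c) = P_fail(c) · (Ent(D) − Ent(D | c failed)),

where `P_fail(c)` is the mass of diagnoses intersecting `{c} ∪ ancestors(c)`.
This equals the full expected-posterior-entropy reduction because the pass
branch leaves `D` unchanged. "One of its inputs" is read transitively;
direct-parents-only filtering is strictly weaker and breaks ground-truth
retention. Two edge cases:

* The filter-and-renormalize update is not Bayesian conditioning, so the
  entropy difference can in rare configurations be negative (a fail that
  drops a dominant singleton while keeping several equal larger diagnoses
  spreads belief). Such probes are reported as zero gain: they must neither
  win the argmax nor keep the loop alive. Empirically this occurred in ~0.1%
  of candidate evaluations on synthetic batches.
* Termination: the loop stops at `|D| ≤ 1`, when candidates run out, or
  (info-gain policy) when the best gain is zero — a zero-gain probe's fail
  update is the identity or impossible, so the set cannot shrink further.

Equal-gain ties break uniformly at random from the session seed; sessions
are fully reproducible. A probe answer that eliminates every diagnosis
aborts the session with the partial log attached — it means the true fault
set was not among the minimal diagnoses — rather than silently
re-diagnosing; re-running `diagnose` with the augmented observations is the
documented follow-up. The `random` baseline picks uniformly among
candidates and terminates when candidates are exhausted; on the same answer
map both policies converge to the same final set once every informative
probe has been asked.

## Synthetic anatomy generator

The generator emulates the structure of an upper-body model innervated by
the C3–T1 roots: 7 nerve roots, 18 nerves, 30 muscles, 20 dermatomes (75
components). Each non-root draws `1 + Poisson(edges_per_node − 1)` parents
from the layer above; the default mean in-degree of 1.2 mirrors real
innervation, where most muscles and dermatomes are served by a single nerve
and most nerves arise from one or two roots. Denser wiring is available but
rapidly entangles the root layer: with mean in-degree 2 the chance that
five or six random faults have pairwise disjoint ancestor closures drops
below 10⁻³ and the simulator's rejection rule cannot be satisfied.
Direct root→muscle and root→dermatome edges are off by default (toggles
exist); whether the original clinical model contains them is unknown.

What the generator does **not** emulate: anatomical locality (adjacent roots
serving adjacent nerves), graded symptom severity, movement-level
observations, or realistic component naming. Passing tests on this fixture
show algorithmic correctness on structurally comparable DAGs, not clinical
validity of any particular anatomy.

## Scenario simulator

Per scenario: draw `k` distinct faultable components uniformly; reject and
redraw (budget 5000) while any two faults have overlapping self-inclusive
ancestor closures — overlap is exactly when minimal-cardinality reasoning
can merge the two faults, covering both a shared ancestor and one fault
affecting the other. Label every component in `faults ∪ descendants(faults)`
as failing with probability `fail_prob` (default 0.5; 1.0 is the relaxed
always-fail regime) and everything else as passing; force one uniformly
chosen explaining symptom for any fault left symptomless. Observations are
`s ~ U[1, min(k, #failing)]` failing labels drawn without replacement — the
cap by `k` matches the evaluation protocol, the uniform size is a choice
(only the range is prescribed). A generate-then-discard mode
(`discard_mode="filter"`) is available for audit; the default redraw mode
reaches configured batch sizes and reports the number of rejected draws.

Batches: exhaustive single-fault scenarios (one per faultable component)
plus 150 random instances per cardinality 2–6, giving 825 requested
instances on a 75-faultable anatomy.

## Metrics

All populations are faultable components only; counting the always-healthy
dermatomes would deflate false-positive rates.

* **Weighted FPR** — `Σ_Δ P(Δ)·FP(Δ)/(FP(Δ)+TN(Δ))`; a degenerate term
  (`FP+TN = 0`) contributes 0 and emits a warning.
* **Health-state AUC** — 11 thresholds 0.0..1.0 step 0.1, predicted-faulty
  = `H(c) > t` (strict), corner points (0,0) and (1,1) added, points sorted
  by FPR (TPR secondary), trapezoidal integration. Undefined without faults.
* **Top-K** — exact-set membership of the truth among the K most probable
  diagnoses; ranking ties break by (cardinality, lexicographic), the
  canonical set order.
* **Wasted effort** — inspect components in decreasing `H`; count healthy
  inspections until all faults are seen. Ties at the weakest fault's level
  resolve analytically: `m` healthy and `r` faulty tied components
  contribute `m·r/(r+1)` expected extra inspections.
* **Improvement orientation** — before−after for set size, weighted FPR and
  wasted effort; after−before for AUC and top-K, so every improvement is
  non-negative when troubleshooting helps. Both absolute and relative
  tables are emitted (the absolute one is primary).

Batch evaluation diagnoses each scenario's initial observations, runs the
probing loop against the scenario's label map, scores both endpoints and
aggregates per cardinality; AUC is computed per scenario and then averaged.
The policy comparison uses the fractional set-size reduction after the
first probe, paired per scenario, with a one-sided paired t-test.

## Problem sizes and determinism

The bundled study conditions are the default 75-component anatomy with
805-scenario batches (55 faultable singles + 150×5 multi-fault instances)
per labeling regime; brute-force cross-checks run on 10-faultable models
where exhaustive subset enumeration is exact. Every stochastic entry point
takes an explicit seed; batch and evaluation runs spawn per-scenario seeds
from it, so reports are bit-reproducible.

## Known limitations

* Strong fault models, fault modes and abductive reasoning are out of
  scope; so are non-binary or probabilistic test outcomes and probe costs.
* Only minimal diagnoses are enumerated: a true fault set that strictly
  contains a minimal diagnosis (a redundant real-world diagnosis) is
  unreachable by construction.
* The initial observations of a simulated scenario need not jointly explain
  every injected fault; high-cardinality truths are then not in the initial
  diagnosis set, which mirrors how partial first consultations behave.
* The entropy heuristic is myopic (one probe lookahead).
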