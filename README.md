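# physdx

Consistency-based diagnosis and troubleshooting for neuromuscular clinical
evaluation, built for teaching and benchmarking. When a patient reports a
weakened motion (a muscle test) or a defected sensation (a dermatome test),
the root cause can lie in the tested structure itself or anywhere upstream —
the innervating nerve or its spinal nerve root. `physdx` models this as
model-based diagnosis over a typed anatomical influence DAG and helps
disambiguate the candidates with an information-gain probing loop.

## The model

Components come in four kinds — nerve roots (sources), nerves, muscles and
dermatomes (sinks) — joined by directed influence edges. Only healthy
behaviour is modeled (a *weak fault model*): a passed test never exonerates
anything, while a failed test of component `c` implicates `c` or one of its
ancestors. Dermatomes are assumed healthy; they only serve as test surfaces
for their ancestors.

Each failed test therefore yields a **conflict** — the faultable part of
`{c} ∪ ancestors(c)` — and the candidate diagnoses are exactly the
subset-minimal hitting sets of the conflicts. Assuming independent failures
with prior `p` (default 0.1), each diagnosis Δ gets probability
`P(Δ) ∝ p^|Δ|`, normalized. The per-component **health state** is
`H(c) = Σ_{Δ ∋ c} P(Δ)`.

Probes are ranked by expected information gain over the diagnosis
distribution, `IG(c) = P_fail(c) · (Ent(D) − Ent(D_fail))` with
`Ent(D) = −Σ P(Δ) log₂ P(Δ)`; a failed probe filters the set to the
diagnoses intersecting the probe's ancestor closure. The loop stops when one
diagnosis remains or no probe can shrink the set.

A fault-injection simulator generates seeded ground-truth scenarios
(injected faults, full simulated test labels, initial observations), and the
metrics module scores diagnosis sets before/after troubleshooting: set size,
probability-weighted FPR, health-state ROC AUC (11 thresholds), top-K and
wasted effort.

## Worked example

```python
import physdx as px

frag = px.paper_fragment_model()        # C6 → {Radial, Median} → muscles/DC6
D = px.diagnose(frag, {"DC6": False})   # tingling thumb: defected DC6 sensation
print(D)
# DiagnosisSet({C6}: 0.5, {Radial}: 0.5)

print(px.expected_information_gain(frag, D, "Median"))
# 0.5        (bits: P_fail = 0.5, a failure leaves only {C6})

labels = {c: False for c in ["C6"] + sorted(frag.descendants("C6"))}
Df, log = px.run_probing(frag, D, px.MappingOracle(labels), seed=0)
print(Df)
# DiagnosisSet({C6}: 1)
```

The defected thumb sensation implicates the radial nerve or the C6 root
(never the dermatome itself), each at probability 0.5. Probing the median
nerve is worth half a bit: if it fails, only `{C6}` explains both symptoms.
With ground truth "C6 faulty" the session ends with the correct singleton.

The same flow is available from the shell:

```sh
physdx genmodel --seed 3 --out model.json          # 75-component synthetic anatomy
physdx simulate --model model.json --seed 5 --out sim/
physdx evaluate --model model.json --scenarios sim/scenarios.jsonl \
                --policy both --seed 2 --out eval/ --plots
```

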