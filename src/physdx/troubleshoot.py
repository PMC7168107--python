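"""Sequential probing driven by expected information gain.

After the initial diagnosis the set of candidates may still be large. The
troubleshooting loop repeatedly proposes one component to test (a *probe*)
from the union of all diagnosis members, asks the oracle (in the clinic: the
physiotherapist performing the test), and updates the diagnosis set:

* a **passed** probe changes nothing — under the weak fault model a pass
  never exonerates;
* a **failed** probe of ``c`` keeps exactly the diagnoses intersecting
  ``{c} ∪ ancestors(c)`` and renormalizes.

Probe value is measured in bits: the expected reduction of the Shannon
entropy of the diagnosis distribution, ``P_fail(c) · (Ent(D) − Ent(D_fail))``
— the pass branch contributes nothing since it leaves ``D`` unchanged. The
loop stops when a single diagnosis remains, no candidates are left, or (for
the information-gain policy) no candidate has positive expected gain. A
uniform-random probe policy is provided as the baseline.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Mapping, Union

import numpy as np

from .diagnosis import DiagnosisSet
from .errors import ConfigError, InconsistentAnswerError, UndefinedMetricError
from .model import AnatomyModel

__all__ = [
    "POLICIES",
    "MappingOracle",
    "ProbeRecord",
    "entropy",
    "candidate_probes",
    "update_on_answer",
    "fail_probability",
    "expected_information_gain",
    "run_probing",
    "save_session_log",
]

#: Supported probe-selection policies.
POLICIES = ("info_gain", "random")


class MappingOracle:
    """Answer oracle backed by a full test-label map.

    Components absent from the map answer ``True`` (test passes). Answers
    are cached, so repeated queries are consistent by construction and the
    set of actually-queried components can be inspected afterwards.
    """

    def __init__(self, labels: Mapping[str, bool]):
        self._labels = dict(labels)
        self.queried: dict[str, bool] = {}

    def __call__(self, component_id: str) -> bool:
        if component_id not in self.queried:
            self.queried[component_id] = bool(self._labels.get(component_id, True))
        return self.queried[component_id]


@dataclass(frozen=True)
class ProbeRecord:
    """One step of a probing session."""

    probe: str
    expected_gain: float
    answer: bool
    set_size_after: int

    def to_json_obj(self) -> dict:
        return {
            "probe": self.probe,
            "expected_gain": self.expected_gain,
            "answer": self.answer,
            "set_size_after": self.set_size_after,
        }


def entropy(D: DiagnosisSet) -> float:
    """Shannon entropy of the diagnosis distribution, in bits."""
    if len(D) == 0:
        raise UndefinedMetricError("entropy of an empty diagnosis set")
    return -sum(
        d.probability * math.log2(d.probability) for d in D if d.probability > 0.0
    )


def candidate_probes(
    model: AnatomyModel, D: DiagnosisSet, already_tested: set[str] = frozenset()
) -> set[str]:
    """Union of all diagnosis members minus components already tested."""
    return D.component_union() - set(already_tested)


def update_on_answer(
    model: AnatomyModel, D: DiagnosisSet, component_id: str, test_ok: bool
) -> DiagnosisSet:
    """Filter the diagnosis set on a probe answer.

    A pass returns ``D`` unchanged. A fail keeps the diagnoses intersecting
    the probe's ancestor closure, preserving relative probabilities
    (renormalized). Raises :class:`InconsistentAnswerError` if nothing
    survives.
    """
    if test_ok:
        return D
    closure = model.closure(component_id)
    survivors = [d for d in D if d.delta & closure]
    if not survivors:
        raise InconsistentAnswerError(component_id, [])
    return DiagnosisSet(survivors, D.prior_fault_prob)


def fail_probability(model: AnatomyModel, D: DiagnosisSet, component_id: str) -> float:
    """Probability mass of diagnoses that would survive a failed test of
    ``component_id`` — i.e. the predicted probability that the test fails."""
    closure = model.closure(component_id)
    return sum(d.probability for d in D if d.delta & closure)


def expected_information_gain(
    model: AnatomyModel,
    D: DiagnosisSet,
    component_id: str,
    optimistic: bool = False,
) -> float:
    """Expected entropy reduction from probing ``component_id``, in bits.

    ``P_fail · (Ent(D) − Ent(D_fail))``: only the fail branch informs, since
    a pass leaves the distribution untouched. With ``optimistic=True`` the
    fail outcome is assumed (the raw ``Ent(D) − Ent(D_fail)`` difference,
    unweighted). A fail branch that *spreads* belief (drops a dominant small
    diagnosis while keeping several larger ones) would make the difference
    negative; such probes are reported as zero gain — they are never worth
    selecting over a genuinely informative probe and must not keep the
    probing loop alive.
    """
    p_fail = fail_probability(model, D, component_id)
    if p_fail <= 0.0:
        return 0.0
    posterior = update_on_answer(model, D, component_id, test_ok=False)
    gain = entropy(D) - entropy(posterior)
    if not optimistic:
        gain *= p_fail
    return max(0.0, gain)


def run_probing(
    model: AnatomyModel,
    D0: DiagnosisSet,
    oracle: Callable[[str], bool],
    policy: str = "info_gain",
    seed: int = 0,
    optimistic: bool = False,
) -> tuple[DiagnosisSet, list[ProbeRecord]]:
    """Run a full probing session; returns the final set and the step log.

    Each iteration computes the candidate probes, stops if at most one
    diagnosis remains, no candidates remain, or (``info_gain`` policy) every
    candidate has zero expected gain; otherwise it selects the max-gain
    candidate (ties broken uniformly at random from ``seed``) or, under the
    ``random`` policy, a uniform-random candidate, queries the oracle,
    filters the set and logs the step. Deterministic given oracle and seed.

    An answer that eliminates every diagnosis raises
    :class:`InconsistentAnswerError` carrying the partial log.
    """
    if policy not in POLICIES:
        raise ConfigError(f"unknown policy {policy!r}; expected one of {POLICIES}")
    rng = np.random.default_rng(seed)
    D = D0
    tested: set[str] = set()
    records: list[ProbeRecord] = []
    while True:
        if len(D) <= 1:
            break
        candidates = sorted(candidate_probes(model, D, tested))
        if not candidates:
            break
        gains = {
            c: expected_information_gain(model, D, c, optimistic=optimistic)
            for c in candidates
        }
        if policy == "info_gain":
            gmax = max(gains.values())
            if gmax <= 0.0:
                break
            best = [c for c in candidates if gains[c] >= gmax * (1.0 - 1e-9)]
            probe = best[int(rng.integers(len(best)))]
        else:
            probe = candidates[int(rng.integers(len(candidates)))]
        answer = bool(oracle(probe))
        try:
            D = update_on_answer(model, D, probe, answer)
        except InconsistentAnswerError:
            raise InconsistentAnswerError(probe, records) from None
        tested.add(probe)
        records.append(ProbeRecord(probe, gains[probe], answer, len(D)))
    return D, records


def save_session_log(records: list[ProbeRecord], path: Union[str, Path]) -> None:
    """Write a session log as JSON-lines, one probe record per line."""
    with open(path, "w", encoding="utf-8") as fh:
        for r in records:
            fh.write(json.dumps(r.to_json_obj()) + "\n")
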