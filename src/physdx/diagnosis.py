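"""Consistency-based diagnosis under a weak fault model.

Only healthy behaviour is modeled: a healthy component with proper inputs
produces proper outputs, and proper outputs make the component's test pass.
Consequently a *passed* test never exonerates anything, while a *failed* test
of component ``c`` implicates ``c`` or one of its (transitive) ancestors.
Each failed observation therefore yields one conflict — the ancestor closure
of the tested component with dermatomes removed (dermatomes are assumed
healthy) — and the subset-minimal diagnoses are exactly the minimal hitting
sets of those conflicts.

Diagnosis probabilities assume components fail independently with a common
prior ``p``, so ``P(Δ) ∝ p^|Δ|``, normalized over the returned minimal set;
with ``p < 0.5`` smaller diagnoses are likelier. The per-component *health
state* ``H(c) = Σ_{Δ ∋ c} P(Δ)`` is the posterior probability that ``c`` is
faulty under that distribution.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import FrozenSet, Iterable, Mapping, Optional, Sequence, Union

from .errors import (
    ConfigError,
    ModelFormatError,
    ModelInconsistencyError,
    UnknownComponentError,
)
from .model import AnatomyModel

__all__ = [
    "Conflict",
    "Diagnosis",
    "DiagnosisSet",
    "validate_observations",
    "load_observations",
    "save_observations",
    "compute_conflicts",
    "minimal_hitting_sets",
    "diagnose",
    "is_diagnosis",
    "health_state",
]


@dataclass(frozen=True)
class Conflict:
    """A set of components that cannot all be healthy.

    ``members`` is the faultable part of ``{origin} ∪ ancestors(origin)``
    for a failed test of ``origin``.
    """

    members: FrozenSet[str]
    origin: str


@dataclass(frozen=True)
class Diagnosis:
    """A candidate fault set with its normalized probability."""

    delta: FrozenSet[str]
    probability: float


def _delta_key(delta: FrozenSet[str]):
    return (len(delta), tuple(sorted(delta)))


class DiagnosisSet:
    """An ordered collection of subset-minimal diagnoses with probabilities.

    Diagnoses are kept sorted by decreasing probability, ties broken by
    (cardinality, lexicographic id order), so iteration order, top-K ranking
    and serialisation are deterministic. Probabilities always sum to 1.
    """

    def __init__(self, diagnoses: Iterable[Diagnosis], prior_fault_prob: float):
        self.prior_fault_prob = float(prior_fault_prob)
        ds = list(diagnoses)
        total = sum(d.probability for d in ds)
        if not ds or total <= 0:
            raise ConfigError("a DiagnosisSet needs at least one diagnosis with mass")
        ds = [Diagnosis(d.delta, d.probability / total) for d in ds]
        ds.sort(key=lambda d: (-d.probability,) + _delta_key(d.delta))
        self.diagnoses: list[Diagnosis] = ds

    @classmethod
    def from_deltas(
        cls, deltas: Iterable[Iterable[str]], prior_fault_prob: float = 0.1
    ) -> "DiagnosisSet":
        """Build from bare fault sets, weighting each Δ by ``p^|Δ|``."""
        if not 0.0 < prior_fault_prob < 1.0:
            raise ConfigError(
                f"prior_fault_prob must be in (0, 1), got {prior_fault_prob}"
            )
        ds = [
            Diagnosis(frozenset(d), prior_fault_prob ** len(frozenset(d)))
            for d in deltas
        ]
        return cls(ds, prior_fault_prob)

    def __len__(self) -> int:
        return len(self.diagnoses)

    def __iter__(self):
        return iter(self.diagnoses)

    @property
    def deltas(self) -> list[FrozenSet[str]]:
        return [d.delta for d in self.diagnoses]

    def contains_delta(self, delta: Iterable[str]) -> bool:
        return frozenset(delta) in set(self.deltas)

    def probability_of(self, delta: Iterable[str]) -> float:
        target = frozenset(delta)
        return sum(d.probability for d in self.diagnoses if d.delta == target)

    def component_union(self) -> set[str]:
        out: set[str] = set()
        for d in self.diagnoses:
            out |= d.delta
        return out

    def __eq__(self, other) -> bool:
        if not isinstance(other, DiagnosisSet):
            return NotImplemented
        return [(d.delta, d.probability) for d in self.diagnoses] == [
            (d.delta, d.probability) for d in other.diagnoses
        ]

    def __repr__(self) -> str:
        inner = ", ".join(
            "{%s}: %.4g" % (",".join(sorted(d.delta)), d.probability)
            for d in self.diagnoses[:6]
        )
        more = "" if len(self.diagnoses) <= 6 else f", ... ({len(self)} total)"
        return f"DiagnosisSet({inner}{more})"

    def to_json_obj(self) -> list[dict]:
        return [
            {"components": sorted(d.delta), "probability": d.probability}
            for d in self.diagnoses
        ]


# -- observations -----------------------------------------------------------


def validate_observations(model: AnatomyModel, obs: Mapping[str, bool]) -> None:
    """Raise :class:`UnknownComponentError` if any observed id is not in the model."""
    for c in obs:
        if c not in model:
            raise UnknownComponentError(c)


def load_observations(path: Union[str, Path]) -> dict[str, bool]:
    """Read an observation JSON file: ``[{"component": id, "testOK": bool}, ...]``."""
    try:
        data = json.loads(Path(path).read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise ModelFormatError(f"{path}: not valid JSON: {exc}") from exc
    if not isinstance(data, list):
        raise ModelFormatError(f"{path}: observation JSON must be a list")
    out: dict[str, bool] = {}
    for i, entry in enumerate(data):
        try:
            c, ok = str(entry["component"]), bool(entry["testOK"])
        except (KeyError, TypeError) as exc:
            raise ModelFormatError(f"{path}: bad observation entry #{i}") from exc
        if c in out and out[c] != ok:
            raise ModelFormatError(
                f"{path}: contradictory observations for component {c!r}"
            )
        out[c] = ok
    return out


def save_observations(obs: Mapping[str, bool], path: Union[str, Path]) -> None:
    data = [{"component": c, "testOK": bool(ok)} for c, ok in sorted(obs.items())]
    Path(path).write_text(json.dumps(data, indent=2) + "\n", encoding="utf-8")


# -- conflicts and hitting sets ---------------------------------------------


def compute_conflicts(
    model: AnatomyModel, obs: Mapping[str, bool]
) -> list[Conflict]:
    """One conflict per failed observation: the faultable ancestor closure.

    Passed observations contribute nothing (weak fault model). Duplicate
    member sets and supersets of other conflicts are dropped, so the result
    is an antichain of minimal conflicts in deterministic order.
    """
    validate_observations(model, obs)
    raw: list[Conflict] = []
    for c in sorted(obs):
        if obs[c]:
            continue
        members = frozenset(
            x for x in model.closure(c) if model.components[x].kind.faultable
        )
        if not members:
            raise ModelInconsistencyError(
                f"failed test of {c!r} implicates no faultable component"
            )
        raw.append(Conflict(members, c))
    out: list[Conflict] = []
    seen: set[FrozenSet[str]] = set()
    for k in sorted(raw, key=lambda k: (len(k.members), k.origin)):
        if k.members in seen or any(o.members < k.members for o in raw):
            continue
        seen.add(k.members)
        out.append(k)
    return out


def minimal_hitting_sets(
    conflicts: Sequence[Union[Conflict, Iterable[str]]],
) -> list[FrozenSet[str]]:
    """All subset-minimal sets intersecting every conflict.

    Incremental construction with minimality pruning after each conflict
    (Reiter-style; conflict sets here are small ancestor closures, so no
    compilation machinery is needed). With no conflicts the empty set is the
    unique answer. Output is sorted by (size, lexicographic) for determinism.
    """
    sets = [
        frozenset(k.members if isinstance(k, Conflict) else k) for k in conflicts
    ]
    hs: list[FrozenSet[str]] = [frozenset()]
    for k in sorted(sets, key=lambda s: (len(s), tuple(sorted(s)))):
        grown: set[FrozenSet[str]] = set()
        for h in hs:
            if h & k:
                grown.add(h)
            else:
                grown.update(h | {e} for e in k)
        hs = [h for h in grown if not any(o < h for o in grown)]
    return sorted(hs, key=_delta_key)


def diagnose(
    model: AnatomyModel,
    obs: Mapping[str, bool],
    prior_fault_prob: float = 0.1,
) -> DiagnosisSet:
    """Subset-minimal diagnoses of the observations with normalized probabilities.

    With no failed observation the all-healthy assumption is consistent and
    the unique (empty) diagnosis gets probability 1.
    """
    conflicts = compute_conflicts(model, obs)
    return DiagnosisSet.from_deltas(minimal_hitting_sets(conflicts), prior_fault_prob)


def is_diagnosis(
    model: AnatomyModel, obs: Mapping[str, bool], delta: Iterable[str]
) -> bool:
    """Consistency check: does assuming exactly ``delta`` faulty explain ``obs``?

    Under the weak fault model a passed test imposes nothing, and a failed
    test of ``c`` requires ``delta`` to intersect ``{c} ∪ ancestors(c)``.
    This is the definitional oracle the hitting-set route is tested against.
    """
    dset = frozenset(delta)
    for c in dset:
        if c not in model:
            raise UnknownComponentError(c)
        if not model.components[c].kind.faultable:
            raise ConfigError(f"dermatome {c!r} cannot be part of a diagnosis")
    validate_observations(model, obs)
    for c, ok in obs.items():
        if not ok and not (dset & model.closure(c)):
            return False
    return True


def health_state(
    D: DiagnosisSet, model: Optional[AnatomyModel] = None
) -> dict[str, float]:
    """Per-component fault probability ``H(c) = Σ_{Δ ∋ c} P(Δ)``.

    With ``model`` given, every faultable component appears in the result
    (those in no diagnosis at 0.0); otherwise only diagnosis members do.
    """
    H: dict[str, float] = (
        {c: 0.0 for c in model.faultable_ids} if model is not None else {}
    )
    for d in D:
        for c in d.delta:
            H[c] = H.get(c, 0.0) + d.probability
    return H
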