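"""Fault-injection scenario simulator.

Each scenario injects a random set of faultable components (the "real
diagnosis"), labels every component that could be affected — the faults and
their descendants — as failing with probability ``fail_prob`` (forcing at
least one explaining symptom per fault), and exposes a random subset of the
failing labels as the initial observations, with the subset size capped by
the fault cardinality. The label map doubles as the probing oracle: it is
the answer a real examiner would give for any elective test.

Fault sets in which two faults share an affecting component (overlapping
self-inclusive ancestor closures) are rejected: under minimal-cardinality
reasoning one such fault can explain the other's symptoms, so ground truth
would not be recoverable. Rejection is handled either by redrawing (so a
batch reaches its configured size) or by generate-then-discard; both modes
report the discard count.

``fail_prob=1.0`` is the *relaxed* variant in which every affected component
always fails its test; in practice real faults fail their tests with
probability much closer to 1 than to the 0.5 default, so the relaxed batches
show the attainable improvement.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Union

import numpy as np
import yaml

from .diagnosis import validate_observations
from .errors import ConfigError, GenerationError
from .model import AnatomyModel
from .troubleshoot import MappingOracle

__all__ = [
    "SimulationConfig",
    "GroundTruthScenario",
    "BatchResult",
    "inject_faults",
    "has_shared_affecting_component",
    "label_symptoms",
    "select_observations",
    "generate_scenario",
    "generate_batch",
    "oracle_from_scenario",
    "save_scenarios",
    "load_scenarios",
]

_MAX_RETRIES = 5000


@dataclass(frozen=True)
class SimulationConfig:
    """Batch composition and labeling parameters.

    ``singles_exhaustive`` emits one scenario per faultable component;
    ``cardinality_range`` (inclusive) drives the additional random multi-fault
    scenarios, ``instances_per_cardinality`` of each. The defaults — singles
    plus 150 instances per cardinality 2..6 — yield 825 requested scenarios
    on a model with 75 faultable components.
    """

    cardinality_range: tuple[int, int] = (2, 6)
    fail_prob: float = 0.5
    singles_exhaustive: bool = True
    instances_per_cardinality: int = 150
    seed: int = 0
    discard_mode: str = "retry"  # "retry" (redraw to size) or "filter" (drop)

    def validate_for(self, model: AnatomyModel) -> None:
        lo, hi = self.cardinality_range
        n_faultable = len(model.faultable_ids)
        if not 1 <= lo <= hi:
            raise ConfigError(f"bad cardinality_range {self.cardinality_range}")
        if hi > n_faultable:
            raise ConfigError(
                f"cardinality upper bound {hi} exceeds the {n_faultable} "
                "faultable components"
            )
        if not 0.0 < self.fail_prob <= 1.0:
            raise ConfigError(f"fail_prob must be in (0, 1], got {self.fail_prob}")
        if self.instances_per_cardinality < 0:
            raise ConfigError("instances_per_cardinality must be >= 0")
        if self.discard_mode not in ("retry", "filter"):
            raise ConfigError(f"unknown discard_mode {self.discard_mode!r}")

    @classmethod
    def from_file(cls, path: Union[str, Path]) -> "SimulationConfig":
        """Read a YAML or JSON config file mirroring the dataclass fields."""
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        if not isinstance(data, dict):
            raise ConfigError(f"{path}: config must be a mapping")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"{path}: unknown config keys {sorted(unknown)}")
        if "cardinality_range" in data:
            data["cardinality_range"] = tuple(data["cardinality_range"])
        return cls(**data)


@dataclass(frozen=True)
class GroundTruthScenario:
    """One injected-fault scenario with full simulated labels."""

    faults: frozenset[str]
    labels: dict[str, bool]
    initial_obs: dict[str, bool]
    seed: int

    @property
    def cardinality(self) -> int:
        return len(self.faults)

    def to_json_obj(self) -> dict:
        return {
            "faults": sorted(self.faults),
            "labels": {c: bool(v) for c, v in sorted(self.labels.items())},
            "initial_obs": {c: bool(v) for c, v in sorted(self.initial_obs.items())},
            "seed": self.seed,
        }

    @classmethod
    def from_json_obj(cls, data: dict) -> "GroundTruthScenario":
        return cls(
            faults=frozenset(data["faults"]),
            labels=dict(data["labels"]),
            initial_obs=dict(data["initial_obs"]),
            seed=int(data["seed"]),
        )


@dataclass
class BatchResult:
    """Scenarios plus the generation manifest."""

    scenarios: list[GroundTruthScenario]
    config: SimulationConfig
    n_requested: int
    n_discarded: int

    def manifest(self) -> dict:
        cfg = dict(self.config.__dict__)
        cfg["cardinality_range"] = list(self.config.cardinality_range)
        return {
            "config": cfg,
            "n_requested": self.n_requested,
            "n_discarded": self.n_discarded,
            "n_returned": len(self.scenarios),
        }


def inject_faults(
    model: AnatomyModel, k: int, rng: np.random.Generator
) -> frozenset[str]:
    """Draw ``k`` distinct faultable components uniformly without replacement."""
    pool = model.faultable_ids
    if not 1 <= k <= len(pool):
        raise ConfigError(f"fault cardinality {k} out of range [1, {len(pool)}]")
    idx = rng.choice(len(pool), size=k, replace=False)
    return frozenset(pool[i] for i in idx)


def has_shared_affecting_component(
    model: AnatomyModel, faults: Iterable[str]
) -> bool:
    """True iff two faults have overlapping self-inclusive ancestor closures.

    Covers both a common ancestor and one fault affecting another — exactly
    the cases where minimal-cardinality reasoning can merge the faults.
    """
    closures = [model.closure(f) for f in sorted(set(faults))]
    for i in range(len(closures)):
        for j in range(i + 1, len(closures)):
            if closures[i] & closures[j]:
                return True
    return False


def label_symptoms(
    model: AnatomyModel,
    faults: Iterable[str],
    fail_prob: float,
    rng: np.random.Generator,
) -> dict[str, bool]:
    """Simulated testOK label for every component.

    Components in ``faults ∪ descendants(faults)`` fail with probability
    ``fail_prob``; everything else passes. Every fault is then guaranteed at
    least one explaining symptom: if ``{f} ∪ descendants(f)`` has no failing
    label, one uniformly-drawn member is forced to fail.
    """
    faults = sorted(set(faults))
    if not faults:
        raise ConfigError("label_symptoms requires a non-empty fault set")
    affected: set[str] = set()
    for f in faults:
        affected |= model.down_closure(f)
    labels = {c: True for c in sorted(model.components)}
    for c in sorted(affected):
        if rng.random() < fail_prob:
            labels[c] = False
    for f in faults:
        down = sorted(model.down_closure(f))
        if all(labels[c] for c in down):
            labels[down[int(rng.integers(len(down)))]] = False
    return labels


def select_observations(
    labels: dict[str, bool], k: int, rng: np.random.Generator
) -> dict[str, bool]:
    """Initial observation set: 1..min(k, #failing) failing labels, drawn
    uniformly; all reported as testOK=False."""
    failing = sorted(c for c, ok in labels.items() if not ok)
    if not failing:
        raise ConfigError("no failing labels to observe")
    s = int(rng.integers(1, min(k, len(failing)) + 1))
    idx = rng.choice(len(failing), size=s, replace=False)
    return {failing[i]: False for i in sorted(idx)}


def generate_scenario(
    model: AnatomyModel,
    k: int,
    fail_prob: float = 0.5,
    seed: int = 0,
    max_retries: int = _MAX_RETRIES,
    faults: Optional[Iterable[str]] = None,
) -> GroundTruthScenario:
    """One complete scenario: inject (redrawing while faults share an
    affecting component), label, observe.

    ``faults`` pins the injected set (used for the exhaustive single-fault
    scenarios); it is still rejected if its closures overlap.
    """
    rng = np.random.default_rng(seed)
    if faults is not None:
        fault_set = frozenset(faults)
        if has_shared_affecting_component(model, fault_set):
            raise GenerationError(f"pinned fault set {sorted(fault_set)} is entangled")
    else:
        for _ in range(max_retries):
            fault_set = inject_faults(model, k, rng)
            if not has_shared_affecting_component(model, fault_set):
                break
        else:
            raise GenerationError(
                f"no ancestor-disjoint fault set of size {k} found in "
                f"{max_retries} draws; the model is too entangled"
            )
    labels = label_symptoms(model, fault_set, fail_prob, rng)
    obs = select_observations(labels, len(fault_set), rng)
    validate_observations(model, obs)
    return GroundTruthScenario(fault_set, labels, obs, seed)


def generate_batch(model: AnatomyModel, config: SimulationConfig) -> BatchResult:
    """Exhaustive singles plus ``instances_per_cardinality`` random scenarios
    per cardinality in ``config.cardinality_range``.

    ``discard_mode="retry"`` redraws entangled fault sets so the batch reaches
    its requested size; ``"filter"`` drops them (the requested count is then
    an upper bound). Either way the discard count is reported.
    """
    config.validate_for(model)
    master = np.random.default_rng(config.seed)
    scenarios: list[GroundTruthScenario] = []
    n_requested = 0
    n_discarded = 0

    def child_seed() -> int:
        return int(master.integers(2**31))

    if config.singles_exhaustive:
        for comp in model.faultable_ids:
            n_requested += 1
            scenarios.append(
                generate_scenario(
                    model, 1, config.fail_prob, seed=child_seed(), faults=[comp]
                )
            )

    lo, hi = config.cardinality_range
    for k in range(lo, hi + 1):
        for _ in range(config.instances_per_cardinality):
            n_requested += 1
            seed = child_seed()
            if config.discard_mode == "retry":
                rng_probe = np.random.default_rng(seed)
                # count redraws for the manifest, then generate for real
                draws = 0
                while has_shared_affecting_component(
                    model, inject_faults(model, k, rng_probe)
                ):
                    draws += 1
                    if draws >= _MAX_RETRIES:
                        break
                n_discarded += draws
                scenarios.append(
                    generate_scenario(model, k, config.fail_prob, seed=seed)
                )
            else:
                rng = np.random.default_rng(seed)
                faults = inject_faults(model, k, rng)
                if has_shared_affecting_component(model, faults):
                    n_discarded += 1
                    continue
                labels = label_symptoms(model, faults, config.fail_prob, rng)
                obs = select_observations(labels, k, rng)
                scenarios.append(GroundTruthScenario(faults, labels, obs, seed))
    return BatchResult(scenarios, config, n_requested, n_discarded)


def oracle_from_scenario(scenario: GroundTruthScenario) -> MappingOracle:
    """Probing oracle answering from the scenario's full label map."""
    return MappingOracle(scenario.labels)


def save_scenarios(
    scenarios: Iterable[GroundTruthScenario], path: Union[str, Path]
) -> None:
    """JSON-lines, one scenario per line."""
    with open(path, "w", encoding="utf-8") as fh:
        for s in scenarios:
            fh.write(json.dumps(s.to_json_obj()) + "\n")


def load_scenarios(path: Union[str, Path]) -> list[GroundTruthScenario]:
    out = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line:
                out.append(GroundTruthScenario.from_json_obj(json.loads(line)))
    return out
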