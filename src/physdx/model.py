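"""Typed anatomical influence models.

The neuromuscular system is represented as a directed acyclic graph over four
component kinds: nerve roots (spinal origin segments, sources of the graph),
nerves, muscles and dermatomes (skin sensory areas). An edge ``a -> b`` states
that an output of ``a`` is an input of ``b``, i.e. damage to ``a`` can affect
the behaviour observed when ``b`` is tested. Dermatomes are assumed healthy:
they are pure test surfaces for their ancestors and can never themselves be
part of a diagnosis. Muscles and dermatomes are sinks; nerve roots are sources.

This module provides the container, validation, JSON (de)serialisation, a DOT
export for visual inspection, transitive reachability queries used by every
other module, a small hand-encoded fragment of the upper-limb anatomy used
throughout the documentation and tests, and a seeded generator of layered
synthetic models.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Union

import networkx as nx
import numpy as np

from .errors import (
    ConfigError,
    ModelFormatError,
    ModelValidationError,
    UnknownComponentError,
)

__all__ = [
    "ComponentKind",
    "Component",
    "InfluenceEdge",
    "AnatomyModel",
    "MODEL_JSON_SCHEMA",
    "validate",
    "load_model",
    "save_model",
    "to_dot",
    "paper_fragment_model",
    "generate_synthetic_model",
]


class ComponentKind(str, Enum):
    """The four anatomical component kinds."""

    NERVE_ROOT = "nerve_root"
    NERVE = "nerve"
    MUSCLE = "muscle"
    DERMATOME = "dermatome"

    @property
    def faultable(self) -> bool:
        """Dermatomes are assumed healthy; every other kind can be faulty."""
        return self is not ComponentKind.DERMATOME


#: Kinds that may appear in conflicts, diagnoses and injected fault sets.
FAULTABLE_KINDS = frozenset(k for k in ComponentKind if k.faultable)

#: Kinds that must be sinks (no outgoing influence edges).
SINK_KINDS = frozenset({ComponentKind.MUSCLE, ComponentKind.DERMATOME})


@dataclass(frozen=True)
class Component:
    id: str
    name: str
    kind: ComponentKind


@dataclass(frozen=True)
class InfluenceEdge:
    """Directed influence: an output of ``source`` is an input of ``target``."""

    source: str
    target: str


#: Shape of the model JSON dialect (informative; validation is structural,
#: performed by :func:`load_model` / :func:`validate`).
MODEL_JSON_SCHEMA = {
    "type": "object",
    "required": ["components", "edges"],
    "properties": {
        "components": {
            "type": "array",
            "items": {
                "type": "object",
                "required": ["id", "name", "kind"],
                "properties": {
                    "id": {"type": "string", "minLength": 1},
                    "name": {"type": "string"},
                    "kind": {"enum": [k.value for k in ComponentKind]},
                },
            },
        },
        "edges": {
            "type": "array",
            "items": {
                "type": "object",
                "required": ["source", "target"],
                "properties": {
                    "source": {"type": "string"},
                    "target": {"type": "string"},
                },
            },
        },
    },
}


class AnatomyModel:
    """A typed influence DAG over anatomical components.

    Parameters
    ----------
    components
        Iterable of :class:`Component`. Ids must be unique (checked by
        :meth:`violations`, raised by :func:`load_model`).
    edges
        Iterable of :class:`InfluenceEdge` (or ``(source, target)`` pairs).

    The constructor never raises on an *invalid* model so that
    :func:`validate` can describe what is wrong; loaders raise
    :class:`~physdx.errors.ModelValidationError` when violations exist.
    """

    def __init__(
        self,
        components: Iterable[Component],
        edges: Iterable[Union[InfluenceEdge, tuple]],
    ):
        self._component_list = list(components)
        self.components: dict[str, Component] = {c.id: c for c in self._component_list}
        norm = []
        for e in edges:
            if not isinstance(e, InfluenceEdge):
                e = InfluenceEdge(*e)
            norm.append(e)
        # preserve insertion order, drop exact duplicates
        self.edges: list[InfluenceEdge] = list(dict.fromkeys(norm))
        self._graph = nx.DiGraph()
        self._graph.add_nodes_from(self.components)
        self._graph.add_edges_from((e.source, e.target) for e in self.edges)

    # -- basic queries ------------------------------------------------------

    def __contains__(self, component_id: str) -> bool:
        return component_id in self.components

    def __len__(self) -> int:
        return len(self.components)

    def kind(self, component_id: str) -> ComponentKind:
        self._check(component_id)
        return self.components[component_id].kind

    @property
    def graph(self) -> nx.DiGraph:
        return self._graph

    @property
    def faultable_ids(self) -> list[str]:
        """Sorted ids of all non-dermatome components."""
        return sorted(c.id for c in self.components.values() if c.kind.faultable)

    @property
    def dermatome_ids(self) -> list[str]:
        return sorted(
            c.id for c in self.components.values() if c.kind is ComponentKind.DERMATOME
        )

    def _check(self, component_id: str) -> None:
        if component_id not in self.components:
            raise UnknownComponentError(component_id)

    # -- reachability -------------------------------------------------------

    def ancestors(self, component_id: str) -> set[str]:
        """All components with a directed path to ``component_id`` (exclusive)."""
        self._check(component_id)
        return set(nx.ancestors(self._graph, component_id)) & set(self.components)

    def descendants(self, component_id: str) -> set[str]:
        """All components reachable from ``component_id`` (exclusive)."""
        self._check(component_id)
        return set(nx.descendants(self._graph, component_id)) & set(self.components)

    def closure(self, component_id: str) -> set[str]:
        """``{c} ∪ ancestors(c)``: everything a failed test of ``c`` implicates."""
        return self.ancestors(component_id) | {component_id}

    def down_closure(self, component_id: str) -> set[str]:
        """``{c} ∪ descendants(c)``: everything a fault in ``c`` can affect."""
        return self.descendants(component_id) | {component_id}

    # -- validation ---------------------------------------------------------

    def violations(self) -> list[str]:
        """Describe every violated structural invariant (empty list iff valid)."""
        out: list[str] = []
        seen: set[str] = set()
        for c in self._component_list:
            if not c.id:
                out.append("component with empty id")
            elif c.id in seen:
                out.append(f"duplicate component id {c.id!r}")
            seen.add(c.id)
        known = set(self.components)
        ok_edges = []
        for e in self.edges:
            if e.source not in known:
                out.append(f"edge references unknown source {e.source!r}")
            elif e.target not in known:
                out.append(f"edge {e.source!r}->{e.target!r} references unknown target")
            elif e.source == e.target:
                out.append(f"self-loop on {e.source!r}")
            else:
                ok_edges.append(e)
        g = nx.DiGraph()
        g.add_nodes_from(known)
        g.add_edges_from((e.source, e.target) for e in ok_edges)
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            path = " -> ".join([cycle[0][0]] + [b for _, b in cycle])
            out.append(f"influence graph contains a cycle: {path}")
        for e in ok_edges:
            skind = self.components[e.source].kind
            tkind = self.components[e.target].kind
            if skind in SINK_KINDS:
                out.append(
                    f"{skind.value} {e.source!r} has an outgoing edge "
                    f"(muscles and dermatomes are sinks)"
                )
            if tkind is ComponentKind.NERVE_ROOT:
                out.append(
                    f"nerve_root {e.target!r} has an incoming edge "
                    f"(nerve roots are sources)"
                )
        return out

    def raise_if_invalid(self) -> "AnatomyModel":
        v = self.violations()
        if v:
            raise ModelValidationError(v)
        return self

    # -- (de)serialisation --------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "components": [
                {"id": c.id, "name": c.name, "kind": c.kind.value}
                for c in self._component_list
            ],
            "edges": [{"source": e.source, "target": e.target} for e in self.edges],
        }

    @classmethod
    def from_dict(cls, data: dict) -> "AnatomyModel":
        if not isinstance(data, dict) or "components" not in data or "edges" not in data:
            raise ModelFormatError(
                "model JSON must be an object with 'components' and 'edges'"
            )
        comps = []
        for i, c in enumerate(data["components"]):
            try:
                comps.append(
                    Component(
                        id=str(c["id"]),
                        name=str(c.get("name", c["id"])),
                        kind=ComponentKind(c["kind"]),
                    )
                )
            except (KeyError, TypeError, ValueError) as exc:
                raise ModelFormatError(f"bad component entry #{i}: {exc}") from exc
        edges = []
        for i, e in enumerate(data["edges"]):
            try:
                edges.append(InfluenceEdge(str(e["source"]), str(e["target"])))
            except (KeyError, TypeError) as exc:
                raise ModelFormatError(f"bad edge entry #{i}: {exc}") from exc
        return cls(comps, edges)

    def __eq__(self, other) -> bool:
        if not isinstance(other, AnatomyModel):
            return NotImplemented
        return (
            self.components == other.components
            and set(self.edges) == set(other.edges)
        )


def validate(model: AnatomyModel) -> list[str]:
    """Return one description per violated invariant; ``[]`` iff valid."""
    return model.violations()


def load_model(path: Union[str, Path]) -> AnatomyModel:
    """Load and validate a model JSON file.

    Raises :class:`ModelFormatError` on malformed files and
    :class:`ModelValidationError` (listing every violation) on invalid models.
    """
    try:
        data = json.loads(Path(path).read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise ModelFormatError(f"{path}: not valid JSON: {exc}") from exc
    return AnatomyModel.from_dict(data).raise_if_invalid()


def save_model(model: AnatomyModel, path: Union[str, Path]) -> None:
    Path(path).write_text(
        json.dumps(model.to_dict(), indent=2) + "\n", encoding="utf-8"
    )


_DOT_COLORS = {
    ComponentKind.NERVE_ROOT: "lightsalmon",
    ComponentKind.NERVE: "lightskyblue",
    ComponentKind.MUSCLE: "palegreen",
    ComponentKind.DERMATOME: "khaki",
}


def to_dot(model: AnatomyModel) -> str:
    """Graphviz DOT rendering of the influence graph, one node per component,
    colored by kind."""
    lines = ["digraph anatomy {", "  rankdir=TB;"]
    for c in sorted(model.components.values(), key=lambda c: c.id):
        lines.append(
            f'  "{c.id}" [label="{c.name}" style=filled '
            f'fillcolor="{_DOT_COLORS[c.kind]}"];'
        )
    for e in sorted(model.edges, key=lambda e: (e.source, e.target)):
        lines.append(f'  "{e.source}" -> "{e.target}";')
    lines.append("}")
    return "\n".join(lines) + "\n"


def paper_fragment_model() -> AnatomyModel:
    """A small hand-encoded fragment of the upper-limb anatomy.

    The C6 nerve root innervates the radial and median nerves; the radial
    nerve serves the deltoid and extensor carpi ulnaris muscles and the DC6
    dermatome (thumb sensation); the median nerve serves the brachialis.
    A failed shoulder-extension test (deltoid) therefore implicates the
    deltoid itself, the radial nerve or C6; a defected thumb sensation (DC6)
    implicates only the radial nerve or C6, never the dermatome itself.
    """
    comps = [
        Component("C6", "Nerve root C-6", ComponentKind.NERVE_ROOT),
        Component("Radial", "Radial nerve", ComponentKind.NERVE),
        Component("Median", "Median nerve", ComponentKind.NERVE),
        Component("Deltoid", "Deltoid muscle", ComponentKind.MUSCLE),
        Component(
            "ExtensorCarpiUlnaris", "Extensor carpi ulnaris muscle", ComponentKind.MUSCLE
        ),
        Component("Brachialis", "Brachialis muscle", ComponentKind.MUSCLE),
        Component("DC6", "Dermatome DC-6", ComponentKind.DERMATOME),
    ]
    edges = [
        ("C6", "Radial"),
        ("C6", "Median"),
        ("Radial", "Deltoid"),
        ("Radial", "ExtensorCarpiUlnaris"),
        ("Median", "Brachialis"),
        ("Radial", "DC6"),
    ]
    return AnatomyModel(comps, edges).raise_if_invalid()


def generate_synthetic_model(
    n_roots: int = 7,
    n_nerves: int = 18,
    n_muscles: int = 30,
    n_dermatomes: int = 20,
    edges_per_node: float = 1.2,
    seed: int = 0,
    root_to_muscle: bool = False,
    root_to_dermatome: bool = False,
) -> AnatomyModel:
    """Generate a layered synthetic anatomy: roots -> nerves -> muscles/dermatomes.

    Every non-root component receives at least one parent; the number of
    parents is ``1 + Poisson(edges_per_node - 1)`` capped by the parent pool,
    so ``edges_per_node`` is the mean in-degree of non-root components.
    Deterministic for a fixed seed. The default counts total 75 components
    (7 roots for the C3..T1 segments, 18 nerves, 30 muscles, 20 dermatomes);
    the default in-degree of 1.2 mirrors real innervation, where most muscles
    and dermatomes are served by a single nerve and most nerves arise from
    one or two roots.

    ``root_to_muscle`` / ``root_to_dermatome`` admit roots into the parent
    pools of the sink layers (off by default).
    """
    for name, n in [
        ("n_roots", n_roots),
        ("n_nerves", n_nerves),
        ("n_muscles", n_muscles),
        ("n_dermatomes", n_dermatomes),
    ]:
        if n < 1:
            raise ConfigError(f"{name} must be >= 1, got {n}")
    if edges_per_node < 1.0:
        raise ConfigError("edges_per_node must be >= 1")
    rng = np.random.default_rng(seed)

    roots = [
        Component(f"R{i + 1}", f"Nerve root {i + 1}", ComponentKind.NERVE_ROOT)
        for i in range(n_roots)
    ]
    nerves = [
        Component(f"N{i + 1}", f"Nerve {i + 1}", ComponentKind.NERVE)
        for i in range(n_nerves)
    ]
    muscles = [
        Component(f"M{i + 1}", f"Muscle {i + 1}", ComponentKind.MUSCLE)
        for i in range(n_muscles)
    ]
    dermatomes = [
        Component(f"D{i + 1}", f"Dermatome {i + 1}", ComponentKind.DERMATOME)
        for i in range(n_dermatomes)
    ]

    def pick_parents(pool: list[str]) -> list[str]:
        k = 1 + int(rng.poisson(edges_per_node - 1.0))
        k = min(k, len(pool))
        return [pool[i] for i in sorted(rng.choice(len(pool), size=k, replace=False))]

    edges: list[tuple] = []
    root_ids = [c.id for c in roots]
    nerve_ids = [c.id for c in nerves]
    for n in nerves:
        edges.extend((p, n.id) for p in pick_parents(root_ids))
    muscle_pool = nerve_ids + (root_ids if root_to_muscle else [])
    for m in muscles:
        edges.extend((p, m.id) for p in pick_parents(muscle_pool))
    derm_pool = nerve_ids + (root_ids if root_to_dermatome else [])
    for d in dermatomes:
        edges.extend((p, d.id) for p in pick_parents(derm_pool))

    return AnatomyModel(roots + nerves + muscles + dermatomes, edges).raise_if_invalid()
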