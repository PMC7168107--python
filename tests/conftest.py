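"""Shared fixtures and brute-force oracles.

The toy models are the smallest graphs exercising each structural case:
a 3-chain with a dermatome leaf and a diamond with a shared root.
"""

from __future__ import annotations

from itertools import combinations

import pytest

import physdx as px
from physdx import AnatomyModel, Component, ComponentKind


@pytest.fixture
def toy_chain() -> AnatomyModel:
    """R1 -> N1 -> M1 with dermatome D1 under R1."""
    return AnatomyModel(
        [
            Component("R1", "root 1", ComponentKind.NERVE_ROOT),
            Component("N1", "nerve 1", ComponentKind.NERVE),
            Component("M1", "muscle 1", ComponentKind.MUSCLE),
            Component("D1", "dermatome 1", ComponentKind.DERMATOME),
        ],
        [("R1", "N1"), ("N1", "M1"), ("R1", "D1")],
    ).raise_if_invalid()


@pytest.fixture
def toy_diamond() -> AnatomyModel:
    """R1 -> {N1, N2} -> M1: two nerves sharing root and muscle."""
    return AnatomyModel(
        [
            Component("R1", "root 1", ComponentKind.NERVE_ROOT),
            Component("N1", "nerve 1", ComponentKind.NERVE),
            Component("N2", "nerve 2", ComponentKind.NERVE),
            Component("M1", "muscle 1", ComponentKind.MUSCLE),
        ],
        [("R1", "N1"), ("R1", "N2"), ("N1", "M1"), ("N2", "M1")],
    ).raise_if_invalid()


@pytest.fixture
def fragment() -> AnatomyModel:
    return px.paper_fragment_model()


@pytest.fixture(scope="session")
def synth75() -> AnatomyModel:
    """The default 75-component synthetic anatomy used by batch tests."""
    return px.generate_synthetic_model(seed=42)


def small_random_model(seed: int) -> AnatomyModel:
    """A model with 10 faultable components (2 roots, 3 nerves, 5 muscles)."""
    return px.generate_synthetic_model(
        n_roots=2, n_nerves=3, n_muscles=5, n_dermatomes=3,
        edges_per_node=1.5, seed=seed,
    )


def brute_force_minimal_diagnoses(model, obs) -> set[frozenset]:
    """Definitional oracle: scan all subsets of faultable components, keep
    those consistent with the observations, filter to subset-minimal."""
    comps = model.faultable_ids
    consistent = [
        frozenset(sub)
        for r in range(len(comps) + 1)
        for sub in combinations(comps, r)
        if px.is_diagnosis(model, obs, sub)
    ]
    return {
        d for d in consistent if not any(o < d for o in consistent)
    }


def brute_force_minimal_hitting_sets(conflicts) -> set[frozenset]:
    """Enumerate every subset of the conflict universe."""
    universe = sorted(set().union(*map(set, conflicts)) if conflicts else set())
    hitting = [
        frozenset(sub)
        for r in range(len(universe) + 1)
        for sub in combinations(universe, r)
        if all(set(sub) & set(k) for k in conflicts)
    ]
    return {h for h in hitting if not any(o < h for o in hitting)}
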