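"""Shared strategies and fixtures for the test suite."""

from __future__ import annotations

import random

import pytest
from hypothesis import HealthCheck, settings, strategies as st

from rnadel.structures import Mutation, MutationKind, SecondaryStructure

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@st.composite
def rna_sequences(draw, min_size: int = 1, max_size: int = 30) -> str:
    return draw(
        st.text(alphabet="ACGU", min_size=min_size, max_size=max_size)
    )


@st.composite
def nested_structures(draw, n: int | None = None, max_n: int = 40) -> SecondaryStructure:
    """Random non-crossing structure built by greedy compatible insertion."""
    if n is None:
        n = draw(st.integers(min_value=1, max_value=max_n))
    raw = draw(
        st.lists(
            st.tuples(st.integers(1, n), st.integers(1, n)),
            max_size=n,
        )
    )
    chosen: list[tuple[int, int]] = []
    used: set[int] = set()
    for a, b in raw:
        if a == b:
            continue
        i, j = min(a, b), max(a, b)
        if i in used or j in used:
            continue
        if any(x < i <= y < j or i < x <= j < y for x, y in chosen):
            continue  # would cross
        chosen.append((i, j))
        used.update((i, j))
    return SecondaryStructure.from_pairs(n, chosen)


@st.composite
def mutations_for(draw, wt: str) -> Mutation:
    kind = draw(st.sampled_from(list(MutationKind)))
    if kind is MutationKind.INS:
        pos = draw(st.integers(1, len(wt) + 1))
        return Mutation(kind, pos, new_base=draw(st.sampled_from("ACGU")))
    pos = draw(st.integers(1, len(wt)))
    wt_base = wt[pos - 1]
    if kind is MutationKind.DEL:
        return Mutation(kind, pos, wt_base=wt_base)
    new = draw(st.sampled_from(sorted(set("ACGU") - {wt_base})))
    return Mutation(kind, pos, wt_base=wt_base, new_base=new)


@st.composite
def edit_scripts(draw, wt: str, max_size: int = 5):
    from rnadel.structures import EditScript

    n_mut = draw(st.integers(0, min(max_size, len(wt))))
    muts: list[Mutation] = []
    used: set[int] = set()
    for _ in range(n_mut):
        m = draw(mutations_for(wt))
        if m.position in used:
            continue
        used.add(m.position)
        muts.append(m)
    return EditScript(muts)


@pytest.fixture
def rng() -> random.Random:
    return random.Random(1729)
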