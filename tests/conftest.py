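"""Shared fixtures: random sequence helpers and cached synthetic panels."""

from __future__ import annotations

import numpy as np
import pytest

from gmoscreen import generate_panel, make_panel_spec

BASES = "ACGT"


def random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, size=length))


def substitute_interior(seq: str, positions: tuple[int, ...]) -> str:
    """Plant substitutions at interior positions, choosing bases that also
    differ from both neighbours so a one-base frame shift cannot silently
    absorb the mismatch."""
    s = list(seq)
    for p in positions:
        assert 0 < p < len(seq) - 1, "positions must be interior"
        avoid = {s[p], s[p - 1], s[p + 1]}
        s[p] = next(b for b in BASES if b not in avoid)
    return "".join(s)


@pytest.fixture(scope="session")
def small_panel():
    """8 events x 4 methods with one self-pair cell; fast, reused widely."""
    spec = make_panel_spec(8, 4, seed=11, n_self_pairs=1)
    return generate_panel(spec)


@pytest.fixture(scope="session")
def panel48():
    """48 events x 6 methods, 3 self-pair cells, one two-sequence event —
    the shape of a realistic verification panel."""
    spec = make_panel_spec(
        48, 6, seed=1, n_self_pairs=3, two_sequence_events=frozenset({2})
    )
    return generate_panel(spec)
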