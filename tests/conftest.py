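"""Shared fixtures: the worked example pair, the backward-extension pair,
and seeded random-pair factories."""
from __future__ import annotations

import numpy as np
import pytest

from acsk import DNA, SequenceRecord, mutated_pair, random_sequence


@pytest.fixture
def worked_pair() -> tuple[SequenceRecord, SequenceRecord]:
    """The 12/13-residue DNA pair used throughout the module docs: the
    exact anchor of suffix 4 of X sits at position 2 of Y (1-based)."""
    return (SequenceRecord("X", "CATTGCATACGA"),
            SequenceRecord("Y", "ATGGATCCAATAG"))


@pytest.fixture
def backward_pair() -> tuple[SequenceRecord, SequenceRecord]:
    """Pair where only a backward extension finds the best 1-mismatch match:
    the greedy forward anchor of X_1 is AAT at Y_1, but the true lambda_1(1)=7
    match starts at Y_8."""
    return (SequenceRecord("X", "AATCGGT"),
            SequenceRecord("Y", "AATGGGAAACCGGT"))


@pytest.fixture
def random_pairs():
    """Factory for seeded independent random DNA pairs."""

    def make(count: int, length: int, seed: int = 7):
        rng = np.random.default_rng(seed)
        out = []
        for _ in range(count):
            out.append((random_sequence(length, DNA, rng, name="x"),
                        random_sequence(length, DNA, rng, name="y")))
        return out

    return make


@pytest.fixture
def mutated_pairs():
    """Factory for seeded (original, point-mutated) DNA pairs."""

    def make(count: int, length: int, rates, seed: int = 100):
        rates = list(np.broadcast_to(rates, count)) if np.isscalar(rates) \
            else list(rates)
        return [mutated_pair(length, float(r), seed=seed + s)
                for s, r in enumerate(rates)]

    return make
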