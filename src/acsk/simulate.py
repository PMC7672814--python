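"""Seeded synthetic data: random sequences, point-mutation pairs, and
clock-tree sequence evolution.

The substitution model is deliberately simple and Jukes–Cantor-like: each
site mutates independently with a fixed probability, and a mutated site is
replaced by a uniformly chosen *different* core symbol.  This reproduces the
divergence regime in which matching-statistics distances are informative;
it makes no attempt at indels, rate heterogeneity, or codon structure.
Every generator is a pure function of its seed.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ParameterError
from .phylo import Tree, read_newick
from .seqio import DNA, Alphabet, SequenceRecord


@dataclass(frozen=True)
class MutationModel:
    """Per-site substitution model: probability, alphabet, seed."""

    substitution_probability: float
    alphabet: Alphabet = DNA
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.substitution_probability <= 1.0:
            raise ParameterError("substitution probability must be in [0, 1]")


def _rng(seed: int | np.random.Generator) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def random_sequence(length: int, alphabet: Alphabet = DNA,
                    seed: int | np.random.Generator = 0,
                    name: str = "random") -> SequenceRecord:
    """An i.i.d. uniform sequence over the alphabet's core symbols."""
    if length < 1:
        raise ParameterError("sequence length must be >= 1")
    rng = _rng(seed)
    core = np.frombuffer(alphabet.core.encode("latin-1"), dtype=np.uint8)
    draws = rng.integers(0, len(core), size=length)
    return SequenceRecord(name, core[draws].tobytes().decode("latin-1"))


def mutate(record: SequenceRecord, model: MutationModel,
           rng: np.random.Generator | None = None,
           name: str | None = None) -> SequenceRecord:
    """Apply the per-site substitution model; length is preserved and every
    substituted site differs from the original."""
    rng = _rng(model.seed) if rng is None else rng
    core = np.frombuffer(model.alphabet.core.encode("latin-1"), dtype=np.uint8)
    arr = np.frombuffer(record.residues.encode("latin-1"), dtype=np.uint8).copy()
    hit = rng.random(len(arr)) < model.substitution_probability
    if hit.any():
        # choose among the |core|-1 symbols different from the current one
        lut = np.zeros(256, dtype=np.int64)
        lut[core] = np.arange(len(core))
        shift = rng.integers(1, len(core), size=int(hit.sum()))
        arr[hit] = core[(lut[arr[hit]] + shift) % len(core)]
    out_name = name if name is not None else record.name + "_mut"
    return SequenceRecord(out_name, arr.tobytes().decode("latin-1"))


def mutated_pair(length: int, rate: float, seed: int,
                 alphabet: Alphabet = DNA) -> tuple[SequenceRecord, SequenceRecord]:
    """A random sequence and a point-mutated copy at the given per-site rate."""
    rng = _rng(seed)
    x = random_sequence(length, alphabet, rng, name="x")
    model = MutationModel(rate, alphabet)
    y = mutate(x, model, rng=rng, name="y")
    return x, y


def simulate_tree_and_sequences(num_taxa: int, seq_length: int, rate: float,
                                seed: int, alphabet: Alphabet = DNA
                                ) -> tuple[Tree, list[SequenceRecord]]:
    """A random bifurcating clock-style tree plus sequences evolved along it.

    The topology comes from successive random pair-joins of the active
    lineages (an arbitrary-but-seeded shape distribution); every branch
    carries the same per-branch substitution probability, which also serves
    as its length.  The root sequence is uniform random and each branch
    applies the substitution model once.  Returns the true tree and the leaf
    sequences, both keyed by taxon names ``t1..tN``.
    """
    if num_taxa < 4:
        raise ParameterError("need at least 4 taxa")
    if seq_length < 1:
        raise ParameterError("sequence length must be >= 1")
    model = MutationModel(rate, alphabet)
    rng = _rng(seed)
    # topology: random joins over nested tuples of taxon indices
    nodes: list[object] = list(range(num_taxa))
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(int(j))
        a = nodes.pop(int(i))
        nodes.append((a, b))
    root_seq = random_sequence(seq_length, alphabet, rng, name="root")
    names = [f"t{i + 1}" for i in range(num_taxa)]
    leaves: dict[int, SequenceRecord] = {}

    def evolve(node: object, seq: SequenceRecord) -> str:
        if isinstance(node, int):
            leaves[node] = SequenceRecord(names[node], seq.residues)
            return f"{names[node]}:{rate:.6f}"
        left, right = node
        lseq = mutate(seq, model, rng=rng)
        rseq = mutate(seq, model, rng=rng)
        return f"({evolve(left, lseq)},{evolve(right, rseq)}):{rate:.6f}"

    root = nodes[0]
    if isinstance(root, int):  # unreachable for num_taxa >= 4
        raise ParameterError("degenerate topology")
    left, right = root
    newick = (f"({evolve(left, mutate(root_seq, model, rng=rng))},"
              f"{evolve(right, mutate(root_seq, model, rng=rng))});")
    tree = read_newick(newick)
    records = [leaves[i] for i in range(num_taxa)]
    return tree, records
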