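"""Shared fixtures: compact genome builders and random genome generators."""

from __future__ import annotations

import random

import pytest

from dcjindel.genomes import Chromosome, Genome


def g(name: str, *specs: str) -> Genome:
    """Build a genome from compact strings: "1 -2 3" linear, "( 1 2" circular."""
    chroms = []
    for s in specs:
        circ = s.startswith("(")
        toks = s.lstrip("( ").split()
        seq = tuple(((t[1:], -1) if t.startswith("-") else (t, 1)) for t in toks)
        chroms.append(Chromosome(seq, circ))
    return Genome(name, tuple(chroms))


def _chromosomize(rng: random.Random, toks: list[str], p_circular: float) -> list[Chromosome]:
    rng.shuffle(toks)
    chroms = []
    while toks:
        k = rng.randint(1, len(toks))
        seq = tuple((t, rng.choice((1, -1))) for t in toks[:k])
        toks = toks[k:]
        chroms.append(Chromosome(seq, rng.random() < p_circular))
    return chroms


def random_canonical_pair(rng: random.Random, max_markers: int = 5):
    """Two genomes over the same singular marker set (canonical instances)."""
    n = rng.randint(1, max_markers)

    def one(name):
        return Genome(name, tuple(_chromosomize(rng, [str(i + 1) for i in range(n)], 0.4)))

    return one("A"), one("B")


def random_singular_pair(rng: random.Random, max_common: int = 10, max_excl: int = 4):
    """Singular genomes with exclusive markers, mixed topologies."""
    n = rng.randint(0, max_common)

    def one(name, side):
        toks = [str(i + 1) for i in range(n)]
        toks += [f"{side}{j}" for j in range(rng.randint(0, max_excl))]
        if not toks:
            toks = [f"{side}0"]
        return Genome(name, tuple(_chromosomize(rng, toks, 0.35)))

    return one("A", "x"), one("B", "y")


def random_natural_pair(rng: random.Random, max_occ: int = 8, max_copy: int = 3):
    """Tiny natural genomes: duplicated common markers plus exclusives."""

    def one(name, side):
        toks = []
        for m in range(1, 5):
            toks += [str(m)] * rng.randint(0, max_copy)
        toks += [f"{side}{j}" for j in range(rng.randint(0, 2))]
        rng.shuffle(toks)
        toks = toks[:max_occ]
        if not toks:
            toks = [f"{side}0"]
        return Genome(name, tuple(_chromosomize(rng, toks, 0.3)))

    return one("A", "x"), one("B", "y")


@pytest.fixture
def rng() -> random.Random:
    return random.Random(20260923)
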