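"""Genome evolution simulator and registered worked-example fixtures.

Marker-order genomes are evolved along a rooted weighted tree.  On each edge
the number of DCJ events is Poisson with mean equal to the edge weight;
duplications, deletions and insertions are Poisson with mean ``weight x
rate``.  Events are applied in the order DCJs, duplications, deletions,
insertions; segment lengths are Zipf-distributed (shape 4 for indels, 6 for
duplications by default) and event locations are uniform over the genome.

Everything is driven by a single :class:`numpy.random.Generator` seeded from
the config, so a run is bit-reproducible, and every event is logged with the
parameters needed to replay it.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Optional

import dendropy
import numpy as np

from .genomes import Chromosome, Genome
from .oracle import adjacencies_to_genome, genome_adjacencies

__all__ = ["SimConfig", "SimEvent", "SimResult", "simulate", "replay_edge", "make_fixture"]


@dataclass(frozen=True)
class SimConfig:
    """Simulation settings; the defaults reproduce the benchmark conditions
    (root length 20000, insertion/deletion rates 0.1/0.2, duplication rate
    0.4, Zipf shapes 4 and 6)."""

    root_length: int = 20000
    tree: str = "(L1:10,L2:10):0;"  # newick; edge weights = expected DCJ counts
    insertion_rate: float = 0.1
    deletion_rate: float = 0.2
    duplication_rate: float = 0.4
    zipf_s_indel: float = 4.0
    zipf_s_dup: float = 6.0
    seed: int = 0


@dataclass
class SimEvent:
    edge: tuple[str, str]  # (parent node, child node)
    op: str  # dcj / duplication / deletion / insertion
    detail: dict


@dataclass
class SimResult:
    config: SimConfig
    genomes: dict  # node name -> Genome
    leaves: list[str]
    events: list[SimEvent]

    def counts(self, edge: Optional[tuple[str, str]] = None) -> dict:
        out = {"dcj": 0, "duplication": 0, "deletion": 0, "insertion": 0}
        for ev in self.events:
            if edge is None or ev.edge == edge:
                out[ev.op] += 1
        return out

    def event_log_tsv(self) -> str:
        lines = ["parent\tchild\top\tdetail"]
        for ev in self.events:
            det = ";".join(f"{k}={v}" for k, v in sorted(ev.detail.items()))
            lines.append(f"{ev.edge[0]}\t{ev.edge[1]}\t{ev.op}\t{det}")
        return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# elementary mutations (each deterministic given its recorded detail)


def _apply_dcj(g: Genome, rng: np.random.Generator) -> tuple[Genome, dict]:
    adjs, exts = genome_adjacencies(g)
    adjs = set(adjs)
    telomeres = sorted(exts - {x for a in adjs for x in a})
    elements: list = [tuple(sorted(a)) for a in adjs]
    elements.sort()
    elements += [(t,) for t in telomeres]
    if len(elements) < 2:
        return g, {"skipped": "fewer than two breakpoints"}
    i, j = rng.choice(len(elements), size=2, replace=False)
    p, q = elements[int(i)], elements[int(j)]
    for el in (p, q):
        if len(el) == 2:
            adjs.discard(frozenset(el))
    variant = int(rng.integers(2))
    if len(p) == 2 and len(q) == 2:
        (a, b), (c, d) = p, q
        new = [(a, c), (b, d)] if variant == 0 else [(a, d), (b, c)]
    elif len(p) == 2 or len(q) == 2:
        (a, b) = p if len(p) == 2 else q
        (c,) = q if len(q) == 1 else p
        new = [(a, c)] if variant == 0 else [(b, c)]
    else:
        new = [(p[0], q[0])]
    for pair in new:
        adjs.add(frozenset(pair))
    return (
        adjacencies_to_genome(g.name, frozenset(adjs), exts),
        {"cut1": p, "cut2": q, "join": new},
    )


def _pick_position(g: Genome, rng: np.random.Generator) -> tuple[int, int]:
    """Uniform occurrence position over the whole genome: (chrom idx, offset)."""
    lengths = [len(c) for c in g.chromosomes]
    pos = int(rng.integers(sum(lengths)))
    for ci, L in enumerate(lengths):
        if pos < L:
            return ci, pos
        pos -= L
    raise AssertionError


def _zipf(rng: np.random.Generator, s: float) -> int:
    return int(rng.zipf(s))


def _take_segment(chrom: Chromosome, start: int, length: int):
    seq = list(chrom.markers)
    if chrom.circular:
        seg = [seq[(start + k) % len(seq)] for k in range(length)]
        rest = [seq[(start + length + k) % len(seq)] for k in range(len(seq) - length)]
    else:
        seg = seq[start:start + length]
        rest = seq[:start] + seq[start + length:]
    return seg, rest


def _replace_chrom(g: Genome, ci: int, new_markers, circular) -> Genome:
    chroms = list(g.chromosomes)
    if new_markers:
        chroms[ci] = Chromosome(tuple(new_markers), circular)
    else:
        del chroms[ci]
    return Genome(g.name, tuple(chroms))


def _apply_duplication(
    g: Genome, rng: np.random.Generator, s: float
) -> tuple[Genome, dict]:
    ci, start = _pick_position(g, rng)
    chrom = g.chromosomes[ci]
    length = min(_zipf(rng, s), len(chrom))
    seg, _ = _take_segment(chrom, start, length)
    tci, tpos = _pick_position(g, rng)
    target = g.chromosomes[tci]
    seq = list(target.markers)
    if tci == ci and not chrom.circular and tpos > start:
        tpos = min(tpos, len(seq))
    seq[tpos:tpos] = seg
    out = _replace_chrom(g, tci, seq, target.circular)
    return out, {"chrom": ci, "start": start, "len": length, "to_chrom": tci, "to_pos": tpos}


def _apply_deletion(g: Genome, rng: np.random.Generator, s: float) -> tuple[Genome, dict]:
    ci, start = _pick_position(g, rng)
    chrom = g.chromosomes[ci]
    # never delete a whole chromosome: keep at least one occurrence
    length = min(_zipf(rng, s), len(chrom) - 1)
    if length == 0:
        return g, {"chrom": ci, "start": start, "len": 0}
    _, rest = _take_segment(chrom, start, length)
    out = _replace_chrom(g, ci, rest, chrom.circular)
    return out, {"chrom": ci, "start": start, "len": length}


def _apply_insertion(
    g: Genome, rng: np.random.Generator, s: float, fresh: "itertools.count"
) -> tuple[Genome, dict]:
    length = _zipf(rng, s)
    seg = [(f"n{next(fresh)}", 1) for _ in range(length)]
    ci, pos = _pick_position(g, rng)
    chrom = g.chromosomes[ci]
    seq = list(chrom.markers)
    seq[pos:pos] = seg
    out = _replace_chrom(g, ci, seq, chrom.circular)
    return out, {"chrom": ci, "pos": pos, "len": length, "markers": [m for m, _ in seg]}


_APPLIERS = {
    "dcj": lambda g, rng, cfg, fresh: _apply_dcj(g, rng),
    "duplication": lambda g, rng, cfg, fresh: _apply_duplication(g, rng, cfg.zipf_s_dup),
    "deletion": lambda g, rng, cfg, fresh: _apply_deletion(g, rng, cfg.zipf_s_indel),
    "insertion": lambda g, rng, cfg, fresh: _apply_insertion(
        g, rng, cfg.zipf_s_indel, fresh
    ),
}


def simulate(config: SimConfig) -> SimResult:
    """Evolve genomes over the configured tree; fully reproducible from the seed."""
    if config.root_length < 1:
        raise ValueError("root_length must be >= 1")
    rng = np.random.default_rng(config.seed)
    tree = dendropy.Tree.get(data=config.tree, schema="newick")
    fresh = itertools.count(1)

    root = Genome(
        "root",
        (Chromosome(tuple((str(i + 1), 1) for i in range(config.root_length))),),
    )
    genomes = {"root": root}
    events: list[SimEvent] = []
    leaves: list[str] = []
    anon = itertools.count(1)

    def node_name(node) -> str:
        if node.taxon is not None and node.taxon.label:
            return node.taxon.label
        if node.label:
            return node.label
        node.label = f"node{next(anon)}"
        return node.label

    tree.seed_node.label = "root"
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            if node.is_leaf():
                leaves.append("root")
            continue
        parent = node_name(node.parent_node) if node.parent_node is not tree.seed_node else "root"
        child = node_name(node)
        weight = float(node.edge.length or 0.0)
        g = replace_name(genomes[parent], child)
        plan = [
            ("dcj", rng.poisson(weight)),
            ("duplication", rng.poisson(weight * config.duplication_rate)),
            ("deletion", rng.poisson(weight * config.deletion_rate)),
            ("insertion", rng.poisson(weight * config.insertion_rate)),
        ]
        for op, count in plan:
            for _ in range(int(count)):
                g, detail = _APPLIERS[op](g, rng, config, fresh)
                events.append(SimEvent((parent, child), op, detail))
        genomes[child] = g
        if node.is_leaf():
            leaves.append(child)
    return SimResult(config, genomes, leaves, events)


def replace_name(g: Genome, name: str) -> Genome:
    return Genome(name, g.chromosomes)


def replay_edge(parent: Genome, result: SimResult, edge: tuple[str, str]) -> Genome:
    """Re-apply the logged events of one edge; must reproduce the child."""
    g = replace_name(parent, edge[1])
    for ev in result.events:
        if ev.edge != edge:
            continue
        g = _replay_one(g, ev)
    return g


def _replay_one(g: Genome, ev: SimEvent) -> Genome:
    d = ev.detail
    if ev.op == "dcj":
        if "skipped" in d:
            return g
        adjs, exts = genome_adjacencies(g)
        adjs = set(adjs)
        for el in (d["cut1"], d["cut2"]):
            if len(el) == 2:
                adjs.discard(frozenset(el))
        for pair in d["join"]:
            adjs.add(frozenset(pair))
        return adjacencies_to_genome(g.name, frozenset(adjs), exts)
    if ev.op == "duplication":
        chrom = g.chromosomes[d["chrom"]]
        seg, _ = _take_segment(chrom, d["start"], d["len"])
        target = g.chromosomes[d["to_chrom"]]
        seq = list(target.markers)
        seq[d["to_pos"]:d["to_pos"]] = seg
        return _replace_chrom(g, d["to_chrom"], seq, target.circular)
    if ev.op == "deletion":
        if d["len"] == 0:
            return g
        chrom = g.chromosomes[d["chrom"]]
        _, rest = _take_segment(chrom, d["start"], d["len"])
        return _replace_chrom(g, d["chrom"], rest, chrom.circular)
    if ev.op == "insertion":
        chrom = g.chromosomes[d["chrom"]]
        seq = list(chrom.markers)
        seq[d["pos"]:d["pos"]] = [(m, 1) for m in d["markers"]]
        return _replace_chrom(g, d["chrom"], seq, chrom.circular)
    raise ValueError(f"unknown op {ev.op!r}")


# ---------------------------------------------------------------------------
# worked-example fixtures


def _g(name: str, chroms: list[tuple[str, bool]]) -> Genome:
    out = []
    for text, circular in chroms:
        seq = []
        for tok in text.split():
            sign = 1
            if tok.startswith("-"):
                sign, tok = -1, tok[1:]
            seq.append((tok, sign))
        out.append(Chromosome(tuple(seq), circular))
    return Genome(name, tuple(out))


_FIXTURES = {
    # running example: one linear chromosome each, heavy duplication
    "sec2_running": (
        [("1 3 2 -5 -4 3 5 4", False)],
        [("1 6 2 3 1 7 3 4 1 3", False)],
    ),
    # two linear chromosomes each, exclusive markers 6,7,8
    "fig1": (
        [("1 -6 5 3", False), ("4 2", False)],
        [("1 7 2 3 4 5", False), ("7 -8", False)],
    ),
    # same pair as sec2_running, used for matchings/capping illustrations
    "fig5": (
        [("1 3 2 -5 -4 3 5 4", False)],
        [("1 6 2 3 1 7 3 4 1 3", False)],
    ),
    # canonical genomes whose diagram is 2 AA-paths + 2 BB-paths
    "fig6": (
        [("2 1", False), ("4 3", False)],
        [("1 2", False), ("3 4", False)],
    ),
    # the unsigned reading realizes the four chained-recombination source
    # paths (2x AA^AB + BB^A + BB^B) that this example optimally caps
    "fig7": (
        [("5 2 1", False), ("5 4 5 3", False)],
        [("6 1 6 2", False), ("3 6 4", False)],
    ),
}


def make_fixture(name: str) -> tuple[Genome, Genome]:
    """Return a registered worked-example genome pair."""
    try:
        a, b = _FIXTURES[name]
    except KeyError:
        raise KeyError(
            f"unknown fixture {name!r}; available: {sorted(_FIXTURES)}"
        ) from None
    return _g("A", a), _g("B", b)
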