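"""Independent brute-force references used to validate the fast paths.

* ``bfs_dcj_distance`` -- breadth-first search over genome states under all
  DCJ operations; the ground truth for tiny canonical instances.
* ``min_over_matchings`` -- exhaustive enumeration of maximal sibling sets;
  each one is realized as a pair of matched singular genomes and scored with
  the closed form, mirroring the definition of the natural-genome distance as
  a minimum over matchings.
* ``exact_delta`` -- optimal recombination deduction by memoized search over
  the primitive path-recombination operations, the reference for the greedy.

Everything here trades speed for transparency and is guarded against
combinatorial blow-up.
"""

from __future__ import annotations

import itertools
from collections import Counter, deque
from typing import Iterator, Optional

from .diagram import build_multi_relational, sibling_sets
from .genomes import Chromosome, Genome
from .singular import PathTypeCount, distance_singular

__all__ = [
    "genome_adjacencies",
    "adjacencies_to_genome",
    "dcj_neighbor_states",
    "bfs_dcj_distance",
    "matched_singular_genomes",
    "min_over_matchings",
    "exact_delta",
]

# An extremity is (marker, occurrence, end); an adjacency is a frozenset of
# two extremities; a genome state is a frozenset of adjacencies plus the
# implicit set of telomeres (extremities in no adjacency).


def _flip(ext):
    m, o, e = ext
    return (m, o, "h" if e == "t" else "t")


def genome_adjacencies(g: Genome):
    """(adjacency set, all extremities) of a genome."""
    adjs = set()
    exts = set()
    seen: Counter = Counter()
    for chrom in g.chromosomes:
        row = []
        for m, s in chrom.markers:
            seen[m] += 1
            occ = seen[m]
            t, h = (m, occ, "t"), (m, occ, "h")
            exts.update((t, h))
            row.append((t, h) if s > 0 else (h, t))  # (left, right)
        for (_, r1), (l2, _) in zip(row, row[1:]):
            adjs.add(frozenset((r1, l2)))
        if chrom.circular:
            adjs.add(frozenset((row[-1][1], row[0][0])))
    return frozenset(adjs), frozenset(exts)


def adjacencies_to_genome(name: str, adjs, exts) -> Genome:
    """Rebuild a genome (chromosome lists) from an adjacency set."""
    partner: dict = {}
    for adj in adjs:
        a, b = tuple(adj)  # two distinct extremities, even within one occurrence
        partner[a] = b
        partner[b] = a
    occurrences = sorted({(m, o) for (m, o, _) in exts})
    visited: set = set()
    chroms: list[Chromosome] = []

    def read(start):
        seq = []
        ext = start
        while True:
            m, o, e = ext
            visited.add((m, o))
            seq.append((m, 1 if e == "t" else -1))
            nxt = partner.get(_flip(ext))
            if nxt is None:
                return seq, False
            if nxt == start:
                return seq, True
            ext = nxt

    telomeres = [x for x in sorted(exts) if x not in partner]
    for tel in telomeres:
        if (tel[0], tel[1]) in visited:
            continue
        seq, _ = read(tel)
        chroms.append(Chromosome(tuple(seq), circular=False))
    for m, o in occurrences:
        if (m, o) not in visited:
            seq, closed = read((m, o, "t"))
            assert closed
            chroms.append(Chromosome(tuple(seq), circular=True))
    return Genome(name, tuple(chroms))


def dcj_neighbor_states(adjs, exts) -> Iterator[frozenset]:
    """All genome states one DCJ away.

    Cases: two adjacencies rejoined either of the two new ways; an adjacency
    and a telomere; two telomeres joined; a single adjacency cut open.
    """
    adjs = set(adjs)
    telomeres = sorted(exts - {x for adj in adjs for x in adj})
    adj_list = sorted(adjs, key=sorted)
    for i, p in enumerate(adj_list):
        a, b = sorted(p)
        for q in adj_list[i + 1:]:
            c, d = sorted(q)
            base = adjs - {p, q}
            yield frozenset(base | {frozenset((a, c)), frozenset((b, d))})
            yield frozenset(base | {frozenset((a, d)), frozenset((b, c))})
        for t in telomeres:
            base = adjs - {p}
            yield frozenset(base | {frozenset((a, t))})
            yield frozenset(base | {frozenset((b, t))})
        yield frozenset(adjs - {p})  # cut, both ends become telomeres
    for t1, t2 in itertools.combinations(telomeres, 2):
        yield frozenset(adjs | {frozenset((t1, t2))})


def bfs_dcj_distance(A: Genome, B: Genome, bound: int = 12) -> int:
    """True minimum DCJ count between canonical genomes, by breadth-first search.

    Requires identical singular marker content; refuses to search beyond
    ``bound`` operations.
    """
    adjA, extA = genome_adjacencies(A)
    adjB, extB = genome_adjacencies(B)
    if extA != extB:
        raise ValueError("genomes must share the same singular marker content")
    if adjA == adjB:
        return 0
    frontier = deque([(adjA, 0)])
    seen = {adjA}
    while frontier:
        state, depth = frontier.popleft()
        if depth >= bound:
            continue
        for nxt in dcj_neighbor_states(state, extA):
            if nxt == adjB:
                return depth + 1
            if nxt not in seen:
                seen.add(nxt)
                frontier.append((nxt, depth + 1))
    raise ValueError(f"no DCJ sorting within {bound} operations")


# ---------------------------------------------------------------------------
# exhaustive matching oracle


def matched_singular_genomes(A: Genome, B: Genome, matching) -> tuple[Genome, Genome]:
    """Realize a sibling set as a pair of matched singular genomes.

    Matched occurrence pairs of a common marker receive a shared composite
    identifier ``m:k`` (k = rank within the matching); unmatched excess
    occurrences become fresh exclusive markers ``m:xA<j>`` / ``m:xB<j>``.
    """
    rankA: dict = {}
    rankB: dict = {}
    for m, pairs in matching.items():
        for k, (occA, occB) in enumerate(pairs, start=1):
            rankA[(m, occA)] = f"{m}:{k}"
            rankB[(m, occB)] = f"{m}:{k}"

    def relabel(g: Genome, rank: dict, side: str) -> Genome:
        seen: Counter = Counter()
        chroms = []
        for chrom in g.chromosomes:
            seq = []
            for m, s in chrom.markers:
                seen[m] += 1
                occ = seen[m]
                if (m, occ) in rank:
                    seq.append((rank[(m, occ)], s))
                elif m in matching:  # excess occurrence of a common marker
                    seq.append((f"{m}:x{side}{occ}", s))
                else:
                    seq.append((m, s))
            chroms.append(Chromosome(tuple(seq), chrom.circular))
        return Genome(g.name, tuple(chroms))

    return relabel(A, rankA, "A"), relabel(B, rankB, "B")


def min_over_matchings(
    A: Genome, B: Genome, bound: int = 100_000, return_breakdown: bool = False
):
    """Natural-genome distance by exhausting all maximal sibling sets."""
    diagram = build_multi_relational(A, B, capped=False)
    best = None
    best_matching = None
    for matching in sibling_sets(diagram, bound=bound):
        As, Bs = matched_singular_genomes(A, B, matching)
        d = distance_singular(As, Bs).distance
        if best is None or d < best:
            best, best_matching = d, matching
    if return_breakdown:
        return best, best_matching
    return best


# ---------------------------------------------------------------------------
# recombination cost enumeration


def dcj_neighbor_genomes(g: Genome) -> Iterator[Genome]:
    """All genomes one DCJ away from ``g`` (duplicates allowed)."""
    adjs, exts = genome_adjacencies(g)
    seen = set()
    for state in dcj_neighbor_states(adjs, exts):
        if state not in seen:
            seen.add(state)
            yield adjacencies_to_genome(g.name, state, exts)


def enumerate_dcj_costs(A: Genome, B: Genome):
    """Yield (mutated pair, DCJ-indel cost Delta-d, components after).

    Applies every possible DCJ to genome A and, symmetrically, to genome B,
    scoring each operation rho by Delta-d = ||rho|| + Delta-lambda, where the
    DCJ cost ||rho|| = 1 - Delta(c + i/2) (optimal operations increase the
    number of AB-cycles by one or AB-paths by two) and Delta-lambda is the
    change in total indel potential.
    """
    from .diagram import build_relational, decompose
    from .singular import indel_potential

    def stats(X, Y):
        d = build_relational(X, Y)
        comps = decompose(d, [e.idx for e in d.edges])
        c = sum(1 for k in comps if k.cls == "AB_cycle")
        i = sum(1 for k in comps if k.cls == "AB_path")
        lam = sum(indel_potential(k.Lambda) for k in comps)
        return c, i, lam, comps

    c0, i0, lam0, _ = stats(A, B)
    for side in ("A", "B"):
        base = A if side == "A" else B
        for mut in dcj_neighbor_genomes(base):
            pair = (mut, B) if side == "A" else (A, mut)
            c1, i1, lam1, comps = stats(*pair)
            rho = 1 - ((c1 - c0) + (i1 - i0) // 2)
            yield pair, rho + (lam1 - lam0), comps


# ---------------------------------------------------------------------------
# exact recombination deduction

# primitive recombinations: (consumed, produced, DCJ-indel cost Delta-d);
# resultants that can never recombine again ("plain" AB-paths) are dropped.
_OPS: list[tuple[tuple[str, ...], tuple[str, ...], int]] = [
    (("W", "M"), (), -2),
    (("W", "Mbar"), ("N",), -1),
    (("W", "Mund"), ("Z",), -1),
    (("Wbar", "M"), ("Z",), -1),
    (("Wund", "M"), ("N",), -1),
    (("Wbar", "Mbar"), (), -1),
    (("Wund", "Mund"), (), -1),
    (("W", "W"), ("Wbar", "Wund"), -1),
    (("M", "M"), ("Mbar", "Mund"), -1),
    (("W", "Z"), ("Wbar",), -1),
    (("W", "N"), ("Wund",), -1),
    (("M", "Z"), ("Mund",), -1),
    (("M", "N"), ("Mbar",), -1),
    (("Z", "N"), (), -1),
    (("Wbar", "N"), ("W",), 0),
    (("Wund", "Z"), ("W",), 0),
    (("Mbar", "Z"), ("M",), 0),
    (("Mund", "N"), ("M",), 0),
    (("Wbar", "Mund"), ("Z",), 0),
    (("Wund", "Mbar"), ("N",), 0),
    (("Z", "Z"), ("Wbar", "Mund"), 0),
    (("N", "N"), ("Wund", "Mbar"), 0),
]

_TYPES = ("W", "Wbar", "Wund", "M", "Mbar", "Mund", "Z", "N")


def exact_delta(paths) -> int:
    """Optimal total deduction -min(sum of Delta-d) over recombination chains.

    ``paths`` may be a :class:`PathTypeCount` or a mapping of type letters to
    counts.  Exponential in principle; memoized over count vectors and meant
    for small oracle instances.
    """
    if isinstance(paths, PathTypeCount):
        counts = paths.as_dict()
    else:
        counts = {t: int(paths.get(t, 0)) for t in _TYPES}
    state0 = tuple(counts.get(t, 0) for t in _TYPES)
    index = {t: i for i, t in enumerate(_TYPES)}
    memo: dict[tuple, int] = {}
    on_stack: set = set()

    def best(state: tuple) -> int:
        if state in memo:
            return memo[state]
        if state in on_stack:
            return 0  # revisiting within a chain cannot improve
        on_stack.add(state)
        val = 0
        for consumed, produced, dd in _OPS:
            nxt = list(state)
            ok = True
            for t in consumed:
                nxt[index[t]] -= 1
                if nxt[index[t]] < 0:
                    ok = False
                    break
            if not ok:
                continue
            for t in produced:
                nxt[index[t]] += 1
            val = min(val, dd + best(tuple(nxt)))
        on_stack.discard(state)
        memo[state] = val
        return val

    return -best(state0)
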