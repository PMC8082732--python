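"""Closed-form DCJ-indel distance for singular genomes.

The distance of singular genomes A, B (no duplicated common marker) is

    d = |G| - c - i/2 + sum_C lambda(C) - delta

where G is the common marker set, c the number of AB-cycles and i the number
of AB-paths of the relational diagram R(A,B), lambda(C) the indel potential
of component C, and delta the total deduction obtainable by recombinations
acting across pairs of indel-enclosing paths.  delta is computed by a greedy
sweep over chained recombination groups:

    delta = 2*P + 3*Q + 2*T + S + 2*M + N

with one group kind per part.  Path types are written with the conventional
letters: W = AA-path whose runs read A...B (mixed), Wbar = AA-path with runs
A...A, Wund = AA-path with runs B...B; M / Mbar / Mund are the BB-path
analogues; Z = AB-path reading A...B and N = AB-path reading B...A (AB-paths
are always read from their A endpoint).  Linear singletons enter the counts
as AA-paths of signature A (Wbar) or BB-paths of signature B (Mund).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

from .diagram import Component, build_relational, decompose
from .genomes import Genome, census

__all__ = [
    "indel_potential",
    "transition_count",
    "PathTypeCount",
    "GreedyDeduction",
    "greedy_delta",
    "SingularDistance",
    "distance_singular",
]


def indel_potential(Lambda: int) -> int:
    """Minimum number of indels chargeable to a component with ``Lambda`` runs.

    0 for an indel-free component, ceil((Lambda+1)/2) otherwise: runs can be
    pairwise merged by optimal DCJs until roughly half of them remain.
    """
    if Lambda < 0:
        raise ValueError("run count must be non-negative")
    if Lambda == 0:
        return 0
    return (Lambda + 2) // 2


def transition_count(Lambda: int) -> int:
    """Number of transitions aleph of a cycle with ``Lambda`` runs.

    A transition is an indel-free stretch flanked by indel edges of opposite
    genomes; a cycle with 0 or 1 runs has none, otherwise runs alternate
    around the cycle and every run boundary is a transition.
    """
    if Lambda < 0:
        raise ValueError("run count must be non-negative")
    return 0 if Lambda <= 1 else Lambda


@dataclass
class PathTypeCount:
    """Counts of the deduction-relevant path types of one relational diagram."""

    W: int = 0  # AA-path, runs A..B
    Wbar: int = 0  # AA-path, runs A..A (incl. linear singletons in A)
    Wund: int = 0  # AA-path, runs B..B
    M: int = 0  # BB-path, runs A..B
    Mbar: int = 0  # BB-path, runs A..A
    Mund: int = 0  # BB-path, runs B..B (incl. linear singletons in B)
    Z: int = 0  # AB-path, runs A..B
    N: int = 0  # AB-path, runs B..A
    # non-deducting components, kept for bookkeeping
    ab_plain: int = 0  # AB-paths with signature eps/A/B
    aa_free: int = 0  # indel-free AA-paths
    bb_free: int = 0  # indel-free BB-paths
    circular_singletons: int = 0

    @classmethod
    def from_components(cls, components: Iterable[Component]) -> "PathTypeCount":
        c = cls()
        for comp in components:
            if comp.is_cycle:
                if comp.cls == "circular_singleton":
                    c.circular_singletons += 1
                continue
            sig = comp.run_signature
            if comp.cls == "AA_path" or (
                comp.cls == "linear_singleton"
                and _singleton_owner(comp) == "A"
            ):
                if sig == "AB":
                    c.W += 1
                elif sig == "A":
                    c.Wbar += 1
                elif sig == "B":
                    c.Wund += 1
                else:
                    c.aa_free += 1
            elif comp.cls in ("BB_path", "linear_singleton"):
                if sig == "AB":
                    c.M += 1
                elif sig == "A":
                    c.Mbar += 1
                elif sig == "B":
                    c.Mund += 1
                else:
                    c.bb_free += 1
            elif comp.cls == "AB_path":
                if sig == "AB":
                    c.Z += 1
                elif sig == "BA":
                    c.N += 1
                else:
                    c.ab_plain += 1
        return c

    def as_dict(self) -> dict[str, int]:
        return {
            "W": self.W, "Wbar": self.Wbar, "Wund": self.Wund,
            "M": self.M, "Mbar": self.Mbar, "Mund": self.Mund,
            "Z": self.Z, "N": self.N,
        }


def _singleton_owner(comp: Component) -> str:
    # a linear singleton has a pure-A or pure-B run signature
    return "A" if comp.run_signature == "A" else "B"


@dataclass
class GreedyDeduction:
    P: int = 0
    Q: int = 0
    T: int = 0
    S: int = 0
    M: int = 0
    N: int = 0
    applications: list = field(default_factory=list)  # (part, group, count)

    @property
    def delta(self) -> int:
        return 2 * self.P + 3 * self.Q + 2 * self.T + self.S + 2 * self.M + self.N


# Chained recombination groups, applied greedily top-down.  Each group is a
# multiset of source path types; applying it `k` times consumes `k` copies of
# each source and contributes the part's deduction per application.
_GROUPS: list[tuple[str, list[tuple[str, ...]]]] = [
    ("P", [("W", "M")]),
    ("Q", [("W", "W", "Mbar", "Mund"), ("M", "M", "Wbar", "Wund")]),
    (
        "T",
        [
            # one-W / one-M groups first: they spend fewer W/M per deduction
            ("W", "Mbar", "Z"),
            ("W", "Mund", "N"),
            ("M", "Wbar", "N"),
            ("M", "Wund", "Z"),
            ("W", "W", "Mbar"),
            ("W", "W", "Mund"),
            ("M", "M", "Wbar"),
            ("M", "M", "Wund"),
        ],
    ),
    (
        "S",
        [
            ("Z", "N"),
            ("Wbar", "Mbar"),
            ("Wund", "Mund"),
            ("W", "Mbar"),
            ("W", "Mund"),
            ("Wbar", "M"),
            ("Wund", "M"),
            ("W", "Z"),
            ("W", "N"),
            ("M", "Z"),
            ("M", "N"),
            # last: these spend two deducting paths for a single deduction
            ("W", "W"),
            ("M", "M"),
        ],
    ),
    ("M", [("Z", "Z", "Wund", "Mbar"), ("N", "N", "Wbar", "Mund")]),
    (
        "N",
        [
            ("Z", "Z", "Mbar"),
            ("Z", "Z", "Wund"),
            ("Z", "Wund", "Mbar"),
            ("N", "N", "Wbar"),
            ("N", "N", "Mund"),
            ("N", "Wbar", "Mund"),
        ],
    ),
]


def greedy_delta(paths: PathTypeCount) -> GreedyDeduction:
    """Greedy top-down application of the chained recombination groups.

    Within every part each group is exhausted in turn with integer
    arithmetic; resultants are never reused across groups, so the number of
    applications depends only on the initial type counts.
    """
    avail = paths.as_dict()
    out = GreedyDeduction()
    for part, groups in _GROUPS:
        for group in groups:
            need: dict[str, int] = {}
            for t in group:
                need[t] = need.get(t, 0) + 1
            k = min(avail[t] // n for t, n in need.items())
            if k <= 0:
                continue
            for t, n in need.items():
                avail[t] -= k * n
            setattr(out, part, getattr(out, part) + k)
            out.applications.append((part, "".join(group), k))
    return out


@dataclass
class SingularDistance:
    distance: int
    n_common: int
    c: int  # AB-cycles
    i: int  # AB-paths
    sum_lambda: int
    delta: int
    components: list[Component]
    path_types: PathTypeCount

    @property
    def lemma_bound(self) -> int:
        """Upper bound |G| - c - i/2 + sum(lambda), before path recombinations."""
        return self.n_common - self.c - self.i // 2 + self.sum_lambda


def distance_singular(A: Genome, B: Genome) -> SingularDistance:
    """Exact DCJ-indel distance of two singular genomes, with its breakdown."""
    diagram = build_relational(A, B)
    components = decompose(diagram, [e.idx for e in diagram.edges])
    c = sum(1 for comp in components if comp.cls == "AB_cycle")
    i = sum(1 for comp in components if comp.cls == "AB_path")
    sum_lambda = sum(indel_potential(comp.Lambda) for comp in components)
    ptc = PathTypeCount.from_components(components)
    delta = greedy_delta(ptc).delta
    n_common = len(diagram.census.common)
    dist = n_common - c - i // 2 + sum_lambda - delta
    return SingularDistance(dist, n_common, c, i, sum_lambda, delta, components, ptc)
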