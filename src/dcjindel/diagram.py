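"""Relational diagrams for genome pairs and their decompositions.

Three closely related graphs are built here:

* the relational diagram ``R(A,B)`` of two singular genomes, whose vertices
  are the marker-extremity occurrences of both genomes and whose edges are
  adjacency, extremity and indel edges -- its components (cycles and paths)
  directly drive the closed-form DCJ-indel distance;
* the multi-relational diagram ``MR(A,B)`` of two natural genomes, where a
  common marker occurring several times contributes *all* candidate extremity
  edges between its occurrences, so that every matching of occurrences
  (sibling set) induces one classical relational diagram;
* the capped diagram ``MR°(A,B)``, obtained by adding ``4 p*`` cap-extremity
  vertices, one cap adjacency per telomere, ``a*`` artificial adjacencies on
  the genome with fewer linear chromosomes, and the complete bipartite set of
  cap extremity edges between A-caps and B-caps.  Every capped consistent
  decomposition is a vertex-disjoint set of cycles.

Components of a decomposition are classified (AB-cycle, AA-/BB-/AB-path,
singletons) and annotated with their number of runs Lambda, run signature and
transition count aleph, the quantities from which indel costs are computed.
"""

from __future__ import annotations

import itertools
import math
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterator, Optional, Sequence

from .genomes import Genome, MarkerCensus, census

__all__ = [
    "Vertex",
    "Edge",
    "Diagram",
    "Component",
    "build_relational",
    "build_multi_relational",
    "decompose",
    "sibling_sets",
    "sibling_edges",
    "capping_sets",
    "consistent_decomposition",
]

ADJACENCY = "adjacency"
ARTIFICIAL = "artificial_adjacency"
EXTREMITY = "extremity"
INDEL = "indel"
CAP = "cap_extremity"

TAIL, HEAD, CAPEND = "t", "h", "c"


@dataclass(frozen=True)
class Vertex:
    vid: int  # 1-based, dense
    owner: str  # 'A' or 'B'
    marker: Optional[str]  # None for cap extremities
    occ: int  # occurrence index (cap serial for caps)
    end: str  # 't', 'h' or 'c'
    chrom: Optional[tuple[str, int]]  # (owner, chromosome index); None for caps

    @property
    def is_cap(self) -> bool:
        return self.marker is None


@dataclass
class Edge:
    idx: int
    kind: str
    u: int
    v: int
    genome: Optional[str] = None  # adjacency / indel edges belong to one genome
    sibling: Optional[int] = None  # paired extremity edge
    # extremity edges record which occurrence pair they match
    match: Optional[tuple[str, int, int]] = None  # (marker, occA, occB)

    def other(self, vid: int) -> int:
        return self.v if vid == self.u else self.u


@dataclass
class Diagram:
    genomeA: Genome
    genomeB: Genome
    census: MarkerCensus
    capped: bool
    vertices: list[Vertex] = field(default_factory=list)
    edges: list[Edge] = field(default_factory=list)
    vertex_edges: list[list[int]] = field(default_factory=list)  # per vid-1
    # (owner, marker, occ, end) -> vid ; caps under marker None keyed by serial
    _vindex: dict = field(default_factory=dict)
    # (marker, occA, occB) -> (tail edge idx, head edge idx)
    ext_index: dict = field(default_factory=dict)
    # circular chromosomes eligible to be singletons: chrom key -> indel edges
    singleton_chromosomes: dict = field(default_factory=dict)

    # -- construction helpers ------------------------------------------------

    def _add_vertex(self, owner, marker, occ, end, chrom) -> int:
        vid = len(self.vertices) + 1
        self.vertices.append(Vertex(vid, owner, marker, occ, end, chrom))
        self.vertex_edges.append([])
        self._vindex[(owner, marker, occ, end)] = vid
        return vid

    def _add_edge(self, kind, u, v, genome=None, match=None) -> int:
        idx = len(self.edges)
        self.edges.append(Edge(idx, kind, u, v, genome=genome, match=match))
        self.vertex_edges[u - 1].append(idx)
        self.vertex_edges[v - 1].append(idx)
        return idx

    # -- queries -------------------------------------------------------------

    def vertex(self, vid: int) -> Vertex:
        return self.vertices[vid - 1]

    def vid(self, owner, marker, occ, end) -> int:
        return self._vindex[(owner, marker, occ, end)]

    def edges_of_kind(self, *kinds: str) -> list[Edge]:
        return [e for e in self.edges if e.kind in kinds]

    def adjacency_edge_indices(self) -> list[int]:
        return [e.idx for e in self.edges if e.kind in (ADJACENCY, ARTIFICIAL)]

    def incident_kinds(self, vid: int) -> set[str]:
        return {self.edges[i].kind for i in self.vertex_edges[vid - 1]}

    @property
    def n_caps_per_side(self) -> int:
        return 2 * self.census.p_star if self.capped else 0

    def cap_vids(self, owner: str) -> list[int]:
        return [v.vid for v in self.vertices if v.is_cap and v.owner == owner]


def _extremity_order(sign: int) -> tuple[str, str]:
    """(left, right) extremity ends of an occurrence read along the chromosome."""
    return (TAIL, HEAD) if sign > 0 else (HEAD, TAIL)


def build_multi_relational(A: Genome, B: Genome, capped: bool = False) -> Diagram:
    """Build MR(A,B), optionally capped into MR°(A,B).

    Vertex ids are assigned deterministically: genome A chromosomes left to
    right (tail before head per occurrence), then genome B, then caps.
    """
    cen = census(A, B)
    d = Diagram(A, B, cen, capped)

    telomeres = {"A": [], "B": []}
    for owner, g in (("A", A), ("B", B)):
        seen: Counter = Counter()  # genome-wide occurrence numbering
        for ci, chrom in enumerate(g.chromosomes):
            row = []
            for m, s in chrom.markers:
                seen[m] += 1
                occ = seen[m]
                tv = d._add_vertex(owner, m, occ, TAIL, (owner, ci))
                hv = d._add_vertex(owner, m, occ, HEAD, (owner, ci))
                left_end, right_end = _extremity_order(s)
                left = tv if left_end == TAIL else hv
                right = hv if right_end == HEAD else tv
                row.append((left, right, m, occ))
            for (l1, r1, _, _), (l2, r2, _, _) in zip(row, row[1:]):
                d._add_edge(ADJACENCY, r1, l2, genome=owner)
            if chrom.circular:
                if len(row) > 1:
                    d._add_edge(ADJACENCY, row[-1][1], row[0][0], genome=owner)
                else:
                    d._add_edge(ADJACENCY, row[0][1], row[0][0], genome=owner)
            else:
                telomeres[owner].append(row[0][0])
                telomeres[owner].append(row[-1][1])

    # indel edges: one per occurrence of every marker over-represented in its genome
    over = {"A": [], "B": []}
    for m in cen.universe:
        if cen.deltaPhi[m] > 0:
            over["A"].append(m)
        elif cen.deltaPhi[m] < 0:
            over["B"].append(m)
    indel_of_chrom: dict = defaultdict(list)
    for owner, g, phi_self, phi_other in (
        ("A", A, cen.phiA, cen.phiB),
        ("B", B, cen.phiB, cen.phiA),
    ):
        for m in over[owner]:
            for occ in range(1, phi_self[m] + 1):
                e = d._add_edge(
                    INDEL,
                    d.vid(owner, m, occ, TAIL),
                    d.vid(owner, m, occ, HEAD),
                    genome=owner,
                )
                v = d.vertex(d.vid(owner, m, occ, TAIL))
                indel_of_chrom[v.chrom].append(e)

    # extremity edges between all same-marker occurrence pairs, sibling-paired
    for m in sorted(cen.common):
        for occA in range(1, cen.phiA[m] + 1):
            for occB in range(1, cen.phiB[m] + 1):
                et = d._add_edge(
                    EXTREMITY,
                    d.vid("A", m, occA, TAIL),
                    d.vid("B", m, occB, TAIL),
                    match=(m, occA, occB),
                )
                eh = d._add_edge(
                    EXTREMITY,
                    d.vid("A", m, occA, HEAD),
                    d.vid("B", m, occB, HEAD),
                    match=(m, occA, occB),
                )
                d.edges[et].sibling = eh
                d.edges[eh].sibling = et
                d.ext_index[(m, occA, occB)] = (et, eh)

    # circular chromosomes that can be circular singletons: every occurrence
    # carries an indel edge
    for owner, g in (("A", A), ("B", B)):
        for ci, chrom in enumerate(g.chromosomes):
            if chrom.circular and len(indel_of_chrom.get((owner, ci), ())) == len(chrom):
                d.singleton_chromosomes[(owner, ci)] = list(indel_of_chrom[(owner, ci)])

    if capped:
        p_star = cen.p_star
        caps = {"A": [], "B": []}
        for owner in ("A", "B"):
            for k in range(1, 2 * p_star + 1):
                vid = d._add_vertex(owner, None, k, CAPEND, None)
                caps[owner].append(vid)
        for owner in ("A", "B"):
            tels = telomeres[owner]
            for tel, capv in zip(tels, caps[owner]):
                d._add_edge(ADJACENCY, tel, capv, genome=owner)
            # artificial adjacencies pair the surplus caps on the deficient side
            spare = caps[owner][len(tels):]
            for i in range(0, len(spare), 2):
                d._add_edge(ARTIFICIAL, spare[i], spare[i + 1], genome=owner)
        for ca in caps["A"]:
            for cb in caps["B"]:
                d._add_edge(CAP, ca, cb)
    return d


def build_relational(A: Genome, B: Genome) -> Diagram:
    """Build R(A,B) for singular genomes (rejects duplicated common markers)."""
    cen = census(A, B)
    for m in cen.common:
        if cen.phiA[m] > 1 or cen.phiB[m] > 1:
            raise ValueError(
                f"common marker {m!r} is duplicated; use build_multi_relational"
            )
    return build_multi_relational(A, B, capped=False)


# ---------------------------------------------------------------------------
# components


@dataclass
class Component:
    edge_walk: list[int]  # ordered edge indices along the component
    vertex_walk: list[int]  # ordered vids; paths have len(edges)+1 entries
    is_cycle: bool
    cls: str  # AB_cycle / AA_path / BB_path / AB_path / *_singleton
    Lambda: int
    run_signature: str  # paths: eps/A/B/AB/BA ; cycles: eps/single/even
    aleph: int
    indel_enclosing: bool

    @property
    def n_edges(self) -> int:
        return len(self.edge_walk)


def decompose(diagram: Diagram, selected: Sequence[int]) -> list[Component]:
    """Split the selected edge set into vertex-disjoint components.

    ``selected`` must contain every adjacency (and artificial adjacency) edge
    and induce degree <= 2 on every vertex.
    """
    sel = set(selected)
    missing = [i for i in diagram.adjacency_edge_indices() if i not in sel]
    if missing:
        raise ValueError("selected edge set must contain all adjacency edges")
    nbr: dict[int, list[int]] = defaultdict(list)
    for i in sel:
        e = diagram.edges[i]
        nbr[e.u].append(i)
        nbr[e.v].append(i)
    for vid, inc in nbr.items():
        if len(inc) > 2:
            raise ValueError(f"vertex {vid} has degree {len(inc)} > 2")

    visited_v: set[int] = set()
    visited_e: set[int] = set()
    comps: list[Component] = []

    def walk(start: int) -> tuple[list[int], list[int], bool]:
        edges_w: list[int] = []
        verts_w = [start]
        visited_v.add(start)
        cur, prev_e = start, None
        while True:
            nxt = [i for i in nbr[cur] if i != prev_e and i not in visited_e]
            if not nxt:
                return edges_w, verts_w, False
            ei = nxt[0]
            visited_e.add(ei)
            edges_w.append(ei)
            cur = diagram.edges[ei].other(cur)
            prev_e = ei
            if cur == start:
                return edges_w, verts_w, True
            verts_w.append(cur)
            visited_v.add(cur)

    all_vids = [v.vid for v in diagram.vertices]
    # paths first (start at vertices of degree < 2)
    for vid in all_vids:
        if vid not in visited_v and len(nbr.get(vid, ())) < 2:
            e_w, v_w, cyc = walk(vid)
            comps.append(_classify(diagram, e_w, v_w, cyc))
    for vid in all_vids:
        if vid not in visited_v:
            e_w, v_w, cyc = walk(vid)
            comps.append(_classify(diagram, e_w, v_w, cyc))
    return comps


def _classify(diagram: Diagram, edge_walk, vertex_walk, is_cycle) -> Component:
    edges = [diagram.edges[i] for i in edge_walk]
    crossing = any(e.kind in (EXTREMITY, CAP) for e in edges)
    indel_seq = [e.genome for e in edges if e.kind == INDEL]

    if is_cycle:
        Lambda = _circular_runs(indel_seq)
        cls = "AB_cycle" if crossing else "circular_singleton"
        sig = "eps" if Lambda == 0 else ("single" if Lambda == 1 else "even")
        aleph = 0 if Lambda <= 1 else Lambda
        return Component(edge_walk, vertex_walk, True, cls, Lambda, sig, aleph, Lambda >= 1)

    end1 = diagram.vertex(vertex_walk[0]).owner
    end2 = diagram.vertex(vertex_walk[-1]).owner
    if end1 != end2:
        cls = "AB_path"
        # read from the A endpoint
        if end1 == "B":
            edge_walk = list(reversed(edge_walk))
            vertex_walk = list(reversed(vertex_walk))
            edges = list(reversed(edges))
            indel_seq = [e.genome for e in edges if e.kind == INDEL]
    elif not crossing and indel_seq:
        cls = "linear_singleton"
    else:
        cls = "AA_path" if end1 == "A" else "BB_path"
    Lambda = _linear_runs(indel_seq)
    if Lambda == 0:
        sig = "eps"
    else:
        first = indel_seq[0]
        other = "B" if first == "A" else "A"
        if Lambda % 2 == 1:
            sig = first
        elif cls == "AB_path":
            sig = first + other
        else:
            sig = "AB"  # AA/BB paths: the two reading directions coincide
    return Component(edge_walk, vertex_walk, False, cls, Lambda, sig, 0, Lambda >= 1)


def component_census(components: Sequence[Component]) -> dict[str, int]:
    """Count components by class, with linear singletons rolled into their
    path class (a linear singleton in A is a particular AA-path, etc.)."""
    out = {"AB_cycle": 0, "AA_path": 0, "BB_path": 0, "AB_path": 0,
           "circular_singleton": 0, "linear_singleton": 0}
    for c in components:
        out[c.cls] += 1
        if c.cls == "linear_singleton":
            out["AA_path" if c.run_signature == "A" else "BB_path"] += 1
    return out


def _linear_runs(indel_seq: list[str]) -> int:
    if not indel_seq:
        return 0
    return 1 + sum(1 for a, b in zip(indel_seq, indel_seq[1:]) if a != b)


def _circular_runs(indel_seq: list[str]) -> int:
    if not indel_seq:
        return 0
    boundaries = sum(
        1 for i in range(len(indel_seq)) if indel_seq[i] != indel_seq[i - 1]
    )
    return boundaries if boundaries else 1


# ---------------------------------------------------------------------------
# sibling sets, capping sets, consistent decompositions


def sibling_sets(
    diagram: Diagram, bound: int = 1_000_000
) -> Iterator[dict[str, tuple[tuple[int, int], ...]]]:
    """Enumerate all maximal sibling sets of a multi-relational diagram.

    Yields matchings as ``{marker: ((occA, occB), ...)}``; every occurrence on
    the minority side of each common marker is matched injectively into the
    majority side.  Intended for desk-scale oracle use; refuses when the
    number of matchings exceeds ``bound``.
    """
    cen = diagram.census
    total = 1
    for m in cen.common:
        p, q = sorted((cen.phiA[m], cen.phiB[m]))
        total *= math.perm(q, p)
        if total > bound:
            raise ValueError(f"matching space exceeds bound {bound}")
    per_marker: list[list[tuple[str, tuple[tuple[int, int], ...]]]] = []
    for m in sorted(cen.common):
        pA, pB = cen.phiA[m], cen.phiB[m]
        options = []
        if pA <= pB:
            for perm in itertools.permutations(range(1, pB + 1), pA):
                options.append((m, tuple((a + 1, b) for a, b in enumerate(perm))))
        else:
            for perm in itertools.permutations(range(1, pA + 1), pB):
                options.append((m, tuple((a, b + 1) for b, a in enumerate(perm))))
        per_marker.append(options)
    for combo in itertools.product(*per_marker):
        yield {m: pairs for m, pairs in combo}


def sibling_edges(diagram: Diagram, matching) -> list[int]:
    """Edge indices of the sibling set realizing an occurrence matching."""
    out: list[int] = []
    for m, pairs in matching.items():
        for occA, occB in pairs:
            et, eh = diagram.ext_index[(m, occA, occB)]
            out.extend((et, eh))
    return out


def capping_sets(diagram: Diagram) -> Iterator[list[int]]:
    """Enumerate maximal capping sets (perfect matchings of cap extremities)."""
    if not diagram.capped:
        raise ValueError("diagram is not capped")
    capsA = diagram.cap_vids("A")
    capsB = diagram.cap_vids("B")
    cap_edge = {}
    for e in diagram.edges:
        if e.kind == CAP:
            cap_edge[(e.u, e.v)] = e.idx
            cap_edge[(e.v, e.u)] = e.idx
    if not capsA:
        yield []
        return
    for perm in itertools.permutations(capsB):
        yield [cap_edge[(a, b)] for a, b in zip(capsA, perm)]


def consistent_decomposition(
    diagram: Diagram, matching, capping: Optional[Sequence[int]] = None
) -> list[int]:
    """Edge set of the consistent decomposition induced by a sibling set.

    Step (i): all adjacency (and artificial) edges plus the sibling set (plus
    the capping set, for capped diagrams).  Step (ii): the indel edge of every
    unmatched occurrence is added, completing the cover.  (Matched occurrences
    are recognized by their selected extremity edges; a matched occurrence
    whose extremities are telomeres still has free degree, but adding its
    indel edge would diverge from the diagram of the matched singular
    genomes, where that occurrence has no indel edge at all.)
    """
    selected = diagram.adjacency_edge_indices()
    sib = sibling_edges(diagram, matching)
    selected += sib
    if capping is not None:
        selected += list(capping)
    deg: Counter = Counter()
    for i in selected:
        e = diagram.edges[i]
        deg[e.u] += 1
        deg[e.v] += 1
    matched_vertices = set()
    for i in sib:
        e = diagram.edges[i]
        matched_vertices.update((e.u, e.v))
    for e in diagram.edges:
        if (
            e.kind == INDEL
            and e.u not in matched_vertices
            and e.v not in matched_vertices
            and deg[e.u] <= 1
            and deg[e.v] <= 1
        ):
            selected.append(e.idx)
            deg[e.u] += 1
            deg[e.v] += 1
    return selected
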