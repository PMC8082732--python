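"""ILP formulation of the DCJ-indel distance over the capped diagram.

The distance of natural genomes A and B equals ``n* + p* - w`` where ``w`` is
the maximum weight of a capped consistent cycle decomposition Q[S,P] of
MR°(A,B):

    w(Q[S,P]) = (# indel-free cycles) - (# transitions)/2 - (# circular singletons)

The decomposition is searched by a mixed-integer program:

* ``x_e``  -- edge selected (adjacencies are forced in);
* ``y_i``  -- cycle label of vertex ``i`` (equal along selected edges, at most
  the smallest vertex id of the cycle, and forced to 0 on cycles through a
  selected indel edge);
* ``z_i``  -- 1 iff vertex ``i`` represents (labels) an indel-free cycle;
* ``r_v``  -- run label of vertex ``v`` (0 inside an A-run, 1 inside a B-run);
* ``t_e``  -- transition observed on edge ``e``; only adjacency edges of
  genome A that touch an indel edge can host a transition, which canonizes
  the counting without losing any optimum;
* ``s_k``  -- 1 iff circular chromosome ``k`` is selected as a whole circular
  singleton (only chromosomes all of whose occurrences carry indel edges can
  be singletons and get a variable).

The objective maximizes ``sum z - 1/2 sum t - sum s``.  The solver backend is
HiGHS via :func:`scipy.optimize.milp`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import sparse
from scipy.optimize import Bounds, LinearConstraint, milp

from . import diagram as dg
from .diagram import Diagram, build_multi_relational, decompose
from .genomes import Genome

__all__ = ["IlpModel", "IlpSolution", "build_ilp", "solve", "distance_natural"]


@dataclass
class IlpModel:
    diagram: Diagram
    n_vars: int
    names: list[str]
    lb: np.ndarray
    ub: np.ndarray
    integrality: np.ndarray
    objective: np.ndarray  # minimization coefficients (= -w)
    rows: list  # (coeff dict, lower, upper)
    x_offset: int = 0
    y_offset: int = 0
    z_offset: int = 0
    r_offset: int = 0
    t_cols: dict = field(default_factory=dict)  # edge idx -> column
    s_cols: dict = field(default_factory=dict)  # chrom key -> column

    def constraint_matrix(self):
        data, ri, ci, lo, hi = [], [], [], [], []
        for r, (coeffs, lower, upper) in enumerate(self.rows):
            for c, a in coeffs.items():
                ri.append(r)
                ci.append(c)
                data.append(a)
            lo.append(lower)
            hi.append(upper)
        A = sparse.csr_matrix(
            (data, (ri, ci)), shape=(len(self.rows), self.n_vars)
        )
        return A, np.array(lo, dtype=float), np.array(hi, dtype=float)


@dataclass
class IlpSolution:
    status: str  # optimal / feasible_gap / infeasible / timeout_no_solution
    objective: Optional[float]  # w of the incumbent decomposition
    distance: Optional[int]
    gap: float
    distance_bounds: tuple[Optional[int], Optional[int]]
    selected_edges: list[int]
    selected_siblings: dict
    selected_caps: list[int]
    component_summary: list
    n_star: int
    p_star: int
    message: str = ""

    def report(self) -> dict:
        return {
            "status": self.status,
            "distance": self.distance,
            "objective": self.objective,
            "gap": self.gap,
            "distance_bounds": list(self.distance_bounds),
            "n_star": self.n_star,
            "p_star": self.p_star,
        }


def build_ilp(diagram: Diagram) -> IlpModel:
    """Assemble the MILP for a capped multi-relational diagram."""
    if not diagram.capped:
        raise ValueError("the ILP requires a capped diagram")
    nE = len(diagram.edges)
    nV = len(diagram.vertices)

    # eligible transition hosts: A-adjacency edges touching an indel edge
    def touches_indel(e) -> bool:
        return any(
            diagram.edges[i].kind == dg.INDEL
            for v in (e.u, e.v)
            for i in diagram.vertex_edges[v - 1]
        )

    t_edges = [
        e.idx
        for e in diagram.edges
        if e.kind in (dg.ADJACENCY, dg.ARTIFICIAL)
        and e.genome == "A"
        and touches_indel(e)
    ]
    s_chroms = sorted(diagram.singleton_chromosomes)

    x_off = 0
    y_off = nE
    z_off = y_off + nV
    r_off = z_off + nV
    t_off = r_off + nV
    s_off = t_off + len(t_edges)
    n = s_off + len(s_chroms)

    lb = np.zeros(n)
    ub = np.ones(n)
    integrality = np.ones(n)
    obj = np.zeros(n)
    names = [""] * n
    for e in diagram.edges:
        names[x_off + e.idx] = f"x_{e.idx}"
        if e.kind in (dg.ADJACENCY, dg.ARTIFICIAL):
            lb[x_off + e.idx] = 1.0  # C.01
    for v in diagram.vertices:
        i = v.vid
        names[y_off + i - 1] = f"y_{i}"
        ub[y_off + i - 1] = float(i)
        integrality[y_off + i - 1] = 0  # y is integral at optimum anyway
        names[z_off + i - 1] = f"z_{i}"
        names[r_off + i - 1] = f"r_{i}"
        obj[z_off + i - 1] = -1.0
    t_cols = {}
    for k, eidx in enumerate(t_edges):
        t_cols[eidx] = t_off + k
        names[t_off + k] = f"t_{eidx}"
        obj[t_off + k] = 0.5
    s_cols = {}
    for k, ch in enumerate(s_chroms):
        s_cols[ch] = s_off + k
        names[s_off + k] = f"s_{ch[0]}{ch[1]}"
        obj[s_off + k] = 1.0

    rows: list = []

    def add(coeffs: dict, lower: float, upper: float) -> None:
        rows.append((coeffs, lower, upper))

    # C.02 vertex degree 2
    for v in diagram.vertices:
        add({x_off + i: 1.0 for i in diagram.vertex_edges[v.vid - 1]}, 2.0, 2.0)
    # C.03 sibling coupling
    for e in diagram.edges:
        if e.kind == dg.EXTREMITY and e.sibling is not None and e.idx < e.sibling:
            add({x_off + e.idx: 1.0, x_off + e.sibling: -1.0}, 0.0, 0.0)
    # C.04 equal labels along selected edges (big-M on the vertex ids)
    for e in diagram.edges:
        i, j = e.u, e.v
        add({y_off + i - 1: 1.0, y_off + j - 1: -1.0, x_off + e.idx: i}, -np.inf, i)
        add({y_off + j - 1: 1.0, y_off + i - 1: -1.0, x_off + e.idx: j}, -np.inf, j)
    # C.05 selected indel edges force label 0
    for e in diagram.edges:
        if e.kind == dg.INDEL:
            for v in (e.u, e.v):
                add({y_off + v - 1: 1.0, x_off + e.idx: v}, -np.inf, v)
    # C.06 a vertex represents its cycle only if the label equals its id
    for v in diagram.vertices:
        i = v.vid
        add({z_off + i - 1: i, y_off + i - 1: -1.0}, -np.inf, 0.0)
    # C.07 run labels at indel edges: 0 in A-runs, 1 in B-runs
    for e in diagram.edges:
        if e.kind == dg.INDEL:
            for v in (e.u, e.v):
                if e.genome == "A":
                    add({r_off + v - 1: 1.0, x_off + e.idx: 1.0}, -np.inf, 1.0)
                else:
                    add({x_off + e.idx: 1.0, r_off + v - 1: -1.0}, -np.inf, 0.0)
    # C.08 transitions on eligible A-adjacencies (always selected)
    for eidx, col in t_cols.items():
        e = diagram.edges[eidx]
        add({t_cols[eidx]: 1.0, r_off + e.u - 1: -1.0, r_off + e.v - 1: 1.0}, 0.0, np.inf)
        add({t_cols[eidx]: 1.0, r_off + e.v - 1: -1.0, r_off + e.u - 1: 1.0}, 0.0, np.inf)
    # C.09 constant run label across adjacencies that cannot host a transition
    for e in diagram.edges:
        if e.kind in (dg.ADJACENCY, dg.ARTIFICIAL) and e.idx not in t_cols:
            add({r_off + e.u - 1: 1.0, r_off + e.v - 1: -1.0}, 0.0, 0.0)
    # C.10 no label change across selected extremity/cap edges
    for e in diagram.edges:
        if e.kind in (dg.EXTREMITY, dg.CAP):
            add(
                {r_off + e.u - 1: 1.0, r_off + e.v - 1: -1.0, x_off + e.idx: 1.0},
                -np.inf,
                1.0,
            )
            add(
                {r_off + e.v - 1: 1.0, r_off + e.u - 1: -1.0, x_off + e.idx: 1.0},
                -np.inf,
                1.0,
            )
    # C.11 circular singletons
    for ch in s_chroms:
        eids = diagram.singleton_chromosomes[ch]
        coeffs = {x_off + i: 1.0 for i in eids}
        coeffs[s_cols[ch]] = -1.0
        add(coeffs, -np.inf, len(eids) - 1)

    return IlpModel(
        diagram=diagram,
        n_vars=n,
        names=names,
        lb=lb,
        ub=ub,
        integrality=integrality,
        objective=obj,
        rows=rows,
        x_offset=x_off,
        y_offset=y_off,
        z_offset=z_off,
        r_offset=r_off,
        t_cols=t_cols,
        s_cols=s_cols,
    )


def solve(
    model: IlpModel,
    time_limit: Optional[float] = None,
    mip_gap: Optional[float] = None,
    threads: int = 1,
    seed: int = 0,
) -> IlpSolution:
    """Solve the model with HiGHS.

    ``threads`` and ``seed`` are accepted for interface stability; the scipy
    HiGHS backend runs single-threaded and is deterministic, so they have no
    effect on the solve.
    """
    del threads, seed
    A, lo, hi = model.constraint_matrix()
    options: dict = {"disp": False}
    if time_limit is not None:
        options["time_limit"] = float(time_limit)
    if mip_gap is not None:
        options["mip_rel_gap"] = float(mip_gap)
    res = milp(
        c=model.objective,
        constraints=LinearConstraint(A, lo, hi),
        integrality=model.integrality,
        bounds=Bounds(model.lb, model.ub),
        options=options,
    )
    diagram = model.diagram
    n_star = diagram.census.n_star
    p_star = diagram.census.p_star

    if res.status == 2:
        raise RuntimeError(
            "ILP reported infeasible; the capped diagram always admits a "
            "decomposition, so this indicates a model construction bug: "
            + res.message
        )
    has_x = res.x is not None
    gap = float(getattr(res, "mip_gap", 0.0) or 0.0)
    if res.status == 0:
        status = "optimal"
    elif has_x:
        status = "feasible_gap"
    else:
        status = "timeout_no_solution"

    if not has_x:
        dual = getattr(res, "mip_dual_bound", None)
        lower = None if dual is None else int(np.ceil(n_star + p_star + dual - 1e-6))
        return IlpSolution(
            status, None, None, gap, (lower, None), [], {}, [], [], n_star, p_star,
            message=res.message,
        )

    w = -res.fun + 0.0  # normalize -0.0
    distance = int(round(n_star + p_star - w))
    selected = [
        e.idx for e in diagram.edges if res.x[model.x_offset + e.idx] > 0.5
    ]
    siblings: dict = {}
    caps: list[int] = []
    for i in selected:
        e = diagram.edges[i]
        if e.kind == dg.EXTREMITY and e.match is not None:
            m, occA, occB = e.match
            siblings.setdefault(m, set()).add((occA, occB))
        elif e.kind == dg.CAP:
            caps.append(i)
    siblings = {m: tuple(sorted(v)) for m, v in siblings.items()}
    components = decompose(diagram, selected)
    dual = getattr(res, "mip_dual_bound", None)
    lower = distance if res.status == 0 else (
        None if dual is None else int(np.ceil(n_star + p_star + dual - 1e-6))
    )
    return IlpSolution(
        status=status,
        objective=w,
        distance=distance,
        gap=gap,
        distance_bounds=(lower, distance),
        selected_edges=selected,
        selected_siblings=siblings,
        selected_caps=caps,
        component_summary=components,
        n_star=n_star,
        p_star=p_star,
        message=res.message,
    )


def distance_natural(
    A: Genome,
    B: Genome,
    time_limit: Optional[float] = None,
    mip_gap: Optional[float] = None,
    threads: int = 1,
    seed: int = 0,
) -> IlpSolution:
    """DCJ-indel distance of two natural genomes (census -> MR° -> ILP)."""
    diagram = build_multi_relational(A, B, capped=True)
    model = build_ilp(diagram)
    return solve(model, time_limit=time_limit, mip_gap=mip_gap, threads=threads, seed=seed)
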