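"""k-shortest support enumeration by mixed-integer programming.

This module enumerates the support-minimal nonzero solutions of any
"irreversible-network-shaped" linear system: the steady-state cone of an
all-irreversible network (whose support-minimal patterns are the elementary
modes) or the Farkas-dual certificate system (whose support-minimal vp/vn
patterns are the minimal cut sets of the primal network).

Two enumeration schemes are provided:

* ``iterative`` — repeatedly minimise the number of active indicators,
  record the optimum's support, and add an integer cut (exclusion row)
  forbidding that support and all its supersets;
* ``fixed_size`` — find the smallest support size s once, then for each size
  s, s+1, ... enumerate *all* feasible supports of exactly that size as pure
  feasibility problems, adding the size class's exclusion rows only after the
  class is complete. Solvers with a solution pool can sweep a size class in
  one call; the backend here has no pool, so the class is swept by repeated
  feasibility solves with per-solution exclusion rows — a documented
  fallback with identical output.

Indicator semantics (binary = 1 <=> continuous >= c, binary = 0 <=>
continuous = 0) are realised in two interchangeable modes:

* ``bigm`` — one MILP with linking rows x <= M z and x >= c z, solved by
  HiGHS; exact whenever M bounds the needed certificate magnitudes;
* ``indicator`` — an exact, M-free branch-and-fix search that fixes binaries
  along a depth-first tree and prunes with LP feasibility of the continuous
  system (this is precisely how solvers with native indicator constraints
  treat them internally).

Both modes must produce identical solution families; the test suite enforces
this on every fixture.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import Bounds, LinearConstraint, milp

from ._lp import solve_lp
from .cutset import CutSet
from .dual_system import DualSystem, build_dual_system
from .network_model import MetabolicNetwork, ValidationError

_INT_TOL = 1e-5


class TimeLimitReached(Exception):
    """Internal signal that the wall-clock budget ran out."""


class SolverError(RuntimeError):
    """The MILP backend reported neither optimality nor infeasibility."""


# ---------------------------------------------------------------------------
# System containers
# ---------------------------------------------------------------------------

@dataclass
class ContinuousSystem:
    """Linear system A x (sense) rhs with variable bounds; senses are L/G/E."""

    A: np.ndarray
    rhs: np.ndarray
    sense: list[str]
    lb: np.ndarray
    ub: np.ndarray

    @property
    def n_vars(self) -> int:
        return self.A.shape[1]


@dataclass
class Indicator:
    column: int          # continuous column this binary controls
    label: str           # reporting label (reaction id)
    fixed_zero: bool = False


@dataclass
class IndicatorSystem:
    """A continuous system plus binaries linked to selected columns."""

    cont: ContinuousSystem
    indicators: list[Indicator]
    pairs: list[tuple[int, int]]     # indices into ``indicators``
    threshold: float = 1.0

    @property
    def n_labels(self) -> int:
        return len({ind.label for ind in self.indicators if not ind.fixed_zero})


def attach_indicators(cont: ContinuousSystem, columns, labels=None,
                      pairs=(), threshold: float = 1.0,
                      fixed_zero=()) -> IndicatorSystem:
    """Attach one binary per continuous column in ``columns``.

    ``pairs`` lists positions (into ``columns``) of mutually exclusive
    indicator pairs — split reversible reactions in primal elementary-mode
    search, or the vp/vn split of the dual v variables — for which the row
    z_s + z_t <= 1 is added. ``fixed_zero`` positions get their binary (and
    hence their continuous variable) pinned to zero. All linked columns must
    be non-negative.
    """
    columns = list(columns)
    if labels is None:
        labels = [f"x{c}" for c in columns]
    fixed = set(fixed_zero)
    for c in columns:
        if cont.lb[c] < 0:
            raise ValidationError(
                f"indicator attached to variable {c} with negative lower bound")
    inds = [Indicator(c, lab, i in fixed)
            for i, (c, lab) in enumerate(zip(columns, labels))]
    return IndicatorSystem(cont, inds, [tuple(p) for p in pairs], threshold)


# ---------------------------------------------------------------------------
# Configuration and state
# ---------------------------------------------------------------------------

@dataclass
class EnumerationConfig:
    """Knobs of a single enumeration run.

    ``size_lb``/``size_ub`` realise the size-control row; ``mode`` selects the
    indicator realisation (``bigm`` or ``indicator``); ``threads`` and
    ``seed`` are recorded for provenance (the HiGHS backend runs
    single-threaded and is deterministic).
    """

    algorithm: str = "fixed_size"          # or "iterative"
    size_lb: int = 1
    size_ub: int = 5
    max_solutions: int | None = None
    time_limit_s: float | None = None
    threads: int = 1
    seed: int = 0
    mode: str = "bigm"                     # or "indicator"
    big_m: float = 1e5

    def __post_init__(self):
        if not 1 <= self.size_lb <= self.size_ub:
            raise ValidationError("need 1 <= size_lb <= size_ub")
        if self.algorithm not in ("iterative", "fixed_size"):
            raise ValidationError(f"unknown algorithm '{self.algorithm}'")
        if self.mode not in ("bigm", "indicator"):
            raise ValidationError(f"unknown indicator mode '{self.mode}'")


@dataclass
class EnumerationState:
    """Result of an enumeration: supports found (non-decreasing size) and cuts."""

    found: list = field(default_factory=list)            # list[frozenset[str]]
    exclusion_rows: list = field(default_factory=list)   # list[frozenset[str]]
    current_size: int = 0
    status: str = "complete"
    size_complete: dict = field(default_factory=dict)    # size -> bool

    def counts_per_size(self) -> dict[int, int]:
        out: dict[int, int] = {}
        for s in self.found:
            out[len(s)] = out.get(len(s), 0) + 1
        return out


def add_exclusion_constraint(state: EnumerationState, support) -> EnumerationState:
    """Record an integer cut excluding ``support`` and all its supersets."""
    support = frozenset(support)
    if not support:
        raise ValidationError("cannot exclude the empty support")
    state.exclusion_rows.append(support)
    return state


# ---------------------------------------------------------------------------
# Backends
# ---------------------------------------------------------------------------

def _deadline(config: EnumerationConfig) -> float | None:
    return None if config.time_limit_s is None else time.monotonic() + config.time_limit_s


def _remaining(deadline) -> float | None:
    if deadline is None:
        return None
    left = deadline - time.monotonic()
    if left <= 0:
        raise TimeLimitReached
    return left


def _split_senses(cont: ContinuousSystem):
    """Convert the L/G/E row senses into (A_ub, b_ub, A_eq, b_eq) parts."""
    ub_rows, ub_rhs, eq_rows, eq_rhs = [], [], [], []
    for a, s, b in zip(cont.A, cont.sense, cont.rhs):
        if s == "L":
            ub_rows.append(a); ub_rhs.append(b)
        elif s == "G":
            ub_rows.append(-a); ub_rhs.append(-b)
        else:
            eq_rows.append(a); eq_rhs.append(b)
    return (np.array(ub_rows) if ub_rows else None,
            np.array(ub_rhs) if ub_rows else None,
            np.array(eq_rows) if eq_rows else None,
            np.array(eq_rhs) if eq_rows else None)


class _SupportVerifier:
    """Exact, M-free feasibility check of a binary assignment.

    Fixing the binaries fixes bounds on their continuous variables (on ->
    lower bound c, off -> 0); a single LP then decides whether the assignment
    is genuinely feasible. This is the ground truth both backends defer to.
    """

    def __init__(self, isys: IndicatorSystem):
        self.isys = isys
        self.A_ub, self.b_ub, self.A_eq, self.b_eq = _split_senses(isys.cont)
        self.lb = isys.cont.lb.copy()
        self.ub = isys.cont.ub.copy()
        for ind in isys.indicators:
            if ind.fixed_zero:
                self.ub[ind.column] = min(self.ub[ind.column], 0.0)
        self.c = isys.threshold
        self.zero_obj = np.zeros(isys.cont.n_vars)

    def solve(self, on, off_all_others=True, off=()):
        lb, ub = self.lb.copy(), self.ub.copy()
        on = set(on)
        off = set(off)
        for k, ind in enumerate(self.isys.indicators):
            if k in on:
                lb[ind.column] = max(lb[ind.column], self.c)
            elif k in off or off_all_others:
                ub[ind.column] = min(ub[ind.column], 0.0)
        bounds = [(None if np.isinf(l) else l, None if np.isinf(u) else u)
                  for l, u in zip(lb, ub)]
        return solve_lp(self.zero_obj, self.A_ub, self.b_ub,
                        self.A_eq, self.b_eq, bounds)

    def assignment_feasible(self, on) -> bool:
        return self.solve(on).feasible


class _BigMBackend:
    """Single-MILP realisation with x <= M z / x >= c z linking rows.

    Every candidate the MILP solver accepts is re-certified by the exact
    support LP; a candidate that only looked feasible because of big-M row
    scaling is rejected with a no-good cut on its exact binary assignment
    (never an integer cut, which would also exclude genuine supersets) and
    the solve is repeated.
    """

    capabilities = {"indicator constraints": False,
                    "solution pool with fixed objective": False,
                    "warm start": False}

    def __init__(self, isys: IndicatorSystem, big_m: float):
        self.isys = isys
        self.big_m = float(big_m)
        self.verifier = _SupportVerifier(isys)
        cont = isys.cont
        self.nc = cont.n_vars
        self.nb = len(isys.indicators)
        n = self.nc + self.nb

        rows, lo, hi = [], [], []
        for a, s, b in zip(cont.A, cont.sense, cont.rhs):
            rows.append(np.concatenate([a, np.zeros(self.nb)]))
            lo.append(b if s in ("G", "E") else -np.inf)
            hi.append(b if s in ("L", "E") else np.inf)
        c_thr = isys.threshold
        for k, ind in enumerate(isys.indicators):
            if ind.fixed_zero:
                continue
            row = np.zeros(n)
            row[ind.column] = 1.0
            row[self.nc + k] = -self.big_m
            rows.append(row); lo.append(-np.inf); hi.append(0.0)   # x <= M z
            row = np.zeros(n)
            row[ind.column] = 1.0
            row[self.nc + k] = -c_thr
            rows.append(row); lo.append(0.0); hi.append(np.inf)    # x >= c z
        for a, b in self.isys.pairs:
            row = np.zeros(n)
            row[self.nc + a] = 1.0
            row[self.nc + b] = 1.0
            rows.append(row); lo.append(-np.inf); hi.append(1.0)
        self._base = (np.array(rows), np.array(lo), np.array(hi))

        self.var_lb = np.concatenate([cont.lb, np.zeros(self.nb)])
        self.var_ub = np.concatenate([cont.ub, np.ones(self.nb)])
        for k, ind in enumerate(isys.indicators):
            if ind.fixed_zero:
                self.var_ub[self.nc + k] = 0.0
                self.var_ub[ind.column] = min(self.var_ub[ind.column], 0.0)
            else:
                self.var_ub[ind.column] = min(self.var_ub[ind.column], self.big_m)
        self.integrality = np.concatenate(
            [np.zeros(self.nc), np.ones(self.nb)])

    def _size_row(self) -> np.ndarray:
        row = np.zeros(self.nc + self.nb)
        row[self.nc:] = 1.0
        return row

    def _exclusion_rows(self, exclusions):
        rows, lo, hi = [], [], []
        for support in exclusions:
            row = np.zeros(self.nc + self.nb)
            for k, ind in enumerate(self.isys.indicators):
                if ind.label in support:
                    row[self.nc + k] = 1.0
            rows.append(row); lo.append(-np.inf); hi.append(len(support) - 1)
        return rows, lo, hi

    def _nogood_row(self, assignment):
        """Row excluding exactly one binary assignment (not its supersets)."""
        row = np.zeros(self.nc + self.nb)
        for k, ind in enumerate(self.isys.indicators):
            if ind.fixed_zero:
                continue
            row[self.nc + k] = 1.0 if k in assignment else -1.0
        return row, len(assignment) - 1

    def _solve(self, objective, exclusions, size_lo, size_hi, deadline):
        base_rows, base_lo, base_hi = self._base
        ex_rows, ex_lo, ex_hi = self._exclusion_rows(exclusions)
        nogood_rows, nogood_hi = [], []
        while True:
            rows = [base_rows, self._size_row()[None, :]]
            lo = [base_lo, [size_lo]]
            hi = [base_hi, [size_hi]]
            if ex_rows:
                rows.append(np.array(ex_rows)); lo.append(ex_lo); hi.append(ex_hi)
            if nogood_rows:
                rows.append(np.array(nogood_rows))
                lo.append([-np.inf] * len(nogood_rows)); hi.append(nogood_hi)
            A = np.vstack(rows)
            options = {}
            left = _remaining(deadline)
            if left is not None:
                options["time_limit"] = left
            res = milp(c=objective,
                       constraints=LinearConstraint(
                           A, np.concatenate(lo), np.concatenate(hi)),
                       integrality=self.integrality,
                       bounds=Bounds(self.var_lb, self.var_ub),
                       options=options)
            if res.status == 2:
                return None
            if res.status == 1:  # halted by iteration/time limit
                raise TimeLimitReached
            if res.status != 0 or res.x is None:
                raise SolverError(
                    f"MILP failed (status {res.status}): {res.message}")
            z = res.x[self.nc:]
            assignment = frozenset(k for k in range(self.nb) if z[k] > 0.5)
            if self.verifier.assignment_feasible(assignment):
                return frozenset(self.isys.indicators[k].label
                                 for k in assignment)
            # numerically spurious under big-M scaling: forbid this exact
            # assignment and ask the solver again
            row, rhs = self._nogood_row(assignment)
            nogood_rows.append(row)
            nogood_hi.append(rhs)

    def solve_min(self, exclusions, size_lb, size_ub, deadline):
        obj = np.concatenate([np.zeros(self.nc), np.ones(self.nb)])
        return self._solve(obj, exclusions, size_lb, size_ub, deadline)

    def feasible_at_size(self, s, exclusions, deadline):
        obj = np.zeros(self.nc + self.nb)
        return self._solve(obj, exclusions, s, s, deadline)


class _BranchBackend:
    """Exact indicator semantics by branch-and-fix over the binaries.

    No big-M constant appears anywhere: a binary fixed to 0 pins its
    continuous variable's upper bound to 0, a binary fixed to 1 raises the
    lower bound to the threshold c, and free binaries leave their variable
    merely non-negative (a valid relaxation). LP infeasibility prunes the
    subtree; complete depth-first traversal guarantees every support of the
    requested size is visited.
    """

    capabilities = {"indicator constraints": True,
                    "solution pool with fixed objective": False,
                    "warm start": False}

    def __init__(self, isys: IndicatorSystem, big_m: float = 0.0):
        self.isys = isys
        cont = isys.cont
        self.A_ub, self.b_ub, self.A_eq, self.b_eq = _split_senses(cont)
        self.base_lb = cont.lb.copy()
        self.base_ub = cont.ub.copy()
        self.partner = {}
        for a, b in isys.pairs:
            self.partner[a] = b
            self.partner[b] = a
        self.active = [k for k, ind in enumerate(isys.indicators)
                       if not ind.fixed_zero]
        for ind in isys.indicators:
            if ind.fixed_zero:
                self.base_ub[ind.column] = min(self.base_ub[ind.column], 0.0)
        self.c = isys.threshold
        self.zero_obj = np.zeros(cont.n_vars)

    def _lp(self, lb, ub):
        bounds = [(None if np.isinf(l) and l < 0 else l,
                   None if np.isinf(u) else u) for l, u in zip(lb, ub)]
        return solve_lp(self.zero_obj, self.A_ub, self.b_ub,
                        self.A_eq, self.b_eq, bounds)

    def _enumerate(self, s, exclusions, deadline, emit):
        """DFS over binary fixings; calls emit(support) for every solution of
        size exactly s. emit returning True stops the search."""
        inds = self.isys.indicators
        lb = self.base_lb.copy()
        ub = self.base_ub.copy()
        order = list(self.active)

        def superset_of_excluded(labels):
            return any(labels >= ex for ex in exclusions)

        def dfs(pos_free, fix1):
            _remaining(deadline)
            labels1 = frozenset(inds[k].label for k in fix1)
            if superset_of_excluded(labels1):
                return False
            if len(fix1) == s:
                # all remaining free binaries drop to zero: exact-support LP
                saved = [(k, ub[inds[k].column]) for k in pos_free]
                for k in pos_free:
                    ub[inds[k].column] = min(ub[inds[k].column], 0.0)
                feas = self._lp(lb, ub).feasible
                for k, u in saved:
                    ub[inds[k].column] = u
                if feas:
                    return bool(emit(labels1))
                return False
            if len(fix1) + len(pos_free) < s:
                return False
            res = self._lp(lb, ub)
            if not res.feasible:
                return False
            # branch on the free binary whose variable is most active in the
            # relaxation; deterministic tie-break by position
            x = res.x
            pick, best = pos_free[0], -1.0
            if x is not None:
                for k in pos_free:
                    v = x[inds[k].column]
                    if v > best + 1e-12:
                        pick, best = k, v
            rest = [k for k in pos_free if k != pick]
            col = inds[pick].column
            partner = self.partner.get(pick)
            # branch 1 (unless the mutually exclusive partner is already on)
            if partner is None or partner not in fix1:
                saved_lb = lb[col]
                lb[col] = max(lb[col], self.c)
                sub_free = rest
                saved_partner = None
                if partner is not None and partner in rest:
                    sub_free = [k for k in rest if k != partner]
                    pc = inds[partner].column
                    saved_partner = ub[pc]
                    ub[pc] = min(ub[pc], 0.0)
                stop = dfs(sub_free, fix1 | {pick})
                lb[col] = saved_lb
                if saved_partner is not None:
                    ub[inds[partner].column] = saved_partner
                if stop:
                    return True
            # branch 0
            saved_ub = ub[col]
            ub[col] = min(ub[col], 0.0)
            stop = dfs(rest, fix1)
            ub[col] = saved_ub
            return stop

        dfs(order, frozenset())

    def solve_min(self, exclusions, size_lb, size_ub, deadline):
        for s in range(size_lb, size_ub + 1):
            hit = []
            self._enumerate(s, exclusions, deadline,
                            lambda sup: hit.append(sup) or True)
            if hit:
                return hit[0]
        return None

    def feasible_at_size(self, s, exclusions, deadline):
        hit = []
        self._enumerate(s, exclusions, deadline,
                        lambda sup: hit.append(sup) or True)
        return hit[0] if hit else None


def _make_backend(isys: IndicatorSystem, config: EnumerationConfig):
    cls = _BigMBackend if config.mode == "bigm" else _BranchBackend
    return cls(isys, config.big_m)


# ---------------------------------------------------------------------------
# Enumeration drivers
# ---------------------------------------------------------------------------

def _finish_status(state: EnumerationState, isys: IndicatorSystem,
                   config: EnumerationConfig) -> str:
    if not state.found and config.size_ub >= isys.n_labels:
        return "infeasible"
    return "complete"


def enumerate_iterative(isys: IndicatorSystem,
                        config: EnumerationConfig) -> EnumerationState:
    """ALGO-style iterative scheme: optimise, record, exclude, repeat.

    Every integer cut, once added, is kept for all later iterations, so the
    optima form a non-decreasing size sequence and no support is ever a
    superset of an earlier one.
    """
    backend = _make_backend(isys, config)
    state = EnumerationState(status="complete")
    deadline = _deadline(config)
    lb = config.size_lb
    while True:
        try:
            support = backend.solve_min(state.exclusion_rows, lb,
                                        config.size_ub, deadline)
        except TimeLimitReached:
            state.status = "time_limit"
            break
        if support is None:
            state.status = _finish_status(state, isys, config)
            break
        state.found.append(support)
        state.current_size = len(support)
        lb = max(lb, len(support))
        add_exclusion_constraint(state, support)
        if config.max_solutions is not None and \
                len(state.found) >= config.max_solutions:
            state.status = "solution_limit"
            break
    for s in range(config.size_lb, config.size_ub + 1):
        state.size_complete[s] = (state.status in ("complete", "infeasible")
                                  or s < state.current_size)
    return state


def enumerate_fixed_size(isys: IndicatorSystem,
                         config: EnumerationConfig) -> EnumerationState:
    """Fixed-size scheme: one optimisation for the smallest size, then pure
    feasibility sweeps per size class.

    Exclusion rows of a size class are committed to the global cut list only
    after the class is fully enumerated; within a class, the pool-less
    backend uses per-solution exclusion rows to sweep all solutions.
    """
    backend = _make_backend(isys, config)
    state = EnumerationState(status="complete")
    deadline = _deadline(config)
    try:
        first = backend.solve_min([], config.size_lb, config.size_ub, deadline)
    except TimeLimitReached:
        state.status = "time_limit"
        return state
    if first is None:
        state.status = _finish_status(state, isys, config)
        for s in range(config.size_lb, config.size_ub + 1):
            state.size_complete[s] = True
        return state

    s0 = len(first)
    for s in range(config.size_lb, s0):
        state.size_complete[s] = True
    limit_hit = False
    for s in range(s0, config.size_ub + 1):
        pool = [first] if s == s0 else []
        local = list(pool)
        state.found.extend(pool)
        state.current_size = s
        complete = True
        while True:
            if config.max_solutions is not None and \
                    len(state.found) >= config.max_solutions:
                state.status = "solution_limit"
                complete = False
                limit_hit = True
                break
            try:
                sol = backend.feasible_at_size(
                    s, state.exclusion_rows + local, deadline)
            except TimeLimitReached:
                state.status = "time_limit"
                complete = False
                limit_hit = True
                break
            if sol is None:
                break
            local.append(sol)
            state.found.append(sol)
        state.size_complete[s] = complete
        for sup in local:
            add_exclusion_constraint(state, sup)
        if limit_hit:
            break
    if not limit_hit:
        state.status = _finish_status(state, isys, config) \
            if not state.found else "complete"
    return state


def enumerate_supports(isys: IndicatorSystem,
                       config: EnumerationConfig) -> EnumerationState:
    """Dispatch to the scheme named by ``config.algorithm``."""
    if config.algorithm == "iterative":
        return enumerate_iterative(isys, config)
    return enumerate_fixed_size(isys, config)


# ---------------------------------------------------------------------------
# Front doors: shortest EMs and smallest MCSs
# ---------------------------------------------------------------------------

def em_indicator_system(net: MetabolicNetwork, pairing=None,
                        threshold: float = 1.0) -> IndicatorSystem:
    """Indicator system whose supports are the EM supports of ``net``.

    ``net`` must be all-irreversible (apply split_reversible first);
    ``pairing`` maps forward split ids to backward ids so that the spurious
    two-cycles get mutual-exclusion rows.
    """
    if net.reversible.any():
        raise ValidationError("shortest-EM search needs an all-irreversible "
                              "network; apply split_reversible first")
    n = net.n_reactions
    cont = ContinuousSystem(net.stoich.copy(), np.zeros(net.n_metabolites),
                            ["E"] * net.n_metabolites,
                            np.zeros(n), np.full(n, np.inf))
    pairs = []
    if pairing:
        idx = {rid: j for j, rid in enumerate(net.reaction_ids)}
        pairs = [(idx[f], idx[b]) for f, b in pairing.items()]
    return attach_indicators(cont, range(n), labels=list(net.reaction_ids),
                             pairs=pairs, threshold=threshold)


def shortest_ems(net: MetabolicNetwork, config: EnumerationConfig,
                 pairing=None) -> EnumerationState:
    """k-shortest elementary modes of an all-irreversible network.

    Returned supports are exactly the support-minimal nonzero flux patterns,
    in non-decreasing size; ``state.found`` holds them as frozensets of
    reaction ids.
    """
    isys = em_indicator_system(net, pairing=pairing)
    return enumerate_supports(isys, config)


def dual_indicator_system(dsys: DualSystem) -> IndicatorSystem:
    """Attach zp/zn indicators (with mutual exclusion) to a dual system."""
    cont = ContinuousSystem(dsys.matrix.copy(), dsys.rhs.copy(),
                            list(dsys.row_sense),
                            dsys.var_lb.copy(), dsys.var_ub.copy())
    n = dsys.n_reactions
    vp, vn = dsys.block("vp"), dsys.block("vn")
    columns = list(vp) + list(vn)
    labels = list(dsys.reaction_ids) * 2
    pairs = [(i, n + i) for i in range(n)]
    fixed = [i for i in range(n) if not dsys.knockable_mask[i]]
    fixed += [n + i for i in range(n) if not dsys.knockable_mask[i]]
    return attach_indicators(cont, columns, labels=labels, pairs=pairs,
                             threshold=dsys.c, fixed_zero=fixed)


def smallest_mcs(problem, config: EnumerationConfig | None = None,
                 compression_map=None, c: float = 1.0,
                 return_state: bool = False):
    """Enumerate the smallest minimal cut sets of an intervention problem.

    Builds the dual certificate system, enumerates its shortest elementary
    modes restricted to the vp/vn support, collapses each solution to a cut
    set, and (when a CompressionMap from preprocessing is supplied) expands
    lumped reactions back to original reactions. Every returned set blocks
    the target polyhedron and is support-minimal.
    """
    if config is None:
        config = EnumerationConfig(size_ub=problem.max_size,
                                   max_solutions=problem.max_solutions,
                                   time_limit_s=problem.time_limit_s)
    dsys = build_dual_system(problem.network, problem.target,
                             knockable=problem.knockable, c=c)
    isys = dual_indicator_system(dsys)
    state = enumerate_supports(isys, config)
    cutsets = [CutSet(sup, is_mcs=True) for sup in state.found]
    if compression_map is not None:
        from .preprocessing import decompress_cutsets
        cutsets = decompress_cutsets(cutsets, compression_map)
    if return_state:
        return cutsets, state
    return cutsets
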