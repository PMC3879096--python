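"""Search-space reduction before dualization.

Three standard reductions shrink a cut-set search problem without changing its
answer set:

* *blocked reactions* — reactions that cannot carry any steady-state flux
  under the given context are found by flux variability analysis (two LPs per
  reaction with early exit) and removed;
* *network compression* — reactions whose fluxes are fully coupled (fixed,
  nonzero ratio in every steady state) are merged into single lumped
  reactions; cut sets found in the compressed network are expanded back by a
  Cartesian product over each lumped member set;
* *exclusions* — non-knockable reactions and reactions essential for the
  desired flux space are taken out of the knockable universe up front.

Full coupling is detected with a kernel ratio test: two reactions are merged
exactly when their rows in a nullspace basis of N are proportional with a
fixed nonzero factor, which is the classical enzyme-subset criterion.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import null_space

from ._lp import lp_feasible, solve_lp
from .cutset import CutSet
from .network_model import (LinearFluxConstraintSet, MetabolicNetwork,
                            ValidationError, ZERO_TOL, flux_lp_parts)

#: Flux magnitudes below this count as zero in FVA.
FVA_TOL = 1e-7
#: Objective cap for otherwise unbounded FVA LPs; blockedness only needs a
#: nonzero witness, so any large finite cap works.
FVA_CAP = 1e6


# ---------------------------------------------------------------------------
# Flux variability analysis
# ---------------------------------------------------------------------------

def fva_blocked_reactions(net: MetabolicNetwork,
                          context: LinearFluxConstraintSet | None = None,
                          tol: float = FVA_TOL) -> set[str]:
    """Reactions whose min and max steady-state flux are both ~0 under ``context``.

    Raises ``ValueError("context polyhedron empty")`` when the steady-state
    system intersected with the context rows is infeasible.
    """
    A_ub, b_ub, A_eq, b_eq, bounds = flux_lp_parts(net, extra=context, cap=FVA_CAP)
    n = net.n_reactions
    if not lp_feasible(A_ub, b_ub, A_eq, b_eq, bounds, n=n):
        raise ValueError("context polyhedron empty")
    blocked = set()
    c = np.zeros(n)
    for j, rid in enumerate(net.reaction_ids):
        c[j] = -1.0  # maximize r_j
        res = solve_lp(c, A_ub, b_ub, A_eq, b_eq, bounds)
        if res.feasible and res.fun is not None and -res.fun > tol:
            c[j] = 0.0
            continue  # nonzero flux witnessed, no second LP needed
        c[j] = 1.0  # minimize r_j
        res = solve_lp(c, A_ub, b_ub, A_eq, b_eq, bounds)
        if not (res.feasible and res.fun is not None and res.fun < -tol):
            blocked.add(rid)
        c[j] = 0.0
    return blocked


def remove_reactions(net: MetabolicNetwork, remove) -> MetabolicNetwork:
    """Drop the named reactions (and any metabolite row that becomes all-zero)."""
    remove = set(remove)
    keep = [j for j, r in enumerate(net.reaction_ids) if r not in remove]
    stoich = net.stoich[:, keep]
    mkeep = np.abs(stoich).max(axis=1, initial=0.0) > ZERO_TOL
    return MetabolicNetwork(
        stoich[mkeep],
        [net.reaction_ids[j] for j in keep],
        [m for m, k in zip(net.metabolite_ids, mkeep) if k],
        net.reversible[keep],
        lower_bound=None if net.lower_bound is None else net.lower_bound[keep],
        upper_bound=None if net.upper_bound is None else net.upper_bound[keep],
        knockable=net.knockable[keep],
        exchange=net.exchange[keep],
        spontaneous=net.spontaneous[keep],
    )


def apply_regulation(net: MetabolicNetwork, disabled) -> MetabolicNetwork:
    """Apply a regulation-derived disable list by removing the reactions.

    The list is consumed as data (one reaction id per line in the sidecar
    file); no regulatory logic is computed here.
    """
    return remove_reactions(net, disabled)


def read_reaction_list(path) -> list[str]:
    """Sidecar format: one reaction id per line, '#' comments allowed."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if line:
                out.append(line)
    return out


# ---------------------------------------------------------------------------
# Compression
# ---------------------------------------------------------------------------

@dataclass
class CompressionSubset:
    """One lumped reaction: members and their fixed flux ratios.

    A member with ratio rho carries flux ``rho * v_lumped`` in every steady
    state. The lumped column equals the ratio-weighted sum of member columns.
    """

    lumped_id: str
    members: list[str]
    ratios: list[float]
    knockable_members: list[str]


@dataclass
class CompressionMap:
    """Invertible record of a compression, for decompressing cut sets."""

    subsets: list[CompressionSubset]
    removed_blocked: list[str] = field(default_factory=list)
    disabled_by_regulation: list[str] = field(default_factory=list)

    def __post_init__(self):
        seen = set()
        for s in self.subsets:
            for m in s.members:
                if m in seen:
                    raise ValidationError(f"reaction '{m}' appears in two subsets")
                seen.add(m)
        self._by_id = {s.lumped_id: s for s in self.subsets}

    def subset(self, lumped_id: str) -> CompressionSubset:
        try:
            return self._by_id[lumped_id]
        except KeyError:
            raise KeyError(f"unknown lumped reaction '{lumped_id}'") from None

    def map_constraints(self, cs: LinearFluxConstraintSet,
                        original: MetabolicNetwork) -> LinearFluxConstraintSet:
        """Express constraint rows over original rates in the compressed space.

        Column for a lumped reaction = sum of ratio * original column; columns
        of removed (blocked/disabled) reactions are dropped, which is exact
        because those rates are identically zero.
        """
        cs.check_width(original)
        cols = []
        for s in self.subsets:
            col = np.zeros(cs.n_rows)
            for m, rho in zip(s.members, s.ratios):
                col += rho * cs.coeffs[:, original.reaction_index(m)]
            cols.append(col)
        return LinearFluxConstraintSet(np.column_stack(cols), cs.rhs.copy(),
                                       label=cs.label)


def compress_network(net: MetabolicNetwork,
                     tol: float = ZERO_TOL
                     ) -> tuple[MetabolicNetwork, CompressionMap]:
    """Merge fully coupled reactions into lumped reactions.

    Expects blocked reactions to have been removed already (see
    :func:`fva_blocked_reactions`); reactions that are blocked even in the
    purely linear sense (zero kernel row) are tolerated and recorded in
    ``removed_blocked``. A lumped reaction is knockable iff at least one
    member is knockable.
    """
    n = net.n_reactions
    kernel = null_space(net.stoich)  # n x d
    if kernel.size == 0:
        kernel = np.zeros((n, 1))
    norms = np.linalg.norm(kernel, axis=1)
    blocked = [net.reaction_ids[j] for j in range(n) if norms[j] <= tol]
    active = [j for j in range(n) if norms[j] > tol]

    # group proportional kernel rows: j ~ ref iff K_j == rho * K_ref
    groups: list[tuple[int, list[int], list[float]]] = []  # (ref, members, ratios)
    for j in active:
        row = kernel[j]
        for ref, members, ratios in groups:
            rref = kernel[ref]
            rho = float(row @ rref) / float(rref @ rref)
            if abs(rho) > tol and np.linalg.norm(row - rho * rref) <= tol * norms[j]:
                members.append(j)
                ratios.append(rho)
                break
        else:
            groups.append((j, [j], [1.0]))

    subsets, cols, rids, revs, knock = [], [], [], [], []
    for ref, members, ratios in groups:
        ratios = np.array(ratios)
        irrev = [k for k, j in enumerate(members) if not net.reversible[j]]
        if irrev:
            signs = np.sign(ratios[irrev])
            if len(set(signs)) > 1:
                ids = [net.reaction_ids[members[k]] for k in irrev]
                raise ValidationError(
                    f"coupled irreversible reactions with opposing orientations "
                    f"{ids}; remove blocked reactions before compressing")
            if signs[0] < 0:
                ratios = -ratios  # orient the lump along its irreversible members
        col = sum(rho * net.stoich[:, j] for j, rho in zip(members, ratios))
        member_ids = [net.reaction_ids[j] for j in members]
        lumped_id = member_ids[0] if len(members) == 1 else "+".join(member_ids)
        knockable_members = [net.reaction_ids[j] for j in members if net.knockable[j]]
        subsets.append(CompressionSubset(lumped_id, member_ids, [float(r) for r in ratios],
                                         knockable_members))
        cols.append(col)
        rids.append(lumped_id)
        revs.append(bool(all(net.reversible[j] for j in members)))
        knock.append(bool(knockable_members))

    stoich = np.column_stack(cols) if cols else np.zeros((net.n_metabolites, 0))
    mkeep = np.abs(stoich).max(axis=1, initial=0.0) > tol
    cnet = MetabolicNetwork(
        stoich[mkeep], rids,
        [m for m, k in zip(net.metabolite_ids, mkeep) if k],
        np.array(revs, dtype=bool),
        knockable=np.array(knock, dtype=bool),
        exchange=np.zeros(len(rids), dtype=bool),
        spontaneous=np.zeros(len(rids), dtype=bool),
    )
    return cnet, CompressionMap(subsets, removed_blocked=blocked)


def decompress_cutsets(cutsets, cmap: CompressionMap) -> list[CutSet]:
    """Expand compressed cut sets by the Cartesian product over lumped members.

    Every member of every input cut set must be a lumped_id of ``cmap``; each
    expanded set keeps the size of its compressed parent, and the output is
    duplicate-free in input order.
    """
    out, seen = [], set()
    for cs in cutsets:
        choice_lists = []
        for lumped in sorted(cs.reactions):
            sub = cmap.subset(lumped)
            members = sub.knockable_members or sub.members
            choice_lists.append(sorted(members))
        for combo in itertools.product(*choice_lists):
            expanded = frozenset(combo)
            if expanded not in seen:
                seen.add(expanded)
                out.append(CutSet(expanded, is_mcs=cs.is_mcs, is_cmcs=cs.is_cmcs))
    return out


# ---------------------------------------------------------------------------
# Desired-space essentials
# ---------------------------------------------------------------------------

def desired_essential_reactions(net: MetabolicNetwork,
                                desired: LinearFluxConstraintSet,
                                knockable=None) -> set[str]:
    """Knockable reactions whose single removal empties the desired flux space.

    These can never occur in a constrained MCS, so they are excluded from the
    search universe before enumeration when cMCS filtering is requested.
    Raises if the desired polyhedron itself is empty.
    """
    A_ub, b_ub, A_eq, b_eq, bounds = flux_lp_parts(net, extra=desired)
    n = net.n_reactions
    if not lp_feasible(A_ub, b_ub, A_eq, b_eq, bounds, n=n):
        raise ValueError("desired polyhedron empty")
    if knockable is None:
        knockable = net.knockable_ids()
    essential = set()
    for rid in knockable:
        j = net.reaction_index(rid)
        saved = bounds[j]
        bounds[j] = (0.0, 0.0)
        if not lp_feasible(A_ub, b_ub, A_eq, b_eq, bounds, n=n):
            essential.add(rid)
        bounds[j] = saved
    return essential
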