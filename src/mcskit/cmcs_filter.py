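"""Constrained-MCS filtering and strain-design metrics.

An MCS blocks every undesired (target) flux vector, but a useful strain
design must also leave at least one *desired* flux vector intact — growth
plus maintenance, say. Cut sets with that extra property are constrained
MCSs (cMCSs). The filter is a single feasibility LP per cut set: is

    N r = 0,  irreversibilities,  D r <= d,  r_i = 0 (i in cut set)

feasible? Each surviving design is then scored by three standard metrics:
maximal growth rate of the mutant, minimal guaranteed product yield at the
stated substrate uptake, and substrate-specific productivity (SSP = growth
rate x product yield, evaluated here at the mutant's maximum-growth state
with the worst-case yield at that state).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from ._lp import LPNumericalError, lp_feasible, solve_lp
from .cutset import CutSet
from .network_model import (LinearFluxConstraintSet, MetabolicNetwork,
                            flux_lp_parts)

_MU_TOL = 1e-6


class IndeterminateError(RuntimeError):
    """LP numerics prevented a definite cMCS verdict (never silently true)."""


@dataclass
class CutSetEvaluation:
    """Performance record of one cut set (all rates in the model's units)."""

    cutset: CutSet
    desired_feasible: bool | None = None
    feasible: bool = True
    max_growth: float = 0.0
    min_guaranteed_yield: float = 0.0
    ssp: float = 0.0


def is_cmcs(net: MetabolicNetwork, desired: LinearFluxConstraintSet,
            cutset) -> bool:
    """True iff the desired flux polyhedron survives the cut.

    Raises :class:`IndeterminateError` on LP numerical failure rather than
    guessing.
    """
    members = cutset.reactions if isinstance(cutset, CutSet) else set(cutset)
    unknown = set(members) - set(net.reaction_ids)
    if unknown:
        raise KeyError(f"cut set members not in network: {sorted(unknown)}")
    A_ub, b_ub, A_eq, b_eq, bounds = flux_lp_parts(net, extra=desired,
                                                   knocked=members)
    try:
        return lp_feasible(A_ub, b_ub, A_eq, b_eq, bounds, n=net.n_reactions)
    except LPNumericalError as exc:
        raise IndeterminateError(
            f"cMCS status of {sorted(members)} is indeterminate: {exc}") from exc


def filter_cmcs(net: MetabolicNetwork, desired: LinearFluxConstraintSet,
                cutsets) -> list[CutSet]:
    """Keep only the cut sets that admit the desired behaviour.

    Input order is preserved; every retained set is annotated as a cMCS.
    This runs after full enumeration (the LP checks are cheap relative to
    the MILP search); for streaming use call :func:`is_cmcs` per solution as
    it is found — same result, different scheduling.
    """
    kept = []
    for cs in cutsets:
        if is_cmcs(net, desired, cs):
            kept.append(replace(cs, is_cmcs=True))
    return kept


def evaluate_cutset(net: MetabolicNetwork, cutset, product_rxn: str,
                    substrate_rxn: str, growth_rxn: str,
                    uptake_limit: float,
                    desired: LinearFluxConstraintSet | None = None
                    ) -> CutSetEvaluation:
    """Score a mutant defined by ``cutset``.

    * ``max_growth``: LP maximising the growth reaction with cut rates 0 and
      substrate uptake at most ``uptake_limit``;
    * ``min_guaranteed_yield``: LP minimising product flux at uptake fixed to
      ``uptake_limit`` (worst case over all mutant behaviours), divided by
      the uptake — the yield the design guarantees without assuming optimal
      growth;
    * ``ssp``: max_growth times the worst-case yield at the maximum-growth
      state.

    Substrate uptake is measured as a non-negative flux through
    ``substrate_rxn`` in uptake direction.
    """
    members = cutset.reactions if isinstance(cutset, CutSet) else set(cutset)
    for rid in (product_rxn, substrate_rxn, growth_rxn):
        net.reaction_index(rid)
    cs = cutset if isinstance(cutset, CutSet) else CutSet(frozenset(members))
    n = net.n_reactions
    jp = net.reaction_index(product_rxn)
    js = net.reaction_index(substrate_rxn)
    jg = net.reaction_index(growth_rxn)

    A_ub, b_ub, A_eq, b_eq, bounds = flux_lp_parts(net, knocked=members)
    cap_row = np.zeros(n)
    cap_row[js] = 1.0
    A_cap = cap_row[None, :] if A_ub is None else np.vstack([A_ub, cap_row])
    b_cap = np.array([uptake_limit]) if b_ub is None \
        else np.concatenate([b_ub, [uptake_limit]])

    obj = np.zeros(n)
    obj[jg] = -1.0
    res = solve_lp(obj, A_cap, b_cap, A_eq, b_eq, bounds)
    if not res.feasible:
        return CutSetEvaluation(cs, desired_feasible=False, feasible=False)
    max_growth = -res.fun if np.isfinite(res.fun) else np.inf

    # worst-case product formation at full substrate uptake
    bounds_fix = list(bounds)
    bounds_fix[js] = (uptake_limit, uptake_limit)
    obj = np.zeros(n)
    obj[jp] = 1.0
    res = solve_lp(obj, A_ub, b_ub, A_eq, b_eq, bounds_fix)
    min_yield = (res.fun / uptake_limit) if res.feasible else 0.0

    # worst-case yield while growing at the mutant's maximum rate
    bounds_mu = list(bounds_fix)
    if np.isfinite(max_growth):
        bounds_mu[jg] = (max_growth - _MU_TOL, None)
    res = solve_lp(obj, A_ub, b_ub, A_eq, b_eq, bounds_mu)
    yield_at_mu = (res.fun / uptake_limit) if res.feasible else 0.0
    ssp = max_growth * yield_at_mu if np.isfinite(max_growth) else 0.0

    ev = CutSetEvaluation(cs, feasible=True, max_growth=float(max_growth),
                          min_guaranteed_yield=float(min_yield),
                          ssp=float(ssp))
    if desired is not None:
        ev.desired_feasible = is_cmcs(net, desired, cs)
    return ev


def yield_constraint_row(net: MetabolicNetwork, product_rxn: str,
                         substrate_rxn: str, min_yield: float,
                         sense: str = ">=") -> np.ndarray:
    """Linearised yield bound: product - Y * uptake >= 0 (or <= for targets).

    Yields are ratios, so a bound Y(r) >= Y_min enters the linear target or
    desired rows as product_flux - Y_min * uptake_flux >= 0, with uptake
    measured as a non-negative uptake-direction flux. Returns the row for
    use in a LinearFluxConstraintSet (caller supplies rhs 0 with the matching
    sense convention).
    """
    row = np.zeros(net.n_reactions)
    row[net.reaction_index(product_rxn)] = 1.0
    row[net.reaction_index(substrate_rxn)] = -min_yield
    if sense == ">=":
        return -row   # normalised <= form: -(product - Y*uptake) <= 0
    return row


def evaluations_table(evaluations) -> "pandas.DataFrame":
    """Results table: one row per cut set with members, size, flags, metrics."""
    import pandas as pd

    rows = []
    for ev in evaluations:
        rows.append({
            "members": "|".join(ev.cutset.sorted()),
            "size": ev.cutset.size,
            "cmcs": ev.cutset.is_cmcs if ev.cutset.is_cmcs is not None
            else ev.desired_feasible,
            "feasible": ev.feasible,
            "max_growth": ev.max_growth,
            "min_guaranteed_yield": ev.min_guaranteed_yield,
            "ssp": ev.ssp,
        })
    return pd.DataFrame(rows)
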