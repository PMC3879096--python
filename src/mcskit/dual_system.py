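"""Farkas-dual construction for cut-set enumeration.

A cut set S blocks the target flux polyhedron exactly when the primal system

    N r = 0,   r_i >= 0 (i in Irrev),   T r <= b,   r_i = 0 (i in S)

is infeasible. By the Farkas lemma this infeasibility is certified by dual
multipliers: u (free, one per metabolite, dual to the steady-state
equalities), a slack absorbed into the row sense for each irreversibility
constraint, w >= 0 (one per target row) and a free v_i for each deletable
rate-zero row. The certificate system, written with v split into
non-negative parts vp/vn, has one structural row per primal reaction

    (N^T u)_i + vp_i - vn_i + (T^T w)_i  >= 0   for irreversible i,
                                          = 0   for reversible i,

plus the inhomogeneity row  b^T w <= -c  with an arbitrary constant c > 0
that pins the certificate's scale. A feasible dual solution whose vp/vn
support lies within S proves that deleting S blocks the target; the
support-minimal solutions (the elementary modes of this dual system,
restricted to the v variables) are exactly the minimal cut sets.

Because published sign conventions for such dual systems are notoriously easy
to garble, :func:`certify_cut_set` provides the independent primal-side check
that gates every enumerated solution in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._lp import lp_feasible
from .cutset import CutSet
from .network_model import (LinearFluxConstraintSet, MetabolicNetwork,
                            ValidationError, flux_lp_parts, validate_target)


@dataclass
class IndicatorLink:
    """Semantics tying a binary to a non-negative continuous variable.

    binary = 1  <=>  continuous >= threshold;  binary = 0  <=>  continuous = 0.
    The threshold is the dual scaling constant c.
    """

    continuous_var: int
    binary_name: str
    threshold: float = 1.0


@dataclass
class DualSystem:
    """The dual certificate system in block form.

    Columns are ordered [u | vp | vn | w]; rows are the n structural reaction
    rows followed by the single inhomogeneity row. ``row_sense`` entries are
    'G' (>=), 'E' (=) or 'L' (<=) against ``rhs``.
    """

    matrix: np.ndarray
    rhs: np.ndarray
    row_sense: list[str]
    var_index: dict[str, range]
    var_lb: np.ndarray
    var_ub: np.ndarray
    knockable_mask: np.ndarray
    reaction_ids: list[str]
    c: float = 1.0

    @property
    def n_reactions(self) -> int:
        return len(self.reaction_ids)

    def block(self, name: str) -> range:
        return self.var_index[name]


def build_dual_system(net: MetabolicNetwork,
                      target: LinearFluxConstraintSet,
                      knockable=None,
                      c: float = 1.0) -> DualSystem:
    """Build the dual certificate system for ``net`` and ``target``.

    ``knockable`` restricts which reactions may appear in a cut set; the vp/vn
    columns of non-knockable reactions carry upper bound 0 (their indicators
    are fixed to 0 downstream). ``c`` may be any positive value; the family of
    support-minimal solutions does not depend on it.
    """
    if c <= 0:
        raise ValueError("the scaling constant c must be positive")
    target.check_width(net)
    report = validate_target(net, target)
    if report.zero_in_polyhedron:
        raise ValidationError(report.messages[0])
    if knockable is None:
        knockable = set(net.knockable_ids())
    else:
        knockable = set(knockable)
        unknown = knockable - set(net.reaction_ids)
        if unknown:
            raise ValidationError(f"knockable reactions not in network: {sorted(unknown)}")

    m, n = net.n_metabolites, net.n_reactions
    k = target.n_rows
    nu, nvp, nvn, nw = m, n, n, k
    ncol = nu + nvp + nvn + nw
    var_index = {
        "u": range(0, nu),
        "vp": range(nu, nu + nvp),
        "vn": range(nu + nvp, nu + nvp + nvn),
        "w": range(nu + nvp + nvn, ncol),
    }

    A = np.zeros((n + 1, ncol))
    A[:n, var_index["u"]] = net.stoich.T                      # N^T u
    A[:n, var_index["vp"]] = np.eye(n)                        # +vp
    A[:n, var_index["vn"]] = -np.eye(n)                       # -vn
    A[:n, var_index["w"]] = target.coeffs.T                   # T^T w
    A[n, var_index["w"]] = target.rhs                         # b^T w <= -c
    rhs = np.zeros(n + 1)
    rhs[n] = -c
    sense = ["E" if net.reversible[i] else "G" for i in range(n)] + ["L"]

    lb = np.full(ncol, -np.inf)
    ub = np.full(ncol, np.inf)
    lb[list(var_index["vp"])] = 0.0
    lb[list(var_index["vn"])] = 0.0
    lb[list(var_index["w"])] = 0.0
    mask = np.array([rid in knockable for rid in net.reaction_ids])
    for i in range(n):
        if not mask[i]:
            ub[var_index["vp"][i]] = 0.0
            ub[var_index["vn"][i]] = 0.0

    return DualSystem(A, rhs, sense, var_index, lb, ub, mask,
                      list(net.reaction_ids), c=c)


def dump_matrix(dsys: DualSystem, path) -> None:
    """Debug dump of the dual matrix in MatrixMarket coordinate format."""
    from scipy.io import mmwrite
    from scipy.sparse import coo_matrix

    mmwrite(str(path), coo_matrix(dsys.matrix))


def collapse_solution(zp, zn, reaction_ids) -> CutSet:
    """Collapse split indicators into a cut set: z_i = zp_i + zn_i.

    The cut set contains every reaction with z_i = 1. Both indicators active
    for the same reaction is an internal consistency error (the mutual
    exclusion rows forbid it).
    """
    zp = np.asarray(zp, dtype=int)
    zn = np.asarray(zn, dtype=int)
    if zp.shape != zn.shape or len(zp) != len(reaction_ids):
        raise ValidationError("indicator vectors do not match the reaction list")
    both = zp & zn
    if both.any():
        bad = [reaction_ids[i] for i in np.where(both)[0]]
        raise ValidationError(f"zp and zn simultaneously active for {bad}")
    members = {reaction_ids[i] for i in np.where(zp | zn)[0]}
    return CutSet(frozenset(members), is_mcs=True)


def certify_cut_set(net: MetabolicNetwork,
                    target: LinearFluxConstraintSet,
                    cutset) -> bool:
    """Primal-side Farkas check: does deleting ``cutset`` block the target?

    True iff the LP {N r = 0, irreversibilities, T r <= b, r_i = 0 for i in
    cutset} is infeasible. Independent of the dual construction, so it can
    vouch for any sign convention used there.
    """
    members = cutset.reactions if isinstance(cutset, CutSet) else cutset
    A_ub, b_ub, A_eq, b_eq, bounds = flux_lp_parts(net, extra=target, knocked=members)
    return not lp_feasible(A_ub, b_ub, A_eq, b_eq, bounds, n=net.n_reactions)


def is_minimal_cut_set(net: MetabolicNetwork,
                       target: LinearFluxConstraintSet,
                       cutset) -> bool:
    """True iff the cut set blocks the target and no single-member drop does."""
    members = set(cutset.reactions if isinstance(cutset, CutSet) else cutset)
    if not certify_cut_set(net, target, members):
        return False
    return all(not certify_cut_set(net, target, members - {m}) for m in members)
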