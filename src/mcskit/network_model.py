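"""Stoichiometric networks and linear flux-constraint sets.

A :class:`MetabolicNetwork` holds the stoichiometric matrix ``N`` (m
metabolites x n reactions), reaction reversibilities (the set *Irrev* of
irreversible reactions), optional flux bounds and per-reaction tags. The
steady-state flux cone is ``{r : N r = 0, r_i >= 0 for i in Irrev}``.

A :class:`LinearFluxConstraintSet` is a polyhedron ``{r : M r <= rhs}`` over
the reaction rates, used both for the *target* (undesired) flux vectors that a
cut set must block and for the *desired* flux vectors of which at least one
must survive. All inequalities are normalised to ``<=`` rows internally; ``>=``
and ``=`` inputs are converted (``=`` becomes two rows).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

import numpy as np

from ._lp import lp_feasible

#: Coefficients with absolute value below this are treated as zero.
ZERO_TOL = 1e-9

_ARROWS = ("<->", "<=>", "<--", "<-", "-->", "->", "=>", "=")


class FormatError(ValueError):
    """A model or constraint file could not be parsed."""


class ValidationError(ValueError):
    """A model or problem definition violates an invariant."""


# ---------------------------------------------------------------------------
# MetabolicNetwork
# ---------------------------------------------------------------------------

@dataclass
class MetabolicNetwork:
    """Stoichiometric model with reaction/metabolite identities and tags.

    Parameters
    ----------
    stoich
        Dense (m x n) stoichiometric matrix.
    reaction_ids, metabolite_ids
        Unique identifier lists; their lengths fix n and m.
    reversible
        Boolean flags per reaction; ``~reversible`` is the set Irrev.
    lower_bound, upper_bound
        Optional per-reaction bounds (``None`` means no bounds were supplied;
        fluxes are then unbounded subject to irreversibility).
    knockable, exchange, spontaneous
        Per-reaction tags. By convention exchange and spontaneous reactions
        default to non-knockable.
    """

    stoich: np.ndarray
    reaction_ids: list[str]
    metabolite_ids: list[str]
    reversible: np.ndarray
    lower_bound: np.ndarray | None = None
    upper_bound: np.ndarray | None = None
    knockable: np.ndarray = None
    exchange: np.ndarray = None
    spontaneous: np.ndarray = None

    def __post_init__(self):
        self.stoich = np.atleast_2d(np.asarray(self.stoich, dtype=float))
        self.reversible = np.asarray(self.reversible, dtype=bool)
        n = len(self.reaction_ids)
        m = len(self.metabolite_ids)
        if self.stoich.shape != (m, n):
            raise ValidationError(
                f"stoichiometric matrix is {self.stoich.shape}, expected ({m}, {n})")
        if len(set(self.reaction_ids)) != n:
            raise ValidationError("duplicate reaction identifiers")
        if len(set(self.metabolite_ids)) != m:
            raise ValidationError("duplicate metabolite identifiers")
        if self.reversible.shape != (n,):
            raise ValidationError("reversible flags must have one entry per reaction")
        for name in ("lower_bound", "upper_bound"):
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v, dtype=float)
                if v.shape != (n,):
                    raise ValidationError(f"{name} must have one entry per reaction")
                setattr(self, name, v)
        if self.lower_bound is not None:
            bad = (~self.reversible) & (self.lower_bound < -ZERO_TOL)
            if bad.any():
                ids = [self.reaction_ids[i] for i in np.where(bad)[0]]
                raise ValidationError(
                    f"irreversible reactions with negative lower bound: {ids}")
        if self.spontaneous is None:
            self.spontaneous = np.zeros(n, dtype=bool)
        else:
            self.spontaneous = np.asarray(self.spontaneous, dtype=bool)
        if self.exchange is None:
            # a column touching no metabolite, or declared via sidecar, is exchange
            self.exchange = (np.abs(self.stoich) > ZERO_TOL).sum(axis=0) == 0
        else:
            self.exchange = np.asarray(self.exchange, dtype=bool)
        if self.knockable is None:
            self.knockable = ~(self.exchange | self.spontaneous)
        else:
            self.knockable = np.asarray(self.knockable, dtype=bool)

    # -- basic accessors ----------------------------------------------------

    @property
    def n_reactions(self) -> int:
        return len(self.reaction_ids)

    @property
    def n_metabolites(self) -> int:
        return len(self.metabolite_ids)

    @property
    def irreversible(self) -> np.ndarray:
        """Boolean mask of the set Irrev."""
        return ~self.reversible

    def reaction_index(self, rid: str) -> int:
        try:
            return self.reaction_ids.index(rid)
        except ValueError:
            raise KeyError(f"unknown reaction '{rid}'") from None

    def knockable_ids(self) -> list[str]:
        return [r for r, k in zip(self.reaction_ids, self.knockable) if k]

    # -- construction helpers ----------------------------------------------

    @classmethod
    def from_equations(cls, reactions, **kwargs) -> "MetabolicNetwork":
        """Build a network from ``(reaction_id, equation, reversible)`` triples.

        Equations use text arrow notation, e.g. ``"2 A + B -> C"``; an empty
        side denotes an exchange with the environment. The arrow ``<->`` (or an
        explicit third tuple element) marks reversibility.
        """
        rids, revs, parsed = [], [], []
        metabolites: list[str] = []
        seen = set()
        for entry in reactions:
            rid, equation, rev = entry[0], entry[1], bool(entry[2])
            coeffs, arrow_rev = parse_equation(equation)
            rids.append(rid)
            revs.append(rev or arrow_rev)
            parsed.append(coeffs)
            for met in coeffs:
                if met not in seen:
                    seen.add(met)
                    metabolites.append(met)
        stoich = np.zeros((len(metabolites), len(rids)))
        midx = {m: i for i, m in enumerate(metabolites)}
        for j, coeffs in enumerate(parsed):
            for met, coef in coeffs.items():
                stoich[midx[met], j] = coef
        return cls(stoich, rids, metabolites, np.array(revs, dtype=bool), **kwargs)


def parse_equation(equation: str) -> tuple[dict[str, float], bool]:
    """Parse ``"2 A + B -> C"`` into net coefficients and a reversibility flag."""
    for arrow in _ARROWS:
        if arrow in equation:
            lhs, rhs = equation.split(arrow, 1)
            reversible = arrow in ("<->", "<=>")
            break
    else:
        raise FormatError(f"no reaction arrow in equation '{equation}'")
    coeffs: dict[str, float] = {}

    def add_side(side: str, sign: float):
        side = side.strip()
        if not side:
            return
        for term in side.split("+"):
            term = term.strip()
            if not term:
                raise FormatError(f"empty term in equation '{equation}'")
            parts = term.split()
            if len(parts) == 1:
                coef, met = 1.0, parts[0]
            elif len(parts) == 2:
                try:
                    coef = float(parts[0])
                except ValueError:
                    raise FormatError(
                        f"bad coefficient '{parts[0]}' in equation '{equation}'") from None
                met = parts[1]
            else:
                raise FormatError(f"bad term '{term}' in equation '{equation}'")
            coeffs[met] = coeffs.get(met, 0.0) + sign * coef

    add_side(lhs, -1.0)
    add_side(rhs, +1.0)
    return {m: c for m, c in coeffs.items() if abs(c) > ZERO_TOL}, reversible


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

_TABULAR_COLUMNS = ["reaction_id", "equation", "reversible", "lb", "ub", "knockable"]


def load_network(path, format: str | None = None) -> MetabolicNetwork:
    """Read a model from SBML (Level 3 / FBC, via cobrapy) or the tabular dialect.

    The tabular dialect is tab-separated with header columns
    ``reaction_id  equation  reversible  lb  ub  knockable`` where *equation*
    uses text arrow notation and *reversible*/*knockable* are {0,1}. Empty
    lb/ub cells mean "unbounded subject to irreversibility".
    """
    path = str(path)
    if format is None:
        format = "sbml" if path.endswith((".xml", ".sbml")) else "tabular"
    if format == "sbml":
        return _load_sbml(path)
    if format == "tabular":
        return _load_tabular(path)
    raise ValueError(f"unknown format '{format}'")


def _load_tabular(path) -> MetabolicNetwork:
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    missing = [c for c in _TABULAR_COLUMNS[:3] if c not in df.columns]
    if missing:
        raise FormatError(f"tabular model {path} lacks columns {missing}")
    reactions, lbs, ubs, knock = [], [], [], []
    have_bounds = "lb" in df.columns or "ub" in df.columns
    for _, row in df.iterrows():
        rid = str(row["reaction_id"]).strip()
        try:
            rev = bool(int(row["reversible"]))
        except (TypeError, ValueError):
            raise FormatError(
                f"record '{rid}': reversible flag '{row['reversible']}' is not 0/1"
            ) from None
        try:
            reactions.append((rid, str(row["equation"]), rev))
        except FormatError as exc:
            raise FormatError(f"record '{rid}': {exc}") from None

        def cell(col, default):
            if col not in df.columns or pd.isna(row[col]) or str(row[col]).strip() == "":
                return default
            return float(row[col])

        lbs.append(cell("lb", -np.inf if rev else 0.0))
        ubs.append(cell("ub", np.inf))
        knock.append(bool(int(cell("knockable", 1))))
    kwargs = {"knockable": np.array(knock, dtype=bool)}
    if have_bounds:
        kwargs["lower_bound"] = np.array(lbs)
        kwargs["upper_bound"] = np.array(ubs)
    try:
        return MetabolicNetwork.from_equations(reactions, **kwargs)
    except FormatError as exc:
        raise FormatError(f"{path}: {exc}") from None


def _load_sbml(path) -> MetabolicNetwork:
    import cobra.io

    model = cobra.io.read_sbml_model(path)
    rids = [r.id for r in model.reactions]
    mids = [m.id for m in model.metabolites]
    stoich = np.zeros((len(mids), len(rids)))
    midx = {m: i for i, m in enumerate(mids)}
    rev = np.zeros(len(rids), dtype=bool)
    lb = np.zeros(len(rids))
    ub = np.zeros(len(rids))
    exch = np.zeros(len(rids), dtype=bool)
    for j, rxn in enumerate(model.reactions):
        for met, coef in rxn.metabolites.items():
            stoich[midx[met.id], j] = coef
        rev[j] = rxn.reversibility
        lb[j], ub[j] = rxn.lower_bound, rxn.upper_bound
        exch[j] = rxn.boundary
    return MetabolicNetwork(stoich, rids, mids, rev, lower_bound=lb,
                            upper_bound=ub, exchange=exch)


def write_network(net: MetabolicNetwork, path) -> None:
    """Write a network in the tabular dialect (round-trips with load_network)."""
    lines = ["\t".join(_TABULAR_COLUMNS)]
    for j, rid in enumerate(net.reaction_ids):
        subs, prods = [], []
        for i, met in enumerate(net.metabolite_ids):
            coef = net.stoich[i, j]
            if coef < -ZERO_TOL:
                subs.append(f"{-coef:g} {met}" if abs(coef + 1) > ZERO_TOL else met)
            elif coef > ZERO_TOL:
                prods.append(f"{coef:g} {met}" if abs(coef - 1) > ZERO_TOL else met)
        arrow = "<->" if net.reversible[j] else "->"
        eq = f"{' + '.join(subs)} {arrow} {' + '.join(prods)}".strip()
        lb = "" if net.lower_bound is None or np.isinf(net.lower_bound[j]) \
            else f"{net.lower_bound[j]:.12g}"
        ub = "" if net.upper_bound is None or np.isinf(net.upper_bound[j]) \
            else f"{net.upper_bound[j]:.12g}"
        lines.append("\t".join([rid, eq, str(int(net.reversible[j])), lb, ub,
                                str(int(net.knockable[j]))]))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Reversible splitting
# ---------------------------------------------------------------------------

def split_reversible(net: MetabolicNetwork) -> tuple[MetabolicNetwork, dict[str, str]]:
    """Decompose every reversible reaction into an irreversible (fwd, bwd) pair.

    Returns the all-irreversible network and a pairing ``{fwd_id: bwd_id}``.
    The backward column is the negated forward column; identifiers get the
    deterministic suffixes ``_fwd`` / ``_bwd`` (collision-checked). Networks
    that are already irreversible are returned unchanged with an empty pairing.
    """
    if not net.reversible.any():
        return net, {}
    cols, rids, revs, knock, exch, spon = [], [], [], [], [], []
    lb = [] if net.lower_bound is not None else None
    ub = [] if net.upper_bound is not None else None
    pairing: dict[str, str] = {}
    existing = set(net.reaction_ids)
    for j, rid in enumerate(net.reaction_ids):
        col = net.stoich[:, j]
        if net.reversible[j]:
            fwd, bwd = f"{rid}_fwd", f"{rid}_bwd"
            if fwd in existing or bwd in existing:
                raise ValidationError(f"split identifiers for '{rid}' collide")
            pairing[fwd] = bwd
            cols += [col, -col]
            rids += [fwd, bwd]
            revs += [False, False]
            knock += [net.knockable[j]] * 2
            exch += [net.exchange[j]] * 2
            spon += [net.spontaneous[j]] * 2
            if lb is not None:
                lb += [0.0, 0.0]
                ub += [max(net.upper_bound[j], 0.0),
                       max(-net.lower_bound[j], 0.0)]
        else:
            cols.append(col)
            rids.append(rid)
            revs.append(False)
            knock.append(net.knockable[j])
            exch.append(net.exchange[j])
            spon.append(net.spontaneous[j])
            if lb is not None:
                lb.append(net.lower_bound[j])
                ub.append(net.upper_bound[j])
    return MetabolicNetwork(
        np.column_stack(cols), rids, list(net.metabolite_ids),
        np.array(revs, dtype=bool),
        lower_bound=None if lb is None else np.array(lb),
        upper_bound=None if ub is None else np.array(ub),
        knockable=np.array(knock, dtype=bool),
        exchange=np.array(exch, dtype=bool),
        spontaneous=np.array(spon, dtype=bool),
    ), pairing


# ---------------------------------------------------------------------------
# LinearFluxConstraintSet
# ---------------------------------------------------------------------------

@dataclass
class LinearFluxConstraintSet:
    """A flux polyhedron ``{r : coeffs r <= rhs}`` (row sense fixed as <=)."""

    coeffs: np.ndarray
    rhs: np.ndarray
    label: str = ""

    def __post_init__(self):
        self.coeffs = np.atleast_2d(np.asarray(self.coeffs, dtype=float))
        self.rhs = np.atleast_1d(np.asarray(self.rhs, dtype=float))
        if self.coeffs.shape[0] != self.rhs.shape[0]:
            raise ValidationError("constraint matrix and rhs row counts differ")

    @property
    def n_rows(self) -> int:
        return self.coeffs.shape[0]

    def check_width(self, net: MetabolicNetwork) -> None:
        if self.coeffs.shape[1] != net.n_reactions:
            raise ValidationError(
                f"constraint set '{self.label}' has {self.coeffs.shape[1]} columns, "
                f"network has {net.n_reactions} reactions")

    def contains(self, r: np.ndarray, tol: float = ZERO_TOL) -> bool:
        return bool(np.all(self.coeffs @ np.asarray(r) <= self.rhs + tol))

    @classmethod
    def flux_bound(cls, net: MetabolicNetwork, rid: str, sense: str,
                   value: float, label: str = "") -> "LinearFluxConstraintSet":
        """Single-row set like ``r_id >= value`` (sense in {<=, >=, =})."""
        return cls.from_text([f"1 {rid} {sense} {value}"], net, label=label)

    @classmethod
    def from_text(cls, lines, net: MetabolicNetwork,
                  label: str = "") -> "LinearFluxConstraintSet":
        """Parse constraint lines ``"coef rid [+ coef rid ...] <= value"``.

        ``>=`` rows are negated into ``<=`` form and ``=`` rows become two
        rows, so the stored sense is uniformly ``<=``.
        """
        rows, rhs = [], []
        for line in lines:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            m = re.search(r"(<=|>=|=)", line)
            if m is None:
                raise FormatError(f"no relational operator in constraint '{line}'")
            op = m.group(1)
            lhs_txt, rhs_txt = line[:m.start()], line[m.end():]
            try:
                value = float(rhs_txt)
            except ValueError:
                raise FormatError(f"bad right-hand side in constraint '{line}'") from None
            row = np.zeros(net.n_reactions)
            for sign_txt, term in re.findall(r"([+-]?)\s*([^+-]+)", lhs_txt):
                term = term.strip()
                if not term:
                    continue
                parts = term.split()
                if len(parts) == 1:
                    coef, rid = 1.0, parts[0]
                elif len(parts) == 2:
                    try:
                        coef = float(parts[0])
                    except ValueError:
                        raise FormatError(
                            f"bad coefficient in constraint '{line}'") from None
                    rid = parts[1]
                else:
                    raise FormatError(f"bad term '{term}' in constraint '{line}'")
                if sign_txt == "-":
                    coef = -coef
                row[net.reaction_index(rid)] += coef
            if op == "<=":
                rows.append(row); rhs.append(value)
            elif op == ">=":
                rows.append(-row); rhs.append(-value)
            else:
                rows.append(row); rhs.append(value)
                rows.append(-row); rhs.append(-value)
        if not rows:
            raise FormatError("constraint text contains no rows")
        return cls(np.vstack(rows), np.array(rhs), label=label)


# ---------------------------------------------------------------------------
# LP assembly and target validation
# ---------------------------------------------------------------------------

def flux_lp_parts(net: MetabolicNetwork,
                  extra: LinearFluxConstraintSet | None = None,
                  knocked=(), cap: float | None = None):
    """Assemble (A_ub, b_ub, A_eq, b_eq, bounds) for the steady-state system.

    The system is ``N r = 0`` with irreversibility and (if present) the
    network's flux bounds, optionally intersected with ``extra`` rows and with
    the rates of ``knocked`` reactions fixed to zero. ``cap`` clips otherwise
    unbounded variables at +-cap (useful to keep FVA objectives finite).
    """
    n = net.n_reactions
    bounds = []
    for j in range(n):
        lo = net.lower_bound[j] if net.lower_bound is not None else -np.inf
        hi = net.upper_bound[j] if net.upper_bound is not None else np.inf
        if not net.reversible[j]:
            lo = max(lo, 0.0)
        if cap is not None:
            lo, hi = max(lo, -cap), min(hi, cap)
        bounds.append((None if np.isinf(lo) else lo, None if np.isinf(hi) else hi))
    knocked_idx = {k if isinstance(k, int) else net.reaction_index(k) for k in knocked}
    for j in knocked_idx:
        bounds[j] = (0.0, 0.0)
    A_ub = b_ub = None
    if extra is not None:
        extra.check_width(net)
        A_ub, b_ub = extra.coeffs, extra.rhs
    return A_ub, b_ub, net.stoich, np.zeros(net.n_metabolites), bounds


@dataclass
class TargetValidation:
    """Report of :func:`validate_target` (both facts are always stated)."""

    zero_in_polyhedron: bool
    polyhedron_nonempty: bool
    messages: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return (not self.zero_in_polyhedron) and self.polyhedron_nonempty


def validate_target(net: MetabolicNetwork,
                    target: LinearFluxConstraintSet) -> TargetValidation:
    """Check that a target polyhedron is blockable and non-empty.

    The zero flux vector must violate at least one target row (no knockout can
    remove r = 0 from the flux cone), and the target intersected with the
    steady-state constraints should be non-empty (otherwise there is nothing
    to block and enumeration returns no cut sets).
    """
    target.check_width(net)
    zero_in = bool(np.all(0.0 <= target.rhs + ZERO_TOL))
    A_ub, b_ub, A_eq, b_eq, bounds = flux_lp_parts(net, extra=target)
    nonempty = lp_feasible(A_ub, b_ub, A_eq, b_eq, bounds, n=net.n_reactions)
    msgs = []
    if zero_in:
        msgs.append("INVALID: the zero flux vector satisfies every target row; "
                    "no knockout can block it")
    if not nonempty:
        msgs.append("target polyhedron empty: no steady-state flux satisfies the "
                    "target rows; enumeration would return no MCSs")
    return TargetValidation(zero_in, nonempty, msgs)


# ---------------------------------------------------------------------------
# InterventionProblem
# ---------------------------------------------------------------------------

@dataclass
class InterventionProblem:
    """A complete cut-set search problem.

    Bundles the network, the target polyhedron to block, an optional desired
    polyhedron to preserve, the knockable reaction subset and the enumeration
    limits.
    """

    network: MetabolicNetwork
    target: LinearFluxConstraintSet
    desired: LinearFluxConstraintSet | None = None
    knockable: frozenset = None
    max_size: int = 5
    max_solutions: int | None = None
    time_limit_s: float | None = None

    def __post_init__(self):
        if self.knockable is None:
            self.knockable = frozenset(self.network.knockable_ids())
        else:
            self.knockable = frozenset(self.knockable)
        unknown = self.knockable - set(self.network.reaction_ids)
        if unknown:
            raise ValidationError(f"knockable reactions not in network: {sorted(unknown)}")
        if not 1 <= self.max_size <= len(self.knockable):
            raise ValidationError(
                f"max_size must be in [1, {len(self.knockable)}], got {self.max_size}")
        self.target.check_width(self.network)
        if self.desired is not None:
            self.desired.check_width(self.network)
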