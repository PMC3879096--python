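"""Brute-force ground truth and toy fixtures.

Everything the MILP path computes can be cross-checked at desk scale:

* :func:`enumerate_ems_bruteforce` finds all elementary-mode supports of a
  small all-irreversible network by subset enumeration with one feasibility
  LP per candidate support;
* :func:`minimal_hitting_sets` is a Berge-style incremental transversal,
  giving the minimal cut sets of a family of target mode supports;
* :func:`make_toy` / :func:`make_random` build the named fixtures used
  throughout the test suite and seeded random networks, so no downloads are
  ever needed.

The hitting-set route is valid for homogeneous targets (block every mode
through the target reactions); for inhomogeneous targets only the LP
soundness/minimality checks apply, which is why both oracles exist.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from ._lp import lp_feasible
from .network_model import MetabolicNetwork, ValidationError, split_reversible

_BRUTE_FORCE_MAX = 15


@dataclass
class ToyNetworkSpec:
    """Parameters of a random toy network (resampled until non-degenerate)."""

    seed: int = 0
    n_metabolites: int = 4
    n_reactions: int = 8
    reversible_fraction: float = 0.2
    density: float = 2.0

    def __post_init__(self):
        if self.n_reactions > 12:
            raise ValidationError("toy networks are capped at 12 reactions")


# ---------------------------------------------------------------------------
# Brute-force elementary modes
# ---------------------------------------------------------------------------

def _support_feasible(net: MetabolicNetwork, support: tuple[int, ...]) -> bool:
    """Is there a steady-state flux with r_i >= 1 on ``support`` and 0 elsewhere?"""
    n = net.n_reactions
    bounds = [(0.0, 0.0)] * n
    for j in support:
        bounds[j] = (1.0, None)
    return lp_feasible(A_eq=net.stoich, b_eq=np.zeros(net.n_metabolites),
                       bounds=bounds, n=n)


def enumerate_ems_bruteforce(net: MetabolicNetwork,
                             forbidden_pairs=()) -> list[frozenset]:
    """All EM supports of a small all-irreversible network, by enumeration.

    Candidate supports are visited in increasing size; a support is an EM
    support iff it admits a flux that is strictly positive exactly on it and
    no proper subset does (guaranteed by skipping supersets of accepted
    supports). ``forbidden_pairs`` (id pairs from split reversible reactions)
    discards the spurious two-cycle and its supersets.
    """
    if net.reversible.any():
        raise ValidationError("brute-force EM enumeration needs an "
                              "all-irreversible network")
    n = net.n_reactions
    if n > _BRUTE_FORCE_MAX:
        raise ValidationError(
            f"{n} reactions exceed the brute-force guard ({_BRUTE_FORCE_MAX}); "
            "use the MILP path")
    idx = {rid: j for j, rid in enumerate(net.reaction_ids)}
    bad_pairs = [frozenset((idx[a], idx[b])) for a, b in forbidden_pairs]
    found: list[frozenset] = []      # index sets
    for size in range(1, n + 1):
        for support in itertools.combinations(range(n), size):
            sset = frozenset(support)
            if any(p <= sset for p in bad_pairs):
                continue
            if any(f <= sset for f in found):
                continue
            if _support_feasible(net, support):
                found.append(sset)
    return [frozenset(net.reaction_ids[j] for j in f) for f in found]


def target_em_supports(net: MetabolicNetwork, target_reactions) -> list[frozenset]:
    """EM supports using at least one of ``target_reactions``.

    These are the target modes of the homogeneous intervention problem "block
    all flux through the target reactions"; their minimal hitting sets are
    its MCSs. Reversible networks are split internally and supports are
    reported on the original reactions (two-cycles discarded).
    """
    snet, pairing = split_reversible(net)
    ems = enumerate_ems_bruteforce(snet, forbidden_pairs=pairing.items())
    strip = {}
    for f, b in pairing.items():
        root = f[:-len("_fwd")]
        strip[f] = root
        strip[b] = root
    mapped, seen = [], set()
    for sup in ems:
        orig = frozenset(strip.get(r, r) for r in sup)
        if orig not in seen:
            seen.add(orig)
            mapped.append(orig)
    # distinct split EMs can project onto nested original supports; keep minimal
    minimal = [s for s in mapped if not any(o < s for o in mapped)]
    targets = set(target_reactions)
    return [s for s in minimal if s & targets]


# ---------------------------------------------------------------------------
# Berge transversal
# ---------------------------------------------------------------------------

def minimal_hitting_sets(sets, universe, max_size: int | None = None
                         ) -> list[frozenset]:
    """All inclusion-minimal subsets of ``universe`` hitting every member set.

    Berge's incremental algorithm: intersect the running transversal family
    with each hyperedge in turn, keeping only minimal sets. ``max_size``
    prunes partial transversals early (safe, since partial transversals only
    ever grow).
    """
    sets = [frozenset(s) for s in sets]
    if not sets:
        raise ValidationError("empty family has no hitting sets")
    universe = frozenset(universe)
    for s in sets:
        if not s & universe:
            raise ValidationError(
                f"untargetable mode: {sorted(s)} is disjoint from the universe")
    family: list[frozenset] = [frozenset()]
    for s in sets:
        hit = [h for h in family if h & s]
        miss = [h for h in family if not h & s]
        grown = {h | {e} for h in miss for e in (s & universe)}
        new = hit + [g for g in grown
                     if not any(h <= g for h in hit)]
        # keep inclusion-minimal only, then apply the size budget
        new = [g for g in new if not any(o < g for o in new)]
        if max_size is not None:
            new = [g for g in new if len(g) <= max_size]
        family = new
    return sorted(set(family), key=lambda f: (len(f), sorted(f)))


# ---------------------------------------------------------------------------
# Fixtures
# ---------------------------------------------------------------------------

_TOYS = {
    # linear pathway: one EM, fully coupled
    "chain": [("R1", "-> A", False),
              ("R2", "A -> B", False),
              ("R3", "B ->", False)],
    # two parallel routes A -> B: EMs {R1,R2,R4}, {R1,R3,R4}
    "diamond": [("R1", "-> A", False),
                ("R2", "A -> B", False),
                ("R3", "A -> B", False),
                ("R4", "B ->", False)],
    # branch point at A: EMs {R1,R2,R4}, {R1,R3,R5}
    "branch": [("R1", "-> A", False),
               ("R2", "A -> B", False),
               ("R3", "A -> C", False),
               ("R4", "B ->", False),
               ("R5", "C ->", False)],
    # one reversible interconversion inside a loop
    "cycle_rev": [("R1", "-> A", False),
                  ("R2", "A <-> B", True),
                  ("R3", "B -> C", False),
                  ("R4", "C -> A", False),
                  ("R5", "B ->", False)],
}


def make_toy(name: str) -> MetabolicNetwork:
    """Named toy fixtures: chain, diamond, branch, cycle_rev."""
    try:
        spec = _TOYS[name]
    except KeyError:
        raise ValidationError(
            f"unknown toy '{name}'; available: {sorted(_TOYS)}") from None
    return MetabolicNetwork.from_equations(spec)


def make_random(spec: ToyNetworkSpec) -> MetabolicNetwork:
    """Seeded random toy network admitting nonzero steady-state flux.

    The layout mimics a miniature metabolism: an import of the first
    metabolite, an export of the last, and random sparse internal columns
    with coefficients in {1, 2}. Candidates are resampled until the export
    reaction can carry flux, so every generated network has at least one
    usable pathway; generation is reproducible from the seed.
    """
    rng = np.random.default_rng(spec.seed)
    m, n = spec.n_metabolites, spec.n_reactions
    if n < 3:
        raise ValidationError("need at least 3 reactions (import, export, internal)")
    for _ in range(200):
        stoich = np.zeros((m, n))
        stoich[0, 0] = 1.0                      # import -> M0
        stoich[m - 1, n - 1] = -1.0             # export M_last ->
        for j in range(1, n - 1):
            k = max(2, min(m, rng.poisson(spec.density)))
            mets = rng.choice(m, size=k, replace=False)
            coefs = rng.choice([1.0, 2.0], size=k)
            signs = np.ones(k)
            signs[rng.integers(0, k):] = -1.0   # at least one product, one substrate
            rng.shuffle(signs)
            if (signs > 0).all() or (signs < 0).all():
                signs[0] *= -1
            stoich[mets, j] = coefs * signs
        reversible = np.zeros(n, dtype=bool)
        internal = rng.random(n - 2) < spec.reversible_fraction
        reversible[1:n - 1] = internal
        rids = [f"R{j + 1}" for j in range(n)]
        mids = [f"M{i}" for i in range(m)]
        net = MetabolicNetwork(stoich, rids, mids, reversible,
                               knockable=np.ones(n, dtype=bool))
        if _reaction_can_carry_flux(net, n - 1):
            return net
    raise ValidationError("could not sample a viable random network; "
                          "loosen the spec")


def _reaction_can_carry_flux(net: MetabolicNetwork, j: int) -> bool:
    n = net.n_reactions
    bounds = [(None if net.reversible[i] else 0.0, None) for i in range(n)]
    bounds[j] = (1.0, None)
    return lp_feasible(A_eq=net.stoich, b_eq=np.zeros(net.n_metabolites),
                       bounds=bounds, n=n)
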