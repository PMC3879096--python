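# Methods

## Model and scope

`mcskit` operates on constraint-based metabolic models: a stoichiometric
matrix *N* (m × n), a set *Irrev* of irreversible reactions, optional flux
bounds, and per-reaction tags (knockable / exchange / spontaneous). All flux
statements are about the steady-state cone `{r : N r = 0, r_i ≥ 0 (i ∈
Irrev)}`; kinetics and regulation are out of scope, except that a
user-supplied list of regulation-disabled reactions is honoured by removing
those reactions before analysis.

Intervention goals are linear: a *target* polyhedron `T r ≤ b` of flux
vectors that the knockouts must make infeasible, and optionally a *desired*
polyhedron `D r ≤ d` of which at least one vector must remain feasible. All
constraint inputs (`≤`, `≥`, `=`) are normalised to `≤` rows (`=` becomes two
rows) so that a single canonical form enters the dualization. Ratio
objectives such as minimal product yield are linearised as
`product_flux − Y_min · uptake_flux ≥ 0` with uptake measured as a
non-negative uptake-direction flux; this is exact for fixed-sign uptake.

A target is rejected up front when the zero flux vector satisfies all its
rows (no knockout can remove `r = 0` from the cone), and a warning-grade
report is produced when the target polyhedron is empty under the steady-state
constraints (enumeration would trivially return nothing).

## The dual certificate system

Deleting a reaction set S blocks the target iff the LP
`{N r = 0, irreversibilities, T r ≤ b, r_i = 0 (i ∈ S)}` is infeasible. The
Farkas certificate of that infeasibility solves

    (Nᵀu)_i + vp_i − vn_i + (Tᵀw)_i ≥ 0   (i irreversible)
    (Nᵀu)_i + vp_i − vn_i + (Tᵀw)_i = 0   (i reversible)
    bᵀw ≤ −c,   vp, vn, w ≥ 0,  u free

with `v = vp − vn` supported within S. Support-minimal certificates (in the
v-block) correspond one-to-one with minimal cut sets, so enumerating the
shortest elementary modes of this dual system — restricted to the vp/vn
support — enumerates the smallest MCSs. Non-knockable reactions have their
vp/vn upper bounds (equivalently their indicator variables) fixed to 0.

Sign conventions in such dual constructions are notoriously easy to garble,
so correctness is *gated* rather than trusted: for every enumerated support
the primal-side check (`certify_cut_set` / `is_minimal_cut_set`) must confirm
that the target LP is infeasible under the cut and becomes feasible when any
single member is dropped. The test suite enforces this for 100% of outputs on
fixtures and seeded random networks, including inhomogeneous targets.

Design choices made where the construction was genuinely open:

* the inhomogeneity row is an inequality `bᵀw ≤ −c`; an equality also passes
  the self-validation gate, the inequality is the laxer and numerically
  kinder choice;
* the scaling constant defaults to `c = 1`; any positive value yields the
  same cut-set family (verified for c ∈ {0.5, 1, 10} in the suite);
* reversible reactions are *not* split before dualization — their dual rows
  are equalities. Target rows constrain net fluxes, and a net-flux row
  describes the identical polyhedron whether or not a reversible reaction is
  split (`t_j r_j = t_j (r_fwd − r_bwd)` on the projection), so automatic
  splitting would change nothing for the linear rows this package accepts.
  Direction-specific goals (e.g. "block only the forward direction") should
  be posed on an explicitly split model (`split_reversible` is public API and
  reports a fwd/bwd pairing).

## MILP enumeration

Both elementary-mode search in an all-irreversible network and cut-set search
in the dual system are instances of one problem: enumerate the
support-minimal nonzero solutions of a linear system with non-negative
distinguished variables. One binary *indicator* per distinguished variable
carries the semantics `z = 1 ⇔ x ≥ c`, `z = 0 ⇔ x = 0` (legitimate because
solutions are scalable: any nonzero solution can be scaled until its support
entries reach c). Mutual-exclusion rows `z_s + z_t ≤ 1` forbid the spurious
two-cycle of a split reversible pair and simultaneous vp/vn activity. Found
supports are excluded, together with all their supersets, by integer cuts
`Σ_{support} z ≤ |support| − 1`, which are kept for the remainder of the run;
enumerating sizes in non-decreasing order then guarantees that every reported
support is minimal.

Two schemes:

* **iterative** — minimise Σz, record the optimum, add its integer cut,
  repeat until infeasibility or a limit. Optima are non-decreasing in size
  because constraints only accumulate.
* **fixed-size** — one minimisation finds the smallest size s; afterwards
  each size class s, s+1, ... is swept as a pure feasibility problem with the
  size row fixed (`sz_lb = sz_ub = s`), and the class's exclusion rows are
  committed only after the class is complete. Solvers with a solution pool
  can sweep a class in one call; HiGHS has no pool, so the class is swept by
  repeated feasibility solves with per-solution exclusion rows — a
  documented fallback with identical output, enforced equal to the iterative
  scheme on every test instance.

Indicator semantics are realised in two interchangeable modes:

* `bigm` (default) — linking rows `x ≤ M z` and `x ≥ c z` with `M = 1e5`
  (configurable). Because the MILP solver's feasibility tolerances are not
  adjustable through `scipy.optimize.milp`, rows scaled by M can mask a
  marginal infeasibility; every candidate assignment is therefore
  re-certified by an exact M-free LP (variables of active binaries bounded
  below by c, all others fixed to 0). A candidate failing certification is
  removed with a *no-good* cut on its exact binary assignment — an integer
  cut would also exclude genuine supersets — and the solve repeats. Returned
  solutions are consequently always LP-certified and M-independent.
* `indicator` — exact, M-free branch-and-fix: depth-first fixing of binaries
  (0 → variable upper bound 0; 1 → lower bound c; free → non-negative, a
  valid relaxation), pruning by LP infeasibility, by the size budget, and by
  exclusion rows; leaves are verified with the exact support LP. This is the
  mechanism solvers with native indicator constraints use internally, here
  made explicit over an LP oracle.

Determinism: HiGHS runs single-threaded and deterministically, the
branch-and-fix search breaks ties by position, so repeated runs reproduce the
same output order. Within a size class the order is solver-dependent and
treated as meaningless; families are compared as sets. The `threads` and
`seed` knobs are recorded for provenance; the bundled backend ignores them.

Status semantics of a run: `complete` — every size up to `size_ub` fully
enumerated (an empty result is still complete); `infeasible` — exhausted with
no solution although the size budget covered the whole support space;
`solution_limit` / `time_limit` — stopped early, with the interrupted size
class flagged incomplete in `size_complete` (partial results are never
presented as complete).

## Preprocessing

* **Blocked reactions** (FVA): per reaction, maximise then minimise its rate
  under the steady-state system plus an optional context constraint set; both
  extrema within 1e-7 of zero ⇒ blocked. The maximisation is skipped as a
  witness shortcut when it already exceeds the tolerance, and otherwise
  unbounded objectives are capped at ±1e6 (blockedness only needs a nonzero
  witness). An infeasible context is an error, not an all-blocked verdict.
* **Compression**: reactions whose rows in a nullspace basis of N are
  proportional with a fixed nonzero factor carry proportional flux in every
  steady state and are lumped into one reaction (the classical enzyme-subset
  criterion); the lumped column is the ratio-weighted sum of member columns,
  a lump is knockable iff a member is, and constraint rows are mapped by the
  same ratios, so the compressed problem is in exact linear correspondence
  with the original. Lumps whose irreversible members demand opposite
  orientations can carry no flux; they indicate blocked reactions and are
  rejected with an instruction to run FVA first. Parallel reactions
  (identical columns) are *not* merged — they are not flux-coupled, and their
  members appear as alternatives in distinct cut sets. Cut sets found in the
  compressed network are decompressed by the Cartesian product over each
  lump's knockable members; the suite checks the compressed and uncompressed
  paths return identical families.
* **Desired-essential reactions**: knockable reactions whose single deletion
  already empties the desired polyhedron can never occur in a cMCS and are
  excluded from the search universe up front when cMCS filtering is
  requested.

## cMCS filtering and strain metrics

Filtering runs after enumeration by default (one feasibility LP per cut set
is cheap relative to the MILP search); a streaming check per found solution
gives the same result with different scheduling. LP numerical failures raise
an explicit indeterminate error — a cut set is never silently promoted to
cMCS. Metrics per design: maximal growth rate (LP), minimal guaranteed
product yield at the stated maximal substrate uptake (worst-case LP over all
mutant behaviours — no optimal-growth assumption), and substrate-specific
productivity. SSP is the product of growth rate and yield; since the flux
state at which a mutant's SSP is quoted is a convention, it is evaluated here
at the mutant's maximum-growth state with the worst-case yield at that state,
which makes the reported value a guarantee rather than an optimistic bound.

## Oracle and synthetic data

The brute-force oracle enumerates EM supports of networks with ≤ 15 reactions
by subset enumeration with one feasibility LP per candidate (increasing size,
superset skipping), and computes MCSs as Berge-transversal minimal hitting
sets of the target EMs. The hitting-set route is valid for homogeneous
targets ("block all flux through these reactions"); inhomogeneous targets are
validated through the LP soundness/minimality gate instead, which keeps the
oracle honest about its validity domain.

Random toy networks emulate a miniature metabolism: an import of the first
metabolite, an export of the last, and sparse internal columns (expected two
nonzeros, stoichiometric coefficients 1 or 2, ~25% reversible by default);
candidates are resampled until the export reaction can carry steady-state
flux. Sizes are capped at 12 reactions so the brute-force oracle stays
exhaustive; the test and acceptance runs use 20 seeded networks of 6–10
reactions with cut sets up to size 3, sizes at which complete enumeration
and all cross-checks finish in well under a minute. What these fixtures do
not emulate: genome-scale dimensions, realistic biomass compositions, flux
bound structure, or gene–protein–reaction mappings — passing tests certify
the algorithmic machinery (duality, enumeration completeness, compression
invertibility), not biological conclusions about any real organism.

## Numerical choices

* zero/coupling tolerance 1e-9 (matches LP feasibility tolerances);
  FVA blockedness tolerance 1e-7; indicator threshold c = 1; big-M 1e5.
* Tie-breaks inside a size class are solver order; canonical output order
  (size, then lexicographic members) is applied at the CLI boundary for
  diffability.
* Degenerate inputs: empty constraint files, unblockable targets, empty
  desired polyhedra, unknown identifiers and infeasible contexts raise typed
  errors with the offending record named; the empty cut set is never
  returned (the at-least-one-active row excludes it).

## Known limitations

* Inhomogeneous flux bounds participate only through target/desired rows or
  preprocessing contexts; boxes are not dualized separately.
* The big-M mode inherits M-sensitivity in principle; the lazy LP
  certification removes unsound outputs, and an M chosen too small could
  only cause missed certificates (none observed at 1e5 on the bundled
  problem sizes — the branch-and-fix mode is the M-free reference).
* The integrated MILP+LP formulation that would compute cMCSs in one model
  is deliberately not implemented; filtering after enumeration is simpler
  and the LP stage is not the bottleneck.
* Reaction-level cut sets only; translating to gene knockouts requires
  gene–protein–reaction associations outside this package's scope.
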