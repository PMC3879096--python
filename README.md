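# mcskit

Enumeration of the smallest **minimal cut sets** (MCSs) and **constrained
MCSs** (cMCSs) in stoichiometric metabolic networks, by computing k-shortest
**elementary modes** (EMs) of a Farkas-dual system with mixed-integer linear
programming.

## The problem

A metabolic network with stoichiometric matrix *N* (m metabolites × n
reactions) operates at steady state in the flux cone

    {r : N r = 0,  r_i ≥ 0 for i ∈ Irrev}.

A metabolic engineer or geneticist often wants to *abolish* some behaviour: all
flux vectors in a **target flux polyhedron** `T r ≤ b` (growth above a
threshold, product yield below a floor, ...). A **cut set** is a set of
reaction deletions (rates forced to 0) after which no steady-state flux
satisfies the target constraints; it is a **minimal** cut set when no proper
subset suffices. A **constrained** MCS additionally keeps a **desired flux
polyhedron** `D r ≤ d` non-empty — the cell must still be able to grow, so
cMCSs are directly usable as growth-coupled strain designs and MCSs against a
growth target are the network's synthetic lethals.

Enumerating MCSs through the classical route (all EMs, then minimal hitting
sets) is infeasible at genome scale. `mcskit` instead exploits a duality: a
cut set S blocks the target exactly when the LP

    N r = 0,  r_i ≥ 0 (i ∈ Irrev),  T r ≤ b,  r_i = 0 (i ∈ S)

is infeasible, and by the Farkas lemma that infeasibility has a certificate
(u, v, w) solving

    (Nᵀu)_i + vp_i − vn_i + (Tᵀw)_i  ≥ 0   (i irreversible)
                                      = 0   (i reversible)
    bᵀw ≤ −c,   vp, vn, w ≥ 0,  u free,  c > 0 arbitrary,

with v = vp − vn supported inside S. The support-minimal solutions of this
dual system — its elementary modes, restricted to the v variables — are
exactly the MCSs of the primal network. Smallest MCSs are therefore the
*shortest* EMs of the dual system, which a MILP finds directly: one binary
indicator per vp/vn (binary = 1 ⇔ variable ≥ c), mutual exclusion
`zp_i + zn_i ≤ 1`, a size-control row on Σ(zp+zn), and *integer cuts*
`Σ_{i∈S}(zp_i+zn_i) ≤ |S|−1` that exclude each found support and its
supersets. Two schemes are provided: **iterative** (minimise Σz, record,
exclude, repeat) and **fixed-size** (find the minimum size once, then sweep
each size class as pure feasibility problems, committing the class's
exclusion rows only when it is complete). cMCSs are obtained by one
feasibility LP per MCS against the desired polyhedron.

Around the core the package provides LP-based preprocessing (blocked-reaction
removal by flux variability analysis, lumping of fully coupled reaction
subsets with Cartesian decompression of the resulting cut sets),
strain-design metrics (maximal growth rate, minimal guaranteed yield,
substrate-specific productivity), a brute-force oracle (exhaustive EM
enumeration + Berge transversal) for independent verification, and a CLI.

MILPs are solved with HiGHS (via `scipy.optimize.milp`) using a big-M
realisation of the indicators that is lazily certified by exact M-free LPs;
an alternative `indicator` mode realises exact indicator semantics by LP-based
branch-and-fix. Both modes give identical families.

## Worked example

```python
import mcskit as mk

net = mk.make_toy("branch")           # R1: ->A; R2: A->B; R3: A->C; R4: B->; R5: C->
net.knockable[:] = True
target  = mk.LinearFluxConstraintSet.flux_bound(net, "R5", ">=", 1, label="target")
desired = mk.LinearFluxConstraintSet.flux_bound(net, "R4", ">=", 1, label="desired")

problem = mk.InterventionProblem(net, target, desired=desired, max_size=3)
mcss  = mk.smallest_mcs(problem)
cmcss = mk.filter_cmcs(net, desired, mcss)
print([c.sorted() for c in mcss])     # [('R1',), ('R3',), ('R5',)]
print([c.sorted() for c in cmcss])    # [('R3',), ('R5',)]
```

The three MCSs `{R1}`, `{R3}`, `{R5}` each make flux through R5 impossible
and are minimal. Only `{R3}` and `{R5}` survive the desired-behaviour filter:
cutting the substrate import R1 also kills the desired flux through R4, so it
is an MCS but not a cMCS. The same computation from the shell:

```sh
mcskit cmcs --model branch.tsv --target target.txt --desired desired.txt \
        --max-size 3 --out branch_run
```

writes `branch_run.cutsets.tsv` (members, size, cMCS flag, metrics) and
`branch_run.meta.json` (model hash, flags, per-size counts and completion
status).

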