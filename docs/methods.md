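# Methods

## Model

The wrist is idealized as a planar hinge in the neutral position: one degree
of freedom per motion direction (flexion, extension, radial deviation, ulnar
deviation), muscle lines of action parallel to the forearm, and a single
moment-equilibrium equation

M = Σᵢ dᵢ·Fᵢ,  Fᵢ ≥ 0,

where dᵢ (mm) is the moment arm of muscle i for the active direction and M
(N·mm) the external moment, the product of the applied force and its lever
arm. Only the agonist group of a direction is modeled; antagonist
co-contraction, joint reaction forces, contact surfaces, ligaments, wrist
angle dependence and force–length/velocity properties are out of scope. The
forearm's own weight is neglected. With m > 1 agonists the equation is
statically indeterminate and a selection criterion closes the model.

Canonical units are N, mm, N·mm and degrees everywhere in memory; tables or
configs using cm or N·cm are converted at the I/O boundary (1 cm = 10 mm,
1 N·m = 100 N·cm = 1000 N·mm).

## Anatomy

PCSA of a parallel-fibered muscle is mass/(ρ·ℓ) with ρ = 0.0010567 g/mm³
and ℓ the optimum fiber length (mm); pennate muscles are projected by
cos θ. Peak force is PCSA·σ with specific tension σ reported between 0.2
and 1.0 N/mm² under isometric conditions; values outside that band are
accepted with a warning.

The packaged literature compilation keeps one record per (muscle, source).
Cells printed as 0.00 in such compilations mean "not reported" and are
loaded as missing, never as zeros — a literal zero fiber length or PCSA
would silently corrupt any statistic computed downstream. Reported PCSA
and PCSA recomputed from mass/fiber length frequently disagree (sources
differ in whether they applied the cos θ projection); records carry a
provenance tag and both routes are exposed rather than reconciled. When a
pennation angle is absent it defaults to 0°, reducing the pennate formula
to the parallel one.

## Solvers

**Weighted sum.** Weights wᵢ = PCSAᵢ/ΣPCSA and a single scalar F solve
M = Σ dᵢ·wᵢ·F. The `two_decimal` rounding mode reproduces the hand
calculation convention used in the worked example: weights rounded to two
decimals and each product (arm in cm)·wᵢ rounded to two decimals before
summing. That mode intentionally violates exact equilibrium by the rounding
error (~0.2 % here); the residual is reported in the solution rather than
suppressed, and the exact mode is the default.

**Polynomial stress cost.** Minimizing Σ(Fᵢ/PCSAᵢ)ⁿ under the linear
constraint dispatches on n: n = 1 is solved as a linear program
(scipy/HiGHS). For n > 1 the optimum is interior on the positive-arm subset
(the marginal cost of stress vanishes at zero), so the solver runs a damped
Newton iteration on the KKT stationarity system in stress variables —
n·sᵢⁿ⁻¹ = λ·dᵢ·PCSAᵢ with the equilibrium constraint — started from the
equal-stress point. For n = 2 the system is linear and one step solves the
quadratic program exactly; other exponents converge in a handful of
iterations. Muscles with a zero arm are fixed at zero force. Any real
n ≥ 1 is accepted. The analytic interior solution
Fᵢ = M·cᵢ/Σdⱼcⱼ, cᵢ = dᵢ^{1/(n−1)}·PCSAᵢ^{n/(n−1)}, is kept as a separate
oracle (`cb_interior_closed_form`) and the tests require Newton-vs-closed-form
agreement to 1e-9 relative.

LP degeneracy: when two muscles tie on dᵢ·PCSAᵢ the n = 1 optimum is
non-unique; the implementation returns the first-index vertex
deterministically and flags non-uniqueness in the diagnostics.

**Minimax stress.** Solved as the epigraph linear program min σ s.t.
Fᵢ ≤ PCSAᵢ·σ, Σ dᵢFᵢ = M, F ≥ 0. LP vertices can leave slack muscles below
the optimal stress level; on all-positive-arm instances the canonical
equal-stress representative Fᵢ = σ*·PCSAᵢ is returned (same objective
value).

No upper bound Fᵢ ≤ peak force is imposed by default: the worked examples
never bind it and the peak-force formula is treated as an output, not a
constraint.

Tolerances: equilibrium violation ≤ 1e-8·max(1, M) inside solvers
(packaged solutions are additionally checked at 1e-6·max(1, M)); Newton
stationarity ≤ 1e-10 relative. Forces are kept at full precision and
rounded only for display.

**Brute-force oracle.** For m ≤ 4, the equality constraint eliminates one
positive-arm force and the remaining forces are gridded over [0, M/dᵢ]
(default 101 points/axis), followed by three compounding local zoom passes
around the incumbent. It certifies any objective to well under 1 % of total
force at desk scale and is used only as an independent check.

## Sensitivity analysis

Peak force PCSA·σ and moment contribution PCSA·σ·d are multilinear and
non-decreasing in each input, so envelope extremes over a box of ranges are
attained at the corners; the analytic corner rule is the primary route and
the full-factorial grid (default 11 points/axis, adequate for multilinear
maps) is retained for plotting and as the exhaustive cross-check in tests.
Total-moment envelopes sum the per-muscle extremes, valid because each term
attains its extreme independently. The motion-to-muscle map comes from the
packaged ranges table (flexion: FCR, PL, FCU; extension: ECU, ECRB, ECRL;
radial: FCR, PL, ECRB, ECRL; ulnar: FCU, ECU); directions a muscle does not
serve are absent from its ranges, never zero-filled. One-at-a-time sweeps
fix all parameters at a baseline (midpoint by default) and vary one across
its range; the induced span of the total moment ranks parameter influence.

## Synthetic instances

The generator draws PCSAs and arms uniformly within configurable bounds
whose defaults are the global spans of the packaged ranges table
(PCSA 30–850 mm², arms 0–30 mm, tension 0.2–1.0 N/mm²) with the worked
example's 10 000 N·mm moment; only ranges, not distributions, are reported
in the anatomy literature, so uniform is the least-informative choice and
the distribution is a config hook. At least one strictly positive arm is
guaranteed (redraw), all randomness flows through a single seeded
numpy Generator, and a fixed seed reproduces instances exactly across runs.

What the generator does *not* emulate: correlations between PCSA and moment
arm within a muscle, anthropometric scaling, antagonist groups, or
multi-joint coupling. Passing tests therefore certify the optimization and
sweep machinery on the model's own assumptions, not the physiological
fidelity of the planar wrist idealization.

## Validation scale

The test suite and the acceptance script run the worked three-extensor
example exactly, plus 100 seeded random 3-muscle instances for the
solver-vs-oracle, equilibrium/non-negativity and exponent-monotonicity
properties, and 7–11-point grids for the sweep cross-checks; the whole
suite completes in a few seconds on one CPU. These sizes were chosen as
comfortable desk scale for a 3–6 muscle planar model.

## Known limitations

- Single moment equation: no simultaneous multi-direction equilibrium.
- The minimax equal-stress representative assumes a common stress level is
  feasible, which holds when every agonist has a positive arm.
- The two-decimal weighted-sum mode is a presentation convention of the
  worked example, not a recommended computation path.
- The oracle is exponential in muscle count and capped at m = 4.
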