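# wristopt

Static muscle-force estimation for a planar model of the human wrist.

More muscles cross the wrist than there are equilibrium equations: when a
load on the hand puts a moment `M` on the joint, the single planar balance

```
M = Σᵢ dᵢ·Fᵢ ,   Fᵢ ≥ 0
```

(with `dᵢ` the moment arm of muscle `i`) admits infinitely many force
distributions — the *muscle redundancy problem*. This package implements the
standard selection criteria used in musculoskeletal modeling and the
parameter bookkeeping around them, for the six primary wrist movers (FCR,
PL, FCU, ECU, ECRB, ECRL):

- **Weighted sum** — each muscle carries a share of one common force scalar
  proportional to its physiological cross-sectional area (PCSA),
  `Fᵢ = wᵢ·F` with `wᵢ = PCSAᵢ/ΣPCSA`; a substitution, not an optimization.
- **Polynomial stress cost (Crowninshield–Brand)** — minimize
  `U = Σᵢ (Fᵢ/PCSAᵢ)ⁿ` subject to equilibrium: a linear program for `n = 1`,
  a quadratic program for `n = 2`, a nonlinear program for larger `n`.
  Larger exponents spread load more evenly (the fatigue argument).
- **Minimax stress (An et al.)** — minimize `max σᵢ` with `σᵢ = Fᵢ/PCSAᵢ`;
  with all arms positive this equalizes stresses at
  `σ* = M / Σ dᵢ·PCSAᵢ`.

Around the solvers: PCSA from mass and optimum fiber length
(`PCSA = m·cosθ/(ρ·ℓ)`, density ρ = 0.0010567 g/mm³), peak force
`PFC = PCSA·σ` with specific tension σ ∈ [0.2, 1.0] N/mm², packaged
literature tables and min/max parameter ranges, a sensitivity engine that
turns those ranges into force/moment envelopes, and a seeded random-instance
generator plus a brute-force grid oracle for validation.

## Worked example

The canonical load case: a 100 N load at a 10 cm lever arm (10 N·m), held
by the three extensors with PCSAs 480/450/370 mm² and mean extension moment
arms 6/12/7 mm.

```python
>>> from wristopt import worked_example_instance, solve_cb, solve_minimax
>>> inst = worked_example_instance()
>>> solve_cb(inst, 2).forces.round(2)
array([313.03, 550.24, 216.99])
>>> solve_minimax(inst).forces.round(2)
array([441.58, 413.98, 340.39])
```

Running `python examples/worked_example.py` (or the CLI `wristopt demo`)
prints the full comparison:

```
                 ECU    ECRB    ECRL  max_stress_N_mm2
weighted_sum  440.48  416.67  333.33             0.926
cb(n=1)         0.00  833.33    0.00             1.852
cb(n=2)       313.03  550.24  216.99             1.223
cb(n=3)       377.05  484.03  275.62             1.076
minimax       441.58  413.98  340.39             0.920
```

Forces are in newtons. The linear cost loads ECRB alone (it maximizes
`dᵢ·PCSAᵢ`, so it buys the most moment per unit stress); increasing the
exponent distributes load across the group; minimax ends with every muscle
at the same stress, 0.92 N/mm². The weighted-sum row uses the two-decimal
substitution convention (`--rounding 2dp`), giving the total `F` = 1190.48 N
from PCSA shares 36.9/34.6/28.5 %.

Other entry points: `examples/pcsa_and_peak_force.py` (anatomical tables →
PCSA → peak-force bounds), `examples/sensitivity_sweep.py` (moment envelopes
and parameter influence ranking), `examples/random_instances_vs_oracle.py`
(solver validation against the grid oracle). The `wristopt` CLI mirrors
these as `pcsa`, `solve`, `sweep`, `generate`, `demo`, `oracle-check`.

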