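"""Redundancy-resolution strategies for the planar wrist moment equation.

Four strategies distribute a joint moment M over m muscles with moment arms
d_i and cross-sectional areas PCSA_i, all subject to sum(d_i * F_i) = M and
F_i >= 0:

``solve_weighted_sum``
    PCSA-fraction weights: every muscle receives a share of one common force
    scalar proportional to its PCSA.  Not an optimization; a direct
    substitution that renders the single equation determinate.
``solve_cb``
    Minimum of the polynomial stress cost sum((F_i/PCSA_i)^n) — a linear
    program for n = 1, a quadratic program for n = 2 and a general nonlinear
    program for other n > 1.  Larger exponents spread load more evenly
    across the agonists (the fatigue-minimization rationale).
``solve_minimax``
    Minimum of the largest muscle stress; when every agonist has a positive
    arm this equalizes stresses at sigma* = M / sum(d_i * PCSA_i).

Verification routes kept deliberately separate from the solvers:

``cb_interior_closed_form``
    Analytic stationarity solution F_i = M c_i / sum(d_j c_j) with
    c_i = d_i^(1/(n-1)) * PCSA_i^(n/(n-1)), valid for n > 1 on all-positive
    arm instances.
``brute_force_oracle``
    Feasible-set grid search (equality constraint eliminates one force)
    with local zoom refinement; works for any objective at desk scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from scipy.optimize import linprog

from .exceptions import (
    InfeasibleInstanceError,
    InvalidParameterError,
    SolverConvergenceError,
)
from .statics import JointInstance, equilibrium_residual, residual_tolerance

#: Relative equilibrium tolerance accepted from a solver, vs max(1, M).
CONSTRAINT_RTOL = 1e-8
#: Relative stationarity tolerance of the Newton-KKT iteration.
STATIONARITY_RTOL = 1e-10


@dataclass
class ForceSolution:
    """Per-muscle forces and stresses returned by one strategy.

    ``stresses`` are F_i / PCSA_i in N/mm^2; ``residual`` is the signed
    equilibrium defect M - sum(d_i F_i) in N*mm.
    """

    method: str
    forces: np.ndarray  # N
    stresses: np.ndarray  # N/mm^2
    objective_value: float
    residual: float
    diagnostics: str = ""
    names: tuple[str, ...] = ()

    @property
    def total_force(self) -> float:
        return float(np.sum(self.forces))

    @property
    def max_stress(self) -> float:
        return float(np.max(self.stresses))

    def as_records(self) -> list[dict]:
        """Tidy rows (muscle, force_N, stress_N_mm2, ...) for serialization."""
        names = self.names or tuple(f"m{i+1}" for i in range(len(self.forces)))
        return [
            {
                "muscle": name,
                "force_N": float(f),
                "stress_N_mm2": float(s),
                "method": self.method,
                "objective": self.objective_value,
                "residual": self.residual,
            }
            for name, f, s in zip(names, self.forces, self.stresses)
        ]


def _package(
    method: str,
    instance: JointInstance,
    forces: np.ndarray,
    objective: float,
    diagnostics: str = "",
    check_equilibrium: bool = True,
) -> ForceSolution:
    forces = np.maximum(np.asarray(forces, dtype=float), 0.0)
    residual = equilibrium_residual(forces, instance)
    if check_equilibrium:
        tol = max(residual_tolerance(instance, CONSTRAINT_RTOL), 1e-9)
        if abs(residual) > tol:
            raise SolverConvergenceError(
                f"{method}: equilibrium violated by {residual:.3e} N*mm", method
            )
    return ForceSolution(
        method=method,
        forces=forces,
        stresses=forces / instance.pcsa_array(),
        objective_value=float(objective),
        residual=residual,
        diagnostics=diagnostics,
        names=instance.names,
    )


# ---------------------------------------------------------------------------
# Weighted-sum method
# ---------------------------------------------------------------------------

def solve_weighted_sum(
    instance: JointInstance, rounding: str = "none"
) -> ForceSolution:
    """Distribute the moment by PCSA-fraction weights.

    Each muscle carries F_i = w_i * F with w_i = PCSA_i / sum(PCSA); the
    common scalar F solves M = sum(d_i * w_i) * F.

    ``rounding="two_decimal"`` reproduces the hand substitution used in the
    worked wrist-extension example: weights rounded to two decimals and each
    product (arm in cm) x weight rounded to two decimals before summing.
    That mode intentionally carries the rounding error into the equilibrium
    residual, which is reported rather than enforced.
    """
    if rounding not in ("none", "two_decimal"):
        raise InvalidParameterError(f"unknown rounding mode {rounding!r}")
    pcsa = instance.pcsa_array()
    arms = instance.arm_array()
    weights = pcsa / pcsa.sum()

    if rounding == "two_decimal":
        weights_r = np.round(weights, 2)
        coeff_cm = np.round((arms / 10.0) * weights_r, 2)  # cm units, 2 dp
        denom_cm = coeff_cm.sum()
        if denom_cm <= 0:
            raise InfeasibleInstanceError("all arm-weight products are zero")
        total = (instance.moment / 10.0) / denom_cm  # N*cm / cm
        forces = weights_r * total
        return _package(
            "weighted_sum",
            instance,
            forces,
            objective=total,
            diagnostics="two-decimal substitution; equilibrium holds only to rounding",
            check_equilibrium=False,
        )

    denom = float(arms @ weights)
    if denom <= 0:
        raise InfeasibleInstanceError("sum(d_i * w_i) must be positive")
    total = instance.moment / denom
    return _package("weighted_sum", instance, weights * total, objective=total)


def pcsa_shares(instance: JointInstance) -> np.ndarray:
    """Each muscle's percentage of the summed cross-sectional area."""
    pcsa = instance.pcsa_array()
    return 100.0 * pcsa / pcsa.sum()


# ---------------------------------------------------------------------------
# Polynomial stress cost (Crowninshield-Brand family)
# ---------------------------------------------------------------------------

def cb_objective(pcsa: Sequence[float], n: float) -> Callable[[np.ndarray], np.ndarray]:
    """Vectorized cost sum((F_i/PCSA_i)^n) over the last axis."""
    p = np.asarray(pcsa, dtype=float)

    def cost(forces: np.ndarray) -> np.ndarray:
        f = np.asarray(forces, dtype=float)
        return np.sum((f / p) ** n, axis=-1)

    return cost


def max_stress_objective(pcsa: Sequence[float]) -> Callable[[np.ndarray], np.ndarray]:
    """Vectorized largest muscle stress over the last axis."""
    p = np.asarray(pcsa, dtype=float)

    def cost(forces: np.ndarray) -> np.ndarray:
        f = np.asarray(forces, dtype=float)
        return np.max(f / p, axis=-1)

    return cost


def _solve_cb_lp(instance: JointInstance) -> ForceSolution:
    pcsa = instance.pcsa_array()
    arms = instance.arm_array()
    res = linprog(
        c=1.0 / pcsa,
        A_eq=arms.reshape(1, -1),
        b_eq=[instance.moment],
        bounds=[(0, None)] * instance.m,
        method="highs",
    )
    if res.status == 2:
        raise InfeasibleInstanceError("linear program infeasible")
    if not res.success:
        raise SolverConvergenceError("linear program failed", res.message)

    forces = res.x
    diagnostics = "unique vertex"
    # d_i * PCSA_i is moment per unit cost; ties make the optimum non-unique.
    score = arms * pcsa
    best = score.max()
    winners = np.flatnonzero(score >= best * (1 - 1e-12))
    if len(winners) > 1:
        j = int(winners[0])
        forces = np.zeros(instance.m)
        forces[j] = instance.moment / arms[j]
        diagnostics = (
            "non-unique optimum (tie on d_i*PCSA_i); first-index vertex returned"
        )
    objective = float(np.sum(forces / pcsa))
    return _package("cb(n=1)", instance, forces, objective, diagnostics)


def _newton_kkt(
    stresses: np.ndarray,
    weights: np.ndarray,  # d_i * PCSA_i (moment per unit stress)
    moment: float,
    n: float,
    max_iter: int = 200,
) -> tuple[np.ndarray, int]:
    """Damped Newton on the stationarity system of the stress-cost problem.

    Variables are the muscle stresses s_i (> 0 at the optimum for n > 1) and
    the Lagrange multiplier lam:

        n * s_i^(n-1) - lam * w_i = 0,   sum(w_i * s_i) = M.

    For n = 2 the system is linear and one step solves the quadratic program
    exactly; for other n the iteration is a general nonlinear solve.
    """
    m = len(weights)
    s = np.maximum(stresses, 1e-12 * max(moment, 1.0))
    lam = float(n * s[0] ** (n - 1) / weights[0])
    scale = max(1.0, moment)
    for it in range(max_iter):
        g = n * s ** (n - 1) - lam * weights
        h = moment - float(weights @ s)
        g_scale = max(1.0, abs(lam) * float(weights.max()), n * float(s.max()) ** (n - 1))
        if np.max(np.abs(g)) <= STATIONARITY_RTOL * g_scale and abs(h) <= CONSTRAINT_RTOL * scale:
            return s, it
        # KKT Jacobian: diag(n(n-1)s^(n-2)) for s, -w for lam; constraint row -w.
        diag = n * (n - 1) * s ** (n - 2)
        J = np.zeros((m + 1, m + 1))
        J[:m, :m] = np.diag(diag)
        J[:m, m] = -weights
        J[m, :m] = -weights
        rhs = -np.concatenate([g, [-h]])
        try:
            step = np.linalg.solve(J, rhs)
        except np.linalg.LinAlgError as exc:
            raise SolverConvergenceError("singular KKT system", str(exc)) from exc
        # Damp to keep stresses strictly positive (fractional n needs s > 0).
        ds = step[:m]
        alpha = 1.0
        neg = ds < 0
        if np.any(neg):
            alpha = min(1.0, 0.95 * float(np.min(-s[neg] / ds[neg])))
        s = s + alpha * ds
        lam = lam + alpha * step[m]
    raise SolverConvergenceError(
        f"Newton-KKT did not converge in {max_iter} iterations", f"n={n}"
    )


def solve_cb(instance: JointInstance, n: float) -> ForceSolution:
    """Minimize sum((F_i/PCSA_i)^n) subject to equilibrium and F >= 0.

    Dispatch: n = 1 linear program (HiGHS); n = 2 quadratic program (one
    exact Newton-KKT step); n > 1 otherwise general nonlinear solve (damped
    Newton on the KKT conditions, started from the equal-stress point).
    Muscles with a zero arm contribute no moment at positive cost and are
    fixed at zero force.
    """
    if n < 1:
        raise InvalidParameterError("exponent n must be >= 1")
    if instance.moment == 0:
        return _package(f"cb(n={n:g})", instance, np.zeros(instance.m), 0.0)
    if n == 1:
        return _solve_cb_lp(instance)

    pcsa = instance.pcsa_array()
    arms = instance.arm_array()
    active = arms > 0
    w = (arms * pcsa)[active]
    # Equal-stress start: robust and strictly feasible.
    s0 = np.full(w.shape, instance.moment / w.sum())
    s_act, iters = _newton_kkt(s0, w, instance.moment, n)
    forces = np.zeros(instance.m)
    forces[active] = s_act * pcsa[active]
    objective = float(np.sum((forces / pcsa) ** n))
    tag = "QP Newton-KKT" if n == 2 else "NLP Newton-KKT"
    return _package(
        f"cb(n={n:g})", instance, forces, objective, f"{tag}, {iters} iterations"
    )


def cb_interior_closed_form(instance: JointInstance, n: float) -> np.ndarray:
    """Analytic interior minimizer of the stress-cost problem for n > 1.

    From stationarity of the Lagrangian, F_i = M c_i / sum(d_j c_j) with
    c_i = d_i^(1/(n-1)) * PCSA_i^(n/(n-1)).  Requires every arm positive
    (interior solution); kept separate from :func:`solve_cb` as its oracle.
    """
    if n <= 1:
        raise InvalidParameterError("closed form requires n > 1")
    arms = instance.arm_array()
    if np.any(arms <= 0):
        raise InvalidParameterError("closed form requires all moment arms > 0")
    pcsa = instance.pcsa_array()
    c = arms ** (1.0 / (n - 1.0)) * pcsa ** (n / (n - 1.0))
    return instance.moment * c / float(arms @ c)


# ---------------------------------------------------------------------------
# Minimax stress
# ---------------------------------------------------------------------------

def minimax_equal_stress(instance: JointInstance) -> float:
    """Equal-stress level sigma* = M / sum(d_i * PCSA_i) (all-positive arms)."""
    denom = float(instance.arm_array() @ instance.pcsa_array())
    if denom <= 0:
        raise InfeasibleInstanceError("sum(d_i * PCSA_i) must be positive")
    return instance.moment / denom


def solve_minimax(instance: JointInstance) -> ForceSolution:
    """Minimize the largest muscle stress subject to equilibrium and F >= 0.

    Solved as the epigraph linear program: min sigma with
    F_i - PCSA_i * sigma <= 0, sum(d_i F_i) = M, F >= 0.  On instances where
    every arm is positive the optimum equalizes stresses, F_i = sigma* PCSA_i.
    """
    m = instance.m
    pcsa = instance.pcsa_array()
    arms = instance.arm_array()
    # Variables: (F_1..F_m, sigma)
    c = np.zeros(m + 1)
    c[m] = 1.0
    A_ub = np.hstack([np.eye(m), -pcsa.reshape(-1, 1)])
    A_eq = np.hstack([arms, [0.0]]).reshape(1, -1)
    res = linprog(
        c,
        A_ub=A_ub,
        b_ub=np.zeros(m),
        A_eq=A_eq,
        b_eq=[instance.moment],
        bounds=[(0, None)] * (m + 1),
        method="highs",
    )
    if res.status == 2:
        raise InfeasibleInstanceError("minimax linear program infeasible")
    if not res.success:
        raise SolverConvergenceError("minimax linear program failed", res.message)

    sigma = float(res.x[m])
    forces = res.x[:m]
    diagnostics = "epigraph LP"
    if np.all(arms > 0):
        # LP vertices may under-use slack muscles at equal optimum sigma;
        # the equal-stress point is the canonical representative.
        sigma_star = minimax_equal_stress(instance)
        if sigma <= sigma_star * (1 + 1e-9):
            forces = sigma_star * pcsa
            sigma = sigma_star
            diagnostics = "epigraph LP, equal-stress representative"
    return _package("minimax", instance, forces, sigma, diagnostics)


# ---------------------------------------------------------------------------
# Brute-force oracle
# ---------------------------------------------------------------------------

def brute_force_oracle(
    instance: JointInstance,
    objective: Callable[[np.ndarray], np.ndarray],
    grid_points: int = 101,
    refine_passes: int = 3,
) -> np.ndarray:
    """Grid-search minimizer over the feasible set, for desk-scale m <= 4.

    The equality constraint eliminates the last positive-arm force; the
    remaining forces are gridded over [0, M/d_i].  The best grid point is
    refined by local zoom passes.  Accuracy is limited by the grid, so use
    it only as an independent check, never as a solver.
    """
    if instance.m > 4:
        raise InvalidParameterError("oracle is desk-scale only (m <= 4)")
    arms = instance.arm_array()
    pos = np.flatnonzero(arms > 0)
    if len(pos) == 0:
        raise InfeasibleInstanceError("no positive moment arm")
    dep = int(pos[-1])
    free = [i for i in range(instance.m) if i != dep]

    def evaluate(free_grid: list[np.ndarray]) -> tuple[np.ndarray, float]:
        """Best feasible full force vector over the cartesian grid."""
        mesh = np.meshgrid(*free_grid, indexing="ij") if free_grid else []
        pts = (
            np.stack([g.ravel() for g in mesh], axis=-1)
            if free_grid
            else np.zeros((1, 0))
        )
        f_dep = (instance.moment - pts @ arms[free]) / arms[dep]
        ok = f_dep >= -1e-12
        if not np.any(ok):
            raise InfeasibleInstanceError("empty feasible grid")
        full = np.zeros((int(ok.sum()), instance.m))
        full[:, free] = pts[ok]
        full[:, dep] = np.maximum(f_dep[ok], 0.0)
        vals = np.asarray(objective(full), dtype=float)
        k = int(np.argmin(vals))
        return full[k], float(vals[k])

    # Coarse pass over the full feasible box.
    lims = [
        (0.0, instance.moment / arms[i]) if arms[i] > 0 else (0.0, 0.0)
        for i in free
    ]
    grids = [np.linspace(lo, hi, grid_points if hi > lo else 1) for lo, hi in lims]
    spacing = [
        (hi - lo) / max(grid_points - 1, 1) if hi > lo else 0.0 for lo, hi in lims
    ]
    best, _ = evaluate(grids)

    # Compounding local zoom around the incumbent: each pass shrinks the
    # per-axis spacing by ~(grid_points - 1)/4.
    for _ in range(refine_passes):
        new_grids = []
        for ax, i in enumerate(free):
            lo, hi = lims[ax]
            if spacing[ax] == 0.0:
                new_grids.append(np.array([lo]))
                continue
            a = max(lo, best[i] - 2.0 * spacing[ax])
            b = min(hi, best[i] + 2.0 * spacing[ax])
            new_grids.append(np.linspace(a, b, grid_points if b > a else 1))
            spacing[ax] = (b - a) / max(grid_points - 1, 1)
        best, _ = evaluate(new_grids)
    return best
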