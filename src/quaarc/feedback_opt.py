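"""Experimentally constrained least-squares MU reweighting.

This is the heart of the verification model: the per-control-point monitor
units recorded in the delivery log are adjusted so that the calculated dose
matches what the rolled films and the isocenter chamber actually measured,

    min_x  1/2 || C x - d ||^2
    s.t.   A x <= b          (per-row dose-difference tolerance, both signs)
           Aeq x = beq       (total treatment MU is conserved)
           lb <= x <= ub     (per-CP bounds, fractions of the log MU)

where column j of C is the dose per *log-file MU* of CP j (the per-MU
contribution matrix scaled by each CP's logged MU), x is the dimensionless
per-CP weight vector (x = 1 reproduces the log), and d stacks the film
scroll dose samples with the chamber reading.  The per-CP bounds keep each
change small, so the adjustment is carried by the lateral overlap of
neighboring CPs on the film — which is exactly the information a
continuously recording scroll adds over a discrete detector array.

The solver is deterministic: the equivalent quadratic program (analytic
gradient, constant Hessian) is solved by sequential quadratic programming
with the dose-tolerance rows handled by an active-set outer loop — only
violated rows are promoted into the constraint set, since almost all of
them are slack at the optimum.  If the tolerance set is infeasible it is
relaxed progressively by a factor 1.5 up to a cap, with every relaxation
recorded in the solution — never silently.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .dose_engine import ContributionMatrix
from .phantom_scroll import ScrollImage
from .plan_log import DiscretizedArc, angular_mu_distribution

__all__ = [
    "MeasurementVector",
    "ConstraintSet",
    "MUSolution",
    "assemble_measurements",
    "solve_mu_adjustment",
    "mu_change_report",
]

log = logging.getLogger("quaarc")


@dataclass
class MeasurementVector:
    """Stacked measurement samples: film-scroll doses plus the chamber."""

    d: np.ndarray                       # Gy, (n_rows,)
    points: np.ndarray                  # (n_rows, 3) world mm
    row_weights: np.ndarray             # least-squares weight per row
    provenance: np.ndarray              # str label per row

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.d)) or np.any(self.d < 0):
            raise ValueError("measurements must be finite and non-negative")


def _scroll_rows(scroll: ScrollImage, downsample: int):
    vals = scroll.values
    pts = scroll.sample_points().reshape(*vals.shape, 3)
    if downsample > 1:
        vals = vals[::downsample, ::downsample]
        pts = pts[::downsample, ::downsample]
    return vals.ravel(), pts.reshape(-1, 3)


def assemble_measurements(
    outer: ScrollImage | list[ScrollImage],
    inner: ScrollImage | None,
    chamber_gy: float,
    chamber_point=(0.0, 0.0, 0.0),
    downsample: int = 1,
    dose_threshold_gy: float = 0.0,
    chamber_weight: float | None = None,
) -> MeasurementVector:
    """Stack scroll pixels (optionally downsampled and dose-thresholded)
    and the chamber point into the measurement vector d.

    The chamber row's least-squares weight defaults to
    ``n_scroll_rows / 100`` so one absolute point is not drowned out by
    thousands of film pixels.
    """
    if chamber_gy <= 0:
        raise ValueError("chamber dose must be positive")
    outers = outer if isinstance(outer, list) else [outer]
    scrolls = [("outer", s) for s in outers]
    if inner is not None:
        scrolls.append(("inner", inner))

    vals, pts, prov = [], [], []
    for label, s in scrolls:
        v, p = _scroll_rows(s, downsample)
        keep = v >= dose_threshold_gy
        vals.append(v[keep])
        pts.append(p[keep])
        prov.extend([label] * int(keep.sum()))
    d = np.concatenate(vals)
    if len(d) == 0:
        raise ValueError("no scroll pixels above the dose threshold")
    points = np.vstack(pts)

    if chamber_weight is None:
        chamber_weight = max(len(d) / 100.0, 1.0)
    d = np.append(d, chamber_gy)
    points = np.vstack([points, np.asarray(chamber_point, float)])
    prov.append("chamber")
    weights = np.ones(len(d))
    weights[-1] = chamber_weight
    return MeasurementVector(d=d, points=points, row_weights=weights,
                             provenance=np.array(prov))


@dataclass
class ConstraintSet:
    """Constraints of the MU adjustment.

    tol_rel / tol_abs_gy : per-row dose tolerance — each |(Cx - d)_i| must
        stay within max(tol_rel * d_i, tol_abs_gy) ("both positive and
        negative differences").
    lb / ub : per-CP weight bounds as fractions of the log MU.
    relax_factor / max_relax : progressive tolerance relaxation policy when
        the inequality set is infeasible.
    """

    tol_rel: float = 0.03
    tol_abs_gy: float = 0.02
    lb: float | np.ndarray = 0.90
    ub: float | np.ndarray = 1.10
    conserve_total_mu: bool = True
    relax_factor: float = 1.5
    max_relax: int = 8

    def bounds(self, n: int) -> tuple[np.ndarray, np.ndarray]:
        lb = np.broadcast_to(np.asarray(self.lb, float), (n,)).copy()
        ub = np.broadcast_to(np.asarray(self.ub, float), (n,)).copy()
        if np.any(lb > 1.0 + 1e-12) or np.any(ub < 1.0 - 1e-12):
            raise ValueError("bounds must bracket 1 (the log solution)")
        return lb, ub

    def row_tolerances(self, d: np.ndarray) -> np.ndarray:
        return np.maximum(self.tol_rel * d, self.tol_abs_gy)


@dataclass
class MUSolution:
    """Result of the adjustment: weights, adjusted MU and diagnostics."""

    x: np.ndarray                       # per-CP weight, 1 = log value
    mu_log: np.ndarray                  # MU from the log
    objective: float                    # 1/2 ||Cx - d||^2 (weighted)
    objective_at_log: float             # same at x = 1
    tol_relaxations: int                # times the dose tolerance was relaxed
    feasible: bool
    binding_rows: np.ndarray            # rows at the dose-tolerance edge
    degenerate: bool = False

    @property
    def mu_adjusted(self) -> np.ndarray:
        return self.x * self.mu_log

    @property
    def change_pct(self) -> np.ndarray:
        return 100.0 * (self.x - 1.0)


def solve_mu_adjustment(
    C: ContributionMatrix,
    d: MeasurementVector,
    cons: ConstraintSet | None = None,
) -> MUSolution:
    """Solve the constrained least-squares MU adjustment.

    The QP is solved in weight space (x = 1 means "as logged"): columns of
    the per-MU contribution matrix are scaled by the log MU, rows by the
    measurement weights.  Deterministic for fixed inputs.  Infeasible dose
    tolerances are relaxed progressively (factor ``cons.relax_factor``), and
    the number of relaxations is reported on the solution.
    """
    cons = cons or ConstraintSet()
    if C.n_rows != len(d.d):
        raise ValueError(
            f"contribution rows ({C.n_rows}) != measurement rows ({len(d.d)})"
        )
    n = C.n_cps
    mu_log = C.cp_mu.astype(float)
    A = C.entries * mu_log[None, :]          # Gy at x
    w = np.sqrt(d.row_weights)
    Aw = A * w[:, None]
    dw = d.d * w

    H = Aw.T @ Aw
    g = -Aw.T @ dw
    const = 0.5 * float(dw @ dw)

    # conditioning diagnostic
    sv = np.linalg.svd(Aw, compute_uv=False)
    degenerate = bool(sv[-1] < 1e-10 * sv[0])
    if degenerate:
        log.warning("contribution matrix is rank-deficient; the adjustment "
                    "is reported but not unique")

    lb, ub = cons.bounds(n)
    x0 = np.ones(n)

    def objective(x):
        return 0.5 * float(x @ (H @ x)) + float(g @ x) + const

    def grad(x):
        return H @ x + g

    eq_cons = []
    if cons.conserve_total_mu:
        total = float(mu_log.sum())
        eq_cons.append({"type": "eq",
                        "fun": lambda x: mu_log @ x - total,
                        "jac": lambda x: mu_log})

    def solve_with(active_rows: np.ndarray, tol: np.ndarray, start):
        constraints = list(eq_cons)
        if len(active_rows):
            Aa = A[active_rows]
            hi = d.d[active_rows] + tol[active_rows]
            lo = d.d[active_rows] - tol[active_rows]
            constraints.append({"type": "ineq",
                                "fun": lambda x: hi - Aa @ x,
                                "jac": lambda x: -Aa})
            constraints.append({"type": "ineq",
                                "fun": lambda x: Aa @ x - lo,
                                "jac": lambda x: Aa})
        return optimize.minimize(
            objective, start, jac=grad, method="SLSQP",
            bounds=list(zip(lb, ub)), constraints=constraints,
            options={"maxiter": 500, "ftol": 1e-16},
        )

    # Active-set outer loop: the dose-tolerance inequality has one row pair
    # per measurement, but almost all rows are slack at the optimum — only
    # violated rows are promoted into the constraint set.  When even the
    # promoted set cannot be satisfied (the solver stalls with violations
    # remaining) the tolerance is relaxed progressively — never silently.
    tol = cons.row_tolerances(d.d)
    relaxations = 0
    res = solve_with(np.array([], dtype=int), tol, x0)
    while True:
        resid = A @ res.x - d.d
        slack = np.abs(resid) - tol
        violated = np.nonzero(slack > 1e-6 * tol + 1e-9)[0]
        if len(violated) == 0:
            break
        active = np.array([], dtype=int)
        prev_violation = np.inf
        for _ in range(8):
            active = np.union1d(active, violated)
            trial = solve_with(active, tol, res.x)
            t_resid = A @ trial.x - d.d
            t_slack = np.abs(t_resid) - tol
            violation = float(t_slack.max())
            if trial.status == 0 and violation <= 1e-6 * max(1.0, float(tol.max())):
                res = trial
                break
            if violation >= prev_violation - 1e-12 or trial.status != 0:
                break                    # infeasible within bounds
            prev_violation = violation
            res = trial
            violated = np.nonzero(t_slack > 1e-6 * tol + 1e-9)[0]
        resid = A @ res.x - d.d
        if np.max(np.abs(resid) - tol) <= 1e-6 * max(1.0, float(tol.max())):
            break
        if relaxations >= cons.max_relax:
            log.warning("dose tolerance still infeasible after %d "
                        "relaxations; reporting the best effort", relaxations)
            break
        relaxations += 1
        tol = tol * cons.relax_factor
        log.info("dose tolerance infeasible; relaxed x%.1f (round %d)",
                 cons.relax_factor, relaxations)

    x = np.asarray(res.x, dtype=float)
    resid = A @ x - d.d
    violation = float(np.max(np.abs(resid) - tol))
    feasible = violation <= 1e-6 * max(1.0, float(tol.max()))
    binding = np.nonzero(np.abs(np.abs(resid) - tol) <= 1e-6 * tol)[0]

    obj_x = objective(x)
    obj_log = objective(x0)
    # never return a worse point than the log solution when x0 = 1 is itself
    # feasible under the (possibly relaxed) tolerance
    x0_feasible = np.max(np.abs(A @ x0 - d.d) - tol) <= 1e-9
    if x0_feasible and obj_x > obj_log:
        x = x0
        obj_x = obj_log
        binding = np.array([], dtype=int)
        feasible = True
    return MUSolution(x=x, mu_log=mu_log, objective=obj_x,
                      objective_at_log=obj_log, tol_relaxations=relaxations,
                      feasible=feasible, binding_rows=binding,
                      degenerate=degenerate)


def mu_change_report(
    sol: MUSolution,
    arc: DiscretizedArc,
    bin_width: float = 10.0,
):
    """Per-CP and per-angular-bin MU differences (adjusted - log).

    Returns a DataFrame with one row per angular bin (columns ``angle_lo``,
    ``angle_hi``, ``mu_log``, ``mu_adjusted``, ``mu_diff``); the bin sums of
    ``mu_diff`` total zero whenever the equality constraint was active.
    """
    import pandas as pd

    if len(arc) != len(sol.x):
        raise ValueError("solution does not match the arc")
    base = angular_mu_distribution(arc, bin_width).rename(
        columns={"mu": "mu_log"})
    adj_arc_mu = sol.mu_adjusted
    ang = arc.angles
    edges = np.append(base["angle_lo"].to_numpy(), base["angle_hi"].iloc[-1])
    idx = np.clip(np.digitize(ang, edges, right=True) - 1, 0, len(base) - 1)
    base["mu_adjusted"] = np.bincount(idx, weights=adj_arc_mu,
                                      minlength=len(base))
    base["mu_diff"] = base["mu_adjusted"] - base["mu_log"]
    return base
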