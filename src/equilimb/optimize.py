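"""Static optimization of the redundant muscle-force distribution.

More actuators cross the three joints than there are balance equations, so
the force distribution is chosen by minimizing the cubic, PCSA-normalized
cost

    U(F) = sum_i (F_i / PCSA_i)^3

subject to the moment balance ``A @ F = M`` and physiological box bounds.
The cubic muscle-stress criterion favors load sharing proportional to
muscle size and is the standard efficiency criterion for static muscle
redundancy problems.

Bounds:

* muscles: lower = 1% of the maximum isometric force (resting tonus),
  upper = the maximum isometric force;
* the superficial digital flexor additionally gets a floor of 90% of the
  ground-reaction-force magnitude, standing in for the stabilizing moment
  of the hock, which the three-joint model does not represent;
* ligaments: lower = 0 (they only transmit, never actively contract).

Internally the problem is conditioned by optimizing over activations
``a_i = F_i / (PCSA_i * sigma0)`` with a nominal muscle stress ``sigma0``
(default 0.3 MPa), which keeps the cubic and its derivatives near unit
scale.  Since all bounds keep ``F >= 0``, the objective is convex on the
feasible set and any KKT point is the global minimum; the solver result is
certified post hoc by the projected-gradient (KKT) residual.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import linprog, lsq_linear, minimize

from .errors import ConvergenceError, InfeasibleError
from .statics import NetJointMoments
from .system import SystemMatrix

#: Nominal maximum isometric muscle stress (Pa) used only for conditioning.
SIGMA0 = 0.3e6

_SDF_ALIASES = ("superficial digital flexor", "flexor digitalis superficialis")


@dataclass
class BoundSpec:
    """Per-actuator force bounds (N) with provenance tags."""

    lower: np.ndarray
    upper: np.ndarray
    provenance: list  # per actuator: tonus | payne_max | sdf_grf | ligament | custom

    def __post_init__(self):
        self.lower = np.asarray(self.lower, dtype=float)
        self.upper = np.asarray(self.upper, dtype=float)
        if np.any(self.lower < 0) or np.any(self.lower > self.upper):
            raise InfeasibleError("invalid bounds: need 0 <= lower <= upper")


def is_sdf(name: str) -> bool:
    low = name.lower()
    return any(alias in low for alias in _SDF_ALIASES)


def default_bounds(actuators, grf_magnitude: float, tonus_fraction: float = 0.01,
                   sdf_grf_fraction: float = 0.9) -> BoundSpec:
    """Physiological bounds from the standing-model rules (see module docstring)."""
    lower, upper, prov = [], [], []
    for a in actuators:
        hi = a.f_max
        if a.kind == "ligament":
            lo, tag = 0.0, "ligament"
        else:
            lo, tag = tonus_fraction * a.f_max, "tonus"
            if is_sdf(a.name):
                floor = sdf_grf_fraction * abs(grf_magnitude)
                if floor > lo:
                    lo, tag = floor, "sdf_grf"
        if a.f_min > lo:
            lo, tag = a.f_min, "custom"
        if lo > hi:
            raise InfeasibleError(
                f"actuator {a.name!r}: lower bound {lo:.1f} N exceeds upper bound {hi:.1f} N"
            )
        lower.append(lo)
        upper.append(hi)
        prov.append(tag)
    return BoundSpec(np.array(lower), np.array(upper), prov)


@dataclass
class ForceSolution:
    """Optimized actuator forces with convergence diagnostics."""

    names: list
    forces: np.ndarray  # N
    objective: float  # U = sum (F/PCSA)^3
    moment_residual: np.ndarray  # A @ F - M, per joint row (N·m)
    active_lower: np.ndarray
    active_upper: np.ndarray
    converged: bool
    n_iter: int
    method: str
    kkt: Optional[float] = None
    bounds: Optional[BoundSpec] = None

    @property
    def residual_norm(self) -> float:
        return float(np.linalg.norm(self.moment_residual))

    def force(self, name: str) -> float:
        return float(self.forces[self.names.index(name)])

    def as_dict(self) -> dict:
        return dict(zip(self.names, self.forces))


def _coerce_rhs(moments, joint_order) -> np.ndarray:
    if isinstance(moments, NetJointMoments):
        return moments.stacked(joint_order)
    return np.asarray(moments, dtype=float).reshape(-1)


def _reduce_equalities(A: np.ndarray, m: np.ndarray, rtol: float = 1e-12):
    """Full-row-rank reduction of ``A x = m`` via SVD.

    Returns ``(Ar, mr)`` with independent rows, or raises if ``m`` has a
    component outside the row space (linearly inconsistent system).
    """
    U, s, Vt = np.linalg.svd(A, full_matrices=True)
    scale = s[0] if s.size and s[0] > 0 else 1.0
    r = int(np.sum(s > rtol * scale))
    Um = U.T @ m
    out_of_range = np.linalg.norm(Um[r:]) if Um.size > r else 0.0
    if out_of_range > 1e-8 * max(1.0, np.linalg.norm(m)):
        raise InfeasibleError(
            "equality system is linearly inconsistent "
            f"(unreachable moment component of norm {out_of_range:.3e} N·m)",
            residual=out_of_range,
        )
    Ar = s[:r, None] * Vt[:r, :]
    mr = Um[:r]
    return Ar, mr


def _certify_infeasible(A, m, lower, upper):
    """Minimal-residual certificate for an equality system with no solution in the box."""
    out = lsq_linear(A, m, bounds=(lower, upper), tol=1e-12)
    return InfeasibleError(
        "no force vector within bounds balances the target moments "
        f"(minimal residual {np.linalg.norm(out.fun):.3e} N·m)",
        residual=float(np.linalg.norm(out.fun)),
        best_forces=out.x,
    )


def _box_feasible(A, m, lower, upper) -> Optional[np.ndarray]:
    """A feasible point of {A x = m, l <= x <= u}, or None."""
    res = linprog(
        c=np.zeros(A.shape[1]),
        A_eq=A,
        b_eq=m,
        bounds=list(zip(lower, upper)),
        method="highs",
    )
    return res.x if res.status == 0 else None


def _active_sets(a, la, ua, tol_scale=1e-8):
    span = np.maximum(1.0, ua - la)
    lo = a - la <= tol_scale * span
    hi = ua - a <= tol_scale * span
    return lo, hi & ~lo


def _newton_polish(Ar, mr, la, ua, a0, max_outer=60, max_inner=80):
    """Active-set Newton refinement of a near-optimal activation vector.

    Minimizes ``sum a^3`` s.t. ``Ar a = mr`` and box bounds, exploiting the
    diagonal Hessian ``6 a``.  Converges to machine-precision stationarity
    from a good start; returns (a, lambda, ok).
    """
    n = Ar.shape[1]
    a = np.clip(np.asarray(a0, dtype=float), la, ua)
    lam = np.zeros(Ar.shape[0])
    released = set()
    for _outer in range(max_outer):
        lo, hi = _active_sets(a, la, ua)
        for i in released:
            lo[i] = hi[i] = False
        free = ~(lo | hi)
        a = np.where(lo, la, np.where(hi, ua, a))
        if not np.any(free):
            ok = np.linalg.norm(Ar @ a - mr) <= 1e-9 * max(1.0, np.linalg.norm(mr))
            return a, lam, ok
        Af = Ar[:, free]
        rhs_fixed = mr - Ar[:, ~free] @ a[~free]
        af = a[free].copy()
        hit_bound = False
        for _inner in range(max_inner):
            g = 3.0 * af**2
            H = np.maximum(6.0 * af, 1e-10)
            # KKT Newton step: [diag(H) Af^T; Af 0] [da; lam] = [-g; rhs - Af af]
            k = Af.shape[0]
            KKT = np.zeros((len(af) + k, len(af) + k))
            KKT[: len(af), : len(af)] = np.diag(H)
            KKT[: len(af), len(af):] = Af.T
            KKT[len(af):, : len(af)] = Af
            rhs = np.concatenate([-g, rhs_fixed - Af @ af])
            try:
                sol = np.linalg.solve(KKT, rhs)
            except np.linalg.LinAlgError:
                sol, *_ = np.linalg.lstsq(KKT, rhs, rcond=None)
            da, lam = sol[: len(af)], sol[len(af):]
            if not np.all(np.isfinite(da)):
                return a, lam, False
            # step length keeping free vars inside the box
            alpha = 1.0
            laf, uaf = la[free], ua[free]
            for i in range(len(af)):
                if da[i] < 0 and af[i] + da[i] < laf[i]:
                    alpha = min(alpha, (laf[i] - af[i]) / da[i])
                elif da[i] > 0 and af[i] + da[i] > uaf[i]:
                    alpha = min(alpha, (uaf[i] - af[i]) / da[i])
            af = np.clip(af + alpha * da, laf, uaf)
            if alpha < 1.0:
                hit_bound = True
            step = np.linalg.norm(da) * alpha
            stat = np.linalg.norm(3.0 * af**2 + Af.T @ lam)
            feas = np.linalg.norm(Af @ af - rhs_fixed)
            if stat <= 1e-11 * max(1.0, np.linalg.norm(3.0 * af**2)) and feas <= 1e-11 * max(
                1.0, np.linalg.norm(mr)
            ):
                break
            if step <= 1e-14 * max(1.0, np.linalg.norm(af)):
                break
        a[free] = af
        if hit_bound:
            released.clear()
            continue
        # check multiplier signs at active bounds; release the worst violator
        mu = 3.0 * a**2 + Ar.T @ lam
        worst, worst_i = 0.0, -1
        for i in range(n):
            if lo[i] and mu[i] < -worst:
                worst, worst_i = -mu[i], i
            elif hi[i] and mu[i] > worst:
                worst, worst_i = mu[i], i
        if worst_i < 0 or worst <= 1e-9 * max(1.0, np.linalg.norm(3.0 * a**2)):
            return a, lam, True
        released = {worst_i}
    return a, lam, False


def _projected_gradient_norm(a, Ar, la, ua):
    """Norm of the gradient of sum a^3 projected onto feasible directions,
    relative to the gradient scale."""
    g = 3.0 * a**2
    lo, hi = _active_sets(a, la, ua, tol_scale=1e-7)
    free = ~(lo | hi)
    if Ar.shape[0] and np.any(free):
        lam, *_ = np.linalg.lstsq(Ar[:, free].T, -g[free], rcond=None)
    else:
        lam = np.zeros(Ar.shape[0])
    mu = g + Ar.T @ lam
    viol = np.where(free, mu, 0.0)
    viol = viol + np.where(lo, np.minimum(mu, 0.0), 0.0)  # lower active: need mu >= 0
    viol = viol + np.where(hi, np.maximum(mu, 0.0), 0.0)  # upper active: need mu <= 0
    return float(np.linalg.norm(viol) / max(1.0, np.linalg.norm(g)))


def solve_forces(system: SystemMatrix, moments, pcsa: Sequence, bounds: BoundSpec,
                 sigma0: float = SIGMA0, tol: float = 1e-8) -> ForceSolution:
    """Minimize the cubic cost subject to moment balance and bounds.

    Deterministic: starts from the midpoint of the bounds, refines the
    scipy solution with an active-set Newton polish, and certifies the
    result with the projected-gradient residual.
    """
    A = system.coefficients
    m = _coerce_rhs(moments, system.joint_order)
    if m.shape[0] != A.shape[0]:
        raise ValueError(f"moment vector length {m.shape[0]} != system rows {A.shape[0]}")
    pcsa = np.asarray(pcsa, dtype=float)
    if pcsa.shape[0] != A.shape[1]:
        raise ValueError("pcsa length does not match number of actuators")
    scale = np.where(pcsa > 0, pcsa, 1.0) * sigma0

    Aa = A * scale  # columns scaled: (Aa) @ a = A @ F
    la, ua = bounds.lower / scale, bounds.upper / scale
    Ar, mr = _reduce_equalities(Aa, m)

    feas_pt = _box_feasible(Ar, mr, la, ua)
    if feas_pt is None:
        raise _certify_infeasible(Aa, m, la, ua)

    x0 = 0.5 * (la + ua)
    res = minimize(
        lambda a: float(np.sum(a**3)),
        x0,
        jac=lambda a: 3.0 * a**2,
        method="SLSQP",
        bounds=list(zip(la, ua)),
        constraints=[{"type": "eq", "fun": lambda a: Ar @ a - mr, "jac": lambda a: Ar}],
        options={"maxiter": 800, "ftol": 1e-14},
    )
    a = np.clip(res.x, la, ua)
    n_iter = int(res.get("nit", 0))
    method = "slsqp+newton"
    if not res.success or np.linalg.norm(Ar @ a - mr) > 1e-4 * max(1.0, np.linalg.norm(mr)):
        # fall back to starting the polish from an interior feasible point
        a = np.clip(feas_pt, la, ua)
        method = "feasible+newton"
    a, _lam, polished = _newton_polish(Ar, mr, la, ua, a)
    kkt = _projected_gradient_norm(a, Ar, la, ua)

    forces = a * scale
    residual = A @ forces - m
    feas_ok = np.linalg.norm(residual) <= tol * max(1.0, np.linalg.norm(m))
    converged = bool(polished and feas_ok and kkt <= 1e-6)
    if not feas_ok:
        raise ConvergenceError(
            f"moment residual {np.linalg.norm(residual):.3e} N·m exceeds tolerance",
            best_forces=forces,
            diagnostics={"kkt": kkt, "method": method},
        )
    lo, hi = _active_sets(a, la, ua, tol_scale=1e-7)
    objective = float(np.sum((forces / np.where(pcsa > 0, pcsa, 1.0)) ** 3))
    return ForceSolution(
        names=list(system.actuator_order),
        forces=forces,
        objective=objective,
        moment_residual=residual,
        active_lower=lo,
        active_upper=hi,
        converged=converged,
        n_iter=n_iter,
        method=method,
        kkt=kkt,
        bounds=bounds,
    )


def kkt_residual(solution: ForceSolution, system: SystemMatrix, pcsa, bounds: BoundSpec,
                 sigma0: float = SIGMA0) -> float:
    """Relative projected-gradient norm at a solution.

    Since the cubic cost is convex for nonnegative forces, a (near-)zero
    value certifies global optimality.
    """
    pcsa = np.asarray(pcsa, dtype=float)
    scale = np.where(pcsa > 0, pcsa, 1.0) * sigma0
    a = solution.forces / scale
    Aa = system.coefficients * scale
    m = Aa @ a  # evaluate stationarity on the achieved moment
    Ar, _ = _reduce_equalities(Aa, m)
    return _projected_gradient_norm(a, Ar, bounds.lower / scale, bounds.upper / scale)


def brute_force_oracle(system: SystemMatrix, moments, pcsa, bounds: BoundSpec,
                       grid_n: int = 15, sigma0: float = SIGMA0) -> ForceSolution:
    """Grid-search reference solver for tiny instances (<= 4 actuators).

    Parameterizes the equality-feasible affine set, scans a grid over the
    null-space coefficients, and refines the best feasible candidates with
    a generic local minimizer.  Used only as an independent check of
    :func:`solve_forces`.
    """
    A = system.coefficients
    n = A.shape[1]
    if n > 4:
        raise ValueError(f"brute-force oracle limited to <= 4 actuators, got {n}")
    m = _coerce_rhs(moments, system.joint_order)
    pcsa = np.asarray(pcsa, dtype=float)
    scale = np.where(pcsa > 0, pcsa, 1.0) * sigma0
    Aa = A * scale
    la, ua = bounds.lower / scale, bounds.upper / scale
    Ar, mr = _reduce_equalities(Aa, m)

    U, s, Vt = np.linalg.svd(Ar, full_matrices=True) if Ar.size else (None, np.array([]), np.eye(n))
    r = Ar.shape[0]
    if r:
        particular = np.linalg.pinv(Ar) @ mr
        N = Vt[r:, :].T  # orthonormal null-space basis, n x k
    else:
        particular = np.zeros(n)
        N = np.eye(n)
    k = N.shape[1]

    def obj(t):
        return float(np.sum((particular + N @ t) ** 3))

    candidates = []
    if k == 0:
        a = particular
        span = np.maximum(1.0, ua - la)
        if np.all(a >= la - 1e-7 * span) and np.all(a <= ua + 1e-7 * span):
            candidates.append(np.zeros(0))
    else:
        # box diameter bounds the null-space coefficients of any feasible point
        diam = np.linalg.norm(ua - la) + np.linalg.norm(0.5 * (la + ua) - particular)
        axes = [np.linspace(-diam, diam, grid_n)] * k
        mesh = np.meshgrid(*axes, indexing="ij")
        T = np.stack([g.ravel() for g in mesh], axis=1)
        X = particular[None, :] + T @ N.T
        ok = np.all(X >= la - 1e-12, axis=1) & np.all(X <= ua + 1e-12, axis=1)
        Tok = T[ok]
        if Tok.shape[0]:
            vals = np.sum(X[ok] ** 3, axis=1)
            order = np.argsort(vals)
            candidates.extend(Tok[order[:5]])
        else:
            fp = _box_feasible(Ar, mr, la, ua)
            if fp is not None:
                candidates.append(N.T @ (fp - particular))
    if not candidates:
        raise _certify_infeasible(Aa, m, la, ua)

    best_t, best_val = None, np.inf
    for t0 in candidates:
        if k == 0:
            best_t, best_val = t0, obj(np.zeros(0)) if t0.size == 0 else obj(t0)
            break
        cons = [
            {"type": "ineq", "fun": lambda t: particular + N @ t - la, "jac": lambda t: N},
            {"type": "ineq", "fun": lambda t: ua - particular - N @ t, "jac": lambda t: -N},
        ]
        out = minimize(obj, t0, method="SLSQP", constraints=cons,
                       options={"maxiter": 400, "ftol": 1e-14})
        t = out.x if out.success else t0
        x = np.clip(particular + N @ t, la, ua)
        t = N.T @ (x - particular)
        val = obj(t)
        if val < best_val:
            best_t, best_val = t, val

    a = np.clip(particular + (N @ best_t if k else 0.0), la, ua)
    forces = a * scale
    residual = A @ forces - m
    lo, hi = _active_sets(a, la, ua, tol_scale=1e-7)
    return ForceSolution(
        names=list(system.actuator_order),
        forces=forces,
        objective=float(np.sum((forces / np.where(pcsa > 0, pcsa, 1.0)) ** 3)),
        moment_residual=residual,
        active_lower=lo,
        active_upper=hi,
        converged=True,
        n_iter=0,
        method="brute_force",
        kkt=None,
        bounds=bounds,
    )
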