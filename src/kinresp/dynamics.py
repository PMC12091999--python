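"""Stiff integration, steady-state attractors and conservation analysis.

Any object exposing ``n_state``, ``rhs(x)`` and ``jac(x)`` (plus an
optional ``flux_scale(x)`` and integer stoichiometry ``S``/``exchange``
for conservation analysis) can be driven by this module; the generated
mass-action, catalytic and RCRN models all satisfy the contract, and
external plug-in models may too.

Relaxation is declared converged when

    ||dx/dt||_inf < eps_abs + eps_rel * max_r |J_r(x)|

with eps_rel = 1e-6: the residual must be six orders of magnitude below the
largest individual flux still running through the network (for driven
steady states the individual fluxes stay finite while their sum cancels);
the remaining drift along ultra-slow modes is removed by a Newton polish
of the endpoint.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
import sympy
from scipy.integrate import solve_ivp
from scipy.linalg import null_space
from scipy.optimize import root

logger = logging.getLogger(__name__)

__all__ = [
    "Trajectory",
    "SteadyState",
    "MultistabilityScreen",
    "integrate",
    "relax",
    "find_attractor",
    "conserved_pools",
    "screen_multistability",
    "linearize",
    "LinearizedModel",
    "max_real_eigenvalue",
    "AttractorNotFoundError",
    "ScreeningError",
]

# convergence / identity tolerances (no values are dictated by the science;
# see docs/methods.md for the rationale).  Generated networks can contain
# strongly uphill reactions with effective rates as low as v*k ~ 1e-12, so
# an overly strict residual criterion would never fire within any practical
# horizon; the Newton polish removes the remaining slow-mode drift instead.
EPS_REL_CONV = 1e-6
EPS_ABS_CONV = 1e-10
# second disjunct: the state is also "relaxed" when every concentration
# moves slower than EPS_LOGV e-folds per unit time (sluggish chains where
# the largest flux is itself the slow relaxation flux never satisfy the
# flux-relative criterion; here the Newton polish bridges the remainder)
EPS_LOGV = 3e-8
CLUSTER_TOL = 1e-4          # max log-distance for "same attractor"
POLISH_TOL = 0.5            # max log move the Newton polish may take
DEFAULT_RELTOL = 1e-6
DEFAULT_ABSTOL = 1e-9
MAX_TOTAL_TIME = 1e8        # ~1e6 exchange timescales (D = 1)
_FLOOR = 1e-300


class AttractorNotFoundError(RuntimeError):
    pass


class ScreeningError(RuntimeError):
    pass


@dataclass
class Trajectory:
    """Concatenated adaptive-solver output of one integration."""

    times: np.ndarray            # strictly increasing, starts at 0
    states: np.ndarray           # n_state x len(times)
    converged: bool
    failure_reason: str | None = None
    _interpolants: list = field(default_factory=list, repr=False)

    @property
    def x0(self) -> np.ndarray:
        return self.states[:, 0]

    @property
    def x_end(self) -> np.ndarray:
        return self.states[:, -1]

    def sample(self, t: np.ndarray) -> np.ndarray:
        """Evaluate the dense solver output at arbitrary times."""
        t = np.asarray(t, dtype=float)
        out = np.empty((self.states.shape[0], t.size))
        edges = np.array([s.t_max for s in self._interpolants])
        idx = np.searchsorted(edges, t, side="left")
        idx = np.clip(idx, 0, len(self._interpolants) - 1)
        for k in np.unique(idx):
            sel = idx == k
            out[:, sel] = self._interpolants[k](t[sel])
        return np.maximum(out, _FLOOR)


class _BudgetExceeded(RuntimeError):
    """Raised inside a solver callback when the RHS evaluation budget runs
    out; bounds both wall time and dense-output memory per trajectory."""


# generous: typical trajectories need ~1e3 evaluations. Pathological
# instances (near-oscillatory stiffness) can otherwise accumulate millions
# of dense-output steps and exhaust memory.
MAX_RHS_EVALS = 30_000


def _wrap_rhs(model, budget: int | None = None):
    if not getattr(model, "requires_positive", True):
        base = lambda t, y: model.rhs(y)  # noqa: E731
    else:
        base = lambda t, y: model.rhs(np.maximum(y, 0.0))  # noqa: E731
    if budget is None:
        return base
    count = [0]

    def f(t, y):
        count[0] += 1
        if count[0] > budget:
            raise _BudgetExceeded(f"RHS evaluation budget ({budget}) exhausted")
        return base(t, y)

    return f


def _wrap_jac(model):
    if not getattr(model, "requires_positive", True):
        return lambda t, y: model.jac(y)
    return lambda t, y: model.jac(np.maximum(y, 0.0))


def _flux_scale(model, x) -> float:
    fs = getattr(model, "flux_scale", None)
    if fs is not None:
        return fs(x)
    return float(np.max(np.abs(model.rhs(x))))


def _conv_measure(model, x, eps_abs, eps_rel, eps_logv=EPS_LOGV) -> float:
    """Signed convergence measure; negative once either criterion holds."""
    fast = getattr(model, "conv_measure", None)
    if fast is not None:  # fused kernel (evaluated once per solver step)
        return fast(x, eps_abs, eps_rel, eps_logv)
    dx = np.abs(model.rhs(x))
    g_flux = float(dx.max()) - (eps_abs + eps_rel * _flux_scale(model, x))
    g_logv = float((dx / (np.abs(x) + _FLOOR)).max()) - eps_logv
    return min(g_flux, g_logv)


def residual_converged(model, x, eps_abs=EPS_ABS_CONV, eps_rel=EPS_REL_CONV) -> bool:
    return _conv_measure(model, x, eps_abs, eps_rel) < 0


def _solve(model, x0, t_span, reltol, abstol, events=None):
    """One stiff solve with solver and tolerance fallbacks.

    LSODA first (fast Fortran core); on solver breakdown or positivity
    violation retried with 100x tighter tolerances, then with BDF.
    """
    positive = getattr(model, "requires_positive", True)
    attempts = [
        ("LSODA", reltol, abstol),
        ("LSODA", reltol / 100, abstol / 100),
        ("BDF", reltol, abstol),
    ]
    reason = "solver breakdown"
    for method, rt, at in attempts:
        try:
            sol = solve_ivp(
                _wrap_rhs(model, MAX_RHS_EVALS), t_span, x0, method=method,
                jac=_wrap_jac(model), rtol=rt, atol=at,
                dense_output=True, events=events,
            )
        except _BudgetExceeded as exc:
            reason = str(exc)
            break  # budget is method-independent; fallbacks would also burn it
        except (FloatingPointError, ValueError) as exc:
            reason = f"solver error: {exc}"
            continue
        if not sol.success or not np.all(np.isfinite(sol.y)):
            reason = sol.message if not sol.success else "non-finite state"
            continue
        if positive and sol.y.min() <= -100 * at:
            reason = "positivity violation"
            continue
        return sol, None
    return None, reason


def integrate(
    model,
    x0: np.ndarray,
    horizon: float,
    reltol: float = DEFAULT_RELTOL,
    abstol: float = DEFAULT_ABSTOL,
) -> Trajectory:
    """Adaptive stiff integration over a fixed horizon with dense output.

    Positivity is enforced by floor-clipping solver states before RHS
    evaluation plus a post-hoc violation check with tolerance-tightening
    and solver fallback; failures are reported in ``failure_reason``,
    never silently dropped.
    """
    x0 = np.asarray(x0, dtype=float)
    positive = getattr(model, "requires_positive", True)
    if positive and np.any(x0 <= 0):
        raise ValueError("initial state must be strictly positive")
    sol, reason = _solve(model, x0, (0.0, horizon), reltol, abstol)
    if sol is None:
        return Trajectory(np.array([0.0]), x0[:, None], False, reason)
    states = np.maximum(sol.y, _FLOOR) if positive else sol.y
    return Trajectory(sol.t, states, True, None, [sol.sol])


def relax(
    model,
    x0: np.ndarray,
    reltol: float = DEFAULT_RELTOL,
    abstol: float = DEFAULT_ABSTOL,
    max_time: float = MAX_TOTAL_TIME,
    eps_abs: float = EPS_ABS_CONV,
    eps_rel: float = EPS_REL_CONV,
) -> Trajectory:
    """Integrate until the steady-state residual criterion holds.

    A terminal solver event stops the integration as soon as
    ||dx/dt||_inf falls below eps_abs + eps_rel * max|J_r|; hitting the
    time cap without meeting the criterion is a loud failure
    (``failure_reason='no convergence by t=...'``), never a silent drop.
    """
    x0 = np.asarray(x0, dtype=float)
    positive = getattr(model, "requires_positive", True)
    if positive and np.any(x0 <= 0):
        raise ValueError("initial state must be strictly positive")
    if residual_converged(model, x0, eps_abs, eps_rel):
        return Trajectory(np.array([0.0]), x0[:, None], True, None)

    def conv_event(t, y):
        x = np.maximum(y, 0.0) if positive else y
        return _conv_measure(model, x, eps_abs, eps_rel)

    conv_event.terminal = True
    conv_event.direction = -1
    sol, reason = _solve(model, x0, (0.0, max_time), reltol, abstol, events=[conv_event])
    if sol is None:
        return Trajectory(np.array([0.0]), x0[:, None], False, reason)
    states = np.maximum(sol.y, _FLOOR) if positive else sol.y
    if sol.status != 1:  # no event: time cap reached
        converged = residual_converged(model, states[:, -1], eps_abs, eps_rel)
        if not converged:
            # solver-resolution floor: a slaved coordinate can sit within
            # the error tolerance of its quasi-equilibrium and carry a
            # residual the criterion can never see below.  If the state
            # has been numerically frozen over the second half of the
            # horizon, treat it as relaxed (the Newton polish lands on the
            # exact root); genuine creep or oscillation stays a failure.
            half = np.maximum(np.asarray(sol.sol(0.5 * max_time)), _FLOOR)
            last = np.maximum(states[:, -1], _FLOOR)
            converged = bool(np.max(np.abs(np.log(last) - np.log(half))) < 1e-6)
        return Trajectory(
            sol.t, states, converged,
            None if converged else f"no convergence by t={max_time:g}",
            [sol.sol],
        )
    return Trajectory(sol.t, states, True, None, [sol.sol])


# ---------------------------------------------------------------------------
# conservation analysis
# ---------------------------------------------------------------------------

def conserved_pools(model) -> np.ndarray:
    """Integer basis of conserved pools, as rows over the full state.

    Computes the left null space, in exact rational arithmetic, of the
    stoichiometric matrix restricted to dynamic species, augmented with one
    unit column per exchanged species (exchange breaks conservation of any
    pool touching it).  Returns an (n_pools x n_state) integer array; empty
    (0 x n_state) when nothing is conserved.  Models without an integer
    stoichiometry (e.g. RCRN) have no structural pools and return empty.
    """
    S = getattr(model, "S", None)
    n = model.n_state
    if S is None:
        return np.zeros((0, n), dtype=int)
    mask = np.asarray(getattr(model, "dynamic_mask", np.ones(n, dtype=bool)))
    exch = np.asarray(getattr(model, "exchange", np.zeros(n, dtype=bool)))
    rows = np.flatnonzero(mask)
    M = np.asarray(S, dtype=float)[rows, :]
    ex_local = np.flatnonzero(exch[rows])
    if ex_local.size:
        eye = np.zeros((len(rows), ex_local.size))
        eye[ex_local, np.arange(ex_local.size)] = 1.0
        M = np.hstack([M, eye])
    Mint = sympy.Matrix(M.round().astype(int))
    basis = Mint.T.nullspace()
    pools = np.zeros((len(basis), n), dtype=int)
    for b, vec in enumerate(basis):
        fracs = [Fraction(sympy.Rational(v).p, sympy.Rational(v).q) for v in vec]
        lcm = np.lcm.reduce([f.denominator for f in fracs]) if fracs else 1
        ints = np.array([int(f * lcm) for f in fracs])
        nz = ints[ints != 0]
        if nz.size:
            ints = ints // np.gcd.reduce(np.abs(nz))
            if ints[ints != 0][0] < 0:
                ints = -ints
        pools[b, rows] = ints
    return pools


def pool_values(pools: np.ndarray, x: np.ndarray) -> np.ndarray:
    return pools @ x if len(pools) else np.zeros(0)


def project_onto_pools(
    x: np.ndarray,
    pools: np.ndarray,
    target: np.ndarray,
    free: np.ndarray | None = None,
) -> np.ndarray:
    """Multiplicative projection of x onto the surface {P x = target}.

    Applies x -> x * exp(P^T lam) on the ``free`` coordinates (all by
    default) with lam solved by Newton on the SPD Gram system; preserves
    positivity for arbitrary signed, overlapping pool vectors and reduces
    to a uniform rescaling for a single unit pool.  Long integrations let
    conserved quantities drift at the solver tolerance; this puts states
    back on the exact invariant surface of their initial condition.
    """
    x = np.asarray(x, dtype=float)
    P = np.atleast_2d(np.asarray(pools, dtype=float))
    if P.size == 0:
        return x
    target = np.asarray(target, dtype=float)
    if free is None:
        free = np.ones(len(x), dtype=bool)
    keep = np.any(P[:, free] != 0, axis=1)  # frozen-only pools hold trivially
    P, target = P[keep], target[keep]
    if len(P) == 0:
        return x
    Pf = P[:, free]
    lam = np.zeros(len(P))
    for _ in range(100):
        xf = x[free] * np.exp(Pf.T @ lam)
        g = Pf @ xf + P[:, ~free] @ x[~free] - target
        scale = np.abs(target) + np.abs(Pf) @ xf
        if np.all(np.abs(g) <= 1e-14 * scale):
            break
        H = (Pf * xf) @ Pf.T  # SPD Gram matrix of the exponential family
        try:
            step = np.linalg.solve(H, g)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, g, rcond=None)[0]
        lam -= np.clip(step, -5.0, 5.0)
    else:
        raise RuntimeError("conserved-pool projection did not converge")
    out = x.copy()
    out[free] = x[free] * np.exp(Pf.T @ lam)
    return out


# ---------------------------------------------------------------------------
# steady states
# ---------------------------------------------------------------------------

STABILITY_TOL = 1e-8  # eigenvalues within this fraction of the spectral
                      # scale of zero are treated as neutral, not unstable


@dataclass
class SteadyState:
    x_st: np.ndarray
    max_re_eig: float
    pools: np.ndarray          # conserved-pool values at x_st
    pool_matrix: np.ndarray
    residual: float
    spectral_scale: float = 1.0

    @property
    def stable(self) -> bool:
        return self.max_re_eig < STABILITY_TOL * max(self.spectral_scale, 1.0)


def _polish(
    model,
    x_end: np.ndarray,
    accept_tol: float = POLISH_TOL,
    pools: np.ndarray | None = None,
    target: np.ndarray | None = None,
) -> np.ndarray:
    """Newton-polish a steady state in log coordinates.

    When pool targets are supplied the conservation constraints are solved
    together with the steady-state condition as one augmented
    least-squares system, so the returned root sits on the exact invariant
    surface; a plain least-squares root search would drift along the
    (neutral) pool directions.  The polished root is accepted only if it
    stays within half a log unit of the integration endpoint (same basin;
    the residual criterion can leave genuinely slow modes, e.g. growth
    dilution at a small uptake rate, short of the root) and improves the
    residual; otherwise the endpoint is kept.
    """
    z0 = np.log(np.maximum(x_end, _FLOOR))
    constrained = pools is not None and len(pools) and target is not None
    has_jac = hasattr(model, "jac")
    if constrained:
        P = np.asarray(pools, dtype=float)
        t = np.asarray(target, dtype=float)
        # balance the two blocks, then weight the (exactly satisfiable)
        # constraints strongly so lm pins them to machine precision
        f_scale = max(float(np.max(np.abs(model.rhs(x_end)))), _FLOOR)
        p_scale = np.abs(t) + np.abs(P) @ np.abs(x_end)

        def g(z):
            x = np.exp(np.clip(z, -500, 500))
            return np.concatenate(
                [model.rhs(x) / f_scale, 1e3 * (P @ x - t) / p_scale]
            )

        def gjac(z):  # chain rule through x = exp(z)
            x = np.exp(np.clip(z, -500, 500))
            return np.vstack(
                [model.jac(x) * x / f_scale,
                 1e3 * (P * x) / p_scale[:, None]]
            )
    else:

        def g(z):
            return model.rhs(np.exp(np.clip(z, -500, 500)))

        def gjac(z):
            x = np.exp(np.clip(z, -500, 500))
            return model.jac(x) * x

    try:
        sol = root(g, z0, method="lm", jac=gjac if has_jac else None,
                   options={"xtol": 1e-14, "ftol": 1e-14})
    except Exception:
        return x_end
    if not np.all(np.isfinite(sol.x)):
        return x_end
    if np.max(np.abs(sol.x - z0)) > accept_tol:
        return x_end
    x_new = np.exp(sol.x)
    if np.max(np.abs(model.rhs(x_new))) <= np.max(np.abs(model.rhs(x_end))):
        return x_new
    return x_end


def max_real_eigenvalue(model, x_st: np.ndarray, pool_matrix: np.ndarray | None = None):
    """Largest real part of the Jacobian spectrum on the dynamic subspace.

    Directions along conserved pools are neutrally stable by construction
    (they carry exact zero eigenvalues), so the Jacobian is deflated onto
    the orthogonal complement of the pool vectors before taking the
    spectrum; clamped coordinates are excluded the same way.
    Returns (max_re, spectral_scale).
    """
    n = model.n_state
    mask = np.asarray(getattr(model, "dynamic_mask", np.ones(n, dtype=bool)))
    J = model.jac(np.asarray(x_st, dtype=float))[np.ix_(mask, mask)]
    if pool_matrix is None:
        pool_matrix = conserved_pools(model)
    P = np.asarray(pool_matrix, dtype=float)[:, mask] if len(pool_matrix) else None
    if P is not None and P.size and np.any(P != 0):
        Q = null_space(P)
        J = Q.T @ J @ Q
    if J.size == 0:
        return 0.0, 0.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if np.linalg.cond(J) > 1e12:
            warnings.warn("ill-conditioned Jacobian at steady state", stacklevel=2)
    eig = np.linalg.eigvals(J)
    return float(eig.real.max()), float(np.abs(eig).max())


def find_attractor(
    model,
    x0_set,
    reltol: float = DEFAULT_RELTOL,
    abstol: float = DEFAULT_ABSTOL,
    max_time: float = MAX_TOTAL_TIME,
    cluster_tol: float = CLUSTER_TOL,
) -> SteadyState:
    """Relax every initial state, polish, and certify the common attractor.

    Raises :class:`AttractorNotFoundError` if no trajectory converges or if
    the converged endpoints split into several attractors.
    """
    x0_set = [np.asarray(x, dtype=float) for x in x0_set]
    if not x0_set:
        raise AttractorNotFoundError("empty initial-condition set")
    pools = conserved_pools(model)
    endpoints = []
    for x0 in x0_set:
        traj = relax(model, x0, reltol=reltol, abstol=abstol, max_time=max_time)
        if traj.converged:
            # undo solver pool drift: the steady state must sit on the
            # invariant surface of its own initial condition
            target = pool_values(pools, x0)
            e = project_onto_pools(traj.x_end, pools, target)
            endpoints.append(_polish(model, e, pools=pools, target=target))
        else:
            logger.debug("relaxation failed: %s", traj.failure_reason)
    if not endpoints:
        raise AttractorNotFoundError("no initial condition relaxed to a steady state")
    clusters = _cluster(endpoints, cluster_tol)
    if len(clusters) > 1:
        raise AttractorNotFoundError(f"{len(clusters)} distinct attractors found")
    x_st = endpoints[clusters[0][0]]
    if np.any(x_st <= 0):
        raise AttractorNotFoundError("polished root left the positive orthant")
    pools = conserved_pools(model)
    max_re, scale = max_real_eigenvalue(model, x_st, pools)
    return SteadyState(
        x_st=x_st,
        max_re_eig=max_re,
        pools=pool_values(pools, x_st),
        pool_matrix=pools,
        residual=float(np.max(np.abs(model.rhs(x_st)))),
        spectral_scale=scale,
    )


def _cluster(points: list[np.ndarray], tol: float) -> list[list[int]]:
    """Greedy clustering by max log-distance."""
    logs = [np.log(np.maximum(p, _FLOOR)) for p in points]
    clusters: list[list[int]] = []
    for i, z in enumerate(logs):
        for cl in clusters:
            if np.max(np.abs(z - logs[cl[0]])) < tol:
                cl.append(i)
                break
        else:
            clusters.append([i])
    return clusters


@dataclass
class MultistabilityScreen:
    attractors: list[np.ndarray]
    single_attractor: bool
    n_failed: int
    assignments: list[int]


def log_uniform_sampler(low: float = 1e-3, high: float = 1e3):
    """Initial-condition rule: componentwise log-uniform in (low, high)."""

    def sample(rng, n):
        return np.exp(rng.uniform(np.log(low), np.log(high), size=n))

    return sample


def screen_multistability(
    model,
    n_init: int = 32,
    rng=None,
    sampler=None,
    x0_set=None,
    cluster_tol: float = CLUSTER_TOL,
    **relax_kwargs,
) -> MultistabilityScreen:
    """Relax many random starts and cluster the endpoints into attractors.

    Either supply ``x0_set`` explicitly or let ``sampler(rng, n_state)``
    draw ``n_init`` starts (default: log-uniform in (1e-3, 1e3) per
    species). Failed integrations are counted, never silently dropped.
    """
    if x0_set is None:
        if n_init < 2:
            raise ValueError("n_init must be >= 2")
        rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
        sampler = sampler or log_uniform_sampler()
        x0_set = [sampler(rng, model.n_state) for _ in range(n_init)]
    pools = conserved_pools(model)
    endpoints, n_failed = [], 0
    for x0 in x0_set:
        x0 = np.asarray(x0, dtype=float)
        traj = relax(model, x0, **relax_kwargs)
        if traj.converged:
            target = pool_values(pools, x0)
            e = project_onto_pools(traj.x_end, pools, target)
            endpoints.append(_polish(model, e, pools=pools, target=target))
        else:
            n_failed += 1
    if not endpoints:
        raise ScreeningError("all integrations failed during multistability screen")
    clusters = _cluster(endpoints, cluster_tol)
    assignments = np.empty(len(endpoints), dtype=int)
    for ci, cl in enumerate(clusters):
        for i in cl:
            assignments[i] = ci
    return MultistabilityScreen(
        attractors=[endpoints[cl[0]] for cl in clusters],
        single_attractor=len(clusters) == 1,
        n_failed=n_failed,
        assignments=list(assignments),
    )


# ---------------------------------------------------------------------------
# linearization
# ---------------------------------------------------------------------------

class LinearizedModel:
    """Linear dynamics d(dx)/dt = J (x - x_st) around a steady state."""

    kind = "linearized"
    requires_positive = False  # linear propagation may leave the orthant

    def __init__(self, J: np.ndarray, x_st: np.ndarray):
        self.J = np.asarray(J, dtype=float)
        self.x_st = np.asarray(x_st, dtype=float)
        self.n_state = len(self.x_st)
        self._scale = float(np.max(np.abs(self.J @ self.x_st))) or 1.0

    def rhs(self, x: np.ndarray) -> np.ndarray:
        return self.J @ (x - self.x_st)

    def jac(self, x: np.ndarray) -> np.ndarray:
        return self.J

    def flux_scale(self, x: np.ndarray) -> float:
        return self._scale


def linearize(model, x_st: np.ndarray) -> tuple[np.ndarray, LinearizedModel]:
    """Analytic Jacobian at the steady state plus the linear simulator."""
    x_st = np.asarray(x_st, dtype=float)
    J = model.jac(x_st)
    return J, LinearizedModel(J, x_st)
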