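"""Random mass-action kinetic models with cofactor coupling.

This module generates the ensemble of toy metabolic models used throughout
the package: a sparse "backbone" network of N chemicals connected by R
reversible uni-uni reactions (a linear chain plus random extra reactions),
optionally coupled to a three-form cofactor pool (A**, A*, A — an abstract
ATP/ADP/AMP-like carrier) whose total concentration is conserved.  A
catalytic variant replaces cofactor coupling by enzyme-like catalysis
C_n + C_l <=> C_m + C_l.

Rate constants are thermodynamically consistent: every reaction carries a
standard chemical-potential difference Delta_mu and irreversibility factors
k+- = min{1, exp(-+ beta * Delta_mu)}, so closed systems relax to a
detailed-balance equilibrium with zero flux through every reaction.

The governing ODE is

    dx_n/dt = sum_r S_nr * J_r(x) + D_n * (X_n - x_n),
    J_r(x)  = v_r * (k_r+ * prod_{Sub(r)} x - k_r- * prod_{Prd(r)} x),

with S the stoichiometric matrix, D_n = 1 for species exchanged with the
environment (external concentration X_n) and 0 otherwise.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field, replace

import numpy as np

from .util import as_rng, round_half_away

try:  # JIT kernels for the hot RHS/Jacobian path; numpy fallback below
    from numba import njit as _njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is an optional accelerator
    _HAVE_NUMBA = False

    def _njit(*args, **kwargs):
        def deco(f):
            return f

        return deco(args[0]) if args and callable(args[0]) else deco


@_njit(cache=True)
def _rhs_kernel(x, v, kp, km, sub1, sub2, prd1, prd2, D, X):  # pragma: no cover
    n = x.shape[0]
    dx = np.empty(n)
    for i in range(n):
        dx[i] = D[i] * (X[i] - x[i])
    for r in range(v.shape[0]):
        xf = x[sub1[r]]
        if sub2[r] >= 0:
            xf *= x[sub2[r]]
        xb = x[prd1[r]]
        if prd2[r] >= 0:
            xb *= x[prd2[r]]
        J = v[r] * (kp[r] * xf - km[r] * xb)
        dx[sub1[r]] -= J
        if sub2[r] >= 0:
            dx[sub2[r]] -= J
        dx[prd1[r]] += J
        if prd2[r] >= 0:
            dx[prd2[r]] += J
    return dx


@_njit(cache=True)
def _fluxmax_kernel(x, v, kp, km, sub1, sub2, prd1, prd2):  # pragma: no cover
    mx = 0.0
    for r in range(v.shape[0]):
        xf = x[sub1[r]]
        if sub2[r] >= 0:
            xf *= x[sub2[r]]
        xb = x[prd1[r]]
        if prd2[r] >= 0:
            xb *= x[prd2[r]]
        J = abs(v[r] * (kp[r] * xf - km[r] * xb))
        if J > mx:
            mx = J
    return mx


@_njit(cache=True)
def _conv_kernel(x, v, kp, km, sub1, sub2, prd1, prd2, D, X,
                 eps_abs, eps_rel, eps_logv):  # pragma: no cover
    n = x.shape[0]
    dx = np.empty(n)
    for i in range(n):
        dx[i] = D[i] * (X[i] - x[i])
    max_flux = 0.0
    for r in range(v.shape[0]):
        xf = x[sub1[r]]
        if sub2[r] >= 0:
            xf *= x[sub2[r]]
        xb = x[prd1[r]]
        if prd2[r] >= 0:
            xb *= x[prd2[r]]
        J = v[r] * (kp[r] * xf - km[r] * xb)
        if abs(J) > max_flux:
            max_flux = abs(J)
        dx[sub1[r]] -= J
        if sub2[r] >= 0:
            dx[sub2[r]] -= J
        dx[prd1[r]] += J
        if prd2[r] >= 0:
            dx[prd2[r]] += J
    max_dx = 0.0
    max_lv = 0.0
    for i in range(n):
        a = abs(dx[i])
        if a > max_dx:
            max_dx = a
        lv = a / (abs(x[i]) + 1e-300)
        if lv > max_lv:
            max_lv = lv
    return min(max_dx - (eps_abs + eps_rel * max_flux), max_lv - eps_logv)


@_njit(cache=True)
def _jac_kernel(x, v, kp, km, sub1, sub2, prd1, prd2, D):  # pragma: no cover
    n = x.shape[0]
    J = np.zeros((n, n))
    for r in range(v.shape[0]):
        vkp = v[r] * kp[r]
        vkm = v[r] * km[r]
        s1, s2, p1, p2 = sub1[r], sub2[r], prd1[r], prd2[r]
        cols = [(s1, vkp * (x[s2] if s2 >= 0 else 1.0))]
        if s2 >= 0:
            cols.append((s2, vkp * x[s1]))
        cols.append((p1, -vkm * (x[p2] if p2 >= 0 else 1.0)))
        if p2 >= 0:
            cols.append((p2, -vkm * x[p1]))
        for col, d in cols:
            J[s1, col] -= d
            if s2 >= 0:
                J[s2, col] -= d
            J[p1, col] += d
            if p2 >= 0:
                J[p2, col] += d
    for i in range(n):
        J[i, i] -= D[i]
    return J

__all__ = [
    "CofactorSpec",
    "Reaction",
    "ReactionNetwork",
    "MassActionModel",
    "build_backbone",
    "couple_cofactors",
    "assign_thermodynamics",
    "assign_rates",
    "build_model",
    "build_minimal_model",
    "build_catalytic_variant",
    "sup_delta_mu",
    "EXCHANGE_FRACTION",
    "NUTRIENT_EXTERNAL",
    "LOG10_RATE_RANGE",
    "MU_RANGE",
]

# Study-condition constants. The log10 rate-constant range matches the
# empirical span of kinetic constants in genome-scale E. coli models; the
# nutrient is held at a 100-fold excess over the other externals.
EXCHANGE_FRACTION = 0.05
NUTRIENT_EXTERNAL = 100.0
LOG10_RATE_RANGE = (-3.66, 7.13)
MU_RANGE = (0.0, 1.0)


class ParameterError(ValueError):
    """Raised when generator parameters are infeasible."""


@dataclass(frozen=True)
class CofactorSpec:
    """A conserved pool of interconverting carrier forms.

    ``potentials`` are the standard chemical potentials of the forms, in
    strictly decreasing order (most activated first); ``total`` is the
    conserved pool concentration.
    """

    forms: tuple[str, str, str] = ("A**", "A*", "A")
    potentials: tuple[float, float, float] = (1.0, 0.5, 0.0)
    total: float = 1.0

    def __post_init__(self):
        if len(self.forms) != 3 or len(self.potentials) != 3:
            raise ParameterError("cofactor spec requires exactly 3 forms")
        if not (self.potentials[0] > self.potentials[1] > self.potentials[2]):
            raise ParameterError("cofactor potentials must be strictly decreasing")
        if self.total <= 0:
            raise ParameterError("cofactor total must be positive")


@dataclass
class Reaction:
    """One reversible reaction over state-vector indices.

    ``substrates``/``products`` are multisets of state indices (length 1 or
    2); for cofactor-coupled reactions ``cofactor_pair = (from_form,
    to_form)`` records which forms were attached; for the catalytic variant
    ``catalyst`` records the catalyst species (present on both sides).
    """

    substrates: tuple[int, ...]
    products: tuple[int, ...]
    v: float | None = None
    k_plus: float | None = None
    k_minus: float | None = None
    delta_mu: float | None = None
    cofactor_pair: tuple[int, int] | None = None
    catalyst: int | None = None

    @property
    def backbone_pair(self) -> tuple[int, int]:
        """(substrate, product) backbone species of the reaction."""
        return self.substrates[0], self.products[0]


@dataclass
class ReactionNetwork:
    """Species, reactions, exchange terms and (once assigned) potentials."""

    n_species: int
    reactions: list[Reaction]
    exchange: np.ndarray  # bool, length n_state
    external: np.ndarray  # float, length n_state
    cofactor: CofactorSpec | None = None
    mu: np.ndarray | None = None  # standard potentials, length n_state
    beta: float | None = None

    @property
    def n_state(self) -> int:
        return self.n_species + (3 if self.cofactor is not None else 0)

    @property
    def n_reactions(self) -> int:
        return len(self.reactions)

    @property
    def species_names(self) -> list[str]:
        names = [f"C{i + 1}" for i in range(self.n_species)]
        if self.cofactor is not None:
            names += list(self.cofactor.forms)
        return names

    def copy(self) -> "ReactionNetwork":
        return copy.deepcopy(self)


# ---------------------------------------------------------------------------
# backbone construction
# ---------------------------------------------------------------------------

def build_backbone(n_species: int, n_reactions: int, rng) -> ReactionNetwork:
    """Connect N chemicals by a linear chain C1-...-CN plus random extras.

    The chain uses N-1 uni-uni reactions; the remaining R-(N-1) reactions
    are drawn uniformly without replacement from the unordered species pairs
    not yet connected (no self-loops, no duplicate pairs).  Exchange with
    the environment is attached to Round(0.05*N) species, always including
    the two chain endpoints (so the network has no dead ends); the endpoint
    C1 is the nutrient with external concentration 100, all other exchanged
    species have external concentration 1.
    """
    rng = as_rng(rng)
    if n_species < 2:
        raise ParameterError("need at least 2 species")
    n_pairs = n_species * (n_species - 1) // 2
    if n_reactions < n_species - 1:
        raise ParameterError(
            f"need at least N-1={n_species - 1} reactions to connect {n_species} species"
        )
    if n_reactions > n_pairs:
        raise ParameterError(
            f"cannot place {n_reactions} distinct uni-uni reactions on "
            f"{n_species} species (max {n_pairs})"
        )

    reactions = [Reaction((i,), (i + 1,)) for i in range(n_species - 1)]
    n_extra = n_reactions - (n_species - 1)
    if n_extra > 0:
        # explicit complement of the chain edge set: rejection-free sampling
        pool = [
            (i, j)
            for i in range(n_species)
            for j in range(i + 1, n_species)
            if j != i + 1
        ]
        idx = rng.choice(len(pool), size=n_extra, replace=False)
        for k in idx:
            i, j = pool[k]
            reactions.append(Reaction((i,), (j,)))

    exchange = np.zeros(n_species, dtype=bool)
    external = np.ones(n_species, dtype=float)
    n_ex = max(2, round_half_away(EXCHANGE_FRACTION * n_species))
    n_ex = min(n_ex, n_species)
    exchange[0] = exchange[n_species - 1] = True
    remaining = n_ex - 2
    if remaining > 0:
        interior = np.arange(1, n_species - 1)
        picks = rng.choice(interior, size=remaining, replace=False)
        exchange[picks] = True
    external[0] = NUTRIENT_EXTERNAL  # C1 is the nutrient endpoint

    return ReactionNetwork(
        n_species=n_species,
        reactions=reactions,
        exchange=exchange,
        external=external,
    )


def couple_cofactors(
    net: ReactionNetwork,
    f: float,
    rng,
    cofactor: CofactorSpec | None = None,
) -> ReactionNetwork:
    """Couple Round(f*R) backbone reactions to cofactor interconversions.

    Each selected reaction gets two distinct cofactor forms attached with a
    random direction: the "from" form is consumed on the forward side of
    the reaction and the "to" form produced. Cofactors never appear as
    backbone species and carry no exchange.
    """
    rng = as_rng(rng)
    if not 0.0 <= f <= 1.0:
        raise ParameterError(f"coupling fraction f={f} outside [0, 1]")
    if net.cofactor is not None or any(r.cofactor_pair for r in net.reactions):
        raise ParameterError("network already carries cofactor couplings")
    net = net.copy()
    net.cofactor = cofactor or CofactorSpec()
    net.exchange = np.concatenate([net.exchange, np.zeros(3, dtype=bool)])
    net.external = np.concatenate([net.external, np.ones(3)])

    n_couple = round_half_away(f * net.n_reactions)
    chosen = rng.choice(net.n_reactions, size=n_couple, replace=False)
    base = net.n_species
    for r_idx in chosen:
        r = net.reactions[r_idx]
        frm, to = rng.permutation(3)[:2]
        net.reactions[r_idx] = replace(
            r,
            substrates=r.substrates + (base + int(frm),),
            products=r.products + (base + int(to),),
            cofactor_pair=(int(frm), int(to)),
        )
    return net


def assign_thermodynamics(net: ReactionNetwork, beta: float, rng) -> ReactionNetwork:
    """Draw standard potentials and set detailed-balance irreversibilities.

    Backbone potentials mu_n ~ U(0, 1); cofactor forms keep their fixed
    potentials.  For each reaction Delta_mu = sum_prd mu - sum_sub mu and
    k+- = min{1, exp(-+ beta * Delta_mu)}, so k+/k- = exp(-beta*Delta_mu)
    exactly (detailed balance) and the downhill direction has k = 1.
    """
    rng = as_rng(rng)
    net = net.copy()
    mu = rng.uniform(*MU_RANGE, size=net.n_species)
    if net.cofactor is not None:
        mu = np.concatenate([mu, np.asarray(net.cofactor.potentials)])
    net.mu = mu
    net.beta = float(beta)
    for i, r in enumerate(net.reactions):
        dmu = float(mu[list(r.products)].sum() - mu[list(r.substrates)].sum())
        net.reactions[i] = replace(
            r,
            delta_mu=dmu,
            k_plus=min(1.0, math.exp(-beta * dmu)),
            k_minus=min(1.0, math.exp(beta * dmu)),
        )
    return net


def assign_rates(net: ReactionNetwork, rng) -> ReactionNetwork:
    """Draw rate constants v_r = 10^u_r with u_r ~ U(-3.66, 7.13)."""
    rng = as_rng(rng)
    net = net.copy()
    u = rng.uniform(*LOG10_RATE_RANGE, size=net.n_reactions)
    for i, r in enumerate(net.reactions):
        net.reactions[i] = replace(r, v=float(10.0 ** u[i]))
    return net


def sup_delta_mu(cofactor: CofactorSpec | None, mu_range=MU_RANGE) -> float:
    """Largest |Delta_mu| any admissible reaction can carry.

    The backbone contributes at most the width of the potential range; a
    cofactor coupling adds at most the largest pairwise gap between form
    potentials. The catalyst of the catalytic variant appears on both sides
    and cancels, so pass ``cofactor=None`` for that variant.
    """
    span = mu_range[1] - mu_range[0]
    if cofactor is None:
        return span
    pots = cofactor.potentials
    return span + max(abs(a - b) for a in pots for b in pots)


# ---------------------------------------------------------------------------
# model assembly
# ---------------------------------------------------------------------------

class MassActionModel:
    """Fully parameterized mass-action kinetic model.

    Stacks backbone species then the three cofactor forms into one state
    vector and evaluates dx/dt = S J(x) + D (X - x) with per-reaction flux
    J_r = v_r (k+ prod_sub x - k- prod_prd x). The Jacobian is analytic.
    """

    kind = "mass_action"

    def __init__(self, network: ReactionNetwork, beta: float):
        for r in network.reactions:
            if r.v is None or r.k_plus is None or r.k_minus is None:
                raise ParameterError("reaction not fully parameterized")
        self.network = network
        self.beta = float(beta)
        m, nr = network.n_state, network.n_reactions
        self.n_state = m
        S = np.zeros((m, nr))
        sub = -np.ones((nr, 2), dtype=np.intp)
        prd = -np.ones((nr, 2), dtype=np.intp)
        for j, r in enumerate(network.reactions):
            for n in r.substrates:
                S[n, j] -= 1.0
            for n in r.products:
                S[n, j] += 1.0
            sub[j, : len(r.substrates)] = r.substrates
            prd[j, : len(r.products)] = r.products
        self.S = S
        self._sub1, self._sub2 = sub[:, 0], sub[:, 1]
        self._prd1, self._prd2 = prd[:, 0], prd[:, 1]
        self._sub2_mask = self._sub2 >= 0
        self._prd2_mask = self._prd2 >= 0
        self.v = np.array([r.v for r in network.reactions])
        self.k_plus = np.array([r.k_plus for r in network.reactions])
        self.k_minus = np.array([r.k_minus for r in network.reactions])
        self.D = network.exchange.astype(float)
        self.X = network.external.astype(float)
        self.exchange = network.exchange
        self.dynamic_mask = np.ones(m, dtype=bool)

    # -- contract -----------------------------------------------------------
    def fluxes(self, x: np.ndarray) -> np.ndarray:
        fwd = x[self._sub1] * np.where(self._sub2_mask, x[self._sub2], 1.0)
        bwd = x[self._prd1] * np.where(self._prd2_mask, x[self._prd2], 1.0)
        return self.v * (self.k_plus * fwd - self.k_minus * bwd)

    def _rhs_numpy(self, x: np.ndarray) -> np.ndarray:
        return self.S @ self.fluxes(x) + self.D * (self.X - x)

    def rhs(self, x: np.ndarray) -> np.ndarray:
        if _HAVE_NUMBA:
            return _rhs_kernel(
                np.asarray(x, dtype=float), self.v, self.k_plus, self.k_minus,
                self._sub1, self._sub2, self._prd1, self._prd2, self.D, self.X,
            )
        return self._rhs_numpy(x)

    def flux_scale(self, x: np.ndarray) -> float:
        if _HAVE_NUMBA:
            return float(_fluxmax_kernel(
                np.asarray(x, dtype=float), self.v, self.k_plus, self.k_minus,
                self._sub1, self._sub2, self._prd1, self._prd2,
            ))
        J = np.abs(self.fluxes(x))
        return float(J.max()) if J.size else 0.0

    def conv_measure(self, x, eps_abs, eps_rel, eps_logv) -> float:
        """Fused relaxation-criterion evaluation (hot path of the solver's
        terminal convergence event); semantics match the generic fallback
        in :mod:`kinresp.dynamics`."""
        if _HAVE_NUMBA:
            return float(_conv_kernel(
                np.asarray(x, dtype=float), self.v, self.k_plus, self.k_minus,
                self._sub1, self._sub2, self._prd1, self._prd2, self.D, self.X,
                eps_abs, eps_rel, eps_logv,
            ))
        dx = np.abs(self._rhs_numpy(x))
        g_flux = float(dx.max()) - (eps_abs + eps_rel * self.flux_scale(x))
        g_logv = float((dx / (np.abs(x) + 1e-300)).max()) - eps_logv
        return min(g_flux, g_logv)

    def _jac_numpy(self, x: np.ndarray) -> np.ndarray:
        nr, m = len(self.v), self.n_state
        dJ = np.zeros((nr, m))
        rows = np.arange(nr)
        vkp, vkm = self.v * self.k_plus, self.v * self.k_minus
        x2s = np.where(self._sub2_mask, x[self._sub2], 1.0)
        x2p = np.where(self._prd2_mask, x[self._prd2], 1.0)
        np.add.at(dJ, (rows, self._sub1), vkp * x2s)
        bi = self._sub2_mask
        np.add.at(dJ, (rows[bi], self._sub2[bi]), (vkp * x[self._sub1])[bi])
        np.add.at(dJ, (rows, self._prd1), -vkm * x2p)
        bi = self._prd2_mask
        np.add.at(dJ, (rows[bi], self._prd2[bi]), (-vkm * x[self._prd1])[bi])
        return self.S @ dJ - np.diag(self.D)

    def jac(self, x: np.ndarray) -> np.ndarray:
        if _HAVE_NUMBA:
            return _jac_kernel(
                np.asarray(x, dtype=float), self.v, self.k_plus, self.k_minus,
                self._sub1, self._sub2, self._prd1, self._prd2, self.D,
            )
        return self._jac_numpy(x)

    def default_initial(self) -> np.ndarray:
        x0 = np.ones(self.n_state)
        cof = self.network.cofactor
        if cof is not None:
            x0[self.network.n_species:] = cof.total / 3.0
        return x0

    def closed_copy(self) -> "MassActionModel":
        """Variant with all exchange removed (closed system)."""
        net = self.network.copy()
        net.exchange = np.zeros_like(net.exchange)
        return MassActionModel(net, self.beta)


def build_model(net: ReactionNetwork, beta: float | None = None) -> MassActionModel:
    if beta is None:
        beta = net.beta
    if beta is None:
        raise ParameterError("beta not set; assign thermodynamics first")
    return MassActionModel(net, beta)


def build_minimal_model(
    n_species: int = 64,
    n_reactions: int = 96,
    f: float = 0.5,
    beta: float = 10.0,
    rng=None,
    cofactor: CofactorSpec | None = None,
) -> MassActionModel:
    """One-shot construction of the minimal cofactor model."""
    rng = as_rng(rng)
    net = build_backbone(n_species, n_reactions, rng)
    net = couple_cofactors(net, f, rng, cofactor=cofactor)
    net = assign_thermodynamics(net, beta, rng)
    net = assign_rates(net, rng)
    return build_model(net, beta)


def build_catalytic_variant(
    n_species: int = 67,
    n_reactions: int = 96,
    beta: float = 20.0,
    rng=None,
) -> MassActionModel:
    """Catalytic variant: each reaction C_n + C_l <=> C_m + C_l.

    The catalyst C_l is drawn uniformly over all species (autocatalysis
    allowed), so every flux is bilinear like the fully coupled (f=1)
    cofactor model, but no conserved carrier pool exists.  Default beta is
    twice the cofactor model's because the maximum potential difference is
    1.0 here versus 2.0 with cofactors.
    """
    rng = as_rng(rng)
    net = build_backbone(n_species, n_reactions, rng)
    for i, r in enumerate(net.reactions):
        cat = int(rng.integers(net.n_species))
        net.reactions[i] = replace(
            r,
            substrates=r.substrates + (cat,),
            products=r.products + (cat,),
            catalyst=cat,
        )
    net = assign_thermodynamics(net, beta, rng)
    net = assign_rates(net, rng)
    return build_model(net, beta)
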