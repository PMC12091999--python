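"""Random catalytic reaction network (RCRN) toy cell model.

Every metabolite doubles as a catalyst.  The dynamics of concentration
x_i are

    dx_i/dt = sum_{j,k} x_k (v_ijk x_j - v_jik x_i)
              + D_i x_{T(i)} x_i_ext - mu * x_i,

where v_ijk is the rate constant of C_j -> C_i catalyzed by C_k, D_i flags
nutrient uptake, T(i) is the transporter metabolite mediating uptake of
C_i, and the growth-dilution rate equals the total uptake,
mu = sum_i D_i x_{T(i)} x_i_ext.  Only the first metabolite is taken up
(D_1 = 1, external concentration 1) and its transporter is the last
metabolite.  The catalytic part conserves total concentration exactly, so
d(sum x)/dt = mu (1 - sum x) and attractors sit on the simplex sum x = 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .minimal_model import LOG10_RATE_RANGE, ParameterError
from .util import as_rng

__all__ = ["RcrnInstance", "build_rcrn", "rcrn_rhs", "default_rate_pool"]


def default_rate_pool(n: int, rng) -> np.ndarray:
    """Log-uniform rate-constant pool matching the minimal model's v_r range."""
    rng = as_rng(rng)
    return 10.0 ** rng.uniform(*LOG10_RATE_RANGE, size=n)


@dataclass
class RcrnInstance:
    """One RCRN model: directed rate entries plus uptake bookkeeping.

    ``prod``/``sub``/``cat``/``rate`` are parallel arrays over directed
    reactions (both directions of each reversible edge appear).
    """

    n_species: int
    prod: np.ndarray
    sub: np.ndarray
    cat: np.ndarray
    rate: np.ndarray
    uptake: np.ndarray        # D_i
    external: np.ndarray      # x_i_ext
    transporter: np.ndarray   # T(i)
    edges: list[tuple[int, int, int]]  # (i, j, catalyst) per undirected edge

    kind = "rcrn"

    @property
    def n_state(self) -> int:
        return self.n_species

    # -- model contract -----------------------------------------------------
    def _uptake_terms(self, x: np.ndarray) -> np.ndarray:
        return self.uptake * x[self.transporter] * self.external

    def growth_rate(self, x: np.ndarray) -> float:
        return float(self._uptake_terms(x).sum())

    def fluxes(self, x: np.ndarray) -> np.ndarray:
        """Directed catalytic fluxes v_ijk * x_j * x_k."""
        return self.rate * x[self.sub] * x[self.cat]

    def net_edge_fluxes(self, x: np.ndarray) -> np.ndarray:
        """Net flux per reversible edge (forward minus backward direction)."""
        J = self.fluxes(x)
        return J[0::2] - J[1::2]

    def flux_scale(self, x: np.ndarray) -> float:
        # directed fluxes of one edge nearly cancel near equilibrium, so the
        # characteristic scale uses net edge fluxes plus uptake and dilution
        J = np.abs(self.net_edge_fluxes(x))
        up = self._uptake_terms(x)
        dil = up.sum() * float(x.max(initial=0.0))
        return float(max(J.max(initial=0.0), up.max(initial=0.0), dil))

    def rhs(self, x: np.ndarray) -> np.ndarray:
        if np.any(x < 0):
            raise ValueError("negative concentration passed to RCRN rhs")
        J = self.fluxes(x)
        dx = np.zeros(self.n_species)
        np.add.at(dx, self.prod, J)
        np.subtract.at(dx, self.sub, J)
        up = self._uptake_terms(x)
        return dx + up - up.sum() * x

    def jac(self, x: np.ndarray) -> np.ndarray:
        n = self.n_species
        J = np.zeros((n, n))
        # catalytic terms: d/dx_s and d/dx_c of rate*x_s*x_c on rows prod/sub
        vs, vc = self.rate * x[self.cat], self.rate * x[self.sub]
        np.add.at(J, (self.prod, self.sub), vs)
        np.add.at(J, (self.prod, self.cat), vc)
        np.subtract.at(J, (self.sub, self.sub), vs)
        np.subtract.at(J, (self.sub, self.cat), vc)
        # uptake D_i x_T(i) X_i on row i, derivative wrt the transporter
        up = np.flatnonzero(self.uptake)
        np.add.at(J, (up, self.transporter[up]), self.uptake[up] * self.external[up])
        # dilution -mu(x) x_i with mu = sum_i D_i x_T(i) X_i
        np.fill_diagonal(J, J.diagonal() - self.growth_rate(x))
        dmu = np.zeros(n)
        np.add.at(dmu, self.transporter[up], self.uptake[up] * self.external[up])
        J -= np.outer(x, dmu)
        return J

    def default_initial(self) -> np.ndarray:
        return np.full(self.n_species, 1.0 / self.n_species)


def build_rcrn(
    n_species: int,
    n_reactions: int,
    rate_pool: np.ndarray | None = None,
    rng=None,
    max_retries: int = 200,
) -> RcrnInstance:
    """Generate a connected RCRN instance.

    Draws an Erdos-Renyi-style uniform edge set of ``n_reactions``
    undirected edges (redrawn until connected, up to a retry cap), assigns
    one uniform-random catalyst per edge, and samples both directed rate
    constants from ``rate_pool`` (default: the minimal model's log-uniform
    v_r distribution).
    """
    rng = as_rng(rng)
    if n_species < 2:
        raise ParameterError("need at least 2 species")
    n_pairs = n_species * (n_species - 1) // 2
    if n_reactions < n_species - 1:
        raise ParameterError("too few reactions for a connected network")
    if n_reactions > n_pairs:
        raise ParameterError("more reactions than distinct species pairs")

    pairs = [(i, j) for i in range(n_species) for j in range(i + 1, n_species)]
    for _ in range(max_retries):
        idx = rng.choice(n_pairs, size=n_reactions, replace=False)
        g = nx.Graph(pairs[k] for k in idx)
        if g.number_of_nodes() == n_species and nx.is_connected(g):
            break
    else:
        raise ParameterError(
            f"no connected draw in {max_retries} tries for N={n_species}, R={n_reactions}"
        )

    if rate_pool is None:
        rate_pool = default_rate_pool(max(64, 2 * n_reactions), rng)
    rate_pool = np.asarray(rate_pool, dtype=float)
    if rate_pool.size == 0 or np.any(rate_pool <= 0):
        raise ParameterError("rate pool must be nonempty and positive")

    edges, prod, sub, cat, rate = [], [], [], [], []
    for k in idx:
        i, j = pairs[k]
        c = int(rng.integers(n_species))
        edges.append((i, j, c))
        for p, s in ((i, j), (j, i)):  # reversible: both directions present
            prod.append(p)
            sub.append(s)
            cat.append(c)
            rate.append(float(rng.choice(rate_pool)))

    uptake = np.zeros(n_species)
    external = np.zeros(n_species)
    transporter = np.zeros(n_species, dtype=np.intp)
    uptake[0] = 1.0      # single nutrient metabolite
    external[0] = 1.0
    transporter[0] = n_species - 1  # the last metabolite is its transporter

    return RcrnInstance(
        n_species=n_species,
        prod=np.array(prod, dtype=np.intp),
        sub=np.array(sub, dtype=np.intp),
        cat=np.array(cat, dtype=np.intp),
        rate=np.array(rate),
        uptake=uptake,
        external=external,
        transporter=transporter,
        edges=edges,
    )


def rcrn_rhs(inst: RcrnInstance, x: np.ndarray) -> np.ndarray:
    """Functional alias for :meth:`RcrnInstance.rhs`."""
    return inst.rhs(np.asarray(x, dtype=float))
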