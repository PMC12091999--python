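"""Network expansion: densify a model with random reactions, re-measure chi.

Random uni-uni reactions between existing non-cofactor species are added
(never new species), each upgraded with probability p to a bi-bi reaction
coupled to the cofactor pool, where p defaults to the fraction of
cofactor-coupled reactions in the base model.  Parameters of added
reactions are bootstrap-resampled from the base model's per-scheme rate
pools; irreversibility factors follow from the already-assigned standard
potentials, keeping the extended model thermodynamically consistent.
Extended models are screened for a unique attractor before the
perturbation-response protocol runs.

The module also provides the enzymatic rate-law templates (reversible
Michaelis-Menten, ordered bi-bi, factorized bi-bi) used when expanding
plug-in models with saturating kinetics, and the elementary reaction
decomposition (ERD) that rewrites an enzymatic reaction as mass-action
binding/conversion/release steps with a conserved enzyme moiety.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .dynamics import (
    AttractorNotFoundError,
    ScreeningError,
    conserved_pools,
    find_attractor,
    screen_multistability,
)
from .minimal_model import MassActionModel, ParameterError, Reaction, build_model
from .response import EnsembleError, perturb_state, response_distribution
from .util import as_rng

logger = logging.getLogger(__name__)

__all__ = [
    "sample_added_reaction",
    "add_random_reactions",
    "reversible_mm",
    "ordered_bibi",
    "factorized_bibi",
    "ElementaryStep",
    "ErdNetwork",
    "erd_decompose",
    "ExpansionResult",
    "expand_and_measure",
    "cofactor_coupling_probability",
]


# ---------------------------------------------------------------------------
# reaction sampling
# ---------------------------------------------------------------------------

def cofactor_coupling_probability(model: MassActionModel) -> float:
    """Fraction of cofactor-coupled reactions in the model."""
    rxns = model.network.reactions
    return sum(r.cofactor_pair is not None for r in rxns) / len(rxns)


def _scheme_pool(model: MassActionModel, coupled: bool) -> np.ndarray:
    pool = np.array(
        [r.v for r in model.network.reactions if (r.cofactor_pair is not None) == coupled]
    )
    if pool.size == 0:  # no same-scheme reaction to resample from
        pool = np.array([r.v for r in model.network.reactions])
    return pool


def sample_added_reaction(
    base: MassActionModel, p_cofactor: float | None = None, rng=None
) -> Reaction:
    """Draw one random addition, parameterized from the base model.

    A uni-uni reaction between two distinct random non-cofactor species;
    with probability ``p_cofactor`` (default: the base model's coupled
    fraction) it is upgraded to a bi-bi reaction interconverting two random
    cofactor forms.  v is bootstrap-resampled from the base model's
    same-scheme rate pool; k+- follow from the base potentials via the
    detailed-balance rule.
    """
    rng = as_rng(rng)
    net = base.network
    if net.mu is None or net.beta is None:
        raise ParameterError("base model lacks assigned thermodynamics")
    if net.n_species < 2:
        raise ParameterError("need at least 2 non-cofactor species")
    if p_cofactor is None:
        p_cofactor = cofactor_coupling_probability(base)
    if p_cofactor > 0 and net.cofactor is None:
        raise ParameterError("cofactor coupling requested on a cofactor-free base")

    a, b = rng.choice(net.n_species, size=2, replace=False)
    subs, prds = (int(a),), (int(b),)
    pair = None
    coupled = bool(p_cofactor > 0 and rng.random() < p_cofactor)
    if coupled:
        frm, to = rng.permutation(3)[:2]
        subs += (net.n_species + int(frm),)
        prds += (net.n_species + int(to),)
        pair = (int(frm), int(to))
    v = float(rng.choice(_scheme_pool(base, coupled)))
    mu = net.mu
    dmu = float(mu[list(prds)].sum() - mu[list(subs)].sum())
    beta = net.beta
    return Reaction(
        substrates=subs,
        products=prds,
        v=v,
        k_plus=min(1.0, float(np.exp(-beta * dmu))),
        k_minus=min(1.0, float(np.exp(beta * dmu))),
        delta_mu=dmu,
        cofactor_pair=pair,
    )


def add_random_reactions(
    base: MassActionModel, n_add: int, rng=None, p_cofactor: float | None = None
) -> MassActionModel:
    """Extended copy of the model with ``n_add`` sampled reactions appended.

    Duplicate reactant pairs are permitted; the species set never changes.
    """
    rng = as_rng(rng)
    net = base.network.copy()
    for _ in range(n_add):
        net.reactions.append(sample_added_reaction(base, p_cofactor, rng))
    return build_model(net, base.beta)


# ---------------------------------------------------------------------------
# enzymatic rate-law templates (for plug-in models with saturating kinetics)
# ---------------------------------------------------------------------------

def reversible_mm(s1, p1, v_plus, v_minus, k_s1, k_p1):
    """Reversible Michaelis-Menten rate for a uni-uni reaction."""
    return (v_plus * s1 - v_minus * p1) / (1.0 + s1 / k_s1 + p1 / k_p1)


def ordered_bibi(s1, s2, p1, p2, v_plus, v_minus, k_s1, k_s2, k_p1, k_p2):
    """Ordered bi-bi rate law (substrates bind in a fixed order)."""
    num = v_plus * s1 * s2 - v_minus * p1 * p2
    den = (1.0 + s1 / k_s1 + p1 / k_p1
           + s1 * s2 / (k_s1 * k_s2) + p1 * p2 / (k_p1 * k_p2))
    return num / den


def factorized_bibi(s1, s2, p1, p2, v_plus, v_minus, k_s1, k_s2, k_p1, k_p2):
    """Bi-bi rate with a factorized (independent-site) denominator."""
    num = v_plus * s1 * s2 - v_minus * p1 * p2
    den = (1.0 + s1 / k_s1 + p1 / k_p1) * (1.0 + s2 / k_s2 + p2 / k_p2)
    return num / den


# ---------------------------------------------------------------------------
# elementary reaction decomposition
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ElementaryStep:
    """One irreversible mass-action step (forward and backward reactions of
    a reversible step are separate entries)."""

    reactants: tuple[str, ...]
    products: tuple[str, ...]
    k: float


@dataclass
class ErdNetwork:
    """Elementary decomposition of one enzymatic reaction.

    ``enzyme_forms`` lists the free enzyme and its complexes; their summed
    concentration is the conserved enzyme moiety (= ``enzyme_total``).
    """

    metabolites: tuple[str, ...]
    enzyme_forms: tuple[str, ...]
    steps: tuple[ElementaryStep, ...]
    enzyme_total: float

    def qss_flux(self, met_conc: dict[str, float]) -> float:
        """Steady-state flux at fixed metabolite concentrations.

        Solves the linear steady state of the enzyme forms (rates are
        linear in the forms once metabolites are held fixed) under the
        enzyme conservation constraint, then evaluates the net rate of the
        first binding step (equal to every other net step rate at steady
        state).
        """
        forms = {f: i for i, f in enumerate(self.enzyme_forms)}
        nf = len(forms)
        A = np.zeros((nf, nf))
        for st in self.steps:
            f_in = [s for s in st.reactants if s in forms]
            f_out = [s for s in st.products if s in forms]
            coeff = st.k
            for s in st.reactants:
                if s not in forms:
                    coeff *= met_conc[s]
            i, j = forms[f_in[0]], forms[f_out[0]]
            A[i, i] -= coeff
            A[j, i] += coeff
        A[-1, :] = 1.0
        b = np.zeros(nf)
        b[-1] = self.enzyme_total
        e = np.linalg.solve(A, b)
        # net flux through the first (substrate binding) reversible step
        fwd, bwd = self.steps[0], self.steps[1]
        rate = lambda st: st.k * np.prod(
            [e[forms[s]] if s in forms else met_conc[s] for s in st.reactants]
        )
        return float(rate(fwd) - rate(bwd))


def erd_decompose(
    substrates: tuple[str, ...] | list[str],
    products: tuple[str, ...] | list[str],
    enzyme_total: float = 1.0,
    rate_constants: list[tuple[float, float]] | None = None,
    enzyme: str = "E",
) -> ErdNetwork:
    """Decompose a uni-uni, bi-uni or bi-bi reaction into elementary steps.

    Uni-uni A<=>B yields E+A<=>EA, EA<=>EB, EB<=>E+B (3 reversible steps,
    3 new enzyme species).  Bi-uni A+B<=>C yields the 4-step ordered
    scheme E+A<=>EA, EA+B<=>EAB, EAB<=>EC, EC<=>E+C; bi-bi adds an ordered
    product release.  ``rate_constants`` supplies (k_forward, k_backward)
    per reversible step, defaulting to 1.
    """
    substrates, products = tuple(substrates), tuple(products)
    ns, np_ = len(substrates), len(products)
    if ns not in (1, 2) or np_ not in (1, 2):
        raise ParameterError("ERD supports uni-uni, bi-uni and bi-bi reactions only")

    E = enzyme
    forms = [E]
    rev: list[tuple[tuple[str, ...], tuple[str, ...]]] = []
    # ordered substrate binding
    acc = E
    for s in substrates:
        nxt = acc + s if acc != E else f"{E}{s}"
        rev.append(((acc, s), (nxt,)))
        forms.append(nxt)
        acc = nxt
    # internal conversion to the product-side complex
    prod_complex = f"{E}{''.join(products)}"
    rev.append(((acc,), (prod_complex,)))
    forms.append(prod_complex)
    # ordered product release
    acc = prod_complex
    for i, p in enumerate(products):
        rest = "".join(products[i + 1:])
        nxt = f"{E}{rest}" if rest else E
        if nxt == E:
            rev.append(((acc,), (E, p)))
        else:
            rev.append(((acc,), (nxt, p)))
            forms.append(nxt)
        acc = nxt

    if rate_constants is None:
        rate_constants = [(1.0, 1.0)] * len(rev)
    if len(rate_constants) != len(rev):
        raise ParameterError(f"expected {len(rev)} (k_f, k_b) pairs")
    steps = []
    for (reac, prod), (kf, kb) in zip(rev, rate_constants):
        steps.append(ElementaryStep(reac, prod, float(kf)))
        steps.append(ElementaryStep(prod, reac, float(kb)))
    # deduplicate forms, preserve order
    seen: dict[str, None] = {}
    for f in forms:
        seen.setdefault(f)
    return ErdNetwork(
        metabolites=substrates + products,
        enzyme_forms=tuple(seen),
        steps=tuple(steps),
        enzyme_total=float(enzyme_total),
    )


# ---------------------------------------------------------------------------
# expansion ensembles
# ---------------------------------------------------------------------------

@dataclass
class ExpansionResult:
    n_add: int
    mean_chis: list[float]
    n_rejected_multistable: int
    n_rejected_failed: int

    @property
    def n_accepted(self) -> int:
        return len(self.mean_chis)


def _network_rngs(seed: int, i: int):
    """(sample, screen, respond) child generators for extension i."""
    child = np.random.SeedSequence(seed).spawn(i + 1)[i]
    return [np.random.default_rng(s) for s in child.spawn(3)]


def expand_and_measure(
    base: MassActionModel,
    x_st: np.ndarray,
    n_add: int,
    n_networks: int,
    n_ini: int = 128,
    strength: float = 0.4,
    seed: int = 0,
    n_screen: int = 128,
    p_cofactor: float | None = None,
    accept_hook=None,
    **relax_kwargs,
) -> ExpansionResult:
    """Measure mean chi over an ensemble of randomly extended models.

    For each extension: add ``n_add`` sampled reactions, screen the
    extended model with ``n_screen`` initial states obtained by perturbing
    the base attractor; only extensions relaxing to a single attractor are
    accepted, and their response ensemble uses a fresh perturbation set
    around the *extended* model's attractor.  ``accept_hook(model, x_st)``
    can impose extra acceptance conditions (e.g. a minimum steady growth
    rate); it is None by default.
    """
    x_st = np.asarray(x_st, dtype=float)
    mean_chis: list[float] = []
    n_multi = n_fail = 0
    for i in range(n_networks):
        rng_sample, rng_screen, rng_respond = _network_rngs(seed, i)
        try:
            ext = add_random_reactions(base, n_add, rng_sample, p_cofactor)
            pools = conserved_pools(ext)
            x0_set = [
                perturb_state(x_st, strength, pools, rng_screen)
                for _ in range(n_screen)
            ]
            screen = screen_multistability(ext, x0_set=x0_set, **relax_kwargs)
            if not screen.single_attractor:
                n_multi += 1
                continue
            st = find_attractor(ext, [screen.attractors[0]], **relax_kwargs)
            if not st.stable:
                n_fail += 1
                continue
            if accept_hook is not None and not accept_hook(ext, st.x_st):
                n_fail += 1
                continue
            ens = response_distribution(
                ext, st.x_st, n_ini=n_ini, strength=strength,
                rng=rng_respond, pools=pools, **relax_kwargs,
            )
        except (ScreeningError, AttractorNotFoundError, EnsembleError) as exc:
            logger.info("extension %d rejected: %s", i, exc)
            n_fail += 1
            continue
        mean_chis.append(ens.mean_chi)
    if not mean_chis:
        raise EnsembleError(
            f"all {n_networks} extensions rejected "
            f"({n_multi} multistable, {n_fail} failed)"
        )
    return ExpansionResult(n_add, mean_chis, n_multi, n_fail)
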