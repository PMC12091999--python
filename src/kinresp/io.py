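"""Serialization, result tables and ensemble sweeps.

Models round-trip losslessly through JSON (floats are written with full
double precision, so reloaded models reproduce RHS evaluations bit for
bit).  Reaction graphs export to GraphML.  ``run_sweep`` drives the
Fig-4-style ensembles: grids over (R, f) for the minimal cofactor model or
over R for the catalytic variant, one tidy CSV row per generated network,
plus a JSON manifest carrying the seed, tolerances, versions and failure
accounting needed to reproduce every stochastic output exactly.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from . import __version__
from .dynamics import (
    AttractorNotFoundError,
    ScreeningError,
    find_attractor,
    screen_multistability,
)
from .minimal_model import (
    CofactorSpec,
    MassActionModel,
    Reaction,
    ReactionNetwork,
    build_catalytic_variant,
    build_minimal_model,
    build_model,
)
from .rcrn import RcrnInstance, build_rcrn
from .response import EnsembleError, response_distribution

logger = logging.getLogger(__name__)

__all__ = [
    "serialize_model",
    "load_model",
    "save_model",
    "model_to_dict",
    "model_from_dict",
    "to_graphml",
    "run_sweep",
    "SchemaError",
]

SCHEMA_VERSION = 1


class SchemaError(ValueError):
    pass


# ---------------------------------------------------------------------------
# model (de)serialization
# ---------------------------------------------------------------------------

def model_to_dict(model) -> dict:
    head = {"format": "kinresp-model", "schema": SCHEMA_VERSION}
    if isinstance(model, MassActionModel):
        net = model.network
        return {
            **head,
            "kind": "mass_action",
            "beta": model.beta,
            "n_species": net.n_species,
            "cofactor": None if net.cofactor is None else {
                "forms": list(net.cofactor.forms),
                "potentials": list(net.cofactor.potentials),
                "total": net.cofactor.total,
            },
            "mu": None if net.mu is None else net.mu.tolist(),
            "exchange": np.flatnonzero(net.exchange).tolist(),
            "external": net.external.tolist(),
            "reactions": [
                {
                    "substrates": list(r.substrates),
                    "products": list(r.products),
                    "v": r.v,
                    "k_plus": r.k_plus,
                    "k_minus": r.k_minus,
                    "delta_mu": r.delta_mu,
                    "cofactor_pair": None if r.cofactor_pair is None else list(r.cofactor_pair),
                    "catalyst": r.catalyst,
                }
                for r in net.reactions
            ],
        }
    if isinstance(model, RcrnInstance):
        return {
            **head,
            "kind": "rcrn",
            "n_species": model.n_species,
            "edges": [list(e) for e in model.edges],
            "prod": model.prod.tolist(),
            "sub": model.sub.tolist(),
            "cat": model.cat.tolist(),
            "rate": model.rate.tolist(),
            "uptake": model.uptake.tolist(),
            "external": model.external.tolist(),
            "transporter": model.transporter.tolist(),
        }
    raise TypeError(f"cannot serialize model of type {type(model).__name__}")


def model_from_dict(d: dict):
    if d.get("format") != "kinresp-model" or d.get("schema") != SCHEMA_VERSION:
        raise SchemaError(
            f"unsupported model file (format={d.get('format')!r}, schema={d.get('schema')!r})"
        )
    if d["kind"] == "mass_action":
        cof = None
        if d["cofactor"] is not None:
            c = d["cofactor"]
            cof = CofactorSpec(tuple(c["forms"]), tuple(c["potentials"]), c["total"])
        n_state = d["n_species"] + (3 if cof else 0)
        exchange = np.zeros(n_state, dtype=bool)
        exchange[d["exchange"]] = True
        net = ReactionNetwork(
            n_species=d["n_species"],
            reactions=[
                Reaction(
                    substrates=tuple(r["substrates"]),
                    products=tuple(r["products"]),
                    v=r["v"],
                    k_plus=r["k_plus"],
                    k_minus=r["k_minus"],
                    delta_mu=r["delta_mu"],
                    cofactor_pair=None if r["cofactor_pair"] is None else tuple(r["cofactor_pair"]),
                    catalyst=r["catalyst"],
                )
                for r in d["reactions"]
            ],
            exchange=exchange,
            external=np.array(d["external"]),
            cofactor=cof,
            mu=None if d["mu"] is None else np.array(d["mu"]),
            beta=d["beta"],
        )
        return build_model(net, d["beta"])
    if d["kind"] == "rcrn":
        return RcrnInstance(
            n_species=d["n_species"],
            prod=np.array(d["prod"], dtype=np.intp),
            sub=np.array(d["sub"], dtype=np.intp),
            cat=np.array(d["cat"], dtype=np.intp),
            rate=np.array(d["rate"]),
            uptake=np.array(d["uptake"]),
            external=np.array(d["external"]),
            transporter=np.array(d["transporter"], dtype=np.intp),
            edges=[tuple(e) for e in d["edges"]],
        )
    raise SchemaError(f"unknown model kind {d['kind']!r}")


def serialize_model(model, path: str | Path) -> None:
    Path(path).write_text(json.dumps(model_to_dict(model), indent=1))


save_model = serialize_model


def load_model(path: str | Path):
    return model_from_dict(json.loads(Path(path).read_text()))


def to_graphml(model, path: str | Path) -> None:
    """Export the reaction graph (one node per species, one edge per reaction)."""
    g = nx.MultiGraph()
    if isinstance(model, MassActionModel):
        names = model.network.species_names
        g.add_nodes_from(names)
        for r in model.network.reactions:
            a, b = r.backbone_pair
            g.add_edge(
                names[a], names[b],
                v=r.v, k_plus=r.k_plus, k_minus=r.k_minus,
                cofactor_pair="" if r.cofactor_pair is None else f"{r.cofactor_pair}",
                catalyst=-1 if r.catalyst is None else r.catalyst,
            )
    elif isinstance(model, RcrnInstance):
        g.add_nodes_from(range(model.n_species))
        for i, j, c in model.edges:
            g.add_edge(i, j, catalyst=c)
    else:
        raise TypeError(f"cannot export model of type {type(model).__name__}")
    nx.write_graphml(g, path)


# ---------------------------------------------------------------------------
# ensemble sweeps
# ---------------------------------------------------------------------------

def _config_hash(config: dict) -> str:
    return hashlib.sha256(json.dumps(config, sort_keys=True).encode()).hexdigest()[:16]


def run_sweep(
    kind: str = "minimal",
    n_species: int = 16,
    r_values=(15, 23, 31),
    f_values=(0.75,),
    beta: float = 10.0,
    n_networks: int = 64,
    n_traj: int = 32,
    strength: float = 0.4,
    seed: int = 0,
    n_screen: int = 0,
    reltol: float = 1e-6,
    abstol: float = 1e-9,
    outdir: str | Path | None = None,
    keep_chis: bool = False,
) -> tuple[pd.DataFrame, dict]:
    """Ensemble of random networks per (R, f) grid cell; one row per network.

    ``kind`` is 'minimal' (cofactor model; f grid applies), 'catalytic'
    (f ignored) or 'rcrn'.  ``n_screen`` > 0 additionally screens each
    network for multistability from log-uniform random starts and excludes
    multistable instances (always on, with 32 starts, for RCRN).  Returns
    the tidy result table and a manifest; with ``outdir`` both are written
    (results.csv, manifest.json) byte-reproducibly.
    """
    if kind not in ("minimal", "catalytic", "rcrn"):
        raise ValueError(f"unknown sweep kind {kind!r}")
    fs = list(f_values) if kind == "minimal" else [None]
    cells = [(int(r), f) for r in r_values for f in fs]
    config = {
        "kind": kind, "n_species": n_species, "r_values": [int(r) for r in r_values],
        "f_values": [None if f is None else float(f) for f in fs], "beta": beta,
        "n_networks": n_networks, "n_traj": n_traj, "strength": strength,
        "seed": seed, "n_screen": n_screen, "reltol": reltol, "abstol": abstol,
    }
    relax_kwargs = {"reltol": reltol, "abstol": abstol}
    rows = []
    n_excluded = {"multistable": 0, "failed": 0}
    cell_seeds = np.random.SeedSequence(seed).spawn(len(cells))
    for (r_val, f), cell_ss in zip(cells, cell_seeds):
        for i, net_ss in enumerate(cell_ss.spawn(n_networks)):
            rng_build, rng_respond, rng_screen = (
                np.random.default_rng(s) for s in net_ss.spawn(3)
            )
            row = {"kind": kind, "R": r_val, "f": np.nan if f is None else f,
                   "network": i, "mean_chi": np.nan, "n_failed": -1, "status": "ok"}
            try:
                if kind == "minimal":
                    model = build_minimal_model(n_species, r_val, f, beta, rng_build)
                elif kind == "catalytic":
                    model = build_catalytic_variant(n_species, r_val, beta, rng_build)
                else:
                    model = build_rcrn(n_species, r_val, rng=rng_build)
                screen_n = 32 if kind == "rcrn" else n_screen
                if screen_n:
                    screen = screen_multistability(
                        model, n_init=screen_n, rng=rng_screen, **relax_kwargs
                    )
                    if not screen.single_attractor:
                        row["status"] = "multistable"
                        n_excluded["multistable"] += 1
                        rows.append(row)
                        continue
                    x0_set = [screen.attractors[0]]
                else:
                    x0_set = [model.default_initial()]
                st = find_attractor(model, x0_set, **relax_kwargs)
                if not st.stable:
                    raise AttractorNotFoundError("attractor not linearly stable")
                ens = response_distribution(
                    model, st.x_st, n_ini=n_traj, strength=strength,
                    rng=rng_respond, **relax_kwargs,
                )
            except (AttractorNotFoundError, EnsembleError, ScreeningError) as exc:
                logger.info("network (R=%s, f=%s, %d) excluded: %s", r_val, f, i, exc)
                row["status"] = "failed"
                n_excluded["failed"] += 1
                rows.append(row)
                continue
            row.update(mean_chi=ens.mean_chi, n_failed=ens.n_failed)
            if keep_chis:
                row["chis"] = ens.chis
            rows.append(row)
    df = pd.DataFrame(rows)
    manifest = {
        "config": config,
        "config_hash": _config_hash(config),
        "seed": seed,
        "excluded": n_excluded,
        "versions": {"kinresp": __version__, "numpy": np.__version__},
    }
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        df.drop(columns=["chis"], errors="ignore").to_csv(outdir / "results.csv", index=False)
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return df, manifest


def plot_sweep(df: pd.DataFrame, path: str | Path) -> None:
    """Violin summary of mean chi per (R, f) cell."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ok = df[df["status"] == "ok"]
    labels, groups = [], []
    for (r, f), grp in ok.groupby(["R", "f"], dropna=False):
        labels.append(f"R={r}" + ("" if pd.isna(f) else f", f={f}"))
        groups.append(grp["mean_chi"].to_numpy())
    fig, ax = plt.subplots(figsize=(1.2 * len(groups) + 2, 4))
    if groups:
        ax.violinplot(groups, showmeans=True)
        ax.set_xticks(range(1, len(groups) + 1), labels, rotation=45, ha="right")
    ax.set_ylabel(r"mean $\chi$ per network")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
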