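"""Synthetic constraint-based models and proteome tables for testing.

Real central-carbon models and strain-level proteomic surveys are
external resources; this module builds small stand-ins with the same
structural features: a single input flux, several outputs, planted
pathway modularity (parallel chains through hub metabolites), GPR rules,
and enzyme abundances generated from a hidden flux vector through the
same flux-enzyme relations used in the simulation study.  Everything is
deterministic given a seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd

from .model_io import MetabolicModel, parse_gpr

__all__ = [
    "SyntheticSpec",
    "toy_models",
    "random_cbm",
    "planted_pathways",
    "synthetic_proteome",
]


@dataclass
class SyntheticSpec:
    """Shape parameters for a random modular constraint-based model."""

    n_metabolites: int
    n_reactions: int
    n_pathways: int
    n_exchanges: int
    reversible_fraction: float = 0.25
    bound_width: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_reactions <= self.n_metabolites:
            raise ValueError("need n_reactions > n_metabolites for a nontrivial kernel")
        if self.n_exchanges < 2:
            raise ValueError("need at least one input and one output exchange")
        if not 0 <= self.reversible_fraction <= 1:
            raise ValueError("reversible_fraction must be in [0, 1]")
        if self.bound_width <= 0:
            raise ValueError("bound_width must be positive")
        n_sinks = min(self.n_pathways, self.n_exchanges - 1)
        internal = self.n_metabolites - 1 - n_sinks
        if internal < 0:
            raise ValueError("too few metabolites for the requested pathways")
        if internal + self.n_pathways + self.n_exchanges > self.n_reactions:
            raise ValueError("too few reactions for the requested shape")


def _build(mets, reactions) -> MetabolicModel:
    """Assemble a model from (id, stoich, lb, ub, gpr, exchange) tuples."""
    met_ids = list(mets)
    idx = {m: i for i, m in enumerate(met_ids)}
    N = len(reactions)
    S = np.zeros((len(met_ids), N))
    rids, lb, ub, exch = [], np.zeros(N), np.zeros(N), np.zeros(N, bool)
    gpr = {}
    for j, (rid, stoich, lo, hi, rule, is_exch) in enumerate(reactions):
        rids.append(rid)
        for m, c in stoich.items():
            S[idx[m], j] = c
        lb[j], ub[j], exch[j] = lo, hi, is_exch
        if rule:
            gpr[rid] = parse_gpr(rule)
    return MetabolicModel(met_ids, rids, S, lb, ub, exch, gpr)


def toy_models() -> Dict[str, MetabolicModel]:
    """Named collection of hand-built fixture models.

    ``segment``: one metabolite between an input and an output (kernel
    dimension 1).  ``branch``: one input splitting into two outputs.
    ``diamond``: two parallel routes between the same metabolites.
    ``toy_central_carbon``: a 15-reaction caricature of yeast central
    carbon metabolism - a glycolysis-like trunk fed by a single glucose
    input, a pentose-phosphate-like bypass, glycerol and ethanol branches
    and a short TCA-like tail, with GPR rules on two thirds of the
    reactions.
    """
    models = {}
    models["segment"] = _build(
        ["A"],
        [("r1", {"A": 1}, 0, 1, "E1", True),
         ("r2", {"A": -1}, 0, 1, "E2a OR E2b", True)])
    models["branch"] = _build(
        ["A"],
        [("v1", {"A": 1}, 0, 1, "E1", True),
         ("v2", {"A": -1}, 0, 1, "E2", True),
         ("v3", {"A": -1}, 0, 1, None, True)])
    models["diamond"] = _build(
        ["A", "B"],
        [("in", {"A": 1}, 0, 1, "E0", True),
         ("top", {"A": -1, "B": 1}, 0, 1, "Ta AND Tb", False),
         ("bot", {"A": -1, "B": 1}, 0, 1, "Ba OR Bb", False),
         ("out", {"B": -1}, 0, 1, None, True)])
    models["toy_central_carbon"] = _build(
        ["GLC", "G6P", "F6P", "T3P", "GOL", "PYR", "ACA", "ETH", "CO2",
         "OAA", "MAL"],
        [
            ("glc_in", {"GLC": 1}, 0, 1, None, True),
            ("hex", {"GLC": -1, "G6P": 1}, 0, 1, "HXK1 OR HXK2", False),
            ("pgi", {"G6P": -1, "F6P": 1}, -1, 1, "PGI1", False),
            ("pfk", {"F6P": -1, "T3P": 2}, 0, 1, "PFK1 AND PFK2", False),
            ("ppp", {"G6P": -1, "T3P": 1}, 0, 1, "ZWF1", False),
            ("gpd", {"T3P": -1, "GOL": 1}, 0, 1, "GPD1 OR GPD2", False),
            ("gol_out", {"GOL": -1}, 0, 1, None, True),
            ("pyk", {"T3P": -1, "PYR": 1}, 0, 1, "CDC19", False),
            ("pdc", {"PYR": -1, "ACA": 1, "CO2": 1}, 0, 1, "PDC1", False),
            ("adh", {"ACA": -1, "ETH": 1}, -1, 1, "ADH1 OR ADH3", False),
            ("eth_out", {"ETH": -1}, 0, 1, None, True),
            ("co2_out", {"CO2": -1}, 0, 2, None, True),
            ("pyc", {"PYR": -1, "CO2": -1, "OAA": 1}, 0, 1, "PYC1 OR PYC2", False),
            ("mdh", {"OAA": -1, "MAL": 1}, 0, 1, "MDH1", False),
            ("mal_out", {"MAL": -1}, 0, 1, None, True),
        ])
    return models


def planted_pathways(model: MetabolicModel) -> Dict[str, int]:
    """Planted pathway labels recorded by :func:`random_cbm` (chain index)."""
    labels = getattr(model, "_planted_pathways", None)
    if labels is None:
        raise ValueError("model carries no planted pathway annotation")
    return dict(labels)


def random_cbm(spec: SyntheticSpec) -> MetabolicModel:
    """Random feasible modular model with planted parallel pathways.

    ``n_pathways`` chains of unit-stoichiometry reactions run from a
    shared source hub to a shared sink hub; one input exchange feeds the
    source, the remaining exchanges drain the sink.  Reactions beyond the
    chain skeleton are added as isoenzyme-style parallel duplicates of
    random chain steps.  Bounds are ``[0, w]``, or ``[-w, w]`` for a
    ``reversible_fraction`` of internal reactions.  The zero flux vector
    is always feasible.  Deterministic given ``spec.seed``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    w = spec.bound_width
    n_sinks = min(spec.n_pathways, spec.n_exchanges - 1)
    internal = spec.n_metabolites - 1 - n_sinks
    if internal < 0:
        raise ValueError("too few metabolites for the source/sink structure")
    # distribute internal metabolites evenly over pathways (balanced chains)
    counts = np.full(spec.n_pathways, internal // spec.n_pathways, dtype=int)
    counts[: internal % spec.n_pathways] += 1
    rng.shuffle(counts)
    sinks = [f"snk{s}" for s in range(n_sinks)]
    mets = ["hub_src"] + sinks + [f"m{i}" for i in range(internal)]
    reactions = []
    pathway_of: Dict[str, int] = {}
    met_cursor = 0
    chain_steps = []  # (rid, stoich, pathway) for duplication
    for p in range(spec.n_pathways):
        # pathways drain to distinct terminal products where exchanges allow
        nodes = (["hub_src"]
                 + [f"m{met_cursor + k}" for k in range(counts[p])]
                 + [sinks[p % n_sinks]])
        met_cursor += counts[p]
        for k in range(len(nodes) - 1):
            rid = f"p{p}_s{k}"
            stoich = {nodes[k]: -1, nodes[k + 1]: 1}
            reversible = rng.random() < spec.reversible_fraction
            lo = -w if reversible else 0.0
            reactions.append((rid, stoich, lo, w, f"E_{rid}", False))
            pathway_of[rid] = p
            chain_steps.append((rid, stoich, p))
    n_extra = spec.n_reactions - spec.n_exchanges - len(chain_steps)
    if n_extra < 0:
        raise ValueError("too few reactions for the requested shape")
    for e in range(n_extra):
        # bypass shortcut parallel to a whole pathway: preserves the strict
        # series coupling inside every chain while adding a degree of freedom
        p = int(rng.integers(spec.n_pathways))
        rid = f"bypass{e}_p{p}"
        stoich = {"hub_src": -1, sinks[p % n_sinks]: 1}
        reversible = rng.random() < spec.reversible_fraction
        lo = -w if reversible else 0.0
        reactions.append((rid, stoich, lo, w, f"E_{rid}", False))
        pathway_of[rid] = p
    reactions.append(("exch_in", {"hub_src": 1}, 0, w, None, True))
    for e in range(spec.n_exchanges - 1):
        reactions.append((f"exch_out{e}", {sinks[e % n_sinks]: -1}, 0, w, None, True))
    model = _build(mets, reactions)
    model._planted_pathways = pathway_of  # fixture metadata, not part of the contract
    return model


def _assign_leaf_abundances(expr, target: float, out: Dict[str, float]) -> None:
    """Distribute a reaction weighting back onto protein leaves.

    Inverse of the min/sum GPR evaluation: every AND member receives the
    full target (so the min reproduces it), OR branches split it equally
    (so the sum reproduces it).
    """
    if expr.op == "leaf":
        out[expr.name] = target
    elif expr.op == "and":
        for c in expr.children:
            _assign_leaf_abundances(c, target, out)
    else:  # or
        share = target / len(expr.children)
        for c in expr.children:
            _assign_leaf_abundances(c, share, out)


def synthetic_proteome(
    model: MetabolicModel,
    relation: str = "hyperbolic",
    noise_sd: float = 0.0,
    n_samples: int = 10,
    seed: int = 0,
    posterior=None,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Proteins x samples abundance table with its hidden ground truth.

    Per sample a true flux vector is drawn from the polytope posterior,
    mapped to reaction weightings through ``relation`` (``identity``,
    ``hyperbolic``, ``linear`` or ``hill``), distributed onto the protein
    leaves of each GPR so that min/sum evaluation reconstructs the
    weighting, and finally perturbed by multiplicative log-normal noise
    of standard deviation ``noise_sd`` (on the log scale; 0 reproduces
    noiseless simulations).  Returns ``(abundances, true_fluxes)``:
    proteins x samples and reactions x samples DataFrames.
    """
    from .posterior import ep_fit
    from .sim_validate import SimulationConfig, enzymes_from_fluxes

    if posterior is None:
        posterior = ep_fit(model)
    rng = np.random.default_rng(seed)
    config = SimulationConfig(relation=relation, N_s=1, seed=seed)
    sub_seeds = rng.integers(0, 2**31 - 1, size=2 * n_samples)
    gpr_rids = [rid for rid in model.reaction_ids if rid in model.gpr]
    gpr_idx = {rid: model.reaction_index(rid) for rid in gpr_rids}
    flux_cols = {}
    abun_cols = {}
    for s in range(n_samples):
        v = posterior.sample(1, seed=int(sub_seeds[2 * s])).fluxes[0]
        E = enzymes_from_fluxes(v, relation, config, seed=int(sub_seeds[2 * s + 1]))
        proteins: Dict[str, float] = {}
        for rid in gpr_rids:
            _assign_leaf_abundances(model.gpr[rid], float(E[gpr_idx[rid]]), proteins)
        if noise_sd > 0:
            noise_rng = np.random.default_rng(int(sub_seeds[2 * s + 1]) + 1)
            for name in proteins:
                proteins[name] *= np.exp(noise_rng.normal(0.0, noise_sd))
        name = f"sample{s}"
        flux_cols[name] = v
        abun_cols[name] = proteins
    fluxes = pd.DataFrame(flux_cols, index=model.reaction_ids)
    abundances = pd.DataFrame(abun_cols).sort_index()
    return abundances, fluxes
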