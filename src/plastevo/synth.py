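"""Synthetic inputs with known ground truth.

Three families of generators:

* :func:`gen_triplets` — expression-like o/p/a triplets with planted category
  fractions (reversing / reinforcing / plastic_only / unchanged), built so the
  planted category is unambiguous at the default cutoff (20% of L_o) with a
  safety margin, then perturbed by multiplicative log-normal noise.
* :func:`gen_mechanism_triplets` — triplets whose values are monotone
  functions of a latent fitness trajectory (1 -> f_p -> f_a), reproducing the
  mechanism by which a deep plastic fitness drop forces PC > TC and hence an
  excess of reversion.
* :func:`gen_forced_reversion_triplets` — triplets with a directly planted
  fraction q of PC > TC traits and otherwise direction-symmetric genetic
  changes, the cleanest setting in which C_RI/C_RV should approach
  (1 - q)/(1 + q).
* :func:`gen_toy_model` — tiny metabolic networks (linear chain, diamond,
  two-source) with closed-form FBA/MOMA solutions, used as solver fixtures.

All generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .model import Environment, MetabolicModel


# ---------------------------------------------------------------------- #
@dataclass
class TripletSpec:
    """Specification of a planted-category triplet set.

    Fractions apply to the planted categories at a 0.2 cutoff; whatever
    probability mass remains is planted as 'unchanged'. Effect sizes are
    multiples of L_o chosen to clear the cutoff with a margin (appreciable
    changes are drawn at least ``margin`` above 0.2, inappreciable ones at
    most ``margin`` below), so the ground truth survives small noise.
    """

    n_genes: int = 1000
    frac_reversing: float = 0.3
    frac_reinforcing: float = 0.1
    frac_plastic_only: float = 0.1
    lognormal_mu: float = 0.0
    lognormal_sigma: float = 1.0
    noise_sd: float = 0.02
    margin: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        total = self.frac_reversing + self.frac_reinforcing + self.frac_plastic_only
        if total > 1 + 1e-12:
            raise ValueError(f"planted fractions sum to {total} > 1")
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")


def gen_triplets(spec: TripletSpec) -> tuple[pd.DataFrame, pd.Series]:
    """Generate a triplet table plus ground-truth category labels.

    Returns ``(table, labels)`` where table has columns trait_id, L_o, L_p,
    L_a and labels is the planted category per trait.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_genes
    L_o = rng.lognormal(spec.lognormal_mu, spec.lognormal_sigma, size=n)

    labels = np.full(n, "unchanged", dtype=object)
    u = rng.random(n)
    edges = np.cumsum(
        [spec.frac_reversing, spec.frac_reinforcing, spec.frac_plastic_only]
    )
    labels[u < edges[0]] = "reversing"
    labels[(u >= edges[0]) & (u < edges[1])] = "reinforcing"
    labels[(u >= edges[1]) & (u < edges[2])] = "plastic_only"

    lo_app = 0.2 + spec.margin  # appreciable changes start here (x L_o)
    hi_neg = 0.45  # cap for downward moves so values stay positive
    small = max(0.2 - spec.margin, 0.0)  # inappreciable changes stay below this

    sign = rng.choice([-1.0, 1.0], size=n)
    pc_mag = rng.uniform(lo_app, hi_neg, size=n)
    gc_mag = rng.uniform(lo_app, hi_neg, size=n)
    pc_small = rng.uniform(0.0, small, size=n)
    gc_small = rng.uniform(0.0, small, size=n)

    d_p = np.where(
        np.isin(labels, ["reversing", "reinforcing", "plastic_only"]),
        sign * pc_mag,
        sign * pc_small,
    )
    gc_dir = np.where(labels == "reinforcing", sign, -sign)
    d_g = np.where(
        np.isin(labels, ["reversing", "reinforcing"]),
        gc_dir * gc_mag,
        gc_dir * gc_small,
    )
    # keep 'unchanged'/'plastic_only' genetic moves small enough that TC also
    # stays clearly on one side of the cutoff
    L_p = L_o * (1.0 + d_p)
    L_a = L_p + L_o * d_g

    if spec.noise_sd > 0:
        L_o = L_o * rng.lognormal(0.0, spec.noise_sd, size=n)
        L_p = L_p * rng.lognormal(0.0, spec.noise_sd, size=n)
        L_a = L_a * rng.lognormal(0.0, spec.noise_sd, size=n)

    table = pd.DataFrame(
        {
            "trait_id": [f"g{i}" for i in range(n)],
            "L_o": L_o,
            "L_p": L_p,
            "L_a": L_a,
        }
    )
    return table, pd.Series(labels, name="category")


# ---------------------------------------------------------------------- #
@dataclass
class MechanismSpec:
    """Latent-fitness coupling producing the PC > TC excess.

    Fitness runs 1 -> f_p -> f_a across the three stages. Each trait responds
    to fitness with its own exponent drawn uniformly from
    [-coupling, coupling]; an independent per-trait displacement of the new
    optimum (sd ``env_shift_sd``, applied at stage a) provides genuine
    adaptive change, and log-normal noise (sd ``noise_sd``) applies at every
    stage.
    """

    f_p: float = 0.1
    f_a: float = 1.0
    coupling: float = 1.0
    n_traits: int = 2000
    env_shift_sd: float = 0.2
    noise_sd: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.f_p <= 1:
            raise ValueError("f_p must be in (0, 1]")
        if self.f_a <= 0:
            raise ValueError("f_a must be positive")


def gen_mechanism_triplets(spec: MechanismSpec) -> pd.DataFrame:
    """Generate fitness-coupled triplets (columns trait_id, L_o, L_p, L_a).

    Stage-p values deviate most when f_p is small, so the fraction of traits
    with PC > TC grows as f_p drops, and the mean PC shrinks as f_p -> 1.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_traits
    base = rng.lognormal(0.0, 1.0, size=n)
    expo = rng.uniform(-spec.coupling, spec.coupling, size=n)
    shift = rng.normal(0.0, spec.env_shift_sd, size=n)

    def stage(fitness: float, extra_log: np.ndarray | float = 0.0) -> np.ndarray:
        noise = rng.lognormal(0.0, spec.noise_sd, size=n) if spec.noise_sd > 0 else 1.0
        return base * fitness**expo * np.exp(extra_log) * noise

    L_o = stage(1.0)
    L_p = stage(spec.f_p)
    L_a = stage(spec.f_a, shift)
    return pd.DataFrame(
        {
            "trait_id": [f"t{i}" for i in range(n)],
            "L_o": L_o,
            "L_p": L_p,
            "L_a": L_a,
        }
    )


def gen_forced_reversion_triplets(
    q: float, n: int, seed: int = 0, noise_sd: float = 0.0
) -> pd.DataFrame:
    """Triplets with a planted fraction *q* of PC > TC traits.

    A forced trait has an appreciable plastic change overshooting the final
    value (PC > TC), so its genetic change must reverse. The remaining
    traits have PC < TC with the genetic-change direction chosen by a fair
    coin, so they split evenly between reinforcement and reversion. Expected
    C_RI/C_RV is therefore (1 - q)/(1 + q).
    """
    if not 0 <= q <= 1:
        raise ValueError(f"q must be in [0, 1], got {q}")
    rng = np.random.default_rng(seed)
    L_o = rng.lognormal(0.0, 1.0, size=n)
    s = rng.choice([-1.0, 1.0], size=n)
    forced = rng.random(n) < q

    d_p = np.empty(n)
    d_t = np.empty(n)  # signed total change as multiple of L_o
    # forced: large plastic excursion, small signed total change (< PC)
    pc_f = rng.uniform(0.5, 0.9, size=n)
    tc_f = rng.uniform(-0.2, 0.2, size=n)
    # free: moderate plastic change; genetic change either reinforces or
    # over-reverses so that TC > PC either way
    pc_o = rng.uniform(0.25, 0.45, size=n)
    reinforce = rng.random(n) < 0.5
    gc_plus = rng.uniform(0.25, 0.45, size=n)  # reinforcing move
    gc_minus = 2.0 * pc_o + rng.uniform(0.1, 0.5, size=n)  # over-reversing move

    d_p[forced] = (s * pc_f)[forced]
    d_t[forced] = (s * tc_f)[forced]
    d_p[~forced] = (s * pc_o)[~forced]
    d_t_free = np.where(reinforce, s * (pc_o + gc_plus), s * (pc_o - gc_minus))
    d_t[~forced] = d_t_free[~forced]

    L_p = L_o * (1.0 + d_p)
    L_a = L_o * (1.0 + d_t)
    if noise_sd > 0:
        L_o = L_o * rng.lognormal(0.0, noise_sd, size=n)
        L_p = L_p * rng.lognormal(0.0, noise_sd, size=n)
        L_a = L_a * rng.lognormal(0.0, noise_sd, size=n)
    return pd.DataFrame(
        {
            "trait_id": [f"t{i}" for i in range(n)],
            "L_o": L_o,
            "L_p": L_p,
            "L_a": L_a,
        }
    )


# ---------------------------------------------------------------------- #
def gen_case_bundle(
    n_cases: int = 44,
    n_genes: int = 1000,
    n_majority_reversing: int = 42,
    noise_sd: float = 0.02,
    seed: int = 0,
):
    """A multi-case expression bundle with a planted reversion excess.

    Emulates a collection of experimental-evolution adaptations: each case
    gets its own stage-o/p/a expression profiles over a shared gene set. In
    ``n_majority_reversing`` of the cases reversing traits outnumber
    reinforcing ones (30% vs 5% planted); in the remaining cases the planted
    fractions are swapped. Returns ``(dataset, manifest, truth)`` where
    truth records each case's planted majority direction.

    The bundle plugs directly into the transcriptome pipeline
    (:func:`plastevo.transcriptome.build_triplets`).
    """
    from .transcriptome import CaseManifest, ExpressionDataset

    rng = np.random.default_rng(seed)
    reversing_major = np.ones(n_cases, dtype=bool)
    flipped = rng.choice(n_cases, size=n_cases - n_majority_reversing, replace=False)
    reversing_major[flipped] = False

    columns = {}
    meta = []
    cases = {}
    for i in range(n_cases):
        rv, ri = (0.30, 0.05) if reversing_major[i] else (0.05, 0.30)
        table, _ = gen_triplets(
            TripletSpec(
                n_genes=n_genes,
                frac_reversing=rv,
                frac_reinforcing=ri,
                frac_plastic_only=0.1,
                noise_sd=noise_sd,
                seed=int(rng.integers(2**31 - 1)),
            )
        )
        cid = f"case{i:02d}"
        sample_ids = {}
        for st, col in zip(("o", "p", "a"), ("L_o", "L_p", "L_a")):
            sid = f"{cid}_{st}"
            columns[sid] = table[col].to_numpy()
            meta.append(pd.Series({"stage": st, "line": cid}, name=sid))
            sample_ids[st] = [sid]
        cases[cid] = sample_ids

    values = pd.DataFrame(columns, index=[f"g{j}" for j in range(n_genes)])
    ds = ExpressionDataset(values, pd.DataFrame(meta), name="synthetic_bundle")
    manifest = CaseManifest(cases=cases)
    truth = pd.DataFrame(
        {
            "case": [f"case{i:02d}" for i in range(n_cases)],
            "planted_reversing_majority": reversing_major,
        }
    )
    return ds, manifest, truth


# ---------------------------------------------------------------------- #
def _build_model(
    name,
    reactions,
    metabolites,
    S,
    lower,
    upper,
    objective_rxn,
    carbon,
):
    n = len(reactions)
    objective = np.zeros(n)
    objective[reactions.index(objective_rxn)] = 1.0
    is_exchange = np.array([r.startswith("EX_") for r in reactions])
    carbon_source = np.empty(n, dtype=object)
    carbon_source[:] = None
    for rid, src in carbon.items():
        carbon_source[reactions.index(rid)] = src
    return MetabolicModel(
        reactions=reactions,
        metabolites=metabolites,
        S=sp.csc_matrix(np.asarray(S, dtype=float)),
        lower=np.asarray(lower, dtype=float),
        upper=np.asarray(upper, dtype=float),
        objective=objective,
        is_exchange=is_exchange,
        carbon_source=carbon_source,
        is_diffusion=np.zeros(n, dtype=bool),
        has_gene=~is_exchange,
        name=name,
    )


def gen_toy_model(kind: str, **params) -> tuple[MetabolicModel, dict]:
    """Build a small metabolic network with documented analytic solutions.

    Kinds
    -----
    linear
        EX_C1 -> T1 -> BIOMASS chain, yield y biomass per substrate.
        FBA biomass = uptake * y.
    diamond
        Two parallel internal paths P1/P2 from substrate to precursor.
        FBA biomass = uptake (split across paths arbitrary). MOMA from a
        reference flux all on P1 under a reduced uptake u keeps everything
        on P1 at level u.
    two_source
        Two carbon sources with different biomass yields y1, y2. The C1->C2
        shift has closed-form plastic (MOMA) and adapted (FBA) fitnesses:
        with reference biomass B0 = y1*U, the MOMA flux through the C2 path
        is u* = y2*B0/(2 + y2**2) (when u* is within the uptake bound) and
        the plastic biomass y2*u*; the adapted biomass is y2*U.

    Returns ``(model, analytic)`` where analytic maps quantity names to their
    closed-form values for the parameters used.
    """
    if kind == "linear":
        uptake = float(params.get("uptake", 10.0))
        y = float(params.get("yield_", 1.0))
        model = _build_model(
            "linear_toy",
            reactions=["EX_C1", "T1", "BIOMASS"],
            metabolites=["C1", "X"],
            S=[[-1, -1, 0], [0, y, -1]],
            lower=[-uptake, 0, 0],
            upper=[1000, 1000, 1000],
            objective_rxn="BIOMASS",
            carbon={"EX_C1": "C1"},
        )
        analytic = {
            "env": Environment.single("C1", uptake),
            "fba_biomass": uptake * y,
            "fba_fluxes": {"EX_C1": -uptake, "T1": uptake, "BIOMASS": uptake * y},
        }
        return model, analytic

    if kind == "diamond":
        uptake = float(params.get("uptake", 10.0))
        reduced = float(params.get("reduced_uptake", 5.0))
        model = _build_model(
            "diamond_toy",
            reactions=["EX_C1", "P1", "P2", "BIOMASS"],
            metabolites=["C1", "A"],
            S=[[-1, -1, -1, 0], [0, 1, 1, -1]],
            lower=[-uptake, 0, 0, 0],
            upper=[1000, 1000, 1000, 1000],
            objective_rxn="BIOMASS",
            carbon={"EX_C1": "C1"},
        )
        v0 = np.array([-uptake, uptake, 0.0, uptake])
        analytic = {
            "env": Environment.single("C1", uptake),
            "fba_biomass": uptake,
            "reduced_env": Environment.single("C1", reduced),
            "moma_v0": v0,
            # projecting the all-on-P1 reference onto the reduced polytope
            # keeps P2 at its bound: v = (-u, u, 0, u) with u = reduced uptake
            "moma_fluxes": np.array([-reduced, reduced, 0.0, reduced]),
            "moma_distance": 3.0 * (uptake - reduced) ** 2,
            "moma_b_biomass": reduced,
        }
        return model, analytic

    if kind == "two_source":
        uptake = float(params.get("uptake", 10.0))
        y1 = float(params.get("yield1", 1.0))
        y2 = float(params.get("yield2", 0.5))
        model = _build_model(
            "two_source_toy",
            reactions=["EX_C1", "EX_C2", "T1", "T2", "BIOMASS"],
            metabolites=["C1", "C2", "X"],
            S=[
                [-1, 0, -1, 0, 0],
                [0, -1, 0, -1, 0],
                [0, 0, y1, y2, -1],
            ],
            lower=[-uptake, 0, 0, 0, 0],  # original env: C1 only
            upper=[1000, 1000, 1000, 1000, 1000],
            objective_rxn="BIOMASS",
            carbon={"EX_C1": "C1", "EX_C2": "C2"},
        )
        B0 = y1 * uptake
        u_star = min(y2 * B0 / (2.0 + y2**2), uptake)
        biomass_p = y2 * u_star
        analytic = {
            "env_o": Environment.single("C1", uptake),
            "env_a": Environment.single("C2", uptake),
            "fba_biomass_o": B0,
            "fba_biomass_a": y2 * uptake,
            "v_o": np.array([-uptake, 0.0, uptake, 0.0, B0]),
            "moma_t2_flux": u_star,
            "moma_biomass": biomass_p,
            "f_p": biomass_p / B0,
            "f_a": (y2 * uptake) / B0,
        }
        return model, analytic

    raise ValueError(f"unknown toy model kind {kind!r}")


def toy_sbml(model: MetabolicModel, path) -> None:
    """Write a toy model to SBML (via cobrapy) for parser round-trip tests."""
    import cobra

    cm = cobra.Model(model.name)
    carbon_mets = {s for s in model.carbon_source if s is not None}
    mets = {
        mid: cobra.Metabolite(
            mid,
            compartment="c",
            formula="C6H12O6" if mid in carbon_mets else "H2O",
        )
        for mid in model.metabolites
    }
    S = model.S.toarray()
    for j, rid in enumerate(model.reactions):
        rxn = cobra.Reaction(rid)
        rxn.lower_bound = float(model.lower[j])
        rxn.upper_bound = float(model.upper[j])
        cm.add_reactions([rxn])
        rxn.add_metabolites(
            {mets[model.metabolites[i]]: S[i, j] for i in np.flatnonzero(S[:, j])}
        )
        if not model.is_exchange[j]:
            rxn.gene_reaction_rule = f"g_{rid}"
    cm.objective = model.reactions[model.biomass_index]
    cobra.io.write_sbml_model(cm, str(path))
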