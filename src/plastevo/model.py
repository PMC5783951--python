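"""Constraint-based metabolic model container and environment handling.

The central object is :class:`MetabolicModel`, a plain numerical view of a
constraint-based model: stoichiometric matrix ``S`` (metabolites x reactions),
flux bounds, a single biomass objective, and per-reaction annotations that the
adaptation analysis needs (exchange status, transported carbon source,
diffusion/no-enzyme status, gene association).

Models come from two sources: SBML files (parsed with cobrapy) or a small
explicit JSON dialect used for hand-constructed fixtures.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import scipy.sparse as sp

#: Global numeric tolerance: flux values and differences smaller than this are
#: treated as zero throughout the package.
EPS = 1e-4

#: Elemental formulas of carbon-containing metabolites that are not treated as
#: nutritive carbon sources (inorganic / fully oxidized carbon).
DEFAULT_CARBON_BLOCKLIST = frozenset(
    {"CO2", "CO", "HCO3", "H2CO3", "CO3", "CN", "C"}
)


class ModelValidationError(ValueError):
    """Raised when a model violates a structural invariant."""


class UnknownCarbonSourceError(KeyError):
    """Raised when an environment references a carbon source absent from the model."""


@dataclass
class MetabolicModel:
    """A constraint-based metabolic model in matrix form.

    Parameters
    ----------
    reactions, metabolites
        Ordered identifier lists; their lengths fix the dimensions of ``S``.
    S
        Stoichiometric matrix, metabolites x reactions (CSC sparse).
    lower, upper
        Flux bounds per reaction (mmol/gDW/h).
    objective
        Biomass-contribution weights; exactly one nonzero entry (the biomass
        reaction) is required.
    is_exchange
        True for boundary reactions exchanging a single metabolite.
    carbon_source
        For carbon-transporting exchange reactions, the identifier of the
        transported source (used to address environments); None elsewhere.
    is_diffusion
        True for reactions excluded from the phenotypic-trait list (no
        dedicated enzyme: exchanges and spontaneous inter-compartment
        transport).
    has_gene
        True if the reaction has an associated gene (gene-protein-reaction
        rule non-empty).
    """

    reactions: list[str]
    metabolites: list[str]
    S: sp.csc_matrix
    lower: np.ndarray
    upper: np.ndarray
    objective: np.ndarray
    is_exchange: np.ndarray
    carbon_source: np.ndarray  # dtype=object, None where not a carbon exchange
    is_diffusion: np.ndarray
    has_gene: np.ndarray
    name: str = "model"

    def __post_init__(self) -> None:
        self.S = sp.csc_matrix(self.S, dtype=float)
        self.lower = np.asarray(self.lower, dtype=float)
        self.upper = np.asarray(self.upper, dtype=float)
        self.objective = np.asarray(self.objective, dtype=float)
        self.is_exchange = np.asarray(self.is_exchange, dtype=bool)
        self.carbon_source = np.asarray(self.carbon_source, dtype=object)
        self.is_diffusion = np.asarray(self.is_diffusion, dtype=bool)
        self.has_gene = np.asarray(self.has_gene, dtype=bool)
        self.validate()

    # ------------------------------------------------------------------ #
    @property
    def n_reactions(self) -> int:
        return len(self.reactions)

    @property
    def n_metabolites(self) -> int:
        return len(self.metabolites)

    @property
    def biomass_index(self) -> int:
        return int(np.flatnonzero(self.objective)[0])

    def reaction_index(self, rid: str) -> int:
        try:
            return self.reactions.index(rid)
        except ValueError:
            raise KeyError(f"unknown reaction {rid!r}") from None

    def carbon_sources(self) -> list[str]:
        """Identifiers of all carbon sources the model can exchange."""
        return [s for s in self.carbon_source if s is not None]

    def carbon_exchange_index(self, source: str) -> int:
        idx = [i for i, s in enumerate(self.carbon_source) if s == source]
        if not idx:
            raise UnknownCarbonSourceError(
                f"unknown carbon source {source!r}; valid sources: "
                f"{sorted(self.carbon_sources())}"
            )
        return idx[0]

    # ------------------------------------------------------------------ #
    def validate(self) -> None:
        n, m = self.n_reactions, self.n_metabolites
        if self.S.shape != (m, n):
            raise ModelValidationError(
                f"S has shape {self.S.shape}, expected ({m}, {n})"
            )
        for arr, label in (
            (self.lower, "lower"),
            (self.upper, "upper"),
            (self.objective, "objective"),
            (self.is_exchange, "is_exchange"),
            (self.carbon_source, "carbon_source"),
            (self.is_diffusion, "is_diffusion"),
            (self.has_gene, "has_gene"),
        ):
            if len(arr) != n:
                raise ModelValidationError(
                    f"{label} has length {len(arr)}, expected {n}"
                )
        bad = np.flatnonzero(self.lower > self.upper)
        if bad.size:
            raise ModelValidationError(
                "lower bound exceeds upper bound for reaction(s): "
                + ", ".join(self.reactions[i] for i in bad[:5])
            )
        nz = np.flatnonzero(self.objective)
        if nz.size != 1:
            raise ModelValidationError(
                f"exactly one biomass objective reaction required, found {nz.size}"
            )
        sources = [s for s in self.carbon_source if s is not None]
        if len(sources) != len(set(sources)):
            raise ModelValidationError("duplicate carbon source identifiers")

    def copy(self) -> "MetabolicModel":
        return MetabolicModel(
            reactions=list(self.reactions),
            metabolites=list(self.metabolites),
            S=self.S.copy(),
            lower=self.lower.copy(),
            upper=self.upper.copy(),
            objective=self.objective.copy(),
            is_exchange=self.is_exchange.copy(),
            carbon_source=self.carbon_source.copy(),
            is_diffusion=self.is_diffusion.copy(),
            has_gene=self.has_gene.copy(),
            name=self.name,
        )

    # ------------------------------------------------------------------ #
    def to_json(self) -> str:
        """Serialize to the explicit JSON model dialect."""
        payload = {
            "name": self.name,
            "reactions": self.reactions,
            "metabolites": self.metabolites,
            "S": self.S.toarray().tolist(),
            "lower": self.lower.tolist(),
            "upper": self.upper.tolist(),
            "objective": self.objective.tolist(),
            "is_exchange": self.is_exchange.tolist(),
            "carbon_source": [s for s in self.carbon_source],
            "is_diffusion": self.is_diffusion.tolist(),
            "has_gene": self.has_gene.tolist(),
        }
        return json.dumps(payload, indent=1)

    @classmethod
    def from_json(cls, text_or_path) -> "MetabolicModel":
        """Load from the explicit JSON dialect (a path or a JSON string)."""
        text = str(text_or_path)
        if not text.lstrip().startswith("{"):
            with open(text) as fh:
                text = fh.read()
        d = json.loads(text)
        return cls(
            reactions=list(d["reactions"]),
            metabolites=list(d["metabolites"]),
            S=sp.csc_matrix(np.asarray(d["S"], dtype=float)),
            lower=np.asarray(d["lower"], dtype=float),
            upper=np.asarray(d["upper"], dtype=float),
            objective=np.asarray(d["objective"], dtype=float),
            is_exchange=np.asarray(d["is_exchange"], dtype=bool),
            carbon_source=np.asarray(d["carbon_source"], dtype=object),
            is_diffusion=np.asarray(d["is_diffusion"], dtype=bool),
            has_gene=np.asarray(d["has_gene"], dtype=bool),
            name=d.get("name", "model"),
        )


# ---------------------------------------------------------------------- #
@dataclass(frozen=True)
class Environment:
    """A growth environment: available carbon sources and their uptake bounds.

    ``sources`` maps carbon-source identifiers to maximum uptake rates
    (mmol/gDW/h, non-negative). Non-carbon exchange settings are inherited
    from the model's defaults.
    """

    sources: Mapping[str, float] = field(default_factory=dict)
    name: str = ""

    DEFAULT_UPTAKE = 10.0

    @classmethod
    def single(cls, source: str, uptake: float = DEFAULT_UPTAKE) -> "Environment":
        return cls(sources={source: float(uptake)}, name=source)

    @classmethod
    def from_sources(
        cls, sources: Iterable[str], uptake: float = DEFAULT_UPTAKE, name: str = ""
    ) -> "Environment":
        return cls(sources={s: float(uptake) for s in sources}, name=name)

    def __post_init__(self) -> None:
        for s, u in self.sources.items():
            if u < 0:
                raise ValueError(f"negative uptake bound for source {s!r}")

    def __eq__(self, other) -> bool:
        return isinstance(other, Environment) and dict(self.sources) == dict(
            other.sources
        )

    def __hash__(self) -> int:
        return hash(frozenset(self.sources.items()))


def apply_environment(model: MetabolicModel, env: Environment) -> MetabolicModel:
    """Return a copy of *model* with carbon-exchange bounds set for *env*.

    Each available source's exchange reaction gets lower bound ``-uptake``;
    every other carbon exchange has its uptake closed (lower bound 0) while
    secretion (positive flux) stays allowed. Non-carbon exchanges are left
    untouched.
    """
    out = model.copy()
    carbon_idx = {s: i for i, s in enumerate(out.carbon_source) if s is not None}
    for source in env.sources:
        if source not in carbon_idx:
            raise UnknownCarbonSourceError(
                f"unknown carbon source {source!r}; valid sources: "
                f"{sorted(carbon_idx)}"
            )
    for source, i in carbon_idx.items():
        if source in env.sources:
            out.lower[i] = -float(env.sources[source])
        else:
            out.lower[i] = 0.0
        out.upper[i] = max(out.upper[i], 0.0)
    out.validate()
    return out


def mutable_reactions(model: MetabolicModel) -> list[str]:
    """Reactions treated as phenotypic traits (enzyme-backed, non-diffusion)."""
    traits = [r for r, d in zip(model.reactions, model.is_diffusion) if not d]
    if not traits:
        warnings.warn("model has no mutable reactions; trait list is empty")
    return traits


# ---------------------------------------------------------------------- #
def default_diffusion_predicate(reaction) -> bool:
    """Default rule flagging a cobra reaction as enzyme-free (not a trait).

    A reaction is excluded from the trait list when it is a boundary/exchange
    reaction, or when it has no gene association and moves metabolites between
    compartments (spontaneous diffusion/transport). The biomass objective
    (a sink in some reconstructions) always stays a trait.
    """
    if reaction.objective_coefficient != 0:
        return False
    if reaction.boundary:
        return True
    if reaction.gene_reaction_rule.strip():
        return False
    compartments = {m.compartment for m in reaction.metabolites}
    return len(compartments) > 1


def _is_carbon_source(metabolite, blocklist: frozenset[str]) -> bool:
    formula = (metabolite.formula or "").strip()
    if formula in blocklist:
        return False
    elements = metabolite.elements or {}
    return elements.get("C", 0) >= 1


def load_sbml(
    path,
    carbon_blocklist: frozenset[str] = DEFAULT_CARBON_BLOCKLIST,
    diffusion_predicate: Callable | None = default_diffusion_predicate,
) -> MetabolicModel:
    """Load an SBML constraint-based model into a :class:`MetabolicModel`.

    Exchange reactions are auto-detected as single-metabolite boundary
    reactions; carbon-transporting exchanges are annotated from metabolite
    elemental formulas (contains carbon, excluding the inorganic blocklist);
    diffusion flags follow *diffusion_predicate* (see
    :func:`default_diffusion_predicate`).
    """
    import cobra.io

    try:
        cm = cobra.io.read_sbml_model(str(path))
    except Exception as exc:  # cobra raises several parse error types
        raise ModelValidationError(f"failed to parse SBML {path!r}: {exc}") from exc

    rxns = cm.reactions
    reactions = [r.id for r in rxns]
    metabolites = [m.id for m in cm.metabolites]

    objective = np.array([r.objective_coefficient for r in rxns], dtype=float)
    if np.flatnonzero(objective).size == 0:
        raise ModelValidationError(f"model {cm.id!r} has no biomass objective")

    met_pos = {m.id: i for i, m in enumerate(cm.metabolites)}
    rows, cols, vals = [], [], []
    for j, r in enumerate(rxns):
        for m, coef in r.metabolites.items():
            rows.append(met_pos[m.id])
            cols.append(j)
            vals.append(float(coef))
    S = sp.csc_matrix(
        (vals, (rows, cols)), shape=(len(metabolites), len(reactions))
    )

    lower = np.array([r.lower_bound for r in rxns], dtype=float)
    upper = np.array([r.upper_bound for r in rxns], dtype=float)
    # single-metabolite boundary reactions; the biomass objective is a sink
    # but never an exchange
    is_exchange = np.array(
        [
            r.boundary and len(r.metabolites) == 1 and objective[j] == 0
            for j, r in enumerate(rxns)
        ],
        dtype=bool,
    )
    has_gene = np.array(
        [bool(r.gene_reaction_rule.strip()) for r in rxns], dtype=bool
    )

    carbon_source = np.empty(len(reactions), dtype=object)
    carbon_source[:] = None
    seen: dict[str, str] = {}
    for j, r in enumerate(rxns):
        if not (r.boundary and len(r.metabolites) == 1):
            continue
        met = next(iter(r.metabolites))
        if _is_carbon_source(met, carbon_blocklist) and met.id not in seen:
            carbon_source[j] = met.id
            seen[met.id] = r.id

    if diffusion_predicate is None:
        is_diffusion = np.zeros(len(reactions), dtype=bool)
    else:
        is_diffusion = np.array([diffusion_predicate(r) for r in rxns], dtype=bool)

    return MetabolicModel(
        reactions=reactions,
        metabolites=metabolites,
        S=S,
        lower=lower,
        upper=upper,
        objective=objective,
        is_exchange=is_exchange,
        carbon_source=carbon_source,
        is_diffusion=is_diffusion,
        has_gene=has_gene,
        name=cm.id or "model",
    )
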