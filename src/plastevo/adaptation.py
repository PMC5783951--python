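"""Two-phase adaptation protocol over metabolic networks.

For an environment shift the three stages are:

* stage o — FBA in the original environment (fully adapted ancestor);
* stage p — MOMA in the new environment from the stage-o flux (plastic
  response, no mutation);
* stage a — FBA in the new environment (fully adapted), or alternatively
  MOMA-b from the stage-p flux with biomass pinned at the FBA optimum.

Relative fitnesses f_p and f_a divide each stage's biomass rate by the
stage-o rate. An environment counts as adaptable when f_p exceeds a small
threshold (default 1e-4): with a lower plastic fitness the organism is not
expected to survive the shift at all.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .classify import classify_triplets, summarize
from .model import EPS, Environment, MetabolicModel, apply_environment, mutable_reactions
from .solvers import FluxSolution, fba, moma, moma_b

logger = logging.getLogger(__name__)

STAGE_A_METHODS = ("fba", "moma_b")


class GrowthError(RuntimeError):
    """Raised when the model cannot grow in the original environment."""


@dataclass
class AdaptationRun:
    """Fluxes and fitnesses for one environment shift (stages o, p, a)."""

    env_o: Environment
    env_a: Environment
    v_o: np.ndarray
    v_p: np.ndarray
    v_a: np.ndarray
    biomass_o: float
    biomass_p: float
    biomass_a: float
    f_p: float
    f_a: float
    trait_ids: list[str]
    trait_index: np.ndarray
    stage_a_method: str = "fba"

    @property
    def fitness_asymmetry(self) -> float:
        """|log10 f_p| - |log10 f_a|; positive when the plastic stage is the
        fitness outlier (f_p further from 1 than f_a on a log scale)."""
        return abs(np.log10(self.f_p)) - abs(np.log10(self.f_a))

    def triplets(self) -> pd.DataFrame:
        """Per-trait (L_o, L_p, L_a) table over the mutable reactions."""
        idx = self.trait_index
        return pd.DataFrame(
            {
                "trait_id": self.trait_ids,
                "L_o": self.v_o[idx],
                "L_p": self.v_p[idx],
                "L_a": self.v_a[idx],
            }
        )


def run_adaptation(
    model: MetabolicModel,
    env_o: Environment,
    env_a: Environment,
    stage_a_method: str = "fba",
    v_o: np.ndarray | None = None,
    biomass_o: float | None = None,
) -> AdaptationRun:
    """Simulate the o -> p -> a protocol for one environment shift.

    ``v_o``/``biomass_o`` may be passed to reuse a stage-o FBA solution when
    running many shifts from the same original environment.
    """
    if stage_a_method not in STAGE_A_METHODS:
        raise ValueError(f"stage_a_method must be one of {STAGE_A_METHODS}")

    if v_o is None:
        sol_o = fba(apply_environment(model, env_o))
        if not sol_o.ok:
            raise GrowthError(f"FBA infeasible in original environment {env_o.name!r}")
        v_o, biomass_o = sol_o.fluxes, sol_o.biomass
    if biomass_o is None or biomass_o <= EPS:
        raise GrowthError(
            f"no growth in original environment {env_o.name!r} "
            f"(biomass {biomass_o}); relative fitness undefined"
        )

    m_a = apply_environment(model, env_a)
    sol_p = moma(m_a, v_o)
    if not sol_p.ok:
        raise GrowthError(f"MOMA infeasible in new environment {env_a.name!r}")

    sol_fba_a = fba(m_a)
    if not sol_fba_a.ok:
        raise GrowthError(f"FBA infeasible in new environment {env_a.name!r}")
    if stage_a_method == "fba":
        sol_a: FluxSolution = sol_fba_a
    else:
        sol_a = moma_b(m_a, sol_p.fluxes, sol_fba_a.biomass)
        if not sol_a.ok:
            raise GrowthError(
                f"MOMA-b infeasible at biomass {sol_fba_a.biomass} in {env_a.name!r}"
            )

    traits = mutable_reactions(model)
    pos = {r: i for i, r in enumerate(model.reactions)}
    trait_index = np.array([pos[r] for r in traits], dtype=int)

    return AdaptationRun(
        env_o=env_o,
        env_a=env_a,
        v_o=v_o,
        v_p=sol_p.fluxes,
        v_a=sol_a.fluxes,
        biomass_o=float(biomass_o),
        biomass_p=float(sol_p.biomass),
        biomass_a=float(sol_a.biomass),
        f_p=float(sol_p.biomass) / float(biomass_o),
        f_a=float(sol_a.biomass) / float(biomass_o),
        trait_ids=traits,
        trait_index=trait_index,
        stage_a_method=stage_a_method,
    )


def screen_environments(
    model: MetabolicModel,
    env_o: Environment,
    candidates: list[Environment],
    threshold: float = EPS,
) -> list[Environment]:
    """Return the candidate environments that are adaptable from *env_o*.

    Adaptable means the MOMA-predicted relative biomass (plastic fitness
    f_p, computed from the stage-o FBA flux) exceeds *threshold*. Candidate
    order is preserved.
    """
    sol_o = fba(apply_environment(model, env_o))
    if not sol_o.ok or sol_o.biomass <= EPS:
        raise GrowthError(f"no growth in original environment {env_o.name!r}")
    keep = []
    for env in candidates:
        sol_p = moma(apply_environment(model, env), sol_o.fluxes)
        if sol_p.ok and sol_p.biomass / sol_o.biomass > threshold:
            keep.append(env)
    return keep


# ---------------------------------------------------------------------- #
@dataclass
class EnvironmentEnsembleSpec:
    """Random mixed-carbon environments.

    For each (environment, source) pair an availability probability g is
    drawn from an exponential distribution (mean 0.1 by default), truncated
    to [0, 1], and the source's presence is a Bernoulli(g) event. ``mode``
    selects whether g is redrawn per source (``per_source``) or drawn once
    per environment and shared by all its sources (``per_environment``).
    """

    n: int
    sources: list[str]
    mean: float = 0.1
    mode: str = "per_source"
    uptake: float = Environment.DEFAULT_UPTAKE
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.mean <= 0:
            raise ValueError("mean must be positive")
        if self.mode not in ("per_source", "per_environment"):
            raise ValueError(f"unknown draw mode {self.mode!r}")


def random_environments(spec: EnvironmentEnsembleSpec) -> list[Environment]:
    """Draw random mixed-carbon environments per *spec* (reproducible).

    Each environment uses its own seed substream, so extending ``n`` leaves
    earlier environments unchanged.
    """
    streams = np.random.SeedSequence(spec.seed).spawn(spec.n)
    k = len(spec.sources)
    envs = []
    for i, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        if spec.mode == "per_source":
            g = np.minimum(rng.exponential(spec.mean, size=k), 1.0)
        else:
            g = np.minimum(rng.exponential(spec.mean), 1.0)
        present = rng.random(k) < g
        envs.append(
            Environment.from_sources(
                [s for s, p in zip(spec.sources, present) if p],
                uptake=spec.uptake,
                name=f"random_{i}",
            )
        )
    return envs


def shuffle_reaction_order(model: MetabolicModel, seed: int) -> MetabolicModel:
    """Permute reaction columns (with all annotations); semantics unchanged.

    FBA and MOMA optima are invariant to reaction order, but degenerate FBA
    problems may return a different optimal vertex — this utility exposes
    that effect for robustness checks.
    """
    rng = np.random.default_rng(seed)
    perm = rng.permutation(model.n_reactions)
    return MetabolicModel(
        reactions=[model.reactions[i] for i in perm],
        metabolites=list(model.metabolites),
        S=model.S[:, perm],
        lower=model.lower[perm],
        upper=model.upper[perm],
        objective=model.objective[perm],
        is_exchange=model.is_exchange[perm],
        carbon_source=model.carbon_source[perm],
        is_diffusion=model.is_diffusion[perm],
        has_gene=model.has_gene[perm],
        name=model.name,
    )


# ---------------------------------------------------------------------- #
SUMMARY_FIELDS = [
    "model",
    "environment",
    "f_p",
    "f_a",
    "fitness_asymmetry",
    "c_ri",
    "c_rv",
    "ri_rv_ratio",
    "q",
    "restored",
    "over_restored",
    "under_restored",
    "c_fac",
    "c_hin",
    "plastic_only",
    "mean_pc",
    "mean_tc",
    "p_two_tailed",
]


def adaptation_summary_row(
    model_name: str, run: AdaptationRun, theta: float = 0.2, eps: float = EPS
) -> dict:
    """Classify one adaptation's trait fluxes and flatten into a table row."""
    tr = run.triplets()
    table = classify_triplets(
        tr["L_o"], tr["L_p"], tr["L_a"], theta=theta, eps=eps, trait_ids=tr["trait_id"]
    )
    s = summarize(table)
    return {
        "model": model_name,
        "environment": run.env_a.name,
        "f_p": run.f_p,
        "f_a": run.f_a,
        "fitness_asymmetry": run.fitness_asymmetry,
        "c_ri": s.c_ri,
        "c_rv": s.c_rv,
        "ri_rv_ratio": s.ri_rv_ratio,
        "q": s.q,
        "restored": s.restored,
        "over_restored": s.over_restored,
        "under_restored": s.under_restored,
        "c_fac": s.c_fac,
        "c_hin": s.c_hin,
        "plastic_only": s.plastic_only,
        "mean_pc": s.mean_pc,
        "mean_tc": s.mean_tc,
        "p_two_tailed": s.p_two_tailed,
    }


def run_ensemble(
    models: list[MetabolicModel],
    env_o: Environment,
    candidates: list[Environment],
    theta: float = 0.2,
    eps: float = EPS,
    threshold: float = EPS,
    stage_a_method: str = "fba",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run every model against its adaptable candidate environments.

    Returns ``(per_run, medians)``: one summary row per model x adaptable
    environment, and across-model medians of the headline statistics per
    environment. Models that fail to grow in *env_o* are skipped with a
    warning.
    """
    rows = []
    for k, model in enumerate(models):
        name = model.name if model.name != "model" else f"model_{k}"
        try:
            adaptable = screen_environments(model, env_o, candidates, threshold)
        except GrowthError as exc:
            warnings.warn(f"skipping {name}: {exc}")
            logger.warning("skipping %s: %s", name, exc)
            continue
        sol_o = fba(apply_environment(model, env_o))
        for env in adaptable:
            run = run_adaptation(
                model,
                env_o,
                env,
                stage_a_method=stage_a_method,
                v_o=sol_o.fluxes,
                biomass_o=sol_o.biomass,
            )
            rows.append(adaptation_summary_row(name, run, theta=theta, eps=eps))
    per_run = pd.DataFrame(rows, columns=SUMMARY_FIELDS)
    median_cols = ["c_rv", "c_ri", "ri_rv_ratio", "q", "f_p", "fitness_asymmetry"]
    if per_run.empty:
        medians = pd.DataFrame(columns=median_cols)
    else:
        medians = per_run.groupby("environment")[median_cols].median()
    return per_run, medians
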