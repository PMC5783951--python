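"""End-to-end fluxome analysis of a genome-scale model.

Runs the full single-carbon adaptation study on a loaded model: screen all
single-source environments for adaptability from an original environment,
simulate each adaptable shift with the o -> p -> a protocol, classify every
mutable reaction's flux triplet, and aggregate the headline statistics
(category fractions, restoration breakdown, q, fitness trajectory and its
correlations with mean PC / mean TC).

The reference subject is the E. coli genome-scale reconstruction iAF1260
(glucose original environment, 10 mmol/gDW/h uptake); the SBML file is not
shipped and must be supplied by the caller (see scripts/reproduce_iaf1260.py).
The same entry point runs unchanged on toy or user-supplied models.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .adaptation import (
    SUMMARY_FIELDS,
    adaptation_summary_row,
    run_adaptation,
    screen_environments,
)
from .model import EPS, Environment, MetabolicModel, apply_environment
from .solvers import fba
from .classify import binom_one_tailed, binom_two_tailed

#: BiGG identifier of extracellular glucose in iAF1260.
GLUCOSE = "glc__D_e"


@dataclass
class FluxomeResult:
    """Per-adaptation summary table plus study-level aggregates."""

    per_adaptation: pd.DataFrame
    aggregates: dict

    def to_json(self) -> dict:
        return {
            "aggregates": self.aggregates,
            "per_adaptation": self.per_adaptation.to_dict(orient="records"),
        }


def single_source_candidates(
    model: MetabolicModel, origin: str, uptake: float = Environment.DEFAULT_UPTAKE
) -> list[Environment]:
    """All single-carbon-source environments except the origin's."""
    return [
        Environment.single(s, uptake)
        for s in model.carbon_sources()
        if s != origin
    ]


def reproduce_fluxome(
    model: MetabolicModel,
    origin: str = GLUCOSE,
    uptake: float = Environment.DEFAULT_UPTAKE,
    theta: float = 0.2,
    eps: float = EPS,
    threshold: float = EPS,
    stage_a_method: str = "fba",
    max_environments: int | None = None,
) -> FluxomeResult:
    """Run the single-carbon adaptation study from *origin* on *model*.

    ``max_environments`` caps the number of adaptable environments analyzed
    (None = all), useful for smoke runs on large models.
    """
    env_o = Environment.single(origin, uptake)
    candidates = single_source_candidates(model, origin, uptake)
    adaptable = screen_environments(model, env_o, candidates, threshold)
    if max_environments is not None:
        adaptable = adaptable[:max_environments]

    sol_o = fba(apply_environment(model, env_o))
    rows = []
    tc_appreciable_counts = []
    for env in adaptable:
        run = run_adaptation(
            model,
            env_o,
            env,
            stage_a_method=stage_a_method,
            v_o=sol_o.fluxes,
            biomass_o=sol_o.biomass,
        )
        row = adaptation_summary_row(model.name, run, theta=theta, eps=eps)
        rows.append(row)
        # count of traits with appreciable total change, for the
        # comparative-biology view
        from .classify import classify_triplets, condition_on_tc

        tr = run.triplets()
        table = classify_triplets(
            tr["L_o"], tr["L_p"], tr["L_a"], theta=theta, eps=eps
        )
        tc_appreciable_counts.append(len(condition_on_tc(table)))

    per = pd.DataFrame(rows, columns=SUMMARY_FIELDS)
    agg: dict = {
        "n_carbon_exchanges": len(model.carbon_sources()),
        "n_traits": int((~model.is_diffusion).sum()),
        "n_candidates": len(candidates),
        "n_adaptable": len(adaptable),
    }
    if len(per):
        agg.update(
            mean_c_rv=float(per["c_rv"].mean()),
            median_c_rv=float(per["c_rv"].median()),
            mean_c_ri=float(per["c_ri"].mean()),
            median_c_ri=float(per["c_ri"].median()),
            mean_restored=float(per["restored"].mean()),
            mean_over_restored=float(per["over_restored"].mean()),
            mean_under_restored=float(per["under_restored"].mean()),
            mean_q=float(per["q"].mean()),
            median_q=float(per["q"].median()),
            mean_plastic_only=float(per["plastic_only"].mean()),
            n_fp_below_1=int((per["f_p"] < 1).sum()),
            n_asymmetry_positive=int((per["fitness_asymmetry"] > 0).sum()),
            p_asymmetry_one_tailed=binom_one_tailed(
                int((per["fitness_asymmetry"] > 0).sum()), len(per)
            ),
            n_rv_gt_ri=int((per["c_rv"] > per["c_ri"]).sum()),
            p_rv_gt_ri_two_tailed=binom_two_tailed(
                int((per["c_rv"] > per["c_ri"]).sum()), len(per)
            ),
            mean_tc_appreciable=float(np.mean(tc_appreciable_counts)),
        )
        if len(per) >= 3:
            rho_pc, p_pc = spearmanr(per["f_p"], per["mean_pc"])
            rho_tc, p_tc = spearmanr(per["f_a"], per["mean_tc"])
            agg.update(
                spearman_fp_mean_pc=float(rho_pc),
                spearman_fp_mean_pc_p=float(p_pc),
                spearman_fa_mean_tc=float(rho_tc),
                spearman_fa_mean_tc_p=float(p_tc),
            )
    return FluxomeResult(per_adaptation=per, aggregates=agg)
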