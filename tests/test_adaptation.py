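"""The o -> p -> a protocol, environment screening, random environments."""

import numpy as np
import pandas as pd
import pytest

from plastevo import (
    Environment,
    EnvironmentEnsembleSpec,
    apply_environment,
    fba,
    random_environments,
    run_adaptation,
    run_ensemble,
    screen_environments,
    shuffle_reaction_order,
)
from plastevo.adaptation import GrowthError, adaptation_summary_row


class TestRunAdaptation:
    def test_identity_shift_is_neutral(self, two_source_toy):
        model, a = two_source_toy
        run = run_adaptation(model, a["env_o"], a["env_o"])
        assert run.f_p == pytest.approx(1.0, abs=1e-6)
        assert run.f_a == pytest.approx(1.0, abs=1e-6)
        tr = run.triplets()
        np.testing.assert_allclose(tr["L_p"], tr["L_o"], atol=1e-4)

    def test_two_source_shift_analytic_fitnesses(self, two_source_toy):
        """C1 -> C2 shift: f_p = y2^2*B0/(2+y2^2)/B0 = 1/9, f_a = y2 = 1/2."""
        model, a = two_source_toy
        run = run_adaptation(model, a["env_o"], a["env_a"])
        assert run.f_p == pytest.approx(a["f_p"], abs=1e-5)
        assert run.f_a == pytest.approx(a["f_a"], abs=1e-5)
        assert run.f_p < 1 <= run.f_a / a["f_a"] + 1e-9
        assert run.fitness_asymmetry == pytest.approx(
            abs(np.log10(a["f_p"])) - abs(np.log10(a["f_a"])), abs=1e-4
        )

    def test_stage_a_dominates_plastic_fitness(self, two_source_toy):
        model, a = two_source_toy
        for method in ("fba", "moma_b"):
            run = run_adaptation(model, a["env_o"], a["env_a"], stage_a_method=method)
            assert run.f_a >= run.f_p - 1e-6

    def test_moma_b_stage_a_keeps_fba_biomass(self, two_source_toy):
        model, a = two_source_toy
        run = run_adaptation(model, a["env_o"], a["env_a"], stage_a_method="moma_b")
        assert run.biomass_a == pytest.approx(a["fba_biomass_a"], abs=1e-5)

    def test_zero_growth_origin_rejected(self, two_source_toy):
        model, a = two_source_toy
        with pytest.raises(GrowthError, match="no growth|infeasible"):
            run_adaptation(model, Environment(), a["env_a"])

    def test_unknown_method_rejected(self, two_source_toy):
        model, a = two_source_toy
        with pytest.raises(ValueError, match="stage_a_method"):
            run_adaptation(model, a["env_o"], a["env_a"], stage_a_method="qp")


class TestScreenEnvironments:
    def test_dead_end_source_excluded(self, two_source_toy):
        """A source with no catabolic route is screened out."""
        model, a = two_source_toy
        m = model.copy()
        i = m.reaction_index("T2")
        m.upper[i] = 0.0  # cut the C2 catabolic path
        kept = screen_environments(m, a["env_o"], [a["env_a"]])
        assert kept == []

    def test_adaptable_sources_retained_in_order(self, two_source_toy):
        model, a = two_source_toy
        mixed = Environment.from_sources(["C1", "C2"], name="mixed")
        kept = screen_environments(model, a["env_o"], [a["env_a"], mixed])
        assert kept == [a["env_a"], mixed]

    def test_monotone_in_threshold(self, two_source_toy):
        model, a = two_source_toy
        lo = screen_environments(model, a["env_o"], [a["env_a"]], threshold=0.0)
        hi = screen_environments(model, a["env_o"], [a["env_a"]], threshold=0.9)
        assert set(hi) <= set(lo)


class TestRandomEnvironments:
    SOURCES = [f"S{i}" for i in range(258)]

    def test_reproducible_given_seed(self):
        spec = EnvironmentEnsembleSpec(n=5, sources=self.SOURCES, seed=7)
        a = random_environments(spec)
        b = random_environments(spec)
        assert [set(e.sources) for e in a] == [set(e.sources) for e in b]

    def test_prefix_stable_when_n_grows(self):
        small = random_environments(
            EnvironmentEnsembleSpec(n=3, sources=self.SOURCES, seed=7)
        )
        big = random_environments(
            EnvironmentEnsembleSpec(n=6, sources=self.SOURCES, seed=7)
        )
        assert [set(e.sources) for e in small] == [set(e.sources) for e in big[:3]]

    def test_structure(self):
        envs = random_environments(
            EnvironmentEnsembleSpec(n=3, sources=self.SOURCES, seed=1)
        )
        assert len(envs) == 3
        for e in envs:
            assert set(e.sources) <= set(self.SOURCES)

    def test_marginal_presence_matches_truncated_exponential(self):
        """Per-source mode: presence frequency ~ E[min(g,1)] for Exp(0.1).

        E[min(g,1)] = (1 - exp(-10))/10 ~ 0.0999955; at 10^4 environments x
        258 sources the empirical frequency must fall inside the 99%
        binomial interval.
        """
        n = 10_000
        envs = random_environments(
            EnvironmentEnsembleSpec(n=n, sources=self.SOURCES, seed=11)
        )
        counts = np.array([len(e.sources) for e in envs])
        p = (1 - np.exp(-10)) / 10
        draws = n * len(self.SOURCES)
        freq = counts.sum() / draws
        half = 2.576 * np.sqrt(p * (1 - p) / draws)
        assert abs(freq - p) < half
        # mean sources per environment ~ 258 * p ~ 25.8
        assert counts.mean() == pytest.approx(258 * p, rel=0.02)

    def test_per_environment_mode_right_skewed(self):
        """One g per environment produces a heavier-tailed source count
        (mean exceeding the median), matching the right-skewed pattern."""
        envs = random_environments(
            EnvironmentEnsembleSpec(
                n=4000, sources=self.SOURCES, mode="per_environment", seed=3
            )
        )
        counts = np.array([len(e.sources) for e in envs])
        assert counts.mean() > np.median(counts)

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            EnvironmentEnsembleSpec(n=0, sources=self.SOURCES)
        with pytest.raises(ValueError):
            EnvironmentEnsembleSpec(n=1, sources=self.SOURCES, mean=-1)
        with pytest.raises(ValueError):
            EnvironmentEnsembleSpec(n=1, sources=self.SOURCES, mode="bulk")


class TestShuffle:
    def test_fba_objective_invariant(self, two_source_toy):
        model, a = two_source_toy
        m = apply_environment(model, a["env_o"])
        ref = fba(m).objective
        assert fba(shuffle_reaction_order(m, seed=5)).objective == pytest.approx(
            ref, abs=1e-6
        )

    def test_deterministic_permutation(self, two_source_toy):
        model, _ = two_source_toy
        assert (
            shuffle_reaction_order(model, seed=9).reactions
            == shuffle_reaction_order(model, seed=9).reactions
        )


class TestEnsemble:
    def test_single_model_medians_equal_values(self, two_source_toy):
        model, a = two_source_toy
        per_run, medians = run_ensemble([model], a["env_o"], [a["env_a"]])
        assert len(per_run) == 1
        row = per_run.iloc[0]
        med = medians.loc[row["environment"]]
        for col in ("c_rv", "c_ri", "q", "f_p"):
            assert med[col] == pytest.approx(row[col])

    def test_medians_permutation_invariant(self, two_source_toy, diamond_toy):
        m1, a = two_source_toy
        m2 = m1.copy()
        m2.upper[m2.reaction_index("T2")] = 5.0  # a second, distinct model
        m2.name = "variant"
        _, med_ab = run_ensemble([m1, m2], a["env_o"], [a["env_a"]])
        _, med_ba = run_ensemble([m2, m1], a["env_o"], [a["env_a"]])
        pd.testing.assert_frame_equal(med_ab, med_ba)

    def test_non_growing_model_skipped_with_warning(self, two_source_toy):
        model, a = two_source_toy
        dead = model.copy()
        dead.name = "dead"
        dead.upper[dead.reaction_index("T1")] = 0.0
        dead.upper[dead.reaction_index("T2")] = 0.0
        with pytest.warns(UserWarning, match="skipping dead"):
            per_run, _ = run_ensemble([dead, model], a["env_o"], [a["env_a"]])
        assert set(per_run["model"]) == {"two_source_toy"}

    def test_summary_row_two_source_hand_check(self, two_source_toy):
        """The C1->C2 shift on the two-source toy is fully hand-checkable:
        traits EX_C1, EX_C2, T1, T2, BIOMASS all change appreciably; the
        uptake/transport swaps are plastic-then-kept or amplified while
        biomass drops then partially recovers (reversing)."""
        model, a = two_source_toy
        run = run_adaptation(model, a["env_o"], a["env_a"])
        row = adaptation_summary_row("toy", run)
        # v_o=(-10,0,10,0,10), v_p=(0,-20/9,0,20/9,10/9), v_a=(0,-10,0,10,5)
        # EX_C1: -10 -> 0 -> 0      plastic_only (PC=TC=10, not an excess)
        # EX_C2: 0 -> -2.22 -> -10  reinforcing
        # T1:    10 -> 0 -> 0       plastic_only (PC=TC=10)
        # T2:    0 -> 2.22 -> 10    reinforcing
        # BIOMASS: 10 -> 1.11 -> 5  reversing (partial recovery), PC>TC
        assert row["c_ri"] == pytest.approx(2 / 5)
        assert row["c_rv"] == pytest.approx(1 / 5)
        assert row["q"] == pytest.approx(1 / 5)
        assert row["f_p"] == pytest.approx(1 / 9, abs=1e-5)
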