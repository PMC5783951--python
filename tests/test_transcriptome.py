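"""Expression-matrix pipeline: filtering, normalization, triplet assembly."""

import numpy as np
import pandas as pd
import pytest

from plastevo import binom_two_tailed, classify_triplets, summarize
from plastevo.synth import gen_case_bundle
from plastevo.transcriptome import (
    CaseManifest,
    ExpressionDataset,
    average_replicates,
    build_triplets,
    filter_missing,
    growth_independent_mask,
    normalize_mean,
)


def make_ds(values, stages, lines=None, name="ds"):
    cols = list(values.keys())
    samples = pd.DataFrame(
        {
            "stage": stages,
            "line": lines if lines is not None else ["L1"] * len(cols),
        },
        index=cols,
    )
    return ExpressionDataset(pd.DataFrame(values, index=["g1", "g2", "g3"]), samples, name)


@pytest.fixture()
def tiny_ds():
    return make_ds(
        {"s_o": [1.0, 2.0, 3.0], "s_p": [2.0, 1.0, 3.0], "s_a": [1.0, 3.0, 3.0]},
        stages=["o", "p", "a"],
    )


class TestFilterMissing:
    def test_gene_with_missing_cell_dropped(self):
        ds = make_ds(
            {"a": [1.0, np.nan, 2.0], "b": [1.0, 2.0, 3.0]}, stages=["o", "p"]
        )
        out = filter_missing(ds)
        assert list(out.values.index) == ["g1", "g3"]

    def test_no_missing_is_identity(self, tiny_ds):
        out = filter_missing(tiny_ds)
        pd.testing.assert_frame_equal(out.values, tiny_ds.values)

    def test_sentinel_markers_equivalent_to_nan(self):
        with_nan = make_ds(
            {"a": [1.0, np.nan, 2.0], "b": [1.0, 2.0, 3.0]}, stages=["o", "p"]
        )
        with_sentinel = make_ds(
            {"a": [1.0, -999.0, 2.0], "b": [1.0, 2.0, 3.0]}, stages=["o", "p"]
        )
        out_nan = filter_missing(with_nan)
        out_sent = filter_missing(with_sentinel, sentinels=(-999.0,))
        pd.testing.assert_frame_equal(out_nan.values, out_sent.values)

    def test_all_dropped_is_error(self):
        ds = make_ds(
            {"a": [np.nan, np.nan, np.nan], "b": [1.0, 2.0, 3.0]}, stages=["o", "p"]
        )
        with pytest.raises(ValueError, match="all genes dropped"):
            filter_missing(ds)


class TestNormalizeMean:
    def test_scalar_factors(self):
        d1 = make_ds({"a": [2.0, 2.0, 2.0]}, stages=["o"], name="d1")
        d2 = make_ds({"a": [4.0, 4.0, 4.0]}, stages=["o"], name="d2")
        n1, n2 = normalize_mean([d1, d2], target=1.0)
        assert float(n1.values.to_numpy().mean()) == pytest.approx(1.0)
        assert float(n2.values.to_numpy().mean()) == pytest.approx(1.0)
        np.testing.assert_allclose(n1.values["a"], 0.5 * d1.values["a"])
        np.testing.assert_allclose(n2.values["a"], 0.25 * d2.values["a"])

    def test_idempotent(self, tiny_ds):
        once = normalize_mean([tiny_ds])[0]
        twice = normalize_mean([once])[0]
        pd.testing.assert_frame_equal(once.values, twice.values)

    def test_zero_mean_rejected(self):
        ds = make_ds({"a": [0.0, 0.0, 0.0]}, stages=["o"])
        with pytest.raises(ValueError, match="zero mean"):
            normalize_mean([ds])

    def test_classification_invariant_to_rescaling(self, tiny_ds):
        """Cutoffs scale with L_o, so a per-dataset scalar cannot change
        any category."""
        scaled = normalize_mean([tiny_ds], target=7.3)[0]
        for ds in (tiny_ds, scaled):
            t = ds.values
            cls = classify_triplets(t["s_o"], t["s_p"], t["s_a"], 0.2)
            if ds is tiny_ds:
                ref = cls["category"]
            else:
                assert (cls["category"] == ref).all()


class TestAverageReplicates:
    def test_arithmetic_mean_within_group(self):
        ds = make_ds(
            {"r1": [2.0, 2.0, 2.0], "r2": [4.0, 4.0, 4.0]},
            stages=["a", "a"],
            lines=["L1", "L1"],
        )
        out = average_replicates(ds, ["stage", "line"])
        assert out.values.shape[1] == 1
        np.testing.assert_allclose(out.values.iloc[:, 0], 3.0)
        assert out.samples.iloc[0]["n_replicates"] == 2

    def test_single_replicate_identity(self, tiny_ds):
        out = average_replicates(tiny_ds, ["stage"])
        np.testing.assert_allclose(
            out.values.to_numpy(), tiny_ds.values.to_numpy()
        )

    def test_unknown_grouping_column_rejected(self, tiny_ds):
        with pytest.raises(KeyError, match="batch"):
            average_replicates(tiny_ds, ["batch"])


class TestBuildTriplets:
    def test_shared_o_p_profiles_across_cases(self):
        ds = make_ds(
            {
                "anc_o": [1.0, 2.0, 3.0],
                "anc_p": [2.0, 1.0, 3.0],
                "ev1": [1.0, 3.0, 3.0],
                "ev2": [2.0, 2.0, 3.0],
            },
            stages=["o", "p", "a", "a"],
        )
        manifest = CaseManifest(
            cases={
                "c1": {"o": ["anc_o"], "p": ["anc_p"], "a": ["ev1"]},
                "c2": {"o": ["anc_o"], "p": ["anc_p"], "a": ["ev2"]},
            }
        )
        tables = build_triplets(ds, manifest)
        assert set(tables) == {"c1", "c2"}
        pd.testing.assert_series_equal(tables["c1"]["L_o"], tables["c2"]["L_o"])
        pd.testing.assert_series_equal(tables["c1"]["L_p"], tables["c2"]["L_p"])
        assert not tables["c1"]["L_a"].equals(tables["c2"]["L_a"])

    def test_missing_stage_in_manifest_rejected(self):
        with pytest.raises(ValueError, match="missing stage"):
            CaseManifest(cases={"c1": {"o": ["x"], "p": ["y"]}})

    def test_absent_sample_named_in_error(self, tiny_ds):
        manifest = CaseManifest(
            cases={"c1": {"o": ["s_o"], "p": ["s_p"], "a": ["ghost"]}}
        )
        with pytest.raises(KeyError, match="ghost"):
            build_triplets(tiny_ds, manifest)

    def test_synthetic_44_case_bundle_structure(self):
        ds, manifest, _ = gen_case_bundle(n_cases=44, n_genes=50, seed=0)
        tables = build_triplets(ds, manifest)
        assert len(tables) == 44
        for t in tables.values():
            assert list(t.columns) == ["trait_id", "L_o", "L_p", "L_a"]


class TestGrowthIndependence:
    @pytest.mark.parametrize(
        "profile, independent",
        [
            ((1, 2, 3, 4), False),  # monotone increasing
            ((1, 3, 2, 4), True),  # non-monotone
            ((4, 4, 2, 1), False),  # non-increasing with a tie
        ],
    )
    def test_monotonicity_convention(self, profile, independent):
        df = pd.DataFrame([profile], index=["g"], columns=list("abcd"))
        assert bool(growth_independent_mask(df).iloc[0]) is independent

    def test_strict_convention_flags_ties(self):
        df = pd.DataFrame([(4, 4, 2, 1)], index=["g"], columns=list("abcd"))
        assert bool(growth_independent_mask(df, strict=True).iloc[0]) is True

    def test_too_few_rate_columns_rejected(self):
        df = pd.DataFrame([(1, 2)], columns=["a", "b"])
        with pytest.raises(ValueError, match="at least 3"):
            growth_independent_mask(df)


class TestPipelineEndToEnd:
    def test_planted_reversion_majority_recovered(self):
        """On the synthetic multi-case bundle the pipeline reproduces
        C_RV > C_RI in exactly the planted majority of cases, and the
        cross-case sign test points in the planted direction."""
        ds, manifest, truth = gen_case_bundle(
            n_cases=24, n_genes=600, n_majority_reversing=22, seed=13
        )
        ds = normalize_mean([filter_missing(ds)])[0]
        tables = build_triplets(ds, manifest)
        majority = {}
        for cid, t in tables.items():
            s = summarize(classify_triplets(t["L_o"], t["L_p"], t["L_a"], 0.2))
            majority[cid] = s.c_rv > s.c_ri
        expected = dict(
            zip(truth["case"], truth["planted_reversing_majority"])
        )
        assert majority == expected
        k = sum(majority.values())
        assert binom_two_tailed(k, len(majority)) < 0.05
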