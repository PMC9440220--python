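"""Inclusion filter, volcano windows, presence calls, tissue accounting."""

import numpy as np
import pandas as pd
import pytest

from gnotodiff import (
    InclusionPolicy,
    InputError,
    VolcanoPolicy,
    apply_inclusion_filter,
    call_presence,
    heatmap_matrix,
    tabulate_tissue_summary,
    volcano_classify,
    volcano_table,
)


def make_records(rows):
    defaults = {
        "feature_id": "RP+:F000",
        "tissue": "cecum",
        "mean_gf": 150_000.0,
        "mean_mpf": 100_000.0,
        "fc": 1.5,
        "log2fc": np.log2(1.5),
        "p": 0.01,
        "q": 0.03,
        "presence": "both",
        "max_abundance": 150_000.0,
    }
    return pd.DataFrame([{**defaults, **r} for r in rows])


def make_meta(feature_ids, rt=1.2, has_msms=True):
    return pd.DataFrame(
        {
            "mode": "RP+",
            "mz": 200.0,
            "rt": rt,
            "has_msms": has_msms,
        },
        index=pd.Index(feature_ids, name="feature_id"),
    )


class TestInclusionFilter:
    def test_fully_qualifying_record_passes(self):
        rec = make_records([{"fc": 2.0, "p": 0.008, "q": 0.03}])
        out = apply_inclusion_filter(rec, make_meta(rec["feature_id"]))
        assert len(out) == 1

    @pytest.mark.parametrize(
        "override, meta_kwargs",
        [
            ({"fc": 1.1, "log2fc": np.log2(1.1)}, {}),  # FC inside the window
            ({"p": 0.06}, {}),
            ({"q": 0.06}, {}),
            ({"max_abundance": 90_000.0}, {}),
            ({}, {"rt": 0.5}),  # below the 0.7 min retention-time cut
            ({}, {"has_msms": False}),
        ],
    )
    def test_single_criterion_failure_excludes(self, override, meta_kwargs):
        rec = make_records([override])
        out = apply_inclusion_filter(rec, make_meta(rec["feature_id"], **meta_kwargs))
        assert len(out) == 0

    def test_fc_criterion_is_two_sided(self):
        rec = make_records([{"fc": 0.5, "log2fc": -1.0}])
        assert len(apply_inclusion_filter(rec, make_meta(rec["feature_id"]))) == 1
        one_sided = InclusionPolicy(two_sided=False)
        assert len(apply_inclusion_filter(rec, make_meta(rec["feature_id"]), one_sided)) == 0

    def test_exclusive_counts_as_passing_fc(self):
        rec = make_records(
            [{"presence": "gf_only", "fc": np.nan, "log2fc": np.nan, "p": 2 / 252, "q": 0.02}]
        )
        out = apply_inclusion_filter(rec, make_meta(rec["feature_id"]))
        assert len(out) == 1

    def test_absent_never_passes(self):
        rec = make_records([{"presence": "absent", "fc": np.nan, "p": np.nan, "q": np.nan}])
        assert len(apply_inclusion_filter(rec, make_meta(rec["feature_id"]))) == 0

    def test_tightening_any_threshold_shrinks_pass_set(self):
        rng = np.random.default_rng(6)
        n = 300
        rec = make_records(
            [
                {
                    "feature_id": f"RP+:F{i:03d}",
                    "fc": float(np.exp(rng.normal(0, 1))),
                    "p": float(rng.uniform(0, 0.2)),
                    "q": float(rng.uniform(0, 0.2)),
                    "max_abundance": float(rng.uniform(5e4, 5e5)),
                }
                for i in range(n)
            ]
        )
        meta = make_meta(rec["feature_id"], rt=1.0)
        base = InclusionPolicy()
        passed = set(apply_inclusion_filter(rec, meta, base)["feature_id"])
        for tightened in [
            InclusionPolicy(fc_min=2.0),
            InclusionPolicy(p_max=0.01),
            InclusionPolicy(q_max=0.02),
            InclusionPolicy(abundance_min=2e5),
            InclusionPolicy(rt_min=1.5),
        ]:
            sub = set(apply_inclusion_filter(rec, meta, tightened)["feature_id"])
            assert sub <= passed

    def test_missing_field_rejected(self):
        with pytest.raises(InputError, match="max_abundance"):
            apply_inclusion_filter(
                make_records([{}]).drop(columns=["max_abundance"]), make_meta(["RP+:F000"])
            )


class TestVolcano:
    @pytest.mark.parametrize(
        "tissue, fc, q, expected",
        [
            ("cecum", 250.0, 0.05, "highlighted"),  # beyond the 200x cut
            ("cecum", 150.0, 0.05, "background"),  # inside the cecum window
            ("cecum", 0.004, 0.05, "highlighted"),
            ("duodenum", 150.0, 0.05, "highlighted"),  # small intestine: 100x cut
            ("heart", 40.0, 0.05, "highlighted"),  # "rest" class: 30x cut
            ("heart", 25.0, 0.05, "background"),
            ("heart", 40.0, 0.2, "background"),  # fails q < 0.1
        ],
    )
    def test_tissue_class_windows(self, tissue, fc, q, expected):
        record = {"fc": fc, "q": q, "presence": "both"}
        assert volcano_classify(record, tissue, VolcanoPolicy()) == expected

    def test_exclusive_lands_at_extreme(self):
        record = {
            "fc": np.nan,
            "q": 0.01,
            "presence": "gf_only",
            "mean_gf": 500_000.0,
        }
        assert volcano_classify(record, "cecum") == "highlighted"

    def test_table_coordinates_and_consistency(self):
        rec = make_records(
            [
                {"feature_id": "RP+:F000", "fc": 250.0, "log2fc": np.log2(250), "q": 0.05},
                {"feature_id": "RP+:F001", "fc": 4.0, "log2fc": 2.0, "q": 0.05},
                {"feature_id": "RP+:F002", "fc": 300.0, "log2fc": np.log2(300), "q": 0.5},
            ]
        )
        out = volcano_table(rec)
        assert out["highlighted"].tolist() == [True, False, False]
        np.testing.assert_allclose(out["neg_log10_q"].iloc[0], -np.log10(0.05))
        np.testing.assert_allclose(out["log2fc"].iloc[1], 2.0)
        # every highlighted point satisfies the q cut
        assert (out.loc[out["highlighted"], "neg_log10_q"] > -np.log10(0.1)).all()

    def test_bad_window_rejected(self):
        from gnotodiff import ConfigurationError

        with pytest.raises(ConfigurationError):
            VolcanoPolicy(fc_windows={"large_intestine": (2.0, 200.0), "small_intestine": (0.01, 100.0), "other": (0.033, 30.0)})


class TestPresence:
    def test_examples(self):
        assert call_presence([35000, 20000, 30000, 40000, 50000], [0, 0, 0, 0, 0]) == "gf_only"
        assert call_presence([0, 0, 0, 0, 0], [0, 0, 0, 0, 0]) == "absent"
        assert call_presence([0, 0, 0, 0, 0], [1, 1, 1, 1, 2]) == "mpf_only"
        assert call_presence([5, 5], [5, 5]) == "both"

    def test_short_vector_rejected(self):
        with pytest.raises(InputError):
            call_presence([1], [2, 3])


class TestTissueSummary:
    def test_partition_identity_and_counts(self, small_dataset):
        from gnotodiff import apply_inclusion_filter, differential_all_tissues, impute_table

        table, _ = small_dataset
        imputed, _ = impute_table(table)
        rec = differential_all_tissues(imputed)
        filt = apply_inclusion_filter(rec, imputed.feature_meta)
        summary = tabulate_tissue_summary(filt, rec, imputed)
        assert set(summary["tissue"]) == set(table.tissues)
        part = summary["n_gf_only"] + summary["n_mpf_only"] + summary["n_shared"]
        assert (part == summary["n_significant"]).all()
        assert ((summary["pct_of_all_features"] >= 0) & (summary["pct_of_all_features"] <= 100)).all()
        assert (summary["n_detected"] <= table.n_features).all()

    def test_planted_exclusives_counted(self, clean_dataset):
        from gnotodiff import (
            apply_inclusion_filter,
            differential_all_tissues,
            impute_table,
            plant_exclusive,
        )

        table, _ = clean_dataset
        ids = list(table.feature_ids[:60])
        planted = plant_exclusive(table, "cecum", "GF", ids)
        imputed, _ = impute_table(planted)
        rec = differential_all_tissues(imputed)
        filt = apply_inclusion_filter(rec, imputed.feature_meta)
        summary = tabulate_tissue_summary(filt, rec, imputed).set_index("tissue")
        # every planted exclusive that passes the abundance/msms/rt criteria
        # appears in the GF-only count; none appear as MPF-only
        expected = len(
            filt[(filt["tissue"] == "cecum") & (filt["feature_id"].isin(ids))]
        )
        assert summary.loc["cecum", "n_gf_only"] == expected
        assert expected > 0
        assert summary.loc["cecum", "n_mpf_only"] == 0
        # uniqueness among all detected features recovers the plant exactly
        detected = tabulate_tissue_summary(
            filt, rec, imputed, uniqueness_among="detected"
        ).set_index("tissue")
        assert detected.loc["cecum", "n_gf_only"] == len(ids)
        part = detected[["n_gf_only", "n_mpf_only", "n_shared"]].sum(axis=1)
        assert (part == detected["n_detected"]).all()


class TestHeatmap:
    def test_direction_semantics(self):
        rec = make_records(
            [
                {"feature_id": "RP+:F000", "tissue": "liver", "fc": 3.0, "log2fc": np.log2(3)},
                {"feature_id": "RP+:F001", "tissue": "liver", "fc": 0.2, "log2fc": np.log2(0.2)},
                {
                    "feature_id": "RP+:F002",
                    "tissue": "cecum",
                    "presence": "mpf_only",
                    "fc": np.nan,
                    "log2fc": np.nan,
                },
            ]
        )
        groups = {"RP+:F000": "metA", "RP+:F001": "metB", "RP+:F002": "metC"}
        mat = heatmap_matrix(rec, groups)
        assert mat.loc["metA", "liver"] == 1  # FC > 1: higher in GF
        assert mat.loc["metB", "liver"] == -1  # FC < 1: higher in MPF
        assert mat.loc["metC", "cecum"] == -1  # MPF-exclusive
        assert mat.loc["metA", "cecum"] == 0  # not found there

    def test_unmapped_feature_raises(self):
        rec = make_records([{}])
        with pytest.raises(KeyError):
            heatmap_matrix(rec, {})
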