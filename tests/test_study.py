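"""Study-level analyses: agreement tables, group comparison, accuracy."""

import numpy as np
import pandas as pd
import pytest

from pirads_cde import (
    GeneratorConfig,
    LesionManifest,
    LesionReport,
    StudyDesign,
    category_agreement_table,
    design_from_study,
    diagnostic_accuracy,
    feature_agreement_table,
    generate_study,
    group_score_comparison,
)
from pirads_cde.errors import DegenerateDataError, InsufficientDataError
from pirads_cde.study import analyzed_features, build_rating_matrix


def make_category_reports(manifest, raters, scores):
    """Reports with only manual categories; ``scores[rater][lesion]`` = overall."""
    reports = []
    for rater in raters:
        for m in manifest:
            for session in (1, 2):
                reports.append(
                    LesionReport(
                        lesion_id=m.lesion_id, rater_id=rater, session=session,
                        categories={"overall": scores[rater][m.lesion_id],
                                    "t2w": 3, "dwi": 3, "dce": "Negative"},
                    )
                )
    return reports


@pytest.fixture(scope="module")
def tiny_manifest():
    return [
        LesionManifest("L1", "PZ", True),
        LesionManifest("L2", "PZ", True),
        LesionManifest("L3", "TZ", False),
        LesionManifest("L4", "TZ", False),
    ]


@pytest.fixture(scope="module")
def tiny_design(tiny_manifest):
    return StudyDesign(
        rater_groups={"e1": "experienced", "e2": "experienced",
                      "i1": "inexperienced", "i2": "inexperienced"},
        manifest=tuple(tiny_manifest),
    )


class TestFeatureTable:
    def test_row_per_analyzed_feature(self, default_study, default_design, schema):
        tab = feature_agreement_table(default_study.reports, default_design)
        assert len(tab) == len(analyzed_features(schema)) == 35  # 34 CDEs + size >= 1.5 cm
        assert {"pa", "ac1", "ci_low", "ci_high", "band"} <= set(tab.columns)
        assert tab["pa"].between(0, 100).all()

    def test_unanimous_reports_give_full_agreement(self, tiny_design, tiny_manifest):
        values = {"lesion_dim_max": "≥15", "lesion_location": "PZ"}
        reports = [
            LesionReport(m.lesion_id, r, s, values=dict(values))
            for m in tiny_manifest for r in tiny_design.raters for s in (1, 2)
        ]
        tab = feature_agreement_table(
            reports, tiny_design,
            features=[("GLOBAL", "lesion_dim_max"), ("GLOBAL", "lesion_ge_15mm")],
        )
        assert (tab["pa"] == 100.0).all()
        assert (tab["ac1"] == 1.0).all()

    def test_low_noise_feature_outranks_high_noise_feature(self):
        # abnormality generated noise-free, shape with eps = 0.4
        wins = 0
        reps = 40
        for seed in range(reps):
            study = generate_study(GeneratorConfig(
                seed=seed, epsilon={"abnormality": 0.0, "shape": 0.4},
            ))
            design = design_from_study(study)
            tab = feature_agreement_table(
                study.reports, design,
                features=[("T2W", "t2w_abnormality"), ("T2W", "t2w_shape")],
            ).set_index("feature")
            if tab.loc["t2w_abnormality", "ac1"] > tab.loc["t2w_shape", "ac1"]:
                wins += 1
        assert wins == reps  # ordering holds in every replicate here

    def test_smaller_stratum_has_wider_cis(self, default_study, default_design):
        features = [("T2W", "t2w_focality"), ("DWI", "dwi_focality")]
        pz = feature_agreement_table(
            default_study.reports, default_design, zone="PZ", features=features
        )
        afms = feature_agreement_table(
            default_study.reports, default_design, zone="AFMS", features=features
        )
        pz_width = (pz["ci_high"] - pz["ci_low"]).mean()
        afms_width = (afms["ci_high"] - afms["ci_low"]).mean()
        assert afms_width > pz_width

    def test_single_lesion_stratum_rejected(self, default_study, default_design):
        design = StudyDesign(
            rater_groups=dict(default_design.rater_groups),
            manifest=(default_design.manifest[0],),
        )
        with pytest.raises(InsufficientDataError):
            feature_agreement_table(default_study.reports, design)

    def test_mean_pooling_lies_between_session_values(self, default_study, default_design):
        features = [("T2W", "t2w_abnormality")]
        s1 = feature_agreement_table(default_study.reports, default_design,
                                     session=1, features=features)["ac1"][0]
        s2 = feature_agreement_table(default_study.reports, default_design,
                                     session=2, features=features)["ac1"][0]
        overall = feature_agreement_table(default_study.reports, default_design,
                                          pooling="mean", features=features)["ac1"][0]
        assert min(s1, s2) - 1e-12 <= overall <= max(s1, s2) + 1e-12


class TestCategoryTable:
    def test_structure(self, default_study, default_design):
        tab = category_agreement_table(default_study.reports, default_design)
        assert set(tab["feature"]) == {
            "pirads_t2w", "pirads_dwi", "pirads_dce", "pirads_overall"
        }
        assert set(tab["analysis"]) == {"interrater", "intrarater"}
        assert len(tab) == 4 * 6  # 3 inter strata + 3 intra strata per feature

    def test_identical_assignments_give_pa_100(self, tiny_design, tiny_manifest):
        scores = {r: {m.lesion_id: 4 for m in tiny_manifest} for r in tiny_design.raters}
        reports = make_category_reports(tiny_manifest, tiny_design.raters, scores)
        tab = category_agreement_table(reports, tiny_design)
        assert (tab["pa"] == 100.0).all()

    def test_dce_pa_at_least_overall_pa(self, default_study, default_design):
        # three possible DCE outcomes vs five overall categories: raw
        # agreement is higher for the coarser variable in expectation
        tab = category_agreement_table(default_study.reports, default_design)
        inter = tab[(tab["analysis"] == "interrater") & (tab["stratum"] == "overall")]
        inter = inter.set_index("feature")["pa"]
        assert inter["pirads_dce"] >= inter["pirads_overall"]

    def test_intra_rater_pa_matches_confusion_closed_form(self):
        # one rater, q = 5, symmetric 10% confusion of a fixed truth between
        # sessions: P(equal) = (1 - eps)^2 + eps^2/(q - 1)
        rng = np.random.default_rng(77)
        eps, q, n = 0.1, 5, 4000
        truth = rng.integers(1, 6, size=n)

        def observe():
            flip = rng.random(n) < eps
            shift = rng.integers(1, q, size=n)
            return np.where(flip, (truth - 1 + shift) % q + 1, truth)

        manifest = [LesionManifest(f"L{i}", "PZ", True) for i in range(n)]
        s1, s2 = observe(), observe()
        design = StudyDesign(
            rater_groups={"r": "experienced", "pad": "inexperienced"},
            manifest=tuple(manifest),
        )
        reports = []
        for sess, vals in ((1, s1), (2, s2)):
            for m, v in zip(manifest, vals):
                reports.append(LesionReport(m.lesion_id, "r", sess,
                                            categories={"overall": int(v)}))
        mat1 = build_rating_matrix(reports, "pirads_overall", 1, ["r"], [m.lesion_id for m in manifest])
        mat2 = build_rating_matrix(reports, "pirads_overall", 2, ["r"], [m.lesion_id for m in manifest])
        from pirads_cde import intra_rater_agreement

        res = intra_rater_agreement(mat1, mat2)["r"]
        expected = (1 - eps) ** 2 + eps**2 / (q - 1)
        se = np.sqrt(expected * (1 - expected) / n)
        assert abs(res.pa - expected) < 3 * se


class TestGroupComparison:
    def test_identical_distributions_report_no_difference(self, tiny_design, tiny_manifest):
        scores = {r: {m.lesion_id: 3 for m in tiny_manifest} for r in tiny_design.raters}
        reports = make_category_reports(tiny_manifest, tiny_design.raters, scores)
        comp = group_score_comparison(reports, tiny_design)
        assert comp.no_difference
        assert comp.p_value == 1.0

    def test_single_lesion_minimal_case(self, tiny_design):
        manifest = [LesionManifest("L1", "PZ", True)]
        design = StudyDesign(rater_groups=dict(tiny_design.rater_groups),
                             manifest=tuple(manifest))
        scores = {"e1": {"L1": 5}, "e2": {"L1": 5}, "i1": {"L1": 4}, "i2": {"L1": 4}}
        reports = make_category_reports(manifest, design.raters, scores)
        comp = group_score_comparison(reports, design)
        assert comp.n_lesions == 1
        assert comp.p_value == 1.0  # exact test on one pair cannot reject

    def test_shifted_groups_detected_with_power(self):
        # The paired Wilcoxon over the 16 cs lesions detects a systematic
        # inexperienced-rater downgrade.  Reference detection rates were
        # frozen from a 200-replicate simulation: 0.63 at downgrade
        # probability 0.5 (rating noise at the default fair-to-moderate
        # agreement level is substantial), 0.99 at a full one-category
        # shift, null rate 0.025.
        def detection_rate(downgrade, reps=50):
            hits = 0
            for seed in range(reps):
                study = generate_study(
                    GeneratorConfig(seed=seed, inexperienced_downgrade=downgrade)
                )
                comp = group_score_comparison(study.reports, design_from_study(study))
                if comp.p_value < 0.05:
                    hits += 1
            return hits / reps

        assert detection_rate(1.0) > 0.8
        assert detection_rate(0.5) > 0.4

    def test_empty_subset_rejected(self, tiny_design):
        manifest = [LesionManifest("L1", "PZ", False)]
        design = StudyDesign(rater_groups=dict(tiny_design.rater_groups),
                             manifest=tuple(manifest))
        with pytest.raises(InsufficientDataError):
            group_score_comparison([], design)


class TestDiagnosticAccuracy:
    def test_constant_positive_prediction(self, tiny_design, tiny_manifest):
        scores = {r: {m.lesion_id: 5 for m in tiny_manifest} for r in tiny_design.raters}
        reports = make_category_reports(tiny_manifest, tiny_design.raters, scores)
        acc = diagnostic_accuracy(reports, tiny_manifest, design=tiny_design)
        assert (acc.per_rater["recall"] == 1.0).all()
        assert (acc.per_rater["specificity"] == 0.0).all()
        assert (acc.per_rater["precision"] == 0.5).all()

    def test_perfect_separation_auc_one(self, tiny_design, tiny_manifest):
        scores = {
            r: {m.lesion_id: 5 if m.clinically_significant else 1 for m in tiny_manifest}
            for r in tiny_design.raters
        }
        reports = make_category_reports(tiny_manifest, tiny_design.raters, scores)
        acc = diagnostic_accuracy(reports, tiny_manifest, design=tiny_design)
        assert (acc.per_rater["auc"] == 1.0).all()

    def test_single_class_labels_rejected(self, tiny_design):
        manifest = [LesionManifest("L1", "PZ", True), LesionManifest("L2", "TZ", True)]
        with pytest.raises(DegenerateDataError):
            diagnostic_accuracy([], manifest)

    def test_null_scores_give_auc_half(self):
        rng = np.random.default_rng(5)
        n = 32
        aucs = []
        for _ in range(300):
            manifest = [LesionManifest(f"L{i}", "PZ", i < 16) for i in range(n)]
            scores = {"r": {f"L{i}": int(rng.integers(1, 6)) for i in range(n)},
                      "p": {f"L{i}": int(rng.integers(1, 6)) for i in range(n)}}
            design = StudyDesign(rater_groups={"r": "experienced", "p": "inexperienced"},
                                 manifest=tuple(manifest))
            reports = make_category_reports(manifest, ["r"], scores)
            acc = diagnostic_accuracy(reports, manifest, design=design)
            aucs.append(float(acc.per_rater["auc"].iloc[0]))
        se = np.std(aucs, ddof=1) / np.sqrt(len(aucs))
        assert abs(np.mean(aucs) - 0.5) < 3 * se

    def test_threshold_monotonicity(self, default_study, default_design):
        acc3 = diagnostic_accuracy(default_study.reports, list(default_study.manifest),
                                   threshold=3, design=default_design)
        acc4 = diagnostic_accuracy(default_study.reports, list(default_study.manifest),
                                   threshold=4, design=default_design)
        merged = acc3.per_rater.merge(acc4.per_rater, on="rater", suffixes=("_3", "_4"))
        assert (merged["recall_4"] <= merged["recall_3"] + 1e-12).all()
        assert (merged["specificity_4"] >= merged["specificity_3"] - 1e-12).all()

    def test_auc_invariant_under_monotone_transform(self, tiny_design, tiny_manifest):
        rng = np.random.default_rng(9)
        scores = {r: {m.lesion_id: int(rng.integers(1, 6)) for m in tiny_manifest}
                  for r in tiny_design.raters}
        reports = make_category_reports(tiny_manifest, tiny_design.raters, scores)
        acc = diagnostic_accuracy(reports, tiny_manifest, design=tiny_design)
        transformed = {r: {k: v**3 for k, v in d.items()} for r, d in scores.items()}
        reports2 = make_category_reports(tiny_manifest, tiny_design.raters, transformed)
        acc2 = diagnostic_accuracy(reports2, tiny_manifest, design=tiny_design)
        assert np.allclose(acc.per_rater["auc"], acc2.per_rater["auc"])


def test_rerun_reproduces_tables_bit_identically():
    cfg = GeneratorConfig(seed=123)
    frames = []
    for _ in range(2):
        study = generate_study(cfg)
        design = design_from_study(study)
        frames.append(feature_agreement_table(
            study.reports, design, features=[("T2W", "t2w_shape"), ("DCE", "dce_enhancement")]
        ))
    pd.testing.assert_frame_equal(frames[0], frames[1])
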