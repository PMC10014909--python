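"""Routing, VI imputation, prediction, registry build and concordance."""

import copy
import itertools

import numpy as np
import pytest

from conftest import TINY_BUILD, make_record
from nils import reference
from nils.cohort import Variant, encode_record
from nils.ensemble import ensemble_predict
from nils.exceptions import IneligibleRecordError, NilsError
from nils.synthetic import GeneratorConfig, generate_technical_validation_set
from nils.workflow import (
    ModelRegistry,
    build_registry,
    concordance_check,
    impute_vi,
    predict_n0,
    route,
)


class TestRouting:
    def test_truth_table_over_all_missingness_patterns(self):
        # routing depends only on (VI missing?, any of ER/PR/Ki67 missing?)
        for vi_m, er_m, pr_m, ki_m in itertools.product([False, True], repeat=4):
            rec = make_record(
                vi=None if vi_m else True,
                er=None if er_m else True,
                pr=None if pr_m else False,
                ki67_percent=None if ki_m else 15.0,
            )
            decision = route(rec)
            any_receptor_missing = er_m or pr_m or ki_m
            if not vi_m and not any_receptor_missing:
                expected = (None, Variant.N0_FULL, "full")
            elif not vi_m:
                expected = (None, Variant.N0_REDUCED, "reduced")
            elif not any_receptor_missing:
                expected = (Variant.VI_FULL, Variant.N0_FULL, "full_vi_imputed")
            else:
                expected = (Variant.VI_REDUCED, Variant.N0_REDUCED, "reduced_vi_imputed")
            assert (decision.vi_imputer, decision.n0_model, decision.pathway) == expected

    def test_missing_multifocality_is_ineligible(self):
        with pytest.raises(IneligibleRecordError, match="multifocality"):
            route(make_record(multifocality=None))


class TestPredict:
    def test_impute_vi_equals_direct_ensemble_call(self, tiny_build):
        registry, _ = tiny_build
        rec = make_record(vi=None)
        p = impute_vi(registry, rec)
        enc = encode_record(rec, registry.normalization, Variant.VI_FULL)
        assert p == pytest.approx(
            ensemble_predict(registry.models[Variant.VI_FULL], enc), abs=1e-12
        )

    def test_impute_vi_requires_missing_vi(self, tiny_build):
        registry, _ = tiny_build
        with pytest.raises(NilsError):
            impute_vi(registry, make_record(vi=True))

    def test_missing_ki67_routes_to_reduced_imputer(self, tiny_build):
        registry, _ = tiny_build
        result = predict_n0(registry, make_record(vi=None, ki67_percent=None))
        assert result.imputer_key == "vi_reduced"
        assert result.pathway == "reduced_vi_imputed"
        assert registry.models[Variant.VI_REDUCED].members[0].input_dim == 12

    def test_complete_record_uses_full_model_and_cutpoint(self, tiny_build):
        registry, _ = tiny_build
        rec = make_record()
        result = predict_n0(registry, rec)
        enc = encode_record(rec, registry.normalization, Variant.N0_FULL)
        assert result.p_n0 == pytest.approx(
            ensemble_predict(registry.models[Variant.N0_FULL], enc), abs=1e-12
        )
        assert result.cutpoint_used == registry.cutpoints["full"]
        assert result.pathway == "full"
        assert result.imputed_vi is None

    def test_classification_follows_cutpoint_rule(self, tiny_build, small_cohort):
        registry, _ = tiny_build
        for rec in small_cohort[:40]:
            res = predict_n0(registry, rec)
            assert (res.classification == "predict_N0") == (res.p_n0 >= res.cutpoint_used)

    def test_soft_imputed_vi_is_a_probability(self, tiny_build):
        registry, _ = tiny_build
        res = predict_n0(registry, make_record(vi=None))
        assert 0.0 < res.imputed_vi < 1.0
        assert res.pathway == "full_vi_imputed"

    def test_hard_threshold_binarizes_the_vi_slot(self, tiny_build):
        registry, _ = tiny_build
        hard = copy.copy(registry)
        hard.vi_hard_threshold = 0.5
        rec = make_record(vi=None)
        p_soft = predict_n0(registry, rec).p_n0
        res_hard = predict_n0(hard, rec)
        enc = encode_record(
            rec,
            registry.normalization,
            Variant.N0_FULL,
            vi_value=1.0 if res_hard.imputed_vi >= 0.5 else 0.0,
        )
        expected = ensemble_predict(registry.models[Variant.N0_FULL], enc)
        assert res_hard.p_n0 == pytest.approx(expected, abs=1e-12)
        assert res_hard.p_n0 != p_soft


class TestBuildRegistry:
    def test_structure_four_models_two_cutpoints(self, tiny_build):
        registry, report = tiny_build
        assert set(registry.models) == set(Variant)
        assert set(registry.cutpoints) == {"full", "reduced"}
        assert all(0.0 < c < 1.0 for c in registry.cutpoints.values())
        assert set(registry.backgrounds) == {"full", "reduced"}
        assert set(report["models"]) == {v.value for v in Variant}

    def test_member_counts_are_three_times_repeats(self, tiny_build):
        registry, _ = tiny_build
        for model in registry.models.values():
            assert len(model.members) == 3 * TINY_BUILD.ensemble_repeats

    def test_fnr_constraint_holds_on_selection_lists(self, tiny_build):
        _, report = tiny_build
        for key in ("n0_full", "n0_reduced"):
            assert report["models"][key]["metrics_at_cutpoint"]["fnr"] <= 0.10

    def test_backgrounds_integrate_to_one(self, tiny_build):
        registry, _ = tiny_build
        for bg in registry.backgrounds.values():
            assert bg.integral() == pytest.approx(1.0, abs=0.01)

    def test_same_seed_builds_byte_identical_registries(self, small_cohort):
        import dataclasses

        fast = dataclasses.replace(
            TINY_BUILD, cv_repeats=1, ensemble_repeats=1, max_iterations=100
        )
        a, _ = build_registry(small_cohort[:100], fast)
        b, _ = build_registry(small_cohort[:100], fast)
        assert a.to_json() == b.to_json()

    def test_unlabeled_record_rejected(self, small_cohort):
        import dataclasses

        records = [dataclasses.replace(small_cohort[0], nodal_status=None)]
        with pytest.raises(NilsError):
            build_registry(records + small_cohort[1:20], TINY_BUILD)


class TestSerialization:
    def test_round_trip_reproduces_predictions(self, tiny_build, small_cohort, tmp_path):
        registry, _ = tiny_build
        path = tmp_path / "registry.json"
        registry.save(path)
        back = ModelRegistry.load(path)
        for rec in small_cohort[:25]:
            assert predict_n0(back, rec).p_n0 == pytest.approx(
                predict_n0(registry, rec).p_n0, abs=1e-12
            )

    def test_version_mismatch_refused(self, tiny_build):
        registry, _ = tiny_build
        d = registry.to_json_dict()
        d["format_version"] = "0.0"
        with pytest.raises(NilsError, match="format"):
            ModelRegistry.from_json_dict(d)


@pytest.fixture(scope="module")
def tv_records():
    cfg = GeneratorConfig(n=160, seed=3)
    return generate_technical_validation_set(cfg, seed=8).records


class TestConcordance:
    def test_all_eligible_records_match(self, tiny_build, tv_records):
        registry, _ = tiny_build
        rep = concordance_check(registry, tv_records)
        assert rep.n_evaluated == 100
        assert rep.n_matched == 100
        assert rep.n_mismatched == 0
        assert rep.n_ineligible == 0

    def test_ineligible_records_counted_not_matched(self, tiny_build):
        registry, _ = tiny_build
        cfg = GeneratorConfig(n=160, seed=3)
        tv = generate_technical_validation_set(cfg, seed=8, inject_ineligible=True)
        rep = concordance_check(registry, tv.records)
        assert (rep.n_evaluated, rep.n_ineligible) == (98, 2)
        assert rep.n_matched == 98

    def test_weight_perturbation_detected(self, tiny_build, tv_records):
        # a drifted deployed copy: one stored weight off by 1e-3 must surface
        # as at least one mismatch with its delta reported
        registry, _ = tiny_build
        drifted = registry.to_json_dict()
        drifted = copy.deepcopy(drifted)
        drifted["models"]["n0_full"]["members"][0]["w2"][0] += 1e-3
        rep = concordance_check(registry, tv_records[:30], reference_dict=drifted)
        assert rep.n_mismatched >= 1
        assert max(d["delta_p"] for d in rep.deltas) > 1e-8

    def test_reference_path_agrees_to_machine_precision(self, tiny_build, tv_records):
        registry, _ = tiny_build
        d = registry.to_json_dict()
        for rec in tv_records[:20]:
            p_ref, cut_ref, path_ref = reference.reference_predict(d, rec)
            res = predict_n0(registry, rec)
            assert abs(res.p_n0 - p_ref) < 1e-12
            assert res.cutpoint_used == cut_ref
            assert res.pathway == path_ref
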