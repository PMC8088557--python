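"""Deviation classification, accept/resubmit decisions and review sequencing."""

import numpy as np
import pytest

from rtqa_bench import (
    ConstraintRule,
    DoseMetricSpec,
    Mask3D,
    PerturbationSpec,
    RoundInput,
    SequencingError,
    decide_round,
    default_rules,
    evaluate_delineation,
    evaluate_dose_constraints,
    make_dose,
    perturb_structure,
    run_benchmark,
)
from rtqa_bench.errors import ConfigError
from rtqa_bench.phantoms import DosePrescription, PhantomSpec, StructureRecipe, make_phantom
from rtqa_bench.qa_rules import DelineationRule, DeviationRecord


def rule(structure="brainstem_prv", metric="Dmax", comp="<", pp=35.0, av=None, role="oar"):
    return ConstraintRule(structure, DoseMetricSpec.parse(metric), comp, pp, av, role)


def record(severity="unacceptable", category="oar_delineation", **kw):
    defaults = dict(
        institution_id="I1", round_number=1, structure_name="s",
        criterion_id="c", category=category, severity=severity,
    )
    defaults.update(kw)
    return DeviationRecord(**defaults)


class TestConstraintClassification:
    def test_brainstem_over_hard_limit_is_unacceptable(self):
        assert rule().classify(36.0) == "unacceptable"

    def test_strict_inequality_at_limit_violates(self):
        assert rule().classify(35.0) == "unacceptable"
        assert rule().classify(34.999) == "per_protocol"

    def test_banded_parotid_value_in_band_is_acceptable_variation(self):
        r = rule("contralateral_parotid", "Dmean", "<", 5.0, 10.0)
        assert r.classify(7.0) == "acceptable_variation"
        assert r.classify(4.9) == "per_protocol"
        assert r.classify(10.0) == "unacceptable"

    def test_coverage_rule_greater_than(self):
        r = rule("therapeutic_ptv", "D95%", ">", 62.7, role="target")
        assert r.classify(63.9) == "per_protocol"
        assert r.classify(62.7) == "unacceptable"

    def test_band_on_wrong_side_rejected(self):
        with pytest.raises(ConfigError):
            rule(pp=35.0, av=30.0)

    def test_full_protocol_rule_set_boundary_cases(self):
        """Every shipped dose rule classifies its three regimes correctly."""
        _, rules = default_rules()
        assert len(rules) == 15
        eps = 0.01
        for r in rules:
            sign = -1 if r.comparator == "<" else 1
            assert r.classify(r.per_protocol_limit + sign * eps) == "per_protocol"
            if r.acceptable_variation_limit is None:
                assert r.classify(r.per_protocol_limit - sign * eps) == "unacceptable"
            else:
                assert r.classify(r.per_protocol_limit - sign * eps) == "acceptable_variation"
                assert r.classify(r.acceptable_variation_limit - sign * eps) == "unacceptable"

    def test_missing_structure_yields_delineation_record(self):
        records = evaluate_dose_constraints({}, [rule(role="oar")])
        assert len(records) == 1
        assert records[0].criterion_id == "missing_structure"
        assert records[0].category == "oar_delineation"
        assert records[0].severity == "unacceptable"


class TestDecision:
    def test_no_records_accepted(self):
        assert decide_round([]) == "accepted"

    def test_acceptable_variation_only_is_accepted(self):
        assert decide_round([record("acceptable_variation")]) == "accepted"

    def test_single_blocker_forces_resubmission(self):
        records = [record("per_protocol") for _ in range(5)] + [record("unacceptable")]
        assert decide_round(records) == "resubmission_required"

    def test_adding_unacceptable_never_flips_to_accepted(self):
        base = [record("per_protocol"), record("acceptable_variation")]
        assert decide_round(base) == "accepted"
        assert decide_round(base + [record("unacceptable")]) == "resubmission_required"


# ---------------------------------------------------------------------------
# delineation review + workflow on a small phantom
# ---------------------------------------------------------------------------

def small_gold():
    R = StructureRecipe.make
    spec = PhantomSpec(
        shape=(40, 24, 24),
        spacing=(2.0, 2.0, 2.0),
        origin=(0.0, 0.0, 0.0),
        structures={
            "target": R("ellipsoid", role="target", center=(40.0, 22.0, 22.0), radii=(14.0, 10.0, 10.0)),
            "cord": R("tube", center=(36.0, 10.0), radius=4.0, z_range=(4.0, 72.0)),
        },
    )
    return make_phantom(spec)


def small_rules():
    delin = [
        DelineationRule("target", "absent_structure", "target_delineation", "presence"),
        DelineationRule("target", "dsi_below_threshold", "target_delineation", "dsi_min", threshold=0.7),
        DelineationRule("cord", "absent_structure", "oar_delineation", "presence"),
        DelineationRule("cord", "hd_above_threshold", "oar_delineation", "hd_max", threshold=15.0),
        DelineationRule("cord", "volume_out_of_band", "oar_delineation", "volume_ratio", band=(0.5, 2.0)),
    ]
    dose = [rule("target", "D95%", ">", 20.0, role="target")]
    return delin, dose


class TestDelineationReview:
    def test_identical_submission_passes_clean(self):
        gold = small_gold()
        delin, _ = small_rules()
        records, agreements = evaluate_delineation(gold, gold, delin)
        assert records == []
        assert agreements["target"].dsi == 1.0

    def test_missing_structure_is_unacceptable(self):
        gold = small_gold()
        delin, _ = small_rules()
        sub = {"target": gold["target"]}
        records, _ = evaluate_delineation(sub, gold, delin)
        assert [(r.structure_name, r.criterion_id, r.severity) for r in records] == [
            ("cord", "absent_structure", "unacceptable")
        ]

    def test_low_overlap_triggers_dsi_criterion(self):
        gold = small_gold()
        delin, _ = small_rules()
        sub = dict(gold)
        sub["target"] = perturb_structure(gold["target"], PerturbationSpec("dilate", 10.0))
        records, agreements = evaluate_delineation(sub, gold, delin)
        assert [(r.structure_name, r.criterion_id) for r in records] == [
            ("target", "dsi_below_threshold")
        ]
        assert records[0].observed_value == pytest.approx(agreements["target"].dsi)

    def test_volume_ratio_band(self):
        gold = small_gold()
        delin = [DelineationRule("cord", "volume_out_of_band", "oar_delineation",
                                 "volume_ratio", band=(0.9, 1.1))]
        sub = {"cord": perturb_structure(gold["cord"], PerturbationSpec("dilate", 4.0))}
        records, _ = evaluate_delineation(sub, {"cord": gold["cord"]}, delin)
        assert records and records[0].criterion_id == "volume_out_of_band"

    def test_reevaluation_is_idempotent(self):
        gold = small_gold()
        delin, _ = small_rules()
        sub = dict(gold)
        sub["target"] = perturb_structure(gold["target"], PerturbationSpec("dilate", 10.0))
        first, _ = evaluate_delineation(sub, gold, delin)
        second, _ = evaluate_delineation(sub, gold, delin)
        assert first == second


class TestBenchmarkWorkflow:
    def setup_method(self):
        self.gold = small_gold()
        self.delin, self.dose_rules = small_rules()
        self.rx = DosePrescription(
            therapeutic_gy=66.0, elective_gy=54.45, falloff_mm=8.0, margin_mm=4.0,
            therapeutic_name="target", prophylactic_name="target",
        )
        self.dose = make_dose(self.gold, self.rx)

    def test_clean_first_round_accepted_in_one_round(self):
        subs = {"A": [RoundInput(structures=dict(self.gold), dose=self.dose)]}
        hist = run_benchmark(subs, self.gold, self.delin, self.dose_rules)["A"]
        assert hist.accepted and hist.n_rounds == 1
        assert hist.rounds[0].dose_metrics["target"]["D95%"] > 20.0

    def test_rejected_then_fixed_accepted_at_round_two(self):
        bad = dict(self.gold)
        bad["target"] = perturb_structure(self.gold["target"], PerturbationSpec("dilate", 10.0))
        subs = {"A": [
            RoundInput(structures=bad),
            RoundInput(structures=dict(self.gold), dose=self.dose),
        ]}
        hist = run_benchmark(subs, self.gold, self.delin, self.dose_rules)["A"]
        assert [r.decision for r in hist.rounds] == ["resubmission_required", "accepted"]

    def test_dose_before_volume_approval_is_a_sequencing_error(self):
        bad = dict(self.gold)
        bad["target"] = perturb_structure(self.gold["target"], PerturbationSpec("dilate", 10.0))
        subs = {"A": [RoundInput(structures=bad, dose=self.dose)]}
        with pytest.raises(SequencingError):
            run_benchmark(subs, self.gold, self.delin, self.dose_rules)

    def test_no_planning_records_before_first_volume_approval(self):
        bad = dict(self.gold)
        bad["cord"] = perturb_structure(self.gold["cord"], PerturbationSpec("crop_longitudinal", 30.0))
        subs = {"A": [
            RoundInput(structures=bad),
            RoundInput(structures=dict(self.gold), dose=self.dose),
        ]}
        hist = run_benchmark(subs, self.gold, self.delin, self.dose_rules)["A"]
        approval_round = next(
            rnd.round_number for rnd in hist.rounds
            if not any(r.severity == "unacceptable" and r.category.endswith("delineation")
                       for r in rnd.records)
        )
        for rnd in hist.rounds:
            for r in rnd.records:
                if r.category == "planning":
                    assert rnd.round_number >= approval_round

    def test_category_partition_and_conservation(self):
        bad = dict(self.gold)
        bad["cord"] = perturb_structure(self.gold["cord"], PerturbationSpec("omit_structure"))
        subs = {"A": [
            RoundInput(structures=bad),
            RoundInput(structures=dict(self.gold), dose=self.dose),
        ]}
        hist = run_benchmark(subs, self.gold, self.delin, self.dose_rules)["A"]
        records = hist.all_records()
        cats = [r.category for r in records]
        assert all(c in ("target_delineation", "oar_delineation", "planning") for c in cats)
        assert sum(cats.count(c) for c in set(cats)) == len(records)


class TestRuleLoading:
    def test_default_rules_cover_the_fifteen_structures(self):
        delin, dose = default_rules()
        assert len(dose) == 15
        structures = {r.structure_name for r in dose}
        assert len(structures) == 15
        assert {r.structure_name for r in delin} == structures
        # three delineation criteria (presence, DSI, HD) per structure
        assert len(delin) == 45

    def test_bad_category_rejected(self):
        with pytest.raises(ConfigError):
            DelineationRule("s", "c", "planning", "presence")

    def test_unknown_predicate_rejected(self):
        with pytest.raises(ConfigError):
            DelineationRule("s", "c", "oar_delineation", "fractal_dimension")
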