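import itertools
from datetime import date

import pytest

from eqaplan.inventory import IndicationScope, ParticipationRecord
from eqaplan.scheduler import (
    ASPECT_GENOTYPING_INTERPRETATION,
    ASPECT_TECHNIQUE,
    ChangeEvent,
    InfeasiblePlanError,
    Requirement,
    apply_performance_rules,
    audit,
    derive_requirements,
    participation_counts,
    plan,
    read_plan,
    review_triggers,
    satisfies,
    write_plan,
)

from conftest import make_center, make_scheme, make_technique, random_instance

MINN = 297


def tech_req(subject="sequencing", period="annual", reason="S1", documented=True):
    return Requirement(subject, ASPECT_TECHNIQUE, period, reason, documented)


def gi_req(subject="RD001", period="triennial", reason="S2", due_year=None):
    return Requirement(
        subject, ASPECT_GENOTYPING_INTERPRETATION, period, reason, due_year=due_year
    )


class TestDeriveRequirements:
    def test_exemption_when_all_conditions_met(self):
        center = make_center(techniques=[make_technique(validation_year=2019, volume=400)])
        (req,) = derive_requirements(center, 2024, MINN)
        assert req.period == "triennial" and req.reason == "S1-exemption"

    def test_annual_when_volume_below_threshold(self):
        center = make_center(techniques=[make_technique(validation_year=2019, volume=100)])
        (req,) = derive_requirements(center, 2024, MINN)
        assert req.period == "annual" and req.reason == "S1"

    def test_annual_when_too_recent(self):
        center = make_center(techniques=[make_technique(validation_year=2023, volume=1000)])
        (req,) = derive_requirements(center, 2024, MINN)
        assert req.period == "annual"

    def test_three_years_is_strict(self):
        # validated exactly 3 years before January 1 of the plan year: not "more than"
        center = make_center(techniques=[make_technique(validation_year=2021, volume=400)])
        (req,) = derive_requirements(center, 2024, MINN)
        assert req.period == "annual"

    def test_recent_method_change_blocks_exemption(self):
        tech = make_technique(validation_year=2015, volume=400, last_method_change=date(2022, 6, 1))
        (req,) = derive_requirements(make_center(techniques=[tech]), 2024, MINN)
        assert req.period == "annual"

    def test_indication_requirement_is_triennial(self):
        center = make_center(
            techniques=[make_technique()],
            indications=[IndicationScope("RD001", frozenset({"sequencing"}))],
        )
        reqs = derive_requirements(center, 2024, MINN)
        gi = [r for r in reqs if r.aspect == ASPECT_GENOTYPING_INTERPRETATION]
        assert len(gi) == 1 and gi[0].period == "triennial" and gi[0].reason == "S2"


class TestPerformanceRules:
    inventory = [make_scheme("S001", indication="RD001")]

    def test_critical_error_escalates_next_year(self):
        rec = ParticipationRecord("C1", "S001", 2023, "critical_interpretation_error")
        reqs, _ = apply_performance_rules([], [rec], 2024, self.inventory)
        (req,) = reqs
        assert req.reason == "S4-escalation" and req.due_year == 2024
        assert req.subject == "RD001" and req.period == "once"

    def test_genotyping_error_escalates(self):
        rec = ParticipationRecord("C1", "S001", 2023, "genotyping_error")
        reqs, _ = apply_performance_rules([], [rec], 2024, self.inventory)
        assert len(reqs) == 1

    def test_older_errors_do_not_escalate(self):
        rec = ParticipationRecord("C1", "S001", 2021, "genotyping_error")
        reqs, _ = apply_performance_rules([], [rec], 2024, self.inventory)
        assert reqs == []

    def test_documented_clerical_error_is_silent(self):
        rec = ParticipationRecord("C1", "S001", 2023, "clerical_error", capa_documented=True)
        reqs, findings = apply_performance_rules([], [rec], 2024, self.inventory)
        assert reqs == [] and findings == []

    def test_undocumented_error_flags_capa(self):
        rec = ParticipationRecord("C1", "S001", 2022, "analytical_error", capa_documented=False)
        reqs, findings = apply_performance_rules([], [rec], 2024, self.inventory)
        assert reqs == []
        assert [f.status for f in findings] == ["capa_missing"]

    def test_empty_history_is_identity(self):
        base = [tech_req()]
        reqs, findings = apply_performance_rules(base, [], 2024, self.inventory)
        assert reqs == base and findings == []


class TestSatisfies:
    def test_virtual_scheme_covers_technique(self):
        scheme = make_scheme(
            techniques=("karyotyping",), flags=(True, False, True), modality="virtual"
        )
        assert satisfies(scheme, tech_req("karyotyping"))

    def test_technique_only_scheme_does_not_cover_gi(self):
        scheme = make_scheme(indication="RD001", flags=(True, False, False))
        assert not satisfies(scheme, gi_req("RD001"))

    def test_indication_mismatch(self):
        scheme = make_scheme(indication="RD001")
        assert not satisfies(scheme, gi_req("RD002"))

    def test_interpretation_only_counts_for_gi(self):
        scheme = make_scheme(indication="RD001", flags=(False, False, True), modality="virtual")
        assert satisfies(scheme, gi_req("RD001"))

    def test_indication_comparison_is_normalized(self):
        scheme = make_scheme(indication="  Fragile   X ")
        assert satisfies(scheme, gi_req("fragile x"))


class TestPlan:
    def test_cheaper_equivalent_scheme_always_chosen(self):
        cheap = make_scheme("S001", fee=100_00, flags=(True, False, False))
        dear = make_scheme("S002", fee=200_00, flags=(True, False, False))
        center = make_center(techniques=[make_technique(validation_year=2023, volume=10)])
        p = plan(center, [cheap, dear], horizon=(2024, 2026), minn=MINN)
        assert all(sids == ("S001",) for sids in p.assignments.values())

    def test_rotation_between_truly_equivalent_schemes(self):
        a = make_scheme("S001", fee=100_00, flags=(True, False, False))
        b = make_scheme("S002", fee=100_00, flags=(True, False, False))
        center = make_center(techniques=[make_technique(validation_year=2023, volume=10)])
        p = plan(center, [a, b], horizon=(2024, 2027), minn=MINN)
        chosen = [p.assignments[y][0] for y in sorted(p.assignments)]
        assert set(chosen) == {"S001", "S002"}  # turnover happens
        assert chosen == ["S001", "S002", "S001", "S002"]

    def test_triennial_obligation_window_after_history(self):
        scheme = make_scheme("S001", indication="RD001", fee=500_00)
        tech = make_technique(validation_year=2015, volume=1000)
        center = make_center(
            techniques=[tech],
            indications=[IndicationScope("RD001", frozenset({"sequencing"}))],
        )
        history = [ParticipationRecord("C1", "S001", 2023, "satisfactory")]
        p = plan(center, [scheme], history, horizon=(2024, 2028), minn=MINN)
        years_with_assignments = [y for y, sids in p.assignments.items() if sids]
        # last covered 2023 -> next obligation due by 2026; after 2026 the
        # next deadline (2029) is beyond the horizon
        assert years_with_assignments == [2026]

    def test_escalation_covered_in_due_year(self):
        scheme = make_scheme("S001", indication="RD001", fee=500_00)
        center = make_center(
            techniques=[make_technique(validation_year=2015, volume=1000)],
            indications=[IndicationScope("RD001", frozenset({"sequencing"}))],
        )
        history = [
            ParticipationRecord("C1", "S001", 2023, "satisfactory"),
            ParticipationRecord("C1", "S001", 2023, "critical_interpretation_error"),
        ]
        p = plan(center, [scheme], history, horizon=(2024, 2026), minn=MINN)
        assert "S001" in p.assignments[2024]
        assert "S4-escalation" in p.justifications[(2024, "S001")]

    def test_infeasible_requirement_raises(self):
        scheme = make_scheme("S001", techniques=("mlpa",), flags=(True, False, False))
        center = make_center(techniques=[make_technique("sequencing", 2023, volume=10)])
        with pytest.raises(InfeasiblePlanError, match="sequencing"):
            plan(center, [scheme], horizon=(2024, 2024), minn=MINN)

    def test_offered_years_respected(self):
        only_2025 = make_scheme("S001", fee=100_00, flags=(True, False, False), offered_years=(2025,))
        always = make_scheme("S002", fee=300_00, flags=(True, False, False))
        center = make_center(techniques=[make_technique(validation_year=2023, volume=10)])
        p = plan(center, [only_2025, always], horizon=(2024, 2026), minn=MINN)
        assert p.assignments[2024] == ("S002",)
        assert p.assignments[2025] == ("S001",)

    def test_determinism_and_round_trip(self, tmp_path):
        _cfg, inventory, center, history = random_instance(11)
        p1 = plan(center, inventory, history, horizon=(2024, 2026), minn=MINN)
        p2 = plan(center, inventory, history, horizon=(2024, 2026), minn=MINN)
        assert p1 == p2
        f1, f2 = tmp_path / "a.csv", tmp_path / "b.csv"
        write_plan(p1, f1)
        write_plan(p2, f2)
        assert f1.read_bytes() == f2.read_bytes()
        reread = read_plan(f1)
        assert reread.assignments == p1.assignments
        assert reread.justifications == p1.justifications


class TestAudit:
    def test_plan_passes_audit(self):
        _cfg, inventory, center, history = random_instance(3)
        p = plan(center, inventory, history, horizon=(2024, 2026), minn=MINN)
        findings = audit(p, center, inventory, (2024, 2026), minn=MINN, history=history)
        assert not [f for f in findings if f.status in ("overdue", "due_this_year")]

    def test_empty_history_everything_overdue(self):
        scheme = make_scheme("S001", indication="RD001")
        center = make_center(
            techniques=[make_technique(validation_year=2015, volume=10)],
            indications=[IndicationScope("RD001", frozenset({"sequencing"}))],
        )
        findings = audit([], center, [scheme], (2020, 2023), minn=MINN)
        statuses = {f.subject: f.status for f in findings}
        assert statuses == {"sequencing": "overdue", "RD001": "overdue"}

    def test_empty_history_three_year_window(self):
        # in a 3-year window the triennial deadline lands on the final year,
        # which is still actionable: reported as due_this_year, not overdue
        scheme = make_scheme("S001", indication="RD001")
        center = make_center(
            techniques=[make_technique(validation_year=2015, volume=10)],
            indications=[IndicationScope("RD001", frozenset({"sequencing"}))],
        )
        findings = audit([], center, [scheme], (2021, 2023), minn=MINN)
        statuses = {f.subject: f.status for f in findings}
        assert statuses["sequencing"] == "overdue"
        assert statuses["RD001"] == "due_this_year"

    def test_undocumented_exemption_flagged(self):
        tech = make_technique(validation_year=2015, volume=1000, documented=False)
        scheme = make_scheme("S001", flags=(True, False, False))
        center = make_center(techniques=[tech])
        p = plan(center, [scheme], horizon=(2024, 2026), minn=MINN)
        assert p.exemptions == (("sequencing", False),)
        findings = audit(p, center, [scheme], (2024, 2026), minn=MINN)
        flagged = [f for f in findings if f.status == "exempt_documented"]
        assert len(flagged) == 1 and flagged[0].subject == "sequencing"

    def test_capa_missing_from_history(self):
        scheme = make_scheme("S001", indication="RD001")
        center = make_center(
            techniques=[make_technique(validation_year=2015, volume=10)],
            indications=[IndicationScope("RD001", frozenset({"sequencing"}))],
        )
        history = [
            ParticipationRecord("C1", "S001", y, "satisfactory") for y in (2021, 2022, 2023)
        ] + [ParticipationRecord("C1", "S001", 2022, "clerical_error", capa_documented=False)]
        findings = audit(history, center, [scheme], (2021, 2023), minn=MINN, history=history)
        assert [f for f in findings if f.status == "capa_missing"]

    def test_audit_of_raw_history(self):
        scheme = make_scheme("S001", indication="RD001")
        center = make_center(
            techniques=[make_technique(validation_year=2015, volume=10)],
            indications=[IndicationScope("RD001", frozenset({"sequencing"}))],
        )
        history = [
            ParticipationRecord("C1", "S001", y, "satisfactory") for y in (2021, 2022, 2023)
        ]
        findings = audit(history, center, [scheme], (2021, 2023), minn=MINN, history=history)
        assert all(f.status == "met" for f in findings)

    def test_participation_counts(self):
        records = [
            ParticipationRecord("C1", "S001", 2021, "satisfactory"),
            ParticipationRecord("C1", "S002", 2021, "satisfactory"),
            ParticipationRecord("C2", "S001", 2022, "satisfactory"),
        ]
        assert participation_counts(records) == {("C1", 2021): 2, ("C2", 2022): 1}


class TestReviewTriggers:
    def _plan_with_exemption(self):
        tech = make_technique(validation_year=2015, volume=400)
        scheme = make_scheme("S001", flags=(True, False, False))
        center = make_center(techniques=[tech])
        return plan(center, [scheme], horizon=(2024, 2026), minn=MINN)

    def test_method_change_revokes_exemption(self):
        p = self._plan_with_exemption()
        flags = review_triggers([ChangeEvent("method_change", technique_id="sequencing")], p)
        assert [f.action for f in flags] == ["exemption_revoked"]

    def test_volume_drop_below_threshold_revokes(self):
        p = self._plan_with_exemption()
        event = ChangeEvent("volume_change", technique_id="sequencing", old_volume=400, new_volume=100)
        flags = review_triggers([event], p, minn=MINN)
        assert [f.action for f in flags] == ["exemption_revoked"]
        # cross-check against a re-derivation with the new volume
        center = make_center(techniques=[make_technique(validation_year=2015, volume=100)])
        (req,) = derive_requirements(center, 2024, MINN)
        assert req.period == "annual"

    def test_small_volume_change_no_flag(self):
        p = self._plan_with_exemption()
        event = ChangeEvent("volume_change", technique_id="sequencing", old_volume=400, new_volume=390)
        assert review_triggers([event], p, minn=MINN) == []

    def test_new_scheme_flags_reoptimization(self):
        p = self._plan_with_exemption()
        flags = review_triggers([ChangeEvent("scheme_added", scheme_id="S099")], p)
        assert [f.action for f in flags] == ["reoptimize"]

    def test_no_events_no_flags(self):
        assert review_triggers([], self._plan_with_exemption()) == []
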