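"""Participation requirement derivation, multi-year planning and auditing.

The decisional rules implemented here:

* every technique/platform in use must be assessed every year, possibly by
  a virtual scheme (tag ``S1``);
* a technique qualifies for a *triennial* frequency instead (tag
  ``S1-exemption``) when it has been validated for more than 3 years as of
  January 1 of the plan year (strict), its annual volume reaches the
  error-model threshold (297 tests/year at the default settings) and no
  method change occurred within the last 3 years; the rationale must be
  documented in the quality management system;
* genotyping + interpretation for every clinical indication in scope must
  be assessed at least once in every rolling window of 3 consecutive
  calendar years (tag ``S2``); interpretation-only virtual schemes count;
* a genotyping or critical-interpretation error in year Y forces a
  participation covering that indication in year Y+1 (tag
  ``S4-escalation``); clerical/analytical errors require documented CAPA
  but do not change the frequency;
* the planner selects, per year, a fee-minimal set of offered schemes
  covering everything due that year — exhaustively when at most 12
  candidate schemes are relevant, by greedy weighted set cover otherwise —
  with deterministic rotation across equivalent schemes.

``audit`` re-derives the requirements and verifies coverage from scratch;
it shares no selection logic with ``plan`` and is the independent check
that any emitted plan is compliant.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date

from .inventory import (
    CRITICAL_OUTCOMES,
    CenterProfile,
    EQAScheme,
    InventoryError,
    ParticipationRecord,
    classify_scope,
    normalize_indication,
)

__all__ = [
    "Requirement",
    "Plan",
    "ComplianceFinding",
    "ChangeEvent",
    "ReplanFlag",
    "InfeasiblePlanError",
    "derive_requirements",
    "apply_performance_rules",
    "satisfies",
    "plan",
    "audit",
    "review_triggers",
    "participation_counts",
    "write_plan",
    "read_plan",
    "ASPECT_TECHNIQUE",
    "ASPECT_GENOTYPING_INTERPRETATION",
]

ASPECT_TECHNIQUE = "technique_coverage"
ASPECT_GENOTYPING_INTERPRETATION = "genotyping_interpretation"

PERIOD_ANNUAL = "annual"
PERIOD_TRIENNIAL = "triennial"
PERIOD_ONCE = "once"  # one-shot next-year obligation after a critical error

#: rolling-window length in years for triennial obligations
TRIENNIAL_WINDOW = 3

FINDING_STATUSES = ("met", "due_this_year", "overdue", "exempt_documented", "capa_missing")

PLAN_COLUMNS = ("center_id", "year", "scheme_id", "justifications")


class InfeasiblePlanError(ValueError):
    """No offered scheme can discharge a requirement."""


@dataclass(frozen=True)
class Requirement:
    subject: str            # technique_id or indication
    aspect: str             # ASPECT_TECHNIQUE | ASPECT_GENOTYPING_INTERPRETATION
    period: str             # annual | triennial | once
    reason: str             # S1 | S1-exemption | S2 | S4-escalation
    exemption_documented: bool = True
    due_year: int | None = None  # set for one-shot (S4) requirements


@dataclass(frozen=True)
class ComplianceFinding:
    subject: str
    window: tuple[int, int]
    status: str
    detail: str = ""


@dataclass
class Plan:
    center_id: str
    horizon: tuple[int, int]
    assignments: dict[int, tuple[str, ...]]
    justifications: dict[tuple[int, str], tuple[str, ...]]
    exemptions: tuple[tuple[str, bool], ...] = ()

    def total_fee_cents(self, inventory: list[EQAScheme]) -> int:
        idx = {s.scheme_id: s for s in inventory}
        return sum(
            idx[sid].annual_fee_cents for sids in self.assignments.values() for sid in sids
        )


@dataclass(frozen=True)
class ChangeEvent:
    kind: str                      # method_change | volume_change | scheme_added
    technique_id: str | None = None
    old_volume: int | None = None
    new_volume: int | None = None
    scheme_id: str | None = None


@dataclass(frozen=True)
class ReplanFlag:
    subject: str
    action: str                    # exemption_revoked | recheck_exemption | reoptimize
    detail: str = ""


# ---------------------------------------------------------------------------
# requirement derivation
# ---------------------------------------------------------------------------

def derive_requirements(center: CenterProfile, plan_year: int, minn: int) -> list[Requirement]:
    """Baseline obligations of a center for ``plan_year``.

    One technique-coverage requirement per technique (annual, or triennial
    under the volume/age/stability exemption evaluated at January 1 of the
    plan year) and one triennial genotyping/interpretation requirement per
    indication in scope.
    """
    if minn <= 0:
        raise ValueError("minn must be positive")
    cutoff = date(plan_year - TRIENNIAL_WINDOW, 1, 1)
    reqs: list[Requirement] = []
    for t in center.techniques:
        exempt = (
            t.validation_date < cutoff
            and t.annual_volume >= minn
            and (t.last_method_change is None or t.last_method_change < cutoff)
        )
        if exempt:
            reqs.append(
                Requirement(
                    subject=t.technique_id,
                    aspect=ASPECT_TECHNIQUE,
                    period=PERIOD_TRIENNIAL,
                    reason="S1-exemption",
                    exemption_documented=t.exemption_documented,
                )
            )
        else:
            reqs.append(
                Requirement(
                    subject=t.technique_id,
                    aspect=ASPECT_TECHNIQUE,
                    period=PERIOD_ANNUAL,
                    reason="S1",
                )
            )
    for ind in center.indications:
        reqs.append(
            Requirement(
                subject=ind.indication,
                aspect=ASPECT_GENOTYPING_INTERPRETATION,
                period=PERIOD_TRIENNIAL,
                reason="S2",
            )
        )
    return reqs


def apply_performance_rules(
    reqs: list[Requirement],
    history: list[ParticipationRecord],
    plan_year: int,
    inventory: list[EQAScheme],
) -> tuple[list[Requirement], list[ComplianceFinding]]:
    """Escalations and CAPA flags from past performance.

    A genotyping or critical-interpretation error in ``plan_year − 1``
    adds a one-shot obligation on that scheme's indication due in
    ``plan_year``.  Any unsatisfactory outcome without documented CAPA is
    flagged (``capa_missing``) but does not change the frequency.
    """
    idx = {s.scheme_id: s for s in inventory}
    out = list(reqs)
    findings: list[ComplianceFinding] = []
    escalated: set[str] = set()
    for rec in history:
        if rec.year >= plan_year:
            continue
        if rec.year == plan_year - 1 and rec.outcome in CRITICAL_OUTCOMES:
            scheme = idx.get(rec.scheme_id)
            if scheme is None:
                raise InventoryError(f"history references unknown scheme {rec.scheme_id!r}")
            key = normalize_indication(scheme.indication)
            if key not in escalated:
                escalated.add(key)
                out.append(
                    Requirement(
                        subject=scheme.indication,
                        aspect=ASPECT_GENOTYPING_INTERPRETATION,
                        period=PERIOD_ONCE,
                        reason="S4-escalation",
                        due_year=plan_year,
                    )
                )
        if rec.outcome != "satisfactory" and not rec.capa_documented:
            findings.append(
                ComplianceFinding(
                    subject=rec.scheme_id,
                    window=(rec.year, rec.year),
                    status="capa_missing",
                    detail=f"{rec.outcome} in {rec.year} without documented CAPA",
                )
            )
    return out, findings


def satisfies(scheme: EQAScheme, req: Requirement) -> bool:
    """Whether participation in ``scheme`` discharges ``req``.

    Technique coverage accepts any scheme assessing the technique, wet or
    virtual.  Genotyping/interpretation coverage requires a matching
    indication and at least one of the genotyping/interpretation aspects
    (an interpretation-only virtual scheme counts; a technique-only scheme
    does not).
    """
    if req.aspect == ASPECT_TECHNIQUE:
        return req.subject in scheme.techniques
    if req.aspect == ASPECT_GENOTYPING_INTERPRETATION:
        return normalize_indication(scheme.indication) == normalize_indication(req.subject) and (
            scheme.scope_genotyping or scheme.scope_interpretation
        )
    raise ValueError(f"unknown aspect {req.aspect!r}")


# ---------------------------------------------------------------------------
# planning
# ---------------------------------------------------------------------------

def _scope_rank(scheme: EQAScheme) -> int:
    cat = classify_scope(scheme)
    return {"TGI": 0, "TG": 1}.get(cat, 2)


def _rotated_order(
    candidates: list[EQAScheme], due: list[Requirement], year_index: int
) -> list[EQAScheme]:
    """Deterministic preference order with round-robin turnover.

    Base order is (fee, scope breadth, scheme_id); schemes equivalent on
    fee, scope category and due-requirement coverage form a rotation group
    shifted by the year index, so equally good schemes alternate across
    years instead of the lexicographically first always winning.
    """
    base = sorted(
        candidates, key=lambda s: (s.annual_fee_cents, _scope_rank(s), s.scheme_id)
    )

    def signature(s: EQAScheme):
        return (
            s.annual_fee_cents,
            classify_scope(s),
            tuple(satisfies(s, r) for r in due),
        )

    out: list[EQAScheme] = []
    i = 0
    while i < len(base):
        j = i
        sig = signature(base[i])
        while j < len(base) and signature(base[j]) == sig:
            j += 1
        group = base[i:j]
        shift = year_index % len(group)
        out.extend(group[shift:] + group[:shift])
        i = j
    return out


def _cover_masks(ordered: list[EQAScheme], due: list[Requirement]) -> list[int]:
    masks = []
    for s in ordered:
        m = 0
        for b, r in enumerate(due):
            if satisfies(s, r):
                m |= 1 << b
        masks.append(m)
    return masks


def _exhaustive_cover(ordered: list[EQAScheme], due: list[Requirement]) -> list[EQAScheme]:
    """Fee-minimal covering subset, exact over all subsets.

    Dynamic program over covered-requirement bitmasks; equivalent to full
    subset enumeration (every subset corresponds to a DP path) but only
    distinct coverage states are kept.  Ties broken by the preference
    order of ``ordered`` (tuple of member indices).
    """
    if not due:
        return []
    if len(ordered) > 24:
        raise InfeasiblePlanError(
            f"exhaustive optimizer refuses {len(ordered)} candidates (> 24); use greedy"
        )
    masks = _cover_masks(ordered, due)
    full = (1 << len(due)) - 1
    fees = [s.annual_fee_cents for s in ordered]
    # dp: covered mask -> (fee, member index tuple), minimal by that key
    dp: dict[int, tuple[int, tuple[int, ...]]] = {0: (0, ())}
    for i in range(len(ordered)):
        updates: dict[int, tuple[int, tuple[int, ...]]] = {}
        for covered, (fee, members) in dp.items():
            new_cov = covered | masks[i]
            if new_cov == covered:
                continue
            cand = (fee + fees[i], members + (i,))
            prev = dp.get(new_cov)
            best = updates.get(new_cov, prev)
            if best is None or cand < best:
                updates[new_cov] = cand
        dp.update(updates)
    if full not in dp:
        raise InfeasiblePlanError("no covering subset exists")
    return [ordered[i] for i in dp[full][1]]


def _greedy_cover(ordered: list[EQAScheme], due: list[Requirement]) -> list[EQAScheme]:
    """Greedy weighted set cover (fee per newly covered requirement)."""
    if not due:
        return []
    masks = _cover_masks(ordered, due)
    full = (1 << len(due)) - 1
    covered = 0
    chosen: list[int] = []
    while covered != full:
        best_i = None
        best_ratio = None
        for i, s in enumerate(ordered):
            if i in chosen:
                continue
            new = bin(masks[i] & ~covered).count("1")
            if new == 0:
                continue
            ratio = s.annual_fee_cents / new
            if best_ratio is None or ratio < best_ratio:
                best_ratio, best_i = ratio, i
        if best_i is None:
            raise InfeasiblePlanError("no covering subset exists")
        chosen.append(best_i)
        covered |= masks[best_i]
    # prune redundant picks, most expensive first
    for i in sorted(chosen, key=lambda i: -ordered[i].annual_fee_cents):
        rest = [j for j in chosen if j != i]
        acc = 0
        for j in rest:
            acc |= masks[j]
        if acc == full:
            chosen = rest
    return [ordered[i] for i in sorted(chosen)]


def _last_coverage(
    req: Requirement, events: list[tuple[int, EQAScheme]], before: int
) -> int | None:
    years = [y for y, s in events if y < before and satisfies(s, req)]
    return max(years) if years else None


def _pareto_subsets(
    ordered: list[EQAScheme], reqs: list[Requirement], base_forced: int
) -> list[tuple[int, int, tuple[int, ...]]]:
    """Non-dominated candidate subsets for one year of the global optimizer.

    Enumerates every subset of ``ordered`` covering ``base_forced`` (the
    state-independent obligations of the year), keeps the cheapest
    representative per coverage mask, then drops any subset dominated by a
    no-more-expensive superset coverage.  Returns (covered, fee, members).
    """
    masks = _cover_masks(ordered, reqs)
    fees = [s.annual_fee_cents for s in ordered]
    n = len(ordered)
    best: dict[int, tuple[int, tuple[int, ...]]] = {}
    for subset in range(1 << n):
        fee = 0
        covered = 0
        members = []
        sub = subset
        while sub:
            i = (sub & -sub).bit_length() - 1
            sub &= sub - 1
            fee += fees[i]
            covered |= masks[i]
            members.append(i)
        if covered & base_forced != base_forced:
            continue
        cand = (fee, tuple(members))
        prev = best.get(covered)
        if prev is None or cand < prev:
            best[covered] = cand
    items = sorted(
        ((cov, fee, members) for cov, (fee, members) in best.items()),
        key=lambda t: (t[1], t[2]),
    )
    kept: list[tuple[int, int, tuple[int, ...]]] = []
    for cov, fee, members in items:
        if any(k_fee <= fee and k_cov | cov == k_cov and k_cov != cov for k_cov, k_fee, _m in kept):
            continue
        kept.append((cov, fee, members))
    return kept


def plan(
    center: CenterProfile,
    inventory: list[EQAScheme],
    history: list[ParticipationRecord] = (),
    horizon: tuple[int, int] = (2024, 2026),
    minn: int = 297,
    optimizer: str = "auto",
    seed: int = 0,
) -> Plan:
    """Select a cost-minimal compliant participation schedule.

    Obligations per year: annual technique coverage; triennial
    requirements due when their rolling-window deadline — last coverage
    year + 3, seeded by the history — is reached (a never-covered
    requirement is due by the third horizon year); one-shot escalations in
    their due year.  Schemes chosen for one requirement also credit every
    other requirement they satisfy, deferring its next deadline.

    Two optimizers are available.  ``exhaustive`` (chosen automatically
    when no year has more than 12 relevant candidate schemes) minimizes
    the total fee over the whole horizon by dynamic programming over
    triennial coverage states — equivalent to enumerating every
    combination of per-year candidate subsets.  ``greedy`` covers each
    year's due set by weighted set cover and is used for larger instances;
    its total fee is never below the exhaustive optimum.  Both are fully
    deterministic; turnover between equivalent schemes rotates with the
    year index.
    """
    if optimizer not in ("auto", "exhaustive", "greedy"):
        raise ValueError("optimizer must be auto, exhaustive or greedy")
    y0, y1 = horizon
    if y1 < y0:
        raise ValueError("empty horizon")
    idx: dict[str, EQAScheme] = {}
    for s in inventory:
        if s.scheme_id in idx:
            raise InventoryError(f"duplicate scheme_id {s.scheme_id!r}")
        idx[s.scheme_id] = s

    years = list(range(y0, y1 + 1))
    reqs_by_year: dict[int, list[Requirement]] = {}
    cands_by_year: dict[int, list[EQAScheme]] = {}
    exemptions: dict[str, bool] = {}
    for year in years:
        reqs = derive_requirements(center, year, minn)
        reqs, _ = apply_performance_rules(
            reqs, [r for r in history if r.year < year], year, inventory
        )
        reqs_by_year[year] = reqs
        for r in reqs:
            if r.reason == "S1-exemption":
                exemptions[r.subject] = r.exemption_documented
        cands_by_year[year] = sorted(
            (
                s
                for s in inventory
                if s.offered_in(year) and any(satisfies(s, r) for r in reqs)
            ),
            key=lambda s: s.scheme_id,
        )
        for r in reqs:
            immediate = r.period == PERIOD_ANNUAL or (
                r.period == PERIOD_ONCE and r.due_year == year
            )
            if immediate:
                if not any(satisfies(s, r) for s in cands_by_year[year]):
                    raise InfeasiblePlanError(
                        f"requirement on {r.subject!r} ({r.aspect}, {r.reason}) has no "
                        f"offered scheme in year {year}"
                    )
            elif not any(
                satisfies(s, r) and any(s.offered_in(yy) for yy in years) for s in inventory
            ):
                raise InfeasiblePlanError(
                    f"requirement on {r.subject!r} ({r.aspect}, {r.reason}) has no "
                    f"offered scheme within {y0}-{y1}"
                )

    mode = optimizer
    if mode == "auto":
        mode = "exhaustive" if max(len(c) for c in cands_by_year.values()) <= 12 else "greedy"
    if mode == "exhaustive" and max(len(c) for c in cands_by_year.values()) > 16:
        raise InfeasiblePlanError(
            "exhaustive optimizer limited to 16 candidate schemes per year; use greedy"
        )

    hist_events: list[tuple[int, EQAScheme]] = [
        (r.year, idx[r.scheme_id]) for r in history if r.scheme_id in idx
    ]
    if mode == "greedy":
        assignments, justifications = _plan_greedy(
            years, reqs_by_year, cands_by_year, hist_events, y0
        )
    else:
        assignments, justifications = _plan_exhaustive(
            years, reqs_by_year, cands_by_year, hist_events, y0
        )

    return Plan(
        center_id=center.center_id,
        horizon=(y0, y1),
        assignments=assignments,
        justifications=justifications,
        exemptions=tuple(sorted(exemptions.items())),
    )


def _due_triennial(
    req: Requirement, last: int | None, year: int, y0: int
) -> bool:
    deadline = last + TRIENNIAL_WINDOW if last is not None else y0 + TRIENNIAL_WINDOW - 1
    return deadline <= year


def _finalize_year(
    chosen: list[EQAScheme], reqs: list[Requirement], year: int
) -> tuple[tuple[str, ...], dict[tuple[int, str], tuple[str, ...]]]:
    chosen = sorted(chosen, key=lambda s: s.scheme_id)
    justif = {
        (year, s.scheme_id): tuple(sorted({r.reason for r in reqs if satisfies(s, r)}))
        for s in chosen
    }
    return tuple(s.scheme_id for s in chosen), justif


def _plan_greedy(years, reqs_by_year, cands_by_year, hist_events, y0):
    events = list(hist_events)
    assignments: dict[int, tuple[str, ...]] = {}
    justifications: dict[tuple[int, str], tuple[str, ...]] = {}
    for year in years:
        reqs = reqs_by_year[year]
        due: list[Requirement] = []
        for r in reqs:
            if r.period == PERIOD_ANNUAL:
                due.append(r)
            elif r.period == PERIOD_ONCE:
                if r.due_year == year:
                    due.append(r)
            elif _due_triennial(r, _last_coverage(r, events, before=year), year, y0):
                due.append(r)
        candidates = [s for s in cands_by_year[year] if any(satisfies(s, r) for r in due)]
        for r in due:
            if not any(satisfies(s, r) for s in candidates):
                raise InfeasiblePlanError(
                    f"requirement on {r.subject!r} ({r.aspect}, {r.reason}) has no "
                    f"offered scheme in year {year}"
                )
        ordered = _rotated_order(candidates, due, year - y0)
        chosen = _greedy_cover(ordered, due)
        assignments[year], justif = _finalize_year(chosen, reqs, year)
        justifications.update(justif)
        events.extend((year, s) for s in chosen)
    return assignments, justifications


def _plan_exhaustive(years, reqs_by_year, cands_by_year, hist_events, y0):
    """Horizon-global fee minimization.

    State: last coverage year of every requirement that is triennial in at
    least one horizon year (annual coverage refreshes it too, seeding a
    later exemption).  Transitions are the Pareto-optimal candidate
    subsets of each year; states dominated in both fee and freshness are
    pruned, so the result equals full enumeration of all per-year subset
    combinations at a fraction of the work.
    """
    tri_reqs: dict[tuple[str, str], Requirement] = {}
    for year in years:
        for r in reqs_by_year[year]:
            if r.period == PERIOD_TRIENNIAL:
                tri_reqs.setdefault((r.subject, r.aspect), r)
    tri_keys = sorted(tri_reqs)
    init = tuple(
        _last_coverage(tri_reqs[k], hist_events, before=years[0]) for k in tri_keys
    )
    # states: last-coverage tuple -> (fee, tie, per-year chosen scheme lists)
    states: dict[tuple, tuple[int, tuple, tuple]] = {init: (0, (), ())}
    for year in years:
        reqs = reqs_by_year[year]
        ordered = _rotated_order(cands_by_year[year], reqs, year - y0)
        base_forced = 0
        tri_bits: list[tuple[int, tuple[str, str]]] = []
        for b, r in enumerate(reqs):
            if r.period == PERIOD_ANNUAL or (r.period == PERIOD_ONCE and r.due_year == year):
                base_forced |= 1 << b
            elif r.period == PERIOD_TRIENNIAL:
                tri_bits.append((b, (r.subject, r.aspect)))
        options = _pareto_subsets(ordered, reqs, base_forced)
        tri_cover_masks = {
            ki: sum(
                1 << i
                for i, s in enumerate(ordered)
                if satisfies(s, tri_reqs[k])
            )
            for ki, k in enumerate(tri_keys)
        }
        new_states: dict[tuple, tuple[int, tuple, tuple]] = {}
        key_index = {k: ki for ki, k in enumerate(tri_keys)}
        for state in sorted(states, key=lambda st: states[st][:2]):
            fee0, tie0, chosen0 = states[state]
            forced = base_forced
            for b, key in tri_bits:
                if _due_triennial(tri_reqs[key], state[key_index[key]], year, y0):
                    forced |= 1 << b
            for covered, fee, members in options:
                if covered & forced != forced:
                    continue
                member_mask = 0
                for i in members:
                    member_mask |= 1 << i
                new_state = tuple(
                    year if tri_cover_masks[ki] & member_mask else state[ki]
                    for ki in range(len(tri_keys))
                )
                cand = (fee0 + fee, tie0 + (members,), chosen0 + (members,))
                prev = new_states.get(new_state)
                if prev is None or cand[:2] < prev[:2]:
                    new_states[new_state] = cand
        if not new_states:
            raise InfeasiblePlanError(f"no feasible scheme subset in year {year}")
        # dominance pruning: drop states that are costlier and staler
        pruned: dict[tuple, tuple[int, tuple, tuple]] = {}
        items = sorted(new_states.items(), key=lambda kv: (kv[1][0], kv[1][1]))
        for state, value in items:
            dominated = any(
                pv[0] <= value[0]
                and all(
                    (ps is not None and (s is None or ps >= s))
                    or (ps is None and s is None)
                    for ps, s in zip(pstate, state)
                )
                for pstate, pv in pruned.items()
            )
            if not dominated:
                pruned[state] = value
        states = pruned
    best_state = min(states, key=lambda st: states[st][:2])
    _fee, _tie, chosen_members = states[best_state]
    assignments: dict[int, tuple[str, ...]] = {}
    justifications: dict[tuple[int, str], tuple[str, ...]] = {}
    for year, members in zip(years, chosen_members):
        reqs = reqs_by_year[year]
        ordered = _rotated_order(cands_by_year[year], reqs, year - y0)
        chosen = [ordered[i] for i in members]
        assignments[year], justif = _finalize_year(chosen, reqs, year)
        justifications.update(justif)
    return assignments, justifications


# ---------------------------------------------------------------------------
# auditing (independent of the planner's selection logic)
# ---------------------------------------------------------------------------

def audit(
    source: "Plan | list[ParticipationRecord]",
    center: CenterProfile,
    inventory: list[EQAScheme],
    window: tuple[int, int],
    minn: int = 297,
    history: list[ParticipationRecord] = (),
) -> list[ComplianceFinding]:
    """Verify a plan or a participation history against the rules.

    Requirements are re-derived per year and coverage is simulated over the
    window.  A missed deadline strictly before the final window year is
    ``overdue``; a deadline missed exactly in the final year (still
    actionable) is ``due_this_year``; otherwise ``met``.  Undocumented
    triennial exemptions and missing CAPA documentation are also flagged.
    ``history`` seeds triennial coverage before the window and provides the
    performance records for escalations/CAPA checks.
    """
    w0, w1 = window
    if w1 < w0:
        raise ValueError("empty audit window")
    idx = {s.scheme_id: s for s in inventory}
    if isinstance(source, Plan):
        events = [
            (year, idx[sid])
            for year, sids in source.assignments.items()
            for sid in sids
            if sid in idx
        ]
    else:
        events = [(r.year, idx[r.scheme_id]) for r in source if r.scheme_id in idx]
    pre_events = [(y, s) for y, s in events if y < w0] + [
        (r.year, idx[r.scheme_id]) for r in history if r.scheme_id in idx and r.year < w0
    ]
    by_year: dict[int, list[EQAScheme]] = {}
    for y, s in events:
        by_year.setdefault(y, []).append(s)

    last_cov: dict[tuple, int | None] = {}
    first_viol: dict[tuple, int] = {}
    seen: dict[tuple, Requirement] = {}
    undocumented: set[str] = set()

    for year in range(w0, w1 + 1):
        reqs = derive_requirements(center, year, minn)
        reqs, _ = apply_performance_rules(
            reqs, [r for r in history if r.year < year], year, inventory
        )
        cov_year = by_year.get(year, [])
        for r in reqs:
            if r.reason == "S1-exemption" and not r.exemption_documented:
                undocumented.add(r.subject)
            key = (
                (r.subject, r.aspect, r.due_year)
                if r.period == PERIOD_ONCE
                else (r.subject, r.aspect, None)
            )
            seen.setdefault(key, r)
            if key not in last_cov:
                years_pre = [y for y, s in pre_events if satisfies(s, r)]
                last_cov[key] = max(years_pre) if years_pre else None
            if any(satisfies(s, r) for s in cov_year):
                last_cov[key] = year
                continue
            if key in first_viol:
                continue
            if r.period == PERIOD_ANNUAL:
                first_viol[key] = year
            elif r.period == PERIOD_ONCE:
                if r.due_year == year:
                    first_viol[key] = year
            else:
                last = last_cov[key]
                if last is None:
                    if year - w0 >= TRIENNIAL_WINDOW - 1:
                        first_viol[key] = year
                elif year - last >= TRIENNIAL_WINDOW:
                    first_viol[key] = year

    findings: list[ComplianceFinding] = []
    for key, req in sorted(seen.items(), key=lambda kv: (kv[0][0], kv[0][1], str(kv[0][2]))):
        if key in first_viol:
            v = first_viol[key]
            status = "due_this_year" if v == w1 else "overdue"
            detail = f"{req.aspect} ({req.reason}) uncovered, deadline year {v}"
        else:
            status = "met"
            detail = f"{req.aspect} ({req.reason})"
        findings.append(ComplianceFinding(subject=req.subject, window=(w0, w1), status=status, detail=detail))
    for tech in sorted(undocumented):
        findings.append(
            ComplianceFinding(
                subject=tech,
                window=(w0, w1),
                status="exempt_documented",
                detail="triennial exemption used without documented rationale",
            )
        )
    capa_seen: set[tuple] = set()
    for rec in history:
        if rec.outcome != "satisfactory" and not rec.capa_documented and w0 <= rec.year <= w1:
            key = (rec.scheme_id, rec.year)
            if key in capa_seen:
                continue
            capa_seen.add(key)
            findings.append(
                ComplianceFinding(
                    subject=rec.scheme_id,
                    window=(rec.year, rec.year),
                    status="capa_missing",
                    detail=f"{rec.outcome} in {rec.year} without documented CAPA",
                )
            )
    return findings


def participation_counts(records: list[ParticipationRecord]) -> dict[tuple[str, int], int]:
    """Per-(center, year) participation counts, for trend summaries."""
    counts: dict[tuple[str, int], int] = {}
    for r in records:
        key = (r.center_id, r.year)
        counts[key] = counts.get(key, 0) + 1
    return counts


# ---------------------------------------------------------------------------
# change management
# ---------------------------------------------------------------------------

def review_triggers(
    center_events: list[ChangeEvent],
    current_plan: Plan,
    minn: int | None = None,
    volume_change_ratio: float = 0.5,
) -> list[ReplanFlag]:
    """Re-planning flags after changes in activities or scheme availability.

    A method/platform change revokes the technique's exemption (the
    validation clock resets).  A volume change beyond ``volume_change_ratio``
    triggers a re-check of exemption eligibility — revocation outright when
    the new volume falls below ``minn``.  A newly offered scheme flags an
    optional re-optimization.
    """
    exempt = {tech for tech, _doc in current_plan.exemptions}
    flags: list[ReplanFlag] = []
    for e in center_events:
        if e.kind == "method_change":
            if e.technique_id in exempt:
                flags.append(
                    ReplanFlag(
                        subject=e.technique_id,
                        action="exemption_revoked",
                        detail="method change resets the validation clock; annual participation resumes",
                    )
                )
            else:
                flags.append(
                    ReplanFlag(
                        subject=e.technique_id or "",
                        action="recheck_exemption",
                        detail="method change; re-derive requirements",
                    )
                )
        elif e.kind == "volume_change":
            if e.old_volume and e.new_volume is not None:
                rel = abs(e.new_volume - e.old_volume) / e.old_volume
                if rel >= volume_change_ratio:
                    if minn is not None and e.new_volume < minn and e.technique_id in exempt:
                        flags.append(
                            ReplanFlag(
                                subject=e.technique_id,
                                action="exemption_revoked",
                                detail=f"volume {e.old_volume}→{e.new_volume} below threshold {minn}",
                            )
                        )
                    else:
                        flags.append(
                            ReplanFlag(
                                subject=e.technique_id or "",
                                action="recheck_exemption",
                                detail=f"volume change {e.old_volume}→{e.new_volume} beyond ±{volume_change_ratio:.0%}",
                            )
                        )
        elif e.kind == "scheme_added":
            flags.append(
                ReplanFlag(
                    subject=e.scheme_id or "",
                    action="reoptimize",
                    detail="new scheme on the market; plan may no longer be cost-minimal",
                )
            )
        else:
            raise ValueError(f"unknown change event kind {e.kind!r}")
    return flags


# ---------------------------------------------------------------------------
# plan I/O
# ---------------------------------------------------------------------------

def write_plan(p: Plan, path) -> None:
    import csv

    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, lineterminator="\n")
        w.writerow(PLAN_COLUMNS)
        for year in sorted(p.assignments):
            for sid in p.assignments[year]:
                tags = ";".join(p.justifications.get((year, sid), ()))
                w.writerow([p.center_id, year, sid, tags])


def read_plan(path) -> Plan:
    import csv

    with open(path, newline="", encoding="utf-8") as fh:
        rows = list(csv.reader(fh))
    if not rows or tuple(rows[0]) != PLAN_COLUMNS:
        raise InventoryError(f"{path}: expected header {','.join(PLAN_COLUMNS)}")
    assignments: dict[int, list[str]] = {}
    justifications: dict[tuple[int, str], tuple[str, ...]] = {}
    center_id = ""
    for i, row in enumerate(rows[1:], start=2):
        if len(row) != len(PLAN_COLUMNS):
            raise InventoryError(f"row {i}: expected {len(PLAN_COLUMNS)} fields")
        center_id, year_s, sid, tags = row
        year = int(year_s)
        assignments.setdefault(year, []).append(sid)
        justifications[(year, sid)] = tuple(t for t in tags.split(";") if t)
    years = sorted(assignments)
    horizon = (years[0], years[-1]) if years else (0, 0)
    return Plan(
        center_id=center_id,
        horizon=horizon,
        assignments={y: tuple(v) for y, v in assignments.items()},
        justifications=justifications,
    )
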