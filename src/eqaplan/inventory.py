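"""Data model and delimited-text I/O for EQA participation planning.

Three kinds of records are handled:

* :class:`EQAScheme` — one external quality assessment scheme with its
  assessed aspects (technique / genotyping / interpretation), modality,
  indication, technique list and annual fee.
* :class:`CenterProfile` — a genetics laboratory: the techniques it runs
  (validation date, method class, annual volume) and the clinical
  indications in its scope.
* :class:`ParticipationRecord` — one (center, scheme, year, outcome) event
  with a CAPA-documentation flag.

File formats are plain text: a comma-separated inventory (``schemes.csv``)
and history (``history.csv``) with a mandatory header, semicolons as the
inner-list separator, and a YAML center profile (``center.yaml``).  Money
is stored as integer euro cents so sums are exact.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field
from datetime import date
from decimal import Decimal, InvalidOperation
from pathlib import Path

import yaml

__all__ = [
    "EQAScheme",
    "TechniqueUse",
    "IndicationScope",
    "CenterProfile",
    "ParticipationRecord",
    "InventoryError",
    "read_inventory",
    "write_inventory",
    "read_center",
    "write_center",
    "read_history",
    "write_history",
    "classify_scope",
    "scope_summary",
    "normalize_indication",
    "format_eur",
    "MODALITIES",
    "METHOD_CLASSES",
    "OUTCOMES",
    "ERROR_OUTCOMES",
]

MODALITIES = ("wet", "virtual")
METHOD_CLASSES = ("in_house", "ce_kit")
OUTCOMES = (
    "satisfactory",
    "clerical_error",
    "analytical_error",
    "genotyping_error",
    "critical_interpretation_error",
)
#: outcomes counting as unsatisfactory performance
ERROR_OUTCOMES = OUTCOMES[1:]
#: outcomes with a diagnostic impact that trigger a next-year obligation
CRITICAL_OUTCOMES = ("genotyping_error", "critical_interpretation_error")

YEAR_MIN, YEAR_MAX = 1990, 2100

INVENTORY_COLUMNS = (
    "scheme_id",
    "provider",
    "indication",
    "techniques",
    "scope_technique",
    "scope_genotyping",
    "scope_interpretation",
    "modality",
    "fee_eur",
    "offered_years",
)
HISTORY_COLUMNS = ("center_id", "scheme_id", "year", "outcome", "capa_documented")


class InventoryError(ValueError):
    """Malformed or inconsistent inventory / center / history data."""


def normalize_indication(text: str) -> str:
    """Canonical key for an indication name: collapse whitespace, casefold."""
    return " ".join(text.split()).casefold()


def format_eur(cents: int) -> str:
    """Render integer euro cents for display, e.g. ``€70,600`` / ``€12.50``."""
    units, cc = divmod(abs(int(cents)), 100)
    sign = "-" if cents < 0 else ""
    body = f"{sign}€{units:,}"
    return body if cc == 0 else f"{body}.{cc:02d}"


@dataclass(frozen=True)
class EQAScheme:
    """One quality-control scheme offered by an accredited provider."""

    scheme_id: str
    provider: str
    indication: str
    techniques: frozenset[str]
    scope_technique: bool
    scope_genotyping: bool
    scope_interpretation: bool
    modality: str = "wet"
    annual_fee_cents: int = 0
    offered_years: frozenset[int] = frozenset()  # empty = always offered

    def __post_init__(self) -> None:
        object.__setattr__(self, "techniques", frozenset(self.techniques))
        object.__setattr__(self, "offered_years", frozenset(self.offered_years))
        if not self.scheme_id:
            raise InventoryError("scheme_id must be non-empty")
        if not (self.scope_technique or self.scope_genotyping or self.scope_interpretation):
            raise InventoryError(
                f"scheme {self.scheme_id!r}: at least one scope flag must be set"
            )
        if self.modality not in MODALITIES:
            raise InventoryError(
                f"scheme {self.scheme_id!r}: modality must be one of {MODALITIES}"
            )
        if self.annual_fee_cents < 0:
            raise InventoryError(f"scheme {self.scheme_id!r}: annual_fee_cents < 0")

    def offered_in(self, year: int) -> bool:
        return not self.offered_years or year in self.offered_years


@dataclass(frozen=True)
class TechniqueUse:
    """A technique or technological platform run by a center.

    ``exemption_documented`` records whether the rationale for a reduced
    (triennial) participation frequency is written down in the center's
    quality management system; it is only meaningful when the technique
    actually qualifies for the exemption.
    """

    technique_id: str
    validation_date: date
    method_class: str
    annual_volume: int
    last_method_change: date | None = None
    exemption_documented: bool = False

    def __post_init__(self) -> None:
        if self.method_class not in METHOD_CLASSES:
            raise InventoryError(
                f"technique {self.technique_id!r}: method_class must be one of {METHOD_CLASSES}"
            )
        if self.annual_volume < 0:
            raise InventoryError(f"technique {self.technique_id!r}: annual_volume < 0")
        if self.last_method_change is not None and self.last_method_change < self.validation_date:
            raise InventoryError(
                f"technique {self.technique_id!r}: last_method_change predates validation_date"
            )


@dataclass(frozen=True)
class IndicationScope:
    """A clinical indication in a center's diagnostic scope."""

    indication: str
    techniques_used: frozenset[str]
    annual_requests: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "techniques_used", frozenset(self.techniques_used))
        if not self.techniques_used:
            raise InventoryError(f"indication {self.indication!r}: techniques_used is empty")
        if self.annual_requests < 0:
            raise InventoryError(f"indication {self.indication!r}: annual_requests < 0")


@dataclass(frozen=True)
class CenterProfile:
    center_id: str
    techniques: tuple[TechniqueUse, ...]
    indications: tuple[IndicationScope, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "techniques", tuple(self.techniques))
        object.__setattr__(self, "indications", tuple(self.indications))
        ids = [t.technique_id for t in self.techniques]
        if len(ids) != len(set(ids)):
            raise InventoryError(f"center {self.center_id!r}: duplicate technique ids")
        known = set(ids)
        for ind in self.indications:
            missing = ind.techniques_used - known
            if missing:
                raise InventoryError(
                    f"center {self.center_id!r}: indication {ind.indication!r} uses "
                    f"unknown techniques {sorted(missing)}"
                )

    @property
    def technique_ids(self) -> frozenset[str]:
        return frozenset(t.technique_id for t in self.techniques)


@dataclass(frozen=True)
class ParticipationRecord:
    center_id: str
    scheme_id: str
    year: int
    outcome: str
    capa_documented: bool = True

    def __post_init__(self) -> None:
        if not (YEAR_MIN <= self.year <= YEAR_MAX):
            raise InventoryError(
                f"record {self.center_id}/{self.scheme_id}: year {self.year} outside "
                f"[{YEAR_MIN}, {YEAR_MAX}]"
            )
        if self.outcome not in OUTCOMES:
            raise InventoryError(
                f"record {self.center_id}/{self.scheme_id}: unknown outcome {self.outcome!r}"
            )


# ---------------------------------------------------------------------------
# scope classification
# ---------------------------------------------------------------------------

def classify_scope(scheme: EQAScheme) -> str:
    """Scope category token built from the three aspect flags.

    (1,1,1) → ``TGI``, (1,1,0) → ``TG``, (0,0,1) → ``I`` and so on; total
    and injective on every flag triple with at least one flag set.
    """
    letters = ""
    if scheme.scope_technique:
        letters += "T"
    if scheme.scope_genotyping:
        letters += "G"
    if scheme.scope_interpretation:
        letters += "I"
    return letters


def scope_summary(inventory: list[EQAScheme]) -> dict[str, tuple[int, int]]:
    """Per-category ``(count, percent)`` over an inventory.

    Percentages are rounded half-up to the nearest integer; counts always
    sum to the inventory size.
    """
    if not inventory:
        raise InventoryError("scope_summary: empty inventory")
    counts: dict[str, int] = {}
    for s in inventory:
        cat = classify_scope(s)
        counts[cat] = counts.get(cat, 0) + 1
    total = len(inventory)
    out: dict[str, tuple[int, int]] = {}
    for cat in sorted(counts, key=lambda c: (-counts[c], c)):
        n = counts[cat]
        pct = int(Decimal(100 * n) / Decimal(total) + Decimal("0.5"))
        out[cat] = (n, pct)
    return out


# ---------------------------------------------------------------------------
# CSV / YAML I/O
# ---------------------------------------------------------------------------

def _parse_flag(text: str, row: int, col: str) -> bool:
    if text in ("0", "1"):
        return text == "1"
    raise InventoryError(f"row {row}: column {col!r}: expected 0 or 1, got {text!r}")


def _parse_int(text: str, row: int, col: str) -> int:
    try:
        return int(text)
    except ValueError:
        raise InventoryError(f"row {row}: column {col!r}: expected integer, got {text!r}") from None


def _parse_fee(text: str, row: int) -> int:
    try:
        cents = Decimal(text) * 100
    except InvalidOperation:
        raise InventoryError(f"row {row}: column 'fee_eur': not a number: {text!r}") from None
    if cents != cents.to_integral_value():
        raise InventoryError(f"row {row}: column 'fee_eur': sub-cent fee {text!r}")
    return int(cents)


def _check_header(header: list[str] | None, expected: tuple[str, ...], what: str) -> None:
    if header is None or tuple(header) != expected:
        raise InventoryError(f"{what}: expected header {','.join(expected)}")


def read_inventory(path: str | Path) -> list[EQAScheme]:
    """Read ``schemes.csv``; duplicate ids and invalid rows are rejected."""
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        rows = list(reader)
    _check_header(rows[0] if rows else None, INVENTORY_COLUMNS, str(path))
    schemes: list[EQAScheme] = []
    seen: set[str] = set()
    for i, row in enumerate(rows[1:], start=2):
        if len(row) != len(INVENTORY_COLUMNS):
            raise InventoryError(f"row {i}: expected {len(INVENTORY_COLUMNS)} fields, got {len(row)}")
        rec = dict(zip(INVENTORY_COLUMNS, row))
        if rec["scheme_id"] in seen:
            raise InventoryError(f"duplicate scheme_id {rec['scheme_id']!r} (row {i})")
        seen.add(rec["scheme_id"])
        try:
            scheme = EQAScheme(
                scheme_id=rec["scheme_id"],
                provider=rec["provider"],
                indication=rec["indication"],
                techniques=frozenset(t for t in rec["techniques"].split(";") if t),
                scope_technique=_parse_flag(rec["scope_technique"], i, "scope_technique"),
                scope_genotyping=_parse_flag(rec["scope_genotyping"], i, "scope_genotyping"),
                scope_interpretation=_parse_flag(rec["scope_interpretation"], i, "scope_interpretation"),
                modality=rec["modality"],
                annual_fee_cents=_parse_fee(rec["fee_eur"], i),
                offered_years=frozenset(
                    _parse_int(y, i, "offered_years") for y in rec["offered_years"].split(";") if y
                ),
            )
        except InventoryError as exc:
            raise InventoryError(f"row {i}: {exc}") from None
        schemes.append(scheme)
    return schemes


def _fee_text(cents: int) -> str:
    units, cc = divmod(cents, 100)
    return str(units) if cc == 0 else f"{units}.{cc:02d}"


def write_inventory(schemes: list[EQAScheme], path: str | Path) -> None:
    """Write the canonical comma-separated inventory format."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, lineterminator="\n")
        w.writerow(INVENTORY_COLUMNS)
        for s in schemes:
            w.writerow(
                [
                    s.scheme_id,
                    s.provider,
                    s.indication,
                    ";".join(sorted(s.techniques)),
                    int(s.scope_technique),
                    int(s.scope_genotyping),
                    int(s.scope_interpretation),
                    s.modality,
                    _fee_text(s.annual_fee_cents),
                    ";".join(str(y) for y in sorted(s.offered_years)),
                ]
            )


def inventory_to_text(schemes: list[EQAScheme]) -> str:
    buf = io.StringIO()
    w = csv.writer(buf, lineterminator="\n")
    w.writerow(INVENTORY_COLUMNS)
    for s in schemes:
        w.writerow(
            [
                s.scheme_id,
                s.provider,
                s.indication,
                ";".join(sorted(s.techniques)),
                int(s.scope_technique),
                int(s.scope_genotyping),
                int(s.scope_interpretation),
                s.modality,
                _fee_text(s.annual_fee_cents),
                ";".join(str(y) for y in sorted(s.offered_years)),
            ]
        )
    return buf.getvalue()


def _coerce_date(value, what: str) -> date:
    if isinstance(value, date):
        return value
    if isinstance(value, str):
        try:
            return date.fromisoformat(value)
        except ValueError:
            pass
    raise InventoryError(f"{what}: expected ISO date, got {value!r}")


def read_center(path: str | Path) -> CenterProfile:
    """Read a YAML center profile (``center.yaml``)."""
    with open(path, encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict) or "center_id" not in data:
        raise InventoryError(f"{path}: not a center profile (missing center_id)")
    techniques = []
    for t in data.get("techniques", []):
        lmc = t.get("last_method_change")
        techniques.append(
            TechniqueUse(
                technique_id=str(t["technique_id"]),
                validation_date=_coerce_date(t["validation_date"], "validation_date"),
                method_class=str(t["method_class"]),
                annual_volume=int(t["annual_volume"]),
                last_method_change=None if lmc is None else _coerce_date(lmc, "last_method_change"),
                exemption_documented=bool(t.get("exemption_documented", False)),
            )
        )
    indications = [
        IndicationScope(
            indication=str(i["indication"]),
            techniques_used=frozenset(str(x) for x in i["techniques_used"]),
            annual_requests=int(i.get("annual_requests", 0)),
        )
        for i in data.get("indications", [])
    ]
    return CenterProfile(str(data["center_id"]), tuple(techniques), tuple(indications))


def write_center(center: CenterProfile, path: str | Path) -> None:
    data = {
        "center_id": center.center_id,
        "techniques": [
            {
                "technique_id": t.technique_id,
                "validation_date": t.validation_date.isoformat(),
                "method_class": t.method_class,
                "annual_volume": t.annual_volume,
                "last_method_change": (
                    None if t.last_method_change is None else t.last_method_change.isoformat()
                ),
                "exemption_documented": t.exemption_documented,
            }
            for t in center.techniques
        ],
        "indications": [
            {
                "indication": i.indication,
                "techniques_used": sorted(i.techniques_used),
                "annual_requests": i.annual_requests,
            }
            for i in center.indications
        ],
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)


def read_history(path: str | Path) -> list[ParticipationRecord]:
    """Read ``history.csv`` participation records."""
    with open(path, newline="", encoding="utf-8") as fh:
        rows = list(csv.reader(fh))
    _check_header(rows[0] if rows else None, HISTORY_COLUMNS, str(path))
    records = []
    for i, row in enumerate(rows[1:], start=2):
        if len(row) != len(HISTORY_COLUMNS):
            raise InventoryError(f"row {i}: expected {len(HISTORY_COLUMNS)} fields, got {len(row)}")
        rec = dict(zip(HISTORY_COLUMNS, row))
        try:
            records.append(
                ParticipationRecord(
                    center_id=rec["center_id"],
                    scheme_id=rec["scheme_id"],
                    year=_parse_int(rec["year"], i, "year"),
                    outcome=rec["outcome"],
                    capa_documented=_parse_flag(rec["capa_documented"], i, "capa_documented"),
                )
            )
        except InventoryError as exc:
            raise InventoryError(f"row {i}: {exc}") from None
    return records


def write_history(records: list[ParticipationRecord], path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, lineterminator="\n")
        w.writerow(HISTORY_COLUMNS)
        for r in records:
            w.writerow([r.center_id, r.scheme_id, r.year, r.outcome, int(r.capa_documented)])
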