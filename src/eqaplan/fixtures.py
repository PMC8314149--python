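"""Seeded synthetic generators for inventories, centers and histories.

The default configuration reproduces the structure of the reference
setting: 90 schemes over 72 rare-disease indications, scope-category mix
TGI 65 / TG 21 / GI 1 / T 1 / G 1 / I 1, 15 indications offered by 2–3
providers, uniform fees between €500 and €2,500, 8 centers with log-normal
annual test volumes (median 150), and a 1% per-participation error
probability.  Everything is deterministic per seed, with independent
streams for inventory, center and history generation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .inventory import (
    ERROR_OUTCOMES,
    CenterProfile,
    EQAScheme,
    IndicationScope,
    ParticipationRecord,
    TechniqueUse,
    normalize_indication,
)
from datetime import date

__all__ = [
    "FixtureConfig",
    "generate_inventory",
    "generate_center",
    "generate_history",
    "TECHNIQUE_VOCAB",
    "DEFAULT_SCOPE_MIX",
]

#: synthetic technique vocabulary assigned to indications at random
TECHNIQUE_VOCAB = (
    "sequencing",
    "mlpa",
    "karyotyping",
    "fish",
    "fragment_analysis",
    "qpcr",
    "array",
)

DEFAULT_SCOPE_MIX = {"TGI": 65, "TG": 21, "GI": 1, "T": 1, "G": 1, "I": 1}

_PROVIDERS = ("AlphaQA", "BetaPT", "GammaEQA", "DeltaQC", "EpsilonLab")

# stream tags keep the inventory / center / history RNGs independent
_STREAM_INVENTORY, _STREAM_CENTER, _STREAM_HISTORY = 17, 23, 31


@dataclass
class FixtureConfig:
    n_schemes: int = 90
    n_indications: int = 72
    scope_mix: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_SCOPE_MIX))
    n_multiprovider_indications: int = 15
    fee_range_cents: tuple[int, int] = (500_00, 2500_00)
    n_centers: int = 8
    volume_median: float = 150.0
    volume_sigma: float = 1.0
    error_prob: float = 0.01
    capa_prob: float = 0.8
    method_change_prob: float = 0.15
    horizon: tuple[int, int] = (2024, 2026)
    seed: int = 1

    def validate(self) -> None:
        if self.n_schemes < 1 or self.n_indications < 1:
            raise ValueError("n_schemes and n_indications must be positive")
        if sum(self.scope_mix.values()) != self.n_schemes:
            raise ValueError(
                f"scope_mix counts sum to {sum(self.scope_mix.values())}, "
                f"expected n_schemes={self.n_schemes}"
            )
        for cat in self.scope_mix:
            if cat not in ("TGI", "TG", "TI", "GI", "T", "G", "I"):
                raise ValueError(f"unknown scope category {cat!r}")
        extras = self.n_schemes - self.n_indications
        if extras < 0:
            raise ValueError("n_schemes must be >= n_indications")
        nm = self.n_multiprovider_indications
        if nm > self.n_indications:
            raise ValueError("more multiprovider indications than indications")
        if not (nm <= extras <= 2 * nm):
            raise ValueError(
                f"{extras} duplicate schemes cannot be spread over {nm} multiprovider "
                f"indications with 2-3 providers each"
            )
        if not 0.0 <= self.error_prob <= 1.0 or not 0.0 <= self.capa_prob <= 1.0:
            raise ValueError("probabilities must be in [0, 1]")
        if self.fee_range_cents[0] > self.fee_range_cents[1] or self.fee_range_cents[0] < 0:
            raise ValueError("invalid fee range")


def _flags(category: str) -> tuple[bool, bool, bool]:
    return "T" in category, "G" in category, "I" in category


def generate_inventory(cfg: FixtureConfig) -> list[EQAScheme]:
    """Deterministic synthetic scheme inventory matching ``cfg`` exactly."""
    cfg.validate()
    rng = np.random.default_rng([_STREAM_INVENTORY, cfg.seed])
    width = max(3, len(str(cfg.n_indications)))
    indications = [f"RD{i:0{width}d}" for i in range(1, cfg.n_indications + 1)]
    ind_techniques = {
        ind: frozenset(
            str(t) for t in rng.choice(TECHNIQUE_VOCAB, size=int(rng.integers(1, 3)), replace=False)
        )
        for ind in indications
    }

    extras = cfg.n_schemes - cfg.n_indications
    multi = sorted(
        str(x)
        for x in rng.choice(indications, size=cfg.n_multiprovider_indications, replace=False)
    )
    extra_counts = {m: 1 for m in multi}
    surplus = extras - len(multi)
    if surplus > 0:
        for m in rng.choice(multi, size=surplus, replace=False):
            extra_counts[str(m)] = 2
    elif extras < len(multi):
        # fewer duplicates than multiprovider slots: trim deterministically
        multi = multi[:extras]
        extra_counts = {m: 1 for m in multi}

    slots: list[tuple[str, int]] = [(ind, 0) for ind in indications]
    for m in multi:
        for dup in range(1, extra_counts.get(m, 0) + 1):
            slots.append((m, dup))
    slots.sort()

    categories = [cat for cat, count in sorted(cfg.scope_mix.items()) for _ in range(count)]
    rng.shuffle(categories)

    fee_lo, fee_hi = cfg.fee_range_cents
    schemes: list[EQAScheme] = []
    base_provider = {
        ind: str(rng.choice(_PROVIDERS)) for ind in indications
    }
    extra_providers: dict[str, list[str]] = {}
    for m in multi:
        others = [p for p in _PROVIDERS if p != base_provider[m]]
        picks = rng.choice(others, size=extra_counts.get(m, 0), replace=False)
        extra_providers[m] = [str(p) for p in picks]
    for i, ((ind, dup), category) in enumerate(zip(slots, categories), start=1):
        if dup == 0:
            provider = base_provider[ind]
        else:
            provider = extra_providers[ind][dup - 1]
        t, g, interp = _flags(category)
        fee = int(rng.integers(fee_lo // 100, fee_hi // 100 + 1)) * 100
        schemes.append(
            EQAScheme(
                scheme_id=f"S{i:03d}",
                provider=provider,
                indication=ind,
                techniques=ind_techniques[ind],
                scope_technique=t,
                scope_genotyping=g,
                scope_interpretation=interp,
                modality="wet" if t else "virtual",
                annual_fee_cents=fee,
                offered_years=frozenset(),
            )
        )
    return schemes


def generate_center(
    cfg: FixtureConfig,
    inventory: list[EQAScheme],
    seed: int,
    center_index: int = 0,
) -> CenterProfile:
    """A synthetic center whose scope is a feasible subset of the inventory.

    Only indications covered by at least one genotyping/interpretation
    scheme are eligible, so every derived requirement is satisfiable.
    """
    if not inventory:
        raise ValueError("inventory must be non-empty")
    rng = np.random.default_rng([_STREAM_CENTER, seed, center_index])
    by_ind: dict[str, list[EQAScheme]] = {}
    for s in inventory:
        by_ind.setdefault(s.indication, []).append(s)
    eligible = sorted(
        ind
        for ind, ss in by_ind.items()
        if any(s.scope_genotyping or s.scope_interpretation for s in ss)
    )
    if not eligible:
        raise ValueError("no indication with genotyping/interpretation coverage")
    lo = min(5, len(eligible))
    hi = min(15, len(eligible))
    k = int(rng.integers(lo, hi + 1))
    chosen = sorted(str(x) for x in rng.choice(eligible, size=k, replace=False))

    ref_year = cfg.horizon[0]
    tech_ids = sorted({t for ind in chosen for s in by_ind[ind] for t in s.techniques})
    techniques = []
    for tid in tech_ids:
        sigma = cfg.volume_sigma
        volume = int(round(float(rng.lognormal(math.log(cfg.volume_median), sigma))))
        back = int(rng.integers(0, 11))
        vdate = date(ref_year - back, int(rng.integers(1, 13)), int(rng.integers(1, 29)))
        change = None
        if back >= 1 and rng.random() < cfg.method_change_prob:
            cyear = int(rng.integers(vdate.year, ref_year))
            change = max(vdate, date(cyear, int(rng.integers(1, 13)), int(rng.integers(1, 29))))
        techniques.append(
            TechniqueUse(
                technique_id=tid,
                validation_date=vdate,
                method_class=str(rng.choice(("in_house", "ce_kit"))),
                annual_volume=volume,
                last_method_change=change,
                exemption_documented=bool(rng.random() < 0.9),
            )
        )
    indications = []
    for ind in chosen:
        used = frozenset(t for s in by_ind[ind] for t in s.techniques)
        indications.append(
            IndicationScope(
                indication=ind,
                techniques_used=used,
                annual_requests=int(rng.integers(1, 60)),
            )
        )
    return CenterProfile(
        center_id=f"C{center_index + 1}",
        techniques=tuple(techniques),
        indications=tuple(indications),
    )


def generate_history(
    center: CenterProfile,
    inventory: list[EQAScheme],
    years: list[int],
    error_prob: float,
    seed: int,
    capa_prob: float = 0.8,
) -> list[ParticipationRecord]:
    """One participation per (year, indication in scope), seeded outcomes.

    An error occurs with ``error_prob`` and is split uniformly across the
    four error categories; CAPA documentation is drawn with ``capa_prob``.
    """
    if not 0.0 <= error_prob <= 1.0:
        raise ValueError("error_prob must be in [0, 1]")
    rng = np.random.default_rng([_STREAM_HISTORY, seed])
    by_ind: dict[str, list[EQAScheme]] = {}
    for s in inventory:
        if s.scope_genotyping or s.scope_interpretation:
            by_ind.setdefault(normalize_indication(s.indication), []).append(s)
    for ss in by_ind.values():
        ss.sort(key=lambda s: s.scheme_id)
    records: list[ParticipationRecord] = []
    for year in years:
        for ind in center.indications:
            candidates = by_ind.get(normalize_indication(ind.indication))
            if not candidates:
                continue
            scheme = candidates[int(rng.integers(len(candidates)))]
            if rng.random() < error_prob:
                outcome = ERROR_OUTCOMES[int(rng.integers(len(ERROR_OUTCOMES)))]
            else:
                outcome = "satisfactory"
            records.append(
                ParticipationRecord(
                    center_id=center.center_id,
                    scheme_id=scheme.scheme_id,
                    year=year,
                    outcome=outcome,
                    capa_documented=bool(rng.random() < capa_prob),
                )
            )
    return records
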