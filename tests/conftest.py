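from datetime import date

import pytest

from eqaplan.fixtures import FixtureConfig, generate_center, generate_history, generate_inventory
from eqaplan.inventory import (
    CenterProfile,
    EQAScheme,
    IndicationScope,
    TechniqueUse,
)


def make_scheme(
    scheme_id="S001",
    provider="AlphaQA",
    indication="RD001",
    techniques=("sequencing",),
    flags=(True, True, True),
    modality="wet",
    fee=1000_00,
    offered_years=(),
):
    return EQAScheme(
        scheme_id=scheme_id,
        provider=provider,
        indication=indication,
        techniques=frozenset(techniques),
        scope_technique=flags[0],
        scope_genotyping=flags[1],
        scope_interpretation=flags[2],
        modality=modality,
        annual_fee_cents=fee,
        offered_years=frozenset(offered_years),
    )


def make_technique(
    technique_id="sequencing",
    validation_year=2015,
    volume=400,
    method_class="in_house",
    last_method_change=None,
    documented=True,
):
    return TechniqueUse(
        technique_id=technique_id,
        validation_date=date(validation_year, 1, 1),
        method_class=method_class,
        annual_volume=volume,
        last_method_change=last_method_change,
        exemption_documented=documented,
    )


def make_center(center_id="C1", techniques=(), indications=()):
    return CenterProfile(center_id, tuple(techniques), tuple(indications))


def small_config(seed, **overrides):
    """A compact feasible random instance for planner property tests."""
    params = dict(
        n_schemes=18,
        n_indications=15,
        n_multiprovider_indications=3,
        scope_mix={"TGI": 10, "TG": 5, "GI": 1, "T": 1, "I": 1},
        seed=seed,
    )
    params.update(overrides)
    return FixtureConfig(**params)


def tiny_config(seed):
    """<= 12 candidate schemes per year; exhaustive optimizer territory."""
    return FixtureConfig(
        n_schemes=6,
        n_indications=5,
        n_multiprovider_indications=1,
        scope_mix={"TGI": 3, "TG": 1, "GI": 1, "I": 1},
        seed=seed,
    )


def random_instance(seed, cfg_factory=small_config, error_prob=0.1):
    cfg = cfg_factory(seed)
    inventory = generate_inventory(cfg)
    center = generate_center(cfg, inventory, seed=seed)
    history = generate_history(center, inventory, [2021, 2022, 2023], error_prob, seed=seed)
    return cfg, inventory, center, history


@pytest.fixture(scope="session")
def default_inventory():
    return generate_inventory(FixtureConfig(seed=1))


@pytest.fixture(scope="session")
def default_config():
    return FixtureConfig(seed=1)


@pytest.fixture
def simple_center():
    tech = make_technique("sequencing", validation_year=2015, volume=400)
    ind = IndicationScope("RD001", frozenset({"sequencing"}), annual_requests=10)
    return make_center(techniques=[tech], indications=[ind])
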