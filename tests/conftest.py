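"""Shared fixtures: packaged data and session-scoped trained models."""

import warnings

import pytest

from pksmith import assembly_order as ao
from pksmith import at_specificity as ats
from pksmith import fixtures as fx
from pksmith import pipeline as pl
from pksmith import structure_gen as sg
from pksmith.substrate_rules import MonomerLibrary


@pytest.fixture(scope="session")
def monomer_library() -> MonomerLibrary:
    return MonomerLibrary.load()


@pytest.fixture(scope="session")
def rule_db() -> sg.RuleDatabase:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return sg.load_modification_db()


@pytest.fixture(scope="session")
def reference() -> ats.ReferenceProfile:
    return ats.load_reference()


@pytest.fixture(scope="session")
def at_training():
    return fx.make_at_training(seed=3)


@pytest.fixture(scope="session")
def specificity_model(at_training) -> ats.SpecificityModel:
    return pl.train_specificity_from_signatures(at_training, seed=0)


@pytest.fixture(scope="session")
def interaction_model() -> ao.InteractionModel:
    return ao.train_interaction_model(fx.make_docking_training(seed=5), seed=0)
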