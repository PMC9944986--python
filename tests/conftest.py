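import numpy as np
import pytest

from tdpquant import synthdata
from tdpquant.records import Modification, MS1Feature, PrSMRecord


def make_prsm(**kw):
    """A valid PrSM with overridable fields, for focused unit tests."""
    defaults = dict(
        run_id="S01",
        cv=-40,
        scan=100,
        rt_min=30.0,
        precursor_mass=10000.0,
        charge=10,
        evalue=1e-8,
        accession="P00001",
        proteoform="MKVLAAGITK",
        first_residue=1,
        last_residue=10,
        engine="toppic",
    )
    defaults.update(kw)
    return PrSMRecord(**defaults)


def make_feature(**kw):
    defaults = dict(
        run_id="S01",
        cv=-40,
        mono_mass=10000.0,
        rt_apex=30.0,
        abundance=1e6,
    )
    defaults.update(kw)
    defaults.setdefault("rt_start", defaults["rt_apex"] - 0.5)
    defaults.setdefault("rt_end", defaults["rt_apex"] + 0.5)
    return MS1Feature(**defaults)


@pytest.fixture(scope="session")
def small_truth():
    """A modest noisy synthetic study shared across read-only tests."""
    return synthdata.generate_truth(40, seed=11)


@pytest.fixture(scope="session")
def small_tables(small_truth):
    return synthdata.simulate_tables(small_truth)


@pytest.fixture(scope="session")
def clean_truth():
    return synthdata.generate_truth(40, seed=5, params=synthdata.SynthParams.clean())


@pytest.fixture(scope="session")
def clean_tables(clean_truth):
    return synthdata.simulate_tables(clean_truth)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
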