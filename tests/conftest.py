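import numpy as np
import pytest

from sbipred.features import build_feature_bundle
from sbipred.synthetic_data import SimConfig, generate_universe

TINY = SimConfig(
    n_smd=30,
    n_biod=10,
    n_protein=24,
    n_events=3,
    seq_length_range=(40, 90),
    positive_rate=0.2,
    hidden_positive_fraction=0.1,
    min_count=2,
    seed=11,
)


@pytest.fixture(scope="session")
def tiny_sim():
    """A 30x10 universe with planted signal plus its hidden positives and
    latent factors."""
    return generate_universe(TINY)


@pytest.fixture(scope="session")
def tiny_universe(tiny_sim):
    return tiny_sim[0]


@pytest.fixture(scope="session")
def tiny_bundle(tiny_universe):
    return build_feature_bundle(
        tiny_universe, smd_max_len=64, biod_max_len=80, pca_k=16, seed=0
    )


@pytest.fixture(scope="session")
def tiny_positive_map(tiny_universe):
    out = {}
    for q in tiny_universe.quaternaries:
        eid = tiny_universe.catalog.event_id(q.mechanism, q.action)
        out.setdefault((q.drug_a, q.drug_b), set()).add(eid)
    return {k: tuple(sorted(v)) for k, v in out.items()}


@pytest.fixture(scope="session")
def tiny_unlabeled(tiny_universe, tiny_positive_map):
    allp = {
        (s, b) for s in tiny_universe.smd_ids for b in tiny_universe.biod_ids
    }
    return sorted(allp - set(tiny_positive_map))
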