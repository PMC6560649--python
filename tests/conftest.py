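import numpy as np
import pytest

from ditras import mdl, synth
from ditras.tessellation import Location, WeightedSpatialTessellation


@pytest.fixture(scope="session")
def toy_tess():
    """Small heavy-tailed tessellation for unit tests."""
    return synth.generate_toy_tessellation(10, seed=1)


@pytest.fixture(scope="session")
def tess50():
    """The 50-location tessellation used for cohort-scale runs."""
    return synth.generate_toy_tessellation(50, seed=7)


@pytest.fixture(scope="session")
def meridian_tess():
    """Colinear locations on one meridian: exact pairwise distances.

    Along a meridian the haversine distance is linear in the latitude
    difference, so distances can be dialled in exactly: A-B = 1 km,
    A-C = 2 km, B-C = 3 km.
    """
    km_per_deg = 6371.0 * np.pi / 180.0
    return WeightedSpatialTessellation(
        [
            Location("A", 0.0, 0.0, 1.0),
            Location("B", 1.0 / km_per_deg, 0.0, 2.0),
            Location("C", -2.0 / km_per_deg, 0.0, 3.0),
        ]
    )


@pytest.fixture(scope="session")
def synth_corpus():
    """Synthetic CDR corpus at the default study conditions, with truth."""
    spec = synth.SynthSpec()  # 100 users, 50 locations, 28 days
    tess = synth.generate_toy_tessellation(spec.n_locations, seed=spec.seed)
    records, truth = synth.generate_synthetic_cdr(spec, tess)
    return spec, tess, records, truth


@pytest.fixture(scope="session")
def fitted_model(synth_corpus):
    """Markov diary model fitted on the synthetic corpus (weekly period)."""
    _, _, records, truth = synth_corpus
    corpus = []
    for user, recs in records.items():
        traj = mdl.abstractify(
            [(r.timestamp, r.location_id) for r in recs],
            3600,
            start=0.0,
            n_slots=truth["n_slots"],
        )
        corpus.append((traj, mdl.estimate_typical_diary(traj)))
    return mdl.fit_markov(corpus, n_period=168, slot_seconds=3600)
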