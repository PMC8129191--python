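import numpy as np
import pytest

import seegdecode as sd


def tiny_session(seed=0, n_trials=10, n_shafts=2, contacts_per_shaft=8, **kwargs):
    cfg = sd.SimConfig(
        seed=seed,
        n_shafts=n_shafts,
        contacts_per_shaft=contacts_per_shaft,
        n_trials_per_class=n_trials // 2,
        **kwargs,
    )
    return sd.generate_session(cfg)


@pytest.fixture(scope="session")
def small_null_session():
    """16 contacts, 10 trials, no effects: exchangeable by construction."""
    session, gt = tiny_session(seed=11)
    return session


@pytest.fixture(scope="session")
def effect_session():
    """One discriminative contact (gain 3 at 60-145 Hz, onset 300 ms)."""
    cfg = sd.SimConfig(
        seed=7,
        n_trials_per_class=30,
        effects=[sd.EffectSpec(contact_id="S1-3")],
    )
    session, gt = sd.generate_session(cfg)
    return session, gt


@pytest.fixture(scope="session")
def effect_epochs(effect_session):
    session, _ = effect_session
    return sd.preprocess_session(session)


@pytest.fixture(scope="session")
def null_epochs(small_null_session):
    return sd.preprocess_session(small_null_session)


def make_feature_set(matrix, labels, n_bins_per_contact=None):
    """Wrap a plain matrix as a FeatureSet with synthetic provenance."""
    matrix = np.asarray(matrix, dtype=float)
    n_feat = matrix.shape[1]
    if n_bins_per_contact is None:
        n_bins_per_contact = min(100, n_feat)
    contact_ids = np.array(
        [f"C{j // n_bins_per_contact}" for j in range(n_feat)], dtype=object
    )
    bin_index = np.array([j % n_bins_per_contact for j in range(n_feat)])
    return sd.FeatureSet(
        matrix=matrix,
        contact_ids=contact_ids,
        bin_index=bin_index,
        labels=np.asarray(labels, dtype=object),
    )
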