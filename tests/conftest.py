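import pytest

from icufusion.config import ModelConfig
from icufusion.ingest import PatientEpisode, RawEvent, RawNote
from icufusion.synthetic import CohortSpec, generate_cohort, write_cohort
from icufusion.ingest import read_tables


@pytest.fixture(scope="session")
def small_cohort_dir(tmp_path_factory):
    """A 60-patient cohort directory shared by read-only tests."""
    out = tmp_path_factory.mktemp("cohort60")
    spec = CohortSpec(n_patients=60, prevalence=0.3, seed=7,
                      signal_strength=0.9, temporal_effect=1.5)
    write_cohort(generate_cohort(spec), out)
    return out, spec


@pytest.fixture(scope="session")
def small_episodes(small_cohort_dir):
    out, spec = small_cohort_dir
    return read_tables(out), spec


@pytest.fixture()
def tiny_config():
    """A minimal configuration that keeps forward passes near-instant."""
    return ModelConfig(variant="multi_atten_chronic", hidden_dim=8, embed_dim=6,
                       joint_dim=4, n_filters=5, filter_size=3, sim_window=3,
                       max_len=40, batch_size=4, learning_rate=1e-2,
                       max_epochs=3, early_stop_rounds=3, dropout_rate=0.0,
                       seed=0)


def make_episode(stay_id="s1", age=50.0, chronic=False, label=0,
                 event_times=(0.5, 47.0, 48.5), notes=()):
    """Hand-built episode with heart-rate events at the given times."""
    events = [RawEvent(stay_id, "heart_rate", t, 80.0) for t in event_times]
    raw_notes = [RawNote(stay_id, t, "Nursing", text) for t, text in notes]
    return PatientEpisode(stay_id=stay_id, age=age, chronic=chronic,
                          events=events, notes=raw_notes, label=label)
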