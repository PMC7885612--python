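"""Fusion head, loss decomposition, training behavior and predict-time
contracts."""

import dataclasses

import numpy as np
import pytest

from icufusion.autodiff import Adam, Tensor
from icufusion.config import ModelConfig
from icufusion.fusion import MortalityNet, compute_loss, train
from icufusion.ingest import PatientEpisode, RawEvent, filter_cohort
from icufusion.metrics import aucroc
from icufusion.synthetic import CohortSpec, generate_cohort, write_cohort
from icufusion.ingest import read_tables


@pytest.fixture(scope="module")
def quick_model(small_episodes, tiny_config):
    """A briefly trained tiny multimodal model shared by predict-time tests."""
    episodes, _ = small_episodes
    return train(episodes, tiny_config), episodes


# make tiny_config usable at module fixture scope
@pytest.fixture(scope="module")
def tiny_config():
    return ModelConfig(variant="multi_atten_chronic", hidden_dim=8, embed_dim=6,
                       joint_dim=4, n_filters=5, filter_size=3, max_len=60,
                       batch_size=8, learning_rate=1e-2, max_epochs=4,
                       early_stop_rounds=4, dropout_rate=0.0, seed=1)


def _tiny_batch(config, vocab_size=20, n=3, rng=None):
    rng = rng or np.random.default_rng(0)
    L = config.max_len
    ids = rng.integers(2, vocab_size, size=(n, L))
    mask = np.ones((n, L), dtype=bool)
    return {
        "temporal": rng.normal(size=(n, config.n_hours, 17)),
        "ids": ids, "content_mask": mask,
        "labels": rng.integers(0, 2, size=n),
    }


def test_zero_head_weights_predict_half(tiny_config):
    net = MortalityNet(tiny_config, vocab_size=20)
    net.params["head_W"].data[:] = 0.0
    net.params["head_b"].data[:] = 0.0
    pred = net.predict_batch(_tiny_batch(tiny_config))
    np.testing.assert_allclose(pred.y_hat, 0.5, atol=1e-12)


def test_fused_dimension_is_h_plus_filters():
    cfg = ModelConfig(hidden_dim=256, n_filters=100)
    assert cfg.fused_dim == 356
    assert ModelConfig(variant="lstm_only", hidden_dim=256).fused_dim == 256
    assert ModelConfig(variant="cn_only", n_filters=100).fused_dim == 100


def test_fused_vector_shape_in_forward(tiny_config):
    net = MortalityNet(tiny_config, vocab_size=20)
    pred = net.predict_batch(_tiny_batch(tiny_config, n=4))
    assert pred.fused.shape == (4, tiny_config.fused_dim)
    assert np.all((pred.y_hat > 0) & (pred.y_hat < 1))


def test_lstm_only_ignores_note_content(tiny_config):
    cfg = dataclasses.replace(tiny_config, variant="lstm_only")
    net = MortalityNet(cfg, vocab_size=20)
    batch = _tiny_batch(cfg)
    p1 = net.predict_batch(batch).y_hat
    batch["ids"] = np.random.default_rng(9).integers(2, 20, size=batch["ids"].shape)
    p2 = net.predict_batch(batch).y_hat
    np.testing.assert_array_equal(p1, p2)


def test_loss_decomposition_is_exact():
    rng = np.random.default_rng(1)
    y_hat = Tensor(rng.random(6) * 0.98 + 0.01)
    aux = Tensor(rng.normal(size=(6, 2)))
    labels = rng.integers(0, 2, 6)
    total, lv = compute_loss(y_hat, aux, labels)
    assert abs(lv.total - (lv.ce_term + lv.joint_term)) < 1e-9
    assert lv.ce_term >= 0 and lv.joint_term >= 0
    assert abs(float(total.data) - lv.total) < 1e-12


def test_perfect_prediction_has_near_zero_ce():
    labels = np.array([1, 0, 1])
    y_hat = Tensor(labels.astype(float))
    _, lv = compute_loss(y_hat, None, labels)
    assert lv.ce_term < 1e-5
    assert lv.joint_term == 0.0


def test_half_probability_costs_ln_two():
    _, lv = compute_loss(Tensor(np.array([0.5])), None, np.array([1]))
    assert abs(lv.ce_term - np.log(2.0)) < 1e-9


def test_saturated_aux_logits_zero_the_joint_term():
    labels = np.array([1, 0])
    aux = Tensor(np.array([[-30.0, 30.0], [30.0, -30.0]]))  # sigma -> one-hot
    _, lv = compute_loss(Tensor(np.array([0.9, 0.1])), aux, labels)
    assert lv.joint_term < 1e-5


def test_non_binary_labels_rejected():
    with pytest.raises(ValueError):
        compute_loss(Tensor(np.array([0.5])), None, np.array([2]))


def test_single_class_training_cohort_rejected(tmp_path):
    write_cohort(generate_cohort(CohortSpec(n_patients=10, prevalence=0.0, seed=1)),
                 tmp_path)
    with pytest.raises(ValueError, match="single-class"):
        train(read_tables(tmp_path), ModelConfig(max_epochs=1))


@pytest.mark.parametrize("variant", ["lstm_only", "multi_atten_chronic"])
def test_overfit_capacity_on_ten_samples(variant):
    """The classification term is driven near zero on a memorizable set.

    (The joint-embedding regularizer has an irreducible log-2 floor for the
    absent label class, so capacity is asserted on the CE term.)
    """
    cfg = ModelConfig(variant=variant, hidden_dim=8, embed_dim=6, joint_dim=4,
                      n_filters=5, filter_size=3, max_len=30, batch_size=10,
                      learning_rate=2e-2, dropout_rate=0.0, batch_norm=False,
                      seed=0)
    rng = np.random.default_rng(2)
    net = MortalityNet(cfg, vocab_size=15)
    batch = _tiny_batch(cfg, vocab_size=15, n=10, rng=rng)
    batch["labels"] = np.array([0, 1] * 5)
    opt = Adam(net.params, lr=cfg.learning_rate)
    ce = np.inf
    for _ in range(200):
        y_hat, _, _, m_label = net.forward(batch, training=True)
        loss_t, lv = compute_loss(y_hat, m_label, batch["labels"])
        opt.zero_grad()
        loss_t.backward()
        opt.step()
        ce = lv.ce_term
        if ce < 0.05:
            break
    assert ce < 0.05


def test_fixed_seed_reproduces_loss_trajectory(small_episodes, tiny_config):
    episodes, _ = small_episodes
    cfg = dataclasses.replace(tiny_config, max_epochs=3)
    h1 = train(episodes, cfg).history
    h2 = train(episodes, cfg).history
    assert [r.train_loss for r in h1] == [r.train_loss for r in h2]
    assert [r.val_aucpr for r in h1] == [r.val_aucpr for r in h2]


def test_predictions_ignore_labels_entirely(quick_model):
    model, episodes = quick_model
    eps = filter_cohort(episodes)[:10]
    p1 = model.predict_episodes(eps)
    scrambled = [dataclasses.replace(ep) for ep in eps]
    for ep in scrambled:
        ep.label = None
    p2 = model.predict_episodes(scrambled)
    flipped = [dataclasses.replace(ep) for ep in eps]
    for ep in flipped:
        ep.label = 1 - ep.label
    p3 = model.predict_episodes(flipped)
    np.testing.assert_array_equal(p1, p2)
    np.testing.assert_array_equal(p1, p3)


def test_prediction_order_and_alignment(quick_model):
    model, episodes = quick_model
    eps = filter_cohort(episodes)[:8]
    probs = model.predict_episodes(eps)
    assert probs.shape == (8,)
    # per-episode predictions match the batched path, in order
    singles = np.array([model.predict_episodes([ep])[0] for ep in eps])
    np.testing.assert_allclose(probs, singles, atol=1e-12)


def test_empty_notes_patient_gets_valid_probability(quick_model):
    model, _ = quick_model
    ep = PatientEpisode("ghost", 60.0, False,
                        events=[RawEvent("ghost", "heart_rate", float(t), 80.0)
                                for t in range(49)],
                        notes=[], label=None)
    p = model.predict_episodes([ep])
    assert 0.0 < p[0] < 1.0


def test_lstm_only_is_chance_level_on_text_only_signal(tmp_path):
    """With no temporal effect planted, the temporal-only model cannot beat
    a permutation null (two-sided test at alpha = 0.01)."""
    spec = CohortSpec(n_patients=150, prevalence=0.3, seed=13,
                      signal_strength=1.0, temporal_effect=0.0)
    write_cohort(generate_cohort(spec), tmp_path)
    episodes = read_tables(tmp_path)
    cfg = ModelConfig(variant="lstm_only", hidden_dim=16, max_len=40,
                      batch_size=16, learning_rate=2e-3, max_epochs=10,
                      early_stop_rounds=10, dropout_rate=0.0, seed=13)
    model = train(episodes, cfg)
    test_ids = set(model.split_ids["test"])
    test_eps = [ep for ep in filter_cohort(episodes) if ep.stay_id in test_ids]
    probs = model.predict_episodes(test_eps)
    labels = np.array([ep.label for ep in test_eps])
    observed = aucroc(probs, labels)
    rng = np.random.default_rng(0)
    null = []
    for _ in range(500):
        null.append(aucroc(probs, rng.permutation(labels)))
    p_val = np.mean([abs(a - 0.5) >= abs(observed - 0.5) for a in null])
    assert p_val > 0.01
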