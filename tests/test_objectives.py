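"""Analytic values and gradient contracts for the four training losses."""

import numpy as np
import pytest

from dementnet.autodiff import Tensor
from dementnet.cohort import ConfoundVocab
from dementnet.objectives import (adversarial_encoder_loss,
                                  classification_loss, cluster_loss,
                                  cluster_loss_point, cross_entropy,
                                  discriminator_loss, kl_loss, LossBreakdown,
                                  LossWeights)
from collections import Counter


def make_vocab(sizes):
    vocab, modal, counts = {}, {}, {}
    for cat, k in sizes.items():
        values = tuple(f"{cat}{i}" for i in range(k))
        vocab[cat] = values
        modal[cat] = values[0]
        counts[cat] = Counter({v: 1 for v in values})
    return ConfoundVocab(vocab=vocab, modal=modal, counts=counts)


class TestClassificationLoss:
    def test_perfect_scores_near_zero(self):
        scores = Tensor(np.array([[0.9999999, 0.0000001]]))
        loss = classification_loss(scores, np.array([[1.0, 0.0]]))
        assert float(loss.data) < 1e-6

    def test_half_scores_give_ln2(self):
        scores = Tensor(np.full((3, 2), 0.5))
        loss = classification_loss(scores, np.zeros((3, 2)))
        assert float(loss.data) == pytest.approx(np.log(2), abs=1e-9)

    def test_hand_value(self):
        loss = classification_loss(Tensor(np.array([[0.8]])),
                                   np.array([[1.0]]))
        assert float(loss.data) == pytest.approx(-np.log(0.8), abs=1e-6)

    def test_task_mask_skips_entries(self):
        scores = Tensor(np.array([[0.8, 0.1]]))
        labels = np.array([[1.0, 1.0]])
        mask = np.array([[True, False]])
        loss = classification_loss(scores, labels, mask)
        assert float(loss.data) == pytest.approx(-np.log(0.8), abs=1e-6)


class TestAdversarialLosses:
    def test_uniform_heads_give_log_k(self):
        vocab = make_vocab({"a": 2, "b": 3})
        scores = {"a": Tensor(np.zeros((4, 2))), "b": Tensor(np.zeros((4, 3)))}
        loss = adversarial_encoder_loss(scores, vocab, [])
        expected = (np.log(2) + np.log(3)) / 2
        assert float(loss.data) == pytest.approx(expected, abs=1e-9)

    def test_confident_modal_prediction_near_zero(self):
        vocab = make_vocab({"a": 2})
        logits = np.zeros((3, 2))
        logits[:, 0] = 50.0   # modal value is index 0
        loss = adversarial_encoder_loss({"a": Tensor(logits)}, vocab, [])
        assert float(loss.data) < 1e-6

    def test_discriminator_targets_true_values(self):
        vocab = make_vocab({"a": 2})
        logits = np.zeros((2, 2))
        logits[0, 1] = 50.0
        logits[1, 0] = 50.0
        values = [{"a": "a1"}, {"a": "a0"}]
        loss = discriminator_loss({"a": Tensor(logits)}, vocab, values)
        assert float(loss.data) < 1e-6
        # uniform logits give ln 2
        loss_u = discriminator_loss({"a": Tensor(np.zeros((2, 2)))}, vocab,
                                    values)
        assert float(loss_u.data) == pytest.approx(np.log(2), abs=1e-9)


class TestClusterLoss:
    def test_hand_example_minus_six(self):
        latent = Tensor(np.zeros(2))
        label_means = {"same": np.zeros(2), "other": np.array([3.0, 4.0])}
        conf_means = {"own": np.array([1.0, 0.0]), "other": np.zeros(2)}
        loss = cluster_loss_point(latent, "same", "own", label_means,
                                  conf_means)
        assert float(loss.data) == pytest.approx(-6.0, abs=1e-5)

    def test_all_means_equal_point_gives_zero(self):
        latent = Tensor(np.ones(3))
        means = {"a": np.ones(3), "b": np.ones(3)}
        loss = cluster_loss_point(latent, "a", "a", means, dict(means))
        assert float(loss.data) == pytest.approx(0.0, abs=1e-5)

    def test_step_toward_same_label_mean_decreases_loss(self):
        """With the group means held fixed, moving a point toward its own
        label's mean strictly decreases its loss contribution."""
        rng = np.random.default_rng(0)
        label_means = {"a": rng.normal(size=4), "b": rng.normal(size=4)}
        point = rng.normal(size=4) + 2.0
        base = float(cluster_loss_point(Tensor(point), "a", None,
                                        label_means, {}).data)
        stepped = point + 0.05 * (label_means["a"] - point)
        after = float(cluster_loss_point(Tensor(stepped), "a", None,
                                         label_means, {}).data)
        assert after < base

    def test_single_label_batch_contributes_zero(self):
        latents = Tensor(np.random.default_rng(1).normal(size=(4, 3)))
        loss = cluster_loss(latents, np.zeros(4), None)
        assert float(loss.data) == 0.0

    def test_rotation_invariance(self):
        rng = np.random.default_rng(2)
        latents = rng.normal(size=(8, 3))
        labels = np.array([0, 1] * 4)
        confs = np.array(["x", "x", "y", "y"] * 2)
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        a = float(cluster_loss(Tensor(latents), labels, confs).data)
        b = float(cluster_loss(Tensor(latents @ q), labels, confs).data)
        assert a == pytest.approx(b, abs=1e-9)


class TestKLLoss:
    def test_standard_normal_is_zero(self):
        loss = kl_loss(Tensor(np.zeros((2, 4))), Tensor(np.zeros((2, 4))))
        assert float(loss.data) == pytest.approx(0.0, abs=1e-12)

    def test_closed_form_half(self):
        mean = Tensor(np.array([[1.0, 0.0]]))
        logvar = Tensor(np.zeros((1, 2)))
        assert float(kl_loss(mean, logvar).data) == pytest.approx(0.5, abs=1e-12)

    def test_nonnegative_on_random_inputs(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            loss = kl_loss(Tensor(rng.normal(size=(3, 5))),
                           Tensor(rng.normal(size=(3, 5))))
            assert float(loss.data) >= -1e-12


def test_loss_breakdown_total_is_weighted_sum():
    w = LossWeights(classification=1.0, adversarial=2.0, cluster=0.5, kl=0.1)
    b = LossBreakdown(classification=0.3, adversarial=0.7, cluster=-0.2,
                      kl=1.5, weights=w)
    assert b.total == pytest.approx(0.3 + 1.4 - 0.1 + 0.15)


def test_gradient_partition_discriminator_vs_encoder(tiny_model, small_cohort):
    """Discriminator loss on detached latents leaves encoder grads empty;
    the adversarial encoder loss reaches encoder parameters."""
    patients, _ = small_cohort
    model = tiny_model
    images = patients[0].images
    confs = [im.confounds(patients[0].sex) for im in images]

    latents, _, _ = model.encode_images(images, sample=False)
    model.zero_grad()
    d_loss = discriminator_loss(model.confound_heads(latents.detach()),
                                model.vocab, confs)
    d_loss.backward()
    assert all(p.grad is None for p in model.encoder.parameters())
    assert any(p.grad is not None for p in model.confound_heads.parameters())

    latents, _, _ = model.encode_images(images, sample=False)
    model.zero_grad()
    a_loss = adversarial_encoder_loss(model.confound_heads(latents),
                                      model.vocab, confs)
    a_loss.backward()
    assert any(p.grad is not None for p in model.encoder.parameters())
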