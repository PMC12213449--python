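"""Encoder, text hashing, token stack and the optional-input contract."""


import numpy as np
import pytest

from dementnet.autodiff import Tensor
from dementnet.cohort import PatientRecord, build_confound_vocab
from dementnet.encoder import (DementiaNet, ModelConfig, assemble_stack,
                               encode_text, hash_text_token,
                               age_positional_encoding, normalize_volume)
from conftest import make_image, make_patient, tiny_model_config


class TestTextHashing:
    def test_deterministic_across_calls(self):
        assert np.array_equal(hash_text_token("M", 64), hash_text_token("M", 64))

    def test_unit_norm(self):
        assert np.linalg.norm(hash_text_token("F", 128)) == pytest.approx(
            1.0, abs=1e-6)

    def test_near_orthogonality_at_128(self):
        a, b = hash_text_token("M", 128), hash_text_token("F", 128)
        assert abs(float(a @ b)) < 0.5

    def test_unknown_category_rejected(self):
        with pytest.raises(ValueError, match="not in vocabulary"):
            encode_text("martian", {"M", "F"}, 16)

    def test_missing_always_allowed(self):
        vec = encode_text("missing", {"hispanic", "non_hispanic"}, 16)
        assert np.isfinite(vec).all()


class TestEncodeImage:
    def test_deterministic_inference(self, tiny_model, small_cohort):
        patients, _ = small_cohort
        images = patients[0].images[:1]
        a, _, _ = tiny_model.encode_images(images, sample=False)
        b, _, _ = tiny_model.encode_images(images, sample=False)
        np.testing.assert_array_equal(a.data, b.data)

    def test_default_latent_length_is_128(self):
        assert ModelConfig().latent_dim == 128

    def test_volume_smaller_than_patch_rejected(self):
        with pytest.raises(ValueError, match="patch"):
            normalize_volume(np.zeros((4, 4, 4)), tiny_model_config())

    def test_patch_permutation_equivariance(self, tiny_model, small_cohort):
        """Permuting patches together with their positional embeddings
        leaves the latent unchanged (transformer permutation symmetry)."""
        patients, _ = small_cohort
        image = patients[0].images[0]
        base, _, _ = tiny_model.encode_images([image], sample=False)
        enc = tiny_model.encoder
        n = enc.config.n_patches
        perm = np.random.default_rng(0).permutation(n)
        from dementnet.encoder import volume_to_patches
        patches = volume_to_patches(
            normalize_volume(image.volume, enc.config), enc.config)
        original_pos = enc.pos_embed.data.copy()
        try:
            enc.pos_embed.data = np.concatenate(
                [original_pos[:1], original_pos[1:][perm]])
            mean, _ = enc.forward_patches(patches[perm][None])
            np.testing.assert_allclose(mean.data, base.data, atol=1e-5)
        finally:
            enc.pos_embed.data = original_pos


class TestTokenStack:
    def test_fourteen_images_fill_all_slots(self):
        p = make_patient("p0", n_images=14)
        stack = assemble_stack(p, np.arange(14), tiny_model_config())
        assert stack.slot_mask.all()

    def test_image_count_bounds(self):
        with pytest.raises(ValueError):
            assemble_stack(make_patient("p0", n_images=15), np.arange(15),
                           tiny_model_config())

    def test_text_slots_always_occupied(self):
        stack = assemble_stack(make_patient("p0", n_images=1), np.arange(1),
                               tiny_model_config())
        assert stack.slot_mask[14] and stack.slot_mask[15]
        assert stack.slot_mask[1:14].sum() == 0

    def test_age_encoding_varies_with_age(self):
        a = age_positional_encoding(40.0, 32)
        b = age_positional_encoding(80.0, 32)
        assert not np.allclose(a, b)


class TestOptionalInputContract:
    def test_zeroed_head_gives_half_scores(self, tiny_model, small_cohort):
        patients, _ = small_cohort
        head = tiny_model.classifier.head
        saved_w, saved_b = head.weight.data.copy(), head.bias.data.copy()
        try:
            head.weight.data[:] = 0.0
            head.bias.data[:] = 0.0
            out = tiny_model.predict_patients(patients[:3])
            np.testing.assert_allclose(out["scores"], 0.5, atol=1e-12)
        finally:
            head.weight.data, head.bias.data = saved_w, saved_b

    def test_scores_bounded(self, tiny_model, small_cohort):
        patients, _ = small_cohort
        scores = tiny_model.predict_patients(patients[:4])["scores"]
        assert np.all(scores > 0) and np.all(scores < 1)

    def test_masked_slot_content_ignored_bit_for_bit(self, tiny_model):
        cfg = tiny_model.config
        rng = np.random.default_rng(0)
        stack = rng.normal(size=(1, cfg.stack_slots, cfg.latent_dim))
        mask = np.zeros((1, cfg.stack_slots), dtype=bool)
        mask[0, [0, 14, 15]] = True
        ages = np.array([60.0])
        out1 = tiny_model.classifier(Tensor(stack), mask, ages).data
        stack2 = stack.copy()
        stack2[0, 5] = 1e3   # masked slot
        out2 = tiny_model.classifier(Tensor(stack2), mask, ages).data
        assert out1.tobytes() == out2.tobytes()

    def test_image_order_permutation_invariance(self, tiny_model):
        ages = [55.0, 62.0, 71.0]
        base = make_patient("p0", n_images=3, ages=ages)
        permuted = PatientRecord(
            patient_id="p0", sex=base.sex, ethnicity=base.ethnicity,
            images=[base.images[2], base.images[0], base.images[1]],
            icd_codes=set(), medications=set())
        s1 = tiny_model.predict_patients([base])["scores"]
        s2 = tiny_model.predict_patients([permuted])["scores"]
        np.testing.assert_allclose(s1, s2, atol=1e-5)

    def test_occupied_slot_patterns_exhaustive_at_three_images(self, tiny_model):
        """Outputs depend only on occupied slots: a 1-image patient scores
        identically no matter which latents pad the unused slots."""
        p = make_patient("solo", n_images=1, ages=[60.0])
        ref = tiny_model.predict_patients([p])["scores"]
        for _ in range(3):
            again = tiny_model.predict_patients([p])["scores"]
            np.testing.assert_array_equal(ref, again)


class TestConfoundHeads:
    def test_score_vector_lengths_match_vocab(self, tiny_model, small_cohort):
        patients, _ = small_cohort
        latents, _, _ = tiny_model.encode_images(patients[0].images,
                                                 sample=False)
        scores = tiny_model.confound_heads(latents)
        for cat, logits in scores.items():
            assert logits.shape[-1] == tiny_model.vocab.size(cat)

    def test_attention_rows_normalized(self, tiny_model, small_cohort):
        patients, _ = small_cohort
        tiny_model.encode_images(patients[0].images[:1], sample=False)
        att = tiny_model.encoder.last_patch_attention
        np.testing.assert_allclose(att.sum(axis=-1), 1.0, atol=1e-10)
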