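"""Multi- and optional-input network: 3D ViT encoder, token stack, heads.

One patient contributes 1-14 brain images plus sex and ethnicity. Each
image is encoded by a small 3D vision transformer to a Gaussian latent
(mean and log-variance, VAE-style); text categories are hashed to
stable pseudo-random unit vectors; everything is stacked into a fixed
16-row token array (14 image slots + sex + ethnicity) with sinusoidal
positional encoding of the age at scan added to the image tokens. A
second transformer over the stack, with numeric age appended to the
pooled representation, produces independent per-task probabilities.
Adversarial confound heads read the per-image latents.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from .autodiff import Linear, Module, Tensor, TransformerBlock
from .cohort import (CONFOUND_CATEGORIES, DEFAULT_TASKS, ConfoundVocab,
                     PatientRecord)


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters (defaults match the full-size model)."""

    latent_dim: int = 128
    grid_size: int = 32
    patch_size: int = 8
    vit_width: int = 64
    vit_layers: int = 2
    vit_heads: int = 4
    mlp_ratio: int = 2
    stack_layers: int = 2
    stack_heads: int = 4
    max_images: int = 14
    stack_slots: int = 16          # 14 image slots + sex + ethnicity
    tasks: tuple = DEFAULT_TASKS
    brain_mask_percentile: float = 70.0

    def __post_init__(self):
        if self.grid_size % self.patch_size:
            raise ValueError("grid_size must be a multiple of patch_size")
        if self.stack_slots != self.max_images + 2:
            raise ValueError("stack_slots must equal max_images + 2")

    @property
    def n_patches(self) -> int:
        return (self.grid_size // self.patch_size) ** 3


# -------------------------------------------------------------------------
# Input preparation
# -------------------------------------------------------------------------


def normalize_volume(volume: np.ndarray, config: ModelConfig) -> np.ndarray:
    """Crop/pad to the configured grid and z-normalize within the brain mask.

    The brain mask is taken as the voxels above the configured intensity
    percentile (the phantom/brain occupies the bright minority of the
    field of view); mask mean and SD normalize the whole volume.
    """
    g = config.grid_size
    vol = np.asarray(volume, dtype=np.float64)
    if min(vol.shape) < config.patch_size:
        raise ValueError(
            f"volume shape {vol.shape} smaller than one patch "
            f"({config.patch_size}^3)")
    out = np.zeros((g, g, g))
    # center crop / pad each axis
    src, dst = [], []
    for s in vol.shape:
        if s >= g:
            a = (s - g) // 2
            src.append(slice(a, a + g))
            dst.append(slice(0, g))
        else:
            a = (g - s) // 2
            src.append(slice(0, s))
            dst.append(slice(a, a + s))
    out[tuple(dst)] = vol[tuple(src)]
    mask = out > np.percentile(out, config.brain_mask_percentile)
    mu, sd = out[mask].mean(), out[mask].std()
    return (out - mu) / max(sd, 1e-9)


def volume_to_patches(volume: np.ndarray, config: ModelConfig) -> np.ndarray:
    """(g,g,g) -> (n_patches, patch_size**3), raster patch order."""
    g, p = config.grid_size, config.patch_size
    n = g // p
    v = volume.reshape(n, p, n, p, n, p)
    v = v.transpose(0, 2, 4, 1, 3, 5)
    return v.reshape(n ** 3, p ** 3)


def hash_text_token(category: str, dim: int) -> np.ndarray:
    """Deterministic unit-norm pseudo-random vector for a category string.

    Stable across runs and processes: the category string is hashed with
    SHA-256 to seed the generator.
    """
    digest = hashlib.sha256(category.encode("utf-8")).digest()
    seed = int.from_bytes(digest[:8], "little")
    vec = np.random.default_rng(seed).standard_normal(dim)
    return vec / np.linalg.norm(vec)


def encode_text(category: str, vocabulary, dim: int) -> np.ndarray:
    """Hash a categorical text value from a known vocabulary to a vector."""
    if category not in vocabulary and category != "missing":
        raise ValueError(
            f"category {category!r} not in vocabulary and not 'missing'")
    return hash_text_token(category, dim)


def age_positional_encoding(age_years: float, dim: int) -> np.ndarray:
    """Standard sinusoidal positional encoding with age (years) as position."""
    pe = np.zeros(dim)
    i = np.arange(0, dim, 2)
    div = np.exp(-np.log(10000.0) * i / dim)
    pe[0::2] = np.sin(age_years * div)
    pe[1::2] = np.cos(age_years * div[: len(pe[1::2])])
    return pe


# -------------------------------------------------------------------------
# Networks
# -------------------------------------------------------------------------


class ImageEncoder(Module):
    """3D vision transformer mapping a volume to a Gaussian latent."""

    def __init__(self, config: ModelConfig, rng: np.random.Generator):
        c = config
        self.config = c
        self.patch_embed = Linear(c.patch_size ** 3, c.vit_width, rng)
        self.pos_embed = ad.Parameter(
            rng.normal(0, 0.02, size=(c.n_patches + 1, c.vit_width)))
        self.summary_token = ad.Parameter(np.zeros(c.vit_width))
        self.blocks = [TransformerBlock(c.vit_width, c.vit_heads, c.mlp_ratio, rng)
                       for _ in range(c.vit_layers)]
        self.ln = ad.LayerNorm(c.vit_width)
        self.to_mean = Linear(c.vit_width, c.latent_dim, rng)
        self.to_logvar = Linear(c.vit_width, c.latent_dim, rng, zero_init=True)
        self.last_patch_attention = None   # (B, layers, heads, patches)

    def forward_patches(self, patches: np.ndarray):
        """patches: (B, n_patches, patch_vol) -> (mean, logvar) Tensors."""
        B, P, _ = patches.shape
        x = self.patch_embed(Tensor(patches))               # (B,P,W)
        summary = (self.summary_token
                   .reshape(1, 1, -1) * np.ones((B, 1, 1)))
        x = ad.concat([summary, x], axis=1)                 # (B,P+1,W)
        x = x + self.pos_embed
        per_layer = []
        for blk in self.blocks:
            x = blk(x)
            per_layer.append(blk.attn.last_attention)   # (B, H, T, T)
        # full per-layer attention kept for interpretation (rollout or raw)
        self.last_patch_attention = np.stack(per_layer, axis=1)  # (B,L,H,T,T)
        x = self.ln(x)
        summary_out = x[:, 0, :]
        return self.to_mean(summary_out), self.to_logvar(summary_out)


class ConfoundHeads(Module):
    """One linear categorical head per confound category on image latents."""

    def __init__(self, config: ModelConfig, vocab: ConfoundVocab,
                 rng: np.random.Generator):
        self.heads = {cat: Linear(config.latent_dim, vocab.size(cat), rng)
                      for cat in CONFOUND_CATEGORIES}
        self.vocab = vocab

    def __call__(self, latents: Tensor) -> dict:
        return {cat: head(latents) for cat, head in self.heads.items()}


class StackClassifier(Module):
    """Transformer over the 16-token stack with per-task sigmoid heads."""

    def __init__(self, config: ModelConfig, rng: np.random.Generator):
        c = config
        self.config = c
        d = c.latent_dim
        self.blocks = [TransformerBlock(d, c.stack_heads, c.mlp_ratio, rng)
                       for _ in range(c.stack_layers)]
        self.ln = ad.LayerNorm(d)
        self.head = Linear(d + 1, len(c.tasks), rng)

    def __call__(self, stack: Tensor, slot_mask: np.ndarray,
                 ages: np.ndarray) -> Tensor:
        """stack: (B,16,d); slot_mask: (B,16) bool; ages: (B,) years.

        Returns per-task logits (B, n_tasks); apply ``.sigmoid()`` for
        probabilities.
        """
        bias = np.where(slot_mask, 0.0, -1e9)
        x = stack
        for blk in self.blocks:
            x = blk(x, bias)
        x = self.ln(x)
        # masked mean-pool over occupied slots
        m = slot_mask.astype(np.float64)[..., None]
        pooled = (x * Tensor(m)).sum(axis=1) / Tensor(m.sum(axis=1))
        age_feat = Tensor((ages / 100.0)[:, None])
        return self.head(ad.concat([pooled, age_feat], axis=1))


@dataclass
class TokenStack:
    """Assembled 16 x d token array for one patient (numpy side)."""

    positional: np.ndarray   # (16, d) additive encoding (zeros on text rows)
    slot_mask: np.ndarray    # (16,) bool
    text_tokens: np.ndarray  # (2, d) sex then ethnicity
    ages: np.ndarray         # per image slot, years (NaN when empty)
    image_index: np.ndarray  # indices into the batch latent matrix, -1 empty


def assemble_stack(patient: PatientRecord, image_index: np.ndarray,
                   config: ModelConfig) -> TokenStack:
    """Lay out one patient's slots: images 0-13, sex 14, ethnicity 15."""
    n = len(patient.images)
    if not 1 <= n <= config.max_images:
        raise ValueError(
            f"{patient.patient_id}: needs 1-{config.max_images} images, has {n}")
    d = config.latent_dim
    slots = config.stack_slots
    positional = np.zeros((slots, d))
    mask = np.zeros(slots, dtype=bool)
    ages = np.full(slots - 2, np.nan)
    index = np.full(slots - 2, -1, dtype=np.int64)
    for k, image in enumerate(patient.images):
        positional[k] = age_positional_encoding(image.age_at_scan, d)
        ages[k] = image.age_at_scan
        index[k] = image_index[k]
        mask[k] = True
    mask[slots - 2:] = True   # text slots always occupied
    sex_tok = encode_text(patient.sex, {"M", "F"}, d)
    eth_tok = encode_text(patient.ethnicity,
                          {"hispanic", "non_hispanic", "missing"}, d)
    return TokenStack(positional=positional, slot_mask=mask,
                      text_tokens=np.stack([sex_tok, eth_tok]),
                      ages=ages, image_index=index)


class DementiaNet(Module):
    """Full model: image encoder + confound heads + stack classifier.

    The confound heads are the adversarial discriminators; their
    parameters are disjoint from the encoder/classifier set and the two
    sets are alternately frozen during training.
    """

    def __init__(self, config: ModelConfig, vocab: ConfoundVocab, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.config = config
        self.vocab = vocab
        self.encoder = ImageEncoder(config, rng)
        self.confound_heads = ConfoundHeads(config, vocab, rng)
        self.classifier = StackClassifier(config, rng)

    # parameter partitions for alternating optimization
    def encoder_parameters(self):
        return self.encoder.parameters() + self.classifier.parameters()

    def discriminator_parameters(self):
        return self.confound_heads.parameters()

    # ---- forward passes --------------------------------------------------
    def encode_images(self, images, sample: bool = False,
                      rng: np.random.Generator | None = None):
        """Encode a list of ImageRecords to latents.

        Returns ``(latents, mean, logvar)`` Tensors of shape (B, d).
        At inference (``sample=False``) the latent is the mean,
        deterministically; in training a reparameterized sample.
        """
        patches = np.stack([
            volume_to_patches(normalize_volume(im.volume, self.config),
                              self.config)
            for im in images])
        mean, logvar = self.encoder.forward_patches(patches)
        if sample:
            if rng is None:
                raise ValueError("sampling requires an rng")
            eps = rng.standard_normal(mean.shape)
            latents = mean + (logvar * 0.5).exp() * Tensor(eps)
        else:
            latents = mean
        return latents, mean, logvar

    def forward_patients(self, patients, latents: Tensor,
                         stacks: list) -> Tensor:
        """Assemble per-patient stacks from batch latents; return logits."""
        d = self.config.latent_dim
        rows = []
        masks, ages = [], []
        for patient, st in zip(patients, stacks):
            occupied = st.image_index[st.image_index >= 0]
            img_tok = latents[occupied] + Tensor(st.positional[: len(occupied)])
            pad = Tensor(np.zeros((self.config.max_images - len(occupied), d)))
            stack_t = ad.concat([img_tok, pad, Tensor(st.text_tokens)], axis=0)
            rows.append(stack_t)
            masks.append(st.slot_mask)
            ages.append(np.nanmean(st.ages))
        batch = ad.stack(rows, axis=0)
        return self.classifier(batch, np.stack(masks), np.asarray(ages))

    def encode_images_batched(self, images, batch: int = 64,
                              keep_attention: bool = False):
        """Inference-mode encoding in chunks (bounds tape memory).

        Returns ``(latents, attention)`` numpy arrays of shape (B, d)
        and (B, layers, heads, T, T); attention is None unless
        requested.
        """
        lat = np.empty((len(images), self.config.latent_dim))
        atts = [] if keep_attention else None
        for start in range(0, len(images), batch):
            chunk = images[start:start + batch]
            latents, _, _ = self.encode_images(chunk, sample=False)
            lat[start:start + len(chunk)] = latents.data
            if keep_attention:
                atts.append(self.encoder.last_patch_attention)
        attention = np.concatenate(atts) if keep_attention else None
        return lat, attention

    def predict_patients(self, patients, keep_attention: bool = False) -> dict:
        """Inference: per-task probabilities and per-image latents.

        Returns a dict with ``scores`` (n_patients, n_tasks) numpy array,
        ``latents`` (n_images, d) and ``image_owner`` (patient index per
        image row).
        """
        images, owner = [], []
        for i, p in enumerate(patients):
            for im in p.images:
                images.append(im)
                owner.append(i)
        lat, attention = self.encode_images_batched(
            images, keep_attention=keep_attention)
        stacks, cursor = [], 0
        for p in patients:
            idx = np.arange(cursor, cursor + len(p.images))
            stacks.append(assemble_stack(p, idx, self.config))
            cursor += len(p.images)
        logits = self.forward_patients(patients, Tensor(lat), stacks)
        scores = 1.0 / (1.0 + np.exp(-logits.data))
        return {"scores": scores, "latents": lat,
                "image_owner": np.asarray(owner),
                "patch_attention": attention}
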