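"""GAN-style alternating training with age-matched resampling.

Each step draws an age-matched batch (equal case/control counts, the
controls resampled from the cases' age bins so the heavy age imbalance
between dementia cases and controls cannot drive the classifier), then
alternates:

1. a discriminator step — the confound heads learn to predict the true
   confound values from *detached* image latents;
2. an encoder/classifier step — task cross-entropy, the adversarial
   loss pushing the (frozen) confound heads toward the modal confound
   value, the latent cluster/de-cluster loss, and the KL term.

No patient is ever excluded by matching: batches are resampled with
replacement throughout training, so atypically aged patients are simply
rarer, not absent.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .autodiff import Adam
from .cohort import CONFOUND_CATEGORIES, ConfoundVocab, build_confound_vocab
from .confidence import BankEntry, LatentBank
from .encoder import DementiaNet, ModelConfig, assemble_stack
from .objectives import (LossBreakdown, LossWeights, adversarial_encoder_loss,
                         classification_loss, cluster_loss, discriminator_loss,
                         kl_loss)

CHECKPOINT_VERSION = 1


@dataclass
class TrainConfig:
    steps: int = 300
    batch_size: int = 8
    lr_encoder: float = 1e-3
    lr_discriminator: float = 1e-3
    disc_steps_per_encoder_step: int = 1
    decluster_scale: float = 8.0   # confound de-cluster term, relative to cluster weight
    adversarial_warmup_steps: int = 0   # task-only steps before the game starts
    age_bin_width: float = 10.0
    seed: int = 0
    loss_weights: LossWeights = field(default_factory=LossWeights)
    tasks: tuple | None = None     # None = every task with >= 2 cases
    adversarial: bool = True       # ablation switch for the adversarial term
    log_every: int = 10


def sample_age_matched_batch(cohort, task: str, batch_size: int,
                             bin_width: float, rng: np.random.Generator):
    """Draw an equal case/control batch, controls matched to case age bins.

    Cases are sampled with replacement; each control is drawn from the
    same age bin (floor(age / bin_width)) as a sampled case, falling
    back to the nearest occupied bin when a bin holds no controls.
    """
    pool = [p for p in cohort if not p.labels.excluded]
    cases = [p for p in pool if p.labels[task] == 1]
    controls = [p for p in pool if p.labels[task] == 0]
    if len(cases) < 2:
        raise ValueError(f"task {task!r} has {len(cases)} cases; need >= 2")
    if not controls:
        raise ValueError(f"task {task!r} has no controls")

    def patient_age(p):
        return float(np.mean([im.age_at_scan for im in p.images]))

    control_bins: dict = {}
    for p in controls:
        control_bins.setdefault(int(patient_age(p) // bin_width), []).append(p)
    bins_avail = np.array(sorted(control_bins))

    half = max(batch_size // 2, 1)
    picked_cases = [cases[i] for i in rng.integers(len(cases), size=half)]
    picked_controls = []
    for case in picked_cases:
        b = int(patient_age(case) // bin_width)
        if b not in control_bins:
            b = int(bins_avail[np.argmin(np.abs(bins_avail - b))])
        group = control_bins[b]
        picked_controls.append(group[rng.integers(len(group))])
    batch = picked_cases + picked_controls
    order = rng.permutation(len(batch))
    return [batch[i] for i in order]


def _trainable_tasks(cohort, model_tasks) -> list:
    pool = [p for p in cohort if not p.labels.excluded]
    tasks = []
    for task in model_tasks:
        n_cases = sum(p.labels[task] for p in pool)
        if n_cases >= 2 and n_cases < len(pool):
            tasks.append(task)
    return tasks


@dataclass
class Checkpoint:
    """Self-describing training artifact: weights, vocab, config, bank."""

    model_config: ModelConfig
    train_config: TrainConfig
    vocab: ConfoundVocab
    arrays: list
    latent_bank: "LatentBank | None" = None
    version: int = CHECKPOINT_VERSION

    def build_model(self) -> DementiaNet:
        model = DementiaNet(self.model_config, self.vocab, seed=0)
        model.load_state_arrays(self.arrays)
        return model

    def config_hash(self) -> str:
        blob = json.dumps(
            {"model": dataclasses.asdict(self.model_config),
             "train": dataclasses.asdict(self.train_config)},
            sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    def save(self, path) -> Path:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        meta = {
            "version": self.version,
            "config_hash": self.config_hash(),
            "model_config": dataclasses.asdict(self.model_config),
            "train_config": dataclasses.asdict(self.train_config),
            "vocab": {"vocab": {k: list(v) for k, v in self.vocab.vocab.items()},
                      "modal": self.vocab.modal,
                      "counts": {k: dict(v) for k, v in self.vocab.counts.items()}},
            "n_arrays": len(self.arrays),
        }
        (path / "checkpoint.json").write_text(json.dumps(meta, indent=2,
                                                         default=str))
        payload = {f"arr_{i}": a for i, a in enumerate(self.arrays)}
        if self.latent_bank is not None:
            for (task, lab), entry in self.latent_bank.entries.items():
                key = f"bank_{task}_{lab}"
                payload[f"{key}_mean"] = entry.mean
                payload[f"{key}_cov"] = entry.cov
                payload[f"{key}_count"] = np.array(entry.count)
        np.savez(path / "weights.npz", **payload)
        return path

    @classmethod
    def load(cls, path) -> "Checkpoint":
        from collections import Counter

        path = Path(path)
        meta = json.loads((path / "checkpoint.json").read_text())
        if meta["version"] != CHECKPOINT_VERSION:
            raise ValueError(f"unsupported checkpoint version {meta['version']}")
        mc = dict(meta["model_config"])
        mc["tasks"] = tuple(mc["tasks"])
        model_config = ModelConfig(**mc)
        tc = dict(meta["train_config"])
        tc["loss_weights"] = LossWeights(**tc["loss_weights"])
        if tc.get("tasks") is not None:
            tc["tasks"] = tuple(tc["tasks"])
        train_config = TrainConfig(**tc)
        vocab = ConfoundVocab(
            vocab={k: tuple(v) for k, v in meta["vocab"]["vocab"].items()},
            modal=meta["vocab"]["modal"],
            counts={k: Counter(v) for k, v in meta["vocab"]["counts"].items()})
        with np.load(path / "weights.npz") as z:
            arrays = [z[f"arr_{i}"] for i in range(meta["n_arrays"])]
            entries = {}
            for key in z.files:
                if key.startswith("bank_") and key.endswith("_mean"):
                    stem = key[len("bank_"):-len("_mean")]
                    task, lab = stem.rsplit("_", 1)
                    entries[(task, int(lab))] = BankEntry(
                        mean=z[f"bank_{stem}_mean"],
                        cov=z[f"bank_{stem}_cov"],
                        count=int(z[f"bank_{stem}_count"]))
        bank = LatentBank(entries) if entries else None
        return cls(model_config=model_config, train_config=train_config,
                   vocab=vocab, arrays=arrays, latent_bank=bank)


def train(cohort, model_config: ModelConfig | None = None,
          train_config: TrainConfig | None = None,
          vocab: ConfoundVocab | None = None):
    """Train the model on a cohort; returns (Checkpoint, log DataFrame)."""
    mc = model_config or ModelConfig()
    tc = train_config or TrainConfig()
    rng = np.random.default_rng(tc.seed)
    vocab = vocab or build_confound_vocab(cohort)
    model = DementiaNet(mc, vocab, seed=tc.seed)

    opt_enc = Adam(model.encoder_parameters(), lr=tc.lr_encoder)
    opt_disc = Adam(model.discriminator_parameters(), lr=tc.lr_discriminator)

    tasks = list(tc.tasks) if tc.tasks else _trainable_tasks(cohort, mc.tasks)
    if not tasks:
        raise ValueError("no trainable task has both classes in the cohort")
    task_index = {t: i for i, t in enumerate(mc.tasks)}

    log_rows = []
    last_good = [p.data.copy() for p in model.parameters()]
    for step in range(tc.steps):
        task = tasks[step % len(tasks)]
        batch = sample_age_matched_batch(cohort, task, tc.batch_size,
                                         tc.age_bin_width, rng)
        images, owner, true_confounds = [], [], []
        for i, p in enumerate(batch):
            for im in p.images:
                images.append(im)
                owner.append(i)
                true_confounds.append(im.confounds(p.sex))
        stacks, cursor = [], 0
        for p in batch:
            idx = np.arange(cursor, cursor + len(p.images))
            stacks.append(assemble_stack(p, idx, mc))
            cursor += len(p.images)

        # ---- (i) discriminator step(s): detached latents, true targets
        disc_val = np.nan
        for _ in range(tc.disc_steps_per_encoder_step):
            latents, _, _ = model.encode_images(images, sample=False)
            detached = latents.detach()
            scores = model.confound_heads(detached)
            d_loss = discriminator_loss(scores, vocab, true_confounds)
            opt_disc.zero_grad()
            model.encoder.zero_grad()
            d_loss.backward()
            opt_disc.step()
            disc_val = float(d_loss.data)

        # ---- (ii) encoder/classifier step
        latents, mean, logvar = model.encode_images(images, sample=True, rng=rng)
        logits = model.forward_patients(batch, latents, stacks)
        probs = logits.sigmoid()
        y = np.array([[p.labels[t] for t in mc.tasks] for p in batch],
                     dtype=np.float64)
        task_mask = np.zeros_like(y, dtype=bool)
        for t in tasks:
            task_mask[:, task_index[t]] = True
        cls = classification_loss(probs, y, task_mask)

        # masking terms act on the deterministic mean latents — the
        # representation probes and the confidence measure see at test
        # time; the sampled path feeds classification and KL only
        conf_scores = model.confound_heads(mean)
        adv = adversarial_encoder_loss(conf_scores, vocab, true_confounds)

        # cluster/de-cluster on per-image latents. Label clustering acts
        # on the sampled latents (the reparameterization noise keeps it
        # from collapsing the representation); confound de-clustering —
        # part of the masking scheme, disabled with the adversarial term
        # in ablations — acts on the mean latents, merging each
        # confound category's group means in the representation used at
        # test time.
        img_labels = np.array([batch[o].labels[task] for o in owner])
        clu = cluster_loss(latents, img_labels, None)
        masking_on = tc.adversarial and step >= tc.adversarial_warmup_steps
        if masking_on:
            img_confs = {cat: np.array([c[cat] for c in true_confounds])
                         for cat in CONFOUND_CATEGORIES}
            # de-cluster within each label group: merging confound means
            # across labels would fight the task separation (confounds
            # correlate with the label by construction), so the term
            # targets only within-class confound structure
            for g in np.unique(img_labels):
                idx = np.flatnonzero(img_labels == g)
                if len(idx) < 2:
                    continue
                sub_confs = {cat: v[idx] for cat, v in img_confs.items()}
                clu = clu + cluster_loss(mean[idx], np.zeros(len(idx)),
                                         sub_confs) * tc.decluster_scale
        kl = kl_loss(mean, logvar)

        w = tc.loss_weights
        total = (cls * w.classification + clu * w.cluster + kl * w.kl)
        if masking_on:
            total = total + adv * w.adversarial
        opt_enc.zero_grad()
        opt_disc.zero_grad()
        total.backward()
        opt_enc.step()

        breakdown = LossBreakdown(
            classification=float(cls.data),
            adversarial=float(adv.data) if tc.adversarial else 0.0,
            cluster=float(clu.data), kl=float(kl.data), weights=w)
        if not np.isfinite(breakdown.total):
            # abort with the last good parameters
            checkpoint = Checkpoint(mc, tc, vocab, last_good)
            log = pd.DataFrame(log_rows)
            log.attrs["diverged_at_step"] = step
            return checkpoint, log
        last_good = [p.data.copy() for p in model.parameters()]
        log_rows.append({
            "step": step, "task": task,
            "classification": breakdown.classification,
            "adversarial": breakdown.adversarial,
            "discriminator": disc_val,
            "cluster": breakdown.cluster, "kl": breakdown.kl,
            "total": breakdown.total})

    checkpoint = Checkpoint(mc, tc, vocab,
                            [p.data.copy() for p in model.parameters()])
    return checkpoint, pd.DataFrame(log_rows)


def build_latent_bank(model: DementiaNet, cohort, tasks=None,
                      ridge_scale: float = 1e-3,
                      batch_images: int = 64) -> LatentBank:
    """Per task-label mean and ridge-regularized covariance of latents.

    For each task and each label value the bank stores the mean (length
    d) and covariance (d x d) of the training images' latent means,
    regularized as S + eps*I with eps = ridge_scale * trace(S)/d. Labels
    with fewer than d/4 images get a 10x harder shrink (and a warning).
    """
    import warnings

    mc = model.config
    tasks = tasks or _trainable_tasks(cohort, mc.tasks)
    pool = [p for p in cohort if not p.labels.excluded]
    images, patient_of = [], []
    for p in pool:
        for im in p.images:
            images.append(im)
            patient_of.append(p)
    lat, _ = model.encode_images_batched(images, batch=batch_images)
    entries = {}
    for task in tasks:
        labels = np.array([p.labels[task] for p in patient_of])
        for value in (0, 1):
            sel = lat[labels == value]
            if len(sel) == 0:
                continue
            mu = sel.mean(axis=0)
            cov = np.cov(sel, rowvar=False) if len(sel) > 1 else np.zeros(
                (mc.latent_dim, mc.latent_dim))
            scale = ridge_scale
            if len(sel) < mc.latent_dim / 4:
                warnings.warn(
                    f"latent bank for ({task}, {value}) has only {len(sel)} "
                    f"images (< d/4); covariance shrunk harder")
                scale *= 10
            eps = scale * max(np.trace(cov), 1e-8) / mc.latent_dim
            entries[(task, value)] = BankEntry(
                mean=mu, cov=cov + eps * np.eye(mc.latent_dim), count=len(sel))
    return LatentBank(entries)
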