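"""Training objectives: classification, adversarial masking, clustering, KL.

Four losses drive training. The classifier minimizes binary
cross-entropy on the disease tasks. The confound discriminators are
trained (on detached latents) to predict the true confound values,
while the encoder is trained adversarially against the *modal* value of
each confound — pushing, say, CT and PET latents to look like the
majority MR modality. A latent cluster/de-cluster term pulls same-label
latents together and pushes same-confound latents apart, and a KL term
against the standard normal keeps the latent distribution Gaussian,
VAE-style, which stabilizes the Mahalanobis confidence measure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor

EPS = 1e-7


@dataclass
class LossWeights:
    classification: float = 1.0
    adversarial: float = 1.0
    cluster: float = 0.1
    kl: float = 0.001


@dataclass
class LossBreakdown:
    classification: float
    adversarial: float
    cluster: float
    kl: float
    weights: LossWeights

    @property
    def total(self) -> float:
        w = self.weights
        return (w.classification * self.classification
                + w.adversarial * self.adversarial
                + w.cluster * self.cluster + w.kl * self.kl)


def _clamp_probs(p: Tensor) -> Tensor:
    # epsilon-clamp via affine squeeze keeps gradients defined at 0/1
    return p * (1 - 2 * EPS) + EPS


def classification_loss(task_scores: Tensor, labels: np.ndarray,
                        task_mask: np.ndarray | None = None) -> Tensor:
    """Mean binary cross-entropy over configured tasks.

    ``task_scores``: (B, T) probabilities; ``labels``: (B, T) in {0,1};
    ``task_mask``: (B, T) bool, False entries (e.g. excluded patients)
    are skipped.
    """
    p = _clamp_probs(task_scores)
    y = np.asarray(labels, dtype=np.float64)
    ll = Tensor(y) * p.log() + Tensor(1 - y) * (1 - p).log()
    if task_mask is None:
        return -ll.mean()
    m = np.asarray(task_mask, dtype=np.float64)
    return -(ll * Tensor(m)).sum() / max(m.sum(), 1.0)


def cross_entropy(logits: Tensor, target_index: np.ndarray) -> Tensor:
    """Mean categorical cross-entropy from logits; integer targets."""
    logp = logits.softmax(axis=-1).log()
    n = logits.shape[0]
    picked = logp[np.arange(n), np.asarray(target_index, dtype=np.int64)]
    return -picked.mean()


def adversarial_encoder_loss(confound_scores: dict, vocab,
                             confound_values: list) -> Tensor:
    """Encoder-side adversarial loss: push heads toward the modal value.

    ``confound_scores``: category -> (B, k) logits from the (frozen)
    confound heads on non-detached latents; targets are the training
    set's most frequent value per category, not the true one.
    """
    terms = []
    n = next(iter(confound_scores.values())).shape[0]
    for cat, logits in confound_scores.items():
        modal_idx = vocab.index(cat, vocab.modal[cat])
        target = np.full(n, modal_idx)
        terms.append(cross_entropy(logits, target))
    total = terms[0]
    for t in terms[1:]:
        total = total + t
    return total * (1.0 / len(terms))


def discriminator_loss(confound_scores: dict, vocab,
                       confound_values: list) -> Tensor:
    """Discriminator-side loss: predict the true confound values.

    ``confound_values``: per image, the dict of true category values
    (latents must be detached upstream so encoder parameters are
    untouched by this loss).
    """
    terms = []
    for cat, logits in confound_scores.items():
        target = np.array([vocab.index(cat, cv[cat]) for cv in confound_values])
        terms.append(cross_entropy(logits, target))
    total = terms[0]
    for t in terms[1:]:
        total = total + t
    return total * (1.0 / len(terms))


def _norm(x: Tensor) -> Tensor:
    return ((x * x).sum() + 1e-12) ** 0.5


def _group_means(latents: Tensor, values: np.ndarray) -> dict:
    means = {}
    for u in sorted(set(values.tolist())):
        idx = np.flatnonzero(values == u)
        means[u] = latents[idx].mean(axis=0)
    return means


def cluster_loss(latents: Tensor, labels: np.ndarray,
                 confounds: np.ndarray | dict | None) -> Tensor:
    """Latent cluster/de-cluster loss over one batch.

    For each latent I with label l and confound value c:

        ||I - mu_{L=l}|| - ||I - mu_{L!=l}|| + ||I - mu_{C!=c}|| - ||I - mu_{C=c}||

    where mu_{L=l} is the batch mean latent of the same label,
    mu_{L!=l} the unweighted mean of the other label groups' means, and
    symmetrically for the confound value: minimizing the loss pulls
    same-label points together and each point toward the *other*
    confound groups' means, merging confound clusters.

    ``confounds`` may be one value per latent, a dict mapping category
    name -> per-latent values (the confound term is then averaged over
    categories), or None (label terms only). Batches with a single
    label (or a single value in a confound category) drop the
    corresponding pair of terms.
    """
    labels = np.asarray(labels)
    n = latents.shape[0]
    if confounds is None:
        conf_cats = {}
    elif isinstance(confounds, dict):
        conf_cats = {k: np.asarray(v) for k, v in confounds.items()}
    else:
        conf_cats = {"confound": np.asarray(confounds)}

    label_means = _group_means(latents, labels)
    conf_means = {cat: _group_means(latents, vals)
                  for cat, vals in conf_cats.items()}
    active_cats = [cat for cat, m in conf_means.items() if len(m) >= 2]
    total = Tensor(0.0)
    for i in range(n):
        total = total + cluster_loss_point(
            latents[i], labels[i], None, label_means, {})
        for cat in active_cats:
            term = cluster_loss_point(latents[i], None, conf_cats[cat][i],
                                      {}, conf_means[cat])
            total = total + term * (1.0 / len(active_cats))
    return total * (1.0 / n)


def cluster_loss_point(latent: Tensor, label, confound,
                       label_means: dict, conf_means: dict) -> Tensor:
    """One point's cluster/de-cluster contribution given group means.

    ``label_means``/``conf_means`` map group value -> mean latent
    (Tensor or array). Groups with fewer than two distinct values
    contribute zero (nothing to cluster against).
    """
    I = latent if isinstance(latent, Tensor) else Tensor(latent)
    total = Tensor(0.0)
    if len(label_means) >= 2:
        same = _norm(I - _as_tensor(label_means[label]))
        others = [_norm(I - _as_tensor(m))
                  for u, m in label_means.items() if u != label]
        total = total + same - _mean_of(others)
    if len(conf_means) >= 2:
        same_c = _norm(I - _as_tensor(conf_means[confound]))
        others = [_norm(I - _as_tensor(m))
                  for u, m in conf_means.items() if u != confound]
        total = total + _mean_of(others) - same_c
    return total


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _mean_of(terms: list) -> Tensor:
    total = terms[0]
    for t in terms[1:]:
        total = total + t
    return total * (1.0 / len(terms))


def kl_loss(mean: Tensor, log_variance: Tensor) -> Tensor:
    """KL( N(mean, diag var) || N(0, I) ), averaged over the batch.

    Closed form: 0.5 * sum(var + mean^2 - 1 - log var) per sample.
    """
    var = log_variance.exp()
    per = (var + mean * mean - 1.0 - log_variance).sum(axis=-1) * 0.5
    if per.ndim == 0:
        return per
    return per.mean()
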