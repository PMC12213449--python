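"""Mahalanobis confidence and in/out-of-distribution filtering.

At test time each image's latent is compared with the stored
distribution of training latents for its predicted label: the raw
confidence is the quadratic form (I - mu)^T S^-1 (I - mu), where mu and
S are the per-label mean and (ridge-regularized) covariance held in the
latent bank. The thresholded quantity is the per-dimension mean
(raw / d), which keeps the default cutoff of 1.2 independent of the
latent width; images above the cutoff are flagged out-of-distribution
and can be excluded from evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

DEFAULT_THRESHOLD = 1.2


@dataclass
class BankEntry:
    mean: np.ndarray    # (d,)
    cov: np.ndarray     # (d, d), symmetric positive-definite after ridge
    count: int

    def __post_init__(self):
        self.mean = np.asarray(self.mean, dtype=np.float64)
        self.cov = np.asarray(self.cov, dtype=np.float64)
        if self.cov.shape != (self.mean.size, self.mean.size):
            raise ValueError(
                f"covariance shape {self.cov.shape} does not match mean "
                f"length {self.mean.size}")
        if not np.allclose(self.cov, self.cov.T, atol=1e-8):
            raise ValueError("covariance must be symmetric")


@dataclass
class LatentBank:
    """Per (task, label-value) latent statistics from the training set."""

    entries: dict   # (task, 0/1) -> BankEntry

    def entry(self, task: str, label: int) -> BankEntry:
        return self.entries[(task, int(label))]

    @property
    def dim(self) -> int:
        return next(iter(self.entries.values())).mean.size


@dataclass
class ConfidenceResult:
    image_id: str
    raw_distance: float
    normalized_distance: float
    in_distribution: bool


def mahalanobis_confidence(latent: np.ndarray, entry: BankEntry,
                           threshold: float = DEFAULT_THRESHOLD,
                           image_id: str = "") -> ConfidenceResult:
    """Squared Mahalanobis distance of a latent from a bank entry.

    raw = (I - mu)^T S^-1 (I - mu); normalized = raw / d. The image is
    in-distribution iff normalized <= threshold.
    """
    latent = np.asarray(latent, dtype=np.float64)
    if latent.shape != entry.mean.shape:
        raise ValueError(
            f"latent dimension {latent.shape} does not match bank entry "
            f"dimension {entry.mean.shape}")
    delta = latent - entry.mean
    try:
        solved = np.linalg.solve(entry.cov, delta)
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(
            "singular covariance: regularize the latent bank (ridge S + eps*I) "
            "before computing Mahalanobis confidence") from err
    raw = float(delta @ solved)
    norm = raw / latent.size
    return ConfidenceResult(image_id=image_id, raw_distance=raw,
                            normalized_distance=norm,
                            in_distribution=bool(norm <= threshold))


def confidence_for_images(latents: np.ndarray, image_ids, bank: LatentBank,
                          task: str, predicted_labels,
                          threshold: float = DEFAULT_THRESHOLD) -> list:
    """Per-image confidence against the bank of each predicted label."""
    out = []
    for lat, iid, lab in zip(latents, image_ids, predicted_labels):
        out.append(mahalanobis_confidence(
            lat, bank.entry(task, int(lab)), threshold, image_id=str(iid)))
    return out


def filter_by_confidence(results, threshold: float = DEFAULT_THRESHOLD):
    """Partition confidence results into (in_distribution, out_of_distribution).

    The partition is stable (input order preserved) and re-derived from
    the normalized distances at the given threshold.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    in_dist = [r for r in results if r.normalized_distance <= threshold]
    out_dist = [r for r in results if r.normalized_distance > threshold]
    return in_dist, out_dist
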