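"""Attention-map aggregation over a parcellation.

The vision transformer's summary token attends over image patches; its
attention weights indicate where the model looked when encoding an
image. Per image, the patch weights (raw last-layer attention averaged
over heads, or attention rollout through all layers) are upsampled to
voxel resolution by nearest-patch assignment and z-scored within the
brain mask. Per disease, at least ``min_samples`` such volumes are
averaged within each parcel of the aligned parcellation; parcels whose
mean z-score is at least one standard deviation above average
(mean z >= 1, the 68th percentile) are flagged as foci.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .encoder import ModelConfig, normalize_volume

DEFAULT_MIN_SAMPLES = 20
FLAG_Z = 1.0


@dataclass
class AttentionVolume:
    zscores: np.ndarray       # voxel grid of attention z-scores
    brain_mask: np.ndarray    # bool grid; z-scores are mean 0 / SD 1 inside
    image_id: str = ""
    trained: bool = True      # False marks attention from an untrained model


def patch_weights_from_attention(patch_attention: np.ndarray,
                                 rollout: bool = False) -> np.ndarray:
    """Reduce stored per-layer, per-head attention to one weight per patch.

    ``patch_attention``: (layers, heads, T, T) softmax weights for one
    image, token 0 being the summary token. Raw mode returns the last
    layer's summary-token row averaged over heads; rollout multiplies
    the head-averaged, residual-corrected attention matrices through
    the layers first.
    """
    att = np.asarray(patch_attention)
    if att.ndim != 4:
        raise ValueError("expected (layers, heads, T, T) attention")
    layer_mats = att.mean(axis=1)                    # (L, T, T)
    if rollout:
        T = layer_mats.shape[-1]
        result = np.eye(T)
        for mat in layer_mats:
            aug = 0.5 * mat + 0.5 * np.eye(T)
            aug = aug / aug.sum(axis=-1, keepdims=True)
            result = aug @ result
        weights = result[0, 1:]
    else:
        weights = layer_mats[-1, 0, 1:]
    total = weights.sum()
    return weights / total if total > 0 else weights


def attention_to_volume(patch_attention: np.ndarray, volume: np.ndarray,
                        config: ModelConfig, rollout: bool = False,
                        image_id: str = "", trained: bool = True
                        ) -> AttentionVolume:
    """Upsample patch attention to voxels and z-score within the brain mask."""
    weights = patch_weights_from_attention(patch_attention, rollout=rollout)
    g, p = config.grid_size, config.patch_size
    n = g // p
    if weights.size != n ** 3:
        raise ValueError(
            f"{weights.size} patch weights do not tile a {g}^3 grid with "
            f"patch {p}^3")
    grid = weights.reshape(n, n, n)
    vox = np.repeat(np.repeat(np.repeat(grid, p, 0), p, 1), p, 2)
    norm = normalize_volume(volume, config)
    mask = norm > np.percentile(norm, config.brain_mask_percentile)
    inside = vox[mask]
    z = (vox - inside.mean()) / max(inside.std(), 1e-12)
    return AttentionVolume(zscores=z, brain_mask=mask, image_id=image_id,
                           trained=trained)


def aggregate_parcels(attention_volumes, parcellations,
                      min_samples: int = DEFAULT_MIN_SAMPLES,
                      flag_z: float = FLAG_Z) -> pd.DataFrame:
    """Average per-image parcel attention z-scores across a disease group.

    ``attention_volumes``: AttentionVolume list (>= min_samples);
    ``parcellations``: aligned integer label grids, one per volume.
    Returns a DataFrame (parcel_id, mean_z, n_images, flagged) sorted by
    mean_z descending; parcels are flagged when mean_z >= flag_z.
    """
    volumes = list(attention_volumes)
    parcs = list(parcellations)
    if len(volumes) != len(parcs):
        raise ValueError("one parcellation per attention volume required")
    if len(volumes) < min_samples:
        raise ValueError(
            f"need at least {min_samples} samples, got {len(volumes)}")
    per_image: dict = {}
    for av, parc in zip(volumes, parcs):
        parc = np.asarray(parc)
        if parc.shape != av.zscores.shape:
            raise ValueError("parcellation shape does not match attention grid")
        for pid in np.unique(parc):
            if pid == 0:
                continue
            sel = parc == pid
            per_image.setdefault(int(pid), []).append(
                float(av.zscores[sel].mean()))
    rows = []
    for pid, values in per_image.items():
        mean_z = float(np.mean(values))
        rows.append({"parcel_id": pid, "mean_z": mean_z,
                     "n_images": len(values),
                     "flagged": bool(mean_z >= flag_z)})
    report = pd.DataFrame(rows).sort_values(
        "mean_z", ascending=False, ignore_index=True)
    return report
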