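import numpy as np
import pytest

from dementnet.cohort import ImageRecord, PatientRecord, build_confound_vocab
from dementnet.encoder import DementiaNet, ModelConfig
from dementnet.synthetic import generate_cohort


def tiny_model_config(**overrides) -> ModelConfig:
    """A deliberately small geometry for fast unit tests."""
    defaults = dict(latent_dim=16, grid_size=16, patch_size=8, vit_width=16,
                    vit_layers=1, vit_heads=2, mlp_ratio=2, stack_layers=1,
                    stack_heads=2, tasks=("dementia", "G30"))
    defaults.update(overrides)
    return ModelConfig(**defaults)


def make_image(image_id="im0", patient_id="p0", shape=(16, 16, 16),
               seed=0, **kw):
    rng = np.random.default_rng(seed)
    vol = rng.normal(0.3, 0.1, size=shape)
    vol[4:12, 4:12, 4:12] += 1.0   # a bright "brain" so masking is stable
    return ImageRecord(image_id=image_id, patient_id=patient_id, volume=vol,
                       **kw)


def make_patient(patient_id="p0", n_images=2, sex="F", ethnicity="non_hispanic",
                 codes=frozenset(), meds=frozenset(), seed=0, ages=None):
    images = [make_image(f"{patient_id}_im{j}", patient_id, seed=seed * 100 + j,
                         age_at_scan=(ages[j] if ages else 60.0 + j))
              for j in range(n_images)]
    return PatientRecord(patient_id=patient_id, sex=sex, ethnicity=ethnicity,
                         images=images, icd_codes=set(codes),
                         medications=set(meds))


@pytest.fixture(scope="session")
def small_cohort():
    patients, truth = generate_cohort(20, seed=42)
    return patients, truth


@pytest.fixture(scope="session")
def tiny_model(small_cohort):
    patients, _ = small_cohort
    config = tiny_model_config(grid_size=32)
    vocab = build_confound_vocab(patients)
    return DementiaNet(config, vocab, seed=0)
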