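"""Seeded multi-site phantom cohorts with planted biomarkers and confounds.

The generator renders small 3D "brain" phantoms — an outer brain
ellipsoid containing labeled subregion analogs (ventricle, hippocampus,
caudate, brainstem, cortex shell) — and plants three kinds of structure:

* disease effects: per-task scaling of subregion radii and intensity
  shifts (e.g. hippocampus-analog shrinkage with ventricle-analog
  enlargement for the dementia label);
* confound signatures: modality-specific intensity transfer curves and
  noise, per-site smooth multiplicative bias fields, sex/age size
  effects, and a configurable contingency between modality/site and the
  disease label;
* comorbidity codes with controlled odds ratios against the disease
  label.

Every image carries its aligned ground-truth parcellation, so planted
effect sizes are recoverable from the rendered volumes by direct parcel
measurement. All randomness flows from a single integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .cohort import ImageRecord, PatientRecord

PARCEL_NAMES = ("ventricle_analog", "hippocampus_analog", "caudate_analog",
                "brainstem_analog", "cortex_shell")


@dataclass(frozen=True)
class Parcel:
    parcel_id: int
    name: str
    center: tuple
    radii: tuple
    base_intensity: float


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry of the phantom: brain ellipsoid plus subregion analogs."""

    grid_size: int = 32
    brain_center: tuple = (16.0, 16.0, 16.0)
    brain_radii: tuple = (14.0, 12.5, 11.5)
    cortex_shell_fraction: float = 0.82  # inner boundary of the shell
    tissue_intensity: float = 0.5
    parcels: tuple = (
        Parcel(1, "ventricle_analog", (16.0, 16.0, 17.0), (3.5, 2.6, 3.0), 0.10),
        Parcel(2, "hippocampus_analog", (10.0, 19.0, 13.0), (3.2, 2.6, 2.6), 0.85),
        Parcel(3, "caudate_analog", (22.0, 13.0, 15.0), (2.6, 2.2, 2.6), 0.70),
        Parcel(4, "brainstem_analog", (16.0, 16.0, 7.5), (2.6, 2.6, 3.6), 0.62),
    )
    cortex_intensity: float = 0.95

    @property
    def cortex_shell_id(self) -> int:
        return max(p.parcel_id for p in self.parcels) + 1

    def parcel_id_of(self, name: str) -> int:
        if name == "cortex_shell":
            return self.cortex_shell_id
        for p in self.parcels:
            if p.name == name:
                return p.parcel_id
        raise KeyError(name)


@dataclass(frozen=True)
class EffectModel:
    """Planted disease, demographic, modality and site effects.

    ``disease_effects`` maps task -> parcel name -> (radius_scale,
    intensity_shift). ``confound_label_correlation`` maps disease label
    (0/1) -> {modality: probability}; rows must sum to 1.
    """

    disease_effects: dict = field(default_factory=lambda: {
        "dementia": {"hippocampus_analog": (0.80, -0.10),
                     "ventricle_analog": (1.30, 0.0)},
    })
    age_shrink_per_decade: float = 0.01      # global tissue shrink
    ventricle_growth_per_decade: float = 0.03
    age_reference: float = 60.0
    sex_size_scale: dict = field(default_factory=lambda: {"M": 1.03, "F": 0.97})
    # modality -> (gain, gamma, offset, noise_sigma); curve y = gain*x**gamma + offset
    # The FLAIR-like gamma curve changes relative tissue contrast, so the
    # modality stays decodable after per-image normalization (which removes
    # purely affine intensity differences)
    modality_effect: dict = field(default_factory=lambda: {
        "T1": (1.0, 1.0, 0.0, 0.05),
        "FLAIR": (0.7, 2.6, 0.1, 0.05),
    })
    site_bias_amplitude: float = 0.10
    # symmetric contingency: the image modality agrees with the disease
    # label 60% of the time
    confound_label_correlation: dict = field(default_factory=lambda: {
        0: {"T1": 0.60, "FLAIR": 0.40},
        1: {"T1": 0.40, "FLAIR": 0.60},
    })
    site_label_correlation: dict | None = None   # None = uniform over sites
    case_age_mean: float = 72.0
    case_age_sd: float = 8.0
    control_age_mean: float = 52.0
    control_age_sd: float = 14.0
    prevalence: float = 0.5
    ethnicity_missing_rate: float = 0.37
    hispanic_rate: float = 0.086                  # among non-missing
    images_per_patient_p: float = 0.45            # truncated geometric on [1,14]
    max_images: int = 14
    noise_sigma_scale: float = 1.0
    # how cases receive their diagnosis: (icd code or "medication", prob)
    case_code_distribution: tuple = (("G30", 0.6), ("G31.84", 0.2),
                                     ("F01", 0.1), ("medication", 0.1))

    def __post_init__(self):
        for label, row in self.confound_label_correlation.items():
            total = sum(row.values())
            if not np.isclose(total, 1.0):
                raise ValueError(
                    f"confound_label_correlation[{label}] sums to {total}, not 1")
        for task, effects in self.disease_effects.items():
            for parcel, (scale, _) in effects.items():
                if scale <= 0:
                    raise ValueError(
                        f"disease effect for task {task!r} gives parcel "
                        f"{parcel!r} a non-positive radius scale {scale}")


def null_effects() -> EffectModel:
    """All effects neutral: no disease, age, sex, modality or site signal."""
    return EffectModel(
        disease_effects={},
        age_shrink_per_decade=0.0, ventricle_growth_per_decade=0.0,
        sex_size_scale={"M": 1.0, "F": 1.0},
        modality_effect={"T1": (1.0, 1.0, 0.0, 0.05)},
        site_bias_amplitude=0.0,
        confound_label_correlation={0: {"T1": 1.0}, 1: {"T1": 1.0}},
        case_age_mean=60.0, case_age_sd=12.0,
        control_age_mean=60.0, control_age_sd=12.0)


@dataclass(frozen=True)
class ComorbiditySpec:
    """Comorbidity codes with marginal prevalence and odds vs. disease.

    ``codes`` maps ICD-10-style code -> (control prevalence in (0,1),
    odds multiplier given the disease label, positive).
    """

    codes: dict = field(default_factory=lambda: {
        "I10": (0.20, 3.0),   # essential hypertension, helps detection
        "E78": (0.15, 2.5),   # lipoprotein metabolism disorder
        "G47": (0.12, 2.0),   # sleep disorder
        "R41": (0.08, 3.0),   # cognitive symptoms
        "R51": (0.10, 0.5),   # headache, enriched in controls
    })

    def __post_init__(self):
        for code, (prev, odds) in self.codes.items():
            if not 0 < prev < 1:
                raise ValueError(f"{code}: prevalence must be in (0,1)")
            if odds <= 0:
                raise ValueError(f"{code}: odds multiplier must be positive")


# -------------------------------------------------------------------------
# Rendering
# -------------------------------------------------------------------------


def _ellipsoid_mask(grid: int, center, radii) -> np.ndarray:
    ax = np.arange(grid, dtype=np.float64)
    x, y, z = np.meshgrid(ax, ax, ax, indexing="ij")
    cx, cy, cz = center
    rx, ry, rz = radii
    return (((x - cx) / rx) ** 2 + ((y - cy) / ry) ** 2
            + ((z - cz) / rz) ** 2) <= 1.0


def render_parcellation(phantom: PhantomSpec, radius_scales: dict) -> np.ndarray:
    """Render the integer parcel label volume at the given radius scales.

    ``radius_scales`` maps parcel name -> multiplicative radius factor
    (cortex_shell scales with the brain ellipsoid). Raises if any scaled
    radius drops to zero or below.
    """
    g = phantom.grid_size
    brain = _ellipsoid_mask(g, phantom.brain_center, phantom.brain_radii)
    inner = _ellipsoid_mask(
        g, phantom.brain_center,
        tuple(r * phantom.cortex_shell_fraction for r in phantom.brain_radii))
    labels = np.zeros((g, g, g), dtype=np.int32)
    shell_scale = radius_scales.get("cortex_shell", 1.0)
    if shell_scale <= 0:
        raise ValueError("parcel cortex_shell scaled to non-positive radius")
    labels[brain & ~inner] = phantom.cortex_shell_id
    for p in phantom.parcels:
        scale = radius_scales.get(p.name, 1.0)
        radii = tuple(r * scale for r in p.radii)
        if min(radii) <= 0:
            raise ValueError(f"parcel {p.name} scaled to non-positive radius")
        mask = _ellipsoid_mask(g, p.center, radii) & inner
        labels[mask] = p.parcel_id
    return labels


def render_intensity(phantom: PhantomSpec, labels: np.ndarray,
                     intensity_shifts: dict) -> np.ndarray:
    """Paint base intensities (plus per-parcel shifts) over a label volume."""
    vol = np.zeros(labels.shape, dtype=np.float64)
    brain = labels > 0
    vol[brain] = phantom.tissue_intensity
    # tissue between parcels keeps tissue_intensity; labels==cortex id etc:
    vol[labels == phantom.cortex_shell_id] = (
        phantom.cortex_intensity + intensity_shifts.get("cortex_shell", 0.0))
    for p in phantom.parcels:
        vol[labels == p.parcel_id] = (
            p.base_intensity + intensity_shifts.get(p.name, 0.0))
    return vol


def _site_bias_field(grid: int, amplitude: float,
                     rng: np.random.Generator) -> np.ndarray:
    """Smooth multiplicative bias: 1 + amplitude * low-order polynomial."""
    ax = np.linspace(-1, 1, grid)
    x, y, z = np.meshgrid(ax, ax, ax, indexing="ij")
    c = rng.normal(size=9)
    poly = (c[0] * x + c[1] * y + c[2] * z + c[3] * x * y + c[4] * x * z
            + c[5] * y * z + c[6] * x ** 2 + c[7] * y ** 2 + c[8] * z ** 2)
    poly /= max(np.abs(poly).max(), 1e-9)
    return 1.0 + amplitude * poly


def _truncated_geometric(p: float, high: int, rng: np.random.Generator) -> int:
    return int(min(rng.geometric(p), high))


def _radius_scales(effects: EffectModel, tasks_positive, age: float,
                   sex: str) -> tuple:
    """Combined radius scales and intensity shifts for one patient."""
    decades = (age - effects.age_reference) / 10.0
    sex_scale = effects.sex_size_scale.get(sex, 1.0)
    tissue = sex_scale * (1.0 - effects.age_shrink_per_decade) ** decades
    vent = sex_scale * (1.0 + effects.ventricle_growth_per_decade) ** decades
    scales = {name: tissue for name in PARCEL_NAMES}
    scales["ventricle_analog"] = vent
    shifts = {}
    for task in tasks_positive:
        for parcel, (rscale, ishift) in effects.disease_effects.get(task, {}).items():
            scales[parcel] = scales.get(parcel, 1.0) * rscale
            shifts[parcel] = shifts.get(parcel, 0.0) + ishift
    return scales, shifts


def _apply_modality(vol: np.ndarray, curve) -> np.ndarray:
    gain, gamma, offset, _sigma = curve
    return gain * np.clip(vol, 0.0, None) ** gamma + offset


def generate_cohort(n_patients: int,
                    phantom: PhantomSpec | None = None,
                    effects: EffectModel | None = None,
                    comorbidities: ComorbiditySpec | None = None,
                    sites: int = 3,
                    seed: int = 0,
                    render_volumes: bool = True):
    """Generate a seeded phantom cohort.

    Returns ``(patients, truth)`` where ``truth`` is a DataFrame with one
    row per image carrying the planted ground truth (disease label,
    per-image confounds, OOD flag). ``render_volumes=False`` skips
    volume rendering (tiny zero placeholders instead) for metadata-only
    studies where only the manifest columns matter.
    """
    if n_patients < 2:
        raise ValueError("need at least 2 patients")
    phantom = phantom or PhantomSpec()
    effects = effects or EffectModel()
    comorbidities = comorbidities or ComorbiditySpec()
    rng = np.random.default_rng(seed)
    site_rngs = [np.random.default_rng(seed * 1000 + 17 + s) for s in range(sites)]
    site_fields = [
        _site_bias_field(phantom.grid_size, effects.site_bias_amplitude, r)
        for r in site_rngs]

    patients, truth_rows = [], []
    for i in range(n_patients):
        pid = f"p{i:05d}"
        diseased = int(rng.random() < effects.prevalence)
        if diseased:
            age = float(np.clip(rng.normal(effects.case_age_mean,
                                           effects.case_age_sd), 18, 100))
        else:
            age = float(np.clip(rng.normal(effects.control_age_mean,
                                           effects.control_age_sd), 18, 100))
        sex = "M" if rng.random() < 0.5 else "F"
        if rng.random() < effects.ethnicity_missing_rate:
            ethnicity = "missing"
        else:
            ethnicity = ("hispanic" if rng.random() < effects.hispanic_rate
                         else "non_hispanic")

        codes, meds = set(), set()
        if diseased:
            options = effects.case_code_distribution
            probs = np.array([p for _, p in options])
            choice = options[rng.choice(len(options), p=probs / probs.sum())][0]
            if choice == "medication":
                meds.add("donepezil")
            else:
                codes.add(choice)
        for code, (prev, odds_mult) in comorbidities.codes.items():
            base_odds = prev / (1 - prev)
            odds = base_odds * (odds_mult if diseased else 1.0)
            if rng.random() < odds / (1 + odds):
                codes.add(code)

        tasks_positive = {"dementia"} if diseased else set()
        scales, shifts = _radius_scales(effects, tasks_positive, age, sex)

        if effects.site_label_correlation is not None:
            site_probs = np.asarray(effects.site_label_correlation[diseased])
        else:
            site_probs = np.full(sites, 1.0 / sites)
        site = int(rng.choice(sites, p=site_probs))

        n_images = _truncated_geometric(effects.images_per_patient_p,
                                        effects.max_images, rng)
        mod_row = effects.confound_label_correlation[diseased]
        mods = list(mod_row)
        mod_p = np.array([mod_row[m] for m in mods])
        images = []
        for j in range(n_images):
            modality = mods[rng.choice(len(mods), p=mod_p)]
            curve = effects.modality_effect[modality]
            if render_volumes:
                labels = render_parcellation(phantom, scales)
                vol = render_intensity(phantom, labels, shifts)
                vol = _apply_modality(vol, curve)
                vol = vol * site_fields[site]
                sigma = curve[3] * effects.noise_sigma_scale
                if sigma > 0:
                    vol = vol + rng.normal(0.0, sigma, size=vol.shape)
            else:
                labels = None
                vol = np.zeros((8, 8, 8))
            thickness = 3.0 if modality in ("CT", "PET") else 1.0
            image = ImageRecord(
                image_id=f"{pid}_im{j}", patient_id=pid, volume=vol,
                modality=modality, angle="axial", slice_thickness=thickness,
                sequence=f"seq_{modality}", site_id=f"site{site}",
                age_at_scan=age, parcellation=labels)
            images.append(image)
            truth_rows.append({
                "patient_id": pid, "image_id": image.image_id,
                "disease": diseased, "modality": modality,
                "site_id": f"site{site}", "age": age, "sex": sex,
                "ood": False})
        patients.append(PatientRecord(
            patient_id=pid, sex=sex, ethnicity=ethnicity, images=images,
            icd_codes=codes, medications=meds, site_id=f"site{site}"))
    truth = pd.DataFrame(truth_rows)
    return patients, truth


def generate_ood_images(n_images: int,
                        phantom: PhantomSpec | None = None,
                        effects: EffectModel | None = None,
                        shift: dict | None = None,
                        sites: int = 3,
                        seed: int = 0) -> list:
    """Images from the same phantom family under a distributional shift.

    ``shift`` keys: ``bias_scale`` (multiplies the site bias amplitude),
    ``noise_scale`` (multiplies voxel noise sigma), ``unseen_modality``
    (adds a modality tag absent from the training vocabulary, with its
    own transfer curve). All default to the identity shift.
    """
    shift = dict(shift or {})
    bias_scale = float(shift.pop("bias_scale", 1.0))
    noise_scale = float(shift.pop("noise_scale", 1.0))
    unseen = shift.pop("unseen_modality", None)
    if shift:
        raise ValueError(f"unknown shift keys: {sorted(shift)}")
    phantom = phantom or PhantomSpec()
    effects = effects or EffectModel()
    shifted = replace(effects,
                      site_bias_amplitude=effects.site_bias_amplitude * bias_scale,
                      noise_sigma_scale=effects.noise_sigma_scale * noise_scale)
    if unseen is not None:
        mod_eff = dict(shifted.modality_effect)
        mod_eff[unseen] = (1.6, 0.4, 0.3, 0.08)
        shifted = replace(
            shifted, modality_effect=mod_eff,
            confound_label_correlation={0: {unseen: 1.0}, 1: {unseen: 1.0}})
    # render via generate_cohort with 1 image per patient
    shifted = replace(shifted, images_per_patient_p=1.0)
    patients, truth = generate_cohort(
        max(n_images, 2), phantom=phantom, effects=shifted,
        comorbidities=ComorbiditySpec(), sites=sites, seed=seed)
    images = [p.images[0] for p in patients][:n_images]
    return images
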