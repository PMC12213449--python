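"""Domain types, controlled vocabularies, and diagnosis-label derivation.

A cohort is a collection of :class:`PatientRecord` objects, each holding
one or more :class:`ImageRecord` volumes plus demographics, ICD-10-style
diagnosis codes and a medication list. Task labels (the broad "dementia"
label and the disease-specific ICD tasks) are derived from codes and
medication history by hierarchical prefix matching; patients with head
injury or malignant neoplasm codes are excluded.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

MODALITIES = ("T1", "T2", "FLAIR", "DWI", "SWI", "MR_OTHER", "CT", "PET")
ANGLES = ("axial", "sagittal", "coronal")
SEXES = ("M", "F")
ETHNICITIES = ("hispanic", "non_hispanic", "missing")

#: default classification tasks: the umbrella dementia label, the five
#: neurodegenerative ICD tasks it envelops, and comparison disorders.
DEFAULT_TASKS = ("dementia", "F01", "G30", "G31", "G31.01", "G31.83",
                 "G31.84", "G20", "G35", "G40")

#: codes whose presence (any of them) sets the umbrella dementia label
DEMENTIA_CODE_PREFIXES = ("F01", "G30", "G31", "G31.01", "G31.83", "G31.84")

#: memory-impairment drugs whose prescription sets the dementia label
MEMORY_IMPAIRMENT_DRUGS = frozenset(
    {"galantamine", "memantine", "donepezil", "rivastigmine"})

#: exclusion: head injury S00-S09, malignant neoplasm C00-C97
HEAD_INJURY_PREFIXES = tuple(f"S{i:02d}" for i in range(10))
MALIGNANT_NEOPLASM_PREFIXES = tuple(f"C{i:02d}" for i in range(98))

CONFOUND_CATEGORIES = ("modality", "angle", "slice_thickness_bin", "sequence",
                       "site_id", "sex", "age_bin")

_CODE_RE = re.compile(r"^[A-Z][0-9]{2}[0-9A-Z]*$")


def normalize_code(code: str) -> str:
    """Upper-case and strip the dot from an ICD-10-style code.

    Raises ``ValueError`` for malformed codes (the prefix must be a
    letter followed by two digits).
    """
    stripped = code.strip().upper().replace(".", "")
    if not _CODE_RE.match(stripped):
        raise ValueError(f"malformed ICD-10-style code: {code!r}")
    return stripped


def slice_thickness_bin(thickness_mm: float) -> str:
    """Discretize slice thickness (mm) into {thin, medium, thick}."""
    if thickness_mm <= 1.5:
        return "thin(<=1.5mm)"
    if thickness_mm <= 3.0:
        return "medium(1.5-3mm)"
    return "thick(>3mm)"


def age_bin(age_years: float, width: float = 10.0) -> str:
    """Fixed-width decade bin of age, clipped to [0, 100)."""
    lo = int(np.clip(age_years, 0, 99.999) // width) * int(width)
    return f"{lo:03d}-{lo + int(width):03d}"


@dataclass
class ImageRecord:
    """One 3D brain image with its acquisition metadata."""

    image_id: str
    patient_id: str
    volume: np.ndarray
    spacing: tuple = (1.0, 1.0, 1.0)
    modality: str = "T1"
    angle: str = "axial"
    slice_thickness: float = 1.0
    sequence: str = "default"
    site_id: str = "site0"
    age_at_scan: float = 60.0
    parcellation: np.ndarray | None = None

    def __post_init__(self):
        v = np.asarray(self.volume)
        if v.ndim != 3 or min(v.shape) < 8:
            raise ValueError(
                f"{self.image_id}: volume must be 3D with every extent >= 8, "
                f"got shape {v.shape}")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"{self.image_id}: spacing must be positive")
        if self.parcellation is not None and self.parcellation.shape != v.shape:
            raise ValueError(
                f"{self.image_id}: parcellation shape {self.parcellation.shape} "
                f"!= volume shape {v.shape}")
        if not np.isfinite(self.age_at_scan) or self.age_at_scan < 0:
            raise ValueError(f"{self.image_id}: age_at_scan must be finite and >= 0")

    def confounds(self, sex: str) -> dict:
        return {
            "modality": self.modality,
            "angle": self.angle,
            "slice_thickness_bin": slice_thickness_bin(self.slice_thickness),
            "sequence": self.sequence,
            "site_id": self.site_id,
            "sex": sex,
            "age_bin": age_bin(self.age_at_scan),
        }


@dataclass
class PatientRecord:
    """One EHR-like unit: images, demographics, diagnosis codes, drugs."""

    patient_id: str
    sex: str
    ethnicity: str
    images: list
    icd_codes: set = field(default_factory=set)
    medications: set = field(default_factory=set)
    site_id: str = "site0"

    def __post_init__(self):
        if not self.images:
            raise ValueError(f"{self.patient_id}: at least one image required")
        for im in self.images:
            if im.patient_id != self.patient_id:
                raise ValueError(
                    f"image {im.image_id} belongs to {im.patient_id}, "
                    f"not {self.patient_id}")
        if self.sex not in SEXES:
            raise ValueError(f"{self.patient_id}: sex must be one of {SEXES}")
        if self.ethnicity not in ETHNICITIES:
            raise ValueError(
                f"{self.patient_id}: ethnicity must be one of {ETHNICITIES}")

    @property
    def labels(self) -> "TaskLabelSet":
        return assign_task_labels(self.icd_codes, self.medications)


@dataclass
class TaskLabelSet:
    """Per-task 0/1 labels plus the exclusion flag."""

    labels: dict
    excluded: bool

    def __getitem__(self, task: str) -> int:
        return self.labels[task]


def assign_task_labels(codes, medications, tasks=DEFAULT_TASKS) -> TaskLabelSet:
    """Derive task labels from diagnosis codes and medication history.

    Matching is hierarchical by code prefix on dot-stripped codes:
    "G31.84" sets G31.84, G31 and dementia. The umbrella dementia label
    is also set by prescription of any memory-impairment drug. The
    exclusion flag marks head-injury (S00-S09) or malignant-neoplasm
    (C00-C97) codes.
    """
    norm = {normalize_code(c) for c in codes}
    meds = {m.strip().lower() for m in medications}
    labels = {}
    for task in tasks:
        if task == "dementia":
            continue
        prefix = task.replace(".", "")
        labels[task] = int(any(c.startswith(prefix) for c in norm))
    if "dementia" in tasks:
        dem_codes = any(
            c.startswith(p.replace(".", "")) for c in norm
            for p in DEMENTIA_CODE_PREFIXES)
        labels["dementia"] = int(dem_codes or bool(meds & MEMORY_IMPAIRMENT_DRUGS))
    excluded = any(
        c.startswith(p) for c in norm
        for p in HEAD_INJURY_PREFIXES + MALIGNANT_NEOPLASM_PREFIXES)
    ordered = {t: labels[t] for t in tasks}
    return TaskLabelSet(labels=ordered, excluded=excluded)


@dataclass
class ConfoundVocab:
    """Per-category ordered value vocabulary and modal (most frequent) value."""

    vocab: dict       # category -> tuple of values (sorted)
    modal: dict       # category -> most frequent value (lexicographic ties)
    counts: dict      # category -> Counter

    def index(self, category: str, value: str) -> int:
        try:
            return self.vocab[category].index(value)
        except ValueError:
            raise KeyError(
                f"value {value!r} not in training vocabulary for {category!r}")

    def size(self, category: str) -> int:
        return len(self.vocab[category])


def build_confound_vocab(cohort) -> ConfoundVocab:
    """Build per-category confound vocabularies from a training cohort.

    The modal value per category is the target the encoder is
    adversarially pushed toward (e.g. CT and PET latents made to look
    like the majority MR modality). Ties are broken lexicographically so
    vocabulary building is order-independent.
    """
    cohort = list(cohort)
    if not cohort:
        raise ValueError("cannot build a confound vocabulary from an empty cohort")
    counts = {cat: Counter() for cat in CONFOUND_CATEGORIES}
    for patient in cohort:
        for image in patient.images:
            for cat, val in image.confounds(patient.sex).items():
                counts[cat][val] += 1
    vocab, modal = {}, {}
    for cat, counter in counts.items():
        vocab[cat] = tuple(sorted(counter))
        modal[cat] = min(counter, key=lambda v: (-counter[v], v))
    return ConfoundVocab(vocab=vocab, modal=modal, counts=counts)


# -------------------------------------------------------------------------
# Manifest I/O (TSV + NIfTI)
# -------------------------------------------------------------------------

MANIFEST_COLUMNS = [
    "patient_id", "image_id", "nifti_path", "modality", "angle",
    "slice_thickness", "sequence", "site_id", "age_at_scan", "sex",
    "ethnicity", "icd_codes", "medications", "parcellation_path",
]


def write_manifest(cohort, out_dir, compress: bool = True) -> Path:
    """Write a cohort as a TSV manifest plus NIfTI volumes/parcellations."""
    import nibabel as nib

    out_dir = Path(out_dir)
    (out_dir / "nifti").mkdir(parents=True, exist_ok=True)
    ext = ".nii.gz" if compress else ".nii"
    rows = []
    for patient in cohort:
        for image in patient.images:
            path = out_dir / "nifti" / f"{image.image_id}{ext}"
            nib.save(nib.Nifti1Image(np.asarray(image.volume, dtype=np.float64),
                                     np.eye(4)), str(path))
            parc_path = ""
            if image.parcellation is not None:
                parc_path = str(out_dir / "nifti" / f"{image.image_id}_parc{ext}")
                nib.save(nib.Nifti1Image(
                    image.parcellation.astype(np.int16), np.eye(4)), parc_path)
            rows.append({
                "patient_id": patient.patient_id,
                "image_id": image.image_id,
                "nifti_path": str(path),
                "modality": image.modality,
                "angle": image.angle,
                "slice_thickness": image.slice_thickness,
                "sequence": image.sequence,
                "site_id": image.site_id,
                "age_at_scan": image.age_at_scan,
                "sex": patient.sex,
                "ethnicity": patient.ethnicity,
                "icd_codes": ";".join(sorted(patient.icd_codes)),
                "medications": ";".join(sorted(patient.medications)),
                "parcellation_path": parc_path,
            })
    manifest = out_dir / "manifest.tsv"
    pd.DataFrame(rows, columns=MANIFEST_COLUMNS).to_csv(
        manifest, sep="\t", index=False)
    return manifest


def read_manifest(manifest_path) -> list:
    """Read a TSV manifest (plus NIfTI volumes) back into PatientRecords."""
    import nibabel as nib

    df = pd.read_csv(manifest_path, sep="\t", dtype={"patient_id": str,
                                                     "image_id": str},
                     keep_default_na=False)
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    patients = []
    for pid, group in df.groupby("patient_id", sort=True):
        images = []
        for _, row in group.iterrows():
            vol = np.asarray(nib.load(row["nifti_path"]).dataobj,
                             dtype=np.float64)
            parc = None
            if row["parcellation_path"]:
                parc = np.asarray(nib.load(row["parcellation_path"]).dataobj,
                                  dtype=np.int32)
            images.append(ImageRecord(
                image_id=row["image_id"], patient_id=pid, volume=vol,
                modality=row["modality"], angle=row["angle"],
                slice_thickness=float(row["slice_thickness"]),
                sequence=row["sequence"], site_id=row["site_id"],
                age_at_scan=float(row["age_at_scan"]), parcellation=parc))
        first = group.iloc[0]
        codes = set(filter(None, str(first["icd_codes"]).split(";")))
        meds = set(filter(None, str(first["medications"]).split(";")))
        site = Counter(group["site_id"]).most_common(1)[0][0]
        patients.append(PatientRecord(
            patient_id=pid, sex=first["sex"], ethnicity=first["ethnicity"],
            images=images, icd_codes=codes, medications=meds, site_id=site))
    return patients
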