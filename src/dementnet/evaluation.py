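"""Evaluation machinery: AUC, baselines, modality combinations, comorbidities.

Everything downstream of prediction lives here: Mann-Whitney AUC (with
per-site and confidence-stratified variants), the metadata-only random
forest baseline that measures how far the confounds alone can go, the
additive value of imaging over that baseline, AUC by modality
combination and image count, the comorbidity scan (per-ICD-code
performance effects with Kruskal-Wallis and chi-squared dependence
statistics and a residual-from-regression standout analysis), and the
first-visit subset.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_MIN_CODE_COUNT = 20
IMAGE_COUNT_BUCKETS = ((1, 1), (2, 5), (6, 10), (11, 14))


@dataclass
class EvalResult:
    task: str
    subset: str
    auc: float | None     # None when a class is absent (never reported as 0.5)
    n_cases: int
    n_controls: int
    note: str = ""


def auc(scores, labels) -> float:
    """Probability a random case outscores a random control, ties count 1/2.

    Computed from the Mann-Whitney U statistic via rank sums.
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("AUC undefined: both classes must be present")
    ranks = stats.rankdata(scores)
    u = ranks[labels == 1].sum() - len(pos) * (len(pos) + 1) / 2
    return float(u / (len(pos) * len(neg)))


def evaluate_subset(scores, labels, task: str, subset: str) -> EvalResult:
    labels = np.asarray(labels)
    n_cases = int((labels == 1).sum())
    n_controls = int((labels == 0).sum())
    if n_cases == 0 or n_controls == 0:
        return EvalResult(task, subset, None, n_cases, n_controls,
                          note="undefined: one class absent")
    return EvalResult(task, subset, auc(scores, labels), n_cases, n_controls)


def auc_by_site(scores, labels, sites, task: str) -> list:
    """One EvalResult per site holding at least one case and one control."""
    sites = np.asarray(sites)
    out = []
    for site in sorted(set(sites.tolist())):
        sel = sites == site
        out.append(evaluate_subset(np.asarray(scores)[sel],
                                   np.asarray(labels)[sel], task,
                                   subset=f"site:{site}"))
    return out


# -------------------------------------------------------------------------
# Metadata-only baseline
# -------------------------------------------------------------------------

METADATA_FEATURES = ("age_at_scan", "sex", "ethnicity", "modality", "angle",
                     "slice_thickness", "sequence")


def _metadata_frame(patients) -> pd.DataFrame:
    rows = []
    for p in patients:
        y = p.labels
        for im in p.images:
            rows.append({
                "patient_id": p.patient_id, "image_id": im.image_id,
                "age_at_scan": im.age_at_scan, "sex": p.sex,
                "ethnicity": p.ethnicity, "modality": im.modality,
                "angle": im.angle, "slice_thickness": im.slice_thickness,
                "sequence": im.sequence, "site_id": im.site_id,
                "_labels": y})
    return pd.DataFrame(rows)


def metadata_baseline(train_patients, test_patients, task: str,
                      seed: int = 0) -> dict:
    """Random-forest classification from tabular metadata only.

    Features are age, sex, ethnicity and the per-image acquisition
    metadata (modality, angle, slice thickness, sequence) — no
    image-derived quantity. Returns per-image scores and the AUC on the
    test images; degenerate single-valued features are dropped.
    """
    import warnings

    from sklearn.ensemble import RandomForestClassifier

    train_df = _metadata_frame(train_patients)
    test_df = _metadata_frame(test_patients)
    y_train = np.array([lab[task] for lab in train_df["_labels"]])
    y_test = np.array([lab[task] for lab in test_df["_labels"]])

    features = list(METADATA_FEATURES)
    for col in list(features):
        if train_df[col].nunique() < 2:
            warnings.warn(f"dropping degenerate single-valued feature {col!r}")
            features.remove(col)
    combined = pd.concat([train_df[features], test_df[features]])
    encoded = pd.get_dummies(combined, columns=[
        c for c in features if combined[c].dtype == object])
    x_train = encoded.iloc[: len(train_df)].to_numpy(dtype=np.float64)
    x_test = encoded.iloc[len(train_df):].to_numpy(dtype=np.float64)

    clf = RandomForestClassifier(n_estimators=200, random_state=seed)
    clf.fit(x_train, y_train)
    scores = clf.predict_proba(x_test)[:, list(clf.classes_).index(1)]
    result = evaluate_subset(scores, y_test, task, subset="metadata")
    return {"scores": scores, "image_ids": test_df["image_id"].to_numpy(),
            "patient_ids": test_df["patient_id"].to_numpy(),
            "auc": result.auc, "features": features, "result": result}


def additive_value(imaging_auc: float, metadata_auc: float) -> float:
    """Imaging AUC on the high-confidence subset minus the metadata AUC."""
    return float(imaging_auc - metadata_auc)


# -------------------------------------------------------------------------
# Modality combinations and image-count buckets
# -------------------------------------------------------------------------


def modality_combination_analysis(patient_scores, patient_labels,
                                  patients, task: str) -> pd.DataFrame:
    """AUC per modality pair (singletons on the diagonal) and count bucket.

    A patient qualifies for cell (m1, m2) when their record holds at
    least one image of each modality (m1 == m2 selects patients with
    that modality). Count buckets {1, 2-5, 6-10, 11-14} partition
    patients by number of images. Cells where AUC is undefined are
    reported with auc = NaN and a note.
    """
    scores = np.asarray(patient_scores, dtype=np.float64)
    labels = np.asarray(patient_labels)
    modsets = [frozenset(im.modality for im in p.images) for p in patients]
    counts = np.array([len(p.images) for p in patients])
    all_mods = sorted(set().union(*modsets))
    rows = []
    for i, m1 in enumerate(all_mods):
        for m2 in all_mods[i:]:
            sel = np.array([(m1 in s) and (m2 in s) for s in modsets])
            rows.append(_combo_row(f"{m1}+{m2}" if m1 != m2 else m1,
                                   "modality_pair", scores, labels, sel, task))
    for lo, hi in IMAGE_COUNT_BUCKETS:
        sel = (counts >= lo) & (counts <= hi)
        rows.append(_combo_row(f"{lo}-{hi}", "image_count", scores, labels,
                               sel, task))
    return pd.DataFrame(rows)


def _combo_row(name, kind, scores, labels, sel, task):
    res = (evaluate_subset(scores[sel], labels[sel], task, name)
           if sel.any() else EvalResult(task, name, None, 0, 0, "empty cell"))
    return {"task": task, "kind": kind, "cell": name,
            "auc": np.nan if res.auc is None else res.auc,
            "n_cases": res.n_cases, "n_controls": res.n_controls,
            "note": res.note}


# -------------------------------------------------------------------------
# Comorbidity scan
# -------------------------------------------------------------------------


def chi_squared_dependence(a, b) -> tuple:
    """Pearson chi-squared (no continuity correction) for two binary vectors."""
    a = np.asarray(a, dtype=int)
    b = np.asarray(b, dtype=int)
    table = np.array([[np.sum((a == i) & (b == j)) for j in (0, 1)]
                      for i in (0, 1)])
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        return 0.0, 1.0
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(chi2), float(p)


def comorbidity_scan(patient_scores, patient_labels, patient_codes,
                     task: str, scan_codes=None,
                     min_count: int = DEFAULT_MIN_CODE_COUNT) -> pd.DataFrame:
    """Per-ICD-code effect of comorbidity on model performance.

    The per-patient performance score is 1 - |Y - Y'| with Y the task
    label and Y' the predicted probability. Per code: the signed effect
    (mean score with code minus without), Kruskal-Wallis H/p of score
    vs. code presence, chi-squared dependence of the code on the task
    label, Benjamini-Hochberg adjusted p-values, and the residual of the
    signed effect from its least-squares regression on the chi-squared
    statistic across codes (standouts above the line).
    """
    yprime = np.asarray(patient_scores, dtype=np.float64)
    y = np.asarray(patient_labels, dtype=np.float64)
    perf = 1.0 - np.abs(y - yprime)
    code_sets = [set(c) for c in patient_codes]
    if scan_codes is None:
        scan_codes = sorted(set().union(*code_sets))
    rows, skipped = [], []
    for code in scan_codes:
        has = np.array([code in c for c in code_sets])
        if has.sum() < min_count or (~has).sum() < min_count:
            skipped.append(code)
            continue
        effect = float(perf[has].mean() - perf[~has].mean())
        if np.ptp(perf) == 0:
            kw_h, kw_p = 0.0, 1.0
        else:
            kw_h, kw_p = stats.kruskal(perf[has], perf[~has])
        chi2, chi2_p = chi_squared_dependence(has, y > 0.5)
        rows.append({"code": code, "n_with": int(has.sum()), "effect": effect,
                     "kw_H": float(kw_h), "kw_p": float(kw_p),
                     "chi2": chi2, "chi2_p": chi2_p})
    df = pd.DataFrame(rows)
    if len(df):
        df["kw_p_adj"] = stats.false_discovery_control(df["kw_p"], method="bh")
        if len(df) >= 2 and df["chi2"].nunique() > 1:
            slope, intercept = np.polyfit(df["chi2"], df["effect"], 1)
        else:
            slope, intercept = 0.0, float(df["effect"].mean())
        df["residual"] = df["effect"] - (slope * df["chi2"] + intercept)
    df.attrs["skipped_codes"] = skipped
    return df


def first_visit_subset(cohort) -> list:
    """Restrict each patient to the images at their earliest age_at_scan."""
    out = []
    for p in cohort:
        earliest = min(im.age_at_scan for im in p.images)
        keep = [im for im in p.images if im.age_at_scan == earliest]
        out.append(replace_images(p, keep))
    return out


def replace_images(patient, images):
    from dataclasses import replace as dc_replace

    return dc_replace(patient, images=list(images))
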