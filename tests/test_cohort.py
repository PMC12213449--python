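"""Label derivation, confound vocabularies and manifest round-trips."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dementnet.cohort import (ImageRecord, assign_task_labels,
                              build_confound_vocab, normalize_code,
                              read_manifest, slice_thickness_bin,
                              write_manifest)
from conftest import make_image, make_patient


class TestAssignTaskLabels:
    @pytest.mark.parametrize("codes,meds,expect_pos,expect_excl", [
        ({"G30"}, set(), {"dementia", "G30"}, False),
        (set(), {"donepezil"}, {"dementia"}, False),
        (set(), set(), set(), False),
        ({"C71.9"}, set(), set(), True),
        ({"S06.2"}, set(), set(), True),
        ({"G31.84"}, set(), {"dementia", "G31", "G31.84"}, False),
        ({"G20"}, set(), {"G20"}, False),
        ({"G35", "F01"}, set(), {"G35", "F01", "dementia"}, False),
    ])
    def test_mapping(self, codes, meds, expect_pos, expect_excl):
        result = assign_task_labels(codes, meds)
        positives = {t for t, v in result.labels.items() if v == 1}
        assert positives == expect_pos
        assert result.excluded is expect_excl

    def test_malformed_code_rejected(self):
        with pytest.raises(ValueError, match="12X"):
            assign_task_labels({"12X"}, set())

    def test_dot_stripping(self):
        assert normalize_code("g31.84") == "G3184"

    def test_monotone_adding_codes_never_clears(self):
        base = assign_task_labels({"G31.83"}, set())
        more = assign_task_labels({"G31.83", "F01", "I10"}, set())
        for task, value in base.labels.items():
            assert more.labels[task] >= value

    @settings(max_examples=500, deadline=None)
    @given(st.sets(st.sampled_from(
        ["G30", "G31", "G31.01", "G31.83", "G31.84", "F01", "G20", "G35",
         "G40", "I10", "E78", "R51", "C50", "S06"]), max_size=6))
    def test_hierarchy_invariants(self, codes):
        labels = assign_task_labels(codes, set()).labels
        if any(labels[t] for t in ("G31.01", "G31.83", "G31.84")):
            assert labels["G31"] == 1
        if any(labels[t] for t in ("F01", "G30", "G31")):
            assert labels["dementia"] == 1
        # idempotence
        assert assign_task_labels(codes, set()).labels == labels


class TestConfoundVocab:
    def test_modal_by_majority(self):
        patients = [make_patient(f"p{i}") for i in range(3)]
        for p in patients:
            for im in p.images:
                im.modality = "T1"
        pet = make_patient("p3")
        for im in pet.images:
            im.modality = "PET"
        vocab = build_confound_vocab(patients + [pet])
        assert vocab.vocab["modality"] == ("PET", "T1")
        assert vocab.modal["modality"] == "T1"

    def test_lexicographic_tie_break(self):
        a = make_patient("p0", n_images=2)
        b = make_patient("p1", n_images=2)
        for im in a.images:
            im.modality = "T1"
        for im in b.images:
            im.modality = "CT"
        vocab = build_confound_vocab([a, b])
        assert vocab.modal["modality"] == "CT"

    def test_all_female_cohort(self):
        patients = [make_patient(f"p{i}", sex="F") for i in range(4)]
        assert build_confound_vocab(patients).modal["sex"] == "F"

    def test_order_independent(self):
        patients = [make_patient(f"p{i}", seed=i) for i in range(6)]
        for i, p in enumerate(patients):
            for im in p.images:
                im.modality = ["T1", "CT", "PET"][i % 3]
        v1 = build_confound_vocab(patients)
        v2 = build_confound_vocab(list(reversed(patients)))
        assert v1.vocab == v2.vocab and v1.modal == v2.modal

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            build_confound_vocab([])


class TestDomainTypes:
    def test_volume_too_small_rejected(self):
        with pytest.raises(ValueError, match="extent"):
            ImageRecord("x", "p", np.zeros((4, 16, 16)))

    def test_parcellation_shape_mismatch(self):
        with pytest.raises(ValueError, match="parcellation"):
            make_image(parcellation=np.zeros((8, 8, 8), dtype=int))

    def test_patient_image_ownership(self):
        from dementnet.cohort import PatientRecord

        bad = make_image("i", "other")
        with pytest.raises(ValueError, match="belongs"):
            PatientRecord(patient_id="p0", sex="F", ethnicity="missing",
                          images=[bad])

    @pytest.mark.parametrize("mm,expected", [
        (1.0, "thin(<=1.5mm)"), (1.5, "thin(<=1.5mm)"),
        (2.0, "medium(1.5-3mm)"), (5.0, "thick(>3mm)")])
    def test_slice_thickness_bins(self, mm, expected):
        assert slice_thickness_bin(mm) == expected


def test_manifest_round_trip(tmp_path):
    patients = [make_patient("p0", codes={"G30", "I10"}, meds={"donepezil"}),
                make_patient("p1", sex="M", ethnicity="missing")]
    patients[0].images[0].parcellation = np.ones(
        patients[0].images[0].volume.shape, dtype=np.int32)
    manifest = write_manifest(patients, tmp_path)
    loaded = read_manifest(manifest)
    assert [p.patient_id for p in loaded] == ["p0", "p1"]
    assert loaded[0].icd_codes == {"G30", "I10"}
    assert loaded[0].medications == {"donepezil"}
    assert loaded[1].ethnicity == "missing"
    orig = patients[0].images[0]
    back = loaded[0].images[0]
    np.testing.assert_array_equal(back.volume, orig.volume)
    np.testing.assert_array_equal(back.parcellation, orig.parcellation)
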