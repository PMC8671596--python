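"""Segmentation, demons warp estimation and PET normalization."""

import numpy as np
import pytest

from centipet import phantom_sim as ph
from centipet.errors import ContractViolation
from centipet.image_core import (
    DeformationField,
    RigidTransform,
    Volume,
    resample,
)
from centipet.spatial_normalization import (
    estimate_warp,
    load_deformation,
    normalize_pet,
    normalize_pet_only,
    save_deformation,
    segment_tissues,
)


def _flat_priors(shape, classes, affine=None):
    aff = affine if affine is not None else np.eye(4)
    return {
        c: Volume(np.full(shape, 1.0 / len(classes)), aff, modality="PRIOR")
        for c in classes
    }


class TestSegmentation:
    def test_three_class_mixture_means_recovered(self):
        """Well-separated 3-class image, flat priors: means within 1%."""
        rng = np.random.default_rng(60)
        shape = (24, 24, 24)
        labels = rng.integers(0, 3, size=shape)
        true_means = {"A": 20.0, "B": 100.0, "C": 200.0}
        data = np.choose(labels, [20.0, 100.0, 200.0])
        vol = Volume(data, np.eye(4), modality="MRI")
        post = segment_tissues(vol, _flat_priors(shape, ("A", "B", "C")),
                               modality="MRI", bias_order=0)
        recovered = sorted(post.means.values())
        for got, want in zip(recovered, sorted(true_means.values())):
            assert got == pytest.approx(want, rel=0.01)

    def test_posteriors_sum_to_one(self, template):
        truth = ph.synthesize_subject(template, 61, deform_amp_mm=2.0,
                                      rigid_amp=(0.0, 0.0))
        mri = ph.render_modalities(truth, template)["mri"]
        anat = mri.with_data(mri.data, frame="template")
        post = segment_tissues(anat, template.priors, "MRI")
        total = sum(p.data for p in post.posteriors.values())
        rng = np.random.default_rng(0)
        idx = tuple(rng.integers(0, s, 1000) for s in anat.shape)
        np.testing.assert_allclose(total[idx], 1.0, atol=1e-6)

    def test_linear_bias_field_corrected(self, template):
        """10% linear intensity ramp: corrected means within 3% of truth."""
        truth = ph.synthesize_subject(
            template, 62, deform_amp_mm=0.0, rigid_amp=(0.0, 0.0),
            noise_sd={"mri": 1.0, "ct": 0.0, "pet": 0.0},
        )
        mri = ph.render_modalities(truth, template)["mri"]
        nx = mri.shape[0]
        ramp = 1.0 + 0.1 * (np.arange(nx) / (nx - 1) - 0.5)[:, None, None]
        biased = mri.with_data(mri.data * ramp, frame="template")
        post = segment_tissues(biased, template.priors, "MRI")
        for tissue in ("GM", "WM", "CSF"):
            assert post.means[tissue] == pytest.approx(
                ph.MRI_INTENSITY[tissue], rel=0.03
            )

    def test_ct_gm_wm_intensity_tied(self, template):
        truth = ph.synthesize_subject(template, 63, deform_amp_mm=2.0,
                                      rigid_amp=(0.0, 0.0))
        ct = ph.render_modalities(truth, template)["ct"]
        anat = ct.with_data(ct.data, frame="template")
        post = segment_tissues(anat, template.priors, "CT")
        assert post.means["GM"] == post.means["WM"]
        assert post.bias is None


class TestWarpEstimation:
    def test_identity_subject_gives_small_field(self, template, brain_mask):
        truth = ph.synthesize_subject(
            template, 64, deform_amp_mm=0.0, rigid_amp=(0.0, 0.0),
            noise_sd={"mri": 0.0, "ct": 0.0, "pet": 0.0},
        )
        mri = ph.render_modalities(truth, template)["mri"]
        anat = mri.with_data(mri.data, frame="template")
        post = segment_tissues(anat, template.priors, "MRI")
        field = estimate_warp(post, template)
        mag = np.sqrt((field.displacement**2).sum(-1))
        assert mag[brain_mask].mean() < 0.5

    def test_known_warp_recovered(self, warp_battery, brain_mask):
        for entry in warp_battery:
            resid = entry["MRI"].displacement - entry["truth"].warp_truth.displacement
            rmag = np.sqrt((resid**2).sum(-1))
            assert rmag[brain_mask].mean() < 1.5

    def test_jacobian_positive_on_brain(self, warp_battery, brain_mask):
        for entry in warp_battery:
            for route in ("MRI", "CT"):
                jac = entry[route].jacobian_determinant()
                assert jac[brain_mask].min() > 0

    def test_ct_weakness_concentrates_in_posterior_fossa(
        self, template, warp_battery
    ):
        """CT-vs-MRI warp disagreement is larger infratentorially on average."""
        cereb = template.compartments["cerebellum"]
        supra = template.compartments["cortical_gm"] | template.compartments[
            "cerebral_wm"
        ]
        post_means, supra_means = [], []
        for entry in warp_battery:
            d = np.sqrt(
                ((entry["MRI"].displacement - entry["CT"].displacement) ** 2).sum(-1)
            )
            post_means.append(d[cereb].mean())
            supra_means.append(d[supra].mean())
        assert np.mean(post_means) >= np.mean(supra_means)

    def test_mri_ct_warps_agree_supratentorially(self, template, warp_battery):
        supra = template.compartments["cortical_gm"] | template.compartments[
            "cerebral_wm"
        ]
        for entry in warp_battery:
            d = np.sqrt(
                ((entry["MRI"].displacement - entry["CT"].displacement) ** 2).sum(-1)
            )
            assert d[supra].mean() < 2.0


class TestNormalizePet:
    def test_identity_mappings_resample_only(self, template):
        truth = ph.synthesize_subject(template, 65, deform_amp_mm=0.0,
                                      rigid_amp=(0.0, 0.0), target_cl=40.0)
        pet = ph.render_modalities(truth, template)["pet"]
        out = normalize_pet(pet, None, np.eye(4), None, template.grid)
        ref = resample(pet, None, template.grid)
        np.testing.assert_allclose(out.data, ref.data, atol=1e-12)
        assert out.frame == "template"

    def test_intensity_scaling_equivariance(self, template):
        truth = ph.synthesize_subject(template, 66, target_cl=40.0)
        pet = ph.render_modalities(truth, template)["pet"]
        rigid = RigidTransform(np.deg2rad([1.0, 0, 0]),
                               np.array([2.0, -1.0, 0.5]), np.zeros(3))
        field = DeformationField.zero(template.grid.shape,
                                      template.grid.affine)
        a = normalize_pet(pet.with_data(3.0 * pet.data), rigid, np.eye(4),
                          field, template.grid)
        b = normalize_pet(pet, rigid, np.eye(4), field, template.grid)
        np.testing.assert_allclose(a.data, 3.0 * b.data, atol=1e-6)

    def test_single_vs_two_step_interpolation(self, template):
        """Composing mappings before resampling loses < 1% intensity."""
        truth = ph.synthesize_subject(template, 67, target_cl=60.0)
        pet = ph.render_modalities(truth, template)["pet"]
        rigid = truth.pet_offset
        affine = truth.rigid_offset.as_matrix()
        warp = truth.warp_truth
        one = normalize_pet(pet, rigid, affine, warp, template.grid)
        step1 = resample(pet, [affine, rigid], template.grid)
        two = resample(step1, warp, template.grid)
        interior = template.brain_mask
        mae = np.abs(one.data - two.data)[interior].mean()
        assert mae < 0.01 * np.ptp(one.data)

    def test_field_round_trip_serialization(self, template, tmp_path):
        truth = ph.synthesize_subject(template, 68, deform_amp_mm=3.0)
        path = tmp_path / "warp.nii.gz"
        save_deformation(truth.warp_truth, path)
        back = load_deformation(path)
        np.testing.assert_allclose(
            back.displacement, truth.warp_truth.displacement, atol=1e-6
        )


class TestNormalizePetOnly:
    def test_already_normalized_pet_nearly_unchanged(self, template):
        from centipet.quantification import compute_suvr

        pet = ph.render_template_pet(template, 50.0, "positive",
                                     noise_sd=0.02, seed=1)
        out = normalize_pet_only(pet, ph.render_template_pet(
            template, 50.0, "positive"))
        assert out.shape == template.grid.shape
        suvr_in = compute_suvr(pet, template.vois)
        suvr_out = compute_suvr(out, template.vois)
        assert suvr_out == pytest.approx(suvr_in, rel=0.01)

    def test_mismatched_template_degrades_accuracy(self, template):
        """Normalizing a negative scan with a positive atlas hurts CL."""
        from centipet.quantification import compute_suvr, suvr_to_centiloid

        truth = ph.synthesize_subject(template, 69, target_cl=0.0,
                                      pattern="negative")
        pet = ph.render_modalities(truth, template)["pet"]
        tmpl_neg = ph.render_template_pet(template, -1.0, "negative")
        tmpl_pos = ph.render_template_pet(template, 92.0, "positive")
        cl_matched = float(suvr_to_centiloid(
            compute_suvr(normalize_pet_only(pet, tmpl_neg), template.vois)))
        cl_mismatched = float(suvr_to_centiloid(
            compute_suvr(normalize_pet_only(pet, tmpl_pos), template.vois)))
        assert abs(cl_mismatched - 0.0) > abs(cl_matched - 0.0)

    def test_requires_template_frame(self, template):
        pet = ph.render_template_pet(template, 10.0, "negative")
        native = pet.with_data(pet.data, frame="native")
        with pytest.raises(ContractViolation):
            normalize_pet_only(pet, native)
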