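import dataclasses

import numpy as np
import pytest

import petcbda.synthetic_pet as sp


class TestBrainGrid:
    def test_default_grid(self, grid):
        assert grid.dims == (24, 28, 24)
        assert np.allclose(grid.affine[:3, :3], np.diag([4.0, 4.0, 4.0]))
        assert np.linalg.det(grid.affine) != 0

    def test_full_scale_grid(self):
        assert sp.full_scale_grid().dims == (91, 109, 91)
        assert sp.full_scale_grid().voxel_size_mm == (2.0, 2.0, 2.0)

    @pytest.mark.parametrize("dims", [(4, 8, 8), (8, 8, 7), (2, 2, 1)])
    def test_too_small_rejected(self, dims):
        with pytest.raises(ValueError, match="dims"):
            sp.BrainGrid(dims=dims, voxel_size_mm=(4.0, 4.0, 4.0))


class TestAtlas:
    def test_required_labels_present_with_min_size(self, atlas):
        names = {sp.full_label_name(*v) for v in atlas.label_table.values()}
        assert set(sp.REQUIRED_LABEL_NAMES) <= names
        for lab in atlas.label_table:
            assert (atlas.labels == lab).sum() >= 20

    def test_putamen_anterior_example(self, atlas):
        labs = atlas.labels_named("putamen(anterior)")
        assert labs and all((atlas.labels == l).sum() >= 20 for l in labs)

    def test_deterministic_for_seed(self, grid):
        a = sp.build_default_atlas(grid, seed=11)
        b = sp.build_default_atlas(grid, seed=11)
        assert np.array_equal(a.labels, b.labels)
        assert a.label_table == b.label_table

    def test_label_count_matches_table(self, atlas):
        present = set(np.unique(atlas.labels)) - {0}
        assert len(present) == len(atlas.label_table)

    def test_bilateral_share_roi_name(self, atlas):
        labs = atlas.labels_named("insula(anterior)")
        assert len(labs) == 2

    def test_grid_too_small_names_roi(self):
        tiny = sp.BrainGrid(dims=(8, 8, 8), voxel_size_mm=(4.0, 4.0, 4.0))
        with pytest.raises(ValueError, match="too small to place ROI"):
            sp.build_default_atlas(tiny, seed=0)

    def test_masks(self, atlas, masks):
        assert masks["CFN"].mask.sum() > masks["RCL"].mask.sum() > 0
        # RCL mask is exactly the basal ganglia labels
        bg = atlas.mask_of(sorted(sp.BASAL_GANGLIA_ROIS))
        assert np.array_equal(masks["RCL"].mask, bg)
        # cerebellum excluded from the CFN mask
        assert not (masks["CFN"].mask & atlas.mask_of(["cerebellar grey"])).any()


class TestCohort:
    def test_default_counts(self, default_sessions):
        counts = sp.summarize_counts(default_sessions)
        assert counts["images"] == 198
        assert counts["CFN_subjects"] == 61
        assert counts["CFN_images"] == 138
        assert counts["RCL_subjects"] == 22
        assert counts["RCL_images"] == 60
        assert counts["migraine_images"] == 132
        assert counts["CFN_em_interictal_images"] == 62
        assert counts["RCL_em_interictal_images"] == 24

    def test_image_count_is_twice_sessions(self, default_sessions):
        assert len(sp.list_images(default_sessions)) == 2 * len(default_sessions)

    @pytest.mark.parametrize("n_hc,n_em", [(2, 3), (5, 1), (0, 4)])
    def test_closed_form_counts(self, n_hc, n_em):
        spec = sp.CohortSpec(
            strata=(
                sp.Stratum("hc", "CFN", "HC", "none", n_hc, n_hc // 2),
                sp.Stratum("em", "CFN", "EM", "interictal", n_em, n_em // 2),
            )
        )
        sessions = sp.generate_cohort(spec)
        assert len(sp.list_images(sessions)) == 2 * (n_hc + n_em)

    def test_linked_subjects_are_stable(self, default_sessions):
        by_stratum = {}
        for s in default_sessions:
            by_stratum.setdefault((s.tracer, s.group, s.state), set()).add(s.subject_id)
        # RCL HC subjects are a subset of CFN HC subjects, same ids
        assert by_stratum[("RCL", "HC", "none")] <= by_stratum[("CFN", "HC", "none")]
        # ictal EM subjects are a subset of the interictal EM roster
        assert by_stratum[("CFN", "EM", "ictal")] <= by_stratum[("CFN", "EM", "interictal")]
        assert by_stratum[("RCL", "EM", "ictal")] <= by_stratum[("RCL", "EM", "interictal")]

    def test_linked_stratum_too_large_fails(self):
        spec = sp.CohortSpec(
            strata=(
                sp.Stratum("em", "CFN", "EM", "interictal", 3, 2),
                sp.Stratum("em_ictal", "CFN", "EM", "ictal", 5, 2, link_to="em"),
            )
        )
        with pytest.raises(ValueError, match="larger"):
            sp.generate_cohort(spec)

    def test_unknown_parent_fails(self):
        spec = sp.CohortSpec(
            strata=(sp.Stratum("x", "CFN", "EM", "ictal", 1, 0, link_to="nope"),)
        )
        with pytest.raises(ValueError, match="unknown"):
            sp.generate_cohort(spec)


def _flat_effects(**kw):
    base = dict(baseline_dvr={"default": 1.0}, noise_sd=0.0)
    base.update(kw)
    return sp.EffectSpec(**base)


class TestSimulateImage:
    def _record(self, group="HC", tracer="CFN", phase="early"):
        return sp.ImageRecord("s1", tracer, group, "none", phase, "F")

    def test_flat_baseline_gives_unit_dvr(self, atlas):
        im = sp.simulate_image(self._record(), _flat_effects(), atlas,
                               np.random.default_rng(0))
        in_brain = atlas.labels > 0
        assert np.allclose(im.dvr[in_brain], 1.0)
        assert np.allclose(im.bpnd[in_brain], 0.0)

    def test_group_effect_recovered_exactly(self, atlas):
        eff = _flat_effects(
            baseline_dvr={"default": 2.0, "occipital": 1.0, "cerebellar grey": 1.0},
            group_effects=(sp.GroupEffect("CFN", 0.5, labels=("insula(anterior)",)),),
        )
        rng = np.random.default_rng
        em = sp.simulate_image(self._record(group="EM"), eff, atlas, rng(0))
        hc = sp.simulate_image(self._record(group="HC"), eff, atlas, rng(0))
        diff = em.dvr - hc.dvr
        roi = atlas.mask_of(["insula(anterior)"])
        assert np.allclose(diff[roi], 0.5)
        assert np.allclose(diff[~roi], 0.0)

    def test_effect_requires_matching_tracer(self, atlas):
        eff = _flat_effects(
            group_effects=(sp.GroupEffect("RCL", 0.5, labels=("insula(anterior)",)),)
        )
        em = sp.simulate_image(self._record(group="EM"), eff, atlas,
                               np.random.default_rng(0))
        assert np.allclose(em.dvr[atlas.labels > 0], 1.0)

    def test_phase_effect_on_late_only(self, atlas):
        eff = _flat_effects(phase_effect=0.25)
        early = sp.simulate_image(self._record(phase="early"), eff, atlas,
                                  np.random.default_rng(0))
        late = sp.simulate_image(self._record(phase="late"), eff, atlas,
                                 np.random.default_rng(0))
        in_brain = (atlas.labels > 0) & ~atlas.mask_of(["occipital"])
        assert np.allclose((late.dvr - early.dvr)[in_brain], 0.25)

    def test_noise_deterministic_given_rng(self, atlas):
        eff = _flat_effects(noise_sd=0.3)
        a = sp.simulate_image(self._record(), eff, atlas, np.random.default_rng(42))
        b = sp.simulate_image(self._record(), eff, atlas, np.random.default_rng(42))
        assert np.array_equal(a.bpnd, b.bpnd)

    def test_reference_region_pinned_despite_noise(self, atlas):
        eff = _flat_effects(noise_sd=0.5)
        im = sp.simulate_image(self._record(tracer="CFN"), eff, atlas,
                               np.random.default_rng(1))
        assert np.all(im.dvr[atlas.mask_of(["occipital"])] == 1.0)
        rcl = sp.simulate_image(self._record(tracer="RCL"), eff, atlas,
                                np.random.default_rng(1))
        assert np.all(rcl.dvr[atlas.mask_of(["cerebellar grey"])] == 1.0)

    def test_dvr_clipped_nonnegative(self, atlas):
        eff = _flat_effects(noise_sd=3.0)
        im = sp.simulate_image(self._record(), eff, atlas, np.random.default_rng(2))
        assert np.all(im.dvr >= 0)
        assert np.all(im.bpnd >= -1)


class TestSimulateCohort:
    def test_bit_identical_for_same_seed(self, atlas):
        spec = sp.mini_cohort_spec()
        eff = sp.default_effect_spec(seed=9, noise_sd=0.2)
        a = sp.simulate_cohort(spec, eff, atlas)
        b = sp.simulate_cohort(spec, eff, atlas)
        assert len(a) == len(b) == 24
        for x, z in zip(a, b):
            assert dataclasses.asdict(x) | {"bpnd": None} == dataclasses.asdict(z) | {"bpnd": None}
            assert np.array_equal(x.bpnd, z.bpnd)

    def test_seed_changes_volumes(self, atlas):
        spec = sp.mini_cohort_spec()
        a = sp.simulate_cohort(spec, sp.default_effect_spec(seed=1, noise_sd=0.2), atlas)
        b = sp.simulate_cohort(spec, sp.default_effect_spec(seed=2, noise_sd=0.2), atlas)
        assert not np.array_equal(a[0].bpnd, b[0].bpnd)


class TestWriteCohort:
    def test_roundtrip(self, atlas, tmp_path):
        spec = sp.CohortSpec(
            strata=(sp.Stratum("hc", "CFN", "HC", "none", 2, 1),)
        )
        eff = sp.default_effect_spec(seed=5, noise_sd=0.2)
        images = sp.simulate_cohort(spec, eff, atlas)
        assert len(images) == 4
        manifest = sp.write_cohort(images, tmp_path)
        assert len(manifest) == 4
        assert (tmp_path / "manifest.tsv").exists()
        back = sp.read_cohort(tmp_path)
        assert len(back) == 4
        for orig, rb in zip(images, back):
            assert orig.subject_id == rb.subject_id
            assert np.max(np.abs(orig.bpnd - rb.bpnd)) <= 1e-6

    def test_atlas_roundtrip(self, atlas, tmp_path):
        sp.write_atlas(atlas, tmp_path)
        back = sp.read_atlas(tmp_path)
        assert np.array_equal(back.labels, atlas.labels)
        assert back.label_table == atlas.label_table
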