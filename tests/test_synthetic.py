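import numpy as np
import pytest
from scipy import ndimage

from histotriage.classifier import texture_statistics
from histotriage.hierarchy import CLASSES, DiagnosticClass, class_from_code
from histotriage.synthetic import (
    CohortSpec,
    GroundTruthMap,
    SlidePlacementError,
    SyntheticSlideSpec,
    add_artifacts,
    generate_class_tile,
    generate_cohort,
    generate_slide,
)

D = DiagnosticClass


def small_spec(**kw):
    defaults = dict(
        slide_id="SP1-A-1",
        true_classes=[D.normal_large_bowel],
        n_sections=2,
        image_size=(1024, 1024),
        seed=1,
    )
    defaults.update(kw)
    return SyntheticSlideSpec(**defaults)


class TestGenerateSlide:
    def test_sections_rendered_and_single_class_truth(self):
        spec = small_spec(n_sections=3)
        slide, truth = generate_slide(spec)
        assert slide.pixels.shape == (1024, 1024, 3)
        _, n_components = ndimage.label(truth.label_image > 0)
        assert n_components == 3
        assert truth.slide_truth is D.normal_large_bowel

    def test_mixed_slide_truth_is_hierarchy_maximum(self):
        spec = small_spec(true_classes=[D.normal_large_bowel, D.adenoma])
        _, truth = generate_slide(spec)
        assert truth.classes_present() == {D.normal_large_bowel, D.adenoma}
        assert truth.slide_truth is D.adenoma

    def test_deterministic_for_identical_spec_and_seed(self):
        a, ta = generate_slide(small_spec(seed=7))
        b, tb = generate_slide(small_spec(seed=7))
        assert np.array_equal(a.pixels, b.pixels)
        assert np.array_equal(ta.label_image, tb.label_image)

    def test_different_seeds_differ(self):
        a, _ = generate_slide(small_spec(seed=1))
        b, _ = generate_slide(small_spec(seed=2))
        assert not np.array_equal(a.pixels, b.pixels)

    def test_ground_truth_consistency_brute_force(self):
        """slide_truth always equals the min-rank over codes in the raster."""
        for seed in range(3):
            spec = small_spec(
                true_classes=[D.inflammation, D.hp_ssl], n_sections=3, seed=seed
            )
            _, truth = generate_slide(spec)
            codes = {int(c) for c in np.unique(truth.label_image) if c > 0}
            expected = min(
                (class_from_code(c) for c in codes), key=lambda cls: cls.rank
            )
            assert truth.slide_truth is expected

    def test_placement_error_when_sections_do_not_fit(self):
        with pytest.raises(SlidePlacementError):
            generate_slide(small_spec(image_size=(512, 512), n_sections=12))

    @pytest.mark.parametrize(
        "kw",
        [
            dict(n_sections=0),
            dict(image_size=(256, 1024)),
            dict(true_classes=[]),
            dict(artifact_types=frozenset({"scratch"})),
        ],
    )
    def test_invalid_spec_rejected(self, kw):
        with pytest.raises(ValueError):
            small_spec(**kw)


class TestArtifacts:
    def _image(self):
        rng = np.random.default_rng(0)
        return np.clip(246 + 3 * rng.standard_normal((600, 600, 3)), 0, 255).astype(
            np.uint8
        )

    def test_empty_set_is_identity(self):
        img = self._image()
        assert np.array_equal(add_artifacts(img, set(), seed=0), img)

    def test_unknown_artifact_rejected(self):
        with pytest.raises(ValueError, match="unknown artifact"):
            add_artifacts(self._image(), {"smudge"}, seed=0)

    def test_coverslip_edge_draws_dark_line_near_border(self):
        out = add_artifacts(self._image(), {"coverslip_edge"}, seed=3)
        h, w = out.shape[:2]
        margin = int(0.06 * h) + 3
        border = np.concatenate(
            [
                out[:margin].reshape(-1, 3),
                out[-margin:].reshape(-1, 3),
                out[:, :margin].reshape(-1, 3),
                out[:, -margin:].reshape(-1, 3),
            ]
        )
        assert (border.mean(axis=1) < 80).sum() > 500  # a dark straight segment

    def test_deterministic_overlay(self):
        img = self._image()
        a = add_artifacts(img, {"bubble", "printing", "dust"}, seed=9)
        b = add_artifacts(img, {"bubble", "printing", "dust"}, seed=9)
        assert np.array_equal(a, b)

    def test_artifacts_do_not_touch_ground_truth(self):
        spec = small_spec(artifact_types=frozenset({"fold", "dust"}))
        _, with_art = generate_slide(spec)
        _, without = generate_slide(small_spec())
        assert np.array_equal(with_art.label_image, without.label_image)

    def test_input_must_be_rgb(self):
        with pytest.raises(ValueError, match="RGB"):
            add_artifacts(np.zeros((10, 10), np.uint8), {"dust"}, seed=0)


class TestCohort:
    def test_identifier_scheme_and_structure(self):
        spec = CohortSpec(
            n_cases=2,
            class_mix={D.normal_large_bowel: 1.0},
            image_size=(1024, 1024),
            n_sections=1,
            seed=0,
        )
        cases = generate_cohort(spec, render=False)
        assert [c.case_id for c in cases] == ["SP2312345", "SP2312346"]
        for case in cases:
            for i, letter in enumerate(sorted(case.specimens)):
                assert letter == "ABCDE"[i]
                for k, slide_id in enumerate(case.specimens[letter], start=1):
                    assert slide_id == f"{case.case_id}-{letter}-{k}"
            for slide_id in [s for ids in case.specimens.values() for s in ids]:
                _, truth = case.slide_data[slide_id]
                assert isinstance(truth, GroundTruthMap)

    def test_pure_mix_gives_uniform_truth(self):
        spec = CohortSpec(
            n_cases=5, class_mix={D.normal_large_bowel: 1.0}, seed=3
        )
        for case in generate_cohort(spec, render=False):
            assert case.truth_diagnosis is D.normal_large_bowel

    def test_case_truth_is_hierarchy_max_over_slides(self):
        spec = CohortSpec(
            n_cases=8,
            class_mix={D.adenoma: 0.5, D.inflammation: 0.5},
            image_size=(1024, 1024),
            n_sections=1,
            specimens_per_case=(1, 2),
            seed=5,
        )
        for case in generate_cohort(spec, render=True):
            slide_truths = [t.slide_truth for _, t in case.slide_data.values()]
            assert case.truth_diagnosis is min(slide_truths, key=lambda c: c.rank)

    def test_class_mix_binomial_recovery(self):
        """Sampled adenoma fraction within 3 binomial SEs of the mix."""
        p = 0.30
        n = 500
        spec = CohortSpec(
            n_cases=n,
            class_mix={D.adenoma: p, D.normal_large_bowel: 1 - p},
            seed=42,
        )
        cases = generate_cohort(spec, render=False)
        frac = np.mean([c.truth_diagnosis is D.adenoma for c in cases])
        assert abs(frac - p) <= 3 * np.sqrt(p * (1 - p) / n)

    def test_reproducible_by_seed(self):
        spec = dict(
            n_cases=3,
            class_mix={D.adenoma: 0.5, D.normal_large_bowel: 0.5},
            image_size=(1024, 1024),
            n_sections=1,
            seed=9,
        )
        a = generate_cohort(CohortSpec(**spec))
        b = generate_cohort(CohortSpec(**spec))
        for ca, cb in zip(a, b):
            assert ca.case_id == cb.case_id
            assert ca.scan_complete == cb.scan_complete
            for sid in ca.slide_data:
                assert np.array_equal(
                    ca.slide_data[sid][0].pixels, cb.slide_data[sid][0].pixels
                )

    def test_invalid_cohort_specs(self):
        with pytest.raises(ValueError):
            CohortSpec(n_cases=0, class_mix={D.adenoma: 1.0})
        with pytest.raises(ValueError, match="sum to 1"):
            CohortSpec(n_cases=1, class_mix={D.adenoma: 0.7})


def test_class_textures_are_separable():
    """Mean texture statistics differ between every class pair by more than
    5 within-class standard deviations in at least one feature."""
    per_class = 100
    stats = {
        cls: np.array(
            [
                texture_statistics(generate_class_tile(cls, size=128, seed=i))
                for i in range(per_class)
            ]
        )
        for cls in CLASSES
    }
    for i, a in enumerate(CLASSES):
        for b in CLASSES[i + 1 :]:
            mu_gap = np.abs(stats[a].mean(axis=0) - stats[b].mean(axis=0))
            sd = np.maximum(stats[a].std(axis=0), stats[b].std(axis=0))
            assert (mu_gap > 5 * np.maximum(sd, 1e-9)).any(), (a, b)
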