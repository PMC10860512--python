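"""Phantom generator: geometry oracles, determinism, observer simulation."""

import numpy as np
import pytest
from dataclasses import replace

from gtvseg.metrics import pairwise_observer_dsc
from gtvseg.phantom import (
    DomainSpec,
    ObserverSimConfig,
    attach_observers,
    generate_cohort,
    generate_subject,
    simulate_observers,
)


def _sphere_spec(radius=8.0, thickness=2.0):
    return DomainSpec(
        name="sphere",
        image_size=64,
        n_slices_range=(16, 16),
        pixel_spacing_mm=1.0,
        slice_thickness_mm=thickness,
        noise_sd_hu=0.0,
        tumour_irregularity=0.0,
        tumour_radius_range_mm=(radius, radius),
    )


class TestGenerateSubject:
    def test_deterministic_for_fixed_seed(self, source_spec):
        a = generate_subject(source_spec, 42)
        b = generate_subject(source_spec, 42)
        assert np.array_equal(a.volume.data, b.volume.data)
        assert np.array_equal(a.truth_mask, b.truth_mask)

    def test_different_seeds_differ(self, source_spec):
        a = generate_subject(source_spec, 1)
        b = generate_subject(source_spec, 2)
        assert not np.array_equal(a.volume.data, b.volume.data)

    def test_noiseless_sphere_volume_matches_analytic(self):
        """Zero irregularity: the mask is a discretized ellipsoid whose voxel
        count matches 4/3*pi*r^3 divided by the voxel volume."""
        spec = _sphere_spec()
        voxel_mm3 = spec.slice_thickness_mm * spec.pixel_spacing_mm ** 2
        analytic = 4 / 3 * np.pi * 8.0 ** 3 / voxel_mm3
        for seed in (5, 6, 7):
            sub = generate_subject(spec, seed)
            count = int(sub.truth_mask.sum())
            assert abs(count - analytic) / analytic < 0.12

    def test_equatorial_slice_area_matches_circle(self):
        """Largest per-slice area of an 8 mm sphere at 1 mm/px is ~ pi*8^2,
        checked against brute-force pixel counting inside the analytic circle."""
        spec = _sphere_spec(thickness=1.0)  # fine z sampling puts a slice at the equator
        sub = generate_subject(spec, 9)
        max_area = int(sub.truth_mask.sum(axis=(1, 2)).max())
        # oracle: count pixels inside a radius-8 circle on the same grid offsets
        xs = np.arange(64)
        best = max(
            int((((xs[:, None] - cr) ** 2 + (xs[None, :] - cc) ** 2) <= 64.0).sum())
            for cr in np.linspace(20, 44, 9) for cc in np.linspace(20, 44, 9)
        )
        assert abs(max_area - np.pi * 64) / (np.pi * 64) < 0.1
        assert max_area <= best + 8

    def test_tumour_intensity_and_lung_layout(self, source_spec):
        sub = generate_subject(replace(source_spec, noise_sd_hu=0.0), 3)
        inside = sub.volume.data[sub.truth_mask.astype(bool)]
        lo, hi = source_spec.tumour_hu_range
        assert lo - 1 <= inside.mean() <= hi + 1
        assert (sub.volume.data.min() < source_spec.lung_hu + 50)  # lung fields present

    def test_image_too_small_rejected(self):
        spec = replace(_sphere_spec(radius=12.0), image_size=32)
        with pytest.raises(ValueError):
            generate_subject(spec, 0)

    def test_feet_first_is_flipped_head_first(self, source_spec):
        hf = generate_subject(source_spec, 21)
        ff = generate_subject(replace(source_spec, orientation="feet-first"), 21)
        assert np.array_equal(ff.truth_mask[::-1], hf.truth_mask)
        assert np.array_equal(ff.canonical().truth_mask, hf.truth_mask)


class TestGenerateCohort:
    def test_single_subject_matches_derived_seed(self, source_spec):
        cohort = generate_cohort(source_spec, 1, seed=99)
        derived = int(np.random.SeedSequence(99).generate_state(1)[0] % (2 ** 31))
        solo = generate_subject(source_spec, derived, subject_id=cohort[0].id)
        assert np.array_equal(cohort[0].volume.data, solo.volume.data)

    def test_unique_ids_and_seed_sensitivity(self, source_spec):
        c1 = generate_cohort(source_spec, 4, seed=1)
        c2 = generate_cohort(source_spec, 4, seed=2)
        assert len({s.id for s in c1}) == 4
        assert not np.array_equal(c1[0].volume.data, c2[0].volume.data)

    def test_tumour_volume_distribution_in_configured_range(self, source_spec):
        """Monte-Carlo: median tumour volume lies inside the interval implied
        by the configured radius range."""
        spec = replace(source_spec, tumour_irregularity=0.2)
        cohort = generate_cohort(spec, 200, seed=5)
        voxel_mm3 = spec.slice_thickness_mm * spec.pixel_spacing_mm ** 2
        volumes = np.array([s.truth_mask.sum() * voxel_mm3 for s in cohort])
        v_lo = 4 / 3 * np.pi * spec.tumour_radius_range_mm[0] ** 3
        v_hi = 4 / 3 * np.pi * spec.tumour_radius_range_mm[1] ** 3
        assert v_lo < np.median(volumes) < v_hi


class TestSimulateObservers:
    def test_zero_perturbation_identity(self, source_spec):
        sub = generate_subject(source_spec, 8)
        cfg = ObserverSimConfig(boundary_sd_mm=0.0, bias_mm=(0.0,) * 5, seed=1)
        for m in simulate_observers(sub.truth_mask, cfg, sub.volume.spacing):
            assert np.array_equal(m.astype(bool), sub.truth_mask.astype(bool))

    def test_positive_bias_strict_superset(self, source_spec):
        sub = generate_subject(source_spec, 8)
        cfg = ObserverSimConfig(boundary_sd_mm=0.0, bias_mm=(2.0,) * 5, seed=1)
        truth = sub.truth_mask.astype(bool)
        for m in simulate_observers(sub.truth_mask, cfg, sub.volume.spacing):
            m = m.astype(bool)
            assert np.all(m >= truth) and m.sum() > truth.sum()

    def test_consensus_brackets_truth(self, source_spec):
        """With unbiased jitter the unanimous region sits inside the truth
        and the union contains it (voxelwise vote-count oracle)."""
        sub = generate_subject(replace(source_spec, tumour_radius_range_mm=(6.0, 6.5)), 8)
        cfg = ObserverSimConfig(boundary_sd_mm=1.0, bias_mm=(0.0,) * 5, seed=3)
        masks = simulate_observers(sub.truth_mask, cfg, sub.volume.spacing)
        votes = sum(m.astype(int) for m in masks)
        truth = sub.truth_mask.astype(bool)
        assert np.all((votes >= 5) <= truth)
        assert np.all(truth <= (votes >= 1))

    def test_aggressive_config_raises(self, source_spec):
        sub = generate_subject(source_spec, 8)
        cfg = ObserverSimConfig(boundary_sd_mm=0.0, bias_mm=(-50.0,) * 5, seed=1)
        with pytest.raises(ValueError):
            simulate_observers(sub.truth_mask, cfg, sub.volume.spacing)

    def test_default_config_lands_in_expert_dsc_band(self, source_spec):
        """Calibration check: pairwise observer DSC median in [0.7, 0.9]."""
        cfg = ObserverSimConfig(seed=7)
        dscs = []
        for seed in range(300, 310):
            sub = attach_observers(generate_subject(source_spec, seed), cfg)
            dscs += [r.dsc for r in pairwise_observer_dsc(sub.observer_masks, sub.id)]
        assert 0.7 <= float(np.median(dscs)) <= 0.9

    def test_determinism(self, source_spec):
        sub = generate_subject(source_spec, 8)
        cfg = ObserverSimConfig(seed=11)
        m1 = simulate_observers(sub.truth_mask, cfg, sub.volume.spacing)
        m2 = simulate_observers(sub.truth_mask, cfg, sub.volume.spacing)
        assert all(np.array_equal(a, b) for a, b in zip(m1, m2))


def test_domain_shift_changes_intensity_histogram(source_spec, target_spec):
    """Two domains differing in offset/noise give a nonzero KS statistic on
    normalized intensities — the property transfer learning depends on."""
    from scipy.stats import ks_2samp
    from gtvseg.imaging import window_normalize

    shifted = replace(
        source_spec,
        intensity_offset_hu=target_spec.intensity_offset_hu,
        noise_sd_hu=target_spec.noise_sd_hu,
    )
    a = window_normalize(generate_subject(source_spec, 4).volume).data.ravel()[:15000]
    b = window_normalize(generate_subject(shifted, 4).volume).data.ravel()[:15000]
    assert ks_2samp(a, b).statistic > 0.05
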