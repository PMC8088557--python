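"""Synthetic phantom generation, controlled perturbations and analytic dose."""

import numpy as np
import pytest

from rtqa_bench import (
    DosePrescription,
    GeometryError,
    Mask3D,
    PerturbationSpec,
    PhantomSpec,
    StructureRecipe,
    compute_hd,
    compute_dsi,
    directed_percentile_hd,
    extract_surface,
    make_cohort,
    make_dose,
    make_phantom,
    perturb_structure,
    structure_dose_metric,
)
from rtqa_bench.dosimetry import DoseMetricSpec
from rtqa_bench.errors import ConfigError
from rtqa_bench.phantoms import DELINEATION_DEVIATION_COUNTS, default_schedule

R = StructureRecipe.make


def sphere_spec(radius=20.0, spacing=2.0, n=40):
    c = n * spacing / 2
    return PhantomSpec(
        shape=(n, n, n), spacing=(spacing,) * 3, origin=(0.0, 0.0, 0.0),
        structures={"sphere": R("ellipsoid", center=(c, c, c), radii=(radius,) * 3)},
    )


def tube_spec(length=100.0, radius=8.0, spacing=2.0):
    return PhantomSpec(
        shape=(70, 20, 20), spacing=(spacing,) * 3, origin=(0.0, 0.0, 0.0),
        structures={"tube": R("tube", center=(20.0, 20.0), radius=radius,
                              z_range=(10.0, 10.0 + length))},
    )


class TestMakePhantom:
    def test_sphere_volume_matches_analytic_within_five_percent(self):
        gold = make_phantom(sphere_spec(radius=20.0, spacing=2.0))
        analytic = 4.0 / 3.0 * np.pi * 20.0**3
        assert gold["sphere"].n_voxels * 8.0 == pytest.approx(analytic, rel=0.05)

    def test_deterministic(self):
        a = make_phantom(sphere_spec())["sphere"]
        b = make_phantom(sphere_spec())["sphere"]
        assert np.array_equal(a.data, b.data)

    def test_nested_ptv_containment_holds_voxelwise(self, head_neck_gold):
        t = head_neck_gold["therapeutic_ptv"].data
        p = head_neck_gold["prophylactic_ptv"].data
        assert not np.any(t & ~p)

    def test_all_fifteen_structures_nonempty(self, head_neck_gold):
        assert len(head_neck_gold) == 15
        assert all(not m.is_empty for m in head_neck_gold.values())

    def test_out_of_grid_recipe_raises(self):
        spec = sphere_spec()
        spec.structures["oob"] = R("ellipsoid", center=(200.0, 0.0, 0.0), radii=(5.0, 5.0, 5.0))
        with pytest.raises(GeometryError):
            make_phantom(spec)


class TestPerturbations:
    def test_zero_magnitude_is_identity_for_every_geometric_mode(self):
        gold = make_phantom(sphere_spec())["sphere"]
        for mode in ("dilate", "erode", "translate", "crop_longitudinal",
                     "extend_longitudinal", "boundary_noise"):
            out = perturb_structure(gold, PerturbationSpec(mode, 0.0))
            assert np.array_equal(out.data, gold.data), mode

    def test_omit_returns_empty_mask(self):
        gold = make_phantom(sphere_spec())["sphere"]
        assert perturb_structure(gold, PerturbationSpec("omit_structure")).is_empty

    def test_translated_sphere_hd_equals_shift(self):
        gold = make_phantom(sphere_spec())["sphere"]
        shifted = perturb_structure(
            gold, PerturbationSpec("translate", 4.0, direction=(0, 0, 1))
        )
        voxel_diag = np.linalg.norm(gold.spacing)
        assert compute_hd(gold, shifted, 100).hd == pytest.approx(4.0, abs=voxel_diag)

    def test_cropped_tube_directed_hd_equals_crop_length(self):
        gold = make_phantom(tube_spec())["tube"]
        k_mm = 10.0
        cropped = perturb_structure(gold, PerturbationSpec("crop_longitudinal", k_mm))
        d = directed_percentile_hd(extract_surface(gold), extract_surface(cropped), 100)
        assert d == pytest.approx(k_mm, abs=gold.spacing[0])

    def test_erosion_to_emptiness_is_legal(self):
        gold = make_phantom(sphere_spec(radius=6.0))["sphere"]
        out = perturb_structure(gold, PerturbationSpec("erode", 10.0))
        assert out.is_empty

    def test_boundary_noise_is_seeded(self):
        gold = make_phantom(sphere_spec())["sphere"]
        a = perturb_structure(gold, PerturbationSpec("boundary_noise", 0.2, seed=42))
        b = perturb_structure(gold, PerturbationSpec("boundary_noise", 0.2, seed=42))
        c = perturb_structure(gold, PerturbationSpec("boundary_noise", 0.2, seed=43))
        assert np.array_equal(a.data, b.data)
        assert not np.array_equal(a.data, c.data)

    def test_translation_magnitude_recovery_slope(self):
        """Measured HD(p=100) tracks the scripted shift with unit slope."""
        gold = make_phantom(sphere_spec())["sphere"]
        mags = np.array([2.0, 4.0, 6.0, 8.0, 10.0, 12.0])
        measured = [
            compute_hd(gold, perturb_structure(
                gold, PerturbationSpec("translate", m, direction=(0, 1, 0))), 100).hd
            for m in mags
        ]
        slope = np.polyfit(mags, measured, 1)[0]
        assert slope == pytest.approx(1.0, abs=np.linalg.norm(gold.spacing) / np.ptp(mags))

    def test_dilation_dsi_matches_shell_volume_ratio(self):
        """DSI of sphere vs dilated sphere ~ 2r^3/(r^3 + (r+t)^3)."""
        r, t = 24.0, 4.0
        gold = make_phantom(sphere_spec(radius=r, spacing=2.0, n=40))["sphere"]
        dil = perturb_structure(gold, PerturbationSpec("dilate", t))
        expected = 2 * r**3 / (r**3 + (r + t) ** 3)
        assert compute_dsi(gold, dil) == pytest.approx(expected, rel=0.10)

    def test_longitudinal_crop_hits_hd_but_spares_dsi(self):
        """Cropping 10% of a 100 mm tube: DSI stays >= 0.90 while the
        directed HD from gold reaches the crop length — the boundary-error
        sensitivity that makes percentile HD the better screen for
        elongated organs."""
        gold = make_phantom(tube_spec(length=100.0))["tube"]
        cropped = perturb_structure(gold, PerturbationSpec("crop_longitudinal", 10.0))
        assert compute_dsi(gold, cropped) >= 0.90
        d = directed_percentile_hd(extract_surface(gold), extract_surface(cropped), 100)
        assert d >= 9.0


class TestDose:
    def test_prescription_dose_inside_therapeutic_ptv(self, head_neck_gold):
        dose = make_dose(head_neck_gold)
        assert np.all(dose.data[head_neck_gold["therapeutic_ptv"].data] == 66.0)

    def test_far_corner_receives_negligible_dose(self, head_neck_gold):
        dose = make_dose(head_neck_gold)
        assert dose.data[0, 0, 0] < 1.0

    def test_target_coverage_by_construction(self, head_neck_gold):
        dose = make_dose(head_neck_gold)
        d95 = structure_dose_metric(
            dose, head_neck_gold["therapeutic_ptv"], DoseMetricSpec("Dcoverage", 95)
        )
        assert d95 >= 0.95 * 66.0

    def test_missing_ptv_is_a_config_error(self, head_neck_gold):
        structures = {k: v for k, v in head_neck_gold.items() if k != "therapeutic_ptv"}
        with pytest.raises(ConfigError):
            make_dose(structures)


class TestCohortScripting:
    def test_default_schedule_counts(self):
        schedule = default_schedule(35)
        assert len(schedule) == 35
        rounds = sorted(len(s) for s in schedule)
        assert sum(r > 1 for r in rounds) == 23
        assert (rounds[0], rounds[-1]) == (1, 4)
        bad_total = sum(len(rs.bad_structures) for s in schedule for rs in s)
        assert bad_total == sum(DELINEATION_DEVIATION_COUNTS.values())
        planning = sum(rs.planning_bad for s in schedule for rs in s)
        assert planning == 9

    def test_no_structure_repeats_within_a_round(self):
        for scripts in default_schedule(35):
            for rs in scripts:
                assert len(rs.bad_structures) == len(set(rs.bad_structures))

    def test_same_seed_gives_identical_cohort(self):
        a = make_cohort(2, seed=11)
        b = make_cohort(2, seed=11)
        for inst in a.submissions:
            for ra, rb in zip(a.submissions[inst], b.submissions[inst]):
                for name in ra.structures:
                    assert np.array_equal(ra.structures[name].data, rb.structures[name].data)
                if ra.dose is not None:
                    assert np.array_equal(ra.dose.data, rb.dose.data)

    def test_different_seed_changes_contour_noise(self):
        a = make_cohort(1, seed=1)
        b = make_cohort(1, seed=2)
        same = all(
            np.array_equal(
                a.submissions["INST-01"][0].structures[n].data,
                b.submissions["INST-01"][0].structures[n].data,
            )
            for n in a.gold
        )
        assert not same
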