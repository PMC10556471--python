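"""Subfields, weighting, feathering, normalization, and composite invariants."""

import hashlib

import numpy as np
import pytest

import csiplan as cp
from csiplan.beams import PlanningError
from csiplan.dose import DoseGrid
from csiplan.planning import (Prescription, assemble_composite,
                              coverage_scalar, feather_plan, normalize,
                              optimize_spine_weights)
from csiplan.precheck import run_precheck
from csiplan.structures import Grid, LabeledVolume


class TestPrescription:
    def test_defaults_are_the_csi_prescription(self):
        rx = Prescription()
        assert rx.total_dose_gy == 23.4
        assert rx.n_fractions == 13
        assert rx.feather_fractions == (5, 5, 3)
        assert rx.threshold_gy == pytest.approx(0.95 * 23.4)

    def test_validation(self):
        with pytest.raises(ValueError):
            Prescription(feather_fractions=(5, 5, 5))
        with pytest.raises(ValueError):
            Prescription(brain_coverage_rule=0.0)


class TestSubfields:
    def test_single_plan_has_one_subfield(self, default_plan):
        for fs in default_plan.sub_plans:
            assert len(fs.spine_subfields) == 1

    def test_multiple_plan_has_four_subfields(self, multiple_plan):
        for fs in multiple_plan.sub_plans:
            assert len(fs.spine_subfields) == 4
            assert len(fs.spine_beams) == 2

    @pytest.mark.parametrize("plan_fixture", ["default_plan", "multiple_plan"])
    def test_subfield_aperture_subset_of_parent(self, plan_fixture, request):
        plan = request.getfixturevalue(plan_fixture)
        for fs in plan.sub_plans:
            parents = {b.label: b for b in fs.spine_beams}
            for sub in fs.spine_subfields:
                parent = parents[sub.label.rsplit("_sub", 1)[0]]
                for l, r, pl, pr in zip(sub.mlc_left_cm, sub.mlc_right_cm,
                                        parent.mlc_left_cm, parent.mlc_right_cm):
                    closed = l == r
                    assert closed or (pl - 1e-9 <= l and r <= pr + 1e-9)


class TestOptimizer:
    def test_flat_profile_keeps_zero_weights(self):
        w, _ = optimize_spine_weights(np.full(40, 2.0), [np.ones(40)])
        assert np.all(w == 0.0)

    def test_matches_brute_force_grid_on_toy_midline(self):
        # one hot segment; the subfield is open only over the cold one
        parent = np.array([1.2, 1.2, 1.0, 1.0])
        sub = np.array([0.0, 0.0, 1.0, 1.0])
        w, _ = optimize_spine_weights(parent, [sub])

        grid = np.arange(0.0, 1.5001, 0.01)
        spreads = [(np.max(parent + g * sub) - np.min(parent + g * sub))
                   / np.mean(parent + g * sub) for g in grid]
        w_grid = grid[int(np.argmin(spreads))]
        assert abs(w[0] - w_grid) <= 0.011

    def test_never_increases_spread(self):
        rng = np.random.default_rng(4)
        for _ in range(10):
            parent = 1.0 + 0.2 * rng.random(30)
            subs = [rng.random(30) for _ in range(2)]

            def spread(p):
                return (p.max() - p.min()) / p.mean()

            w, info = optimize_spine_weights(parent, subs)
            after = parent + sum(wi * s for wi, s in zip(w, subs))
            assert spread(after) <= spread(parent) + 1e-12
            assert info["spread_after"] == pytest.approx(spread(after))

    def test_deterministic(self):
        parent = 1.0 + 0.3 * np.sin(np.linspace(0, 3, 50))
        subs = [np.linspace(0, 1, 50)]
        assert np.array_equal(optimize_spine_weights(parent, subs)[0],
                              optimize_spine_weights(parent, subs)[0])


class TestFeathering:
    def test_junctions_shift_superiorly_by_spacing(self, default_plan):
        s_mm = default_plan.report.junction_spacing_cm * 10.0
        z0 = default_plan.sub_plans[0].junction_z_mm[0]
        got = [fs.junction_z_mm[0] for fs in default_plan.sub_plans]
        assert got == pytest.approx([z0, z0 + s_mm, z0 + 2 * s_mm])

    def test_multiple_config_feathers_both_junctions(self, multiple_plan):
        s_mm = multiple_plan.report.junction_spacing_cm * 10.0
        for j in range(2):
            zs = [fs.junction_z_mm[j] for fs in multiple_plan.sub_plans]
            assert zs[1] - zs[0] == pytest.approx(s_mm)
            assert zs[2] - zs[0] == pytest.approx(2 * s_mm)

    def test_half_beam_edge_follows_each_junction(self, default_plan):
        # abutment per sub-plan: the brain iso (= half-beam edge plane) and the
        # spine superior jaw both sit on that sub-plan's junction
        for fs in default_plan.sub_plans:
            z_j = fs.junction_z_mm[0]
            for b in fs.brain_beams:
                assert b.isocenter_mm[2] == pytest.approx(z_j)
                assert b.jaws_cm[2] == 0.0
            spine = fs.spine_beams[0]
            assert spine.isocenter_mm[2] + spine.jaws_cm[3] * 10.0 == pytest.approx(z_j)

    def test_zero_spacing_gives_three_identical_subplans(self, default_phantom):
        from csiplan.io import fieldset_to_dict
        _, _, sv = default_phantom
        rep = run_precheck(sv)
        sets = feather_plan(sv, rep, spacing_cm=0.0)
        assert len(sets) == 3
        d0 = fieldset_to_dict(sets[0])
        assert fieldset_to_dict(sets[1]) == d0
        assert fieldset_to_dict(sets[2]) == d0


def _toy_volume():
    g = Grid((10.0, 10.0, 10.0), (0, 0, 0), (4, 4, 4))
    brain = np.zeros(g.shape, bool)
    brain[:2] = True
    canal = np.zeros(g.shape, bool)
    canal[2:] = True
    return g, LabeledVolume(g, {"brain": brain, "spinal_canal": canal})


class TestNormalize:
    def test_uniform_brain_dose_closed_form(self):
        g, sv = _toy_volume()
        brain_dose = DoseGrid(g, np.where(sv.get("brain"), 20.0, 0.0))
        spine_dose = DoseGrid(g, np.where(sv.get("spinal_canal"), 20.0, 0.0))
        a, b = normalize(brain_dose, spine_dose, sv, Prescription())
        # 23.4 * 0.95 / 20 = 1.1115
        assert a == pytest.approx(1.1115, rel=2e-4)
        scaled = a * brain_dose.values + b * spine_dose.values
        assert np.all(scaled[sv.get("brain")] >= 0.95 * 23.4)

    def test_already_normalized_plan_gets_unit_scalars(self):
        g, sv = _toy_volume()
        rx = Prescription()
        brain_dose = DoseGrid(g, np.where(sv.get("brain"), rx.threshold_gy, 0.0))
        spine_dose = DoseGrid(g, np.where(sv.get("spinal_canal"), rx.threshold_gy, 0.0))
        a, b = normalize(brain_dose, spine_dose, sv, rx)
        assert a == pytest.approx(1.0, rel=1e-3)
        assert b == pytest.approx(1.0, rel=1e-3)

    def test_coverage_monotone_in_scalar(self):
        rng = np.random.default_rng(1)
        comp = rng.random(500) * 20
        fixed = np.zeros(500)
        mask = np.ones(500, bool)

        def v95(s):
            return np.mean(s * comp + fixed >= 22.23)

        s_star = coverage_scalar(comp, fixed, mask, 22.23, 0.95)
        assert v95(s_star) >= 0.95
        svals = [v95(s) for s in np.linspace(0.5, 3.0, 20) * s_star]
        assert all(a <= b + 1e-12 for a, b in zip(svals, svals[1:]))

    def test_unreachable_coverage_raises(self):
        g, sv = _toy_volume()
        zero = DoseGrid(g, np.zeros(g.shape))
        with pytest.raises(PlanningError):
            normalize(zero, zero, sv, Prescription())


class TestComposite:
    def test_identical_subplans_compose_to_themselves(self):
        g = Grid((1, 1, 1), (0, 0, 0), (3, 3, 3))
        d = DoseGrid(g, np.random.default_rng(0).random((3, 3, 3)))
        comp, fw = assemble_composite([d, d, d], Prescription())
        np.testing.assert_allclose(comp.values, d.values)
        assert fw == pytest.approx((5 / 13, 5 / 13, 3 / 13))
        assert sum(fw) == pytest.approx(1.0)

    def test_wrong_subplan_count_rejected(self):
        g = Grid((1, 1, 1), (0, 0, 0), (2, 2, 2))
        d = DoseGrid(g, np.ones((2, 2, 2)))
        with pytest.raises(ValueError):
            assemble_composite([d, d], Prescription())

    def test_composite_bounded_by_subplans_pointwise(self, default_plan):
        comp = default_plan.composite_dose.values
        stack = np.stack([d.values for d in default_plan.sub_plan_doses])
        assert np.all(comp <= stack.max(axis=0) + 1e-9)
        assert np.all(comp >= stack.min(axis=0) - 1e-9)

    def test_junction_deviation_never_exceeds_worst_subplan(self, default_plan,
                                                            default_phantom):
        # feathering can only smooth: |composite - Rx| <= max_k |D_k - Rx|
        # pointwise (convexity), checked over the junction neighbourhood
        _, _, sv = default_phantom
        rx = default_plan.prescription.total_dose_gy
        z = sv.grid.axis_coords(2)
        z_j = default_plan.sub_plans[0].junction_z_mm[0]
        near = np.abs(z - z_j) <= 15.0
        body = sv.get("body")[:, :, near]
        comp = np.abs(default_plan.composite_dose.values[:, :, near] - rx)[body]
        worst = np.max(np.stack(
            [np.abs(d.values[:, :, near] - rx)[body]
             for d in default_plan.sub_plan_doses]), axis=0)
        assert np.all(comp <= worst + 1e-9)

    def test_integral_dose_conserved(self, default_plan):
        comp = default_plan.composite_dose.values.sum()
        parts = sum(w * d.values.sum() for w, d in
                    zip(default_plan.fraction_weights, default_plan.sub_plan_doses))
        assert comp == pytest.approx(parts, rel=1e-9)


class TestGeneratePlan:
    def test_normalization_guarantees_on_composite(self, default_plan,
                                                   default_phantom):
        _, _, sv = default_phantom
        thr = default_plan.prescription.threshold_gy
        comp = default_plan.composite_dose.values
        assert np.all(comp[sv.get("brain")] >= thr)          # V95(brain) = 100%
        canal = comp[sv.get("spinal_canal")]
        assert np.mean(canal >= thr) >= 0.95                 # V95(canal) >= 95%

    def test_each_subplan_meets_coverage_rules(self, default_plan, default_phantom):
        _, _, sv = default_phantom
        thr = default_plan.prescription.threshold_gy
        for d in default_plan.sub_plan_doses:
            assert np.all(d.values[sv.get("brain")] >= thr - 1e-9)
            assert np.mean(d.values[sv.get("spinal_canal")] >= thr) >= 0.95

    def test_rejected_phantom_raises_with_reasons(self):
        dens, sv = cp.generate_phantom(
            cp.PhantomSpec(mandible_shoulder_gap_cm=0.5, seed=1))
        with pytest.raises(PlanningError, match="feathering"):
            cp.generate_plan(sv, dens)

    def test_full_pipeline_deterministic_hash_stable(self):
        spec = cp.PhantomSpec(seed=3, voxel_spacing_mm=(5.0, 5.0, 5.0))
        hashes = []
        for _ in range(2):
            dens, sv = cp.generate_phantom(spec)
            plan = cp.generate_plan(sv, dens)
            hashes.append(hashlib.sha256(
                plan.composite_dose.values.tobytes()).hexdigest())
        assert hashes[0] == hashes[1]

    def test_positive_scalars_recorded(self, default_plan):
        for sc in default_plan.normalization_scalars:
            assert sc["brain"] > 0 and sc["spine"] > 0
        assert all(w >= 0 for w in default_plan.subfield_weights)
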