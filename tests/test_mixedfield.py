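"""Mixed-field effect model, isoeffective solver, fixed-RBE comparator and
the mucosa-constraint time scaling."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from isodose.grid import DoseGrid, GridError, ROIMask
from isodose.mixedfield import (
    FixedRBEFactors,
    MixedFieldDose,
    RadiobiologicalModel,
    fixed_rbe_dose,
    isoeffective_dose,
    isoeffective_grid,
    mixed_effect,
    photon_effect,
    scale_to_constraint,
)
from isodose.tcp import TCPParameters, tcp_nonuniform

MODEL = RadiobiologicalModel()


def bisection_oracle(components, model, tissue=None, lo=0.0, hi=1000.0, iters=200):
    """Independent bisection on the photon-effect equation."""
    target = mixed_effect(components, model, tissue)
    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        if photon_effect(mid, model) < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def make_field(values_by_component, boron_map=None, units="Gy_per_min", voxel=(10.0,) * 3):
    grids = [DoseGrid(np.asarray(v, dtype=float), voxel, units) for v in values_by_component]
    shape = grids[0].shape
    b10 = boron_map if boron_map is not None else np.full(shape, 30.0)
    return MixedFieldDose(*grids, b10)


class TestMixedEffect:
    def test_zero_and_photon_reference(self):
        assert mixed_effect((0, 0, 0, 0), MODEL) == 0.0
        d = 7.3
        assert mixed_effect((0, 0, 0, d), MODEL) == pytest.approx(
            MODEL.alpha_R * d + MODEL.beta_R * d * d, rel=1e-12
        )

    @given(seed=st.integers(0, 500))
    @settings(max_examples=30, derandomize=True, deadline=None)
    def test_monotone_in_every_component(self, seed):
        rng = np.random.default_rng(seed)
        model = RadiobiologicalModel(
            alpha_R=rng.uniform(0.01, 0.5),
            beta_R=rng.uniform(0.0, 0.05),
            a_boron=rng.uniform(0.01, 0.5),
            a_nitrogen=rng.uniform(0.01, 0.5),
            a_fast=rng.uniform(0.01, 0.5),
            boron_by_tissue={},
        )
        doses = rng.uniform(0, 10, 4)
        base = mixed_effect(doses, model)
        assert mixed_effect(doses * 2, model) >= base
        for i in range(4):
            bumped = doses.copy()
            bumped[i] += 0.5
            assert mixed_effect(bumped, model) > base

    def test_tissue_override(self):
        d = (5.0, 0, 0, 0)
        assert mixed_effect(d, MODEL, tissue="tumour") > mixed_effect(d, MODEL, tissue="brain")

    def test_negative_component_rejected(self):
        with pytest.raises(ValueError):
            mixed_effect((-1, 0, 0, 0), MODEL)


class TestIsoeffectiveSolver:
    def test_zero_field_and_pure_photon_identity(self):
        assert isoeffective_dose((0, 0, 0, 0), MODEL) == 0.0
        for d in (0.5, 6.0, 30.0, 80.0):
            assert isoeffective_dose((0, 0, 0, d), MODEL) == pytest.approx(d, abs=1e-8)

    @given(seed=st.integers(0, 300))
    @settings(max_examples=40, derandomize=True, deadline=None)
    def test_agrees_with_bisection_oracle(self, seed):
        rng = np.random.default_rng(seed)
        model = RadiobiologicalModel(
            alpha_R=rng.uniform(0.01, 0.3),
            beta_R=rng.uniform(0.001, 0.02),
            a_boron=rng.uniform(0.01, 0.4),
            a_nitrogen=rng.uniform(0.01, 0.2),
            a_fast=rng.uniform(0.01, 0.2),
            boron_by_tissue={},
        )
        doses = rng.uniform(0, 15, 4)
        got = isoeffective_dose(doses, model)
        assert got == pytest.approx(bisection_oracle(doses, model), abs=1e-8)

    def test_strictly_increasing_in_each_component(self, rng):
        doses = rng.uniform(1, 8, 4)
        base = isoeffective_dose(doses, MODEL)
        for i in range(4):
            bumped = doses.copy()
            bumped[i] += 0.25
            assert isoeffective_dose(bumped, MODEL) > base

    def test_grid_conversion_properties(self, rng):
        shape = (3, 3, 3)
        comps = [rng.uniform(0, 5, shape) for _ in range(4)]
        field = make_field(comps, units="Gy_absorbed")
        out = isoeffective_grid(field, MODEL)
        assert out.units == "Gy_IsoE_BNCT"
        # voxelwise equality with the scalar solver
        i, j, k = 1, 2, 0
        scalar = isoeffective_dose([c[i, j, k] for c in comps], MODEL)
        assert out.values[i, j, k] == pytest.approx(scalar, abs=1e-9)
        # spatially constant field -> constant output
        const = make_field([np.full(shape, v) for v in (1.0, 0.2, 0.1, 0.5)], units="Gy_absorbed")
        out_const = isoeffective_grid(const, MODEL)
        assert np.ptp(out_const.values) == 0.0
        # permutation applied jointly to all components commutes
        perm = rng.permutation(27)
        permuted = make_field(
            [c.ravel()[perm].reshape(shape) for c in comps], units="Gy_absorbed"
        )
        out_perm = isoeffective_grid(permuted, MODEL)
        np.testing.assert_allclose(
            np.sort(out_perm.values.ravel()), np.sort(out.values.ravel()), rtol=1e-12
        )

    def test_rate_units_rejected_for_conversion(self):
        field = make_field([np.ones((2, 2, 2))] * 4, units="Gy_per_min")
        with pytest.raises(GridError):
            isoeffective_grid(field, MODEL)


class TestFixedRBE:
    def test_weighted_sum_example(self):
        factors = FixedRBEFactors(boron=3.8, nitrogen=3.2, fast=3.2, photon=1.0)
        got = fixed_rbe_dose((1.0, 0.5, 0.25, 2.0), factors)
        assert got == pytest.approx(3.8 + 1.6 + 0.8 + 2.0)
        assert fixed_rbe_dose((0, 0, 0, 0), factors) == 0.0
        ones = FixedRBEFactors(1.0, 1.0, 1.0, 1.0)
        assert fixed_rbe_dose((1, 2, 3, 4), ones) == 10.0

    def test_component_count_enforced(self):
        with pytest.raises(ValueError):
            fixed_rbe_dose((1.0, 2.0, 3.0), FixedRBEFactors())

    def test_saturated_weighted_dose_gives_certain_control(self):
        """Fixed-RBE weighting above 60 Gy-Eq everywhere drives the TCP model
        past 0.999 — the comparator's unrealistically certain prediction."""
        weighted = np.linspace(61.0, 90.0, 57)  # GTV-sized ROI, all > 60 Gy-Eq
        assert tcp_nonuniform(weighted, 1.0, TCPParameters()) > 0.999


class TestConstraintScaling:
    def test_time_arithmetic_and_self_consistency(self):
        shape = (2, 2, 2)
        comps = [np.full(shape, r) for r in (0.1, 0.05, 0.05, 0.05)]  # total 0.25
        field = make_field(comps)
        mucosa = ROIMask("mucosa", np.ones(shape, dtype=bool))
        t = scale_to_constraint(field, mucosa, limit=6.0)
        assert t == pytest.approx(24.0, rel=1e-12)
        absorbed = field.scaled(t, "Gy_absorbed")
        assert absorbed.total().values[mucosa.values].max() == pytest.approx(6.0, abs=1e-12)

    def test_scale_covariance(self, rng):
        shape = (3, 3, 3)
        comps = [rng.uniform(0.01, 0.2, shape) for _ in range(4)]
        mucosa = ROIMask("mucosa", rng.random(shape) > 0.5)
        t1 = scale_to_constraint(make_field(comps), mucosa, 6.0)
        t2 = scale_to_constraint(make_field([2 * c for c in comps]), mucosa, 6.0)
        assert t2 == pytest.approx(t1 / 2, rel=1e-12)

    def test_zero_rate_in_mucosa_rejected(self):
        shape = (2, 2, 2)
        field = make_field([np.zeros(shape)] * 4)
        mucosa = ROIMask("mucosa", np.ones(shape, dtype=bool))
        with pytest.raises(GridError):
            scale_to_constraint(field, mucosa, 6.0)
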