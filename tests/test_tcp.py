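"""TCP model: uniform, equivalent-subvolume non-uniform, and CI propagation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from isodose.tcp import (
    TCPParameters,
    survival,
    tcp_ci,
    tcp_nonuniform,
    tcp_uniform,
)

PARAMS = TCPParameters()  # c1=2.4, c2=0.12, alpha=0.022, beta=alpha/10


def oracle_tcp(doses, voxel_volume, params=PARAMS):
    """Extended-precision naive evaluation of the equivalent-subvolume TCP."""
    d = np.asarray(doses, dtype=np.longdouble)
    a, b = np.longdouble(params.alpha), np.longdouble(params.beta_value)
    log_s = -(a * d + b * d * d)
    v = np.longdouble(d.size * voxel_volume)
    if params.c2 < 1e-6:
        mean_term = np.exp(log_s.max())
    else:
        c2 = np.longdouble(params.c2)
        # naive sum of S^(1/c2), shifted to survive underflow
        shift = log_s.max() / c2
        mean = np.mean(np.exp(log_s / c2 - shift))
        mean_term = np.exp(c2 * (np.log(mean) + shift))
    return float(np.exp(-np.longdouble(params.c1) * v**np.longdouble(params.c2) * mean_term))


class TestSurvival:
    def test_lq_form(self):
        assert survival(0.0, 0.022, 0.0022) == 1.0
        d = 20.7
        expected = math.exp(-(0.022 * d + 0.0022 * d * d))
        assert survival(d, 0.022, 0.0022) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(0.2471, abs=2e-4)
        assert survival(5.0, 0.1, 0.0) == pytest.approx(math.exp(-0.5), rel=1e-12)

    def test_strictly_decreasing_and_domain(self):
        d = np.linspace(0, 100, 200)
        s = survival(d, 0.022, 0.0022)
        assert np.all(np.diff(s) < 0)
        assert np.all((s > 0) & (s <= 1))
        with pytest.raises(ValueError):
            survival(-1.0, 0.022, 0.0022)


class TestUniform:
    def test_printed_parameter_defaults(self):
        p = TCPParameters()
        assert (p.c1, p.c2, p.alpha) == (2.4, 0.12, 0.022)
        assert p.beta_value == pytest.approx(0.0022)
        assert p.ci68["c1"] == (1.1, 3.7)
        assert p.ci68["c2"] == (0.0, 0.26)
        assert p.ci68["alpha"] == (0.016, 0.028)

    def test_worked_examples(self):
        # independent arithmetic: TCP = exp(-c1 v^c2 S(D))
        v, d = 57.4, 20.7
        s = math.exp(-(0.022 * d + 0.0022 * d * d))
        expected = math.exp(-2.4 * v**0.12 * s)
        assert tcp_uniform(v, d, PARAMS) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(0.381, abs=1e-3)
        assert tcp_uniform(v, 0.0, PARAMS) == pytest.approx(math.exp(-2.4 * v**0.12), rel=1e-12)
        assert tcp_uniform(v, 0.0, PARAMS) == pytest.approx(0.020, abs=1e-3)

    def test_limits_and_monotonicity(self):
        assert tcp_uniform(57.4, 500.0, PARAMS) > 0.999999
        doses = np.linspace(0, 60, 50)
        tcps = [tcp_uniform(57.4, d, PARAMS) for d in doses]
        assert np.all(np.diff(tcps) > 0)
        vols = np.linspace(1, 300, 50)
        by_vol = [tcp_uniform(v, 20.0, PARAMS) for v in vols]
        assert np.all(np.diff(by_vol) < 0)
        with pytest.raises(ValueError):
            tcp_uniform(0.0, 10.0, PARAMS)


class TestNonUniform:
    def test_uniform_reduction_exact(self):
        doses = np.full(57, 20.7)
        assert tcp_nonuniform(doses, 1.0, PARAMS) == pytest.approx(
            tcp_uniform(57.0, 20.7, PARAMS), rel=1e-9
        )

    def test_two_voxel_worked_example(self):
        got = tcp_nonuniform([10.0, 30.0], 1.0, PARAMS)
        assert got == pytest.approx(oracle_tcp([10.0, 30.0], 1.0), rel=1e-9)
        assert got == pytest.approx(0.213, abs=1e-3)

    @given(
        n=st.integers(1, 100),
        seed=st.integers(0, 10_000),
        c2=st.sampled_from([0.02, 0.12, 0.26, 0.8]),
    )
    @settings(max_examples=40, derandomize=True, deadline=None)
    def test_matches_extended_precision_oracle(self, n, seed, c2):
        """Log-sum-exp path equals the naive high-precision sum to 1e-9."""
        rng = np.random.default_rng(seed)
        doses = rng.uniform(0.0, 100.0, n)
        params = TCPParameters(c2=c2, ci68={})
        assert tcp_nonuniform(doses, 1.0, params) == pytest.approx(
            oracle_tcp(doses, 1.0, params), rel=1e-9
        )

    def test_no_overflow_extreme_inputs(self):
        doses = np.array([0.0, 100.0] * 50)
        for c2 in (1e-6, 1e-4, 0.12):
            t = tcp_nonuniform(doses, 1.0, TCPParameters(c2=c2, ci68={}))
            assert 0.0 < t < 1.0

    def test_small_c2_limit_branch(self):
        """As c2 -> 0+ the power mean tends to the coldest voxel's survival."""
        doses = np.array([5.0, 18.0, 40.0])
        params = TCPParameters(c2=1e-8, ci68={})
        s_max = math.exp(-(0.022 * 5.0 + 0.0022 * 25.0))
        expected = math.exp(-2.4 * s_max)  # v**c2 -> 1
        assert tcp_nonuniform(doses, 1.0, params) == pytest.approx(expected, rel=1e-6)

    def test_cold_spot_strictly_lowers_tcp(self, rng):
        doses = rng.uniform(15, 30, 40)
        base = tcp_nonuniform(doses, 1.0, PARAMS)
        cooled = doses.copy()
        cooled[7] -= 5.0
        assert tcp_nonuniform(cooled, 1.0, PARAMS) < base

    def test_permutation_invariance(self, rng):
        doses = rng.uniform(0, 50, 60)
        shuffled = rng.permutation(doses)
        assert tcp_nonuniform(doses, 1.0, PARAMS) == pytest.approx(
            tcp_nonuniform(shuffled, 1.0, PARAMS), rel=1e-12
        )

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            tcp_nonuniform([], 1.0, PARAMS)


class TestCIPropagation:
    DOSES = np.linspace(12, 30, 57)

    def test_deterministic_under_seed(self):
        a = tcp_ci(self.DOSES, 1.0, PARAMS, n_samples=2000, seed=7)
        b = tcp_ci(self.DOSES, 1.0, PARAMS, n_samples=2000, seed=7)
        assert a == b
        c = tcp_ci(self.DOSES, 1.0, PARAMS, n_samples=2000, seed=8)
        assert c.ci68 != a.ci68

    def test_zero_width_bounds_collapse(self):
        p = TCPParameters(ci68={"c1": (2.4, 2.4), "c2": (0.12, 0.12), "alpha": (0.022, 0.022)})
        r = tcp_ci(self.DOSES, 1.0, p, n_samples=500, seed=1)
        assert r.ci68[0] == pytest.approx(r.tcp, rel=1e-12)
        assert r.ci68[1] == pytest.approx(r.tcp, rel=1e-12)
        assert not r.flagged

    def test_halved_bounds_narrow_interval(self):
        """Shrinking parameter bounds shrinks the TCP interval (MC, n=1e4)."""

        def halved(lo, hi, centre):
            return (centre - (centre - lo) / 2, centre + (hi - centre) / 2)

        wide = PARAMS
        narrow = TCPParameters(
            ci68={
                "c1": halved(1.1, 3.7, 2.4),
                "c2": halved(0.0, 0.26, 0.12),
                "alpha": halved(0.016, 0.028, 0.022),
            }
        )
        r_wide = tcp_ci(self.DOSES, 1.0, wide, n_samples=10_000, seed=3)
        r_narrow = tcp_ci(self.DOSES, 1.0, narrow, n_samples=10_000, seed=3)
        assert (r_narrow.ci68[1] - r_narrow.ci68[0]) < (r_wide.ci68[1] - r_wide.ci68[0])

    def test_needs_bounds_and_samples(self):
        with pytest.raises(ValueError):
            tcp_ci(self.DOSES, 1.0, TCPParameters(ci68={}), n_samples=100, seed=0)
        with pytest.raises(ValueError):
            tcp_ci(self.DOSES, 1.0, PARAMS, n_samples=1, seed=0)
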